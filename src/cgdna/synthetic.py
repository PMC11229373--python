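"""Synthetic reference data: fluctuating ideal B-DNA ensembles, matched
all-atom frames, and supercoiled minicircle starting structures.

This module stands in for the atomistic MD reference data that bottom-up
parameterisation and back-map training normally consume.  It generates:

* deterministic ideal B-form C1' bead builds (:func:`ideal_bdna_beads`);
* Gaussian-fluctuating bead ensembles whose stacking / pairing distance
  standard deviations converge to the requested values and whose tangent
  decorrelation follows a worm-like-chain with a requested persistence
  length (:func:`synth_ensemble`);
* matched heavy-atom frames built by rigid placement of idealised
  nucleotide templates on the same base-pair frames
  (:func:`ideal_bdna_atomistic`, :func:`synth_paired_ensemble`) — geometric
  fixtures only, with no claim of force-field accuracy;
* planar minicircle builds with an explicit twist registration
  (:func:`build_minicircle`).

The fluctuation model is Gaussian and mode-based: independent per-step
noise on the internal helical coordinates (stacking length, pairing
diameter, twist) plus a random-walk of small frame tilts along the contour
(the worm-like-chain bending).  It deliberately does not attempt the full
anharmonic, sequence-detailed statistics of real atomistic MD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import TrajectoryEnsemble
from .topology import DuplexSequence, build_duplex_topology

__all__ = [
    "HelixSpec",
    "FluctuationSpec",
    "CircularBuildSpec",
    "AtomisticStructure",
    "AtomisticEnsemble",
    "ideal_bdna_beads",
    "synth_ensemble",
    "synth_paired_ensemble",
    "ideal_bdna_atomistic",
    "build_minicircle",
    "BACKBONE_ATOMS",
    "BASE_ATOMS",
    "nucleotide_template",
]


@dataclass(frozen=True)
class HelixSpec:
    """Ideal B-form helix geometry.

    ``rise`` Å/bp, ``twist`` deg/bp, ``radius`` the C1' distance from the
    helix axis (Å), ``phase`` the inter-strand angle (deg) between the two
    C1' beads of a bp around the axis.  The default phase of 180 deg places
    the two beads diametrically opposite so every bp C1'-midpoint lies
    exactly on the helix axis.  ``rise_steps``/``twist_steps`` optionally
    override the equilibrium value per dinucleotide step (e.g. ``"AA"``).
    """

    rise: float = 3.38
    twist: float = 34.3
    radius: float = 9.0
    phase: float = 180.0
    rise_steps: dict | None = None
    twist_steps: dict | None = None

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360) deg")

    def step_rise(self, step: str) -> float:
        if self.rise_steps and step in self.rise_steps:
            return self.rise_steps[step]
        return self.rise

    def step_twist(self, step: str) -> float:
        if self.twist_steps and step in self.twist_steps:
            return self.twist_steps[step]
        return self.twist

    def stack_length(self, rise: float, twist: float) -> float:
        """Intra-strand C1'-C1' distance implied by a (rise, twist) step."""
        chord2 = 2.0 * self.radius**2 * (1.0 - math.cos(math.radians(twist)))
        return math.sqrt(rise * rise + chord2)


@dataclass(frozen=True)
class FluctuationSpec:
    """Gaussian fluctuation amplitudes for the synthetic ensemble.

    ``sd_stacking``/``sd_pairing`` are the target standard deviations (Å) of
    the intra-strand stacking and cross-strand pairing C1'-C1' distances;
    ``sd_twist`` (deg) jitters the per-step twist, the dial behind the
    backbone-angle fluctuations (the default yields a backbone-angle SD of
    about 4 deg on top of the other noise sources, in the range seen in
    atomistic B-DNA); ``persistence_length`` (nm) sets the worm-like-chain
    bending amplitude (``inf`` or 0 disables bending).  ``tetramer_sd``
    optionally overrides the stacking SD for the central step of a given
    canonical tetramer.
    """

    sd_stacking: float = 0.3
    sd_pairing: float = 0.3
    sd_twist: float = 1.0
    persistence_length: float = 60.0
    bend_correlation: int = 16
    tetramer_sd: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_stacking", "sd_pairing", "sd_twist"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bend_correlation < 1:
            raise ValueError("bend_correlation must be >= 1")

    def bend_diffusion(self, rise: float = 3.38) -> float:
        """Tangent-direction variance accumulated per step and transverse
        axis: q = rise / PL, the worm-like-chain decorrelation rate."""
        if not self.persistence_length or math.isinf(self.persistence_length):
            return 0.0
        return rise / (self.persistence_length * 10.0)

    def bend_marginal_sd(self, rise: float = 3.38) -> float:
        """Marginal per-step tilt SD (rad, per axis).  Bending is a smooth
        mode: tilt increments are correlated over ``bend_correlation``
        steps, so the same persistence length is reached with a
        sqrt(bend_correlation)-fold smaller per-step bp-plane tilt."""
        return math.sqrt(self.bend_diffusion(rise) / self.bend_correlation)


@dataclass(frozen=True)
class CircularBuildSpec:
    """Minicircle build: size, linking-number difference, intrinsic Lk0."""

    n_bp: int
    delta_lk: int = 0
    lk0: int | None = None

    def __post_init__(self) -> None:
        if self.n_bp < 12:
            raise ValueError("circular build needs n_bp >= 12")

    @property
    def lk(self) -> int:
        lk0 = self.lk0 if self.lk0 is not None else round(self.n_bp / 10.5)
        return lk0 + self.delta_lk


# ---------------------------------------------------------------------------
# bp-frame machinery


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class _BpFrames:
    """Origins, rotations and per-bp radii describing one conformation."""

    origins: np.ndarray  # (n, 3)
    rotations: np.ndarray  # (n, 3, 3)
    radii: np.ndarray  # (n,)
    phase: float  # rad


def _frames_one_conformation(
    seq: DuplexSequence,
    helix: HelixSpec,
    fluct: FluctuationSpec | None,
    rng: np.random.Generator | None,
) -> _BpFrames:
    n = len(seq)
    w = seq.watson
    origins = np.zeros((n, 3))
    rotations = np.empty((n, 3, 3))
    rotations[0] = np.eye(3)

    if fluct is not None and rng is not None:
        radii = helix.radius + rng.normal(0.0, fluct.sd_pairing / 2.0, size=n)
        # smooth bending: sliding-window sums of white noise give tilt
        # increments correlated over bend_correlation steps
        q = fluct.bend_diffusion(helix.rise)
        m = fluct.bend_correlation
        if q > 0:
            white = rng.normal(0.0, 1.0, size=(n - 1 + m - 1, 2))
            kernel = np.ones(m) / m * math.sqrt(q)
            # correlated bending directions in the lab frame ...
            tilt_lab = np.stack(
                [np.convolve(white[:, k], kernel, mode="valid") for k in (0, 1)],
                axis=1,
            )
            # ... counter-rotated by the accumulated helical twist so the
            # per-step frame rotation does not cancel the smooth mode
            phi = -math.radians(helix.twist) * np.arange(1, n)
            cph, sph = np.cos(phi), np.sin(phi)
            tilt = np.stack(
                [
                    cph * tilt_lab[:, 0] - sph * tilt_lab[:, 1],
                    sph * tilt_lab[:, 0] + cph * tilt_lab[:, 1],
                ],
                axis=1,
            )
        else:
            tilt = np.zeros((n - 1, 2))
        twist_jit = rng.normal(0.0, math.radians(fluct.sd_twist), size=n - 1)
        # the rigid-bp tilt moves the 9 Å-radius beads out of plane; its
        # contribution to the stacking distance is subtracted from the
        # requested SD so the sample SD converges to sd_stacking
        sigma_tilt = fluct.bend_marginal_sd(helix.rise)
        l0_default = helix.stack_length(helix.rise, helix.twist)
        bend_on_stack = helix.radius * sigma_tilt * helix.rise / l0_default
        stack_noise = np.empty(n - 1)
        for s in range(n - 1):
            sd = fluct.sd_stacking
            if fluct.tetramer_sd and 1 <= s <= n - 3:
                from .topology import canonical_tetramer

                tet = canonical_tetramer(w[s - 1 : s + 3])
                sd = fluct.tetramer_sd.get(tet, sd)
            sd_eff = math.sqrt(max(sd * sd - bend_on_stack * bend_on_stack, 0.0))
            stack_noise[s] = rng.normal(0.0, sd_eff)
    else:
        radii = np.full(n, helix.radius)
        tilt = np.zeros((n - 1, 2))
        twist_jit = np.zeros(n - 1)
        stack_noise = np.zeros(n - 1)

    for s in range(n - 1):
        step = w[s : s + 2]
        twist0 = helix.step_twist(step)
        rise0 = helix.step_rise(step)
        twist = math.radians(twist0) + twist_jit[s]
        # target stacking length: nominal geometry plus Gaussian noise
        l_target = helix.stack_length(rise0, twist0) + stack_noise[s]
        # horizontal chord implied by the sampled radii and twist
        chord2 = radii[s] ** 2 + radii[s + 1] ** 2 - 2 * radii[s] * radii[
            s + 1
        ] * math.cos(twist)
        rise = math.sqrt(max(l_target**2 - chord2, 0.25))
        step_rot = _rot_z(twist)
        if tilt[s, 0] or tilt[s, 1]:
            step_rot = step_rot @ _rot_x(tilt[s, 0]) @ _rot_y(tilt[s, 1])
        rotations[s + 1] = rotations[s] @ step_rot
        origins[s + 1] = origins[s] + rise * rotations[s + 1][:, 2]
    return _BpFrames(
        origins=origins,
        rotations=rotations,
        radii=radii,
        phase=math.radians(helix.phase),
    )


def _beads_from_frames(frames: _BpFrames) -> np.ndarray:
    """Bead coordinates (2n, 3) in bead-id order (Watson then Crick)."""
    n = len(frames.origins)
    u_w = np.array([1.0, 0.0, 0.0])
    u_c = np.array([math.cos(frames.phase), math.sin(frames.phase), 0.0])
    dir_w = frames.rotations @ u_w
    dir_c = frames.rotations @ u_c
    watson = frames.origins + frames.radii[:, None] * dir_w
    crick_by_bp = frames.origins + frames.radii[:, None] * dir_c
    coords = np.empty((2 * n, 3))
    coords[:n] = watson
    # crick bead id for bp p is 2n-1-p
    coords[n:] = crick_by_bp[::-1]
    return coords


def ideal_bdna_beads(
    sequence: DuplexSequence | str, helix: HelixSpec | None = None
) -> np.ndarray:
    """Deterministic ideal-helix C1' bead build, (2n, 3) Å.

    With the default 180 deg inter-strand phase, every bp C1'-midpoint lies
    on the z-axis and consecutive midpoints are ``rise`` apart.
    """
    seq = DuplexSequence(sequence) if isinstance(sequence, str) else sequence
    helix = helix or HelixSpec()
    frames = _frames_one_conformation(seq, helix, None, None)
    return _beads_from_frames(frames)


def _ensemble_frames(
    seq: DuplexSequence,
    helix: HelixSpec,
    fluct: FluctuationSpec,
    n_frames: int,
) -> list[_BpFrames]:
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.Generator(np.random.PCG64(fluct.seed))
    return [
        _frames_one_conformation(seq, helix, fluct, rng) for _ in range(n_frames)
    ]


def synth_ensemble(
    sequence: DuplexSequence | str,
    helix: HelixSpec | None = None,
    fluct: FluctuationSpec | None = None,
    n_frames: int = 200,
) -> TrajectoryEnsemble:
    """Seeded Gaussian-fluctuating bead ensemble around the ideal helix.

    Frames are statistically independent draws (no time correlation); the
    time axis is a frame index.  Reproducible from ``(helix, fluct,
    n_frames)``.
    """
    seq = DuplexSequence(sequence) if isinstance(sequence, str) else sequence
    helix = helix or HelixSpec()
    fluct = fluct or FluctuationSpec()
    frames = _ensemble_frames(seq, helix, fluct, n_frames)
    coords = np.stack([_beads_from_frames(f) for f in frames])
    topo = build_duplex_topology(seq)
    return TrajectoryEnsemble(
        frames=coords,
        times=np.arange(n_frames, dtype=float),
        topology=topo,
        provenance={
            "generator": "cgdna synthetic helical ensemble",
            "seed": fluct.seed,
            "sd_stacking": fluct.sd_stacking,
            "sd_pairing": fluct.sd_pairing,
            "sd_twist_deg": fluct.sd_twist,
            "persistence_length_nm": fluct.persistence_length,
        },
    )


# ---------------------------------------------------------------------------
# all-atom templates (geometric fixtures)

BACKBONE_ATOMS = [
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
]

BASE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"],
    "G": ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "O6", "N2"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "T": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
}

_SIDE = 1.55  # ring bond length used throughout the fixture templates, Å


def _regular_ring(anchor: np.ndarray, center_dir: float, k: int) -> np.ndarray:
    """Vertices of a regular k-ring (in the base plane z=0) whose first
    vertex is ``anchor``; the ring centre sits at angle ``center_dir`` (rad)
    from the anchor."""
    circum = _SIDE / (2.0 * math.sin(math.pi / k))
    center = anchor[:2] + circum * np.array(
        [math.cos(center_dir), math.sin(center_dir)]
    )
    a0 = math.atan2(anchor[1] - center[1], anchor[0] - center[0])
    verts = np.zeros((k, 3))
    for idx in range(k):
        a = a0 - idx * 2.0 * math.pi / k
        verts[idx, :2] = center + circum * np.array([math.cos(a), math.sin(a)])
    return verts


def _fused_hexagon(v_from: np.ndarray, v_to: np.ndarray, away: np.ndarray):
    """Regular hexagon sharing the edge (v_from, v_to), fused away from
    ``away``; returns the 4 new vertices walking from v_from towards v_to
    around the far side."""
    e = (v_to - v_from)[:2]
    side = float(np.linalg.norm(e))
    mid = (v_from + v_to)[:2] / 2.0
    nrm = np.array([-e[1], e[0]]) / side
    if np.dot(mid - away[:2], nrm) < 0:
        nrm = -nrm
    center = mid + (side * math.sqrt(3.0) / 2.0) * nrm
    a_from = math.atan2(v_from[1] - center[1], v_from[0] - center[0])
    a_to = math.atan2(v_to[1] - center[1], v_to[0] - center[0])
    # walk from a_from in 60 deg steps in the direction that reaches a_to
    # after 5 steps (i.e. around the far side)
    for sign in (+1.0, -1.0):
        a_end = a_from + sign * 5.0 * math.pi / 3.0
        if abs(((a_end - a_to + math.pi) % (2 * math.pi)) - math.pi) < 1e-6:
            break
    verts = np.zeros((4, 3))
    for idx in range(4):
        a = a_from + sign * (idx + 1) * math.pi / 3.0
        verts[idx, :2] = center + side * np.array([math.cos(a), math.sin(a)])
    return verts, center


def _base_template(base: str) -> dict[str, np.ndarray]:
    """Heavy-atom base coordinates in the nucleotide local frame (C1' at the
    origin, base extending towards -x, base plane z = 0)."""
    glyco = np.array([-1.52, 0.0, 0.0])
    coords: dict[str, np.ndarray] = {}
    if base in "AG":
        pent = _regular_ring(glyco, math.radians(170.0), 5)
        for name, v in zip(["N9", "C8", "N7", "C5", "C4"], pent):
            coords[name] = v
        pc = pent.mean(axis=0)
        hexv, hc = _fused_hexagon(coords["C4"], coords["C5"], pc)
        for name, v in zip(["N3", "C2", "N1", "C6"], hexv):
            coords[name] = v
        hc3 = np.array([hc[0], hc[1], 0.0])
        if base == "A":
            coords["N6"] = coords["C6"] + _SIDE * _unit(coords["C6"] - hc3)
        else:
            coords["O6"] = coords["C6"] + _SIDE * _unit(coords["C6"] - hc3)
            coords["N2"] = coords["C2"] + _SIDE * _unit(coords["C2"] - hc3)
    else:
        hexv = _regular_ring(glyco, math.radians(170.0), 6)
        for name, v in zip(["N1", "C2", "N3", "C4", "C5", "C6"], hexv):
            coords[name] = v
        hc = hexv.mean(axis=0)
        coords["O2"] = coords["C2"] + _SIDE * _unit(coords["C2"] - hc)
        if base == "C":
            coords["N4"] = coords["C4"] + _SIDE * _unit(coords["C4"] - hc)
        else:
            coords["O4"] = coords["C4"] + _SIDE * _unit(coords["C4"] - hc)
            coords["C7"] = coords["C5"] + _SIDE * _unit(coords["C5"] - hc)
    return coords


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sugar_backbone_template() -> dict[str, np.ndarray]:
    """Sugar ring + backbone coordinates in the nucleotide local frame.

    The sugar pentagon lies in a plane tilted 25 deg out of the bp plane;
    the backbone extends radially outwards, O3' towards the 3' neighbour
    (+z locally) and the 5' phosphate towards -z.
    """
    tau = math.radians(25.0)
    w_hat = np.array([0.0, math.cos(tau), math.sin(tau)])
    x_hat = np.array([1.0, 0.0, 0.0])

    circum = _SIDE / (2.0 * math.sin(math.pi / 5.0))
    center2 = circum * np.array([math.cos(math.radians(-30.0)),
                                 math.sin(math.radians(-30.0))])
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    a0 = math.atan2(-center2[1], -center2[0])
    coords: dict[str, np.ndarray] = {}
    plane2: dict[str, np.ndarray] = {}
    for idx, name in enumerate(names):
        a = a0 - idx * 2.0 * math.pi / 5.0
        uv = center2 + circum * np.array([math.cos(a), math.sin(a)])
        plane2[name] = uv
        coords[name] = uv[0] * x_hat + uv[1] * w_hat
    coords["O3'"] = coords["C3'"] + _SIDE * _unit(np.array([0.35, 0.0, 0.94]))
    coords["C5'"] = coords["C4'"] + _SIDE * _unit(np.array([0.45, 0.35, -0.82]))
    coords["O5'"] = coords["C5'"] + _SIDE * _unit(np.array([0.55, 0.0, -0.84]))
    coords["P"] = coords["O5'"] + 1.62 * _unit(np.array([0.45, -0.35, -0.82]))
    coords["OP1"] = coords["P"] + _SIDE * _unit(np.array([0.75, 0.66, 0.0]))
    coords["OP2"] = coords["P"] + _SIDE * _unit(np.array([0.30, -0.95, 0.10]))
    return coords


_SUGAR_BACKBONE = _sugar_backbone_template()
_BASE_TEMPLATES = {b: _base_template(b) for b in "ACGT"}

_RING_BONDS = {
    "A": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"), ("C4", "N9"),
          ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"), ("C6", "C5"),
          ("C6", "N6")],
    "G": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"), ("C4", "N9"),
          ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"), ("C6", "C5"),
          ("C6", "O6"), ("C2", "N2")],
    "C": [("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1"), ("C2", "O2"), ("C4", "N4")],
    "T": [("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1"), ("C2", "O2"), ("C4", "O4"), ("C5", "C7")],
}
_SUGAR_BONDS = [
    ("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"),
    ("O4'", "C1'"), ("C3'", "O3'"), ("C4'", "C5'"), ("C5'", "O5'"),
    ("O5'", "P"), ("P", "OP1"), ("P", "OP2"),
]


def nucleotide_template(base: str) -> tuple[list[str], np.ndarray, list[tuple[str, str]]]:
    """Atom names, local coordinates and bond list of one nucleotide.

    Local frame: C1' at the origin, +x radially outwards from the helix
    axis, +z towards the 3' neighbour, base plane at z = 0.
    """
    names = BACKBONE_ATOMS + BASE_ATOMS[base]
    local = dict(_SUGAR_BACKBONE)
    local.update(_BASE_TEMPLATES[base])
    glyco_anchor = "N9" if base in "AG" else "N1"
    bonds = _SUGAR_BONDS + _RING_BONDS[base] + [("C1'", glyco_anchor)]
    return names, np.array([local[nm] for nm in names]), bonds


@dataclass
class AtomisticStructure:
    """A duplex heavy-atom structure with residue/chain bookkeeping.

    Residue order matches bead-id order: Watson residues 0..n-1 (5'->3'),
    then Crick residues n..2n-1 (5'->3' along the Crick strand), so the C1'
    of residue ``r`` corresponds to bead ``r``.
    """

    sequence: DuplexSequence
    atom_names: list[str]
    residue_index: np.ndarray  # (n_atoms,)
    residue_base: list[str]  # per residue
    coords: np.ndarray  # (n_atoms, 3)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_base)

    def atom_indices(self, residue: int, names: list[str] | None = None) -> np.ndarray:
        sel = np.where(self.residue_index == residue)[0]
        if names is None:
            return sel
        name_map = {self.atom_names[i]: i for i in sel}
        return np.array([name_map[nm] for nm in names], dtype=np.intp)

    def c1_coords(self) -> np.ndarray:
        """C1' coordinates in bead-id order, (2n, 3)."""
        idx = [
            i
            for i in range(self.n_atoms)
            if self.atom_names[i] == "C1'"
        ]
        return self.coords[np.array(idx, dtype=np.intp)]


@dataclass
class AtomisticEnsemble:
    """A fixed atom layout with many coordinate frames."""

    structure: AtomisticStructure  # coords hold frame 0
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, f: int) -> AtomisticStructure:
        s = self.structure
        return AtomisticStructure(
            sequence=s.sequence,
            atom_names=s.atom_names,
            residue_index=s.residue_index,
            residue_base=s.residue_base,
            coords=self.frames[f].copy(),
            bonds=s.bonds,
            provenance=dict(s.provenance),
        )


def _structure_layout(seq: DuplexSequence):
    """Atom names / residue indices / bases / bonds for a duplex (coords
    filled in separately)."""
    n = len(seq)
    bases = list(seq.watson) + list(seq.crick)
    atom_names: list[str] = []
    residue_index: list[int] = []
    bonds: list[tuple[int, int]] = []
    offsets = []
    for r, base in enumerate(bases):
        names, _, local_bonds = nucleotide_template(base)
        off = len(atom_names)
        offsets.append(off)
        name_pos = {nm: off + k for k, nm in enumerate(names)}
        atom_names.extend(names)
        residue_index.extend([r] * len(names))
        bonds.extend((name_pos[a], name_pos[b]) for a, b in local_bonds)
    # inter-residue O3'(r) - P(r+1) linkage within each strand
    for r in range(2 * n - 1):
        if r == n - 1:  # strand boundary
            continue
        names_r, _, _ = nucleotide_template(bases[r])
        names_n, _, _ = nucleotide_template(bases[r + 1])
        o3 = offsets[r] + names_r.index("O3'")
        p = offsets[r + 1] + names_n.index("P")
        bonds.append((o3, p))
    return atom_names, np.array(residue_index, dtype=np.intp), bases, bonds


def _atoms_from_frames(seq: DuplexSequence, frames: _BpFrames) -> np.ndarray:
    """Heavy-atom coordinates from bp frames by rigid template placement."""
    n = len(seq)
    u_w = np.array([1.0, 0.0, 0.0])
    u_c = np.array([math.cos(frames.phase), math.sin(frames.phase), 0.0])
    out: list[np.ndarray] = [None] * (2 * n)  # type: ignore[list-item]
    for p in range(n):
        Q = frames.rotations[p]
        o = frames.origins[p]
        r = frames.radii[p]
        # Watson residue p
        x_hat = Q @ u_w
        z_hat = Q[:, 2]
        y_hat = np.cross(z_hat, x_hat)
        M = np.column_stack([x_hat, y_hat, z_hat])
        bead = o + r * x_hat
        _, local, _ = nucleotide_template(seq.watson[p])
        out[p] = bead + local @ M.T
        # Crick residue 2n-1-p
        xc = Q @ u_c
        zc = -Q[:, 2]
        yc = np.cross(zc, xc)
        Mc = np.column_stack([xc, yc, zc])
        beadc = o + r * xc
        _, localc, _ = nucleotide_template(seq.crick[n - 1 - p])
        out[2 * n - 1 - p] = beadc + localc @ Mc.T
    return np.concatenate(out)


def ideal_bdna_atomistic(
    sequence: DuplexSequence | str, helix: HelixSpec | None = None
) -> AtomisticStructure:
    """Ideal heavy-atom duplex built by rigid placement of the nucleotide
    templates on the ideal helix frames; the C1' subset reproduces
    :func:`ideal_bdna_beads` exactly."""
    seq = DuplexSequence(sequence) if isinstance(sequence, str) else sequence
    helix = helix or HelixSpec()
    frames = _frames_one_conformation(seq, helix, None, None)
    atom_names, residue_index, bases, bonds = _structure_layout(seq)
    coords = _atoms_from_frames(seq, frames)
    return AtomisticStructure(
        sequence=seq,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_base=bases,
        coords=coords,
        bonds=bonds,
        provenance={"generator": "cgdna synthetic ideal B-form build"},
    )


def synth_paired_ensemble(
    sequence: DuplexSequence | str,
    helix: HelixSpec | None = None,
    fluct: FluctuationSpec | None = None,
    n_frames: int = 200,
) -> tuple[TrajectoryEnsemble, AtomisticEnsemble]:
    """Matched bead and heavy-atom ensembles from the same fluctuating bp
    frames (training data for the back-map regressions)."""
    seq = DuplexSequence(sequence) if isinstance(sequence, str) else sequence
    helix = helix or HelixSpec()
    fluct = fluct or FluctuationSpec()
    frames = _ensemble_frames(seq, helix, fluct, n_frames)
    bead_frames = np.stack([_beads_from_frames(f) for f in frames])
    atom_frames = np.stack([_atoms_from_frames(seq, f) for f in frames])
    topo = build_duplex_topology(seq)
    beads = TrajectoryEnsemble(
        frames=bead_frames,
        times=np.arange(n_frames, dtype=float),
        topology=topo,
        provenance={"generator": "cgdna synthetic paired ensemble",
                    "seed": fluct.seed},
    )
    atom_names, residue_index, bases, bonds = _structure_layout(seq)
    structure = AtomisticStructure(
        sequence=seq,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_base=bases,
        coords=atom_frames[0].copy(),
        bonds=bonds,
        provenance={"generator": "cgdna synthetic paired ensemble"},
    )
    return beads, AtomisticEnsemble(structure=structure, frames=atom_frames)


def build_minicircle(
    sequence: DuplexSequence | str,
    spec: CircularBuildSpec,
    helix: HelixSpec | None = None,
) -> np.ndarray:
    """Planar-ring minicircle bead build with explicit twist registration.

    The bp centres lie on a circle of circumference ``n_bp * rise``; the
    two beads of each bp sit in the plane normal to the local tangent,
    rotated by the accumulated twist ``(Lk0 + dLk) * 360 / n_bp`` per step.
    A dLk of 0 gives a relaxed (torsionally homogeneous) planar ring of
    writhe ~0; non-zero dLk changes only the twist registration of the
    strands around the same centreline.
    """
    seq = DuplexSequence(sequence) if isinstance(sequence, str) else sequence
    if not seq.circular:
        seq = DuplexSequence(seq.watson, circular=True)
    helix = helix or HelixSpec()
    n = len(seq)
    if n != spec.n_bp:
        raise ValueError(f"spec.n_bp={spec.n_bp} does not match sequence ({n} bp)")
    ring_r = n * helix.rise / (2.0 * math.pi)
    twist_step = 2.0 * math.pi * spec.lk / n
    phase = math.radians(helix.phase)
    coords = np.empty((2 * n, 3))
    for p in range(n):
        phi = 2.0 * math.pi * p / n
        center = ring_r * np.array([math.cos(phi), math.sin(phi), 0.0])
        r_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        psi = p * twist_step
        dir_w = math.cos(psi) * r_hat + math.sin(psi) * z_hat
        dir_c = math.cos(psi + phase) * r_hat + math.sin(psi + phase) * z_hat
        coords[p] = center + helix.radius * dir_w
        coords[2 * n - 1 - p] = center + helix.radius * dir_c
    return coords


def minicircle_twist_registration(spec: CircularBuildSpec) -> np.ndarray:
    """Per-step twist angles (deg) of a minicircle build; they sum to
    ``(Lk0 + dLk) * 360``."""
    return np.full(spec.n_bp, 360.0 * spec.lk / spec.n_bp)
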