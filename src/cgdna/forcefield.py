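"""Energy function and analytic forces for the bead model.

Total energy = sequential (bonded) + remote (non-bonded) terms.  Bonded
distance and angle terms are truncated quartic polynomials around an
equilibrium value,

    E(x) = K2 (x - x0)^2 + K3 (x - x0)^3 + K4 (x - x0)^4 ,

with the quadratic term carrying the basal harmonicity, the cubic the
anharmonic skew, and the quartic a confinement that prevents unphysical
excursions under stress.  Remote terms are a 12-6 Lennard-Jones repulsion/
dispersion plus Debye-Hueckel screened electrostatics with one unit negative
charge per bead, switched off for bead pairs closer than 6 bp along either
strand (they are already covered by the bonded window).

Units: kcal/mol, Å, radians; see :mod:`cgdna.constants`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import COULOMB_CONSTANT
from .topology import (
    BeadTopology,
    ExclusionMask,
    InteractionTable,
    ResolvedParameters,
    enumerate_interactions,
    remote_exclusion_mask,
    resolve_parameters,
    tetramer_roles,
)

__all__ = [
    "BondedTerm",
    "RemoteSettings",
    "ParameterLibrary",
    "EnergyBreakdown",
    "ForceField",
    "bonded_energy",
]

#: bead count above which remote pair search switches to a k-d tree
_TREE_THRESHOLD = 400


@dataclass(frozen=True)
class BondedTerm:
    """Quartic bonded term: force constants and equilibrium value.

    ``k2`` in kcal/mol/Å² (or rad²), ``k3``/``k4`` in the matching higher
    powers, ``x0`` in Å (distances) or radians (angles).
    """

    k2: float
    k3: float
    k4: float
    x0: float

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError(f"K2 must be > 0, got {self.k2}")
        if self.k4 < 0:
            raise ValueError(f"K4 must be >= 0, got {self.k4}")


@dataclass(frozen=True)
class RemoteSettings:
    """Remote-term parameters.

    Defaults correspond to 100 mM monovalent salt in water: Debye screening
    kappa = 0.104 1/Å, relative dielectric 78.5, bead charge -1 e, and the
    LJ pair sigma = 10 Å, epsilon = 0.59 kcal/mol.
    """

    q: float = -1.0
    sigma: float = 10.0
    eps_lj: float = 0.59
    eps_r: float = 78.5
    kappa: float = 0.104
    cutoff: float = 25.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.eps_lj < 0:
            raise ValueError("eps_LJ must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.cutoff <= self.sigma:
            raise ValueError("cutoff must exceed sigma")


class ParameterLibrary:
    """Bonded parameters per tetramer class plus distant and remote settings.

    ``tetramer`` maps a canonical tetramer class (lexicographically smaller
    of the tetramer and its reverse complement) to a role -> term dict;
    ``fallback`` is the sequence-averaged role -> term set used by truncated
    terminal windows; ``distant`` maps signed bp offsets (as strings, e.g.
    ``"+4"``) to sequence-averaged fan terms.
    """

    def __init__(
        self,
        tetramer: dict[str, dict[str, BondedTerm]],
        fallback: dict[str, BondedTerm],
        distant: dict[str, BondedTerm],
        remote: RemoteSettings | None = None,
        scheme: str = "eq5",
    ) -> None:
        self.tetramer = tetramer
        self.fallback = fallback
        self.distant = distant
        self.remote = remote if remote is not None else RemoteSettings()
        self.scheme = scheme

    # -- lookups -----------------------------------------------------------
    def bonded_term(
        self, cls: str | None, role: str, allow_fallback: bool = True
    ) -> BondedTerm:
        if cls is not None and cls in self.tetramer:
            terms = self.tetramer[cls]
            if role in terms:
                return terms[role]
        if cls is not None and not allow_fallback:
            raise KeyError(
                f"no parameters for tetramer class {cls!r} (role {role!r}) "
                "and fallback is disabled"
            )
        if cls is None and not allow_fallback:
            raise KeyError(
                f"truncated terminal context (role {role!r}) requires the "
                "sequence-averaged fallback, which is disabled"
            )
        return self.fallback[role]

    def distant_term(self, offset: int) -> BondedTerm:
        return self.distant[f"{offset:+d}"]

    # -- constructors ------------------------------------------------------
    @classmethod
    def uniform(
        cls,
        stacking: BondedTerm,
        pairing: BondedTerm,
        angle: BondedTerm,
        fan: dict[int, BondedTerm],
        distant: dict[int, BondedTerm],
        remote: RemoteSettings | None = None,
        scheme: str = "eq5",
    ) -> "ParameterLibrary":
        """Sequence-independent library: every class equals the fallback.

        ``fan`` and ``distant`` are keyed by signed bp offset.
        """
        fallback: dict[str, BondedTerm] = {}
        for role in tetramer_roles(scheme):
            if role.startswith("stack"):
                fallback[role] = stacking
            elif role.startswith("pair"):
                fallback[role] = pairing
            elif role.startswith("angle"):
                fallback[role] = angle
            else:
                off = int(role.rsplit("_", 1)[1])
                fallback[role] = fan[off]
        dist = {f"{off:+d}": term for off, term in distant.items()}
        return cls({}, fallback, dist, remote=remote, scheme=scheme)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def term_d(t: BondedTerm) -> dict:
            return {"K2": t.k2, "K3": t.k3, "K4": t.k4, "x0": t.x0}

        return {
            "format": "cgdna-parameters",
            "version": 1,
            "units": {
                "energy": "kcal/mol",
                "length": "Å",
                "angle": "rad",
                "charge": "e",
            },
            "scheme": self.scheme,
            "tetramer": {
                cls: {role: term_d(t) for role, t in roles.items()}
                for cls, roles in self.tetramer.items()
            },
            "fallback": {role: term_d(t) for role, t in self.fallback.items()},
            "distant": {off: term_d(t) for off, t in self.distant.items()},
            "remote": asdict(self.remote),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterLibrary":
        if data.get("format") != "cgdna-parameters":
            raise ValueError("not a cgdna parameter file")

        def term(d: dict) -> BondedTerm:
            return BondedTerm(d["K2"], d["K3"], d["K4"], d["x0"])

        return cls(
            tetramer={
                c: {r: term(t) for r, t in roles.items()}
                for c, roles in data["tetramer"].items()
            },
            fallback={r: term(t) for r, t in data["fallback"].items()},
            distant={o: term(t) for o, t in data["distant"].items()},
            remote=RemoteSettings(**data["remote"]),
            scheme=data.get("scheme", "eq5"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterLibrary":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EnergyBreakdown:
    """Per-channel energy totals, kcal/mol."""

    stacking: float = 0.0
    pairing: float = 0.0
    angle: float = 0.0
    fan: float = 0.0
    distant: float = 0.0
    lj: float = 0.0
    electrostatic: float = 0.0

    @property
    def sequential(self) -> float:
        return self.stacking + self.pairing + self.angle + self.fan + self.distant

    @property
    def remote(self) -> float:
        return self.lj + self.electrostatic

    @property
    def total(self) -> float:
        return self.sequential + self.remote

    def as_dict(self) -> dict[str, float]:
        return {
            "stacking": self.stacking,
            "pairing": self.pairing,
            "angle": self.angle,
            "fan": self.fan,
            "distant": self.distant,
            "lj": self.lj,
            "electrostatic": self.electrostatic,
            "total": self.total,
        }


def bonded_energy(x: float | np.ndarray, term: BondedTerm) -> float | np.ndarray:
    """Energy of one bonded term at observed distance/angle ``x``."""
    d = np.asarray(x, dtype=float) - term.x0
    out = term.k2 * d**2 + term.k3 * d**3 + term.k4 * d**4
    return float(out) if np.isscalar(x) else out


class ForceField:
    """Precompiled energy/force evaluator for one topology and library.

    Compiles the interaction table into flat index/parameter arrays so a
    single evaluation is a handful of vectorised operations; remote pairs
    are pre-enumerated from the exclusion mask (or found with a k-d tree for
    large systems) and cut off at ``remote.cutoff``.
    """

    def __init__(
        self,
        topology: BeadTopology,
        library: ParameterLibrary,
        scheme: str | None = None,
        remote_enabled: bool = True,
    ) -> None:
        self.topology = topology
        self.library = library
        self.scheme = scheme or library.scheme
        self.table: InteractionTable = enumerate_interactions(topology, self.scheme)
        self.params: ResolvedParameters = resolve_parameters(self.table, library)
        self.remote_enabled = remote_enabled
        self.mask: ExclusionMask = remote_exclusion_mask(topology)
        self.n_beads = topology.n_beads

        p = self.params
        # channel bookkeeping for distance instances
        self._channels = ("stacking", "pairing", "fan", "distant")
        self._chan_sel = {c: p.dist_kind == c for c in self._channels}

        # static included remote pairs (upper triangle, not excluded)
        iu, ju = np.triu_indices(self.n_beads, k=1)
        keep = ~self.mask.excluded[iu, ju]
        self._rem_i = iu[keep]
        self._rem_j = ju[keep]
        self._use_tree = self.n_beads > _TREE_THRESHOLD
        # bp positions for tree-path exclusion filtering
        self._bp_pos = topology.bp_positions

        # combined scatter index for force accumulation:
        # [dist_i, dist_j, ang_i, ang_j, ang_k] (+ remote appended per call)
        self._scatter_idx = np.concatenate(
            [p.dist_i, p.dist_j, p.ang_i, p.ang_j, p.ang_k]
        )

    # -- remote pair list --------------------------------------------------
    def _remote_pairs(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Included remote pairs within cutoff for this conformation."""
        cutoff = self.library.remote.cutoff
        if not self._use_tree:
            i, j = self._rem_i, self._rem_j
            d = coords[j] - coords[i]
            r2 = np.einsum("ij,ij->i", d, d)
            keep = r2 <= cutoff * cutoff
            return i[keep], j[keep]
        tree = cKDTree(coords)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return pairs.reshape(0).astype(np.intp), pairs.reshape(0).astype(np.intp)
        i, j = pairs[:, 0], pairs[:, 1]
        sep = np.abs(self._bp_pos[i] - self._bp_pos[j])
        if self.topology.circular:
            sep = np.minimum(sep, self.topology.n_bp - sep)
        keep = sep > 5
        return i[keep], j[keep]

    def remote_energy(
        self, coords: np.ndarray, brute_force: bool = False
    ) -> EnergyBreakdown:
        """LJ + screened-electrostatic energy only.

        ``brute_force=True`` forces the O(N^2) pair loop regardless of size
        (used to validate the accelerated path).
        """
        eb = EnergyBreakdown()
        if not self.remote_enabled:
            return eb
        if brute_force:
            iu, ju = np.triu_indices(self.n_beads, k=1)
            keep = ~self.mask.excluded[iu, ju]
            i, j = iu[keep], ju[keep]
            d = coords[j] - coords[i]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            sel = r <= self.library.remote.cutoff
            i, j, r = i[sel], j[sel], r[sel]
        else:
            i, j = self._remote_pairs(coords)
            d = coords[j] - coords[i]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if len(r) and r.min() == 0.0:
            raise ValueError("overlapping beads: zero distance in remote pair")
        s = self.library.remote
        inv6 = (s.sigma / r) ** 6 if len(r) else r
        eb.lj = float(np.sum(4.0 * s.eps_lj * (inv6**2 - inv6)))
        eb.electrostatic = float(
            np.sum(COULOMB_CONSTANT * s.q * s.q * np.exp(-s.kappa * r) / (s.eps_r * r))
        )
        return eb

    # -- full evaluation ---------------------------------------------------
    def _check_coords(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_beads, 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match topology "
                f"({self.n_beads} beads)"
            )
        return coords

    def energy_forces(
        self, coords: np.ndarray
    ) -> tuple[np.ndarray, EnergyBreakdown]:
        """Analytic forces (-grad E, kcal/mol/Å) and the energy breakdown."""
        coords = self._check_coords(coords)
        p = self.params
        eb = EnergyBreakdown()

        # distance terms
        dvec = coords[p.dist_j] - coords[p.dist_i]
        r = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        dl = r - p.dist_x0
        e_inst = dl * dl * (p.dist_k2 + dl * (p.dist_k3 + dl * p.dist_k4))
        for c in self._channels:
            setattr(eb, c, float(e_inst[self._chan_sel[c]].sum()))
        dEdl = dl * (2.0 * p.dist_k2 + dl * (3.0 * p.dist_k3 + dl * 4.0 * p.dist_k4))
        u = dvec / r[:, None]
        w_dist_i = dEdl[:, None] * u  # force on i
        w_dist_j = -w_dist_i

        # angle terms (vertex at j)
        a = coords[p.ang_i] - coords[p.ang_j]
        b = coords[p.ang_k] - coords[p.ang_j]
        la = np.sqrt(np.einsum("ij,ij->i", a, a))
        lb = np.sqrt(np.einsum("ij,ij->i", b, b))
        ah = a / la[:, None]
        bh = b / lb[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", ah, bh), -1.0, 1.0)
        theta = np.arccos(cosang)
        da = theta - p.ang_x0
        eb.angle = float(
            np.sum(da * da * (p.ang_k2 + da * (p.ang_k3 + da * p.ang_k4)))
        )
        dEdt = da * (2.0 * p.ang_k2 + da * (3.0 * p.ang_k3 + da * 4.0 * p.ang_k4))
        sin = np.sqrt(1.0 - cosang * cosang)
        np.maximum(sin, 1e-8, out=sin)
        # dtheta/dxi and dtheta/dxk
        gi = (cosang[:, None] * ah - bh) / (la * sin)[:, None]
        gk = (cosang[:, None] * bh - ah) / (lb * sin)[:, None]
        w_ang_i = -dEdt[:, None] * gi
        w_ang_k = -dEdt[:, None] * gk
        w_ang_j = -(w_ang_i + w_ang_k)

        weights = [w_dist_i, w_dist_j, w_ang_i, w_ang_j, w_ang_k]
        idx = self._scatter_idx

        # remote terms
        if self.remote_enabled:
            ri, rj = self._remote_pairs(coords)
            rd = coords[rj] - coords[ri]
            rr = np.sqrt(np.einsum("ij,ij->i", rd, rd))
            if len(rr) and rr.min() == 0.0:
                raise ValueError("overlapping beads: zero distance in remote pair")
            s = self.library.remote
            inv6 = (s.sigma / rr) ** 6
            eb.lj = float(np.sum(4.0 * s.eps_lj * (inv6**2 - inv6)))
            ele = COULOMB_CONSTANT * s.q * s.q * np.exp(-s.kappa * rr) / (s.eps_r * rr)
            eb.electrostatic = float(np.sum(ele))
            # dE/dr
            dlj = 4.0 * s.eps_lj * (-12.0 * inv6**2 + 6.0 * inv6) / rr
            dele = -ele * (s.kappa + 1.0 / rr)
            dEdr = dlj + dele
            ru = rd / rr[:, None]
            w_rem_i = dEdr[:, None] * ru
            idx = np.concatenate([idx, ri, rj])
            weights.extend([w_rem_i, -w_rem_i])

        w = np.concatenate(weights)
        forces = np.empty((self.n_beads, 3))
        for dim in range(3):
            forces[:, dim] = np.bincount(idx, weights=w[:, dim], minlength=self.n_beads)
        return forces, eb

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        """Energy breakdown only (forces discarded)."""
        _, eb = self.energy_forces(coords)
        return eb

    def sequential_energy(self, coords: np.ndarray) -> EnergyBreakdown:
        """Bonded channels only (remote zeroed)."""
        coords = self._check_coords(coords)
        p = self.params
        eb = EnergyBreakdown()
        dvec = coords[p.dist_j] - coords[p.dist_i]
        r = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        dl = r - p.dist_x0
        e_inst = dl * dl * (p.dist_k2 + dl * (p.dist_k3 + dl * p.dist_k4))
        for c in self._channels:
            setattr(eb, c, float(e_inst[self._chan_sel[c]].sum()))
        a = coords[p.ang_i] - coords[p.ang_j]
        b = coords[p.ang_k] - coords[p.ang_j]
        cosang = np.clip(
            np.einsum("ij,ij->i", a, b)
            / (
                np.sqrt(np.einsum("ij,ij->i", a, a))
                * np.sqrt(np.einsum("ij,ij->i", b, b))
            ),
            -1.0,
            1.0,
        )
        da = np.arccos(cosang) - p.ang_x0
        eb.angle = float(np.sum(da * da * (p.ang_k2 + da * (p.ang_k3 + da * p.ang_k4))))
        return eb

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_forces(coords)[0]
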