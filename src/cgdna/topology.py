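"""Bead topology of a duplex and enumeration of its bonded interactions.

The duplex is represented with one bead per nucleotide, anchored at the C1'
sugar atom.  Watson-strand beads come first (ids ``0 .. n-1``, 5'->3'),
Crick-strand beads follow (ids ``n .. 2n-1``, 5'->3' along the Crick
strand).  Base-pair (bp) positions are indexed on the Watson strand; the
Crick bead paired with bp ``p`` is ``2n - 1 - p`` for a linear duplex.

The bonded part of the energy is built from 11-bead windows: every Watson
bead interacts with its sequence neighbours (stacking, backbone angles),
with its Watson-Crick partner (pairing), and with the partner's neighbours
up to 5 bp away (fan terms).  Local terms are parameterised at the tetramer
level (four consecutive bp read on the Watson strand); interactions shared
by two tetramer windows take the arithmetic mean of the two parameter sets.
Large fan offsets are treated as sequence-averaged "distant" terms.

Two accounting schemes are provided for how fan offsets split between the
tetramer-specific and the sequence-averaged sets:

``"eq5"`` (default)
    offsets +-1, +-2 are tetramer-specific (8 fan terms per window, matching
    the per-window term count of the Hamiltonian); +-3, +-4, +-5 are
    sequence-averaged distant terms.
``"fig1"``
    offsets +-1 .. +-3 are tetramer-specific (12 fan terms per window);
    +-4, +-5 are distant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_MASSES, DNA_ALPHABET, reverse_complement

__all__ = [
    "DuplexSequence",
    "BeadTopology",
    "DistanceInstance",
    "AngleInstance",
    "InteractionTable",
    "ExclusionMask",
    "ResolvedParameters",
    "SCHEMES",
    "canonical_tetramer",
    "tetramer_roles",
    "build_duplex_topology",
    "enumerate_interactions",
    "resolve_parameters",
    "remote_exclusion_mask",
]

#: scheme id -> (tetramer-level fan offsets, sequence-averaged distant offsets)
SCHEMES: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "eq5": ((1, 2), (3, 4, 5)),
    "fig1": ((1, 2, 3), (4, 5)),
}

MIN_LINEAR_BP = 4
MIN_CIRCULAR_BP = 12


@dataclass(frozen=True)
class DuplexSequence:
    """A duplex defined by its Watson strand (5'->3') and a circular flag.

    The Crick strand is always the reverse complement; it is derived, never
    stored.
    """

    watson: str
    circular: bool = False

    def __post_init__(self) -> None:
        seq = self.watson.upper()
        object.__setattr__(self, "watson", seq)
        for pos, base in enumerate(seq):
            if base not in DNA_ALPHABET:
                raise ValueError(
                    f"invalid base {base!r} at position {pos}: "
                    "sequence must be over A, C, G, T"
                )
        min_len = MIN_CIRCULAR_BP if self.circular else MIN_LINEAR_BP
        if len(seq) < min_len:
            kind = "circular" if self.circular else "linear"
            raise ValueError(
                f"{kind} duplex needs at least {min_len} bp, got {len(seq)}"
            )

    @property
    def crick(self) -> str:
        """Crick strand, 5'->3'."""
        return reverse_complement(self.watson)

    def __len__(self) -> int:
        return len(self.watson)


@dataclass
class BeadTopology:
    """Bead bookkeeping for a duplex: ids, pairing, masses, neighbours."""

    sequence: DuplexSequence
    masses: np.ndarray  # (2 n_bp,), Da

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return 2 * self.n_bp

    @property
    def circular(self) -> bool:
        return self.sequence.circular

    def watson_bead(self, p: int) -> int:
        """Bead id of the Watson nucleotide at bp position ``p``."""
        return p % self.n_bp if self.circular else p

    def crick_bead(self, p: int) -> int:
        """Bead id of the Crick nucleotide paired with bp position ``p``."""
        n = self.n_bp
        return n + (n - 1 - p % n if self.circular else n - 1 - p)

    def pair_of(self, bead: int) -> int:
        """Watson-Crick partner bead (an involution)."""
        n = self.n_bp
        return 2 * n - 1 - bead if bead < n else 2 * n - 1 - bead

    def bp_position(self, bead: int) -> int:
        """bp position (Watson index) a bead belongs to."""
        n = self.n_bp
        return bead if bead < n else 2 * n - 1 - bead

    @property
    def bp_positions(self) -> np.ndarray:
        """bp position of every bead, in bead-id order."""
        n = self.n_bp
        return np.concatenate([np.arange(n), n - 1 - np.arange(n)])

    def bp_separation(self, bead_a: int, bead_b: int) -> int:
        """Separation in bp between two beads, on the circle if circular."""
        d = abs(self.bp_position(bead_a) - self.bp_position(bead_b))
        if self.circular:
            d = min(d, self.n_bp - d)
        return d


@dataclass(frozen=True)
class DistanceInstance:
    """A distance-type bonded interaction between two beads.

    ``contexts`` lists ``(tetramer_class, role)`` labels; a class of ``None``
    marks a truncated terminal window resolved from the sequence-averaged
    fallback set.  Distant instances carry no tetramer context: they are
    resolved from the per-offset distant table.
    """

    kind: str  # "stacking" | "pairing" | "fan" | "distant"
    i: int
    j: int
    offset: int = 0  # signed bp offset (fan/distant), 0 otherwise
    contexts: tuple[tuple[str | None, str], ...] = ()


@dataclass(frozen=True)
class AngleInstance:
    """A three-bead backbone angle interaction (vertex at ``j``)."""

    i: int
    j: int
    k: int
    contexts: tuple[tuple[str | None, str], ...] = ()


@dataclass
class InteractionTable:
    """All bonded interaction instances of a topology under one scheme."""

    scheme: str
    stacking: list[DistanceInstance] = field(default_factory=list)
    pairing: list[DistanceInstance] = field(default_factory=list)
    fan: list[DistanceInstance] = field(default_factory=list)
    distant: list[DistanceInstance] = field(default_factory=list)
    angles: list[AngleInstance] = field(default_factory=list)

    @property
    def distances(self) -> list[DistanceInstance]:
        return self.stacking + self.pairing + self.fan + self.distant

    def counts(self) -> dict[str, int]:
        return {
            "stacking": len(self.stacking),
            "pairing": len(self.pairing),
            "fan": len(self.fan),
            "distant": len(self.distant),
            "angle": len(self.angles),
        }


@dataclass
class ExclusionMask:
    """Symmetric boolean relation over bead pairs excluded from remote terms."""

    excluded: np.ndarray  # (2n, 2n) bool, True = excluded

    def is_excluded(self, a: int, b: int) -> bool:
        return bool(self.excluded[a, b])


def canonical_tetramer(tet: str) -> str:
    """Canonical representative of a tetramer class under reverse-complement
    symmetry: the lexicographically smaller of the tetramer and its reverse
    complement."""
    rc = reverse_complement(tet)
    return tet if tet <= rc else rc


def _flip_role(role: str) -> str:
    """Map a within-window parameter role onto the reverse-complement view.

    Reading a window from the Crick strand reverses bp order and swaps the
    strands, so Watson/Crick roles and first/second window slots exchange and
    fan offsets change sign.
    """
    table = {
        "stack_w": "stack_c",
        "stack_c": "stack_w",
        "pair_a": "pair_b",
        "pair_b": "pair_a",
        "angle_w_a": "angle_c_b",
        "angle_w_b": "angle_c_a",
        "angle_c_a": "angle_w_b",
        "angle_c_b": "angle_w_a",
    }
    if role in table:
        return table[role]
    if role.startswith("fan_"):
        _, slot, off = role.split("_")
        flipped_slot = "b" if slot == "a" else "a"
        flipped_off = -int(off)
        return f"fan_{flipped_slot}_{flipped_off:+d}"
    raise KeyError(f"unknown role {role!r}")


def tetramer_roles(scheme: str = "eq5") -> list[str]:
    """Parameter roles a tetramer class carries under a scheme."""
    fan_offsets, _ = SCHEMES[scheme]
    roles = [
        "stack_w",
        "stack_c",
        "pair_a",
        "pair_b",
        "angle_w_a",
        "angle_w_b",
        "angle_c_a",
        "angle_c_b",
    ]
    for off in fan_offsets:
        for slot in ("a", "b"):
            roles.append(f"fan_{slot}_{+off:+d}")
            roles.append(f"fan_{slot}_{-off:+d}")
    return roles


def build_duplex_topology(
    seq: DuplexSequence, masses: dict[str, float] | None = None
) -> BeadTopology:
    """Build the bead topology of a duplex.

    Each nucleotide becomes one bead carrying the mass of its nucleotide;
    bead order is Watson 5'->3' then Crick 5'->3'.
    """
    table = DEFAULT_MASSES if masses is None else masses
    bead_masses = np.array(
        [table[b] for b in seq.watson] + [table[b] for b in seq.crick], dtype=float
    )
    return BeadTopology(sequence=seq, masses=bead_masses)


def _window_context(
    topo: BeadTopology, t: int, role: str
) -> tuple[str | None, str]:
    """Context label contributed by the tetramer window starting at bp ``t``.

    Returns ``(None, role)`` when the window is truncated by a linear end.
    """
    n = topo.n_bp
    if topo.circular:
        tet = "".join(topo.sequence.watson[(t + k) % n] for k in range(4))
    else:
        if t < 0 or t > n - 4:
            return (None, role)
        tet = topo.sequence.watson[t : t + 4]
    canon = canonical_tetramer(tet)
    if canon != tet:
        role = _flip_role(role)
    return (canon, role)


def enumerate_interactions(
    topology: BeadTopology, scheme: str = "eq5"
) -> InteractionTable:
    """Enumerate every bonded interaction instance of a topology.

    Under the default ``"eq5"`` scheme each interior tetramer window
    contributes 2 stacking, 2 pairing, 4 angle and 8 fan terms; fan offsets
    +-3, +-4, +-5 appear once per bead as sequence-averaged distant
    instances.  Out-of-range offsets at linear ends are silently dropped;
    circular topologies wrap, so every window is complete.
    """
    if scheme not in SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; available schemes: {sorted(SCHEMES)}"
        )
    fan_offsets, distant_offsets = SCHEMES[scheme]
    n = topology.n_bp
    circ = topology.circular
    table = InteractionTable(scheme=scheme)

    def valid_bp(p: int) -> bool:
        return circ or 0 <= p < n

    # Stacking: one instance per bp step and strand.  The step (s, s+1) is
    # the central step of the window starting at s-1, its only context.
    steps = range(n) if circ else range(n - 1)
    for s in steps:
        ctx_w = (_window_context(topology, s - 1, "stack_w"),)
        ctx_c = (_window_context(topology, s - 1, "stack_c"),)
        table.stacking.append(
            DistanceInstance(
                "stacking",
                topology.watson_bead(s),
                topology.watson_bead(s + 1),
                contexts=ctx_w,
            )
        )
        table.stacking.append(
            DistanceInstance(
                "stacking",
                topology.crick_bead(s),
                topology.crick_bead(s + 1),
                contexts=ctx_c,
            )
        )

    # Pairing: one instance per bp, shared by two windows.
    for p in range(n):
        ctx = (
            _window_context(topology, p - 1, "pair_a"),
            _window_context(topology, p - 2, "pair_b"),
        )
        table.pairing.append(
            DistanceInstance(
                "pairing",
                topology.watson_bead(p),
                topology.crick_bead(p),
                contexts=ctx,
            )
        )

    # Backbone angles: one per interior bp and strand, shared by two windows.
    centers = range(n) if circ else range(1, n - 1)
    for c in centers:
        ctx_w = (
            _window_context(topology, c - 1, "angle_w_a"),
            _window_context(topology, c - 2, "angle_w_b"),
        )
        ctx_c = (
            _window_context(topology, c - 1, "angle_c_a"),
            _window_context(topology, c - 2, "angle_c_b"),
        )
        table.angles.append(
            AngleInstance(
                topology.watson_bead(c - 1),
                topology.watson_bead(c),
                topology.watson_bead(c + 1),
                contexts=ctx_w,
            )
        )
        table.angles.append(
            AngleInstance(
                topology.crick_bead(c - 1),
                topology.crick_bead(c),
                topology.crick_bead(c + 1),
                contexts=ctx_c,
            )
        )

    # Fan: Watson bead at bp p with the Crick bead paired to bp p+off.
    # Enumerating from the Watson side with signed offsets covers every
    # cross-strand pair once.
    for off_mag in fan_offsets:
        for off in (+off_mag, -off_mag):
            for p in range(n):
                if not valid_bp(p + off):
                    continue
                ctx = (
                    _window_context(topology, p - 1, f"fan_a_{off:+d}"),
                    _window_context(topology, p - 2, f"fan_b_{off:+d}"),
                )
                table.fan.append(
                    DistanceInstance(
                        "fan",
                        topology.watson_bead(p),
                        topology.crick_bead(p + off),
                        offset=off,
                        contexts=ctx,
                    )
                )

    # Distant: sequence-averaged fan offsets, one instance per bead/offset.
    for off_mag in distant_offsets:
        for off in (+off_mag, -off_mag):
            for p in range(n):
                if not valid_bp(p + off):
                    continue
                table.distant.append(
                    DistanceInstance(
                        "distant",
                        topology.watson_bead(p),
                        topology.crick_bead(p + off),
                        offset=off,
                    )
                )

    _check_no_duplicates(table)
    return table


def _check_no_duplicates(table: InteractionTable) -> None:
    seen: set[tuple[int, int]] = set()
    for inst in table.distances:
        key = (min(inst.i, inst.j), max(inst.i, inst.j))
        if key in seen:
            raise AssertionError(f"duplicate distance instance {key}")
        seen.add(key)
    seen_a: set[tuple[int, ...]] = set()
    for ang in table.angles:
        key = tuple(sorted((ang.i, ang.j, ang.k)))
        if key in seen_a:
            raise AssertionError(f"duplicate angle instance {key}")
        seen_a.add(key)


def remote_exclusion_mask(topology: BeadTopology) -> ExclusionMask:
    """Pairs excluded from the remote (non-bonded) terms.

    A pair is excluded iff the bp separation of the two beads is <= 5
    (computed on the circle for circular duplexes), on either strand or
    across strands; self pairs are always excluded.
    """
    n = topology.n_bp
    pos = np.concatenate([np.arange(n), (n - 1 - np.arange(n))])
    d = np.abs(pos[:, None] - pos[None, :])
    if topology.circular:
        d = np.minimum(d, n - d)
    return ExclusionMask(excluded=d <= 5)


@dataclass
class ResolvedParameters:
    """Per-instance effective bonded parameters, as flat arrays.

    Distance instances are concatenated in the order stacking, pairing, fan,
    distant; ``dist_kind`` stores the channel name per instance.  Effective
    parameters are the arithmetic mean over the instance's context labels.
    """

    dist_i: np.ndarray
    dist_j: np.ndarray
    dist_kind: np.ndarray  # object array of channel names
    dist_k2: np.ndarray
    dist_k3: np.ndarray
    dist_k4: np.ndarray
    dist_x0: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_k2: np.ndarray
    ang_k3: np.ndarray
    ang_k4: np.ndarray
    ang_x0: np.ndarray

    @property
    def n_distances(self) -> int:
        return len(self.dist_i)

    @property
    def n_angles(self) -> int:
        return len(self.ang_i)


def _effective_term(inst, lib, allow_fallback: bool):
    """Mean (k2, k3, k4, x0) over an instance's contexts."""
    if getattr(inst, "kind", None) == "distant":
        term = lib.distant_term(inst.offset)
        return term.k2, term.k3, term.k4, term.x0
    acc = np.zeros(4)
    for cls, role in inst.contexts:
        term = lib.bonded_term(cls, role, allow_fallback=allow_fallback)
        acc += (term.k2, term.k3, term.k4, term.x0)
    acc /= len(inst.contexts)
    return tuple(acc)


def resolve_parameters(
    table: InteractionTable, lib, allow_fallback: bool = True
) -> ResolvedParameters:
    """Resolve every interaction instance against a parameter library.

    ``lib`` must provide ``bonded_term(cls, role, allow_fallback)`` and
    ``distant_term(offset)`` (see :class:`cgdna.forcefield.ParameterLibrary`).
    Instances shared by two tetramer windows get the arithmetic mean of the
    two parameter sets; truncated terminal contexts resolve from the
    sequence-averaged fallback set (rejected if ``allow_fallback=False``).
    """
    dists = table.distances
    nd = len(dists)
    out = ResolvedParameters(
        dist_i=np.array([d.i for d in dists], dtype=np.intp),
        dist_j=np.array([d.j for d in dists], dtype=np.intp),
        dist_kind=np.array([d.kind for d in dists], dtype=object),
        dist_k2=np.empty(nd),
        dist_k3=np.empty(nd),
        dist_k4=np.empty(nd),
        dist_x0=np.empty(nd),
        ang_i=np.array([a.i for a in table.angles], dtype=np.intp),
        ang_j=np.array([a.j for a in table.angles], dtype=np.intp),
        ang_k=np.array([a.k for a in table.angles], dtype=np.intp),
        ang_k2=np.empty(len(table.angles)),
        ang_k3=np.empty(len(table.angles)),
        ang_k4=np.empty(len(table.angles)),
        ang_x0=np.empty(len(table.angles)),
    )
    for idx, inst in enumerate(dists):
        k2, k3, k4, x0 = _effective_term(inst, lib, allow_fallback)
        out.dist_k2[idx] = k2
        out.dist_k3[idx] = k3
        out.dist_k4[idx] = k4
        out.dist_x0[idx] = x0
    for idx, inst in enumerate(table.angles):
        k2, k3, k4, x0 = _effective_term(inst, lib, allow_fallback)
        out.ang_k2[idx] = k2
        out.ang_k3[idx] = k3
        out.ang_k4[idx] = k4
        out.ang_x0[idx] = x0
    return out
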