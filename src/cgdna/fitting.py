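"""Bottom-up parameterisation from reference bead ensembles.

The pipeline mirrors how a bead Hamiltonian is calibrated against
atomistic reference data:

1. :func:`extract_observables` measures per-instance means and variances
   of every bonded distance and angle in a reference ensemble, pooled by
   (tetramer class, role).
2. :func:`fit_baseline` inverts the harmonic relation Var = k_B T / (2 K2)
   to produce a first, sequence-independent-then-classwise parameter set
   with equilibrium values at the reference means.
3. :func:`refine_tetramers` sweeps tetramer classes with a COBYLA
   derivative-free optimiser, adjusting each class's terms against the
   reference statistics in the context of the current values of all other
   classes (interactions shared by two windows average their parameters,
   which couples classes); sweeps repeat until parameters stop moving.
4. :func:`refine_distant` re-adjusts the sequence-averaged distant fan
   terms against the end-to-end mean and variance of a 40-mer duplex, by
   Metropolis annealing over an effective-temperature ladder followed by a
   conjugate-gradient polish of the best candidate.

Model-implied observables during refinement come from the harmonic closed
form by default (fast, deterministic); a simulation-backed mode runs short
seeded Langevin trajectories instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import KB
from .dynamics import DynamicsSettings, TrajectoryEnsemble, run_simulation
from .forcefield import BondedTerm, ForceField, ParameterLibrary, RemoteSettings
from .topology import (
    BeadTopology,
    InteractionTable,
    enumerate_interactions,
    tetramer_roles,
)

__all__ = [
    "ReferenceObservables",
    "FitReport",
    "RefineSettings",
    "AnnealSettings",
    "extract_observables",
    "fit_baseline",
    "refine_tetramers",
    "refine_distant",
    "fit_from_reference",
]

logger = logging.getLogger("cgdna.fitting")

_FALLBACK = "__fallback__"
_K4_FRACTION = 0.01  # quartic confinement seeded as this fraction of K2


@dataclass
class ReferenceObservables:
    """Sample statistics of every bonded observable in a reference ensemble.

    ``dist_mean``/``dist_var`` (and the angle twins) are per-instance, in
    the enumeration order of the interaction table.  ``groups`` pools them
    by (tetramer class, role) with one unit weight per instance-context;
    truncated terminal contexts pool under the fallback class.  ``distant``
    pools per signed offset.  ``covariances`` holds sample covariances for
    pairs of same-kind distance instances sharing a bead.
    """

    table: InteractionTable
    dist_mean: np.ndarray
    dist_var: np.ndarray
    ang_mean: np.ndarray
    ang_var: np.ndarray
    groups: dict[tuple[str, str], tuple[float, float, int]]
    distant: dict[str, tuple[float, float, int]]
    covariances: list[tuple[int, int, float]] = field(default_factory=list)
    n_frames: int = 0
    topology: BeadTopology | None = None

    def group_stats(self, cls: str | None, role: str) -> tuple[float, float, int]:
        key = (_FALLBACK if cls is None else cls, role)
        return self.groups[key]


def _pool(entries: list[tuple[float, float]]) -> tuple[float, float, int]:
    means = np.array([m for m, _ in entries])
    varis = np.array([v for _, v in entries])
    return float(means.mean()), float(varis.mean()), len(entries)


def extract_observables(
    ensemble: TrajectoryEnsemble,
    topology: BeadTopology,
    scheme: str = "eq5",
    with_covariances: bool = False,
) -> ReferenceObservables:
    """Per-instance and per-class statistics of a reference ensemble."""
    frames = ensemble.frames
    if frames.ndim != 3 or frames.shape[1] != topology.n_beads:
        raise ValueError(
            f"ensemble frames {frames.shape} do not match topology "
            f"({topology.n_beads} beads)"
        )
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    table = enumerate_interactions(topology, scheme)
    dists = table.distances
    di = np.array([d.i for d in dists])
    dj = np.array([d.j for d in dists])
    vals = np.linalg.norm(frames[:, dj] - frames[:, di], axis=2)  # (F, nd)
    dist_mean = vals.mean(axis=0)
    dist_var = vals.var(axis=0)

    ai = np.array([a.i for a in table.angles])
    aj = np.array([a.j for a in table.angles])
    ak = np.array([a.k for a in table.angles])
    va = frames[:, ai] - frames[:, aj]
    vb = frames[:, ak] - frames[:, aj]
    cosang = np.einsum("fpd,fpd->fp", va, vb) / (
        np.linalg.norm(va, axis=2) * np.linalg.norm(vb, axis=2)
    )
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang_mean = angles.mean(axis=0)
    ang_var = angles.var(axis=0)

    buckets: dict[tuple[str, str], list[tuple[float, float]]] = {}
    distant_buckets: dict[str, list[tuple[float, float]]] = {}
    for idx, inst in enumerate(dists):
        if inst.kind == "distant":
            distant_buckets.setdefault(f"{inst.offset:+d}", []).append(
                (dist_mean[idx], dist_var[idx])
            )
            continue
        for cls, role in inst.contexts:
            key = (_FALLBACK if cls is None else cls, role)
            buckets.setdefault(key, []).append((dist_mean[idx], dist_var[idx]))
    for idx, inst in enumerate(table.angles):
        for cls, role in inst.contexts:
            key = (_FALLBACK if cls is None else cls, role)
            buckets.setdefault(key, []).append((ang_mean[idx], ang_var[idx]))

    covariances: list[tuple[int, int, float]] = []
    if with_covariances:
        bead_map: dict[int, list[int]] = {}
        for idx, inst in enumerate(dists):
            bead_map.setdefault(inst.i, []).append(idx)
            bead_map.setdefault(inst.j, []).append(idx)
        seen = set()
        for shared in bead_map.values():
            for a in shared:
                for b in shared:
                    if a < b and (a, b) not in seen:
                        seen.add((a, b))
                        cov = float(
                            np.mean(
                                (vals[:, a] - dist_mean[a]) * (vals[:, b] - dist_mean[b])
                            )
                        )
                        covariances.append((a, b, cov))

    return ReferenceObservables(
        table=table,
        dist_mean=dist_mean,
        dist_var=dist_var,
        ang_mean=ang_mean,
        ang_var=ang_var,
        groups={k: _pool(v) for k, v in buckets.items()},
        distant={k: _pool(v) for k, v in distant_buckets.items()},
        covariances=covariances,
        n_frames=len(frames),
        topology=topology,
    )


def observables_from_library(
    lib: ParameterLibrary,
    topology: BeadTopology,
    temperature: float = 300.0,
    scheme: str | None = None,
) -> ReferenceObservables:
    """Synthesize reference observables implied by a parameter library
    under the harmonic closed form (Var = k_B T / (2 K2_eff), mean = x0_eff
    per instance).  Used as the self-consistency oracle for parameter
    recovery: fitting these observables should return the library."""
    scheme = scheme or lib.scheme
    kbt = KB * temperature
    table = enumerate_interactions(topology, scheme)

    def implied(inst):
        if getattr(inst, "kind", None) == "distant":
            t = lib.distant_term(inst.offset)
            return t.x0, kbt / (2.0 * t.k2)
        terms = [lib.bonded_term(c, r, allow_fallback=True) for c, r in inst.contexts]
        k2 = float(np.mean([t.k2 for t in terms]))
        x0 = float(np.mean([t.x0 for t in terms]))
        return x0, kbt / (2.0 * k2)

    dist_stats = [implied(i) for i in table.distances]
    ang_stats = [implied(a) for a in table.angles]
    dist_mean = np.array([m for m, _ in dist_stats])
    dist_var = np.array([v for _, v in dist_stats])
    ang_mean = np.array([m for m, _ in ang_stats])
    ang_var = np.array([v for _, v in ang_stats])

    buckets: dict[tuple[str, str], list[tuple[float, float]]] = {}
    distant_buckets: dict[str, list[tuple[float, float]]] = {}
    for idx, inst in enumerate(table.distances):
        if inst.kind == "distant":
            distant_buckets.setdefault(f"{inst.offset:+d}", []).append(
                (dist_mean[idx], dist_var[idx])
            )
            continue
        for cls, role in inst.contexts:
            key = (_FALLBACK if cls is None else cls, role)
            buckets.setdefault(key, []).append((dist_mean[idx], dist_var[idx]))
    for idx, inst in enumerate(table.angles):
        for cls, role in inst.contexts:
            key = (_FALLBACK if cls is None else cls, role)
            buckets.setdefault(key, []).append((ang_mean[idx], ang_var[idx]))
    return ReferenceObservables(
        table=table,
        dist_mean=dist_mean,
        dist_var=dist_var,
        ang_mean=ang_mean,
        ang_var=ang_var,
        groups={k: _pool(v) for k, v in buckets.items()},
        distant={k: _pool(v) for k, v in distant_buckets.items()},
        n_frames=0,
        topology=topology,
    )


# ---------------------------------------------------------------------------
# baseline fit


def fit_baseline(
    obs: ReferenceObservables,
    temperature: float = 300.0,
    remote: RemoteSettings | None = None,
    k2_cap: float = 100.0,
) -> ParameterLibrary:
    """Harmonic-inversion baseline: x0 from means, K2 = k_B T / (2 Var).

    K3 starts at zero and K4 at a small positive fraction of K2 so the
    terms stay bounded below.  Classes observed in the reference get their
    own entries; the fallback set pools every context.
    """
    kbt = KB * temperature

    def term(mean: float, var: float) -> BondedTerm:
        if var <= 0:
            raise ValueError("zero variance observable; cannot invert")
        k2 = min(kbt / (2.0 * var), k2_cap)
        return BondedTerm(k2=k2, k3=0.0, k4=_K4_FRACTION * k2, x0=mean)

    scheme = obs.table.scheme
    classes = sorted({c for (c, _r) in obs.groups if c != _FALLBACK})
    all_roles = tetramer_roles(scheme)

    # sequence-averaged fallback: pool every class contribution per role
    fallback: dict[str, BondedTerm] = {}
    for role in all_roles:
        entries = [
            (m, v)
            for (c, r), (m, v, n) in obs.groups.items()
            if r == role
            for _ in range(n)
        ]
        if not entries:
            continue
        m, v, _ = _pool(entries)
        fallback[role] = term(m, v)

    tetramer: dict[str, dict[str, BondedTerm]] = {}
    for cls in classes:
        roles: dict[str, BondedTerm] = {}
        for role in all_roles:
            stats = obs.groups.get((cls, role))
            if stats is None:
                continue
            roles[role] = term(stats[0], stats[1])
        tetramer[cls] = roles

    distant = {off: term(m, v) for off, (m, v, _n) in obs.distant.items()}
    return ParameterLibrary(
        tetramer=tetramer,
        fallback=fallback,
        distant=distant,
        remote=remote,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# tetramer refinement


@dataclass
class RefineSettings:
    """Tetramer-sweep refinement settings.

    ``tolerance`` is the max relative parameter change that ends the
    sweeps; ``bounds`` guard against physically unrealistic parameters
    (K2 capped, |K3| <= K2, K4 <= K2).  ``observable_model`` selects how
    model-implied observables are computed: ``"harmonic"`` closed form or
    ``"simulation"`` short seeded runs.
    """

    temperature: float = 300.0
    tolerance: float = 1e-2
    max_sweeps: int = 6
    k2_cap: float = 100.0
    observable_model: str = "harmonic"
    sim_steps: int = 20000
    sim_stride: int = 20
    seed: int = 2024
    cobyla_maxiter: int = 80
    relaxation: float = 1.0  # optional over-relaxation of sweep updates
    anchor_weight: float = 1e-3  # Tikhonov pull toward the baseline values
    linear_init: bool = True  # precondition with a global linear solve


@dataclass
class FitReport:
    """Refinement trace: per-sweep parameter change and merit."""

    sweeps: int = 0
    converged: bool = False
    max_change_trace: list[float] = field(default_factory=list)
    merit_trace: list[float] = field(default_factory=list)
    effective_classes: int = 0
    failed_classes: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _implied_group_stats(
    obs: ReferenceObservables, lib: ParameterLibrary, kbt: float
) -> dict[tuple[str, str], tuple[float, float]]:
    """Model-implied (mean, var) per (class, role) under the harmonic
    closed form: each instance's effective K2/x0 is the context average,
    its implied variance k_B T / (2 K2_eff), pooled like the reference."""
    buckets: dict[tuple[str, str], list[tuple[float, float]]] = {}
    table = obs.table
    for inst in table.distances + table.angles:  # type: ignore[operator]
        if getattr(inst, "kind", None) == "distant":
            continue
        terms = [
            lib.bonded_term(cls, role, allow_fallback=True)
            for cls, role in inst.contexts
        ]
        k2_eff = float(np.mean([t.k2 for t in terms]))
        x0_eff = float(np.mean([t.x0 for t in terms]))
        implied = (x0_eff, kbt / (2.0 * k2_eff))
        for cls, role in inst.contexts:
            key = (_FALLBACK if cls is None else cls, role)
            buckets.setdefault(key, []).append(implied)
    return {
        k: (float(np.mean([m for m, _ in v])), float(np.mean([x for _, x in v])))
        for k, v in buckets.items()
    }


def _group_merit(
    implied: dict[tuple[str, str], tuple[float, float]],
    obs: ReferenceObservables,
    keys=None,
) -> float:
    """Sum of squared relative errors of group means and variances."""
    total = 0.0
    for key, (rm, rv, _n) in obs.groups.items():
        if keys is not None and key not in keys:
            continue
        im, iv = implied[key]
        total += ((im - rm) / rm) ** 2 + ((iv - rv) / rv) ** 2
    return total


def _linear_precondition(lib, obs, kbt, settings, get_term, set_term) -> None:
    """Global linear least-squares solve for per-group K2 and x0.

    The context-averaging of shared interactions makes the per-instance
    effective K2 and x0 linear in the group parameters, so the harmonic
    targets (K2_eff = k_B T / (2 Var), x0_eff = mean) form an
    overdetermined linear system.  Solving it (with a small ridge toward
    the incoming values) lands the subsequent COBYLA sweeps next to the
    fixed point.
    """
    keys = sorted(obs.groups)
    col = {k: i for i, k in enumerate(keys)}
    recs = []
    for idx, inst in enumerate(obs.table.distances):
        if inst.kind == "distant":
            continue
        recs.append((inst.contexts, obs.dist_mean[idx], obs.dist_var[idx]))
    for idx, inst in enumerate(obs.table.angles):
        recs.append((inst.contexts, obs.ang_mean[idx], obs.ang_var[idx]))
    a = np.zeros((len(recs), len(keys)))
    bk = np.empty(len(recs))
    bx = np.empty(len(recs))
    for r, (ctx, m, v) in enumerate(recs):
        for cls, role in ctx:
            key = (_FALLBACK if cls is None else cls, role)
            a[r, col[key]] += 1.0 / len(ctx)
        bk[r] = kbt / (2.0 * max(v, 1e-12))
        bx[r] = m
    lam = 1e-6
    k_base = np.array([get_term(c, r).k2 for c, r in keys])
    x_base = np.array([get_term(c, r).x0 for c, r in keys])
    ata = a.T @ a + lam * np.eye(len(keys))
    k_sol = np.linalg.solve(ata, a.T @ bk + lam * k_base)
    x_sol = np.linalg.solve(ata, a.T @ bx + lam * x_base)
    for i, (c, r) in enumerate(keys):
        k2 = float(np.clip(k_sol[i], 1e-6, settings.k2_cap))
        t = get_term(c, r)
        set_term(
            c, r, BondedTerm(k2, t.k3, max(_K4_FRACTION * k2, 1e-12), float(x_sol[i]))
        )


def refine_tetramers(
    lib: ParameterLibrary,
    obs: ReferenceObservables,
    settings: RefineSettings | None = None,
) -> tuple[ParameterLibrary, FitReport]:
    """Iterative per-class refinement with COBYLA.

    Classes are swept sequentially; for each (class, role) a 2-parameter
    COBYLA problem adjusts (x0, K2) to minimise the squared relative error
    of the model-implied group mean and variance, holding every other class
    at its current values (the coupling enters through interactions shared
    between windows).  K3 is kept and K4 follows K2 proportionally.  Sweeps
    stop when the max relative parameter change drops below tolerance.
    """
    settings = settings or RefineSettings()
    kbt = KB * settings.temperature
    report = FitReport()
    # deep copy of the mutable dicts
    lib = ParameterLibrary(
        tetramer={c: dict(r) for c, r in lib.tetramer.items()},
        fallback=dict(lib.fallback),
        distant=dict(lib.distant),
        remote=lib.remote,
        scheme=lib.scheme,
    )
    class_keys = sorted({c for (c, _r) in obs.groups})
    report.effective_classes = len([c for c in class_keys if c != _FALLBACK])

    def get_term(cls: str, role: str) -> BondedTerm:
        if cls == _FALLBACK:
            return lib.fallback[role]
        return lib.tetramer[cls][role]

    # instances contributing to each (class, role) group, for cheap
    # group-restricted objectives
    group_insts: dict[tuple[str, str], list[tuple[tuple[str | None, str], ...]]] = {}
    for inst in obs.table.distances + obs.table.angles:  # type: ignore[operator]
        if getattr(inst, "kind", None) == "distant":
            continue
        for cls, role in inst.contexts:
            key = (_FALLBACK if cls is None else cls, role)
            group_insts.setdefault(key, []).append(inst.contexts)

    def implied_for_group(key: tuple[str, str]) -> tuple[float, float]:
        means, varis = [], []
        for contexts in group_insts[key]:
            terms = [
                lib.bonded_term(c, r, allow_fallback=True) for c, r in contexts
            ]
            k2_eff = float(np.mean([t.k2 for t in terms]))
            means.append(float(np.mean([t.x0 for t in terms])))
            varis.append(kbt / (2.0 * k2_eff))
        return float(np.mean(means)), float(np.mean(varis))

    def set_term(cls: str, role: str, t: BondedTerm) -> None:
        if cls == _FALLBACK:
            lib.fallback[role] = t
        else:
            lib.tetramer[cls][role] = t

    if settings.linear_init:
        _linear_precondition(lib, obs, kbt, settings, get_term, set_term)

    # anchors: a tiny Tikhonov pull toward the preconditioned values
    # resolves the gauge freedom of parameters that enter the merit only
    # through averages over shared interactions
    anchors = {key: (get_term(*key).k2, get_term(*key).x0) for key in obs.groups}

    # simulation-backed mode: once per sweep, a short seeded run of the
    # current library measures the true group statistics; the fast
    # harmonic surrogate used inside the optimiser is then corrected by
    # the per-group simulated/harmonic bias factors
    bias: dict[tuple[str, str], tuple[float, float]] = {}

    def refresh_bias() -> None:
        if settings.observable_model != "simulation":
            return
        topology = obs.topology
        if topology is None:
            raise ValueError(
                "simulation-backed refinement needs observables that carry "
                "their topology"
            )
        dyn = DynamicsSettings(
            n_steps=settings.sim_steps,
            temperature=settings.temperature,
            seed=settings.seed,
            save_stride=settings.sim_stride,
        )
        traj = run_simulation(ForceField(topology, lib), settings=dyn)
        start = max(1, traj.n_frames // 4)
        sub = TrajectoryEnsemble(
            frames=traj.frames[start:], times=traj.times[:1], topology=topology
        )
        sim_obs = extract_observables(sub, topology, scheme=obs.table.scheme)
        for key in obs.groups:
            hm, hv = implied_for_group(key)
            sm, sv, _n = sim_obs.groups[key]
            # clamp against short-run estimation noise
            bm = min(max(sm / hm if hm else 1.0, 0.5), 2.0)
            bv = min(max(sv / hv if hv else 1.0, 0.2), 5.0)
            bias[key] = (bm, bv)

    for sweep in range(settings.max_sweeps):
        refresh_bias()
        max_change = 0.0
        for cls in class_keys:
            roles = [r for (c, r) in obs.groups if c == cls]
            for role in roles:
                current = get_term(cls, role)
                rm, rv, _n = obs.groups[(cls, role)]
                scale_x = abs(current.x0) if current.x0 else 1.0
                scale_k = current.k2

                def objective(p: np.ndarray) -> float:
                    x0 = p[0] * scale_x
                    k2 = p[1] * scale_k
                    if k2 <= 0 or k2 > settings.k2_cap:
                        return 1e6 + abs(k2)
                    set_term(
                        cls,
                        role,
                        BondedTerm(
                            k2=k2,
                            k3=current.k3,
                            k4=max(_K4_FRACTION * k2, 1e-12),
                            x0=x0,
                        ),
                    )
                    im, iv = implied_for_group((cls, role))
                    if bias:
                        bm, bv = bias[(cls, role)]
                        im, iv = im * bm, iv * bv
                    merit = ((im - rm) / rm) ** 2 + ((iv - rv) / rv) ** 2
                    ak2, ax0 = anchors[(cls, role)]
                    merit += settings.anchor_weight * (
                        ((k2 - ak2) / ak2) ** 2
                        + ((x0 - ax0) / (abs(ax0) or 1.0)) ** 2
                    )
                    return merit

                p0 = np.array([1.0, 1.0])
                try:
                    res = minimize(
                        objective,
                        p0,
                        method="COBYLA",
                        tol=1e-7,
                        options={
                            "maxiter": settings.cobyla_maxiter,
                            "rhobeg": 0.1,
                        },
                        constraints=[
                            {"type": "ineq", "fun": lambda p: p[1] * scale_k - 1e-6},
                            {
                                "type": "ineq",
                                "fun": lambda p: settings.k2_cap - p[1] * scale_k,
                            },
                        ],
                    )
                    best = res.x
                except Exception:  # pragma: no cover - optimizer failure path
                    report.failed_classes.append(f"{cls}:{role}")
                    set_term(cls, role, current)
                    continue
                omega = settings.relaxation
                k2_new = current.k2 + omega * (best[1] * scale_k - current.k2)
                x0_new = current.x0 + omega * (best[0] * scale_x - current.x0)
                new = BondedTerm(
                    k2=float(np.clip(k2_new, 1e-6, settings.k2_cap)),
                    k3=current.k3,
                    k4=max(_K4_FRACTION * float(k2_new), 1e-12),
                    x0=float(x0_new),
                )
                set_term(cls, role, new)
                change = max(
                    abs(new.k2 - current.k2) / max(current.k2, 1e-12),
                    abs(new.x0 - current.x0) / max(abs(current.x0), 1e-12),
                )
                max_change = max(max_change, change)
        implied = _implied_group_stats(obs, lib, kbt)
        if bias:
            implied = {
                k: (m * bias[k][0], v * bias[k][1]) for k, (m, v) in implied.items()
            }
        merit = _group_merit(implied, obs)
        report.max_change_trace.append(max_change)
        report.merit_trace.append(merit)
        report.sweeps = sweep + 1
        logger.info("sweep %d: max change %.3g merit %.3g", sweep + 1, max_change, merit)
        if max_change < settings.tolerance:
            report.converged = True
            break
    return lib, report


# ---------------------------------------------------------------------------
# distant-term refinement


@dataclass
class AnnealSettings:
    """Metropolis ladder + conjugate-gradient polish for the distant terms."""

    target_mean: float = 0.0
    target_var: float = 0.0
    n_temps: int = 4
    moves_per_temp: int = 4
    t_start: float = 0.05
    t_peak: float = 0.4
    step_x0: float = 0.2  # Å proposal SD
    step_logk2: float = 0.2  # proposal SD in log K2
    sim_steps: int = 20000
    sim_stride: int = 50
    equil_fraction: float = 0.25
    seed: int = 7
    cg_maxiter: int = 0  # 0 skips the gradient polish
    temperature: float = 300.0


def _simulated_ete(
    lib: ParameterLibrary,
    topology: BeadTopology,
    settings: AnnealSettings,
    seed: int,
) -> tuple[float, float]:
    dyn = DynamicsSettings(
        n_steps=settings.sim_steps,
        temperature=settings.temperature,
        seed=seed,
        save_stride=settings.sim_stride,
    )
    ff = ForceField(topology, lib)
    traj = run_simulation(ff, settings=dyn)
    from .analysis import end_to_end

    start = int(len(traj.frames) * settings.equil_fraction)
    sub = TrajectoryEnsemble(
        frames=traj.frames[start:], times=traj.times[start:], topology=topology
    )
    return end_to_end(sub)


def refine_distant(
    lib: ParameterLibrary,
    topology: BeadTopology,
    settings: AnnealSettings,
) -> tuple[ParameterLibrary, FitReport]:
    """Metropolis annealing of the distant fan terms against end-to-end
    targets, with an optional conjugate-gradient polish.

    The merit is the sum of squared relative errors of the simulated
    end-to-end mean and variance of the given duplex (a 40-mer in the
    standard protocol) versus the targets.  The effective-temperature
    ladder rises from ``t_start`` to ``t_peak`` and descends again; the
    best parameter set seen anywhere is kept and polished.
    """
    report = FitReport()
    rng = np.random.Generator(np.random.PCG64(settings.seed))
    offsets = sorted(lib.distant)

    def make_lib(vec: np.ndarray) -> ParameterLibrary:
        distant = {}
        for idx, off in enumerate(offsets):
            base = lib.distant[off]
            distant[off] = BondedTerm(
                k2=float(np.exp(vec[2 * idx])),
                k3=base.k3,
                k4=max(_K4_FRACTION * float(np.exp(vec[2 * idx])), 1e-12),
                x0=float(vec[2 * idx + 1]),
            )
        return ParameterLibrary(
            tetramer=lib.tetramer,
            fallback=lib.fallback,
            distant=distant,
            remote=lib.remote,
            scheme=lib.scheme,
        )

    def merit(vec: np.ndarray) -> float:
        cand = make_lib(vec)
        m, s = _simulated_ete(cand, topology, settings, seed=settings.seed)
        v = s * s
        tm, tv = settings.target_mean, settings.target_var
        out = ((m - tm) / tm) ** 2 if tm else 0.0
        if tv:
            out += ((v - tv) / tv) ** 2
        return out

    vec = np.array(
        [
            val
            for off in offsets
            for val in (math.log(lib.distant[off].k2), lib.distant[off].x0)
        ]
    )
    current = vec.copy()
    current_merit = merit(current)
    best, best_merit = current.copy(), current_merit
    report.merit_trace.append(best_merit)

    ladder = list(
        np.linspace(settings.t_start, settings.t_peak, settings.n_temps)
    ) + list(np.linspace(settings.t_peak, settings.t_start, settings.n_temps))
    for eff_t in ladder:
        for _ in range(settings.moves_per_temp):
            prop = current.copy()
            idx = rng.integers(len(prop))
            prop[idx] += rng.normal(
                0.0, settings.step_logk2 if idx % 2 == 0 else settings.step_x0
            )
            prop_merit = merit(prop)
            if prop_merit < current_merit or rng.random() < math.exp(
                (current_merit - prop_merit) / max(eff_t, 1e-9)
            ):
                current, current_merit = prop, prop_merit
                if current_merit < best_merit:
                    best, best_merit = current.copy(), current_merit
            report.merit_trace.append(best_merit)

    if settings.cg_maxiter:
        res = minimize(
            merit,
            best,
            method="CG",
            options={"maxiter": settings.cg_maxiter, "eps": 1e-2},
        )
        if res.fun < best_merit:
            best, best_merit = res.x, float(res.fun)
        report.merit_trace.append(best_merit)

    if best_merit >= report.merit_trace[0] > 1e-12:
        report.notes.append(
            "merit did not improve over the ladder; returning best-so-far"
        )
        logger.warning("distant refinement: merit did not improve")
    report.converged = True
    report.sweeps = len(ladder)
    return make_lib(best), report


# ---------------------------------------------------------------------------
# convenience pipeline


def fit_from_reference(
    ensemble: TrajectoryEnsemble,
    topology: BeadTopology,
    temperature: float = 300.0,
    scheme: str = "eq5",
    refine: RefineSettings | None = None,
    remote: RemoteSettings | None = None,
) -> tuple[ParameterLibrary, FitReport]:
    """extract -> baseline -> tetramer refinement in one call."""
    obs = extract_observables(ensemble, topology, scheme)
    lib = fit_baseline(obs, temperature, remote=remote)
    settings = refine or RefineSettings(temperature=temperature)
    return refine_tetramers(lib, obs, settings)
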