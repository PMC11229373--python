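"""Langevin dynamics engine.

Velocity-Verlet integration with a Langevin bath, using the BAOAB splitting
(kick / drift / Ornstein-Uhlenbeck / drift / kick), which gives accurate
configurational averages at the 0.1 ps default timestep.  Gaussian bath
deviates are produced by a Box-Muller transformation of the seeded uniform
stream, so a run is bit-reproducible from its settings and seed.

Units: Å, ps, kcal/mol, Da.  Forces in kcal/mol/Å convert to accelerations
in Å/ps² through the factor 418.4 (see :mod:`cgdna.constants`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import KB, KCAL_TO_DA_A2_PS2
from .forcefield import ForceField
from .topology import BeadTopology

__all__ = [
    "DynamicsSettings",
    "SimulationState",
    "TrajectoryEnsemble",
    "SimulationDiverged",
    "BoxMullerStream",
    "initialize_velocities",
    "langevin_step",
    "run_simulation",
    "kinetic_temperature",
]

logger = logging.getLogger("cgdna.dynamics")


class SimulationDiverged(RuntimeError):
    """Raised when a non-finite coordinate, velocity or force appears."""

    def __init__(self, step: int, detail: str = "") -> None:
        self.step = step
        super().__init__(f"simulation diverged at step {step}: {detail}")


@dataclass
class DynamicsSettings:
    """Integrator settings.

    ``dt`` in ps (default 0.1), ``temperature`` in K, ``friction`` (Langevin
    collision rate) in 1/ps.  ``save_stride`` counts integration steps
    between saved frames; ``log_interval`` (steps) controls energy-channel
    logging, 0 disables it.
    """

    n_steps: int
    dt: float = 0.1
    temperature: float = 300.0
    friction: float = 1.0
    seed: int = 0
    save_stride: int = 100
    log_interval: int = 0
    check_interval: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


class BoxMullerStream:
    """Standard-normal deviates via Box-Muller from a seeded uniform stream."""

    def __init__(self, seed: int) -> None:
        self.rng = np.random.Generator(np.random.PCG64(seed))

    def normals(self, shape: tuple[int, ...]) -> np.ndarray:
        n = int(np.prod(shape))
        m = (n + 1) // 2
        # u1 in (0, 1]: 1 - random() avoids log(0)
        u1 = 1.0 - self.rng.random(m)
        u2 = self.rng.random(m)
        radius = np.sqrt(-2.0 * np.log(u1))
        z = np.concatenate([radius * np.cos(2 * np.pi * u2),
                            radius * np.sin(2 * np.pi * u2)])[:n]
        return z.reshape(shape)


@dataclass
class SimulationState:
    """Mutable integrator state."""

    coords: np.ndarray  # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/ps
    masses: np.ndarray  # (n,) Da
    step: int = 0
    forces: Optional[np.ndarray] = None  # cached, kcal/mol/Å


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of bead coordinates with time and provenance metadata."""

    frames: np.ndarray  # (n_frames, n_beads, 3) Å
    times: np.ndarray  # (n_frames,) ps
    topology: Optional[BeadTopology] = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def __iter__(self):
        return iter(self.frames)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature, K (3N degrees of freedom)."""
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2)) / KCAL_TO_DA_A2_PS2
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * KB)


def initialize_velocities(
    masses: np.ndarray, temperature: float, seed: int | BoxMullerStream
) -> np.ndarray:
    """Maxwell-Boltzmann start: Gaussian per component with variance
    k_B T / m, centre-of-mass velocity removed."""
    stream = seed if isinstance(seed, BoxMullerStream) else BoxMullerStream(seed)
    n = len(masses)
    if temperature == 0:
        return np.zeros((n, 3))
    sigma = np.sqrt(KB * temperature * KCAL_TO_DA_A2_PS2 / masses)
    v = stream.normals((n, 3)) * sigma[:, None]
    v -= np.average(v, axis=0, weights=masses)
    return v


def langevin_step(
    state: SimulationState,
    ff: ForceField,
    settings: DynamicsSettings,
    stream: BoxMullerStream,
):
    """One BAOAB update in place; returns the energy breakdown at the new
    positions.

    B: half kick; A: half drift; O: exact Ornstein-Uhlenbeck velocity update
    with the fluctuation-dissipation noise amplitude; A: half drift; B: half
    kick with freshly evaluated forces (cached for the next step).
    """
    dt = settings.dt
    m = state.masses[:, None]
    inv_m = KCAL_TO_DA_A2_PS2 / m
    if state.forces is None:
        state.forces, _ = ff.energy_forces(state.coords)
    # B
    state.velocities += 0.5 * dt * state.forces * inv_m
    # A
    state.coords += 0.5 * dt * state.velocities
    # O
    gamma = settings.friction
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
        sigma_v = np.sqrt(KB * settings.temperature * KCAL_TO_DA_A2_PS2 / state.masses)
        state.velocities *= c1
        if settings.temperature > 0:
            state.velocities += c2 * sigma_v[:, None] * stream.normals(
                state.velocities.shape
            )
    # A
    state.coords += 0.5 * dt * state.velocities
    # B
    forces, eb = ff.energy_forces(state.coords)
    state.velocities += 0.5 * dt * forces * inv_m
    state.forces = forces
    state.step += 1
    return eb


def run_simulation(
    topology_or_ff: BeadTopology | ForceField,
    library=None,
    settings: DynamicsSettings | None = None,
    coords0: np.ndarray | None = None,
    velocities0: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Run a Langevin trajectory.

    Accepts either a prebuilt :class:`ForceField` or a topology plus a
    parameter library.  When ``coords0`` is omitted an ideal helical build
    of the topology's sequence is used.  The returned ensemble carries the
    saved frames (frame 0 is the initial conformation), time stamps, the
    mean kinetic temperature over the run, and full RNG provenance.

    Raises :class:`SimulationDiverged` (with the step index and the worst
    offending bead) if a non-finite coordinate or force appears.
    """
    if settings is None:
        raise TypeError("settings is required")
    if isinstance(topology_or_ff, ForceField):
        ff = topology_or_ff
        topology = ff.topology
    else:
        topology = topology_or_ff
        ff = ForceField(topology, library)
    if coords0 is None:
        from .synthetic import HelixSpec, ideal_bdna_beads, build_minicircle, CircularBuildSpec

        if topology.circular:
            coords0 = build_minicircle(
                topology.sequence, CircularBuildSpec(n_bp=topology.n_bp), HelixSpec()
            )
        else:
            coords0 = ideal_bdna_beads(topology.sequence, HelixSpec())
    coords0 = np.array(coords0, dtype=float)

    stream = BoxMullerStream(settings.seed)
    if velocities0 is None:
        velocities0 = initialize_velocities(
            topology.masses, settings.temperature, stream
        )
    state = SimulationState(
        coords=coords0.copy(),
        velocities=np.array(velocities0, dtype=float),
        masses=topology.masses,
    )

    n_saved = settings.n_steps // settings.save_stride + 1
    frames = np.empty((n_saved, topology.n_beads, 3))
    times = np.empty(n_saved)
    frames[0] = state.coords
    times[0] = 0.0
    saved = 1
    kin_sum = 0.0
    kin_n = 0

    for step in range(settings.n_steps):
        eb = langevin_step(state, ff, settings, stream)
        if (step + 1) % settings.check_interval == 0 or (
            step + 1
        ) % settings.save_stride == 0:
            if not np.all(np.isfinite(state.coords)) or not np.all(
                np.isfinite(state.forces)
            ):
                bad = np.where(~np.isfinite(state.coords).all(axis=1))[0]
                fmax = (
                    float(np.nanmax(np.abs(state.forces)))
                    if state.forces is not None
                    else float("nan")
                )
                raise SimulationDiverged(
                    step + 1,
                    f"non-finite state (beads {bad[:5].tolist()}, max|F|={fmax:.3g})",
                )
        if (step + 1) % settings.save_stride == 0:
            frames[saved] = state.coords
            times[saved] = (step + 1) * settings.dt
            saved += 1
            kin_sum += kinetic_temperature(state.velocities, state.masses)
            kin_n += 1
        if settings.log_interval and (step + 1) % settings.log_interval == 0:
            logger.info(
                "step %d t=%.1f ps E=%.3f kcal/mol %s T_kin=%.1f K",
                step + 1,
                (step + 1) * settings.dt,
                eb.total,
                {k: round(v, 3) for k, v in eb.as_dict().items() if k != "total"},
                kinetic_temperature(state.velocities, state.masses),
            )

    provenance = {
        "engine": "cgdna BAOAB Langevin",
        "dt_ps": settings.dt,
        "temperature_K": settings.temperature,
        "friction_per_ps": settings.friction,
        "seed": settings.seed,
        "n_steps": settings.n_steps,
        "save_stride": settings.save_stride,
        "scheme": ff.scheme,
        "mean_kinetic_temperature_K": kin_sum / kin_n if kin_n else None,
    }
    return TrajectoryEnsemble(
        frames=frames[:saved], times=times[:saved], topology=topology,
        provenance=provenance,
    )
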