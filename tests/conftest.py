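"""Shared fixtures: sequences, synthetic references, fitted libraries."""

from __future__ import annotations

import numpy as np
import pytest

from cgdna.dynamics import TrajectoryEnsemble
from cgdna.fitting import extract_observables, fit_baseline, refine_tetramers
from cgdna.forcefield import BondedTerm, EnergyBreakdown, ForceField, ParameterLibrary
from cgdna.synthetic import FluctuationSpec, synth_ensemble
from cgdna.topology import DuplexSequence, build_duplex_topology

#: the Dickerson-Drew dodecamer motif extended to 18 bp; the standard
#: duplex used across the fitting and dynamics tests
SEQ18 = "CGCGAATTCGCGAATTCG"


@pytest.fixture(scope="session")
def seq18() -> DuplexSequence:
    return DuplexSequence(SEQ18)


@pytest.fixture(scope="session")
def topo18(seq18):
    return build_duplex_topology(seq18)


@pytest.fixture(scope="session")
def reference_18(seq18):
    """Synthetic fluctuating reference for the 18-mer (default conditions)."""
    return synth_ensemble(seq18, fluct=FluctuationSpec(seed=0), n_frames=400)


@pytest.fixture(scope="session")
def fitted_library(reference_18, topo18):
    """Bonded parameters fitted to the synthetic 18-mer reference."""
    obs = extract_observables(reference_18, topo18)
    lib, report = refine_tetramers(fit_baseline(obs), obs)
    assert report.converged
    return lib


@pytest.fixture
def uniform_library():
    """Small hand-set sequence-independent library (test probe, not fitted)."""
    return ParameterLibrary.uniform(
        stacking=BondedTerm(3.0, -0.3, 0.3, 6.32),
        pairing=BondedTerm(3.0, 0.2, 0.2, 18.0),
        angle=BondedTerm(5.0, 0.0, 0.5, 2.56),
        fan={o: BondedTerm(1.0, 0.0, 0.1, 12.0) for o in (-2, -1, 1, 2)},
        distant={o: BondedTerm(0.5, 0.0, 0.05, 15.0) for o in (-5, -4, -3, 3, 4, 5)},
    )


class HarmonicDimer:
    """Minimal two-bead harmonic force field (engine statistical oracle)."""

    def __init__(self, k2: float, l0: float):
        self.k2 = k2
        self.l0 = l0
        self.n_beads = 2
        self.scheme = "dimer"

    def energy_forces(self, x):
        d = x[1] - x[0]
        r = float(np.linalg.norm(d))
        dl = r - self.l0
        u = d / r
        f = np.empty((2, 3))
        f[0] = 2.0 * self.k2 * dl * u
        f[1] = -f[0]
        return f, EnergyBreakdown(stacking=self.k2 * dl * dl)


@pytest.fixture
def harmonic_dimer_cls():
    return HarmonicDimer


def ensemble_from(frames, topology=None) -> TrajectoryEnsemble:
    frames = np.asarray(frames, dtype=float)
    return TrajectoryEnsemble(
        frames=frames, times=np.arange(len(frames), dtype=float), topology=topology
    )


@pytest.fixture
def make_ensemble():
    return ensemble_from
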