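"""Shared fixtures: boxes, Poisson slabs, and one expensive MC run reused by
the dilute-limit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from pairpot.coords import BoxGeometry
from pairpot.rdf import PotentialCurve, average_rdfs, compute_rdf, pmf_from_rdf
from pairpot.simulate import PotentialSpec, SimulationConfig, run_mc, sample_poisson

SLAB_EXTENTS = (800.0, 800.0, 100.0)

YUKAWA_SIGMA = 7.0
YUKAWA_BETA_EPS = 2.0
YUKAWA_KAPPA = 0.5
YUKAWA_RHO_SIGMA3 = 0.005


@pytest.fixture(scope="session")
def slab_box() -> BoxGeometry:
    return BoxGeometry((0.0, 0.0, 0.0), SLAB_EXTENTS)


@pytest.fixture(scope="session")
def poisson_slab(slab_box):
    """One canonical uniform slab, N = 5000."""
    return sample_poisson(slab_box, n=5000, seed=11)


def make_yukawa_potential() -> PotentialSpec:
    return PotentialSpec(
        "yukawa", sigma=YUKAWA_SIGMA, epsilon=YUKAWA_BETA_EPS, kappa=YUKAWA_KAPPA
    )


def true_potential_curve(r_max: float = 30.0) -> PotentialCurve:
    pot = make_yukawa_potential()
    r = np.linspace(1e-3, r_max, 6001)
    u = pot.beta_u(r)
    return PotentialCurve(
        r, np.where(np.isfinite(u), u, np.nan), np.isfinite(u), kind="PIP"
    )


@pytest.fixture(scope="session")
def yukawa_run():
    """Dilute Yukawa MC at rho*sigma^3 = 0.005: 50 frames plus derived g/W.

    This is the workhorse ground-truth dataset for the dilute-limit,
    KBI-agreement and S(0) consistency tests; it takes ~1 min including the
    numba warm-up, hence session scope.
    """
    pot = make_yukawa_potential()
    rho = YUKAWA_RHO_SIGMA3 / YUKAWA_SIGMA**3
    n = 16000
    side = (n / rho) ** (1.0 / 3.0)
    box = BoxGeometry((0.0, 0.0, 0.0), (side, side, side), (True, True, True))
    cfg = SimulationConfig(
        potential=pot,
        box=box,
        n_particles=n,
        n_sweeps_equil=300,
        n_sweeps_sample=500,
        sample_every=10,
        seed=7,
    )
    frames, info = run_mc(cfg)
    rdf = average_rdfs([compute_rdf(f) for f in frames])
    pmf = pmf_from_rdf(rdf)
    return {
        "potential": pot,
        "rho": rho,
        "box": box,
        "frames": frames,
        "info": info,
        "rdf": rdf,
        "pmf": pmf,
        "true_curve": true_potential_curve(),
    }
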