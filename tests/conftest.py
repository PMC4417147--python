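"""Shared fixtures: small chain models, a seeded synthetic instance, and the
desk-scale inference configuration used by the slower end-to-end tests."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from chromens import (
    Conformation,
    EnergyParams,
    InferenceConfig,
    RestraintSet,
    SegmentModel,
    SyntheticSpec,
    generate_truth,
    simulate_frequencies,
)


@pytest.fixture(scope="session")
def eparams():
    return EnergyParams()


@pytest.fixture(scope="session")
def unit_model(eparams):
    """10 segments of 3900 bp each: every rest length is exactly 1.0."""
    spans = np.column_stack([np.arange(10) * 3900, np.arange(1, 11) * 3900])
    return SegmentModel.from_spans("chrT", spans, eparams)


@pytest.fixture()
def straight_conformation(unit_model):
    """The unit-rest chain laid out straight along x (zero stretch/bend)."""
    n = unit_model.n
    coords = np.zeros((n + 1, 3))
    coords[:, 0] = np.arange(n + 1, dtype=float)
    return Conformation(coords)


def random_chain(n_points: int, seed: int, scale: float = 1.0) -> Conformation:
    """A random open chain with ~unit steps (no exact coincidences)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, scale, (n_points - 1, 3))
    steps += 0.3 * np.sign(steps)  # keep bonds away from zero length
    return Conformation(np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)]))


@pytest.fixture(scope="session")
def default_fixture(eparams):
    """The default synthetic instance: 20 fragments, alpha*=0.5,
    sigma*=0.1, 5 ground-truth conformations, seed 42."""
    spec = SyntheticSpec()
    model, truths = generate_truth(spec, eparams)
    fm = simulate_frequencies(model, truths, spec)
    return spec, model, truths, fm


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale inference configuration for the flagship fixture run."""
    return InferenceConfig(k=20, seed=42, brownian_steps=5000,
                           ascent_max_steps=6000)


def self_consistent_restraints(model, conf, alpha=1.0, beta=1.0,
                               pairs="all") -> RestraintSet:
    """Restraints whose frequencies invert exactly to the midpoint distances
    of ``conf`` at the given conversion parameters."""
    mids = conf.segment_midpoints()
    iu, ju = np.triu_indices(model.n, k=1)
    if pairs == "adjacent":
        keep = ju - iu == 1
        iu, ju = iu[keep], ju[keep]
    d = np.linalg.norm(mids[iu] - mids[ju], axis=-1)
    freqs = (d / beta) ** (-1.0 / alpha)
    return RestraintSet(iu, ju, freqs, d, beta=beta, alpha=alpha)
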