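"""Self-contained synthetic test instances with the statistical structure the
inference assumes.

A ground-truth *ensemble* of conformations (not a single structure) is drawn
by Brownian simulation, mirroring the population averaging inherent in
3C-based measurements over many cells.  Pairwise fragment-midpoint distances
are averaged over the truth ensemble, perturbed with Gaussian noise in
distance space (the noise model of the likelihood), and inverted through the
power law F = (D/β)^(−1/α) to produce an interaction-frequency matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .polymer_model import Conformation, EnergyParams, SegmentModel
from .restraints import FrequencyMatrix, write_frequency_matrix, write_structure
from .inference import InferenceConfig, brownian_initialize

__all__ = [
    "SyntheticSpec",
    "generate_truth",
    "simulate_frequencies",
    "make_fixture",
]

# Equilibration length for the truth-ensemble Brownian runs: at the chain
# sizes generated here (tens of segments) this decorrelates the chain from
# its straight-walk start while keeping fixture generation cheap.
TRUTH_BROWNIAN_STEPS = 20_000

MANIFEST_FILENAME = "manifest.json"
FRAGMENTS_FILENAME = "fragments.tsv"
FREQUENCIES_FILENAME = "frequencies.tsv"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic instance.

    Fragment lengths are drawn log-uniform over [min_fragment_bp,
    max_fragment_bp] (yeast restriction fragments span roughly 1–40 kb)
    unless ``fragment_bp`` pins them explicitly.  ``beta=None`` calibrates
    the conversion scale to the mean adjacent-pair distance of the truth
    ensemble, which centres adjacent frequencies near 1.  ``noise_sigma``
    is the Gaussian noise on ensemble-mean distances, in reduced length
    units (1 unit = 30 nm).
    """

    n_segments: int = 20
    min_fragment_bp: int = 1_000
    max_fragment_bp: int = 40_000
    fragment_bp: tuple | None = None
    alpha: float = 0.5
    beta: float | None = None
    noise_sigma: float = 0.1
    k_truth: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if self.alpha <= 0 or self.noise_sigma < 0 or self.k_truth < 1:
            raise ValueError("alpha > 0, noise_sigma >= 0, k_truth >= 1 "
                             "required")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive when given")


def generate_truth(spec: SyntheticSpec,
                   eparams: EnergyParams | None = None):
    """Ground-truth chain model and conformations, reproducible from the seed.

    Returns (SegmentModel, list of k_truth Conformations).
    """
    eparams = eparams or EnergyParams()
    rng = np.random.default_rng(spec.seed)
    if spec.fragment_bp is not None:
        bp = np.asarray(spec.fragment_bp, dtype=np.int64)
        if len(bp) != spec.n_segments:
            raise ValueError("fragment_bp length must equal n_segments")
    else:
        logs = rng.uniform(np.log(spec.min_fragment_bp),
                           np.log(spec.max_fragment_bp), spec.n_segments)
        bp = np.round(np.exp(logs)).astype(np.int64)
    edges = np.concatenate([[0], np.cumsum(bp)])
    spans = np.column_stack([edges[:-1], edges[1:]])
    model = SegmentModel.from_spans("chrS", spans, eparams)

    cfg = InferenceConfig(k=spec.k_truth, seed=spec.seed,
                          brownian_steps=TRUTH_BROWNIAN_STEPS)
    truths = brownian_initialize(model, eparams, cfg, rng=rng)
    return model, truths


def simulate_frequencies(model: SegmentModel, truths: list,
                         spec: SyntheticSpec) -> FrequencyMatrix:
    """Invert ensemble-mean distances through the power law into frequencies.

    For every fragment pair, the mean midpoint distance over the truth
    conformations is perturbed with N(0, noise_sigma) noise (truncated below
    at 5% of the mean so distances stay positive) and converted to
    F = (D'/β)^(−1/α).
    """
    if not truths:
        raise ValueError("need at least one truth conformation")
    n = model.n
    mean_d = np.zeros((n, n))
    for conf in truths:
        mids = conf.segment_midpoints()
        diff = mids[:, None, :] - mids[None, :, :]
        mean_d += np.linalg.norm(diff, axis=-1)
    mean_d /= len(truths)

    beta = spec.beta
    if beta is None:
        adj = np.array([mean_d[i, i + 1] for i in range(n - 1)])
        beta = float(np.mean(adj))

    rng = np.random.default_rng([spec.seed, 1])  # independent noise stream
    iu, ju = np.triu_indices(n, k=1)
    d_bar = mean_d[iu, ju]
    noisy = d_bar + rng.normal(0.0, spec.noise_sigma, size=d_bar.shape)
    noisy = np.maximum(noisy, 0.05 * d_bar)
    freqs = (noisy / beta) ** (-1.0 / spec.alpha)

    values = np.zeros((n, n))
    values[iu, ju] = freqs
    values[ju, iu] = freqs
    labels = tuple(f"frag{i + 1}" for i in range(n))
    return FrequencyMatrix(values=values, labels=labels)


def effective_beta(model: SegmentModel, truths: list,
                   spec: SyntheticSpec) -> float:
    """The conversion scale actually used by :func:`simulate_frequencies`."""
    if spec.beta is not None:
        return spec.beta
    mean_d = np.zeros(model.n - 1)
    for conf in truths:
        mids = conf.segment_midpoints()
        mean_d += np.linalg.norm(mids[1:] - mids[:-1], axis=-1)
    mean_d /= len(truths)
    return float(np.mean(mean_d))


def make_fixture(spec: SyntheticSpec, out_dir,
                 eparams: EnergyParams | None = None) -> dict:
    """Write a complete test instance to ``out_dir``.

    Emits the fragment table, the square frequency matrix, one XYZ file per
    truth conformation and a manifest recording the generating parameters,
    so recovery can be scored later.  Regeneration from the same spec is
    byte-identical.  Returns the manifest dict.
    """
    eparams = eparams or EnergyParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model, truths = generate_truth(spec, eparams)
    fm = simulate_frequencies(model, truths, spec)
    beta = effective_beta(model, truths, spec)

    with open(out / FRAGMENTS_FILENAME, "w") as fh:
        for start, end in model.spans:
            fh.write(f"{model.chrom}\t{start}\t{end}\n")
    write_frequency_matrix(fm, out / FREQUENCIES_FILENAME)
    for i, conf in enumerate(truths):
        write_structure(conf, model, eparams, out / f"truth_{i:03d}.xyz",
                        format="xyz")

    manifest = {
        "n_segments": spec.n_segments,
        "alpha": spec.alpha,
        "beta": beta,
        "noise_sigma": spec.noise_sigma,
        "k_truth": spec.k_truth,
        "seed": spec.seed,
        "fragments": FRAGMENTS_FILENAME,
        "frequencies": FREQUENCIES_FILENAME,
        "truth_structures": [f"truth_{i:03d}.xyz" for i in range(len(truths))],
    }
    with open(out / MANIFEST_FILENAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
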