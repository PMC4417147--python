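"""Model assessment and structure-ensemble analysis: k-fold cross-validation
of the distance restraints, Kabsch (SVD) superposition, ensemble-expected
locus-pair distances, close-contact counting and the spatial-vs-sequential
distance trend curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

from .bayes import EnsembleState, back_compute_distances
from .polymer_model import (
    ChromensError,
    Conformation,
    EnergyParams,
    SegmentModel,
)
from .restraints import (
    ConversionParams,
    FrequencyMatrix,
    RestraintSet,
    build_segment_model,
    convert_frequencies,
)
from .inference import InferenceConfig, run_em_on_restraints

__all__ = [
    "CVReport",
    "pearson_correlation",
    "kfold_split",
    "cross_validate",
    "kabsch_align",
    "align_ensemble",
    "expected_distance",
    "contact_pairs",
    "fit_distance_curve",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ChromensError):
    """Correlation requested for a zero-variance vector."""


@dataclass
class CVReport:
    """Result of k-fold cross-validation over the restraint set."""

    fold_assignments: np.ndarray        # (m,) fold index per restraint
    fold_correlations: list             # per-fold test correlation
    predicted: np.ndarray               # pooled predicted distances
    expected: np.ndarray                # pooled expected (target) distances
    pooled_correlation: float
    fold_alphas: list = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_correlations)


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D vectors of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a "
                                        "zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def kfold_split(restraints: RestraintSet, folds: int,
                seed: int) -> np.ndarray:
    """Seeded random partition of the restraint records into k folds.

    Fold sizes differ by at most one.  Returns the fold index of every
    record.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > restraints.m:
        raise ValueError(f"cannot split {restraints.m} restraints into "
                         f"{folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(restraints.m)
    assignment = np.empty(restraints.m, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = fold
    return assignment


def cross_validate(fm: FrequencyMatrix, fragment_table,
                   config: InferenceConfig | None = None,
                   folds: int = 10,
                   eparams: EnergyParams | None = None) -> CVReport:
    """k-fold cross-validation of the inference pipeline.

    For each fold the EM is run on the training restraints only; the test
    restraints are then scored by comparing the ensemble-weighted mean
    back-computed distance against the target distance converted at the
    fold's fitted α (and the fold's training-calibrated β) — the fit of the
    test fold never informs the model that predicts it.
    """
    cfg = config or InferenceConfig()
    eparams = eparams or EnergyParams()
    if isinstance(fragment_table, SegmentModel):
        model = fragment_table
    else:
        model = build_segment_model(fragment_table, eparams)

    rng = np.random.default_rng(cfg.seed)
    # the full record list; targets here are provisional (alpha is re-fit
    # per fold), only the pair/frequency structure matters
    full = convert_frequencies(
        fm, ConversionParams(alpha=1.0, beta=1.0, min_freq=cfg.min_freq))
    assignment = kfold_split(full, folds, seed=int(rng.integers(2**31)))

    predicted_all = np.empty(full.m)
    expected_all = np.empty(full.m)
    fold_corrs = []
    fold_alphas = []
    for fold in range(folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        train = full.subset(train_idx)
        ensemble, nuisance, trace = run_em_on_restraints(
            model, train, eparams, cfg, rng=rng)
        # test targets use the alpha fitted on (and the beta calibrated
        # from) the training folds only, so nothing leaks from the test set
        beta = trace.beta
        test = RestraintSet(full.idx_i[test_idx], full.idx_j[test_idx],
                            full.freqs[test_idx],
                            beta * full.freqs[test_idx] ** (-nuisance.alpha),
                            beta=beta, alpha=nuisance.alpha)
        w = ensemble.weights
        pred = np.zeros(test.m)
        for i, conf in enumerate(ensemble.conformations):
            pred += w[i] * back_compute_distances(conf, model, test)
        expect = test.targets_d
        predicted_all[test_idx] = pred
        expected_all[test_idx] = expect
        fold_corrs.append(pearson_correlation(pred, expect))
        fold_alphas.append(nuisance.alpha)
        logger.info("fold %d/%d: test correlation %.4f (alpha=%.3f)",
                    fold + 1, folds, fold_corrs[-1], nuisance.alpha)

    pooled = pearson_correlation(predicted_all, expected_all)
    return CVReport(fold_assignments=assignment,
                    fold_correlations=fold_corrs,
                    predicted=predicted_all,
                    expected=expected_all,
                    pooled_correlation=pooled,
                    fold_alphas=fold_alphas)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_align(ref: Conformation, mobile: Conformation):
    """Optimal rigid superposition of ``mobile`` onto ``ref`` (Kabsch/SVD).

    Returns (aligned conformation, RMSD).  The rotation is proper (any
    reflection is corrected by the sign of the determinant inside the SVD
    solver), so chirality is preserved.
    """
    a = ref.coords
    b = mobile.coords
    if a.shape != b.shape:
        raise ValueError("point counts differ between conformations")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a_c, b_c)
    aligned = rot.apply(b_c) + a.mean(axis=0)
    # RMSD from the superposed coordinates directly (scipy's rssd loses
    # precision to cancellation for near-exact matches)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - a) ** 2, axis=1))))
    return Conformation(aligned), rmsd


def align_ensemble(ensemble: EnsembleState) -> EnsembleState:
    """Align every member onto the highest-weight member.

    Member order is preserved and the reference member is returned
    unchanged; weight ties break toward the lower member index.
    """
    weights = ensemble.weights
    ref_idx = int(np.argmax(weights))  # argmax takes the first of any tie
    ref = ensemble.conformations[ref_idx]
    members = []
    for idx, (conf, w) in enumerate(ensemble.members):
        if idx == ref_idx:
            members.append((conf, w))
        else:
            aligned, _ = kabsch_align(ref, conf)
            members.append((aligned, w))
    return EnsembleState(members=members,
                         log_likelihoods=ensemble.log_likelihoods.copy())


# ---------------------------------------------------------------------------
# locus queries
# ---------------------------------------------------------------------------

def _bp_to_point(coords: np.ndarray, model: SegmentModel, bp: float) -> np.ndarray:
    """Map a genomic position to a 3D point by linear interpolation within
    its containing fragment; cut sites map exactly onto chain end points."""
    start = model.spans[0, 0]
    end = model.spans[-1, 1]
    if bp < start or bp > end:
        raise ValueError(f"position {bp} outside modeled span "
                         f"[{start}, {end}]")
    seg = int(np.searchsorted(model.spans[:, 1], bp, side="left"))
    seg = min(seg, model.n - 1)
    s0, s1 = model.spans[seg]
    frac = (bp - s0) / (s1 - s0)
    return (1.0 - frac) * coords[seg] + frac * coords[seg + 1]


def expected_distance(ensemble: EnsembleState, model: SegmentModel,
                      eparams: EnergyParams, bp_a: float, bp_b: float) -> float:
    """Ensemble-expected spatial distance between two genomic positions, nm.

    The expectation is the weight-averaged distance over all conformations.
    """
    total = 0.0
    for conf, w in ensemble.members:
        pa = _bp_to_point(conf.coords, model, bp_a)
        pb = _bp_to_point(conf.coords, model, bp_b)
        total += w * float(np.linalg.norm(pa - pb))
    return total * eparams.length_scale_nm


def contact_pairs(ensemble: EnsembleState, model: SegmentModel,
                  eparams: EnergyParams, min_sep_segments: int = 5,
                  dmin_nm: float = 45.0, dmax_nm: float = 100.0):
    """Fragment pairs in spatial contact despite sequence separation.

    Considers all fragment midpoint pairs at least ``min_sep_segments``
    apart along the chain and returns those whose ensemble-expected distance
    falls within [dmin_nm, dmax_nm], plus the count.
    """
    w = ensemble.weights
    mean_d = np.zeros((model.n, model.n))
    for i, conf in enumerate(ensemble.conformations):
        mids = conf.segment_midpoints()
        diff = mids[:, None, :] - mids[None, :, :]
        mean_d += w[i] * np.linalg.norm(diff, axis=-1)
    mean_d *= eparams.length_scale_nm
    pairs = []
    for i in range(model.n):
        for j in range(i + min_sep_segments, model.n):
            if dmin_nm <= mean_d[i, j] <= dmax_nm:
                pairs.append((i, j, float(mean_d[i, j])))
    return pairs, len(pairs)


def fit_distance_curve(ensemble: EnsembleState, model: SegmentModel,
                       eparams: EnergyParams):
    """Fit the spatial-vs-sequential distance trend d(s) = d_max(1 − e^(−s/s0)).

    ``s`` is the genomic separation (bp) between fragment midpoints and
    ``d`` the ensemble-expected spatial distance (nm) over all fragment
    pairs.  The saturating-exponential family captures the empirically
    observed flattening of spatial distance at large sequence separation.
    Returns (d_max, s0, residual) with residual the root-mean-square fit
    error in nm.
    """
    mid_bp = model.midpoints_bp()
    w = ensemble.weights
    mean_d = np.zeros((model.n, model.n))
    for i, conf in enumerate(ensemble.conformations):
        mids = conf.segment_midpoints()
        diff = mids[:, None, :] - mids[None, :, :]
        mean_d += w[i] * np.linalg.norm(diff, axis=-1)
    mean_d *= eparams.length_scale_nm
    iu, ju = np.triu_indices(model.n, k=1)
    s = np.abs(mid_bp[iu] - mid_bp[ju])
    d = mean_d[iu, ju]
    if len(np.unique(s)) < 3:
        raise ChromensError("need at least 3 distinct sequential separations")

    return fit_saturating_curve(s, d)


def saturating_curve(s, d_max, s0):
    """d(s) = d_max (1 − e^(−s/s0)): rises with genomic separation and
    saturates, reflecting the finite size of the nucleus."""
    return d_max * (1.0 - np.exp(-np.asarray(s, dtype=float) / s0))


def fit_saturating_curve(s, d):
    """Least-squares fit of the saturating curve to (separation, distance)
    pairs; returns (d_max, s0, RMS residual)."""
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    p0 = (float(np.max(d)), float(np.median(s)))
    try:
        popt, _ = optimize.curve_fit(saturating_curve, s, d, p0=p0,
                                     maxfev=20_000,
                                     bounds=([0, 1e-9], [np.inf, np.inf]))
    except RuntimeError as exc:
        raise ChromensError(f"distance-curve fit failed: {exc}") from exc
    resid = float(np.sqrt(np.mean((saturating_curve(s, *popt) - d) ** 2)))
    return float(popt[0]), float(popt[1]), resid
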