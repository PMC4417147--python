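"""Log-posterior of a conformation given distance restraints, its gradient,
and the ensemble weighting machinery.

The posterior combines a Boltzmann prior on the conformational energy,
Pr(S) ∝ exp(−E_s/kBT), with an independent Gaussian likelihood on each
restraint, Pr(D_i|S) ∝ (1/σ) exp(−(D_i^s − D_i)²/2σ²), and scale-invariant
Jeffreys priors on the two positive nuisance parameters (noise σ and
conversion exponent α).  Up to an additive constant the log-posterior is

    L(S | D, σ, α) = −log σ − log α − E_s/kBT
                     − (1/2σ²) Σ_i (D_i^s − D_i)² − m log σ,

where D_i^s is the distance between the two restrained fragment midpoints
back-computed from S, D_i = β F_i^(−α) is the converted target, and m the
number of restraints.  An ensemble is a set of k weighted conformations;
member weights are the normalised per-member likelihoods (computed in log
space via log-sum-exp) and the EM convergence objective is the ensemble
likelihood Σ_i L_i w_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .polymer_model import (
    ChromensError,
    Conformation,
    EnergyParams,
    SegmentModel,
    _batch_energy_gradient,
    total_energy,
)
from .restraints import RestraintSet

__all__ = [
    "NuisanceParams",
    "EnsembleState",
    "back_compute_distances",
    "log_posterior",
    "posterior_gradient",
    "compute_weights",
    "ensemble_likelihood",
]


@dataclass(frozen=True)
class NuisanceParams:
    """The two nuisance parameters estimated by EM: conversion exponent
    alpha and Gaussian noise sigma (reduced length units)."""

    alpha: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    @property
    def data_weight(self) -> float:
        """The factor 1/(2σ²) weighting the data term against the energy."""
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class EnsembleState:
    """k weighted conformations plus their per-member log-likelihoods."""

    members: list  # list of (Conformation, weight)
    log_likelihoods: np.ndarray

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")
        self.log_likelihoods = np.asarray(self.log_likelihoods, dtype=float)
        if len(self.log_likelihoods) != len(self.members):
            raise ValueError("log_likelihoods length must equal member count")
        w = self.weights
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if abs(float(np.sum(w)) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.members], dtype=float)

    @property
    def conformations(self) -> list:
        return [c for c, _ in self.members]


def back_compute_distances(conf: Conformation, model: SegmentModel,
                           restraints: RestraintSet) -> np.ndarray:
    """Distance between restrained fragment midpoints in a conformation.

    A restraint anchors at the spatial midpoint of each fragment,
    m_i = (s_i + s_{i+1})/2, since a ligation event localises within the
    fragment rather than at either cut site.
    """
    if restraints.m and (restraints.idx_j.max() >= model.n
                         or restraints.idx_i.min() < 0):
        raise IndexError("restraint fragment index out of range for model")
    mids = conf.segment_midpoints()
    diff = mids[restraints.idx_i] - mids[restraints.idx_j]
    return np.linalg.norm(diff, axis=-1)


def log_posterior(conf: Conformation, model: SegmentModel,
                  restraints: RestraintSet, eparams: EnergyParams,
                  nuisance: NuisanceParams) -> float:
    """Log-posterior of a conformation (up to an additive constant).

    Targets are re-converted at the current exponent ``nuisance.alpha`` with
    the restraint set's calibrated scale beta held fixed.
    """
    energy = total_energy(conf, model, eparams)
    if not np.isfinite(energy):
        return -np.inf
    targets = restraints.targets_at(nuisance.alpha)
    residuals = back_compute_distances(conf, model, restraints) - targets
    ssr = float(np.dot(residuals, residuals))
    return (-np.log(nuisance.sigma) - np.log(nuisance.alpha)
            - energy / eparams.kBT
            - nuisance.data_weight * ssr
            - restraints.m * np.log(nuisance.sigma))


def posterior_gradient(conf: Conformation, model: SegmentModel,
                       restraints: RestraintSet, eparams: EnergyParams,
                       nuisance: NuisanceParams) -> np.ndarray:
    """Gradient of the log-posterior w.r.t. every end point, (n+1)×3.

    −(1/kBT)∇E_s − (1/σ²) Σ_i (D_i^s − D_i) ∇D_i^s; each midpoint distance
    distributes its pull equally onto the two end points of each fragment.
    """
    grad = -_batch_energy_gradient(conf.coords, model, eparams,
                                   check=True) / eparams.kBT
    if restraints.m:
        mids = conf.segment_midpoints()
        diff = mids[restraints.idx_i] - mids[restraints.idx_j]
        dists = np.linalg.norm(diff, axis=-1)
        if np.any(dists == 0):
            raise ChromensError("coincident restrained midpoints: distance "
                                "gradient undefined")
        targets = restraints.targets_at(nuisance.alpha)
        coef = (dists - targets) / (nuisance.sigma**2 * dists)
        pull = coef[:, None] * diff  # ∂/∂m_i of the data term, per record
        data_grad = np.zeros_like(conf.coords)
        for seg_idx, sign in ((restraints.idx_i, 1.0), (restraints.idx_j, -1.0)):
            half = 0.5 * sign * pull
            np.add.at(data_grad, seg_idx, half)
            np.add.at(data_grad, seg_idx + 1, half)
        grad -= data_grad
    return grad


def compute_weights(log_likelihoods: np.ndarray) -> np.ndarray:
    """Normalised ensemble weights w_i = exp(L_i − logsumexp(L)).

    Performed in log space so that yeast-scale restraint counts (hundreds of
    records, log-likelihoods in the thousands) cannot underflow.
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.size < 1:
        raise ValueError("need at least one log-likelihood")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihoods must all be finite")
    return np.exp(ll - logsumexp(ll))


def ensemble_likelihood(log_likelihoods: np.ndarray,
                        weights: np.ndarray) -> float:
    """The ensemble likelihood Σ_i L_i w_i (the EM convergence objective)."""
    ll = np.asarray(log_likelihoods, dtype=float)
    w = np.asarray(weights, dtype=float)
    if ll.shape != w.shape:
        raise ValueError("log-likelihoods and weights must have equal length")
    return float(np.dot(ll, w))
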