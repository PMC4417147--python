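"""EM algorithm for joint inference of the structure ensemble and the
nuisance parameters (conversion exponent α, noise σ).

Outline:

1. generate an initial pool of k conformations by overdamped Langevin
   (Brownian) dynamics on the conformational energy, confined to a sphere;
2. initialise (α, σ) by an M-step grid search over the uniform-weight pool,
   re-calibrate the conversion scale β once at that α, and repeat the M
   step (β stays fixed afterwards);
3. E step — optimize every conformation by gradient ascent on its
   log-posterior at the current (α, σ), then set member weights to the
   normalised likelihoods;
4. M step — grid search over (α, 1/(2σ²)), coarse scan first, then a fine
   scan inside the bracketing coarse cells, maximising the ensemble
   likelihood Σ_i L_i w_i with structures and weights held fixed;
5. repeat 3–4 until the relative change of the ensemble likelihood falls
   below tolerance or the iteration cap is reached.

All randomness flows from a single integer seed, so a run is exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bayes import (
    EnsembleState,
    NuisanceParams,
    back_compute_distances,
    compute_weights,
    ensemble_likelihood,
)
from .polymer_model import (
    _BEND_SIN_EPS,
    ChromensError,
    Conformation,
    DegenerateGeometryError,
    EnergyParams,
    SegmentModel,
    _batch_energy_gradient,
    _batch_total_energy,
)
from .restraints import (
    ConversionParams,
    FrequencyMatrix,
    RestraintSet,
    build_segment_model,
    calibrate_beta,
    convert_frequencies,
)

__all__ = [
    "GridSpec",
    "InferenceConfig",
    "EMTrace",
    "brownian_initialize",
    "optimize_structure",
    "e_step",
    "m_step",
    "run_em",
    "run_em_on_restraints",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """A two-stage (coarse → fine) search grid over one parameter axis."""

    lo: float
    hi: float
    coarse_points: int = 10
    fine_points: int = 10

    def __post_init__(self) -> None:
        if not (self.hi > self.lo > 0):
            raise ValueError("grid requires hi > lo > 0")
        if self.coarse_points < 1 or self.fine_points < 1:
            raise ValueError("grids must be nonempty")

    def coarse(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.coarse_points)

    def fine_around(self, index: int) -> np.ndarray:
        """Fine grid spanning the coarse cells bracketing ``index``."""
        coarse = self.coarse()
        lo = coarse[max(index - 1, 0)]
        hi = coarse[min(index + 1, len(coarse) - 1)]
        fine = np.linspace(lo, hi, self.fine_points)
        # keep the incumbent coarse point among the candidates
        return np.unique(np.append(fine, coarse[index]))

    @property
    def coarse_step(self) -> float:
        if self.coarse_points == 1:
            return self.hi - self.lo
        return (self.hi - self.lo) / (self.coarse_points - 1)

    @property
    def fine_step(self) -> float:
        """Resolution of the fine scan (interior bracketing interval)."""
        if self.fine_points == 1:
            return 2.0 * self.coarse_step
        return 2.0 * self.coarse_step / (self.fine_points - 1)


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the EM inference.

    ``k`` is the ensemble size (200 in the full-scale setting).  The noise
    axis is parameterised as τ = 1/(2σ²), the weighting factor between the
    data term and the conformational energy.  ``confinement_radius`` (reduced
    units) bounds the Brownian initialisation; ``None`` means a quarter of
    the chain's rest contour length.
    """

    k: int = 200
    confinement_radius: float | None = None
    max_em_iter: int = 20
    em_rel_tol: float = 1e-4
    ascent_max_steps: int = 2000
    ascent_tol: float = 1e-3
    ascent_init_step: float = 1e-2
    alpha_grid: GridSpec = field(default_factory=lambda: GridSpec(0.1, 1.5))
    tau_grid: GridSpec = field(default_factory=lambda: GridSpec(0.1, 10.0))
    min_freq: float = 0.0
    seed: int = 0
    brownian_steps: int = 50_000
    brownian_dt: float = 1e-4
    brownian_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("ensemble size k must be >= 1")
        for name in ("brownian_dt", "brownian_gamma", "ascent_init_step",
                     "ascent_tol", "em_rel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def radius_for(self, model: SegmentModel) -> float:
        if self.confinement_radius is not None:
            return self.confinement_radius
        return model.contour_length / 4.0


@dataclass
class EMTrace:
    """Per-iteration record of the EM run plus run-level metadata."""

    ensemble_likelihoods: list = field(default_factory=list)
    alphas: list = field(default_factory=list)
    sigmas: list = field(default_factory=list)
    correlations: list = field(default_factory=list)
    beta: float = float("nan")
    seed: int | None = None
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.ensemble_likelihoods)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iterations + 1),
            "ensemble_likelihood": self.ensemble_likelihoods,
            "alpha": self.alphas,
            "sigma": self.sigmas,
            "restraint_correlation": self.correlations,
        })


# ---------------------------------------------------------------------------
# Brownian (overdamped Langevin) initialisation
# ---------------------------------------------------------------------------

# cap on the deterministic per-step displacement; guards against the d^-13
# divergence of the WCA force when the noise pushes two beads very close
_MAX_DRIFT = 0.1


def _random_walk(model: SegmentModel, radius: float, k: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Seeded random walks with step lengths l_i0, reflected into a sphere."""
    coords = np.zeros((k, model.n + 1, 3))
    for seg in range(model.n):
        step = rng.standard_normal((k, 3))
        step /= np.linalg.norm(step, axis=-1, keepdims=True)
        nxt = coords[:, seg, :] + model.rest_lengths[seg] * step
        r = np.linalg.norm(nxt, axis=-1)
        factor = np.where(r > radius,
                          np.maximum(2.0 * radius - r, 0.5 * radius) / np.maximum(r, 1e-12),
                          1.0)
        coords[:, seg + 1, :] = nxt * factor[:, None]
    return coords


def _langevin(coords: np.ndarray, model: SegmentModel, eparams: EnergyParams,
              cfg: InferenceConfig, radius: float,
              rng: np.random.Generator) -> np.ndarray:
    """Batched overdamped Langevin dynamics with spherical reflection."""
    dt = cfg.brownian_dt
    gamma = cfg.brownian_gamma
    noise_scale = np.sqrt(2.0 * eparams.kBT * dt / gamma)
    x = coords.copy()
    for _ in range(cfg.brownian_steps):
        grad = _batch_energy_gradient(x, model, eparams, check=False)
        drift = np.clip(-(dt / gamma) * grad, -_MAX_DRIFT, _MAX_DRIFT)
        x += drift + noise_scale * rng.standard_normal(x.shape)
        r = np.linalg.norm(x, axis=-1)
        outside = r > radius
        if np.any(outside):
            factor = np.where(outside,
                              np.maximum(2.0 * radius - r, 0.0)
                              / np.maximum(r, 1e-12),
                              1.0)
            x *= factor[..., None]
    return x


def brownian_initialize(model: SegmentModel, eparams: EnergyParams,
                        cfg: InferenceConfig,
                        rng: np.random.Generator | None = None) -> list:
    """Generate k starting conformations by Brownian simulation.

    Each member starts from a random walk with the segment rest lengths and
    is then propagated by overdamped Langevin dynamics on the conformational
    energy, s ← s − (dt/γ)∇E + √(2·kBT·dt/γ)·ξ, confined to a sphere of the
    configured radius by radial reflection.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    radius = cfg.radius_for(model)
    coords = _random_walk(model, radius, cfg.k, rng)
    coords = _langevin(coords, model, eparams, cfg, radius, rng)
    energies = _batch_total_energy(coords, model, eparams)
    for _ in range(5):
        bad = ~np.isfinite(energies)
        if not np.any(bad):
            break
        idx = np.flatnonzero(bad)
        logger.warning("re-initializing %d member(s) with non-finite energy",
                       len(idx))
        redo = _random_walk(model, radius, len(idx), rng)
        redo = _langevin(redo, model, eparams, cfg, radius, rng)
        coords[idx] = redo
        energies = _batch_total_energy(coords, model, eparams)
    if np.any(~np.isfinite(energies)):
        raise ChromensError("Brownian initialization failed to produce "
                            "finite-energy conformations after 5 retries")
    return [Conformation(coords[i]) for i in range(cfg.k)]


# ---------------------------------------------------------------------------
# E step: per-structure gradient ascent on the log-posterior
# ---------------------------------------------------------------------------

def _batch_logpost(x: np.ndarray, model: SegmentModel,
                   restraints: RestraintSet, eparams: EnergyParams,
                   nuisance: NuisanceParams,
                   targets: np.ndarray) -> np.ndarray:
    """Log-posterior for coordinates of shape (..., n+1, 3); degenerate
    geometry maps to −inf so line searches can reject it."""
    energy = _batch_total_energy(x, model, eparams, strict=False)
    mids = 0.5 * (x[..., :-1, :] + x[..., 1:, :])
    diff = mids[..., restraints.idx_i, :] - mids[..., restraints.idx_j, :]
    dists = np.linalg.norm(diff, axis=-1)
    ssr = np.sum((dists - targets) ** 2, axis=-1)
    out = (-(restraints.m + 1) * np.log(nuisance.sigma)
           - np.log(nuisance.alpha)
           - energy / eparams.kBT
           - nuisance.data_weight * ssr)
    return np.where(np.isfinite(energy), out, -np.inf)


def _logpost_coords(x: np.ndarray, model: SegmentModel,
                    restraints: RestraintSet, eparams: EnergyParams,
                    nuisance: NuisanceParams,
                    targets: np.ndarray) -> float:
    return float(_batch_logpost(x, model, restraints, eparams, nuisance,
                                targets))


def _posterior_grad_coords(x: np.ndarray, model: SegmentModel,
                           restraints: RestraintSet, eparams: EnergyParams,
                           nuisance: NuisanceParams,
                           targets: np.ndarray) -> np.ndarray:
    grad = -_batch_energy_gradient(x, model, eparams, check=True) / eparams.kBT
    if restraints.m:
        mids = 0.5 * (x[:-1] + x[1:])
        diff = mids[restraints.idx_i] - mids[restraints.idx_j]
        dists = np.linalg.norm(diff, axis=-1)
        if np.any(dists == 0):
            raise DegenerateGeometryError("coincident restrained midpoints")
        coef = (dists - targets) / (nuisance.sigma**2 * dists)
        pull = 0.5 * coef[:, None] * diff
        data_grad = np.zeros_like(x)
        np.add.at(data_grad, restraints.idx_i, pull)
        np.add.at(data_grad, restraints.idx_i + 1, pull)
        np.subtract.at(data_grad, restraints.idx_j, pull)
        np.subtract.at(data_grad, restraints.idx_j + 1, pull)
        grad -= data_grad
    return grad


def optimize_structure(conf: Conformation, model: SegmentModel,
                       restraints: RestraintSet, eparams: EnergyParams,
                       nuisance: NuisanceParams,
                       cfg: InferenceConfig) -> Conformation:
    """Maximise the log-posterior of one conformation by gradient ascent.

    Uses a backtracking line search (step halved until the objective
    improves, then doubled for the next iteration, capped at 1) and stops
    when the gradient norm drops below ``ascent_tol`` or after
    ``ascent_max_steps`` accepted steps.  The returned conformation never
    has a lower log-posterior than the input.
    """
    targets = restraints.targets_at(nuisance.alpha)
    x = conf.coords.copy()
    f = _logpost_coords(x, model, restraints, eparams, nuisance, targets)
    step = cfg.ascent_init_step
    jitter_rng = None
    for _ in range(cfg.ascent_max_steps):
        try:
            g = _posterior_grad_coords(x, model, restraints, eparams,
                                       nuisance, targets)
        except DegenerateGeometryError:
            if jitter_rng is None:
                jitter_rng = np.random.default_rng(cfg.seed)
            x = x + 1e-6 * jitter_rng.standard_normal(x.shape)
            f = _logpost_coords(x, model, restraints, eparams, nuisance,
                                targets)
            continue
        gnorm = float(np.linalg.norm(g))
        if gnorm < cfg.ascent_tol:
            break
        improved = False
        while step >= 1e-14:
            x_new = x + step * g
            f_new = _logpost_coords(x_new, model, restraints, eparams,
                                    nuisance, targets)
            if f_new > f:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        x, f = x_new, f_new
        step = min(step * 2.0, 1.0)
    return Conformation(x)


def _batch_posterior_grad(x: np.ndarray, model: SegmentModel,
                          restraints: RestraintSet, eparams: EnergyParams,
                          nuisance: NuisanceParams,
                          targets: np.ndarray) -> np.ndarray:
    """Batched log-posterior gradient for coordinates (k, n+1, 3).

    Degenerate contributions (zero-length bonds, coincident pairs) are
    zeroed rather than raised: the line search rejects any state with
    non-finite posterior, so the batch as a whole keeps moving.
    """
    grad = -_batch_energy_gradient(x, model, eparams, check=False) / eparams.kBT
    if restraints.m:
        mids = 0.5 * (x[..., :-1, :] + x[..., 1:, :])
        diff = mids[..., restraints.idx_i, :] - mids[..., restraints.idx_j, :]
        dists = np.linalg.norm(diff, axis=-1)
        safe = np.where(dists > 0, dists, 1.0)
        coef = np.where(dists > 0,
                        (dists - targets) / (nuisance.sigma**2 * safe), 0.0)
        pull = 0.5 * coef[..., None] * diff
        data_grad = np.zeros_like(x)
        np.add.at(data_grad, (slice(None), restraints.idx_i), pull)
        np.add.at(data_grad, (slice(None), restraints.idx_i + 1), pull)
        np.subtract.at(data_grad, (slice(None), restraints.idx_j), pull)
        np.subtract.at(data_grad, (slice(None), restraints.idx_j + 1), pull)
        grad -= data_grad
    return grad


def _batch_logpost_grad(x: np.ndarray, model: SegmentModel,
                        restraints: RestraintSet, eparams: EnergyParams,
                        nuisance: NuisanceParams, targets: np.ndarray):
    """Fused log-posterior value and gradient on a (k, n+1, 3) batch.

    One pass shares the bond, angle, pairwise-distance and midpoint work
    between the objective and its gradient; this is the hot path of the
    E step.  Degenerate contributions are zeroed (see
    :func:`_batch_posterior_grad`).
    """
    k, npts, _ = x.shape
    grad = np.zeros_like(x)

    # stretch
    bonds = x[:, 1:, :] - x[:, :-1, :]
    lengths = np.linalg.norm(bonds, axis=-1)
    zero_bond = np.any(lengths == 0, axis=-1)
    e_stretch = 0.5 * eparams.k_s * np.sum(
        (lengths - model.rest_lengths) ** 2, axis=-1)
    safe_len = np.where(lengths > 0, lengths, 1.0)
    unit = bonds / safe_len[..., None]
    pull = (eparams.k_s * (lengths - model.rest_lengths))[..., None] * unit
    grad[:, 1:, :] += pull
    grad[:, :-1, :] -= pull

    # bend
    u = bonds[:, :-1, :]
    v = bonds[:, 1:, :]
    lu = safe_len[:, :-1]
    lv = safe_len[:, 1:]
    cos = np.clip(np.sum(u * v, axis=-1) / (lu * lv), -1.0, 1.0)
    theta = np.arccos(cos)
    e_bend = 0.5 * eparams.k_theta * np.sum(theta**2, axis=-1)
    sin = np.sqrt(np.maximum(1.0 - cos**2, 0.0))
    ratio = theta / np.maximum(sin, _BEND_SIN_EPS)
    fac = -eparams.k_theta * np.where(sin > _BEND_SIN_EPS, ratio, 1.0)
    dcos_du = (v / lv[..., None] - cos[..., None] * u / lu[..., None]) / lu[..., None]
    dcos_dv = (u / lu[..., None] - cos[..., None] * v / lv[..., None]) / lv[..., None]
    gu = fac[..., None] * dcos_du
    gv = fac[..., None] * dcos_dv
    grad[:, 1:-1, :] += gu - gv
    grad[:, :-2, :] -= gu
    grad[:, 2:, :] += gv

    # excluded volume (WCA)
    diff = x[:, :, None, :] - x[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    eye = np.eye(npts, dtype=bool)
    inside = (d < eparams.wca_cutoff) & ~eye
    dsafe = np.where(d > 0, d, 1.0)
    with np.errstate(over="ignore"):
        sr6 = np.where(inside, (eparams.delta / dsafe) ** 6, 0.0)
    term = 4.0 * eparams.epsilon * (sr6**2 - sr6 + 0.25)
    pair_ok = inside & (d > 0)
    e_excl = 0.5 * np.sum(np.where(pair_ok, term, 0.0), axis=(1, 2))
    e_excl = np.where(np.any(inside & (d == 0.0), axis=(1, 2)), np.inf, e_excl)
    dE_dd = 4.0 * eparams.epsilon * (-12.0 * sr6**2 + 6.0 * sr6) / dsafe
    w = np.where(pair_ok, dE_dd / dsafe, 0.0)
    grad += np.einsum("kij,kijc->kic", w, diff)

    energy = np.where(zero_bond, np.inf, e_stretch + e_bend + e_excl)
    grad = -grad / eparams.kBT

    # data term
    mids = 0.5 * (x[:, :-1, :] + x[:, 1:, :])
    rdiff = mids[:, restraints.idx_i, :] - mids[:, restraints.idx_j, :]
    dists = np.linalg.norm(rdiff, axis=-1)
    ssr = np.sum((dists - targets) ** 2, axis=-1)
    rsafe = np.where(dists > 0, dists, 1.0)
    coef = np.where(dists > 0,
                    (dists - targets) / (nuisance.sigma**2 * rsafe), 0.0)
    dpull = 0.5 * coef[..., None] * rdiff
    data_grad = np.zeros_like(x)
    np.add.at(data_grad, (slice(None), restraints.idx_i), dpull)
    np.add.at(data_grad, (slice(None), restraints.idx_i + 1), dpull)
    np.subtract.at(data_grad, (slice(None), restraints.idx_j), dpull)
    np.subtract.at(data_grad, (slice(None), restraints.idx_j + 1), dpull)
    grad -= data_grad

    f = (-(restraints.m + 1) * np.log(nuisance.sigma)
         - np.log(nuisance.alpha)
         - energy / eparams.kBT
         - nuisance.data_weight * ssr)
    f = np.where(np.isfinite(energy), f, -np.inf)
    return f, grad


def _batch_ascent(coords: np.ndarray, model: SegmentModel,
                  restraints: RestraintSet, eparams: EnergyParams,
                  nuisance: NuisanceParams, cfg: InferenceConfig):
    """Gradient ascent with per-member backtracking line search, run on all
    k members simultaneously.  Returns (coords, log-posteriors)."""
    targets = restraints.targets_at(nuisance.alpha)
    x = coords.copy()
    f, g = _batch_logpost_grad(x, model, restraints, eparams, nuisance,
                               targets)
    k = x.shape[0]
    step = np.full(k, cfg.ascent_init_step)
    done = np.zeros(k, dtype=bool)
    for _ in range(cfg.ascent_max_steps):
        gnorm = np.linalg.norm(g.reshape(k, -1), axis=1)
        done |= gnorm < cfg.ascent_tol
        done |= step < 1e-14
        if np.all(done):
            break
        active = ~done
        x_new = x + step[:, None, None] * g
        f_new, g_new = _batch_logpost_grad(x_new, model, restraints, eparams,
                                           nuisance, targets)
        improved = active & (f_new > f)
        x[improved] = x_new[improved]
        f[improved] = f_new[improved]
        g[improved] = g_new[improved]
        step[improved] = np.minimum(step[improved] * 2.0, 1.0)
        rejected = active & ~improved
        step[rejected] *= 0.5
    return x, f


def e_step(ensemble: EnsembleState, model: SegmentModel,
           restraints: RestraintSet, eparams: EnergyParams,
           nuisance: NuisanceParams, cfg: InferenceConfig) -> EnsembleState:
    """Optimize every member at the current nuisance parameters, recompute
    per-member log-posteriors and set weights to their normalisation.

    Members are optimized independently (the batch runs them in lock-step
    but no member's update depends on another's state).
    """
    coords = np.stack([c.coords for c in ensemble.conformations])
    coords, lls = _batch_ascent(coords, model, restraints, eparams,
                                nuisance, cfg)
    weights = compute_weights(lls)
    members = [(Conformation(coords[i]), float(weights[i]))
               for i in range(len(weights))]
    return EnsembleState(members=members, log_likelihoods=lls)


# ---------------------------------------------------------------------------
# M step: two-stage grid search over (alpha, tau = 1/(2 sigma^2))
# ---------------------------------------------------------------------------

def _member_stats(ensemble: EnsembleState, model: SegmentModel,
                  restraints: RestraintSet, eparams: EnergyParams):
    """Per-member energies (kBT) and back-computed distance matrix (k, m)."""
    energies = np.array([
        float(_batch_total_energy(c.coords, model, eparams))
        for c in ensemble.conformations
    ])
    dists = np.stack([
        back_compute_distances(c, model, restraints)
        for c in ensemble.conformations
    ])
    return energies, dists


def _grid_objective(alphas: np.ndarray, taus: np.ndarray,
                    weighted_ssr: callable, e_bar: float, m: int,
                    log_alpha_penalty: bool = True) -> np.ndarray:
    """Ensemble likelihood on the (alpha, tau) grid; shape (A, T)."""
    s_alpha = np.array([weighted_ssr(a) for a in alphas])
    log_sigma = -0.5 * np.log(2.0 * taus)
    obj = (-(m + 1) * log_sigma[None, :]
           - np.log(alphas)[:, None]
           - e_bar
           - s_alpha[:, None] * taus[None, :])
    return obj


def _argmax_tie_break(obj: np.ndarray, alphas: np.ndarray,
                      taus: np.ndarray) -> tuple:
    """Arg-max with ties broken toward smaller alpha, then smaller sigma
    (i.e. larger tau)."""
    best = (-np.inf, None, None)
    order_a = np.argsort(alphas)
    order_t = np.argsort(taus)[::-1]  # descending tau = ascending sigma
    for ia in order_a:
        for it in order_t:
            if obj[ia, it] > best[0]:
                best = (obj[ia, it], ia, it)
    return best


def m_step(ensemble: EnsembleState, model: SegmentModel,
           restraints: RestraintSet, eparams: EnergyParams,
           cfg: InferenceConfig) -> NuisanceParams:
    """Grid search for (α, σ) maximising the ensemble likelihood.

    Structures and weights are held fixed; restraint targets are
    re-converted per candidate α at the calibrated β.  A coarse scan over
    the full ranges is followed by a fine scan inside the coarse cells that
    bracket the coarse optimum.  Ties break toward smaller α, then smaller σ.
    """
    w = ensemble.weights
    energies, dists = _member_stats(ensemble, model, restraints, eparams)
    e_bar = float(np.dot(w, energies)) / eparams.kBT
    freqs = restraints.freqs
    beta = restraints.beta
    m = restraints.m

    def weighted_ssr(alpha: float) -> float:
        targets = beta * freqs ** (-alpha)
        ssr = np.sum((dists - targets[None, :]) ** 2, axis=1)
        return float(np.dot(w, ssr))

    alphas_c = cfg.alpha_grid.coarse()
    taus_c = cfg.tau_grid.coarse()
    obj_c = _grid_objective(alphas_c, taus_c, weighted_ssr, e_bar, m)
    _, ia, it = _argmax_tie_break(obj_c, alphas_c, taus_c)

    alphas_f = cfg.alpha_grid.fine_around(ia)
    taus_f = cfg.tau_grid.fine_around(it)
    obj_f = _grid_objective(alphas_f, taus_f, weighted_ssr, e_bar, m)
    _, ja, jt = _argmax_tie_break(obj_f, alphas_f, taus_f)

    alpha_hat = float(alphas_f[ja])
    tau_hat = float(taus_f[jt])
    sigma_hat = float(np.sqrt(1.0 / (2.0 * tau_hat)))
    return NuisanceParams(alpha=alpha_hat, sigma=sigma_hat)


# ---------------------------------------------------------------------------
# the full EM loop
# ---------------------------------------------------------------------------

def _calibrate_beta_pool(restraints: RestraintSet, pool: list,
                         alpha: float) -> float:
    """Calibrate β so the mean converted adjacent-pair distance matches the
    mean adjacent midpoint distance observed in the Brownian pool.

    The pool is a sample from the conformational-energy prior, so its
    adjacent-pair statistics estimate the distance the data's adjacent
    frequencies actually encode (slightly below the rest length, since
    thermal bending contracts midpoint separations).
    """
    adjacent = (restraints.idx_j - restraints.idx_i) == 1
    freqs = restraints.freqs[adjacent]
    if freqs.size == 0 or not np.any(freqs > 0):
        return restraints.beta
    coords = np.stack([c.coords for c in pool])
    mids = 0.5 * (coords[:, :-1] + coords[:, 1:])
    diff = (mids[:, restraints.idx_i[adjacent]]
            - mids[:, restraints.idx_j[adjacent]])
    d_bar = float(np.mean(np.linalg.norm(diff, axis=-1)))
    return d_bar / float(np.mean(freqs[freqs > 0] ** (-alpha)))

def _ensemble_likelihood_at(ensemble: EnsembleState, model: SegmentModel,
                            restraints: RestraintSet, eparams: EnergyParams,
                            nuisance: NuisanceParams):
    """(ensemble likelihood, per-record ensemble-mean distances, targets)."""
    targets = restraints.targets_at(nuisance.alpha)
    lls = np.empty(ensemble.k)
    mean_dists = np.zeros(restraints.m)
    w = ensemble.weights
    for i, conf in enumerate(ensemble.conformations):
        lls[i] = _logpost_coords(conf.coords, model, restraints, eparams,
                                 nuisance, targets)
        mean_dists += w[i] * back_compute_distances(conf, model, restraints)
    return ensemble_likelihood(lls, w), mean_dists, targets


def run_em_on_restraints(model: SegmentModel, restraints: RestraintSet,
                         eparams: EnergyParams, cfg: InferenceConfig,
                         nuisance0: NuisanceParams | None = None,
                         rng: np.random.Generator | None = None):
    """EM on an explicit restraint set (the core loop behind :func:`run_em`).

    With ``nuisance0=None`` (the default) the nuisance parameters are
    initialised data-driven: a grid-search M step over the uniform-weight
    Brownian pool picks the (α, σ) whose target curve best matches the
    energy-equilibrated starting geometry, the conversion scale β is then
    re-calibrated once at that α, and the M step is repeated.  β stays fixed
    afterwards.  (A uniform random draw of α over the grid frequently
    anchors β so far off-scale that the targets become geometrically
    unreachable, τ = 1/(2σ²) collapses to the grid floor and EM strands in
    a spurious fixed point; the pool-based initialisation starts the search
    inside the basin the data support.)

    Returns (EnsembleState, NuisanceParams, EMTrace).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    pool = brownian_initialize(model, eparams, cfg, rng=rng)
    k = len(pool)
    ensemble = EnsembleState(members=[(c, 1.0 / k) for c in pool],
                             log_likelihoods=np.zeros(k))

    if nuisance0 is None:
        nuisance = m_step(ensemble, model, restraints, eparams, cfg)
        beta = _calibrate_beta_pool(restraints, pool, nuisance.alpha)
        restraints = RestraintSet(
            restraints.idx_i, restraints.idx_j, restraints.freqs,
            beta * restraints.freqs ** (-nuisance.alpha),
            beta=beta, alpha=nuisance.alpha)
        nuisance = m_step(ensemble, model, restraints, eparams, cfg)
    else:
        nuisance = nuisance0

    trace = EMTrace(beta=restraints.beta, seed=cfg.seed)
    prev_L = None
    for _ in range(cfg.max_em_iter):
        ensemble = e_step(ensemble, model, restraints, eparams, nuisance, cfg)
        nuisance = m_step(ensemble, model, restraints, eparams, cfg)
        L, mean_dists, targets = _ensemble_likelihood_at(
            ensemble, model, restraints, eparams, nuisance)
        if np.std(mean_dists) > 0 and np.std(targets) > 0:
            corr = float(np.corrcoef(mean_dists, targets)[0, 1])
        else:
            corr = float("nan")
        trace.ensemble_likelihoods.append(L)
        trace.alphas.append(nuisance.alpha)
        trace.sigmas.append(nuisance.sigma)
        trace.correlations.append(corr)
        if prev_L is not None:
            rel = abs(L - prev_L) / max(abs(prev_L), 1e-12)
            if rel < cfg.em_rel_tol:
                trace.converged = True
                break
        prev_L = L
    if not trace.converged:
        logger.warning("EM did not converge within %d iterations",
                       cfg.max_em_iter)
    return ensemble, nuisance, trace


def run_em(fm: FrequencyMatrix, fragment_table,
           config: InferenceConfig | None = None,
           eparams: EnergyParams | None = None):
    """Full pipeline: fragment table + frequency matrix → inferred ensemble.

    ``fragment_table`` may be a path to a BED-like TSV or a prebuilt
    :class:`SegmentModel`.  Returns (EnsembleState, NuisanceParams, EMTrace);
    the calibrated β is recorded on the trace.
    """
    cfg = config or InferenceConfig()
    eparams = eparams or EnergyParams()
    if isinstance(fragment_table, SegmentModel):
        model = fragment_table
    else:
        model = build_segment_model(fragment_table, eparams)
    if fm.n != model.n:
        raise ChromensError(f"frequency matrix has {fm.n} fragments but the "
                            f"fragment table defines {model.n}")

    rng = np.random.default_rng(cfg.seed)
    # provisional conversion; the scale and exponent are re-estimated from
    # the Brownian pool before the EM loop starts
    alpha_prov = 1.0
    beta = calibrate_beta(fm, model, alpha_prov)
    restraints = convert_frequencies(
        fm, ConversionParams(alpha=alpha_prov, beta=beta,
                             min_freq=cfg.min_freq))
    return run_em_on_restraints(model, restraints, eparams, cfg, rng=rng)
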