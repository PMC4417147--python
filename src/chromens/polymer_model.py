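"""Bead–spring polymer representation of a chromosome and its conformational energy.

A chromosome is modelled as a linear chain of ``n`` genomic segments joined at
``n + 1`` end points, one segment per restriction fragment.  The conformational
energy of a chain is the sum of three terms:

* a harmonic stretching term penalising deviation of each segment length from
  its equilibrium (rest) length,
* a harmonic bending term on the planar angle between consecutive segments,
* a purely repulsive excluded-volume term of Weeks–Chandler–Andersen (WCA)
  form, i.e. a Lennard–Jones potential truncated and shifted at ``2^(1/6) δ``.

All computation is carried out in reduced units: the excluded-volume size
``δ = 1`` corresponds to 30 nm and the thermal energy ``kBT = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChromensError",
    "InvalidModelError",
    "DegenerateGeometryError",
    "EnergyParams",
    "SegmentModel",
    "Conformation",
    "segment_lengths",
    "stretch_energy",
    "bend_energy",
    "exclude_energy",
    "total_energy",
    "energy_gradient",
]

# physical constants used only when converting reduced units to SI
BOLTZMANN_J_PER_K = 1.380649e-23
DEFAULT_TEMPERATURE_K = 300.0

WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


class ChromensError(Exception):
    """Base class for all errors raised by this package."""


class InvalidModelError(ChromensError):
    """A chain model or conformation violates a structural invariant."""


class DegenerateGeometryError(ChromensError):
    """Geometry for which an angle or gradient is undefined (zero-length bond,
    coincident excluded-volume pair)."""


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the conformational energy model (reduced units).

    Attributes
    ----------
    kBT : thermal energy unit; 1.0 reduced ≡ k_B·300 K ≈ 4.1e-21 J.
    delta : excluded-volume (Lennard–Jones) size; 1.0 reduced ≡ 30 nm.
    epsilon : excluded-volume energy depth, in units of kBT.
    k_s : bond spring constant, kBT/δ².
    k_theta : bending constant, kBT/rad².
    packing_density : chromatin fibre packing, base pairs per nm.
    length_scale_nm : nm per reduced length unit.
    """

    kBT: float = 1.0
    delta: float = 1.0
    epsilon: float = 1.0
    k_s: float = 500.0
    k_theta: float = 4.0
    packing_density: float = 130.0
    length_scale_nm: float = 30.0

    def __post_init__(self) -> None:
        for name in ("kBT", "delta", "epsilon", "k_s", "k_theta",
                     "packing_density", "length_scale_nm"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"EnergyParams.{name} must be strictly positive")

    @property
    def wca_cutoff(self) -> float:
        """Distance beyond which the excluded-volume term is exactly zero."""
        return WCA_CUTOFF_FACTOR * self.delta

    def kBT_si_joule(self, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
        """Thermal energy in joules at the given absolute temperature."""
        return self.kBT * BOLTZMANN_J_PER_K * temperature_k

    def k_s_si(self, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
        """Bond spring constant in J/m²."""
        delta_m = self.delta * self.length_scale_nm * 1e-9
        return self.k_s * self.kBT_si_joule(temperature_k) / delta_m**2

    def k_theta_si(self, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
        """Bending constant in J/rad²."""
        return self.k_theta * self.kBT_si_joule(temperature_k)


@dataclass(frozen=True)
class SegmentModel:
    """The segment chain of one chromosome.

    ``spans`` are fragment intervals in base pairs (0-based, half-open),
    contiguous and strictly increasing.  ``rest_lengths`` are the equilibrium
    segment lengths in reduced units, derived from the base-pair content via
    the fibre packing density and the length scale.
    """

    chrom: str
    spans: np.ndarray          # (n, 2) int
    bp_lengths: np.ndarray     # (n,) int
    rest_lengths: np.ndarray   # (n,) float, reduced units

    def __post_init__(self) -> None:
        spans = np.asarray(self.spans)
        if spans.ndim != 2 or spans.shape[1] != 2 or spans.shape[0] < 2:
            raise InvalidModelError("segment model needs at least 2 fragment spans")
        if np.any(spans[:, 1] <= spans[:, 0]):
            raise InvalidModelError("every fragment span must have end > start")
        if np.any(spans[1:, 0] != spans[:-1, 1]):
            bad = int(np.flatnonzero(spans[1:, 0] != spans[:-1, 1])[0]) + 1
            raise InvalidModelError(
                f"fragment spans must be contiguous; gap/overlap before row {bad}"
            )
        if np.any(np.asarray(self.rest_lengths) <= 0):
            raise InvalidModelError("all rest lengths must be positive")

    @classmethod
    def from_spans(cls, chrom: str, spans: np.ndarray,
                   params: EnergyParams) -> "SegmentModel":
        spans = np.asarray(spans, dtype=np.int64)
        bp = spans[:, 1] - spans[:, 0]
        rest = bp / params.packing_density / params.length_scale_nm
        return cls(chrom=chrom, spans=spans, bp_lengths=bp, rest_lengths=rest)

    @property
    def n(self) -> int:
        """Number of segments."""
        return self.spans.shape[0]

    @property
    def n_endpoints(self) -> int:
        return self.n + 1

    @property
    def contour_length(self) -> float:
        """Total rest contour length in reduced units."""
        return float(np.sum(self.rest_lengths))

    def midpoints_bp(self) -> np.ndarray:
        """Genomic midpoint of every fragment, in bp."""
        return (self.spans[:, 0] + self.spans[:, 1]) / 2.0


@dataclass(frozen=True)
class Conformation:
    """3D coordinates of the n+1 chain end points, in reduced units."""

    coords: np.ndarray  # (n+1, 3) float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise InvalidModelError("a conformation needs at least 2 points in 3D")
        if not np.all(np.isfinite(coords)):
            raise InvalidModelError("conformation coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_segments(self) -> int:
        return self.coords.shape[0] - 1

    def segment_midpoints(self) -> np.ndarray:
        """Spatial midpoints of the n segments, shape (n, 3)."""
        return 0.5 * (self.coords[:-1] + self.coords[1:])

    def translated(self, offset: np.ndarray) -> "Conformation":
        return Conformation(self.coords + np.asarray(offset, dtype=float))


def _check_match(conf: Conformation, model: SegmentModel) -> None:
    if conf.n_segments != model.n:
        raise InvalidModelError(
            f"conformation has {conf.n_segments} segments, model has {model.n}"
        )


# ---------------------------------------------------------------------------
# Energy terms.  The private _batch_* functions operate on coordinate arrays
# of shape (..., n+1, 3) so the Langevin initialiser can propagate a whole
# ensemble at once; the public API wraps them for single conformations.
# ---------------------------------------------------------------------------

def segment_lengths(conf: Conformation) -> np.ndarray:
    """Euclidean length of every segment, |s_{i+1} - s_i|."""
    bonds = np.diff(conf.coords, axis=0)
    return np.linalg.norm(bonds, axis=-1)


def _batch_stretch(coords: np.ndarray, rest: np.ndarray, k_s: float) -> np.ndarray:
    bonds = coords[..., 1:, :] - coords[..., :-1, :]
    lengths = np.linalg.norm(bonds, axis=-1)
    return 0.5 * k_s * np.sum((lengths - rest) ** 2, axis=-1)


def stretch_energy(conf: Conformation, model: SegmentModel,
                   params: EnergyParams) -> float:
    """Harmonic stretching energy Σ ½ k_s (l_i − l_i0)², in kBT."""
    _check_match(conf, model)
    return float(_batch_stretch(conf.coords, model.rest_lengths, params.k_s))


def _batch_bend(coords: np.ndarray, k_theta: float,
                strict: bool = True) -> np.ndarray:
    bonds = coords[..., 1:, :] - coords[..., :-1, :]
    lengths = np.linalg.norm(bonds, axis=-1)
    degenerate = np.any(lengths == 0, axis=-1)
    if np.any(degenerate):
        if strict:
            raise DegenerateGeometryError(
                "zero-length bond: bending angle undefined")
        lengths = np.where(lengths > 0, lengths, 1.0)
    u = bonds[..., :-1, :]
    v = bonds[..., 1:, :]
    cos = np.sum(u * v, axis=-1) / (lengths[..., :-1] * lengths[..., 1:])
    theta = np.arccos(np.clip(cos, -1.0, 1.0))
    energy = 0.5 * k_theta * np.sum(theta**2, axis=-1)
    if not strict:
        energy = np.where(degenerate, np.inf, energy)
    return energy


def bend_energy(conf: Conformation, params: EnergyParams) -> float:
    """Harmonic bending energy Σ ½ k_θ θ_i² over interior end points, in kBT.

    θ_i is the planar angle between bond vectors (s_{i+1}−s_i) and
    (s_i−s_{i−1}), obtained as a clamped arccos of their normalised dot
    product.
    """
    if conf.n_segments < 2:
        return 0.0
    return float(_batch_bend(conf.coords, params.k_theta))


def _pair_distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[..., :, None, :] - coords[..., None, :, :]
    return np.linalg.norm(diff, axis=-1)


def _batch_exclude(coords: np.ndarray, params: EnergyParams) -> np.ndarray:
    npts = coords.shape[-2]
    d = _pair_distance_matrix(coords)
    iu, ju = np.triu_indices(npts, k=1)
    dpair = d[..., iu, ju]
    cutoff = params.wca_cutoff
    out_shape = coords.shape[:-2]
    energy = np.zeros(out_shape)
    inside = dpair < cutoff
    if np.any(inside):
        coincident = inside & (dpair == 0.0)
        if np.any(coincident):
            energy = np.where(np.any(coincident, axis=-1), np.inf, energy)
        with np.errstate(divide="ignore", over="ignore"):
            sr6 = (params.delta / np.where(dpair > 0, dpair, np.nan)) ** 6
        term = 4.0 * params.epsilon * (sr6**2 - sr6 + 0.25)
        term = np.where(inside & (dpair > 0), term, 0.0)
        energy = energy + np.nansum(term, axis=-1)
    return energy


def exclude_energy(conf: Conformation, params: EnergyParams) -> float:
    """WCA excluded-volume energy over all end-point pairs, in kBT.

    For each pair at distance d < 2^(1/6) δ the contribution is
    4ε[(δ/d)¹² − (δ/d)⁶ + ¼]; pairs at or beyond the cutoff contribute
    exactly zero, so the potential is continuous and purely repulsive.
    A coincident pair (d = 0) yields ``+inf`` so that an optimizer can
    reject the state rather than crash.
    """
    return float(_batch_exclude(conf.coords, params))


def total_energy(conf: Conformation, model: SegmentModel,
                 params: EnergyParams) -> float:
    """Total conformational energy: stretch + bend + excluded volume (kBT)."""
    return (stretch_energy(conf, model, params)
            + bend_energy(conf, params)
            + exclude_energy(conf, params))


def _batch_total_energy(coords: np.ndarray, model: SegmentModel,
                        params: EnergyParams,
                        strict: bool = True) -> np.ndarray:
    """Batched total energy; ``strict=False`` maps degenerate geometry to
    ``+inf`` instead of raising (used inside line searches, where a bad
    trial state must be rejectable rather than fatal)."""
    return (_batch_stretch(coords, model.rest_lengths, params.k_s)
            + _batch_bend(coords, params.k_theta, strict=strict)
            + _batch_exclude(coords, params))


_BEND_SIN_EPS = 1e-12


def _batch_energy_gradient(coords: np.ndarray, model: SegmentModel,
                           params: EnergyParams,
                           check: bool = True) -> np.ndarray:
    """Analytic gradient of the total energy w.r.t. every end point.

    Works on arrays of shape (..., n+1, 3).  With ``check=False`` degenerate
    geometry is tolerated by zeroing the affected contributions, which the
    stochastic integrator needs (thermal noise immediately breaks the tie).
    """
    coords = np.asarray(coords, dtype=float)
    npts = coords.shape[-2]
    grad = np.zeros_like(coords)

    # stretch
    bonds = coords[..., 1:, :] - coords[..., :-1, :]
    lengths = np.linalg.norm(bonds, axis=-1)
    if check and np.any(lengths == 0):
        raise DegenerateGeometryError("zero-length bond in gradient")
    safe_len = np.where(lengths > 0, lengths, 1.0)
    unit = bonds / safe_len[..., None]
    f = params.k_s * (lengths - model.rest_lengths)
    pull = f[..., None] * unit
    grad[..., 1:, :] += pull
    grad[..., :-1, :] -= pull

    # bend
    if npts >= 3:
        u = bonds[..., :-1, :]
        v = bonds[..., 1:, :]
        lu = safe_len[..., :-1]
        lv = safe_len[..., 1:]
        cos = np.sum(u * v, axis=-1) / (lu * lv)
        cos = np.clip(cos, -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.maximum(1.0 - cos**2, 0.0))
        # dE/dθ · dθ/dcos = k_θ θ · (−1/sin θ); θ/sin θ → 1 as θ → 0
        ratio = theta / np.maximum(sin, _BEND_SIN_EPS)
        fac = -params.k_theta * np.where(sin > _BEND_SIN_EPS, ratio, 1.0)
        dcos_du = (v / lv[..., None] - cos[..., None] * u / lu[..., None]) / lu[..., None]
        dcos_dv = (u / lu[..., None] - cos[..., None] * v / lv[..., None]) / lv[..., None]
        gu = fac[..., None] * dcos_du
        gv = fac[..., None] * dcos_dv
        # u = x_i − x_{i−1} (i = 1..n−1), v = x_{i+1} − x_i
        grad[..., 1:-1, :] += gu - gv
        grad[..., :-2, :] -= gu
        grad[..., 2:, :] += gv

    # excluded volume (WCA)
    d = _pair_distance_matrix(coords)
    cutoff = params.wca_cutoff
    eye = np.eye(npts, dtype=bool)
    inside = (d < cutoff) & ~eye
    if np.any(inside):
        if check and np.any(inside & (d == 0.0)):
            raise DegenerateGeometryError("coincident excluded-volume pair")
        dsafe = np.where(d > 0, d, 1.0)
        with np.errstate(over="ignore"):
            sr6 = (params.delta / dsafe) ** 6
            dE_dd = 4.0 * params.epsilon * (-12.0 * sr6**2 + 6.0 * sr6) / dsafe
        w = np.where(inside & (d > 0), dE_dd / dsafe, 0.0)
        diff = coords[..., :, None, :] - coords[..., None, :, :]
        grad += np.einsum("...ij,...ijk->...ik", w, diff)
    return grad


def energy_gradient(conf: Conformation, model: SegmentModel,
                    params: EnergyParams) -> np.ndarray:
    """Analytic ∂E/∂s_j for every end point, shape (n+1, 3).

    Raises
    ------
    DegenerateGeometryError
        if any bond has zero length or any counted excluded-volume pair is
        coincident; the caller should perturb the geometry and retry.
    """
    _check_match(conf, model)
    return _batch_energy_gradient(conf.coords, model, params, check=True)
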