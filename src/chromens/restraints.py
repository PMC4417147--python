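"""I/O for interaction-frequency matrices, fragment tables and structures,
plus the frequency → spatial-distance conversion.

The conversion law is the inverse power law ``D = β · F^(−α)``: the exponent
``α`` is a nuisance parameter estimated by the EM algorithm, while the scale
``β`` is calibrated once from sequence-adjacent fragment pairs so that the
converted distances are commensurate with the chain's rest lengths.

File dialects
-------------
* frequency matrix: square TSV with a label header row/column, or sparse
  triplet TSV ``i<TAB>j<TAB>F`` with 1-based fragment indices;
* fragment table: BED-like 3-column TSV (chrom, start, end), 0-based
  half-open, sorted and contiguous;
* structures: XYZ (coordinates in nm) or PDB (CA pseudo-atom trace, nm
  written into the Å coordinate fields);
* ensembles: one structure file per member plus a ``weights.tsv`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .polymer_model import (
    ChromensError,
    Conformation,
    EnergyParams,
    SegmentModel,
)

__all__ = [
    "ParseError",
    "CalibrationError",
    "NoDataError",
    "FrequencyMatrix",
    "ConversionParams",
    "RestraintSet",
    "read_frequency_matrix",
    "write_frequency_matrix",
    "build_segment_model",
    "convert_frequencies",
    "calibrate_beta",
    "write_structure",
    "read_structure",
    "write_ensemble",
    "read_ensemble",
]

logger = logging.getLogger(__name__)


class ParseError(ChromensError):
    """Malformed input file; the message carries the offending line."""


class CalibrationError(ChromensError):
    """The frequency → distance scale cannot be calibrated."""


class NoDataError(ChromensError):
    """An operation produced or received an empty data set."""


@dataclass(frozen=True)
class FrequencyMatrix:
    """Symmetric n×n matrix of pairwise interaction frequencies."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ParseError("frequency matrix must be square")
        if np.any(values < 0):
            raise ParseError("frequency matrix must be nonnegative")
        if not np.allclose(values, values.T, rtol=0, atol=0):
            raise ParseError("frequency matrix must be symmetric after load")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != values.shape[0]:
            raise ParseError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConversionParams:
    """Parameters of the power-law conversion D = beta * F**(-alpha)."""

    alpha: float
    beta: float
    min_freq: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if self.min_freq < 0:
            raise ValueError("min_freq must be >= 0")


@dataclass(frozen=True)
class RestraintSet:
    """Distance restraints derived from a frequency matrix.

    Stores, per record, the fragment pair (0-based, i < j), the raw
    frequency F and the converted target distance D (reduced units) at the
    conversion parameters used to build the set.  The raw frequencies and
    the scale ``beta`` are retained so targets can be re-converted whenever
    the exponent ``alpha`` changes during inference.
    """

    idx_i: np.ndarray
    idx_j: np.ndarray
    freqs: np.ndarray
    targets_d: np.ndarray
    beta: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("idx_i", "idx_j", "freqs", "targets_d"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.idx_i) == len(self.idx_j) == len(self.freqs)
                == len(self.targets_d)):
            raise ValueError("restraint arrays must have equal length")
        if np.any(self.idx_i >= self.idx_j):
            raise ValueError("restraint records require i < j")
        pairs = set(zip(self.idx_i.tolist(), self.idx_j.tolist()))
        if len(pairs) != len(self.idx_i):
            raise ValueError("duplicate restraint pair")
        if np.any(self.targets_d <= 0):
            raise ValueError("all target distances must be positive")

    @property
    def m(self) -> int:
        return len(self.idx_i)

    @property
    def records(self) -> list:
        return list(zip(self.idx_i.tolist(), self.idx_j.tolist(),
                        self.freqs.tolist(), self.targets_d.tolist()))

    def targets_at(self, alpha: float) -> np.ndarray:
        """Target distances re-converted at a different exponent alpha."""
        return self.beta * self.freqs ** (-alpha)

    def subset(self, indices: np.ndarray) -> "RestraintSet":
        """A new RestraintSet containing only the given record indices."""
        idx = np.asarray(indices)
        return RestraintSet(self.idx_i[idx], self.idx_j[idx],
                            self.freqs[idx], self.targets_d[idx],
                            self.beta, self.alpha)


# ---------------------------------------------------------------------------
# frequency matrix I/O
# ---------------------------------------------------------------------------

def _symmetrize(values: np.ndarray, source: str) -> np.ndarray:
    if not np.allclose(values, values.T, rtol=1e-12, atol=1e-12):
        logger.warning("asymmetric frequency matrix in %s; symmetrizing by "
                       "averaging", source)
        warnings.warn(f"asymmetric frequency matrix in {source}; "
                      "symmetrized by averaging", stacklevel=3)
    return 0.5 * (values + values.T)


def read_frequency_matrix(path, dialect: str = "square",
                          n: int | None = None) -> FrequencyMatrix:
    """Read a frequency matrix from TSV.

    ``dialect='square'`` expects a label header row and column;
    ``dialect='triplet'`` expects lines ``i<TAB>j<TAB>F`` with 1-based
    indices (pass ``n`` to fix the fragment count; otherwise the maximum
    index observed is used).  Asymmetric input is symmetrized by averaging
    with a warning.  The diagonal is zeroed (self-contacts carry no spatial
    information).
    """
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"no such file: {path}")
    if dialect == "square":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001 - surface as parse error
            raise ParseError(f"{path}: {exc}") from exc
        values = df.to_numpy(dtype=float, na_value=np.nan)
        if values.shape[0] != values.shape[1]:
            raise ParseError(f"{path}: matrix is {values.shape[0]}x"
                             f"{values.shape[1]}, expected square")
        if np.any(~np.isfinite(values)):
            row = int(np.argwhere(~np.isfinite(values))[0, 0]) + 2
            raise ParseError(f"{path}: non-numeric or missing cell at line {row}")
        if np.any(values < 0):
            row = int(np.argwhere(values < 0)[0, 0]) + 2
            raise ParseError(f"{path}: negative frequency at line {row}")
        labels = tuple(str(c) for c in df.columns)
        values = _symmetrize(values, str(path))
    elif dialect == "triplet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 tab-separated "
                                     f"fields, got {len(parts)}")
                try:
                    i, j, f = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if i < 1 or j < 1:
                    raise ParseError(f"{path}:{lineno}: indices are 1-based")
                if f < 0:
                    raise ParseError(f"{path}:{lineno}: negative frequency")
                rows.append((i - 1, j - 1, f))
        if not rows:
            raise NoDataError(f"{path}: empty triplet file")
        size = n if n is not None else max(max(r[0], r[1]) for r in rows) + 1
        raw = np.zeros((size, size))
        filled = np.zeros((size, size), dtype=bool)
        for i, j, f in rows:
            if i >= size or j >= size:
                raise ParseError(f"{path}: index {max(i, j) + 1} exceeds n={size}")
            raw[i, j] = f
            filled[i, j] = True
        both = filled & filled.T
        if np.any(both & (raw != raw.T)):
            values = _symmetrize(np.where(filled, raw, raw.T), str(path))
        else:
            values = np.where(filled, raw, raw.T)
        labels = tuple(f"frag{i + 1}" for i in range(size))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    np.fill_diagonal(values, 0.0)
    return FrequencyMatrix(values=values, labels=labels)


def write_frequency_matrix(fm: FrequencyMatrix, path) -> None:
    """Write a frequency matrix as a square labelled TSV."""
    df = pd.DataFrame(fm.values, index=list(fm.labels), columns=list(fm.labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# fragment table → segment model
# ---------------------------------------------------------------------------

def build_segment_model(fragment_table_path,
                        params: EnergyParams | None = None) -> SegmentModel:
    """Build the segment chain from a BED-like fragment table.

    n fragment rows yield a chain with n segments and n+1 end points; rest
    lengths are (end − start) / packing_density / length_scale_nm.
    """
    params = params or EnergyParams()
    path = Path(fragment_table_path)
    if not path.is_file():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64})
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise NoDataError(f"{path}: empty fragment table")
    if df["chrom"].nunique() != 1:
        raise ParseError(f"{path}: fragment table must describe one chromosome")
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    bad = np.flatnonzero(starts[1:] != ends[:-1])
    if bad.size:
        row = int(bad[0]) + 2
        raise ParseError(f"{path}: gap or overlap between fragments at row {row}")
    spans = np.column_stack([starts, ends])
    return SegmentModel.from_spans(str(df["chrom"].iloc[0]), spans, params)


# ---------------------------------------------------------------------------
# frequency → distance conversion
# ---------------------------------------------------------------------------

def convert_frequencies(fm: FrequencyMatrix,
                        cp: ConversionParams) -> RestraintSet:
    """Convert frequencies into distance restraints, D = beta * F**(-alpha).

    Pairs with F ≤ min_freq are dropped: an unobserved contact is treated as
    censoring, not as an infinite-distance measurement.
    """
    iu, ju = np.triu_indices(fm.n, k=1)
    freqs = fm.values[iu, ju]
    keep = freqs > cp.min_freq
    if not np.any(keep):
        raise NoDataError("no fragment pair passes the frequency threshold")
    freqs = freqs[keep]
    targets = cp.beta * freqs ** (-cp.alpha)
    return RestraintSet(idx_i=iu[keep], idx_j=ju[keep], freqs=freqs,
                        targets_d=targets, beta=cp.beta, alpha=cp.alpha)


def calibrate_beta(fm: FrequencyMatrix, model: SegmentModel,
                   alpha: float) -> float:
    """Calibrate the conversion scale beta from sequence-adjacent pairs.

    beta is chosen so that the mean converted distance over adjacent
    fragment pairs with F > 0 equals the mean rest length of the chain.
    """
    if fm.n != model.n:
        raise CalibrationError(
            f"matrix has {fm.n} fragments, model has {model.n}")
    adj = np.array([fm.values[i, i + 1] for i in range(fm.n - 1)])
    adj = adj[adj > 0]
    if adj.size == 0:
        raise CalibrationError("no sequence-adjacent pair with positive "
                               "frequency; cannot calibrate beta")
    mean_rest = float(np.mean(model.rest_lengths))
    return mean_rest / float(np.mean(adj ** (-alpha)))


def calibrate_beta_records(restraints_freqs: np.ndarray,
                           idx_i: np.ndarray, idx_j: np.ndarray,
                           model: SegmentModel, alpha: float) -> float:
    """Like :func:`calibrate_beta` but from an explicit record list (used by
    cross-validation, where only the training pairs may inform the scale)."""
    adjacent = (np.asarray(idx_j) - np.asarray(idx_i)) == 1
    freqs = np.asarray(restraints_freqs)[adjacent]
    freqs = freqs[freqs > 0]
    if freqs.size == 0:
        raise CalibrationError("no adjacent pair in the record set")
    mean_rest = float(np.mean(model.rest_lengths))
    return mean_rest / float(np.mean(freqs ** (-alpha)))


# ---------------------------------------------------------------------------
# structure I/O (coordinates on disk are in nm)
# ---------------------------------------------------------------------------

def write_structure(conf: Conformation, model: SegmentModel,
                    params: EnergyParams, path, format: str = "xyz") -> None:
    """Write a conformation in nm as XYZ or as a PDB CA pseudo-atom trace."""
    path = Path(path)
    coords_nm = conf.coords * params.length_scale_nm
    if format == "xyz":
        lines = [f"{conf.n_points}", f"chromens chain {model.chrom} (nm)"]
        for x, y, z in coords_nm:
            lines.append(f"C {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "pdb":
        n = conf.n_points
        atoms = AtomArray(n)
        atoms.coord = np.asarray(coords_nm, dtype=np.float32)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.full(n, "GLY")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        atoms.hetero = np.full(n, False)
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))
    else:
        raise ValueError(f"unknown structure format: {format!r}")


def read_structure(path, params: EnergyParams | None = None) -> Conformation:
    """Read a conformation written by :func:`write_structure` (any format)."""
    params = params or EnergyParams()
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty structure file")
    if text.lstrip().split(None, 1)[0].isdigit():  # XYZ: first token is a count
        lines = text.splitlines()
        try:
            count = int(lines[0].strip())
            coords = []
            for lineno, line in enumerate(lines[2:2 + count], start=3):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 'El x y z'")
                coords.append([float(v) for v in parts[1:]])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed XYZ file: {exc}") from exc
        if len(coords) != count:
            raise ParseError(f"{path}: XYZ declares {count} atoms, "
                             f"found {len(coords)}")
        coords_nm = np.asarray(coords)
    else:
        try:
            pdb = PDBFile.read(str(path))
            atoms = pdb.get_structure(model=1)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"{path}: malformed PDB file: {exc}") from exc
        coords_nm = np.asarray(atoms.coord, dtype=float)
    return Conformation(coords_nm / params.length_scale_nm)


# ---------------------------------------------------------------------------
# ensemble I/O
# ---------------------------------------------------------------------------

WEIGHTS_FILENAME = "weights.tsv"


def write_ensemble(ensemble, model: SegmentModel, params: EnergyParams,
                   directory, format: str = "xyz") -> None:
    """Write every member structure plus a weights table to a directory."""
    from .bayes import EnsembleState  # local import to avoid a cycle

    if not isinstance(ensemble, EnsembleState):
        raise TypeError("expected an EnsembleState")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, (conf, weight) in enumerate(ensemble.members):
        fname = f"member_{idx:04d}.{format}"
        write_structure(conf, model, params, directory / fname, format=format)
        rows.append((idx, weight, ensemble.log_likelihoods[idx]))
    df = pd.DataFrame(rows, columns=["index", "weight", "log_likelihood"])
    df.to_csv(directory / WEIGHTS_FILENAME, sep="\t", index=False,
              float_format="%.12g")


def read_ensemble(directory, params: EnergyParams | None = None):
    """Read an ensemble directory written by :func:`write_ensemble`."""
    from .bayes import EnsembleState

    params = params or EnergyParams()
    directory = Path(directory)
    weights_path = directory / WEIGHTS_FILENAME
    if not weights_path.is_file():
        raise NoDataError(f"{directory}: no {WEIGHTS_FILENAME} found")
    df = pd.read_csv(weights_path, sep="\t")
    structure_files = sorted(p for p in directory.iterdir()
                             if p.name.startswith("member_"))
    if len(structure_files) != len(df):
        raise ChromensError(
            f"{directory}: {len(structure_files)} structures but "
            f"{len(df)} weight rows")
    total = float(df["weight"].sum())
    if abs(total - 1.0) > 1e-9:
        raise ChromensError(
            f"{directory}: weights sum to {total:.6g}, expected 1")
    members = []
    for idx, path in enumerate(structure_files):
        conf = read_structure(path, params)
        members.append((conf, float(df["weight"].iloc[idx])))
    return EnsembleState(members=members,
                         log_likelihoods=df["log_likelihood"].to_numpy(float))
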