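"""Expression-matrix I/O, normalization and fold planning.

The in-memory container is :class:`ExpressionDataset`: a samples x features
float matrix with a binary class label per sample.  Labels are stored as
+1 / -1 (positive class = minority by default, overridable) because the
downstream metrics (sensitivity, specificity, balanced rate) depend on which
class is "positive".

Supported on-disk formats: delimited text (CSV/TSV, header row required) and
a dense ARFF subset (numeric attributes plus one nominal label attribute).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold


class DatasetFormatError(ValueError):
    """File structure is not a readable expression matrix (e.g. no label column)."""


class DatasetParseError(ValueError):
    """A cell could not be parsed; message carries the row/column position."""


class UnsupportedTaskError(ValueError):
    """The label column does not describe a two-class problem."""


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with binary labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Expression values, arbitrary units.
    labels : ndarray of shape (n_samples,)
        +1 for the positive class, -1 for the negative class.
    feature_names : list of str
        Unique name per feature (column).
    sample_ids : list of str
        Identifier per sample (row).
    positive_label, negative_label : str
        The original label values mapped to +1 / -1.
    discrete_mask : ndarray of bool, optional
        Features flagged as discrete (affects the Relief diff); default all
        continuous.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    positive_label: str = "+1"
    negative_label: str = "-1"
    discrete_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.values.ndim != 2:
            raise DatasetFormatError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if n < 4:
            raise DatasetFormatError(f"need at least 4 samples, got {n}")
        if p < 2:
            raise DatasetFormatError(f"need at least 2 features, got {p}")
        if self.labels.shape != (n,):
            raise DatasetFormatError("labels length must equal n_samples")
        if not np.isfinite(self.values).all():
            raise DatasetParseError("missing or non-finite values in matrix")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {-1, 1} or len(uniq) != 2:
            raise UnsupportedTaskError("labels must contain exactly the two classes +1/-1")
        if min((self.labels == 1).sum(), (self.labels == -1).sum()) < 2:
            raise UnsupportedTaskError("each class needs at least 2 samples")
        if len(self.feature_names) != p:
            raise DatasetFormatError("feature_names length must equal n_features")
        if len(set(self.feature_names)) != p:
            raise DatasetFormatError("feature_names must be unique")
        if len(self.sample_ids) != n:
            raise DatasetFormatError("sample_ids length must equal n_samples")
        if self.discrete_mask is not None:
            self.discrete_mask = np.asarray(self.discrete_mask, dtype=bool)
            if self.discrete_mask.shape != (p,):
                raise DatasetFormatError("discrete_mask length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        return int((self.labels == 1).sum()), int((self.labels == -1).sum())


@dataclass
class FoldPlan:
    """Repeated stratified k-fold assignment.

    ``assignments[r, i]`` is the fold id (0..k-1) of sample ``i`` in repeat
    ``r``.  Each repeat partitions all samples exactly once.
    """

    k: int
    repeats: int
    assignments: np.ndarray = field(repr=False)
    seed: int = 0

    def test_rows(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_rows(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _map_labels(raw: pd.Series, positive_label: str | None) -> tuple[np.ndarray, str, str]:
    classes = sorted(raw.astype(str).unique())
    if len(classes) < 2:
        raise UnsupportedTaskError(f"label column has a single class {classes!r}")
    if len(classes) > 2:
        raise UnsupportedTaskError(
            f"label column has {len(classes)} classes {classes!r}; only binary tasks are supported"
        )
    if positive_label is not None:
        pos = str(positive_label)
        if pos not in classes:
            raise DatasetFormatError(f"positive label {pos!r} not found among {classes!r}")
    else:
        # minority class is "positive"; ties resolved by sorted order
        counts = raw.astype(str).value_counts()
        pos = classes[0] if counts[classes[0]] <= counts[classes[1]] else classes[1]
    neg = classes[0] if classes[1] == pos else classes[1]
    y = np.where(raw.astype(str).to_numpy() == pos, 1, -1).astype(np.int8)
    return y, pos, neg


def _parse_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        return pd.read_csv(path, sep=sep, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DatasetFormatError(f"cannot read {path}: {exc}") from exc


_ARFF_ATTR = re.compile(r"@attribute\s+('([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)", re.IGNORECASE)


def _parse_arff(path: Path) -> pd.DataFrame:
    """Dense-ARFF reader: numeric attributes and nominal specifications only."""
    names: list[str] = []
    in_data = False
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            m = _ARFF_ATTR.match(line)
            if m is None:
                raise DatasetFormatError(f"{path}:{lineno}: malformed @attribute line")
            names.append(m.group(2) or m.group(3) or m.group(4))
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if in_data:
            if line.startswith("{"):
                raise DatasetFormatError(f"{path}:{lineno}: sparse ARFF rows are not supported")
            cells = [c.strip().strip("'\"") for c in line.split(",")]
            if len(cells) != len(names):
                raise DatasetParseError(
                    f"{path}:{lineno}: expected {len(names)} cells, got {len(cells)}"
                )
            rows.append(cells)
    if not in_data or not names:
        raise DatasetFormatError(f"{path}: not a parseable dense ARFF file")
    return pd.DataFrame(rows, columns=names, dtype=str)


def load_dataset(
    path: str | Path,
    label_column: str | int,
    fmt: str | None = None,
    transpose: bool = False,
    positive_label: str | None = None,
) -> ExpressionDataset:
    """Load an expression matrix with a binary label column.

    Parameters
    ----------
    path : path
        CSV/TSV (header required) or dense ARFF file; format autodetected
        from the extension unless ``fmt`` is given (``"delimited"``/``"arff"``).
    label_column : str or int
        Column name, or positional index into the (possibly transposed) table.
    transpose : bool
        Set when the file stores genes as rows and samples as columns.
    positive_label : str, optional
        Which label value is the positive class; default: the minority class.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "arff" if path.suffix.lower() == ".arff" else "delimited"
    if fmt == "arff":
        frame = _parse_arff(path)
    elif fmt == "delimited":
        frame = _parse_delimited(path)
    else:
        raise DatasetFormatError(f"unknown format {fmt!r}")

    if transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(names="sample")
        frame.columns = [str(c) for c in frame.columns]

    if isinstance(label_column, int):
        if not 0 <= label_column < frame.shape[1]:
            raise DatasetFormatError(f"label column index {label_column} out of range")
        label_name = frame.columns[label_column]
    else:
        label_name = str(label_column)
        if label_name not in frame.columns:
            raise DatasetFormatError(
                f"label column {label_name!r} not found; columns: {list(frame.columns)[:8]}..."
            )
    raw_labels = frame[label_name]
    body = frame.drop(columns=[label_name])

    # a non-numeric first column is treated as sample ids
    sample_ids = [str(i) for i in range(len(body))]
    first = body.columns[0] if body.shape[1] else None
    if first is not None:
        probe = pd.to_numeric(body[first], errors="coerce")
        if probe.isna().any():
            sample_ids = body[first].astype(str).tolist()
            body = body.drop(columns=[first])

    try:
        # astype(float) round-trips repr-formatted values exactly, unlike
        # pandas' fast to_numeric parser
        numeric = body.astype(float)
    except (TypeError, ValueError):
        probe = body.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(probe.isna().to_numpy() & body.notna().to_numpy())
        pos = bad[0] if len(bad) else np.argwhere(probe.isna().to_numpy())[0]
        raise DatasetParseError(
            f"non-numeric cell at row {pos[0]}, column {body.columns[pos[1]]!r} "
            f"(value {body.iat[pos[0], pos[1]]!r})"
        ) from None
    if numeric.isna().to_numpy().any():
        pos = np.argwhere(numeric.isna().to_numpy())[0]
        raise DatasetParseError(f"missing value at row {pos[0]}, column {body.columns[pos[1]]!r}")
    y, pos, neg = _map_labels(raw_labels, positive_label)
    return ExpressionDataset(
        values=numeric.to_numpy(dtype=float),
        labels=y,
        feature_names=[str(c) for c in body.columns],
        sample_ids=sample_ids,
        positive_label=pos,
        negative_label=neg,
    )


def write_dataset(data: ExpressionDataset, path: str | Path, label_column: str = "class") -> None:
    """Write a dataset as delimited text (round-trips values bit-exactly)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.DataFrame(data.values, columns=data.feature_names)
    frame.insert(0, "sample", data.sample_ids)
    frame[label_column] = np.where(data.labels == 1, data.positive_label, data.negative_label)
    # repr-based float formatting guarantees exact round-trip
    frame.to_csv(path, sep=sep, index=False, float_format=lambda v: repr(float(v)))


def subset_samples(data: ExpressionDataset, rows: np.ndarray) -> ExpressionDataset:
    """Row-subset view (copy) keeping feature metadata."""
    rows = np.asarray(rows, dtype=int)
    return ExpressionDataset(
        values=data.values[rows],
        labels=data.labels[rows],
        feature_names=list(data.feature_names),
        sample_ids=[data.sample_ids[i] for i in rows],
        positive_label=data.positive_label,
        negative_label=data.negative_label,
        discrete_mask=None if data.discrete_mask is None else data.discrete_mask.copy(),
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def minmax_stats(values: np.ndarray, stats_from: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (min, range) computed over the ``stats_from`` rows only."""
    stats_from = np.asarray(stats_from, dtype=int)
    if stats_from.size == 0:
        raise ValueError("stats_from must be non-empty")
    sub = values[stats_from]
    lo = sub.min(axis=0)
    rng = sub.max(axis=0) - lo
    return lo, rng


def apply_minmax(values: np.ndarray, lo: np.ndarray, rng: np.ndarray) -> np.ndarray:
    """Rescale to [0,1] with clipping; constant features map to 0."""
    safe = np.where(rng > 0, rng, 1.0)
    out = (values - lo) / safe
    out[:, rng <= 0] = 0.0
    return np.clip(out, 0.0, 1.0)


def minmax_normalize(data: ExpressionDataset, stats_from: np.ndarray | None = None) -> ExpressionDataset:
    """Min-max rescale every feature to [0,1].

    Statistics come ONLY from ``stats_from`` rows (training rows); out-of-range
    values in the remaining rows are clipped.  Constant features map to 0.
    """
    if stats_from is None:
        stats_from = np.arange(data.n_samples)
    lo, rng = minmax_stats(data.values, stats_from)
    out = subset_samples(data, np.arange(data.n_samples))
    out.values = apply_minmax(data.values, lo, rng)
    return out


# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------

def make_folds(data: ExpressionDataset, k: int, repeats: int, seed: int) -> FoldPlan:
    """Repeated stratified k-fold plan; deterministic for a fixed seed.

    Falls back to unstratified folds (with a warning) when a class has fewer
    than ``k`` samples.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > data.n_samples:
        raise ValueError(f"k={k} exceeds n_samples={data.n_samples}")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    min_class = min(data.class_counts)
    assignments = np.empty((repeats, data.n_samples), dtype=np.int32)
    root = np.random.SeedSequence(seed)
    for r, child in enumerate(root.spawn(repeats)):
        state = int(child.generate_state(1)[0] % (2**32 - 1))
        if min_class >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
            split = splitter.split(data.values, data.labels)
        else:
            warnings.warn(
                f"class with {min_class} samples < k={k}; stratification relaxed",
                stacklevel=2,
            )
            splitter = KFold(n_splits=k, shuffle=True, random_state=state)
            split = splitter.split(data.values)
        for fold, (_, test_idx) in enumerate(split):
            assignments[r, test_idx] = fold
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)
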