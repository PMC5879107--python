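"""Count-table and covariate-table containers.

The model operates on an ``N x J`` matrix of OTU counts (``N`` samples,
``J`` OTUs) together with a per-time-point design matrix.  Samples are
indexed by a time point ``t_i`` (``i = 1..n``) and a replicate number
``k = 1..K_i``, so ``N = sum_i K_i``.  This module reads, validates,
filters and encodes those tables; it contains no inference code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountData",
    "CovariateTable",
    "load_count_table",
    "save_count_table",
    "load_metadata",
    "filter_otus",
    "build_design",
]


@dataclass
class CountData:
    """Validated OTU count matrix with its time/replicate layout.

    Parameters
    ----------
    counts
        Integer matrix, shape ``(N, J)``; rows are samples, columns OTUs.
    time_of_sample
        Time stamp of each sample, length ``N`` (same units as the
        covariate table's ``time`` column).
    replicate_index
        1-based replicate number ``k`` within a time point, length ``N``.
    otu_ids, sample_ids
        Column and row labels.
    """

    counts: np.ndarray
    time_of_sample: np.ndarray
    replicate_index: np.ndarray
    otu_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x OTUs)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {bad[0]}, OTU {bad[1]}: counts must be >= 0"
            )
        self.time_of_sample = np.asarray(self.time_of_sample, dtype=float)
        self.replicate_index = np.asarray(self.replicate_index, dtype=int)
        N, J = self.counts.shape
        if self.time_of_sample.shape != (N,):
            raise ValueError("time_of_sample must have one entry per sample")
        if self.replicate_index.shape != (N,):
            raise ValueError("replicate_index must have one entry per sample")
        if not self.otu_ids:
            self.otu_ids = [f"OTU{j + 1}" for j in range(J)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(N)]
        if len(set(self.otu_ids)) != J:
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != N:
            raise ValueError("duplicate sample ids")
        row_tot = self.counts.sum(axis=1)
        if np.any(row_tot == 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(row_tot == 0)]
            raise ValueError(
                f"all-zero sample rows {bad}: size factors would degenerate; "
                "remove these samples before analysis"
            )
        pairs = set(zip(self.time_of_sample.tolist(), self.replicate_index.tolist()))
        if len(pairs) != N:
            raise ValueError("duplicate (time, replicate) pair: samples must be unique")

    # -- layout helpers -------------------------------------------------
    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def time_points(self) -> np.ndarray:
        """Sorted unique observation times ``t_1 < ... < t_n``."""
        return np.unique(self.time_of_sample)

    @property
    def n(self) -> int:
        return self.time_points.size

    @property
    def T(self) -> float:
        """Span of the observation window (max time)."""
        return float(self.time_points[-1])

    @property
    def replicates_per_time(self) -> np.ndarray:
        """``K_i``: number of replicate samples at each time point."""
        _, counts = np.unique(self.time_of_sample, return_counts=True)
        return counts

    @property
    def sample_time_index(self) -> np.ndarray:
        """Index ``i`` of each sample's time point into ``time_points``."""
        return np.searchsorted(self.time_points, self.time_of_sample)


@dataclass
class CovariateTable:
    """Per-time-point design information.

    ``continuous`` holds standardized continuous covariates (mean 0,
    variance 1 over the ``n`` time points).  ``categorical`` holds ordinal
    covariates coded ``0..C-1`` with ``-1`` marking a missing value;
    level 0 is the baseline ("none") and is absorbed into the intercept-free
    baseline mean, so a covariate with ``C`` levels contributes ``C - 1``
    indicator columns to the design.
    """

    continuous: np.ndarray  # (n, P_cont), standardized
    categorical: np.ndarray  # (n, P_cat), levels 0..C-1, missing = -1
    n_levels: list[int]  # C_q per categorical covariate
    continuous_names: list[str]
    categorical_names: list[str]
    times: np.ndarray  # (n,) time points, sorted

    def __post_init__(self) -> None:
        self.continuous = np.atleast_2d(np.asarray(self.continuous, dtype=float))
        self.categorical = np.atleast_2d(np.asarray(self.categorical, dtype=int))
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        if self.continuous.size == 0:
            self.continuous = np.zeros((n, 0))
        if self.categorical.size == 0:
            self.categorical = np.zeros((n, 0), dtype=int)
        for q, C in enumerate(self.n_levels):
            col = self.categorical[:, q]
            if np.any((col < -1) | (col >= C)):
                raise ValueError(
                    f"categorical covariate {self.categorical_names[q]} has a level "
                    f"outside -1..{C - 1}"
                )

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, P_cat) mask of missing categorical cells."""
        return self.categorical == -1

    @property
    def P(self) -> int:
        return self.continuous.shape[1] + sum(C - 1 for C in self.n_levels)

    @property
    def column_labels(self) -> list[str]:
        labels = list(self.continuous_names)
        for name, C in zip(self.categorical_names, self.n_levels):
            labels += [f"{name}:{lev}" for lev in range(1, C)]
        return labels

    def design_matrix(self, categorical_values: np.ndarray | None = None) -> np.ndarray:
        """Expand to the ``(n, P)`` design matrix ``X``.

        Parameters
        ----------
        categorical_values
            Optional ``(n, P_cat)`` replacement for the stored categorical
            levels (used by the sampler to plug in imputed values).  Any
            remaining ``-1`` is treated as the baseline level 0.
        """
        cats = self.categorical if categorical_values is None else np.asarray(
            categorical_values, dtype=int
        )
        blocks = [self.continuous]
        for q, C in enumerate(self.n_levels):
            col = np.maximum(cats[:, q], 0)
            dummies = (col[:, None] == np.arange(1, C)[None, :]).astype(float)
            blocks.append(dummies)
        return np.hstack(blocks)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_count_table(
    path,
    orientation: str = "samples_x_otus",
    metadata: pd.DataFrame | None = None,
) -> CountData:
    """Read an OTU count table from TSV or BIOM-style JSON.

    TSV layout: first column holds row IDs, header row holds column IDs.
    ``orientation`` says which axis is samples (``"samples_x_otus"`` or
    ``"otus_x_samples"``; the matrix is transposed to samples-by-OTUs).
    BIOM JSON (classic dense or sparse format) is detected by a ``.biom``
    or ``.json`` suffix, or by the file starting with ``{``.

    ``metadata`` maps sample IDs to ``time`` and ``replicate``; without it
    samples are laid out as one replicate per unit time (mostly useful in
    tests and examples).
    """
    path = str(path)
    with open(path) as fh:
        head = fh.read(1)
    if path.endswith((".biom", ".json")) or head == "{":
        mat, sample_ids, otu_ids = _read_biom_json(path)
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"malformed count table {path}: {exc}") from exc
        if df.isna().any().any():
            line = int(np.argwhere(df.isna().to_numpy())[0][0]) + 2
            raise ValueError(f"malformed count table {path}: missing cell near line {line}")
        arr = df.to_numpy()
        if not np.all(np.mod(arr, 1) == 0):
            raise ValueError(f"non-integer count in {path}")
        if orientation == "otus_x_samples":
            mat = arr.T.astype(np.int64)
            sample_ids = [str(c) for c in df.columns]
            otu_ids = [str(i) for i in df.index]
        elif orientation == "samples_x_otus":
            mat = arr.astype(np.int64)
            sample_ids = [str(i) for i in df.index]
            otu_ids = [str(c) for c in df.columns]
        else:
            raise ValueError(f"unknown orientation {orientation!r}")

    if metadata is not None:
        meta = metadata.set_index(metadata.columns[0]) if "sample" not in metadata.columns else metadata.set_index("sample")
        time = meta.loc[sample_ids, "time"].to_numpy(dtype=float)
        rep = meta.loc[sample_ids, "replicate"].to_numpy(dtype=int)
    else:
        time = np.arange(len(sample_ids), dtype=float)
        rep = np.ones(len(sample_ids), dtype=int)
    return CountData(mat, time, rep, otu_ids=otu_ids, sample_ids=sample_ids)


def _read_biom_json(path: str):
    """Minimal reader for classic BIOM 1.0 JSON tables (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_rows, n_cols = doc["shape"]
        row_ids = [r["id"] for r in doc["rows"]]
        col_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((n_rows, n_cols))
        if doc.get("matrix_type", "sparse") == "dense":
            mat[:] = np.asarray(doc["data"])
        else:
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed BIOM table {path}: {exc}") from exc
    # BIOM convention: rows are observations (OTUs), columns are samples.
    return mat.T.astype(np.int64), col_ids, row_ids


def save_count_table(data: CountData, path) -> None:
    """Write counts as TSV (samples in rows), the inverse of ``load_count_table``."""
    df = pd.DataFrame(data.counts, index=data.sample_ids, columns=data.otu_ids)
    df.to_csv(path, sep="\t", index_label="sample")


def load_metadata(path, days_to_years: bool = False) -> pd.DataFrame:
    """Read the sample metadata TSV (columns ``sample``, ``time``, ``replicate``).

    ``days_to_years`` divides the time column by 365.25 for studies whose
    metadata records day counts but whose analysis (e.g. yearly-periodic
    trajectories) works on the year scale.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "replicate"):
        if col not in df.columns:
            raise ValueError(f"metadata {path} lacks required column {col!r}")
    if days_to_years:
        df = df.assign(time=df["time"] / 365.25)
    return df


# ---------------------------------------------------------------------------
# Filtering and design construction
# ---------------------------------------------------------------------------

def filter_otus(data: CountData, min_mean: float = 5.0) -> CountData:
    """Keep OTUs whose mean count over samples is at least ``min_mean``.

    Low-frequency OTUs carry almost no information about covariate effects
    and inflate the regression dimension; the conventional screen retains
    OTUs averaging at least five reads per sample.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = data.counts.mean(axis=0) >= min_mean
    if not keep.any():
        raise ValueError(f"filter_otus(min_mean={min_mean}) removed every OTU")
    return CountData(
        data.counts[:, keep],
        data.time_of_sample,
        data.replicate_index,
        otu_ids=[o for o, k in zip(data.otu_ids, keep) if k],
        sample_ids=list(data.sample_ids),
    )


def build_design(
    raw_covariates: pd.DataFrame,
    discretization_breaks: dict[str, np.ndarray] | None = None,
    categorical: list[str] | None = None,
    time_column: str = "time",
) -> CovariateTable:
    """Standardize, discretize and dummy-encode a raw covariate table.

    Parameters
    ----------
    raw_covariates
        One row per time point.  Must contain ``time_column``; every other
        column is a covariate.
    discretization_breaks
        Mapping from covariate name to strictly increasing break points.
        Values below the first break map to level 0, between breaks ``b_l``
        and ``b_{l+1}`` to level ``l+1``, and so on — the standard treatment
        of heavily right-skewed concentration measurements (none / low /
        medium / high / very high).  ``-1`` in the input marks missing and
        is carried through.
    categorical
        Names of columns that are already ordinal-coded (integers, with
        ``-1`` for missing).  Columns listed in ``discretization_breaks``
        are categorical automatically.
    """
    breaks = discretization_breaks or {}
    categorical = list(categorical or [])
    df = raw_covariates.sort_values(time_column).reset_index(drop=True)
    times = df[time_column].to_numpy(dtype=float)
    if np.unique(times).size != times.size:
        raise ValueError("raw covariate table must have one row per time point")

    cont_cols, cont_names = [], []
    cat_cols, cat_names, n_levels = [], [], []
    for name in df.columns:
        if name == time_column:
            continue
        col = df[name].to_numpy()
        if name in breaks:
            b = np.asarray(breaks[name], dtype=float)
            if b.ndim != 1 or b.size == 0 or np.any(np.diff(b) <= 0):
                raise ValueError(f"breaks for {name!r} must be strictly increasing")
            miss = col == -1
            lev = np.searchsorted(b, col.astype(float), side="right")
            lev[miss] = -1
            col, is_cat, C = lev.astype(int), True, b.size + 1
        elif name in categorical:
            col = col.astype(int)
            C = int(col.max()) + 1
            is_cat = True
        else:
            col = col.astype(float)
            if np.isnan(col).any():
                raise ValueError(
                    f"continuous covariate {name!r} has missing values; only "
                    "categorical covariates may be missing (code -1)"
                )
            sd = col.std(ddof=0)
            if sd == 0:
                raise ValueError(f"continuous covariate {name!r} is constant: cannot standardize")
            cont_cols.append((col - col.mean()) / sd)
            cont_names.append(name)
            continue
        observed = np.unique(col[col >= 0])
        if observed.size < 2:
            warnings.warn(
                f"categorical covariate {name!r} has a single observed level; dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        cat_cols.append(col)
        cat_names.append(name)
        n_levels.append(max(C, 2))

    return CovariateTable(
        continuous=np.column_stack(cont_cols) if cont_cols else np.zeros((times.size, 0)),
        categorical=np.column_stack(cat_cols) if cat_cols else np.zeros((times.size, 0), dtype=int),
        n_levels=n_levels,
        continuous_names=cont_names,
        categorical_names=cat_names,
        times=times,
    )
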