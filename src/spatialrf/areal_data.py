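"""Areal attribute tables: the unit of analysis.

An :class:`AreaDataset` holds one row per region — a response (a proportion in
the motivating small-area application, but any real response is accepted),
named covariates (numeric or categorical), and optional planar centroids.
Missing values are tolerated up to :func:`impute_spatial`, which fills them
from contiguity neighbourhoods: continuous values by the neighbourhood mean,
categorical values by the modal neighbourhood category.  Regions whose missing
values cannot be filled because no neighbour carries an observed value (e.g.
islands with no contiguous neighbours) are dropped and reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .weights import NeighborhoodStructure

logger = logging.getLogger(__name__)

#: strings treated as missing in CSV input
NA_VALUES = ["", "NA"]


@dataclass
class AreaDataset:
    """Per-region response, covariates, and optional centroids.

    ``y`` and ``X`` are indexed by ``region_ids``; centroids, when present,
    are an (n, 2) array of planar (x, y) coordinates aligned with the regions.
    """

    region_ids: tuple[str, ...]
    y: pd.Series
    X: pd.DataFrame
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(r) for r in self.region_ids)
        if len(set(ids)) != len(ids):
            raise DataError("duplicate region identifiers")
        self.region_ids = ids
        idx = pd.Index(ids, name="region_id")
        if len(self.y) != len(ids) or len(self.X) != len(ids):
            raise DataError("response/covariates misaligned with region ids")
        self.y = pd.Series(np.asarray(self.y, dtype=object), index=idx, name=self.y.name or "y")
        self.y = pd.to_numeric(self.y, errors="coerce")
        self.X = self.X.set_axis(idx, axis=0)
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (len(ids), 2):
                raise DataError("centroids must be an (n, 2) array")
            self.centroids = c

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.X.columns)

    def has_missing(self) -> bool:
        return bool(self.y.isna().any() or self.X.isna().any().any())

    def subset(self, positions: Sequence[int]) -> "AreaDataset":
        pos = list(positions)
        return AreaDataset(
            tuple(self.region_ids[i] for i in pos),
            self.y.iloc[pos],
            self.X.iloc[pos],
            None if self.centroids is None else self.centroids[pos],
        )

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Numeric (n, p) matrix with categorical columns one-hot encoded.

        Dummy columns are named ``col=level`` and ordered deterministically.
        """
        parts, names = [], []
        for col in self.X.columns:
            s = self.X[col]
            if pd.api.types.is_numeric_dtype(s):
                parts.append(np.asarray(s, dtype=float)[:, None])
                names.append(col)
            else:
                levels = sorted(x for x in s.dropna().unique())
                for lev in levels:
                    parts.append((s == lev).to_numpy(dtype=float)[:, None])
                    names.append(f"{col}={lev}")
        if not parts:
            raise DataError("dataset has no covariates")
        return np.hstack(parts), names

    def with_centroids(self, centroids: np.ndarray) -> "AreaDataset":
        return replace(self, centroids=np.asarray(centroids, dtype=float))


def read_area_table(
    path,
    response_col: str,
    covariate_cols: Sequence[str],
    id_col: str,
    categorical_cols: Sequence[str] = (),
) -> AreaDataset:
    """Read an areal attribute table from CSV (header row, UTF-8).

    Cells that are empty, ``NA``, or unparseable as numbers become missing
    values rather than errors; named columns that are absent raise a
    configuration error and duplicate region ids a data error.  Columns listed
    in ``categorical_cols`` are kept as string categories.
    """
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=NA_VALUES, encoding="utf-8"
    )
    needed = [id_col, response_col, *covariate_cols]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise DataError(f"{path}: duplicate region id(s) {dups}")
    y = pd.to_numeric(df[response_col], errors="coerce")
    cats = set(categorical_cols)
    X = pd.DataFrame(index=df.index)
    for col in covariate_cols:
        X[col] = df[col] if col in cats else pd.to_numeric(df[col], errors="coerce")
    data = AreaDataset(tuple(ids), y.rename(response_col), X)
    out_of_range = int(((y < 0) | (y > 1)).sum())
    if out_of_range:
        # accepted — the library is not proportion-specific — but flagged
        logger.warning("%s: %d response values outside [0, 1]", path, out_of_range)
    return data


def read_centroids(path, id_col: str = "region_id", x_col: str = "x", y_col: str = "y") -> pd.DataFrame:
    """Read region centroids from CSV; returns a frame indexed by region id."""
    df = pd.read_csv(path, dtype={id_col: str}, na_values=NA_VALUES, keep_default_na=False)
    for c in (id_col, x_col, y_col):
        if c not in df.columns:
            raise ConfigurationError(f"{path}: missing column {c!r}")
    out = df.set_index(id_col)[[x_col, y_col]].astype(float)
    out.columns = ["x", "y"]
    return out


def attach_centroids(data: AreaDataset, table: pd.DataFrame) -> AreaDataset:
    """Align a centroid table (from :func:`read_centroids`) with a dataset."""
    missing = [r for r in data.region_ids if r not in table.index]
    if missing:
        raise DataError(f"centroids missing for region(s) {missing[:5]}")
    return data.with_centroids(table.loc[list(data.region_ids)].to_numpy())


def _modal_category(values: pd.Series) -> str:
    """Most frequent category; ties broken by lexicographic order of label."""
    counts = values.value_counts()
    top = counts.max()
    return sorted(counts[counts == top].index)[0]


def impute_spatial(
    data: AreaDataset, nbrs: NeighborhoodStructure
) -> tuple[AreaDataset, list[str]]:
    """Fill missing values from contiguity neighbourhoods.

    Continuous missing values become the mean of the neighbours' originally
    observed values; categorical missing values the modal neighbourhood
    category (ties broken lexicographically).  Only pre-imputation values feed
    the fill (single pass, order-independent), which also makes the operation
    idempotent.  A region with a missing value and no neighbour observing that
    variable — islands in particular — is removed and returned in ``dropped``.
    """
    sub = nbrs.subgraph(data.region_ids)
    y = data.y.copy()
    X = data.X.copy()
    dropped: set[int] = set()

    columns: list[tuple[str, pd.Series]] = [("__response__", data.y)]
    columns += [(c, data.X[c]) for c in data.X.columns]
    for name, original in columns:
        numeric = pd.api.types.is_numeric_dtype(original)
        miss = np.flatnonzero(original.isna().to_numpy())
        for i in miss:
            nb = sub.neighbors[i]
            donor = original.iloc[nb].dropna()
            if donor.empty:
                dropped.add(i)
                continue
            fill = float(donor.mean()) if numeric else _modal_category(donor)
            if name == "__response__":
                y.iloc[i] = fill
            else:
                X.iloc[i, X.columns.get_loc(name)] = fill

    if dropped:
        names = [data.region_ids[i] for i in sorted(dropped)]
        logger.warning(
            "dropping %d region(s) with unfillable missing values: %s",
            len(names), ", ".join(names),
        )
    keep = [i for i in range(data.n) if i not in dropped]
    out = AreaDataset(
        tuple(data.region_ids[i] for i in keep),
        y.iloc[keep],
        X.iloc[keep],
        None if data.centroids is None else data.centroids[keep],
    )
    return out, [data.region_ids[i] for i in sorted(dropped)]


def train_test_split(
    data: AreaDataset, train_frac: float, seed: int
) -> tuple[AreaDataset, AreaDataset]:
    """Random disjoint/exhaustive split; train gets floor(train_frac * n) regions.

    Deterministic given ``(data, train_frac, seed)``.  Within each part,
    regions keep their original file order.
    """
    if data.n < 2:
        raise ConfigurationError("need at least 2 regions to split")
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must be in (0, 1)")
    n_train = math.floor(train_frac * data.n)
    # guard both nominal shares: a fraction whose train or test share rounds
    # below one region is treated as an empty partition
    if n_train < 1 or math.floor((1.0 - train_frac) * data.n) < 1 or n_train >= data.n:
        raise ConfigurationError(
            f"train_frac={train_frac} yields an empty partition for n={data.n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    train_pos = sorted(perm[:n_train].tolist())
    test_pos = sorted(perm[n_train:].tolist())
    return data.subset(train_pos), data.subset(test_pos)


def write_dropped_report(dropped: Sequence[str], path) -> None:
    """One-column CSV listing regions removed during imputation."""
    pd.DataFrame({"region_id": list(dropped)}).to_csv(path, index=False)
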