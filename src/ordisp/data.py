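"""Clustered ordinal data: covariate schemas, design-matrix encoding and data splitting.

Long-format input has one row per observation with a cluster identifier, an ordinal
response and covariate values. Covariates are declared through :class:`CovariateSchema`
as continuous, binary or ordinal; ordinal covariates with L levels are expanded into
L-1 dummy columns with the first level as the reference. Columns can be standardized
to mean 0 / variance 1 (sample SD, ddof=1); the (mean, SD) record is stored so that
validation and test parts can reuse the record computed on the training part.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_KINDS = ("continuous", "binary", "ordinal")
VALID_ROLES = ("location", "dispersion", "both")


class EncodingError(ValueError):
    """Raised when the raw table cannot be encoded under the declared schemas."""


@dataclass(frozen=True)
class CovariateSchema:
    """Declaration of a single covariate.

    Parameters
    ----------
    name : column name in the raw table.
    kind : one of ``continuous``, ``binary``, ``ordinal``.
    levels : ordered level labels for binary/ordinal covariates. The first level is
        the reference category and receives no dummy column.
    """

    name: str
    kind: str
    levels: tuple = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            if self.levels is not None:
                raise ValueError(f"continuous covariate {self.name!r} must not declare levels")
        else:
            if self.levels is None:
                raise ValueError(f"{self.kind} covariate {self.name!r} requires levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate level labels for {self.name!r}")
            if self.kind == "binary" and len(self.levels) != 2:
                raise ValueError(f"binary covariate {self.name!r} must have exactly 2 levels")
            if self.kind == "ordinal" and len(self.levels) < 3:
                raise ValueError(f"ordinal covariate {self.name!r} needs >= 3 levels")

    @property
    def reference_level(self):
        return None if self.levels is None else self.levels[0]

    @property
    def n_columns(self) -> int:
        return 1 if self.kind == "continuous" else len(self.levels) - 1


@dataclass(frozen=True)
class ColumnInfo:
    """Metadata for one design-matrix column."""

    name: str        # e.g. "x3[2]" for level 2 of ordinal x3, or "age"
    covariate: str   # owning covariate name
    kind: str
    level: object = None  # level label for dummy columns, None for continuous


@dataclass
class ClusteredOrdinalData:
    """Encoded clustered ordinal data.

    ``X`` is the location design matrix, ``Z`` the dispersion design matrix; both have
    one row per observation. ``cluster`` holds integer codes 0..n_clusters-1 into
    ``cluster_ids``. ``standardization`` maps column names to the (mean, sd) pair used
    (sample SD convention, ddof=1), or is None when not standardized.
    """

    y: np.ndarray
    cluster: np.ndarray
    cluster_ids: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    k: int
    schemas: tuple
    x_columns: tuple
    z_columns: tuple
    roles: dict
    standardization: dict | None = None
    raw: pd.DataFrame | None = None
    cluster_col: str = "cluster"
    response_col: str = "y"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.y.size and (self.y.min() < 1 or self.y.max() > self.k):
            raise ValueError(f"responses must lie in 1..{self.k}")
        if not (len(self.y) == len(self.cluster) == self.X.shape[0] == self.Z.shape[0]):
            raise ValueError("row counts of y, cluster, X, Z must agree")
        self._pack_cache = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, minlength=self.n_clusters)

    def subset(self, rows: np.ndarray) -> "ClusteredOrdinalData":
        """Row subset with cluster codes recomputed (empty clusters dropped)."""
        rows = np.asarray(rows)
        labels = self.cluster_ids[self.cluster[rows]]
        new_ids, codes = np.unique(labels, return_inverse=True)
        return ClusteredOrdinalData(
            y=self.y[rows], cluster=codes, cluster_ids=new_ids,
            X=self.X[rows], Z=self.Z[rows], k=self.k, schemas=self.schemas,
            x_columns=self.x_columns, z_columns=self.z_columns, roles=dict(self.roles),
            standardization=self.standardization,
            raw=None if self.raw is None else self.raw.iloc[rows].reset_index(drop=True),
            cluster_col=self.cluster_col, response_col=self.response_col,
        )

    def restrict_to_cluster(self, label) -> "ClusteredOrdinalData":
        code = np.flatnonzero(self.cluster_ids == label)
        if code.size != 1:
            raise KeyError(f"unknown cluster {label!r}")
        return self.subset(np.flatnonzero(self.cluster == code[0]))


@dataclass(frozen=True)
class DataSplit:
    """Train/validation/test partition sharing the training standardization record."""

    train: ClusteredOrdinalData
    validation: ClusteredOrdinalData
    test: ClusteredOrdinalData


def _encode_column_block(values: pd.Series, schema: CovariateSchema) -> tuple[np.ndarray, list[ColumnInfo]]:
    if schema.kind == "continuous":
        col = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            bad = int(np.flatnonzero(np.isnan(col))[0])
            raise EncodingError(f"non-numeric/missing value for {schema.name!r} at row {bad}")
        return col[:, None], [ColumnInfo(schema.name, schema.name, schema.kind)]
    # binary / ordinal -> dummies against the reference (first) level
    level_index = {lv: i for i, lv in enumerate(schema.levels)}
    idx = values.map(level_index)
    if idx.isna().any():
        bad = int(np.flatnonzero(idx.isna().to_numpy())[0])
        raise EncodingError(
            f"unknown level {values.iloc[bad]!r} for covariate {schema.name!r} at row {bad}"
        )
    idx = idx.to_numpy(dtype=int)
    cols = np.zeros((len(idx), len(schema.levels) - 1))
    for j in range(1, len(schema.levels)):
        cols[:, j - 1] = idx == j
    if schema.kind == "binary":
        info = [ColumnInfo(schema.name, schema.name, schema.kind, schema.levels[1])]
    else:
        info = [
            ColumnInfo(f"{schema.name}[{lv}]", schema.name, schema.kind, lv)
            for lv in schema.levels[1:]
        ]
    return cols, info


def encode_covariates(
    raw_table,
    schemas: Sequence[CovariateSchema],
    roles: Mapping[str, str] | None = None,
    standardize: bool = False,
    *,
    cluster_col: str = "cluster",
    response_col: str = "y",
    k: int | None = None,
    standardization: Mapping[str, tuple] | None = None,
) -> ClusteredOrdinalData:
    """Encode a long-format table into design matrices.

    ``roles`` maps covariate names to ``location`` / ``dispersion`` / ``both``
    (default ``both``). With ``standardize=True`` each design column is centered and
    scaled to unit sample variance and the (mean, sd) record is stored; passing an
    existing ``standardization`` record applies it instead (used for validation/test
    parts).
    """
    table = raw_table if isinstance(raw_table, pd.DataFrame) else pd.DataFrame(list(raw_table))
    table = table.reset_index(drop=True)
    for col in (cluster_col, response_col):
        if col not in table.columns:
            raise EncodingError(f"required column {col!r} missing from input table")
    if roles is None:
        roles = {s.name: "both" for s in schemas}
    roles = dict(roles)
    for name, role in roles.items():
        if role not in VALID_ROLES:
            raise ValueError(f"invalid role {role!r} for covariate {name!r}")
    schema_map = {s.name: s for s in schemas}
    missing = [s.name for s in schemas if s.name not in table.columns]
    if missing:
        raise EncodingError(f"declared covariates missing from table: {missing}")
    if table[[s.name for s in schemas] + [cluster_col, response_col]].isna().any().any():
        raise EncodingError("missing values are not supported; remove incomplete rows")

    # response: map labels to 1..k by sorted order unless already 1..k integers
    y_raw = table[response_col]
    uniq = np.unique(y_raw.to_numpy())
    if k is not None and np.issubdtype(uniq.dtype, np.number):
        y = y_raw.to_numpy(dtype=np.int64)
        if y.size and (y.min() < 1 or y.max() > k):
            raise EncodingError(f"response values outside 1..{k}")
        n_cat = k
    else:
        mapping = {v: i + 1 for i, v in enumerate(uniq)}
        if np.issubdtype(uniq.dtype, np.number) and uniq.size and uniq[0] == 1 and np.array_equal(
            uniq, np.arange(1, uniq.size + 1)
        ):
            y = y_raw.to_numpy(dtype=np.int64)
        else:
            y = y_raw.map(mapping).to_numpy(dtype=np.int64)
        n_cat = k if k is not None else int(uniq.size)

    cluster_ids, cluster = np.unique(table[cluster_col].to_numpy(), return_inverse=True)

    blocks: dict[str, tuple[np.ndarray, list[ColumnInfo]]] = {}
    for schema in schemas:
        blocks[schema.name] = _encode_column_block(table[schema.name], schema)

    def assemble(component: str):
        cols, infos = [], []
        for schema in schemas:
            role = roles.get(schema.name, "both")
            if role == "both" or role == component:
                arr, info = blocks[schema.name]
                cols.append(arr)
                infos.extend(info)
        if cols:
            return np.column_stack(cols), tuple(infos)
        return np.empty((len(table), 0)), tuple()

    X, x_columns = assemble("location")
    Z, z_columns = assemble("dispersion")

    record = None
    if standardization is not None:
        record = dict(standardization)
    elif standardize:
        record = {}
        for infos, mat in ((x_columns, X), (z_columns, Z)):
            for j, info in enumerate(infos):
                if info.name not in record:
                    col = mat[:, j]
                    sd = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
                    if sd == 0.0:
                        raise EncodingError(
                            f"column {info.name!r} has zero variance; cannot standardize"
                        )
                    record[info.name] = (float(np.mean(col)), sd)
    if record is not None:
        for infos, mat in ((x_columns, X), (z_columns, Z)):
            for j, info in enumerate(infos):
                if info.name in record:
                    m, s = record[info.name]
                    mat[:, j] = (mat[:, j] - m) / s

    return ClusteredOrdinalData(
        y=y, cluster=cluster, cluster_ids=cluster_ids, X=X, Z=Z, k=n_cat,
        schemas=tuple(schemas), x_columns=x_columns, z_columns=z_columns, roles=roles,
        standardization=record, raw=table, cluster_col=cluster_col,
        response_col=response_col,
    )


def _allocate_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of n items to parts; largest-remainder rounding."""
    exact = n * fractions
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(exact - counts))
        counts[order[:short]] += 1
    return counts


def split_train_valid_test(
    data: ClusteredOrdinalData,
    fractions: Sequence[float],
    seed: int,
    stratify_by_cluster: bool = True,
    holdout_clusters: Iterable | None = None,
) -> DataSplit:
    """Random train/validation/test split of the observations.

    With ``stratify_by_cluster`` the split is carried out within every cluster, so each
    cluster is represented in all nonempty parts (clusters with fewer rows than split
    parts are assigned entirely to train, with a warning). With ``holdout_clusters``
    those clusters form the entire test set and the first two fractions (renormalized)
    split the remainder into train/validation. Standardization, if the source data are
    standardized, is recomputed on the training part and reused for validation/test.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or (fractions < 0).any() or abs(fractions.sum() - 1) > 1e-9:
        raise ValueError("fractions must be three nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    n = data.n_obs
    parts = [np.empty(0, dtype=int)] * 3

    holdout_rows = np.empty(0, dtype=int)
    active = np.arange(n)
    if holdout_clusters is not None:
        holdout_clusters = list(holdout_clusters)
        unknown = [c for c in holdout_clusters if c not in set(data.cluster_ids.tolist())]
        if unknown:
            raise ValueError(f"holdout clusters not present in data: {unknown}")
        codes = {int(np.flatnonzero(data.cluster_ids == c)[0]) for c in holdout_clusters}
        is_held = np.isin(data.cluster, list(codes))
        holdout_rows = np.flatnonzero(is_held)
        active = np.flatnonzero(~is_held)
        tot = fractions[0] + fractions[1]
        fractions = np.array([fractions[0] / tot, fractions[1] / tot, 0.0]) if tot > 0 else np.array([1.0, 0.0, 0.0])

    n_parts = int((fractions > 0).sum())
    if stratify_by_cluster:
        idx_parts = [[], [], []]
        for code in range(data.n_clusters):
            rows = active[data.cluster[active] == code]
            if rows.size == 0:
                continue
            if rows.size < n_parts:
                warnings.warn(
                    f"cluster {data.cluster_ids[code]!r} has fewer rows ({rows.size}) than "
                    f"split parts; assigning all rows to train"
                )
                idx_parts[0].append(rows)
                continue
            perm = rng.permutation(rows)
            counts = _allocate_counts(rows.size, fractions)
            # guarantee representation in every nonzero-fraction part when possible
            for p in np.flatnonzero(fractions > 0):
                if counts[p] == 0:
                    donor = int(np.argmax(counts))
                    counts[donor] -= 1
                    counts[p] += 1
            stops = np.cumsum(counts)
            idx_parts[0].append(perm[: stops[0]])
            idx_parts[1].append(perm[stops[0]: stops[1]])
            idx_parts[2].append(perm[stops[1]: stops[2]])
        parts = [np.sort(np.concatenate(p)) if p else np.empty(0, dtype=int) for p in idx_parts]
    else:
        perm = rng.permutation(active)
        counts = _allocate_counts(active.size, fractions)
        stops = np.cumsum(counts)
        parts = [np.sort(perm[: stops[0]]), np.sort(perm[stops[0]: stops[1]]), np.sort(perm[stops[1]: stops[2]])]

    if holdout_rows.size:
        parts[2] = np.sort(np.concatenate([parts[2], holdout_rows]))

    if data.standardization is not None and data.raw is not None:
        # recompute the record on the training rows only, reuse it downstream
        schemas, roles = data.schemas, data.roles
        kw = dict(cluster_col=data.cluster_col, response_col=data.response_col, k=data.k)
        train = encode_covariates(data.raw.iloc[parts[0]], schemas, roles, standardize=True, **kw)
        valid = encode_covariates(
            data.raw.iloc[parts[1]], schemas, roles, standardization=train.standardization, **kw
        ) if parts[1].size else data.subset(parts[1])
        test = encode_covariates(
            data.raw.iloc[parts[2]], schemas, roles, standardization=train.standardization, **kw
        ) if parts[2].size else data.subset(parts[2])
        return DataSplit(train=train, validation=valid, test=test)
    return DataSplit(train=data.subset(parts[0]), validation=data.subset(parts[1]), test=data.subset(parts[2]))
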