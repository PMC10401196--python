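"""Sparse clinical feature tables, per-site datasets, and their on-disk formats.

Every downstream stage (feature selection, federated training, evaluation)
consumes the in-memory containers defined here; nothing else reads raw files.

Two interchange formats are supported:

* **long CSV** — header ``person_id,covariate_id,value``, one nonzero cell per
  row.  Canonical, diff-friendly.  Absent (person, covariate) pairs are
  semantic zeros, mirroring sparse covariate extraction from EHR databases.
* **MatrixMarket** — coordinate ``.mtx`` plus two sidecar id lists
  (``<path>.rows``, ``<path>.cols``, one id per line), for bulk data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FeatureMatrix",
    "SiteDataset",
    "FederationDataset",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "split_site",
    "SPLIT_NAMES",
]

Format = Literal["long_csv", "matrix_market"]
SPLIT_NAMES = ("train", "tune", "test")


@dataclass
class FeatureMatrix:
    """Persons x covariates sparse matrix with opaque string ids on both axes.

    Row/column order is deterministic (ids sorted lexicographically by the
    readers/constructors).  Values are finite; most covariates are binary
    0/1 indicators, nonnegative reals are allowed for measurement-like
    features.
    """

    persons: np.ndarray  # ordered person ids (str)
    covariates: np.ndarray  # ordered covariate ids (str)
    values: sp.csr_matrix  # shape (len(persons), len(covariates))

    def __post_init__(self) -> None:
        self.persons = np.asarray(self.persons, dtype=object)
        self.covariates = np.asarray(self.covariates, dtype=object)
        if len(set(self.persons)) != len(self.persons):
            raise ValueError("duplicate person ids")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariate ids")
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.values.shape != (len(self.persons), len(self.covariates)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with indices "
                f"({len(self.persons)}, {len(self.covariates)})"
            )
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("non-finite feature values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_records(
        cls,
        person_ids,
        covariate_ids,
        vals,
    ) -> "FeatureMatrix":
        """Build from parallel record arrays; duplicate pairs are an error."""
        person_ids = np.asarray(person_ids, dtype=object)
        covariate_ids = np.asarray(covariate_ids, dtype=object)
        vals = np.asarray(vals, dtype=np.float64)
        persons = np.array(sorted(set(person_ids)), dtype=object)
        covs = np.array(sorted(set(covariate_ids)), dtype=object)
        pidx = {p: i for i, p in enumerate(persons)}
        cidx = {c: j for j, c in enumerate(covs)}
        rows = np.fromiter((pidx[p] for p in person_ids), dtype=np.int64, count=len(person_ids))
        cols = np.fromiter((cidx[c] for c in covariate_ids), dtype=np.int64, count=len(covariate_ids))
        seen = set(zip(rows.tolist(), cols.tolist()))
        if len(seen) != len(rows):
            raise ValueError("duplicate (person_id, covariate_id) pair in table")
        m = sp.coo_matrix((vals, (rows, cols)), shape=(len(persons), len(covs)))
        return cls(persons, covs, m.tocsr())

    def subset_columns(self, covariate_ids) -> "FeatureMatrix":
        """Column-project onto ``covariate_ids`` in the given order.

        Covariates absent from this matrix become all-zero columns, so a
        model trained on one site's feature list can be applied anywhere.
        """
        covariate_ids = list(covariate_ids)
        cidx = {c: j for j, c in enumerate(self.covariates)}
        pairs = [(jn, cidx[c]) for jn, c in enumerate(covariate_ids) if c in cidx]
        n = self.shape[0]
        if not pairs:
            out = sp.csr_matrix((n, len(covariate_ids)))
        else:
            new_js, old_js = zip(*pairs)
            sub = self.values.tocsc()[:, list(old_js)].tocoo()
            remap = np.asarray(new_js)[sub.col]
            out = sp.coo_matrix(
                (sub.data, (sub.row, remap)), shape=(n, len(covariate_ids))
            ).tocsr()
        return FeatureMatrix(
            self.persons, np.array(covariate_ids, dtype=object), out
        )

    def row_subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.persons[mask], self.covariates, self.values[mask])

    def equals(self, other: "FeatureMatrix") -> bool:
        return (
            np.array_equal(self.persons, other.persons)
            and np.array_equal(self.covariates, other.covariates)
            and (self.values != other.values).nnz == 0
        )


@dataclass
class SiteDataset:
    """One client's feature matrix, binary outcome labels, and 7:1:2 split."""

    site_id: str
    features: FeatureMatrix
    labels: np.ndarray  # int {0,1}, aligned with features.persons
    split: np.ndarray  # str in {"train","tune","test"}, aligned with persons

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split, dtype=object)
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels not aligned with persons")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.split.shape != (n,):
            raise ValueError("split not aligned with persons")
        if not np.isin(self.split, SPLIT_NAMES).all():
            raise ValueError("split values must be train/tune/test")

    def partition(self, name: str) -> tuple[FeatureMatrix, np.ndarray]:
        """(features, labels) of one split; ``name='all'`` returns everything."""
        if name == "all":
            return self.features, self.labels
        if name not in SPLIT_NAMES:
            raise ValueError(f"unknown split {name!r}")
        mask = self.split == name
        return self.features.row_subset(mask), self.labels[mask]


@dataclass
class FederationDataset:
    """Development clients plus an optional external-validation site.

    The external site never contributes training rows; it is scored whole.
    """

    clients: list[SiteDataset]
    external: SiteDataset | None = None

    def __post_init__(self) -> None:
        ids = [c.site_id for c in self.clients]
        if self.external is not None:
            ids.append(self.external.site_id)
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")


def _parse_long_csv(path: Path) -> FeatureMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split(",") != ["person_id", "covariate_id", "value"]:
            raise ValueError(f"{path}: bad header {header!r}")
        persons, covs, vals = [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            p, c, v = parts
            try:
                val = float(v)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {v!r}") from None
            persons.append(p)
            covs.append(c)
            vals.append(val)
    if not persons:
        return FeatureMatrix(
            np.array([], dtype=object),
            np.array([], dtype=object),
            sp.csr_matrix((0, 0)),
        )
    return FeatureMatrix.from_records(persons, covs, vals)


def read_feature_table(path, format: Format = "long_csv") -> FeatureMatrix:
    """Read a sparse feature table from disk.

    ``long_csv`` expects a ``person_id,covariate_id,value`` header;
    ``matrix_market`` expects ``path`` plus sidecars ``path+'.rows'`` and
    ``path+'.cols'``.  Duplicate (person, covariate) pairs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "long_csv":
        return _parse_long_csv(path)
    if format == "matrix_market":
        m = sp.csr_matrix(scipy.io.mmread(str(path)))
        rows = Path(str(path) + ".rows").read_text(encoding="utf-8").splitlines()
        cols = Path(str(path) + ".cols").read_text(encoding="utf-8").splitlines()
        fm = FeatureMatrix(
            np.array(rows, dtype=object), np.array(cols, dtype=object), m
        )
        # normalize to sorted-id order so both formats agree
        rorder = np.argsort(fm.persons.astype(str), kind="stable")
        corder = np.argsort(fm.covariates.astype(str), kind="stable")
        return FeatureMatrix(
            fm.persons[rorder], fm.covariates[corder], fm.values[rorder][:, corder]
        )
    raise ValueError(f"unknown format {format!r}")


def write_feature_table(m: FeatureMatrix, path, format: Format = "long_csv") -> None:
    """Write a feature table; the file re-reads to an equal matrix."""
    path = Path(path)
    if format == "long_csv":
        coo = m.values.tocoo()
        df = pd.DataFrame(
            {
                "person_id": m.persons[coo.row],
                "covariate_id": m.covariates[coo.col],
                "value": coo.data,
            }
        )
        df = df.sort_values(["person_id", "covariate_id"], kind="stable")
        buf = io.StringIO()
        buf.write("person_id,covariate_id,value\n")
        for p, c, v in df.itertuples(index=False):
            buf.write(f"{p},{c},{v:.17g}\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif format == "matrix_market":
        scipy.io.mmwrite(str(path), m.values.tocoo())
        Path(str(path) + ".rows").write_text(
            "\n".join(str(p) for p in m.persons) + ("\n" if len(m.persons) else ""),
            encoding="utf-8",
        )
        Path(str(path) + ".cols").write_text(
            "\n".join(str(c) for c in m.covariates) + ("\n" if len(m.covariates) else ""),
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path) -> pd.Series:
    """Read a ``person_id,outcome`` CSV into a Series indexed by person id."""
    df = pd.read_csv(path, dtype={"person_id": str})
    if list(df.columns) != ["person_id", "outcome"]:
        raise ValueError(f"{path}: expected header person_id,outcome")
    if not df["outcome"].isin((0, 1)).all():
        raise ValueError(f"{path}: outcome must be 0/1")
    return df.set_index("person_id")["outcome"].astype(int)


def write_labels(labels: pd.Series, path) -> None:
    df = labels.rename("outcome").rename_axis("person_id").reset_index()
    df.to_csv(path, index=False)


def split_site(
    features: FeatureMatrix,
    labels,
    seed: int,
    site_id: str = "site",
) -> SiteDataset:
    """Randomly partition persons 7:1:2 into train/tune/test.

    Counts are deterministic: floor(0.7 n) train, floor(0.1 n) tune, the
    remainder test.  Assignment is uniform per patient, unstratified by
    outcome (small sites can therefore land few or zero cases in a split,
    matching the volatility of real small cohorts).
    """
    n = features.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 persons to populate all splits, got {n}")
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    try:
        y = labels.loc[features.persons.astype(str)].to_numpy()
    except KeyError as e:
        raise ValueError(f"labels missing person {e}") from None
    n_train = int(np.floor(0.7 * n))
    n_tune = int(np.floor(0.1 * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_tune]] = "tune"
    split[order[n_train + n_tune :]] = "test"
    return SiteDataset(site_id, features, y, split)


def split_sizes(n: int) -> tuple[int, int, int]:
    """Deterministic 7:1:2 split counts for ``n`` persons."""
    n_train = int(np.floor(0.7 * n))
    n_tune = int(np.floor(0.1 * n))
    return n_train, n_tune, n - n_train - n_tune
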