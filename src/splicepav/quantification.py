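"""Isoform FPKM matrix loading, validation and condition slicing.

The quantitative input is a plain TSV matrix (isoforms in rows, one column
per sample, first column ``isoform_id``) paired with a sample-metadata TSV
(columns ``sample_id, ecotype, age_days, treatment, replicate``).  A
*condition* is an (ecotype, age, treatment) cell of the design; the default
emulated layout has two ecotypes x two ages x {flight, ground} x four
biological replicates.  Zeros are legitimate FPKM values, never missing
data; no normalisation is applied downstream of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TREATMENTS = ("flight", "ground")

META_COLUMNS = ["sample_id", "ecotype", "age_days", "treatment", "replicate"]


class MatrixValidationError(ValueError):
    """Raised when the matrix or metadata violate the input contract."""


@dataclass(frozen=True, order=True)
class Condition:
    """One replicate group of the design."""

    ecotype: str
    age_days: int
    treatment: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.ecotype}_{self.age_days}d_{self.treatment}"

    def counterpart(self) -> "Condition":
        """The other treatment at the same ecotype and age."""
        other = "ground" if self.treatment == "flight" else "flight"
        return Condition(self.ecotype, self.age_days, other)


@dataclass
class ExpressionMatrix:
    """Isoform x sample FPKM values plus sample metadata.

    ``values`` is a DataFrame indexed by isoform_id with one column per
    sample_id; ``meta`` is indexed by sample_id with columns ecotype,
    age_days, treatment, replicate.  Construction validates the contract
    (non-negative finite values, unique ids, matrix/metadata agreement).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        v, m = self.values, self.meta
        if v.index.duplicated().any():
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise MatrixValidationError(f"duplicate isoform ids: {dups}")
        if m.index.duplicated().any():
            dups = sorted(m.index[m.index.duplicated()].unique())
            raise MatrixValidationError(f"duplicate sample ids: {dups}")
        only_matrix = sorted(set(v.columns) - set(m.index))
        only_meta = sorted(set(m.index) - set(v.columns))
        if only_matrix or only_meta:
            raise MatrixValidationError(
                "matrix/metadata sample mismatch: "
                f"matrix-only={only_matrix}, metadata-only={only_meta}"
            )
        bad = ~np.isfinite(v.to_numpy(dtype=float))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-numeric/non-finite value at isoform {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )
        neg = v.to_numpy(dtype=float) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise MatrixValidationError(
                f"negative FPKM at isoform {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        design = m[["ecotype", "age_days", "treatment", "replicate"]]
        if design.duplicated().any():
            raise MatrixValidationError(
                "duplicate (ecotype, age_days, treatment, replicate) in metadata"
            )
        # normalise order: isoforms lexicographic, samples by condition then rep
        order = m.sort_values(
            ["ecotype", "age_days", "treatment", "replicate"]
        ).index
        object.__setattr__(self, "meta", m.loc[order])
        object.__setattr__(self, "values", v.sort_index().loc[:, order])

    # -- basic accessors -------------------------------------------------
    @property
    def isoform_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def conditions(self) -> list[Condition]:
        seen = self.meta[["ecotype", "age_days", "treatment"]].drop_duplicates()
        return [
            Condition(r.ecotype, int(r.age_days), r.treatment)
            for r in seen.itertuples()
        ]

    def condition_pairs(self) -> list[tuple[Condition, Condition]]:
        """(flight, ground) condition pairs per ecotype x age present in meta."""
        pairs = []
        cells = {(c.ecotype, c.age_days) for c in self.conditions()}
        for eco, age in sorted(cells):
            f = Condition(eco, age, "flight")
            g = Condition(eco, age, "ground")
            if self.samples_of(f) and self.samples_of(g):
                pairs.append((f, g))
        return pairs

    def samples_of(self, c: Condition) -> list[str]:
        m = self.meta
        sel = (
            (m.ecotype == c.ecotype)
            & (m.age_days == c.age_days)
            & (m.treatment == c.treatment)
        )
        return list(m.index[sel])

    def restrict_isoforms(self, ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [i for i in self.isoform_ids if i in set(ids)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.meta.copy())


def load_matrix(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Load and validate the FPKM matrix and sample metadata TSVs."""
    vals = pd.read_csv(matrix_path, sep="\t", comment="#", dtype={0: str})
    if vals.columns[0] != "isoform_id":
        raise MatrixValidationError(
            f"{matrix_path}: first column must be 'isoform_id', got {vals.columns[0]!r}"
        )
    vals = vals.set_index("isoform_id")
    try:
        vals = vals.astype(float)
    except ValueError as exc:
        raise MatrixValidationError(f"{matrix_path}: non-numeric value: {exc}") from exc

    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise MatrixValidationError(f"{meta_path}: missing metadata columns {missing}")
    meta["age_days"] = meta["age_days"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["age_days"] <= 0).any() or (meta["replicate"] <= 0).any():
        raise MatrixValidationError(f"{meta_path}: age_days and replicate must be positive")
    bad_tr = sorted(set(meta["treatment"]) - set(TREATMENTS))
    if bad_tr:
        raise MatrixValidationError(f"{meta_path}: unknown treatment values {bad_tr}")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(vals, meta)


def write_matrix(m: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="isoform_id", float_format="%.6g")
    m.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def condition_slice(m: ExpressionMatrix, c: Condition) -> pd.DataFrame:
    """Replicate columns of one condition (isoforms x replicates).

    Raises ``MatrixValidationError`` when the condition has no samples.
    A single-replicate condition is allowed: the strict "all replicates"
    presence rule simply binds to however many replicates exist.
    """
    cols = m.samples_of(c)
    if not cols:
        raise MatrixValidationError(f"no samples for condition {c.label}")
    return m.values[cols]


def mean_fpkm(m: ExpressionMatrix, c: Condition) -> pd.Series:
    """Arithmetic mean FPKM per isoform over the condition's replicates."""
    return condition_slice(m, c).mean(axis=1)
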