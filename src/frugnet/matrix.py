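"""Weighted plant x frugivore consumption matrices.

The central data structure of the package is the community consumption
matrix: rows are plant species, columns are frugivore species, and each
cell holds the number of fruits of that plant handled by that frugivore
(or, after :func:`normalize_percent`, the within-plant percentage).

Matrices are built from focal-tree visit records: for every visit we know
the visiting species, the visit duration in minutes, and a set of focal
feeding-rate samples (fruits manipulated during short fixed intervals --
30 s for primates, 10 s for birds in the field protocol this emulates).
Fruits handled per cell = total feeding time x mean feeding rate.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VisitRecord",
    "ConsumptionMatrix",
    "fruits_handled",
    "reallocate_group",
    "binarize",
    "normalize_percent",
    "read_matrix",
    "write_matrix",
    "normalize_label",
]

Scale = Literal["counts", "percent"]


def normalize_label(label: str) -> str:
    """Canonicalise a species label: trim, collapse whitespace, and unify
    the spacing of ``cf.`` / ``aff.`` qualifiers so the same species matches
    across independently typed tables."""
    s = re.sub(r"\s+", " ", str(label).strip())
    s = re.sub(r"\b(cf|aff)\.\s*", r"\1. ", s, flags=re.IGNORECASE)
    return s


@dataclass(frozen=True)
class VisitRecord:
    """One focal-tree visit by one frugivore.

    ``focal_counts`` are fruits manipulated per focal interval of
    ``focal_interval_s`` seconds; they may be empty when the visit had no
    usable focal sample (allowed only for zero-duration visits).
    """

    plant: str
    frugivore: str
    duration_min: float
    focal_counts: tuple[int, ...] = ()
    focal_interval_s: int = 30

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError(f"negative visit duration for {self.plant}/{self.frugivore}")
        if self.focal_interval_s <= 0:
            raise ValueError("focal_interval_s must be positive")
        if any(c < 0 for c in self.focal_counts):
            raise ValueError("focal counts must be non-negative")


class ConsumptionMatrix:
    """Labelled non-negative plants x frugivores interaction matrix.

    Parameters
    ----------
    values : array-like, shape (n_plants, n_frugivores)
        Non-negative interaction weights.
    plant_labels, frugivore_labels : sequences of unique strings.
    scale : {"counts", "percent"}
        Whether cells are fruit counts or within-plant-row percentages.
    """

    def __init__(
        self,
        values,
        plant_labels: Sequence[str],
        frugivore_labels: Sequence[str],
        scale: Scale = "counts",
    ) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("matrix must be two-dimensional")
        plants = [normalize_label(p) for p in plant_labels]
        frugs = [normalize_label(f) for f in frugivore_labels]
        if arr.shape != (len(plants), len(frugs)):
            raise ValueError(
                f"shape {arr.shape} does not match {len(plants)} plants x {len(frugs)} frugivores"
            )
        if len(set(plants)) != len(plants):
            raise ValueError("duplicate plant labels")
        if len(set(frugs)) != len(frugs):
            raise ValueError("duplicate frugivore labels")
        if np.any(~np.isfinite(arr)):
            raise ValueError("matrix contains non-finite values")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(f"negative value at ({plants[i]}, {frugs[j]})")
        if scale not in ("counts", "percent"):
            raise ValueError(f"unknown scale {scale!r}")
        self._df = pd.DataFrame(arr, index=pd.Index(plants, name="plant"),
                                columns=pd.Index(frugs, name="frugivore"))
        self.scale: Scale = scale

    # -- basic accessors ---------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def plant_labels(self) -> list[str]:
        return list(self._df.index)

    @property
    def frugivore_labels(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    # -- marginals ---------------------------------------------------------

    @property
    def plant_totals(self) -> pd.Series:
        """Row totals A_i (fruits per plant over all frugivores)."""
        return self._df.sum(axis=1)

    @property
    def frugivore_totals(self) -> pd.Series:
        """Column totals A_j (fruits per frugivore over all plants)."""
        return self._df.sum(axis=0)

    @property
    def grand_total(self) -> float:
        """M, the total number of interaction units in the web."""
        return float(self._df.to_numpy().sum())

    @property
    def fill(self) -> int:
        """F, the number of realised (non-zero) links."""
        return int(np.count_nonzero(self._df.to_numpy()))

    @property
    def connectance(self) -> float:
        return self.fill / (self.shape[0] * self.shape[1])

    # -- conveniences ------------------------------------------------------

    def copy(self) -> "ConsumptionMatrix":
        return ConsumptionMatrix(self.values, self.plant_labels,
                                 self.frugivore_labels, self.scale)

    def transpose(self) -> "ConsumptionMatrix":
        return ConsumptionMatrix(self.values.T, self.frugivore_labels,
                                 self.plant_labels, self.scale)

    def drop_plants(self, plants: Iterable[str]) -> "ConsumptionMatrix":
        drop = {normalize_label(p) for p in plants}
        missing = drop - set(self.plant_labels)
        if missing:
            raise KeyError(f"plants not in matrix: {sorted(missing)}")
        keep = [p for p in self.plant_labels if p not in drop]
        if not keep:
            raise ValueError("cannot drop every plant")
        sub = self._df.loc[keep]
        return ConsumptionMatrix(sub.to_numpy(), keep, self.frugivore_labels, self.scale)

    def __repr__(self) -> str:  # pragma: no cover
        r, c = self.shape
        return (f"<ConsumptionMatrix {r} plants x {c} frugivores, "
                f"scale={self.scale}, M={self.grand_total:.6g}, F={self.fill}>")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConsumptionMatrix):
            return NotImplemented
        return (self.scale == other.scale
                and self.plant_labels == other.plant_labels
                and self.frugivore_labels == other.frugivore_labels
                and np.array_equal(self.values, other.values))


# ---------------------------------------------------------------------------
# construction from visit records
# ---------------------------------------------------------------------------

def fruits_handled(records: Iterable[VisitRecord], *, per_visit_rates: bool = False
                   ) -> ConsumptionMatrix:
    """Estimate fruits handled per (plant, frugivore) pair from visit records.

    For each pair, cell = total feeding minutes x mean feeding rate, where
    the rate is mean(focal_counts) x 60 / focal_interval_s in fruits/min.
    By default all focal counts for the pair are pooled before averaging;
    with ``per_visit_rates=True`` each visit's mean rate is averaged instead.

    Raises if a pair has positive total duration but no focal counts at all,
    or if one frugivore species mixes different focal interval lengths.
    """
    recs = list(records)
    interval_by_frug: dict[str, int] = {}
    for r in recs:
        frug = normalize_label(r.frugivore)
        prev = interval_by_frug.setdefault(frug, r.focal_interval_s)
        if prev != r.focal_interval_s:
            raise ValueError(
                f"mixed focal interval lengths for frugivore {frug!r}: "
                f"{prev}s and {r.focal_interval_s}s")

    plants: list[str] = []
    frugs: list[str] = []
    by_pair: dict[tuple[str, str], list[VisitRecord]] = {}
    for r in recs:
        key = (normalize_label(r.plant), normalize_label(r.frugivore))
        if key[0] not in plants:
            plants.append(key[0])
        if key[1] not in frugs:
            frugs.append(key[1])
        by_pair.setdefault(key, []).append(r)

    arr = np.zeros((len(plants), len(frugs)))
    p_idx = {p: i for i, p in enumerate(plants)}
    f_idx = {f: j for j, f in enumerate(frugs)}
    for (plant, frug), group in by_pair.items():
        total_min = sum(g.duration_min for g in group)
        if total_min == 0:
            continue
        counts = [c for g in group for c in g.focal_counts]
        if not counts:
            raise ValueError(
                f"pair ({plant}, {frug}) has {total_min} min of feeding "
                "but no focal counts")
        interval = interval_by_frug[frug]
        if per_visit_rates:
            visit_rates = [np.mean(g.focal_counts) * 60.0 / interval
                           for g in group if g.focal_counts]
            rate = float(np.mean(visit_rates))
        else:
            rate = float(np.mean(counts)) * 60.0 / interval
        arr[p_idx[plant], f_idx[frug]] = total_min * rate
    return ConsumptionMatrix(arr, plants, frugs, scale="counts")


def reallocate_group(matrix: ConsumptionMatrix, group_members: Sequence[str],
                     proportions: pd.DataFrame, *, tol: float = 1e-6
                     ) -> ConsumptionMatrix:
    """Redistribute each plant's total consumption by a species group
    among the group's members according to externally supplied proportions.

    This supports replacing noisy within-group splits by better-sampled
    relative consumption estimates (the field protocol's primate
    reallocation): the per-plant group total is conserved exactly, only the
    split among ``group_members`` changes. ``proportions`` is indexed by
    plant label with one column per group member, each row summing to 1.
    """
    members = [normalize_label(m) for m in group_members]
    missing = set(members) - set(matrix.frugivore_labels)
    if missing:
        raise ValueError(f"group members absent from matrix: {sorted(missing)}")
    props = proportions.copy()
    props.index = [normalize_label(i) for i in props.index]
    props.columns = [normalize_label(c) for c in props.columns]
    if set(members) - set(props.columns):
        raise ValueError("proportions table missing columns for some group members")

    df = matrix.df
    for plant in df.index:
        group_sum = df.loc[plant, members].sum()
        if group_sum == 0:
            continue
        if plant not in props.index:
            raise ValueError(f"no proportions supplied for plant {plant!r}")
        p = props.loc[plant, members].astype(float)
        if abs(p.sum() - 1.0) > tol:
            raise ValueError(
                f"proportions for plant {plant!r} sum to {p.sum():.8f}, not 1")
        df.loc[plant, members] = group_sum * p.to_numpy()
    return ConsumptionMatrix(df.to_numpy(), matrix.plant_labels,
                             matrix.frugivore_labels, matrix.scale)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def binarize(matrix: ConsumptionMatrix) -> ConsumptionMatrix:
    """Presence/absence skeleton: 1 wherever weight > 0.

    No minimum-weight threshold is applied; arbitrarily small positive
    percentages stay present. All-zero rows or columns are kept but
    reported through a warning.
    """
    vals = (matrix.values > 0).astype(float)
    empty_rows = [p for p, s in zip(matrix.plant_labels, vals.sum(axis=1)) if s == 0]
    empty_cols = [f for f, s in zip(matrix.frugivore_labels, vals.sum(axis=0)) if s == 0]
    if empty_rows or empty_cols:
        warnings.warn(
            f"binarized matrix has empty rows {empty_rows} / columns {empty_cols}",
            stacklevel=2)
    return ConsumptionMatrix(vals, matrix.plant_labels, matrix.frugivore_labels,
                             scale="counts")


def normalize_percent(matrix: ConsumptionMatrix) -> ConsumptionMatrix:
    """Rescale each non-empty plant row to sum to 100 (percentage of fruits
    handled). Idempotent; empty rows stay zero."""
    vals = matrix.values.astype(float).copy()
    totals = vals.sum(axis=1)
    nz = totals > 0
    vals[nz] = vals[nz] / totals[nz, None] * 100.0
    return ConsumptionMatrix(vals, matrix.plant_labels, matrix.frugivore_labels,
                             scale="percent")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_matrix(path, *, scale: Scale = "counts", transposed: bool = False,
                sheet: int | str = 0) -> ConsumptionMatrix:
    """Read a labelled matrix from delimited text (.csv/.tsv) or a
    spreadsheet (.xlsx). First column holds plant labels (or frugivore
    labels with ``transposed=True``), header row holds the other level."""
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"blank/non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}")
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric matrix entries in {path}: {exc}") from None
    if transposed:
        return ConsumptionMatrix(arr.T, list(df.columns), list(df.index), scale)
    return ConsumptionMatrix(arr, list(df.index), list(df.columns), scale)


def write_matrix(matrix: ConsumptionMatrix, path) -> None:
    """Write as UTF-8 CSV with a header row and plant labels in column 1."""
    matrix._df.to_csv(str(path), encoding="utf-8")
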