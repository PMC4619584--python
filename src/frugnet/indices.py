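"""Species-level centrality and specialization indices for one trophic level.

The table of indices computed here mirrors the standard keystone-screening
battery for weighted bipartite webs:

==========  =============================================================
D           degree: number of realised partners
ND          normalized degree: D / partners available at the other level
NR          nested rank: normalized position in the degree-sorted matrix
            (0 = most generalist)
WB, WC      weighted betweenness and closeness on the one-mode projection,
            each rescaled to sum to 1 across the level
SS          species strength: sum of the partners' dependencies on the
            focal species
EP          effective partners: exp(Shannon entropy) of interaction weights
SSP         species specificity: coefficient of variation of interactions
            scaled to [0, 1]
d, d'       Kullback-Leibler specialization against partner availability,
            raw and standardized between heuristic extremes
G            generality: the level mean of EP (network-level scalar)
==========  =============================================================

For interpretability as "keystone-ness" (bigger = more central/general),
the conversions 1-d, 1-d', 1-NR and 1-SSP are carried alongside the raw
values. Core/periphery membership uses the standardized degree
Gc = (k - mean k)/SD(k), core at Gc >= 1.
"""

from __future__ import annotations

import warnings
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ConsumptionMatrix

__all__ = [
    "degree_indices",
    "nested_rank",
    "bipartite_centrality",
    "species_strength",
    "diversity_indices",
    "kl_specialization",
    "core_periphery",
    "species_index_table",
    "summarize_indices",
    "correlate_indices",
    "one_mode_projection",
]

Level = Literal["plants", "frugivores"]

CONVERTED = {"d": "one_minus_d", "d_prime": "one_minus_d_prime",
             "NR": "one_minus_NR", "SSP": "one_minus_SSP"}


def _level_view(matrix: ConsumptionMatrix, level: Level) -> tuple[np.ndarray, list[str]]:
    """(rows = focal level, columns = partners), labels of the focal level."""
    if level == "plants":
        return matrix.values, matrix.plant_labels
    if level == "frugivores":
        return matrix.values.T, matrix.frugivore_labels
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# degree family
# ---------------------------------------------------------------------------

def degree_indices(matrix: ConsumptionMatrix, level: Level) -> pd.DataFrame:
    """Degree D (number of partners with weight > 0) and normalized degree
    ND = D / (species at the other level)."""
    arr, labels = _level_view(matrix, level)
    d = np.count_nonzero(arr > 0, axis=1)
    return pd.DataFrame({"D": d, "ND": d / arr.shape[1]}, index=labels)


def nested_rank(matrix: ConsumptionMatrix, level: Level) -> pd.Series:
    """Normalized rank of each species in the degree-sorted (nested) matrix.

    Species are ordered by decreasing degree, ties broken by decreasing
    total weight then by label; rank r in {0..S-1} maps to NR = r/(S-1),
    so 0 marks the most generalist species and the level mean is 0.5.
    """
    arr, labels = _level_view(matrix, level)
    if len(labels) < 2:
        raise ValueError("nested rank needs at least 2 species at the level")
    deg = np.count_nonzero(arr > 0, axis=1)
    tot = arr.sum(axis=1)
    order = sorted(range(len(labels)), key=lambda i: (-deg[i], -tot[i], labels[i]))
    nr = np.empty(len(labels))
    for r, i in enumerate(order):
        nr[i] = r / (len(labels) - 1)
    return pd.Series(nr, index=labels, name="NR")


# ---------------------------------------------------------------------------
# centrality on the one-mode projection
# ---------------------------------------------------------------------------

def one_mode_projection(matrix: ConsumptionMatrix, level: Level,
                        weighting: str = "product") -> nx.Graph:
    """Weighted one-mode projection of one trophic level.

    Edge weight between species i and k is the co-use product
    sum_j X_ij * X_kj over shared partners j ("product", default) or
    sum_j min(X_ij, X_kj) ("min"). Shortest-path distance is 1/weight.
    """
    arr, labels = _level_view(matrix, level)
    g = nx.Graph()
    g.add_nodes_from(labels)
    if weighting == "product":
        w = arr @ arr.T
    elif weighting == "min":
        w = np.array([[np.minimum(a, b).sum() for b in arr] for a in arr])
    else:
        raise ValueError(f"unknown projection weighting {weighting!r}")
    n = len(labels)
    for i in range(n):
        for k in range(i + 1, n):
            if w[i, k] > 0:
                g.add_edge(labels[i], labels[k],
                           weight=float(w[i, k]), distance=1.0 / float(w[i, k]))
    return g


def bipartite_centrality(matrix: ConsumptionMatrix, level: Level,
                         weighting: str = "product") -> pd.DataFrame:
    """Weighted betweenness (WB) and closeness (WC) on the one-mode
    projection, each rescaled to sum to 1 across the level.

    Distances between mutually unreachable species are imputed as ten
    times the largest finite distance; fully isolated species score 0.
    """
    g = one_mode_projection(matrix, level, weighting)
    labels = list(g.nodes)
    n = len(labels)
    if n < 2:
        return pd.DataFrame({"WB": [0.0] * n, "WC": [0.0] * n}, index=labels)

    bet = nx.betweenness_centrality(g, weight="distance", normalized=False)
    wb = np.array([bet[v] for v in labels])

    # all-pairs shortest path lengths with imputation for unreachable pairs
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    dmat = np.full((n, n), np.inf)
    for i, u in enumerate(labels):
        for v, dv in dist[u].items():
            dmat[i, labels.index(v)] = dv
    np.fill_diagonal(dmat, 0.0)
    finite = dmat[np.isfinite(dmat) & (dmat > 0)]
    if finite.size:
        dmat[np.isinf(dmat)] = finite.max() * 10.0
    else:
        dmat[np.isinf(dmat)] = 1.0
    degs = np.array([g.degree(v) for v in labels])
    wc = np.where(degs > 0, (n - 1) / dmat.sum(axis=1), 0.0)

    def rescale(x: np.ndarray) -> np.ndarray:
        s = x.sum()
        return x / s if s > 0 else x

    return pd.DataFrame({"WB": rescale(wb), "WC": rescale(wc)}, index=labels)


# ---------------------------------------------------------------------------
# weighted dependency / diversity family
# ---------------------------------------------------------------------------

def species_strength(matrix: ConsumptionMatrix, level: Level) -> pd.Series:
    """Sum over partners of the focal species' share of the partner's total
    (dependencies); partners with zero total contribute 0. Across a level
    the strengths sum to the number of non-empty partner columns."""
    arr, labels = _level_view(matrix, level)
    partner_tot = arr.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dep = np.where(partner_tot > 0, arr / partner_tot, 0.0)
    return pd.Series(dep.sum(axis=1), index=labels, name="SS")


def diversity_indices(matrix: ConsumptionMatrix, level: Level) -> pd.DataFrame:
    """Effective partners EP = exp(Shannon entropy of the species' weights)
    and species specificity SSP = population CV of its weights across all
    potential partners divided by sqrt(m-1) (its maximum, all weight on a
    single partner), so SSP is 0 for perfectly even use and 1 for complete
    specificity. Zero-total species get NaN for both."""
    arr, labels = _level_view(matrix, level)
    m = arr.shape[1]
    tot = arr.sum(axis=1)
    ep = np.full(len(labels), np.nan)
    ssp = np.full(len(labels), np.nan)
    for i in range(len(labels)):
        if tot[i] <= 0:
            continue
        p = arr[i] / tot[i]
        pz = p[p > 0]
        ep[i] = float(np.exp(-(pz * np.log(pz)).sum()))
        if m >= 2:
            cv = arr[i].std() / arr[i].mean()  # population SD
            ssp[i] = cv / np.sqrt(m - 1)
        else:
            ssp[i] = 1.0
    return pd.DataFrame({"EP": ep, "SSP": ssp}, index=labels)


def kl_specialization(matrix: ConsumptionMatrix, level: Level) -> pd.DataFrame:
    """Kullback-Leibler specialization d and its standardization d'.

    d_i = sum_j p'_ij ln(p'_ij / q_j), with p'_ij the focal species'
    proportional use of partner j and q_j = A_j / M partner availability.
    d_max concentrates the species' total greedily on the scarcest
    partners (respecting partner totals); d_min redistributes the total
    proportionally to availability -- in integer units when the matrix is
    on the counts scale, continuously otherwise. d' = (d - d_min) /
    (d_max - d_min), clamped to [0, 1]. When the heuristic range collapses
    (d_max == d_min) every attainable allocation has the same divergence:
    d' is 1 if that forced divergence is positive (the species is
    structurally pinned at maximal specialization) and 0 if it is zero
    (a single partner on offer).
    """
    arr, labels = _level_view(matrix, level)
    M = arr.sum()
    if M <= 0:
        raise ValueError("empty matrix")
    q = arr.sum(axis=0) / M
    integer_units = (getattr(matrix, "scale", "counts") == "counts"
                     and np.allclose(arr, np.round(arr)))
    partner_caps = arr.sum(axis=0)

    def kl(weights: np.ndarray) -> float:
        a = weights.sum()
        if a <= 0:
            return np.nan
        p = weights / a
        nz = p > 0
        return float((p[nz] * np.log(p[nz] / q[nz])).sum())

    d = np.full(len(labels), np.nan)
    d_prime = np.full(len(labels), np.nan)
    for i in range(len(labels)):
        a_i = arr[i].sum()
        if a_i <= 0:
            continue
        d[i] = kl(arr[i])
        # d_max: pile onto the scarcest partners first, up to their totals
        order = np.argsort(q, kind="stable")
        w_max = np.zeros_like(q)
        rem = a_i
        for j in order:
            if q[j] <= 0:
                continue
            x = min(rem, partner_caps[j])
            w_max[j] = x
            rem -= x
            if rem <= 1e-12:
                break
        if rem > 1e-12:  # more units than total capacity; spill evenly
            w_max += rem * q
        d_max = kl(w_max)
        # d_min: availability-proportional allocation
        if integer_units:
            target = q * a_i
            w_min = np.floor(target)
            shortfall = int(round(a_i - w_min.sum()))
            if shortfall > 0:
                frac_order = np.argsort(-(target - w_min), kind="stable")
                for j in frac_order[:shortfall]:
                    w_min[j] += 1
        else:
            w_min = q * a_i
        d_min = kl(w_min)
        rng_ = d_max - d_min
        if rng_ <= 1e-12:
            d_prime[i] = 1.0 if d[i] > 1e-12 else 0.0
        else:
            d_prime[i] = float(np.clip((d[i] - d_min) / rng_, 0.0, 1.0))
    return pd.DataFrame({"d": d, "d_prime": d_prime}, index=labels)


# ---------------------------------------------------------------------------
# core/periphery
# ---------------------------------------------------------------------------

def core_periphery(matrix: ConsumptionMatrix, level: Level) -> pd.DataFrame:
    """Standardized degree Gc = (k - mean k)/SD(k) within the level;
    species with Gc >= 1 form the generalist core."""
    arr, labels = _level_view(matrix, level)
    if len(labels) < 2:
        raise ValueError("core/periphery needs at least 2 species")
    k = np.count_nonzero(arr > 0, axis=1).astype(float)
    sd = k.std()  # population SD: keeps Gc monotone in own degree
    if sd == 0:
        warnings.warn("all degrees equal; no core species", stacklevel=2)
        gc = np.zeros_like(k)
    else:
        gc = (k - k.mean()) / sd
    flag = np.where((sd > 0) & (gc >= 1.0), "core", "periphery")
    return pd.DataFrame({"Gc": gc, "core_flag": flag}, index=labels)


# ---------------------------------------------------------------------------
# assembly, summaries, correlations
# ---------------------------------------------------------------------------

def species_index_table(matrix: ConsumptionMatrix, level: Level = "plants",
                        weighting: str = "product") -> pd.DataFrame:
    """All per-species indices for one trophic level, raw plus 1-x
    conversions and the core/periphery class."""
    parts = [
        degree_indices(matrix, level),
        nested_rank(matrix, level),
        bipartite_centrality(matrix, level, weighting),
        species_strength(matrix, level),
        diversity_indices(matrix, level),
        kl_specialization(matrix, level),
        core_periphery(matrix, level),
    ]
    table = pd.concat(parts, axis=1)
    for raw, conv in CONVERTED.items():
        table[conv] = 1.0 - table[raw]
    return table


def generality(matrix: ConsumptionMatrix, level: Level = "plants") -> float:
    """Network-level generality G: level mean of effective partners."""
    return float(diversity_indices(matrix, level)["EP"].mean())


def summarize_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample variance per numeric index column, with the count of
    missing values excluded from each."""
    num = table.select_dtypes(include=[np.number])
    return pd.DataFrame({
        "mean": num.mean(),
        "variance": num.var(ddof=1),
        "n_missing": num.isna().sum(),
    })


def correlate_indices(table: pd.DataFrame, extra_columns: pd.DataFrame | None = None,
                      threshold: float = 0.6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among index columns (plus any
    extra score columns, e.g. a pulp-biomass flow), and a boolean frame
    flagging |r| > threshold. Zero-variance columns yield NaN."""
    num = table.select_dtypes(include=[np.number])
    if extra_columns is not None:
        num = pd.concat([num, extra_columns], axis=1)
    valid = num.notna().sum()
    if (valid < 3).any():
        warnings.warn("columns with fewer than 3 complete values give "
                      "unreliable correlations", stacklevel=2)
    r = num.corr(method="pearson", min_periods=3)
    flags = r.abs().gt(threshold) & ~np.eye(len(r), dtype=bool)
    return r, pd.DataFrame(flags, index=r.index, columns=r.columns)
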