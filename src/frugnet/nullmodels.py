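"""Network-level nestedness (NODF) and specialization (H2') with null models.

NODF scores, for every ordered pair of rows (and of columns) in which the
richer member has strictly more presences than the poorer one, the
percentage of the poorer member's presences that overlap the richer
member's, and averages over all pairs. 100 = perfectly nested, 0 = no
decreasing-fill overlap at all.

H2' measures the deviation of the two-dimensional interaction entropy from
its maximum under the observed marginal totals, rescaled by the
maximum-minus-minimum entropy range, so 0 = maximally generalized use of
partners in proportion to availability and 1 = maximal reciprocal
specialization given the marginals.

Significance is assessed against generative nulls: ER (every cell equally
likely), CE (cell probability = average of row and column fill
probabilities) for the binary skeleton, and a marginal-proportional
fixed-connectance null for weighted webs (the ``vaznull`` scheme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ConsumptionMatrix

__all__ = [
    "nodf",
    "null_matrix",
    "vaznull_matrix",
    "h2_prime",
    "h2_entropy_bounds",
    "null_test",
    "NullTestResult",
]


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ConsumptionMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def nodf(matrix) -> float:
    """Nestedness metric based on Overlap and Decreasing Fill, in [0, 100].

    Accepts a binary matrix (or ConsumptionMatrix with 0/1 values only);
    weighted input raises with a pointer to ``binarize``.
    """
    arr = _as_array(matrix)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("nodf requires a binary matrix; apply matrix.binarize first")
    b = arr.astype(bool)

    def paired_sum(rows: np.ndarray) -> float:
        fills = rows.sum(axis=1)
        total = 0.0
        n = rows.shape[0]
        for i in range(n):
            for k in range(i + 1, n):
                hi, lo = (i, k) if fills[i] > fills[k] else (k, i)
                if fills[hi] > fills[lo] and fills[lo] > 0:
                    shared = np.count_nonzero(rows[hi] & rows[lo])
                    total += 100.0 * shared / fills[lo]
        return total

    n_r, n_c = b.shape
    pairs = n_r * (n_r - 1) / 2 + n_c * (n_c - 1) / 2
    if pairs == 0:
        return 0.0
    return (paired_sum(b) + paired_sum(b.T)) / pairs


# ---------------------------------------------------------------------------
# binary nulls
# ---------------------------------------------------------------------------

def null_matrix(template, model: str, seed=None) -> np.ndarray:
    """One binary null matrix under the ER or CE scheme.

    ER: every cell is Bernoulli(F / (n_r * n_c)).
    CE: cell (i, j) is Bernoulli((f_i/n_c + g_j/n_r) / 2) with f_i the row-i
    fill and g_j the column-j fill, so both margins shape the expectation.
    """
    arr = _as_array(template)
    b = (arr > 0)
    n_r, n_c = b.shape
    rng = np.random.default_rng(seed)
    if model.upper() == "ER":
        p = np.full((n_r, n_c), b.sum() / (n_r * n_c))
    elif model.upper() == "CE":
        f = b.sum(axis=1) / n_c
        g = b.sum(axis=0) / n_r
        p = (f[:, None] + g[None, :]) / 2.0
    else:
        raise ValueError(f"unknown binary null model {model!r} (expected ER or CE)")
    return (rng.random((n_r, n_c)) < p).astype(float)


def vaznull_matrix(template: ConsumptionMatrix, seed=None) -> ConsumptionMatrix:
    """Weighted null conserving the grand total M and the connectance F.

    The binary skeleton is drawn cell by cell with probability proportional
    to the product of the template's relative marginal totals, constrained
    so every row and column ends non-empty, until exactly F cells are
    filled; the remaining M - F interaction units then fall multinomially
    on the filled cells with the same probabilities.
    """
    if template.scale != "counts":
        raise ValueError("vaznull operates on a counts-scale matrix")
    arr = template.values
    keep_r = arr.sum(axis=1) > 0
    keep_c = arr.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("vaznull: dropping empty rows/columns from the template",
                      stacklevel=2)
        arr = arr[keep_r][:, keep_c]
    n_r, n_c = arr.shape
    M = arr.sum()
    F = int(np.count_nonzero(arr))
    if F < n_r + n_c - 1:
        raise ValueError(
            f"fill {F} cannot cover {n_r} rows and {n_c} columns")
    if M < F:
        raise ValueError("grand total smaller than fill; not a counts matrix")

    rng = np.random.default_rng(seed)
    p = np.outer(arr.sum(axis=1) / M, arr.sum(axis=0) / M)

    skel = np.zeros((n_r, n_c), dtype=bool)
    # coverage phase: every row and column must host at least one link
    rows_left = list(range(n_r))
    cols_left = list(range(n_c))
    rng.shuffle(rows_left)
    rng.shuffle(cols_left)
    while rows_left or cols_left:
        if rows_left:
            i = rows_left.pop()
            w = p[i] / p[i].sum()
            j = rng.choice(n_c, p=w)
        else:
            j = cols_left[-1]
            w = p[:, j] / p[:, j].sum()
            i = rng.choice(n_r, p=w)
        skel[i, j] = True
        if j in cols_left:
            cols_left.remove(j)
    # fill phase up to exactly F cells
    flat_p = p.ravel()
    while skel.sum() < F:
        empty = np.flatnonzero(~skel.ravel())
        w = flat_p[empty]
        cell = rng.choice(empty, p=w / w.sum())
        skel.ravel()[cell] = True
    if skel.sum() > F:  # coverage already overshot connectance
        raise ValueError("template connectance too low for row/column coverage")

    counts = np.zeros((n_r, n_c))
    counts[skel] = 1.0
    remaining = int(round(M)) - F
    if remaining > 0:
        filled = np.flatnonzero(skel.ravel())
        w = flat_p[filled]
        extra = rng.multinomial(remaining, w / w.sum())
        counts.ravel()[filled] += extra
    # non-integer grand totals: spread the fractional remainder uniformly
    frac = M - int(round(M))
    if abs(frac) > 1e-9:
        counts[skel] += frac / F
    plants = [p_ for p_, k in zip(template.plant_labels, keep_r) if k]
    frugs = [f_ for f_, k in zip(template.frugivore_labels, keep_c) if k]
    return ConsumptionMatrix(counts, plants, frugs, scale="counts")


# ---------------------------------------------------------------------------
# H2'
# ---------------------------------------------------------------------------

def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2_max(row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    # entropy-maximizing fill under the marginals: the product distribution,
    # whose entropy is the sum of the marginal entropies
    M = row_tot.sum()
    return _shannon(row_tot / M) + _shannon(col_tot / M)

def _h2_min(row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    # greedy concentration: repeatedly put min(remaining row, remaining col)
    # into the cell pairing the currently largest marginals
    r = row_tot.astype(float).copy()
    c = col_tot.astype(float).copy()
    M = r.sum()
    cells = []
    while r.max() > 1e-12 and c.max() > 1e-12:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        x = min(r[i], c[j])
        cells.append(x)
        r[i] -= x
        c[j] -= x
    p = np.asarray(cells) / M
    return _shannon(p)


def h2_entropy_bounds(matrix) -> tuple[float, float, float]:
    """(H2, H2min, H2max) for a weighted matrix: observed two-dimensional
    Shannon entropy and heuristic extremes under fixed marginals.

    H2max is the exact upper bound (sum of marginal entropies, attained by
    the product allocation). H2min comes from the greedy concentration
    heuristic; the observed allocation itself is included in the candidate
    set, so H2min <= H2 holds for every input even where the greedy
    ordering is suboptimal.
    """
    arr = _as_array(matrix)
    M = arr.sum()
    if M <= 0:
        raise ValueError("empty matrix")
    h2 = _shannon(arr.ravel() / M)
    row_tot = arr.sum(axis=1)
    col_tot = arr.sum(axis=0)
    h2min = min(_h2_min(row_tot, col_tot), h2)
    return h2, h2min, _h2_max(row_tot, col_tot)


def h2_prime(matrix) -> float:
    """Network-level specialization H2' in [0, 1]; NaN when max = min
    (single row or column -- no specialization freedom)."""
    h2, h2min, h2max = h2_entropy_bounds(matrix)
    if h2max - h2min <= 1e-12:
        return float("nan")
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# null testing
# ---------------------------------------------------------------------------

@dataclass
class NullTestResult:
    """Observed statistic against a null-model ensemble."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    model: str
    seed: int | None
    alternative: str = "greater"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    @property
    def z(self) -> float:
        sd = self.null_sd
        return float("nan") if sd == 0 else (self.observed - self.null_mean) / sd

    @property
    def p(self) -> float:
        """Empirical one-tailed p with the +1 correction (never exactly 0;
        an observation beyond every null reports p = 1/(R+1))."""
        r = len(self.null_values)
        if self.alternative == "greater":
            k = int(np.sum(self.null_values >= self.observed))
        else:
            k = int(np.sum(self.null_values <= self.observed))
        return (1 + k) / (r + 1)

    def summary(self) -> str:
        return (f"{self.statistic_name} = {self.observed:.4g} vs {self.model} "
                f"({len(self.null_values)} reps): null mean {self.null_mean:.4g} "
                f"(SD {self.null_sd:.4g}), z = {self.z:.3f}, p = {self.p:.4g}")


def null_test(matrix: ConsumptionMatrix, statistic: str, model: str,
              replicates: int = 1000, seed: int | None = None,
              alternative: str = "greater") -> NullTestResult:
    """Test NODF or H2' against a null-model ensemble.

    NODF runs against ER or CE (binary skeleton nulls); H2' against the
    weighted marginal-proportional null. ER/CE with H2' is rejected because
    those nulls discard the weights the statistic needs; NODF on the
    weighted null is allowed but warned about.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    stat = statistic.lower().replace("'", "").replace("_", "")
    model_u = model.lower()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    if stat == "nodf":
        observed = nodf((matrix.values > 0).astype(float))
        nulls = np.empty(replicates)
        if model_u in ("er", "ce"):
            for k in range(replicates):
                nulls[k] = nodf(null_matrix(matrix, model_u, seed=child_seeds[k]))
        elif model_u == "vaznull":
            warnings.warn("NODF against vaznull fixes connectance; ER/CE are the "
                          "conventional comparisons", stacklevel=2)
            for k in range(replicates):
                vm = vaznull_matrix(matrix, seed=child_seeds[k])
                nulls[k] = nodf((vm.values > 0).astype(float))
        else:
            raise ValueError(f"unknown model {model!r}")
    elif stat == "h2":
        if model_u != "vaznull":
            raise ValueError("H2' requires the weighted (vaznull) null; "
                             "ER/CE destroy the interaction weights")
        observed = h2_prime(matrix)
        nulls = np.empty(replicates)
        for k in range(replicates):
            nulls[k] = h2_prime(vaznull_matrix(matrix, seed=child_seeds[k]))
    else:
        raise ValueError(f"unknown statistic {statistic!r} (expected NODF or H2')")

    return NullTestResult(statistic.upper() if stat == "nodf" else "H2'",
                          float(observed), nulls, model_u, seed, alternative)
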