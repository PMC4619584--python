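"""Phylogenetic structure of interaction assemblages (MPD/MNTD, NRI/NTI).

For every plant, the set of frugivores visiting it is an assemblage drawn
from the frugivore phylogeny (and symmetrically for plants used by each
frugivore). Mean pairwise distance (MPD) and mean nearest-taxon distance
(MNTD) summarise how phylogenetically close the assemblage members are;
the net relatedness index NRI = -(MPD_obs - mean MPD_null)/SD(MPD_null)
and nearest taxon index NTI (the MNTD analogue) standardise them against
a null ensemble, so positive values mean phylogenetic aggregation
(clustering) and negative values overdispersion.

The null ensemble randomizes the binary community matrix by sequential
checkerboard (independent) swaps, preserving every species' frequency and
every assemblage's richness, which removes richness/commonness artefacts
from the standardised effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .matrix import ConsumptionMatrix, normalize_label

__all__ = [
    "PhyloDistances",
    "cophenetic_matrix",
    "distance_stats",
    "swap_randomize",
    "ensemble_indices",
    "AssemblageResult",
]


@dataclass
class PhyloDistances:
    """Cophenetic (patristic) distance matrix with tip labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate tip labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("negative phylogenetic distances")
        self.matrix = m
        self._idx = {l: i for i, l in enumerate(self.labels)}

    def submatrix(self, taxa) -> np.ndarray:
        idx = [self._idx[normalize_label(t)] for t in taxa]
        return self.matrix[np.ix_(idx, idx)]

    def __contains__(self, taxon: str) -> bool:
        return normalize_label(taxon) in self._idx


def cophenetic_matrix(tree: str | dendropy.Tree, *,
                      missing_lengths: str = "error") -> PhyloDistances:
    """Pairwise path-length (patristic) distances between all tips.

    ``tree`` is a newick string, a path to a newick file, or a dendropy
    Tree. Edges without branch lengths raise unless
    ``missing_lengths='unit'``, which substitutes length 1.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree.clone(depth=1)
    else:
        s = str(tree)
        if not s.lstrip().startswith("("):
            with open(s) as fh:
                s = fh.read()
        t = dendropy.Tree.get(data=s, schema="newick")
    n_missing = sum(1 for e in t.edges()
                    if e.length is None and e.head_node is not t.seed_node)
    if n_missing:
        if missing_lengths == "unit":
            for e in t.edges():
                if e.length is None:
                    e.length = 1.0
        else:
            raise ValueError(f"{n_missing} edges lack branch lengths "
                             "(pass missing_lengths='unit' to impute)")
    labels = [normalize_label(leaf.taxon.label) for leaf in t.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {normalize_label(tx.label): tx for tx in t.taxon_namespace
            if tx.label is not None}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            m[i, j] = m[j, i] = d
    return PhyloDistances(labels, m)


def distance_stats(assemblage, dist: PhyloDistances) -> tuple[float, float]:
    """(MPD, MNTD) of a species set: mean over unordered pairs, and mean
    over members of the distance to the nearest other member
    (presence-based, unweighted)."""
    taxa = list(dict.fromkeys(normalize_label(t) for t in assemblage))
    if len(taxa) < 2:
        raise ValueError("assemblage must contain at least 2 taxa")
    missing = [t for t in taxa if t not in dist]
    if missing:
        raise KeyError(f"taxa absent from the distance matrix: {missing}")
    sub = dist.submatrix(taxa)
    iu = np.triu_indices(len(taxa), k=1)
    mpd = float(sub[iu].mean())
    offdiag = sub + np.diag(np.full(len(taxa), np.inf))
    mntd = float(offdiag.min(axis=1).mean())
    return mpd, mntd


# ---------------------------------------------------------------------------
# independent-swap null
# ---------------------------------------------------------------------------

def _swap_chain(b: np.ndarray, n_attempts: int, rng: np.random.Generator) -> None:
    """In-place sequential checkerboard swaps; counts attempts, not
    successes (the standard fixed-fixed Markov chain)."""
    n_r, n_c = b.shape
    rows = rng.integers(0, n_r, size=2 * n_attempts)
    cols = rng.integers(0, n_c, size=2 * n_attempts)
    for t in range(n_attempts):
        r1, r2 = rows[2 * t], rows[2 * t + 1]
        c1, c2 = cols[2 * t], cols[2 * t + 1]
        if r1 == r2 or c1 == c2:
            continue
        a, bb, c, d = b[r1, c1], b[r1, c2], b[r2, c1], b[r2, c2]
        if a == d and bb == c and a != bb:
            b[r1, c1] = bb
            b[r2, c2] = bb
            b[r1, c2] = a
            b[r2, c1] = a


def _has_checkerboard(b: np.ndarray) -> bool:
    n_r = b.shape[0]
    for i in range(n_r):
        for k in range(i + 1, n_r):
            if np.any(b[i] & ~b[k]) and np.any(~b[i] & b[k]):
                return True
    return False


def swap_randomize(presence, n_swaps: int | None = None, seed=None,
                   burn_in: int | None = None) -> np.ndarray:
    """One independent-swap randomization of a binary community matrix.

    Row and column totals are preserved exactly. ``n_swaps`` counts swap
    attempts after a burn-in of 10 x fill attempts (default n_swaps =
    fill). If the matrix admits no checkerboard the input is returned
    unchanged with a warning.
    """
    arr = presence.values if isinstance(presence, ConsumptionMatrix) else np.asarray(presence)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("swap_randomize requires a binary matrix")
    b = arr.astype(bool).copy()
    if not _has_checkerboard(b):
        warnings.warn("matrix admits no checkerboard; returning input unchanged",
                      stacklevel=2)
        return b.astype(float)
    fill = int(b.sum())
    rng = np.random.default_rng(seed)
    if burn_in is None:
        burn_in = 10 * fill
    if n_swaps is None:
        n_swaps = fill
    _swap_chain(b, burn_in + n_swaps, rng)
    return b.astype(float)


# ---------------------------------------------------------------------------
# ensemble indices
# ---------------------------------------------------------------------------

@dataclass
class AssemblageResult:
    """Phylogenetic structure of one focal species' partner assemblage."""

    focal: str
    size: int
    mpd: float
    mntd: float
    nri: float
    nti: float
    p_mpd: float
    p_mntd: float
    class_nri: str
    class_nti: str


def ensemble_indices(presence, dist: PhyloDistances, runs: int = 999,
                     seed: int | None = None, alpha: float = 0.05,
                     focal_axis: str = "rows", thin: int | None = None
                     ) -> pd.DataFrame:
    """NRI/NTI per focal species against an independent-swap null.

    ``presence`` is a binary community matrix (ConsumptionMatrix or
    labelled DataFrame); with ``focal_axis='rows'`` each row is a focal
    species whose assemblage is the set of columns it interacts with (the
    column labels must match the tips of ``dist``). Null assemblages come
    from ``runs`` thinned states of a single checkerboard-swap chain over
    the whole community matrix. Classification is two-tailed on the null
    MPD (resp. MNTD) quantiles: 'aggregated' when the observed distance
    falls below the alpha/2 quantile, 'dispersed' above 1-alpha/2,
    'random' otherwise; assemblages of fewer than 2 members, or with a
    degenerate null (zero SD), classify as 'random' with NaN indices.
    """
    if runs < 99:
        raise ValueError("use at least 99 null runs")
    if isinstance(presence, ConsumptionMatrix):
        df = (presence.df > 0).astype(int)
    else:
        df = (pd.DataFrame(presence) > 0).astype(int)
    if focal_axis == "columns":
        df = df.T
    elif focal_axis != "rows":
        raise ValueError("focal_axis must be 'rows' or 'columns'")
    df.columns = [normalize_label(c) for c in df.columns]
    missing = [c for c in df.columns if c not in dist and df[c].sum() > 0]
    if missing:
        raise KeyError(f"community members absent from the tree: {missing}")

    b = df.to_numpy(dtype=bool)
    col_idx = np.array([dist._idx[c] if c in dist else -1 for c in df.columns])
    dm = dist.matrix
    rng = np.random.default_rng(seed)
    fill = int(b.sum())
    if thin is None:
        thin = max(fill, 1)

    def row_stats(mat: np.ndarray) -> np.ndarray:
        out = np.full((mat.shape[0], 2), np.nan)
        for i in range(mat.shape[0]):
            members = col_idx[mat[i]]
            if len(members) < 2:
                continue
            sub = dm[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            out[i, 0] = sub[iu].mean()
            np.fill_diagonal(sub, np.inf)
            out[i, 1] = sub.min(axis=1).mean()
        return out

    obs = row_stats(b)
    chain = b.copy()
    swappable = _has_checkerboard(chain)
    if not swappable:
        warnings.warn("community matrix admits no checkerboard; null is degenerate",
                      stacklevel=2)
    null_mpd = np.empty((runs, b.shape[0]))
    null_mntd = np.empty((runs, b.shape[0]))
    if swappable:
        _swap_chain(chain, 10 * fill, rng)  # burn-in
    for r in range(runs):
        if swappable:
            _swap_chain(chain, thin, rng)
        st = row_stats(chain)
        null_mpd[r] = st[:, 0]
        null_mntd[r] = st[:, 1]

    rows = []
    for i, focal in enumerate(df.index):
        size = int(b[i].sum())
        mpd_o, mntd_o = obs[i]
        res = {"focal": focal, "size": size, "mpd": mpd_o, "mntd": mntd_o}
        for name, o, nulls in (("nri", mpd_o, null_mpd[:, i]),
                               ("nti", mntd_o, null_mntd[:, i])):
            nulls = nulls[~np.isnan(nulls)]
            sd = nulls.std(ddof=1) if len(nulls) > 1 else 0.0
            degenerate = sd <= 1e-10 * max(abs(float(np.mean(nulls))), 1.0) \
                if len(nulls) else True
            if np.isnan(o) or degenerate or len(nulls) < 2:
                res[name] = np.nan
                res[f"p_{'mpd' if name == 'nri' else 'mntd'}"] = np.nan
                res[f"class_{name}"] = "random"
                continue
            ses = -(o - nulls.mean()) / sd
            lo, hi = np.quantile(nulls, [alpha / 2, 1 - alpha / 2])
            if o < lo:
                cls = "aggregated"
            elif o > hi:
                cls = "dispersed"
            else:
                cls = "random"
            # two-tailed empirical p with the +1 correction
            k = min(np.sum(nulls <= o), np.sum(nulls >= o))
            p = min(1.0, 2 * (1 + k) / (len(nulls) + 1))
            res[name] = float(ses)
            res[f"p_{'mpd' if name == 'nri' else 'mntd'}"] = float(p)
            res[f"class_{name}"] = cls
        rows.append(res)
    return pd.DataFrame(rows).set_index("focal")
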