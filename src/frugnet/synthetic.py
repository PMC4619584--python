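"""Synthetic visit logs, interaction matrices, phylogenies and assemblages.

Every downstream stage of the package is testable without field data:
this module generates interaction matrices with tunable nestedness and
specialization, visit logs whose expectation inverts exactly to a given
matrix under :func:`frugnet.matrix.fruits_handled`, Yule (pure-birth)
phylogenies, and species assemblages with controlled phylogenetic
clustering. All generators take a single integer seed and are
deterministic given it.

The matrix generator mixes a deterministic binary skeleton with Bernoulli
noise: at ``nestedness_level=1`` the skeleton is the strict threshold
(triangular) structure with linearly decreasing row fills, at
``specialization_level=1`` it is a one-to-one matching, and intermediate
levels interpolate the cell probabilities between the skeleton and a
uniform fill of the same expected connectance. Weights on realised links
are rounded log-normal with a floor of 1, so count-based indices are
always well defined.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .matrix import ConsumptionMatrix, VisitRecord
from .phylo import PhyloDistances, cophenetic_matrix

__all__ = [
    "SyntheticConfig",
    "gen_matrix",
    "gen_visit_log",
    "gen_phylogeny",
    "gen_assemblage",
    "assemblage_recovery_rates",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """One bundle of generator settings (used by the CLI ``synth`` command)."""

    n_plants: int = 20
    n_frugivores: int = 30
    nestedness_level: float = 0.5
    specialization_level: float = 0.0
    mean_visits: float = 5.0
    seed: int = 0
    tree_taxa: int = 64
    birth_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n_plants < 2 or self.n_frugivores < 2 or self.tree_taxa < 2:
            raise ValueError("all counts must be >= 2")
        for lvl in (self.nestedness_level, self.specialization_level):
            if not 0.0 <= lvl <= 1.0:
                raise ValueError("structure levels must lie in [0, 1]")
        if self.mean_visits <= 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _nested_skeleton(n_r: int, n_c: int) -> np.ndarray:
    """Strict threshold structure: row i keeps the first ceil(n_c*(n_r-i)/n_r)
    columns, giving linearly decreasing fills (4,3,2,1 for a 4x4)."""
    skel = np.zeros((n_r, n_c), dtype=bool)
    for i in range(n_r):
        fill = max(1, int(np.ceil(n_c * (n_r - i) / n_r)))
        skel[i, :fill] = True
    return skel


def _matching_skeleton(n_r: int, n_c: int) -> np.ndarray:
    """(Block-)diagonal matching: each row gets one partner, columns cycle."""
    skel = np.zeros((n_r, n_c), dtype=bool)
    for i in range(n_r):
        skel[i, i % n_c] = True
    return skel


def gen_matrix(n_plants: int, n_frugivores: int, nestedness_level: float = 0.5,
               specialization_level: float = 0.0, mean_weight: float = 5.0,
               seed: int | None = None) -> ConsumptionMatrix:
    """Random consumption matrix with tunable structure.

    The dominant structure (the larger of the two levels) supplies the
    deterministic skeleton; the presence probability of cell (i, j) is
    level * skeleton_ij + (1 - level) * p0 with p0 the skeleton's own
    connectance, so expected fill is level-invariant. Every row and column
    is forced non-empty, and realised links get integer log-normal weights
    with mean ~ ``mean_weight`` (floor 1).

    Raises when ``specialization_level == 1`` with unequal dimensions (a
    perfect matching cannot cover both levels) and when both levels are
    set to 1 (contradictory skeletons).
    """
    if n_plants < 2 or n_frugivores < 2:
        raise ValueError("need at least 2 species per level")
    for lvl in (nestedness_level, specialization_level):
        if not 0.0 <= lvl <= 1.0:
            raise ValueError("structure levels must lie in [0, 1]")
    if nestedness_level == 1.0 and specialization_level == 1.0:
        raise ValueError("cannot request perfect nesting and perfect "
                         "specialization simultaneously")
    if specialization_level == 1.0 and n_plants != n_frugivores:
        raise ValueError("a perfect matching needs equal numbers of plants "
                         "and frugivores (no padding is applied)")

    rng = np.random.default_rng(seed)
    if specialization_level > nestedness_level:
        skel = _matching_skeleton(n_plants, n_frugivores)
        level = specialization_level
    else:
        skel = _nested_skeleton(n_plants, n_frugivores)
        level = nestedness_level
    p0 = skel.mean()
    prob = level * skel + (1.0 - level) * p0
    presence = rng.random(skel.shape) < prob
    # guarantee coverage of every row and column
    for i in np.flatnonzero(~presence.any(axis=1)):
        presence[i, rng.integers(n_frugivores)] = True
    for j in np.flatnonzero(~presence.any(axis=0)):
        presence[rng.integers(n_plants), j] = True

    sigma = 1.0
    mu = np.log(max(mean_weight, 1.0)) - sigma**2 / 2
    weights = np.maximum(1, np.round(rng.lognormal(mu, sigma, skel.shape)))
    arr = np.where(presence, weights, 0.0)
    plants = [f"P{i+1:03d}" for i in range(n_plants)]
    frugs = [f"F{j+1:03d}" for j in range(n_frugivores)]
    return ConsumptionMatrix(arr, plants, frugs, scale="counts")


# ---------------------------------------------------------------------------
# visit logs
# ---------------------------------------------------------------------------

def gen_visit_log(matrix: ConsumptionMatrix, hours_per_plant: float = 20.0,
                  seed: int | None = None, mean_duration_min: float = 2.0,
                  focal_interval_s: int = 30) -> list[VisitRecord]:
    """Visit records whose expectation inverts to ``matrix`` cell-wise.

    For each non-zero cell X the generator draws Poisson(hours_per_plant)
    visits with exponential durations (mean ``mean_duration_min``) and a
    latent feeding rate r = X / (expected total minutes); each visit
    carries >= 1 focal counts drawn Poisson(r x interval). Because the
    pooled focal-count mean is an unbiased rate estimate independent of
    the durations, E[fruits_handled(log)] equals the latent matrix.
    """
    if hours_per_plant <= 0:
        raise ValueError("hours_per_plant must be positive")
    rng = np.random.default_rng(seed)
    records: list[VisitRecord] = []
    arr = matrix.values
    for i, plant in enumerate(matrix.plant_labels):
        for j, frug in enumerate(matrix.frugivore_labels):
            x = arr[i, j]
            if x <= 0:
                continue
            n_visits = rng.poisson(hours_per_plant)
            expected_minutes = hours_per_plant * mean_duration_min
            rate = x / expected_minutes  # fruits per minute
            lam_focal = rate * focal_interval_s / 60.0
            for _ in range(n_visits):
                dur = rng.exponential(mean_duration_min)
                n_focal = 1 + rng.poisson(2)
                counts = tuple(int(c) for c in rng.poisson(lam_focal, n_focal))
                records.append(VisitRecord(plant, frug, float(dur), counts,
                                           focal_interval_s))
    return records


# ---------------------------------------------------------------------------
# phylogenies and assemblages
# ---------------------------------------------------------------------------

def gen_phylogeny(n_taxa: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> str:
    """Yule pure-birth tree with ``n_taxa`` extant tips as a newick string.

    Tip labels are T1..Tn; branch lengths are exponential waiting times,
    strictly positive almost surely.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    py_rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"T{i+1}" for i in range(n_taxa)])
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=py_rng)
    for e in tree.edges():
        if e.length is not None and e.length <= 0:
            e.length = 1e-9
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def gen_assemblage(tree: str | PhyloDistances, k: int, mode: str = "random",
                   seed: int | None = None, focal: str | None = None
                   ) -> list[str]:
    """A k-species subset of the tree's tips with controlled structure.

    clustered : a focal tip (random unless given) plus its k-1 nearest
                tips by cophenetic distance;
    dispersed : greedy maximin -- start from a random tip, repeatedly add
                the tip maximizing its minimum distance to the set;
    random    : uniform sample without replacement.
    """
    dist = tree if isinstance(tree, PhyloDistances) else cophenetic_matrix(tree)
    tips = dist.labels
    if not 2 <= k < len(tips):
        raise ValueError(f"k must satisfy 2 <= k < {len(tips)}")
    rng = np.random.default_rng(seed)
    if mode == "random":
        return sorted(rng.choice(tips, size=k, replace=False).tolist())
    if mode == "clustered":
        f = focal if focal is not None else tips[rng.integers(len(tips))]
        if f not in dist:
            raise KeyError(f"focal tip {f!r} not in tree")
        fi = dist._idx[f]
        d = dist.matrix[fi].copy()
        d[fi] = -np.inf  # focal always first
        order = sorted(range(len(tips)), key=lambda j: (d[j], tips[j]))
        return sorted(tips[j] for j in order[:k])
    if mode == "dispersed":
        start = focal if focal is not None else tips[rng.integers(len(tips))]
        chosen = [dist._idx[start]]
        while len(chosen) < k:
            mind = dist.matrix[:, chosen].min(axis=1)
            mind[chosen] = -np.inf
            j = int(np.argmax(mind))
            chosen.append(j)
        return sorted(tips[j] for j in chosen)
    raise ValueError(f"unknown mode {mode!r}")


def assemblage_recovery_rates(rng: np.random.Generator, n_trees: int = 4,
                              n_per_kind: int = 50, runs: int = 999, k: int = 8,
                              tips: int = 64) -> tuple[float, float, float]:
    """Parameter-recovery experiment for the NRI classification.

    For each of ``n_trees`` independent Yule trees, build one community
    matrix holding ``n_per_kind`` clustered and ``n_per_kind`` random
    assemblages of size ``k`` and classify them with the independent-swap
    null. Detection rates across single trees vary substantially with the
    tree realisation, so rates are averaged over trees. Returns (fraction
    of clustered assemblages classified aggregated, fraction of random
    assemblages classified non-random, mean NRI of clustered assemblages).
    """
    import pandas as pd

    from .phylo import ensemble_indices

    dets, fprs, mean_nri = [], [], []
    for _ in range(n_trees):
        dist = cophenetic_matrix(gen_phylogeny(tips, seed=int(rng.integers(2**31))))
        rows, labels = [], []
        for kind in ("clustered", "random"):
            for i in range(n_per_kind):
                a = gen_assemblage(dist, k, kind, seed=int(rng.integers(2**31)))
                rows.append([1 if t in a else 0 for t in dist.labels])
                labels.append(f"{kind[0].upper()}{i}")
        comm = pd.DataFrame(rows, index=labels, columns=dist.labels)
        res = ensemble_indices(comm, dist, runs=runs,
                               seed=int(rng.integers(2**31)))
        cl = res.loc[[l for l in labels if l.startswith("C")]]
        rd = res.loc[[l for l in labels if l.startswith("R")]]
        dets.append((cl["class_nri"] == "aggregated").mean())
        fprs.append((rd["class_nri"] != "random").mean())
        mean_nri.append(cl["nri"].mean())
    return float(np.mean(dets)), float(np.mean(fprs)), float(np.mean(mean_nri))
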