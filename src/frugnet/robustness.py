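"""Secondary-extinction simulation and attack-tolerance robustness.

Species at one trophic level are removed in sequence; a species at the
other level goes secondarily extinct as soon as its last remaining partner
is gone. The extinction curve records the surviving fraction of the other
level against the fraction removed, and robustness R is the area under
that curve: R -> 1 when survivors persist until the very last removal,
R -> 0 when the first removals already cascade.

Species with no partners at the outset (structural zero rows/columns, as
arise after ablating a plant whose sole partner loses everything) are
excluded from both the removal sequence and the survivor denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ConsumptionMatrix

__all__ = [
    "extinction_sequence",
    "robustness_area",
    "random_robustness",
    "single_removal_experiment",
    "RobustnessResult",
]


@dataclass
class RobustnessResult:
    """Mean extinction curve and robustness under randomized removals."""

    removal_level: str
    strategy: str
    curve: np.ndarray          # shape (k+1, 2): (fraction removed, fraction surviving)
    R: float
    R_sd: float
    n_orders: int
    seed: int | None


def _levels(matrix: ConsumptionMatrix, removal_level: str):
    """(rows = removal level, cols = other level) active species only."""
    if removal_level == "plants":
        arr = matrix.values
        labels = matrix.plant_labels
    elif removal_level == "frugivores":
        arr = matrix.values.T
        labels = matrix.frugivore_labels
    else:
        raise ValueError(f"unknown removal level {removal_level!r}")
    active_rows = arr.sum(axis=1) > 0
    active_cols = arr.sum(axis=0) > 0
    return (arr[active_rows][:, active_cols] > 0,
            [l for l, a in zip(labels, active_rows) if a])


def extinction_sequence(matrix: ConsumptionMatrix, removal_level: str,
                        order: list[str]) -> np.ndarray:
    """Extinction curve for one explicit removal order.

    ``order`` must be a permutation of the active (degree > 0) species at
    the removal level. Returns an array of (fraction removed, fraction of
    the other level surviving), starting at (0, 1) and ending at (1, 0).
    """
    b, labels = _levels(matrix, removal_level)
    if sorted(order) != sorted(labels):
        raise ValueError("order is not a permutation of the active species "
                         f"at the {removal_level} level")
    idx = {l: i for i, l in enumerate(labels)}
    n_rem, n_other = b.shape
    remaining = b.copy()
    alive_rows = np.ones(n_rem, dtype=bool)
    curve = [(0.0, 1.0)]
    for k, sp in enumerate(order, start=1):
        alive_rows[idx[sp]] = False
        survivors = int(np.count_nonzero(remaining[alive_rows].any(axis=0)))
        curve.append((k / n_rem, survivors / n_other))
    return np.asarray(curve)


def robustness_area(curve: np.ndarray) -> float:
    """Trapezoidal area under the extinction curve over x in [0, 1]."""
    curve = np.asarray(curve, dtype=float)
    x, y = curve[:, 0], curve[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValueError("curve x values must be non-decreasing")
    return float(np.trapezoid(y, x))


def random_robustness(matrix: ConsumptionMatrix, removal_level: str,
                      n_orders: int = 100, seed: int | None = None
                      ) -> RobustnessResult:
    """Mean robustness over uniformly random removal orders."""
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    _, labels = _levels(matrix, removal_level)
    rng = np.random.default_rng(seed)
    curves = []
    areas = []
    for _ in range(n_orders):
        order = list(rng.permutation(labels))
        c = extinction_sequence(matrix, removal_level, order)
        curves.append(c[:, 1])
        areas.append(robustness_area(c))
    mean_curve = np.column_stack([curves[0] * 0, np.mean(curves, axis=0)])
    mean_curve[:, 0] = np.linspace(0, 1, len(labels) + 1)
    areas = np.asarray(areas)
    return RobustnessResult(removal_level, "random", mean_curve,
                            float(areas.mean()),
                            float(areas.std(ddof=1)) if n_orders > 1 else 0.0,
                            n_orders, seed)


def single_removal_experiment(matrix: ConsumptionMatrix,
                              plants_to_remove: list[str],
                              n_orders: int = 100, seed: int | None = None
                              ) -> pd.DataFrame:
    """Ablate one plant at a time and re-measure robustness both ways.

    For each listed plant the matrix is copied, that plant's row deleted
    (frugivores left partnerless become structural zero columns), and
    random-removal robustness recomputed for plant removal ("frugivore-
    level R", survivors are frugivores) and frugivore removal ("plant-
    level R"). Returns one row per ablated plant plus summary statistics
    via ``DataFrame.describe`` on the caller's side.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for plant in plants_to_remove:
        sub = matrix.drop_plants([plant])
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        r_plant = random_robustness(sub, "frugivores", n_orders, int(s1)).R
        r_frug = random_robustness(sub, "plants", n_orders, int(s2)).R
        rows.append({"removed_plant": plant,
                     "plant_level_R": r_plant,
                     "frugivore_level_R": r_frug})
    return pd.DataFrame(rows).set_index("removed_plant")
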