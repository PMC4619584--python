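import numpy as np
import pytest

from frugnet.matrix import ConsumptionMatrix


@pytest.fixture
def small_matrix() -> ConsumptionMatrix:
    """4 plants x 3 frugivores with varied degrees and weights."""
    vals = [[10, 5, 0],
            [4, 0, 0],
            [2, 3, 6],
            [0, 0, 8]]
    return ConsumptionMatrix(vals, ["Pa", "Pb", "Pc", "Pd"],
                             ["Fx", "Fy", "Fz"])


@pytest.fixture
def random_matrix() -> ConsumptionMatrix:
    rng = np.random.default_rng(77)
    vals = rng.integers(0, 9, size=(6, 8)).astype(float)
    vals[vals.sum(axis=1) == 0, 0] = 1
    vals[0, vals.sum(axis=0) == 0] = 1
    return ConsumptionMatrix(vals, [f"P{i}" for i in range(6)],
                             [f"F{j}" for j in range(8)])


def enumerate_fixed_marginals(row_tot, col_tot):
    """All non-negative integer matrices with the given marginals
    (exhaustive oracle for small totals)."""
    row_tot = list(row_tot)
    col_tot = list(col_tot)

    def fill(rows_left, cols_rem):
        if not rows_left:
            if all(c == 0 for c in cols_rem):
                yield []
            return
        r = rows_left[0]

        def rowfill(j, rem, partial):
            if j == len(cols_rem) - 1:
                if rem <= cols_rem[j]:
                    yield partial + [rem]
                return
            for x in range(min(rem, cols_rem[j]) + 1):
                yield from rowfill(j + 1, rem - x, partial + [x])

        for row in rowfill(0, r, []):
            new_cols = [c - x for c, x in zip(cols_rem, row)]
            for rest in fill(rows_left[1:], new_cols):
                yield [row] + rest

    for m in fill(row_tot, col_tot):
        yield np.array(m, dtype=float)
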