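"""Energy-flow keystone scores and the trait-regression batteries.

Topological indices rank plants by how connected or central they are in
the interaction network; the pulp-biomass flow score instead estimates how
much dry fruit-pulp mass a plant *population* actually delivers to the
frugivore level per hectare per day:

    flow = consumption rate (fruits h^-1 tree^-1)
           x active foraging hours per day
           x dry pulp mass per fruit (g)
           x density of reproductive adults (trees ha^-1)
           [ x crop_duration/12 when annualized ]

Because abundance enters multiplicatively, common productive trees can be
keystones by flow while being unremarkable topologically -- the two
rankings need not agree, which is what :func:`rank_keystones` /
:func:`overlap` quantify.

The module also hosts the community-level regression screens: per-plant
OLS of visit time on frugivore abundance, and the seven-trait battery
testing the specialized-vs-generalized dispersal-system hypothesis
(lipid-rich pulp should co-occur with long crops, large seeds, large
frugivores, and with small crops, low visitation, low richness and poor
recruitment below parents).
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import normalize_label

__all__ = [
    "pulp_flow",
    "rank_keystones",
    "overlap",
    "abundance_r2",
    "prediction_battery",
    "load_published_keystone_lists",
    "TRAIT_COLUMNS",
    "PREDICTIONS",
]

TRAIT_COLUMNS = {
    "consumption_rate": "fruits h^-1 tree^-1",
    "pulp_fraction": "proportion of fresh fruit mass that is pulp",
    "pulp_dry_mass_per_fruit": "g dry pulp per fruit",
    "crop_duration": "months of fruiting per year",
    "density": "reproductive trees ha^-1",
    "pct_lipids": "proportion lipids in pulp",
    "seed_width": "mm",
    "crop_size": "fruits per crop",
    "recruit_below_parents": "recruitment probability below parents",
}

_FLOW_FIELDS = ("consumption_rate", "pulp_dry_mass_per_fruit", "density")


def pulp_flow(traits: pd.DataFrame, active_hours: float = 12.0,
              annualize: bool = False) -> pd.DataFrame:
    """Dry pulp biomass flow (g ha^-1 day^-1) per plant.

    ``traits`` is indexed by plant label with the columns named in
    ``TRAIT_COLUMNS`` (only the flow ingredients are required). Plants
    missing an ingredient get NaN flow and a reason string; negative
    inputs raise. ``annualize`` multiplies by crop_duration/12, averaging
    the daily flow over the year rather than over the fruiting season.
    """
    if active_hours <= 0:
        raise ValueError("active_hours must be positive")
    t = traits.copy()
    t.index = [normalize_label(i) for i in t.index]
    needed = list(_FLOW_FIELDS) + (["crop_duration"] if annualize else [])
    for col in needed:
        if col not in t.columns:
            t[col] = np.nan
        if (t[col] < 0).any():
            bad = t.index[t[col] < 0][0]
            raise ValueError(f"negative {col} for {bad!r}")
    flow = (t["consumption_rate"] * active_hours
            * t["pulp_dry_mass_per_fruit"] * t["density"])
    if annualize:
        flow = flow * t["crop_duration"] / 12.0
    reason = t[needed].isna().apply(
        lambda row: "" if not row.any()
        else "missing: " + ", ".join(row.index[row]), axis=1)
    return pd.DataFrame({"flow": flow, "missing_reason": reason})


def rank_keystones(flow: pd.Series | pd.DataFrame, k: int | None = None
                   ) -> pd.DataFrame:
    """Plants in descending flow order (ties broken by label), with ranks
    1..n; ``k`` truncates to the top k."""
    s = flow["flow"] if isinstance(flow, pd.DataFrame) else flow
    s = s.dropna()
    if k is not None and k > len(s):
        raise ValueError(f"k={k} exceeds the {len(s)} plants with scores")
    out = s.to_frame("flow")
    out["label"] = out.index
    out = out.sort_values(["flow", "label"], ascending=[False, True]).drop(columns="label")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.head(k) if k is not None else out


def overlap(list_a, list_b) -> list[str]:
    """Species shared by two ranked lists, after label normalisation."""
    a = {normalize_label(x) for x in list_a}
    b = {normalize_label(x) for x in list_b}
    return sorted(a & b)


def load_published_keystone_lists() -> pd.DataFrame:
    """Published top-20 keystone candidate lists for the Tinigua canopy
    frugivory community: the pulp-biomass flow ranking (g ha^-1 day^-1)
    and the scarcity-period production index from an earlier study of the
    same forest. Used as fixed inputs for overlap comparisons."""
    with resources.files("frugnet.data").joinpath("tinigua_keystone_top20.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(R^2, slope sign) of y ~ x; NaN when x has no variance."""
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 0
    res = stats.linregress(x, y)
    return float(res.rvalue**2), int(np.sign(res.slope))


def abundance_r2(visit_times: pd.DataFrame, abundance: pd.Series,
                 min_frugivores: int = 3) -> tuple[pd.DataFrame, dict]:
    """Per-plant OLS of visit time on frugivore abundance.

    ``visit_times`` is plants x frugivores (minutes); ``abundance`` maps
    frugivore label to density. For each plant with at least
    ``min_frugivores`` frugivores having both a time and an abundance
    value, returns R^2 and the slope sign; the community summary reports
    the fraction of plants with a positive slope and the mean R^2.
    """
    ab = abundance.copy()
    ab.index = [normalize_label(i) for i in ab.index]
    vt = visit_times.copy()
    vt.columns = [normalize_label(c) for c in vt.columns]
    common = [c for c in vt.columns if c in ab.index]
    if len(common) < min_frugivores:
        raise ValueError("too few frugivores with abundance data")
    if ab[common].std() == 0:
        raise ValueError("abundance has zero variance across frugivores")
    rows = {}
    for plant, times in vt[common].iterrows():
        mask = times.notna()
        if mask.sum() < min_frugivores:
            warnings.warn(f"plant {plant!r} skipped: fewer than "
                          f"{min_frugivores} frugivores with data", stacklevel=2)
            continue
        r2, sign = _ols_r2(ab[common][mask].to_numpy(dtype=float),
                           times[mask].to_numpy(dtype=float))
        rows[plant] = {"r2": r2, "slope_sign": sign}
    table = pd.DataFrame(rows).T
    ok = table["r2"].notna()
    summary = {
        "n_plants": int(ok.sum()),
        "fraction_positive": float((table.loc[ok, "slope_sign"] > 0).mean())
        if ok.any() else float("nan"),
        "mean_r2": float(table.loc[ok, "r2"].mean()) if ok.any() else float("nan"),
    }
    return table, summary


#: (trait column regressed against pct_lipids, expected slope sign)
PREDICTIONS: list[tuple[str, int]] = [
    ("crop_duration", +1),
    ("seed_width", +1),
    ("frugivore_size", +1),
    ("crop_size", -1),
    ("visitation_rate", -1),
    ("visitor_richness", -1),
    ("recruit_below_parents", -1),
]


def prediction_battery(traits: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """The seven-regression screen of the specialized-vs-generalized
    dispersal-system hypothesis: OLS of pulp lipid content on each
    predictor, reporting expected sign, observed sign, R^2 and n.
    Predictors absent from ``traits`` appear as untested rows."""
    if "pct_lipids" not in traits.columns:
        raise ValueError("traits table lacks a 'pct_lipids' column")
    rows = []
    for col, expected in PREDICTIONS:
        row = {"predictor": col, "expected_sign": expected,
               "r2": float("nan"), "observed_sign": 0, "n": 0,
               "tested": col in traits.columns}
        if col in traits.columns:
            sub = traits[["pct_lipids", col]].dropna()
            row["n"] = len(sub)
            if len(sub) >= min_n:
                r2, sign = _ols_r2(sub[col].to_numpy(dtype=float),
                                   sub["pct_lipids"].to_numpy(dtype=float))
                row["r2"], row["observed_sign"] = r2, sign
        rows.append(row)
    return pd.DataFrame(rows).set_index("predictor")
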