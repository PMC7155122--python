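"""Well-level aggregation and the study's statistical comparisons.

Fields within a well are pseudo-replicates: every inference runs on well
means (the unit of analysis), never on fields. Comparisons follow the
original analysis plan: one-way ANOVA with Dunnett's test against a
control for multi-condition screens, two-way ANOVA with Sidak-adjusted
pairwise contrasts for factorial layouts, and plain arithmetic for the
secretion tables (percent of vWF released, fold inhibition).

Dunnett adjustment is computed by seeded Monte-Carlo sampling of the
max-|t| null distribution at the observed design, which reduces exactly
to the pooled two-sample t-test when there is a single contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class ComparisonResult:
    """One contrast from a multiple-comparison procedure."""

    contrast: str
    estimate: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    n_groups: tuple  # sample sizes of the two groups in the contrast

    def to_dict(self) -> dict:
        return {"contrast": self.contrast, "estimate": self.estimate,
                "t_statistic": self.t_statistic, "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted, "method": self.method,
                "n_treatment": self.n_groups[0], "n_control": self.n_groups[1]}


def comparisons_to_dataframe(results: list) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# --------------------------------------------------------------------------
# Well aggregation
# --------------------------------------------------------------------------

WELL_METRICS = ("wpb_per_cell", "long_area_fraction",
                "n_sites", "prop_large")


def aggregate_wells(image_summaries: pd.DataFrame) -> pd.DataFrame:
    """Unweighted well means of the per-image metrics.

    Flagged (NaN) image metrics are excluded metric-by-metric; a well
    with no valid image for any metric is dropped entirely.
    Columns: condition, well, n_images, mean_<metric> for every metric
    present in the input.
    """
    required = {"condition", "well"}
    if not required <= set(image_summaries.columns):
        raise ValueError("image summaries need condition and well columns")
    metrics = [m for m in WELL_METRICS if m in image_summaries.columns]
    if not metrics:
        raise ValueError("no known metric columns present")
    grouped = image_summaries.groupby(["condition", "well"], sort=True)
    out = grouped.size().rename("n_images").reset_index()
    for m in metrics:
        out[f"mean_{m}"] = grouped[m].mean().to_numpy()
    all_nan = out[[f"mean_{m}" for m in metrics]].isna().all(axis=1)
    if all_nan.any():
        dropped = out.loc[all_nan, "well"].tolist()
        logging.getLogger(__name__).warning(
            "dropping wells with no valid images: %s", dropped)
    return out[~all_nan].reset_index(drop=True)


# --------------------------------------------------------------------------
# One-way ANOVA + Dunnett (Monte-Carlo max-|t|)
# --------------------------------------------------------------------------

def one_way_dunnett(
    values_by_condition: dict,
    control: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> list:
    """Dunnett-style many-to-one comparisons after one-way ANOVA.

    ``values_by_condition`` maps condition label -> 1-D array of well
    values. Each non-control condition is compared with the control
    using t statistics on the pooled (ANOVA) error variance; familywise
    adjustment comes from ``n_mc`` seeded Monte-Carlo draws of the
    max-|t| null at the observed group sizes (two-tailed). The adjusted
    p is never allowed below the raw p.
    """
    if control not in values_by_condition:
        raise ValueError(f"control condition {control!r} not present")
    groups = {k: np.asarray(v, dtype=float)
              for k, v in values_by_condition.items()}
    for k, v in groups.items():
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"condition {k!r} needs >= 2 well values")
    labels = [k for k in groups if k != control]
    if not labels:
        raise ValueError("need at least one non-control condition")
    ns = {k: v.size for k, v in groups.items()}
    means = {k: v.mean() for k, v in groups.items()}
    n_total = sum(ns.values())
    df_err = n_total - len(groups)
    sse = sum(((v - means[k]) ** 2).sum() for k, v in groups.items())
    mse = sse / df_err
    rng = np.random.default_rng(seed)
    # Null draws: group means ~ N(0, 1/n), pooled variance ~ chi2(df)/df
    z = {k: rng.normal(0.0, 1.0 / math.sqrt(ns[k]), size=n_mc)
         for k in groups}
    s2 = rng.chisquare(df_err, size=n_mc) / df_err
    t_null = np.empty((len(labels), n_mc))
    for i, k in enumerate(labels):
        se = np.sqrt(s2 * (1.0 / ns[k] + 1.0 / ns[control]))
        t_null[i] = (z[k] - z[control]) / se
    max_abs_t = np.abs(t_null).max(axis=0)
    results = []
    for k in labels:
        est = means[k] - means[control]
        if mse <= 0:
            t_obs, p_raw, p_adj = 0.0, 1.0, 1.0
        else:
            se = math.sqrt(mse * (1.0 / ns[k] + 1.0 / ns[control]))
            t_obs = est / se
            p_raw = 2.0 * stats.t.sf(abs(t_obs), df_err)
            p_adj = float(np.mean(max_abs_t >= abs(t_obs)))
            p_adj = min(max(p_adj, p_raw), 1.0)
        results.append(ComparisonResult(
            contrast=f"{k} - {control}", estimate=float(est),
            t_statistic=float(t_obs), p_raw=float(p_raw),
            p_adjusted=float(p_adj), method="Dunnett (Monte-Carlo max-|t|)",
            n_groups=(ns[k], ns[control])))
    return results


def one_way_anova_f(values_by_condition: dict) -> tuple:
    """Plain one-way ANOVA F statistic and p value over the groups."""
    groups = [np.asarray(v, float) for v in values_by_condition.values()]
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# --------------------------------------------------------------------------
# Two-way ANOVA + Sidak
# --------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Sidak familywise adjustment: 1 - (1 - p)^m for m contrasts."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def two_way_sidak(
    data: pd.DataFrame,
    contrasts: list,
    value: str = "value",
    factor_a: str = "condition",
    factor_b: str = "treatment",
) -> tuple:
    """Two-way ANOVA with interaction plus Sidak-adjusted cell contrasts.

    ``contrasts`` is a list of pairs of cells, each cell an
    ``(a_level, b_level)`` tuple; every named cell must be non-empty.
    Returns ``(anova_table, [ComparisonResult...])``; contrast t tests
    use the full model's residual mean square as pooled error.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    cells = data.groupby([factor_a, factor_b])[value]
    sizes = cells.size()
    for pair in contrasts:
        for cell in pair:
            if tuple(cell) not in sizes.index or sizes[tuple(cell)] == 0:
                raise ValueError(f"empty cell {tuple(cell)!r}")
    d = data.rename(columns={value: "y", factor_a: "A", factor_b: "B"})
    model = smf.ols("y ~ C(A) * C(B)", data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    df_err = int(model.df_resid)
    means = cells.mean()
    m = len(contrasts)
    results = []
    for (cell1, cell2) in contrasts:
        c1, c2 = tuple(cell1), tuple(cell2)
        n1, n2 = int(sizes[c1]), int(sizes[c2])
        est = float(means[c1] - means[c2])
        if mse <= 0:
            t_obs, p_raw = 0.0, 1.0
        else:
            se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            t_obs = est / se
            p_raw = 2.0 * stats.t.sf(abs(t_obs), df_err)
        results.append(ComparisonResult(
            contrast=f"{c1} - {c2}", estimate=est,
            t_statistic=float(t_obs), p_raw=float(p_raw),
            p_adjusted=sidak_adjust(min(p_raw, 1.0), m),
            method=f"Sidak (m={m})", n_groups=(n1, n2)))
    return anova, results


# --------------------------------------------------------------------------
# Secretion tables
# --------------------------------------------------------------------------

def validate_secretion_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a releasate/lysate table: non-negative values, positive
    totals. Needs columns condition, inhibitor (bool), releasate, lysate."""
    required = {"condition", "inhibitor", "releasate", "lysate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"secretion table missing columns: {sorted(missing)}")
    if (table["releasate"] < 0).any() or (table["lysate"] < 0).any():
        raise ValueError("releasate and lysate must be non-negative")
    if ((table["releasate"] + table["lysate"]) <= 0).any():
        raise ValueError("releasate + lysate must be positive per row")
    return table


def percent_released(table: pd.DataFrame) -> pd.Series:
    """Percent of total vWF released: 100 * releasate / (releasate + lysate)."""
    table = validate_secretion_table(table)
    return 100.0 * table["releasate"] / (table["releasate"] + table["lysate"])


def fold_inhibition(
    table: pd.DataFrame,
    use_percent_released: bool = True,
) -> pd.Series:
    """Fold inhibition per condition: released with inhibitor divided by
    released without. 1 = no effect, < 1 = inhibition, > 1 = enhancement.

    By default 'released' is the percent-released ratio; with
    ``use_percent_released=False`` the raw releasate is used instead.
    """
    table = validate_secretion_table(table).copy()
    table["released"] = (percent_released(table) if use_percent_released
                         else table["releasate"].astype(float))
    out = {}
    for cond, g in table.groupby("condition", sort=True):
        with_i = g.loc[g["inhibitor"].astype(bool), "released"]
        without = g.loc[~g["inhibitor"].astype(bool), "released"]
        if with_i.empty or without.empty:
            raise ValueError(
                f"condition {cond!r} lacks an inhibitor/control pairing")
        out[cond] = float(with_i.mean() / without.mean())
    return pd.Series(out, name="fold_inhibition")


# --------------------------------------------------------------------------
# Size-selection verdict
# --------------------------------------------------------------------------

def detect_size_selection(
    well_summaries: pd.DataFrame,
    control: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
    metric: str = "mean_long_area_fraction",
    count_metric: str = "mean_wpb_per_cell",
) -> pd.DataFrame:
    """Classify each condition's release as long-selective,
    short-selective or non-selective.

    Random (length-independent) release leaves the long-area fraction of
    the retained population unchanged; a Dunnett-adjusted fall below the
    control at level ``alpha`` indicates preferential release of long
    granules, a rise indicates preferential release of short ones. The
    WPB-count comparison is reported alongside so "many granules
    released, fraction unchanged" is representable.
    """
    if metric not in well_summaries.columns:
        raise ValueError(f"missing metric column {metric!r}")
    values = {cond: g[metric].dropna().to_numpy()
              for cond, g in well_summaries.groupby("condition")}
    frac = one_way_dunnett(values, control, n_mc=n_mc, seed=seed)
    count_res = {}
    if count_metric in well_summaries.columns:
        counts = {cond: g[count_metric].dropna().to_numpy()
                  for cond, g in well_summaries.groupby("condition")}
        for r in one_way_dunnett(counts, control, n_mc=n_mc, seed=seed + 1):
            count_res[r.contrast.split(" - ")[0]] = r
    rows = []
    for r in frac:
        cond = r.contrast.split(" - ")[0]
        if r.p_adjusted < alpha and r.estimate < 0:
            verdict = "long-selective"
        elif r.p_adjusted < alpha and r.estimate > 0:
            verdict = "short-selective"
        else:
            verdict = "non-selective"
        row = {"condition": cond, "verdict": verdict,
               "fraction_estimate": r.estimate,
               "fraction_p_adjusted": r.p_adjusted}
        cr = count_res.get(cond)
        if cr is not None:
            row["count_estimate"] = cr.estimate
            row["count_p_adjusted"] = cr.p_adjusted
        rows.append(row)
    return pd.DataFrame(rows)
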