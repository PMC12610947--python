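"""Survival analysis for the RNAi lifespan screen.

Per-animal records (day of death or censoring, measured from the first day
of adulthood) are summarised per group with the Kaplan-Meier product-limit
estimator.  Conventions:

* **mean** lifespan is the restricted mean survival time — the area under
  the KM curve up to the last observed day — with a Greenwood-based standard
  error; with no censoring it equals the arithmetic mean of death days;
* **median** is the first day at which the KM curve drops to 0.5 or below;
* **maximum** is, by default, the mean lifespan of the longest-lived decile
  of animals with observed deaths (at least one animal); the single longest
  death day and the 90th percentile are available alternatives.

Groups are compared with the two-group log-rank test (observed vs. expected
event counts with hypergeometric variance, chi-square with 1 df).  Raw
p-values are Bonferroni-corrected within the family of test clones sharing a
batch, and a clone is a screen hit only if it clears the two-stage rule:
at least 5% mean-lifespan extension with corrected p < 0.05 against the
within-batch negative control in the initial screen, and corrected p < 0.05
again in the independent validation screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ValidationError

#: Required columns of a per-animal lifespan table.
LIFESPAN_COLUMNS = ["animal_id", "group", "batch", "plate", "day", "event"]

MAX_LIFESPAN_METHODS = ("decile_mean", "longest", "p90")


@dataclass
class GroupSummary:
    """Survival summary for one group of animals."""

    group: str
    n_subjects: int
    mean: float
    mean_se: float
    median: float
    maximum: float


def _check_table(table: pd.DataFrame) -> None:
    missing = {"day", "event"} - set(table.columns)
    if missing:
        raise ValidationError(f"lifespan table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValidationError("lifespan table is empty")
    if (table["day"] < 0).any():
        raise ValidationError("day must be >= 0 for every animal")
    if not set(table["event"].unique()) <= {0, 1}:
        raise ValidationError("event must be 0 (censored) or 1 (death)")


def kaplan_meier(table: pd.DataFrame) -> KaplanMeierFitter:
    """Product-limit survival estimate for one group of animals."""
    _check_table(table)
    if int(table["event"].sum()) < 1:
        raise ValidationError("no observed deaths: survival curve not estimable")
    kmf = KaplanMeierFitter()
    kmf.fit(table["day"], event_observed=table["event"])
    return kmf


def km_curve(table: pd.DataFrame) -> pd.DataFrame:
    """(day, survival) pairs of the KM step function, for export/plotting."""
    kmf = kaplan_meier(table)
    sf = kmf.survival_function_
    return pd.DataFrame({"day": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def restricted_mean(table: pd.DataFrame, tau: float | None = None) -> tuple[float, float]:
    """Restricted mean survival time and its Greenwood-based variance.

    The RMST is the exact area under the KM step function from 0 to ``tau``
    (default: the last observed day, death or censoring).  The variance is
    the standard product-limit result

        Var = sum_i  A_i^2 * d_i / (n_i (n_i - d_i)),

    over death times t_i <= tau, where A_i is the area under the curve from
    t_i to tau, d_i the deaths and n_i the number at risk at t_i; terms
    where the risk set is exhausted (n_i = d_i) contribute nothing.
    """
    _check_table(table)
    kmf = kaplan_meier(table)
    if tau is None:
        tau = float(table["day"].max())
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = (times <= tau) & (times > 0)
    # knots of the step function on [0, tau]; S is right-continuous, equal
    # to 1 before the first knot and to surv[i] from knot i onward
    grid = np.concatenate([[0.0], times[keep], [tau]])
    vals = np.concatenate([[1.0], surv[keep]])
    rmst = float(np.sum(vals * np.diff(grid)))

    et = kmf.event_table
    death_times = et.index.to_numpy(dtype=float)
    d = et["observed"].to_numpy(dtype=float)
    n_risk = et["at_risk"].to_numpy(dtype=float)
    mask = (d > 0) & (death_times <= tau)
    var = 0.0
    for ti, di, ni in zip(death_times[mask], d[mask], n_risk[mask]):
        if ni <= di:
            continue
        tail = np.clip(grid, ti, tau)
        a_i = float(np.sum(vals * np.diff(tail)))
        var += a_i * a_i * di / (ni * (ni - di))
    return rmst, float(var)


def maximum_lifespan(death_days: np.ndarray, method: str = "decile_mean") -> float:
    """Maximum-lifespan statistic over observed death days.

    ``decile_mean`` (default): mean of the top 10% of death days, rounding
    the decile size up so at least one animal is always included.
    ``longest``: the single largest death day.  ``p90``: the 90th percentile.
    """
    days = np.sort(np.asarray(death_days, dtype=float))
    if days.size == 0:
        raise ValidationError("maximum lifespan needs >=1 observed death")
    if method == "decile_mean":
        k = max(1, math.ceil(0.1 * days.size))
        return float(days[-k:].mean())
    if method == "longest":
        return float(days[-1])
    if method == "p90":
        return float(np.percentile(days, 90))
    raise ValidationError(f"unknown maximum-lifespan method {method!r}; use one of {MAX_LIFESPAN_METHODS}")


def lifespan_summaries(
    table: pd.DataFrame,
    group: str | None = None,
    max_method: str = "decile_mean",
) -> GroupSummary:
    """Mean (restricted mean +/- SE), median, and maximum lifespan of a group."""
    kmf = kaplan_meier(table)
    rmst, var = restricted_mean(table)
    deaths = table.loc[table["event"] == 1, "day"].to_numpy(dtype=float)
    return GroupSummary(
        group=group if group is not None else str(table["group"].iloc[0]) if "group" in table.columns else "",
        n_subjects=int(len(table)),
        mean=float(rmst),
        mean_se=float(np.sqrt(var)),
        median=float(kmf.median_survival_time_),
        maximum=maximum_lifespan(deaths, max_method),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, raw p)."""
    for tbl in (group_a, group_b):
        _check_table(tbl)
        if int(tbl["event"].sum()) < 1:
            raise ValidationError("log-rank test needs >=1 event in each group")
    res = _ll_logrank(
        group_a["day"], group_b["day"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        raise ValidationError("degenerate risk sets: log-rank statistic undefined")
    return stat, p


def percent_extension(test: GroupSummary, control: GroupSummary) -> dict[str, float]:
    """Signed percent change of the test group vs. its matched control."""
    out = {}
    for stat in ("mean", "median", "maximum"):
        c = getattr(control, stat)
        t = getattr(test, stat)
        if c == 0 or not np.isfinite(c):
            raise ValidationError(f"control {stat} is zero or undefined; extension not computable")
        out[stat] = 100.0 * (t - c) / c
    return out


def round_half_away(x: float) -> int:
    """Display rounding for percent extensions: halves round away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def compare_to_control(
    table: pd.DataFrame,
    control_group: str = "GFP",
    exclude_groups: tuple[str, ...] = (),
    max_method: str = "decile_mean",
) -> pd.DataFrame:
    """Summaries + log-rank comparisons of every test group vs. its batch control.

    Each batch must contain the ``control_group``; test groups are every
    other group in the batch except those in ``exclude_groups`` (additional
    controls such as the empty vector or the *daf-2* positive control, which
    are summarised but kept out of the Bonferroni family downstream).
    Returns one row per (batch, group) comparison with summary statistics,
    percent extensions, and the raw log-rank p.
    """
    _check_table(table)
    if "group" not in table.columns or "batch" not in table.columns:
        raise ValidationError("lifespan table needs 'group' and 'batch' columns")
    rows = []
    for batch, sub in table.groupby("batch"):
        groups = list(dict.fromkeys(sub["group"]))
        if control_group not in groups:
            raise ValidationError(f"batch {batch!r} has no control group {control_group!r}")
        ctrl_tbl = sub.loc[sub["group"] == control_group]
        ctrl = lifespan_summaries(ctrl_tbl, group=control_group, max_method=max_method)
        for g in groups:
            if g == control_group:
                continue
            g_tbl = sub.loc[sub["group"] == g]
            summ = lifespan_summaries(g_tbl, group=g, max_method=max_method)
            ext = percent_extension(summ, ctrl)
            chi2, p = logrank_test(g_tbl, ctrl_tbl)
            rows.append(
                {
                    "batch": batch,
                    "group": g,
                    "is_test_clone": g not in exclude_groups,
                    "n_subjects": summ.n_subjects,
                    "mean": summ.mean,
                    "mean_se": summ.mean_se,
                    "median": summ.median,
                    "maximum": summ.maximum,
                    "control_mean": ctrl.mean,
                    "control_median": ctrl.median,
                    "control_maximum": ctrl.maximum,
                    "pct_ext_mean": ext["mean"],
                    "pct_ext_median": ext["median"],
                    "pct_ext_max": ext["maximum"],
                    "logrank_chi2": chi2,
                    "raw_p": p,
                }
            )
    return pd.DataFrame(rows)


def bonferroni_within_batch(results: pd.DataFrame) -> pd.DataFrame:
    """Multiply each raw p by the number of test clones in its batch (cap 1).

    Only rows with ``is_test_clone`` count toward (and receive) the
    correction; extra control comparisons keep their raw p as adjusted p
    with family size 1.
    """
    out = results.copy()
    fam = (
        out.loc[out["is_test_clone"]].groupby("batch")["group"].nunique()
        if "is_test_clone" in out.columns
        else out.groupby("batch")["group"].nunique()
    )
    m = out["batch"].map(fam).fillna(1).astype(int).clip(lower=1)
    if "is_test_clone" in out.columns:
        m = m.where(out["is_test_clone"], 1)
    out["adjusted_p"] = np.minimum(out["raw_p"] * m, 1.0)
    out["bonferroni_m"] = m
    return out


def adjust_and_call(
    initial: pd.DataFrame,
    validation: pd.DataFrame,
    alpha: float = 0.05,
    min_extension_pct: float = 5.0,
) -> pd.DataFrame:
    """Two-stage hit calling over initial-screen and validation results.

    Both inputs come from :func:`compare_to_control` (rows for test clones).
    Bonferroni correction is applied within each stage's batches; a clone is
    a hit iff it shows >= ``min_extension_pct`` mean-lifespan extension with
    adjusted p < alpha in the initial screen AND adjusted p < alpha in the
    validation screen.  Clones present in only one stage are flagged
    ``not_evaluable`` and are never hits.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    ini = bonferroni_within_batch(initial.loc[initial.get("is_test_clone", True) == True])  # noqa: E712
    val = bonferroni_within_batch(validation.loc[validation.get("is_test_clone", True) == True])  # noqa: E712

    ini_by = ini.set_index("group")
    val_by = val.set_index("group")
    clones = list(dict.fromkeys(list(ini_by.index) + list(val_by.index)))
    rows = []
    for clone in clones:
        in_ini = clone in ini_by.index
        in_val = clone in val_by.index
        rec = {"clone": clone}
        rec["initial_pct_ext_mean"] = float(ini_by.loc[clone, "pct_ext_mean"]) if in_ini else np.nan
        rec["initial_adjusted_p"] = float(ini_by.loc[clone, "adjusted_p"]) if in_ini else np.nan
        rec["validation_adjusted_p"] = float(val_by.loc[clone, "adjusted_p"]) if in_val else np.nan
        if in_ini:
            initial_pass = (
                rec["initial_pct_ext_mean"] >= min_extension_pct
                and rec["initial_adjusted_p"] < alpha
            )
        else:
            initial_pass = False
        rec["initial_pass"] = bool(initial_pass)
        if not (in_ini and in_val):
            # a clone that failed the initial screen legitimately has no
            # validation data; only unexplained absences are not-evaluable
            if in_ini and not initial_pass:
                rec["status"] = "not_hit"
            else:
                rec["status"] = "not_evaluable"
            rec["hit"] = False
        else:
            validation_pass = rec["validation_adjusted_p"] < alpha
            rec["hit"] = bool(initial_pass and validation_pass)
            rec["status"] = "hit" if rec["hit"] else "not_hit"
        rows.append(rec)
    return pd.DataFrame(rows)
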