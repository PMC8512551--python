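"""Participant-level aggregation, Spearman correlation, and the study tables.

The analysis averages each participant's repeated measurements, then
correlates every muscle parameter (4 muscles x {T_c, T_d, D_m} = 12) with
every TUG time (5 subtasks + total) by Spearman's rank correlation.
Significance is flagged both at the raw alpha = 0.05 and at a
Bonferroni-adjusted threshold alpha / k (k = 12 by default, reproducing the
printed 0.0042 threshold; the family size is configurable).

The Spearman p-value uses the exact permutation distribution for n <= 9 and
the usual t approximation with n - 2 degrees of freedom otherwise.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tmg import MUSCLES, TMG_PARAMETERS
from .tug import SUBTASKS

__all__ = [
    "spearman",
    "bonferroni_threshold",
    "build_participant_records",
    "correlation_table",
    "descriptive_table",
    "export_plot_data",
    "TUG_TIMES",
    "TMG_VARIABLES",
]

logger = logging.getLogger(__name__)

#: The six TUG times entering the correlation table.
TUG_TIMES = SUBTASKS + ("total",)

#: The twelve muscle parameters entering the correlation table.
TMG_VARIABLES = tuple((m, p) for m in MUSCLES for p in TMG_PARAMETERS)

#: Largest n for which the exact permutation distribution is enumerated.
EXACT_P_MAX_N = 9


@lru_cache(maxsize=16)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n), as an (n!, n) index array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value of Spearman's rho.

    Enumerates all n! assignments of the y ranks against the fixed x ranks
    (ties kept as average ranks) and counts the fraction with |rho| at least
    |rho_obs|.  Includes the identity permutation, so p >= 1/n!.
    """
    n = rx.size
    perms = _permutation_indices(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho_all = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of the average ranks (ties receive average
    ranks).  The p-value comes from the exact permutation distribution for
    n <= 9 and from the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``
    with n - 2 degrees of freedom for larger n; ``method`` can force
    ``"exact"`` or ``"t"``.

    Raises
    ------
    ValueError
        for fewer than 3 pairs, non-finite values, or zero rank variance in
        either vector (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if method not in ("auto", "exact", "t"):
        raise ValueError(f"unknown method {method!r}")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("undefined correlation: zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_P_MAX_N)
    if use_exact:
        if n > EXACT_P_MAX_N:
            raise ValueError(f"exact permutation p only supported for n <= {EXACT_P_MAX_N}")
        p = _exact_permutation_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Bonferroni-adjusted significance level alpha / k.

    With alpha = 0.05 and the 12 muscle parameters as the family this gives
    0.0042 after 4-decimal rounding (the reporting layer rounds; the value
    returned here is exact).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("family size k must be a positive integer")
    return alpha / k


def build_participant_records(
    tug_results: pd.DataFrame, tmg_params: pd.DataFrame
) -> tuple[pd.DataFrame, list]:
    """Per-participant arithmetic means of all TUG times and muscle parameters.

    Only participants with at least one TUG and one TMG measurement are
    eligible; the rest are excluded and logged.

    Parameters
    ----------
    tug_results : DataFrame
        One row per segmented test: ``participant_id`` plus the six
        ``*_s`` time columns.
    tmg_params : DataFrame
        One row per participant x muscle: ``participant_id``, ``muscle``,
        ``Tc_ms``, ``Td_ms``, ``Dm_mm``.

    Returns
    -------
    (records, excluded)
        ``records``: one row per eligible participant with columns
        ``sit_up_s`` ... ``total_s`` and ``{muscle}_{param}`` for the twelve
        muscle parameters.  ``excluded``: list of (participant_id, reason).
    """
    tug_ids = (
        set(tug_results["participant_id"].unique()) if len(tug_results) else set()
    )
    tmg_ids = (
        set(tmg_params["participant_id"].unique()) if len(tmg_params) else set()
    )
    eligible = sorted(tug_ids & tmg_ids)
    excluded = [(pid, "no TMG measurement") for pid in sorted(tug_ids - tmg_ids)]
    excluded += [(pid, "no TUG measurement") for pid in sorted(tmg_ids - tug_ids)]
    for pid, reason in excluded:
        logger.warning("participant %s excluded: %s", pid, reason)
    if not eligible:
        raise ValueError("no eligible participants (need >= 1 TUG and >= 1 TMG each)")

    time_cols = [f"{t}_s" for t in TUG_TIMES]
    tug_means = (
        tug_results[tug_results["participant_id"].isin(eligible)]
        .groupby("participant_id")[time_cols]
        .mean()
    )

    tmg_sel = tmg_params[tmg_params["participant_id"].isin(eligible)]
    tmg_means = tmg_sel.groupby(["participant_id", "muscle"])[["Tc_ms", "Td_ms", "Dm_mm"]].mean()
    wide = {}
    for m, p in TMG_VARIABLES:
        col = tmg_means[f"{p}_ms" if p != "Dm" else "Dm_mm"].xs(m, level="muscle")
        wide[f"{m}_{p}"] = col
    records = tug_means.join(pd.DataFrame(wide)).loc[eligible]
    records.index.name = "participant_id"
    return records, excluded


def correlation_table(
    records: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int = 12,
    method: str = "auto",
) -> pd.DataFrame:
    """Spearman rho and p for every (muscle parameter x TUG time) pair.

    Returns a tidy table with one row per pair: ``muscle``, ``parameter``,
    ``subtask``, ``rho``, ``p``, ``n``, ``sig_raw`` (p < alpha) and
    ``sig_adj`` (p < alpha / family_size).  Pairs whose correlation is
    undefined (for example zero rank variance) are reported with missing rho
    and p, never fabricated.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 participant records")
    adj = bonferroni_threshold(alpha, family_size)
    rows = []
    for m, p in TMG_VARIABLES:
        x = records[f"{m}_{p}"].to_numpy()
        for t in TUG_TIMES:
            y = records[f"{t}_s"].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            row = {"muscle": m, "parameter": p, "subtask": t, "n": int(ok.sum())}
            try:
                rho, pval = spearman(x[ok], y[ok], method=method)
                row.update(rho=rho, p=pval, sig_raw=pval < alpha, sig_adj=pval < adj)
            except ValueError as err:
                logger.warning("correlation (%s %s, %s) undefined: %s", m, p, t, err)
                row.update(rho=np.nan, p=np.nan, sig_raw=False, sig_adj=False)
            rows.append(row)
    table = pd.DataFrame(rows, columns=["muscle", "parameter", "subtask", "rho", "p", "n", "sig_raw", "sig_adj"])
    table.attrs["alpha"] = alpha
    table.attrs["alpha_adjusted"] = adj
    return table


def descriptive_table(
    tug_results: pd.DataFrame,
    tmg_params: pd.DataFrame,
    granularity: str = "pooled",
) -> pd.DataFrame:
    """Mean, sample SD, min and max of every measured variable.

    With ``granularity="pooled"`` (default) the statistics pool all
    measurements (every test and every muscle session); with
    ``"participant"`` they are computed over participant means.  SD uses the
    n - 1 denominator and is reported missing for a single value.
    """
    if granularity not in ("pooled", "participant"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if granularity == "participant":
        tug_results = (
            tug_results.groupby("participant_id", as_index=False)[
                [f"{t}_s" for t in TUG_TIMES]
            ].mean()
        )
        tmg_params = tmg_params.groupby(
            ["participant_id", "muscle"], as_index=False
        )[["Tc_ms", "Td_ms", "Dm_mm"]].mean()

    rows = []
    for m in MUSCLES:
        sub = tmg_params[tmg_params["muscle"] == m]
        for p in TMG_PARAMETERS:
            col = sub[f"{p}_ms" if p != "Dm" else "Dm_mm"].dropna()
            rows.append(_describe(f"{m}_{p}", "mm" if p == "Dm" else "ms", col))
    rows.append(_describe("total", "s", tug_results["total_s"].dropna()))
    for t in SUBTASKS:
        rows.append(_describe(t, "s", tug_results[f"{t}_s"].dropna()))
    return pd.DataFrame(rows, columns=["variable", "unit", "mean", "sd", "min", "max", "n"])


def _describe(name: str, unit: str, values: pd.Series) -> dict:
    n = len(values)
    return {
        "variable": name,
        "unit": unit,
        "mean": values.mean() if n else np.nan,
        "sd": values.std(ddof=1) if n > 1 else np.nan,
        "min": values.min() if n else np.nan,
        "max": values.max() if n else np.nan,
        "n": n,
    }


def export_plot_data(
    records: pd.DataFrame,
    table: pd.DataFrame,
    outdir,
    tug_results: pd.DataFrame | None = None,
) -> dict:
    """Write scatter data for every raw-significant pair and subtask boxplot data.

    Each significant (muscle parameter, TUG time) pair gets a CSV of
    participant-level (x, y) points; an accompanying ``regressions.csv``
    holds the ordinary-least-squares slope and intercept per pair.  Boxplot
    quartiles per subtask are computed from the pooled test-level results
    when ``tug_results`` is given, else from the participant means.

    Returns a dict mapping logical names to written file paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict = {"scatter": []}

    reg_rows = []
    for _, row in table[table["sig_raw"] == True].iterrows():  # noqa: E712
        xcol = f"{row['muscle']}_{row['parameter']}"
        ycol = f"{row['subtask']}_s"
        pts = records[[xcol, ycol]].dropna().rename(columns={xcol: "x", ycol: "y"})
        fit = sps.linregress(pts["x"], pts["y"])
        path = outdir / f"scatter_{row['muscle']}_{row['parameter']}_vs_{row['subtask']}.csv"
        pts.to_csv(path, index=True, float_format="%.10g")
        written["scatter"].append(str(path))
        reg_rows.append(
            {
                "muscle": row["muscle"],
                "parameter": row["parameter"],
                "subtask": row["subtask"],
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_value": fit.rvalue,
                "n": len(pts),
            }
        )
    reg_path = outdir / "regressions.csv"
    pd.DataFrame(
        reg_rows, columns=["muscle", "parameter", "subtask", "slope", "intercept", "r_value", "n"]
    ).to_csv(reg_path, index=False, float_format="%.10g")
    written["regressions"] = str(reg_path)

    source = tug_results if tug_results is not None else records.reset_index()
    box_rows = []
    for t in TUG_TIMES:
        v = source[f"{t}_s"].dropna().to_numpy()
        q = np.percentile(v, [0, 25, 50, 75, 100]) if v.size else [np.nan] * 5
        box_rows.append(
            {
                "subtask": t,
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
                "n": v.size,
            }
        )
    box_path = outdir / "boxplot_subtasks.csv"
    pd.DataFrame(box_rows).to_csv(box_path, index=False, float_format="%.10g")
    written["boxplot"] = str(box_path)
    return written
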