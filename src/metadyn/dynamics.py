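"""Drug-induced dynamic fold-changes against the model-predicted baseline.

For a treated sample of cell line j at time t, the expected unperturbed
intensity of ion i is reconstructed from the steady-state fit and the cell
number extracted at sampling time:

    FC_{t,i}^{D,j} = log2( I_{t,i}^{D,j} / (alpha_{j,i} * N_{j,t} + beta_i) )

so no untreated control wells are needed at each time point.  Replicate
log2 fold-changes are averaged and tested against zero with a two-sided
one-sample t-test (a two-sample mode against time-matched untreated wells
is available).  Uncertainty in alpha/beta is not propagated into the test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .steady_state import SteadyStateResults, _prepare_meta

logger = logging.getLogger(__name__)

__all__ = [
    "predict_baseline",
    "compute_fold_changes",
    "fold_change_significance",
    "FC_COLUMNS",
]

FC_COLUMNS = [
    "ion",
    "cell_line",
    "treatment",
    "time_h",
    "log2fc",
    "pvalue",
    "n_reps",
    "baseline",
]


def predict_baseline(
    fit: SteadyStateResults, ion, cell_line: str, cell_number: float
) -> float:
    """Expected unperturbed intensity alpha_j * N + beta for one ion."""
    return fit.predict_baseline(ion, cell_line, cell_number)


def fold_change_significance(replicate_fcs) -> float:
    """Two-sided one-sample t-test of replicate log2 fold-changes vs 0.

    Fewer than two replicates -> NaN.  Zero-variance replicates: p = 1 when
    they sit exactly at zero (no evidence of change), p = 0 otherwise.
    """
    x = np.asarray(list(replicate_fcs), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    if np.ptp(x) == 0:
        return 1.0 if x[0] == 0 else 0.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def compute_fold_changes(
    treated: pd.DataFrame,
    meta: pd.DataFrame,
    fit: SteadyStateResults,
    *,
    baseline_treatment: str = "none",
    mode: str = "one-sample",
) -> pd.DataFrame:
    """Per (ion, cell line, treatment, time) log2 fold-change and p-value.

    Parameters
    ----------
    treated
        Ions x samples intensity matrix containing the perturbed samples
        (untreated samples present are used only by the two-sample mode).
    meta
        Sample metadata (same dialect as the steady-state model).
    fit
        Steady-state results providing alpha/beta and reliability flags.
    mode
        ``"one-sample"`` (default): t-test of replicate log2 FCs against 0.
        ``"two-sample"``: Welch t-test of treated replicate log2 FCs against
        time-matched untreated replicate log2 FCs in the same cell line.

    Replicates with non-positive measured intensity or non-positive
    predicted baseline are dropped (logged).  (ion, line) pairs that are
    not reliable in the steady-state fit are excluded.
    """
    if mode not in ("one-sample", "two-sample"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = _prepare_meta(meta)
    cols = [s for s in treated.columns if s in meta.index]
    meta = meta.loc[cols]
    is_treated = meta["treatment"] != baseline_treatment
    rep_rows = _replicate_fcs(treated, meta, fit)
    if rep_rows.empty:
        return pd.DataFrame(columns=FC_COLUMNS)

    treated_fcs = rep_rows[rep_rows["treatment"] != baseline_treatment]
    keys = ["ion", "cell_line", "treatment", "time_h"]
    if mode == "one-sample":
        out = _aggregate_one_sample(treated_fcs, keys)
    else:
        out = []
        for (ion, line, trt, t), grp in treated_fcs.groupby(keys, sort=True):
            fcs = grp["fc"].to_numpy()
            ctrl = rep_rows[
                (rep_rows["ion"] == ion)
                & (rep_rows["cell_line"] == line)
                & (rep_rows["treatment"] == baseline_treatment)
                & (rep_rows["time_h"] == t)
            ]["fc"].to_numpy()
            if len(fcs) >= 2 and len(ctrl) >= 2:
                p = float(stats.ttest_ind(fcs, ctrl, equal_var=False).pvalue)
            else:
                p = float("nan")
            out.append(
                {
                    "ion": ion,
                    "cell_line": line,
                    "treatment": trt,
                    "time_h": t,
                    "log2fc": float(np.mean(fcs)),
                    "pvalue": p,
                    "n_reps": len(fcs),
                    "baseline": float(grp["baseline"].mean()),
                }
            )
        out = pd.DataFrame(out, columns=FC_COLUMNS)
    if not is_treated.any():
        logger.warning("no treated samples found in metadata")
    return out


def _aggregate_one_sample(rep_rows: pd.DataFrame, keys: list) -> pd.DataFrame:
    """Vectorised per-condition mean and one-sample t-test against zero."""
    g = rep_rows.groupby(keys, sort=True)
    agg = g.agg(
        log2fc=("fc", "mean"),
        sd=("fc", lambda x: x.std(ddof=1)),
        n_reps=("fc", "size"),
        baseline=("baseline", "mean"),
    ).reset_index()
    mean = agg["log2fc"].to_numpy()
    sd = agg["sd"].to_numpy()
    n = agg["n_reps"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
    p = np.where(n < 2, np.nan, p)
    agg["pvalue"] = p
    return agg[FC_COLUMNS]


def _replicate_fcs(
    treated: pd.DataFrame, meta: pd.DataFrame, fit: SteadyStateResults
) -> pd.DataFrame:
    """Replicate-level log2(I / (alpha*N + beta)), reliable pairs only."""
    ions = treated.index.intersection(fit.alpha.index)
    rows = []
    n_dropped = 0
    for sample, m in meta.iterrows():
        line = m["cell_line"]
        if line not in fit.alpha.columns:
            raise ValueError(f"cell line {line!r} absent from steady-state fit")
        rel = fit.reliable.loc[ions, line].to_numpy()
        a = fit.alpha.loc[ions, line].to_numpy(float)
        b = fit.beta.loc[ions].to_numpy(float)
        baseline = a * float(m["cell_number"]) + b
        I = treated.loc[ions, sample].to_numpy(float)
        ok = rel & np.isfinite(I) & (I > 0) & (baseline > 0)
        n_dropped += int((rel & np.isfinite(I)).sum() - ok.sum())
        fc = np.log2(I[ok] / baseline[ok])
        rows.append(
            pd.DataFrame(
                {
                    "ion": ions[ok],
                    "cell_line": line,
                    "treatment": m["treatment"],
                    "time_h": m["time_h"],
                    "replicate": m.get("replicate", 0),
                    "fc": fc,
                    "baseline": baseline[ok],
                }
            )
        )
    if n_dropped:
        logger.info(
            "%d replicate measurements dropped (non-positive intensity "
            "or baseline)",
            n_dropped,
        )
    return (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "ion", "cell_line", "treatment", "time_h",
                "replicate", "fc", "baseline",
            ]
        )
    )
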