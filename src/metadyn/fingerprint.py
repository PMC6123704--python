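"""Drug fingerprints and metabolite-set enrichment.

Per-ion fold-change time courses across cell lines are condensed into two
summary statistics: the median, across cell lines, of the signed fold
change at the time point of maximal absolute response, and the product of
each line's minimal p-value over the time course.  Ions with
|median log2 FC| >= 1 and combined p <= 1e-10 form the *conserved*
fingerprint of a drug; ions whose per-line maximal responses vary strongly
(sample SD >= 1.5) form the *cell-line-specific* fingerprint.  Either set
is tested against metabolite pathway sets with a hypergeometric
overrepresentation test and multiple-testing correction.

The combined p-value (product of minima) is a ranking score, not a
calibrated tail probability — min-over-time selection and the product
across lines are both anti-conservative.  It is used here exactly as a
selection score and never interpreted as a significance level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PathwaySet",
    "summarize_across_lines",
    "select_conserved",
    "select_variable",
    "enrich_pathways",
    "adjust_pvalues",
    "hypergeom_pvalue",
]


@dataclass(frozen=True)
class PathwaySet:
    """A named set of metabolite ids (one GMT line)."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


def summarize_across_lines(
    fc: pd.DataFrame, treatment: str, *, absolute: bool = False
) -> pd.DataFrame:
    """Condense fold-change time courses into per-ion summaries.

    For each (ion, cell line): take the signed log2 FC at the time point
    with maximal |FC| (earliest time on ties) and the minimum p-value over
    the time course.  Per ion: ``median_max_fc`` is the median of those
    signed values across lines (of their absolute values if ``absolute``),
    ``combined_p`` the product of the per-line minimal p-values, and
    ``sd_max_fc`` their sample standard deviation (ddof=1; NaN for
    single-line ions).  Lines missing for an ion are skipped and counted in
    ``n_lines``.
    """
    sub = fc[fc["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no fold-changes for treatment {treatment!r}")
    rows = []
    for (ion, line), grp in sub.groupby(["ion", "cell_line"], sort=True):
        grp = grp.sort_values("time_h")
        fcs = grp["log2fc"].to_numpy()
        if not np.isfinite(fcs).any():
            continue
        k = int(np.nanargmax(np.abs(fcs)))
        pvals = grp["pvalue"].to_numpy()
        pmin = np.nanmin(pvals) if np.isfinite(pvals).any() else np.nan
        rows.append({"ion": ion, "cell_line": line, "max_fc": fcs[k], "min_p": pmin})
    per_line = pd.DataFrame(rows)
    if per_line.empty:
        raise ValueError("no finite fold-changes to summarize")

    out = []
    for ion, grp in per_line.groupby("ion", sort=True):
        vals = grp["max_fc"].to_numpy()
        med = float(np.median(np.abs(vals) if absolute else vals))
        pmins = grp["min_p"].to_numpy()
        pmins = pmins[np.isfinite(pmins)]
        combined = float(np.prod(pmins)) if pmins.size else np.nan
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
        out.append(
            {
                "ion": ion,
                "median_max_fc": med,
                "combined_p": combined,
                "sd_max_fc": sd,
                "n_lines": len(grp),
            }
        )
    return pd.DataFrame(out).set_index("ion")


def select_conserved(
    table: pd.DataFrame, fc_cut: float = 1.0, p_cut: float = 1e-10
) -> pd.Index:
    """Conserved-response ions: |median_max_fc| >= fc_cut and
    combined_p <= p_cut (both bounds inclusive)."""
    if table.empty:
        raise ValueError("empty fingerprint table")
    mask = (table["median_max_fc"].abs() >= fc_cut) & (
        table["combined_p"] <= p_cut
    )
    return table.index[mask.fillna(False)]


def select_variable(table: pd.DataFrame, sd_cut: float = 1.5) -> pd.Index:
    """Cell-line-specific ions: sample SD of per-line maximal fold-changes
    >= sd_cut (inclusive).  Single-line ions (SD undefined) are skipped."""
    mask = table["sd_max_fc"] >= sd_cut
    return table.index[mask.fillna(False)]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    selected,
    universe,
    pathways: list[PathwaySet],
    q_cut: float = 0.001,
    method: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each pathway in the selection.

    Pathway memberships are intersected with the universe before testing;
    empty intersections are skipped.  Results are sorted by q then p, with
    a ``significant`` flag at ``q_cut``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected set must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for pw in pathways:
        members = pw.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        rows.append(
            {
                "pathway": pw.pathway_id,
                "name": pw.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_pvalue(k, K, n, N),
            }
        )
    res = pd.DataFrame(
        rows, columns=["pathway", "name", "k", "K", "n", "N", "p"]
    )
    if res.empty:
        res["q"] = []
        res["significant"] = []
        return res
    res["q"] = adjust_pvalues(res["p"].to_numpy(), method=method)
    res["significant"] = res["q"] <= q_cut
    return res.sort_values(["q", "p"], kind="stable").reset_index(drop=True)


def adjust_pvalues(ps, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up (``"bh"``)
    or Storey's q-values (``"storey"``).

    Storey's estimator needs enough tests to estimate the null proportion
    pi0 by lambda-smoothing; with fewer than 100 p-values it falls back to
    BH with a warning.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps.copy()
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    method = method.lower()
    if method in ("bh", "fdr_bh"):
        return multipletests(ps, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown correction method {method!r}")
    if ps.size < 100:
        warnings.warn(
            "fewer than 100 tests: Storey pi0 estimate unstable, "
            "falling back to Benjamini-Hochberg",
            stacklevel=2,
        )
        return multipletests(ps, method="fdr_bh")[1]
    return _storey_qvalues(ps)


def _storey_qvalues(ps: np.ndarray) -> np.ndarray:
    """Storey q-values with cubic-spline lambda-smoothing of pi0."""
    from scipy.interpolate import UnivariateSpline

    m = ps.size
    lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_l = np.array(
        [(ps > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    )
    spline = UnivariateSpline(lambdas, pi0_l, k=3)
    pi0 = float(np.clip(spline(lambdas[-1]), 1e-8, 1.0))
    order = np.argsort(ps)
    ranked = ps[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return out
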