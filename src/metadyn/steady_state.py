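"""Shared linear intensity model for normalization-free metabolomics.

In unperturbed, exponentially growing cultures intracellular metabolite
concentrations are constant, so the measured flow-injection MS intensity of
ion *i* in a sample of cell line *j* scales with the number of extracted
cells N_c on top of a cell-independent instrument background:

    I_{j,i} = alpha_{j,i} * N_c + beta_i

alpha_{j,i} is the per-cell abundance of the metabolite in that cell line
(up to the unknown MS response factor) and beta_i the shared background
offset.  For each ion, all cell lines are regressed at once through a block
design matrix (one N_c column per cell line plus a shared intercept), which
both normalizes for cell number without housekeeping assumptions and flags
ions that show no cell-number dependence (pure background or below the
detection limit): an ion is *reliable* in a line when alpha > 0 with
p <= 0.001 under the F test of the coefficient against zero.

Samples above 80% confluence are excluded before fitting: cell numbers
derived from bright-field imaging are unreliable in crowded wells, and
cultures near confluence deviate from metabolic steady state.

The module follows the Model/Results convention: build a
:class:`SteadyStateModel` from an intensity matrix plus sample metadata,
call :meth:`~SteadyStateModel.fit`, and work with the returned
:class:`SteadyStateResults`.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SteadyStateModel",
    "SteadyStateResults",
    "filter_by_confluence",
    "fit_ion",
    "fit_all",
    "summarize_cv",
    "per_sample_abundance",
    "anova_across_lines",
    "META_COLUMNS",
]

#: Required sample-metadata columns (``sample_id`` may be the index).
META_COLUMNS = (
    "cell_line",
    "replicate",
    "time_h",
    "treatment",
    "cell_number",
    "confluence",
)


def filter_by_confluence(
    meta: pd.DataFrame, max_confluence: float = 0.80
) -> pd.DataFrame:
    """Drop samples whose confluence exceeds ``max_confluence`` (exclusive
    bound: a sample at exactly the threshold is kept).  Order is preserved."""
    if "confluence" not in meta.columns:
        raise ValueError("metadata has no 'confluence' column")
    kept = meta.loc[meta["confluence"] <= max_confluence]
    if kept.empty:
        warnings.warn(
            "all samples exceed the confluence threshold; nothing to fit",
            stacklevel=2,
        )
    return kept


def _prepare_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    missing = [c for c in ("cell_line", "cell_number") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if (meta["cell_number"] < 0).any():
        raise ValueError("negative cell numbers in metadata")
    return meta


def _design_matrix(
    meta: pd.DataFrame, lines: Sequence[str]
) -> np.ndarray:
    """Block design of the multi-cell-line model: one N_c column per line
    (zero elsewhere) plus a shared intercept for the background beta."""
    n = len(meta)
    X = np.zeros((n, len(lines) + 1))
    codes = pd.Categorical(meta["cell_line"], categories=lines).codes
    X[np.arange(n), codes] = meta["cell_number"].to_numpy(float)
    X[:, -1] = 1.0
    return X


def _solve_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised OLS of many responses (rows of Y) on one design X.

    Returns (coef, se, pval, df, n) with shape (n_responses, n_params) for
    the first three.  Per-coefficient significance is the F statistic with
    1 numerator df testing the coefficient against zero (identical to the
    squared t statistic).
    """
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError(f"underdetermined fit: {n} samples for {p} parameters")
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # p x n
    coef = Y @ proj.T  # r x p
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (coef / se) ** 2
    pval = stats.f.sf(fstat, 1, df)
    # Degenerate (zero-residual) fits: exact data give RSS at rounding level,
    # where coef/se is a ratio of rounding errors.  Call the coefficient zero
    # (p = 1) when its fitted contribution is negligible, certain otherwise.
    scale = np.einsum("ij,ij->i", Y, Y) / n
    degen = rss <= 1e-20 * n * np.maximum(scale, 1e-300)
    if degen.any():
        xmax = np.abs(X).max(axis=0)
        contrib = np.abs(coef) * xmax[None, :]
        tiny = contrib <= 1e-8 * np.sqrt(np.maximum(scale, 1e-300))[:, None]
        pval[degen] = np.where(tiny[degen], 1.0, 0.0)
    return coef, se, pval, df, n


def fit_ion(
    intensities: pd.Series | np.ndarray,
    meta: pd.DataFrame,
    lines: Sequence[str] | None = None,
) -> dict:
    """Fit the shared linear model for a single ion.

    Missing intensities are dropped sample-wise.  A cell line whose
    remaining samples do not span at least two distinct cell numbers is
    flagged non-estimable (alpha = NaN) and its column removed from the
    design.  Returns a dict with per-line ``alpha``/``alpha_se``/``alpha_p``
    maps plus ``beta``, ``beta_se``, ``n_used`` and ``df``.
    """
    meta = _prepare_meta(meta)
    y = np.asarray(
        intensities.reindex(meta.index)
        if isinstance(intensities, pd.Series)
        else intensities,
        dtype=float,
    )
    if lines is None:
        lines = sorted(meta["cell_line"].unique())
    mask = np.isfinite(y)
    if not mask.any():
        raise ValueError("all intensities missing for this ion")
    sub = meta.iloc[mask.nonzero()[0]]
    estimable = [
        ln
        for ln in lines
        if sub.loc[sub["cell_line"] == ln, "cell_number"].nunique() >= 2
    ]
    keep = sub["cell_line"].isin(estimable).to_numpy()
    sub = sub.loc[keep]
    X = _design_matrix(sub, estimable)
    coef, se, pval, df, n = _solve_ols(X, y[mask][keep][None, :])
    alpha = {ln: np.nan for ln in lines}
    alpha_se = dict(alpha)
    alpha_p = dict(alpha)
    for k, ln in enumerate(estimable):
        alpha[ln], alpha_se[ln], alpha_p[ln] = coef[0, k], se[0, k], pval[0, k]
    return {
        "alpha": alpha,
        "alpha_se": alpha_se,
        "alpha_p": alpha_p,
        "beta": coef[0, -1],
        "beta_se": se[0, -1],
        "n_used": n,
        "df": df,
    }


class SteadyStateModel:
    """Multi-cell-line linear intensity model I = alpha_j * N_c + beta.

    Parameters
    ----------
    intensities
        Ions x samples matrix (rows indexed by ion id or m/z, columns by
        sample id).  NaN marks missing measurements.
    meta
        Sample metadata with columns ``cell_line``, ``replicate``,
        ``time_h``, ``treatment``, ``cell_number``, ``confluence``
        (``sample_id`` either as index or column).  Only unperturbed samples
        (``treatment == baseline_treatment``) at or below the confluence
        threshold enter the fit.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        meta: pd.DataFrame,
        *,
        max_confluence: float = 0.80,
        baseline_treatment: str = "none",
    ):
        meta = _prepare_meta(meta)
        unknown = [s for s in intensities.columns if s not in meta.index]
        if unknown:
            raise ValueError(f"sample columns absent from metadata: {unknown}")
        if "treatment" in meta.columns:
            meta = meta.loc[meta["treatment"] == baseline_treatment]
        if "confluence" in meta.columns:
            meta = filter_by_confluence(meta, max_confluence)
        meta = meta.loc[meta.index.intersection(intensities.columns)]
        self.meta = meta
        self.intensities = intensities[meta.index]
        self.lines: list[str] = sorted(meta["cell_line"].unique())
        self.max_confluence = max_confluence

    @classmethod
    def from_files(cls, matrix_path, meta_path, **kwargs) -> "SteadyStateModel":
        from . import io

        return cls(
            io.read_intensity_matrix(matrix_path),
            io.read_sample_meta(meta_path),
            **kwargs,
        )

    def fit(self, p_threshold: float = 0.001) -> "SteadyStateResults":
        """Least-squares fit of every ion, with reliability filtering.

        Ions with complete data share one design matrix and are solved in a
        single vectorised pass; ions with missing values fall back to the
        per-ion path.  Reliability per (ion, line): alpha > 0 and
        p <= ``p_threshold``.
        """
        lines = self.lines
        meta = self.meta
        if len(meta) < len(lines) + 2:
            raise ValueError(
                f"{len(meta)} samples cannot identify {len(lines)} slopes "
                "plus a shared offset"
            )
        estimable = [
            ln
            for ln in lines
            if meta.loc[meta["cell_line"] == ln, "cell_number"].nunique() >= 2
        ]
        dropped = sorted(set(lines) - set(estimable))
        if dropped:
            logger.warning(
                "cell lines with constant cell number flagged non-estimable: %s",
                dropped,
            )
        keep = meta["cell_line"].isin(estimable)
        meta_fit = meta.loc[keep]
        Y_all = self.intensities.loc[:, meta_fit.index]

        p = len(estimable) + 1
        ions = Y_all.index
        alpha = pd.DataFrame(np.nan, index=ions, columns=lines)
        alpha_se = alpha.copy()
        alpha_p = alpha.copy()
        beta = pd.Series(np.nan, index=ions)
        beta_se = pd.Series(np.nan, index=ions)
        n_used = pd.Series(0, index=ions, dtype=int)

        Y = Y_all.to_numpy(float)
        complete = np.isfinite(Y).all(axis=1)
        if complete.any():
            X = _design_matrix(meta_fit, estimable)
            coef, se, pv, df, n = _solve_ols(X, Y[complete])
            for k, ln in enumerate(estimable):
                alpha.loc[complete, ln] = coef[:, k]
                alpha_se.loc[complete, ln] = se[:, k]
                alpha_p.loc[complete, ln] = pv[:, k]
            beta.loc[complete] = coef[:, -1]
            beta_se.loc[complete] = se[:, -1]
            n_used.loc[complete] = n
        skipped: list = []
        for ion in ions[~complete]:
            try:
                row = fit_ion(Y_all.loc[ion], meta_fit, lines=estimable)
            except ValueError as err:
                logger.warning("ion %s skipped: %s", ion, err)
                skipped.append(ion)
                continue
            for ln in estimable:
                alpha.loc[ion, ln] = row["alpha"][ln]
                alpha_se.loc[ion, ln] = row["alpha_se"][ln]
                alpha_p.loc[ion, ln] = row["alpha_p"][ln]
            beta.loc[ion] = row["beta"]
            beta_se.loc[ion] = row["beta_se"]
            n_used.loc[ion] = row["n_used"]

        with np.errstate(invalid="ignore", divide="ignore"):
            cv = alpha_se / alpha
        cv = cv.where(alpha > 0)
        reliable = (alpha > 0) & (alpha_p <= p_threshold)
        return SteadyStateResults(
            model=self,
            alpha=alpha,
            alpha_se=alpha_se,
            alpha_p=alpha_p,
            beta=beta,
            beta_se=beta_se,
            cv=cv,
            reliable=reliable.fillna(False),
            n_used=n_used,
            p_threshold=p_threshold,
            skipped_ions=skipped,
        )


class SteadyStateResults:
    """Per-ion estimates of the shared linear intensity model.

    Attributes
    ----------
    alpha, alpha_se, alpha_p, cv, reliable
        Ions x cell-lines frames of slopes (per-cell intensities), their
        standard errors, coefficient-vs-zero p-values, coefficients of
        variation (SE/estimate), and the reliability flags.
    beta, beta_se
        Per-ion shared background offset and its standard error.
    """

    def __init__(
        self,
        *,
        model: SteadyStateModel,
        alpha: pd.DataFrame,
        alpha_se: pd.DataFrame,
        alpha_p: pd.DataFrame,
        beta: pd.Series,
        beta_se: pd.Series,
        cv: pd.DataFrame,
        reliable: pd.DataFrame,
        n_used: pd.Series,
        p_threshold: float,
        skipped_ions: list,
    ):
        self.model = model
        self.alpha = alpha
        self.alpha_se = alpha_se
        self.alpha_p = alpha_p
        self.beta = beta
        self.beta_se = beta_se
        self.cv = cv
        self.reliable = reliable
        self.n_used = n_used
        self.p_threshold = p_threshold
        self.skipped_ions = skipped_ions

    @property
    def lines(self) -> list[str]:
        return list(self.alpha.columns)

    @property
    def reliable_ions(self) -> pd.Index:
        """Ions reliable in at least one cell line."""
        return self.reliable.index[self.reliable.any(axis=1)]

    @property
    def excluded_ions(self) -> pd.Index:
        """Ions with no reliable line: background or below detection limit."""
        return self.reliable.index[~self.reliable.any(axis=1)]

    def median_cv(self) -> float:
        """Median coefficient of variation over reliable (ion, line) pairs,
        in percent."""
        vals = self.cv.where(self.reliable).to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no reliable (ion, line) pairs")
        return float(np.median(vals) * 100.0)

    def predict_baseline(self, ion, cell_line: str, cell_number: float) -> float:
        """Expected unperturbed intensity alpha_j * N + beta for one ion."""
        a = self.alpha.loc[ion, cell_line]
        if not self.reliable.loc[ion, cell_line]:
            raise ValueError(
                f"ion {ion!r} is not reliable in cell line {cell_line!r}"
            )
        return float(a * cell_number + self.beta.loc[ion])

    def per_sample_abundance(
        self,
        intensities: pd.DataFrame | None = None,
        meta: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Per-cell abundance estimates (I - beta) / N_c per sample.

        Negative values are retained (background noise around beta).
        Samples with N_c = 0 are skipped.
        """
        if intensities is None:
            intensities = self.model.intensities
        if meta is None:
            meta = self.model.meta
        else:
            meta = _prepare_meta(meta)
        meta = meta.loc[meta["cell_number"] > 0]
        cols = [s for s in intensities.columns if s in meta.index]
        I = intensities[cols]
        N = meta.loc[cols, "cell_number"].to_numpy(float)
        return I.sub(self.beta, axis=0).div(N, axis=1)

    def anova_across_lines(
        self,
        q_threshold: float = 0.05,
        method: str = "fdr_bh",
    ) -> pd.DataFrame:
        """One-way ANOVA of per-cell abundance across cell lines, per ion.

        Tests whether the baseline abundance of each reliable ion differs
        between cell lines, with Benjamini-Hochberg adjustment across ions.
        """
        abund = self.per_sample_abundance()
        labels = self.model.meta.loc[abund.columns, "cell_line"]
        return anova_across_lines(
            abund, labels, q_threshold=q_threshold, method=method
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy (ion, cell_line) table with alpha/se/p/cv/reliable + beta."""
        rows = []
        for ln in self.lines:
            rows.append(
                pd.DataFrame(
                    {
                        "ion": self.alpha.index,
                        "cell_line": ln,
                        "alpha": self.alpha[ln].to_numpy(),
                        "alpha_se": self.alpha_se[ln].to_numpy(),
                        "alpha_p": self.alpha_p[ln].to_numpy(),
                        "cv": self.cv[ln].to_numpy(),
                        "reliable": self.reliable[ln].to_numpy(),
                        "beta": self.beta.to_numpy(),
                        "beta_se": self.beta_se.to_numpy(),
                        "n_used": self.n_used.to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        n_ions = len(self.alpha.index)
        n_rel = len(self.reliable_ions)
        lines = ", ".join(self.lines)
        try:
            cv = f"{self.median_cv():.1f}%"
        except ValueError:
            cv = "n/a"
        per_line = "\n".join(
            f"    {ln:>12s}: {int(self.reliable[ln].sum())} reliable ions"
            for ln in self.lines
        )
        return (
            "Steady-state intensity model  I = alpha_j * N_c + beta\n"
            f"  cell lines: {lines}\n"
            f"  ions fitted: {n_ions} "
            f"({len(self.skipped_ions)} skipped)\n"
            f"  reliable in >=1 line (alpha > 0, p <= {self.p_threshold:g}): "
            f"{n_rel}\n"
            f"  median CV of reliable alpha estimates: {cv}\n"
            f"{per_line}"
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SteadyStateResults: {len(self.alpha.index)} ions x "
            f"{len(self.lines)} lines, {len(self.reliable_ions)} reliable>"
        )


def fit_all(
    intensities: pd.DataFrame,
    meta: pd.DataFrame,
    p_threshold: float = 0.001,
    max_confluence: float = 0.80,
) -> SteadyStateResults:
    """Functional wrapper: build the model and fit in one call."""
    return SteadyStateModel(
        intensities, meta, max_confluence=max_confluence
    ).fit(p_threshold=p_threshold)


def summarize_cv(fit: SteadyStateResults) -> float:
    """Median CV (percent) over all reliable (ion, line) pairs."""
    return fit.median_cv()


def per_sample_abundance(
    intensities: pd.DataFrame, meta: pd.DataFrame, fit: SteadyStateResults
) -> pd.DataFrame:
    """Functional wrapper around :meth:`SteadyStateResults.per_sample_abundance`."""
    return fit.per_sample_abundance(intensities, meta)


def anova_across_lines(
    abundances: pd.DataFrame,
    labels: Iterable[str],
    q_threshold: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """One-way ANOVA per ion across cell-line groups with FDR adjustment.

    ``abundances`` is ions x samples; ``labels`` assigns each sample column
    to a cell line.  Ions lacking two groups with two finite values each are
    skipped (logged).  Returns a frame with F, p, q and a ``significant``
    flag at ``q_threshold``.
    """
    labels = pd.Series(list(labels), index=abundances.columns)
    out = {"F": {}, "p": {}}
    for ion, row in abundances.iterrows():
        groups = [
            g.dropna().to_numpy()
            for _, g in row.groupby(labels)
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            logger.warning("ion %s skipped in ANOVA: insufficient replication", ion)
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            out["F"][ion], out["p"][ion] = 0.0, 1.0
            continue
        F, p = stats.f_oneway(*groups)
        out["F"][ion], out["p"][ion] = float(F), float(p)
    res = pd.DataFrame(out)
    if res.empty:
        return pd.DataFrame(columns=["F", "p", "q", "significant"])
    res["q"] = multipletests(res["p"].to_numpy(), method=method)[1]
    res["significant"] = res["q"] <= q_threshold
    return res
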