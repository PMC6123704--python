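"""Growth-rate and GI50 estimation from confluence time series.

Adherent cultures are monitored by time-lapse bright-field imaging; the
fraction of well surface covered (confluence) serves as the growth
readout.  Exponential growth rates come from a log-linear least-squares
fit of ln(confluence) on time, pooling replicate wells.  Dose-dependent
growth inhibition relative to the untreated condition,
inh(d) = 1 - r(d)/r(0), is fitted with a two-parameter Hill curve on log
dose, and the GI50 is the concentration at 50% inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ExponentialGrowthModel",
    "GrowthRateResults",
    "HillDoseResponseModel",
    "DoseResponseResults",
    "fit_growth_rate",
    "inhibition_curve",
    "estimate_gi50",
]


@dataclass
class GrowthRateResults:
    """Exponential growth rate (h^-1) with regression standard error."""

    rate: float
    se: float
    n_points: int
    intercept: float  # ln confluence at t = 0

    def doubling_time(self) -> float:
        return np.log(2) / self.rate


class ExponentialGrowthModel:
    """Log-linear model ln(confluence) = ln(c0) + rate * t.

    Replicate wells are pooled into one regression.  Points with
    non-positive confluence are dropped; points above ``max_confluence``
    (where cell-number extraction and steady-state growth both break down)
    are excluded by default.
    """

    def __init__(
        self,
        times_h,
        confluence,
        *,
        max_confluence: float = 0.80,
    ):
        t = np.asarray(times_h, dtype=float).ravel()
        c = np.asarray(confluence, dtype=float).ravel()
        if t.shape != c.shape:
            raise ValueError("times and confluence must have equal length")
        ok = np.isfinite(c) & (c > 0) & (c <= max_confluence) & np.isfinite(t)
        self.times = t[ok]
        self.confluence = c[ok]

    def fit(self) -> GrowthRateResults:
        if self.times.size < 3:
            raise ValueError(
                f"need >= 3 usable points, got {self.times.size}"
            )
        res = stats.linregress(self.times, np.log(self.confluence))
        return GrowthRateResults(
            rate=float(res.slope),
            se=float(res.stderr),
            n_points=int(self.times.size),
            intercept=float(res.intercept),
        )


def fit_growth_rate(
    times_h, confluence, max_confluence: float = 0.80
) -> GrowthRateResults:
    """Pooled log-linear growth-rate fit (functional wrapper)."""
    return ExponentialGrowthModel(
        times_h, confluence, max_confluence=max_confluence
    ).fit()


def inhibition_curve(rates: dict, rate_untreated: float) -> dict:
    """Growth inhibition per dose: 1 - rate(d)/rate(0).

    Values above 1 (net death) or below 0 (stimulation) are retained.
    """
    if rate_untreated is None or not np.isfinite(rate_untreated):
        raise ValueError("untreated growth rate missing")
    if rate_untreated <= 0:
        raise ValueError("untreated growth rate must be positive")
    return {d: 1.0 - r / rate_untreated for d, r in rates.items()}


@dataclass
class DoseResponseResults:
    """Fitted sigmoidal dose-inhibition curve and the derived GI50."""

    gi50: float
    hill_slope: float
    fit_rsq: float
    doses: np.ndarray
    inhibition: np.ndarray
    extrapolated: bool  # GI50 outside the tested dose range
    low_confidence: bool  # observed inhibition does not span [0.2, 0.8]
    flags: list[str] = field(default_factory=list)

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 + (self.gi50 / d) ** self.hill_slope)

    def plot(self, ax=None):  # pragma: no cover - thin display helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.doses, self.inhibition, "o", label="observed")
        grid = np.geomspace(self.doses.min(), self.doses.max(), 200)
        ax.semilogx(grid, self.predict(grid), "-", label="Hill fit")
        ax.axhline(0.5, ls=":", color="grey")
        ax.axvline(self.gi50, ls=":", color="grey")
        ax.set_xlabel("dose (mM)")
        ax.set_ylabel("growth inhibition")
        ax.legend()
        return ax


class HillDoseResponseModel:
    """Two-parameter Hill curve inh(d) = 1 / (1 + (GI50/d)^h) on log dose.

    Asymptotes are fixed at 0 and 1 (inhibition is defined relative to the
    untreated rate, so inh(0) = 0 by construction); a four-parameter
    logistic with free asymptotes is available via ``four_param=True``.
    Dose 0 defines the untreated rate only and is excluded from the fit.
    """

    def __init__(self, doses, inhibition, *, four_param: bool = False):
        d = np.asarray(doses, dtype=float).ravel()
        y = np.asarray(inhibition, dtype=float).ravel()
        ok = np.isfinite(d) & np.isfinite(y) & (d > 0)
        self.doses = d[ok]
        self.inhibition = y[ok]
        self.four_param = four_param
        if self.doses.size < 4:
            raise ValueError(
                f"need >= 4 non-zero doses, got {self.doses.size}"
            )

    def fit(self) -> DoseResponseResults:
        logd = np.log10(self.doses)
        y = self.inhibition

        def hill2(logd, log_gi50, h):
            return 1.0 / (1.0 + 10 ** (h * (log_gi50 - logd)))

        def hill4(logd, log_gi50, h, bottom, top):
            return bottom + (top - bottom) / (
                1.0 + 10 ** (h * (log_gi50 - logd))
            )

        # start at the dose whose inhibition is closest to one half
        g0 = logd[np.argmin(np.abs(y - 0.5))]
        flags: list[str] = []
        try:
            if self.four_param:
                popt, _ = optimize.curve_fit(
                    hill4, logd, y, p0=[g0, 1.0, 0.0, 1.0],
                    bounds=([logd.min() - 3, 0.05, -0.5, 0.5],
                            [logd.max() + 3, 20.0, 0.5, 1.5]),
                    maxfev=20000,
                )
                pred = hill4(logd, *popt)
            else:
                popt, _ = optimize.curve_fit(
                    hill2, logd, y, p0=[g0, 1.0],
                    bounds=([logd.min() - 3, 0.05], [logd.max() + 3, 20.0]),
                    maxfev=20000,
                )
                pred = hill2(logd, *popt)
        except RuntimeError as err:
            raise RuntimeError(
                f"dose-response fit did not converge: {err}; doses="
                f"{self.doses.tolist()}, inhibition={y.tolist()}"
            ) from err
        gi50 = float(10 ** popt[0])
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        if np.ptp(y) < 0.05 and y.max() < 0.2:
            flags.append("no inhibition")
        extrapolated = not (self.doses.min() <= gi50 <= self.doses.max())
        if extrapolated:
            flags.append("extrapolated")
        low_conf = not (y.min() <= 0.2 and y.max() >= 0.8)
        if low_conf:
            flags.append("inhibition range does not span [0.2, 0.8]")
        return DoseResponseResults(
            gi50=gi50,
            hill_slope=float(popt[1]),
            fit_rsq=rsq,
            doses=self.doses,
            inhibition=y,
            extrapolated=extrapolated,
            low_confidence=low_conf,
            flags=flags,
        )


def estimate_gi50(doses, inhibitions, **kwargs) -> DoseResponseResults:
    """Fit the sigmoidal dose-inhibition curve (functional wrapper)."""
    return HillDoseResponseModel(doses, inhibitions, **kwargs).fit()
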