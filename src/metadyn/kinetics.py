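"""Minimal kinetic model of CoA homeostasis and dichloroacetate toxicity.

Two Michaelis-Menten-type reactions couple coenzyme A biosynthesis to
biomass production.  DCA activates CoA biosynthesis (it inhibits PDK and
thereby de-represses the pathway); hopantenate (HoPan) inhibits the first
biosynthetic step, modeled by dividing the maximal biosynthesis rate by
the HoPan concentration; high CoA is ultrasensitively growth-inhibitory
(cubic term in the utilization kinetics):

    v_CoA     = v_CoA,max / max([HoPan], 1)
                * ( [DCA] / ([DCA] + K_DCA) + 1 )
    v_biomass = v_biomass,max * [CoA]
                / ( [CoA] + K_CoA * (1 + [CoA]^3 / K_i) )

State equations (a declared reconstruction — CoA is consumed directly to
form new biomass with stoichiometry ``coupling``, and biomass grows
autocatalytically at the CoA-utilization rate):

    d[CoA]/dt = v_CoA - coupling * v_biomass
    dB/dt     = v_biomass * B

Default parameters are v_biomass,max = 1, K_CoA = 0.01, K_i = 1,
v_CoA,max = 0.45, [CoA]_0 = 10, [DCA] = 0.01, [HoPan] = 5 (all in the
model's arbitrary concentration/time units).  K_DCA is not part of that
printed set; the default 0.01 equals the reference [DCA], giving a 1.5x
activation of biosynthesis, and is exposed as a parameter.  With these
values the model reproduces three regimes: untreated cultures relax to a
stable fixed point where biosynthesis balances utilization; DCA pushes
biosynthesis beyond the maximal utilization capacity so CoA accumulates
without bound and growth collapses (*runaway*); HoPan transiently lifts
growth above the untreated rate while stored CoA is drawn down, before
biosynthesis becomes limiting (*biphasic*).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "CoAModelParams",
    "CoAKineticModel",
    "CoATrajectory",
    "rate_v_coa",
    "rate_v_biomass",
    "simulate",
    "scenario_suite",
    "vbiomass_argmax",
    "stable_fixed_point",
    "SCENARIOS",
]


@dataclass(frozen=True)
class CoAModelParams:
    """Kinetic parameters; defaults are the reference simulation set."""

    v_coa_max: float = 0.45
    v_biomass_max: float = 1.0
    k_coa: float = 0.01
    k_i: float = 1.0  # concentration^3, per the cubic inhibition term
    k_dca: float = 0.01
    dca: float = 0.0
    hopan: float = 0.0  # 0 = untreated; division applies for hopan >= 1
    coa_0: float = 10.0
    biomass_0: float = 1.0
    t_end: float = 200.0
    coupling: float = 1.0

    def __post_init__(self):
        for name in ("k_coa", "k_i", "k_dca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "v_coa_max", "v_biomass_max", "dca", "hopan",
            "coa_0", "biomass_0", "coupling",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_(self, **kwargs) -> "CoAModelParams":
        return replace(self, **kwargs)


def rate_v_coa(params: CoAModelParams, coa: float = 0.0) -> float:
    """CoA biosynthesis rate; saturated w.r.t. precursors, hence
    independent of the CoA pool.  HoPan divides v_CoA,max, but only for
    concentrations >= 1 (dividing by a fraction would *increase*
    biosynthesis, contradicting an inhibitor; hopan = 0 means untreated)."""
    divisor = params.hopan if params.hopan >= 1.0 else 1.0
    activation = params.dca / (params.dca + params.k_dca) + 1.0
    return params.v_coa_max / divisor * activation


def rate_v_biomass(params: CoAModelParams, coa) -> float | np.ndarray:
    """CoA-utilization (growth) rate with cubic substrate inhibition."""
    c = np.maximum(np.asarray(coa, dtype=float), 0.0)
    v = params.v_biomass_max * c / (
        c + params.k_coa * (1.0 + c**3 / params.k_i)
    )
    return float(v) if np.ndim(coa) == 0 else v


def vbiomass_argmax(params: CoAModelParams) -> tuple[float, float]:
    """CoA level maximizing v_biomass and the maximal rate.

    d/dc [c / (c + K(1 + c^3/Ki))] = 0  =>  c* = (K_i / 2)^(1/3).
    """
    c_star = (params.k_i / 2.0) ** (1.0 / 3.0)
    return c_star, rate_v_biomass(params, c_star)


def stable_fixed_point(params: CoAModelParams) -> float | None:
    """CoA level on the low (stable) branch where biosynthesis balances
    consumption, or None when v_CoA exceeds the maximal utilization
    capacity (no fixed point: runaway)."""
    target = rate_v_coa(params) / max(params.coupling, 1e-300)
    c_star, v_max = vbiomass_argmax(params)
    if target > v_max or target <= 0:
        return None
    lo = 1e-12
    f = lambda c: rate_v_biomass(params, c) - target
    if f(c_star) < 0:
        return None
    return float(brentq(f, lo, c_star, xtol=1e-14, rtol=1e-13))


@dataclass
class CoATrajectory:
    """Simulated time courses of CoA, the growth rate and biomass."""

    times: np.ndarray
    coa: np.ndarray
    v_biomass: np.ndarray
    biomass: np.ndarray
    regime: str  # stable | runaway | biphasic
    params: CoAModelParams = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "coa": self.coa,
                "v_biomass": self.v_biomass,
                "biomass": self.biomass,
            }
        )

    def plot(self, ax=None):  # pragma: no cover - thin display helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.v_biomass, label="v_biomass")
        ax.set_ylabel("growth rate v_biomass")
        ax.set_xlabel("time (a.u.)")
        ax2 = ax.twinx()
        ax2.plot(self.times, self.coa, "--", color="tab:red", label="[CoA]")
        ax2.set_ylabel("[CoA]")
        ax.set_title(f"regime: {self.regime}")
        return ax


class CoAKineticModel:
    """Simulator for the two-reaction CoA homeostasis model."""

    def __init__(self, params: CoAModelParams | None = None):
        self.params = params or CoAModelParams()

    def _rhs(self, t, y):
        coa, biomass = y
        vb = rate_v_biomass(self.params, max(coa, 0.0))
        dcoa = rate_v_coa(self.params) - self.params.coupling * vb
        return [dcoa, vb * biomass]

    def simulate(
        self,
        *,
        n_points: int = 2001,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> CoATrajectory:
        """Integrate the ODE system with an adaptive stiff-capable solver
        (LSODA) and classify the resulting regime.

        Classification: *runaway* when CoA keeps accumulating far beyond
        its start while growth collapses (either the tenfold-increase /
        tenth-of-initial-growth criterion, or failure to converge to the
        biosynthesis-consumption balance with CoA still rising); *biphasic*
        when growth transiently exceeds its initial rate by > 5% but ends
        below 80% of it; *stable* otherwise.  The margins keep the
        untreated reference trajectory — which grazes the v_biomass
        maximum on its way to the fixed point and settles only marginally
        below its initial rate — in the stable class.
        """
        p = self.params
        if p.t_end <= 0:
            raise ValueError("t_end must be positive")
        t_eval = np.linspace(0.0, p.t_end, n_points)
        sol = solve_ivp(
            self._rhs,
            (0.0, p.t_end),
            [p.coa_0, p.biomass_0],
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed: {sol.message} "
                f"(nfev={sol.nfev}, last t={sol.t[-1] if sol.t.size else 0})"
            )
        coa = np.maximum(sol.y[0], 0.0)
        biomass = sol.y[1]
        vb = rate_v_biomass(p, coa)
        regime = self._classify(coa, vb)
        return CoATrajectory(
            times=sol.t, coa=coa, v_biomass=vb,
            biomass=biomass, regime=regime, params=p,
        )

    def _classify(self, coa: np.ndarray, vb: np.ndarray) -> str:
        p = self.params
        vb0, vb_end = vb[0], vb[-1]
        v_in = rate_v_coa(p)
        residual = abs(v_in - p.coupling * vb_end)
        converged = residual < 1e-4 * max(v_in, 1e-12)
        rising = coa[-1] > coa[0] and coa[-1] > coa[-2]
        if (coa[-1] > 10.0 * p.coa_0 and vb_end < 0.1 * vb0) or (
            not converged and rising
        ):
            return "runaway"
        if vb.max() > 1.05 * vb0 and vb_end < 0.8 * vb0:
            return "biphasic"
        return "stable"


def simulate(params: CoAModelParams | None = None, **kwargs) -> CoATrajectory:
    """Simulate one parameterization (functional wrapper)."""
    return CoAKineticModel(params).simulate(**kwargs)


#: Reference scenarios: treatments and exogenous-CoA loads.
SCENARIOS = {
    "untreated": dict(dca=0.0, hopan=0.0),
    "dca": dict(dca=0.01, hopan=0.0),
    "hopan": dict(dca=0.0, hopan=5.0),
    "dca+hopan": dict(dca=0.01, hopan=5.0),
    "coa_10": dict(dca=0.0, hopan=0.0, coa_0=10.0),
    "coa_50": dict(dca=0.0, hopan=0.0, coa_0=50.0),
    "coa_100": dict(dca=0.0, hopan=0.0, coa_0=100.0),
}


def scenario_suite(
    params: CoAModelParams | None = None,
) -> tuple[pd.DataFrame, dict[str, CoATrajectory]]:
    """Simulate the reference scenario set.

    Returns a summary frame (regime, initial and final growth rate, final
    CoA) and the trajectory per scenario.  Exogenous CoA is modeled purely
    as a raised initial pool.
    """
    base = params or CoAModelParams()
    trajectories: dict[str, CoATrajectory] = {}
    rows = []
    for name, overrides in SCENARIOS.items():
        traj = CoAKineticModel(base.with_(**overrides)).simulate()
        trajectories[name] = traj
        rows.append(
            {
                "scenario": name,
                "regime": traj.regime,
                "v_biomass_initial": traj.v_biomass[0],
                "v_biomass_final": traj.v_biomass[-1],
                "v_biomass_peak": traj.v_biomass.max(),
                "coa_final": traj.coa[-1],
            }
        )
    return pd.DataFrame(rows).set_index("scenario"), trajectories
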