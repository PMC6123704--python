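"""Synthetic datasets with the generative structure the pipeline assumes.

Every stage of the analysis has a matching generator here that produces
data from the stage's own forward model plus multiplicative lognormal
noise, together with the ground truth, so estimator recovery can be tested
end-to-end without any external download:

* steady state:  I = (alpha_line * N_c + beta) * exp(eps),
  eps ~ N(0, sigma) with sigma matched to a target coefficient of
  variation; cell numbers follow per-line exponential growth; background
  ions have alpha = 0.
* perturbation:  treated intensity = (alpha * N + beta) * 2^fc_true * noise,
  with user-specified fold-change trajectories on chosen ions and slowed
  growth of treated wells.
* growth:        confluence = c0 * exp(rate * (1 - inh(d)) * t) * noise,
  with Hill-shaped dose inhibition.

Default dimensions mirror a five-cell-line, three-replicate screen sampled
at {0, 24, 48, 72, 96} h with nine-dose GI50 grids.  All randomness flows
from a single integer seed; identical configuration and seed give
byte-identical outputs.  What these fixtures deliberately do not emulate:
ion-specific noise floors, drift/batch structure, correlated metabolites,
in-source fragments and isotope peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem

__all__ = [
    "SyntheticConfig",
    "Effect",
    "CURATED_METABOLITES",
    "generate_metabolite_library",
    "generate_steady_state_dataset",
    "generate_perturbation_dataset",
    "generate_growth_curves",
    "generate_pipeline_bundle",
]


@dataclass(frozen=True)
class Effect:
    """Injected fold-change trajectory for one ion.

    ``cell_lines=None`` applies the effect in every line; ``trajectory``
    maps sampling time (h) to the true log2 fold-change.
    """

    ion: str
    trajectory: dict
    cell_lines: tuple | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    n_cell_lines: int = 5
    n_ions: int = 200
    n_background_ions: int = 0
    replicates: int = 3
    time_points_h: tuple = (0.0, 24.0, 48.0, 72.0, 96.0)
    alpha_range: tuple = (0.5, 50.0)  # log-uniform, intensity per cell
    beta_range: tuple = (500.0, 5000.0)  # shared MS background
    n0_range: tuple = (1500.0, 3000.0)  # seeded cells per well
    growth_rate_range: tuple = (0.015, 0.028)  # h^-1
    well_capacity: float = 40000.0  # cells at 100% confluence
    well_jitter_cv: float = 0.05  # seeding variability across wells
    noise_cv: float = 0.15  # multiplicative intensity noise
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for name in ("alpha_range", "beta_range", "n0_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    @property
    def cell_lines(self) -> list[str]:
        return [f"line{j + 1}" for j in range(self.n_cell_lines)]


def _sigma_ln(cv: float) -> float:
    # lognormal sigma giving multiplicative noise with the requested CV
    return float(np.sqrt(np.log1p(cv**2)))


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, _sigma_ln(cv), size=shape))


# --------------------------------------------------------------------------
# metabolite library

#: (id, name, formula, is_keto_acid) of a curated mini-library with correct
#: sum formulas; alpha-keto acids are flagged for derivatization.
CURATED_METABOLITES: tuple = (
    ("water", "water", "H2O", False),
    ("pyruvate", "pyruvic acid", "C3H4O3", True),
    ("lactate", "lactic acid", "C3H6O3", False),
    ("pantothenate", "pantothenic acid", "C9H17NO5", False),
    ("coa", "coenzyme A", "C21H36N7O16P3S", False),
    ("atp", "adenosine triphosphate", "C10H16N5O13P3", False),
    ("s7p", "sedoheptulose 7-phosphate", "C7H15O10P", False),
    ("sorbitol", "sorbitol", "C6H14O6", False),
    ("nacetylaspartate", "N-acetylaspartic acid", "C6H9NO5", False),
    ("oxamate", "oxamic acid", "C2H3NO3", False),
    ("akg", "2-oxoglutaric acid", "C5H6O5", True),
    ("oaa", "oxaloacetic acid", "C4H4O5", True),
    ("citrate", "citric acid", "C6H8O7", False),
    ("glutamate", "glutamic acid", "C5H9NO4", False),
    ("glucose", "glucose", "C6H12O6", False),
    ("fumarate", "fumaric acid", "C4H4O4", False),
    ("malate", "malic acid", "C4H6O5", False),
    ("succinate", "succinic acid", "C4H6O4", False),
    ("hot", "3-amino-1-propanesulfonic acid", "C3H9NO3S", False),
)


def generate_metabolite_library(n_random: int = 0, seed: int = 0) -> pd.DataFrame:
    """Curated mini-library plus ``n_random`` random pseudo-formulas.

    Columns: id, name, formula, is_keto_acid, source.  Pseudo-formulas
    always carry at least H2/O1 so every entry could in principle be
    derivatized.
    """
    rng = np.random.default_rng(seed)
    rows = [
        {
            "id": mid,
            "name": name,
            "formula": formula,
            "is_keto_acid": keto,
            "source": "curated",
        }
        for mid, name, formula, keto in CURATED_METABOLITES
    ]
    for k in range(n_random):
        c = int(rng.integers(4, 26))
        counts = {
            "C": c,
            "H": int(rng.integers(max(2, c // 2), 2 * c + 3)),
            "N": int(rng.integers(0, 5)),
            "O": int(rng.integers(1, 11)),
            "P": int(rng.integers(0, 3)),
            "S": int(rng.integers(0, 2)),
        }
        formula = chem.canonical_string(chem.SumFormula.from_dict(counts))
        rows.append(
            {
                "id": f"pseudo{k:03d}",
                "name": f"pseudo metabolite {k}",
                "formula": formula,
                "is_keto_acid": False,
                "source": "random",
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# steady state

def _cell_numbers(cfg: SyntheticConfig, rng: np.random.Generator):
    """Per-line exponential growth parameters and per-well cell numbers."""
    lines = cfg.cell_lines
    n0 = rng.uniform(*cfg.n0_range, size=len(lines))
    rates = rng.uniform(*cfg.growth_rate_range, size=len(lines))
    rows = []
    for j, line in enumerate(lines):
        for t in cfg.time_points_h:
            for r in range(1, cfg.replicates + 1):
                jitter = float(_noise(rng, cfg.well_jitter_cv, ()))
                N = n0[j] * np.exp(rates[j] * t) * jitter
                rows.append(
                    {
                        "sample_id": f"ss_{line}_t{int(t):03d}_r{r}",
                        "cell_line": line,
                        "replicate": r,
                        "time_h": float(t),
                        "treatment": "none",
                        "cell_number": N,
                        "confluence": min(N / cfg.well_capacity, 1.0),
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta, dict(zip(lines, rates)), dict(zip(lines, n0))


def generate_steady_state_dataset(
    cfg: SyntheticConfig, alpha_override: dict | None = None
):
    """Unperturbed dataset from I = (alpha*N + beta) * noise.

    Returns ``(intensities, meta, truth)`` where ``truth`` holds the true
    ``alpha`` frame (ions x lines, zero rows for background ions), the
    ``beta`` series and the per-line growth parameters.  The first
    ``n_background_ions`` ions (ids ``bg###``) are pure background.
    ``alpha_override`` maps ion ids to a fixed per-cell abundance used in
    every line (e.g. to plant well-detected ions).
    """
    rng = np.random.default_rng(cfg.seed)
    meta, rates, n0 = _cell_numbers(cfg, rng)
    lines = cfg.cell_lines
    n_sig = cfg.n_ions
    ions = [f"bg{k:03d}" for k in range(cfg.n_background_ions)] + [
        f"ion{k:04d}" for k in range(n_sig)
    ]
    lo, hi = np.log(cfg.alpha_range[0]), np.log(cfg.alpha_range[1])
    alpha = np.exp(rng.uniform(lo, hi, size=(len(ions), len(lines))))
    alpha[: cfg.n_background_ions, :] = 0.0
    for ion, val in (alpha_override or {}).items():
        alpha[ions.index(ion), :] = val
    beta = rng.uniform(*cfg.beta_range, size=len(ions))
    N = meta["cell_number"].to_numpy(float)
    codes = pd.Categorical(meta["cell_line"], categories=lines).codes
    expected = alpha[:, codes] * N[None, :] + beta[:, None]
    I = expected * _noise(rng, cfg.noise_cv, expected.shape)
    intensities = pd.DataFrame(I, index=ions, columns=meta.index)
    truth = {
        "alpha": pd.DataFrame(alpha, index=ions, columns=lines),
        "beta": pd.Series(beta, index=ions),
        "growth_rates": rates,
        "n0": n0,
    }
    return intensities, meta, truth


# --------------------------------------------------------------------------
# perturbation

def generate_perturbation_dataset(
    cfg: SyntheticConfig,
    truth: dict,
    effects: list[Effect],
    *,
    treatment: str = "DCA",
    growth_inhibition: float = 0.5,
    time_points_h: tuple | None = None,
    seed_offset: int = 1,
):
    """Treated dataset: I = (alpha*N + beta) * 2^fc_true * noise.

    Treated wells grow at rate * (1 - growth_inhibition) — the dosing
    emulates a GI50-level exposure.  Returns ``(intensities, meta,
    fc_true)`` with ``fc_true`` a tidy (ion, cell_line, time_h) frame of
    injected log2 fold-changes (0 for untouched ions).

    Effects on background ions (alpha = 0) are rejected: their baseline is
    cell-free and a per-cell fold-change is undefined.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    alpha: pd.DataFrame = truth["alpha"]
    beta: pd.Series = truth["beta"]
    rates: dict = truth["growth_rates"]
    n0: dict = truth["n0"]
    lines = list(alpha.columns)
    times = tuple(t for t in (time_points_h or cfg.time_points_h) if t > 0)

    for eff in effects:
        if eff.ion not in alpha.index:
            raise ValueError(f"effect on unknown ion {eff.ion!r}")
        if (alpha.loc[eff.ion] == 0).all():
            raise ValueError(
                f"effect on background ion {eff.ion!r}: baseline undefined"
            )

    rows = []
    for line in lines:
        rate = rates[line] * (1.0 - growth_inhibition)
        for t in times:
            for r in range(1, cfg.replicates + 1):
                jitter = float(_noise(rng, cfg.well_jitter_cv, ()))
                N = n0[line] * np.exp(rate * t) * jitter
                rows.append(
                    {
                        "sample_id": f"{treatment.lower()}_{line}_t{int(t):03d}_r{r}",
                        "cell_line": line,
                        "replicate": r,
                        "time_h": float(t),
                        "treatment": treatment,
                        "cell_number": N,
                        "confluence": min(N / cfg.well_capacity, 1.0),
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")

    ions = alpha.index
    fc = np.zeros((len(ions), len(lines), len(times)))
    ion_pos = {ion: i for i, ion in enumerate(ions)}
    line_pos = {ln: j for j, ln in enumerate(lines)}
    time_pos = {t: k for k, t in enumerate(times)}
    for eff in effects:
        targets = lines if eff.cell_lines is None else list(eff.cell_lines)
        for ln in targets:
            for t, val in eff.trajectory.items():
                if float(t) in time_pos:
                    fc[ion_pos[eff.ion], line_pos[ln], time_pos[float(t)]] = val

    N = meta["cell_number"].to_numpy(float)
    codes_line = pd.Categorical(meta["cell_line"], categories=lines).codes
    codes_time = pd.Categorical(meta["time_h"], categories=list(times)).codes
    A = alpha.to_numpy()
    expected = A[:, codes_line] * N[None, :] + beta.to_numpy()[:, None]
    expected = expected * 2.0 ** fc[:, codes_line, codes_time]
    I = expected * _noise(rng, cfg.noise_cv, expected.shape)
    intensities = pd.DataFrame(I, index=ions, columns=meta.index)

    fc_true = pd.DataFrame(
        [
            {
                "ion": ion,
                "cell_line": ln,
                "time_h": t,
                "fc_true": fc[ion_pos[ion], line_pos[ln], time_pos[t]],
            }
            for ion in ions
            for ln in lines
            for t in times
        ]
    )
    return intensities, meta, fc_true


# --------------------------------------------------------------------------
# growth / dose response

def generate_growth_curves(
    doses=(0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 27.0, 40.0, 60.0),
    *,
    gi50: float = 12.0,
    hill: float = 2.0,
    rate: float = 0.03,
    c0: float = 0.05,
    time_points_h: tuple = (0.0, 24.0, 48.0, 72.0),
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Confluence time series over a dose grid with Hill-shaped inhibition.

    confluence(t) = c0 * exp(rate * (1 - inh(d)) * t) * noise, truncated at
    full confluence; inh(d) = 1 / (1 + (gi50/d)^hill), inh(0) = 0.  The
    default grid is nine non-zero doses plus the untreated condition.
    Returns tidy columns ``time_h, dose, replicate, confluence``.
    """
    if gi50 <= 0:
        raise ValueError("gi50 must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        inh = 0.0 if d == 0 else 1.0 / (1.0 + (gi50 / d) ** hill)
        for r in range(1, replicates + 1):
            for t in time_points_h:
                c = c0 * np.exp(rate * (1.0 - inh) * t)
                c *= float(_noise(rng, noise_cv, ()))
                rows.append(
                    {
                        "time_h": float(t),
                        "dose": float(d),
                        "replicate": r,
                        "confluence": min(c, 1.0),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full pipeline bundle

def generate_pipeline_bundle(seed: int = 0, *, n_random_metabolites: int = 40,
                             n_background_ions: int = 5) -> dict:
    """Self-consistent input bundle for the end-to-end pipeline.

    Builds a metabolite library, an ion matrix keyed by measured m/z
    (expected [M-H]- mass plus a small mass error), baseline and
    DCA-treated samples with injected CoA-pathway fold-changes, pathway
    sets in GMT form, and dose-response confluence curves.  Ground truth
    is included under ``"truth"``.
    """
    rng = np.random.default_rng(seed)
    library = generate_metabolite_library(n_random_metabolites, seed=seed)
    library = library[library["id"] != "water"].reset_index(drop=True)
    cfg = SyntheticConfig(
        n_cell_lines=5,
        n_ions=len(library),
        n_background_ions=n_background_ions,
        seed=seed,
    )
    # the signature metabolites are well-detected ions in every line, as
    # the strong responders in a real screen are
    idx_of = {m: k for k, m in enumerate(library["id"])}
    strong = {
        f"ion{idx_of['pantothenate']:04d}": 30.0,
        f"ion{idx_of['coa']:04d}": 12.0,
        f"ion{idx_of['pyruvate']:04d}": 25.0,
        f"ion{idx_of['sorbitol']:04d}": 18.0,
    }
    intensities, meta, truth = generate_steady_state_dataset(
        cfg, alpha_override=strong
    )

    # rename signal ions to measured m/z of each library metabolite
    records = [
        chem.MetaboliteRecord(
            id=row.id,
            name=row["name"],
            formula=chem.parse_formula(row.formula),
            is_keto_acid=bool(row.is_keto_acid),
            source=row.source,
        )
        for _, row in library.iterrows()
    ]
    mz_measured = [
        round(chem.deprotonated_mz(rec.neutral_mass)
              + float(rng.normal(0.0, 0.0005)), 5)
        for rec in records
    ]
    signal_ids = [i for i in intensities.index if not i.startswith("bg")]
    # background ions sit at m/z values matching nothing in the library
    bg_mz = [round(1000.0 + 7.0 * k + float(rng.uniform(0.1, 0.9)), 5)
             for k in range(n_background_ions)]
    mapping = dict(zip(signal_ids, mz_measured))
    mapping.update(
        {i: bg_mz[k] for k, i in enumerate(intensities.index[:n_background_ions])}
    )
    ion_to_metabolite = dict(zip(mz_measured, library["id"]))

    intensities = intensities.rename(index=mapping)
    truth["alpha"] = truth["alpha"].rename(index=mapping)
    truth["beta"] = truth["beta"].rename(index=mapping)

    # DCA-like fingerprint: pantothenate depleted in every line, CoA and
    # pyruvate responding, one line-specific effect for the variable branch
    mz_of = {m: mz for mz, m in ion_to_metabolite.items()}
    effects = [
        Effect(mz_of["pantothenate"], {24.0: -1.0, 48.0: -2.0, 72.0: -2.0, 96.0: -2.0}),
        Effect(mz_of["coa"], {24.0: 0.5, 48.0: 1.0, 72.0: 1.5, 96.0: 1.5}),
        Effect(mz_of["pyruvate"], {24.0: -1.0, 48.0: -1.5, 72.0: -1.5, 96.0: -1.5}),
        Effect(mz_of["sorbitol"], {48.0: 4.0, 96.0: 4.0}, cell_lines=("line1",)),
    ]
    treated, meta_trt, fc_true = generate_perturbation_dataset(
        cfg.with_(n_ions=len(library)), truth, effects, treatment="DCA"
    )
    matrix = pd.concat([intensities, treated], axis=1)
    all_meta = pd.concat([meta, meta_trt])

    pathways = {
        "map_coa": ("CoA biosynthesis", ["pantothenate", "coa"]),
        "map_glyco": ("Glycolysis", ["pyruvate", "lactate", "glucose"]),
        "map_tca": ("TCA cycle", ["citrate", "succinate", "fumarate", "malate", "akg", "oaa"]),
    }
    pseudo = [m for m in library["id"] if m.startswith("pseudo")]
    for k in range(4):
        chunk = pseudo[k * 10: (k + 1) * 10]
        if chunk:
            pathways[f"map_rand{k}"] = (f"Random set {k}", chunk)

    confluence = generate_growth_curves(seed=seed, noise_cv=0.05)
    return {
        "metabolites": library,
        "matrix": matrix,
        "meta": all_meta,
        "pathways": pathways,
        "confluence": confluence,
        "truth": {**truth, "fc_true": fc_true, "effects": effects,
                  "ion_to_metabolite": ion_to_metabolite},
    }
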