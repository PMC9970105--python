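"""Synthetic inputs with known ground truth.

Every pipeline stage is testable without field data: this module emulates

* burned-plot tree records — Bernoulli mortality from a known logit-linear
  model with plot-level random intercepts, plot-level severity;
* contemporary 1-ha stand tree lists — overstocked relative to their paired
  historical reference (defaults: 4.7x density, 2.3x basal area);
* historical reference summaries — mean +/- SD basal area, density, and
  basal-area composition per national forest x forest type;
* a spatially autocorrelated severity raster with vegetation-type patches;
* independent validation records simulated under the generating model.

Default generating coefficients are configuration, chosen so the qualitative
ecology holds: all species die more at higher severity, fire-tolerant species
(yellow pine, western larch, Douglas-fir) gain strong protection from size,
lodgepole pine gains almost none, and moderate severities thin overstocked
stands toward historical structure while sparing large trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from pyrocast.glmm import MortalityModel
from pyrocast.standsim import (
    COMPOSITION_GROUPS,
    FOREST_TYPES,
    StandInventory,
    simulate_stand,
)
from pyrocast.assessment import HistoricalReference

__all__ = [
    "SpeciesTruth",
    "StandTemplate",
    "SyntheticTruth",
    "default_truth",
    "truth_models",
    "gen_burned_plots",
    "gen_stand_set",
    "gen_historical_refs",
    "gen_landscape",
    "gen_validation_set",
]

SPECIES_GROUPS = (
    "yellow_pine",
    "douglas_fir",
    "white_fir",
    "western_larch",
    "lodgepole_pine",
    "other_conifer",
    "hardwood",
)

FORESTS = ("Malheur", "Fremont-Winema", "Deschutes", "Ochoco")


@dataclass(frozen=True)
class SpeciesTruth:
    """Generating logit-scale coefficients for one species group."""

    intercept: float
    dbh: float  # per cm
    severity: float  # per RdNBR unit
    years: float  # per year post-fire
    dbh_severity: float | None = None  # optional interaction
    re_sd: float = 0.5  # plot random-intercept SD

    def __post_init__(self) -> None:
        if self.re_sd < 0:
            raise ValueError("random-intercept SD must be >= 0")

    @property
    def coefficients(self) -> np.ndarray:
        coef = [self.intercept, self.dbh, self.severity, self.years]
        if self.dbh_severity is not None:
            coef.append(self.dbh_severity)
        return np.array(coef)

    def linear_predictor(self, dbh, severity, years):
        eta = self.intercept + self.dbh * dbh + self.severity * severity + self.years * years
        if self.dbh_severity is not None:
            eta = eta + self.dbh_severity * dbh * severity
        return eta


@dataclass(frozen=True)
class StandTemplate:
    """Contemporary-stand generator for one forest type.

    ``density_mult`` / ``ba_mult`` scale the paired historical reference; the
    departure of contemporary from historical stands is the point of the
    template (defaults 4.7x density, 2.3x basal area).
    """

    mix: dict  # species_group -> proportion of stems
    dbh_lognorm_mu: float = math.log(26.0)
    dbh_lognorm_sigma: float = 0.5
    density_mult: float = 4.7
    ba_mult: float = 2.3
    stand_cv: float = 0.12  # between-stand lognormal CV of both targets

    def __post_init__(self) -> None:
        total = sum(self.mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"species mix must sum to 1, got {total}")
        if all(v == 0 for v in self.mix.values()):
            raise ValueError("degenerate template: all mix weight zero")
        if self.density_mult <= 0 or self.ba_mult <= 0:
            raise ValueError("density and basal-area multipliers must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generating configuration: species coefficients plus stand templates."""

    species: dict  # species_group -> SpeciesTruth
    templates: dict  # forest_type -> StandTemplate
    plot_mix: dict  # species mix of burned-plot records

    def __post_init__(self) -> None:
        if not any(v > 0 for v in self.plot_mix.values()):
            raise ValueError("degenerate plot species mix: all weight zero")


def default_truth(re_sd: float = 0.5) -> SyntheticTruth:
    """The default study conditions used throughout the analysis scripts."""
    species = {
        "yellow_pine": SpeciesTruth(-3.0, -0.055, 0.0090, 0.20, re_sd=re_sd),
        "douglas_fir": SpeciesTruth(-2.9, -0.045, 0.0085, 0.25, re_sd=re_sd),
        "white_fir": SpeciesTruth(-2.6, -0.040, 0.0085, 0.12, re_sd=re_sd),
        "western_larch": SpeciesTruth(-3.4, -0.070, 0.0085, 0.10, re_sd=re_sd),
        "lodgepole_pine": SpeciesTruth(-2.2, -0.004, 0.0075, 0.18, re_sd=re_sd),
        "other_conifer": SpeciesTruth(-2.5, -0.025, 0.0075, 0.15, re_sd=re_sd),
        "hardwood": SpeciesTruth(-2.0, -0.050, 0.0060, 0.25, re_sd=re_sd),
    }
    templates = {
        "dry-mixed-conifer": StandTemplate(
            mix={
                "yellow_pine": 0.33,
                "douglas_fir": 0.25,
                "white_fir": 0.30,
                "western_larch": 0.03,
                "lodgepole_pine": 0.03,
                "other_conifer": 0.06,
            }
        ),
        "ponderosa-pine": StandTemplate(
            mix={
                "yellow_pine": 0.78,
                "douglas_fir": 0.08,
                "white_fir": 0.04,
                "western_larch": 0.01,
                "lodgepole_pine": 0.04,
                "other_conifer": 0.05,
            },
            density_mult=4.6,
            ba_mult=2.3,
        ),
    }
    plot_mix = {
        "yellow_pine": 0.20,
        "douglas_fir": 0.25,
        "white_fir": 0.20,
        "western_larch": 0.03,
        "lodgepole_pine": 0.12,
        "other_conifer": 0.12,
        "hardwood": 0.08,
    }
    return SyntheticTruth(species=species, templates=templates, plot_mix=plot_mix)


def single_species_truth(
    group: str = "douglas_fir",
    *,
    intercept: float = -2.9,
    dbh: float = -0.045,
    severity: float = 0.0085,
    years: float = 0.25,
    dbh_severity: float | None = None,
    re_sd: float = 0.5,
) -> SyntheticTruth:
    """Truth with all burned-plot mix weight on one group (parameter-recovery runs)."""
    base = default_truth(re_sd=re_sd)
    species = dict(base.species)
    species[group] = SpeciesTruth(intercept, dbh, severity, years, dbh_severity, re_sd)
    plot_mix = {g: (1.0 if g == group else 0.0) for g in SPECIES_GROUPS}
    return SyntheticTruth(species=species, templates=base.templates, plot_mix=plot_mix)


# representative coefficient standard errors used when truth stands in for a fit
_TRUTH_SE = {
    "intercept": 0.30,
    "dbh": 0.006,
    "severity": 0.0006,
    "years": 0.04,
    "dbh_severity": 1.5e-5,
}


def truth_models(truth: SyntheticTruth, se_scale: float = 1.0) -> dict:
    """Wrap generating coefficients as MortalityModel objects.

    ``se_scale`` scales the representative standard errors; 0 gives
    deterministic point-estimate models (useful in oracles).
    """
    models = {}
    for group, sp in truth.species.items():
        has_int = sp.dbh_severity is not None
        terms = ["intercept", "dbh", "severity", "years"] + (
            ["dbh_severity"] if has_int else []
        )
        se = np.array([_TRUTH_SE[t] * se_scale for t in terms])
        models[group] = MortalityModel(
            species_group=group,
            has_interaction=has_int,
            coefficients=sp.coefficients,
            std_errors=np.maximum(se, 1e-300),
            random_intercept_sd=sp.re_sd,
            n_trees=0,
            n_plots=0,
            log_likelihood=np.nan,
            dbh_max=250.0,
        )
    return models


def _truncated_lognormal(rng, mu, sigma, lo, size):
    """Lognormal draws left-truncated at ``lo`` by rejection (vectorized)."""
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.lognormal(mu, sigma, size=2 * (size - n) + 16)
        draw = draw[draw >= lo]
        take = min(draw.size, size - n)
        out[n : n + take] = draw[:take]
        n += take
    return out


def gen_burned_plots(
    truth: SyntheticTruth,
    n_plots: int,
    trees_per_plot: int,
    severity_range: tuple[float, float] = (-52.0, 1340.0),
    years_range: tuple[int, int] = (0, 13),
    seed: int = 0,
) -> pd.DataFrame:
    """Burned-plot tree records with known per-tree mortality probabilities.

    One severity value, one survey time, and one standard-normal plot effect
    per plot (scaled by each species' random-intercept SD).  Returns a table
    with the documented tree-record columns plus ``true_p``, the generating
    probability of each tree's death.
    """
    if n_plots < 2:
        raise ValueError("n_plots must be >= 2")
    lo, hi = severity_range
    if lo < -500 or hi > 2000 or lo > hi:
        raise ValueError("severity_range must lie within [-500, 2000]")
    groups = [g for g, wgt in truth.plot_mix.items() if wgt > 0]
    weights = np.array([truth.plot_mix[g] for g in groups])
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    plot_sev = rng.uniform(lo, hi, size=n_plots)
    plot_years = rng.integers(years_range[0], years_range[1] + 1, size=n_plots)
    plot_z = rng.standard_normal(n_plots)  # unit plot effect, scaled per species

    n = n_plots * trees_per_plot
    plot = np.repeat(np.arange(n_plots), trees_per_plot)
    sp_idx = rng.choice(len(groups), size=n, p=weights)
    dbh = np.minimum(_truncated_lognormal(rng, math.log(20.0), 0.55, 7.0, n), 290.0)

    sev = plot_sev[plot]
    yrs = plot_years[plot].astype(float)
    eta = np.empty(n)
    re_sd = np.empty(n)
    for i, g in enumerate(groups):
        sel = sp_idx == i
        sp = truth.species[g]
        eta[sel] = sp.linear_predictor(dbh[sel], sev[sel], yrs[sel])
        re_sd[sel] = sp.re_sd
    p = expit(eta + re_sd * plot_z[plot])
    dead = rng.uniform(size=n) < p

    return pd.DataFrame(
        {
            "plot_id": np.char.add("plot_", np.char.zfill(plot.astype(str), 4)),
            "species_group": np.array(groups, dtype=object)[sp_idx],
            "dbh_cm": dbh,
            "rdnbr": sev,
            "years_post_fire": plot_years[plot],
            "status": np.where(dead, "dead", "live"),
            "true_p": p,
        }
    )


_FOREST_FACTOR = {"Malheur": 1.00, "Fremont-Winema": 0.95, "Deschutes": 1.05, "Ochoco": 1.10}

_HIST_BASE = {
    # forest_type -> (ba_mean m2/ha, ba_sd, tph_mean, tph_sd)
    "dry-mixed-conifer": (16.0, 5.0, 80.0, 25.0),
    "ponderosa-pine": (12.0, 4.0, 65.0, 20.0),
}

_HIST_COMP = {
    "dry-mixed-conifer": {
        "yellow_pine": 0.60,
        "douglas_fir": 0.18,
        "white_fir": 0.12,
        "western_larch": 0.05,
        "other": 0.05,
    },
    "ponderosa-pine": {
        "yellow_pine": 0.85,
        "douglas_fir": 0.06,
        "white_fir": 0.03,
        "western_larch": 0.02,
        "other": 0.04,
    },
}


def gen_historical_refs(preset: str = "default") -> list[HistoricalReference]:
    """Historical reference summaries (mean +/- SD structure, BA composition).

    Presets: ``default`` (forest-specific scaling), ``uniform`` (identical
    references for every forest), ``dmc-vs-pp`` (alias of default; ponderosa
    pine references are more yellow-pine dominated than dry mixed conifer).
    """
    if preset not in ("default", "uniform", "dmc-vs-pp"):
        raise ValueError(f"unknown historical-reference preset {preset!r}")
    refs = []
    for forest in FORESTS:
        factor = 1.0 if preset == "uniform" else _FOREST_FACTOR[forest]
        for ftype in FOREST_TYPES:
            ba_m, ba_s, tph_m, tph_s = _HIST_BASE[ftype]
            refs.append(
                HistoricalReference(
                    forest=forest,
                    forest_type=ftype,
                    ba_mean=ba_m * factor,
                    ba_sd=ba_s * factor,
                    tph_mean=tph_m * factor,
                    tph_sd=tph_s * factor,
                    composition=dict(_HIST_COMP[ftype]),
                )
            )
    return refs


def gen_stand_set(
    truth: SyntheticTruth,
    forests: list[str],
    types: list[str],
    n_stands: int,
    seed: int = 0,
    refs: list[HistoricalReference] | None = None,
    records_per_stand: int = 110,
) -> list[StandInventory]:
    """Contemporary overstocked 1-ha stand tree lists.

    Each stand targets density = historical mean x ``density_mult`` and basal
    area = historical mean x ``ba_mult`` (lognormal between-stand noise with CV
    ``stand_cv``); per-record expansion factors are uniform within a stand so
    the density target is met exactly, and diameters are rescaled so basal
    area matches before re-flooring at the 15 cm threshold.
    """
    if n_stands < 1:
        raise ValueError("n_stands must be >= 1")
    if refs is None:
        refs = gen_historical_refs("default")
    ref_map = {(r.forest, r.forest_type): r for r in refs}
    rng = np.random.default_rng(seed)
    stands = []
    for forest in forests:
        for ftype in types:
            if ftype not in truth.templates:
                raise ValueError(f"unknown forest-type label {ftype!r}")
            if (forest, ftype) not in ref_map:
                raise ValueError(f"unknown forest label {forest!r} (no reference)")
            tpl = truth.templates[ftype]
            ref = ref_map[(forest, ftype)]
            groups = [g for g, wgt in tpl.mix.items() if wgt > 0]
            weights = np.array([tpl.mix[g] for g in groups])
            weights = weights / weights.sum()
            for j in range(n_stands):
                noise = rng.lognormal(-0.5 * tpl.stand_cv**2, tpl.stand_cv, size=2)
                tph_target = ref.tph_mean * tpl.density_mult * noise[0]
                ba_target = ref.ba_mean * tpl.ba_mult * noise[1]
                m = max(20, int(rng.poisson(records_per_stand)))
                ef = tph_target / m
                dbh = _truncated_lognormal(rng, tpl.dbh_lognorm_mu, tpl.dbh_lognorm_sigma, 15.0, m)
                ba_now = ef * np.sum(np.pi * (dbh / 200.0) ** 2)
                dbh = np.maximum(dbh * math.sqrt(ba_target / ba_now), 15.0)
                sp = np.array(groups, dtype=object)[rng.choice(len(groups), size=m, p=weights)]
                trees = pd.DataFrame(
                    {
                        "species_group": sp,
                        "dbh_cm": dbh,
                        "expansion_factor": np.full(m, ef),
                    }
                )
                stands.append(
                    StandInventory(
                        stand_id=f"{forest[:3].lower()}-{ftype[:3]}-{j:03d}",
                        forest=forest,
                        forest_type=ftype,
                        trees=trees,
                    )
                )
    return stands


def gen_landscape(
    rows: int,
    cols: int,
    autocorrelation_scale: float = 6.0,
    pvt_patch_scale: float = 10.0,
    seed: int = 0,
    severity_mean: float = 450.0,
    severity_sd: float = 280.0,
    type_weights: tuple[float, float, float] = (0.45, 0.35, 0.20),
):
    """Spatially autocorrelated severity raster with vegetation-type patches.

    Severity is Gaussian white noise smoothed at ``autocorrelation_scale``
    pixels and rescaled to the target mean/SD.  Vegetation type is the argmax
    of three smoothed noise fields (dry mixed conifer, ponderosa pine, other)
    biased by ``type_weights``; "other" pixels are masked downstream.
    """
    from pyrocast.landscape import SeverityLandscape, VEG_CODES

    if rows < 8 or cols < 8:
        raise ValueError("rows and cols must be >= 8")
    if autocorrelation_scale <= 0 or pvt_patch_scale <= 0:
        raise ValueError("scales must be positive")
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.standard_normal((rows, cols)), autocorrelation_scale, mode="wrap")
    raw = (raw - raw.mean()) / max(raw.std(), 1e-12)
    severity = severity_mean + severity_sd * raw

    fields = gaussian_filter(
        rng.standard_normal((3, rows, cols)), (0, pvt_patch_scale, pvt_patch_scale), mode="wrap"
    )
    fields = fields / np.maximum(fields.std(axis=(1, 2), keepdims=True), 1e-12)
    bias = np.array(type_weights)
    bias = np.log(np.maximum(bias, 1e-12) / bias.sum())[:, None, None]
    vegtype = np.argmax(fields + 0.6 * bias, axis=0).astype(np.uint8)
    vegtype = np.vectorize({0: VEG_CODES["dry-mixed-conifer"],
                            1: VEG_CODES["ponderosa-pine"],
                            2: VEG_CODES["other"]}.get)(vegtype).astype(np.uint8)
    return SeverityLandscape(severity=severity, vegtype=vegtype, pixel_size=30.0)


def gen_validation_set(
    truth: SyntheticTruth,
    stands: list[StandInventory],
    n: int,
    seed: int = 0,
    *,
    models: dict | None = None,
    years: float = 3.0,
    severity: float | None = None,
    severity_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Independent validation plots: one simulated post-fire outcome each.

    Each record draws a stand and a severity and simulates a single post-fire
    outcome.  With ``models`` given (e.g. the fitted models), the outcome is a
    draw from the predictive distribution itself; otherwise it is simulated
    under the generating truth with a fresh plot random intercept.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not stands:
        raise ValueError("empty stand collection")
    rng = np.random.default_rng(seed)
    if severity_grid is None:
        severity_grid = np.arange(-50.0, 1000.0 + 2.5, 5.0)
    use_models = models if models is not None else truth_models(truth, se_scale=0.0)
    records = []
    for _ in range(n):
        stand = stands[rng.integers(len(stands))]
        sev = float(severity) if severity is not None else float(rng.choice(severity_grid))
        if models is None:
            out = _simulate_truth_outcome(truth, stand, sev, years, rng)
        else:
            out = simulate_stand(stand, use_models, sev, rng, years=years)
        records.append(
            {
                "severity": sev,
                "forest": stand.forest,
                "forest_type": stand.forest_type,
                "stand_id": stand.stand_id,
                "ba_obs": out.ba_live,
                "tph_obs": out.tph_live,
                "ba_pre": stand.ba_total,
                "tph_pre": stand.tph_total,
            }
        )
    return pd.DataFrame(records)


def _simulate_truth_outcome(truth, stand, sev, years, rng):
    """One post-fire outcome under the generating model (plot effect drawn)."""
    from pyrocast.standsim import _aggregate_outcome

    trees = stand.trees
    dbh = trees["dbh_cm"].to_numpy(dtype=float)
    eta = np.empty(len(trees))
    z = rng.standard_normal()
    for g in trees["species_group"].unique():
        sel = (trees["species_group"] == g).to_numpy()
        sp = truth.species[g]
        eta[sel] = sp.linear_predictor(dbh[sel], sev, years) + sp.re_sd * z
    dead = rng.uniform(size=len(trees)) < expit(eta)
    return _aggregate_outcome(stand, sev, 0, dead)
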