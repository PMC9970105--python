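"""Stand-level post-fire structure simulation.

Contemporary stand tree lists are standardized to 1-ha conifer lists (trees
>= 15 cm DBH), then burned in silico: each tree's mortality probability comes
from a Monte Carlo coefficient draw of its species model evaluated at the
stand's severity three years post-fire, and the tree dies when a uniform(0,1)
deviate falls below that probability.  A sweep across the severity gradient
(-50..1000 RdNBR by 5, five iterations by default) yields the distribution of
post-fire basal area, density, and composition per stand.

Expansion factors are carried as fractional per-hectare tree weights; a
Bernoulli draw applies to each inventory record once and its whole weight
lives or dies, keeping live + dead totals exactly equal to pre-fire totals.
Dead basal area is reported as the complement of live within the pre-fire
total, so conservation is exact in floating point as well as in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.nonparametric.smoothers_lowess import lowess

from pyrocast.glmm import MortalityModel

__all__ = [
    "FOREST_TYPES",
    "COMPOSITION_GROUPS",
    "StandInventory",
    "StandOutcome",
    "pool_species",
    "is_hardwood",
    "standardize_stand",
    "simulate_stand",
    "severity_sweep",
    "composition_profile",
    "default_stand_grid",
]

FOREST_TYPES = ("dry-mixed-conifer", "ponderosa-pine")

#: basal-area composition groups reported at the stand level
COMPOSITION_GROUPS = ("yellow_pine", "douglas_fir", "white_fir", "western_larch", "other")

# species pooling: field codes / common names -> modelling group.
# Ponderosa and Jeffrey pine pool to yellow pine; grand fir pools to white fir.
_CONIFER_POOL = {
    "ponderosa pine": "yellow_pine",
    "jeffrey pine": "yellow_pine",
    "pipo": "yellow_pine",
    "pije": "yellow_pine",
    "yellow_pine": "yellow_pine",
    "douglas-fir": "douglas_fir",
    "douglas fir": "douglas_fir",
    "psme": "douglas_fir",
    "douglas_fir": "douglas_fir",
    "white fir": "white_fir",
    "grand fir": "white_fir",
    "abco": "white_fir",
    "abgr": "white_fir",
    "white_fir": "white_fir",
    "western larch": "western_larch",
    "laoc": "western_larch",
    "western_larch": "western_larch",
    "lodgepole pine": "lodgepole_pine",
    "pico": "lodgepole_pine",
    "lodgepole_pine": "lodgepole_pine",
}

_HARDWOODS = {
    "hardwood",
    "quaking aspen",
    "potr",
    "bigleaf maple",
    "acma",
    "red alder",
    "alru",
    "oregon white oak",
    "quga",
    "tanoak",
    "node",
    "pacific madrone",
    "arme",
}


def pool_species(code: str) -> str:
    """Map a species code or common name to its modelling group.

    Unmapped conifers fall into ``other_conifer``; hardwoods map to
    ``hardwood`` so the stand standardization filter can remove them.
    """
    key = str(code).strip().lower()
    if key in _HARDWOODS:
        return "hardwood"
    return _CONIFER_POOL.get(key, "other_conifer")


def is_hardwood(code: str) -> bool:
    return pool_species(code) == "hardwood"


def _tree_basal_area(dbh_cm: np.ndarray) -> np.ndarray:
    """Per-tree basal area in m^2: pi * (DBH/200)^2."""
    return np.pi * (np.asarray(dbh_cm, dtype=float) / 200.0) ** 2


@dataclass
class StandInventory:
    """A 1-ha stand tree list.

    ``trees`` columns: species_group, dbh_cm, expansion_factor (trees/ha
    represented by the record).  After :func:`standardize_stand` every record
    is a conifer with dbh >= 15 cm.
    """

    stand_id: str
    forest: str
    forest_type: str
    trees: pd.DataFrame
    area_ha: float = 1.0

    def __post_init__(self) -> None:
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(
                f"forest_type must be one of {FOREST_TYPES}, got {self.forest_type!r}"
            )
        if len(self.trees) and (self.trees["expansion_factor"] <= 0).any():
            raise ValueError("expansion factors must be > 0")

    @property
    def tph_total(self) -> float:
        return float(self.trees["expansion_factor"].sum())

    @property
    def ba_total(self) -> float:
        ef = self.trees["expansion_factor"].to_numpy(dtype=float)
        return float(np.sum(ef * _tree_basal_area(self.trees["dbh_cm"])))


@dataclass(frozen=True)
class StandOutcome:
    """Post-fire state of one stand at one severity and iteration."""

    stand_id: str
    forest: str
    forest_type: str
    severity: float
    iteration: int
    ba_live: float
    tph_live: float
    ba_dead: float
    tph_dead: float
    ba_props: dict  # COMPOSITION_GROUPS -> proportion of live basal area


def standardize_stand(
    stand_id: str,
    forest: str,
    forest_type: str,
    raw_trees: pd.DataFrame,
    *,
    species_column: str = "species",
    min_dbh: float = 15.0,
) -> StandInventory:
    """Standardize a raw tree list: pool species, drop hardwoods and small trees.

    Trees with dbh < ``min_dbh`` are removed; dbh exactly at the threshold is
    retained.  An all-removed stand is returned empty with a warning, not an
    error.
    """
    if raw_trees.empty:
        raise ValueError("raw tree list is empty")
    trees = raw_trees.copy()
    if species_column != "species_group" or trees[species_column].map(
        lambda c: c not in set(_CONIFER_POOL.values()) | {"other_conifer", "hardwood"}
    ).any():
        trees["species_group"] = trees[species_column].map(pool_species)
    keep = (trees["species_group"] != "hardwood") & (trees["dbh_cm"] >= min_dbh)
    trees = trees.loc[keep, ["species_group", "dbh_cm", "expansion_factor"]]
    trees = trees.reset_index(drop=True)
    if trees.empty:
        warnings.warn(
            f"stand {stand_id!r}: no conifers >= {min_dbh} cm remain after standardization",
            UserWarning,
        )
    return StandInventory(stand_id=stand_id, forest=forest, forest_type=forest_type, trees=trees)


def _composition_group(groups: pd.Series) -> np.ndarray:
    """Collapse modelling groups to the reported composition groups."""
    g = groups.to_numpy(dtype=object)
    return np.where(np.isin(g, COMPOSITION_GROUPS[:4]), g, "other")


def _aggregate_outcome(stand: StandInventory, severity, iteration, dead: np.ndarray) -> StandOutcome:
    trees = stand.trees
    ef = trees["expansion_factor"].to_numpy(dtype=float)
    ba = ef * _tree_basal_area(trees["dbh_cm"])
    alive = ~dead
    ba_total, tph_total = float(ba.sum()), float(ef.sum())
    ba_live = min(float(ba[alive].sum()), ba_total)
    tph_live = min(float(ef[alive].sum()), tph_total)
    comp = _composition_group(trees["species_group"])
    if ba_live > 0:
        props = {
            g: float(ba[alive & (comp == g)].sum()) / ba_live for g in COMPOSITION_GROUPS
        }
    else:
        props = {g: 0.0 for g in COMPOSITION_GROUPS}
    return StandOutcome(
        stand_id=stand.stand_id,
        forest=stand.forest,
        forest_type=stand.forest_type,
        severity=float(severity),
        iteration=int(iteration),
        ba_live=ba_live,
        tph_live=tph_live,
        ba_dead=ba_total - ba_live,
        tph_dead=tph_total - tph_live,
        ba_props=props,
    )


def _tree_probabilities(stand, models, severity, rng, years, share_draws):
    """Per-record mortality probability with Monte Carlo coefficient draws.

    ``share_draws``: one coefficient draw per species per call instead of one
    per tree (models systematic rather than independent parameter error).
    """
    trees = stand.trees
    dbh = trees["dbh_cm"].to_numpy(dtype=float)
    n = len(trees)
    p = np.empty(n)
    for group in trees["species_group"].unique():
        if group not in models:
            raise KeyError(f"no mortality model for species group {group!r}")
        model = models[group]
        sel = (trees["species_group"] == group).to_numpy()
        m = 1 if share_draws else int(sel.sum())
        draws = rng.normal(
            model.coefficients, model.std_errors, size=(m, model.coefficients.size)
        )
        d = dbh[sel]
        eta = draws[:, 0] + draws[:, 1] * d + draws[:, 2] * severity + draws[:, 3] * years
        if model.has_interaction:
            eta = eta + draws[:, 4] * d * severity
        p[sel] = expit(eta)
    return p


def simulate_stand(
    stand: StandInventory,
    models: dict,
    severity: float,
    rng: np.random.Generator,
    *,
    years: float = 3.0,
    iteration: int = 0,
    share_draws: bool = False,
) -> StandOutcome:
    """Simulate one post-fire outcome of a stand at one severity.

    Each tree gets a fresh coefficient draw, a mortality probability at
    (dbh, severity, years), and dies when u < p for u ~ uniform(0,1).
    """
    p = _tree_probabilities(stand, models, float(severity), rng, years, share_draws)
    dead = rng.uniform(size=len(p)) < p
    return _aggregate_outcome(stand, severity, iteration, dead)


def default_stand_grid() -> np.ndarray:
    """The stand-level severity grid: -50..1000 RdNBR in 5-unit steps."""
    return np.arange(-50.0, 1000.0 + 2.5, 5.0)


def severity_sweep(
    stands: list[StandInventory],
    models: dict,
    grid: np.ndarray | None = None,
    iterations: int = 5,
    seed: int = 0,
    *,
    years: float = 3.0,
    share_draws: bool = False,
) -> pd.DataFrame:
    """Simulate every stand at every grid severity for several iterations.

    Returns the outcomes table: one row per stand x severity x iteration with
    live/dead basal area and density and live basal-area composition
    proportions (columns ``prop_<group>``).  Deterministic under ``seed``.
    """
    if not stands:
        raise ValueError("empty stand collection")
    grid = default_stand_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    n_grid = grid.size
    for stand in stands:
        trees = stand.trees
        n = len(trees)
        if n == 0:
            continue
        dbh = trees["dbh_cm"].to_numpy(dtype=float)
        ef = trees["expansion_factor"].to_numpy(dtype=float)
        ba = ef * _tree_basal_area(dbh)
        comp = _composition_group(trees["species_group"])
        ba_total, tph_total = float(ba.sum()), float(ef.sum())

        # probability tensor (severity, iteration, tree), vectorized per species
        p = np.empty((n_grid, iterations, n))
        for group in trees["species_group"].unique():
            if group not in models:
                raise KeyError(f"no mortality model for species group {group!r}")
            model = models[group]
            sel = (trees["species_group"] == group).to_numpy()
            m = 1 if share_draws else int(sel.sum())
            k = model.coefficients.size
            draws = rng.normal(
                model.coefficients, model.std_errors, size=(n_grid, iterations, m, k)
            )
            d = dbh[sel]
            eta = (
                draws[..., 0]
                + draws[..., 1] * d
                + draws[..., 2] * grid[:, None, None]
                + draws[..., 3] * years
            )
            if model.has_interaction:
                eta = eta + draws[..., 4] * d * grid[:, None, None]
            p[:, :, sel] = expit(eta)
        dead = rng.uniform(size=p.shape) < p
        live = ~dead

        # clamp into [0, total]: reduction order can differ from the np.sum
        # totals by an ulp when every tree lives
        ba_live = np.minimum(np.einsum("sit,t->si", live, ba), ba_total)
        tph_live = np.minimum(np.einsum("sit,t->si", live, ef), tph_total)
        prop_cols = {}
        for g in COMPOSITION_GROUPS:
            ba_g = np.where(comp == g, ba, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                prop_cols[f"prop_{g}"] = np.where(
                    ba_live > 0, np.einsum("sit,t->si", live, ba_g) / ba_live, 0.0
                )
        sev_col = np.repeat(grid, iterations)
        it_col = np.tile(np.arange(iterations), n_grid)
        rows.append(
            pd.DataFrame(
                {
                    "stand_id": stand.stand_id,
                    "forest": stand.forest,
                    "forest_type": stand.forest_type,
                    "severity": sev_col,
                    "iteration": it_col,
                    "ba_live": ba_live.ravel(),
                    "tph_live": tph_live.ravel(),
                    "ba_dead": ba_total - ba_live.ravel(),
                    "tph_dead": tph_total - tph_live.ravel(),
                    "ba_pre": ba_total,
                    "tph_pre": tph_total,
                    **{k: v.ravel() for k, v in prop_cols.items()},
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def composition_profile(
    outcomes: pd.DataFrame, span: float = 0.25
) -> tuple[pd.DataFrame, np.ndarray]:
    """Smoothed mean live basal-area composition across severity.

    Outcomes with zero live basal area are excluded; per-severity group means
    are smoothed with the module-wide locally weighted linear smoother and
    renormalized to sum to one.  Returns the profile table and the array of
    grid severities at which every outcome had zero basal area (reported as
    gaps, not silently interpolated).
    """
    if outcomes.empty:
        raise ValueError("empty outcomes")
    nonzero = outcomes[outcomes["ba_live"] > 0]
    all_sev = np.unique(outcomes["severity"])
    gaps = np.setdiff1d(all_sev, np.unique(nonzero["severity"]))
    prop_cols = [f"prop_{g}" for g in COMPOSITION_GROUPS]
    mean_props = nonzero.groupby("severity")[prop_cols].mean()
    sev = mean_props.index.to_numpy(dtype=float)
    smoothed = {}
    for col in prop_cols:
        if sev.size > 3:
            sm = lowess(mean_props[col].to_numpy(), sev, frac=span, return_sorted=False)
        else:
            sm = mean_props[col].to_numpy()
        smoothed[col] = np.clip(sm, 0.0, None)
    profile = pd.DataFrame(smoothed, index=mean_props.index)
    total = profile.sum(axis=1)
    profile = profile.div(total.where(total > 0, 1.0), axis=0)
    profile = profile.reset_index()
    return profile, gaps
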