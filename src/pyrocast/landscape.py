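"""Landscape-scale reclassification of burn severity into restoration classes.

Each unmasked forest pixel of an RdNBR raster is assigned a restoration-
probability class from the restorative severity windows of its vegetation
type: inside the >=75% window is "restorative"; inside the >=50% window but
below/above the 75% window is "cold"/"hot"; outside the 50% window is "too
cold"/"too hot".  Non-forest ("other") vegetation is masked.  Rasters are
read and written as headered ASCII grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pyrocast.standsim import StandInventory
from pyrocast.assessment import RestorativeRange

__all__ = [
    "VEG_CODES",
    "CLASS_CODES",
    "CLASS_ORDER",
    "SeverityLandscape",
    "RestorationClassMap",
    "classify_pixels",
    "class_summary",
    "residual_structure",
    "write_ascii_grid",
    "read_ascii_grid",
]

#: vegetation-type raster codes
VEG_CODES = {"dry-mixed-conifer": 1, "ponderosa-pine": 2, "other": 3}
_VEG_NAMES = {v: k for k, v in VEG_CODES.items()}

#: restoration class codes, cold -> hot; 255 is masked
CLASS_CODES = {
    "too_cold_lt50": 0,
    "cold_50_to_75": 1,
    "restorative_ge75": 2,
    "hot_50_to_75": 3,
    "too_hot_lt50": 4,
    "masked": 255,
}
CLASS_ORDER = ("too_cold_lt50", "cold_50_to_75", "restorative_ge75", "hot_50_to_75", "too_hot_lt50")


@dataclass
class SeverityLandscape:
    """Gridded RdNBR severity with a vegetation-type layer.

    ``vegtype`` uses :data:`VEG_CODES`; "other" pixels and non-finite
    severities are maskable.
    """

    severity: np.ndarray  # 2-D float RdNBR
    vegtype: np.ndarray  # 2-D uint8
    pixel_size: float = 30.0  # metres

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=float)
        self.vegtype = np.asarray(self.vegtype, dtype=np.uint8)
        if self.severity.ndim != 2 or self.severity.shape != self.vegtype.shape:
            raise ValueError("severity and vegtype must be congruent 2-D grids")
        if min(self.severity.shape) < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel carries no forest class."""
        return (self.vegtype == VEG_CODES["other"]) | ~np.isfinite(self.severity)


@dataclass
class RestorationClassMap:
    """Per-pixel restoration-probability classes plus the legend used."""

    classes: np.ndarray  # 2-D uint8 of CLASS_CODES
    legend: dict  # forest type -> {0.75: (lo, hi), 0.50: (lo, hi)}

    @property
    def masked(self) -> np.ndarray:
        return self.classes == CLASS_CODES["masked"]


def classify_pixels(landscape: SeverityLandscape, ranges: dict) -> RestorationClassMap:
    """Reclassify severity into restoration classes by vegetation type.

    ``ranges`` maps each forest type present to its restorative windows, as
    ``{threshold: RestorativeRange}`` with thresholds 0.75 and 0.50.  Window
    endpoints are inclusive.
    """
    classes = np.full(landscape.severity.shape, CLASS_CODES["masked"], dtype=np.uint8)
    mask = landscape.mask
    for code, ftype in _VEG_NAMES.items():
        if ftype == "other":
            continue
        sel = (landscape.vegtype == code) & ~mask
        if not sel.any():
            continue
        if ftype not in ranges:
            raise KeyError(f"no restorative ranges provided for forest type {ftype!r}")
        r75 = ranges[ftype][0.75]
        r50 = ranges[ftype][0.50]
        if r75.empty or r50.empty:
            raise ValueError(f"empty restorative window for forest type {ftype!r}")
        sev = landscape.severity
        in75 = r75.contains(sev)
        in50 = r50.contains(sev)
        out = np.where(
            in75,
            CLASS_CODES["restorative_ge75"],
            np.where(
                in50,
                np.where(sev < r75.lo, CLASS_CODES["cold_50_to_75"], CLASS_CODES["hot_50_to_75"]),
                np.where(sev < r50.lo, CLASS_CODES["too_cold_lt50"], CLASS_CODES["too_hot_lt50"]),
            ),
        )
        classes[sel] = out[sel].astype(np.uint8)
    legend = {
        ftype: {t: (r.lo, r.hi) for t, r in byt.items()} for ftype, byt in ranges.items()
    }
    return RestorationClassMap(classes=classes, legend=legend)


def class_summary(cmap: RestorationClassMap, landscape: SeverityLandscape) -> pd.DataFrame:
    """Class proportions overall and per vegetation type.

    Proportions are over unmasked pixels (column ``basis='forest'``) and, per
    the all-pixel basis, over every pixel including masked ones
    (``basis='all'``).  ``ge75`` and ``ge50`` cumulate classes (the >=0.50
    share includes the >=0.75 class).
    """
    if cmap.classes.shape != landscape.severity.shape:
        raise ValueError("class map and landscape are not congruent")
    rows = []

    def _summarize(sel: np.ndarray, label: str, basis: str, denom: int) -> None:
        if denom == 0:
            return
        cls = cmap.classes[sel]
        props = {name: float(np.mean(cls == CLASS_CODES[name])) if cls.size else 0.0
                 for name in CLASS_ORDER}
        n_unmasked = int(np.sum(cls != CLASS_CODES["masked"]))
        scale = cls.size / denom if cls.size else 0.0
        row = {"group": label, "basis": basis, "n_pixels": denom}
        for name in CLASS_ORDER:
            row[name] = props[name] * scale
        row["ge75"] = row["restorative_ge75"]
        row["ge50"] = row["restorative_ge75"] + row["cold_50_to_75"] + row["hot_50_to_75"]
        row["lt50"] = row["too_cold_lt50"] + row["too_hot_lt50"]
        rows.append(row)

    unmasked = ~cmap.masked
    _summarize(unmasked, "all", "forest", int(unmasked.sum()))
    _summarize(np.ones_like(unmasked), "all", "all", int(unmasked.size))
    for code, ftype in _VEG_NAMES.items():
        if ftype == "other":
            continue
        sel = (landscape.vegtype == code) & unmasked
        _summarize(sel, ftype, "forest", int(sel.sum()))
    return pd.DataFrame(rows)


def residual_structure(
    models: dict,
    template_stands: list[StandInventory],
    severities: list[float],
    iterations: int,
    dbh_bins: np.ndarray,
    seed: int = 0,
    *,
    years: float = 3.0,
) -> pd.DataFrame:
    """Mean residual live basal area by species group x DBH bin x severity.

    Averages repeated stand simulations, binned by diameter; the per-severity
    totals match the severity-sweep means within Monte Carlo error.
    """
    dbh_bins = np.asarray(dbh_bins, dtype=float)
    if dbh_bins.size < 2:
        raise ValueError("dbh_bins must provide at least two edges")
    from pyrocast.standsim import _tree_probabilities

    rng = np.random.default_rng(seed)
    rows = []
    n_units = len(template_stands) * iterations
    for sev in severities:
        acc: dict[tuple[str, int], float] = {}
        # per-tree simulation (rather than aggregate outcomes) keeps the
        # species x diameter-bin bookkeeping exact
        for stand in template_stands:
            trees = stand.trees
            dbh = trees["dbh_cm"].to_numpy(dtype=float)
            ba = trees["expansion_factor"].to_numpy(dtype=float) * np.pi * (dbh / 200.0) ** 2
            bin_idx = np.clip(np.digitize(dbh, dbh_bins) - 1, 0, dbh_bins.size - 2)
            groups = trees["species_group"].to_numpy(dtype=object)
            for it in range(iterations):
                p = _tree_probabilities(stand, models, float(sev), rng, years, False)
                alive = ~(rng.uniform(size=p.size) < p)
                for g in np.unique(groups):
                    gsel = groups == g
                    for b in range(dbh_bins.size - 1):
                        key = (str(g), b)
                        acc[key] = acc.get(key, 0.0) + float(
                            ba[alive & gsel & (bin_idx == b)].sum()
                        )
        for (g, b), total in sorted(acc.items()):
            rows.append(
                {
                    "severity": float(sev),
                    "species_group": g,
                    "dbh_lo": float(dbh_bins[b]),
                    "dbh_hi": float(dbh_bins[b + 1]),
                    "ba_live_mean": total / n_units,
                }
            )
    return pd.DataFrame(rows)


def write_ascii_grid(path, array: np.ndarray, *, cellsize: float = 30.0, nodata: float = -9999.0):
    """Write a 2-D array as a headered ASCII grid (ESRI .asc layout)."""
    array = np.asarray(array)
    out = np.where(np.isfinite(array.astype(float)), array, nodata)
    header = (
        f"ncols {array.shape[1]}\n"
        f"nrows {array.shape[0]}\n"
        "xllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, float, float]:
    """Read a headered ASCII grid; returns (array, cellsize, nodata)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
        else:
            break
    data = np.loadtxt(lines[i:])
    data = data.reshape(int(meta["nrows"]), int(meta["ncols"]))
    nodata = meta.get("nodata_value", -9999.0)
    return data, meta.get("cellsize", 30.0), nodata
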