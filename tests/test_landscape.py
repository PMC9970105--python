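"""Raster reclassification into restoration-probability classes."""

import numpy as np
import pytest

from pyrocast import landscape as lsc
from pyrocast import synth
from pyrocast.assessment import RestorativeRange
from pyrocast.landscape import (
    CLASS_CODES,
    VEG_CODES,
    SeverityLandscape,
    class_summary,
    classify_pixels,
    read_ascii_grid,
    residual_structure,
    write_ascii_grid,
)


def _ranges(ftype, lo75=400.0, hi75=500.0, lo50=300.0, hi50=600.0):
    return {
        0.75: RestorativeRange("basal_area", 0.75, lo75, hi75, forest_type=ftype),
        0.50: RestorativeRange("basal_area", 0.50, lo50, hi50, forest_type=ftype),
    }


RANGES = {ft: _ranges(ft) for ft in ("dry-mixed-conifer", "ponderosa-pine")}


def brute_force_classify(sev, veg, ranges):
    """Per-pixel oracle implementing the classification rules independently."""
    out = np.empty(sev.shape, dtype=np.uint8)
    for i in range(sev.shape[0]):
        for j in range(sev.shape[1]):
            code = veg[i, j]
            if code == VEG_CODES["other"] or not np.isfinite(sev[i, j]):
                out[i, j] = CLASS_CODES["masked"]
                continue
            ftype = next(k for k, v in VEG_CODES.items() if v == code)
            r75, r50 = ranges[ftype][0.75], ranges[ftype][0.50]
            s = sev[i, j]
            if r75.lo <= s <= r75.hi:
                out[i, j] = CLASS_CODES["restorative_ge75"]
            elif r50.lo <= s <= r50.hi:
                out[i, j] = CLASS_CODES["cold_50_to_75"] if s < r75.lo else CLASS_CODES["hot_50_to_75"]
            elif s < r50.lo:
                out[i, j] = CLASS_CODES["too_cold_lt50"]
            else:
                out[i, j] = CLASS_CODES["too_hot_lt50"]
    return out


class TestClassifyPixels:
    def test_interior_point_is_restorative(self):
        scape = SeverityLandscape(
            severity=np.full((8, 8), 450.0),
            vegtype=np.full((8, 8), VEG_CODES["dry-mixed-conifer"], dtype=np.uint8),
        )
        cmap = classify_pixels(scape, RANGES)
        assert (cmap.classes == CLASS_CODES["restorative_ge75"]).all()

    def test_below_50_window_is_too_cold(self):
        scape = SeverityLandscape(
            severity=np.full((8, 8), 100.0),
            vegtype=np.full((8, 8), VEG_CODES["ponderosa-pine"], dtype=np.uint8),
        )
        cmap = classify_pixels(scape, RANGES)
        assert (cmap.classes == CLASS_CODES["too_cold_lt50"]).all()

    def test_window_endpoints_inclusive(self):
        sev = np.array([[400.0, 500.0, 300.0, 600.0, 299.99, 600.01, 399.99, 500.01]])
        veg = np.full((1, 8), VEG_CODES["dry-mixed-conifer"], dtype=np.uint8)
        cmap = classify_pixels(SeverityLandscape(severity=sev, vegtype=veg), RANGES)
        expect = [
            CLASS_CODES["restorative_ge75"],
            CLASS_CODES["restorative_ge75"],
            CLASS_CODES["cold_50_to_75"],
            CLASS_CODES["hot_50_to_75"],
            CLASS_CODES["too_cold_lt50"],
            CLASS_CODES["too_hot_lt50"],
            CLASS_CODES["cold_50_to_75"],
            CLASS_CODES["hot_50_to_75"],
        ]
        assert cmap.classes[0].tolist() == expect

    def test_matches_brute_force_on_synthetic_raster(self):
        scape = synth.gen_landscape(32, 32, 3.0, 5.0, seed=21)
        cmap = classify_pixels(scape, RANGES)
        oracle = brute_force_classify(scape.severity, scape.vegtype, RANGES)
        np.testing.assert_array_equal(cmap.classes, oracle)

    def test_missing_forest_type_rejected(self):
        scape = SeverityLandscape(
            severity=np.full((8, 8), 450.0),
            vegtype=np.full((8, 8), VEG_CODES["ponderosa-pine"], dtype=np.uint8),
        )
        with pytest.raises(KeyError, match="ponderosa"):
            classify_pixels(scape, {"dry-mixed-conifer": _ranges("dry-mixed-conifer")})

    def test_class_ordering_follows_severity(self):
        sev = np.sort(np.random.default_rng(0).uniform(0, 900, size=(1, 64)))
        veg = np.full((1, 64), VEG_CODES["dry-mixed-conifer"], dtype=np.uint8)
        cmap = classify_pixels(SeverityLandscape(severity=sev, vegtype=veg), RANGES)
        rank = {
            CLASS_CODES["too_cold_lt50"]: 0,
            CLASS_CODES["cold_50_to_75"]: 1,
            CLASS_CODES["restorative_ge75"]: 2,
            CLASS_CODES["hot_50_to_75"]: 3,
            CLASS_CODES["too_hot_lt50"]: 4,
        }
        ranks = [rank[c] for c in cmap.classes[0]]
        assert ranks == sorted(ranks)


class TestClassSummary:
    def test_single_class_map(self):
        scape = SeverityLandscape(
            severity=np.full((8, 8), 450.0),
            vegtype=np.full((8, 8), VEG_CODES["dry-mixed-conifer"], dtype=np.uint8),
        )
        summary = class_summary(classify_pixels(scape, RANGES), scape)
        forest_all = summary[(summary["group"] == "all") & (summary["basis"] == "forest")]
        assert forest_all["restorative_ge75"].iloc[0] == 1.0

    def test_partition_and_cumulation(self):
        scape = synth.gen_landscape(48, 48, 3.0, 5.0, seed=8)
        summary = class_summary(classify_pixels(scape, RANGES), scape)
        forest_all = summary[(summary["group"] == "all") & (summary["basis"] == "forest")]
        total = forest_all[list(lsc.CLASS_ORDER)].sum(axis=1).iloc[0]
        assert total == pytest.approx(1.0, abs=1e-12)
        assert forest_all["ge50"].iloc[0] >= forest_all["ge75"].iloc[0]
        assert forest_all["ge50"].iloc[0] + forest_all["lt50"].iloc[0] == pytest.approx(1.0)

    def test_all_pixel_basis_scales_by_mask(self):
        scape = synth.gen_landscape(48, 48, 3.0, 5.0, seed=8)
        summary = class_summary(classify_pixels(scape, RANGES), scape)
        forest = summary[(summary["group"] == "all") & (summary["basis"] == "forest")]
        allpix = summary[(summary["group"] == "all") & (summary["basis"] == "all")]
        frac_forest = (~scape.mask).mean()
        assert allpix["ge75"].iloc[0] == pytest.approx(
            forest["ge75"].iloc[0] * frac_forest, abs=1e-12
        )


class TestResidualStructure:
    def test_certain_survival_recovers_binned_prefire_stand(self, stands6, models_exact):
        from pyrocast.synth import SpeciesTruth, SyntheticTruth, default_truth

        base = default_truth()
        immortal = {
            g: SpeciesTruth(-40.0, 0.0, 0.0, 0.0, re_sd=0.0) for g in base.species
        }
        truth = SyntheticTruth(immortal, base.templates, base.plot_mix)
        models = synth.truth_models(truth, se_scale=0.0)
        bins = np.array([15.0, 30.0, 60.0, 300.0])
        table = residual_structure(models, stands6[:1], [200.0], 3, bins, seed=0)
        stand = stands6[0]
        ba = (
            stand.trees["expansion_factor"].to_numpy()
            * np.pi
            * (stand.trees["dbh_cm"].to_numpy() / 200.0) ** 2
        )
        assert table["ba_live_mean"].sum() == pytest.approx(ba.sum(), abs=1e-9)

    def test_totals_match_simulation_mean(self, stands6, models_exact):
        from pyrocast.standsim import severity_sweep

        bins = np.array([15.0, 40.0, 300.0])
        sev = 450.0
        table = residual_structure(models_exact, stands6, [sev], 300, bins, seed=4)
        sweep = severity_sweep(stands6, models_exact, np.array([sev]), iterations=300, seed=9)
        # both estimate mean live BA per stand-iteration unit from independent draws
        mc_se = sweep["ba_live"].std() / np.sqrt(len(sweep))
        assert abs(table["ba_live_mean"].sum() - sweep["ba_live"].mean()) < 3 * np.sqrt(2) * mc_se

    def test_small_tree_share_declines_with_severity(self, stands6, models_exact):
        bins = np.array([15.0, 30.0, 300.0])
        table = residual_structure(
            models_exact, stands6[:2], [100.0, 500.0, 900.0], 100, bins, seed=1
        )
        share = {}
        for sev, sub in table.groupby("severity"):
            small = sub[sub["dbh_lo"] == 15.0]["ba_live_mean"].sum()
            share[sev] = small / max(sub["ba_live_mean"].sum(), 1e-12)
        assert share[100.0] >= share[500.0] >= share[900.0] - 1e-9

    def test_bad_bins_rejected(self, stands6, models_exact):
        with pytest.raises(ValueError):
            residual_structure(models_exact, stands6, [100.0], 2, np.array([15.0]), seed=0)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path, rng):
        arr = rng.uniform(-100, 1200, size=(12, 9)).round(3)
        path = tmp_path / "grid.asc"
        write_ascii_grid(path, arr, cellsize=30.0)
        back, cellsize, nodata = read_ascii_grid(path)
        np.testing.assert_allclose(back, arr, rtol=1e-6)
        assert cellsize == 30.0

    def test_nan_becomes_nodata(self, tmp_path):
        arr = np.array([[1.0, np.nan], [3.0, 4.0]])
        path = tmp_path / "grid.asc"
        write_ascii_grid(path, arr, nodata=-9999.0)
        back, _, nodata = read_ascii_grid(path)
        assert back[0, 1] == nodata
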