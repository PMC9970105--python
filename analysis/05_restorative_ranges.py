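#!/usr/bin/env python
"""Derive restorative severity windows against the historical references.

For each forest x forest type and each metric (basal area, density) the
restoration probability per severity is the fraction of simulated outcomes
inside the historical range of variation (mean +/- 1 SD); windows are the
longest contiguous runs meeting the 0.90 / 0.75 / 0.50 thresholds.  Windows
are then averaged across groups and generalized via the interquartile range
of pooled in-window severities, and expressed as a percent of the observed
severity span.
"""

from pathlib import Path

import pandas as pd

from pyrocast import assessment as asmt
from pyrocast import io, standsim

DATA = Path("results/data")
OUT = Path("results")
OBSERVED_SPAN = (-52.0, 1394.0)


def main() -> None:
    sweep = pd.read_csv(OUT / "stand_outcomes.csv")
    refs = io.read_reference_table(DATA / "historical_refs.csv")
    grid = standsim.default_stand_grid()

    rows, pooled = [], {m: {t: [] for t in (0.90, 0.75, 0.50)} for m in asmt.METRIC_COLUMNS}
    for ref in refs:
        sub = sweep[(sweep["forest"] == ref.forest)
                    & (sweep["forest_type"] == ref.forest_type)]
        if sub.empty:
            continue
        for metric in asmt.METRIC_COLUMNS:
            bounds = asmt.hrv_bounds(ref, metric)
            props = asmt.proportions_by_severity(sub, bounds, metric)
            for thr in (0.90, 0.75, 0.50):
                r = asmt.restorative_range(props, thr, metric=metric,
                                           forest=ref.forest,
                                           forest_type=ref.forest_type)
                pooled[metric][thr].append(r)
                rows.append({"forest": ref.forest, "forest_type": ref.forest_type,
                             "metric": metric, "threshold": thr,
                             "lo": r.lo, "hi": r.hi})
    pd.DataFrame(rows).to_csv(OUT / "restorative_ranges.csv", index=False)

    summary = []
    for metric in asmt.METRIC_COLUMNS:
        for thr in (0.90, 0.75):
            lo, hi = asmt.average_range(pooled[metric][thr])
            r = asmt.RestorativeRange(metric=metric, threshold=thr, lo=lo, hi=hi)
            pct = asmt.window_fraction(r, OBSERVED_SPAN)
            summary.append({"metric": metric, "threshold": thr, "kind": "average",
                            "lo": round(lo), "hi": round(hi), "pct_of_span": pct})
            print(f"  {metric} >= {thr:.0%}: average window {lo:.0f}-{hi:.0f} RdNBR "
                  f"({pct}% of the observed span)")
        iqr_lo, iqr_hi = asmt.generalized_range(pooled[metric][0.75], grid)
        summary.append({"metric": metric, "threshold": 0.75, "kind": "iqr",
                        "lo": round(iqr_lo), "hi": round(iqr_hi),
                        "pct_of_span": asmt.window_fraction(
                            asmt.RestorativeRange(metric=metric, threshold=0.75,
                                                  lo=iqr_lo, hi=iqr_hi),
                            OBSERVED_SPAN)})
        print(f"  {metric} generalized IQR of >=75% severities: "
              f"{iqr_lo:.0f}-{iqr_hi:.0f} RdNBR")
    pd.DataFrame(summary).to_csv(OUT / "range_summary.csv", index=False)
    print("wrote results/restorative_ranges.csv and range_summary.csv")


if __name__ == "__main__":
    main()
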