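#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Emulates the four data sources the pipeline consumes: burned-plot tree
records (Bernoulli mortality under a known logit model with plot random
intercepts), overstocked contemporary stand tree lists, historical reference
summaries, and a spatially autocorrelated severity raster with vegetation
patches.  Writes everything under results/data/.
"""

from pathlib import Path

import numpy as np

from pyrocast import io, synth
from pyrocast import landscape as lsc

SEED = 20250925
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = synth.default_truth()

    records = synth.gen_burned_plots(truth, n_plots=300, trees_per_plot=70, seed=SEED)
    io.write_tree_table(OUT / "tree_records.csv", records)
    dead = (records["status"] == "dead").mean()
    print(f"burned plots: {records['plot_id'].nunique()} plots, {len(records)} trees, "
          f"{100 * dead:.1f}% dead, severity {records['rdnbr'].min():.0f}.."
          f"{records['rdnbr'].max():.0f} RdNBR")

    refs = synth.gen_historical_refs("default")
    io.write_reference_table(OUT / "historical_refs.csv", refs)
    print(f"historical references: {len(refs)} forest x type cells")

    forests = ["Malheur", "Fremont-Winema", "Deschutes", "Ochoco"]
    stands = synth.gen_stand_set(truth, forests, ["dry-mixed-conifer", "ponderosa-pine"],
                                 n_stands=9, seed=SEED + 1, refs=refs)
    io.write_stand_table(OUT / "stands.csv", stands)
    tph = np.mean([s.tph_total for s in stands])
    ba = np.mean([s.ba_total for s in stands])
    print(f"contemporary stands: {len(stands)} 1-ha tree lists, "
          f"mean {tph:.0f} trees/ha, {ba:.1f} m2/ha (overstocked by design)")

    scape = synth.gen_landscape(96, 96, autocorrelation_scale=6, pvt_patch_scale=10,
                                seed=SEED + 2)
    lsc.write_ascii_grid(OUT / "severity.asc", scape.severity)
    lsc.write_ascii_grid(OUT / "vegtype.asc", scape.vegtype)
    print(f"landscape: 96x96 pixels, {100 * (~scape.mask).mean():.0f}% forest, "
          f"severity mean {scape.severity.mean():.0f} RdNBR")


if __name__ == "__main__":
    main()
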