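#!/usr/bin/env python
"""Simulate the screening trial: an augmented field book at the study's
design (4 blocks, 5 replicated checks, 41 unreplicated tests), a batch of
canopy thermal images, and SPAD senescence series — each with its ground
truth written alongside so later stages can be read as estimate-vs-truth.

Outputs under results/sim/.
"""
import json
from pathlib import Path

import pandas as pd

import wheatscreen as ws
from wheatscreen.synthetic_data import ThermalSimSpec

SEED = 20260929
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = ws.SimulationSpec(seed=SEED)
    fb, geno_truth, block_truth = ws.simulate_fieldbook(spec)
    ws.write_fieldbook(fb, OUT / "fieldbook.tsv", header_comment=f"seed={SEED}")
    geno_truth.to_csv(OUT / "genotype_truth.tsv", sep="\t", index=False)
    block_truth.to_csv(OUT / "block_truth.tsv", sep="\t", index=False)
    print(f"field book: {len(fb.data)} plots, {len(fb.trait_names)} traits "
          f"({len(fb.checks)} checks x {len(fb.blocks)} blocks + {len(fb.tests)} tests)")

    # thermal images: a gradient of canopy temperatures around T_a = 25 degC
    rows = []
    for i, t_canopy in enumerate([22.0, 23.0, 24.0, 25.0, 26.0, 27.0]):
        tspec = ThermalSimSpec(
            canopy_temp_mean=t_canopy, canopy_temp_sd=0.3, background_offset=4.0,
            ambient_temp=25.0, plant_id=f"plant{i + 1}", seed=SEED + i,
        )
        img, mask, truth = ws.simulate_thermal_image(tspec)
        ws.write_thermal_matrix(img, OUT / f"plant{i + 1}.csv", OUT / f"plant{i + 1}.json")
        rows.append({"plant_id": img.plant_id, "true_canopy_mean": t_canopy,
                     "realized_t_c": truth["realized_t_c"], "n_canopy": truth["n_canopy"]})
    pd.DataFrame(rows).to_csv(OUT / "thermal_truth.tsv", sep="\t", index=False)
    print(f"thermal images: {len(rows)} plants, canopy means 22-27 degC at T_a 25 degC")

    # senescence: slow (stay-green) vs fast senescing series
    series_rows = []
    for label, rate in [("staygreen", 0.4), ("fast", 1.6)]:
        table, truth = ws.simulate_senescence_series(
            initial_spad=50.0, daily_loss_rate=rate, n_weeks=6,
            days_to_maturity=42, noise_sd=0.8, seed=SEED,
        )
        table.insert(0, "series", label)
        table["true_flsm"] = truth["flsm"]
        series_rows.append(table)
    pd.concat(series_rows).to_csv(OUT / "senescence.tsv", sep="\t", index=False)
    print("senescence series: stay-green at 0.4 %/day vs fast at 1.6 %/day")


if __name__ == "__main__":
    main()
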