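#!/usr/bin/env python
"""Interphase arm: simulate painted nuclei, segment, measure CT contact.

Generates a cohort of synthetic diploid nuclei with three painted
chromosome territories (pairwise contact probability 0.95, intermixing
target 5% of nuclear volume), runs the hysteresis + watershed segmentation,
and summarises per-pair contact frequency and median intermixing volume,
comparing against the generator's exact truth masks.

Writes results/interphase_per_cell.csv and results/interphase_contact_summary.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ctkit.metrics import measure_cell, summarize_population
from ctkit.segmentation import segment_nucleus, segment_territories
from ctkit.synthetic import NucleusSpec, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
N_CELLS = 60
SEED = 20260925 % (2**31 - 1)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = NucleusSpec(contact_probability=0.95, seed=SEED)
    rows, records, truth_flags = [], [], []
    for i, (stack, truth) in enumerate(generate_cohort(spec, N_CELLS, seed=SEED)):
        nucleus = segment_nucleus(stack.channels["dna"], stack.voxel_size)
        masks = {
            name: segment_territories(
                stack.channels[name], nucleus, stack.voxel_size, channel_name=name
            )
            for name in spec.channel_names
        }
        measurements, overlaps = measure_cell(nucleus, masks, f"cell{i}")
        records += overlaps
        for m in measurements:
            rows.append(
                dict(cell_id=m.cell_id, chromosome=m.chromosome,
                     volume_um3=m.volume, nuclear_fraction=m.nuclear_fraction)
            )
        truth_flags += list(truth.true_contacts.values())
    per_cell = pd.DataFrame(rows)
    per_cell.to_csv(OUT / "interphase_per_cell.csv", index=False)
    summary = summarize_population(records, replicate_id="rep1")
    summary.to_csv(OUT / "interphase_contact_summary.csv", index=False)

    est = float(np.mean([r.contact for r in records]))
    tru = float(np.mean(truth_flags))
    print(f"measured {len(per_cell)} territories in {N_CELLS} nuclei")
    print(f"mean CT volume: {per_cell.volume_um3.mean():.1f} um3 "
          f"(max nuclear fraction {per_cell.nuclear_fraction.max():.2f})")
    print(summary.to_string(index=False))
    print(f"pooled contact frequency: {100*est:.1f}% (truth masks: {100*tru:.1f}%)")


if __name__ == "__main__":
    sys.exit(main())
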