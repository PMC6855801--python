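#!/usr/bin/env python
"""Effect sizes for a condensin-II-boosted population.

Takes the published total translocation frequencies of an uninduced control
(16.7%) and a Cap-H2-overexpressing population (10.9%) as inputs and reports
the derived effect measures: percent reduction, fold change and signed
percent change.

Writes results/condensin_effect.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from ctkit.stats import EffectSummary, percent_reduction

OUT = Path(__file__).resolve().parents[1] / "results"
CONTROL_PCT = 16.7
BOOSTED_PCT = 10.9


def main() -> None:
    OUT.mkdir(exist_ok=True)
    eff = EffectSummary(control_value=CONTROL_PCT, treated_value=BOOSTED_PCT)
    row = dict(
        control_frequency_pct=CONTROL_PCT,
        treated_frequency_pct=BOOSTED_PCT,
        percent_reduction=percent_reduction(CONTROL_PCT, BOOSTED_PCT),
        percent_reduction_unrounded=percent_reduction(
            CONTROL_PCT, BOOSTED_PCT, round_whole=False
        ),
        fold_change=eff.fold_change,
        percent_change=eff.percent_change,
    )
    df = pd.DataFrame([row])
    df.to_csv(OUT / "condensin_effect.csv", index=False)
    print(df.to_string(index=False))
    print(f"translocation frequency falls {row['percent_reduction']:.0f}% "
          f"({CONTROL_PCT}% -> {BOOSTED_PCT}%)")


if __name__ == "__main__":
    sys.exit(main())
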