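#!/usr/bin/env python
"""Classify reaction-norm patterns and extract per-treatment effect sizes.

Applies the inclusion rules to every experiment (two or more shared common
environments, rank order maintained, counter- or cogradient geometry), then
computes Hedges' d between the polar populations at each treatment.  Writes
one effect-size table per covariation class under results/.
"""

import argparse
from collections import Counter
from pathlib import Path

from covgrad.effect_sizes import (
    ExperimentExcluded,
    PatternLabel,
    classify_covariation_pattern,
    group_experiments,
    per_treatment_effect_sizes,
)
from covgrad.pipeline import read_observations, write_effect_sizes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    obs = read_observations(ROOT / "results" / "data" / "observations.csv")
    experiments = group_experiments(obs)

    tally: Counter = Counter()
    records = {PatternLabel.COUNTERGRADIENT: [], PatternLabel.COGRADIENT: []}
    for key, cells in sorted(experiments.items()):
        try:
            label = classify_covariation_pattern(cells)
        except (ExperimentExcluded, ValueError) as exc:
            tally["excluded"] += 1
            continue
        tally[label.value] += 1
        if label in records:
            records[label].extend(per_treatment_effect_sizes(cells))

    print(f"{len(experiments)} experiments:")
    for k, v in sorted(tally.items()):
        print(f"  {k}: {v}")
    for label, recs in records.items():
        path = ROOT / "results" / f"effect_sizes_{label.value}.csv"
        write_effect_sizes(path, recs)
        print(f"wrote {len(recs)} effect sizes -> {path.name}")


if __name__ == "__main__":
    main()
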