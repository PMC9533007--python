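#!/usr/bin/env python
"""Compensation analysis of the countergradient experiments.

Compares each countergradient experiment's polar populations in their own
home-environment treatments (Hedges' d, positive = the genetically larger
population is also larger at home) and classifies over-/perfect/under-
compensation at the conservative +/-0.5 band and the stricter +/-0.2
sensitivity band.  Writes records and summaries under results/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from covgrad.compensation import compensation_record, compensation_summary
from covgrad.effect_sizes import (
    ExperimentExcluded,
    PatternLabel,
    classify_covariation_pattern,
    group_experiments,
)
from covgrad.pipeline import read_observations

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    obs = read_observations(ROOT / "results" / "data" / "observations.csv")
    records = []
    for key, cells in sorted(group_experiments(obs).items()):
        try:
            if classify_covariation_pattern(cells) != \
                    PatternLabel.COUNTERGRADIENT:
                continue
            records.append(
                compensation_record(cells, require_countergradient=False)
            )
        except (ExperimentExcluded, ValueError):
            continue

    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        ROOT / "results" / "compensation.csv", index=False,
        float_format="%.6g",
    )
    summary = {
        f"bound_{b:g}": compensation_summary(records, bound=b)
        for b in (0.5, 0.2)
    }
    out = ROOT / "results" / "compensation_summary.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    s = summary["bound_0.5"]
    print(f"{s['n']} countergradient experiments:")
    names = {"over": "overcompensating", "perfect": "perfectly compensating",
             "under": "undercompensating"}
    for lab in ("over", "perfect", "under"):
        print(f"  {names[lab]}: {100 * s['proportions'][lab]:.1f}%")
    print(f"  d_comp 5%/95% quantiles: {s['quantiles']['q5']:.2f} / "
          f"{s['quantiles']['q95']:.2f}; range {s['range'][0]:.2f} to "
          f"{s['range'][1]:.2f}")
    print(f"  perfect at +/-0.2 band: "
          f"{100 * summary['bound_0.2']['proportions']['perfect']:.1f}%")


if __name__ == "__main__":
    main()
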