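"""Home-environment phenotypic matching for countergradient experiments.

Countergradient variation means the genetic and environmental effects on a
trait oppose each other along a gradient, so populations can look alike in
the wild while diverging strongly in common gardens.  The compensation
analysis asks how alike they actually are: the trait values of the two polar
populations, each observed in the treatment representing its own home
environment, are compared as a Hedges' d (``d_comp``).  The sign convention
follows the reaction-norm geometry: positive d_comp means the population
with the larger common-garden (genetic) value also expresses the larger
phenotype at home — overcompensation; zero means home phenotypes match —
perfect compensation; negative means the genetically larger population is
smaller at home — undercompensation.

Classification uses a symmetric band around zero (default half-width 0.5, a
medium effect size; 0.2 as a stricter sensitivity bound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .effect_sizes import (
    PatternLabel,
    PopulationObservation,
    classify_covariation_pattern,
    hedges_d,
    select_polar_populations,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CompensationRecord",
    "compensation_effect_size",
    "classify_compensation",
    "compensation_record",
    "compensation_summary",
]

LABELS = ("over", "perfect", "under")


@dataclass(frozen=True)
class CompensationRecord:
    """Home-vs-home standardized difference and its classification."""

    d_comp: float
    label: str
    bound: float
    study_id: str
    experiment_id: str
    trait: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if classify_compensation(self.d_comp, self.bound) != self.label:
            raise ValueError("label inconsistent with d_comp and bound")


def _home_cell(
    cells: Sequence[PopulationObservation], pid: str
) -> PopulationObservation:
    homes = [c for c in cells if c.is_home]
    if not homes:
        raise ValueError(f"population {pid!r} has no home-flagged cell")
    if len(homes) > 1:
        raise ValueError(f"population {pid!r} flags multiple home cells")
    return homes[0]


def compensation_effect_size(
    experiment: Iterable[PopulationObservation],
    require_countergradient: bool = True,
) -> float:
    """Hedges' d between the polar populations' home-environment cells.

    The minuend is the population with the larger common-garden trait value
    (averaged over the treatments shared by the polar pair), so positive
    values indicate overcompensation.  Requires each polar population to
    have exactly one ``is_home``-flagged cell; by default the experiment
    must classify as countergradient.
    """
    cells = list(experiment)
    if require_countergradient:
        pattern = classify_covariation_pattern(cells)
        if pattern != PatternLabel.COUNTERGRADIENT:
            raise ValueError(
                f"compensation is defined for countergradient experiments; "
                f"pattern is {pattern.value!r}"
            )
    lo_id, hi_id = select_polar_populations(cells)
    by_pop = {lo_id: [], hi_id: []}
    for c in cells:
        if c.population_id in by_pop:
            by_pop[c.population_id].append(c)
    shared = sorted(
        {c.treatment_level for c in by_pop[lo_id]}
        & {c.treatment_level for c in by_pop[hi_id]}
    )
    if not shared:
        raise ValueError("polar pair shares no common-garden treatments")

    def cell(pid: str, t: float) -> PopulationObservation:
        return next(c for c in by_pop[pid] if c.treatment_level == t)

    mean_diff = np.mean(
        [cell(hi_id, t).mean - cell(lo_id, t).mean for t in shared]
    )
    big, small = (hi_id, lo_id) if mean_diff >= 0 else (lo_id, hi_id)
    home_big = _home_cell(by_pop[big], big)
    home_small = _home_cell(by_pop[small], small)
    d_comp, _ = hedges_d(
        home_big.mean, home_big.sd, home_big.n,
        home_small.mean, home_small.sd, home_small.n,
    )
    return d_comp


def classify_compensation(d_comp: float, bound: float = 0.5) -> str:
    """Threshold rule: over if d > bound, under if d < -bound, else perfect."""
    if not bound > 0:
        raise ValueError(f"bound must be > 0, got {bound}")
    if d_comp > bound:
        return "over"
    if d_comp < -bound:
        return "under"
    return "perfect"


def compensation_record(
    experiment: Iterable[PopulationObservation],
    bound: float = 0.5,
    require_countergradient: bool = True,
) -> CompensationRecord:
    """Compute and classify compensation for one experiment."""
    cells = list(experiment)
    d_comp = compensation_effect_size(
        cells, require_countergradient=require_countergradient
    )
    meta = cells[0]
    return CompensationRecord(
        d_comp=d_comp,
        label=classify_compensation(d_comp, bound),
        bound=bound,
        study_id=meta.study_id,
        experiment_id=meta.experiment_id,
        trait=meta.trait,
    )


def compensation_summary(
    records: Sequence[CompensationRecord] | Sequence[float],
    bound: float = 0.5,
    quantile_probs: Sequence[float] = (0.05, 0.95),
) -> dict:
    """Label proportions, range and quantiles of the d_comp distribution.

    Accepts either classified records (re-classified at ``bound``) or raw
    d_comp values.  Quantiles use linear interpolation of order statistics
    (type-7 convention).
    """
    if len(records) == 0:
        raise ValueError("no compensation records to summarize")
    if isinstance(records[0], CompensationRecord):
        values = np.array([r.d_comp for r in records], dtype=float)
    else:
        values = np.asarray(records, dtype=float)
    labels = [classify_compensation(v, bound) for v in values]
    n = len(values)
    props = {lab: labels.count(lab) / n for lab in LABELS}
    qs = np.quantile(values, quantile_probs)  # numpy default is type 7
    return {
        "n": n,
        "bound": bound,
        "proportions": props,
        "quantiles": {f"q{100 * p:g}": float(q) for p, q in zip(quantile_probs, qs)},
        "range": [float(values.min()), float(values.max())],
    }
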