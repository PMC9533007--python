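"""Standardized mean differences and covariation-pattern classification.

Common-garden and reciprocal-transplant studies rear several populations from
an environmental gradient in two or more shared environments.  The genetic
effect of local adaptation is quantified as Hedges' *d* — the small-sample
corrected standardized mean difference — between the two most disparate
("polar") populations, computed separately at each treatment level.  The
shape of the polar pair's reaction norms determines whether the experiment
shows countergradient variation (genetic and environmental effects oppose,
cov_GE < 0), cogradient variation (they reinforce, cov_GE > 0), a crossing
genotype-by-environment response, or plasticity alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationObservation",
    "EffectSizeRecord",
    "PatternLabel",
    "DegenerateDispersionError",
    "InsufficientReplicationError",
    "ExperimentExcluded",
    "hedges_d",
    "select_polar_populations",
    "per_treatment_effect_sizes",
    "classify_covariation_pattern",
    "group_experiments",
]


class DegenerateDispersionError(ValueError):
    """Both groups have zero dispersion; d is undefined."""


class InsufficientReplicationError(ValueError):
    """A group has fewer than two replicates; the pooled SD is undefined."""


class ExperimentExcluded(ValueError):
    """The experiment fails an inclusion rule (e.g. < 2 shared treatments)."""


class PatternLabel(str, Enum):
    """Exhaustive, mutually exclusive reaction-norm patterns for a polar pair."""

    COUNTERGRADIENT = "countergradient"
    COGRADIENT = "cogradient"
    CROSSING_GXE = "crossing_gxe"
    PLASTICITY_ONLY = "plasticity_only"


@dataclass(frozen=True)
class PopulationObservation:
    """One population x treatment cell of a common-garden experiment.

    ``mean``/``sd`` are the trait summary over the ``n`` replicates reared in
    that treatment; ``gradient_position`` is in the units of the stated
    gradient (m elevation, degrees latitude, °C, ...); ``is_home`` flags the
    treatment judged to represent the population's home environment.
    ``gradient_type``/``taxon_class`` are optional study metadata carried
    through to the effect-size table.
    """

    study_id: str
    experiment_id: str
    trait: str
    species: str
    population_id: str
    gradient_position: float
    treatment_level: float
    mean: float
    sd: float
    n: int
    is_home: bool = False
    gradient_type: str | None = None
    taxon_class: str | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise InsufficientReplicationError(f"n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class EffectSizeRecord:
    """Hedges' d and its sampling variance for one treatment of one experiment.

    ``orientation`` records which population was the minuend of the mean
    difference, for auditability of the sign convention.
    """

    d: float
    v: float
    study_id: str
    experiment_id: str
    trait: str
    treatment_level: float
    species: str
    gradient_type: str | None = None
    taxon_class: str | None = None
    orientation: str | None = None

    def __post_init__(self) -> None:
        if not (self.v > 0):
            raise ValueError(f"sampling variance must be > 0, got {self.v}")
        if not math.isfinite(self.d):
            raise ValueError("d must be finite")


def hedges_d(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Small-sample corrected standardized mean difference (group 1 minus 2).

    Returns ``(d, v)`` under the Hedges–Olkin convention::

        d = J * (m1 - m2) / s_pooled
        s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))
        J = 1 - 3 / (4 (n1 + n2 - 2) - 1)
        v = 1/n1 + 1/n2 + d^2 / (2 (n1 + n2))

    Raises
    ------
    InsufficientReplicationError
        If either group has n < 2.
    DegenerateDispersionError
        If the pooled standard deviation is zero.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicationError(
            f"both groups need n >= 2 (got n1={n1}, n2={n2})"
        )
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / df)
    if s_pooled == 0.0:
        raise DegenerateDispersionError("pooled SD is zero; d is undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = j * (m1 - m2) / s_pooled
    v = 1.0 / n1 + 1.0 / n2 + d * d / (2.0 * (n1 + n2))
    return d, v


def _by_population(
    experiment: Iterable[PopulationObservation],
) -> dict[str, list[PopulationObservation]]:
    out: dict[str, list[PopulationObservation]] = {}
    for obs in experiment:
        out.setdefault(obs.population_id, []).append(obs)
    return out


def select_polar_populations(
    experiment: Iterable[PopulationObservation],
) -> tuple[str, str]:
    """Identify the most disparate pair along the gradient.

    Returns ``(pop_low, pop_high)`` — the population ids with minimum and
    maximum ``gradient_position``.  Ties at an extreme are broken
    lexicographically on population id, with a logged warning.
    """
    pops = _by_population(experiment)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations to select a polar pair")
    position = {pid: cells[0].gradient_position for pid, cells in pops.items()}
    for pid, cells in pops.items():
        for c in cells:
            if c.gradient_position != position[pid]:
                raise ValueError(
                    f"population {pid!r} has inconsistent gradient positions"
                )
    lo = min(position.values())
    hi = max(position.values())
    lo_ids = sorted(p for p, x in position.items() if x == lo)
    hi_ids = sorted(p for p, x in position.items() if x == hi)
    if len(lo_ids) > 1 or len(hi_ids) > 1:
        logger.warning(
            "tied gradient extremes; breaking ties lexicographically "
            "(low candidates %s, high candidates %s)",
            lo_ids,
            hi_ids,
        )
    return lo_ids[0], hi_ids[0]


def _shared_treatments(
    cells_a: Sequence[PopulationObservation],
    cells_b: Sequence[PopulationObservation],
) -> list[float]:
    ta = {c.treatment_level for c in cells_a}
    tb = {c.treatment_level for c in cells_b}
    return sorted(ta & tb)


def _cell(
    cells: Sequence[PopulationObservation], treatment: float
) -> PopulationObservation:
    for c in cells:
        if c.treatment_level == treatment:
            return c
    raise KeyError(treatment)


def per_treatment_effect_sizes(
    experiment: Iterable[PopulationObservation],
    min_shared_treatments: int = 2,
) -> list[EffectSizeRecord]:
    """One Hedges' d per treatment level shared by the polar pair.

    Treatments where only one polar population was measured are dropped
    pairwise.  The orientation of the difference is fixed experiment-wide:
    the minuend is the population with the larger common-garden trait value
    averaged over the shared treatments, so the experiment-level mean d is
    non-negative.

    Raises :class:`ExperimentExcluded` when the polar pair shares fewer than
    ``min_shared_treatments`` treatments (the two-common-environment
    inclusion rule).
    """
    cells = list(experiment)
    pops = _by_population(cells)
    lo_id, hi_id = select_polar_populations(cells)
    shared = _shared_treatments(pops[lo_id], pops[hi_id])
    if len(shared) < min_shared_treatments:
        raise ExperimentExcluded(
            f"polar pair ({lo_id!r}, {hi_id!r}) shares only {len(shared)} "
            f"treatment(s); >= {min_shared_treatments} common environments required"
        )
    mean_diff = sum(
        _cell(pops[hi_id], t).mean - _cell(pops[lo_id], t).mean for t in shared
    ) / len(shared)
    if mean_diff >= 0:
        minuend, subtrahend = hi_id, lo_id
    else:
        minuend, subtrahend = lo_id, hi_id
    meta = cells[0]
    records = []
    for t in shared:
        a = _cell(pops[minuend], t)
        b = _cell(pops[subtrahend], t)
        d, v = hedges_d(a.mean, a.sd, a.n, b.mean, b.sd, b.n)
        records.append(
            EffectSizeRecord(
                d=d,
                v=v,
                study_id=meta.study_id,
                experiment_id=meta.experiment_id,
                trait=meta.trait,
                treatment_level=t,
                species=meta.species,
                gradient_type=meta.gradient_type,
                taxon_class=meta.taxon_class,
                orientation=f"{minuend}-{subtrahend}",
            )
        )
    return records


def _home_treatment(cells: Sequence[PopulationObservation], pid: str) -> float:
    homes = sorted({c.treatment_level for c in cells if c.is_home})
    if not homes:
        raise ValueError(
            f"population {pid!r} has no is_home flag set; home designation "
            "is required for covariation classification"
        )
    if len(homes) > 1:
        raise ValueError(f"population {pid!r} flags multiple home treatments")
    return homes[0]


def classify_covariation_pattern(
    experiment: Iterable[PopulationObservation],
    negligible_d: float = 0.2,
) -> PatternLabel:
    """Classify the polar pair's reaction norms.

    Rules, applied in order to the per-treatment d values oriented
    high-position minus low-position population:

    1. ``plasticity_only`` — |d| < ``negligible_d`` in every shared treatment
       (the genetic offset is negligible everywhere).
    2. ``crossing_gxe`` — d changes sign across treatments (rank order of the
       genotypes is not maintained).
    3. Otherwise the genotypes keep their rank order and the label depends on
       whether the genetic offset opposes or reinforces the environmental
       trend between the two home environments: ``countergradient`` when
       sign(g) * sign(e) < 0 (negative cov_GE) and ``cogradient`` when > 0,
       with g the mean genetic difference (high minus low population across
       common gardens) and e the within-population trait change from the low
       population's home treatment to the high population's home treatment.

    Requires ``is_home`` flags on the polar populations' home cells.
    """
    cells = list(experiment)
    pops = _by_population(cells)
    lo_id, hi_id = select_polar_populations(cells)
    shared = _shared_treatments(pops[lo_id], pops[hi_id])
    if len(shared) < 2:
        raise ExperimentExcluded(
            "covariation pattern needs >= 2 shared treatments"
        )
    ds = []
    for t in shared:
        a = _cell(pops[hi_id], t)
        b = _cell(pops[lo_id], t)
        d, _ = hedges_d(a.mean, a.sd, a.n, b.mean, b.sd, b.n)
        ds.append(d)
    if all(abs(d) < negligible_d for d in ds):
        return PatternLabel.PLASTICITY_ONLY
    if min(ds) < 0.0 < max(ds):
        return PatternLabel.CROSSING_GXE

    t_home_hi = _home_treatment(pops[hi_id], hi_id)
    t_home_lo = _home_treatment(pops[lo_id], lo_id)
    if t_home_hi == t_home_lo:
        raise ValueError(
            "both polar populations share the same home treatment; "
            "environmental trend (hence cov_GE sign) is undefined"
        )
    g = sum(ds) / len(ds)
    # Environmental trend: within-population change from the low population's
    # home treatment to the high population's — averaged over the populations
    # measured at both, so genotype offsets cancel.
    deltas = []
    for pid in (lo_id, hi_id):
        ts = {c.treatment_level for c in pops[pid]}
        if t_home_hi in ts and t_home_lo in ts:
            deltas.append(
                _cell(pops[pid], t_home_hi).mean - _cell(pops[pid], t_home_lo).mean
            )
    if not deltas:
        raise ValueError(
            "no polar population was measured at both home treatments; "
            "environmental trend is unidentifiable"
        )
    e = sum(deltas) / len(deltas)
    if e == 0.0:
        raise ValueError(
            "environmental trend between home treatments is zero; "
            "covariation sign is undefined"
        )
    if g * e < 0:
        return PatternLabel.COUNTERGRADIENT
    return PatternLabel.COGRADIENT


def group_experiments(
    observations: Iterable[PopulationObservation],
) -> Mapping[tuple[str, str, str], list[PopulationObservation]]:
    """Group observations into experiments keyed (study, experiment, trait)."""
    out: dict[tuple[str, str, str], list[PopulationObservation]] = {}
    for obs in observations:
        out.setdefault((obs.study_id, obs.experiment_id, obs.trait), []).append(obs)
    return out
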