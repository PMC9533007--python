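"""Reaction-norm and meta-dataset generators with known truth.

The generative model for a single common-garden experiment follows the
classical phenotypic variance decomposition V_P = V_E + V_G + V_GxE +
2 cov_GE: the cell mean for population p in treatment t is

    mu0 + G_p + E_t + I_pt,       I_pt ~ N(0, sigma_gxe^2)

with G_p the additive genetic effect (monotone along the gradient), E_t the
environmental effect of the treatment, and within-cell residual s.d.
``sigma_resid`` generating the n replicate measurements whose sample mean
and SD are reported.  The sign of cov_GE is set by the home-treatment map:
countergradient scenarios assign genetically larger populations to
trait-lowering home environments (corr(G_p, E_home(p)) < 0), cogradient
scenarios the reverse.

Whole meta-datasets are generated from the hierarchical truth
(mu, sigma_study, sigma_trait:study, sigma_phylo) over a random balanced
taxonomy, either directly as effect sizes with known sampling variances or
as full observation tables that exercise the entire extraction pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effect_sizes import PopulationObservation
from .hier_meta import MetaDataset
from .phylo_vcv import (
    DEFAULT_RANKS,
    RelatednessMatrix,
    TaxonLineage,
    lineages_to_relatedness,
)

__all__ = [
    "GradientScenario",
    "MetaScenario",
    "simulate_experiment",
    "true_polar_effect",
    "default_home_map",
    "canonical_pattern_scenarios",
    "random_taxonomy",
    "simulate_meta_dataset",
    "simulate_observations_from_meta",
]


@dataclass(frozen=True)
class GradientScenario:
    """Parameters of one simulated common-garden experiment.

    ``env_effects`` maps treatment level -> E_t (trait units).  ``home_map``
    maps population index -> home treatment level; if ``None`` it is derived
    from ``covariation`` (see :func:`default_home_map`).  ``interaction``
    optionally fixes I_pt explicitly (population index, treatment level) ->
    value; otherwise interactions are drawn N(0, sigma_gxe^2).  With
    ``sampling_noise=False`` the reported cell mean and SD are the exact
    population values (mean, sigma_resid) — the no-sampling-error limit used
    for closed-form checks.
    """

    positions: tuple[float, ...]
    genetic_effects: tuple[float, ...]
    env_effects: Mapping[float, float]
    mu0: float = 0.0
    sigma_gxe: float = 0.0
    sigma_resid: float = 1.0
    n_per_cell: int = 20
    covariation: str = "counter"
    home_map: Mapping[int, float] | None = None
    interaction: Mapping[tuple[int, float], float] | None = None
    sampling_noise: bool = True
    study_id: str = "study"
    experiment_id: str = "exp"
    trait: str = "trait"
    species: str = "species"
    gradient_type: str | None = None
    taxon_class: str | None = None

    def __post_init__(self) -> None:
        if len(self.genetic_effects) != len(self.positions):
            raise ValueError("genetic_effects must match positions")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.sigma_gxe < 0 or self.sigma_resid < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.covariation not in ("counter", "co"):
            raise ValueError("covariation must be 'counter' or 'co'")
        if len(self.env_effects) < 2:
            raise ValueError("need >= 2 treatment levels")
        if self.home_map is not None:
            bad = set(self.home_map.values()) - set(self.env_effects)
            if bad:
                raise ValueError(
                    f"home map references unknown treatments: {sorted(bad)}"
                )


def default_home_map(scenario: GradientScenario) -> dict[int, float]:
    """Assign each population a home treatment matching the covariation sign.

    Populations ranked by genetic effect are paired with treatments ranked
    by environmental effect — in the same order for cogradient scenarios
    (corr(G, E_home) > 0) and reversed for countergradient (corr < 0).  With
    fewer treatments than populations the pairing spreads by quantile, so
    the polar populations always get the extreme treatments.
    """
    n_pop = len(scenario.positions)
    g_rank = np.argsort(np.argsort(scenario.genetic_effects))
    treatments = sorted(scenario.env_effects, key=scenario.env_effects.get)
    n_t = len(treatments)
    out = {}
    for p in range(n_pop):
        frac = g_rank[p] / (n_pop - 1) if n_pop > 1 else 0.0
        if scenario.covariation == "counter":
            frac = 1.0 - frac
        out[p] = treatments[round(frac * (n_t - 1))]
    return out


def simulate_experiment(
    scenario: GradientScenario, seed: int
) -> list[PopulationObservation]:
    """Draw one experiment's observation table (one row per cell)."""
    rng = np.random.default_rng(seed)
    home_map = dict(scenario.home_map) if scenario.home_map is not None \
        else default_home_map(scenario)
    treatments = sorted(scenario.env_effects)
    order = np.argsort(scenario.positions, kind="stable")
    obs: list[PopulationObservation] = []
    # draw interactions in a fixed (population, treatment) order for
    # reproducibility regardless of downstream iteration
    inter = {}
    for p in range(len(scenario.positions)):
        for t in treatments:
            if scenario.interaction is not None:
                inter[(p, t)] = scenario.interaction.get((p, t), 0.0)
            elif scenario.sigma_gxe > 0:
                inter[(p, t)] = rng.normal(0.0, scenario.sigma_gxe)
            else:
                inter[(p, t)] = 0.0
    width = len(str(len(scenario.positions)))
    for rank, p in enumerate(order):
        pid = f"p{rank:0{width}d}"
        for t in treatments:
            cell_mean = (
                scenario.mu0
                + scenario.genetic_effects[p]
                + scenario.env_effects[t]
                + inter[(p, t)]
            )
            if scenario.sampling_noise and scenario.sigma_resid > 0:
                draws = rng.normal(cell_mean, scenario.sigma_resid,
                                   scenario.n_per_cell)
                m, s = float(draws.mean()), float(draws.std(ddof=1))
            else:
                m, s = float(cell_mean), float(scenario.sigma_resid)
            obs.append(
                PopulationObservation(
                    study_id=scenario.study_id,
                    experiment_id=scenario.experiment_id,
                    trait=scenario.trait,
                    species=scenario.species,
                    population_id=pid,
                    gradient_position=float(scenario.positions[p]),
                    treatment_level=float(t),
                    mean=m,
                    sd=s,
                    n=scenario.n_per_cell,
                    is_home=(home_map.get(int(p)) == t),
                    gradient_type=scenario.gradient_type,
                    taxon_class=scenario.taxon_class,
                )
            )
    return obs


def true_polar_effect(scenario: GradientScenario) -> float:
    """Expected per-treatment Hedges' d between the polar populations.

    Equals (G at the maximum position - G at the minimum position) /
    sigma_resid.  With sigma_gxe > 0 this is the expectation over
    interaction draws; individual treatments scatter around it.  Undefined
    (raises) when sigma_resid is zero.
    """
    if scenario.sigma_resid == 0:
        raise ValueError(
            "true polar effect is undefined without residual dispersion"
        )
    i_lo = int(np.argmin(scenario.positions))
    i_hi = int(np.argmax(scenario.positions))
    return (
        scenario.genetic_effects[i_hi] - scenario.genetic_effects[i_lo]
    ) / scenario.sigma_resid


def canonical_pattern_scenarios() -> dict[str, GradientScenario]:
    """Four noiseless parameterizations, one per reaction-norm pattern.

    All use two populations, two treatments, unit residual s.d. and exact
    cell summaries, so classification is deterministic: parallel identical
    norms (plasticity only), explicitly crossing norms (crossing G x E), and
    offset norms whose home assignments oppose or follow the environmental
    trend (counter-/cogradient).
    """
    base = dict(
        positions=(0.0, 1.0),
        env_effects={0.0: 0.0, 1.0: 1.0},
        sigma_resid=1.0,
        sampling_noise=False,
        n_per_cell=20,
    )
    return {
        "plasticity_only": GradientScenario(
            genetic_effects=(0.0, 0.0), covariation="co",
            home_map={0: 0.0, 1: 1.0}, **base,
        ),
        "crossing_gxe": GradientScenario(
            genetic_effects=(0.0, 0.0), covariation="co",
            home_map={0: 0.0, 1: 1.0},
            interaction={(1, 0.0): 1.0, (1, 1.0): -1.0}, **base,
        ),
        "countergradient": GradientScenario(
            genetic_effects=(0.0, 2.0), covariation="counter",
            home_map={0: 1.0, 1: 0.0}, **base,
        ),
        "cogradient": GradientScenario(
            genetic_effects=(0.0, 2.0), covariation="co",
            home_map={0: 0.0, 1: 1.0}, **base,
        ),
    }


def random_taxonomy(
    n_species: int,
    seed: int | np.random.Generator,
    genus_size: int = 3,
    family_size: int = 3,
    order_size: int = 3,
    class_size: int = 3,
) -> list[TaxonLineage]:
    """Balanced random assignment of species to higher taxa.

    Species are shuffled and chunked into genera of ``genus_size``, genera
    into families, and so on; everything shares one phylum and kingdom.
    Fan-out parameters control clustering strength in the derived A.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def chunk(labels: list[str], size: int, prefix: str) -> dict[str, str]:
        shuffled = list(labels)
        rng.shuffle(shuffled)
        return {
            lab: f"{prefix}{i // size + 1:02d}"
            for i, lab in enumerate(shuffled)
        }

    width = len(str(n_species))
    species = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    genus = chunk(species, genus_size, "gen")
    genera = sorted(set(genus.values()))
    family = chunk(genera, family_size, "fam")
    families = sorted(set(family.values()))
    order = chunk(families, order_size, "ord")
    orders = sorted(set(order.values()))
    klass = chunk(orders, class_size, "cls")
    out = []
    for sp in species:
        g = genus[sp]
        f = family[g]
        o = order[f]
        out.append(
            TaxonLineage(
                species=sp,
                taxa=("king01", "phy01", klass[o], o, f, g, sp),
                ranks=DEFAULT_RANKS,
            )
        )
    return out


@dataclass(frozen=True)
class MetaScenario:
    """Truth and design of a simulated meta-analytic dataset.

    Defaults give 40 studies x 2 traits with (2, 3) effect sizes per trait
    (200 records) over 25 species, with hierarchical truth
    (mu, sigma_study, sigma_trait:study, sigma_phylo) = (1.0, 0.5, 0.8, 0.5)
    and per-record sampling variances uniform on ``v_range``.
    """

    n_studies: int = 40
    traits_per_study: int = 2
    records_per_trait: tuple[int, ...] = (2, 3)
    n_species: int = 25
    mu: float = 1.0
    sigma_study: float = 0.5
    sigma_trait_study: float = 0.8
    sigma_phylo: float = 0.5
    v_range: tuple[float, float] = (0.05, 0.3)
    genus_size: int = 3
    family_size: int = 3
    trait_categories: tuple[str, ...] = (
        "growth rate", "body size", "developmental rate", "metabolic rate",
    )
    gradient_categories: tuple[str, ...] = (
        "latitude", "temperature", "elevation", "salinity",
    )
    covariate_effects: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        for name in ("sigma_study", "sigma_trait_study", "sigma_phylo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.v_range[0] <= self.v_range[1]):
            raise ValueError("v_range must be positive and ordered")

    @property
    def n_records(self) -> int:
        per_study = sum(
            self.records_per_trait[k % len(self.records_per_trait)]
            for k in range(self.traits_per_study)
        )
        return self.n_studies * per_study


def _draw_phylo_effects(
    rng: np.random.Generator, a: RelatednessMatrix, sigma: float
) -> np.ndarray:
    w, vec = np.linalg.eigh(a.values)
    root = vec @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    return sigma * (root @ rng.standard_normal(len(a.labels)))


def simulate_meta_dataset(
    meta: MetaScenario, seed: int
) -> tuple[MetaDataset, dict]:
    """Draw effect sizes from the hierarchical truth.

    Returns the dataset and a truth record holding the drawn latent effects,
    the generated taxonomy and its relatedness matrix, for recovery
    assertions.  With all sigmas zero, every d_i ~ N(mu, v_i) exactly.
    """
    rng = np.random.default_rng(seed)
    lineages = random_taxonomy(
        meta.n_species, rng,
        genus_size=meta.genus_size, family_size=meta.family_size,
    )
    a = lineages_to_relatedness(lineages)
    p_eff = _draw_phylo_effects(rng, a, meta.sigma_phylo)
    p_by_species = dict(zip(a.labels, p_eff))

    # cycle a shuffled species list over studies so every species is used
    species_pool = [lin.species for lin in lineages]
    rng.shuffle(species_pool)
    study_species = [
        species_pool[s % meta.n_species] for s in range(meta.n_studies)
    ]
    class_of = {
        lin.species: lin.taxa[lin.ranks.index("class")] for lin in lineages
    }

    rows = []
    u_truth, w_truth = {}, {}
    for s in range(meta.n_studies):
        study = f"study{s + 1:03d}"
        u = rng.normal(0.0, meta.sigma_study)
        u_truth[study] = u
        gradient = meta.gradient_categories[s % len(meta.gradient_categories)]
        sp = study_species[s]
        for k in range(meta.traits_per_study):
            trait = meta.trait_categories[
                (s + k) % len(meta.trait_categories)
            ]
            ts = f"{study}::{trait}"
            w = rng.normal(0.0, meta.sigma_trait_study)
            w_truth[ts] = w
            shift = 0.0
            if meta.covariate_effects:
                shift += meta.covariate_effects.get("trait", {}).get(trait, 0.0)
                shift += meta.covariate_effects.get("gradient", {}).get(gradient, 0.0)
            theta = meta.mu + u + w + p_by_species[sp] + shift
            n_rec = meta.records_per_trait[k % len(meta.records_per_trait)]
            for _ in range(n_rec):
                v = rng.uniform(*meta.v_range)
                rows.append(
                    {
                        "study_id": study,
                        "trait_study": ts,
                        "trait": trait,
                        "gradient": gradient,
                        "taxon_class": class_of[sp],
                        "species": sp,
                        "d": rng.normal(theta, math.sqrt(v)),
                        "v": v,
                        "theta": theta,
                    }
                )
    df = pd.DataFrame(rows)
    data = MetaDataset(
        d=df["d"].to_numpy(),
        v=df["v"].to_numpy(),
        study=df["study_id"].to_numpy(object),
        trait_study=df["trait_study"].to_numpy(object),
        species=df["species"].to_numpy(object),
        covariates=df[["trait", "gradient", "taxon_class"]].copy(),
    )
    truth = {
        "mu": meta.mu,
        "study_species": dict(zip((f"study{s + 1:03d}" for s in range(meta.n_studies)), study_species)),
        "sigma_study": meta.sigma_study,
        "sigma_trait_study": meta.sigma_trait_study,
        "sigma_phylo": meta.sigma_phylo,
        "u": u_truth,
        "w": w_truth,
        "p": p_by_species,
        "theta": df["theta"].to_numpy(),
        "lineages": lineages,
        "relatedness": a,
    }
    return data, truth


def simulate_observations_from_meta(
    meta: MetaScenario,
    seed: int,
    counter_fraction: float = 0.8,
    sigma_resid: float = 1.0,
) -> tuple[list[PopulationObservation], list[TaxonLineage], dict]:
    """Realize a meta-scenario as raw common-garden observation tables.

    Each trait-in-study becomes a two-population experiment whose true polar
    effect equals that group's latent mean theta_ts = mu + u + w + p, with
    as many shared treatments as the scenario assigns effect sizes to the
    trait, so the extraction pipeline (polar selection -> per-treatment
    Hedges' d) recovers the hierarchical structure end to end.  A fraction
    ``counter_fraction`` of experiments is countergradient (the remainder
    cogradient), with environmental spans drawn wide enough to mix over-,
    perfect and under-compensation.
    """
    rng = np.random.default_rng(seed)
    _, truth = simulate_meta_dataset(meta, seed)
    lineages = truth["lineages"]
    class_of = {
        lin.species: lin.taxa[lin.ranks.index("class")] for lin in lineages
    }
    study_species = truth["study_species"]

    observations: list[PopulationObservation] = []
    truth_rows = []
    for s in range(meta.n_studies):
        study = f"study{s + 1:03d}"
        sp = study_species[study]
        gradient = meta.gradient_categories[s % len(meta.gradient_categories)]
        for k in range(meta.traits_per_study):
            trait = meta.trait_categories[(s + k) % len(meta.trait_categories)]
            ts = f"{study}::{trait}"
            theta = meta.mu + truth["u"][study] + truth["w"][ts] \
                + truth["p"][sp]
            n_treat = meta.records_per_trait[k % len(meta.records_per_trait)]
            is_counter = rng.random() < counter_fraction
            # the environmental effect covaries with the genetic one by
            # construction; a lognormal ratio spreads experiments across
            # over-, perfect and under-compensation symmetrically
            e_span = max(0.1, abs(theta) * float(rng.lognormal(0.0, 0.75))) \
                * sigma_resid
            env = {
                float(t): e_span * t / max(n_treat - 1, 1)
                for t in range(n_treat)
            }
            v_target = rng.uniform(*meta.v_range)
            n_cell = max(3, round(2.0 / v_target))
            scen = GradientScenario(
                positions=(0.0, 1.0),
                genetic_effects=(0.0, theta * sigma_resid),
                env_effects=env,
                sigma_resid=sigma_resid,
                n_per_cell=n_cell,
                covariation="counter" if is_counter else "co",
                study_id=study,
                experiment_id=f"{study}_e{k + 1}",
                trait=trait,
                species=sp,
                gradient_type=gradient,
                taxon_class=class_of[sp],
            )
            observations.extend(
                simulate_experiment(scen, seed=int(rng.integers(2**31)))
            )
            truth_rows.append(
                {"study_id": study, "trait": trait, "theta": theta,
                 "covariation": scen.covariation, "e_span": e_span}
            )
    truth_out = dict(truth)
    truth_out["experiments"] = pd.DataFrame(truth_rows)
    return observations, lineages, truth_out
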