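"""End-to-end orchestration: ingest, classify, fit, summarize, compensate.

The pipeline mirrors the meta-analytic chain: observation tables are
validated and grouped into experiments; each experiment's covariation
pattern is classified and non-qualifying experiments (crossing G x E,
plasticity only, too few shared treatments) are excluded with logged
reasons; per-treatment Hedges' d records are extracted for the polar pairs;
a taxonomy-derived relatedness matrix is built for the species involved;
the hierarchical Bayesian model (random-effects-only or metaregression) is
sampled; and for countergradient experiments the compensation analysis is
run at both classification bounds.

Runs are driven by a :class:`RunConfig` holding either real input paths or
a synthetic :class:`~covgrad.synthetic_data.MetaScenario`, and produce a
manifest listing every output file with its SHA-256 checksum, so a run is
reproducible from (config, seed, input checksums) alone.  Writers use fixed
float formatting and sorted keys, so identical configs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import compensation as comp
from .effect_sizes import (
    EffectSizeRecord,
    ExperimentExcluded,
    PatternLabel,
    PopulationObservation,
    classify_covariation_pattern,
    group_experiments,
    per_treatment_effect_sizes,
)
from .hier_meta import (
    MetaDataset,
    ModelSpec,
    PriorSpec,
    diagnostics,
    estimated_marginal_means,
    sample_posterior,
    summarize,
)
from .phylo_vcv import (
    DEFAULT_RANKS,
    TaxonLineage,
    build_taxon_tree,
    tree_to_relatedness,
    write_newick,
)
from .synthetic_data import MetaScenario, simulate_observations_from_meta

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ConvergenceError",
    "RunConfig",
    "read_observations",
    "read_lineages",
    "write_observations",
    "write_effect_sizes",
    "write_summaries",
    "run_pipeline",
    "meta_scenario_from_yaml",
    "run_config_from_yaml",
]

REQUIRED_COLUMNS = (
    "study_id",
    "experiment_id",
    "trait",
    "species",
    "population_id",
    "gradient_position",
    "treatment_level",
    "mean",
    "dispersion",
    "dispersion_type",
    "n",
    "is_home",
)
OPTIONAL_COLUMNS = ("gradient_type", "taxon_class")
FLOAT_FORMAT = "%.6g"

PRESETS = ("re_counter", "re_co", "metaregression")


class SchemaError(ValueError):
    """Input table violates the observation schema; lists itemized errors."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "observation table failed validation:\n  "
            + "\n  ".join(self.errors)
        )


class ConvergenceError(RuntimeError):
    """The sampler failed the split R-hat convergence gate."""


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {x!r}")


def read_observations(path) -> list[PopulationObservation]:
    """Read and validate an observation CSV (one population x treatment cell
    per row).

    Dispersion may be given as a standard deviation (``dispersion_type`` =
    ``sd``) or a standard error (``se``, converted via sd = se * sqrt(n) at
    ingest with a logged provenance note).  All schema violations are
    collected and raised together as :class:`SchemaError`.
    """
    df = pd.read_csv(path, encoding="utf-8")
    errors = [
        f"missing required column: {c!r}"
        for c in REQUIRED_COLUMNS
        if c not in df.columns
    ]
    if errors:
        raise SchemaError(errors)
    out: list[PopulationObservation] = []
    se_rows = 0
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        try:
            dtype = str(row.dispersion_type).strip().lower()
            n = int(row.n)
            disp = float(row.dispersion)
            if dtype == "sd":
                sd = disp
            elif dtype == "se":
                sd = disp * math.sqrt(n)
                se_rows += 1
            else:
                raise ValueError(
                    f"dispersion_type must be 'sd' or 'se', got {dtype!r}"
                )
            key = (
                row.study_id, row.experiment_id, row.trait,
                row.population_id, float(row.treatment_level),
            )
            if key in seen:
                raise ValueError(f"duplicate observation cell {key}")
            seen.add(key)
            out.append(
                PopulationObservation(
                    study_id=str(row.study_id),
                    experiment_id=str(row.experiment_id),
                    trait=str(row.trait),
                    species=str(row.species),
                    population_id=str(row.population_id),
                    gradient_position=float(row.gradient_position),
                    treatment_level=float(row.treatment_level),
                    mean=float(row.mean),
                    sd=float(sd),
                    n=n,
                    is_home=_parse_bool(row.is_home),
                    gradient_type=str(row.gradient_type)
                    if "gradient_type" in df.columns
                    and pd.notna(row.gradient_type) else None,
                    taxon_class=str(row.taxon_class)
                    if "taxon_class" in df.columns
                    and pd.notna(row.taxon_class) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise SchemaError(errors)
    if se_rows:
        logger.info(
            "converted dispersion from SE to SD (sd = se * sqrt(n)) "
            "for %d rows", se_rows,
        )
    return out


def write_observations(path, observations: Iterable[PopulationObservation]) -> None:
    rows = []
    for o in observations:
        r = dataclasses.asdict(o)
        r["dispersion"] = r.pop("sd")
        r["dispersion_type"] = "sd"
        rows.append(r)
    cols = list(REQUIRED_COLUMNS) + [
        c for c in OPTIONAL_COLUMNS if any(r.get(c) is not None for r in rows)
    ]
    pd.DataFrame(rows)[cols].to_csv(
        path, index=False, float_format=FLOAT_FORMAT, encoding="utf-8"
    )


def read_lineages(path, ranks: Sequence[str] = DEFAULT_RANKS) -> list[TaxonLineage]:
    """Read a lineage CSV: a ``species`` column plus one column per rank."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("species", *ranks) if c not in df.columns]
    if missing:
        raise SchemaError([f"missing required column: {c!r}" for c in missing])
    out = []
    for row in df.to_dict("records"):  # rank names may shadow keywords
        taxa = {
            r: (None if pd.isna(row[r]) else str(row[r])) for r in ranks
        }
        out.append(TaxonLineage.from_mapping(str(row["species"]), taxa, ranks))
    return out


def write_lineages(path, lineages: Sequence[TaxonLineage]) -> None:
    ranks = lineages[0].ranks
    rows = [
        {"species": lin.species, **dict(zip(ranks, lin.taxa))}
        for lin in lineages
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_effect_sizes(path, records: Sequence[EffectSizeRecord]) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, encoding="utf-8")


def write_summaries(outdir, objects: Mapping[str, object]) -> dict[str, Path]:
    """Write a mapping of name -> DataFrame (CSV) or dict (JSON).

    Writers are deterministic: sorted JSON keys, fixed float formatting.
    Returns the paths written, keyed by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, float_format=FLOAT_FORMAT, encoding="utf-8")
        elif isinstance(obj, Mapping):
            p = outdir / f"{name}.json"
            p.write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=float)
                + "\n",
                encoding="utf-8",
            )
        else:
            raise TypeError(f"cannot write object of type {type(obj)!r}")
        paths[name] = p
    return paths


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``observations_path``, ``scenario``) must be set;
    lineages are read from ``lineages_path`` for real input and generated
    alongside synthetic observations otherwise.
    """

    outdir: str
    seed: int = 0
    preset: str = "re_counter"
    observations_path: str | None = None
    lineages_path: str | None = None
    scenario: MetaScenario | None = None
    chains: int = 4
    iterations: int = 2000
    warmup: int | None = None
    thin: int = 1
    priors: PriorSpec | None = None
    negligible_d: float = 0.2
    compensation_bounds: tuple[float, float] = (0.5, 0.2)
    rhat_threshold: float = 1.05
    store_effects: bool = False

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")
        has_real = self.observations_path is not None
        if has_real == (self.scenario is not None):
            raise ValueError(
                "exactly one of observations_path and scenario must be set"
            )
        if has_real and self.lineages_path is None:
            raise ValueError("real input requires lineages_path")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _model_spec(config: RunConfig) -> ModelSpec:
    if config.priors is not None:
        priors = config.priors
    elif config.preset == "metaregression":
        priors = PriorSpec(coef_scale=2.0)
    else:
        priors = PriorSpec()
    fixed = ("trait", "gradient", "taxon_class") \
        if config.preset == "metaregression" else ()
    return ModelSpec(fixed=fixed, priors=priors)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return (and write) the run manifest.

    Stages: ingest -> pattern classification and filtering -> per-treatment
    effect sizes -> taxonomy/relatedness -> model fit -> posterior summaries
    (plus estimated marginal means for the metaregression preset) ->
    compensation (countergradient subset).  Raises
    :class:`ConvergenceError` when any split R-hat exceeds the configured
    threshold, after writing diagnostics.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("covgrad")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    inputs: dict[str, str] = {}
    try:
        # --- ingest ---
        if config.scenario is not None:
            observations, lineages, _ = simulate_observations_from_meta(
                config.scenario, seed=config.seed
            )
            write_observations(outdir / "observations.csv", observations)
            write_lineages(outdir / "lineages.csv", lineages)
            logger.info(
                "simulated %d observations for %d studies",
                len(observations), config.scenario.n_studies,
            )
        else:
            observations = read_observations(config.observations_path)
            lineages = read_lineages(config.lineages_path)
            inputs[str(config.observations_path)] = _sha256(
                Path(config.observations_path)
            )
            inputs[str(config.lineages_path)] = _sha256(
                Path(config.lineages_path)
            )

        # --- classification / inclusion filtering ---
        experiments = group_experiments(observations)
        wanted = (
            PatternLabel.COGRADIENT
            if config.preset == "re_co"
            else PatternLabel.COUNTERGRADIENT
        )
        kept: dict[tuple, list[PopulationObservation]] = {}
        patterns: dict[tuple, PatternLabel] = {}
        exclusions: list[dict] = []
        for key, cells in sorted(experiments.items()):
            try:
                label = classify_covariation_pattern(
                    cells, negligible_d=config.negligible_d
                )
            except (ExperimentExcluded, ValueError) as exc:
                exclusions.append(
                    {"experiment": list(key), "reason": str(exc)}
                )
                logger.info("excluded %s: %s", key, exc)
                continue
            patterns[key] = label
            if label == wanted:
                kept[key] = cells
            else:
                exclusions.append(
                    {"experiment": list(key),
                     "reason": f"pattern is {label.value}, not {wanted.value}"}
                )
        if not kept:
            raise RuntimeError(
                f"no experiment classified as {wanted.value}; cannot fit"
            )
        logger.info(
            "kept %d/%d experiments with pattern %s",
            len(kept), len(experiments), wanted.value,
        )

        # --- effect sizes ---
        records: list[EffectSizeRecord] = []
        for key, cells in sorted(kept.items()):
            try:
                records.extend(per_treatment_effect_sizes(cells))
            except ExperimentExcluded as exc:
                exclusions.append({"experiment": list(key), "reason": str(exc)})
                logger.info("excluded %s: %s", key, exc)
        write_effect_sizes(outdir / "effect_sizes.csv", records)
        data = MetaDataset.from_records(records)

        # --- taxonomy / relatedness ---
        used = sorted({r.species for r in records})
        lin_by_sp = {lin.species: lin for lin in lineages}
        missing = [s for s in used if s not in lin_by_sp]
        if missing:
            raise SchemaError(
                [f"species without lineage: {s!r}" for s in missing]
            )
        tree = build_taxon_tree([lin_by_sp[s] for s in used])
        write_newick(tree, outdir / "pseudo_tree.nwk")
        a = tree_to_relatedness(tree)
        a.to_dataframe().to_csv(
            outdir / "relatedness.csv", float_format=FLOAT_FORMAT,
            encoding="utf-8",
        )

        # --- model fit ---
        spec = _model_spec(config)
        draws = sample_posterior(
            data, spec, a,
            chains=config.chains, iterations=config.iterations,
            warmup=config.warmup, thin=config.thin, seed=config.seed,
            store_effects=config.store_effects,
        )
        diag = diagnostics(draws)
        outputs: dict[str, pd.DataFrame | dict] = {
            "posterior_summary": summarize(draws),
            "diagnostics": diag,
        }
        if config.preset == "metaregression":
            for cov in spec.fixed:
                outputs[f"emm_{cov}"] = estimated_marginal_means(draws, cov)

        # --- compensation (countergradient experiments only) ---
        counter_keys = [
            k for k, lab in patterns.items()
            if lab == PatternLabel.COUNTERGRADIENT
        ]
        comp_rows = []
        d_comps = []
        for key in sorted(counter_keys):
            try:
                rec = comp.compensation_record(
                    experiments[key], bound=config.compensation_bounds[0],
                    require_countergradient=False,
                )
            except ValueError as exc:
                exclusions.append({"experiment": list(key), "reason": str(exc)})
                logger.info("compensation skipped for %s: %s", key, exc)
                continue
            comp_rows.append(dataclasses.asdict(rec))
            d_comps.append(rec.d_comp)
        if comp_rows:
            outputs["compensation"] = pd.DataFrame(comp_rows).set_index(
                ["study_id", "experiment_id", "trait"]
            )
            outputs["compensation_summary"] = {
                f"bound_{b:g}": comp.compensation_summary(d_comps, bound=b)
                for b in config.compensation_bounds
            }
        outputs["exclusions"] = {"excluded": exclusions}
        paths = write_summaries(outdir, outputs)

        # --- manifest ---
        rhat_max = float(np.nanmax(diag["rhat"].to_numpy())) \
            if diag["rhat"].notna().any() else float("nan")
        artifact_files = sorted(
            p for p in outdir.iterdir()
            if p.is_file() and p.name not in ("run.log", "manifest.json")
        )
        manifest = {
            "config": {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "seed": config.seed,
            "inputs": inputs,
            "n_effect_sizes": len(records),
            "n_experiments_kept": len(kept),
            "n_exclusions": len(exclusions),
            "max_rhat": rhat_max,
            "outputs": {p.name: _sha256(p) for p in artifact_files},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8",
        )
        if np.isfinite(rhat_max) and rhat_max > config.rhat_threshold:
            raise ConvergenceError(
                f"max split R-hat {rhat_max:.3f} exceeds "
                f"{config.rhat_threshold}; diagnostics written to "
                f"{paths['diagnostics']}"
            )
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def meta_scenario_from_yaml(path) -> MetaScenario:
    """Load a :class:`MetaScenario` from a YAML mapping of its fields."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    for key in ("records_per_trait", "v_range", "trait_categories",
                "gradient_categories"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return MetaScenario(**raw)


def run_config_from_yaml(path) -> RunConfig:
    """Load a :class:`RunConfig`; a nested ``scenario`` mapping is inlined."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if isinstance(raw.get("scenario"), Mapping):
        scen = dict(raw["scenario"])
        for key in ("records_per_trait", "v_range", "trait_categories",
                    "gradient_categories"):
            if key in scen and isinstance(scen[key], list):
                scen[key] = tuple(scen[key])
        raw["scenario"] = MetaScenario(**scen)
    if isinstance(raw.get("priors"), Mapping):
        raw["priors"] = PriorSpec(**raw["priors"])
    if isinstance(raw.get("compensation_bounds"), list):
        raw["compensation_bounds"] = tuple(raw["compensation_bounds"])
    return RunConfig(**raw)
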