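"""Hierarchical Bayesian meta-analysis with phylogenetic random effects.

The observation model is the standard normal-normal random-effects
meta-analysis with known sampling variances::

    d_i ~ Normal(theta_i, v_i)
    theta_i = x_i' beta + u_study(i) + w_trait:study(i) + p_species(i)
    u_j ~ Normal(0, sigma_u^2)          (study intercepts)
    w_k ~ Normal(0, sigma_w^2)          (trait-within-study intercepts)
    p   ~ MVN(0, sigma_p^2 * A)         (phylogenetic species intercepts)

with Normal priors on the fixed effects and half-Student-t priors on each
random-effect standard deviation.  The fixed part is either an intercept
alone (random-effects-only model, the pooled effect size) or an intercept
plus treatment-coded categorical moderators (metaregression).

Sampling is by a blocked Gibbs sampler.  All location blocks (beta, u, w, p)
are conjugate normal updates; the half-t scale priors are handled with the
Huang-Wand inverse-gamma scale-mixture augmentation, which makes the
variance updates conjugate as well while leaving the marginal prior on each
sigma exactly half-t(df, scale).  Because v_i are known, no observation-level
residual variance is estimated.

The heterogeneity statistic tau is reported per draw as
sqrt(sigma_u^2 + sigma_w^2) — the combined non-phylogenetic random-effect
standard deviation — and summarized alongside the individual components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_sizes import EffectSizeRecord
from .phylo_vcv import RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MetaDataset",
    "PriorSpec",
    "ModelSpec",
    "PosteriorDraws",
    "log_posterior",
    "sample_posterior",
    "summarize",
    "estimated_marginal_means",
    "diagnostics",
]

RANDOM_TERMS = ("study", "trait_study", "phylo")


@dataclass(frozen=True)
class MetaDataset:
    """Effect sizes with their grouping factors and moderators.

    ``covariates`` holds categorical moderator columns (e.g. trait category,
    gradient type, taxonomic class) aligned with the effect-size vectors.
    """

    d: np.ndarray
    v: np.ndarray
    study: np.ndarray
    trait_study: np.ndarray
    species: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.d)
        for name in ("v", "study", "trait_study", "species"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length of {name} does not match d")
        if n and not np.all(np.asarray(self.v) > 0):
            raise ValueError("all sampling variances must be > 0")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate table length does not match d")

    def __len__(self) -> int:
        return len(self.d)

    @classmethod
    def from_records(cls, records: Sequence[EffectSizeRecord]) -> "MetaDataset":
        d = np.array([r.d for r in records], dtype=float)
        v = np.array([r.v for r in records], dtype=float)
        study = np.array([r.study_id for r in records], dtype=object)
        trait_study = np.array(
            [f"{r.study_id}::{r.trait}" for r in records], dtype=object
        )
        species = np.array([r.species for r in records], dtype=object)
        cov = pd.DataFrame(
            {
                "trait": [r.trait for r in records],
                "gradient": [r.gradient_type or "unknown" for r in records],
                "taxon_class": [r.taxon_class or "unknown" for r in records],
            }
        )
        return cls(d=d, v=v, study=study, trait_study=trait_study,
                   species=species, covariates=cov)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MetaDataset":
        cov_cols = [c for c in ("trait", "gradient", "taxon_class") if c in df]
        return cls(
            d=df["d"].to_numpy(float),
            v=df["v"].to_numpy(float),
            study=df["study_id"].to_numpy(object),
            trait_study=df["trait_study"].to_numpy(object)
            if "trait_study" in df
            else (df["study_id"].astype(str) + "::" + df["trait"].astype(str)).to_numpy(object),
            species=df["species"].to_numpy(object),
            covariates=df[cov_cols].reset_index(drop=True) if cov_cols else None,
        )


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    ``intercept_scale`` may be ``inf`` for an improper flat intercept prior.
    Random-effect standard deviations get half-Student-t(``sd_df``,
    ``sd_scale``) priors.
    """

    intercept_loc: float = 0.0
    intercept_scale: float = 5.0
    coef_loc: float = 0.0
    coef_scale: float = 2.0
    sd_df: float = 3.0
    sd_scale: float = 2.5

    def __post_init__(self) -> None:
        for name in ("intercept_scale", "coef_scale", "sd_df", "sd_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Model definition: fixed-effect design, random terms, priors.

    ``fixed`` names categorical moderator columns of the dataset (empty for
    the intercept-only random-effects model).  ``random`` selects among
    {"study", "trait_study", "phylo"}.  ``fixed_sigma`` pins selected
    random-effect s.d.s to known values (0 removes the term's variability;
    used for degenerate-limit checks).  ``reference_levels`` sets the
    treatment-coding baseline per moderator (default: first sorted level).
    """

    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = RANDOM_TERMS
    priors: PriorSpec = field(default_factory=PriorSpec)
    reference_levels: Mapping[str, str] = field(default_factory=dict)
    fixed_sigma: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term in self.random:
            if term not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {term!r}")
        for term, val in self.fixed_sigma.items():
            if term not in RANDOM_TERMS:
                raise ValueError(f"fixed_sigma for unknown term {term!r}")
            if val < 0:
                raise ValueError("fixed sigma must be >= 0")


@dataclass(frozen=True)
class DesignInfo:
    """Column layout of the fixed-effect design matrix."""

    columns: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]]
    reference: Mapping[str, str]


def build_design(
    data: MetaDataset, spec: ModelSpec
) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + treatment-coded dummies for each categorical moderator."""
    n = len(data)
    cols = ["intercept"]
    mats = [np.ones((n, 1))]
    levels: dict[str, tuple[str, ...]] = {}
    reference: dict[str, str] = {}
    for cov in spec.fixed:
        if data.covariates is None or cov not in data.covariates:
            raise ValueError(f"moderator {cov!r} not present in dataset")
        vals = data.covariates[cov].astype(str)
        levs = tuple(sorted(vals.unique()))
        ref = spec.reference_levels.get(cov, levs[0])
        if ref not in levs:
            raise ValueError(f"reference level {ref!r} not a level of {cov!r}")
        levels[cov] = levs
        reference[cov] = ref
        for lev in levs:
            if lev == ref:
                continue
            cols.append(f"{cov}[{lev}]")
            mats.append((vals == lev).to_numpy(float).reshape(-1, 1))
    x = np.hstack(mats) if n else np.zeros((0, len(cols)))
    return x, DesignInfo(tuple(cols), levels, reference)


def _factor(labels: np.ndarray) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(pd.Series(labels, dtype=object), sort=True)
    return codes.astype(int), list(uniques)


@dataclass
class _Layout:
    """Precomputed indices and matrices shared by the sampler and density."""

    x: np.ndarray
    design: DesignInfo
    study_idx: np.ndarray
    study_levels: list
    ts_idx: np.ndarray
    ts_levels: list
    sp_idx: np.ndarray
    sp_levels: list
    a: np.ndarray | None          # relatedness among sp_levels
    a_inv: np.ndarray | None
    prior_mean: np.ndarray
    prior_prec: np.ndarray        # diagonal precisions; 0 => flat
    ts_study: np.ndarray | None = None  # trait_study level -> study level


def _build_layout(
    data: MetaDataset, spec: ModelSpec, a_mat: RelatednessMatrix | None
) -> _Layout:
    x, design = build_design(data, spec)
    study_idx, study_levels = _factor(np.asarray(data.study))
    ts_idx, ts_levels = _factor(np.asarray(data.trait_study))
    sp_idx, sp_levels = _factor(np.asarray(data.species))
    a = a_inv = None
    if "phylo" in spec.random:
        if a_mat is None:
            raise ValueError("phylo random term requires a relatedness matrix")
        missing = [s for s in sp_levels if s not in a_mat.labels]
        if missing:
            raise ValueError(f"species missing from relatedness matrix: {missing}")
        order = [a_mat.labels.index(s) for s in sp_levels]
        a = a_mat.values[np.ix_(order, order)].copy()
        w, vec = np.linalg.eigh(a)
        if w.min() < -1e-10:
            raise ValueError("relatedness matrix is not positive semidefinite")
        # invert on a jittered copy so nearly singular taxonomies stay usable
        a_inv = vec @ np.diag(1.0 / np.maximum(w, 1e-10)) @ vec.T
    pr = spec.priors
    p = x.shape[1]
    prior_mean = np.full(p, pr.coef_loc)
    prior_mean[0] = pr.intercept_loc
    prior_prec = np.full(p, 1.0 / pr.coef_scale**2)
    prior_prec[0] = 0.0 if np.isinf(pr.intercept_scale) else 1.0 / pr.intercept_scale**2
    # trait-within-study nesting map (None if a trait_study level spans
    # several studies, which disables the joint collapsed update)
    ts_study: np.ndarray | None = None
    if len(ts_levels) and len(study_levels) and len(ts_idx):
        ts_study = np.full(len(ts_levels), -1, dtype=int)
        ok = True
        for k, s in zip(ts_idx, study_idx):
            if ts_study[k] == -1:
                ts_study[k] = s
            elif ts_study[k] != s:
                ok = False
                break
        if not ok or np.any(ts_study < 0):
            ts_study = None
    return _Layout(
        x=x, design=design,
        study_idx=study_idx, study_levels=study_levels,
        ts_idx=ts_idx, ts_levels=ts_levels,
        sp_idx=sp_idx, sp_levels=sp_levels,
        a=a, a_inv=a_inv, prior_mean=prior_mean, prior_prec=prior_prec,
        ts_study=ts_study,
    )


def log_posterior(
    state: Mapping[str, np.ndarray | float],
    data: MetaDataset,
    spec: ModelSpec,
    a_mat: RelatednessMatrix | None = None,
) -> float:
    """Unnormalized log posterior density at ``state``.

    ``state`` maps ``"beta"`` to the fixed-effect vector (intercept first),
    ``"u"``/``"w"``/``"p"`` to the random-effect vectors (ordered by sorted
    factor level), and ``"sigma_study"``/``"sigma_trait_study"``/
    ``"sigma_phylo"`` to the s.d.s.  A non-positive free s.d. returns -inf
    (rejected region) rather than raising.
    """
    lay = _build_layout(data, spec, a_mat)
    pr = spec.priors
    beta = np.atleast_1d(np.asarray(state["beta"], dtype=float))
    if beta.shape[0] != lay.x.shape[1]:
        raise ValueError("beta dimension does not match design")

    lp = 0.0
    for k, (mean, prec) in enumerate(zip(lay.prior_mean, lay.prior_prec)):
        if prec > 0:
            lp += stats.norm.logpdf(beta[k], mean, 1.0 / np.sqrt(prec))

    theta = lay.x @ beta if len(data) else np.zeros(0)

    sig_names = {"study": "sigma_study", "trait_study": "sigma_trait_study",
                 "phylo": "sigma_phylo"}
    eff_names = {"study": "u", "trait_study": "w", "phylo": "p"}
    idxs = {"study": lay.study_idx, "trait_study": lay.ts_idx, "phylo": lay.sp_idx}
    sizes = {"study": len(lay.study_levels), "trait_study": len(lay.ts_levels),
             "phylo": len(lay.sp_levels)}
    for term in spec.random:
        fixed = spec.fixed_sigma.get(term)
        sigma = fixed if fixed is not None else float(state[sig_names[term]])
        if fixed is None:
            if sigma <= 0:
                return -np.inf
            lp += np.log(2.0) + stats.t.logpdf(sigma, pr.sd_df, scale=pr.sd_scale)
        eff = np.asarray(state.get(eff_names[term], np.zeros(sizes[term])), float)
        if eff.shape[0] != sizes[term]:
            raise ValueError(f"effect vector for {term!r} has wrong length")
        if sigma == 0.0:
            if np.any(eff != 0):
                return -np.inf
        elif term == "phylo":
            lp += stats.multivariate_normal.logpdf(
                eff, mean=np.zeros(len(eff)), cov=sigma**2 * lay.a,
                allow_singular=True,
            )
        else:
            lp += stats.norm.logpdf(eff, 0.0, sigma).sum()
        if len(data):
            theta = theta + eff[idxs[term]]

    if len(data):
        lp += stats.norm.logpdf(data.d, theta, np.sqrt(data.v)).sum()
    return float(lp)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (chains, draws) per parameter."""

    params: dict[str, np.ndarray]
    design: DesignInfo
    spec: ModelSpec
    seed: int

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format with chain and draw columns."""
        nc, nd = self.n_chains, self.n_draws
        out = {
            "chain": np.repeat(np.arange(nc), nd),
            "draw": np.tile(np.arange(nd), nc),
        }
        for name, arr in self.params.items():
            out[name] = arr.reshape(-1)
        return pd.DataFrame(out)


def _invgamma_draw(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _slice_step(rng, x0, logf, w=1.0, max_steps=50):
    """One univariate stepping-out slice-sampling update."""
    y = logf(x0) - rng.exponential()
    left = x0 - w * rng.uniform()
    right = left + w
    j = max_steps
    while j > 0 and logf(left) > y:
        left -= w
        j -= 1
    j = max_steps
    while j > 0 and logf(right) > y:
        right += w
        j -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _canonical_order(data: MetaDataset) -> np.ndarray:
    """Deterministic record ordering, so summaries are permutation-invariant."""
    return np.lexsort(
        (
            np.asarray(data.d, float),
            np.asarray(data.v, float),
            np.asarray(data.species, dtype="U64"),
            np.asarray(data.trait_study, dtype="U64"),
            np.asarray(data.study, dtype="U64"),
        )
    )


def sample_posterior(
    data: MetaDataset,
    spec: ModelSpec,
    a_mat: RelatednessMatrix | None = None,
    *,
    chains: int = 4,
    iterations: int = 2000,
    warmup: int | None = None,
    thin: int = 1,
    seed: int = 0,
    store_effects: bool = False,
) -> PosteriorDraws:
    """Blocked Gibbs sampler for the hierarchical meta-analysis model.

    Retains ``chains * (iterations - warmup) / thin`` draws (``warmup``
    defaults to ``iterations // 2``).  Reproducible given ``seed``: each
    chain uses an independent stream spawned from (seed, chain index), and
    updates are order-independent across records (grouped reductions), so
    permuting the dataset rows leaves the draws unchanged.

    With ``store_effects=True`` the per-level random effects are retained as
    ``u[<level>]``/``w[<level>]``/``p[<species>]`` parameters.
    """
    if warmup is None:
        warmup = iterations // 2
    if not 0 <= warmup < iterations:
        raise ValueError("need 0 <= warmup < iterations")
    if len(data):
        order = _canonical_order(data)
        data = replace(
            data,
            d=np.asarray(data.d)[order],
            v=np.asarray(data.v)[order],
            study=np.asarray(data.study)[order],
            trait_study=np.asarray(data.trait_study)[order],
            species=np.asarray(data.species)[order],
            covariates=data.covariates.iloc[order].reset_index(drop=True)
            if data.covariates is not None else None,
        )
    lay = _build_layout(data, spec, a_mat)
    pr = spec.priors
    n = len(data)
    p_fix = lay.x.shape[1]
    w_inv = 1.0 / np.asarray(data.v, float) if n else np.zeros(0)
    d_obs = np.asarray(data.d, float)

    n_study = len(lay.study_levels)
    n_ts = len(lay.ts_levels)
    n_sp = len(lay.sp_levels)

    terms = {
        "study": dict(size=n_study, idx=lay.study_idx),
        "trait_study": dict(size=n_ts, idx=lay.ts_idx),
        "phylo": dict(size=n_sp, idx=lay.sp_idx),
    }
    active = [t for t in RANDOM_TERMS if t in spec.random]

    n_keep = (iterations - warmup) // thin
    names = [f"b_{c}" if c != "intercept" else "b_intercept"
             for c in lay.design.columns]
    sig_name = {"study": "sigma_study", "trait_study": "sigma_trait_study",
                "phylo": "sigma_phylo"}
    out: dict[str, np.ndarray] = {nm: np.empty((chains, n_keep)) for nm in names}
    for t in active:
        out[sig_name[t]] = np.empty((chains, n_keep))
    out["tau"] = np.empty((chains, n_keep))
    eff_keys: dict[str, list[str]] = {}
    if store_effects:
        pref = {"study": "u", "trait_study": "w", "phylo": "p"}
        lev = {"study": lay.study_levels, "trait_study": lay.ts_levels,
               "phylo": lay.sp_levels}
        for t in active:
            eff_keys[t] = [f"{pref[t]}[{l}]" for l in lev[t]]
            for k in eff_keys[t]:
                out[k] = np.empty((chains, n_keep))

    xtw = lay.x.T * w_inv if n else np.zeros((p_fix, 0))
    xtwx = xtw @ lay.x if n else np.zeros((p_fix, p_fix))

    for chain in range(chains):
        rng = np.random.default_rng([int(seed), chain])
        beta = lay.prior_mean.copy()
        eff = {t: np.zeros(terms[t]["size"]) for t in RANDOM_TERMS}
        sigma2 = {}
        aux = {}
        for t in active:
            fx = spec.fixed_sigma.get(t)
            sigma2[t] = fx**2 if fx is not None else pr.sd_scale**2
            aux[t] = 1.0 / pr.sd_scale**2
        keep = 0
        for it in range(iterations):
            contrib = {
                t: (eff[t][terms[t]["idx"]] if n and terms[t]["size"] else 0.0)
                for t in RANDOM_TERMS
            }
            # --- fixed effects ---
            if n:
                resid = d_obs - contrib["study"] - contrib["trait_study"] - contrib["phylo"]
                prec = xtwx + np.diag(lay.prior_prec)
                b = xtw @ resid + lay.prior_prec * lay.prior_mean
            else:
                if np.any(lay.prior_prec == 0):
                    raise ValueError("flat priors require data")
                prec = np.diag(lay.prior_prec)
                b = lay.prior_prec * lay.prior_mean
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(chol.T, np.linalg.solve(chol, b))
            beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p_fix))
            xb = lay.x @ beta if n else np.zeros(0)

            # --- study and trait-within-study blocks ---
            # Scales are updated collapsed: the per-group precision-weighted
            # means z are sufficient, and with the group effects integrated
            # out the marginal likelihood of each sigma is cheap (the nested
            # study covariance is rank-one, handled by Sherman-Morrison per
            # study).  Each sigma is slice-sampled on the log scale against
            # its inverse-gamma conditional prior p(sigma^2 | aux)
            # (Huang-Wand augmentation); effects are then drawn conjugately,
            # u with w still integrated, then w given u.  The collapsed
            # moves avoid the funnel and the sigma_u/sigma_w trade-off that
            # stall purely centered Gibbs.
            both_nested = (
                "study" in spec.random and "trait_study" in spec.random
                and n_study > 0 and n_ts > 0 and lay.ts_study is not None
            )
            if n == 0:
                for t in ("study", "trait_study"):
                    if t not in spec.random:
                        continue
                    if spec.fixed_sigma.get(t) is None:
                        sigma2[t] = _invgamma_draw(
                            rng, 0.5 * pr.sd_df, pr.sd_df * aux[t]
                        )
                    eff[t] = rng.normal(
                        0.0, np.sqrt(sigma2[t]), terms[t]["size"]
                    )
            elif both_nested:
                resid = d_obs - xb - contrib["phylo"]
                prec_k = np.bincount(lay.ts_idx, weights=w_inv, minlength=n_ts)
                z_k = np.bincount(lay.ts_idx, weights=resid * w_inv,
                                  minlength=n_ts) / prec_k
                inv_prec_k = 1.0 / prec_k

                def _nested_loglik(su2: float, sw2: float) -> float:
                    dvar = sw2 + inv_prec_k
                    s1 = np.bincount(lay.ts_study, weights=1.0 / dvar,
                                     minlength=n_study)
                    sz = np.bincount(lay.ts_study, weights=z_k / dvar,
                                     minlength=n_study)
                    sz2 = np.bincount(lay.ts_study, weights=z_k**2 / dvar,
                                      minlength=n_study)
                    denom = 1.0 + su2 * s1
                    return float(
                        -0.5 * np.sum(np.log(dvar))
                        - 0.5 * np.sum(np.log(denom))
                        - 0.5 * np.sum(sz2 - su2 * sz**2 / denom)
                    )

                if spec.fixed_sigma.get("study") is None:
                    def logf_u(x):
                        return (
                            _nested_loglik(np.exp(2.0 * x), sigma2["trait_study"])
                            - pr.sd_df * x
                            - pr.sd_df * aux["study"] * np.exp(-2.0 * x)
                        )

                    x0 = 0.5 * np.log(max(sigma2["study"], 1e-12))
                    sigma2["study"] = np.exp(2.0 * _slice_step(rng, x0, logf_u))
                if spec.fixed_sigma.get("trait_study") is None:
                    def logf_w(x):
                        return (
                            _nested_loglik(sigma2["study"], np.exp(2.0 * x))
                            - pr.sd_df * x
                            - pr.sd_df * aux["trait_study"] * np.exp(-2.0 * x)
                        )

                    x0 = 0.5 * np.log(max(sigma2["trait_study"], 1e-12))
                    sigma2["trait_study"] = np.exp(
                        2.0 * _slice_step(rng, x0, logf_w)
                    )
                # u | sigmas, z (w integrated out)
                if sigma2["study"] == 0.0:
                    eff["study"][:] = 0.0
                else:
                    dvar = sigma2["trait_study"] + inv_prec_k
                    prec_u = 1.0 / sigma2["study"] + np.bincount(
                        lay.ts_study, weights=1.0 / dvar, minlength=n_study
                    )
                    mean_u = np.bincount(
                        lay.ts_study, weights=z_k / dvar, minlength=n_study
                    ) / prec_u
                    eff["study"] = mean_u + rng.standard_normal(
                        n_study) / np.sqrt(prec_u)
                # w | u, sigma_w, z
                if sigma2["trait_study"] == 0.0:
                    eff["trait_study"][:] = 0.0
                else:
                    prec_w = prec_k + 1.0 / sigma2["trait_study"]
                    mean_w = (z_k - eff["study"][lay.ts_study]) * prec_k / prec_w
                    eff["trait_study"] = mean_w + rng.standard_normal(
                        n_ts) / np.sqrt(prec_w)
                contrib["study"] = eff["study"][lay.study_idx]
                contrib["trait_study"] = eff["trait_study"][lay.ts_idx]
            else:
                for t in ("study", "trait_study"):
                    if t not in spec.random or terms[t]["size"] == 0:
                        continue
                    idx = terms[t]["idx"]
                    others = sum(contrib[o] for o in RANDOM_TERMS if o != t)
                    resid = d_obs - xb - others
                    prec_j = np.bincount(idx, weights=w_inv,
                                         minlength=terms[t]["size"])
                    z_j = np.bincount(idx, weights=resid * w_inv,
                                      minlength=terms[t]["size"]) / prec_j
                    if spec.fixed_sigma.get(t) is None:
                        var_j = 1.0 / prec_j

                        def logf(x, z_j=z_j, var_j=var_j, t=t):
                            tot = var_j + np.exp(2.0 * x)
                            return (
                                -0.5 * float(np.sum(np.log(tot) + z_j**2 / tot))
                                - pr.sd_df * x
                                - pr.sd_df * aux[t] * np.exp(-2.0 * x)
                            )

                        x0 = 0.5 * np.log(max(sigma2[t], 1e-12))
                        sigma2[t] = np.exp(2.0 * _slice_step(rng, x0, logf))
                    if sigma2[t] == 0.0:
                        eff[t][:] = 0.0
                        contrib[t] = np.zeros(n)
                        continue
                    post_prec = prec_j + 1.0 / sigma2[t]
                    mean_j = z_j * prec_j / post_prec
                    eff[t] = mean_j + rng.standard_normal(
                        terms[t]["size"]) / np.sqrt(post_prec)
                    contrib[t] = eff[t][idx]

            # --- phylogenetic block (collapsed scale + joint MVN draw) ---
            if "phylo" in spec.random and n_sp:
                idx = lay.sp_idx
                free = spec.fixed_sigma.get("phylo") is None
                if n:
                    resid = d_obs - xb - contrib["study"] - contrib["trait_study"]
                    prec_s = np.bincount(idx, weights=w_inv, minlength=n_sp)
                    z_s = np.bincount(idx, weights=resid * w_inv,
                                      minlength=n_sp) / prec_s
                    if free:
                        d_var = np.diag(1.0 / prec_s)

                        def logf_p(x, z_s=z_s, d_var=d_var):
                            cov = np.exp(2.0 * x) * lay.a + d_var
                            c = np.linalg.cholesky(cov)
                            half = np.linalg.solve(c, z_s)
                            return (
                                -float(np.sum(np.log(np.diag(c))))
                                - 0.5 * float(half @ half)
                                - pr.sd_df * x
                                - pr.sd_df * aux["phylo"] * np.exp(-2.0 * x)
                            )

                        x0 = 0.5 * np.log(max(sigma2["phylo"], 1e-12))
                        sigma2["phylo"] = np.exp(
                            2.0 * _slice_step(rng, x0, logf_p)
                        )
                elif free:
                    sigma2["phylo"] = _invgamma_draw(
                        rng, 0.5 * pr.sd_df, pr.sd_df * aux["phylo"]
                    )
                if sigma2["phylo"] == 0.0:
                    eff["phylo"][:] = 0.0
                    contrib["phylo"] = np.zeros(n) if n else 0.0
                else:
                    prec_m = lay.a_inv / sigma2["phylo"]
                    if n:
                        prec_m = prec_m + np.diag(prec_s)
                        b_p = z_s * prec_s
                    else:
                        b_p = np.zeros(n_sp)
                    cholp = np.linalg.cholesky(prec_m)
                    mean_p = np.linalg.solve(cholp.T, np.linalg.solve(cholp, b_p))
                    eff["phylo"] = mean_p + np.linalg.solve(
                        cholp.T, rng.standard_normal(n_sp)
                    )
                    contrib["phylo"] = eff["phylo"][idx] if n else 0.0

            # --- auxiliary scale-mixture variables ---
            for t in active:
                if spec.fixed_sigma.get(t) is not None:
                    continue
                aux[t] = 1.0 / _invgamma_draw(
                    rng, 0.5 * (pr.sd_df + 1.0),
                    pr.sd_df / sigma2[t] + 1.0 / pr.sd_scale**2,
                )

            if n:
                # location interweaving: the likelihood only sees
                # intercept + block means, so resample the split
                # (mu, eff) -> (mu - delta, eff + delta) from its exact
                # conditional; decorrelates the intercept from the blocks.
                for t in active:
                    m = terms[t]["size"]
                    if m == 0 or sigma2[t] <= 0:
                        continue
                    if t == "phylo":
                        prec_d = float(lay.a_inv.sum()) / sigma2[t]
                        b_d = -float(lay.a_inv.sum(axis=0) @ eff[t]) / sigma2[t]
                    else:
                        prec_d = m / sigma2[t]
                        b_d = -float(eff[t].sum()) / sigma2[t]
                    prec_d += lay.prior_prec[0]
                    b_d += lay.prior_prec[0] * (beta[0] - lay.prior_mean[0])
                    delta = b_d / prec_d + rng.standard_normal() / np.sqrt(prec_d)
                    beta[0] -= delta
                    eff[t] = eff[t] + delta
                xb = lay.x @ beta if n else np.zeros(0)

            if it >= warmup and (it - warmup) % thin == 0:
                for k, nm in enumerate(names):
                    out[nm][chain, keep] = beta[k]
                for t in active:
                    out[sig_name[t]][chain, keep] = np.sqrt(sigma2[t])
                su2 = sigma2.get("study", 0.0) if "study" in spec.random else 0.0
                sw2 = sigma2.get("trait_study", 0.0) if "trait_study" in spec.random else 0.0
                out["tau"][chain, keep] = np.sqrt(su2 + sw2)
                if store_effects:
                    for t in active:
                        for k, nm in enumerate(eff_keys[t]):
                            out[nm][chain, keep] = eff[t][k]
                keep += 1
        if not np.all(np.isfinite(beta)):
            raise FloatingPointError("sampler diverged to a non-finite state")

    return PosteriorDraws(params=out, design=lay.design, spec=spec, seed=int(seed))


def summarize(draws: PosteriorDraws | Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Posterior mean, median and central 95% interval per parameter."""
    params = draws.params if isinstance(draws, PosteriorDraws) else dict(draws)
    rows = []
    for name, arr in params.items():
        flat = np.asarray(arr).reshape(-1)
        if flat.size < 100:
            warnings.warn(
                f"only {flat.size} retained draws for {name!r}; "
                "summaries will be noisy",
                stacklevel=2,
            )
        q = np.quantile(flat, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "median": q[1],
                "q2.5": q[0],
                "q97.5": q[2],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def estimated_marginal_means(
    draws: PosteriorDraws,
    covariate: str,
    quantiles: Sequence[float] = (0.025, 0.25, 0.75, 0.975),
) -> pd.DataFrame:
    """Posterior estimated marginal means for one categorical moderator.

    Per draw, the linear predictor is evaluated on the full reference grid
    (all level combinations of the model's moderators, equal weights, random
    effects at zero) and averaged over the other moderators' levels.  The
    result is coding-invariant: changing the treatment-coding reference
    level does not change the EMMs.
    """
    design = draws.design
    if covariate not in design.levels:
        raise ValueError(f"covariate {covariate!r} is not in the model")
    import itertools

    covs = list(design.levels)
    grid = list(itertools.product(*(design.levels[c] for c in covs)))
    cols = design.columns
    g = np.zeros((len(grid), len(cols)))
    g[:, 0] = 1.0
    col_index = {c: k for k, c in enumerate(cols)}
    for r, combo in enumerate(grid):
        for c, lev in zip(covs, combo):
            key = f"{c}[{lev}]"
            if key in col_index:
                g[r, col_index[key]] = 1.0
    beta = np.stack(
        [draws.params["b_intercept" if c == "intercept" else f"b_{c}"].reshape(-1)
         for c in cols]
    )  # (p, ndraws)
    pred = g @ beta  # (cells, ndraws)
    ci = covs.index(covariate)
    rows = []
    for lev in design.levels[covariate]:
        mask = np.array([combo[ci] == lev for combo in grid])
        emm = pred[mask].mean(axis=0)
        row = {"level": lev, "mean": emm.mean(), "median": np.median(emm)}
        for q in quantiles:
            row[f"q{100 * q:g}"] = np.quantile(emm, q)
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


def diagnostics(draws: PosteriorDraws | Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk ESS per parameter (via ArviZ)."""
    import arviz as az

    params = draws.params if isinstance(draws, PosteriorDraws) else dict(draws)
    rows = []
    single = next(iter(params.values())).shape[0] < 2
    if single:
        warnings.warn("R-hat requires >= 2 chains; reporting ESS only",
                      stacklevel=2)
    for name, arr in params.items():
        arr = np.asarray(arr)
        if np.allclose(arr, arr.reshape(-1)[0]):
            rows.append({"parameter": name, "rhat": np.nan, "ess_bulk": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = np.nan if single else float(az.rhat(arr))
            ess = float(az.ess(arr))
        rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess})
    return pd.DataFrame(rows).set_index("parameter")
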