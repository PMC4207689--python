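"""Bayesian model selection for allele-specific expression.

Two model comparisons drive the pipeline:

* **Imprinting scan** on the four reciprocal-F1 allele series. The null
  model holds the within-cross allelic difference (Cast allele minus B6
  allele, natural-log scale) equal in both crosses; the imprinting model
  forces equal magnitude but opposite sign. Their marginal-likelihood
  ratio is the imprinting Bayes factor.

* **Four-way regulatory classification** on F0 plus pooled F1 data.
  ``conserved`` fixes the F0 strain difference (delta0) and the F1 allelic
  difference (delta1) to zero; ``cis`` ties them (delta0 = delta1 = delta,
  free); ``trans`` frees delta0 with delta1 = 0; ``cis_and_trans`` frees
  both.

Every model is a Gaussian linear model with known heteroscedastic
observation noise (the per-observation posterior sd reported by the
quantifier, optionally inflated in quadrature by a residual sd) and
independent zero-mean Gaussian priors on baselines and effects, so the
marginal likelihood is a closed-form multivariate-Gaussian density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

#: Sample classes: F0 homozygotes and the four F1 cross x allele series.
#: ``F1i`` is the B6 male x Cast female cross (Cast allele maternal),
#: ``F1r`` the reciprocal; the trailing letter is the strain of the allele.
GROUPS = ("F0_B6", "F0_CAST", "F1i_B", "F1i_C", "F1r_B", "F1r_C")
F0_GROUPS = ("F0_B6", "F0_CAST")
F1_GROUPS = ("F1i_B", "F1i_C", "F1r_B", "F1r_C")

#: Regulatory models, in the fixed order used for log-marginal vectors.
MODELS = ("conserved", "cis", "trans", "cis_and_trans")

#: Bayes-factor tiers for the imprinting scan. The ``possible`` tier
#: (BF strictly greater than 3) is the exclusion threshold applied before
#: the four-way classification.
IMPRINTING_TIERS = (("extreme", 30.0), ("high", 10.0), ("possible", 3.0))


class SingularModelError(ValueError):
    """Marginal covariance is not positive definite (degenerate priors/sds)."""


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the Gaussian-marginal model comparison.

    Parameters
    ----------
    baseline_prior_sd
        Prior sd (natural-log scale) of the nuisance group baselines.
        Vague by construction: must be at least 10x the effect prior sd.
    effect_prior_sd
        Prior sd (natural-log scale) of the regulatory effects
        (delta0, delta1, imprinting effect m).
    residual_sd
        Extra gene-level noise added in quadrature to each observation's
        reported posterior sd.
    """

    baseline_prior_sd: float = 10.0
    effect_prior_sd: float = 1.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.baseline_prior_sd > 0 and self.effect_prior_sd > 0):
            raise ValueError("prior sds must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if not np.isfinite([self.baseline_prior_sd, self.effect_prior_sd,
                            self.residual_sd]).all():
            raise ValueError("prior parameters must be finite")
        if self.baseline_prior_sd < 10 * self.effect_prior_sd:
            raise ValueError(
                "baseline prior must be vague: baseline_prior_sd >= "
                "10 * effect_prior_sd")


@dataclass
class ImprintingCall:
    """Imprinting evidence for one gene."""

    gene_id: str
    log_bayes_factor: float
    direction: str  # maternal | paternal | none
    posterior_m: float
    rank: int | None = None

    @property
    def bayes_factor(self) -> float:
        try:
            return math.exp(self.log_bayes_factor)
        except OverflowError:
            return math.inf


@dataclass
class ModelPosterior:
    """Four-way model comparison result for one gene."""

    gene_id: str
    log_marginal: dict[str, float] = field(default_factory=dict)
    posterior: dict[str, float] = field(default_factory=dict)
    winner: str = "unclassified"
    excluded_reason: str = "none"


def log_marginal_likelihood(
    y: Sequence[float],
    obs_sd: Sequence[float],
    design: np.ndarray,
    prior_sd: Sequence[float],
    residual_sd: float = 0.0,
) -> float:
    """Closed-form log marginal likelihood of a Gaussian linear model.

    The coefficient vector has independent N(0, prior_sd_j^2) priors, so
    marginally ``y ~ N(0, X diag(prior_sd^2) X' + diag(obs_sd^2 + residual_sd^2))``.

    Raises
    ------
    SingularModelError
        If the marginal covariance is not positive definite. This is an
        explicit failure: no silent regularization is applied.
    """
    y = np.asarray(y, dtype=float)
    obs_sd = np.asarray(obs_sd, dtype=float)
    design = np.asarray(design, dtype=float)
    prior_sd = np.asarray(prior_sd, dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(obs_sd).all()
            and np.isfinite(prior_sd).all()):
        raise ValueError("non-finite inputs to log_marginal_likelihood")
    noise = obs_sd**2 + residual_sd**2
    cov = (design * prior_sd**2) @ design.T + np.diag(noise)
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularModelError(f"singular marginal covariance: {exc}") from exc
    z = linalg.solve_triangular(chol, y, lower=True)
    return (-0.5 * y.size * math.log(2 * math.pi)
            - np.log(np.diag(chol)).sum()
            - 0.5 * float(z @ z))


def _posterior_coefficients(
    y: np.ndarray,
    obs_sd: np.ndarray,
    design: np.ndarray,
    prior_sd: np.ndarray,
    residual_sd: float,
) -> np.ndarray:
    """Posterior mean of the coefficients of the Gaussian linear model."""
    noise = obs_sd**2 + residual_sd**2
    xw = design.T / noise
    precision = xw @ design + np.diag(1.0 / prior_sd**2)
    return linalg.solve(precision, xw @ y, assume_a="pos")


def _series(gene_df: pd.DataFrame, groups: Iterable[str]):
    sub = gene_df[gene_df["group"].isin(list(groups))]
    return (sub["log_mean"].to_numpy(float),
            sub["log_sd"].to_numpy(float),
            sub["group"].to_numpy())


def four_model_design(groups: np.ndarray, model: str,
                      prior: PriorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and per-coefficient prior sds for one regulatory model.

    Columns: F0 baseline, F1 baseline (both crosses pooled, allele-level),
    then the model's free effects on the Cast side.
    """
    f0 = np.isin(groups, F0_GROUPS).astype(float)
    f1 = np.isin(groups, F1_GROUPS).astype(float)
    cast_f0 = (groups == "F0_CAST").astype(float)
    cast_f1 = np.isin(groups, ("F1i_C", "F1r_C")).astype(float)
    cols = [f0, f1]
    sds = [prior.baseline_prior_sd, prior.baseline_prior_sd]
    if model == "conserved":
        pass
    elif model == "cis":
        cols.append(cast_f0 + cast_f1)          # delta0 = delta1 = delta
        sds.append(prior.effect_prior_sd)
    elif model == "trans":
        cols.append(cast_f0)                    # delta0 free, delta1 = 0
        sds.append(prior.effect_prior_sd)
    elif model == "cis_and_trans":
        cols.extend([cast_f0, cast_f1])         # delta0, delta1 free
        sds.extend([prior.effect_prior_sd, prior.effect_prior_sd])
    else:
        raise ValueError(f"unknown model {model!r}")
    return np.column_stack(cols), np.asarray(sds)


def four_model_log_marginals(gene_df: pd.DataFrame,
                             prior: PriorConfig) -> dict[str, float]:
    """Log marginal likelihoods of the four regulatory models for one gene."""
    y, sd, groups = _series(gene_df, GROUPS)
    out = {}
    for model in MODELS:
        design, prior_sd = four_model_design(groups, model, prior)
        out[model] = log_marginal_likelihood(y, sd, design, prior_sd,
                                             prior.residual_sd)
    return out


def imprinting_designs(groups: np.ndarray,
                       prior: PriorConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Null and imprinting designs for the reciprocal-F1 comparison.

    Both have per-cross baselines. The null adds one shared allelic
    difference d (Cast minus B6 in both crosses); the imprinting model adds
    one effect m entering as +m in the B6xCast cross and -m in the
    reciprocal cross.
    """
    base_i = np.isin(groups, ("F1i_B", "F1i_C")).astype(float)
    base_r = np.isin(groups, ("F1r_B", "F1r_C")).astype(float)
    cast_i = (groups == "F1i_C").astype(float)
    cast_r = (groups == "F1r_C").astype(float)
    tb, te = prior.baseline_prior_sd, prior.effect_prior_sd
    null = (np.column_stack([base_i, base_r, cast_i + cast_r]),
            np.array([tb, tb, te]))
    imprint = (np.column_stack([base_i, base_r, cast_i - cast_r]),
               np.array([tb, tb, te]))
    return {"null": null, "imprinting": imprint}


def imprinting_bayes_factor(
    gene_df: pd.DataFrame,
    prior: PriorConfig,
    direction_threshold: float = 3.0,
) -> ImprintingCall | None:
    """Imprinting-vs-null Bayes factor for one gene's F1 series.

    Returns None (explicit absence) if any of the four F1 group series is
    missing. The sign of the posterior mean of m maps to parental
    direction through cross orientation: in the B6 male x Cast female
    cross the Cast allele is maternal, so m > 0 means the maternal allele
    is the more expressed one.
    """
    gene_id = str(gene_df["gene_id"].iloc[0])
    present = set(gene_df["group"])
    if not set(F1_GROUPS) <= present:
        return None
    y, sd, groups = _series(gene_df, F1_GROUPS)
    designs = imprinting_designs(groups, prior)
    lm = {name: log_marginal_likelihood(y, sd, X, psd, prior.residual_sd)
          for name, (X, psd) in designs.items()}
    log_bf = lm["imprinting"] - lm["null"]
    X, psd = designs["imprinting"]
    post_m = float(_posterior_coefficients(y, sd, X, psd,
                                           prior.residual_sd)[-1])
    if log_bf < math.log(direction_threshold):
        direction = "none"
    else:
        direction = "maternal" if post_m > 0 else "paternal"
    return ImprintingCall(gene_id=gene_id, log_bayes_factor=log_bf,
                          direction=direction, posterior_m=post_m)


def imprinting_tier(bayes_factor: float) -> str:
    """Tier label for an imprinting Bayes factor (>=30 extreme, >=10 high,
    >3 possible, else none; the possible tier marks downstream exclusion)."""
    for label, threshold in IMPRINTING_TIERS:
        if label == "possible":
            if bayes_factor > threshold:
                return label
        elif bayes_factor >= threshold:
            return label
    return "none"


def classify_imprinting(
    measurements: pd.DataFrame,
    prior: PriorConfig | None = None,
    direction_threshold: float = 3.0,
) -> pd.DataFrame:
    """Rank polymorphic genes by imprinting Bayes factor.

    Returns a table (gene_id, log_bayes_factor, bayes_factor, posterior_m,
    direction, tier, rank) sorted by descending Bayes factor; rank is
    1-based. Genes with missing F1 series are skipped with a logged count.
    """
    prior = prior or PriorConfig()
    if measurements.empty:
        raise ValueError("empty dataset")
    rows, skipped = [], 0
    poly = measurements[measurements["polymorphic"]]
    for gene_id, gene_df in poly.groupby("gene_id", sort=True):
        call = imprinting_bayes_factor(gene_df, prior, direction_threshold)
        if call is None:
            skipped += 1
            continue
        rows.append({
            "gene_id": call.gene_id,
            "log_bayes_factor": call.log_bayes_factor,
            "bayes_factor": call.bayes_factor,
            "posterior_m": call.posterior_m,
            "direction": call.direction,
            "tier": imprinting_tier(call.bayes_factor),
        })
    if skipped:
        logger.info("imprinting scan: skipped %d genes with missing F1 series",
                    skipped)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no genes with complete F1 data")
    out = out.sort_values("log_bayes_factor", ascending=False,
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def posteriors_from_log_marginals(log_marginals: Mapping[str, float],
                                  ) -> dict[str, float]:
    """Posterior model probabilities under an equal 1/4 prior, computed in
    log space with max-subtraction."""
    keys = list(log_marginals)
    lm = np.array([log_marginals[k] for k in keys], dtype=float)
    if np.all(np.isneginf(lm)):
        raise ValueError("all model marginals are -inf")
    lm = lm - lm.max()
    w = np.exp(lm)
    w /= w.sum()
    return dict(zip(keys, w.tolist()))


def select_winner(posterior: Mapping[str, float]) -> tuple[str, str]:
    """Apply the confidence rule: the winner needs posterior > 0.5 and at
    least twice the second-best posterior. Returns (winner, reason)."""
    ordered = sorted(posterior.items(), key=lambda kv: kv[1], reverse=True)
    (best, p1), (_, p2) = ordered[0], ordered[1]
    if p1 > 0.5 and p1 >= 2 * p2:
        return best, "none"
    return "unclassified", "low_confidence"


def classify_gene(
    gene_df: pd.DataFrame,
    prior: PriorConfig | None = None,
    imprinting_bf: float | None = None,
    imprinting_bf_threshold: float = 3.0,
) -> ModelPosterior:
    """Four-way regulatory classification of one gene.

    Pre-filters: non-polymorphic genes and genes with imprinting Bayes
    factor strictly above the threshold are excluded before any model is
    scored; genes missing a required group series are unclassifiable.
    """
    prior = prior or PriorConfig()
    gene_id = str(gene_df["gene_id"].iloc[0])
    if not bool(gene_df["polymorphic"].iloc[0]):
        return ModelPosterior(gene_id, excluded_reason="nonpolymorphic")
    if imprinting_bf is not None and imprinting_bf > imprinting_bf_threshold:
        return ModelPosterior(gene_id, excluded_reason="imprinted_bf_gt_3")
    if not set(GROUPS) <= set(gene_df["group"]):
        return ModelPosterior(gene_id, excluded_reason="missing_group")
    log_marginal = four_model_log_marginals(gene_df, prior)
    posterior = posteriors_from_log_marginals(log_marginal)
    winner, reason = select_winner(posterior)
    return ModelPosterior(gene_id, log_marginal=log_marginal,
                          posterior=posterior, winner=winner,
                          excluded_reason=reason)


def classify_dataset(
    measurements: pd.DataFrame,
    prior: PriorConfig | None = None,
    imprinting: pd.DataFrame | None = None,
    imprinting_bf_threshold: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Classify every gene and summarize category counts.

    Exclusions are applied in pipeline order: non-polymorphic genes first,
    then genes with imprinting Bayes factor > threshold, then the
    posterior-confidence rule. ``imprinting`` is the table produced by
    :func:`classify_imprinting`; if None, the scan is run here.

    Returns
    -------
    table : DataFrame
        One row per gene: log-marginals, posteriors, winner,
        excluded_reason.
    summary : dict
        Counts of excluded genes by reason, per-category counts and
        proportions over confidently classified genes.
    """
    prior = prior or PriorConfig()
    if imprinting is None:
        try:
            imprinting = classify_imprinting(measurements, prior)
        except ValueError:
            imprinting = pd.DataFrame(columns=["gene_id", "bayes_factor"])
    bf_map = dict(zip(imprinting["gene_id"], imprinting["bayes_factor"]))
    rows = []
    for gene_id, gene_df in measurements.groupby("gene_id", sort=True):
        res = classify_gene(gene_df, prior, bf_map.get(str(gene_id)),
                            imprinting_bf_threshold)
        row = {"gene_id": res.gene_id, "winner": res.winner,
               "excluded_reason": res.excluded_reason}
        for m in MODELS:
            row[f"log_marginal_{m}"] = res.log_marginal.get(m, np.nan)
            row[f"posterior_{m}"] = res.posterior.get(m, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    classified = table[table["winner"] != "unclassified"]
    counts = classified["winner"].value_counts().to_dict()
    n_classified = int(len(classified))
    summary = {
        "n_genes": int(len(table)),
        "n_classified": n_classified,
        "excluded": table.loc[table["winner"] == "unclassified",
                              "excluded_reason"].value_counts().to_dict(),
        "counts": {m: int(counts.get(m, 0)) for m in MODELS},
        "proportions": {m: (counts.get(m, 0) / n_classified
                            if n_classified else None) for m in MODELS},
    }
    return table, summary
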