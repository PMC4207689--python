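import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from cistrans.models import GROUPS


def make_gene_df(delta0=0.0, delta1=0.0, m=0.0, baseline_f0=2.0,
                 baseline_f1=1.3, sd=0.05, replicates=3, noise_sd=None,
                 seed=0, gene_id="g1", polymorphic=True):
    """Replicate-level table for one gene with configured true effects.

    delta0: F0 Cast-minus-B6 difference; delta1: shared F1 allelic
    difference; m: imprinting effect (+ = Cast allele up in the B6xCast
    cross, down in the reciprocal). noise_sd defaults to sd.
    """
    rng = np.random.default_rng(seed)
    noise_sd = sd if noise_sd is None else noise_sd
    means = {
        "F0_B6": baseline_f0,
        "F0_CAST": baseline_f0 + delta0,
        "F1i_B": baseline_f1,
        "F1i_C": baseline_f1 + delta1 + m,
        "F1r_B": baseline_f1,
        "F1r_C": baseline_f1 + delta1 - m,
    }
    rows = []
    for group in GROUPS:
        for r in range(replicates):
            rows.append({
                "gene_id": gene_id, "group": group, "replicate": r + 1,
                "log_mean": means[group] + rng.normal(0, noise_sd),
                "log_sd": sd, "polymorphic": polymorphic,
            })
    return pd.DataFrame(rows)


def mc_log_marginal(y, obs_sd, design, prior_sd, rng, n_draws=200_000):
    """Prior-sampling Monte-Carlo estimate of the Gaussian-model log
    marginal likelihood, with a delta-method standard error on the log."""
    y = np.asarray(y, float)
    obs_sd = np.asarray(obs_sd, float)
    design = np.asarray(design, float)
    prior_sd = np.asarray(prior_sd, float)
    beta = rng.normal(size=(n_draws, prior_sd.size)) * prior_sd
    loglik = norm.logpdf(y, beta @ design.T, obs_sd).sum(axis=1)
    estimate = logsumexp(loglik) - np.log(n_draws)
    w = np.exp(loglik - loglik.max())
    se_log = w.std() / (w.mean() * np.sqrt(n_draws))
    return estimate, se_log


@pytest.fixture
def gene_df_factory():
    return make_gene_df
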