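"""Posterior summary tables shared by both models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .checking import effective_sample_size, probability_of_direction, rhat


def summarize_posterior(posterior) -> pd.DataFrame:
    """Per-parameter summary: mean, sd, 2.5/50/97.5% quantiles, rhat,
    ess and the posterior probability of a positive effect.

    Works on any posterior object exposing ``param_names`` and a
    ``chains(name)`` accessor (occupancy and GLMM posteriors both do).
    """
    rows = []
    for name in posterior.param_names:
        ch = np.asarray(posterior.chains(name), dtype=float)
        pooled = ch.reshape(-1)
        q = np.quantile(pooled, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": pooled.mean(),
                "sd": pooled.std(ddof=1),
                "q2.5": q[0],
                "q50": q[1],
                "q97.5": q[2],
                "rhat": rhat(ch) if ch.shape[0] >= 2 and ch.shape[1] >= 4 else np.nan,
                "ess": effective_sample_size(ch)
                if ch.shape[0] >= 2 and ch.shape[1] >= 4
                else np.nan,
                "prob_direction": probability_of_direction(pooled),
            }
        )
    return pd.DataFrame(rows)


def draws_to_long(posterior) -> pd.DataFrame:
    """Flat (chain, iteration, parameter, value) export of all draws."""
    nc, nk, npar = posterior.draws.shape
    chains = np.repeat(np.arange(nc), nk * npar)
    iters = np.tile(np.repeat(np.arange(nk), npar), nc)
    params = np.tile(np.asarray(posterior.param_names), nc * nk)
    return pd.DataFrame(
        {
            "chain": chains,
            "iteration": iters,
            "parameter": params,
            "value": posterior.draws.reshape(-1),
        }
    )
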