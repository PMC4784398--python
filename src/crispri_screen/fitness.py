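"""Per-guide fitness from sequencing counts, with resampling uncertainty.

The abundance statistic is the log2-scale median-centered count

    l = log2(c + 0.5) - median over guides in the pool of log2(c' + 0.5)

computed separately for each (pool, sample).  Because count statistics are
noisy at low abundance, each l carries an empirical variance obtained by
resampling: the posterior read frequency of a guide with count c in a
sample with C total pool reads and N pool guides is Gamma(c + 0.5) with
rate (C + 0.5 N); frequency draws are converted back to the centered log2
statistic (the observed pool median held fixed) and their sample variance
is reported.  Guide fitness is then modeled as f ~ Normal(l, s^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CountMatrix

DEFAULT_DRAWS = 1000


def log_median_center(counts: CountMatrix, pool: str, sample: str) -> pd.Series:
    """Median-centered log2 counts for one pool in one sample."""
    if sample not in counts.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    if counts.samples.loc[sample, "pool"] != pool:
        raise KeyError(f"sample {sample!r} does not belong to pool {pool!r}")
    c = counts.pool_counts(sample)
    if len(c) == 0:
        raise KeyError(f"pool {pool!r} has no guides")
    logc = np.log2(c + 0.5)
    return logc - np.median(logc)


def posterior_count_variance(
    c: int,
    total: int,
    n_guides: int,
    n_draws: int = DEFAULT_DRAWS,
    seed=None,
    rng: np.random.Generator | None = None,
) -> float:
    """Resampling variance of the centered log2 count statistic.

    Draws ``n_draws`` posterior read frequencies from
    Gamma(shape=c + 0.5, rate=total + 0.5 * n_guides), converts each to a
    resampled count ``freq * total`` and returns the sample variance of
    log2(count + 0.5).  The pool median is a constant under this scheme
    (only the focal guide is resampled), so it drops out of the variance.
    """
    if total <= 0 or n_guides <= 0:
        raise ValueError("total reads and pool size must be positive")
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    freq = rng.gamma(c + 0.5, 1.0 / (total + 0.5 * n_guides), size=n_draws)
    draws = np.log2(freq * total + 0.5)
    return float(draws.var(ddof=1))


def _posterior_variances(
    counts: np.ndarray, total: int, n_guides: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized resampling variance for all guides of one sample."""
    shape = counts[:, None] + 0.5
    freq = rng.gamma(shape, 1.0 / (total + 0.5 * n_guides), size=(len(counts), n_draws))
    draws = np.log2(freq * total + 0.5)
    return draws.var(axis=1, ddof=1)


def guide_fitness(
    counts: CountMatrix, n_draws: int = DEFAULT_DRAWS, seed: int | None = 0
) -> pd.DataFrame:
    """Fitness table: one Normal(mean, variance) per (guide, sample).

    Returns a DataFrame with columns guide_id, sample, pool, count, mean,
    variance; within each (pool, sample) the median of means is zero by
    construction.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for sample in counts.sample_ids:
        pool = counts.samples.loc[sample, "pool"]
        c = counts.pool_counts(sample)
        total = int(c.sum())
        n = len(c)
        logc = np.log2(c.to_numpy() + 0.5)
        means = logc - np.median(logc)
        if total > 0:
            variances = _posterior_variances(c.to_numpy(), total, n, n_draws, rng)
        else:
            variances = np.full(n, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "guide_id": c.index,
                    "sample": sample,
                    "pool": pool,
                    "count": c.to_numpy(),
                    "mean": means,
                    "variance": variances,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
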