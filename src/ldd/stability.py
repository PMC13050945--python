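"""Sample-size adequacy and subsampling stability of the probability estimator.

Two complementary tools:

* closed-form proportion-estimation arithmetic — the sample size needed for
  a margin of error E at a confidence level (``n >= Z^2 p(1-p)/E^2``, worst
  case p = 1/2) and its inverse (the margin achieved by a given n);
* a subsampling simulation — for sample sizes s_i = 10, 20, ..., the
  conditional probability of a chosen discourse–emotion pair is estimated
  on many random sentence subsets per size; the mean-per-size curve, its
  cumulative and rolling standard deviations, and the relative standard
  error RSE = (std/sqrt(n))/mu (in percent) quantify how quickly the
  estimate stabilizes.  RSE below 1 / 5 / 10 percent is conventionally
  labelled high / good / adequate stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import AnnotatedCorpus, ValidationError
from .relation import LabelSetPair, pair_contributions

__all__ = [
    "required_sample_size",
    "margin_of_error",
    "subsample_estimates",
    "cumulative_std",
    "rolling_std",
    "relative_standard_error",
    "stability_regime",
    "StabilityCurve",
    "stability_curve",
    "DEFAULT_SIZES",
]

#: The study grid: sizes 10, 20, ..., 260.
DEFAULT_SIZES: tuple[int, ...] = tuple(range(10, 261, 10))


def _z_score(confidence_level: float) -> float:
    if not (0.0 < confidence_level < 1.0):
        raise ValidationError("confidence level must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + confidence_level / 2.0))


def required_sample_size(
    confidence_level: float = 0.90,
    margin: float = 0.05,
    p_expected: float = 0.5,
    z_score: float | None = None,
) -> tuple[float, int]:
    """Sample size for estimating a proportion to within ``margin``.

    Returns ``(n_real, ceil(n_real))`` with ``n_real = Z^2 p(1-p)/E^2``.
    The worst case uses p = 1/2.  ``z_score`` overrides the two-sided
    normal quantile implied by ``confidence_level`` (the convention rounds
    Z to e.g. 1.645 at 90%).
    """
    if margin <= 0:
        raise ValidationError("margin must be positive")
    if not (0.0 <= p_expected <= 1.0):
        raise ValidationError("p_expected must be in [0, 1]")
    z = z_score if z_score is not None else _z_score(confidence_level)
    n = z * z * p_expected * (1.0 - p_expected) / (margin * margin)
    return n, ceil(n)


def margin_of_error(
    n: float,
    confidence_level: float = 0.90,
    p_expected: float = 0.5,
    z_score: float | None = None,
) -> float:
    """Margin of error E = Z sqrt(p(1-p)/n); inverse of the size formula."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    z = z_score if z_score is not None else _z_score(confidence_level)
    return float(z * sqrt(p_expected * (1.0 - p_expected) / n))


def subsample_estimates(
    corpus: AnnotatedCorpus,
    pair: LabelSetPair,
    sizes: Sequence[int] = DEFAULT_SIZES,
    n_reps: int = 1000,
    seed: int | None = None,
    mapping: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean conditional-probability estimate per subsample size.

    For each size s, ``n_reps`` uniform subsets of s included sentences are
    drawn without replacement; the estimator is evaluated on each and the
    defined estimates are averaged.  Draws on which the pair's emotion set
    is absent (undefined conditional) are dropped and counted.

    Returns
    -------
    means : ndarray, shape (len(sizes),)
        NaN where every draw was undefined.
    dropped : ndarray of int
        Undefined draws per size.
    """
    included = corpus.included()
    total = len(included)
    sizes = list(sizes)
    if not sizes or min(sizes) < 1:
        raise ValidationError("sizes must be positive")
    if max(sizes) > total:
        raise ValidationError(
            f"largest size {max(sizes)} exceeds corpus size {total}"
        )
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    num, den = pair_contributions(corpus, pair, mapping)
    means = np.full(len(sizes), np.nan)
    dropped = np.zeros(len(sizes), dtype=int)
    for i, s in enumerate(sizes):
        estimates = np.empty(n_reps)
        defined = 0
        for _ in range(n_reps):
            idx = rng.choice(total, size=s, replace=False)
            d = den[idx].sum()
            if d > 0:
                estimates[defined] = num[idx].sum() / d
                defined += 1
        dropped[i] = n_reps - defined
        if defined:
            means[i] = estimates[:defined].mean()
    return means, dropped


def cumulative_std(series: Sequence[float]) -> np.ndarray:
    """Sample std over growing prefixes: c_1 = 0, c_k = std(p_1..p_k)."""
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValidationError("empty series")
    out = np.zeros(series.size)
    for k in range(2, series.size + 1):
        out[k - 1] = np.std(series[:k], ddof=1)
    return out


def rolling_std(series: Sequence[float], window: int = 10) -> np.ndarray:
    """Sample std over sliding windows: r_j = std(p_j..p_{j+w-1})."""
    series = np.asarray(series, dtype=float)
    if window < 2:
        raise ValidationError("window must be >= 2")
    if window > series.size:
        raise ValidationError("window exceeds series length")
    return np.array(
        [np.std(series[j : j + window], ddof=1)
         for j in range(series.size - window + 1)]
    )


def relative_standard_error(
    std: float,
    n: float,
    mu: float,
    denominator: str = "sqrt_n",
) -> float:
    """RSE in percent: 100 * std / (sqrt(n) * mu).

    ``denominator="n"`` selects the literal std/(n*mu) reading instead of
    the standard definition.
    """
    if mu <= 0:
        raise ValidationError("mu must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if denominator == "sqrt_n":
        scale = sqrt(n)
    elif denominator == "n":
        scale = n
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    return 100.0 * std / (scale * mu)


def stability_regime(rse_percent: float) -> str:
    """Classify an RSE (percent): high (<1), good (<5), adequate (<10), unstable."""
    if rse_percent < 0:
        raise ValidationError("RSE cannot be negative")
    if rse_percent < 1.0:
        return "high"
    if rse_percent < 5.0:
        return "good"
    if rse_percent < 10.0:
        return "adequate"
    return "unstable"


@dataclass
class StabilityCurve:
    """Per-size mean estimates with dispersion and RSE series."""

    pair: LabelSetPair
    sizes: np.ndarray
    means: np.ndarray
    dropped: np.ndarray
    cum_std: np.ndarray
    roll_std: np.ndarray
    rse_cumulative: np.ndarray
    rse_rolling: np.ndarray
    mu: float
    window: int
    n_reps: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        k = len(self.sizes)
        offset = k - len(self.roll_std)
        roll = np.full(k, np.nan)
        roll[offset:] = self.roll_std
        rse_roll = np.full(k, np.nan)
        rse_roll[offset:] = self.rse_rolling
        return pd.DataFrame(
            {
                "size": self.sizes,
                "mean": self.means,
                "cum_std": self.cum_std,
                "roll_std": roll,
                "rse_cum": self.rse_cumulative,
                "rse_roll": rse_roll,
                "regime": [stability_regime(v) if np.isfinite(v) else ""
                           for v in self.rse_cumulative],
                "dropped_reps": self.dropped,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def stability_curve(
    corpus: AnnotatedCorpus,
    pair: LabelSetPair,
    sizes: Sequence[int] = DEFAULT_SIZES,
    n_reps: int = 1000,
    window: int = 10,
    seed: int | None = None,
    mapping: Mapping[str, float] | None = None,
    rse_denominator: str = "sqrt_n",
) -> StabilityCurve:
    """Run the full subsampling study for one discourse–emotion pair.

    RSE series use each point's own sample size s_i as n and the grand mean
    of the per-size estimates as mu.
    """
    sizes_arr = np.asarray(list(sizes), dtype=int)
    means, dropped = subsample_estimates(
        corpus, pair, sizes_arr, n_reps=n_reps, seed=seed, mapping=mapping
    )
    if np.isnan(means).any():
        raise ValidationError(
            "some sizes yielded no defined estimates; use larger sizes or "
            "a more frequent emotion set"
        )
    mu = float(means.mean())
    c = cumulative_std(means)
    r = rolling_std(means, window=window)
    rse_c = np.array(
        [relative_standard_error(c[i], sizes_arr[i], mu, rse_denominator)
         for i in range(len(sizes_arr))]
    )
    rse_r = np.array(
        [relative_standard_error(r[j], sizes_arr[j + window - 1], mu, rse_denominator)
         for j in range(len(r))]
    )
    return StabilityCurve(
        pair=pair,
        sizes=sizes_arr,
        means=means,
        dropped=dropped,
        cum_std=c,
        roll_std=r,
        rse_cumulative=rse_c,
        rse_rolling=rse_r,
        mu=mu,
        window=window,
        n_reps=n_reps,
        seed=seed,
    )
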