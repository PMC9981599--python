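"""Inferential machinery.

Surrogate nulls are built two ways: by re-pairing infants with
non-partner adults (group-level dyad shuffling, 1000 pairings by
convention) and by time-locking the analysis to randomly inserted events
in the continuous data (event-count matched per participant).  Observed
values are converted to p-values by z-scoring against the null and
reading the Gaussian upper tail.  Time-frequency maps are corrected with
cluster-based permutation statistics (4-connected clusters scored by
mass).  Condition contrasts use a 2x2 repeated-measures ANOVA with
Tukey-Kramer pairwise correction, JZS Bayes factors quantify evidence
for the null, and the power helper converts an r^2 effect size into the
achieved power of a matched-pairs t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "SurrogateNull",
    "ClusterResult",
    "random_derangement",
    "surrogate_dyad_null",
    "surrogate_event_null",
    "zscore_pvalue",
    "cluster_permutation_test",
    "rm_anova_2x2",
    "tukey_kramer_pairwise",
    "jzs_bayes_factor_paired",
    "power_from_r2",
]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SurrogateNull:
    """A null distribution plus the observed statistic it calibrates."""

    label: str
    observed: Optional[np.ndarray]
    null: np.ndarray  # (n_perm, ...) matching observed's shape

    def __post_init__(self):
        self.null = np.asarray(self.null, float)
        if self.null.shape[0] < 2:
            raise ValueError("need at least 2 permutations")
        if not np.isfinite(self.null).all():
            raise ValueError("null samples must be finite")

    @property
    def n_perm(self) -> int:
        return self.null.shape[0]

    @property
    def mean(self):
        return self.null.mean(axis=0)

    @property
    def sd(self):
        return self.null.std(axis=0, ddof=1)

    def percentile(self, q):
        return np.percentile(self.null, q, axis=0)


@dataclass
class ClusterResult:
    """Clusters of supra-threshold (frequency, time) points with corrected p."""

    clusters: list  # dicts: {"indices", "mass", "p", "sign"}
    forming_alpha: float
    alpha: float

    def significant(self, alpha: Optional[float] = None):
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c["p"] < a]

    @property
    def any_significant(self) -> bool:
        return bool(self.significant())

    @property
    def min_p(self) -> float:
        return min((c["p"] for c in self.clusters), default=1.0)


# --------------------------------------------------------------------------
# surrogate nulls


def random_derangement(n: int, rng) -> np.ndarray:
    """A uniform random permutation of 0..n-1 with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def surrogate_dyad_null(
    infants: Sequence,
    adults: Sequence,
    metric_fn: Callable,
    n_perm: int = 1000,
    rng=None,
    label: str = "dyad-surrogate",
) -> SurrogateNull:
    """Group-mean metric under random infant-adult re-pairings.

    ``metric_fn(infant, adult)`` returns a scalar or vector of synchrony
    values for one (possibly shuffled) pairing.  Each permutation pairs
    every infant with a non-partner adult (derangement-sampled) and
    recomputes the group mean; pair metrics are memoised so repeated
    pairings cost nothing.
    """
    n = len(infants)
    if n != len(adults):
        raise ValueError("need equally many infants and adults")
    if n < 2:
        raise ValueError("re-pairing needs at least 2 dyads")
    if rng is None:
        rng = np.random.default_rng()
    cache: dict = {}

    def pair(i: int, j: int):
        if (i, j) not in cache:
            cache[(i, j)] = np.atleast_1d(np.asarray(metric_fn(infants[i], adults[j]), float))
        return cache[(i, j)]

    observed = np.mean([pair(i, i) for i in range(n)], axis=0)
    null = np.empty((n_perm,) + observed.shape)
    for g in range(n_perm):
        perm = random_derangement(n, rng)
        null[g] = np.mean([pair(i, int(perm[i])) for i in range(n)], axis=0)
    return SurrogateNull(label, observed, null)


def valid_onset_samples(n_samples: int, fs: float, window, mask=None) -> np.ndarray:
    """Sample indices where a full epoch fits inside clean data."""
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    lo, hi = pre, n_samples - post
    if hi <= lo:
        return np.array([], dtype=int)
    candidates = np.arange(lo, hi)
    if mask is not None:
        good = np.asarray(mask, bool).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(good)])
        span = pre + post
        ok = (cs[candidates + post] - cs[candidates - pre]) == span
        candidates = candidates[ok]
    return candidates


def surrogate_event_null(
    n_samples: int,
    fs: float,
    n_events: int,
    analysis_fn: Callable,
    window=(-2.5, 2.5),
    n_perm: int = 1000,
    rng=None,
    mask=None,
    label: str = "random-events",
) -> SurrogateNull:
    """Analysis outcome under randomly inserted pseudo-events.

    Per permutation, ``n_events`` onset times are drawn uniformly from
    the sample positions where a full epoch fits in unmasked data
    (event counts matched to the real data), and
    ``analysis_fn(onset_times_s)`` is evaluated.
    """
    if rng is None:
        rng = np.random.default_rng()
    candidates = valid_onset_samples(n_samples, fs, window, mask)
    if len(candidates) < max(n_events, 1):
        raise ValueError("insufficient clean data to place surrogate events")
    null = None
    for g in range(n_perm):
        picks = rng.choice(candidates, size=n_events, replace=len(candidates) < 4 * n_events)
        vals = np.asarray(analysis_fn(np.sort(picks) / fs), float)
        if null is None:
            null = np.empty((n_perm,) + vals.shape)
        null[g] = vals
    return SurrogateNull(label, None, null)


def zscore_pvalue(observed, null, bonferroni: int = 1):
    """One-sided upper-tail Gaussian p for observed vs null samples.

    z = (observed - mean(null)) / sd(null); p = 1 - Phi(z), multiplied by
    ``bonferroni`` (clipped to 1).  Vectorised over trailing axes.
    """
    null = np.asarray(null, float)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate null distribution (zero SD)")
    z = (np.asarray(observed, float) - mu) / sd
    p = sps.norm.sf(z)
    return np.minimum(p * bonferroni, 1.0), z


# --------------------------------------------------------------------------
# cluster-based permutation


def _cluster_masses(exceed: np.ndarray, stat: np.ndarray):
    """4-connected clusters of True points, scored by sum of |stat|."""
    exceed = np.atleast_2d(exceed)
    stat = np.atleast_2d(stat)
    labels, n = ndimage.label(exceed, structure=_FOUR_CONNECTED)
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        mass = float(np.abs(stat[labels == lab]).sum())
        out.append({"indices": idx, "mass": mass})
    return out


def _max_mass(exceed, stat):
    cl = _cluster_masses(exceed, stat)
    return max((c["mass"] for c in cl), default=0.0)


def cluster_test_vs_null(
    observed: np.ndarray,
    null_maps: np.ndarray,
    forming_alpha: float = 0.05,
    alpha: float = 0.05,
) -> ClusterResult:
    """Observed map against permutation maps (one-sided, synchrony above null).

    Pointwise threshold: (1 - forming_alpha) quantile of the null at each
    point.  Cluster mass uses the z-scored map so masses are comparable
    across (f, t); corrected p is the fraction of permutations whose own
    maximum cluster mass reaches the observed cluster's mass.
    """
    observed = np.atleast_2d(np.asarray(observed, float))
    null_maps = np.asarray(null_maps, float)
    n_perm = null_maps.shape[0]
    if n_perm < 200:
        raise ValueError("cluster permutation needs >= 200 permutations")
    thr = np.quantile(null_maps, 1.0 - forming_alpha, axis=0)
    mu = null_maps.mean(axis=0)
    sd = null_maps.std(axis=0, ddof=1)
    sd = np.where(sd <= 0, np.inf, sd)
    z_obs = (observed - mu) / sd
    clusters = _cluster_masses(observed > thr, z_obs)
    null_max = np.array(
        [_max_mass(null_maps[g] > thr, (null_maps[g] - mu) / sd) for g in range(n_perm)]
    )
    for c in clusters:
        c["p"] = float((1 + np.sum(null_max >= c["mass"])) / (1 + n_perm))
        c["sign"] = 1
    clusters.sort(key=lambda c: c["p"])
    return ClusterResult(clusters, forming_alpha, alpha)


def cluster_test_paired(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    forming_alpha: float = 0.05,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
) -> ClusterResult:
    """Paired condition contrast across participants (two-sided t).

    Pointwise paired t across subjects thresholded at ``forming_alpha``
    (two-sided); positive and negative clusters formed separately, mass =
    sum |t|; the permutation distribution flips condition labels within
    subject (sign flips of the differences).
    """
    if n_perm < 200:
        raise ValueError("cluster permutation needs >= 200 permutations")
    if rng is None:
        rng = np.random.default_rng()
    d = np.asarray(maps_a, float) - np.asarray(maps_b, float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    df = n - 1
    tcrit = sps.t.ppf(1 - forming_alpha / 2, df)

    def tmap(x):
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd <= 0, np.inf, sd)
        return x.mean(axis=0) / (sd / np.sqrt(n))

    t_obs = tmap(d)
    clusters = []
    for sign in (1, -1):
        for c in _cluster_masses(sign * t_obs > tcrit, t_obs):
            c["sign"] = sign
            clusters.append(c)
    null_max = np.empty(n_perm)
    for g in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_g = tmap(d * signs.reshape((n,) + (1,) * (d.ndim - 1)))
        null_max[g] = max(_max_mass(t_g > tcrit, t_g), _max_mass(-t_g > tcrit, t_g))
    for c in clusters:
        c["p"] = float((1 + np.sum(null_max >= c["mass"])) / (1 + n_perm))
    clusters.sort(key=lambda c: c["p"])
    return ClusterResult(clusters, forming_alpha, alpha)


def cluster_permutation_test(
    observed=None,
    null_maps=None,
    maps_a=None,
    maps_b=None,
    forming_alpha: float = 0.05,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
) -> ClusterResult:
    """Dispatch to the baseline (vs surrogate maps) or paired-contrast test."""
    if observed is not None and null_maps is not None:
        return cluster_test_vs_null(observed, null_maps, forming_alpha, alpha)
    if maps_a is not None and maps_b is not None:
        return cluster_test_paired(maps_a, maps_b, forming_alpha, alpha, n_perm, rng)
    raise ValueError("provide either (observed, null_maps) or (maps_a, maps_b)")


# --------------------------------------------------------------------------
# parametric / Bayesian group statistics


def _paired_f(contrast: np.ndarray):
    n = len(contrast)
    sd = contrast.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    t = contrast.mean() / (sd / np.sqrt(n))
    f = t * t
    p = float(sps.f.sf(f, 1, n - 1))
    return float(f), p


def rm_anova_2x2(values: np.ndarray, factor_a: str = "gaze_type", factor_b: str = "frequency"):
    """Two-way fully within-subject ANOVA for a (n, 2, 2) cell table.

    For two-level factors each effect has 1 numerator df and its F equals
    the squared paired t of the corresponding difference contrast, which
    is how the decomposition is computed here (exact, not approximate).
    Returns a dict of {effect: {"F", "df", "p"}} plus Tukey-Kramer
    adjusted pairwise cell comparisons.
    """
    x = np.asarray(values, float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise ValueError("values must be (n_subjects, 2, 2)")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    effects = {}
    a_contrast = x[:, 0, :].mean(axis=1) - x[:, 1, :].mean(axis=1)
    b_contrast = x[:, :, 0].mean(axis=1) - x[:, :, 1].mean(axis=1)
    ab_contrast = (x[:, 0, 0] - x[:, 0, 1]) - (x[:, 1, 0] - x[:, 1, 1])
    for name, c in (
        (factor_a, a_contrast),
        (factor_b, b_contrast),
        (f"{factor_a}*{factor_b}", ab_contrast),
    ):
        f, p = _paired_f(c)
        effects[name] = {"F": f, "df": (1, n - 1), "p": p}
    effects["pairwise"] = tukey_kramer_pairwise(x.reshape(n, 4))
    return effects


def tukey_kramer_pairwise(cells: np.ndarray):
    """Tukey-Kramer adjusted pairwise comparisons of within-subject cells.

    ``cells`` is (n_subjects, k).  The error term is the subject-by-cell
    residual MS on (k-1)(n-1) df; p-values come from the studentized
    range distribution with k groups.
    """
    x = np.asarray(cells, float)
    n, k = x.shape
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    df = (k - 1) * (n - 1)
    ms_err = float((resid**2).sum() / df)
    means = x.mean(axis=0)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(ms_err / n)
            q = abs(diff) / se if se > 0 else 0.0
            p = float(sps.studentized_range.sf(q, k, df)) if se > 0 else 1.0
            out.append({"cells": (i, j), "diff": float(diff), "q": q, "p_adj": min(p, 1.0)})
    return out


def jzs_bayes_factor_paired(x, y=None, scale: float = np.sqrt(2) / 2):
    """JZS (Cauchy-prior) Bayes factor for a paired/one-sample t contrast.

    BF10 integrates the noncentral-t likelihood over a Cauchy(0, scale)
    prior on the standardised effect size and divides by the likelihood
    under the point null.  BF01 = 1/BF10.
    """
    d = np.asarray(x, float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    nu = n - 1

    def integrand(delta):
        return sps.nct.pdf(t, nu, delta * np.sqrt(n)) * sps.cauchy.pdf(delta, scale=scale)

    lower, _ = integrate.quad(integrand, -np.inf, 0.0, limit=200)
    upper, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    like_alt = lower + upper
    like_null = sps.t.pdf(t, nu)
    bf10 = float(like_alt / like_null)
    return {"BF10": bf10, "BF01": 1.0 / bf10, "t": t, "n": n}


def power_from_r2(r_squared: float, n: int, alpha: float = 0.05) -> float:
    """Achieved power of a two-sided matched-pairs t test for an r^2 effect.

    r = sqrt(r^2) is converted to Cohen's d = 2r / sqrt(1 - r^2); power
    follows from the noncentral t distribution with ncp = d * sqrt(n).
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    r = np.sqrt(r_squared)
    d = 2 * r / np.sqrt(1 - r_squared)
    ncp = d * np.sqrt(n)
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
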