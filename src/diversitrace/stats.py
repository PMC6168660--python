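"""Repeated-measures statistical battery for diversity scores.

The analysis strategy mirrors common practice for non-Gaussian
within-subject EEG summaries: a Kolmogorov-Smirnov normality screen, the
Friedman rank test as the omnibus, Wilcoxon signed-rank post hocs with
Bonferroni-Holm correction, default-prior (JZS) Bayes factors with the
conventional interpretation bands (0.1 / 0.33 / 3 / 10), a session-order
quartile model for time-on-task effects, and a cluster-based sign-flip
permutation test over channels for topographic contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats as sps

from . import montage
from .errors import (
    DegenerateSignalError,
    DesignError,
    PrecisionError,
    SampleSizeError,
)

__all__ = [
    "ConditionMatrix",
    "check_normality",
    "friedman_test",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "jzs_bf_from_t",
    "jzs_bf_paired",
    "bf_one_way_rm",
    "interpret_bf",
    "quartile_split",
    "cluster_permutation_test",
    "TopographyResult",
]


@dataclass
class ConditionMatrix:
    """Complete subject x condition matrix of per-subject summary scores."""

    values: np.ndarray
    conditions: list[str]
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DesignError("values must be a 2-D subject x condition matrix")
        if self.values.shape[1] != len(self.conditions):
            raise DesignError("condition labels must match matrix columns")
        if np.isnan(self.values).any():
            raise DesignError("incomplete design: matrix contains missing cells")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise DesignError("need at least 2 subjects and 2 conditions")


def check_normality(values, alpha: float = 0.05, cdf=None):
    """One-sample KS test of a score sample against the standard normal.

    The sample is standardized with its own mean and SD first (the classic
    caveat applies: with estimated parameters the test is conservative).
    A custom reference ``cdf`` callable may be supplied, in which case the
    sample is compared to it un-standardized.  Returns
    ``(statistic, p, decision)`` with decision in {"normal", "non-normal"}
    at the given alpha.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise SampleSizeError("normality screen needs at least 4 observations")
    if cdf is not None:
        stat, p = sps.kstest(x, cdf)
        return float(stat), float(p), ("normal" if p >= alpha else "non-normal")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.5, 0.0, "non-normal"
    z = (x - x.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return float(stat), float(p), ("normal" if p >= alpha else "non-normal")


def friedman_test(m: ConditionMatrix | np.ndarray):
    """Friedman rank test: non-parametric repeated-measures omnibus.

    Within-subject midranks; chi-square statistic with df = k - 1 (with the
    standard tie correction).  Returns ``(chi2, df, p)``.  A matrix with no
    rank variation (all conditions identical per subject) yields (0, df, 1).
    """
    values = m.values if isinstance(m, ConditionMatrix) else np.asarray(m, float)
    if np.isnan(values).any():
        raise DesignError("incomplete design")
    n, k = values.shape
    df = k - 1
    if np.all(values == values[:, [0]]):
        return 0.0, df, 1.0
    stat, p = sps.friedmanchisquare(*values.T)
    return float(stat), df, float(p)


def _signed_rank_stats(d: np.ndarray):
    """Rank machinery shared by the exact and approximate Wilcoxon paths."""
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = d.size
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    return ranks, w_plus, mu, sigma2


def wilcoxon_signed_rank(a, b):
    """Two-sided Wilcoxon signed-rank test for paired scores.

    Zero differences are dropped.  For n <= 15 remaining pairs the p-value
    is exact (full enumeration of the 2^n sign assignments, ties included
    via midranks); above that a normal approximation with continuity and
    tie corrections is used.  Returns ``(Z, p)``; Z always comes from the
    approximation so post-hoc tables have a common effect scale.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateSignalError("all paired differences are zero")
    if d.size < 5:
        raise SampleSizeError("need >= 5 non-zero paired differences")
    n = d.size
    ranks, w_plus, mu, sigma2 = _signed_rank_stats(d)
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(sigma2)
    if n <= 15:
        # distribution of 2*W+ over all sign assignments by convolution
        # (doubling makes midranks integral)
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(np.rint(2 * w_plus))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def jzs_bf_from_t(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """Default-prior (JZS) Bayes factor BF10 from a paired/one-sample t.

    The alternative places a Cauchy(0, scale) prior on the standardized
    effect; its marginal likelihood is the noncentral-t density integrated
    over the prior, evaluated by adaptive quadrature (relative tolerance
    1e-8); the null is the central-t density at the observed t.
    """
    if n < 3:
        raise SampleSizeError("need n >= 3 for a Bayes factor")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        val = sps.nct.pdf(t, nu, delta * sqrt_n) * sps.cauchy.pdf(
            delta, 0.0, cauchy_scale
        )
        # scipy's noncentral-t pdf returns nan for extreme noncentrality
        # where the true density has underflowed to zero
        return val if np.isfinite(val) else 0.0

    # split at the prior mode and the likelihood peak so adaptive quadrature
    # cannot step over a narrow peak at large |t| or n
    cuts = sorted({0.0, t / sqrt_n})
    bounds = [-np.inf, *cuts, np.inf]
    with warnings.catch_warnings():
        # roundoff reports from quadpack on the underflowed far tail
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        num = sum(
            integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-9, limit=400)[0]
            for lo, hi in zip(bounds, bounds[1:])
            if lo != hi
        )
    den = sps.t.pdf(t, nu)
    return float(num / den)


def jzs_bf_paired(a, b, cauchy_scale: float = 0.707) -> float:
    """JZS Bayes factor for the difference of paired scores (BF10)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    if d.size < 3:
        raise SampleSizeError("need at least 3 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSignalError("paired differences have zero variance")
    t = d.mean() / (sd / np.sqrt(d.size))
    return jzs_bf_from_t(float(t), int(d.size), cauchy_scale)


@dataclass
class BayesFactorResult:
    bf10: float
    mc_se: float


def bf_one_way_rm(
    m: ConditionMatrix | np.ndarray,
    fixed_scale: float = 0.5,
    random_scale: float = 1.0,
    draws: int = 10_000,
    seed: int = 0,
) -> BayesFactorResult:
    """One-way repeated-measures Bayes factor under default mixed g-priors.

    Compares (subject + condition effects) against (subject effects only),
    with independent scaled inverse-chi-square(1) priors on the effect
    variance ratios: scale ``random_scale`` for subjects, ``fixed_scale``
    for conditions.  The additive balanced design makes the conditional
    marginal likelihood a closed form of the three classical sums of
    squares, so the g integrals are evaluated by seeded Monte Carlo.
    Returns the BF10 estimate with its Monte Carlo standard error.
    """
    values = m.values if isinstance(m, ConditionMatrix) else np.asarray(m, float)
    if np.isnan(values).any():
        raise DesignError("incomplete design")
    if draws < 10_000:
        raise PrecisionError("need at least 10,000 Monte Carlo draws")
    n, k = values.shape
    big_n = n * k
    grand = values.mean()
    row = values.mean(axis=1)
    col = values.mean(axis=0)
    ss_sub = k * np.sum((row - grand) ** 2)
    ss_cond = n * np.sum((col - grand) ** 2)
    ss_err = np.sum((values - row[:, None] - col[None, :] + grand) ** 2)

    rng = np.random.default_rng(seed)
    # g ~ InvGamma(1/2, r^2/2)  <=>  g = r^2 / chi2(1)
    g_s1 = random_scale**2 / rng.chisquare(1, draws)
    g_c1 = fixed_scale**2 / rng.chisquare(1, draws)
    g_s0 = random_scale**2 / rng.chisquare(1, draws)

    def log_f(gs, gc):
        q = ss_sub / (1 + gs * k) + ss_cond / (1 + gc * n) + ss_err
        return (
            -0.5 * (n - 1) * np.log1p(gs * k)
            - 0.5 * (k - 1) * np.log1p(gc * n)
            - 0.5 * (big_n - 1) * np.log(q)
        )

    log_f1 = log_f(g_s1, g_c1)
    log_f0 = (
        -0.5 * (n - 1) * np.log1p(g_s0 * k)
        - 0.5 * (big_n - 1) * np.log(ss_sub / (1 + g_s0 * k) + ss_cond + ss_err)
    )
    shift = max(log_f1.max(), log_f0.max())
    f1 = np.exp(log_f1 - shift)
    f0 = np.exp(log_f0 - shift)
    m1, m0 = f1.mean(), f0.mean()
    bf = m1 / m0
    rel_var = f1.var(ddof=1) / (draws * m1**2) + f0.var(ddof=1) / (draws * m0**2)
    return BayesFactorResult(bf10=float(bf), mc_se=float(bf * np.sqrt(rel_var)))


#: (upper bound, label); boundaries belong to the lower band.
BF_BANDS = [
    (0.1, "strong evidence for the null"),
    (1 / 3, "moderate evidence for the null"),
    (3.0, "inconclusive"),
    (10.0, "moderate evidence for the alternative"),
    (np.inf, "strong evidence for the alternative"),
]


def interpret_bf(bf10: float) -> str:
    """Conventional evidential band for a Bayes factor (cuts at 0.1, 1/3, 3, 10)."""
    if not np.isfinite(bf10) or bf10 <= 0:
        if bf10 == np.inf:
            return BF_BANDS[-1][1]
        raise ValueError("BF10 must be positive")
    for upper, label in BF_BANDS:
        if bf10 <= upper:
            return label
    raise AssertionError("unreachable")


def quartile_split(session_order, n_groups: int = 4) -> np.ndarray:
    """Assign each epoch a session-time quartile (0..3) by recording order.

    The split ignores condition entirely.  Group sizes differ by at most
    one, with remainders going to the earliest quartiles.
    """
    order = np.asarray(session_order)
    if order.size < n_groups:
        raise SampleSizeError(f"need at least {n_groups} epochs to split")
    if order.size != np.unique(order).size:
        raise ValueError("session_order values must be unique within subject")
    rank = np.argsort(np.argsort(order, kind="stable"), kind="stable")
    groups = np.empty(order.size, dtype=int)
    bounds = np.cumsum([len(c) for c in np.array_split(np.arange(order.size), n_groups)])
    groups = np.searchsorted(bounds, rank, side="right")
    return groups


@dataclass
class TopographyResult:
    """Per-channel contrast with cluster-level permutation inference."""

    mean_diff: np.ndarray
    t_values: np.ndarray
    clusters: list[dict] = field(default_factory=list)
    adjacency: np.ndarray | None = None
    n_perm: int = 0
    cluster_alpha: float = 0.05

    def significant_clusters(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["p"] <= alpha]


def _find_clusters(t: np.ndarray, t_crit: float, neighbors) -> list[tuple]:
    """Connected same-sign supra-threshold channel sets with their |t| mass."""
    clusters = []
    for sign in (1.0, -1.0):
        mask = sign * t > t_crit
        visited = np.zeros(t.size, dtype=bool)
        for start in np.flatnonzero(mask):
            if visited[start]:
                continue
            stack = [start]
            comp = []
            visited[start] = True
            while stack:
                c = stack.pop()
                comp.append(c)
                for nb in neighbors[c]:
                    if mask[nb] and not visited[nb]:
                        visited[nb] = True
                        stack.append(int(nb))
            clusters.append((sign, sorted(comp), float(np.abs(t[comp]).sum())))
    return clusters


def cluster_permutation_test(
    diff: np.ndarray,
    positions: np.ndarray | None = None,
    adjacency: np.ndarray | None = None,
    cluster_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> TopographyResult:
    """One-sample cluster-based permutation test over channels.

    ``diff`` is a subject x channel matrix of paired condition differences.
    Channels whose one-sample |t| exceeds the two-sided critical value at
    ``cluster_alpha`` are grouped into connected same-sign clusters under
    the montage adjacency; each cluster's mass (sum of |t|) is compared to
    the permutation null of the maximal cluster mass obtained by randomly
    sign-flipping whole subjects.
    """
    diff = np.asarray(diff, dtype=float)
    n_subj, n_ch = diff.shape
    if n_subj < 5:
        raise SampleSizeError("cluster permutation test needs >= 5 subjects")
    if n_perm < 500:
        raise PrecisionError("need at least 500 permutations")
    if adjacency is None:
        if positions is None:
            raise ValueError("provide electrode positions or an adjacency matrix")
        adjacency = montage.build_adjacency(positions)
    neighbors = montage.neighbor_lists(adjacency)
    t_crit = float(sps.t.ppf(1 - cluster_alpha / 2, df=n_subj - 1))

    ss = np.sum(diff**2, axis=0)  # invariant under subject sign flips

    def t_from_means(mean):
        var = (ss - n_subj * mean**2) / (n_subj - 1)
        var = np.maximum(var, 1e-300)
        return mean / np.sqrt(var / n_subj)

    obs_mean = diff.mean(axis=0)
    obs_t = t_from_means(obs_mean)
    obs_clusters = _find_clusters(obs_t, t_crit, neighbors)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    perm_means = flips @ diff / n_subj
    perm_t = t_from_means(perm_means)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _find_clusters(perm_t[i], t_crit, neighbors)
        if cl:
            null_max[i] = max(mass for _, _, mass in cl)

    clusters = []
    for sign, channels, mass in obs_clusters:
        p = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        clusters.append(
            {"sign": int(sign), "channels": channels, "mass": mass, "p": float(p)}
        )
    clusters.sort(key=lambda c: c["p"])
    return TopographyResult(
        mean_diff=obs_mean,
        t_values=obs_t,
        clusters=clusters,
        adjacency=adjacency,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
    )
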