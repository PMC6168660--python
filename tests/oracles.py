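"""Independent brute-force oracles used to pin the implementations.

Everything here is deliberately naive and shares no code path with the
package: explicit substring scans for LZ76, full enumeration for the rank
tests, and dense fixed-grid quadrature in an alternative parameterization
for the Bayes factor.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


# ------------------------------------------------------------------- LZ76

def _word_reproducible(s: str, p: int, length: int) -> bool:
    """Does s[p:p+length] occur starting anywhere within s[:p+length-1]?"""
    word = s[p : p + length]
    hist = s[: p + length - 1]
    for start in range(len(hist) - length + 1):
        if hist[start : start + length] == word:
            return True
    return False


def lz76_oracle(s) -> int:
    """Exhaustive-history LZ76 word count by explicit position scanning.

    Each word is the shortest extension not copyable from the (extended)
    history; the trailing word counts even if still copyable.
    """
    if not isinstance(s, str):
        s = "".join(str(int(b)) for b in s)
    n = len(s)
    c = 0
    p = 0
    while p < n:
        length = 1
        while p + length <= n and _word_reproducible(s, p, length):
            length += 1
        c += 1
        p += length
    return c


# ---------------------------------------------------------------- Friedman

def friedman_statistic(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    col = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(col**2) - 3.0 * n * (k + 1)


def friedman_exact_p(values: np.ndarray) -> float:
    """Exact permutation p for a small complete matrix: enumerate all
    (k!)^n within-subject rank permutations."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    obs = friedman_statistic(np.vstack([rankdata(row) for row in values]))
    perms = list(itertools.permutations(range(1, k + 1)))
    count = total = 0
    for combo in itertools.product(range(len(perms)), repeat=n):
        ranks = np.array([perms[c] for c in combo], dtype=float)
        total += 1
        if friedman_statistic(ranks) >= obs - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------- Wilcoxon

def wilcoxon_exact_p(d: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [ranks[np.array(signs, dtype=bool)].sum()
         for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ------------------------------------------------------------ JZS quadrature

def jzs_bf_oracle(t: float, n: int, scale: float = 0.707, nodes: int = 400_001) -> float:
    """JZS BF10 by dense fixed-grid quadrature in the g parameterization.

    The Cauchy effect prior is equivalent to g ~ InverseGamma(1/2, scale^2/2)
    on the variance ratio; substituting g = z/(1-z) maps the integral to
    (0, 1) where the trapezoid rule on a dense grid suffices.
    """
    nu = n - 1
    z = np.linspace(1e-10, 1 - 1e-10, nodes)
    g = z / (1 - z)
    jac = 1.0 / (1 - z) ** 2
    prior = (
        (scale**2 / 2) ** 0.5 / np.sqrt(np.pi) * g**-1.5
        * np.exp(-(scale**2) / (2 * g))
    )
    like = (1 + n * g) ** -0.5 * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
    num = np.trapezoid(like * prior * jac, z)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return float(num / den)
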