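"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (brute
force, enumeration, quadrature) and never calls the code paths it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def wilcoxon_exact_brute(a, b) -> float:
    """One-sided rank-sum p-value (a stochastically smaller) by full
    enumeration of group assignments of the pooled sample."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(a)].sum()
    count = 0
    total = 0
    for idx in combinations(range(n), len(a)):
        total += 1
        if ranks[list(idx)].sum() <= obs:
            count += 1
    return count / total


def logistic_newton(x: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 100):
    """Logistic regression (intercept + slope) by straight Newton-Raphson."""
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta  # [intercept, slope]


class LiabilityOracle:
    """Closed-form conditional-risk integration under the
    liability-threshold model with PGS = PB (no score noise).

    Liability L = A + beta*G + e, A ~ N(0, h2_pb), G ~ HWE(f),
    e ~ N(0, 1 - h2_pb - h2_lev); case iff L > t.
    """

    def __init__(self, h2_pb, h2_lev, f, k, threshold, n_grid=20001):
        self.h2_pb, self.h2_lev, self.f, self.k = h2_pb, h2_lev, f, k
        self.t = threshold
        self.beta = np.sqrt(h2_lev / (2 * f * (1 - f))) if h2_lev > 0 else 0.0
        self.se = np.sqrt(1 - h2_pb - h2_lev)
        self.pg = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        sd_a = np.sqrt(h2_pb) if h2_pb > 0 else 1e-9
        self.a = np.linspace(-7, 7, n_grid) * sd_a
        self.fa = stats.norm.pdf(self.a, 0, sd_a)
        # P(case | a, g), shape (3, grid)
        self.pcase = np.array(
            [stats.norm.sf((self.t - self.a - self.beta * g) / self.se) for g in range(3)]
        )
        self.joint = self.pg[:, None] * self.pcase * self.fa[None, :]  # (g, a)

    def case_rate(self) -> float:
        da = self.a[1] - self.a[0]
        return float(self.joint.sum() * da)

    def carrier_risk(self, g: int) -> float:
        """P(case | G = g): PB and residual integrate to N(0, 1-h2_lev)."""
        return float(stats.norm.sf((self.t - self.beta * g) / np.sqrt(1 - self.h2_lev)))

    def or_of_lev(self) -> float:
        """Population odds ratio of carrier (>=1 allele) vs noncarrier."""
        p_carrier = self.pg[1] + self.pg[2]
        p_case_carrier = (
            self.pg[1] * self.carrier_risk(1) + self.pg[2] * self.carrier_risk(2)
        ) / p_carrier
        p_case_noncarrier = self.carrier_risk(0)
        return float(
            (p_case_carrier / (1 - p_case_carrier))
            / (p_case_noncarrier / (1 - p_case_noncarrier))
        )

    def carriers_per_1000_by_bin(self, n_bins=10) -> np.ndarray:
        """Expected carriers per 1000 cases in each case-PB quantile bin."""
        case_density = self.joint.sum(0)
        cum = np.cumsum(case_density)
        cum = cum / cum[-1]
        out = np.empty(n_bins)
        for b in range(n_bins):
            lo, hi = b / n_bins, (b + 1) / n_bins
            m = (cum > lo) & (cum <= hi)
            out[b] = 1000.0 * self.joint[1:, m].sum() / self.joint[:, m].sum()
        return out

    def or_of_pb_topq(self, q: float) -> float:
        """Odds ratio of PB exposure: top-q of the PB distribution vs rest."""
        da = self.a[1] - self.a[0]
        cut = stats.norm.ppf(1 - q, 0, np.sqrt(self.h2_pb))
        exposed = self.a > cut
        dens = self.joint.sum(0)  # case density over a
        marg = self.fa  # population density over a
        p_case_exp = dens[exposed].sum() / marg[exposed].sum()
        p_case_une = dens[~exposed].sum() / marg[~exposed].sum()
        return float((p_case_exp / (1 - p_case_exp)) / (p_case_une / (1 - p_case_une)))
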