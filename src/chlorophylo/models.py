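"""GTR-family nucleotide substitution models with +I and discrete-Gamma rates.

Families form the nested ladder JC, K80, HKY, TIM1, GTR over exchangeability
constraints; rate variation across sites is the usual mixture of a
proportion of invariant sites (+I) and a discrete Gamma (+G) with category
rates equal to the means of equal-probability quantile bins (4 categories by
default).  Generators are scaled so one unit of branch length equals one
expected substitution per site, accounting for both the invariant fraction
and the (mean-one) Gamma categories.

TIM1 is implemented with the constraint AC=GT and AT=CG while AG, CT and
the reference transversion vary freely (the "transitional model" with two
transition rates and two tied transversion pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

FAMILIES = ("JC", "K80", "HKY", "TIM1", "GTR")

# exchangeability order: AC, AG, AT, CG, CT, GT
_EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

#: number of free exchangeability parameters per family (one rate is the scale)
_FAMILY_EXCH_FREE = {"JC": 0, "K80": 1, "HKY": 1, "TIM1": 3, "GTR": 5}
_FAMILY_EQUAL_FREQS = {"JC": True, "K80": True, "HKY": False, "TIM1": False,
                       "GTR": False}


@dataclass
class SubstitutionModel:
    family: str = "GTR"
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))          # AC, AG, AT, CG, CT, GT
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))    # A, C, G, T
    p_inv: float = 0.0
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if np.all(self.exchangeabilities == 0):
            raise ValueError("all-zero exchangeabilities")
        s = self.base_frequencies.sum()
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError(f"base frequencies sum to {s}, not 1")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self._apply_family_constraints()

    def _apply_family_constraints(self) -> None:
        r = self.exchangeabilities
        if self.family == "JC":
            self.exchangeabilities = np.ones(6)
        elif self.family in ("K80", "HKY"):
            kappa = (r[1] + r[4]) / 2.0
            tv = (r[0] + r[2] + r[3] + r[5]) / 4.0
            self.exchangeabilities = np.array([tv, kappa, tv, tv, kappa, tv])
        elif self.family == "TIM1":
            ac_gt = (r[0] + r[5]) / 2.0
            at_cg = (r[2] + r[3]) / 2.0
            self.exchangeabilities = np.array([ac_gt, r[1], at_cg, at_cg, r[4], ac_gt])
        if _FAMILY_EQUAL_FREQS[self.family]:
            self.base_frequencies = np.full(4, 0.25)

    @property
    def n_free_parameters(self) -> int:
        """Substitution-process parameter count (branch lengths excluded)."""
        k = _FAMILY_EXCH_FREE[self.family]
        if not _FAMILY_EQUAL_FREQS[self.family]:
            k += 3
        if self.p_inv > 0:
            k += 1
        if self.gamma_shape is not None:
            k += 1
        return k

    # cached spectral pieces for fast transition probabilities; models are
    # treated as immutable once constructed
    def _decomposition(self):
        cached = getattr(self, "_decomp", None)
        if cached is not None:
            return cached
        Q = rate_matrix(self)
        pi = self.base_frequencies
        sq = np.sqrt(np.clip(pi, 1e-300, None))
        B = (Q * sq[:, None]) / sq[None, :]      # symmetric for reversible Q
        B = 0.5 * (B + B.T)
        evals, evecs = np.linalg.eigh(B)
        right = evecs / sq[:, None]              # D^-1/2 U
        left = evecs.T * sq[None, :]             # U^T D^1/2
        self._decomp = (evals, right, left)
        return self._decomp

    def category_rates(self) -> np.ndarray:
        """Rates of the Gamma mixture categories (mean one); [1] when no +G."""
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability bins of Gamma(alpha, mean 1)."""
    if alpha <= 0 or k < 1:
        raise ValueError("alpha > 0 and k >= 1 required")
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    upper_cdf = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper_cdf)     # E[X; bin] / P(bin), with E[X]=1
    return rates / rates.mean()        # exact mean one despite rounding


def rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalized GTR generator: q_ij = r_ij * pi_j, mean rate one.

    Scaling accounts for the +I/+Gamma mixture so that a branch of length t
    accumulates t expected substitutions per site overall.
    """
    r = model.exchangeabilities
    if np.all(r == 0):
        raise ValueError("all-zero exchangeabilities")
    pi = model.base_frequencies
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(r, _EXCH_PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))          # mean rate of the plain process
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    # category rates average one by construction, so only p_inv rescales
    effective = mu * (1.0 - model.p_inv)
    return Q / effective


def transition_probabilities(model: SubstitutionModel, t: float,
                             rate: float = 1.0) -> np.ndarray:
    """P(t) = expm(Q * rate * t) via the reversible spectral decomposition."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    evals, right, left = model._decomposition()
    P = (right * np.exp(evals * rate * t)) @ left
    return np.clip(P, 0.0, None)


def aicc(lnL: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
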