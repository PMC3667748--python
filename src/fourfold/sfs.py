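"""Expected site-frequency spectra under mutation-selection balance.

The model follows the Poisson-random-field tradition: each site is
monomorphic or carries a single mutation whose population frequency q is
distributed according to the Wright stationary density under selection
gamma = 4*Ne*s,

    f(q) = theta * (exp(gamma*q) - exp(gamma)) / ((1 - exp(gamma)) * q * (1-q)),

with the neutral limit f(q) = theta/q as gamma -> 0.  The expected sample
spectrum at depth ``n`` is obtained by integrating f against binomial
sampling, and a zero-frequency (monomorphic) class g(0) = 1 - sum_i g(i)
is appended so the spectrum carries density ("amplitude") information as
well as shape.  Spectra are folded onto minor-allele counts.

A mixture of selection categories (neutral / weak / strong purifying)
combines per-category spectra with fractions f_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "SelectionCategory",
    "SelectionMixture",
    "ExpectedSpectrum",
    "stationary_density",
    "expected_unfolded",
    "fold",
    "mixture_spectrum",
    "retention_ratio",
    "segregating_mass",
    "GAMMA_LIMIT",
]

#: largest |gamma| the spectra are computed for; beyond this the selected
#: spectrum is numerically indistinguishable from "no segregating sites"
#: in double precision.
GAMMA_LIMIT = 700.0

_NEUTRAL_EPS = 1e-5  # |gamma| below this uses the exact neutral limit

# Fixed Gauss-Legendre panels on (0,1).  The selected density has a
# boundary layer of width ~1/|gamma| at q=0; the inner panels resolve it
# for all |gamma| <= GAMMA_LIMIT while keeping the node set independent
# of gamma, so the binomial kernel is precomputed once per depth n.
_PANELS = ((0.0, 0.02), (0.02, 0.2), (0.2, 1.0))
_NODES_PER_PANEL = 256


@dataclass(frozen=True)
class ModelParams:
    """Scaled mutation rate theta = 4*Ne*mu per site and sample depth n."""

    theta: float
    n: int

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.n < 2:
            raise ValueError(f"sample depth n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class SelectionCategory:
    label: str
    fraction: float
    gamma: float


@dataclass(frozen=True)
class SelectionMixture:
    """Ordered selection categories (label, fraction f_c, gamma_c).

    Purifying categories carry gamma <= 0.  ``mutation_deficit`` labels a
    category whose sites receive no mutations at all (used in confound
    experiments): it contributes only to the monomorphic class.
    """

    categories: tuple[SelectionCategory, ...]

    def __post_init__(self) -> None:
        fracs = np.array([c.fraction for c in self.categories], float)
        if np.any(fracs < -1e-12):
            raise ValueError("category fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"category fractions must sum to 1, got {fracs.sum():.10f}"
            )
        for c in self.categories:
            if c.gamma > 0:
                raise ValueError("positive gamma (adaptive) categories unsupported")
            if abs(c.gamma) > GAMMA_LIMIT:
                raise ValueError(f"|gamma| exceeds limit {GAMMA_LIMIT}")

    @classmethod
    def neutral(cls) -> "SelectionMixture":
        return cls((SelectionCategory("neutral", 1.0, 0.0),))

    @classmethod
    def three_class(
        cls, f_weak: float, f_strong: float, gamma_weak: float, gamma_strong: float
    ) -> "SelectionMixture":
        return cls(
            (
                SelectionCategory("neutral", 1.0 - f_weak - f_strong, 0.0),
                SelectionCategory("weak", f_weak, gamma_weak),
                SelectionCategory("strong", f_strong, gamma_strong),
            )
        )


@dataclass
class ExpectedSpectrum:
    """Model-predicted folded per-site class proportions g(0..floor(n/2))."""

    n: int
    proportions: np.ndarray
    per_category: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, float)
        if len(self.proportions) != self.n // 2 + 1:
            raise ValueError("folded spectrum must have floor(n/2)+1 classes")
        if np.any(self.proportions < -1e-12):
            raise ValueError("negative class proportion")
        total = self.proportions.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"proportions must sum to 1, got {total:.8f}")

    @property
    def segregating_fraction(self) -> float:
        return float(self.proportions[1:].sum())


def _selected_shape(q: np.ndarray, gamma: float) -> np.ndarray:
    """(exp(gamma q) - exp(gamma)) / (1 - exp(gamma)), stable for gamma <= 0.

    Equals 1 - q in the neutral limit, so ``stationary_density`` is this
    shape times theta/(q(1-q)).
    """
    if abs(gamma) < _NEUTRAL_EPS:
        return 1.0 - q
    # for gamma <= -GAMMA_LIMIT exp(gamma) underflows harmlessly to 0
    with np.errstate(under="ignore"):
        num = np.exp(gamma * q) - np.exp(gamma)
        den = -np.expm1(gamma)
    return num / den


def stationary_density(q, gamma: float, theta: float):
    """Wright stationary density of a selected allele at population frequency q.

    Parameters
    ----------
    q : float or array in the open interval (0, 1)
    gamma : scaled selection coefficient 4*Ne*s (<= 0 for purifying)
    theta : scaled mutation rate 4*Ne*mu

    The gamma -> 0 limit is theta/q exactly.
    """
    q = np.asarray(q, float)
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("q must lie strictly inside (0, 1)")
    out = theta * _selected_shape(q, gamma) / (q * (1.0 - q))
    return float(out) if out.ndim == 0 else out


def _panel_nodes() -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(_NODES_PER_PANEL)
    qs, ws = [], []
    for a, b in _PANELS:
        half = 0.5 * (b - a)
        qs.append(a + half * (x + 1.0))
        ws.append(half * w)
    return np.concatenate(qs), np.concatenate(ws)


@lru_cache(maxsize=8)
def _sampling_kernel(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed K[i-1, k] = C(n,i) q_k^i (1-q_k)^(n-i) w_k / (q_k (1-q_k)).

    h_i(gamma) = sum_k K[i-1,k] * shape(q_k; gamma) gives the per-unit-theta
    expected unfolded spectrum: g(i) = theta * h_i(gamma).
    """
    q, w = _panel_nodes()
    i = np.arange(1, n, dtype=float)[:, None]
    logq, log1mq = np.log(q)[None, :], np.log1p(-q)[None, :]
    logC = (
        gammaln(n + 1.0) - gammaln(i + 1.0) - gammaln(n - i + 1.0)
    )
    with np.errstate(under="ignore"):
        K = np.exp(logC + (i - 1.0) * logq + (n - i - 1.0) * log1mq) * w[None, :]
    return q, K


def unfolded_shape(n: int, gamma: float) -> np.ndarray:
    """h_i(gamma) for i=1..n-1 with g(i) = theta * h_i; h_i(0) = 1/i exactly."""
    if gamma > 0 or abs(gamma) > GAMMA_LIMIT:
        raise ValueError(f"gamma must lie in [-{GAMMA_LIMIT}, 0], got {gamma}")
    if abs(gamma) < _NEUTRAL_EPS:
        return 1.0 / np.arange(1, n, dtype=float)
    q, K = _sampling_kernel(n)
    return K @ _selected_shape(q, gamma)


def expected_unfolded(params: ModelParams, gamma: float) -> tuple[np.ndarray, float]:
    """Expected unfolded spectrum g(1..n-1) plus the monomorphic class g(0).

    g(i) integrates the stationary density against Binomial(n, q) sampling
    by fixed-panel Gauss-Legendre quadrature; g(0) = 1 - sum_i g(i).
    """
    h = unfolded_shape(params.n, gamma)
    g = params.theta * h
    g0 = 1.0 - g.sum()
    if g0 < 0:
        raise ValueError(
            f"theta={params.theta} implies segregating fraction > 1 at n={params.n}"
        )
    return g, g0


def fold(unfolded: Sequence[float], n: int, g0: float = 0.0) -> np.ndarray:
    """Fold a derived-allele spectrum g(1..n-1) onto minor-allele classes.

    Returns (G(0), G(1), ..., G(floor(n/2))) with G(j) = g(j) + g(n-j) off
    the midpoint and the midpoint class (n even) left un-doubled.  Total
    mass is preserved exactly.
    """
    g = np.asarray(unfolded, float)
    if len(g) != n - 1:
        raise ValueError(f"expected n-1={n - 1} unfolded classes, got {len(g)}")
    half = n // 2
    out = np.zeros(half + 1)
    out[0] = g0
    for j in range(1, half + 1):
        if j != n - j:
            out[j] = g[j - 1] + g[n - j - 1]
        else:
            out[j] = g[j - 1]
    return out


def folded_shape(n: int, gamma: float) -> np.ndarray:
    """Folded per-unit-theta segregating spectrum H(1..floor(n/2))."""
    return fold(unfolded_shape(n, gamma), n)[1:]


def mixture_spectrum(params: ModelParams, mixture: SelectionMixture) -> ExpectedSpectrum:
    """Folded expected spectrum of a selection mixture: g(x) = sum_c f_c g(x|c)."""
    n = params.n
    total = np.zeros(n // 2 + 1)
    per_cat: dict[str, np.ndarray] = {}
    for cat in mixture.categories:
        if cat.label == "mutation_deficit":
            comp = np.zeros(n // 2 + 1)
            comp[0] = 1.0
        else:
            g, g0 = expected_unfolded(params, cat.gamma)
            comp = fold(g, n, g0)
        per_cat[cat.label] = comp
        total += cat.fraction * comp
    return ExpectedSpectrum(n=n, proportions=total, per_category=per_cat)


def segregating_mass(n: int, gamma: float) -> float:
    """Per-unit-theta expected segregating fraction sum_i h_i(gamma)."""
    return float(unfolded_shape(n, gamma).sum())


def retention_ratio(params: ModelParams, gamma: float) -> float:
    """Fraction of neutral segregating-site density retained under gamma.

    r(gamma) = sum_i g(i|gamma) / sum_i g(i|0); independent of theta.  The
    missing-polymorphism fraction of a mixture with strong fraction f is
    f * (1 - r(gamma_strong)).
    """
    return segregating_mass(params.n, gamma) / segregating_mass(params.n, 0.0)
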