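"""Maximum-likelihood fit of the selection-mixture model to paired spectra.

A test spectrum (4D synonymous sites) and a neutral reference spectrum
(short-intron sites) are fitted jointly.  The model has five structural
parameters: theta (shared), the mixture fractions f_weak and f_strong
(f_neutral = 1 - f_weak - f_strong) and the category selection strengths
gamma_weak and gamma_strong.  The reference is modelled as all-neutral,
anchoring theta, so the monomorphic class of the test spectrum carries
the signal of missing polymorphism.

Each spectrum contributes a multinomial log-likelihood over its folded
frequency classes (zero class included); the data-only multinomial
constant is dropped throughout, so only likelihood differences are
meaningful.

An optional frequency-class correction multiplies the class probability
of both spectra by a shared modifier alpha_x (alpha_0 = 1), absorbing
demography and other distortions common to test and reference.  The
alphas are profiled out at each structural-parameter point by a concave
fixed-point iteration, so the outer optimisation stays five-dimensional.

Optimisation follows the Nelder-Mead simplex on transformed coordinates
(log theta; additive-log-ratio fractions; bounded-logistic gammas) with
deterministic multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .sfs import (
    GAMMA_LIMIT,
    ExpectedSpectrum,
    ModelParams,
    SelectionMixture,
    folded_shape,
    mixture_spectrum,
    retention_ratio,
)
from .spectra import ObservedSpectrum

__all__ = [
    "FitConfig",
    "AlphaCorrection",
    "SfsMixtureModel",
    "SfsMixtureResults",
    "multinomial_loglik",
    "joint_negloglik",
    "fit_model",
    "fit_model_alpha",
    "simulate_spectrum",
]


@dataclass(frozen=True)
class FitConfig:
    """Category bounds and simplex settings for the mixture fit.

    weak_bound / strong_lower bound |gamma| of the weak and strong
    categories (defaults 5 and 100); gamma_limit caps |gamma_strong| at
    the largest value the spectra are computable for.  ``restarts``
    deterministic simplex starts are spread from a moment-based initial
    point using ``seed``.

    ``collapse_tol`` handles the gamma -> 0 ridge of the mixture: a
    category whose gamma approaches 0 is likelihood-equivalent to the
    neutral class, leaving its fraction unidentified.  After the search,
    a model with the weak category emptied is refitted (f_weak pinned)
    and adopted unless the full model beats it by more than
    ``collapse_tol`` log-likelihood units.  The default (None) uses the
    BIC penalty ln(N_total) for the two parameters the weak category
    adds, a consistent selection rule at these sample sizes; a fixed
    likelihood-ratio cut can be supplied instead.
    """

    weak_bound: float = 5.0
    strong_lower: float = 100.0
    gamma_limit: float = GAMMA_LIMIT
    use_alpha: bool = False
    restarts: int = 8
    maxiter: int = 6000
    xatol: float = 1e-7
    fatol: float = 1e-9
    collapse_tol: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.weak_bound <= self.strong_lower < self.gamma_limit):
            raise ValueError(
                "need 0 < weak_bound <= strong_lower < gamma_limit, got "
                f"{self.weak_bound}, {self.strong_lower}, {self.gamma_limit}"
            )


@dataclass
class AlphaCorrection:
    """Shared per-frequency-class modifiers alpha_x with alpha_0 = 1."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        if self.alpha[0] != 1.0:
            raise ValueError("alpha_0 must be fixed at 1")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")


def multinomial_loglik(observed: ObservedSpectrum, expected) -> float:
    """Sum_x k_x log g(x), the multinomial log-likelihood up to its constant.

    Returns -inf (rather than raising) when some class has k_x > 0 but
    g(x) = 0, so optimisers can treat the point as infeasible.
    """
    g = expected.proportions if isinstance(expected, ExpectedSpectrum) else np.asarray(expected, float)
    k = observed.counts
    if len(g) != len(k):
        raise ValueError("observed and expected spectra have different class counts")
    mask = k > 0
    if np.any(g[mask] <= 0.0):
        return -np.inf
    return float(np.sum(k[mask] * np.log(g[mask])))


def _apply_alpha(p: np.ndarray, alpha: Optional[np.ndarray]) -> np.ndarray:
    """p(x) proportional to alpha_x g(x), renormalised over all classes.

    ``alpha is None`` (or all ones) bypasses the arithmetic entirely so the
    corrected model reduces bit-for-bit to the uncorrected one.
    """
    if alpha is None:
        return p
    alpha = np.asarray(alpha, float)
    if np.all(alpha == 1.0):
        return p
    w = alpha * p
    return w / w.sum()


def _mixture_probs(
    theta: float,
    n: int,
    f: np.ndarray,
    gamma_weak: float,
    gamma_strong: float,
) -> Optional[np.ndarray]:
    """Folded class probabilities of the three-category mixture.

    Returns None when theta is infeasible (segregating mass > 1 for some
    category), which the optimiser treats as +inf.
    """
    half = n // 2
    probs = np.zeros(half + 1)
    gammas = (0.0, gamma_weak, gamma_strong)
    for fc, gc in zip(f, gammas):
        if fc == 0.0:
            continue
        seg = theta * folded_shape(n, gc)
        tot = seg.sum()
        if tot > 1.0:
            return None
        probs[0] += fc * (1.0 - tot)
        probs[1:] += fc * seg
    return probs


def joint_negloglik(
    params: ModelParams,
    mixture: SelectionMixture,
    alpha: Optional[np.ndarray],
    observed_test: ObservedSpectrum,
    observed_ref: ObservedSpectrum,
) -> float:
    """-(loglik_test + loglik_ref) under a shared theta and shared alpha.

    The reference spectrum is modelled as all-neutral.  Invalid model
    points (mixture mass exceeding 1) return +inf, never raise, so the
    function is safe inside a simplex search.
    """
    n = params.n
    fr = {c.label: c.fraction for c in mixture.categories}
    gm = {c.label: c.gamma for c in mixture.categories}
    f = np.array([fr.get("neutral", 0.0), fr.get("weak", 0.0), fr.get("strong", 0.0)])
    p_test = _mixture_probs(params.theta, n, f, gm.get("weak", 0.0), gm.get("strong", 0.0))
    p_ref = _mixture_probs(params.theta, n, np.array([1.0, 0.0, 0.0]), 0.0, 0.0)
    if p_test is None or p_ref is None:
        return np.inf
    p_test = _apply_alpha(p_test, alpha)
    p_ref = _apply_alpha(p_ref, alpha)
    ll = multinomial_loglik(observed_test, p_test) + multinomial_loglik(observed_ref, p_ref)
    return -ll


def _profile_alpha(
    p_test: np.ndarray,
    p_ref: np.ndarray,
    k_test: np.ndarray,
    k_ref: np.ndarray,
    max_iter: int = 400,
    tol: float = 1e-12,
) -> np.ndarray:
    """Maximise the joint likelihood over alpha (alpha_0 = 1) by fixed point.

    The objective sum_s [sum_x k_x log alpha_x - L_s log(sum_y alpha_y g_y)]
    is concave in alpha; the stationarity condition gives the multiplicative
    update alpha_x <- K_x / sum_s L_s g_x^(s) / Z_s, iterated to convergence.
    Classes with zero total count get alpha_x = 0 (their MLE).
    """
    K = k_test + k_ref
    L_t, L_r = k_test.sum(), k_ref.sum()
    alpha = np.ones_like(p_test)
    for _ in range(max_iter):
        Z_t = alpha @ p_test
        Z_r = alpha @ p_ref
        denom = L_t * p_test / Z_t + L_r * p_ref / Z_r
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(denom > 0, K / np.maximum(denom, 1e-300), 0.0)
        new[0] = 1.0
        delta = np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-12))
        alpha = new
        if delta < tol:
            break
    return alpha


@dataclass
class SfsMixtureResults:
    """Estimates, uncertainties and diagnostics from an SFS mixture fit.

    Standard errors of the headline quantities are a replicate-level
    concept here (spread over matched-bootstrap refits), not a Hessian
    product; see the bootstrap module.
    """

    model: "SfsMixtureModel"
    theta: float
    f_neutral: float
    f_weak: float
    f_strong: float
    gamma_weak: float
    gamma_strong: float
    alpha: Optional[np.ndarray]
    loglik: float
    loglik_test: float
    loglik_ref: float
    converged: bool
    at_gamma_limit: bool
    n_restarts: int
    restart_logliks: np.ndarray = field(repr=False)

    @property
    def params(self) -> dict:
        return {
            "theta": self.theta,
            "f_neutral": self.f_neutral,
            "f_weak": self.f_weak,
            "f_strong": self.f_strong,
            "gamma_weak": self.gamma_weak,
            "gamma_strong": self.gamma_strong,
        }

    @property
    def mixture(self) -> SelectionMixture:
        return SelectionMixture.three_class(
            self.f_weak, self.f_strong, self.gamma_weak, self.gamma_strong
        )

    @property
    def missing_polymorphism(self) -> float:
        """Model-implied fraction of segregating sites removed by selection."""
        n = self.model.observed_test.n
        mp = ModelParams(self.theta, n)
        out = self.f_strong * (1.0 - retention_ratio(mp, self.gamma_strong))
        if self.f_weak > 0:
            out += self.f_weak * (1.0 - retention_ratio(mp, self.gamma_weak))
        return out

    def expected_spectra(self) -> tuple[np.ndarray, np.ndarray]:
        """Fitted folded class probabilities (test, reference)."""
        n = self.model.observed_test.n
        f = np.array([self.f_neutral, self.f_weak, self.f_strong])
        p_t = _mixture_probs(self.theta, n, f, self.gamma_weak, self.gamma_strong)
        p_r = _mixture_probs(self.theta, n, np.array([1.0, 0.0, 0.0]), 0.0, 0.0)
        return _apply_alpha(p_t, self.alpha), _apply_alpha(p_r, self.alpha)

    def summary(self) -> str:
        lines = [
            "SFS selection-mixture fit",
            "=" * 45,
            f"{'sample depth n':<28}{self.model.observed_test.n}",
            f"{'sites (test / ref)':<28}{self.model.observed_test.L} / {self.model.observed_ref.L}",
            f"{'theta (4Ne*mu)':<28}{self.theta:.6g}",
            f"{'f_neutral':<28}{self.f_neutral:.4f}",
            f"{'f_weak':<28}{self.f_weak:.4f}",
            f"{'f_strong':<28}{self.f_strong:.4f}",
            f"{'gamma_weak (4Ne*s)':<28}{self.gamma_weak:.4g}",
            f"{'gamma_strong (4Ne*s)':<28}{self.gamma_strong:.4g}",
            f"{'missing polymorphism':<28}{self.missing_polymorphism:.4f}",
            f"{'log-likelihood':<28}{self.loglik:.4f}",
            f"{'alpha correction':<28}{'yes (%d free)' % (len(self.alpha) - 1) if self.alpha is not None else 'no'}",
            f"{'converged':<28}{self.converged}",
            f"{'gamma_strong at limit':<28}{self.at_gamma_limit}",
        ]
        return "\n".join(lines)

    def to_text(self) -> str:
        rows = [(k, f"{v:.10g}") for k, v in self.params.items()]
        rows += [
            ("loglik", f"{self.loglik:.6f}"),
            ("missing_polymorphism", f"{self.missing_polymorphism:.8f}"),
            ("converged", str(self.converged)),
            ("at_gamma_limit", str(self.at_gamma_limit)),
        ]
        if self.alpha is not None:
            rows.append(("alpha", ",".join(f"{a:.8g}" for a in self.alpha)))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


class SfsMixtureModel:
    """Joint likelihood model for a test spectrum and a neutral reference.

    Parameters
    ----------
    observed_test, observed_ref : ObservedSpectrum
        Folded spectra (zero class included) at the same sample depth.
    config : FitConfig, optional

    Examples
    --------
    >>> model = SfsMixtureModel(test_sfs, ref_sfs)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        observed_test: ObservedSpectrum,
        observed_ref: ObservedSpectrum,
        config: Optional[FitConfig] = None,
    ) -> None:
        if observed_test.n != observed_ref.n:
            raise ValueError(
                f"spectra have mismatched depths: {observed_test.n} != {observed_ref.n}"
            )
        self.observed_test = observed_test
        self.observed_ref = observed_ref
        self.config = config or FitConfig()

    @classmethod
    def from_site_table(cls, test_sites, ref_sites, n: int = 130, config=None):
        """Build spectra from two filtered site tables (uniform depth n)."""
        from .sites import build_spectrum

        return cls(build_spectrum(test_sites, n), build_spectrum(ref_sites, n), config)

    # -- parameter transforms --------------------------------------------

    def _unpack(self, z: np.ndarray) -> tuple[float, np.ndarray, float, float]:
        cfg = self.config
        theta = float(np.exp(np.clip(z[0], -30.0, 5.0)))
        a = np.array([0.0, z[1], z[2]])
        a -= a.max()
        e = np.exp(a)
        f = e / e.sum()
        gamma_w = -cfg.weak_bound * expit(z[3])
        gamma_s = -(cfg.strong_lower + (cfg.gamma_limit - cfg.strong_lower) * expit(z[4]))
        return theta, f, gamma_w, gamma_s

    def _pack(self, theta, f_weak, f_strong, gamma_w, gamma_s) -> np.ndarray:
        cfg = self.config
        f_neutral = 1.0 - f_weak - f_strong
        eps = 1e-6
        z1 = np.log(max(f_weak, eps) / max(f_neutral, eps))
        z2 = np.log(max(f_strong, eps) / max(f_neutral, eps))
        t3 = logit(np.clip(-gamma_w / cfg.weak_bound, eps, 1 - eps))
        u = (-gamma_s - cfg.strong_lower) / (cfg.gamma_limit - cfg.strong_lower)
        t4 = logit(np.clip(u, eps, 1 - eps))
        return np.array([np.log(theta), z1, z2, t3, t4])

    # -- likelihood -------------------------------------------------------

    def negloglik(
        self,
        theta: float,
        f_weak: float,
        f_strong: float,
        gamma_weak: float,
        gamma_strong: float,
        alpha: Optional[np.ndarray] = None,
    ) -> float:
        """Joint negative log-likelihood at explicit parameter values."""
        mix = SelectionMixture.three_class(f_weak, f_strong, gamma_weak, gamma_strong)
        mp = ModelParams(theta, self.observed_test.n)
        return joint_negloglik(mp, mix, alpha, self.observed_test, self.observed_ref)

    def _objective(self, z: np.ndarray, profile_alpha: bool):
        theta, f, gamma_w, gamma_s = self._unpack(z)
        n = self.observed_test.n
        p_t = _mixture_probs(theta, n, f, gamma_w, gamma_s)
        p_r = _mixture_probs(theta, n, np.array([1.0, 0.0, 0.0]), 0.0, 0.0)
        if p_t is None or p_r is None:
            return np.inf, None
        alpha = None
        if profile_alpha:
            alpha = _profile_alpha(
                p_t, p_r, self.observed_test.counts, self.observed_ref.counts
            )
            p_t = _apply_alpha(p_t, alpha)
            p_r = _apply_alpha(p_r, alpha)
        ll = multinomial_loglik(self.observed_test, p_t) + multinomial_loglik(
            self.observed_ref, p_r
        )
        return -ll, alpha

    # -- fitting ----------------------------------------------------------

    def _minimize(self, z0: np.ndarray, profile: bool):
        cfg = self.config
        return minimize(
            lambda z: self._objective(z, profile)[0],
            z0,
            method="Nelder-Mead",
            options={
                "maxiter": cfg.maxiter,
                "maxfev": cfg.maxiter,
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
                "adaptive": True,
            },
        )

    def _start_points(self) -> list[np.ndarray]:
        cfg = self.config
        theta0 = max(self.observed_ref.density, 1e-6) / np.log(self.observed_ref.n)
        base = self._pack(theta0, 0.05, 0.20, -2.5, -250.0)
        nearnull = self._pack(theta0, 0.01, 0.01, -1.0, -150.0)
        starts = [base, nearnull]
        rng = np.random.default_rng(cfg.seed)
        scale = np.array([0.25, 1.5, 1.5, 1.5, 1.5])
        while len(starts) < cfg.restarts:
            starts.append(base + rng.normal(0.0, scale))
        return starts[: max(cfg.restarts, 1)]

    def fit(self, use_alpha: Optional[bool] = None, start=None) -> SfsMixtureResults:
        """Maximise the joint likelihood by multi-start Nelder-Mead.

        Parameters
        ----------
        use_alpha : bool, optional
            Override ``config.use_alpha``; when True the shared per-class
            alpha modifiers are profiled at every simplex point.
        start : sequence, optional
            Explicit (theta, f_weak, f_strong, gamma_weak, gamma_strong)
            starting values replacing the default start list.
        """
        cfg = self.config
        profile = cfg.use_alpha if use_alpha is None else use_alpha
        if start is not None:
            starts = [self._pack(*start)]
        else:
            starts = self._start_points()

        best = None
        logliks = []
        any_converged = False
        for z0 in starts:
            res = self._minimize(z0, profile)
            logliks.append(-res.fun)
            any_converged = any_converged or res.success
            if best is None or res.fun < best.fun:
                best = res
        # polish: restart the simplex from the incumbent once
        res = self._minimize(best.x, profile)
        if res.fun <= best.fun:
            best = res
            any_converged = any_converged or res.success

        # collapse the weak category if it is likelihood-equivalent to
        # neutral (the gamma_weak -> 0 ridge leaves f_weak unidentified);
        # the collapsed polish keeps f_weak pinned so it cannot drift back
        # up the flat ridge
        theta, f, gamma_w, gamma_s = self._unpack(best.x)
        if f[1] > 1e-4:
            zc = best.x.copy()
            zc[1] = -30.0  # f_weak ~ 0
            zc[2] = np.log(max(f[2], 1e-12) / (f[0] + f[1]))  # weak mass -> neutral
            free = np.array([0, 2, 3, 4])

            def restricted(zr):
                z = zc.copy()
                z[free] = zr
                return self._objective(z, profile)[0]

            resc = minimize(
                restricted,
                zc[free],
                method="Nelder-Mead",
                options={
                    "maxiter": cfg.maxiter,
                    "maxfev": cfg.maxiter,
                    "xatol": cfg.xatol,
                    "fatol": cfg.fatol,
                    "adaptive": True,
                },
            )
            ctol = cfg.collapse_tol
            if ctol is None:  # BIC penalty for the 2 weak-category params
                ctol = np.log(self.observed_test.L + self.observed_ref.L)
            if resc.fun <= best.fun + ctol:
                zfull = zc.copy()
                zfull[free] = resc.x
                resc.x = zfull
                best = resc
                any_converged = any_converged or resc.success

        theta, f, gamma_w, gamma_s = self._unpack(best.x)
        nll, alpha = self._objective(best.x, profile)
        n = self.observed_test.n
        p_t = _apply_alpha(
            _mixture_probs(theta, n, f, gamma_w, gamma_s), alpha
        )
        p_r = _apply_alpha(
            _mixture_probs(theta, n, np.array([1.0, 0.0, 0.0]), 0.0, 0.0), alpha
        )
        ll_t = multinomial_loglik(self.observed_test, p_t)
        ll_r = multinomial_loglik(self.observed_ref, p_r)
        return SfsMixtureResults(
            model=self,
            theta=theta,
            f_neutral=float(f[0]),
            f_weak=float(f[1]),
            f_strong=float(f[2]),
            gamma_weak=gamma_w,
            gamma_strong=gamma_s,
            alpha=alpha,
            loglik=-nll,
            loglik_test=ll_t,
            loglik_ref=ll_r,
            converged=bool(any_converged and np.isfinite(nll)),
            at_gamma_limit=bool(abs(gamma_s) >= 0.99 * cfg.gamma_limit),
            n_restarts=len(starts),
            restart_logliks=np.array(logliks),
        )


def fit_model(
    observed_test: ObservedSpectrum,
    observed_ref: ObservedSpectrum,
    config: Optional[FitConfig] = None,
) -> SfsMixtureResults:
    """Fit the five-parameter mixture model (no alpha correction)."""
    cfg = replace(config, use_alpha=False) if config else FitConfig()
    return SfsMixtureModel(observed_test, observed_ref, cfg).fit()


def fit_model_alpha(
    observed_test: ObservedSpectrum,
    observed_ref: ObservedSpectrum,
    config: Optional[FitConfig] = None,
) -> SfsMixtureResults:
    """Fit with the shared per-class alpha modifiers (alpha_0 = 1) profiled in."""
    cfg = replace(config, use_alpha=True) if config else FitConfig(use_alpha=True)
    return SfsMixtureModel(observed_test, observed_ref, cfg).fit()


def simulate_spectrum(
    params: ModelParams,
    mixture: SelectionMixture,
    alpha: Optional[np.ndarray],
    L: int,
    seed=None,
    noise: str = "multinomial",
) -> ObservedSpectrum:
    """Draw an observed folded spectrum of L sites from the model.

    noise='none' returns deterministic expected counts: each polymorphic
    class gets round(L*p_j) and the zero class absorbs the remainder so
    the counts sum to L exactly.  noise='multinomial' draws the class
    counts from Multinomial(L, p) with the given seed.
    """
    p = mixture_spectrum(params, mixture).proportions
    p = _apply_alpha(p, alpha)
    if noise == "none":
        counts = np.round(L * p).astype(np.int64)
        counts[0] = L - counts[1:].sum()
    elif noise == "multinomial":
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(L, p / p.sum())
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ObservedSpectrum(n=params.n, counts=counts)
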