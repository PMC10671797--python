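"""Per-taxon robust regression of CLR values with plug-in sandwich variance.

The effect of the variable of interest on each taxon's CLR abundance is
estimated by minimizing an empirical loss of the residuals,

    theta_tilde = argmin (1/n) sum_s L(W_s - z_s' theta),

with L the squared loss (ordinary least squares), Huber's loss, Tukey's
bisquare, or the quantile check loss.  The asymptotic covariance of the
M-estimator is the sandwich

    Sigma = (sum_s z_s z_s')^-1 * E[psi^2(r)] / E[psi'(r)]^2,

estimated by plugging in the fitted residuals (the influence curve psi is
the derivative of L).  Because the standard tuning constants (Huber
c = 1.345, bisquare c0 = 4.685) are calibrated for unit-scale residuals,
the iteratively reweighted least squares (IRLS) loop re-estimates a robust
scale each iteration as s_hat = MAD(residuals)/0.6745 (MAD about zero) and
applies psi to r/s_hat; the plug-in covariance is evaluated on standardized
residuals and mapped back to response units by s_hat^2, which reproduces
the closed-form least-squares case exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.regression.quantile_regression import QuantReg

from .containers import DesignMatrix

_FAMILIES = ("l2", "huber", "bisquare", "quantile")
_DEFAULT_HYPER = {"l2": None, "huber": 1.345, "bisquare": 4.685, "quantile": 0.5}

#: guard against a zero robust scale when residuals are (nearly) degenerate
_SCALE_FLOOR = 1e-12

MAX_ITER = 200
COEF_TOL = 1e-8


def default_grid(family: str) -> list[float]:
    """Hyperparameter grids used for Cauchy combination across tunings.

    huber: 10 values log-equally spaced on [1.345, 5]; bisquare: 10 values
    log-equally spaced on [4.685, 20]; quantile: tau = 0.25, 0.30, ..., 0.75
    (11 values).  l2 has no hyperparameter.
    """
    if family == "huber":
        return list(np.geomspace(1.345, 5.0, 10))
    if family == "bisquare":
        return list(np.geomspace(4.685, 20.0, 10))
    if family == "quantile":
        return [round(0.25 + 0.05 * k, 2) for k in range(11)]
    if family == "l2":
        return []
    raise ValueError(f"unknown loss family: {family!r}")


@dataclass
class LossSpec:
    """Loss family plus tuning value and optional hyperparameter grid."""

    family: str = "huber"
    hyper: float | None = None
    grid: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown loss family: {self.family!r}")
        if self.hyper is None:
            self.hyper = _DEFAULT_HYPER[self.family]
        if self.family in ("huber", "bisquare") and self.hyper <= 0:
            raise ValueError("tuning constant must be > 0")
        if self.family == "quantile" and not 0 < self.hyper < 1:
            raise ValueError("quantile tau must be in (0, 1)")

    def resolved_grid(self) -> list[float]:
        if self.grid is not None:
            return list(self.grid)
        return default_grid(self.family)


@dataclass
class InfluencePair:
    """Influence curve psi = L' and its weak derivative psi'."""

    psi: Callable[[np.ndarray], np.ndarray]
    psi_prime: Callable[[np.ndarray], np.ndarray]


def influence(family: str, hyper: float | None = None) -> InfluencePair:
    """Influence curve for a loss family at tuning value ``hyper``.

    At the Huber kink |r| = c and the bisquare boundary |r| = c0 the weak
    derivative is taken as the left limit (1 and 0 respectively) so results
    are deterministic.
    """
    if hyper is None:
        hyper = _DEFAULT_HYPER[family]
    if family == "l2":
        return InfluencePair(
            psi=lambda r: 2.0 * np.asarray(r, float),
            psi_prime=lambda r: np.full_like(np.asarray(r, float), 2.0),
        )
    if family == "huber":
        c = float(hyper)
        return InfluencePair(
            psi=lambda r: np.clip(np.asarray(r, float), -c, c),
            psi_prime=lambda r: (np.abs(np.asarray(r, float)) <= c).astype(float),
        )
    if family == "bisquare":
        c0 = float(hyper)

        def psi(r: np.ndarray) -> np.ndarray:
            r = np.asarray(r, float)
            t2 = (r / c0) ** 2
            return np.where(t2 <= 1.0, r * (1.0 - t2) ** 2, 0.0)

        def psi_prime(r: np.ndarray) -> np.ndarray:
            r = np.asarray(r, float)
            t2 = (r / c0) ** 2
            return np.where(t2 < 1.0, (1.0 - t2) * (1.0 - 5.0 * t2), 0.0)

        return InfluencePair(psi=psi, psi_prime=psi_prime)
    if family == "quantile":
        tau = float(hyper)
        return InfluencePair(
            psi=lambda r: tau - (np.asarray(r, float) < 0).astype(float),
            psi_prime=lambda r: np.zeros_like(np.asarray(r, float)),
        )
    raise ValueError(f"unknown loss family: {family!r}")


@dataclass
class FitResult:
    """Per-taxon M-estimation output.

    ``theta_tilde`` is ordered (alpha, intercept, beta_1..beta_d); ``scale``
    is the robust residual scale; ``Sigma_hat`` the plug-in covariance of
    theta_tilde with ``sigma2_alpha`` its (0, 0) entry.
    """

    theta_tilde: np.ndarray
    residuals: np.ndarray
    scale: float
    Sigma_hat: np.ndarray
    sigma2_alpha: float
    converged: bool = True
    iterations: int = 0
    family: str = "l2"
    hyper: float | None = None

    @property
    def alpha_tilde(self) -> float:
        return float(self.theta_tilde[0])


def _mad_scale(residuals: np.ndarray) -> float:
    """MAD about zero divided by the normal consistency constant 0.6745."""
    return float(np.median(np.abs(residuals)) / 0.6745)


def _irls(
    w: np.ndarray, Z: np.ndarray, family: str, hyper: float, theta0: np.ndarray
) -> tuple[np.ndarray, float, bool, int]:
    infl = influence(family, hyper)
    theta = theta0.copy()
    scale = 1.0
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        r = w - Z @ theta
        scale = max(_mad_scale(r), _SCALE_FLOOR)
        rs = r / scale
        psi_vals = infl.psi(rs)
        with np.errstate(invalid="ignore", divide="ignore"):
            wts = np.where(rs == 0.0, 1.0, psi_vals / rs)
        wts = np.clip(wts, 0.0, None)
        if wts.sum() <= 0:  # every point rejected (redescending loss)
            break
        sw = np.sqrt(wts)
        theta_new, *_ = np.linalg.lstsq(Z * sw[:, None], w * sw, rcond=None)
        delta = np.max(np.abs(theta_new - theta))
        theta = theta_new
        if delta < COEF_TOL:
            converged = True
            break
    r = w - Z @ theta
    scale = max(_mad_scale(r), _SCALE_FLOOR)
    return theta, scale, converged, it


def fit_taxon(w: np.ndarray, design: DesignMatrix, loss: LossSpec) -> FitResult:
    """Fit one taxon's CLR row against the design under the given loss.

    l2 uses closed-form least squares; huber/bisquare use IRLS with joint
    MAD scale (bisquare is warm-started from the converged Huber fit at the
    default c to avoid bad local minima of the non-convex loss); quantile
    uses the interior-point solver of statsmodels' QuantReg.  Non-convergence
    is reported through ``converged=False``, never as an exception.
    """
    w = np.asarray(w, dtype=float).ravel()
    Z = design.Z
    if w.size != Z.shape[0]:
        raise ValueError("response length does not match design")

    ols_theta, *_ = np.linalg.lstsq(Z, w, rcond=None)

    if loss.family == "l2":
        theta, scale, converged, iters = ols_theta, 1.0, True, 0
    elif loss.family == "huber":
        theta, scale, converged, iters = _irls(w, Z, "huber", loss.hyper, ols_theta)
    elif loss.family == "bisquare":
        warm, *_ = _irls(w, Z, "huber", _DEFAULT_HYPER["huber"], ols_theta)
        theta, scale, converged, iters = _irls(w, Z, "bisquare", loss.hyper, warm)
    elif loss.family == "quantile":
        qr = QuantReg(w, Z).fit(q=loss.hyper, max_iter=2000)
        theta, scale, converged, iters = np.asarray(qr.params), 1.0, True, 0
    else:  # pragma: no cover - guarded by LossSpec
        raise ValueError(loss.family)

    residuals = w - Z @ theta

    if loss.family == "quantile":
        Sigma = quantile_covariance(design, residuals, loss.hyper)
    else:
        Sigma = plug_in_covariance(
            design, residuals, scale, influence(loss.family, loss.hyper)
        )

    return FitResult(
        theta_tilde=theta,
        residuals=residuals,
        scale=scale,
        Sigma_hat=Sigma,
        sigma2_alpha=float(Sigma[0, 0]),
        converged=converged,
        iterations=iters,
        family=loss.family,
        hyper=loss.hyper,
    )


def plug_in_covariance(
    design: DesignMatrix,
    residuals: np.ndarray,
    scale: float,
    infl: InfluencePair,
) -> np.ndarray:
    """Plug-in sandwich covariance of the M-estimator.

    Evaluates (sum z z')^-1 * mean psi^2(r/s) / mean psi'(r/s)^2 on
    scale-standardized residuals and maps back to response units by s^2.
    For the squared loss the scale factors and the constant 2 cancel, giving
    (Z'Z)^-1 * mean(r^2).
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rs = residuals / scale
    num = float(np.mean(infl.psi(rs) ** 2))
    den = float(np.mean(infl.psi_prime(rs)))
    if den == 0.0:
        raise ValueError(
            "mean psi' is zero (all residuals clipped); increase the tuning constant"
        )
    Z = design.Z
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    Sigma = ZtZ_inv * (num / den**2) * scale**2
    return 0.5 * (Sigma + Sigma.T)


def quantile_covariance(
    design: DesignMatrix, residuals: np.ndarray, tau: float
) -> np.ndarray:
    """Sparsity-based covariance for quantile regression.

    The check loss's psi' vanishes almost everywhere, so the sandwich
    denominator is replaced by the residual density at zero:
    Sigma = tau(1-tau) / f(0)^2 * (sum z z')^-1, with f(0) a Gaussian-kernel
    density estimate (Silverman bandwidth).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    from scipy.stats import gaussian_kde

    residuals = np.asarray(residuals, dtype=float).ravel()
    if np.ptp(residuals) == 0:
        raise ValueError("degenerate residuals: density at zero is unbounded")
    f0 = float(gaussian_kde(residuals, bw_method="silverman")(0.0)[0])
    if f0 <= np.finfo(float).eps:
        raise ValueError("estimated residual density at zero is numerically zero")
    Z = design.Z
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    Sigma = ZtZ_inv * tau * (1.0 - tau) / f0**2
    return 0.5 * (Sigma + Sigma.T)


def fit_all_taxa(
    W: np.ndarray, design: DesignMatrix, loss: LossSpec
) -> list[FitResult]:
    """Fit every row of a CLR matrix; per-taxon failures do not abort."""
    W = np.asarray(W, dtype=float)
    return [fit_taxon(W[i], design, loss) for i in range(W.shape[0])]
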