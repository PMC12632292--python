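"""Outlier-robust covariate correction.

Every covariate correction in the analysis goes through the same strategy:
a RANSAC consensus fit of a degree-1 or degree-2 polynomial, the degree
chosen by AIC, followed by an ordinary least-squares refit on the consensus
inlier set. Gestational-age trends, brain-volume scaling, and the depth
correction of thickness are all removed with this one primitive, so a
handful of gross measurement failures cannot bend any trend estimate.

Determinism: all random sampling flows from the ``seed`` argument
(default 42); identical inputs and seed give identical fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FittedModel",
    "ResidualizationResult",
    "fit_growth_model",
    "residualize",
    "residual_brain_volume",
]

#: Number of minimal-subset trials per RANSAC fit.
N_TRIALS = 200

#: Residual threshold = threshold_k * 1.4826 * MAD of the consensus trial's
#: residuals. The default 3.0 (~3 sigma under Gaussian noise) keeps ~99.7% of
#: clean points, so a 20% gross-outlier contamination cannot push the
#: consensus below the 75% inclusion floor, while deviates >= 5 sigma are
#: still excluded.
DEFAULT_THRESHOLD_K = 3.0

#: Gestational-age window of the study; fits on GA are centered mid-window.
_GA_WINDOW = (22.0, 32.0)
_GA_CENTER = 27.0


@dataclass
class FittedModel:
    """A robust polynomial fit of measure against one covariate.

    Coefficients are in the raw (uncentered) basis, low order first:
    ``y = c0 + c1*x`` or ``y = c0 + c1*x + c2*x**2``.
    """

    degree: int
    coefficients: np.ndarray
    inlier_mask: np.ndarray
    aic_linear: float
    aic_quadratic: float
    seed: int
    fallback: bool = False  # consensus below min_inclusion -> full-sample OLS
    center: float = field(default=_GA_CENTER)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.polynomial.polynomial.polyval(x, self.coefficients)

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "coefficients": list(map(float, self.coefficients)),
                "inlier_indices": np.flatnonzero(self.inlier_mask).tolist(),
                "n": int(self.inlier_mask.size),
                "aic_linear": self.aic_linear,
                "aic_quadratic": self.aic_quadratic,
                "seed": self.seed,
                "fallback": self.fallback,
                "center": self.center,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        mask = np.zeros(d["n"], dtype=bool)
        mask[d["inlier_indices"]] = True
        return cls(
            degree=d["degree"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            inlier_mask=mask,
            aic_linear=d["aic_linear"],
            aic_quadratic=d["aic_quadratic"],
            seed=d["seed"],
            fallback=d["fallback"],
            center=d["center"],
        )


def _centered_to_raw(coefs_c: np.ndarray, center: float) -> np.ndarray:
    """Convert coefficients of p(x - center) to the raw basis."""
    p = np.polynomial.Polynomial(coefs_c)
    # substitute x -> x - center
    shifted = p(np.polynomial.Polynomial([-center, 1.0]))
    out = np.zeros(len(coefs_c))
    out[: len(shifted.coef)] = shifted.coef
    return out


def _ols_centered(Xc: np.ndarray, y: np.ndarray) -> np.ndarray:
    coefs, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return coefs


def _aic(rss: float, n: int, degree: int, y_scale: float) -> float:
    """Gaussian AIC on the full sample; k = degree + 2 (coefs + sigma)."""
    # floor keeps noiseless fits finite and preserves the parameter penalty
    floor = n * (1e-12 * max(1.0, y_scale)) ** 2
    rss = max(rss, floor)
    k = degree + 2
    return n * np.log(rss / n) + 2 * k


def _ransac_degree(
    x: np.ndarray,
    y: np.ndarray,
    degree: int,
    rng: np.random.Generator,
    min_inclusion: float,
    center: float,
    threshold_k: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One RANSAC consensus fit at fixed degree.

    Returns (centered coefficients, inlier mask, fallback flag).
    """
    n = x.size
    m = degree + 1
    xc = x - center
    X = np.vander(xc, m, increasing=True)

    y_scale = float(np.median(np.abs(y))) if n else 1.0
    atol = 1e-9 * max(1.0, y_scale)

    # minimal subsets for all trials at once
    idx = np.empty((N_TRIALS, m), dtype=np.intp)
    for t in range(N_TRIALS):
        idx[t] = rng.choice(n, size=m, replace=False)

    A = X[idx]                      # (T, m, m)
    b = y[idx]                      # (T, m)
    coefs = np.linalg.pinv(A) @ b[..., None]      # (T, m, 1)
    preds = X @ coefs[..., 0].T                   # (n, T)
    resid = y[:, None] - preds

    # consensus trial = least median absolute residual (robust to ~50%
    # contamination and immune to threshold inflation by sloppy trials)
    scores = np.median(np.abs(resid), axis=0)
    best = int(np.argmin(scores))                 # ties -> lowest trial index
    r_best = resid[:, best]
    mad = np.median(np.abs(r_best - np.median(r_best)))
    thr = max(threshold_k * 1.4826 * mad, atol)
    mask = np.abs(r_best) <= thr

    fallback = int(mask.sum()) < int(np.ceil(min_inclusion * n))
    if fallback:
        mask = np.ones(n, dtype=bool)
    coefs_c = _ols_centered(X[mask], y[mask])
    return coefs_c, mask, fallback


def fit_growth_model(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 42,
    min_inclusion: float = 0.75,
    threshold_k: float = DEFAULT_THRESHOLD_K,
) -> FittedModel:
    """Robust growth-model fit: RANSAC consensus + OLS refit, AIC degree choice.

    Degree 1 and degree 2 polynomials are each fitted by RANSAC (minimal
    subsets, residual threshold ``threshold_k x 1.4826 x MAD`` of the consensus
    trial's residuals,
    consensus must keep at least ``min_inclusion`` of the sample, otherwise
    the fit falls back to full-sample least squares and is flagged). The
    degree with the lower full-sample Gaussian AIC is returned.

    Parameters
    ----------
    x, y : 1-D arrays of equal length, n >= 10.
    seed : RNG seed for the consensus sampling (analysis default 42).
    min_inclusion : minimum consensus fraction (default 0.75).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")

    in_window = x.min() >= _GA_WINDOW[0] - 1e-9 and x.max() <= _GA_WINDOW[1] + 1e-9
    center = _GA_CENTER if in_window else float(np.median(x))

    y_scale = float(np.median(np.abs(y)))
    if np.ptp(x) <= 1e-12 * max(1.0, np.abs(x).max()):
        # degenerate covariate: constant model, nothing to remove
        coefs = np.array([float(np.mean(y)), 0.0])
        rss = float(np.sum((y - coefs[0]) ** 2))
        aic1 = _aic(rss, n, 1, y_scale)
        return FittedModel(1, coefs, np.ones(n, bool), aic1, np.inf, seed,
                           fallback=True, center=center)

    rng = np.random.default_rng(seed)
    results = {}
    for degree in (1, 2):
        coefs_c, mask, fb = _ransac_degree(x, y, degree, rng, min_inclusion,
                                           center, threshold_k)
        raw = _centered_to_raw(coefs_c, center)
        pred = np.polynomial.polynomial.polyval(x, raw)
        rss_full = float(np.sum((y - pred) ** 2))
        results[degree] = (raw, mask, fb, _aic(rss_full, n, degree, y_scale))

    aic1, aic2 = results[1][3], results[2][3]
    degree = 1 if aic1 <= aic2 else 2
    raw, mask, fb, _ = results[degree]
    return FittedModel(degree, raw, mask, aic1, aic2, seed,
                       fallback=fb, center=center)


@dataclass
class ResidualizationResult:
    """Final residuals plus the per-step fitted models."""

    residuals: np.ndarray
    fits: list[FittedModel | None]


def residualize(
    y: np.ndarray,
    covariates,
    seed: int = 42,
    preserve_mean: bool = False,
) -> ResidualizationResult:
    """Sequential robust residualization against an ordered covariate list.

    ``covariates`` is an ordered list of ``(x, model)`` pairs; ``model`` may
    be None, in which case a robust fit of the current residuals against x
    is made on the fly. Order matters with correlated covariates and follows
    the analysis contract: GA first, then residual brain volume, then (for
    thickness) regional depth.

    With ``preserve_mean`` the prediction is centered before subtraction, so
    the adjusted values keep the sample's mean level (needed wherever group
    means, percent changes, or asymmetry indices of adjusted values are
    formed — pure residuals are zero-mean and would make ratios undefined).
    """
    r = np.asarray(y, dtype=float).ravel().copy()
    fits: list[FittedModel | None] = []
    for x, model in covariates:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != r.size:
            raise ValueError("covariate length does not match y")
        if model is None:
            model = fit_growth_model(x, r, seed=seed)
        pred = model.predict(x)
        if preserve_mean:
            pred = pred - pred.mean()
        r = r - pred
        fits.append(model)
    return ResidualizationResult(r, fits)


def residual_brain_volume(
    brain_volume: np.ndarray, ga: np.ndarray, seed: int = 42
) -> np.ndarray:
    """Supratentorial brain volume with its GA trend removed (mm^3)."""
    return residualize(brain_volume, [(ga, None)], seed=seed).residuals
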