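"""Cumulative ordinal model variants with cluster random intercepts.

Three variants of the cumulative logit model are supported, all with logistic
distribution function F and strictly increasing thresholds theta_1 < ... < theta_{k-1}:

``cumulative_re``
    Random-effects proportional odds: eta_r = theta_r - x'beta - b_loc, with a single
    (scalar) cluster random intercept b_loc ~ N(0, sigma^2).
``location_scale``
    The whole location expression is divided by a log-linear scale:
    eta_r = (theta_r - x'beta - b_loc) / exp(z'alpha + b_disp). Positive dispersion
    effects inflate the latent variability (responses spread to the extremes).
``location_shift``
    Thresholds are shifted additively and symmetrically around the middle:
    eta_r = theta_r - x'beta - b_loc + (r - k/2)(z'alpha + b_disp). A positive shift
    widens the inner threshold intervals (tendency to the middle categories); the
    shifted thresholds must remain increasing.

Cluster random intercepts (b_loc, b_disp) are bivariate normal with covariance
Sigma_b for the dispersion variants.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CUMULATIVE_RE = "cumulative_re"
LOCATION_SCALE = "location_scale"
LOCATION_SHIFT = "location_shift"
VARIANTS = (CUMULATIVE_RE, LOCATION_SCALE, LOCATION_SHIFT)


class ThresholdOrderingError(ValueError):
    """Shifted thresholds of a location-shift model are not strictly increasing."""


@dataclass(frozen=True)
class ModelSpec:
    """Model variant plus design-column usage.

    ``location_columns`` / ``dispersion_columns`` index into the encoded X / Z design
    matrices; ``None`` means all columns.
    """

    variant: str
    k: int
    location_columns: tuple | None = None
    dispersion_columns: tuple | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.variant == CUMULATIVE_RE and self.dispersion_columns:
            raise ValueError("cumulative_re has no dispersion component")

    @property
    def random_effect_dim(self) -> int:
        return 1 if self.variant == CUMULATIVE_RE else 2

    def select_X(self, X: np.ndarray) -> np.ndarray:
        return X if self.location_columns is None else X[:, list(self.location_columns)]

    def select_Z(self, Z: np.ndarray) -> np.ndarray:
        if self.variant == CUMULATIVE_RE:
            return np.empty((Z.shape[0], 0))
        return Z if self.dispersion_columns is None else Z[:, list(self.dispersion_columns)]


@dataclass
class Parameters:
    """Model parameters: thresholds, location/dispersion coefficients, Sigma_b.

    ``Sigma_b`` is the random-intercept covariance: a 2x2 matrix for the dispersion
    variants, a 1x1 matrix (variance sigma^2) for ``cumulative_re``.
    """

    thresholds: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    Sigma_b: np.ndarray

    def __post_init__(self):
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.empty(0)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float)) if np.size(self.alpha) else np.empty(0)
        self.Sigma_b = np.atleast_2d(np.asarray(self.Sigma_b, dtype=float))
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if not np.allclose(self.Sigma_b, self.Sigma_b.T):
            raise ValueError("Sigma_b must be symmetric")
        if np.linalg.eigvalsh(self.Sigma_b).min() < -1e-10:
            raise ValueError("Sigma_b must be positive semidefinite")

    @property
    def sigma2(self) -> float:
        """Location random-intercept variance."""
        return float(self.Sigma_b[0, 0])


@dataclass(frozen=True)
class RandomEffect:
    """Cluster random intercepts; ``b_disp`` is 0 for the cumulative_re variant."""

    b_loc: float
    b_disp: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.b_loc) and np.isfinite(self.b_disp)):
            raise ValueError("random effects must be finite")


def logistic_cdf(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def check_threshold_ordering(params: Parameters, delta: float, k: int) -> bool:
    """Whether thresholds shifted by (r - k/2)*delta are strictly increasing."""
    if k < 3:
        raise ValueError("k must be >= 3")
    r = np.arange(1, k)
    shifted = params.thresholds + (r - k / 2.0) * delta
    return bool(np.all(np.diff(shifted) > 0))


def linear_predictors(
    spec: ModelSpec, params: Parameters, x_row, z_row, b: RandomEffect
) -> np.ndarray:
    """Cumulative-logit linear predictors eta_1..eta_{k-1} for one observation."""
    x_row = np.atleast_1d(np.asarray(x_row, dtype=float)) if np.size(x_row) else np.empty(0)
    z_row = np.atleast_1d(np.asarray(z_row, dtype=float)) if np.size(z_row) else np.empty(0)
    loc = params.thresholds - (x_row @ params.beta if params.beta.size else 0.0) - b.b_loc
    if spec.variant == CUMULATIVE_RE:
        return loc
    disp = (z_row @ params.alpha if params.alpha.size else 0.0) + b.b_disp
    if spec.variant == LOCATION_SCALE:
        return loc / np.exp(disp)
    # location_shift
    if not check_threshold_ordering(params, disp, spec.k):
        raise ThresholdOrderingError(
            f"shift {disp:.4f} violates threshold ordering for thresholds {params.thresholds}"
        )
    r = np.arange(1, spec.k)
    return loc + (r - spec.k / 2.0) * disp


def category_probabilities(
    spec: ModelSpec, params: Parameters, x_row, z_row, b: RandomEffect
) -> np.ndarray:
    """Category probabilities P(y=1..k) for one observation; sums to 1."""
    eta = linear_predictors(spec, params, x_row, z_row, b)
    cdf = np.concatenate([[0.0], logistic_cdf(eta), [1.0]])
    return np.diff(cdf)
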