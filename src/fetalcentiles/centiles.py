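"""Age-conditional reference (centile) models for fetal brain biometry.

The construction follows the Royston-Wright mean-and-SD method for
Gaussian reference intervals:

1. the cross-sectional mean of a measurement is fitted as a function of
   gestational age (GA) by ordinary least squares — a quadratic polynomial
   in centered GA, or a log-linear (exponential) curve for measurements
   with multiplicative growth such as cortical volume;
2. the age-varying SD is fitted by OLS regression of the scaled absolute
   residuals |r|·sqrt(pi/2) on centered GA (the sqrt(pi/2) factor is the
   half-normal mean correction: if r ~ N(0, sigma^2) then
   E|r|·sqrt(pi/2) = sigma);
3. the p-th centile at age g is mean(g) + K(p)·SD(g), with K(p) the
   standard-normal quantile of p.

Measurements are assumed Gaussian at each GA (no Box-Cox/LMS skewness
correction); z-scores are (y - mean(g))/SD(g).

GA is centered (default at 30 weeks) before fitting for numerical
conditioning; coefficients are stored on the centered scale together with
the centering constant, so predictions are invariant to a common shift of
the ages and the center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, DegenerateSDError, DomainError

HALF_NORMAL_SCALE = float(np.sqrt(np.pi / 2.0))

MEAN_FAMILIES = ("quadratic", "exponential")
SD_FAMILIES = ("linear", "quadratic")

_SCHEMA_VERSION = 1


def _design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(t, degree + 1, increasing=True)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares solve with an explicit rank check."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            "design matrix is rank deficient (ages carry no polynomial contrast)"
        )
    coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coeffs


def fit_mean(
    ga: np.ndarray,
    y: np.ndarray,
    family: str = "quadratic",
    ga_center: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the mean curve by OLS; return (coefficients, raw-scale residuals).

    ``family='quadratic'`` fits y = a + b·t + c·t² with t = GA − ga_center.
    ``family='exponential'`` fits ln(y) = α + k·t, i.e. mean = exp(α + k·t);
    residuals are returned on the ORIGINAL measurement scale, y − mean(GA),
    so that the SD model applies to raw values.
    """
    ga = np.asarray(ga, dtype=float)
    y = np.asarray(y, dtype=float)
    if ga.shape != y.shape or ga.ndim != 1:
        raise ValueError("ga and y must be 1-D arrays of equal length")
    if family not in MEAN_FAMILIES:
        raise ValueError(f"unknown mean family {family!r}")
    n_coef = 3 if family == "quadratic" else 2
    if len(ga) < n_coef + 2:
        raise DegenerateDesignError(
            f"need at least {n_coef + 2} points for a {family} mean fit, got {len(ga)}"
        )
    t = ga - ga_center
    if family == "quadratic":
        coeffs = _ols(_design(t, 2), y)
        fitted = _design(t, 2) @ coeffs
    else:
        if np.any(y <= 0):
            raise DomainError("exponential mean family requires strictly positive values")
        coeffs = _ols(_design(t, 1), np.log(y))
        fitted = np.exp(_design(t, 1) @ coeffs)
    if not np.all(np.isfinite(coeffs)):
        raise DegenerateDesignError("non-finite coefficients from mean fit")
    return coeffs, y - fitted


def fit_sd(
    ga: np.ndarray,
    residuals: np.ndarray,
    family: str = "linear",
    ga_center: float = 30.0,
) -> np.ndarray:
    """Fit the SD curve: OLS of |r|·sqrt(pi/2) on centered GA."""
    ga = np.asarray(ga, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if family not in SD_FAMILIES:
        raise ValueError(f"unknown SD family {family!r}")
    n_coef = 2 if family == "linear" else 3
    if len(ga) < n_coef + 2:
        raise DegenerateDesignError(
            f"need at least {n_coef + 2} points for a {family} SD fit, got {len(ga)}"
        )
    if np.allclose(residuals, 0.0):
        raise DegenerateSDError("all residuals are zero; the model would claim no variability")
    scaled = np.abs(residuals) * HALF_NORMAL_SCALE
    degree = 1 if family == "linear" else 2
    return _ols(_design(ga - ga_center, degree), scaled)


@dataclass
class CentileModel:
    """A fitted mean-plus-SD reference model for one measurement.

    Coefficients are on centered GA (t = GA − ga_center), lowest order
    first. For the exponential mean family ``mean_coeffs`` is (α, k) with
    mean(g) = exp(α + k·t); the absolute growth rate is then k·mean(g).
    """

    measurement_name: str
    mean_family: str
    mean_coeffs: list[float]
    sd_family: str
    sd_coeffs: list[float]
    ga_center: float
    ga_domain: tuple[float, float]
    n_scans: int
    diagnostics: dict = field(default_factory=dict)

    # -- curve evaluation -------------------------------------------------
    def mean(self, ga):
        t = np.asarray(ga, dtype=float) - self.ga_center
        c = self.mean_coeffs
        if self.mean_family == "quadratic":
            return c[0] + c[1] * t + c[2] * t * t
        return np.exp(c[0] + c[1] * t)

    def sd(self, ga):
        t = np.asarray(ga, dtype=float) - self.ga_center
        c = self.sd_coeffs
        out = c[0] + c[1] * t
        if self.sd_family == "quadratic":
            out = out + c[2] * t * t
        return out

    def mean_derivative(self, ga):
        """Analytic d mean/d GA in measurement units per week."""
        t = np.asarray(ga, dtype=float) - self.ga_center
        c = self.mean_coeffs
        if self.mean_family == "quadratic":
            return c[1] + 2.0 * c[2] * t
        return c[1] * np.exp(c[0] + c[1] * t)

    def in_domain(self, ga):
        ga = np.asarray(ga, dtype=float)
        lo, hi = self.ga_domain
        return (ga >= lo) & (ga <= hi)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = _SCHEMA_VERSION
        d["ga_domain"] = list(self.ga_domain)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CentileModel":
        d = dict(d)
        d.pop("schema_version", None)
        d["ga_domain"] = tuple(d["ga_domain"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "CentileModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CentileResult:
    """Outcome of placing a value on a reference model at a given GA."""

    percentile: float
    z_score: float
    extrapolated: bool


def _check_sd_positive(model: CentileModel, n_grid: int = 201) -> None:
    lo, hi = model.ga_domain
    grid = np.linspace(lo, hi, n_grid)
    if np.any(model.sd(grid) <= 0):
        raise DegenerateSDError(
            f"fitted SD curve for {model.measurement_name!r} is non-positive "
            f"inside the GA domain [{lo:.2f}, {hi:.2f}]"
        )


def fit_centile_model(
    ga,
    y,
    mean_family: str = "quadratic",
    sd_family: str = "linear",
    measurement_name: str = "measurement",
    ga_center: float = 30.0,
) -> CentileModel:
    """Fit the full reference model: mean curve, then SD curve, then z-scores.

    Raises ``DegenerateSDError`` if the fitted SD line crosses zero inside
    the observed GA range — such a model is unusable as a reference and the
    failure is loud rather than silently floored.
    """
    ga = np.asarray(ga, dtype=float)
    y = np.asarray(y, dtype=float)
    mean_coeffs, residuals = fit_mean(ga, y, mean_family, ga_center)
    sd_coeffs = fit_sd(ga, residuals, sd_family, ga_center)
    model = CentileModel(
        measurement_name=measurement_name,
        mean_family=mean_family,
        mean_coeffs=[float(c) for c in mean_coeffs],
        sd_family=sd_family,
        sd_coeffs=[float(c) for c in sd_coeffs],
        ga_center=float(ga_center),
        ga_domain=(float(ga.min()), float(ga.max())),
        n_scans=int(len(ga)),
    )
    _check_sd_positive(model)
    z = residuals / model.sd(ga)
    model.diagnostics = {
        "residual_sd": float(np.std(residuals, ddof=1)),
        "z_scores": [float(v) for v in z],
        "z_mean": float(np.mean(z)),
    }
    return model


def k_value(p: float) -> float:
    """Standard-normal quantile K(p); K(0.5) = 0, K(p) = −K(1−p)."""
    if not 0.0 < p < 1.0:
        raise DomainError(f"centile probability must be in (0, 1), got {p}")
    return float(stats.norm.ppf(p))


def centile_curve(model: CentileModel, p: float, ga_grid) -> np.ndarray:
    """Evaluate the p-th centile curve: mean(g) + K(p)·SD(g)."""
    ga_grid = np.asarray(ga_grid, dtype=float)
    return model.mean(ga_grid) + k_value(p) * model.sd(ga_grid)


def value_to_centile(model: CentileModel, ga: float, value: float) -> CentileResult:
    """Place a measured value on the reference: percentile in (0, 100) and z."""
    sd = float(model.sd(ga))
    if sd <= 0:
        raise DegenerateSDError(f"SD is non-positive at GA {ga}")
    z = (float(value) - float(model.mean(ga))) / sd
    return CentileResult(
        percentile=float(100.0 * stats.norm.cdf(z)),
        z_score=float(z),
        extrapolated=not bool(model.in_domain(ga)),
    )


def centile_to_value(model: CentileModel, ga: float, p: float) -> float:
    """Inverse of :func:`value_to_centile`: the value at the p-th centile."""
    sd = float(model.sd(ga))
    if sd <= 0:
        raise DegenerateSDError(f"SD is non-positive at GA {ga}")
    return float(model.mean(ga)) + k_value(p) * sd
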