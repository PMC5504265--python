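"""Rater/method agreement statistics.

Used for intra-/inter-rater reliability of the biometric measurements and
for comparing 2D measurements made before versus after motion-corrected
volume reconstruction: intraclass correlation, Bland-Altman limits of
agreement, per-pair percentage error, and the Spearman rank correlation
used for monotone associations throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError


@dataclass
class AgreementReport:
    n_pairs: int
    icc: float
    icc_variant: str
    bias: float
    loa_low: float
    loa_high: float
    percentage_errors: list[float]
    pct_err_min: float
    pct_err_max: float
    pct_err_mean: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "icc": self.icc,
            "icc_variant": self.icc_variant,
            "bland_altman": {"bias": self.bias, "loa_low": self.loa_low, "loa_high": self.loa_high},
            "percentage_error": {
                "min": self.pct_err_min,
                "max": self.pct_err_max,
                "mean": self.pct_err_mean,
            },
        }


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be an (n, 2) array-like")
    return arr[:, 0], arr[:, 1]


def icc(pairs) -> float:
    """ICC(A,1): two-way, absolute-agreement, single-measure intraclass
    correlation from the two-way ANOVA mean squares.

    With n targets and k=2 raters,

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n)

    where MS_R, MS_C, MS_E are the rows (targets), columns (raters) and
    residual mean squares. Absolute agreement: a constant offset between
    raters lowers the coefficient.
    """
    a, b = _pairs_to_arrays(pairs)
    n = len(a)
    if n < 3:
        raise DomainError("need at least 3 pairs for an ICC")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise DomainError("zero total variance: ICC undefined")
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise DomainError("degenerate variance structure: ICC undefined")
    return float((ms_r - ms_e) / denom)


def bland_altman(pairs) -> tuple[float, float, float, np.ndarray]:
    """Bias and 95% limits of agreement of paired differences.

    Returns (bias, loa_low, loa_high, table) with LoA = bias ± 1.96·SD of
    the differences; ``table`` is the (mean, difference) per-pair array
    for plotting.
    """
    a, b = _pairs_to_arrays(pairs)
    if len(a) < 2:
        raise DomainError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = np.column_stack([(a + b) / 2.0, diff])
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, table


def percentage_error(pairs) -> tuple[np.ndarray, dict[str, float]]:
    """Per-pair percent disagreement 100·|a−b|/mean(a,b) and its summary."""
    a, b = _pairs_to_arrays(pairs)
    means = (a + b) / 2.0
    if np.any(means <= 0):
        raise DomainError("pair means must be strictly positive")
    pct = 100.0 * np.abs(a - b) / means
    return pct, {"min": float(pct.min()), "max": float(pct.max()), "mean": float(pct.mean())}


def spearman_r(x, y, with_p: bool = False):
    """Spearman rank correlation (mid-ranks for ties).

    Returns r, or (r, p) with ``with_p=True`` (p from the t approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise DomainError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("constant vector: rank correlation undefined")
    r, p = stats.spearmanr(x, y)
    return (float(r), float(p)) if with_p else float(r)


def agreement_report(pairs) -> AgreementReport:
    """Full agreement analysis for one paired comparison."""
    a, b = _pairs_to_arrays(pairs)
    bias, lo, hi, _ = bland_altman(pairs)
    pct, summ = percentage_error(pairs)
    return AgreementReport(
        n_pairs=len(a),
        icc=icc(pairs),
        icc_variant="ICC(A,1)",
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        percentage_errors=[float(v) for v in pct],
        pct_err_min=summ["min"],
        pct_err_max=summ["max"],
        pct_err_mean=summ["mean"],
    )
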