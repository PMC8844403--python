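"""Agreement statistics for predicted vs. reference cardiac volumes.

Provides the evaluation surface used for EDV/ESV/EF predictions: RMSE, MAE,
Pearson correlation with a two-sided p-value, Bland–Altman bias and
±1.96 SD limits of agreement, a seeded percentile-bootstrap confidence
interval for the MAE, and a Kruskal–Wallis comparison of per-subject error
distributions between two models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "QuantityAgreement",
    "AgreementReport",
    "agreement",
    "agreement_report",
    "bootstrap_mae_ci",
    "compare_models",
]


@dataclass(frozen=True)
class QuantityAgreement:
    """Agreement metrics for one quantity (differences are pred − truth)."""

    rmse: float
    mae: float
    pearson_r: float
    pearson_p: float
    ba_bias: float
    ba_limits: tuple[float, float]
    mae_ci95: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AgreementReport:
    """Per-quantity agreement for the three functional indices."""

    edv: QuantityAgreement
    esv: QuantityAgreement
    ef: QuantityAgreement

    def to_dict(self) -> dict:
        return {"edv": self.edv.to_dict(), "esv": self.esv.to_dict(), "ef": self.ef.to_dict()}


def agreement(
    pred: np.ndarray,
    truth: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> QuantityAgreement:
    """Full agreement analysis of one predicted quantity against reference.

    Bland–Altman limits are ``bias ± 1.96·SD`` of the differences (sample
    SD); the MAE confidence interval uses the seeded percentile bootstrap.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1D arrays of equal length")
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.isnan(pred).any() or np.isnan(truth).any():
        raise ValueError("missing values are not allowed")
    if np.std(pred) == 0 or np.std(truth) == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")

    diff = pred - truth
    rmse = float(np.sqrt(np.mean(diff**2)))
    abs_err = np.abs(diff)
    mae = float(np.mean(abs_err))
    r, p = stats.pearsonr(pred, truth)
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    limits = (bias - 1.96 * sd, bias + 1.96 * sd)
    ci = bootstrap_mae_ci(abs_err, n_boot=n_boot, seed=seed)
    return QuantityAgreement(
        rmse=rmse,
        mae=mae,
        pearson_r=float(r),
        pearson_p=float(p),
        ba_bias=bias,
        ba_limits=limits,
        mae_ci95=ci,
        n=n,
    )


def agreement_report(
    pred_edv, truth_edv, pred_esv, truth_esv, pred_ef, truth_ef, seed: int = 0
) -> AgreementReport:
    """Agreement for all three indices in one report."""
    return AgreementReport(
        edv=agreement(pred_edv, truth_edv, seed=seed),
        esv=agreement(pred_esv, truth_esv, seed=seed),
        ef=agreement(pred_ef, truth_ef, seed=seed),
    )


def bootstrap_mae_ci(
    errors: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile-bootstrap 95% CI of the mean absolute error."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size < 3:
        raise ValueError("need at least 3 errors")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, errors.size, size=(n_boot, errors.size))
    maes = errors[idx].mean(axis=1)
    lo, hi = np.percentile(maes, [2.5, 97.5])
    return float(lo), float(hi)


def compare_models(
    errors_a: np.ndarray, errors_b: np.ndarray
) -> tuple[float, float]:
    """Kruskal–Wallis test on two groups of per-subject errors.

    Rank-based and tie-corrected; for two groups it is equivalent to a
    rank-sum test.  Identical distributions across both groups (all values
    equal) yield ``(0, 1)`` with a warning.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all errors identical in both groups", UserWarning, stacklevel=2)
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)
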