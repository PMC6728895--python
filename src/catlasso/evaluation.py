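"""Evaluation indices: pattern accuracy, parameter recovery, item exposure.

* CSR — correct specification rate: the fraction of item x trait pattern
  entries recovered correctly over the J1 replenished items.
* AME / RMSE — mean absolute and root-mean-squared error of ability or
  item-parameter estimates, averaged over all entries.
* Chi-square exposure statistic — sum over operational items of
  (ER_j - Z0/J0)^2 / (Z0/J0), where ER_j is the observed exposure rate and
  Z0/J0 the uniform benchmark.
* TOR — test overlap ratio, N * sum_j ER_j^2 / ((N-1) * Z0) - 1/(N-1):
  the expected proportion of items shared by two randomly paired
  examinees' tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExposureSummary",
    "csr",
    "ame_theta",
    "rmse_theta",
    "ame_item",
    "exposure_chi_square",
    "test_overlap_ratio",
]


def _check_same_shape(x: np.ndarray, y: np.ndarray, what: str) -> None:
    if x.shape != y.shape:
        raise ValueError(f"{what} shapes differ: {x.shape} vs {y.shape}")


def csr(Q_true: np.ndarray, Q_hat: np.ndarray) -> float:
    """Correct specification rate: fraction of matching pattern entries."""
    Q_true = np.asarray(Q_true, dtype=int)
    Q_hat = np.asarray(Q_hat, dtype=int)
    _check_same_shape(Q_true, Q_hat, "pattern matrix")
    return float(np.mean(Q_true == Q_hat))


def ame_theta(theta_true: np.ndarray, theta_hat: np.ndarray) -> float:
    """Mean absolute error over all N x K ability entries."""
    theta_true = np.asarray(theta_true, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    _check_same_shape(theta_true, theta_hat, "ability matrix")
    return float(np.mean(np.abs(theta_hat - theta_true)))


def rmse_theta(theta_true: np.ndarray, theta_hat: np.ndarray) -> float:
    """Root of the mean squared error over all N x K ability entries."""
    theta_true = np.asarray(theta_true, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    _check_same_shape(theta_true, theta_hat, "ability matrix")
    return float(np.sqrt(np.mean((theta_hat - theta_true) ** 2)))


def ame_item(
    a_true: np.ndarray,
    a_hat: np.ndarray,
    b_true: np.ndarray,
    b_hat: np.ndarray,
) -> tuple[float, float]:
    """Mean absolute errors of discrimination and intercept estimates.

    Discriminations are compared entrywise over all J1 x K coordinates,
    including structural zeros, so pattern misspecifications propagate into
    AME(a).  Returns ``(AME_a, AME_b)``.
    """
    a_true = np.asarray(a_true, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    b_true = np.asarray(b_true, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    _check_same_shape(a_true, a_hat, "discrimination matrix")
    _check_same_shape(b_true, b_hat, "intercept vector")
    return (
        float(np.mean(np.abs(a_hat - a_true))),
        float(np.mean(np.abs(b_hat - b_true))),
    )


@dataclass(frozen=True)
class ExposureSummary:
    """Observed exposure rates of the operational items of one cohort."""

    exposure_rates: np.ndarray
    N: int
    Z0: float
    J0: int

    def __post_init__(self) -> None:
        rates = np.asarray(self.exposure_rates, dtype=float)
        object.__setattr__(self, "exposure_rates", rates)
        if rates.shape != (self.J0,):
            raise ValueError(f"expected {self.J0} exposure rates, got {rates.shape}")
        if (rates < 0).any() or (rates > 1).any():
            raise ValueError("exposure rates must lie in [0, 1]")


def exposure_chi_square(summary: ExposureSummary) -> float:
    """Chi-square departure of the exposure rates from uniform Z0/J0."""
    if summary.Z0 <= 0:
        raise ValueError("Z0 must be positive")
    target = summary.Z0 / summary.J0
    return float(np.sum((summary.exposure_rates - target) ** 2 / target))


def test_overlap_ratio(summary: ExposureSummary) -> float:
    """Expected proportion of shared items between two random examinees."""
    if summary.N < 2:
        raise ValueError("TOR requires at least two examinees")
    N = summary.N
    return float(
        N * np.sum(summary.exposure_rates**2) / ((N - 1) * summary.Z0)
        - 1.0 / (N - 1)
    )
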