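"""Confusion-matrix estimation, additive smoothing, and prior marginalization.

The classifier's error model is a row-stochastic 6x6 matrix C with
C[y, yhat] = P(predicted yhat | true y), estimated from counts on a held-out
test set. Because the test set is finite, downstream inference does not trust
C literally: additive smoothing with parameter alpha pulls every row toward
the uniform distribution,

    C~(alpha)[y, yhat] = (C[y, yhat] + alpha) / (1 + 6 alpha),

and alpha is marginalized under a shifted exponential prior
p(alpha) = lambda * exp(-lambda (alpha - eps)) on [eps, inf). The entrywise
expectation has a convenient form: since

    C~(alpha) = 1/6 + (C - 1/6) / (1 + 6 alpha),

only the scalar g(lambda, eps) = E[1 / (1 + 6 alpha)] is needed, computed by
adaptive quadrature after the substitution u = exp(-lambda (alpha - eps))
which maps the infinite tail to (0, 1]. Row sums are preserved exactly.

The rate lambda is interpretable through the expected average accuracy
c_exp = mean diagonal of E[C~]: lambda -> 0 gives chance level (1/6),
lambda -> inf recovers the eps-smoothed test-set accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .labels import N_TRANSMITTERS, TRANSMITTERS

__all__ = [
    "ConfusionMatrix",
    "SmoothingPrior",
    "DegenerateRowError",
    "estimate_confusion",
    "smooth_confusion",
    "expected_confusion",
    "expected_accuracy",
    "solve_lambda_for_accuracy",
    "uniform_confusion",
    "diagonal_confusion",
]

_K = N_TRANSMITTERS
_ROW_TOL = 1e-9


class DegenerateRowError(ValueError):
    """A confusion-count row has zero total and no smoothing to rescue it."""


@dataclass(frozen=True)
class SmoothingPrior:
    """Shifted exponential prior on the smoothing parameter alpha.

    Parameters
    ----------
    lambda_rate :
        Rate of the exponential; larger values concentrate mass near
        ``epsilon`` (i.e. trust the observed matrix more).
    epsilon :
        Lower bound of the support; the minimal smoothing applied so no
        misclassification probability is exactly zero. Must lie in (0, 0.1).
    """

    lambda_rate: float
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.lambda_rate > 0 and np.isfinite(self.lambda_rate)):
            raise ValueError(f"lambda_rate must be positive, got {self.lambda_rate}")
        if not (0 < self.epsilon < 0.1):
            raise ValueError(f"epsilon must be in (0, 0.1), got {self.epsilon}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic 6x6 error model, rows = true label, columns = predicted.

    ``level`` records whether rows were estimated from per-synapse or
    per-neuron test-set predictions; confidence scoring uses the synapse-level
    matrix, hemilineage inference the neuron-level one.
    """

    C: np.ndarray
    level: str = "neuron"

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (_K, _K):
            raise ValueError(f"confusion matrix must be {_K}x{_K}, got {C.shape}")
        if not np.all(np.isfinite(C)):
            raise ValueError("confusion matrix entries must be finite")
        if np.any(C < 0) or np.any(C > 1):
            raise ValueError("confusion matrix entries must lie in [0, 1]")
        rows = C.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            raise ValueError(f"rows must sum to 1 within {_ROW_TOL}; got {rows}")
        if self.level not in ("synapse", "neuron"):
            raise ValueError(f"level must be 'synapse' or 'neuron', got {self.level!r}")
        object.__setattr__(self, "C", C)

    def __getitem__(self, key):
        return self.C[key]

    @property
    def accuracy(self) -> float:
        """Mean diagonal: average per-class recall on the test set."""
        return float(np.mean(np.diag(self.C)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.C, index=list(TRANSMITTERS), columns=list(TRANSMITTERS))


def uniform_confusion(level: str = "neuron") -> ConfusionMatrix:
    """The maximally uninformative error model (every entry 1/6)."""
    return ConfusionMatrix(np.full((_K, _K), 1.0 / _K), level=level)


def diagonal_confusion(diag: float, level: str = "neuron") -> ConfusionMatrix:
    """Symmetric error model with given per-class recall on the diagonal."""
    if not (0 <= diag <= 1):
        raise ValueError("diagonal value must be in [0, 1]")
    off = (1.0 - diag) / (_K - 1)
    C = np.full((_K, _K), off)
    np.fill_diagonal(C, diag)
    return ConfusionMatrix(C, level=level)


def estimate_confusion(
    counts: np.ndarray, beta: int = 0, level: str = "neuron"
) -> ConfusionMatrix:
    """Estimate the confusion matrix from test-set counts with additive smoothing.

    ``C~[y, yhat] = (N[y, yhat] + beta) / (sum_yhat N[y, yhat] + 6 beta)``.

    Parameters
    ----------
    counts :
        6x6 non-negative integer counts, rows = true label.
    beta :
        Non-negative integer pseudo-count added to every cell.
    """
    N = np.asarray(counts)
    if N.shape != (_K, _K):
        raise ValueError(f"counts must be {_K}x{_K}, got {N.shape}")
    if np.any(N < 0) or not np.allclose(N, np.round(N)):
        raise ValueError("counts must be non-negative integers")
    if beta < 0 or int(beta) != beta:
        raise ValueError(f"beta must be a non-negative integer, got {beta}")
    N = N.astype(float)
    row_sums = N.sum(axis=1)
    if beta == 0:
        zero = np.flatnonzero(row_sums == 0)
        if zero.size:
            names = [TRANSMITTERS[i] for i in zero]
            raise DegenerateRowError(
                f"zero count row(s) for {names} with beta=0; "
                "no estimate exists without smoothing"
            )
    C = (N + beta) / (row_sums + _K * beta)[:, None]
    return ConfusionMatrix(C, level=level)


def smooth_confusion(C: ConfusionMatrix, alpha: float) -> ConfusionMatrix:
    """Additively smooth a confusion matrix toward uniform.

    ``C~[y, yhat] = (C[y, yhat] + alpha) / (1 + 6 alpha)``; alpha = 0 returns
    C unchanged, alpha -> inf drives every entry to 1/6. Row sums are
    preserved exactly.
    """
    if alpha < 0 or not np.isfinite(alpha):
        raise ValueError(f"alpha must be a finite non-negative real, got {alpha}")
    return ConfusionMatrix((C.C + alpha) / (1.0 + _K * alpha), level=C.level)


def _shrinkage_factor(prior: SmoothingPrior) -> float:
    """g(lambda, eps) = E_p(alpha)[1 / (1 + 6 alpha)], by adaptive quadrature.

    Substituting u = exp(-lambda (alpha - eps)) maps the integral over
    [eps, inf) to the unit interval:

        g = int_0^1 du / (1 + 6 (eps - ln(u) / lambda)).

    The integrand is bounded on (0, 1] and vanishes at u -> 0.
    """
    lam, eps = prior.lambda_rate, prior.epsilon

    def integrand(u: float) -> float:
        if u <= 0.0:
            return 0.0
        return 1.0 / (1.0 + _K * (eps - np.log(u) / lam))

    g, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-12, limit=200)
    if not np.isfinite(g) or err > 1e-8:
        raise ArithmeticError(
            f"quadrature for the smoothing expectation did not converge "
            f"(estimate {g}, error {err}, lambda={lam}, eps={eps})"
        )
    return g


def expected_confusion(C: ConfusionMatrix, prior: SmoothingPrior) -> ConfusionMatrix:
    """Entrywise expectation of the smoothed matrix under the alpha prior.

    E[C~] = 1/6 + (C - 1/6) * g(lambda, eps), with g the expected shrinkage
    factor; the result is row-stochastic by construction.
    """
    g = _shrinkage_factor(prior)
    E = 1.0 / _K + (C.C - 1.0 / _K) * g
    return ConfusionMatrix(E, level=C.level)


def expected_accuracy(C: ConfusionMatrix, prior: SmoothingPrior) -> float:
    """Expected average accuracy c_exp: mean diagonal of ``expected_confusion``."""
    g = _shrinkage_factor(prior)
    return float(1.0 / _K + (C.accuracy - 1.0 / _K) * g)


def solve_lambda_for_accuracy(
    C: ConfusionMatrix, target_accuracy: float, epsilon: float = 1e-3
) -> float:
    """Invert lambda |-> c_exp for a matrix whose accuracy exceeds chance.

    Valid targets lie strictly between chance (1/6, the lambda -> 0 limit)
    and the eps-smoothed observed accuracy (the lambda -> inf limit); the map
    is strictly increasing in between, so bisection on log10(lambda) applies.
    """
    a = C.accuracy
    hi_limit = (a + epsilon) / (1.0 + _K * epsilon)
    lo_limit = 1.0 / _K
    if a <= lo_limit:
        raise ValueError(
            "accuracy is not above chance; lambda is not identifiable"
        )
    if not (lo_limit < target_accuracy < hi_limit):
        raise ValueError(
            f"target accuracy {target_accuracy} outside the attainable open "
            f"interval ({lo_limit:.6f}, {hi_limit:.6f})"
        )

    def f(log_lam: float) -> float:
        return expected_accuracy(C, SmoothingPrior(10.0**log_lam, epsilon)) - target_accuracy

    lo, hi = -6.0, 8.0
    # widen until the bracket straddles the root (targets near the limits)
    while f(lo) > 0 and lo > -30:
        lo -= 4.0
    while f(hi) < 0 and hi < 30:
        hi += 4.0
    log_lam = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(10.0**log_lam)
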