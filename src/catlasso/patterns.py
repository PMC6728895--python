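"""Item-trait pattern detection by L1-regularized logistic regression + BIC.

Given a replenished item's 0/1 responses ``Y`` (length n) and the ability
scores ``Theta`` (n x K) of the examinees who answered it, the item's
parameters solve, for each penalty ``lam`` on a grid,

    min_{b, a}  -l(b, a; Y, Theta) + lam * sum_k |a_k|,

where ``l`` is the summed Bernoulli log-likelihood of the M2PLM with known
abilities (an ordinary logistic regression) and the intercept ``b`` is not
penalized.  The support of the penalized discrimination vector at each
``lam`` is a candidate item-trait pattern; the BIC

    BIC = -2 * l + df * log(n),      df = |support| + 1,

selects the pattern along the path.  Detected patterns are then used to
refit unpenalized (relaxed) parameter estimates restricted to the support.

The penalty grid is the right-open interval (0, T] divided into W equal
parts: lam_w = w * T / W.  The penalty multiplies the *summed*
log-likelihood; solvers that scale by 1/n need ``lam / n`` to match.

The solver is cyclical coordinate descent on the iteratively reweighted
least-squares (IRLS) quadratic surrogate with coordinate-wise soft
thresholding, warm-started along the path, so zeros are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "LambdaGrid",
    "PathSolution",
    "PatternResult",
    "lambda_grid",
    "fit_l1_logistic",
    "kkt_residuals",
    "path_fit",
    "bic",
    "select_optimal_patterns",
    "refit_item",
    "detect_patterns",
]

_COEF_CAP = 25.0
_MIN_IRLS_WEIGHT = 1e-10


@dataclass(frozen=True)
class LambdaGrid:
    """Penalty grid lam_w = w * T / W for w = 1..W (strictly increasing)."""

    T: float
    W: int
    values: np.ndarray

    def __len__(self) -> int:
        return self.W


def lambda_grid(T: float, W: int) -> LambdaGrid:
    """Divide (0, T] into W equal parts; the grid points are the right ends."""
    if T <= 0:
        raise ValueError("T must be positive")
    if W < 1:
        raise ValueError("W must be at least 1")
    values = T * np.arange(1, W + 1) / W
    return LambdaGrid(T=float(T), W=int(W), values=values)


def _binary_logistic_loglik(y: np.ndarray, X: np.ndarray, b: float, a: np.ndarray) -> float:
    z = X @ a + b
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def fit_l1_logistic(
    y: Sequence[int] | np.ndarray,
    X: np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 1000,
    warm: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, bool]:
    """Solve the L1-penalized logistic regression at one penalty value.

    Minimizes ``-l(b, a) + lam * sum|a_k|`` with an unpenalized intercept
    via cyclical coordinate descent on the IRLS surrogate.  Zeros in the
    returned ``a`` are exact (soft-threshold output).  On (near-)separation
    coefficients are capped at +-25 and the capped flag returned.

    Returns ``(b_hat, a_hat, capped)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary 0/1")
    n, K = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different numbers of rows")

    if warm is not None:
        b, a = float(warm[0]), np.array(warm[1], dtype=float, copy=True)
    else:
        b, a = 0.0, np.zeros(K)
    xsq = X * X
    capped = False

    def objective(b_: float, a_: np.ndarray) -> float:
        return -_binary_logistic_loglik(y, X, b_, a_) + lam * np.abs(a_).sum()

    obj = objective(b, a)
    for _outer in range(max_iter):
        z = X @ a + b
        p = expit(z)
        w = np.maximum(p * (1.0 - p), _MIN_IRLS_WEIGHT)
        # working response for the quadratic surrogate at (b, a)
        u = z + (y - p) / w
        r = u - z  # residual of the current fit
        # one full cyclical coordinate-descent pass on the surrogate
        for _inner in range(200):
            delta = 0.0
            wsum = w.sum()
            db = float(w @ r) / wsum
            b += db
            r -= db
            delta = max(delta, abs(db))
            for k in range(K):
                wx = w * X[:, k]
                rho = float(wx @ r) + float(w @ xsq[:, k]) * a[k]
                denom = float(w @ xsq[:, k])
                if denom <= 0:
                    continue
                ak_new = _soft(rho, lam) / denom
                dak = ak_new - a[k]
                if dak != 0.0:
                    r -= X[:, k] * dak
                    a[k] = ak_new
                    delta = max(delta, abs(dak))
            if delta < tol * 0.1:
                break
        if np.abs(a).max(initial=0.0) > _COEF_CAP or abs(b) > _COEF_CAP:
            a = np.clip(a, -_COEF_CAP, _COEF_CAP)
            b = float(np.clip(b, -_COEF_CAP, _COEF_CAP))
            capped = True
            warnings.warn(
                "coefficients capped at +-25 (data are separated or nearly so)",
                RuntimeWarning,
            )
            break
        obj_new = objective(b, a)
        if obj - obj_new < tol * 1e-2 * max(1.0, abs(obj_new)) and _kkt_ok(y, X, b, a, lam, tol):
            obj = obj_new
            break
        obj = obj_new
    return b, a, capped


def _soft(x: float, thresh: float) -> float:
    if x > thresh:
        return x - thresh
    if x < -thresh:
        return x + thresh
    return 0.0


def kkt_residuals(
    y: np.ndarray, X: np.ndarray, b: float, a: np.ndarray, lam: float
) -> np.ndarray:
    """Per-coordinate KKT violations of the penalized optimum (0 = exact).

    For coordinate k with gradient g_k of the negative log-likelihood:
    zero coefficients require |g_k| <= lam (violation is the excess);
    nonzero coefficients require g_k + lam*sign(a_k) = 0 (violation is the
    absolute residual).  The intercept contributes |sum(y - p)|.
    """
    y = np.asarray(y, dtype=float)
    p = expit(X @ a + b)
    g = -X.T @ (y - p)
    viol = np.where(a == 0.0, np.maximum(np.abs(g) - lam, 0.0), np.abs(g + lam * np.sign(a)))
    return np.append(viol, abs(float(np.sum(y - p))))


def _kkt_ok(y, X, b, a, lam, tol) -> bool:
    scale = max(1.0, float(len(y)) ** 0.5)
    return bool(kkt_residuals(y, X, b, a, lam).max() <= tol * scale * 10)


@dataclass
class PathSolution:
    """Per-penalty solutions for one item along the grid.

    Arrays are indexed by grid position w = 0..W-1 (ascending lam):
    intercepts (W,), coefs (W, K), patterns (W, K) as the exact nonzero
    support, logliks (unpenalized log-likelihood at the penalized
    estimates) and bics.
    """

    grid: LambdaGrid
    intercepts: np.ndarray
    coefs: np.ndarray
    patterns: np.ndarray
    logliks: np.ndarray
    bics: np.ndarray
    capped: np.ndarray
    n: int


def path_fit(
    y: Sequence[int] | np.ndarray,
    X: np.ndarray,
    grid: LambdaGrid,
    tol: float = 1e-7,
) -> PathSolution:
    """Fit the whole penalty path for one item, warm-starting downward.

    Solutions are computed from the largest penalty (sparsest) to the
    smallest, each warm-started from the previous one, and stored in
    ascending grid order.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, K = X.shape
    W = grid.W
    intercepts = np.empty(W)
    coefs = np.empty((W, K))
    logliks = np.empty(W)
    capped = np.zeros(W, dtype=bool)
    warm: tuple[float, np.ndarray] | None = None
    for w in range(W - 1, -1, -1):
        b, a, cap = fit_l1_logistic(y, X, grid.values[w], tol=tol, warm=warm)
        intercepts[w] = b
        coefs[w] = a
        capped[w] = cap
        logliks[w] = _binary_logistic_loglik(y, X, b, a)
        warm = (b, a.copy())
    patterns = (coefs != 0.0).astype(int)
    dfs = patterns.sum(axis=1) + 1
    bics = np.array([bic(logliks[w], int(dfs[w]), n) for w in range(W)])
    if (coefs < 0).any():
        warnings.warn(
            "negative discrimination estimates on the path; nonzero negative "
            "coordinates still count as measured traits",
            RuntimeWarning,
        )
    return PathSolution(
        grid=grid, intercepts=intercepts, coefs=coefs, patterns=patterns,
        logliks=logliks, bics=bics, capped=capped, n=n,
    )


def bic(loglik: float, df: int, n: int) -> float:
    """Schwarz criterion -2*loglik + df*log(n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return -2.0 * loglik + df * (np.log(n) if df else 0.0)


SelectionMode = Literal["joint", "per_item"]


def select_optimal_patterns(
    paths: Sequence[PathSolution], mode: SelectionMode = "joint"
) -> tuple[np.ndarray, np.ndarray]:
    """Pick each item's pattern by minimizing BIC along the penalty grid.

    ``joint`` minimizes the summed BIC over items at a single shared grid
    position (one penalty for the whole item group); ``per_item`` minimizes
    each item's BIC independently.  Ties break toward the larger penalty
    (the sparser solution).

    Returns ``(patterns (J1, K), selected indices (J1,))``.
    """
    if not paths:
        raise ValueError("no paths supplied")
    g0 = paths[0].grid
    for p in paths:
        if p.grid.W != g0.W or p.grid.T != g0.T:
            raise ValueError("all paths must share the same penalty grid")
    if mode == "joint":
        total = np.sum([p.bics for p in paths], axis=0)
        w_star = _argmin_prefer_last(total)
        idx = np.full(len(paths), w_star, dtype=int)
    elif mode == "per_item":
        idx = np.array([_argmin_prefer_last(p.bics) for p in paths], dtype=int)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    patterns = np.array([p.patterns[i] for p, i in zip(paths, idx)])
    return patterns, idx


def _argmin_prefer_last(values: np.ndarray) -> int:
    """Index of the minimum, ties resolved toward the largest index."""
    rev = values[::-1]
    return len(values) - 1 - int(np.argmin(rev))


def refit_item(
    y: Sequence[int] | np.ndarray,
    X: np.ndarray,
    Q: Sequence[int] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, np.ndarray, bool]:
    """Relaxed (unpenalized) refit restricted to a detected pattern.

    Maximum likelihood with ``a_k`` forced to zero wherever ``q_k = 0``,
    by Newton's method (gradient tolerance 1e-8, step-halving).  An
    all-zero pattern reduces to the closed-form intercept-only model.
    Coefficients are capped at +-25 under separation (flag returned).

    Returns ``(b_hat, a_hat_full_K, capped)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Q = np.asarray(Q, dtype=int)
    n, K = X.shape
    support = np.flatnonzero(Q)
    if n <= support.size + 1:
        raise ValueError("need more observations than free parameters")
    Xs = np.column_stack([np.ones(n), X[:, support]])
    beta = np.zeros(Xs.shape[1])
    capped = False

    def loglik(bta: np.ndarray) -> float:
        z = Xs @ bta
        return float(np.sum(y * z - np.logaddexp(0.0, z)))

    f = loglik(beta)
    for _ in range(max_iter):
        z = Xs @ beta
        p = expit(z)
        g = Xs.T @ (y - p)
        if np.abs(g).max() < tol:
            break
        w = np.maximum(p * (1.0 - p), _MIN_IRLS_WEIGHT)
        H = (Xs * w[:, None]).T @ Xs
        delta = np.linalg.solve(H, g)
        step = 1.0
        for _half in range(40):
            beta_new = beta + step * delta
            f_new = loglik(beta_new)
            if f_new >= f - 1e-12:
                break
            step *= 0.5
        beta, f = beta_new, f_new
        if np.abs(beta).max() > _COEF_CAP:
            beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
            capped = True
            warnings.warn(
                "refit coefficients capped at +-25 (separation)", RuntimeWarning
            )
            break
    a = np.zeros(K)
    a[support] = beta[1:]
    return float(beta[0]), a, capped


@dataclass
class PatternResult:
    """Detected patterns and relaxed refits for a set of replenished items."""

    item_ids: np.ndarray
    patterns: np.ndarray
    selected_idx: np.ndarray
    grid: LambdaGrid
    a_refit: np.ndarray
    b_refit: np.ndarray
    refit_capped: np.ndarray
    paths: list[PathSolution]

    @property
    def selected_lambdas(self) -> np.ndarray:
        return self.grid.values[self.selected_idx]


def detect_patterns(
    responses: Sequence[np.ndarray],
    scores: Sequence[np.ndarray],
    grid: LambdaGrid,
    item_ids: Sequence[int] | None = None,
    selection_mode: SelectionMode = "joint",
    bic_mode: Literal["shrunken", "refit"] = "refit",
    refit: bool = True,
) -> PatternResult:
    """Run the full pattern-detection pipeline for a group of items.

    For each item: fit the penalized path on its respondents' scores,
    record candidate patterns and BICs, then select the optimal patterns
    (jointly over the group by default) and refit relaxed parameter
    estimates restricted to the detected supports.

    ``bic_mode='refit'`` (the default) evaluates each candidate pattern's
    BIC at the relaxed maximum-likelihood fit of its support, so the
    criterion measures the goodness of fit of the *pattern* rather than of
    the shrunken coefficients; ``'shrunken'`` evaluates it at the
    penalized estimates instead.
    """
    if len(responses) != len(scores):
        raise ValueError("responses and scores must pair one-to-one")
    J1 = len(responses)
    ids = np.arange(J1) if item_ids is None else np.asarray(item_ids, dtype=int)
    paths = [path_fit(y, X, grid) for y, X in zip(responses, scores)]
    if bic_mode == "refit":
        for path, y, X in zip(paths, responses, scores):
            n = path.n
            cache: dict[tuple, float] = {}
            for w in range(grid.W):
                key = tuple(path.patterns[w])
                if key not in cache:
                    if any(key):
                        b_r, a_r, _ = refit_item(y, X, np.array(key))
                        cache[key] = _binary_logistic_loglik(y, X, b_r, a_r)
                    else:
                        pbar = np.clip(np.mean(y), 1e-12, 1 - 1e-12)
                        cache[key] = float(
                            len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar))
                        )
                path.logliks[w] = cache[key]
                path.bics[w] = bic(cache[key], int(sum(key)) + 1, n)
    elif bic_mode != "shrunken":
        raise ValueError(f"unknown bic_mode {bic_mode!r}")
    patterns, idx = select_optimal_patterns(paths, mode=selection_mode)

    K = scores[0].shape[1]
    a_refit = np.zeros((J1, K))
    b_refit = np.zeros(J1)
    capped = np.zeros(J1, dtype=bool)
    if refit:
        for j, (y, X) in enumerate(zip(responses, scores)):
            if patterns[j].any():
                b_refit[j], a_refit[j], capped[j] = refit_item(y, X, patterns[j])
            else:
                pbar = np.clip(np.mean(np.asarray(y, dtype=float)), 1e-12, 1 - 1e-12)
                b_refit[j] = float(np.log(pbar) - np.log1p(-pbar))
    return PatternResult(
        item_ids=ids, patterns=patterns, selected_idx=idx, grid=grid,
        a_refit=a_refit, b_refit=b_refit, refit_capped=capped, paths=paths,
    )
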