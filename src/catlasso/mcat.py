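"""Adaptive test administration for the M2PLM.

Implements MAP trait estimation, two item-selection criteria, fixed-length
and posterior-SE (variable-length) stopping, replenished-item
administration and exposure accounting.

Selection criteria
------------------
With ``I_S(th)`` the Fisher information of the administered set evaluated
at the interim MAP estimate ``th`` and ``I_i(th)`` a candidate item's
information:

* D-optimality picks ``argmax_i det(I_S(th) + I_i(th))``;
* Bayesian A-optimality picks
  ``argmin_i trace[(I_S(th) + I_i(th) + Sigma0^-1)^-1]``, where ``Sigma0``
  is the prior ability covariance.

Ties (within a 1e-9 relative tolerance) break toward the lowest item id,
so administrations are reproducible.  The first item is selected by the
active criterion at the prior mean.

The cohort runner vectorizes the whole administration across examinees;
``administer_fixed``/``administer_variable`` run the same core with a batch
of one, so a cohort row is exactly what the single-examinee API produces.
Per-examinee randomness is spawned from one seed: ``SeedSequence(seed)``
spawns N+1 children, child ``i`` driving examinee ``i``'s operational
response draws (one uniform per administered item) and the last child the
replenished-item responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from catlasso.m2plm import ItemPool
from catlasso.pools import GroupAssignment, StudyDesign

__all__ = [
    "PriorSpec",
    "TestState",
    "CohortResult",
    "map_estimate",
    "select_item_D",
    "select_item_bayesA",
    "administer_fixed",
    "administer_variable",
    "run_cohort",
    "spawn_examinee_seeds",
]

Criterion = Literal["D", "bayesA"]

_GRAD_TOL = 1e-6
_MAX_NEWTON = 50
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PriorSpec:
    """Multivariate-normal ability prior N(mean, cov) used for MAP scoring
    and as Sigma0 in Bayesian A-optimality."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("prior mean/cov dimensions disagree")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        np.linalg.cholesky(cov)

    @classmethod
    def identity(cls, K: int) -> "PriorSpec":
        return cls(mean=np.zeros(K), cov=np.eye(K))

    @cached_property
    def cov_inv(self) -> np.ndarray:
        return np.linalg.inv(self.cov)

    @property
    def K(self) -> int:
        return self.mean.size


@dataclass
class TestState:
    """Record of one examinee's adaptive administration."""

    administered: list[int]
    responses: list[int]
    theta_hat: np.ndarray
    posterior_cov: np.ndarray
    se: np.ndarray
    info_accum: np.ndarray
    converged: bool = True
    se_history: np.ndarray | None = None

    __test__ = False  # not a pytest class, despite the name

    @property
    def n_administered(self) -> int:
        return len(self.administered)


# ---------------------------------------------------------------------------
# small linear-algebra helpers (batched over leading axes)
# ---------------------------------------------------------------------------


def _adjugate(M: np.ndarray) -> np.ndarray:
    """Adjugate of K x K matrices, K <= 3, batched over leading axes.

    Uses the Cayley-Hamilton closed forms, which remain valid for singular
    matrices (needed in the first steps of a test when the accumulated
    information is rank-deficient).
    """
    K = M.shape[-1]
    eye = np.eye(K)
    if K == 1:
        return np.ones_like(M)
    tr = np.trace(M, axis1=-2, axis2=-1)[..., None, None]
    if K == 2:
        return tr * eye - M
    if K == 3:
        M2 = M @ M
        tr2 = np.trace(M2, axis1=-2, axis2=-1)[..., None, None]
        return M2 - tr * M + 0.5 * (tr * tr - tr2) * eye
    raise ValueError("adjugate closed form implemented for K <= 3")


def _quad_forms(Mb: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Quadratic forms a_m' M_n a_m for batched matrices.

    Mb is (n, K, K), A is (m, K); returns (n, m).
    """
    n, K, _ = Mb.shape
    G = (A[:, :, None] * A[:, None, :]).reshape(A.shape[0], K * K)
    return Mb.reshape(n, K * K) @ G.T


_D_RIDGE = 1e-6


def _d_scores(Mb: np.ndarray, w: np.ndarray, A: np.ndarray) -> np.ndarray:
    """det(M_n + w_nm a_m a_m' + ridge*I) for every examinee/candidate pair.

    Uses the rank-one determinant identity
    det(M + w a a') = det(M) + w a' adj(M) a.  The tiny ridge (1e-6)
    regularizes the early steps of a test, where the accumulated
    information is rank-deficient and the raw determinant is identically
    zero for every candidate: with the ridge the criterion ranks
    candidates by the information volume on the spanned subspace instead
    of degenerating into a pure tie.  Once the accumulated information is
    full-rank the ridge is negligible.  Larger is better.
    """
    K = Mb.shape[-1]
    Mb = Mb + _D_RIDGE * np.eye(K)
    if K <= 3:
        detM = np.linalg.det(Mb)[:, None]
        return detM + w * _quad_forms(_adjugate(Mb), A)
    outer = A[:, :, None] * A[:, None, :]
    return np.linalg.det(Mb[:, None, :, :] + w[:, :, None, None] * outer[None])


def _bayesA_scores(
    Mb: np.ndarray, w: np.ndarray, A: np.ndarray, prior_inv: np.ndarray
) -> np.ndarray:
    """Negative trace of (M_n + w_nm a_m a_m' + Sigma0^-1)^-1 (larger is better).

    Sherman-Morrison on the (always invertible) base matrix B = M + Sigma0^-1:
    trace[(B + w aa')^-1] = trace(B^-1) - w a' B^-2 a / (1 + w a' B^-1 a).
    """
    B = Mb + prior_inv
    Binv = np.linalg.inv(B)
    t0 = np.trace(Binv, axis1=-2, axis2=-1)[:, None]
    q1 = _quad_forms(Binv, A)
    q2 = _quad_forms(Binv @ Binv, A)
    return -(t0 - w * q2 / (1.0 + w * q1))


def _argbest_rows(scores: np.ndarray) -> np.ndarray:
    """Row-wise argmax with ties (relative tolerance) broken to the lowest index."""
    best = scores.max(axis=1, keepdims=True)
    tol = _TIE_RTOL * np.abs(best)
    return np.argmax(scores >= best - tol, axis=1)


def _accumulated_info(
    theta: np.ndarray, taken: np.ndarray, A_op: np.ndarray, b_op: np.ndarray
) -> np.ndarray:
    """Sum of administered items' Fisher information at the current estimates.

    theta (n, K), taken (n, J0) boolean; returns (n, K, K).
    """
    P = expit(theta @ A_op.T + b_op)
    Wmask = np.where(taken, P * (1.0 - P), 0.0)
    K = A_op.shape[1]
    G = (A_op[:, :, None] * A_op[:, None, :]).reshape(A_op.shape[0], K * K)
    return (Wmask @ G).reshape(-1, K, K)


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------


def _batched_map(
    y: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    prior: PriorSpec,
    theta0: np.ndarray,
    tol: float = _GRAD_TOL,
    max_iter: int = _MAX_NEWTON,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton ascent of the MAP objective for a batch of examinees.

    y, b are (n, s); A is (n, s, K).  Returns (theta (n, K), converged (n,)).
    Step-halving guards against objective decreases; iterations are capped
    at ``max_iter`` and non-converged rows are flagged.
    """
    n, s, K = A.shape
    mu, Sinv = prior.mean, prior.cov_inv
    th = np.array(theta0, dtype=float, copy=True)

    def objective(t: np.ndarray) -> np.ndarray:
        z = np.einsum("nsk,nk->ns", A, t) + b
        ll = np.sum(y * z - np.logaddexp(0.0, z), axis=1)
        d = t - mu
        return ll - 0.5 * np.einsum("nk,kl,nl->n", d, Sinv, d)

    f = objective(th)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        z = np.einsum("nsk,nk->ns", A, th) + b
        p = expit(z)
        g = np.einsum("nsk,ns->nk", A, y - p) - (th - mu) @ Sinv
        converged |= np.abs(g).max(axis=1) < tol
        if converged.all():
            break
        w = p * (1.0 - p)
        H = np.einsum("ns,nsk,nsl->nkl", w, A, A) + Sinv
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        delta[converged] = 0.0
        step = np.ones(n)
        th_new = th + delta
        f_new = objective(th_new)
        for _half in range(30):
            bad = ~converged & (f_new < f - 1e-12)
            if not bad.any():
                break
            step[bad] *= 0.5
            th_new = th + step[:, None] * delta
            f_new = objective(th_new)
        th = np.where(converged[:, None], th, th_new)
        f = np.where(converged, f, f_new)
    return th, converged


def _items_to_arrays(items: Sequence) -> tuple[np.ndarray, np.ndarray]:
    A = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    return A, b


def map_estimate(
    responses: Sequence[int] | np.ndarray,
    items: Sequence,
    prior: PriorSpec,
    theta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """MAP ability estimate and posterior covariance for one examinee.

    Maximizes log-likelihood + log MVN(mean, cov) density by Newton ascent
    (gradient inf-norm tolerance 1e-6, at most 50 iterations with
    step-halving).  The posterior covariance is
    ``(sum_j I_j(theta_hat) + cov^-1)^-1``.  With no responses the estimate
    is the prior mean and the posterior covariance the prior covariance.

    Returns ``(theta_hat, posterior_cov, converged)``.
    """
    y = np.asarray(responses, dtype=float)
    K = prior.K
    if y.size == 0:
        return prior.mean.copy(), prior.cov.copy(), True
    if len(items) != y.size:
        raise ValueError("responses and items must have equal length")
    A, b = _items_to_arrays(items)
    if A.shape[1] != K:
        raise ValueError(f"items have dimension {A.shape[1]}, expected K={K}")
    start = prior.mean if theta0 is None else np.asarray(theta0, dtype=float)
    th, conv = _batched_map(y[None], A[None], b[None], prior, start[None])
    z = A @ th[0] + b
    w = expit(z) * (1.0 - expit(z))
    H = np.einsum("s,sk,sl->kl", w, A, A) + prior.cov_inv
    return th[0], np.linalg.inv(H), bool(conv[0])


# ---------------------------------------------------------------------------
# item selection (public, single-examinee)
# ---------------------------------------------------------------------------


def _selection_inputs(
    state: TestState, remaining: Iterable[int], pool: ItemPool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rem = np.asarray(sorted(remaining), dtype=int)
    if rem.size == 0:
        raise ValueError("remaining item set is empty")
    theta = np.asarray(state.theta_hat, dtype=float)
    adm = np.asarray(state.administered, dtype=int)
    if adm.size:
        A_adm, b_adm = pool.a[adm], pool.b[adm]
        z = A_adm @ theta + b_adm
        w = expit(z) * (1.0 - expit(z))
        K = pool.K
        G = (A_adm[:, :, None] * A_adm[:, None, :]).reshape(adm.size, K * K)
        M = (w @ G).reshape(K, K)
    else:
        M = np.zeros((pool.K, pool.K))
    z_rem = pool.a[rem] @ theta + pool.b[rem]
    p = expit(z_rem)
    return rem, M, p * (1.0 - p), pool.a[rem]


def select_item_D(state: TestState, remaining: Iterable[int], pool: ItemPool) -> int:
    """Item maximizing det(I_S(theta_hat) + I_i(theta_hat)) over ``remaining``."""
    rem, M, w, A = _selection_inputs(state, remaining, pool)
    scores = _d_scores(M[None], w[None], A)
    return int(rem[_argbest_rows(scores)[0]])


def select_item_bayesA(
    state: TestState, remaining: Iterable[int], pool: ItemPool, prior: PriorSpec
) -> int:
    """Item minimizing trace[(I_S + I_i + Sigma0^-1)^-1] over ``remaining``."""
    rem, M, w, A = _selection_inputs(state, remaining, pool)
    scores = _bayesA_scores(M[None], w[None], A, prior.cov_inv)
    return int(rem[_argbest_rows(scores)[0]])


# ---------------------------------------------------------------------------
# administration core (batched over examinees)
# ---------------------------------------------------------------------------


def _administer_batch(
    abilities: np.ndarray,
    pool: ItemPool,
    criterion: Criterion,
    prior: PriorSpec,
    U: np.ndarray,
    Z0: int | None,
    se_threshold: float = 0.3,
    max_items: int = 100,
    min_items: int | None = None,
    track_se: bool = False,
):
    """Vectorized adaptive administration for a batch of examinees.

    U holds pre-drawn uniforms, one per examinee per step; the response to
    the item selected at step s is ``U[:, s] < P(correct | true theta)``.
    Returns op-position index arrays padded with -1, responses, final
    estimates, SEs, posterior covariances, test lengths, convergence flags
    and (optionally) the per-step SE history.
    """
    if criterion not in ("D", "bayesA"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    N, K = abilities.shape
    op_ids = pool.operational_ids
    A_op, b_op = pool.a[op_ids], pool.b[op_ids]
    J0 = op_ids.size
    fixed = Z0 is not None
    if fixed:
        if Z0 > J0:
            raise ValueError(f"Z0={Z0} exceeds the {J0} operational items")
        max_steps = Z0
    else:
        if se_threshold <= 0:
            raise ValueError("se_threshold must be positive")
        max_steps = max_items
        if min_items is None:
            min_items = K
    if U.shape != (N, max_steps):
        raise ValueError("uniform draws must be (N, max_steps)")

    theta = np.tile(prior.mean, (N, 1))
    taken = np.zeros((N, J0), dtype=bool)
    admin = np.full((N, max_steps), -1, dtype=int)
    resp = np.zeros((N, max_steps), dtype=int)
    lengths = np.zeros(N, dtype=int)
    se = np.sqrt(np.diag(prior.cov))[None].repeat(N, axis=0)
    pcov = np.tile(prior.cov, (N, 1, 1))
    conv = np.ones(N, dtype=bool)
    se_hist = np.full((N, max_steps, K), np.nan) if track_se else None

    active = np.arange(N)
    for step in range(max_steps):
        th = theta[active]
        z = th @ A_op.T + b_op
        P = expit(z)
        Wt = P * (1.0 - P)
        Wmask = np.where(taken[active], Wt, 0.0)
        G = (A_op[:, :, None] * A_op[:, None, :]).reshape(J0, K * K)
        M = (Wmask @ G).reshape(-1, K, K)
        if criterion == "D":
            scores = _d_scores(M, Wt, A_op)
        else:
            scores = _bayesA_scores(M, Wt, A_op, prior.cov_inv)
        scores[taken[active]] = -np.inf
        sel = _argbest_rows(scores)

        admin[active, step] = sel
        taken[active, sel] = True
        lengths[active] += 1
        p_true = expit(
            np.sum(A_op[sel] * abilities[active], axis=1) + b_op[sel]
        )
        y = (U[active, step] < p_true).astype(int)
        resp[active, step] = y

        s = step + 1
        idx = admin[active, :s]
        A_adm = A_op[idx]                       # (n_act, s, K)
        b_adm = b_op[idx]
        y_adm = resp[active, :s].astype(float)
        th_new, ok = _batched_map(y_adm, A_adm, b_adm, prior, th)
        theta[active] = th_new
        conv[active] &= ok

        need_se = track_se or not fixed or step == max_steps - 1
        if need_se:
            Macc = _accumulated_info(th_new, taken[active], A_op, b_op)
            pc = np.linalg.inv(Macc + prior.cov_inv)
            pcov[active] = pc
            se_act = np.sqrt(np.diagonal(pc, axis1=-2, axis2=-1))
            se[active] = se_act
            if track_se:
                se_hist[active, step] = se_act
            if not fixed and s >= min_items:
                stop = se_act.max(axis=1) <= se_threshold
                if stop.any():
                    active = active[~stop]
                    if active.size == 0:
                        break
    return admin, resp, theta, se, pcov, lengths, conv, se_hist


def _state_from_batch(pool, batch, row: int = 0) -> TestState:
    admin, resp, theta, se, pcov, lengths, conv, se_hist = batch
    L = int(lengths[row])
    op_ids = pool.operational_ids
    items = [int(op_ids[j]) for j in admin[row, :L]]
    th = theta[row]
    A_adm, b_adm = pool.a[items], pool.b[items]
    z = A_adm @ th + b_adm
    w = expit(z) * (1.0 - expit(z))
    info = np.einsum("s,sk,sl->kl", w, A_adm, A_adm)
    return TestState(
        administered=items,
        responses=[int(r) for r in resp[row, :L]],
        theta_hat=th,
        posterior_cov=pcov[row],
        se=se[row],
        info_accum=info,
        converged=bool(conv[row]),
        se_history=None if se_hist is None else se_hist[row, :L],
    )


def administer_fixed(
    theta_true: np.ndarray,
    pool: ItemPool,
    Z0: int,
    criterion: Criterion,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> TestState:
    """Administer a fixed-length adaptive test of Z0 operational items.

    The interim MAP estimate is refreshed after every response; the final
    state carries the estimate, posterior covariance and SEs.
    """
    theta_true = np.atleast_2d(np.asarray(theta_true, dtype=float))
    U = rng.random(Z0)[None]
    batch = _administer_batch(theta_true, pool, criterion, prior, U, Z0=Z0)
    return _state_from_batch(pool, batch)


def administer_variable(
    theta_true: np.ndarray,
    pool: ItemPool,
    criterion: Criterion,
    prior: PriorSpec,
    se_threshold: float = 0.3,
    max_items: int = 100,
    rng: np.random.Generator | None = None,
) -> TestState:
    """Administer until every posterior SE is <= ``se_threshold``.

    The rule is first checked once K items have been administered (so the
    posterior is informed on every dimension) and the length is capped at
    ``max_items``.
    """
    if rng is None:
        raise ValueError("an rng is required")
    theta_true = np.atleast_2d(np.asarray(theta_true, dtype=float))
    U = rng.random(max_items)[None]
    batch = _administer_batch(
        theta_true, pool, criterion, prior, U,
        Z0=None, se_threshold=se_threshold, max_items=max_items, track_se=True,
    )
    return _state_from_batch(pool, batch)


# ---------------------------------------------------------------------------
# cohort administration
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """Everything a pretest cohort produces.

    ``replenished`` maps each replenished item id to the (examinee ids,
    responses) pair recorded for it; responses to replenished items are
    simulated at the true abilities and never enter the ability estimates.
    ``exposure_counts`` is indexed by pool item id (zero for replenished
    items).
    """

    theta_hat: np.ndarray
    se: np.ndarray
    test_lengths: np.ndarray
    exposure_counts: np.ndarray
    replenished: dict[int, tuple[np.ndarray, np.ndarray]]
    map_converged: np.ndarray
    criterion: str

    @property
    def N(self) -> int:
        return self.theta_hat.shape[0]

    def theta_frame(self) -> pd.DataFrame:
        N, K = self.theta_hat.shape
        data = {"examinee_id": np.arange(N)}
        for k in range(K):
            data[f"theta_{k + 1}"] = self.theta_hat[:, k]
        for k in range(K):
            data[f"se_{k + 1}"] = self.se[:, k]
        data["test_length"] = self.test_lengths
        return pd.DataFrame(data)

    def replenished_frame(self) -> pd.DataFrame:
        rows = []
        for item_id in sorted(self.replenished):
            ex, y = self.replenished[item_id]
            rows.append(pd.DataFrame(
                {"item_id": item_id, "examinee_id": ex, "response": y}
            ))
        return pd.concat(rows, ignore_index=True)

    def exposure_frame(self) -> pd.DataFrame:
        ids = np.flatnonzero(self.exposure_counts >= 0)
        return pd.DataFrame({
            "item_id": ids,
            "exposure_rate": self.exposure_counts[ids] / self.N,
        })

    def write_csvs(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.theta_frame().to_csv(out / "theta_hat.csv", index=False)
        self.replenished_frame().to_csv(out / "replenished_responses.csv", index=False)
        self.exposure_frame().to_csv(out / "exposure.csv", index=False)


def spawn_examinee_seeds(seed, N: int) -> list[np.random.SeedSequence]:
    """The N+1 child seed sequences a cohort run derives from ``seed``.

    Children 0..N-1 drive the operational response draws of the matching
    examinees; child N drives the replenished-item responses.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(N + 1)


def run_cohort(
    pool: ItemPool,
    abilities: np.ndarray,
    assignment: GroupAssignment,
    design: StudyDesign,
    criterion: Criterion,
    prior: PriorSpec,
    seed,
    se_threshold: float = 0.3,
    max_items: int = 100,
) -> CohortResult:
    """Administer the full pretest cohort.

    Every examinee takes an adaptive operational test (fixed length
    ``design.Z0``, or SE-stopped if ``design.Z0 is None``) followed by the
    Z1 replenished items of their group, answered at the true abilities.
    Replenished responses never enter the ability estimates; exposure is
    counted for operational items only.
    """
    abilities = np.asarray(abilities, dtype=float)
    N, K = abilities.shape
    if N != design.N:
        raise ValueError(f"abilities have {N} rows, design expects {design.N}")
    children = spawn_examinee_seeds(seed, N)
    max_steps = design.Z0 if design.Z0 is not None else max_items
    U = np.empty((N, max_steps))
    for i in range(N):
        U[i] = np.random.default_rng(children[i]).random(max_steps)

    batch = _administer_batch(
        abilities, pool, criterion, prior, U,
        Z0=design.Z0, se_threshold=se_threshold, max_items=max_items,
    )
    admin, resp, theta, se, _pcov, lengths, conv, _ = batch

    op_ids = pool.operational_ids
    counts_op = np.bincount(
        np.concatenate([admin[i, :lengths[i]] for i in range(N)]),
        minlength=op_ids.size,
    )
    exposure_counts = np.zeros(len(pool), dtype=int)
    exposure_counts[op_ids] = counts_op

    rng_rep = np.random.default_rng(children[N])
    replenished: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for g in range(assignment.n_groups):
        ex = assignment.examinee_groups[g]
        items = assignment.item_groups[g]
        P = expit(abilities[ex] @ pool.a[items].T + pool.b[items])
        y = (rng_rep.random(P.shape) < P).astype(int)
        for col, item_id in enumerate(items):
            replenished[int(item_id)] = (ex.copy(), y[:, col])

    return CohortResult(
        theta_hat=theta,
        se=se,
        test_lengths=lengths,
        exposure_counts=exposure_counts,
        replenished=replenished,
        map_converged=conv,
        criterion=criterion,
    )
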