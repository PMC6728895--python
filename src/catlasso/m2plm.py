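"""Compensatory multidimensional two-parameter logistic model (M2PLM).

The M2PLM gives the probability that examinee ``i`` answers item ``j``
correctly as

    P(Y_ij = 1 | theta_i, a_j, b_j) = logistic(a_j' theta_i + b_j),

where ``theta_i`` is a K-vector of latent traits, ``a_j`` a K-vector of
discrimination parameters and ``b_j`` a scalar intercept (easiness).  The
model is *compensatory*: a deficit on one trait can be offset by a surplus
on another through the linear predictor.

An item's *item-trait pattern* ``Q_j`` is the binary support of ``a_j``:
``q_jk = 1`` exactly when trait ``k`` is measured by the item
(``a_jk != 0`` for generated items).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "ItemPool",
    "response_probability",
    "log_likelihood",
    "fisher_information",
    "simulate_response",
    "linear_predictor",
    "probability_matrix",
]

# Probabilities are clipped only inside likelihood evaluation, to keep logs
# finite at extreme abilities; response_probability itself is unclipped.
_P_CLIP = 1e-12


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single M2PLM item.

    Attributes
    ----------
    a : ndarray, shape (K,)
        Discrimination parameters; zero entries mark unmeasured traits.
    b : float
        Intercept (easiness) parameter.
    Q : ndarray, shape (K,)
        0/1 item-trait pattern.  For generated items ``Q = (a != 0)``.
    """

    a: np.ndarray
    b: float
    Q: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        q = self.Q
        if q is None:
            q = (a != 0).astype(int)
        q = np.asarray(q, dtype=int)
        object.__setattr__(self, "Q", q)
        if a.ndim != 1 or q.shape != a.shape:
            raise ValueError(
                f"a and Q must be 1-d vectors of equal length, got a{a.shape}, Q{q.shape}"
            )

    @property
    def K(self) -> int:
        return self.a.shape[0]


def _check_theta(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != item.a.shape:
        raise ValueError(
            f"ability vector has dimension {theta.shape[0] if theta.ndim == 1 else theta.shape}, "
            f"expected K={item.K}"
        )
    return theta


def linear_predictor(Theta: np.ndarray, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized ``Theta @ A.T + b`` for an (N, K) ability matrix and (J, K) items."""
    return Theta @ A.T + b


def probability_matrix(Theta: np.ndarray, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """N x J matrix of correct-response probabilities."""
    return expit(linear_predictor(Theta, A, b))


def response_probability(theta: np.ndarray, item: ItemParameters) -> float:
    """Probability of a correct response under the M2PLM.

    Strictly inside (0, 1); increasing in every trait the item measures
    with positive discrimination.
    """
    theta = _check_theta(theta, item)
    return float(expit(item.a @ theta + item.b))


def log_likelihood(
    responses: Sequence[int] | np.ndarray,
    thetas: np.ndarray,
    item: ItemParameters,
) -> float:
    """Bernoulli log-likelihood of 0/1 ``responses`` at known abilities.

    ``thetas`` is an (n, K) matrix whose rows pair with ``responses``.
    Probabilities are clipped to [1e-12, 1 - 1e-12] so the result stays
    finite at extreme abilities.  Empty data gives 0.
    """
    y = np.asarray(responses, dtype=float)
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    if y.size == 0:
        return 0.0
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary 0/1")
    if y.shape[0] != thetas.shape[0]:
        raise ValueError(
            f"{y.shape[0]} responses but {thetas.shape[0]} ability vectors"
        )
    if thetas.shape[1] != item.K:
        raise ValueError(f"ability vectors have dimension {thetas.shape[1]}, expected K={item.K}")
    p = expit(thetas @ item.a + item.b)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fisher_information(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Fisher information matrix ``P(1-P) a a'`` of one item at ``theta``.

    Symmetric, positive semi-definite, rank <= 1; its trace is
    ``P(1-P) ||a||^2``.
    """
    theta = _check_theta(theta, item)
    p = response_probability(theta, item)
    return p * (1.0 - p) * np.outer(item.a, item.a)


def simulate_response(
    theta: np.ndarray, item: ItemParameters, rng: np.random.Generator
) -> int:
    """Draw a single Bernoulli response with M2PLM success probability."""
    p = response_probability(theta, item)
    return int(rng.random() < p)


@dataclass
class ItemPool:
    """An ordered pool of M2PLM items with operational/replenished roles.

    Stored columnwise for vectorized access: ``a`` is (J, K), ``b`` (J,),
    ``Q`` (J, K) and ``operational`` a (J,) boolean mask.  Item ids are the
    row positions 0..J-1.
    """

    a: np.ndarray
    b: np.ndarray
    Q: np.ndarray
    operational: np.ndarray
    K: int = field(init=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.Q = np.asarray(self.Q, dtype=int)
        self.operational = np.asarray(self.operational, dtype=bool)
        J, K = self.a.shape
        if self.Q.shape != (J, K) or self.b.shape != (J,) or self.operational.shape != (J,):
            raise ValueError("inconsistent pool array shapes")
        if (self.Q.sum(axis=1) == 0).any():
            raise ValueError("pool contains an item with an all-zero pattern")
        self.K = K

    def __len__(self) -> int:
        return self.a.shape[0]

    def __getitem__(self, j: int) -> ItemParameters:
        return ItemParameters(a=self.a[j], b=float(self.b[j]), Q=self.Q[j])

    def __iter__(self) -> Iterator[ItemParameters]:
        for j in range(len(self)):
            yield self[j]

    @property
    def operational_ids(self) -> np.ndarray:
        return np.flatnonzero(self.operational)

    @property
    def replenished_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.operational)

    @property
    def n_operational(self) -> int:
        return int(self.operational.sum())

    @property
    def n_replenished(self) -> int:
        return int((~self.operational).sum())

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        K = self.K
        data = {"item_id": np.arange(len(self)),
                "role": np.where(self.operational, "operational", "replenished"),
                "b": self.b}
        for k in range(K):
            data[f"a_{k + 1}"] = self.a[:, k]
        for k in range(K):
            data[f"q_{k + 1}"] = self.Q[:, k]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemPool":
        a_cols = sorted((c for c in df.columns if c.startswith("a_")),
                        key=lambda c: int(c.split("_")[1]))
        q_cols = sorted((c for c in df.columns if c.startswith("q_")),
                        key=lambda c: int(c.split("_")[1]))
        if not a_cols or len(a_cols) != len(q_cols):
            raise ValueError("expected matching a_1..a_K and q_1..q_K columns")
        df = df.sort_values("item_id")
        return cls(
            a=df[a_cols].to_numpy(dtype=float),
            b=df["b"].to_numpy(dtype=float),
            Q=df[q_cols].to_numpy(dtype=int),
            operational=(df["role"] == "operational").to_numpy(),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ItemPool":
        return cls.from_frame(pd.read_csv(path))
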