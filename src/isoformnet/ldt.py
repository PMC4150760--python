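"""Large-dimensional trace (LDT) test of independence between two exon blocks.

Two isoforms are represented as matrices ``X1`` (p exons x n samples) and
``X2`` (q exons x n samples), jointly modelled as a (p+q)-variate normal with
covariance blocks ``S11, S12, S21, S22``.  Independence of the isoforms is the
null hypothesis ``H0: S12 = 0``.  The test statistic is the trace

    L_n = tr(A21 A11^-1 A12 A22^-1),   A_ij = (n-1) * Sigma_hat_ij,

which equals the sum of squared sample canonical correlations between the two
blocks.  Under H0, with dimensions allowed to grow with the sample size,

    T = (L_n - E) / sqrt(V) -> N(0, 1),
    E = p*q/(n-1),   V = 2*p*q*(n-1-p)*(n-1-q) / (n-1)^4,

and a co-expression edge is declared when T exceeds the upper alpha-quantile
of the standard normal (one-sided test).  The asymptotics stay valid when
p/n and q/n are close to 1, the regime where classical canonical-correlation
tests break down; the only hard requirement is n - 1 > max(p, q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BlockCrossProducts",
    "LdtResult",
    "block_cross_products",
    "ldt_statistic",
    "asymptotic_moments",
    "standardized_statistic",
    "ldt_test",
]

#: condition-number threshold above which A11/A22 are treated as singular
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class BlockCrossProducts:
    """Centered cross-product matrices for a pair of exon blocks.

    ``A11`` (p x p), ``A22`` (q x q) and ``A12`` (p x q) are the centered
    cross-products ``sum_k (x_k - xbar)(y_k - ybar)^T``, i.e. (n-1) times the
    unbiased covariance estimates.  ``A21`` is ``A12.T``.
    """

    A11: np.ndarray
    A22: np.ndarray
    A12: np.ndarray
    mean1: np.ndarray
    mean2: np.ndarray
    n: int

    @property
    def A21(self) -> np.ndarray:
        return self.A12.T

    @property
    def p(self) -> int:
        return self.A11.shape[0]

    @property
    def q(self) -> int:
        return self.A22.shape[0]


@dataclass(frozen=True)
class LdtResult:
    """Outcome of the LDT independence test for one isoform pair."""

    L_n: float
    E_asym: float
    V_asym: float
    T: float
    p_value: float
    alpha: float
    critical_value: float
    edge: bool
    p: int
    q: int
    n: int
    dropped_exons_1: tuple = field(default=())
    dropped_exons_2: tuple = field(default=())

    def to_record(self) -> dict:
        """Flat dict for TSV serialization."""
        return {
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "L_n": self.L_n,
            "E": self.E_asym,
            "V": self.V_asym,
            "T": self.T,
            "p_value": self.p_value,
            "edge": int(self.edge),
        }


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.ndim != 2:
        raise ValueError(f"expected a (variables x samples) matrix, got shape {X.shape}")
    return X


def block_cross_products(X1: np.ndarray, X2: np.ndarray) -> BlockCrossProducts:
    """Centered cross-products A11, A22, A12 for blocks sharing a sample axis.

    Parameters
    ----------
    X1, X2
        Arrays of shape (p, n) and (q, n); columns are samples in the same
        order in both blocks.
    """
    X1, X2 = _as_2d(X1), _as_2d(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"sample axes differ: X1 has {X1.shape[1]} samples, X2 has {X2.shape[1]}"
        )
    n = X1.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    m1 = X1.mean(axis=1)
    m2 = X2.mean(axis=1)
    X1c = X1 - m1[:, None]
    X2c = X2 - m2[:, None]
    A11 = X1c @ X1c.T
    A22 = X2c @ X2c.T
    A12 = X1c @ X2c.T
    # enforce exact symmetry against floating-point drift
    A11 = (A11 + A11.T) / 2.0
    A22 = (A22 + A22.T) / 2.0
    return BlockCrossProducts(A11=A11, A22=A22, A12=A12, mean1=m1, mean2=m2, n=n)


def ldt_statistic(B: BlockCrossProducts) -> float:
    """Trace statistic L_n = tr(A21 A11^-1 A12 A22^-1).

    Solved as tr(solve(A11, A12) @ solve(A22, A21)) — no explicit inverses.
    Equals the sum of squared sample canonical correlations between the blocks.
    """
    p, q, n = B.p, B.q, B.n
    if n - 1 <= max(p, q):
        raise ValueError(
            f"LDT requires n - 1 > max(p, q); got n={n}, p={p}, q={q}. "
            "Filter exons (e.g. raise the expressed-fraction threshold) to reduce dimensions."
        )
    for name, A in (("A11", B.A11), ("A22", B.A22)):
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > CONDITION_LIMIT:
            raise np.linalg.LinAlgError(
                f"{name} is singular or ill-conditioned (cond={cond:.3g}); "
                "remove zero-variance or duplicated exons before testing."
            )
    S1 = np.linalg.solve(B.A11, B.A12)  # p x q
    S2 = np.linalg.solve(B.A22, B.A21)  # q x p
    return float(np.einsum("ij,ji->", S1, S2))


def asymptotic_moments(p: int, q: int, n: int) -> tuple[float, float]:
    """Asymptotic null mean E and variance V of L_n.

    E = q*p/(n-1);  V = 2pq(n-1-p)(n-1-q)/(n-1)^4.  Requires n-1 > max(p, q)
    (otherwise V <= 0 and the normal approximation is meaningless).
    """
    if p < 1 or q < 1:
        raise ValueError(f"dimensions must be >= 1, got p={p}, q={q}")
    if n - 1 <= max(p, q):
        raise ValueError(
            f"asymptotic variance requires n - 1 > max(p, q); got n={n}, p={p}, q={q}"
        )
    nm1 = n - 1
    E = q * p / nm1
    V = 2.0 * p * q * (nm1 - p) * (nm1 - q) / nm1**4
    return E, V


def standardized_statistic(L_n: float, E_asym: float, V_asym: float) -> float:
    """Standardized statistic T = (L_n - E)/sqrt(V); N(0,1) under the null."""
    if V_asym <= 0:
        raise ValueError(f"asymptotic variance must be positive, got {V_asym}")
    return (L_n - E_asym) / np.sqrt(V_asym)


def _drop_zero_variance(X: np.ndarray, label: str) -> tuple[np.ndarray, tuple]:
    var = X.var(axis=1)
    dead = np.flatnonzero(var == 0.0)
    if dead.size:
        warnings.warn(
            f"dropping {dead.size} zero-variance exon(s) from block {label} "
            f"(rows {dead.tolist()}) before the LDT test",
            stacklevel=3,
        )
        X = np.delete(X, dead, axis=0)
    return X, tuple(int(i) for i in dead)


def ldt_test(X1: np.ndarray, X2: np.ndarray, alpha: float = 0.05) -> LdtResult:
    """One-sided LDT test of independence between two exon-expression blocks.

    Zero-variance exons are removed first (they make the within-block
    cross-products singular), with p and q updated accordingly.  The p-value is
    ``1 - Phi(T)`` and an edge is declared when ``T > Z_alpha``.

    Parameters
    ----------
    X1, X2
        (p, n) and (q, n) expression blocks over the same ordered samples.
    alpha
        Significance level in (0, 1); default 0.05.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    X1, dropped1 = _drop_zero_variance(_as_2d(X1), "1")
    X2, dropped2 = _drop_zero_variance(_as_2d(X2), "2")
    if X1.shape[0] == 0 or X2.shape[0] == 0:
        raise ValueError("a block has no exons with positive variance; nothing to test")
    B = block_cross_products(X1, X2)
    E, V = asymptotic_moments(B.p, B.q, B.n)
    L = ldt_statistic(B)
    T = standardized_statistic(L, E, V)
    z_alpha = float(stats.norm.isf(alpha))
    p_value = float(stats.norm.sf(T))
    return LdtResult(
        L_n=L,
        E_asym=E,
        V_asym=V,
        T=T,
        p_value=p_value,
        alpha=alpha,
        critical_value=z_alpha,
        edge=bool(T > z_alpha),
        p=B.p,
        q=B.q,
        n=B.n,
        dropped_exons_1=dropped1,
        dropped_exons_2=dropped2,
    )


def _batched_ldt(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Vectorized L_n over a batch: X1 (B, p, n), X2 (B, q, n) -> (B,).

    Used by the Monte-Carlo harness; agrees with :func:`ldt_test` to machine
    precision (asserted in the test suite).  No condition guard: simulated
    blocks with n - 1 > max(p, q) yield well-conditioned Wishart matrices.
    """
    X1c = X1 - X1.mean(axis=2, keepdims=True)
    X2c = X2 - X2.mean(axis=2, keepdims=True)
    A11 = X1c @ X1c.transpose(0, 2, 1)
    A22 = X2c @ X2c.transpose(0, 2, 1)
    A12 = X1c @ X2c.transpose(0, 2, 1)
    S1 = np.linalg.solve(A11, A12)
    S2 = np.linalg.solve(A22, A12.transpose(0, 2, 1))
    return np.einsum("bij,bji->b", S1, S2)
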