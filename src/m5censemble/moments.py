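"""Statistical moments of 2D sequence matrices.

A 41-nt window is embedded in the smallest square matrix that holds it
(7x7, row-major, zero-padded), and described by raw, central and Hahn
moments up to combined order 3 — 10 coefficients per family, 30 in
total. The same descriptor reduces the larger k-mer incidence matrices
(16x16, 64x64) to a fixed-size summary.

Hahn moments project the matrix onto discrete Hahn polynomials
h_n^(u,v)(r, N), orthogonal on r = 0..N-1 under the weight
w(r) = C(u+r, r) * C(v+N-1-r, N-1-r). The implementation evaluates the
hypergeometric (Pochhammer) sum in log space with sign tracking, folds
sqrt(w) into the polynomial values and normalizes each order by its L2
norm, so the resulting basis is orthonormal under the plain (unweighted)
inner product over r. For the default u = v = 0 the weight is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

#: pinned moment orders: all (u, v) with u, v >= 0 and u + v <= 3,
#: ordered by total degree then u
DEFAULT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (0, 1), (1, 0),
    (0, 2), (1, 1), (2, 0),
    (0, 3), (1, 2), (2, 1), (3, 0),
)

MATRIX_SIDE = 7  # smallest square holding a 41-value window


@dataclass(frozen=True)
class MomentConfig:
    """Moment orders and Hahn polynomial parameters.

    hahn_u / hahn_v are the Hahn shape parameters (>= 0); the default
    (0, 0) gives a uniform orthogonality weight.
    """

    orders: tuple[tuple[int, int], ...] = DEFAULT_ORDERS
    hahn_u: float = 0.0
    hahn_v: float = 0.0

    def __post_init__(self) -> None:
        if self.hahn_u < 0 or self.hahn_v < 0:
            raise ValueError("Hahn parameters must be non-negative")


@dataclass(frozen=True)
class MomentSet:
    """Raw, central and Hahn moment coefficients of one matrix."""

    raw: np.ndarray
    central: np.ndarray
    hahn: np.ndarray
    orders: tuple[tuple[int, int], ...] = DEFAULT_ORDERS

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.raw, self.central, self.hahn])

    def names(self, prefix: str = "") -> list[str]:
        out = []
        for family in ("raw", "central", "hahn"):
            out += [f"{prefix}{family}_{u}{v}" for u, v in self.orders]
        return out


def to_matrix(encoded: np.ndarray, side: int = MATRIX_SIDE) -> np.ndarray:
    """Embed an encoded 41-vector in a side x side matrix, row-major.

    Cells beyond position 41 are zero-padded.
    """
    encoded = np.asarray(encoded, dtype=float)
    if encoded.ndim != 1 or encoded.size > side * side:
        raise ValueError(
            f"cannot place {encoded.size} values in a {side}x{side} matrix"
        )
    flat = np.zeros(side * side)
    flat[: encoded.size] = encoded
    return flat.reshape(side, side)


def raw_moments(
    matrix: np.ndarray,
    orders: tuple[tuple[int, int], ...] = DEFAULT_ORDERS,
) -> np.ndarray:
    """R_uv = sum_ab a^u b^v beta_ab, with 1-based row/column indices."""
    matrix = np.asarray(matrix, dtype=float)
    m, n = matrix.shape
    a = np.arange(1, m + 1, dtype=float)[:, None]
    b = np.arange(1, n + 1, dtype=float)[None, :]
    return np.array(
        [float(np.sum(a**u * b**v * matrix)) for u, v in orders]
    )


def central_moments(
    matrix: np.ndarray,
    orders: tuple[tuple[int, int], ...] = DEFAULT_ORDERS,
) -> np.ndarray:
    """n_ij = sum_ab (a - xbar)^i (b - ybar)^j beta_ab.

    The centroid (xbar, ybar) = (R10/R00, R01/R00). A zero-mass matrix
    has no centroid; its central moments are defined as 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    m, n = matrix.shape
    r00 = float(matrix.sum())
    if r00 == 0.0:
        return np.zeros(len(orders))
    a = np.arange(1, m + 1, dtype=float)[:, None]
    b = np.arange(1, n + 1, dtype=float)[None, :]
    xbar = float(np.sum(a * matrix)) / r00
    ybar = float(np.sum(b * matrix)) / r00
    da, db = a - xbar, b - ybar
    return np.array(
        [float(np.sum(da**i * db**j * matrix)) for i, j in orders]
    )


def _signed_log_pochhammer(a: float, k: int) -> tuple[float, float]:
    """(sign, log|x|) of the rising factorial (a)_k = a(a+1)...(a+k-1)."""
    sign, log = 1.0, 0.0
    for i in range(k):
        t = a + i
        if t == 0.0:
            return 0.0, -np.inf
        if t < 0:
            sign = -sign
        log += np.log(abs(t))
    return sign, log


def hahn_polynomial(n: int, r: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Value of the (unnormalized) Hahn polynomial Q_n^(u,v)(r, N).

    Standard hypergeometric form on the points r = 0..N-1:

        Q_n(r) = 3F2(-n, n+u+v+1, -r; u+1, -(N-1); 1)
               = sum_{k=0}^{n} (-n)_k (n+u+v+1)_k (-r)_k
                               / [ (u+1)_k (-(N-1))_k k! ]

    orthogonal under the weight w(r) = C(u+r, r) C(v+N-1-r, N-1-r);
    for u = v = 0 this is the discrete Chebyshev family (uniform
    weight). Pochhammer products are evaluated in log space with sign
    tracking so orders up to N = 64 stay finite.
    """
    if not (0 <= n <= N - 1):
        raise ValueError(f"order n={n} out of range [0, {N - 1}]")
    if not (0 <= r <= N - 1):
        raise ValueError(f"point r={r} out of range [0, {N - 1}]")
    sign, log = _hahn_signed_log(n, r, N, u, v)
    return sign * float(np.exp(log))


def _hahn_signed_log(
    n: int, r: int, N: int, u: float, v: float
) -> tuple[float, float]:
    signs, logs = [], []
    for k in range(min(n, r) + 1):  # (-n)_k or (-r)_k vanishes beyond
        s1, l1 = _signed_log_pochhammer(-n, k)
        s2, l2 = _signed_log_pochhammer(n + u + v + 1, k)
        s3, l3 = _signed_log_pochhammer(-r, k)
        d1, e1 = _signed_log_pochhammer(u + 1, k)
        d2, e2 = _signed_log_pochhammer(-(N - 1), k)
        sk = s1 * s2 * s3 * d1 * d2
        lk = l1 + l2 + l3 - e1 - e2 - gammaln(k + 1)
        if sk != 0.0:
            signs.append(sk)
            logs.append(lk)
    if not signs:
        return 0.0, -np.inf
    logs_arr = np.array(logs)
    shift = logs_arr.max()
    total = float(np.sum(np.array(signs) * np.exp(logs_arr - shift)))
    if total == 0.0:
        return 0.0, -np.inf
    return float(np.sign(total)), shift + np.log(abs(total))


@lru_cache(maxsize=32)
def hahn_basis(
    N: int, u: float = 0.0, v: float = 0.0, n_max: int | None = None
) -> np.ndarray:
    """Orthonormal Hahn basis: row n holds h~_n(r) for r = 0..N-1.

    h~_n(r) = h_n(r) sqrt(w(r)) / ||h_n sqrt(w)||, so the rows satisfy
    sum_r h~_m(r) h~_n(r) = delta_mn to float precision. ``n_max``
    truncates the basis to orders 0..n_max (the low orders are all the
    moment descriptor needs, and high orders at large N lose accuracy
    to cancellation in the alternating hypergeometric sum).
    """
    if n_max is None:
        n_max = N - 1
    if not (0 <= n_max <= N - 1):
        raise ValueError(f"n_max={n_max} out of range [0, {N - 1}]")
    r = np.arange(N)
    # log of the orthogonality weight w(r), up to an n-independent constant
    log_w = (
        gammaln(u + r + 1) - gammaln(r + 1)
        + gammaln(v + N - r) - gammaln(N - r)
    )
    basis = np.empty((n_max + 1, N))
    for n in range(n_max + 1):
        signs = np.empty(N)
        logs = np.empty(N)
        for ri in range(N):
            s, lg = _hahn_signed_log(n, ri, N, u, v)
            signs[ri], logs[ri] = s, lg
        logs = logs + 0.5 * log_w
        # normalize in log space: scale cancels in the final division
        finite = np.isfinite(logs)
        shift = logs[finite].max()
        vals = np.where(finite, signs * np.exp(logs - shift), 0.0)
        basis[n] = vals / np.linalg.norm(vals)
    return basis


def hahn_moments(
    matrix: np.ndarray,
    cfg: MomentConfig = MomentConfig(),
) -> np.ndarray:
    """H_ij = sum_x sum_y h~_i(x) h~_j(y) beta_xy for the pinned orders."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("Hahn moments require a square matrix")
    N = matrix.shape[0]
    n_max = max(max(i, j) for i, j in cfg.orders)
    basis = hahn_basis(N, cfg.hahn_u, cfg.hahn_v, min(n_max, N - 1))
    low = basis @ matrix @ basis.T
    return np.array([low[i, j] for i, j in cfg.orders])


def hahn_transform(
    matrix: np.ndarray, u: float = 0.0, v: float = 0.0
) -> np.ndarray:
    """Full-order Hahn coefficient matrix of a square matrix."""
    matrix = np.asarray(matrix, dtype=float)
    basis = hahn_basis(matrix.shape[0], u, v)
    return basis @ matrix @ basis.T


def inverse_hahn_transform(
    coeffs: np.ndarray, u: float = 0.0, v: float = 0.0
) -> np.ndarray:
    """Reconstruct a matrix from its full-order Hahn coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)
    basis = hahn_basis(coeffs.shape[0], u, v)
    return basis.T @ coeffs @ basis


def moment_descriptor(
    matrix: np.ndarray, cfg: MomentConfig = MomentConfig()
) -> MomentSet:
    """The 30-coefficient raw || central || Hahn descriptor of a matrix."""
    return MomentSet(
        raw=raw_moments(matrix, cfg.orders),
        central=central_moments(matrix, cfg.orders),
        hahn=hahn_moments(matrix, cfg),
        orders=cfg.orders,
    )
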