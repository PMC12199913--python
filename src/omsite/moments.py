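"""Raw, central and orthonormal Hahn moments of square matrices.

The encoder reduces each incidence/grid matrix to ten moments per
family — all exponent pairs (u, v) with u + v <= 3 — so a matrix of any
side contributes a fixed 30-value block (raw | central | Hahn).

Raw moments are index-weighted sums L_uv = sum_ab a^u b^v beta_ab with
1-based grid indices; central moments are the same sums about the
intensity centroid (L10/L00, L01/L00).  Hahn moments project the matrix
onto discrete Hahn polynomials h_n^{(u,v)}(r, N), orthogonal on
r = 0..N-1 under the weight C(v+r, r) * C(u+N-1-r, N-1-r) (uniform when
u = v = 0).  The polynomials are normalized by the weight and their
squared norm so the degree-0..N-1 family is orthonormal, which makes
the full-order transform an exact involution — the property the
truncated degree-<=3 features inherit their stability from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np
from scipy.special import comb

#: Exponent pairs (u, v) with u + v <= 3, in the fixed feature order.
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2),
    (2, 0), (1, 2), (2, 1), (0, 3), (3, 0),
)

MOMENT_FAMILIES = ("raw", "central", "hahn")


@dataclass(frozen=True)
class MomentSet:
    """Ten degree-<=3 moments of one matrix for one family."""

    family: str
    values: np.ndarray
    side: int

    def __post_init__(self) -> None:
        if self.family not in MOMENT_FAMILIES:
            raise ValueError(f"unknown moment family {self.family!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(MOMENT_ORDERS),):
            raise ValueError(f"expected {len(MOMENT_ORDERS)} values, got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite moment values")
        object.__setattr__(self, "values", vals)


def _check_square(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    return m


def raw_moments(matrix: np.ndarray) -> MomentSet:
    """L_uv = sum_{a,b} a^u b^v beta_ab, 1-based indices, 10 order pairs."""
    m = _check_square(matrix)
    idx = np.arange(1, m.shape[0] + 1, dtype=float)
    values = np.array(
        [(idx**u)[:, None] * (idx**v)[None, :] * m for u, v in MOMENT_ORDERS]
    ).sum(axis=(1, 2))
    return MomentSet("raw", values, m.shape[0])


def central_moments(matrix: np.ndarray) -> MomentSet:
    """Moments about the intensity centroid; all-zero (with a warning)
    when the total mass vanishes and the centroid is undefined."""
    m = _check_square(matrix)
    idx = np.arange(1, m.shape[0] + 1, dtype=float)
    total = m.sum()
    if total == 0.0:
        warnings.warn(
            "zero total mass: centroid undefined, central moments set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return MomentSet("central", np.zeros(len(MOMENT_ORDERS)), m.shape[0])
    xbar = (idx[:, None] * m).sum() / total
    ybar = (idx[None, :] * m).sum() / total
    dx = idx - xbar
    dy = idx - ybar
    values = np.array(
        [((dx**u)[:, None] * (dy**v)[None, :] * m).sum() for u, v in MOMENT_ORDERS]
    )
    return MomentSet("central", values, m.shape[0])


def _pochhammer(x: float, k: int) -> float:
    """Rising factorial (x)_k = x (x+1) ... (x+k-1).

    Plain float products suffice at the sides used here (N <= 64,
    degree <= 3): magnitudes stay around 1e12, far from overflow.
    """
    out = 1.0
    for i in range(k):
        out *= x + i
    return out


def hahn_polynomial(n: int, r: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Discrete Hahn polynomial h_n^{(u,v)}(r, N) on r = 0..N-1.

    Computed as (N+v-1)_n (N-1)_n * 3F2(-n, n+u+v+1, -r; v+1, 1-N; 1);
    the hypergeometric sum terminates at k = n.  Degree 0 is the
    constant 1, degree 1 is (N-1)^2 - 2r(N-1) at u = v = 0.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if not 0 <= n <= N - 1:
        raise ValueError(f"degree n={n} outside 0..{N - 1}")
    if not 0 <= r <= N - 1:
        raise ValueError(f"point r={r} outside 0..{N - 1}")
    prefactor = _pochhammer(N + v - 1, n) * _pochhammer(N - 1, n)
    total = 0.0
    for k in range(n + 1):
        total += (
            _pochhammer(-n, k)
            * _pochhammer(n + u + v + 1, k)
            * _pochhammer(-r, k)
            / (_pochhammer(v + 1, k) * _pochhammer(1 - N, k) * factorial(k))
        )
    return prefactor * total


def hahn_weight(r: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Orthogonality weight C(v+r, r) * C(u+N-1-r, N-1-r); 1 when u=v=0."""
    return float(comb(v + r, r) * comb(u + N - 1 - r, N - 1 - r))


@lru_cache(maxsize=None)
def hahn_basis(N: int, max_degree: int, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Rows h~_n(r) = h_n(r) sqrt(w(r) / rho(n)) for n = 0..max_degree.

    rho(n) is the squared norm sum_r w(r) h_n(r)^2, evaluated by direct
    summation (exact for discrete polynomials), so the rows satisfy
    sum_r h~_m(r) h~_n(r) = delta_mn.
    """
    if not 0 <= max_degree <= N - 1:
        raise ValueError(f"max_degree {max_degree} outside 0..{N - 1}")
    w = np.array([hahn_weight(r, N, u, v) for r in range(N)])
    B = np.array(
        [[hahn_polynomial(n, r, N, u, v) for r in range(N)] for n in range(max_degree + 1)]
    )
    B = B * np.sqrt(w)[None, :]
    rho = (B**2).sum(axis=1)
    B = B / np.sqrt(rho)[:, None]
    B.setflags(write=False)
    return B


def hahn_orthonormal(n: int, r: int, N: int, u: float = 0.0, v: float = 0.0) -> float:
    """Weight-and-norm normalized Hahn polynomial value h~_n(r)."""
    return float(hahn_basis(N, n, u, v)[n, r])


def hahn_moments(
    matrix: np.ndarray, u: float = 0.0, v: float = 0.0, max_degree: int | None = None
) -> MomentSet | np.ndarray:
    """Hahn moments H_ij = sum_{q,p} beta_qp h~_i(q) h~_j(p).

    With the default ``max_degree=None`` the ten pairs i + j <= 3 are
    returned as a :class:`MomentSet`.  Passing an explicit max_degree
    returns the full (max_degree+1)^2 coefficient matrix B M B^T — with
    max_degree = N-1 this is the invertible full-order transform.
    """
    m = _check_square(matrix)
    N = m.shape[0]
    if max_degree is not None:
        B = hahn_basis(N, max_degree, u, v)
        return B @ m @ B.T
    B = hahn_basis(N, min(3, N - 1), u, v)
    H = np.zeros((4, 4))
    # degrees above N-1 do not exist for tiny sides; their slots stay 0
    H[: B.shape[0], : B.shape[0]] = B @ m @ B.T
    values = np.array([H[i, j] for i, j in MOMENT_ORDERS])
    return MomentSet("hahn", values, N)


def hahn_reconstruct(coeffs: np.ndarray, N: int, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """Invert a full-order coefficient matrix back to the data matrix."""
    B = hahn_basis(N, N - 1, u, v)
    return B.T @ np.asarray(coeffs, dtype=float) @ B


def moment_block(matrix: np.ndarray, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """[raw(10) | central(10) | hahn(10)] for one matrix, 30 values."""
    return np.concatenate(
        [
            raw_moments(matrix).values,
            central_moments(matrix).values,
            hahn_moments(matrix, u, v).values,
        ]
    )
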