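"""Truncated multivariate polynomial basis with factorial scaling.

The basis spans all monomials of total degree <= m in n state variables,
each carrying a scale of prod_i 1/e_i! for exponent tuple e.  With that
scaling the basis is closed under differentiation with unit coefficients:
d/dx_i of the element with exponents e is exactly the element with
exponents e - e_i (or zero).  Every derivative in the package is therefore
exact table lookup, never numerical.

Ordering convention ("tdeg-lastmajor-v1"): elements are enumerated in
lexicographic order of the reversed exponent tuple (e_n, ..., e_1), i.e.
index 1 is the constant, then for each variable i = 1..n the block
[x_i, x_1 x_i, ..., x_{i-1} x_i, x_i^2/2, ...].  For n = 3, m = 2 this
yields (1, x1, x1^2/2, x2, x1 x2, x2^2/2, x3, x1 x3, x2 x3, x3^2/2), so
e.g. index 5 is x1 x2 and index 10 is x3^2/2.  All documented coefficient
indices used elsewhere in the package refer to this ordering (1-based).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

ORDERING_VERSION = "tdeg-lastmajor-v1"

__all__ = [
    "MonomialBasis",
    "enumerate_monomials",
    "eval_basis",
    "basis_derivatives",
    "ORDERING_VERSION",
]


@dataclass(frozen=True)
class MonomialBasis:
    """Ordered truncated polynomial basis in ``n`` variables up to degree ``m``.

    Attributes
    ----------
    n : int
        State dimension.
    m : int
        Maximum total degree.
    exponents : np.ndarray, shape (size, n)
        Integer exponent tuples, in the canonical ordering.
    scales : np.ndarray, shape (size,)
        Scale factor prod_i 1/e_i! applied to each monomial.
    deriv_index : np.ndarray, shape (size, n)
        ``deriv_index[k, i]`` is the basis index of d(element k)/dx_i, or
        -1 when the derivative vanishes.  Coefficients are always 1 thanks
        to the factorial scaling.
    """

    n: int
    m: int
    exponents: np.ndarray
    scales: np.ndarray
    deriv_index: np.ndarray
    _index_of: dict = field(repr=False, default_factory=dict)

    @property
    def size(self) -> int:
        return self.exponents.shape[0]

    def index_of(self, exponent: tuple) -> int:
        """0-based index of the element with the given exponent tuple."""
        return self._index_of[tuple(int(e) for e in exponent)]

    def __len__(self) -> int:
        return self.size

    def describe(self) -> list:
        """Serialisable descriptor: ordered (exponent tuple, scale) pairs."""
        return [
            {"exponents": [int(e) for e in row], "scale": float(s)}
            for row, s in zip(self.exponents, self.scales)
        ]


def enumerate_monomials(n: int, m: int = 2) -> MonomialBasis:
    """Build the canonical ordered basis of monomials of total degree <= m.

    Parameters
    ----------
    n : int
        Number of state variables (>= 1).
    m : int
        Maximum total degree (>= 1).

    Returns
    -------
    MonomialBasis

    Notes
    -----
    The size is C(n + m, m); for m = 2 that is 1 + n + n(n+1)/2.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"state dimension n must be a positive integer, got {n!r}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"polynomial order m must be a positive integer, got {m!r}")

    rows = []
    # lexicographic in (e_n, ..., e_1): later variables vary slowest
    for rev in itertools.product(range(m + 1), repeat=n):
        e = rev[::-1]
        if sum(e) <= m:
            rows.append(e)
    exponents = np.array(rows, dtype=np.int64)
    scales = np.array(
        [1.0 / math.prod(math.factorial(int(e)) for e in row) for row in rows]
    )
    index_of = {tuple(int(v) for v in row): k for k, row in enumerate(rows)}
    deriv = np.full((len(rows), n), -1, dtype=np.int64)
    for k, row in enumerate(rows):
        for i in range(n):
            if row[i] > 0:
                child = list(row)
                child[i] -= 1
                deriv[k, i] = index_of[tuple(child)]
    basis = MonomialBasis(
        n=int(n), m=int(m), exponents=exponents, scales=scales, deriv_index=deriv
    )
    basis._index_of.update(index_of)
    return basis


def _as_points(basis: MonomialBasis, point: np.ndarray) -> tuple[np.ndarray, bool]:
    pt = np.asarray(point, dtype=float)
    single = pt.ndim == 1
    if single:
        pt = pt[None, :]
    if pt.shape[-1] != basis.n:
        raise ValueError(
            f"point has dimension {pt.shape[-1]}, basis expects {basis.n}"
        )
    return pt, single


def eval_basis(basis: MonomialBasis, point: np.ndarray) -> np.ndarray:
    """Evaluate every basis element at ``point`` (or a batch of points).

    Returns an array of shape (size,) for a single point, (N, size) for a
    batch.  Element k is ``scale_k * prod_i x_i**e_ki``.
    """
    pts, single = _as_points(basis, point)
    # power table P[p, i, d] = x_i**d, then product over variables
    powers = pts[:, :, None] ** np.arange(basis.m + 1)[None, None, :]
    out = np.ones((pts.shape[0], basis.size))
    for i in range(basis.n):
        out *= powers[:, i, basis.exponents[:, i]]
    out *= basis.scales
    return out[0] if single else out


def basis_derivatives(
    basis: MonomialBasis, point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact first and second derivatives of every basis element.

    Returns
    -------
    D1 : np.ndarray, shape (size, n) (or (N, size, n) for a batch)
        ``D1[k, i]`` = d(element k)/dx_i at the point.
    D2 : np.ndarray, shape (size, n, n) (or (N, size, n, n))
        ``D2[k, i, j]`` = d2(element k)/dx_i dx_j.  Symmetric in (i, j).
    """
    pts, single = _as_points(basis, point)
    B = eval_basis(basis, pts)
    N, size, n = pts.shape[0], basis.size, basis.n
    Bpad = np.concatenate([B, np.zeros((N, 1))], axis=1)  # index -1 -> 0
    D1 = Bpad[:, basis.deriv_index]  # (N, size, n)
    # second derivatives by chaining the lookup table
    d2idx = np.full((size, n, n), -1, dtype=np.int64)
    for i in range(n):
        parent = basis.deriv_index[:, i]
        ok = parent >= 0
        d2idx[ok, i, :] = basis.deriv_index[parent[ok], :]
    D2 = Bpad[:, d2idx]
    if single:
        return D1[0], D2[0]
    return D1, D2
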