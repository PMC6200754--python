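"""Spin-1/2 and collective angular-momentum operators.

All operators are dimensionless (hbar = 1) and expressed in the canonical
|j, m> basis ordered m = j, j-1, ..., -j.  A bath of N identical spin-1/2
nuclei coupled collectively decomposes into total-spin sectors: the 2^N
product space splits into blocks of dimension 2j+1, each occurring with a
multiplicity nu(N, j) given by a difference of binomial coefficients.  Only
the multiplicities matter for the dynamics (all copies of a given j are
physically identical here), so no Clebsch-Gordan tables are needed.

Half-integer spins are carried internally as doubled integers (``two_j``)
so that parity/admissibility checks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

__all__ = [
    "SpinOperatorSet",
    "SubspaceCatalog",
    "spin_half_ops",
    "collective_spin_ops",
    "degeneracy",
    "enumerate_subspaces",
    "embed",
]


@dataclass(frozen=True)
class SpinOperatorSet:
    """Cartesian and ladder spin operators for a single spin-j space."""

    jx: np.ndarray
    jy: np.ndarray
    jz: np.ndarray
    jplus: np.ndarray
    jminus: np.ndarray
    dim: int

    @property
    def j(self) -> float:
        return (self.dim - 1) / 2


@dataclass(frozen=True)
class SubspaceCatalog:
    """Decomposition of N spin-1/2 nuclei into total-spin sectors.

    ``entries`` lists ``(j, degeneracy)`` sorted by descending j; the
    degeneracy-weighted dimensions always sum to 2**N.
    """

    N: int
    entries: tuple[tuple[float, int], ...] = field(default=())

    def weights(self) -> dict[float, float]:
        """Probability weight nu(N,j)(2j+1)/2^N of each sector under a
        maximally mixed nuclear state."""
        total = 2**self.N
        return {j: nu * (2 * j + 1) / total for j, nu in self.entries}


def _two_j(j: float) -> int:
    two_j = int(round(2 * j))
    if abs(2 * j - two_j) > 1e-12 or two_j < 0:
        raise ValueError(f"j must be a nonnegative half-integer, got {j}")
    return two_j


def collective_spin_ops(j: float) -> SpinOperatorSet:
    """Angular-momentum operators on the (2j+1)-dimensional spin-j space.

    The ladder matrix elements follow <j,m+1|J+|j,m> = sqrt(j(j+1)-m(m+1)).
    """
    two_j = _two_j(j)
    dim = two_j + 1
    m = (two_j - 2 * np.arange(dim)) / 2.0  # j, j-1, ..., -j
    jz = np.diag(m).astype(complex)
    # J+ raises m: nonzero at (row m+1, col m) => superdiagonal in this order
    amp = np.sqrt(j * (j + 1) - m[1:] * (m[1:] + 1))
    jplus = np.zeros((dim, dim), dtype=complex)
    jplus[np.arange(dim - 1), np.arange(1, dim)] = amp
    jminus = jplus.conj().T
    jx = (jplus + jminus) / 2
    jy = (jplus - jminus) / 2j
    return SpinOperatorSet(jx=jx, jy=jy, jz=jz, jplus=jplus, jminus=jminus, dim=dim)


def spin_half_ops() -> SpinOperatorSet:
    """Pauli-based spin-1/2 operators S = sigma/2."""
    return collective_spin_ops(0.5)


def degeneracy(N: int, j: float) -> int:
    """Multiplicity nu(N, j) of total spin j among N spin-1/2 particles.

    Computed as C(N, N/2-j) - C(N, N/2-j-1) with exact integer arithmetic.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    two_j = _two_j(j)
    if (N - two_j) % 2 != 0:
        raise ValueError(f"j={j} has wrong parity for N={N}")
    if two_j > N:
        raise ValueError(f"j={j} exceeds N/2 for N={N}")
    k = (N - two_j) // 2  # = N/2 - j
    return comb(N, k) - (comb(N, k - 1) if k >= 1 else 0)


def enumerate_subspaces(N: int) -> SubspaceCatalog:
    """All admissible (j, nu) sectors for N spin-1/2 nuclei, descending j."""
    if N < 1:
        raise ValueError("N must be >= 1")
    entries = []
    for two_j in range(N, -1, -2):  # N, N-2, ..., down to 0 or 1
        j = two_j / 2.0
        entries.append((j, degeneracy(N, j)))
    return SubspaceCatalog(N=N, entries=tuple(entries))


def embed(op: np.ndarray, slot: int, dims: list[int]) -> np.ndarray:
    """Kronecker-embed ``op`` at position ``slot`` of a tensor product whose
    factors have dimensions ``dims``; identities fill the other slots."""
    op = np.asarray(op)
    if op.shape != (dims[slot], dims[slot]):
        raise ValueError(
            f"operator shape {op.shape} does not match dims[{slot}]={dims[slot]}"
        )
    out = np.array([[1.0 + 0.0j]])
    for i, d in enumerate(dims):
        factor = op if i == slot else np.eye(d, dtype=complex)
        out = np.kron(out, factor)
    return out
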