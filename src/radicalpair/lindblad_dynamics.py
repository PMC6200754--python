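"""Born-Markov (Lindblad) master equation: assembly and propagation.

The master equation for each radical, in the interaction picture after the
rotating-wave and Born-Markov approximations, is a sum of dissipators built
from the eigenoperator decomposition of the bath coupling:

    d rho/dt =  gamma_D  D[V0](rho)
             + sum_q gamma_q (N_q + 1) D[V_q](rho)      (emission)
             + sum_q gamma_q  N_q      D[V_q^dag](rho)  (absorption)

with D[L](rho) = L rho L^dag - (1/2){L^dag L, rho}.  Because the V_q are
eigenoperators, the same generator with -i[H, .] added propagates the
Schroedinger picture, so both pictures share a time-independent Liouvillian.

The two radicals share no Hamiltonian or dissipative term, so the pair
generator is a sum of terms local to radical A = (electron 1 x nuclei 1)
and radical B = (electron 2 x nuclei 2).  The joint propagator therefore
factorizes, exp(L_joint t) = exp(L_A t) (x) exp(L_B t), and the entangled
singlet pair state is propagated by applying each radical's superoperator
to its own index pair of the joint density matrix.  A brute-force joint-
space generator is also provided as a cross-check oracle for small blocks.

Superoperators use the row-major vectorization vec(X) = X.reshape(-1), for
which vec(A X B) = kron(A, B.T) vec(X).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from .eigenoperators import TransitionSet
from .hamiltonians import BlockHamiltonian, Spectrum
from .rates_env import RateTable

__all__ = [
    "DensityOperator",
    "Liouvillian",
    "dissipator",
    "build_liouvillian",
    "build_joint_liouvillian",
    "propagate",
    "to_schrodinger",
    "initial_pair_state",
    "permute_subsystems",
    "compose_pair_maps",
    "pair_expectations",
    "singlet_state",
]

TRACE_TOL = 1e-8


@dataclass(frozen=True)
class DensityOperator:
    """Validated density matrix with subsystem bookkeeping."""

    matrix: np.ndarray
    dims: tuple[int, ...]
    picture: str = "schrodinger"  # or "interaction"

    def __post_init__(self) -> None:
        rho = self.matrix
        if rho.shape[0] != rho.shape[1]:
            raise ValueError("density matrix must be square")
        if int(np.prod(self.dims)) != rho.shape[0]:
            raise ValueError("dims inconsistent with matrix size")
        if self.picture not in ("schrodinger", "interaction"):
            raise ValueError(f"unknown picture {self.picture!r}")
        if abs(np.trace(rho) - 1.0) > TRACE_TOL:
            raise ValueError(f"trace {np.trace(rho)} deviates from 1")
        if np.abs(rho - rho.conj().T).max() > 1e-8:
            raise ValueError("density matrix not Hermitian")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())

    def purity(self) -> float:
        return float(np.real(np.trace(self.matrix @ self.matrix)))


@dataclass(frozen=True)
class Liouvillian:
    """Vectorized generator acting on row-major vectorized operators."""

    generator: np.ndarray  # (d^2, d^2)
    dims: tuple[int, ...]
    picture: str  # picture whose states this generator propagates
    block_label: str = ""

    @property
    def dim(self) -> int:
        return int(np.prod(self.dims))


def _left(a: np.ndarray) -> np.ndarray:
    return np.kron(a, np.eye(a.shape[0], dtype=complex))


def _right(b: np.ndarray) -> np.ndarray:
    return np.kron(np.eye(b.shape[0], dtype=complex), b.T)


def dissipator(l_op: np.ndarray, rate: float) -> np.ndarray:
    """Superoperator of rate * (L rho L^dag - (1/2){L^dag L, rho})."""
    ldl = l_op.conj().T @ l_op
    return rate * (
        np.kron(l_op, l_op.conj())
        - 0.5 * (_left(ldl) + _right(ldl))
    )


def build_liouvillian(
    ts: TransitionSet,
    rt: RateTable,
    hamiltonian: BlockHamiltonian | None = None,
    dims: tuple[int, ...] | None = None,
    block_label: str = "",
) -> Liouvillian:
    """Assemble the dissipative generator from a transition set and rates.

    Every frequency in ``ts`` must be present in ``rt``.  If ``hamiltonian``
    is given, the coherent term -i[H, .] is included and the generator
    propagates Schroedinger-picture states; otherwise it is the pure
    interaction-picture dissipator.
    """
    d = ts.v0.shape[0]
    gen = dissipator(ts.v0, rt.gamma_d)
    for omega, vq in ts.transitions:
        gamma, n_th = rt.lookup(omega)
        gen += dissipator(vq, gamma * (n_th + 1.0))
        gen += dissipator(vq.conj().T, gamma * n_th)
    picture = "interaction"
    if hamiltonian is not None:
        h = hamiltonian.matrix
        gen += -1j * (_left(h) - _right(h))
        picture = "schrodinger"
        if dims is None:
            dims = hamiltonian.dims
    if dims is None:
        dims = (d,)
    return Liouvillian(generator=gen, dims=tuple(dims), picture=picture,
                       block_label=block_label)


def build_joint_liouvillian(
    l_a: Liouvillian, l_b: Liouvillian
) -> Liouvillian:
    """Brute-force generator on the joint (A x B) space: each single-radical
    superoperator term is lifted to the joint operator space.  Used as the
    oracle the factorized propagation is checked against."""
    da, db = l_a.dim, l_b.dim
    dj = da * db
    # lift: joint vec index ((iA,iB),(jA,jB)) row-major = ((iA*db+iB)*dj + ...)
    # Build via the permutation that maps vec_joint to (vecA x vecB) ordering.
    perm = _pair_vec_permutation(da, db)
    ga = np.kron(l_a.generator, np.eye(db * db, dtype=complex))
    gb = np.kron(np.eye(da * da, dtype=complex), l_b.generator)
    gen = perm.T @ (ga + gb) @ perm
    return Liouvillian(
        generator=gen,
        dims=l_a.dims + l_b.dims,
        picture=l_a.picture,
        block_label=f"joint({l_a.block_label},{l_b.block_label})",
    )


def _pair_vec_permutation(da: int, db: int) -> np.ndarray:
    """Permutation P with (P vec_joint)[(iA,jA,iB,jB)] = vec_joint[(iA,iB,jA,jB)],
    i.e. mapping the joint row-major vec onto the (vec_A (x) vec_B) ordering."""
    dj = da * db
    idx = np.arange(dj * dj).reshape(da, db, da, db).transpose(0, 2, 1, 3).reshape(-1)
    p = np.zeros((dj * dj, dj * dj))
    p[np.arange(dj * dj), idx] = 1.0
    return p


def _uniform_step(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if times[0] != 0:
        raise ValueError("times must start at 0")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
        if len(np.unique(np.round(steps, 15))) > 10_000:
            raise ValueError("non-uniform grid with too many distinct steps")
        return -1.0
    return float(steps[0])


def propagate(
    liouvillian: Liouvillian, rho0: DensityOperator, times: np.ndarray
) -> list[DensityOperator]:
    """Evolve rho0 along ``times`` with exp(L t) (matrix exponential of the
    vectorized generator; the exponential of the uniform step is reused)."""
    times = np.asarray(times, dtype=float)
    d = liouvillian.dim
    if rho0.matrix.shape[0] != d:
        raise ValueError("state dimension does not match generator")
    dt = _uniform_step(times)
    vec = rho0.matrix.reshape(-1)
    out = [replace(rho0, picture=liouvillian.picture)]
    if dt > 0:
        step = expm(liouvillian.generator * dt)
        for _ in times[1:]:
            vec = step @ vec
            out.append(
                DensityOperator(
                    matrix=_rehermitize(vec.reshape(d, d)),
                    dims=rho0.dims,
                    picture=liouvillian.picture,
                )
            )
    else:  # non-uniform grid: exponential per distinct step
        cache: dict[float, np.ndarray] = {}
        for i, t in enumerate(times[1:], start=1):
            h = float(times[i] - times[i - 1])
            if h not in cache:
                cache[h] = expm(liouvillian.generator * h)
            vec = cache[h] @ vec
            out.append(
                DensityOperator(
                    matrix=_rehermitize(vec.reshape(d, d)),
                    dims=rho0.dims,
                    picture=liouvillian.picture,
                )
            )
    return out


def _rehermitize(rho: np.ndarray) -> np.ndarray:
    return 0.5 * (rho + rho.conj().T)


def to_schrodinger(
    rho_i: DensityOperator, spectrum: Spectrum, t: float
) -> DensityOperator:
    """Undo the interaction-picture rotation: rho_S = U rho_I U^dag with
    U = exp(-i H t) applied through the eigendecomposition of H."""
    if rho_i.picture != "interaction":
        raise ValueError("input must be an interaction-picture state")
    v = spectrum.vectors
    phases = np.exp(-1j * spectrum.energies * t)
    u = (v * phases[None, :]) @ v.conj().T
    return DensityOperator(
        matrix=u @ rho_i.matrix @ u.conj().T,
        dims=rho_i.dims,
        picture="schrodinger",
    )


def singlet_state() -> np.ndarray:
    """|S> = (|01> - |10>)/sqrt(2) on two qubits (m = +1/2 listed first)."""
    s = np.zeros(4, dtype=complex)
    s[1] = 1 / np.sqrt(2)
    s[2] = -1 / np.sqrt(2)
    return s


def permute_subsystems(
    op: np.ndarray, dims: tuple[int, ...], perm: tuple[int, ...]
) -> np.ndarray:
    """Reorder the tensor factors of a square operator: factor i of the
    output is factor perm[i] of the input."""
    n = len(dims)
    new_dims = [dims[p] for p in perm]
    tens = op.reshape(*dims, *dims)
    axes = list(perm) + [n + p for p in perm]
    return tens.transpose(axes).reshape(int(np.prod(new_dims)), -1)


def initial_pair_state(dn1: int, dn2: int) -> DensityOperator:
    """Electron singlet |S><S| tensored with maximally mixed nuclear states,
    on the joint ordering (e1, n1, e2, n2)."""
    s = singlet_state()
    rho_e = np.outer(s, s.conj())  # on (e1, e2)
    rho = np.kron(rho_e, np.kron(np.eye(dn1), np.eye(dn2)) / (dn1 * dn2))
    # reorder (e1, e2, n1, n2) -> (e1, n1, e2, n2)
    rho = permute_subsystems(rho, (2, 2, dn1, dn2), (0, 2, 1, 3))
    return DensityOperator(matrix=rho, dims=(2, dn1, 2, dn2), picture="schrodinger")


def _to_pair_matrix(rho: np.ndarray, da: int, db: int) -> np.ndarray:
    """Joint density matrix -> (da^2, db^2) array R with row index the
    row-major A vec index and column index the B vec index."""
    return rho.reshape(da, db, da, db).transpose(0, 2, 1, 3).reshape(da * da, db * db)


def _from_pair_matrix(r: np.ndarray, da: int, db: int) -> np.ndarray:
    return r.reshape(da, da, db, db).transpose(0, 2, 1, 3).reshape(da * db, da * db)


def compose_pair_maps(
    l_a: Liouvillian,
    l_b: Liouvillian,
    rho0: DensityOperator,
    times: np.ndarray,
) -> list[DensityOperator]:
    """Propagate the joint pair state by applying each radical's propagated
    map to its own factor: R(t + dt) = E_A R(t) E_B^T with E = exp(L dt).

    Exactly equivalent to propagating the joint-space generator because the
    two radicals share no coupling term."""
    if l_a.picture != l_b.picture:
        raise ValueError("pictures of the two generators differ")
    da, db = l_a.dim, l_b.dim
    if rho0.matrix.shape[0] != da * db:
        raise ValueError("pair state dimension mismatch")
    times = np.asarray(times, dtype=float)
    dt = _uniform_step(times)
    if dt < 0:
        raise ValueError("compose_pair_maps requires a uniform grid")
    ea = expm(l_a.generator * dt)
    ebt = expm(l_b.generator * dt).T
    r = _to_pair_matrix(rho0.matrix, da, db)
    out = [replace(rho0, picture=l_a.picture)]
    for _ in times[1:]:
        r = ea @ r @ ebt
        out.append(
            DensityOperator(
                matrix=_rehermitize(_from_pair_matrix(r, da, db)),
                dims=rho0.dims,
                picture=l_a.picture,
            )
        )
    return out


def _spectral(gen: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    evals, w = np.linalg.eig(gen)
    cond = np.linalg.cond(w)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"generator eigenbasis ill-conditioned (cond={cond:.2e})"
        )
    return evals, w, np.linalg.inv(w)


def pair_expectations(
    l_a: Liouvillian,
    l_b: Liouvillian,
    rho0: DensityOperator,
    observables: dict[str, np.ndarray],
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Expectation values Tr(O rho(t)) of joint-space observables along the
    factorized pair evolution, without materializing rho(t).

    Uses the spectral form exp(L t) = W exp(D t) W^-1 of each radical's
    generator, reducing each observable to a double sum over eigenmode pairs;
    falls back to :func:`compose_pair_maps` stepping if either generator's
    eigenbasis is ill-conditioned.  Intended for the large collective blocks
    where storing full trajectories would be wasteful.
    """
    da, db = l_a.dim, l_b.dim
    times = np.asarray(times, dtype=float)
    try:
        ev_a, wa, wa_inv = _spectral(l_a.generator)
        ev_b, wb, wb_inv = _spectral(l_b.generator)
    except np.linalg.LinAlgError:
        states = compose_pair_maps(l_a, l_b, rho0, times)
        return {
            name: np.array([np.real(np.trace(o @ st.matrix)) for st in states])
            for name, o in observables.items()
        }
    r0 = _to_pair_matrix(rho0.matrix, da, db)
    c0 = wa_inv @ r0 @ wb_inv.T
    u = np.exp(np.outer(ev_a, times))  # (da^2, nt)
    v = np.exp(np.outer(ev_b, times))  # (db^2, nt)
    out = {}
    for name, o in observables.items():
        s_o = o.reshape(da, db, da, db).transpose(2, 0, 3, 1).reshape(da * da, db * db)
        m = (wa.T @ s_o @ wb) * c0
        out[name] = np.real(np.einsum("at,at->t", u, m @ v))
    return out
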