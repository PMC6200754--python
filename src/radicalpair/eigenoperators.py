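"""Eigenoperator (transition-operator) decomposition of the bath coupling.

Each radical couples to its bosonic bath through V = alpha (Sx + Sz) acting
on the electron.  In the eigenbasis of the radical Hamiltonian H this
operator splits into a zero-frequency part V0 (the decoherence channel) and
transition operators V_q, one per distinct positive energy gap omega_q,
satisfying [H, V_q] = -omega_q V_q and [H, V_q^dag] = +omega_q V_q^dag.
V_q collects the lowering terms |a><a| V |b><b| with E_b - E_a = omega_q > 0,
so that in the master equation the gamma_q (N+1) emission dissipator carries
V_q and the gamma_q N absorption dissipator carries V_q^dag.

Completeness: V0 + sum_q (V_q + V_q^dag) reconstructs V exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonians import BlockHamiltonian, Spectrum
from .spin_algebra import embed, spin_half_ops

__all__ = [
    "TransitionSet",
    "coupling_operator",
    "decompose",
    "verify_commutators",
    "GROUPING_TOL",
]

#: default relative tolerance (vs the largest |E|) for merging energy gaps:
#: physical gaps in this model are kHz-scale or larger while numerical noise
#: on MHz-scale energies sits near 1e-15 relative, so the band is wide.
GROUPING_TOL = 1e-9


@dataclass(frozen=True)
class TransitionSet:
    """V0 plus the (omega_q, V_q) transition operators of one radical block."""

    v0: np.ndarray
    transitions: tuple[tuple[float, np.ndarray], ...]  # omega_q (rad/s) > 0, ascending
    radical_index: int
    grouping_tol: float

    @property
    def frequencies(self) -> np.ndarray:
        """Positive transition angular frequencies, ascending (rad/s)."""
        return np.array([w for w, _ in self.transitions])

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.frequencies / (2 * np.pi)


def coupling_operator(alpha: float, dims: list[int] | tuple[int, ...]) -> np.ndarray:
    """alpha (Sx + Sz) on the electron slot (slot 0), identity elsewhere."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    s = spin_half_ops()
    return alpha * embed(s.jx + s.jz, 0, list(dims))


def decompose(
    v: np.ndarray,
    spectrum: Spectrum,
    grouping_tol: float = GROUPING_TOL,
    radical_index: int = 1,
) -> TransitionSet:
    """Split ``v`` into V0 and transition operators in ``spectrum``'s basis.

    Energy gaps within ``grouping_tol`` (relative to the largest |E|) of each
    other are merged into a single transition frequency; gaps falling in the
    ambiguous band between 0.1x and 10x the tolerance raise, signalling an
    ill-chosen tolerance rather than silently mis-grouping.
    """
    energies = spectrum.energies
    u = spectrum.vectors
    d = len(energies)
    scale = max(np.abs(energies).max(), 1.0)
    tol = grouping_tol * scale

    # v in the energy eigenbasis
    v_eig = u.conj().T @ v @ u

    gaps = energies[None, :] - energies[:, None]  # gaps[a, b] = E_b - E_a
    pos = gaps[gaps > tol]
    if pos.size:
        near = np.abs(gaps[(np.abs(gaps) > 0.1 * tol) & (np.abs(gaps) <= 10 * tol)])
        if near.size:
            raise ValueError(
                "energy gaps fall inside the ambiguous grouping band; "
                "choose a different grouping_tol"
            )

    # cluster positive gaps into distinct frequencies; consecutive sorted
    # gaps must differ by either <=0.1*tol (same cluster) or >10*tol
    reps: list[float] = []
    prev = None
    for w in np.sort(pos):
        if prev is not None and 0.1 * tol < w - prev <= 10 * tol:
            raise ValueError(
                "distinct energy gaps differ by an amount inside the ambiguous "
                "grouping band; choose a different grouping_tol"
            )
        if not reps or w - reps[-1] > tol:
            reps.append(float(w))
        prev = w

    v0 = np.zeros_like(v)
    ops = [np.zeros_like(v) for _ in reps]
    reps_arr = np.array(reps) if reps else np.empty(0)
    for a in range(d):
        for b in range(d):
            w = gaps[a, b]
            term = v_eig[a, b]
            if term == 0:
                continue
            proj = np.zeros_like(v)
            proj[a, b] = term
            if abs(w) <= tol:
                v0 += proj
            elif w > 0:
                q = int(np.argmin(np.abs(reps_arr - w)))
                ops[q] += proj
            # raising terms (w < 0) are implied by conjugation; drop them

    # drop frequencies whose operator vanished (no coupling between those levels)
    norm_scale = max(np.linalg.norm(v), 1.0)
    kept = [
        (w, u @ op @ u.conj().T)
        for w, op in zip(reps, ops)
        if np.linalg.norm(op) > 1e-12 * norm_scale
    ]
    return TransitionSet(
        v0=u @ v0 @ u.conj().T,
        transitions=tuple(kept),
        radical_index=radical_index,
        grouping_tol=grouping_tol,
    )


def verify_commutators(ts: TransitionSet, h: BlockHamiltonian) -> dict[str, float]:
    """Max residuals of [H, V0] = 0 and [H, V_q] = -omega_q V_q (plus the
    conjugate identity), each relative to ||H|| / ||V_q||; test oracle only."""
    hm = h.matrix
    h_norm = max(np.linalg.norm(hm), 1.0)
    res_v0 = np.linalg.norm(hm @ ts.v0 - ts.v0 @ hm) / h_norm
    res_low = 0.0
    res_raise = 0.0
    for w, vq in ts.transitions:
        vn = max(np.linalg.norm(vq), 1e-300)
        comm = hm @ vq - vq @ hm
        res_low = max(res_low, np.linalg.norm(comm + w * vq) / (vn * max(w, h_norm)))
        vqd = vq.conj().T
        commd = hm @ vqd - vqd @ hm
        res_raise = max(
            res_raise, np.linalg.norm(commd - w * vqd) / (vn * max(w, h_norm))
        )
    return {"v0": res_v0, "lowering": res_low, "raising": res_raise}
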