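"""System Hamiltonians for the radical pair.

Only the Zeeman and hyperfine terms are retained: the two electrons are far
enough apart that dipolar and exchange couplings are negligible, and the
nuclear Zeeman term is suppressed by the nuclear gyromagnetic ratio.  With
no electron-electron term the pair Hamiltonian factorizes, so each radical
(electron + its nuclear environment) is built and diagonalized on its own
and the entangled pair state is handled at propagation time.

Two models are supported:

* ``collective`` -- each radical's N spin-1/2 nuclei couple through their
  total angular momentum, so the nuclear space splits into spin-j blocks.
  Per block the radical Hamiltonian is

      H = gamma_e B . S  +  lambda_h sum_n A_nn S_n I_n

  on the (2) x (2j+1) space, with a diagonal hyperfine tensor A (by default
  A1 = diag(2, 2, 1) anisotropic on radical 1, A2 = identity on radical 2 --
  the anisotropy is what makes radical 1 orientation-sensitive, i.e. the
  compass).

* ``noncollective`` -- radical 1's electron couples to two distinct spin-1/2
  nuclei with independent anisotropic coupling triples (omega_x, omega_y,
  omega_z) each, on the (2) x (2) x (2) space; radical 2 is a bare electron.

Units: Hamiltonians are stored in angular frequency (rad/s, hbar = 1).
Couplings supplied in Hz are multiplied by 2*pi on ingestion and reported
transition frequencies divide by 2*pi, so Hz is the external convention
throughout (e.g. the Larmor frequency at 47 uT is g mu_B B0 / h = 1.32 MHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import physical_constants, hbar

from .spin_algebra import SpinOperatorSet, collective_spin_ops, embed, spin_half_ops

__all__ = [
    "GAMMA_E",
    "SystemSpec",
    "BlockHamiltonian",
    "Spectrum",
    "zeeman_angular_frequency",
    "build_collective_block",
    "build_noncollective",
    "bare_electron_block",
    "diagonalize",
]

_MU_B = physical_constants["Bohr magneton"][0]
_G_E = 2.0
#: electron gyromagnetic ratio gamma_e = -g mu_B / hbar (rad s^-1 T^-1), g = 2
GAMMA_E = -_G_E * _MU_B / hbar

_TWO_PI = 2.0 * np.pi


def zeeman_angular_frequency(b0_tesla: float) -> float:
    """|gamma_e| B0 in rad/s; divide by 2*pi for the Larmor frequency in Hz."""
    return abs(GAMMA_E) * b0_tesla


@dataclass
class SystemSpec:
    """Full physical-parameter description of one simulation.

    Parameters
    ----------
    mode:
        ``"collective"`` or ``"noncollective"``.
    b0_tesla:
        External magnetic flux density (default 47 uT, geomagnetic).
    field_axis:
        Unit vector of the field direction (default z, aligned with the
        anisotropy axis of A1).
    temperature_k:
        Bath temperature (default 300 K, physiological).
    alpha:
        Dimensionless weight of the bath-coupling operator alpha*(Sx+Sz);
        Sx and Sz enter equally because neither dissipation (Sx) nor
        decoherence (Sz) is known to dominate.
    dipole_moment_cm:
        Transition dipole magnitude |d| in C m entering the cubic-frequency
        dissipation rate; see :mod:`radicalpair.rates_env` for the default
        calibration.
    n1, n2:
        Collective mode: nuclei per radical.
    lambda_h_hz:
        Collective-mode hyperfine coupling constant (Hz).
    a1, a2:
        Diagonal 3x3 hyperfine tensors (dimensionless) for radicals 1 and 2.
    couplings_hz:
        Non-collective mode: two (omega_x, omega_y, omega_z) triples in Hz,
        one per nucleus on radical 1.
    """

    mode: str = "collective"
    b0_tesla: float = 47e-6
    field_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    temperature_k: float = 300.0
    alpha: float = 1.0
    dipole_moment_cm: float | None = None
    # collective parameters
    n1: int = 1
    n2: int = 1
    lambda_h_hz: float = 1e7
    a1: tuple[float, float, float] = (2.0, 2.0, 1.0)
    a2: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # non-collective parameters (radical 1 carries two nuclei)
    couplings_hz: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("collective", "noncollective"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.b0_tesla <= 0:
            raise ValueError("b0_tesla must be positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.lambda_h_hz < 0:
            raise ValueError("lambda_h_hz must be nonnegative")
        axis = np.asarray(self.field_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("field_axis must be nonzero")
        self.field_axis = tuple(axis / norm)
        if self.mode == "noncollective" and len(self.couplings_hz) != 2:
            raise ValueError("noncollective mode needs exactly two coupling triples")

    def nuclei(self, radical: int) -> int:
        return self.n1 if radical == 1 else self.n2

    def hyperfine_tensor(self, radical: int) -> tuple[float, float, float]:
        return self.a1 if radical == 1 else self.a2


@dataclass(frozen=True)
class BlockHamiltonian:
    """One radical's Hamiltonian on a single (electron x nuclear) block."""

    matrix: np.ndarray  # rad/s, Hermitian
    dims: tuple[int, ...]  # subsystem dimensions, electron first
    block_label: str
    radical_index: int

    def __post_init__(self) -> None:
        h = self.matrix
        if h.shape[0] != h.shape[1] or h.shape[0] != int(np.prod(self.dims)):
            raise ValueError("matrix shape inconsistent with dims")
        scale = max(np.abs(h).max(), 1.0)
        if np.abs(h - h.conj().T).max() > 1e-12 * scale:
            raise ValueError("Hamiltonian is not Hermitian")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Spectrum:
    """Eigendecomposition of a block Hamiltonian (ascending energies)."""

    energies: np.ndarray  # rad/s
    vectors: np.ndarray  # unitary, columns aligned with energies


def _field_dot_spin(spec: SystemSpec, s: SpinOperatorSet) -> np.ndarray:
    nx, ny, nz = spec.field_axis
    return GAMMA_E * spec.b0_tesla * (nx * s.jx + ny * s.jy + nz * s.jz)


def build_collective_block(spec: SystemSpec, radical: int, j: float) -> BlockHamiltonian:
    """Collective-model Hamiltonian of one radical's spin-j nuclear block."""
    if spec.mode != "collective":
        raise ValueError("spec.mode must be 'collective'")
    if radical not in (1, 2):
        raise ValueError("radical must be 1 or 2")
    s = spin_half_ops()
    if j == 0:
        # no nuclear degrees of freedom: bare Zeeman doublet
        h = _field_dot_spin(spec, s)
        return BlockHamiltonian(
            matrix=h, dims=(2, 1), block_label=f"j=0", radical_index=radical
        )
    i_ops = collective_spin_ops(j)
    dims = [2, i_ops.dim]
    h = embed(_field_dot_spin(spec, s), 0, dims)
    lam = _TWO_PI * spec.lambda_h_hz
    a = spec.hyperfine_tensor(radical)
    for axis_idx, (s_ax, i_ax) in enumerate(
        ((s.jx, i_ops.jx), (s.jy, i_ops.jy), (s.jz, i_ops.jz))
    ):
        h = h + lam * a[axis_idx] * (embed(s_ax, 0, dims) @ embed(i_ax, 1, dims))
    return BlockHamiltonian(
        matrix=h, dims=tuple(dims), block_label=f"j={j:g}", radical_index=radical
    )


def bare_electron_block(spec: SystemSpec, radical: int = 2) -> BlockHamiltonian:
    """Zeeman-only Hamiltonian of an electron with no hyperfine partner."""
    s = spin_half_ops()
    return BlockHamiltonian(
        matrix=_field_dot_spin(spec, s),
        dims=(2, 1),
        block_label="bare",
        radical_index=radical,
    )


def build_noncollective(spec: SystemSpec) -> BlockHamiltonian:
    """Radical-1 Hamiltonian with two independently (an)isotropically coupled
    spin-1/2 nuclei: electron x nucleus-1 x nucleus-2.

    Each nucleus n contributes sum_i omega_i^(n) S_i (x) I_i^(n) with the
    coupling triple omega given directly in Hz (the couplings already set the
    interaction scale, so no separate overall hyperfine constant is applied).
    """
    if spec.mode != "noncollective":
        raise ValueError("spec.mode must be 'noncollective'")
    s = spin_half_ops()
    dims = [2, 2, 2]
    h = embed(_field_dot_spin(spec, s), 0, dims)
    for n, triple in enumerate(spec.couplings_hz):
        if len(triple) != 3:
            raise ValueError("each coupling must be an (x, y, z) triple in Hz")
        nuc_slot = 1 + n
        for axis_idx, s_ax in enumerate((s.jx, s.jy, s.jz)):
            w = _TWO_PI * triple[axis_idx]
            h = h + w * (embed(s_ax, 0, dims) @ embed(s_ax, nuc_slot, dims))
    return BlockHamiltonian(
        matrix=h, dims=(2, 2, 2), block_label="2-nuclei", radical_index=1
    )


def diagonalize(h: BlockHamiltonian) -> Spectrum:
    """Eigendecomposition with ascending energies and a deterministic phase
    convention (largest-magnitude component of each vector real positive)."""
    energies, vectors = np.linalg.eigh(h.matrix)
    # fix phases for reproducibility
    idx = np.argmax(np.abs(vectors), axis=0)
    phases = vectors[idx, np.arange(vectors.shape[1])]
    phases = phases / np.abs(phases)
    vectors = vectors / phases[None, :]
    return Spectrum(energies=energies, vectors=vectors)
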