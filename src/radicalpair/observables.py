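"""Singlet/triplet probabilities, lifetimes, oscillation frequencies and
transition-frequency spectra.

The four spin states of the electron pair are the singlet |S> and the three
triplets, labelled Triplet 1/2/3 in order of descending total electron Sz
along the field axis (+1, 0, -1).  Probabilities are expectations of the
four projectors embedded on the joint (e1, n1, e2, n2) space, which is
equivalent to tracing out the nuclei first.

The coherence lifetime is operationalized as the 1/e decay time of the
envelope of the singlet - Triplet-2 population difference computed on the
interaction-picture trajectory (the interaction picture strips the fast
singlet-triplet oscillation, leaving the dissipative envelope); runs whose
envelope never reaches 1/e within the simulated horizon are censored and
reported as infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eigenoperators import coupling_operator, decompose
from .hamiltonians import (
    SystemSpec,
    bare_electron_block,
    build_collective_block,
    build_noncollective,
    diagonalize,
)
from .lindblad_dynamics import DensityOperator, permute_subsystems, singlet_state
from .spin_algebra import enumerate_subspaces

__all__ = [
    "TrajectoryResult",
    "SpectrumReport",
    "pair_projectors",
    "spin_state_probabilities",
    "aggregate_blocks",
    "envelope_lifetime",
    "block_lifetimes",
    "coherence_lifetime",
    "oscillation_frequency",
    "transition_spectrum",
]

_NORM_TOL = 1e-6
_PROB_TOL = 1e-8


@dataclass
class TrajectoryResult:
    """Degeneracy-aggregated singlet/triplet probability trajectory."""

    times: np.ndarray  # s
    p_singlet: np.ndarray
    p_t1: np.ndarray  # total electron Sz = +1
    p_t2: np.ndarray  # Sz = 0
    p_t3: np.ndarray  # Sz = -1
    picture: str = "interaction"
    per_block: dict = field(default_factory=dict)  # (j1, j2) -> (4, nt) array
    weights: dict = field(default_factory=dict)  # (j1, j2) -> weight

    def __post_init__(self) -> None:
        total = self.p_singlet + self.p_t1 + self.p_t2 + self.p_t3
        if np.abs(total - 1.0).max() > _NORM_TOL:
            raise ValueError("spin-state probabilities do not sum to 1")
        for p in (self.p_singlet, self.p_t1, self.p_t2, self.p_t3):
            if p.min() < -_PROB_TOL or p.max() > 1 + _PROB_TOL:
                raise ValueError("probability out of [0, 1]")

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.p_singlet, self.p_t1, self.p_t2, self.p_t3])


@dataclass(frozen=True)
class SpectrumReport:
    """Distinct positive transition frequencies of a system, with provenance."""

    frequencies_hz: np.ndarray  # sorted, distinct
    per_block: dict  # (radical, block label) -> frequencies_hz array
    count: int

    @property
    def min_hz(self) -> float:
        return float(self.frequencies_hz.min())

    @property
    def max_hz(self) -> float:
        return float(self.frequencies_hz.max())


def _electron_pair_basis() -> dict[str, np.ndarray]:
    t_plus = np.array([1, 0, 0, 0], dtype=complex)  # |m=+1/2, m=+1/2>
    t_minus = np.array([0, 0, 0, 1], dtype=complex)
    t_zero = np.array([0, 1, 1, 0], dtype=complex) / np.sqrt(2)
    return {
        "singlet": singlet_state(),
        "t1": t_plus,
        "t2": t_zero,
        "t3": t_minus,
    }


def pair_projectors(dn1: int, dn2: int) -> dict[str, np.ndarray]:
    """Projectors |S><S|, |T1><T1|, |T2><T2|, |T3><T3| (x) identity on the
    nuclei, on the joint ordering (e1, n1, e2, n2)."""
    eye_n = np.kron(np.eye(dn1), np.eye(dn2))
    out = {}
    for name, vec in _electron_pair_basis().items():
        p = np.kron(np.outer(vec, vec.conj()), eye_n)
        out[name] = permute_subsystems(p, (2, 2, dn1, dn2), (0, 2, 1, 3))
    return out


def spin_state_probabilities(rho: DensityOperator) -> tuple[float, float, float, float]:
    """(p_singlet, p_t1, p_t2, p_t3) of a Schroedinger-picture pair state."""
    if rho.picture != "schrodinger":
        raise ValueError("probabilities are defined on Schroedinger-picture states")
    if len(rho.dims) != 4 or rho.dims[0] != 2 or rho.dims[2] != 2:
        raise ValueError("expected a pair state with dims (2, dn1, 2, dn2)")
    projs = pair_projectors(rho.dims[1], rho.dims[3])
    return tuple(
        float(np.real(np.trace(projs[k] @ rho.matrix)))
        for k in ("singlet", "t1", "t2", "t3")
    )


def aggregate_blocks(
    per_block: dict, weights: dict, times: np.ndarray, picture: str = "interaction"
) -> TrajectoryResult:
    """Convex combination of per-block (4, nt) probability series."""
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-12:
        raise ValueError(f"block weights sum to {wsum}, not 1")
    if set(per_block) != set(weights):
        raise ValueError("per_block and weights keys differ")
    total = sum(w * np.asarray(per_block[k]) for k, w in weights.items())
    return TrajectoryResult(
        times=np.asarray(times, dtype=float),
        p_singlet=total[0],
        p_t1=total[1],
        p_t2=total[2],
        p_t3=total[3],
        picture=picture,
        per_block=per_block,
        weights=dict(weights),
    )


def envelope_lifetime(
    times: np.ndarray, p_singlet: np.ndarray, p_t2: np.ndarray,
    level: float = 1.0 / math.e,
) -> float:
    """Time at which the envelope of p_singlet - p_t2 first decays to
    ``level`` of its initial amplitude; ``inf`` if censored (no decay to the
    threshold within the trajectory horizon).

    The envelope is the running maximum of |p_singlet - p_t2| over the
    remainder of the trajectory, which is robust to slow residual
    oscillation in the interaction-picture series.
    """
    signal = np.abs(np.asarray(p_singlet) - np.asarray(p_t2))
    if signal[0] < 1e-12:
        raise ValueError("initial singlet-triplet contrast is zero")
    env = np.maximum.accumulate(signal[::-1])[::-1]
    below = np.nonzero(env <= level * signal[0])[0]
    if below.size == 0:
        return math.inf
    return float(times[below[0]])


def block_lifetimes(tr: TrajectoryResult, level: float = 1.0 / math.e) -> dict:
    """Per-sector 1/e envelope lifetimes, keyed like ``tr.per_block``."""
    return {
        key: envelope_lifetime(tr.times, series[0], series[2], level)
        for key, series in tr.per_block.items()
    }


def coherence_lifetime(tr: TrajectoryResult, level: float = 1.0 / math.e) -> float:
    """Coherence lifetime (s) of a trajectory; ``inf`` if censored.

    For a single decay channel this is the 1/e envelope time of the
    singlet - Triplet-2 contrast.  A collective run is a classical mixture
    of (j1, j2) sectors decaying at very different rates, and a single 1/e
    crossing of the mixed envelope is blind to any long-lived sector of
    weight below 1 - 1/e (notably the j = 0 sectors that dominate the
    even/odd-N distinction); the mixture's lifetime is therefore the
    degeneracy-weighted mean of the per-sector envelope lifetimes, the
    standard amplitude-weighted lifetime of a multi-exponential decay.
    """
    if tr.picture != "interaction":
        raise ValueError("lifetime is computed on interaction-picture trajectories")
    if tr.per_block:
        per = block_lifetimes(tr, level)
        return float(sum(tr.weights[k] * per[k] for k in per))
    return envelope_lifetime(tr.times, tr.p_singlet, tr.p_t2, level)


def oscillation_frequency(tr: TrajectoryResult) -> float:
    """Dominant positive frequency (Hz) of the singlet probability, from the
    discrete spectrum of the (Schroedinger-picture) series; 0 if the series
    carries no oscillation above numerical noise."""
    y = tr.p_singlet - np.mean(tr.p_singlet)
    if np.abs(y).max() < 1e-10:
        return 0.0
    dt = float(tr.times[1] - tr.times[0])
    spec = np.abs(np.fft.rfft(y * np.hanning(len(y))))
    freqs = np.fft.rfftfreq(len(y), dt)
    peak = int(np.argmax(spec[1:]) + 1)
    f = float(freqs[peak])
    nyquist = 0.5 / dt
    if f > nyquist / 4:
        raise ValueError(
            "dominant frequency too close to the Nyquist limit; refine the grid "
            "(need >= 8 samples per period)"
        )
    return f


def _block_frequencies(spec: SystemSpec) -> dict:
    """(radical, block label) -> positive transition frequencies (Hz)."""
    out = {}
    if spec.mode == "collective":
        for radical in (1, 2):
            catalog = enumerate_subspaces(spec.nuclei(radical))
            for j, _ in catalog.entries:
                h = build_collective_block(spec, radical, j)
                ts = decompose(
                    coupling_operator(spec.alpha, h.dims),
                    diagonalize(h),
                    radical_index=radical,
                )
                out[(radical, h.block_label)] = ts.frequencies_hz
    else:
        h1 = build_noncollective(spec)
        out[(1, h1.block_label)] = decompose(
            coupling_operator(spec.alpha, h1.dims), diagonalize(h1), radical_index=1
        ).frequencies_hz
        h2 = bare_electron_block(spec)
        out[(2, h2.block_label)] = decompose(
            coupling_operator(spec.alpha, h2.dims), diagonalize(h2), radical_index=2
        ).frequencies_hz
    return out


def transition_spectrum(
    spec: SystemSpec, merge_tol: float = 1e-6, radicals: tuple[int, ...] = (1, 2)
) -> SpectrumReport:
    """All distinct positive transition frequencies of the system (Hz).

    Conjugate (negative-frequency) partners are implied and counted once;
    frequencies from different blocks or radicals that coincide within
    ``merge_tol`` (relative to the largest frequency) are merged.  The result
    is deterministic and independent of nucleus ordering (the collective
    blocks depend only on N and j).
    """
    per_block = {
        k: v for k, v in _block_frequencies(spec).items() if k[0] in radicals
    }
    allf = np.sort(np.concatenate(list(per_block.values())))
    scale = allf.max()
    merged = [float(allf[0])]
    for w in allf[1:]:
        if w - merged[-1] > merge_tol * scale:
            merged.append(float(w))
    freqs = np.array(merged)
    return SpectrumReport(frequencies_hz=freqs, per_block=per_block, count=len(freqs))
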