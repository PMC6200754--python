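"""High-level pipeline: build -> diagonalize -> decompose -> rates ->
propagate -> singlet/triplet trajectories.

A collective run iterates over every (j1, j2) pair of nuclear-spin sectors,
propagates the entangled singlet pair state on each pair of blocks, and
aggregates the per-block trajectories with the maximally-mixed-nuclei
weights nu(N, j)(2j+1)/2^N per radical.  The decoherence rate gamma_D is
global to the run: ten times the largest dissipation rate over all blocks
of both radicals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eigenoperators import TransitionSet, coupling_operator, decompose
from .hamiltonians import (
    BlockHamiltonian,
    Spectrum,
    SystemSpec,
    bare_electron_block,
    build_collective_block,
    build_noncollective,
    diagonalize,
)
from .lindblad_dynamics import (
    Liouvillian,
    build_liouvillian,
    compose_pair_maps,
    initial_pair_state,
    pair_expectations,
    to_schrodinger,
)
from .observables import TrajectoryResult, aggregate_blocks, pair_projectors
from .rates_env import RateTable, build_rate_table
from .spin_algebra import enumerate_subspaces

__all__ = ["RadicalBlock", "prepare_blocks", "run_collective", "run_noncollective"]


@dataclass(frozen=True)
class RadicalBlock:
    """Everything needed to propagate one radical on one nuclear sector."""

    hamiltonian: BlockHamiltonian
    spectrum: Spectrum
    transitions: TransitionSet
    weight: float  # probability of this sector under maximally mixed nuclei

    @property
    def nuclear_dim(self) -> int:
        return int(np.prod(self.hamiltonian.dims[1:])) if len(self.hamiltonian.dims) > 1 else 1


def _make_block(h: BlockHamiltonian, spec: SystemSpec, weight: float) -> RadicalBlock:
    sp = diagonalize(h)
    ts = decompose(
        coupling_operator(spec.alpha, h.dims), sp, radical_index=h.radical_index
    )
    return RadicalBlock(hamiltonian=h, spectrum=sp, transitions=ts, weight=weight)


def prepare_blocks(spec: SystemSpec) -> tuple[dict, dict, RateTable]:
    """Blocks of both radicals plus the run-global rate table.

    Returns ``(blocks1, blocks2, rate_table)`` where ``blocks{1,2}`` map a
    block key (the sector spin j, or a label for the non-collective model)
    to a :class:`RadicalBlock`.
    """
    blocks1: dict = {}
    blocks2: dict = {}
    if spec.mode == "collective":
        for radical, blocks in ((1, blocks1), (2, blocks2)):
            n = spec.nuclei(radical)
            if n == 0:  # radical with no hyperfine partner: bare Zeeman doublet
                blocks[0.0] = _make_block(bare_electron_block(spec, radical), spec, 1.0)
                continue
            catalog = enumerate_subspaces(n)
            for j, w in catalog.weights().items():
                h = build_collective_block(spec, radical, j)
                blocks[j] = _make_block(h, spec, w)
    else:
        blocks1["2-nuclei"] = _make_block(build_noncollective(spec), spec, 1.0)
        blocks2["bare"] = _make_block(bare_electron_block(spec), spec, 1.0)
    all_ts = [b.transitions for b in (*blocks1.values(), *blocks2.values())]
    rt = build_rate_table(all_ts, spec)
    return blocks1, blocks2, rt


def _pair_series(
    b1: RadicalBlock,
    b2: RadicalBlock,
    rt: RateTable,
    times: np.ndarray,
    schrodinger: bool,
) -> np.ndarray:
    """(4, nt) singlet/triplet probability series for one block pair."""
    dn1, dn2 = b1.nuclear_dim, b2.nuclear_dim
    rho0 = initial_pair_state(dn1, dn2)
    projs = pair_projectors(dn1, dn2)
    if schrodinger:
        l1 = build_liouvillian(b1.transitions, rt, hamiltonian=b1.hamiltonian)
        l2 = build_liouvillian(b2.transitions, rt, hamiltonian=b2.hamiltonian)
    else:
        l1 = build_liouvillian(b1.transitions, rt, dims=b1.hamiltonian.dims)
        l2 = build_liouvillian(b2.transitions, rt, dims=b2.hamiltonian.dims)
    obs = pair_expectations(
        l1, l2, rho0, {k: projs[k] for k in ("singlet", "t1", "t2", "t3")}, times
    )
    return np.vstack([obs["singlet"], obs["t1"], obs["t2"], obs["t3"]])


def run_collective(
    spec: SystemSpec, times: np.ndarray, schrodinger: bool = False
) -> TrajectoryResult:
    """Degeneracy-aggregated trajectory of the collective model.

    ``schrodinger=True`` includes the coherent -i[H, .] term so the series
    carries the fast singlet-triplet oscillation; the default interaction
    picture yields the slow dissipative envelope used for lifetimes.
    """
    if spec.mode != "collective":
        raise ValueError("spec.mode must be 'collective'")
    blocks1, blocks2, rt = prepare_blocks(spec)
    times = np.asarray(times, dtype=float)
    per_block = {}
    weights = {}
    for j1, b1 in blocks1.items():
        for j2, b2 in blocks2.items():
            per_block[(j1, j2)] = _pair_series(b1, b2, rt, times, schrodinger)
            weights[(j1, j2)] = b1.weight * b2.weight
    picture = "schrodinger" if schrodinger else "interaction"
    return aggregate_blocks(per_block, weights, times, picture=picture)


def run_noncollective(
    spec: SystemSpec, times: np.ndarray, schrodinger: bool = False
) -> TrajectoryResult:
    """Trajectory of the two-nucleus (non-collective) model; radical 2 is a
    bare electron, so there is a single block pair."""
    if spec.mode != "noncollective":
        raise ValueError("spec.mode must be 'noncollective'")
    blocks1, blocks2, rt = prepare_blocks(spec)
    times = np.asarray(times, dtype=float)
    (key1, b1), (key2, b2) = next(iter(blocks1.items())), next(iter(blocks2.items()))
    series = _pair_series(b1, b2, rt, times, schrodinger)
    picture = "schrodinger" if schrodinger else "interaction"
    return aggregate_blocks(
        {(key1, key2): series}, {(key1, key2): 1.0}, times, picture=picture
    )
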