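"""Simplified one-dimensional Monte Carlo model of a polysaccharide chain.

The chain is reduced to a list of glycosidic linkages, one discrete
conformational state per linkage.  All linkages are equivalent: each offers
the same set of states with the same relative energies (state 0 is the
lowest, typically the exo-syn conformer; higher states are the anti-phi /
anti-psi conformers read off a free-energy map).  There is no geometry and
no coupling between sites -- the model isolates how the conformer energy
ladder alone shapes the pattern of conformational states along the chain.

Metropolis dynamics: each elementary move picks a linkage uniformly at
random, proposes a uniformly chosen *different* state, and accepts with
probability min(1, exp(-dE/kT)).  The headline observable is the run-length
statistic L: the average uninterrupted length of chain fragments whose
linkages all sit in the lowest-energy state.  A fragment of length L acts
as a rigid rod-like stretch, so L approximates a persistence length
expressed in linkages.

The inner loop is compiled with numba when available (a pure-Python
fallback keeps small problems usable anywhere).  Random draws are made in
a fixed, documented order -- (site, proposed state, acceptance uniform) per
move, generated in per-interval batches from one ``numpy`` Generator -- so
runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, K_B

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class StateModel:
    """Discrete conformational states of one glycosidic linkage.

    ``energies`` are relative state energies in kJ/mol; the ground state
    must come first.  Energies are normalized so the ground state is
    exactly 0.
    """

    energies: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.size < 1:
            raise ValueError("need at least one state")
        if np.argmin(e) != 0:
            raise ValueError("state 0 must be the lowest-energy state")
        self.energies = e - e[0]
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_states(self) -> int:
        return int(self.energies.size)

    @property
    def kT(self) -> float:
        return K_B * self.temperature

    def boltzmann_probabilities(self) -> np.ndarray:
        w = np.exp(-self.energies / self.kT)
        return w / w.sum()


def analytic_L(model: StateModel) -> float:
    """Infinite-chain expectation of the ground-state run length.

    At equilibrium the sites are independent with ground-state probability
    p0 = exp(0)/sum_k exp(-E_k/kT); run lengths are then geometric with
    mean 1/(1 - p0).  A single-state model has p0 = 1 and returns inf.
    """
    p0 = float(model.boltzmann_probabilities()[0])
    if p0 >= 1.0:
        return math.inf
    return 1.0 / (1.0 - p0)


def compute_L(states) -> float:
    """Mean uninterrupted ground-state run length of one configuration.

    Maximal runs of state 0 are counted (runs cut by the chain ends count
    as runs); L is the total number of ground-state linkages divided by
    the number of runs, or 0 if no linkage is in the ground state.
    """
    s = np.asarray(states)
    if s.size == 0:
        raise ValueError("empty chain")
    z = s == 0
    total = int(z.sum())
    if total == 0:
        return 0.0
    starts = int(z[0]) + int(np.count_nonzero(z[1:] & ~z[:-1]))
    return total / starts


@njit(cache=False)
def _mc_kernel(states, sites, props, unifs, accept_prob):  # pragma: no cover - jitted
    n_acc = 0
    for k in range(sites.size):
        i = sites[k]
        c = states[i]
        p = props[k]
        if p >= c:
            p += 1
        if unifs[k] < accept_prob[c, p]:
            states[i] = p
            n_acc += 1
    return n_acc


def _run_moves(states, n_moves, rng, accept_prob, n_states, chunk=1_000_000):
    """Advance the chain by n_moves elementary moves, in batched chunks."""
    n = states.size
    accepted = 0
    done = 0
    while done < n_moves:
        m = min(chunk, n_moves - done)
        sites = rng.integers(0, n, size=m)
        props = rng.integers(0, max(n_states - 1, 1), size=m)
        unifs = rng.random(m)
        accepted += _mc_kernel(states, sites, props, unifs, accept_prob)
        done += m
    return accepted


@dataclass
class Mc1dResult:
    """Samples and bookkeeping from a 1D MC run."""

    samples: np.ndarray  # (n_samples, n_linkages) int
    model: StateModel
    n_sweeps: int
    burn_in: int
    sample_every: int
    accepted_moves: int
    total_moves: int

    @property
    def acceptance_rate(self) -> float:
        return self.accepted_moves / self.total_moves if self.total_moves else 0.0

    def L_values(self) -> np.ndarray:
        return np.array([compute_L(s) for s in self.samples])

    def mean_L(self) -> float:
        return float(self.L_values().mean())

    def state_populations(self) -> np.ndarray:
        counts = np.bincount(self.samples.ravel(), minlength=self.model.n_states)
        return counts / counts.sum()


def run_1d_mc(model: StateModel, n_linkages: int, n_sweeps: int, seed: int,
              sample_every: int = 10, burn_in: int = 100) -> Mc1dResult:
    """Metropolis simulation of the 1D chain model.

    ``n_sweeps``, ``sample_every`` and ``burn_in`` are in sweeps (one sweep
    = ``n_linkages`` elementary moves).  The chain starts with every
    linkage in the ground state.  Configurations are recorded every
    ``sample_every`` sweeps after ``burn_in`` sweeps.
    """
    if n_linkages < 1:
        raise ValueError("n_linkages must be >= 1")
    if n_sweeps <= burn_in:
        raise ValueError("n_sweeps must exceed burn_in")
    if model.n_states == 1:
        logger.warning("single-state model: the chain can never change state")

    kT = model.kT
    e = model.energies
    dE = e[None, :] - e[:, None]
    accept_prob = np.minimum(1.0, np.exp(-np.maximum(dE, 0.0) / kT))
    if model.n_states == 1:
        # proposals map onto a phantom state 1 that is never accepted
        accept_prob = np.zeros((1, 2))

    rng = np.random.default_rng(seed)
    states = np.zeros(n_linkages, dtype=np.int64)

    accepted = _run_moves(states, burn_in * n_linkages, rng, accept_prob, model.n_states)
    total = burn_in * n_linkages

    samples = []
    sweeps_left = n_sweeps - burn_in
    n_intervals = sweeps_left // sample_every
    for _ in range(n_intervals):
        accepted += _run_moves(states, sample_every * n_linkages, rng, accept_prob,
                               model.n_states)
        total += sample_every * n_linkages
        samples.append(states.copy())

    return Mc1dResult(
        samples=np.array(samples, dtype=np.int64),
        model=model,
        n_sweeps=n_sweeps,
        burn_in=burn_in,
        sample_every=sample_every,
        accepted_moves=int(accepted),
        total_moves=int(total),
    )
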