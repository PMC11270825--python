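"""Coarse-grained Metropolis Monte Carlo of a polysaccharide backbone.

The chain energy is a sum of independent per-linkage terms read off a
(Phi, Psi) free-energy map: bond lengths, bond angles and the ring
dihedral are frozen, non-bonded interactions are dropped, and the only
interaction between distant parts of the chain is a hard-sphere excluded
volume (default diameter 0.4 nm between non-neighboring backbone atoms).

An elementary move picks a linkage uniformly, proposes a uniformly chosen
unmasked map bin as its new (Phi, Psi), and applies the Metropolis
criterion to the map-energy difference; a provisionally accepted move is
still rejected if the rebuilt geometry brings any non-neighboring atom
pair closer than the clash cutoff.  Because the proposal is uniform and
symmetric, with clash checking disabled the stationary per-linkage
distribution is exactly the map's Boltzmann distribution, with linkages
statistically independent -- the model's core assumption made literal.

Random draws per move are (linkage, proposal bin, acceptance uniform), in
that order, from a single seeded Generator; the uniform is drawn for every
move whether or not it is consulted, so runs are bit-reproducible.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .chain import ChainState, LinkageGeometry, build_chain, has_clash, set_linkage_inplace
from .constants import DEFAULT_TEMPERATURE, K_B
from .fem import FreeEnergyMap

logger = logging.getLogger(__name__)


@dataclass
class CgMcConfig:
    """Run parameters for the coarse-grained Monte Carlo engine."""

    n_residues: int
    n_sweeps: int
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    clash_cutoff: float = 0.4     # nm; <= 0 disables clash checking
    sample_every: int = 20        # sweeps
    burn_in: int = 200            # sweeps

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.n_sweeps <= self.burn_in:
            raise ValueError("n_sweeps must exceed burn_in")


@dataclass
class MoveLog:
    """Bookkeeping of elementary moves."""

    proposed: int = 0
    accepted: int = 0
    clash_rejected: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0


@dataclass
class CgMcResult:
    """Sampled trajectory of the CG MC engine."""

    frames: np.ndarray            # (n_samples, 3*n_residues, 3) nm
    bin_indices: np.ndarray       # (n_samples, n_linkages, 2) map bin per linkage
    energies: np.ndarray          # (n_samples,) tracked total map energy, kJ/mol
    energies_recomputed: np.ndarray  # same, recomputed from scratch at sampling
    log: MoveLog
    fem: FreeEnergyMap
    geometry: LinkageGeometry
    config: CgMcConfig

    @property
    def n_samples(self) -> int:
        return self.frames.shape[0]

    def chains(self):
        """Samples as :class:`ChainState` objects."""
        out = []
        for k in range(self.n_samples):
            dih = np.column_stack([
                self.fem.axis1[self.bin_indices[k, :, 0]],
                self.fem.axis2[self.bin_indices[k, :, 1]],
            ])
            out.append(ChainState(self.frames[k].copy(), dih, self.geometry))
        return out

    def e2e_series(self) -> np.ndarray:
        return np.linalg.norm(self.frames[:, -1] - self.frames[:, 0], axis=1)

    def rg_series(self) -> np.ndarray:
        centered = self.frames - self.frames.mean(axis=1, keepdims=True)
        return np.sqrt((centered ** 2).sum(axis=2).mean(axis=1))


def run_cg_mc(fem: FreeEnergyMap, geometry: LinkageGeometry,
              config: CgMcConfig) -> CgMcResult:
    """Sample chain configurations from a (Phi, Psi) map by Metropolis MC.

    The chain starts with every linkage at the map's global-minimum bin.
    One sweep attempts one move per linkage; configurations are recorded
    every ``sample_every`` sweeps after ``burn_in`` sweeps.  When clash
    checking is disabled the geometry does not influence the dynamics, so
    coordinates are rebuilt only at sampling times.
    """
    if not fem.is_normalized():
        fem = fem.normalized()
    unmasked = np.nonzero(~fem.mask.ravel())[0]
    if unmasked.size == 0:
        raise ValueError("map has all bins masked")
    n2 = fem.axis2.size
    flat_energy = np.where(fem.mask, np.inf, fem.energy).ravel()

    n_link = config.n_residues - 1
    kT = K_B * config.temperature
    rng = np.random.default_rng(config.seed)

    gmin = int(unmasked[np.argmin(flat_energy[unmasked])])
    bins = np.full(n_link, gmin, dtype=np.int64)  # flat bin index per linkage
    check_clash = config.clash_cutoff > 0

    def bin_angles(flat):
        return float(fem.axis1[flat // n2]), float(fem.axis2[flat % n2])

    chain = _chain_from_bins(fem, geometry, bins)
    if check_clash and has_clash(chain.coords, config.clash_cutoff):
        logger.warning("initial all-minimum configuration already contains a clash")

    energy = float(flat_energy[bins].sum())
    log = MoveLog()
    frames, idx_samples, e_tracked, e_scratch = [], [], [], []

    if unmasked.size == 1:
        logger.warning("single-bin map: the chain is frozen at the initial state")

    def advance(n_sweeps_seg):
        """Attempt n_sweeps_seg * n_link moves with one batch of draws.

        Proposals doomed under the *pre-segment* site states are screened
        out vectorially; whenever a site actually changes state, all of
        its later moves in the segment are re-enqueued and re-evaluated
        against the live state, so the dynamics are exactly the naive
        sequential Metropolis chain.
        """
        nonlocal chain, energy
        m = n_sweeps_seg * n_link
        links = rng.integers(0, n_link, size=m)
        props = unmasked[rng.integers(0, unmasked.size, size=m)]
        unifs = rng.random(m)
        log.proposed += m
        boltz = np.exp(-np.maximum(flat_energy[props] - flat_energy[bins[links]], 0.0) / kT)
        # per-site move indices, for re-enqueueing after a state change
        order = np.argsort(links, kind="stable")
        bounds = np.searchsorted(links[order], np.arange(n_link + 1))
        processed = np.zeros(m, dtype=bool)
        queue = list(np.nonzero(unifs < boltz)[0])
        heapq.heapify(queue)
        while queue:
            k = int(heapq.heappop(queue))
            if processed[k]:
                continue
            processed[k] = True
            l = int(links[k])
            prop = int(props[k])
            cur = bins[l]
            if prop == cur:
                continue
            dE = flat_energy[prop] - flat_energy[cur]
            if dE > 0 and unifs[k] >= np.exp(-dE / kT):
                continue
            if check_clash:
                phi, psi = bin_angles(prop)
                trial = chain.copy()
                set_linkage_inplace(trial, l, phi, psi)
                if has_clash(trial.coords, config.clash_cutoff):
                    log.clash_rejected += 1
                    continue
                chain = trial
            bins[l] = prop
            energy += dE
            log.accepted += 1
            for k2 in order[bounds[l]: bounds[l + 1]]:
                if k2 > k and not processed[k2]:
                    heapq.heappush(queue, int(k2))

    advance(config.burn_in)
    n_intervals = (config.n_sweeps - config.burn_in) // config.sample_every
    for _ in range(n_intervals):
        advance(config.sample_every)
        if not check_clash:
            chain = _chain_from_bins(fem, geometry, bins)
        frames.append(chain.coords.copy())
        idx_samples.append(np.column_stack([bins // n2, bins % n2]))
        e_tracked.append(energy)
        e_scratch.append(float(flat_energy[bins].sum()))

    return CgMcResult(
        frames=np.array(frames),
        bin_indices=np.array(idx_samples, dtype=np.int64),
        energies=np.array(e_tracked),
        energies_recomputed=np.array(e_scratch),
        log=log,
        fem=fem,
        geometry=geometry,
        config=config,
    )


def _chain_from_bins(fem, geometry, bins):
    n2 = fem.axis2.size
    dih = np.column_stack([fem.axis1[bins // n2], fem.axis2[bins % n2]])
    return build_chain(geometry, dih)


def autocorrelation(series, max_lag: int = None) -> np.ndarray:
    """Normalized autocovariance of a scalar time series; C(0) = 1.

    A constant series has no fluctuations to correlate; by convention it
    returns 1 at lag 0 and 0 elsewhere (with a warning).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    out = np.empty(max_lag + 1)
    if var == 0.0:
        logger.warning("constant series: autocorrelation defined as delta at lag 0")
        out[:] = 0.0
        out[0] = 1.0
        return out
    for t in range(max_lag + 1):
        out[t] = np.dot(x[: n - t], x[t:]) / ((n - t) * var)
    return out


def e2e_autocorrelation(result: CgMcResult, max_lag: int = None) -> np.ndarray:
    """Autocorrelation of the end-to-end distance along the MC trajectory.

    Lags are in sampling intervals (``sample_every`` sweeps each).
    Requires a reasonably long trajectory to be meaningful.
    """
    series = result.e2e_series()
    if series.size < 100:
        raise ValueError("need at least 100 samples for a stable autocorrelation")
    return autocorrelation(series, max_lag)
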