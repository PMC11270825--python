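"""2D free-energy maps over glycosidic dihedral pairs.

A :class:`FreeEnergyMap` holds relative free energies on a regular, periodic
grid over a pair of dihedral angles -- either the conventional glycosidic
torsions (phi, psi) or their backbone-only analogues (Phi, Psi) used by the
coarse-grained chain model.  Maps of this kind are the standard output of
enhanced-sampling molecular dynamics (e.g. metadynamics post-processed with
``sum_hills``-style tools) and are consumed here as *inputs*: this module
reads, validates, normalizes and interrogates them but never computes them
from trajectories.

Angles are degrees, energies kJ/mol.  Both axes are periodic with period
360 deg and are canonicalized internally to the half-open interval
[-180, 180).  Grid bins never visited by the sampling that produced the map
have undefined free energy; they are masked and treated as infinitely high
(inaccessible) everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import K_B

logger = logging.getLogger(__name__)

_STEP_TOL = 1e-6  # deg; tolerance on grid regularity


def wrap_angle(a):
    """Canonicalize angles (deg) to the half-open interval [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def circular_distance(a, b):
    """Smallest absolute separation (deg) between two angles on the circle."""
    return np.abs(wrap_angle(np.asarray(a, dtype=float) - b))


@dataclass
class FreeEnergyMap:
    """Regular periodic 2D grid of relative free energies.

    Parameters
    ----------
    axis1, axis2 : ndarray
        Sorted bin-center angles in degrees, each covering one full 360 deg
        period without a duplicated endpoint.
    energy : ndarray, shape (len(axis1), len(axis2))
        Free energies in kJ/mol.  Values at masked bins are ignored.
    mask : ndarray of bool, same shape
        True marks unsampled/undefined bins.
    axis_labels : (str, str)
        Names of the two dihedrals, e.g. ``("phi", "psi")``.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    energy: np.ndarray
    mask: np.ndarray = None
    axis_labels: tuple = ("phi", "psi")

    def __post_init__(self):
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.axis2 = np.asarray(self.axis2, dtype=float)
        self.energy = np.array(self.energy, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.energy)
        self.mask = np.array(self.mask, dtype=bool)
        if self.energy.shape != (self.axis1.size, self.axis2.size):
            raise ValueError("energy shape does not match axes")
        if self.mask.shape != self.energy.shape:
            raise ValueError("mask shape does not match energy")
        for ax in (self.axis1, self.axis2):
            _check_axis(ax)

    # -- basic geometry -------------------------------------------------
    @property
    def step1(self) -> float:
        return float(self.axis1[1] - self.axis1[0]) if self.axis1.size > 1 else 360.0

    @property
    def step2(self) -> float:
        return float(self.axis2[1] - self.axis2[0]) if self.axis2.size > 1 else 360.0

    @property
    def shape(self):
        return self.energy.shape

    @property
    def n_bins(self) -> int:
        return self.energy.size

    def unmasked_energies(self) -> np.ndarray:
        return self.energy[~self.mask]

    def is_normalized(self) -> bool:
        e = self.unmasked_energies()
        return e.size > 0 and abs(e.min()) == 0.0 and np.all(np.isfinite(e))

    def normalized(self) -> "FreeEnergyMap":
        """Return a copy with the global unmasked minimum shifted to zero."""
        e = self.unmasked_energies()
        if e.size == 0:
            raise ValueError("map has no unmasked bins")
        energy = self.energy.copy()
        energy[~self.mask] -= e.min()
        energy[self.mask] = np.inf
        return replace(self, energy=energy, mask=self.mask.copy())

    def nearest_bin(self, angle1: float, angle2: float):
        """Indices of the bin whose center is circularly nearest to a point."""
        i = int(np.argmin(circular_distance(self.axis1, angle1)))
        j = int(np.argmin(circular_distance(self.axis2, angle2)))
        return i, j

    def bin_angles(self, i: int, j: int):
        return float(self.axis1[i]), float(self.axis2[j])


def _check_axis(ax: np.ndarray) -> None:
    if ax.size == 0:
        raise ValueError("empty axis")
    if ax.size == 1:
        return
    steps = np.diff(ax)
    if np.any(np.abs(steps - steps[0]) > _STEP_TOL):
        raise ValueError("irregular grid: non-constant axis step")
    period = ax.size * steps[0]
    if abs(period - 360.0) > _STEP_TOL * ax.size:
        raise ValueError(
            "axis does not cover one full 360 deg period "
            f"(n={ax.size}, step={steps[0]:g})"
        )


@dataclass
class MinimumRecord:
    """A local minimum of a free-energy map.

    ``energy`` is relative to the global minimum (kJ/mol).  ``label``
    classifies the conformer: the global minimum is *exo-syn*; secondary
    minima sharing the psi (resp. phi) coordinate with it are *anti-phi*
    (resp. *anti-psi*); anything else is *other*.
    """

    angle1: float
    angle2: float
    energy: float
    label: str = "other"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fem(path, axis_labels=("phi", "psi")) -> FreeEnergyMap:
    """Read a plain-text free-energy grid (angle1 angle2 energy columns).

    The dialect is the one emitted by metadynamics post-processing tools:
    whitespace-separated columns, ``#`` comments, rows in arbitrary order,
    extra columns ignored.  Both [-180, 180) and [0, 360) axis conventions
    are accepted and canonicalized to [-180, 180).  Rows with a non-finite
    energy, and grid bins absent from the file, become masked bins.

    Returns a normalized map (global unmasked minimum at 0).
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 3:
        raise ValueError("FEM file needs at least 3 columns: angle1 angle2 energy")
    a1 = wrap_angle(data[:, 0])
    a2 = wrap_angle(data[:, 1])
    en = data[:, 2]

    axis1 = _infer_axis(a1)
    axis2 = _infer_axis(a2)
    step1 = axis1[1] - axis1[0] if axis1.size > 1 else 360.0
    step2 = axis2[1] - axis2[0] if axis2.size > 1 else 360.0

    energy = np.full((axis1.size, axis2.size), np.nan)
    i = np.rint((a1 - axis1[0]) / step1).astype(int)
    j = np.rint((a2 - axis2[0]) / step2).astype(int)
    if (np.abs(a1 - (axis1[0] + i * step1)) > _STEP_TOL).any() or (
        np.abs(a2 - (axis2[0] + j * step2)) > _STEP_TOL
    ).any():
        raise ValueError("incomplete grid: rows do not sit on a regular grid")
    for k in range(len(en)):
        prev = energy[i[k], j[k]]
        if np.isfinite(prev) and abs(prev - en[k]) > 1e-9:
            raise ValueError("incomplete grid: duplicate bin with conflicting energy")
        energy[i[k], j[k]] = en[k]

    mask = ~np.isfinite(energy)
    if mask.all():
        raise ValueError("incomplete grid: no finite energies")
    fem = FreeEnergyMap(axis1, axis2, energy, mask, tuple(axis_labels))
    return fem.normalized()


def _infer_axis(values: np.ndarray) -> np.ndarray:
    vals = np.unique(np.round(values / _STEP_TOL) * _STEP_TOL)
    if vals.size > 1:
        steps = np.diff(vals)
        if np.any(np.abs(steps - steps[0]) > 10 * _STEP_TOL):
            raise ValueError("irregular grid: uneven axis values")
    return vals


def write_fem(fem: FreeEnergyMap, path) -> None:
    """Write a map in the 3-column text dialect (axis1-major row order).

    Masked bins are written with energy ``inf`` so that a round trip
    preserves the mask.
    """
    with open(path, "w") as fh:
        fh.write(f"# {fem.axis_labels[0]} [deg]  {fem.axis_labels[1]} [deg]  free energy [kJ/mol]\n")
        for i, a in enumerate(fem.axis1):
            for j, b in enumerate(fem.axis2):
                e = np.inf if fem.mask[i, j] else fem.energy[i, j]
                fh.write(f"{a:.6f} {b:.6f} {e:.9g}\n")


# ---------------------------------------------------------------------------
# Minima and conformer classification
# ---------------------------------------------------------------------------

def find_minima(fem: FreeEnergyMap, energy_cap: float = 45.0,
                tie_eps: float = 1e-9):
    """Locate periodic local minima of a normalized map.

    A bin qualifies if it is unmasked, not higher than any of its eight
    periodic neighbours (within ``tie_eps`` kJ/mol; masked neighbours
    count as infinitely high) and strictly lower than at least one of
    them.  Neighbouring qualifying bins of equal energy -- e.g. a well
    center sitting exactly between two bin centers -- are merged into a
    single record.  Minima above ``energy_cap`` kJ/mol are dropped as
    noise.  Records are sorted by increasing energy; on a non-degenerate
    map the first has energy 0.  A perfectly flat map has no minima and
    yields an empty list.
    """
    if not fem.is_normalized():
        fem = fem.normalized()
    e = np.where(fem.mask, np.inf, fem.energy)
    if not np.isfinite(e).any():
        raise ValueError("map has no unmasked bins")
    not_higher = np.isfinite(e)
    lower_than_one = np.zeros_like(not_higher)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh = np.roll(e, (di, dj), axis=(0, 1))
            not_higher &= e <= neigh + tie_eps
            lower_than_one |= e < neigh - tie_eps
    cand = not_higher & lower_than_one
    n1, n2 = e.shape
    # merge neighbouring equal-energy candidates into one record each
    seen = np.zeros_like(cand)
    out = []
    for i, j in zip(*np.nonzero(cand)):
        if seen[i, j]:
            continue
        stack = [(i, j)]
        seen[i, j] = True
        comp = []
        while stack:
            ci, cj = stack.pop()
            comp.append((ci, cj))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = (ci + di) % n1, (cj + dj) % n2
                    if (cand[ni, nj] and not seen[ni, nj]
                            and abs(e[ni, nj] - e[ci, cj]) <= tie_eps):
                        seen[ni, nj] = True
                        stack.append((ni, nj))
        bi, bj = min(comp, key=lambda t: (e[t], t))
        if e[bi, bj] <= energy_cap:
            out.append(MinimumRecord(float(fem.axis1[bi]), float(fem.axis2[bj]),
                                     float(e[bi, bj])))
    out.sort(key=lambda r: r.energy)
    return out


def classify_conformers(minima, tol_deg: float = 45.0):
    """Assign exo-syn / anti-phi / anti-psi / other labels to map minima.

    The global minimum (first record, energy 0) is the exo-syn conformer.
    A secondary minimum keeping the main minimum's angle2 (psi-like
    coordinate, circular distance <= ``tol_deg``) while departing in angle1
    is anti-phi; the converse is anti-psi; a minimum matching neither (or
    both, resolved toward the smaller distance) falls back accordingly.
    Returns new records; the input list is not modified.
    """
    if not minima:
        return []
    main = minima[0]
    out = [replace(main, label="exo-syn")]
    for rec in minima[1:]:
        d1 = float(circular_distance(rec.angle1, main.angle1))
        d2 = float(circular_distance(rec.angle2, main.angle2))
        if d2 <= tol_deg and d1 > tol_deg:
            label = "anti-phi"
        elif d1 <= tol_deg and d2 > tol_deg:
            label = "anti-psi"
        elif d1 <= tol_deg and d2 <= tol_deg:
            # both coordinates near the main minimum: tie-break by which
            # coordinate is better conserved
            label = "anti-psi" if d1 < d2 else "anti-phi"
        else:
            label = "other"
        out.append(replace(rec, label=label))
    return out


def minima_report(minima) -> str:
    """Tab-separated conformer table (label, angle1, angle2, dE)."""
    lines = ["label\tangle1\tangle2\tdE_kJ_mol"]
    for r in minima:
        lines.append(f"{r.label}\t{r.angle1:.1f}\t{r.angle2:.1f}\t{r.energy:.1f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Scalar interrogation
# ---------------------------------------------------------------------------

def area_fraction_below(fem: FreeEnergyMap, threshold: float) -> float:
    """Fraction of the map area with free energy at or below a threshold.

    Masked (unsampled, hence inaccessible) bins count in the denominator
    but can never fall below the threshold; a negative threshold gives 0.
    Non-decreasing in the threshold by construction.
    """
    if threshold < 0:
        return 0.0
    ok = (~fem.mask) & (fem.energy <= threshold)
    return float(ok.sum()) / fem.n_bins


def boltzmann_weights(fem: FreeEnergyMap, temperature: float = 298.0) -> np.ndarray:
    """Equilibrium bin probabilities exp(-E/kT), zero on masked bins."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not fem.is_normalized():
        fem = fem.normalized()
    w = np.where(fem.mask, 0.0, np.exp(-np.where(fem.mask, 0.0, fem.energy) / (K_B * temperature)))
    return w / w.sum()


# ---------------------------------------------------------------------------
# Axis transformation (phi/psi -> Phi/Psi)
# ---------------------------------------------------------------------------

def fit_axis_shift(source, target, residual_warn_deg: float = 30.0) -> float:
    """Circular offset s minimizing the wrapped residuals of target-(source+s).

    Used to calibrate the backbone dihedral (Phi or Psi) against the
    conventional glycosidic torsion (phi or psi) from paired samples of
    both, under the model ``target = source + s`` on the circle (slope
    fixed at 1).  The mean squared wrapped residual is scanned on a coarse
    grid, refined on a 0.1 deg grid, and polished by iterating the
    circular mean of the wrapped residuals, which avoids the branch-cut
    artifacts of naive linear regression on angles.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.size < 10:
        raise ValueError("need at least 10 paired samples")
    diff = wrap_angle(target - source)

    def cost(s):
        return np.mean(wrap_angle(diff - s) ** 2)

    coarse = np.arange(-180.0, 180.0, 1.0)
    s = coarse[int(np.argmin([cost(c) for c in coarse]))]
    fine = s + np.arange(-1.0, 1.0, 0.1)
    s = fine[int(np.argmin([cost(c) for c in fine]))]
    for _ in range(20):
        delta = float(np.mean(wrap_angle(diff - s)))
        s = float(wrap_angle(s + delta))
        if abs(delta) < 1e-10:
            break
    spread = float(np.sqrt(cost(s)))
    if spread > residual_warn_deg:
        logger.warning(
            "axis-shift residual spread %.1f deg exceeds %.1f deg; "
            "a pure shift may not describe this dihedral pair",
            spread, residual_warn_deg,
        )
    return float(wrap_angle(s))


def transform_map(fem: FreeEnergyMap, shift1: float, shift2: float,
                  new_labels=None) -> FreeEnergyMap:
    """Apply per-axis circular shifts, e.g. map (phi, psi) onto (Phi, Psi).

    The transformed map satisfies E'(a1, a2) = E(a1 - shift1, a2 - shift2)
    with periodic wrap-around, so the energy multiset is preserved exactly.
    Shifts are rounded to the nearest multiple of the grid step (logged
    when rounding is material).
    """
    k1 = _roll_count(shift1, fem.step1, fem.axis1.size)
    k2 = _roll_count(shift2, fem.step2, fem.axis2.size)
    energy = np.roll(fem.energy, (k1, k2), axis=(0, 1))
    mask = np.roll(fem.mask, (k1, k2), axis=(0, 1))
    labels = tuple(new_labels) if new_labels is not None else fem.axis_labels
    return FreeEnergyMap(fem.axis1.copy(), fem.axis2.copy(), energy, mask, labels)


def _roll_count(shift: float, step: float, n: int) -> int:
    k = shift / step
    ki = int(np.rint(k))
    if abs(k - ki) > 1e-9:
        logger.info("shift %.4f deg rounded to %d grid steps of %.4f deg", shift, ki, step)
    return ki % n
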