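"""Synthetic inputs: Gaussian-basin free-energy maps, packaged conformer
energy tables, and reference polymer ensembles.

These generators let every other module be exercised without any
molecular-dynamics data: Gaussian-basin maps emulate the multi-minimum
structure of real glycosidic free-energy maps with analytically known well
locations and depths; the packaged conformer table supplies realistic
state-energy ladders for the 1D model; and the discrete worm-like-chain
generator produces bead chains with an exactly known target persistence
length lp = -b / ln<cos theta> for validating the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .fem import FreeEnergyMap, wrap_angle


@dataclass
class BasinSpec:
    """An isotropic Gaussian free-energy well.

    ``center`` in degrees, ``depth`` in kJ/mol below the plateau,
    ``width`` the Gaussian sigma in degrees.
    """

    center: tuple
    depth: float
    width: float

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")


def make_gaussian_fem(basins, grid_step: float = 2.0, plateau: float = 45.0,
                      axis_labels=("phi", "psi")) -> FreeEnergyMap:
    """Free-energy map with Gaussian wells on a flat plateau.

    E(x, y) = plateau - sum_k depth_k * exp(-d_k^2 / (2 width_k^2)) with
    d_k the toroidal distance to the k-th basin center, normalized so the
    global minimum is 0.  Basins overlapping enough to merge their minima
    are allowed; the map then has fewer strict minima than basins.
    """
    if not basins:
        raise ValueError("need at least one basin")
    if abs(360.0 / grid_step - round(360.0 / grid_step)) > 1e-9:
        raise ValueError("360 must be divisible by grid_step")
    for b in basins:
        if b.width <= grid_step:
            raise ValueError("basin width must exceed the grid step")
    axis = np.arange(-180.0, 180.0, grid_step)
    x = axis[:, None]
    y = axis[None, :]
    energy = np.full((axis.size, axis.size), float(plateau))
    for b in basins:
        dx = wrap_angle(x - b.center[0])
        dy = wrap_angle(y - b.center[1])
        energy -= b.depth * np.exp(-(dx ** 2 + dy ** 2) / (2.0 * b.width ** 2))
    fem = FreeEnergyMap(axis.copy(), axis.copy(), energy,
                        np.zeros_like(energy, dtype=bool), tuple(axis_labels))
    return fem.normalized()


def make_flat_fem(grid_step: float = 2.0, axis_labels=("phi", "psi")) -> FreeEnergyMap:
    """All-zero map: every (Phi, Psi) equally likely (freely rotating chain)."""
    axis = np.arange(-180.0, 180.0, grid_step)
    z = np.zeros((axis.size, axis.size))
    return FreeEnergyMap(axis.copy(), axis.copy(), z,
                         np.zeros_like(z, dtype=bool), tuple(axis_labels))


def make_discrete_wlc(n_bonds: int, b: float, mean_cos: float, seed: int,
                      n_chains: int = 1) -> np.ndarray:
    """Freely rotating bead chains with a fixed bend angle per bond.

    Successive bond directions keep cos(theta) = ``mean_cos`` with the
    azimuth uniform, so the bond autocorrelation is C(n) = mean_cos**n and
    the target persistence length is lp = -b / ln(mean_cos).  Returns
    positions of shape (n_chains, n_bonds + 1, 3); with ``n_chains=1`` the
    leading axis is kept for uniformity.
    """
    if not 0.0 < mean_cos < 1.0:
        raise ValueError("mean_cos must lie in (0, 1)")
    if n_bonds < 1:
        raise ValueError("need at least one bond")
    rng = np.random.default_rng(seed)
    cos_t = mean_cos
    sin_t = np.sqrt(1.0 - cos_t ** 2)

    dirs = np.zeros((n_chains, n_bonds, 3))
    dirs[:, 0] = (0.0, 0.0, 1.0)
    for k in range(1, n_bonds):
        prev = dirs[:, k - 1]
        # orthonormal frame around each previous direction
        ref = np.where(np.abs(prev[:, 2:3]) < 0.9,
                       np.tile((0.0, 0.0, 1.0), (n_chains, 1)),
                       np.tile((1.0, 0.0, 0.0), (n_chains, 1)))
        e1 = np.cross(prev, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(prev, e1)
        az = rng.uniform(0.0, 2.0 * np.pi, size=n_chains)
        dirs[:, k] = (cos_t * prev
                      + sin_t * (np.cos(az)[:, None] * e1 + np.sin(az)[:, None] * e2))
    pos = np.zeros((n_chains, n_bonds + 1, 3))
    pos[:, 1:] = np.cumsum(b * dirs, axis=1)
    return pos


# ---------------------------------------------------------------------------
# Packaged conformer energy table
# ---------------------------------------------------------------------------

@dataclass
class ConformerMinimum:
    label: str
    angle1: float
    angle2: float
    energy: float
    is_minimum: bool = True


@dataclass
class ConformerFixture:
    """Conformer ladder of one force field / linkage combination."""

    force_field: str
    linkage: str
    minima: list

    def state_energies(self, true_minima_only: bool = True):
        """Relative state energies (kJ/mol) for the 1D chain model.

        ``true_minima_only`` drops anti entries that are not genuine local
        minima of the underlying map (the GROMOS anti-phi entries), which
        reduces those systems to two states.
        """
        out = [m.energy for m in self.minima
               if m.is_minimum or not true_minima_only]
        return sorted(out)[:1] + [m.energy for m in self.minima
                                  if (m.is_minimum or not true_minima_only)
                                  and m.energy > 0.0]


def table1_fixture():
    """All packaged force-field x linkage conformer entries."""
    text = resources.files("glycanmc.data").joinpath("conformers.tsv").read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("force_field"):
            continue
        ff, link, label, phi, psi, de, ismin = line.split("\t")
        rows.append((ff, link, ConformerMinimum(
            label, float(phi), float(psi), float(de), ismin == "1")))
    fixtures = {}
    for ff, link, rec in rows:
        fixtures.setdefault((ff, link), ConformerFixture(ff, link, [])).minima.append(rec)
    for fx in fixtures.values():
        ground = [m for m in fx.minima if m.energy == 0.0]
        if len(ground) != 1 or ground[0].label != "exo-syn":
            raise ValueError(f"bad fixture entry {fx.force_field}/{fx.linkage}")
    return list(fixtures.values())


def get_fixture(force_field: str, linkage: str) -> ConformerFixture:
    for fx in table1_fixture():
        if fx.force_field == force_field and fx.linkage == linkage:
            return fx
    raise KeyError(f"no fixture for {force_field}/{linkage}")


def fixture_fem(force_field: str, linkage: str, grid_step: float = 2.0,
                width: float = 18.0, plateau: float = 45.0) -> FreeEnergyMap:
    """Gaussian-basin map whose wells mirror a packaged conformer entry.

    Well depths are chosen so the basin minima sit at the tabulated
    relative energies below a common plateau; entries flagged as
    not-a-minimum are skipped.  A test scaffold, not a force-field
    surrogate.
    """
    fx = get_fixture(force_field, linkage)
    basins = [BasinSpec((m.angle1, m.angle2), plateau - m.energy, width)
              for m in fx.minima if m.is_minimum]
    return make_gaussian_fem(basins, grid_step=grid_step, plateau=plateau)
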