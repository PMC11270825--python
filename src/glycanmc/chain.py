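"""Cartesian backbone of the coarse-grained polysaccharide chain.

Each monosaccharide contributes three backbone atoms -- the linkage carbon
C_n, the anomeric carbon C_1 and the glycosidic oxygen O -- giving the
repeating motif -C_n-C_1-O- along the chain.  All bond lengths, bond
angles and the through-ring dihedral O-C_n-C_1-O are fixed at their
MD-averaged values (:class:`LinkageGeometry`); the only degrees of freedom
are the two backbone dihedrals per linkage,

    Phi = C_n-C_1-O-C_n      (about the C_1-O bond)
    Psi = C_1-O-C_n-C_1      (about the O-C_n bond),

the backbone-only analogues of the usual glycosidic torsions phi/psi.
Chains are built atom by atom with the standard internal-coordinate (NeRF)
construction; edits rotate the downstream part of the chain rigidly about
the relevant bond.  Distances are nm, angles degrees, torsion sign follows
the IUPAC convention (positive clockwise looking from atom 2 to atom 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .fem import wrap_angle


@dataclass
class LinkageGeometry:
    """Fixed internal coordinates of the 3-atoms-per-residue backbone.

    Defaults are placeholders in the physically sensible range for
    pyranose backbones; production use should supply per-force-field,
    per-linkage averages from unbiased MD of the target system.
    """

    d_CnC1: float = 0.290  # nm, virtual through-ring distance
    d_C1O: float = 0.141   # nm
    d_OCn: float = 0.143   # nm
    a_CnC1O: float = 116.0  # deg
    a_C1OCn: float = 117.0  # deg
    a_OCnC1: float = 111.0  # deg
    ring_dihedral: float = 60.0  # deg, O-C_n-C_1-O, fixed during MC

    def __post_init__(self):
        for name in ("d_CnC1", "d_C1O", "d_OCn"):
            d = getattr(self, name)
            if not 0.05 < d < 0.5:
                raise ValueError(f"{name}={d} nm outside (0.05, 0.5)")
        for name in ("a_CnC1O", "a_C1OCn", "a_OCnC1"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"{name}={a} deg outside (0, 180)")
        self.ring_dihedral = float(wrap_angle(self.ring_dihedral))

    @classmethod
    def from_dict(cls, d: dict) -> "LinkageGeometry":
        known = {k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    # internal-coordinate tables for atom k (k >= 3), cycling Cn, C1, O
    def _bond(self, k: int) -> float:
        return (self.d_OCn, self.d_CnC1, self.d_C1O)[k % 3]

    def _angle(self, k: int) -> float:
        return (self.a_C1OCn, self.a_OCnC1, self.a_CnC1O)[k % 3]


ATOM_NAMES = ("Cn", "C1", "O")


def measure_dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed torsion angle (deg) of four points."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))


def _place_atom(p0, p1, p2, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement of the next atom from the previous three."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = p2 - p1
    bc /= np.linalg.norm(bc)
    ab = p1 - p0
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("colinear atom triple: torsion frame undefined")
    n /= nn
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(tau),
        -bond * np.sin(theta) * np.sin(tau),
    ])
    return p2 + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class ChainState:
    """Cartesian backbone coordinates plus the (Phi, Psi) list per linkage."""

    coords: np.ndarray          # (3*n_residues, 3) nm
    dihedrals: np.ndarray       # (n_residues - 1, 2) deg
    geometry: LinkageGeometry

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.n_atoms // 3

    @property
    def n_linkages(self) -> int:
        return self.n_residues - 1

    def copy(self) -> "ChainState":
        return ChainState(self.coords.copy(), self.dihedrals.copy(), self.geometry)

    def oxygen_positions(self) -> np.ndarray:
        """Coordinates of the glycosidic O atoms (one per residue)."""
        return self.coords[2::3]

    def measured_dihedrals(self) -> np.ndarray:
        """(Phi, Psi) per linkage recomputed from the coordinates."""
        c = self.coords
        out = np.empty((self.n_linkages, 2))
        for l in range(self.n_linkages):
            a = 3 * l
            out[l, 0] = measure_dihedral(c[a], c[a + 1], c[a + 2], c[a + 3])
            out[l, 1] = measure_dihedral(c[a + 1], c[a + 2], c[a + 3], c[a + 4])
        return out

    def contour_length(self) -> float:
        """Sum of backbone link lengths (nm); invariant under dihedral edits."""
        return float(np.linalg.norm(np.diff(self.coords, axis=0), axis=1).sum())


def build_chain(geometry: LinkageGeometry, dihedrals) -> ChainState:
    """Build the backbone from internal coordinates and per-linkage (Phi, Psi).

    The first three atoms are placed canonically (origin, +x axis,
    xy-plane); every further atom follows from the previous three via its
    fixed bond length and angle and the appropriate torsion -- Phi, Psi or
    the fixed ring dihedral, cycling with the Cn/C1/O atom pattern.
    """
    dihedrals = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    if dihedrals.size == 0:
        dihedrals = dihedrals.reshape(0, 2)
    if dihedrals.shape[1] != 2:
        raise ValueError("dihedrals must be pairs (Phi, Psi)")
    n_res = dihedrals.shape[0] + 1
    coords = np.zeros((3 * n_res, 3))
    g = geometry
    coords[1] = (g.d_CnC1, 0.0, 0.0)
    th = np.radians(g.a_CnC1O)
    coords[2] = coords[1] + g.d_C1O * np.array([-np.cos(th), np.sin(th), 0.0])
    for k in range(3, 3 * n_res):
        linkage = (k - 3) // 3
        which = k % 3
        if which == 0:
            tau = dihedrals[linkage, 0]        # Phi about C1-O
        elif which == 1:
            tau = dihedrals[linkage, 1]        # Psi about O-Cn
        else:
            tau = g.ring_dihedral              # fixed O-Cn-C1-O
        coords[k] = _place_atom(coords[k - 3], coords[k - 2], coords[k - 1],
                                g._bond(k), g._angle(k), tau)
    return ChainState(coords, wrap_angle(dihedrals), geometry)


def _rotate_about_bond(coords: np.ndarray, i_from: int, axis_a: int, axis_b: int,
                       delta_deg: float) -> None:
    """Rotate atoms [i_from:] about the axis_a->axis_b bond, in place.

    The sign is chosen so the torsion defined about that bond *increases*
    by ``delta_deg`` (IUPAC convention).
    """
    axis = coords[axis_b] - coords[axis_a]
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(-np.radians(delta_deg) * axis)
    pivot = coords[axis_b]
    coords[i_from:] = rot.apply(coords[i_from:] - pivot) + pivot


def set_linkage(chain: ChainState, linkage_index: int, new_phi: float,
                new_psi: float) -> ChainState:
    """Return a copy of the chain with one linkage's (Phi, Psi) replaced.

    Atoms downstream of the linkage are rotated rigidly about the C1-O and
    O-Cn bonds; upstream atoms and every other internal coordinate are
    untouched.
    """
    if not 0 <= linkage_index < chain.n_linkages:
        raise IndexError(f"linkage index {linkage_index} out of range")
    out = chain.copy()
    set_linkage_inplace(out, linkage_index, new_phi, new_psi)
    return out


def set_linkage_inplace(chain: ChainState, linkage_index: int, new_phi: float,
                        new_psi: float) -> None:
    """In-place variant of :func:`set_linkage` (used by the MC inner loop)."""
    l = linkage_index
    a = 3 * l
    cur_phi, cur_psi = chain.dihedrals[l]
    dphi = float(wrap_angle(new_phi - cur_phi))
    dpsi = float(wrap_angle(new_psi - cur_psi))
    if dphi != 0.0:
        _rotate_about_bond(chain.coords, a + 3, a + 1, a + 2, dphi)
    if dpsi != 0.0:
        _rotate_about_bond(chain.coords, a + 4, a + 2, a + 3, dpsi)
    chain.dihedrals[l, 0] = wrap_angle(new_phi)
    chain.dihedrals[l, 1] = wrap_angle(new_psi)


def min_nonneighbor_distance(chain_or_coords, exclusion_window: int = 3,
                             method: str = "brute") -> float:
    """Smallest distance between atoms more than ``exclusion_window`` apart.

    Pairs separated by at most ``exclusion_window`` positions along the
    backbone are exempt: their distances are fixed (or nearly fixed) by
    construction.  ``method="brute"`` scans all pairs; ``method="kdtree"``
    uses a spatial tree and gives identical results.
    """
    coords = getattr(chain_or_coords, "coords", chain_or_coords)
    n = coords.shape[0]
    if n - 1 <= exclusion_window:
        return float("inf")
    if method == "brute":
        i, j = np.triu_indices(n, k=exclusion_window + 1)
        return float(np.linalg.norm(coords[i] - coords[j], axis=1).min())
    if method == "kdtree":
        tree = cKDTree(coords)
        # expand the query radius until a non-neighbor pair is inside it
        r = 2.0 * float(np.linalg.norm(np.diff(coords, axis=0), axis=1).max()) * (
            exclusion_window + 1)
        while True:
            pairs = tree.query_pairs(r, output_type="ndarray")
            sep = np.abs(pairs[:, 0] - pairs[:, 1])
            keep = pairs[sep > exclusion_window]
            if keep.size:
                return float(np.linalg.norm(
                    coords[keep[:, 0]] - coords[keep[:, 1]], axis=1).min())
            r *= 2.0
    raise ValueError(f"unknown method {method!r}")


def has_clash(coords: np.ndarray, cutoff: float, exclusion_window: int = 3) -> bool:
    """True if any non-neighbor atom pair is closer than ``cutoff`` nm."""
    if cutoff <= 0:
        return False
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return False
    return bool((np.abs(pairs[:, 0] - pairs[:, 1]) > exclusion_window).any())
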