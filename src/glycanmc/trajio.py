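"""Snapshot and trajectory I/O for coarse-grained backbones.

XYZ (multi-frame) and minimal PDB (HETATM records, one chain, residues
numbered by monosaccharide) backed by MDAnalysis.  Package-internal
coordinates are nm; files are written in angstrom as both formats expect.
"""

from __future__ import annotations

import warnings

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .chain import ATOM_NAMES

_NM_TO_A = 10.0


def _make_universe(n_atoms: int) -> mda.Universe:
    n_res = n_atoms // 3
    u = mda.Universe.empty(n_atoms, n_residues=n_res,
                           atom_resindex=np.repeat(np.arange(n_res), 3),
                           trajectory=True)
    u.add_TopologyAttr("names", list(ATOM_NAMES) * n_res)
    u.add_TopologyAttr("elements", ["C", "C", "O"] * n_res)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("resnames", ["GLC"] * n_res)
    u.add_TopologyAttr("record_types", ["HETATM"] * n_atoms)
    return u


def write_xyz(frames, path) -> None:
    """Write one or more coordinate frames (nm) as a multi-frame XYZ file."""
    frames = _as_frames(frames)
    u = _make_universe(frames[0].shape[0])
    with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
        for f in frames:
            u.atoms.positions = np.asarray(f) * _NM_TO_A
            w.write(u.atoms)


def read_xyz(path):
    """Read a multi-frame XYZ file; returns a list of (n_atoms, 3) nm arrays."""
    u = mda.Universe(str(path), format="XYZ")
    return [u.atoms.positions.copy() / _NM_TO_A for _ in u.trajectory]


def write_pdb(coords, path) -> None:
    """Write a single snapshot (nm) as a minimal HETATM-only PDB."""
    coords = np.asarray(coords)
    u = _make_universe(coords.shape[0])
    u.atoms.positions = coords * _NM_TO_A
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_pdb(path) -> np.ndarray:
    """Read a snapshot written by :func:`write_pdb`; returns nm coordinates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return u.atoms.positions.copy() / _NM_TO_A


def _as_frames(frames):
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr
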