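"""Periodic-boundary-aware condensation metrics: Dmax, Rg, RMSF.

All distances honour the minimum-image convention in an orthorhombic box.
Dmax is the maximum side length of the axis-aligned bounding box of all
protein atoms; to remove wrap artifacts the measurement is repeated once per
chain, each time re-centering the box on that chain, and the smallest
candidate is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Frame, Topology, Trajectory


# ---------------------------------------------------------------------------
# minimum image primitives
# ---------------------------------------------------------------------------


def minimum_image_displacement(d, box) -> np.ndarray:
    """Minimum-image displacement vector(s) for an orthorhombic box."""
    d = np.asarray(d, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64)
    return d - box * np.round(d / box)


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Euclidean distance between ``a`` and ``b`` under minimum image.

    ``a`` and ``b`` may be single points or broadcastable arrays of points.
    """
    d = minimum_image_displacement(np.asarray(a, float) - np.asarray(b, float), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_min_image_distances(xa: np.ndarray, xb: np.ndarray, box) -> np.ndarray:
    """(len(xa), len(xb)) matrix of minimum-image distances."""
    d = xa[:, None, :] - xb[None, :, :]
    d = minimum_image_displacement(d, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# molecule units and re-centering
# ---------------------------------------------------------------------------


def _molecule_units(topology: Topology) -> list[np.ndarray]:
    """Atom-index groups that move as rigid units when wrapping compounds."""
    units = [topology.chain_atoms(c) for c in range(topology.n_chains)]
    units += [np.array([i]) for _, i in topology.ions]
    units += [row for row in topology.waters]
    return units


def _unwrap_sequential(coords: np.ndarray, box) -> np.ndarray:
    """Make a bonded unit contiguous by cumulative minimum-image steps.

    Atom order follows the chain, so consecutive atoms are near-neighbours;
    each atom is placed at the image closest to its predecessor.
    """
    steps = minimum_image_displacement(np.diff(coords, axis=0), box)
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(steps, axis=0)
    return out


def center_on_chain(frame: Frame, topology: Topology, chain_id: int) -> Frame:
    """Re-center the box on one chain, wrapping everything else by compound.

    The chosen chain is made contiguous and its centroid moved to the box
    center; every other molecule unit (chain, ion, water) is made contiguous
    and translated by whole box vectors so its centroid falls in the central
    box. The chosen chain's connectivity is never split.
    """
    if not 0 <= chain_id < topology.n_chains:
        raise ValueError(f"unknown chain id {chain_id}")
    box = frame.box
    center = box / 2.0
    out = frame.coords.copy()

    ref_atoms = topology.chain_atoms(chain_id)
    ref = _unwrap_sequential(frame.coords[ref_atoms], box)
    shift = center - ref.mean(axis=0)

    for unit in _molecule_units(topology):
        contig = (_unwrap_sequential(frame.coords[unit], box)
                  if len(unit) > 1 else frame.coords[unit])
        contig = contig + shift
        delta = contig.mean(axis=0) - center
        out[unit] = contig - box * np.round(delta / box)
    return Frame(out, box.copy())


# ---------------------------------------------------------------------------
# Dmax
# ---------------------------------------------------------------------------


@dataclass
class DmaxResult:
    value: float
    centering_chain: int
    per_centering_values: np.ndarray


def compute_dmax(frame: Frame, topology: Topology) -> DmaxResult:
    """Smallest over per-chain centerings of the largest box-aligned extent
    of all protein atoms (ions and waters excluded)."""
    protein = topology.is_protein
    if not protein.any():
        raise ValueError("no protein atoms in topology")
    candidates = np.empty(topology.n_chains)
    for c in range(topology.n_chains):
        centered = center_on_chain(frame, topology, c)
        coords = centered.coords[protein]
        candidates[c] = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
    best = int(np.argmin(candidates))
    return DmaxResult(float(candidates[best]), best, candidates)


def dmax_series(trajectory: Trajectory) -> np.ndarray:
    return np.array([compute_dmax(f, trajectory.topology).value
                     for f in trajectory.frames])


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------


def _require_contiguous(coords: np.ndarray, box) -> None:
    raw = np.sqrt(np.sum(np.diff(coords, axis=0) ** 2, axis=-1))
    mic = np.sqrt(np.sum(minimum_image_displacement(
        np.diff(coords, axis=0), box) ** 2, axis=-1))
    if np.any(raw - mic > 1e-6):
        raise ValueError("chain is split across the periodic boundary; "
                         "center_on_chain first")


def compute_rg(frame: Frame, topology: Topology, chain_id: int,
               mass_weighted: bool = True) -> float:
    """Radius of gyration of one chain, in Angstrom (mass-weighted default)."""
    atoms = topology.chain_atoms(chain_id)
    if len(atoms) < 2:
        raise ValueError("chain needs at least two atoms")
    coords = frame.coords[atoms]
    _require_contiguous(coords, frame.box)
    w = topology.masses()[atoms] if mass_weighted else np.ones(len(atoms))
    com = np.average(coords, axis=0, weights=w)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def rg_series(trajectory: Trajectory, mass_weighted: bool = True) -> np.ndarray:
    """(n_frames, n_chains) Rg values; each chain centered before measuring."""
    top = trajectory.topology
    out = np.empty((trajectory.n_frames, top.n_chains))
    for i, frame in enumerate(trajectory.frames):
        for c in range(top.n_chains):
            centered = center_on_chain(frame, top, c)
            out[i, c] = compute_rg(centered, top, c, mass_weighted)
    return out


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


@dataclass
class RmsfProfile:
    per_residue: np.ndarray       # averaged over chains
    per_chain: np.ndarray         # (n_chains, n_residues_per_chain)
    atom_name: str = "CA"


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing RMSD of centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def compute_rmsf(trajectory: Trajectory, chains=None,
                 fit_role: str = "backbone", probe_atom: str = "CA",
                 n_rounds: int = 2) -> RmsfProfile:
    """Per-residue RMSF averaged over chains.

    Each chain is unwrapped per frame, superposed rigid-body (least squares
    on backbone heavy atoms) onto its time-average structure — the average
    is refined over ``n_rounds`` of superposition — and the RMSF is taken
    from the probe atom (C-alpha) deviations.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    top = trajectory.topology
    chains = range(top.n_chains) if chains is None else chains
    profiles = []
    for c in chains:
        atoms = top.chain_atoms(c)
        names = [top.atom_name[i] for i in atoms]
        if fit_role == "backbone":
            fit_mask = np.array([n in ("N", "CA", "C", "O") for n in names])
        else:
            fit_mask = np.ones(len(atoms), dtype=bool)
        probe_mask = np.array([n == probe_atom for n in names])
        X = np.stack([_unwrap_sequential(f.coords[atoms], f.box)
                      for f in trajectory.frames])
        X -= X[:, fit_mask].mean(axis=1, keepdims=True)
        mean = X.mean(axis=0)
        for _ in range(n_rounds):
            for t in range(len(X)):
                R = _kabsch(X[t, fit_mask], mean[fit_mask])
                X[t] = X[t] @ R.T
            mean = X.mean(axis=0)
        dev = X[:, probe_mask] - mean[probe_mask]
        profiles.append(np.sqrt(np.mean(np.sum(dev ** 2, axis=-1), axis=0)))
    per_chain = np.stack(profiles)
    return RmsfProfile(per_chain.mean(axis=0), per_chain, probe_atom)
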