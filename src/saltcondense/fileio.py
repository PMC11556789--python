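"""Structure and trajectory readers/writers.

Canonical in-memory objects are :class:`~saltcondense.model.Topology` /
:class:`~saltcondense.model.Trajectory`; this module adapts them to disk
formats.  PDB goes through biotite (CRYST1 carries the box), DCD through
MDAnalysis, and the multi-frame XYZ flavour used here — a standard XYZ file
whose comment line carries ``box Lx Ly Lz`` — is parsed directly since the
box extension is nonstandard.  Internal residue numbering is 0-based;
PDB files use 1-based numbering per chain.

A periodic box is mandatory on input: files without one are rejected, and
triclinic boxes are rejected rather than silently wrapped.
"""

from __future__ import annotations

import string

import numpy as np

from .model import (BACKBONE_ATOMS, ION_SPECIES, SIDECHAIN_HEAVY, Frame,
                    Residue, ROLE_NAMES, RING_CARBONS, SIDECHAIN_N,
                    SIDECHAIN_O, Topology, Trajectory, normalize_species,
                    residue_charge)

_WATER_RES_NAMES = {"HOH", "WAT", "TIP3", "TIP4", "SOL"}
_ION_RES_NAMES = {"CL", "CLA", "NA", "SOD"}
_CHAIN_LETTERS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _check_orthorhombic(box_matrix: np.ndarray) -> np.ndarray:
    if box_matrix is None:
        raise ValueError("input has no periodic box (CRYST1 / box comment "
                         "line required)")
    m = np.asarray(box_matrix, dtype=float)
    off = m - np.diag(np.diag(m))
    if np.any(np.abs(off) > 1e-3):
        raise ValueError("triclinic box not supported; orthorhombic only")
    box = np.diag(m)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    return box


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def write_pdb(path, topology: Topology, frame: Frame) -> None:
    """Write topology + one frame as PDB with a CRYST1 box record."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame.coords, dtype=np.float32)
    chain_ids = np.empty(n, dtype="U4")
    res_ids = np.empty(n, dtype=int)
    res_names = np.empty(n, dtype="U5")
    hetero = np.zeros(n, dtype=bool)
    for i in range(n):
        r = topology.atom_residue[i]
        c = topology.atom_chain[i]
        if c >= 0:
            chain_ids[i] = _CHAIN_LETTERS[c % len(_CHAIN_LETTERS)]
            res_ids[i] = topology.residues[r].local_index + 1
            res_names[i] = topology.residues[r].res_type
        else:
            hetero[i] = True
    for k, (species, idx) in enumerate(topology.ions):
        chain_ids[idx] = "i"
        res_ids[idx] = k + 1
        res_names[idx] = species
    for k, row in enumerate(topology.waters):
        for idx in row:
            chain_ids[idx] = "w"
            res_ids[idx] = k + 1
            res_names[idx] = "HOH"
    arr.chain_id = chain_ids
    arr.res_id = res_ids
    arr.res_name = res_names
    arr.atom_name = np.array(topology.atom_name, dtype="U6")
    arr.element = np.array([e.upper() for e in topology.element], dtype="U2")
    arr.hetero = hetero
    arr.box = np.diag(frame.box)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _topology_from_records(chain_id, res_id, res_name, atom_name, element):
    """Rebuild a Topology from per-atom PDB-style records (file order)."""
    top = Topology()
    roles = {r: [] for r in ROLE_NAMES}
    residues_idx, chains_idx = [], []

    current_chain_key = None
    current_res_key = None
    chain_counter = -1
    res_counter = -1
    water_atoms: dict = {}
    for i in range(len(atom_name)):
        rname = res_name[i].upper()
        aname = atom_name[i].upper()
        elem = element[i].capitalize() if element[i] else aname[0]
        atom_roles = set()
        if rname in _WATER_RES_NAMES:
            water_atoms.setdefault((chain_id[i], res_id[i]), []).append(i)
            r_idx, c_idx = -1, -1
        elif rname in _ION_RES_NAMES:
            species = normalize_species(rname)
            top.ions.append((species, i))
            elem = ION_SPECIES[species][0]
            r_idx, c_idx = -1, -1
        elif rname in SIDECHAIN_HEAVY:
            if (chain_id[i],) != current_chain_key:
                current_chain_key = (chain_id[i],)
                chain_counter += 1
                top.chain_residues.append([])
                top.protein_charge_per_chain.append(0)
                current_res_key = None
            if (chain_id[i], res_id[i]) != current_res_key:
                current_res_key = (chain_id[i], res_id[i])
                res_counter += 1
                local = len(top.chain_residues[chain_counter])
                top.residues.append(Residue(res_counter, rname,
                                            chain_counter, local))
                top.chain_residues[chain_counter].append(res_counter)
                top.protein_charge_per_chain[chain_counter] += \
                    residue_charge(rname)
            allowed = set(BACKBONE_ATOMS) | set(SIDECHAIN_HEAVY[rname]) | {"OXT"}
            if elem != "H" and aname not in allowed:
                raise ValueError(f"atom {aname!r} inconsistent with residue "
                                 f"type {rname!r} (atom record {i + 1})")
            if elem != "H":
                atom_roles.add("heavy")
                if aname == "N":
                    atom_roles.add("backbone_N")
                elif aname == "O":
                    atom_roles.add("backbone_O")
                if aname in SIDECHAIN_N.get(rname, ()):
                    atom_roles.add("sidechain_N")
                if aname in SIDECHAIN_O.get(rname, ()):
                    atom_roles.add("sidechain_O")
                if aname in RING_CARBONS.get(rname, ()):
                    atom_roles.add("ring_carbon")
            r_idx, c_idx = res_counter, chain_counter
        else:
            raise ValueError(f"unknown residue type {rname!r} "
                             f"(atom record {i + 1})")
        top.atom_name.append(aname)
        top.element.append(elem)
        residues_idx.append(r_idx)
        chains_idx.append(c_idx)
        for role in ROLE_NAMES:
            roles[role].append(role in atom_roles)

    rows = []
    for key, atoms in water_atoms.items():
        if len(atoms) != 3:
            raise ValueError(f"water {key} does not have 3 atoms")
        rows.append(atoms)
    if rows:
        top.waters = np.array(rows, dtype=np.int64)
    top.atom_residue = np.array(residues_idx, dtype=np.int64)
    top.atom_chain = np.array(chains_idx, dtype=np.int64)
    top.chain_residues = [np.array(c, dtype=np.int64)
                          for c in top.chain_residues]
    top.roles = {r: np.array(v, dtype=bool) for r, v in roles.items()}
    top.validate()
    return top


def read_pdb(path):
    """Read a PDB file -> (Topology, Trajectory).

    Multi-MODEL files become multi-frame trajectories.  A CRYST1 record is
    required; triclinic cells are rejected.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if stack.box is None:
        raise ValueError(f"{path}: no CRYST1 record; a periodic box is required")
    top = _topology_from_records(stack.chain_id, stack.res_id,
                                 stack.res_name, stack.atom_name,
                                 stack.element)
    frames = []
    for m in range(stack.stack_depth()):
        box = _check_orthorhombic(stack.box[m])
        frames.append(Frame(np.asarray(stack.coord[m], dtype=np.float64), box))
    return top, Trajectory(top, frames)


# ---------------------------------------------------------------------------
# XYZ with box comment line
# ---------------------------------------------------------------------------


def write_xyz(path, trajectory: Trajectory) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{top.n_atoms}\n")
            fh.write("box {:.6f} {:.6f} {:.6f}\n".format(*frame.box))
            for name, xyz in zip(top.atom_name, frame.coords):
                fh.write(f"{name:<6s} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                         f"{xyz[2]:12.6f}\n")


def read_xyz(path, topology: Topology) -> Trajectory:
    """Read a multi-frame XYZ file whose comment line is 'box Lx Ly Lz'."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected atom count")
        comment = lines[i + 1].split()
        if len(comment) < 4 or comment[0].lower() != "box":
            raise ValueError(f"{path}:{i + 2}: comment line must be "
                             "'box Lx Ly Lz' (periodic box required)")
        box = np.array([float(v) for v in comment[1:4]])
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + k}: malformed atom line")
            coords[k] = [float(v) for v in parts[1:4]]
        frames.append(Frame(coords, box))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty trajectory")
    if len(frames[0].coords) != topology.n_atoms:
        raise ValueError("frame atom count does not match topology")
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# DCD
# ---------------------------------------------------------------------------


def read_dcd(path, topology: Topology, top_pdb_path) -> Trajectory:
    """Read a DCD-style binary trajectory against a PDB topology file."""
    import MDAnalysis as mda

    u = mda.Universe(str(top_pdb_path), str(path))
    frames = []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise ValueError("DCD frame lacks box dimensions")
        if np.any(np.abs(dims[3:6] - 90.0) > 1e-3):
            raise ValueError("triclinic box not supported; orthorhombic only")
        frames.append(Frame(np.asarray(ts.positions, dtype=np.float64),
                            dims[:3].astype(np.float64)))
    if len(frames[0].coords) != topology.n_atoms:
        raise ValueError("DCD atom count does not match topology")
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def read_structure(path, topology: Topology | None = None,
                   top_path=None):
    """Read a structure/trajectory file -> (Topology, Trajectory).

    PDB files are self-contained; XYZ and DCD need a topology (object or a
    PDB path).
    """
    p = str(path)
    if p.lower().endswith(".pdb"):
        return read_pdb(p)
    if topology is None:
        if top_path is None:
            raise ValueError("XYZ/DCD input needs a topology (top_path)")
        topology, _ = read_pdb(top_path)
    if p.lower().endswith(".xyz"):
        return topology, read_xyz(p, topology)
    if p.lower().endswith(".dcd"):
        if top_path is None:
            raise ValueError("DCD input needs a PDB topology file path")
        return topology, read_dcd(p, topology, top_path)
    raise ValueError(f"unrecognized trajectory format: {p}")


def read_fasta(path) -> dict[str, str]:
    """Name -> sequence mapping from a FASTA file (via Biopython)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out
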