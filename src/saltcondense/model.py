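"""Core domain model: atoms, residues, topologies, frames and trajectories.

The package analyses multi-chain systems of intrinsically disordered protein
(IDP) chains solvated with explicit Na+/Cl- ions and water in an orthorhombic
periodic box.  This module holds the shared, format-agnostic containers and
the residue chemistry tables (which atoms are sidechain nitrogens, sidechain
oxygens, aromatic ring carbons, ...) that every downstream stage relies on.

Coordinates are in Angstrom throughout; charges in elementary-charge units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

AVOGADRO = 6.02214076e23

# ---------------------------------------------------------------------------
# residue chemistry
# ---------------------------------------------------------------------------

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: heavy sidechain atoms by residue type, standard PDB naming
SIDECHAIN_HEAVY = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    # phospho-tyrosine: tyrosine sidechain plus phosphate on OH
    "PTR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH",
            "P", "O1P", "O2P", "O3P"),
}

SIDECHAIN_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

SIDECHAIN_O = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "PTR": ("OH", "O1P", "O2P", "O3P"),
}

#: six-carbon aromatic ring; assigned only on Tyr and Phe (phospho-Tyr is
#: treated as de-aromatized, Trp's fused ring is deliberately excluded)
RING_CARBONS = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

#: per-residue formal charge at neutral pH (His neutral unless protonated)
RESIDUE_CHARGE = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1, "PTR": -2}

ATOM_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "S": 32.06, "P": 30.974, "Cl": 35.45, "Na": 22.990}

ION_SPECIES = {"CL": ("Cl", -1), "NA": ("Na", +1)}

_SPECIES_ALIASES = {
    "CL": "CL", "CL-": "CL", "CLA": "CL", "Cl": "CL", "Cl-": "CL",
    "NA": "NA", "NA+": "NA", "SOD": "NA", "Na": "NA", "Na+": "NA",
}


def normalize_species(species: str) -> str:
    """Map common ion naming variants onto the canonical 'CL' / 'NA'."""
    key = _SPECIES_ALIASES.get(species) or _SPECIES_ALIASES.get(species.upper())
    if key is None:
        raise ValueError(f"unknown ion species: {species!r}")
    return key


def residue_charge(res_type: str, protonate_his: bool = False) -> int:
    if protonate_his and res_type == "HIS":
        return 1
    return RESIDUE_CHARGE.get(res_type, 0)


def _element_of(atom_name: str) -> str:
    # protein atom names start with the element letter (N, C, O, S, P)
    return atom_name[0]


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """A single atom with its structural role labels."""

    atom_index: int
    name: str
    element: str
    residue_index: int
    chain_id: int
    roles: frozenset


@dataclass(frozen=True)
class Residue:
    residue_index: int       # global, 0-based, contiguous within a chain
    res_type: str            # 3-letter code, plus PTR
    chain_id: int
    local_index: int         # 0-based position within its chain


ROLE_NAMES = ("heavy", "backbone_N", "backbone_O",
              "sidechain_N", "sidechain_O", "ring_carbon")


class Topology:
    """Chains of residues/atoms plus ion and water records.

    Storage is columnar (NumPy arrays over the global atom index) so that
    distance-based stages can vectorize; :meth:`atom` and :meth:`residue`
    give record views where object access reads better.
    """

    def __init__(self):
        self.atom_name: list[str] = []
        self.element: list[str] = []
        self.atom_residue = np.empty(0, dtype=np.int64)   # -1 for ion/water
        self.atom_chain = np.empty(0, dtype=np.int64)     # -1 for non-protein
        self.roles: dict[str, np.ndarray] = {}
        self.residues: list[Residue] = []
        self.chain_residues: list[np.ndarray] = []        # residue indices per chain
        self.ions: list[tuple[str, int]] = []             # (species, atom_index)
        self.waters = np.empty((0, 3), dtype=np.int64)    # O, H1, H2
        self.protein_charge_per_chain: list[int] = []

    # -- basic sizes ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_chains(self) -> int:
        return len(self.chain_residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def total_protein_charge(self) -> int:
        return int(sum(self.protein_charge_per_chain))

    # -- derived masks ----------------------------------------------------
    @property
    def is_protein(self) -> np.ndarray:
        return self.atom_chain >= 0

    @property
    def is_water(self) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        if self.waters.size:
            mask[self.waters.ravel()] = True
        return mask

    @property
    def is_ion(self) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        for _, idx in self.ions:
            mask[idx] = True
        return mask

    def ion_indices(self, species: str) -> np.ndarray:
        species = normalize_species(species)
        return np.array([i for s, i in self.ions if s == species], dtype=np.int64)

    def masses(self) -> np.ndarray:
        return np.array([ATOM_MASSES[e] for e in self.element])

    def chain_atoms(self, chain_id: int) -> np.ndarray:
        if not 0 <= chain_id < self.n_chains:
            raise ValueError(f"unknown chain id {chain_id}")
        return np.flatnonzero(self.atom_chain == chain_id)

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.atom_residue == residue_index)

    def atom(self, i: int) -> Atom:
        roles = frozenset(r for r in ROLE_NAMES if self.roles[r][i])
        return Atom(i, self.atom_name[i], self.element[i],
                    int(self.atom_residue[i]), int(self.atom_chain[i]), roles)

    def residue(self, residue_index: int) -> Residue:
        return self.residues[residue_index]

    def chain_sequence(self, chain_id: int) -> list[str]:
        return [self.residues[r].res_type for r in self.chain_residues[chain_id]]

    def validate(self) -> None:
        n = self.n_atoms
        for r in ROLE_NAMES:
            if len(self.roles[r]) != n:
                raise ValueError("role mask length mismatch")
        # hydrogens never heavy
        h = np.array([e == "H" for e in self.element])
        if np.any(h & self.roles["heavy"]):
            raise ValueError("hydrogen atom labelled heavy")
        # every atom belongs to exactly one of protein/ion/water
        cover = (self.is_protein.astype(int) + self.is_ion.astype(int)
                 + self.is_water.astype(int))
        if not np.all(cover == 1):
            raise ValueError("atoms must belong to exactly one of protein/ion/water")
        for chain in self.chain_residues:
            locs = [self.residues[r].local_index for r in chain]
            if locs != list(range(len(chain))):
                raise ValueError("residue indices not contiguous within chain")


# ---------------------------------------------------------------------------
# frames and trajectories
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """Coordinates (Angstrom) of every atom plus the orthorhombic box."""

    coords: np.ndarray            # (n_atoms, 3)
    box: np.ndarray               # (Lx, Ly, Lz)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    def copy(self) -> "Frame":
        return Frame(self.coords.copy(), self.box.copy())


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]
    replicate_id: int = 0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for f in self.frames:
            if len(f.coords) != n:
                raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ShellCutoffs:
    """First/second coordination-shell distance thresholds for one species."""

    species: str
    first: float
    second: float

    def __post_init__(self):
        if not 0 < self.first < self.second:
            raise ValueError("require 0 < first < second shell cutoff")


#: cutoffs read off the ion-protein RDF minima: Cl- (4.0, 6.4), Na+ (3.0, 5.4)
DEFAULT_CUTOFFS = {
    "CL": ShellCutoffs("CL", 4.0, 6.4),
    "NA": ShellCutoffs("NA", 3.0, 5.4),
}


@dataclass
class RDFResult:
    """Radial distribution function g(r) on a uniform grid."""

    bin_edges: np.ndarray
    g: np.ndarray
    n_centers: float          # mean number of centers per contributing frame
    n_targets: int
    frames_used: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ReplicateSummary:
    """Per-replicate values with their mean and among-replicate SD (ddof=1)."""

    per_replicate_values: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        vals = np.asarray(self.per_replicate_values, dtype=float)
        if vals.size == 0:
            raise ValueError("no replicate values")
        self.mean = float(vals.mean())
        self.sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------


def _as_three_letter(sequence) -> list[str]:
    if isinstance(sequence, str):
        out = []
        for c in sequence:
            if c.upper() not in AA_1TO3:
                raise ValueError(f"unknown residue code: {c!r}")
            out.append(AA_1TO3[c.upper()])
        return out
    out = []
    for code in sequence:
        code = code.upper()
        if code not in SIDECHAIN_HEAVY:
            raise ValueError(f"unknown residue type: {code!r}")
        out.append(code)
    return out


def build_topology(sequences: Sequence, ions: dict | None = None,
                   waters: int = 0, protonate_his: bool = False) -> Topology:
    """Build a :class:`Topology` from per-chain sequences plus ion/water counts.

    Parameters
    ----------
    sequences:
        One sequence per chain, as a 1-letter string or an iterable of
        3-letter codes ("PTR" allowed for phospho-Tyr).
    ions:
        Mapping species -> count, e.g. ``{"CL": 90, "NA": 18}``.
    waters:
        Number of 3-site water molecules to append.
    protonate_his:
        Count His as +1 in per-chain charges (low-pH behaviour).

    Atom ordering is chains (residue by residue: N CA C O then sidechain),
    then ions, then waters (O H1 H2).  Hydrogens are generated for waters
    only; protein records are heavy-atom.
    """
    if not sequences:
        raise ValueError("at least one chain sequence required")
    top = Topology()
    roles = {r: [] for r in ROLE_NAMES}

    def add_atom(name, element, res_idx, chain_id, atom_roles):
        top.atom_name.append(name)
        top.element.append(element)
        _residues.append(res_idx)
        _chains.append(chain_id)
        for r in ROLE_NAMES:
            roles[r].append(r in atom_roles)

    _residues: list[int] = []
    _chains: list[int] = []

    res_counter = 0
    for chain_id, seq in enumerate(sequences):
        codes = _as_three_letter(seq)
        if not codes:
            raise ValueError(f"chain {chain_id} has an empty sequence")
        chain_res = []
        charge = 0
        for local, code in enumerate(codes):
            top.residues.append(Residue(res_counter, code, chain_id, local))
            chain_res.append(res_counter)
            charge += residue_charge(code, protonate_his)
            scn = set(SIDECHAIN_N.get(code, ()))
            sco = set(SIDECHAIN_O.get(code, ()))
            ring = set(RING_CARBONS.get(code, ()))
            for name in BACKBONE_ATOMS + SIDECHAIN_HEAVY[code]:
                atom_roles = {"heavy"}
                if name == "N":
                    atom_roles.add("backbone_N")
                elif name == "O":
                    atom_roles.add("backbone_O")
                if name in scn:
                    atom_roles.add("sidechain_N")
                if name in sco:
                    atom_roles.add("sidechain_O")
                if name in ring:
                    atom_roles.add("ring_carbon")
                add_atom(name, _element_of(name), res_counter, chain_id, atom_roles)
            res_counter += 1
        top.chain_residues.append(np.array(chain_res, dtype=np.int64))
        top.protein_charge_per_chain.append(charge)

    for species, count in (ions or {}).items():
        species = normalize_species(species)
        elem, _ = ION_SPECIES[species]
        for _ in range(int(count)):
            idx = len(top.atom_name)
            add_atom(species, elem, -1, -1, set())
            top.ions.append((species, idx))

    water_rows = []
    for _ in range(int(waters)):
        idx = len(top.atom_name)
        add_atom("OW", "O", -1, -1, set())
        add_atom("HW1", "H", -1, -1, set())
        add_atom("HW2", "H", -1, -1, set())
        water_rows.append((idx, idx + 1, idx + 2))
    if water_rows:
        top.waters = np.array(water_rows, dtype=np.int64)

    top.atom_residue = np.array(_residues, dtype=np.int64)
    top.atom_chain = np.array(_chains, dtype=np.int64)
    top.roles = {r: np.array(v, dtype=bool) for r, v in roles.items()}
    top.validate()
    return top


def molar_concentration(n_molecules: int, box) -> float:
    """Concentration in mM of ``n_molecules`` in an orthorhombic box (Angstrom).

    1 A^3 = 1e-27 L, so c[mM] = 1000 * n / (N_A * V[A^3] * 1e-27).
    """
    box = np.asarray(box, dtype=float).reshape(3)
    volume = float(np.prod(box))
    if volume <= 0 or np.any(box <= 0):
        raise ValueError("box volume must be positive")
    return 1000.0 * n_molecules / (AVOGADRO * volume * 1e-27)


# ---------------------------------------------------------------------------
# reference sequence
# ---------------------------------------------------------------------------

#: Synthetic stand-in for the 131-residue low-complexity domain of hnRNPA1
#: (A1-LCD).  The composition matches the real domain (51 G, 22 S, 11 F, 7 Y,
#: 13 N, 4 Q, 10 R, 2 K, 3 D; net charge +9); the 8 residues not fixed by the
#: published composition are neutral non-aromatic fillers (4 A, 2 P, 1 T, 1 M)
#: and the ordering is a frozen shuffle, not the native sequence.  Every
#: composition-level quantity (charge counts, aromatic counts, backbone-site
#: counts) is exact; sequence-position-specific analyses are not meaningful
#: on this stand-in.
A1LCD_SEQUENCE = (
    "GGFGSGQSGGQGGGGRYGGNGGDAGGGSNGGYSFNKNGFSGSSSDGAGSGNGGRGFRSFNGQQNMFFAGFG"
    "GSPGSNGGRGGSPSSFGYSSYGTGGGGNNRANFGRGGGNKGRSYDGSNFSGGYGRYSSRR"
)


def build_a1lcd_topology(n_chains: int = 8, ions: dict | None = None,
                         waters: int = 0) -> Topology:
    """Topology of ``n_chains`` A1-LCD-composition chains (+9 each)."""
    return build_topology([A1LCD_SEQUENCE] * n_chains, ions=ions, waters=waters)
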