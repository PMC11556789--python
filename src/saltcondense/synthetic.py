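"""Synthetic multi-chain fixtures with planted, exactly-known structure.

Every analysis stage in this package is testable without external
trajectories: the generators here emit topologies and frames together with
a ground-truth ledger listing the exact contacts, ion shell assignments,
bridging multiplicities and chain geometry that were planted.  Chains are
rigid self-avoiding templates (a straight backbone with ladder sidechains),
not physical conformations — the pipeline under test does counting and
geometry, not thermodynamics.

Planting works constructively (chains are rotated/translated so designated
atoms land at prescribed distances from planted ions or partner residues)
and is then *verified* against the realized coordinates with plain all-pairs
loops; a spec whose plants are not realized exactly raises
:class:`PlantError` naming the offending plant.  The ledger therefore holds
exact integers by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactParams, classify_pair, scope_mask
from .geometry import minimum_image_distance, pairwise_min_image_distances
from .model import (DEFAULT_CUTOFFS, Frame, Topology, Trajectory,
                    build_topology, normalize_species)


class PlantError(ValueError):
    """A planted feature could not be realized."""


# ---------------------------------------------------------------------------
# rigid chain templates
# ---------------------------------------------------------------------------

_RESIDUE_SPACING = 3.8      # backbone step along the chain axis, A
_SIDECHAIN_BASE = 1.5       # CB offset from CA, A
_SIDECHAIN_STEP = 1.35      # ladder step between successive sidechain atoms


def chain_template(codes: list[str]) -> np.ndarray:
    """Local heavy-atom coordinates of one chain laid along +x.

    Atom order matches :func:`saltcondense.model.build_topology`:
    N CA C O then sidechain atoms per residue.  The backbone runs along x,
    carbonyl oxygens point to +y and sidechain ladders to +z, so the
    template is self-avoiding (no two atoms closer than ~1.3 A).
    """
    from .model import BACKBONE_ATOMS, SIDECHAIN_HEAVY
    coords = []
    for i, code in enumerate(codes):
        cx = _RESIDUE_SPACING * i
        coords.append((cx - 1.2, 0.0, 0.0))          # N
        coords.append((cx, 0.0, 0.0))                # CA
        coords.append((cx + 1.2, 0.0, 0.0))          # C
        coords.append((cx + 1.2, 1.3, 0.0))          # O
        for k, _name in enumerate(SIDECHAIN_HEAVY[code]):
            coords.append((cx + 0.35 * (k % 2), 0.0,
                           _SIDECHAIN_BASE + _SIDECHAIN_STEP * k))
    return np.array(coords)


_EX, _EY, _EZ = np.eye(3)

#: (chain axis, anchor direction) pairs for chains meeting at a bridge site;
#: anchor directions are distinct and perpendicular to the paired axis.
_BRIDGE_FRAMES = [(_EX, _EZ), (_EY, -_EZ), (_EZ, _EX),
                  (_EY, -_EX), (_EZ, _EY), (_EX, -_EY)]


def _rotation(axis: np.ndarray, offset_dir_local: str,
              offset_target: np.ndarray) -> np.ndarray:
    """Rotation mapping local +x to ``axis`` and the local sidechain (+z) or
    carbonyl (+y) direction to ``offset_target``."""
    a = axis / np.linalg.norm(axis)
    u = offset_target / np.linalg.norm(offset_target)
    if offset_dir_local == "z":
        ez, ey = u, np.cross(u, a)
    else:
        ey, ez = u, np.cross(a, u)
    return np.column_stack([a, ey, ez])


# ---------------------------------------------------------------------------
# plant specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonPlant:
    """One planted ion.

    ``site``: 'backbone_O' or '<RES>:sidechain_N' / '<RES>:sidechain_O'.
    ``chains``: the chains the ion must be bound to; one entry for a plain
    binding plant, two or more for a bridging plant, empty for an unbound
    bulk ion.  ``shell``: intended band of the minimum ion-site distance.
    """

    species: str
    shell: str = "first"            # "first" | "second" | "unbound"
    site: str = "backbone_O"
    chains: tuple = ()
    distance: float | None = None   # override the default planted distance


@dataclass(frozen=True)
class ContactPlant:
    chain_a: int
    residue_a: int                  # local index within the chain
    chain_b: int
    residue_b: int
    contact: bool = True
    distance: float = 4.0           # planted closest-atom distance


@dataclass
class PlantSpec:
    n_chains: int = 8
    #: one 1-letter sequence for all chains, or a per-chain list; the default
    #: pattern carries the residue types every plant flavour needs
    sequence: str | list | None = None
    chain_length: int = 12
    box: tuple = (120.0, 120.0, 120.0)
    ion_plan: tuple = ()
    contact_plan: tuple = ()
    n_waters: int = 0
    water_depletion_radius: float | None = None   # carve around ring carbons
    n_frames: int = 1
    wrap: str = "none"              # "none" | "random" (re-wrap test input)
    seed: int = 0

    def sequences(self) -> list[str]:
        if isinstance(self.sequence, (list, tuple)):
            if len(self.sequence) != self.n_chains:
                raise ValueError("per-chain sequence list length mismatch")
            return list(self.sequence)
        if self.sequence is not None:
            return [self.sequence] * self.n_chains
        pattern = "GRGDSYNFQKGS"
        seq = (pattern * (self.chain_length // len(pattern) + 1))[:self.chain_length]
        return [seq] * self.n_chains


# ---------------------------------------------------------------------------
# ground truth ledger
# ---------------------------------------------------------------------------


@dataclass
class PlantedIonTruth:
    atom_index: int
    species: str
    shell: str
    site: str
    chains: tuple                   # distinct chains bound (2nd-shell rule)
    bridged_k: int                  # len(chains); 0 for unbound


@dataclass
class GroundTruth:
    """Exact planted/realized structure accompanying a synthetic trajectory."""

    ion_records: list = field(default_factory=list)
    contacts_inter: set = field(default_factory=set)   # (res_i, res_j) global
    contacts_intra: set = field(default_factory=set)
    typed_inter: dict = field(default_factory=dict)    # label -> set of pairs
    bound_ions: dict = field(default_factory=dict)     # species -> count
    bridging_ions: dict = field(default_factory=dict)  # species -> count
    bridge_k: dict = field(default_factory=dict)       # species -> {k: count}
    dmax: float = 0.0
    rg_per_chain: list = field(default_factory=list)
    n_deleted_waters: int = 0

    def write(self, path) -> None:
        """Plain-text key-value sidecar."""
        with open(path, "w") as fh:
            fh.write(f"dmax\t{self.dmax:.6f}\n")
            fh.write("rg_per_chain\t" +
                     ",".join(f"{v:.6f}" for v in self.rg_per_chain) + "\n")
            for sp, n in sorted(self.bound_ions.items()):
                fh.write(f"bound_{sp}\t{n}\n")
            for sp, n in sorted(self.bridging_ions.items()):
                fh.write(f"bridging_{sp}\t{n}\n")
            for rec in self.ion_records:
                fh.write(f"ion\t{rec.atom_index}\t{rec.species}\t{rec.shell}"
                         f"\t{rec.bridged_k}\t{','.join(map(str, rec.chains))}\n")
            for i, j in sorted(self.contacts_inter):
                fh.write(f"contact_inter\t{i}\t{j}\n")
            for i, j in sorted(self.contacts_intra):
                fh.write(f"contact_intra\t{i}\t{j}\n")


# ---------------------------------------------------------------------------
# simple generators
# ---------------------------------------------------------------------------


def make_ideal_gas(n_points: int, box, seed: int) -> Frame:
    """I.i.d. uniform points in the box (the RDF ideal-gas oracle input)."""
    if n_points < 2:
        raise ValueError("need at least two points")
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    return Frame(rng.uniform(0.0, box, size=(n_points, 3)), box)


def make_two_cluster_frames(separation: float, box, seed: int,
                            spans=(30.0, 30.0), n_frames: int = 3):
    """Two rigid all-Gly chains at a controlled x-separation.

    Returns (trajectory, expected_dmax).  The first frame is unwrapped;
    later frames are randomly shifted and wrapped into the box so that
    PBC-aware metrics can be checked for re-wrapping invariance.
    Expected Dmax = span_a + separation + span_b along x.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    spans = tuple(float(s) for s in spans)
    total = spans[0] + separation + spans[1]
    if total >= box[0] - 2.0 or separation < 0:
        raise ValueError("clusters plus separation overflow the box")
    rng = np.random.default_rng(seed)
    chains, offset = [], 1.0
    for span in spans:
        n_res = max(2, int(round(span / _RESIDUE_SPACING)) + 1)
        codes = ["GLY"] * n_res
        local = chain_template(codes)
        x = local[:, 0]
        local = local.copy()
        local[:, 0] = (x - x.min()) * (span / (x.max() - x.min()))
        local[:, 0] += offset
        local[:, 1:] += box[1:] / 2.0
        chains.append((codes, local))
        offset += span + separation
    top = build_topology(["G" * len(c) for c, _ in chains])
    coords0 = np.vstack([xyz for _, xyz in chains])
    frames = [Frame(coords0, box)]
    for _ in range(n_frames - 1):
        shift = rng.uniform(0.0, box, size=3)
        frames.append(Frame(np.mod(coords0 + shift, box), box))
    expected = float(total)
    return Trajectory(top, frames), expected


# ---------------------------------------------------------------------------
# planted condensates
# ---------------------------------------------------------------------------


def _role_atoms_of_chain(top: Topology, chain_id: int, site: str) -> list[int]:
    """Atom indices on one chain matching a site spec, template order."""
    res_type, role = (site.split(":", 1) if ":" in site else (None, site))
    out = []
    for i in top.chain_atoms(chain_id):
        if not top.roles[role][i]:
            continue
        if res_type is not None:
            r = top.residues[top.atom_residue[i]]
            if r.res_type != res_type.upper():
                continue
        out.append(int(i))
    return out


def _outermost_site_atom(top, local_coords, chain_id, site, used_residues,
                         prefer: str = "middle"):
    """Pick the site atom with the largest sidechain extent on an unused
    residue (so the planted ion's nearest selection atom is the target).

    ``prefer`` places the anchor near the chain middle (bridges) or near a
    chain end (single-chain plants, keeping them clear of bridge sites).
    """
    res_type, role = (site.split(":", 1) if ":" in site else (None, site))
    candidates = _role_atoms_of_chain(top, chain_id, site)
    if not candidates:
        raise PlantError(f"chain {chain_id} has no atoms for site {site!r}")
    chain_atoms = top.chain_atoms(chain_id)
    local_of = {int(a): local_coords[k] for k, a in enumerate(chain_atoms)}
    by_res: dict[int, list[int]] = {}
    for a in candidates:
        by_res.setdefault(int(top.atom_residue[a]), []).append(a)
    free = [r for r in sorted(by_res) if (chain_id, r) not in used_residues]
    if not free:
        raise PlantError(f"no unused {site!r} residue left on chain {chain_id}")
    mid = np.median([top.residues[r].local_index for r in by_res])
    if prefer == "middle":
        res = min(free, key=lambda r: abs(top.residues[r].local_index - mid))
    else:
        res = max(free, key=lambda r: abs(top.residues[r].local_index - mid))
    used_residues.add((chain_id, res))
    key = 1 if role == "backbone_O" else 2      # outermost along y or z
    atom = max(by_res[res], key=lambda a: local_of[a][key])
    return atom, ("y" if role == "backbone_O" else "z")


_PLANT_DISTANCES = {("CL", "first"): 3.2, ("CL", "second"): 5.2,
                    ("NA", "first"): 2.4, ("NA", "second"): 4.2}


def make_planted_condensate(spec: PlantSpec):
    """Build a trajectory realizing a :class:`PlantSpec`.

    Returns ``(trajectory, ground_truth)``.  Raises :class:`PlantError` when
    a plant cannot be realized (chain claimed twice, clash below 1 A,
    unintended shell/bridge/contact status after verification).
    """
    box = np.asarray(spec.box, dtype=float).reshape(3)
    sequences = spec.sequences()
    ion_counts: dict[str, int] = {}
    for plant in spec.ion_plan:
        sp = normalize_species(plant.species)
        ion_counts[sp] = ion_counts.get(sp, 0) + 1

    # waters are appended after depletion, so build a provisional topology
    top = build_topology(sequences, ions=ion_counts, waters=0)
    templates = [chain_template(top.chain_sequence(c))
                 for c in range(top.n_chains)]

    # ---- chain placement -------------------------------------------------
    rotations = [np.eye(3) for _ in range(top.n_chains)]
    translations = [None] * top.n_chains
    claimed = [None] * top.n_chains          # which plant fixed this chain

    grid = int(np.ceil(np.sqrt(top.n_chains)))
    spacing = 28.0
    margin = 18.0

    def default_translation(c):
        gy, gz = c % grid, c // grid
        return np.array([margin, margin + spacing * gy, margin + spacing * gz])

    def place_default(c):
        if translations[c] is None:
            translations[c] = default_translation(c)

    def _tip_atom(chain, res_global):
        """Outermost sidechain heavy atom of a residue (CA for Gly)."""
        atoms = top.residue_atoms(res_global)
        local = {int(i): templates[chain][k]
                 for k, i in enumerate(top.chain_atoms(chain))}
        side = [i for i in atoms if top.atom_name[i] not in
                ("N", "CA", "C", "O")]
        if side:
            tip = max(side, key=lambda i: local[int(i)][2])
        else:
            tip = next(i for i in atoms if top.atom_name[i] == "CA")
        return int(tip), local

    # contact plants: chain_b crosses chain_a with its sidechain ladder
    # flipped (-z) so the two residues meet tip-to-tip at the set distance
    for plant in spec.contact_plan:
        if not plant.contact:
            continue
        a, b = plant.chain_a, plant.chain_b
        place_default(a)
        if claimed[b] is not None:
            raise PlantError(f"chain {b} already claimed by {claimed[b]}")
        ra = top.chain_residues[a][plant.residue_a]
        rb = top.chain_residues[b][plant.residue_b]
        tip_a, a_local = _tip_atom(a, ra)
        pa = rotations[a] @ a_local[tip_a] + translations[a]
        Rb = _rotation(_EY, "z", np.array([0.0, 0.0, -1.0]))
        tip_b, b_local = _tip_atom(b, rb)
        rotations[b] = Rb
        translations[b] = (pa + np.array([0.0, 0.0, plant.distance])
                           - Rb @ b_local[tip_b])
        claimed[b] = f"contact plant {plant}"

    # bridging plants claim and re-orient every involved chain
    used_residues: set = set()
    # sites on the box diagonal: an axis-aligned chain anchored at one site
    # stays sqrt(2)*t away from every other site
    t = float(box.min()) / 4.0
    bridge_sites = iter(np.array([box / 2.0 + k * np.array([t, t, t])
                                  for k in (0.0, 1.0, -1.0)]))
    ion_positions: dict[int, np.ndarray] = {}
    truth_ions: list[PlantedIonTruth] = []

    plant_order = sorted(range(len(spec.ion_plan)),
                         key=lambda i: -len(spec.ion_plan[i].chains))
    ion_atom_of_plant: dict[int, int] = {}
    next_ion = {sp: 0 for sp in ion_counts}
    ion_index_pool = {sp: top.ion_indices(sp) for sp in ion_counts}

    for pi in plant_order:
        plant = spec.ion_plan[pi]
        sp = normalize_species(plant.species)
        ion_atom = int(ion_index_pool[sp][next_ion[sp]])
        next_ion[sp] += 1
        ion_atom_of_plant[pi] = ion_atom
        k = len(plant.chains)
        if plant.shell == "unbound":
            continue                      # positioned after chains settle
        d = plant.distance or _PLANT_DISTANCES[(sp, plant.shell)]
        cuts = DEFAULT_CUTOFFS[sp]
        band = ((0.0, cuts.first) if plant.shell == "first"
                else (cuts.first, cuts.second))
        if not band[0] < d <= band[1]:
            raise PlantError(f"planted distance {d} outside {plant.shell} "
                             f"band {band} for {sp}")
        if k >= 2:
            if k > len(_BRIDGE_FRAMES):
                raise PlantError(f"bridge multiplicity {k} unsupported")
            try:
                p = next(bridge_sites)
            except StopIteration:
                raise PlantError("too many bridging plants for site pool")
            ion_positions[ion_atom] = p
            for j, c in enumerate(plant.chains):
                if claimed[c] is not None:
                    raise PlantError(f"chain {c} already claimed "
                                     f"by {claimed[c]}")
                axis, u = _BRIDGE_FRAMES[j]
                atom, off_dir = _outermost_site_atom(
                    top, templates[c], c, plant.site, used_residues)
                R = _rotation(axis, off_dir, -u)
                local = templates[c][list(top.chain_atoms(c)).index(atom)]
                rotations[c] = R
                translations[c] = (p + d * u) - R @ local
                claimed[c] = f"bridge plant {pi}"
        elif k == 1:
            c = plant.chains[0]
            place_default(c)
            atom, off_dir = _outermost_site_atom(
                top, templates[c], c, plant.site, used_residues,
                prefer="end" if claimed[c] else "middle")
            local = templates[c][list(top.chain_atoms(c)).index(atom)]
            out_dir = rotations[c] @ (_EY if off_dir == "y" else _EZ)
            pos = rotations[c] @ local + translations[c] + d * out_dir
            ion_positions[ion_atom] = pos
        else:
            raise PlantError("bound ion plant needs at least one chain")

    for c in range(top.n_chains):
        place_default(c)

    # assemble protein coordinates
    coords = np.zeros((top.n_atoms, 3))
    for c in range(top.n_chains):
        atoms = top.chain_atoms(c)
        coords[atoms] = templates[c] @ rotations[c].T + translations[c]

    protein_no = np.flatnonzero(
        top.is_protein & np.isin(np.array(top.element), ("N", "O")))

    # unbound ions: rejection-sample far from every protein N/O
    rng = np.random.default_rng(spec.seed)
    for pi, plant in enumerate(spec.ion_plan):
        if plant.shell != "unbound":
            continue
        sp = normalize_species(plant.species)
        clearance = DEFAULT_CUTOFFS[sp].second + 2.0
        ion_atom = ion_atom_of_plant[pi]
        for _ in range(2000):
            pos = rng.uniform(0.0, box, size=3)
            d = minimum_image_distance(pos, coords[protein_no], box)
            taken = [v for a, v in ion_positions.items() if a != ion_atom]
            if d.min() > clearance and all(
                    minimum_image_distance(pos, q, box) > 2.0 for q in taken):
                ion_positions[ion_atom] = pos
                break
        else:
            raise PlantError("could not place an unbound ion clear of protein")

    for atom, pos in ion_positions.items():
        coords[atom] = pos

    # clash check among planted atoms (ions vs protein/ions)
    if ion_positions:
        ion_xyz = np.array(list(ion_positions.values()))
        prot_xyz = coords[top.is_protein]
        if pairwise_min_image_distances(ion_xyz, prot_xyz, box).min() < 1.0:
            raise PlantError("planted ion within 1 A of a protein atom")
        if len(ion_xyz) > 1:
            dd = pairwise_min_image_distances(ion_xyz, ion_xyz, box)
            np.fill_diagonal(dd, np.inf)
            if dd.min() < 1.0:
                raise PlantError("two planted ions within 1 A")

    # waters: uniform background, optional depletion around ring carbons
    n_deleted = 0
    water_oxygens = rng.uniform(0.0, box, size=(spec.n_waters, 3))
    if spec.n_waters and spec.water_depletion_radius:
        rings = np.flatnonzero(top.roles["ring_carbon"])
        if rings.size:
            d = pairwise_min_image_distances(water_oxygens, coords[rings], box)
            keep = d.min(axis=1) > spec.water_depletion_radius
            n_deleted = int((~keep).sum())
            water_oxygens = water_oxygens[keep]

    final_top = build_topology(sequences, ions=ion_counts,
                               waters=len(water_oxygens))
    full = np.zeros((final_top.n_atoms, 3))
    full[:top.n_atoms] = coords
    for w, ox in zip(final_top.waters, water_oxygens):
        full[w[0]] = ox
        full[w[1]] = ox + np.array([0.76, 0.59, 0.0])
        full[w[2]] = ox + np.array([-0.76, 0.59, 0.0])

    # ---- verification + ledger (plain all-pairs loops) -------------------
    truth = GroundTruth()
    cuts_by_sp = {sp: DEFAULT_CUTOFFS[sp] for sp in ion_counts}
    site_chain = final_top.atom_chain[protein_no]

    for pi, plant in enumerate(spec.ion_plan):
        sp = normalize_species(plant.species)
        ion_atom = ion_atom_of_plant[pi]
        d_all = minimum_image_distance(full[ion_atom], full[protein_no], box)
        cuts = cuts_by_sp[sp]
        if plant.shell == "unbound":
            if d_all.min() <= cuts.second:
                raise PlantError(f"unbound plant {pi} is within binding range")
            truth.ion_records.append(PlantedIonTruth(
                ion_atom, sp, "unbound", plant.site, (), 0))
            continue
        # shell w.r.t. the named selection
        sel = []
        for c in range(final_top.n_chains):
            sel.extend(_role_atoms_of_chain(final_top, c, plant.site))
        d_sel = minimum_image_distance(full[ion_atom], full[np.array(sel)], box)
        dmin = d_sel.min()
        realized = ("first" if dmin <= cuts.first
                    else "second" if dmin <= cuts.second else "unbound")
        if realized != plant.shell:
            raise PlantError(f"plant {pi} realized shell {realized!r}, "
                             f"intended {plant.shell!r}")
        within = d_all <= cuts.second
        chains_bound = tuple(sorted(set(site_chain[within].tolist())))
        if set(plant.chains) - set(chains_bound):
            raise PlantError(f"plant {pi} bound chains {chains_bound}, "
                             f"intended to include {plant.chains}")
        if len(plant.chains) >= 2 and set(chains_bound) != set(plant.chains):
            raise PlantError(f"bridge plant {pi} bound chains {chains_bound} "
                             f"!= intended {plant.chains}")
        truth.ion_records.append(PlantedIonTruth(
            ion_atom, sp, plant.shell, plant.site,
            chains_bound, len(chains_bound)))

    for sp in ion_counts:
        ks = [r.bridged_k for r in truth.ion_records
              if r.species == sp and r.shell != "unbound"]
        truth.bound_ions[sp] = len(ks)
        truth.bridging_ions[sp] = sum(1 for k in ks if k >= 2)
        hist: dict[int, int] = {}
        for k in ks:
            hist[k] = hist.get(k, 0) + 1
        truth.bridge_k[sp] = hist

    # contacts by direct all-pairs residue loops
    params_all = ContactParams()
    params_side = ContactParams(atom_scope="sidechain_heavy")
    heavy = scope_mask(final_top, "all_heavy")
    side = scope_mask(final_top, "sidechain_heavy")
    res_atoms_all = [np.flatnonzero((final_top.atom_residue == r) & heavy)
                     for r in range(final_top.n_residues)]
    res_atoms_side = [np.flatnonzero((final_top.atom_residue == r) & side)
                      for r in range(final_top.n_residues)]
    typed = {}
    for i in range(final_top.n_residues):
        for j in range(i + 1, final_top.n_residues):
            ri, rj = final_top.residues[i], final_top.residues[j]
            same = ri.chain_id == rj.chain_id
            if same and abs(ri.local_index - rj.local_index) <= \
                    params_all.intra_neighbor_exclusion:
                continue
            d = pairwise_min_image_distances(full[res_atoms_all[i]],
                                             full[res_atoms_all[j]], box)
            if d.min() <= params_all.cutoff:
                (truth.contacts_intra if same else truth.contacts_inter).add((i, j))
            if not same and res_atoms_side[i].size and res_atoms_side[j].size:
                ds = pairwise_min_image_distances(full[res_atoms_side[i]],
                                                  full[res_atoms_side[j]], box)
                if ds.min() <= params_side.cutoff:
                    label = classify_pair(ri.res_type, rj.res_type)
                    typed.setdefault(label, set()).add((i, j))
    truth.typed_inter = typed

    for plant in spec.contact_plan:
        ra = final_top.chain_residues[plant.chain_a][plant.residue_a]
        rb = final_top.chain_residues[plant.chain_b][plant.residue_b]
        pair = (min(ra, rb), max(ra, rb))
        realized = pair in truth.contacts_inter or pair in truth.contacts_intra
        if realized != plant.contact:
            raise PlantError(f"contact plant {plant} realized={realized}")

    prot = full[final_top.is_protein]
    truth.dmax = float(np.max(prot.max(axis=0) - prot.min(axis=0)))
    masses = final_top.masses()
    for c in range(final_top.n_chains):
        atoms = final_top.chain_atoms(c)
        w = masses[atoms]
        com = np.average(full[atoms], axis=0, weights=w)
        truth.rg_per_chain.append(float(np.sqrt(np.average(
            np.sum((full[atoms] - com) ** 2, axis=1), weights=w))))
    truth.n_deleted_waters = n_deleted

    frames = [Frame(full.copy(), box)]
    for _ in range(spec.n_frames - 1):
        if spec.wrap == "random":
            shift = rng.uniform(0.0, box, size=3)
            frames.append(Frame(np.mod(full + shift, box), box))
        else:
            frames.append(Frame(full.copy(), box))
    return Trajectory(final_top, frames, replicate_id=0), truth
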