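"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive: periodic distances enumerate
explicit image shifts instead of using round(), contact and shell searches
are plain all-pairs loops with no spatial indexing, and Dmax re-centering
enumerates candidate image shifts per molecule.  These implementations
share no code path with the package's vectorized/KD-tree routines.
"""

import itertools

import numpy as np

SHIFTS27 = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)
SHIFTS125 = np.array(list(itertools.product((-2, -1, 0, 1, 2), repeat=3)),
                     dtype=float)


def image_min_distance(a, b, box):
    """Min over 27 periodic images of the Euclidean distance a-b.

    Points are first folded into the primary box (a pure modulo, which does
    not change the periodic distance), so the 27 neighbour images suffice.
    """
    box = np.asarray(box, dtype=float)
    a = np.mod(np.asarray(a, dtype=float), box)
    b = np.mod(np.asarray(b, dtype=float), box)
    b_images = b + SHIFTS27 * box
    return float(np.min(np.linalg.norm(a - b_images, axis=1)))


def min_cross_distance(xa, xb, box):
    """Min over all atom pairs of the 27-image distance."""
    best = np.inf
    for a in xa:
        for b in xb:
            d = image_min_distance(a, b, box)
            if d < best:
                best = d
    return best


def residue_contact_sets(frame, top, cutoff, scope_names, exclusion):
    """(inter, intra) residue-pair sets by all-pairs 27-image search.

    ``scope_names``: predicate(atom_index) -> bool for atoms in scope.
    """
    res_atoms = []
    for r in range(top.n_residues):
        atoms = [i for i in np.flatnonzero(top.atom_residue == r)
                 if scope_names(i)]
        res_atoms.append(np.array(atoms, dtype=int))
    inter, intra = set(), set()
    for i in range(top.n_residues):
        if res_atoms[i].size == 0:
            continue
        for j in range(i + 1, top.n_residues):
            if res_atoms[j].size == 0:
                continue
            ri, rj = top.residues[i], top.residues[j]
            same = ri.chain_id == rj.chain_id
            if same and abs(ri.local_index - rj.local_index) <= exclusion:
                continue
            d = min_cross_distance(frame.coords[res_atoms[i]],
                                   frame.coords[res_atoms[j]], frame.box)
            if d <= cutoff:
                (intra if same else inter).add((i, j))
    return inter, intra


def all_heavy_predicate(top):
    heavy = top.roles["heavy"]
    protein = top.is_protein
    return lambda i: bool(heavy[i] and protein[i])


def sidechain_heavy_predicate(top):
    heavy = top.roles["heavy"]
    protein = top.is_protein
    backbone = {"N", "CA", "C", "O", "OXT"}
    return lambda i: bool(heavy[i] and protein[i]
                          and top.atom_name[i] not in backbone)


def ion_shell(frame, top, ion_atom, selection_atoms, cutoffs):
    """'first' / 'second' / None by brute-force min distance to selection."""
    dmin = min(image_min_distance(frame.coords[ion_atom], frame.coords[a],
                                  frame.box) for a in selection_atoms)
    if dmin <= cutoffs.first:
        return "first"
    if dmin <= cutoffs.second:
        return "second"
    return None


def chains_contacted(frame, top, ion_atom, cutoff_second):
    """Distinct chains with a protein N/O atom within the 2nd-shell cutoff."""
    chains = set()
    for a in range(top.n_atoms):
        if top.atom_chain[a] < 0 or top.element[a] not in ("N", "O"):
            continue
        if image_min_distance(frame.coords[ion_atom], frame.coords[a],
                              frame.box) <= cutoff_second:
            chains.add(int(top.atom_chain[a]))
    return chains


def unwrap_unit_27(coords, box):
    """Sequential unwrap choosing each atom's image by 27-shift enumeration."""
    out = [np.asarray(coords[0], dtype=float)]
    for x in coords[1:]:
        images = x + SHIFTS27 * np.asarray(box)
        out.append(images[np.argmin(np.linalg.norm(images - out[-1], axis=1))])
    return np.array(out)


def dmax_enumeration(frame, top):
    """Dmax by explicit image enumeration, mirroring per-chain centering."""
    box = np.asarray(frame.box)
    units = [top.chain_atoms(c) for c in range(top.n_chains)]
    units += [np.array([i]) for _, i in top.ions]
    units += [row for row in top.waters]
    protein = top.is_protein
    candidates = []
    for c in range(top.n_chains):
        ref = unwrap_unit_27(frame.coords[top.chain_atoms(c)], box)
        cref = ref.mean(axis=0)
        coords = frame.coords.copy()
        for unit in units:
            contig = (unwrap_unit_27(frame.coords[unit], box)
                      if len(unit) > 1 else frame.coords[unit].astype(float))
            centroid = contig.mean(axis=0)
            images = centroid + SHIFTS125 * box
            s = SHIFTS125[np.argmin(np.linalg.norm(images - cref, axis=1))]
            coords[unit] = contig + s * box
        p = coords[protein]
        candidates.append(float(np.max(p.max(axis=0) - p.min(axis=0))))
    return min(candidates), candidates
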