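"""Residue-level contact counting and interaction-type classification.

A residue pair is "in contact" in a frame when any in-scope heavy atom of one
lies within the cutoff (default 6 Angstrom, minimum image) of any in-scope
heavy atom of the other.  Contacts are counted once per residue pair per
frame regardless of how many atom pairs satisfy the cutoff.  Interaction
types are assigned purely from residue identity:

    salt bridge : {Arg, Lys} x {Asp, Glu}
    cation-pi   : {Arg, Lys} x {Tyr, Phe}
    amino-pi    : {Asn, Gln} x {Tyr, Phe}
    pi-pi       : {Tyr, Phe} x {Tyr, Phe}

Glu is included in the salt-bridge rule for generality; the reference system
(A1-LCD) contains no Glu so this does not change its counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import (BACKBONE_ATOMS, SIDECHAIN_HEAVY, Frame, ReplicateSummary,
                    Topology, Trajectory)

CATIONIC = {"ARG", "LYS"}
ANIONIC = {"ASP", "GLU"}
AROMATIC = {"TYR", "PHE"}
AMIDE = {"ASN", "GLN"}

INTERACTION_TYPES = ("salt_bridge", "cation_pi", "amino_pi", "pi_pi", "other")


@dataclass(frozen=True)
class ContactParams:
    cutoff: float = 6.0
    atom_scope: str = "all_heavy"          # or "sidechain_heavy"
    intra_neighbor_exclusion: int = 1      # exclude |i-j| <= this within a chain

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.atom_scope not in ("all_heavy", "sidechain_heavy"):
            raise ValueError(f"unknown atom scope {self.atom_scope!r}")


def scope_mask(topology: Topology, atom_scope: str) -> np.ndarray:
    """Boolean mask of protein atoms in scope for contact evaluation."""
    mask = topology.roles["heavy"] & topology.is_protein
    if atom_scope == "sidechain_heavy":
        backbone = np.array([n in BACKBONE_ATOMS or n == "OXT"
                             for n in topology.atom_name])
        mask &= ~backbone
    return mask


def classify_pair(res_type_a: str, res_type_b: str) -> str:
    """Interaction type of a residue pair; symmetric in its arguments."""
    for code in (res_type_a, res_type_b):
        if code not in SIDECHAIN_HEAVY:
            raise ValueError(f"unknown residue type: {code!r}")
    pair = {res_type_a, res_type_b}
    if pair & CATIONIC and pair & ANIONIC:
        return "salt_bridge"
    if pair & CATIONIC and pair & AROMATIC:
        return "cation_pi"
    if pair & AMIDE and pair & AROMATIC:
        return "amino_pi"
    if res_type_a in AROMATIC and res_type_b in AROMATIC:
        return "pi_pi"
    return "other"


# ---------------------------------------------------------------------------
# frame-level contact pairs
# ---------------------------------------------------------------------------


def contact_residue_pairs(frame: Frame, topology: Topology,
                          params: ContactParams) -> set[tuple[int, int]]:
    """All residue pairs (i < j, global indices) in contact in this frame.

    Uses a periodic KD-tree for the atom-pair search; the result is defined
    purely by minimum-image distances, so it is independent of how the input
    coordinates are wrapped. Neighbor exclusion is NOT applied here.
    """
    box = frame.box
    if params.cutoff >= box.min() / 2:
        raise ValueError("cutoff must be below half the smallest box edge")
    mask = scope_mask(topology, params.atom_scope)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return set()
    coords = np.mod(frame.coords[idx], box)
    # floating-point mod can land exactly on the upper box face; fold it back
    np.subtract(coords, box, out=coords, where=coords >= box)
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
    res = topology.atom_residue[idx]
    ri, rj = res[pairs[:, 0]], res[pairs[:, 1]]
    keep = ri != rj
    lo = np.minimum(ri[keep], rj[keep])
    hi = np.maximum(ri[keep], rj[keep])
    return set(zip(lo.tolist(), hi.tolist()))


def _split_pairs(pairs, topology, params):
    """Split residue pairs into inter-chain and intra-chain (exclusion applied)."""
    inter, intra = set(), set()
    for i, j in pairs:
        a, b = topology.residues[i], topology.residues[j]
        if a.chain_id != b.chain_id:
            inter.add((i, j))
        elif abs(a.local_index - b.local_index) > params.intra_neighbor_exclusion:
            intra.add((i, j))
    return inter, intra


def residue_contact_partners(frame: Frame, topology: Topology,
                             residue_index: int,
                             params: ContactParams | None = None,
                             scope: str = "both") -> set[int]:
    """Residues in contact with one query residue in one frame.

    ``scope`` is 'inter', 'intra' or 'both'; intra partners at sequence
    offset <= the exclusion are never returned.
    """
    params = params or ContactParams()
    pairs = contact_residue_pairs(frame, topology, params)
    inter, intra = _split_pairs(pairs, topology, params)
    chosen = {"inter": inter, "intra": intra, "both": inter | intra}[scope]
    out = set()
    for i, j in chosen:
        if i == residue_index:
            out.add(j)
        elif j == residue_index:
            out.add(i)
    return out


# ---------------------------------------------------------------------------
# trajectory-level summaries
# ---------------------------------------------------------------------------


def _as_replicates(trajectories) -> list[Trajectory]:
    if isinstance(trajectories, Trajectory):
        return [trajectories]
    return list(trajectories)


def contacts_per_residue(trajectories, scope: str,
                         params: ContactParams | None = None) -> ReplicateSummary:
    """Mean number of contact partners per residue.

    Averaged over residues and frames within each replicate, then summarized
    among replicates (mean +/- SD). ``scope`` is 'inter' or 'intra'.
    """
    if scope not in ("inter", "intra"):
        raise ValueError("scope must be 'inter' or 'intra'")
    params = params or ContactParams()
    values = []
    for traj in _as_replicates(trajectories):
        top = traj.topology
        n_res = top.n_residues
        per_frame = []
        for frame in traj.frames:
            pairs = contact_residue_pairs(frame, top, params)
            inter, intra = _split_pairs(pairs, top, params)
            chosen = inter if scope == "inter" else intra
            # each pair contributes one partner to each of its two residues
            per_frame.append(2.0 * len(chosen) / n_res)
        values.append(float(np.mean(per_frame)))
    return ReplicateSummary(values)


def typed_pairs_in_frame(frame: Frame, topology: Topology,
                         params: ContactParams | None = None) -> Counter:
    """Counter of inter-chain residue-pair contacts by interaction type."""
    params = params or ContactParams(atom_scope="sidechain_heavy")
    pairs = contact_residue_pairs(frame, topology, params)
    inter, _ = _split_pairs(pairs, topology, params)
    counts = Counter()
    for i, j in inter:
        counts[classify_pair(topology.residues[i].res_type,
                             topology.residues[j].res_type)] += 1
    return counts


def typed_interchain_contacts(trajectories,
                              params: ContactParams | None = None
                              ) -> dict[str, ReplicateSummary]:
    """Inter-chain contact pairs per chain, by interaction type.

    Sidechain-heavy scope by default; pair counts are divided by the number
    of chains, averaged over frames, then summarized among replicates.
    """
    params = params or ContactParams(atom_scope="sidechain_heavy")
    reps = _as_replicates(trajectories)
    per_type: dict[str, list[float]] = {t: [] for t in INTERACTION_TYPES}
    for traj in reps:
        top = traj.topology
        acc = {t: [] for t in INTERACTION_TYPES}
        for frame in traj.frames:
            counts = typed_pairs_in_frame(frame, top, params)
            for t in INTERACTION_TYPES:
                acc[t].append(counts.get(t, 0) / top.n_chains)
        for t in INTERACTION_TYPES:
            per_type[t].append(float(np.mean(acc[t])))
    return {t: ReplicateSummary(v) for t, v in per_type.items()}
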