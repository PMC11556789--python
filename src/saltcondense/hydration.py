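"""Conditional water RDFs around pi-interaction partners.

The water-withdrawal analysis measures the water density around Tyr
six-carbon rings, restricted to Tyr residues that are engaged with a given
partner type in that frame (any partner atom within the condition cutoff of
any ring carbon).  Asp sidechain oxygens engaged in salt bridges serve as
the control.  Waters are counted per atom (O and both H) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import pairwise_min_image_distances
from .ions import _check_rdf_limits, _histogram_distances
from .model import RDFResult, Topology, Trajectory


@dataclass
class PartnerCondition:
    """Which centers qualify: center residues engaged with a partner type."""

    center_res_type: str                 # "TYR" or "ASP"
    center_role: str                     # "ring_carbon" / "sidechain_O"
    partner_res_types: tuple
    partner_role: str                    # "ring_carbon" / "sidechain_N"
    condition_cutoff: float = 6.0

    def __post_init__(self):
        if self.condition_cutoff <= 0:
            raise ValueError("condition cutoff must be positive")


#: the conditions used for the water-withdrawal analysis and its control
STANDARD_CONDITIONS = {
    "pi_pi": PartnerCondition("TYR", "ring_carbon", ("PHE",), "ring_carbon"),
    "cation_pi": PartnerCondition("TYR", "ring_carbon", ("ARG", "LYS"),
                                  "sidechain_N"),
    "amino_pi": PartnerCondition("TYR", "ring_carbon", ("GLN", "ASN"),
                                 "sidechain_N"),
    "salt_bridge_control": PartnerCondition("ASP", "sidechain_O",
                                            ("ARG", "LYS"), "sidechain_N"),
}


def _atoms_by_residue(topology: Topology, res_type: str, role: str):
    """{residue_index: atom indices with the role} for one residue type."""
    mask = topology.roles[role] & topology.is_protein
    out: dict[int, list[int]] = {}
    for i in np.flatnonzero(mask):
        r = int(topology.atom_residue[i])
        if topology.residues[r].res_type == res_type:
            out.setdefault(r, []).append(i)
    return {r: np.array(v) for r, v in out.items()}


def qualifying_centers(frame, topology: Topology,
                       condition: PartnerCondition) -> np.ndarray:
    """Center atoms whose residue satisfies the partner condition this frame."""
    centers = _atoms_by_residue(topology, condition.center_res_type,
                                condition.center_role)
    if not centers:
        raise ValueError(
            f"no {condition.center_res_type} residues with role "
            f"{condition.center_role!r} in topology")
    partner_atoms: list[np.ndarray] = []
    for ptype in condition.partner_res_types:
        partner_atoms.extend(
            _atoms_by_residue(topology, ptype, condition.partner_role).values())
    if not partner_atoms:
        return np.zeros(0, dtype=np.int64)
    p_idx = np.concatenate(partner_atoms)
    chosen = []
    for res, c_idx in centers.items():
        mask = topology.atom_residue[p_idx] != res  # never self-partner
        if not mask.any():
            continue
        d = pairwise_min_image_distances(frame.coords[c_idx],
                                         frame.coords[p_idx[mask]], frame.box)
        if d.min() <= condition.condition_cutoff:
            chosen.append(c_idx)
    if not chosen:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(chosen)


def conditional_water_rdf(trajectory: Trajectory,
                          condition: PartnerCondition,
                          bin_width: float = 0.05,
                          r_max: float | None = None,
                          oxygen_only: bool = False) -> RDFResult:
    """Water RDF around condition-qualifying center atoms.

    Qualification is re-evaluated every frame; frames with no qualifying
    centers contribute nothing (they are tallied via ``frames_used``).
    Water targets are all three atoms per molecule unless ``oxygen_only``.
    """
    top = trajectory.topology
    if top.waters.size == 0:
        raise ValueError("topology contains no waters")
    w_idx = top.waters[:, :1].ravel() if oxygen_only else top.waters.ravel()
    box0 = trajectory.frames[0].box
    if r_max is None:
        r_max = float(min(f.box.min() for f in trajectory.frames) / 2)
    _check_rdf_limits(box0, r_max, bin_width)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    hist = np.zeros(len(edges) - 1, dtype=np.int64)
    denom = np.zeros(len(edges) - 1)
    frames_used = 0
    n_centers_acc = 0
    for frame in trajectory.frames:
        c_idx = qualifying_centers(frame, top, condition)
        if c_idx.size == 0:
            continue
        frames_used += 1
        n_centers_acc += c_idx.size
        hist += _histogram_distances(frame.coords[c_idx], frame.coords[w_idx],
                                     frame.box, edges)
        rho = w_idx.size / float(np.prod(frame.box))
        denom += c_idx.size * rho * shell
    if frames_used == 0:
        raise ValueError("no frame had a qualifying center for this condition")
    g = hist / denom
    return RDFResult(edges, g, n_centers_acc / frames_used, int(w_idx.size),
                     frames_used)
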