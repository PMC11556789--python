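"""Ion-protein RDFs, coordination-shell assignment, unique-ion binding
counts, net-charge accounting and bridging-ion detection.

Coordination sites are protein nitrogen and oxygen atoms.  Shell membership
uses the minimum over site atoms of the minimum-image ion-site distance:
first shell when d <= first cutoff, second shell when first < d <= second
(boundaries inclusive).  Defaults follow the RDF-derived cutoffs 4.0/6.4 A
for Cl- and 3.0/5.4 A for Na+.  An ion is "bridging" when protein N/O atoms
of two or more distinct chains lie within its second-shell cutoff in the
same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import pairwise_min_image_distances
from .model import (DEFAULT_CUTOFFS, Frame, RDFResult, ReplicateSummary,
                    ShellCutoffs, Topology, Trajectory, normalize_species)


# ---------------------------------------------------------------------------
# site selections
# ---------------------------------------------------------------------------


@dataclass
class SiteSelection:
    """A resolved set of ion-coordination site atoms (N/O elements only)."""

    description: str
    atom_indices: np.ndarray
    chain_of_atom: np.ndarray
    residue_of_atom: np.ndarray
    n_residues: int            # residues of the selected type (normalization)

    def __post_init__(self):
        if len(self.atom_indices) == 0:
            raise ValueError(f"empty site selection: {self.description!r}")


def select_sites(topology: Topology, spec: str) -> SiteSelection:
    """Resolve a selection string against a topology.

    Grammar: ``"ROLE"`` (all residues) or ``"RES:ROLE"`` for a residue type,
    with ROLE one of backbone_N, backbone_O, sidechain_N, sidechain_O, or
    the aggregate ``"protein_NO"`` (every protein N and O atom).
    """
    protein = topology.is_protein
    elements = np.array(topology.element)
    if spec == "protein_NO":
        mask = protein & np.isin(elements, ("N", "O"))
        n_res = topology.n_residues
    else:
        res_type = None
        role = spec
        if ":" in spec:
            res_type, role = spec.split(":", 1)
            res_type = res_type.upper()
        if role not in topology.roles:
            raise ValueError(f"unknown site role {role!r}")
        mask = topology.roles[role] & protein
        if res_type is not None:
            res_match = np.array([topology.residues[r].res_type == res_type
                                  if r >= 0 else False
                                  for r in topology.atom_residue])
            mask &= res_match
            n_res = sum(1 for r in topology.residues if r.res_type == res_type)
        else:
            n_res = topology.n_residues
    idx = np.flatnonzero(mask)
    if idx.size and not set(elements[idx]) <= {"N", "O"}:
        raise ValueError(f"selection {spec!r} contains non-N/O atoms")
    return SiteSelection(spec, idx, topology.atom_chain[idx],
                         topology.atom_residue[idx], n_res)


def protein_no_sites(topology: Topology) -> SiteSelection:
    return select_sites(topology, "protein_NO")


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------


def _check_rdf_limits(box, r_max: float, bin_width: float) -> None:
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if r_max > np.min(box) / 2 + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box edge")


def _histogram_distances(xa, xb, box, edges, exclude_identical=None,
                         chunk: int = 256) -> np.ndarray:
    """Histogram of min-image distances between two coordinate sets.

    ``exclude_identical``: optional (idx_a, idx_b) global atom indices used
    to drop self-pairs when the two selections overlap.
    """
    hist = np.zeros(len(edges) - 1, dtype=np.int64)
    for start in range(0, len(xa), chunk):
        block = slice(start, start + chunk)
        d = pairwise_min_image_distances(xa[block], xb, box)
        if exclude_identical is not None:
            ia, ib = exclude_identical
            same = ia[block][:, None] == ib[None, :]
            d[same] = np.inf
        h, _ = np.histogram(d, bins=edges)
        hist += h
    return hist


def rdf_points(centers_xyz: np.ndarray, targets_xyz: np.ndarray | None, box,
               bin_width: float = 0.05, r_max: float | None = None,
               center_indices: np.ndarray | None = None,
               target_indices: np.ndarray | None = None) -> RDFResult:
    """RDF between two point sets in one periodic frame.

    ``targets_xyz=None`` computes the self-RDF of the center set (self-pairs
    excluded).  Normalization is against the ideal-gas expectation:
    g(bin) = H(bin) / (N_c * rho_t * V_shell).
    """
    box = np.asarray(box, dtype=float).reshape(3)
    if r_max is None:
        r_max = float(np.min(box) / 2)
    _check_rdf_limits(box, r_max, bin_width)
    self_rdf = targets_xyz is None
    if self_rdf:
        targets_xyz = centers_xyz
        n = len(centers_xyz)
        center_indices = target_indices = np.arange(n)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    excl = None
    if center_indices is not None and target_indices is not None:
        excl = (np.asarray(center_indices), np.asarray(target_indices))
    hist = _histogram_distances(centers_xyz, targets_xyz, box, edges,
                                exclude_identical=excl)
    volume = float(np.prod(box))
    rho = len(targets_xyz) / volume
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    denom = len(centers_xyz) * rho * shell
    g = hist / denom
    return RDFResult(edges, g, float(len(centers_xyz)), len(targets_xyz), 1)


def compute_rdf(trajectory: Trajectory, centers: SiteSelection | str,
                targets, bin_width: float = 0.05,
                r_max: float | None = None) -> RDFResult:
    """RDF of targets around center sites, averaged over frames.

    ``centers`` may be a :class:`SiteSelection` or a selection string;
    ``targets`` an ion species name or an explicit atom-index array.
    Self-pairs (shared atoms between the two selections) are excluded.
    """
    top = trajectory.topology
    if isinstance(centers, str):
        centers = select_sites(top, centers)
    if isinstance(targets, str):
        t_idx = top.ion_indices(targets)
    else:
        t_idx = np.asarray(targets, dtype=np.int64)
    if t_idx.size == 0:
        raise ValueError("empty target selection")
    c_idx = centers.atom_indices
    box0 = trajectory.frames[0].box
    if r_max is None:
        r_max = float(min(f.box.min() for f in trajectory.frames) / 2)
    _check_rdf_limits(box0, r_max, bin_width)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist = np.zeros(len(edges) - 1, dtype=np.int64)
    denom = np.zeros(len(edges) - 1)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for frame in trajectory.frames:
        hist += _histogram_distances(frame.coords[c_idx], frame.coords[t_idx],
                                     frame.box, edges,
                                     exclude_identical=(c_idx, t_idx))
        rho = t_idx.size / float(np.prod(frame.box))
        denom += c_idx.size * rho * shell
    g = np.where(denom > 0, hist / np.where(denom > 0, denom, 1.0), 0.0)
    return RDFResult(edges, g, float(c_idx.size), int(t_idx.size),
                     trajectory.n_frames)


def suggest_shell_cutoffs(rdf: RDFResult, species: str = "CL") -> ShellCutoffs:
    """Read first/second shell cutoffs off an RDF (advisory only).

    The g(r) profile is smoothed by a 3-bin moving average; the cutoffs are
    the first two local minima that follow the first two local maxima with
    g > 1.  Pipeline defaults remain the fixed values in DEFAULT_CUTOFFS.
    """
    g = rdf.g
    sm = np.convolve(g, np.ones(3) / 3.0, mode="same")
    r = rdf.bin_centers
    maxima = [i for i in range(1, len(sm) - 1)
              if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 1.0]
    if len(maxima) < 2:
        raise ValueError("RDF lacks two resolvable peaks above g=1; "
                         "cannot suggest shell cutoffs")

    def first_min_after(i0, i_stop):
        for i in range(i0 + 1, min(i_stop, len(sm) - 1)):
            if sm[i] < sm[i - 1] and sm[i] <= sm[i + 1]:
                return i
        raise ValueError("no local minimum after RDF peak")

    m1 = first_min_after(maxima[0], maxima[1])
    second_peak = next(i for i in maxima[1:] if i > m1)
    m2 = first_min_after(second_peak, len(sm))
    return ShellCutoffs(normalize_species(species), float(r[m1]), float(r[m2]))


# ---------------------------------------------------------------------------
# shell assignment
# ---------------------------------------------------------------------------


@dataclass
class IonBindingRecord:
    frame_index: int
    ion_index: int
    species: str
    shell: str                                   # "first" | "second"
    partner_residues: list = field(default_factory=list)  # (chain, residue)


def _min_site_distances(frame: Frame, ion_idx: np.ndarray,
                        site_idx: np.ndarray) -> np.ndarray:
    d = pairwise_min_image_distances(frame.coords[ion_idx],
                                     frame.coords[site_idx], frame.box)
    return d


def assign_ion_shells(frame: Frame, topology: Topology,
                      selection: SiteSelection, cutoffs: ShellCutoffs,
                      species: str, frame_index: int = 0
                      ) -> list[IonBindingRecord]:
    """Shell membership of every ion of one species against a selection.

    Partner residues are all selection residues with an atom within the
    second-shell cutoff of the ion.
    """
    species = normalize_species(species)
    ions = topology.ion_indices(species)
    if ions.size == 0:
        raise ValueError(f"no {species} ions in topology")
    d = _min_site_distances(frame, ions, selection.atom_indices)
    dmin = d.min(axis=1)
    records = []
    for k, ion in enumerate(ions):
        if dmin[k] <= cutoffs.first:
            shell = "first"
        elif dmin[k] <= cutoffs.second:
            shell = "second"
        else:
            continue
        within = d[k] <= cutoffs.second
        partners = sorted({(int(selection.chain_of_atom[j]),
                            int(selection.residue_of_atom[j]))
                           for j in np.flatnonzero(within)})
        records.append(IonBindingRecord(frame_index, int(ion), species,
                                        shell, partners))
    return records


# ---------------------------------------------------------------------------
# bound-ion counting
# ---------------------------------------------------------------------------


@dataclass
class BoundIonCount:
    selection: str
    total: ReplicateSummary             # unique bound ions, frame-averaged
    per_residue: ReplicateSummary       # total / residues of that type


def count_bound_ions(trajectories, selections: dict[str, SiteSelection],
                     cutoffs: ShellCutoffs, species: str,
                     shell_mode: str = "first_only"
                     ) -> dict[str, BoundIonCount]:
    """Unique bound ions per selection, frame-averaged then replicate-summarized.

    An ion contacting several residues (or chains) of the same selection is
    counted once toward that selection's total.  ``shell_mode`` is
    'first_only' (d <= first cutoff) or 'first_and_second' (d <= second).
    """
    if shell_mode not in ("first_only", "first_and_second"):
        raise ValueError("shell_mode must be 'first_only' or 'first_and_second'")
    species = normalize_species(species)
    limit = cutoffs.first if shell_mode == "first_only" else cutoffs.second
    reps = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    per_sel: dict[str, list[float]] = {name: [] for name in selections}
    for traj in reps:
        top = traj.topology
        ions = top.ion_indices(species)
        if ions.size == 0:
            raise ValueError(f"no {species} ions in topology")
        acc = {name: [] for name in selections}
        for frame in traj.frames:
            for name, sel in selections.items():
                d = _min_site_distances(frame, ions, sel.atom_indices)
                acc[name].append(int(np.sum(d.min(axis=1) <= limit)))
        for name in selections:
            per_sel[name].append(float(np.mean(acc[name])))
    out = {}
    for name, sel in selections.items():
        total = ReplicateSummary(per_sel[name])
        per_res = ReplicateSummary([v / sel.n_residues for v in per_sel[name]])
        out[name] = BoundIonCount(name, total, per_res)
    return out


# ---------------------------------------------------------------------------
# net charge
# ---------------------------------------------------------------------------


@dataclass
class ChargeSeries:
    per_frame: np.ndarray           # Q(t), elementary charges
    na_bound: np.ndarray
    cl_bound: np.ndarray
    protein_charge: int
    summary: ReplicateSummary | None = None


def _bound_count_frame(frame: Frame, topology: Topology, sites: SiteSelection,
                       species: str, limit: float) -> np.ndarray:
    """Boolean bound-mask over ions of a species (d_min <= limit)."""
    ions = topology.ion_indices(species)
    if ions.size == 0:
        return np.zeros(0, dtype=bool)
    d = _min_site_distances(frame, ions, sites.atom_indices)
    return d.min(axis=1) <= limit


def net_charge_series(trajectory: Trajectory,
                      cutoffs_cl: ShellCutoffs = DEFAULT_CUTOFFS["CL"],
                      cutoffs_na: ShellCutoffs = DEFAULT_CUTOFFS["NA"],
                      protein_charge: int | None = None) -> ChargeSeries:
    """Per-frame net charge Q(t) = Q_protein + N_Na_bound(t) - N_Cl_bound(t).

    "Bound" means within the species' second-shell cutoff of any protein
    N/O atom.
    """
    top = trajectory.topology
    if protein_charge is None:
        protein_charge = top.total_protein_charge
    sites = protein_no_sites(top)
    na, cl, q = [], [], []
    for frame in trajectory.frames:
        n_na = int(_bound_count_frame(frame, top, sites, "NA",
                                      cutoffs_na.second).sum())
        n_cl = int(_bound_count_frame(frame, top, sites, "CL",
                                      cutoffs_cl.second).sum())
        na.append(n_na)
        cl.append(n_cl)
        q.append(protein_charge + n_na - n_cl)
    return ChargeSeries(np.array(q), np.array(na), np.array(cl),
                        int(protein_charge))


def net_charge_replicates(trajectories, **kw) -> ReplicateSummary:
    values = [float(net_charge_series(t, **kw).per_frame.mean())
              for t in trajectories]
    return ReplicateSummary(values)


# ---------------------------------------------------------------------------
# bridging ions
# ---------------------------------------------------------------------------


@dataclass
class BridgeHistogram:
    """Counts of bound ions by number of distinct chains contacted.

    ``counts[species][k]`` is the frame-averaged number of ions of that
    species bound (1st+2nd shell) to exactly k distinct chains; bridging
    ions are those with k >= 2.
    """

    counts: dict[str, np.ndarray]
    bound_total: dict[str, float]
    bridging_total: dict[str, float]

    def fraction_bridging(self, species: str | None = None) -> float:
        if species is not None:
            return self.bridging_total[species] / self.bound_total[species]
        bound = sum(self.bound_total.values())
        return sum(self.bridging_total.values()) / bound


def chains_contacted_per_ion(frame: Frame, topology: Topology,
                             cutoffs: dict[str, ShellCutoffs]
                             ) -> dict[str, np.ndarray]:
    """For each bound ion, the number of distinct chains within its
    second-shell cutoff; unbound ions are omitted (k would be 0)."""
    sites = protein_no_sites(topology)
    out = {}
    for species, cut in cutoffs.items():
        species = normalize_species(species)
        ions = topology.ion_indices(species)
        if ions.size == 0:
            out[species] = np.zeros(0, dtype=int)
            continue
        d = _min_site_distances(frame, ions, sites.atom_indices)
        within = d <= cut.second
        ks = np.array([len(set(sites.chain_of_atom[w].tolist()))
                       for w in (np.flatnonzero(row) for row in within)])
        out[species] = ks[ks >= 1]
    return out


def bridging_ions(trajectories,
                  cutoffs: dict[str, ShellCutoffs] | None = None
                  ) -> BridgeHistogram:
    """Bridging-ion histogram averaged over frames and replicates."""
    cutoffs = cutoffs or DEFAULT_CUTOFFS
    reps = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    top0 = reps[0].topology
    if top0.n_chains < 2:
        raise ValueError("bridging analysis requires at least two chains")
    max_k = top0.n_chains
    counts = {normalize_species(s): np.zeros(max_k + 1) for s in cutoffs}
    n_frames = 0
    for traj in reps:
        for frame in traj.frames:
            per = chains_contacted_per_ion(frame, traj.topology, cutoffs)
            for species, ks in per.items():
                for k in ks:
                    counts[species][min(k, max_k)] += 1
            n_frames += 1
    for species in counts:
        counts[species] /= n_frames
    bound = {s: float(c[1:].sum()) for s, c in counts.items()}
    bridging = {s: float(c[2:].sum()) for s, c in counts.items()}
    return BridgeHistogram(counts, bound, bridging)
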