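"""Run configuration and the umbrella pipeline driver.

A :class:`RunConfig` (typically loaded from YAML) names the topology, the
replicate trajectories, the stages to run and the parameters that deviate
from defaults.  :func:`run_pipeline` executes the requested stages in order
(geometry -> contacts -> ions -> hydration), writes one TSV per stage plus a
machine-readable JSON summary, and logs every default applied so a run is
reconstructible from its log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import contacts as contacts_mod
from . import geometry, hydration, ions
from .fileio import read_pdb, read_xyz
from .model import DEFAULT_CUTOFFS, ShellCutoffs, Trajectory

_STAGES = ("geometry", "contacts", "ions", "hydration")


@dataclass
class RunConfig:
    topology: str = ""
    trajectories: list = field(default_factory=list)   # replicate paths (XYZ)
    stages: list = field(default_factory=list)
    outdir: str = "saltcondense_out"
    contact_cutoff: float = 6.0
    intra_neighbor_exclusion: int = 1
    cutoffs: dict = field(default_factory=lambda: {"CL": (4.0, 6.4),
                                                   "NA": (3.0, 5.4)})
    bin_width: float = 0.05
    rdf_r_max: float | None = None
    hydration_condition: str = "pi_pi"
    seed: int = 0

    def __post_init__(self):
        for sp, (lo, hi) in self.cutoffs.items():
            if not 0 < lo < hi:
                raise ValueError(f"bad cutoffs for {sp}: {(lo, hi)}")
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def shell_cutoffs(self) -> dict[str, ShellCutoffs]:
        return {sp: ShellCutoffs(sp, *pair)
                for sp, pair in self.cutoffs.items()}


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _summ(s) -> dict:
    return {"mean": s.mean, "sd": None if np.isnan(s.sd) else s.sd,
            "per_replicate": list(s.per_replicate_values)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config: {config}"]
    summary: dict = {"stages": list(config.stages)}

    replicates: list[Trajectory] = []
    if config.stages:
        if not config.topology or not config.trajectories:
            raise ValueError("stages requested but topology/trajectories "
                             "missing from config")
        top, _ = read_pdb(config.topology)
        for rep_id, path in enumerate(config.trajectories):
            traj = read_xyz(path, top)
            traj.replicate_id = rep_id
            replicates.append(traj)
        log_lines.append(f"replicates: {len(replicates)}; "
                         f"frames: {[t.n_frames for t in replicates]}")

    cutoffs = config.shell_cutoffs()
    log_lines.append(f"shell cutoffs: { {s: (c.first, c.second) for s, c in cutoffs.items()} }")
    log_lines.append(f"contact cutoff: {config.contact_cutoff} A; "
                     f"intra exclusion: +/-{config.intra_neighbor_exclusion}")

    for stage in config.stages:
        try:
            if stage == "geometry":
                rows = []
                for traj in replicates:
                    for fi, frame in enumerate(traj.frames):
                        res = geometry.compute_dmax(frame, traj.topology)
                        rows.append((traj.replicate_id, fi,
                                     f"{res.value:.4f}", res.centering_chain))
                _write_tsv(outdir / "dmax.tsv",
                           ["replicate", "frame", "dmax_A", "centering_chain"],
                           rows)
                rg = [float(geometry.rg_series(t).mean()) for t in replicates]
                from .model import ReplicateSummary
                summary["geometry"] = {
                    "dmax_mean": float(np.mean([float(r[2]) for r in rows])),
                    "rg": _summ(ReplicateSummary(rg))}
            elif stage == "contacts":
                params = contacts_mod.ContactParams(
                    cutoff=config.contact_cutoff,
                    intra_neighbor_exclusion=config.intra_neighbor_exclusion)
                inter = contacts_mod.contacts_per_residue(replicates, "inter",
                                                          params)
                intra = contacts_mod.contacts_per_residue(replicates, "intra",
                                                          params)
                typed = contacts_mod.typed_interchain_contacts(replicates)
                _write_tsv(outdir / "contacts.tsv",
                           ["scope", "mean", "sd"],
                           [("inter", inter.mean, inter.sd),
                            ("intra", intra.mean, intra.sd)]
                           + [(k, v.mean, v.sd) for k, v in typed.items()])
                summary["contacts"] = {"inter": _summ(inter),
                                       "intra": _summ(intra),
                                       "typed": {k: _summ(v)
                                                 for k, v in typed.items()}}
            elif stage == "ions":
                top = replicates[0].topology
                present = {sp for sp, _ in top.ions}
                rows, ion_summary = [], {}
                for sp in sorted(present):
                    cut = cutoffs.get(sp, DEFAULT_CUTOFFS[sp])
                    sel = {"protein_NO": ions.protein_no_sites(top)}
                    for mode in ("first_only", "first_and_second"):
                        res = ions.count_bound_ions(replicates, sel, cut, sp,
                                                    shell_mode=mode)
                        rows.append((sp, mode, res["protein_NO"].total.mean,
                                     res["protein_NO"].total.sd))
                        ion_summary[f"{sp}_{mode}"] = _summ(
                            res["protein_NO"].total)
                nq = ions.net_charge_replicates(
                    replicates,
                    cutoffs_cl=cutoffs.get("CL", DEFAULT_CUTOFFS["CL"]),
                    cutoffs_na=cutoffs.get("NA", DEFAULT_CUTOFFS["NA"]))
                bridge = ions.bridging_ions(replicates, cutoffs)
                _write_tsv(outdir / "ions.tsv",
                           ["species", "shell_mode", "mean", "sd"], rows)
                _write_tsv(outdir / "bridge.tsv",
                           ["species", "bound", "bridging", "fraction"],
                           [(sp, bridge.bound_total[sp],
                             bridge.bridging_total[sp],
                             bridge.fraction_bridging(sp)
                             if bridge.bound_total[sp] else float("nan"))
                            for sp in sorted(bridge.bound_total)])
                summary["ions"] = {"bound": ion_summary,
                                   "net_charge": _summ(nq),
                                   "bridging": {sp: bridge.bridging_total[sp]
                                                for sp in bridge.bound_total}}
            elif stage == "hydration":
                cond = hydration.STANDARD_CONDITIONS[config.hydration_condition]
                rdfs = [hydration.conditional_water_rdf(
                    t, cond, bin_width=config.bin_width,
                    r_max=config.rdf_r_max) for t in replicates]
                g = np.mean([r.g for r in rdfs], axis=0)
                _write_tsv(outdir / "hydration.tsv", ["r_A", "g"],
                           [(f"{r:.3f}", f"{v:.6f}")
                            for r, v in zip(rdfs[0].bin_centers, g)])
                summary["hydration"] = {
                    "condition": config.hydration_condition,
                    "mean_g_beyond_10A": float(
                        g[rdfs[0].bin_centers > 10.0].mean())}
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
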