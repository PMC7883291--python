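"""End-to-end orchestration: simulate → map → summarize → dock → motion.

A run is driven by a single :class:`RunConfig` (flat key namespace per
stage, serialisable to YAML) and writes every stage output plus a manifest
under one output directory.  Reruns with an identical config and seed give
byte-identical numeric outputs; the manifest records inputs, seeds and
per-stage record counts so a run is reproducible from its archived config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import structio, synthetic, xlmap
from .rigidmodel import (Body, DomainDefinition, accessible_interaction_scan,
                         build_restraints, rigid_dock)
from .motion import interdomain_motion, linker_feasibility
from .structio import CrossLinkTable, read_crosslink_table, read_structure
from .synthetic import SimSpec
from .xlmap import AnalysisConfig

STAGES = ("simulate", "map", "summarize", "dock", "motion")


class PipelineError(Exception):
    pass


class ValidationError(PipelineError):
    pass


@dataclass
class RunConfig:
    """Serialisable configuration of a full run.

    Stage sub-dicts use the field names of the underlying dataclasses
    (:class:`~igxlink.synthetic.SimSpec`,
    :class:`~igxlink.xlmap.AnalysisConfig`, restraint parameters, scan and
    dock parameters).  File inputs may point at external data or at the
    outputs of an earlier stage in the same run.
    """

    output_dir: str = "igx_run"
    seed: int = 0
    # map inputs
    structure_path: str | None = None
    crosslink_path: str | None = None
    dialect: str = "generic"
    chain_proteins: dict[str, str] | None = None
    offsets: dict[str, int] | None = None
    # stage parameter blocks
    simulate: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    restraints: dict = field(default_factory=dict)
    dock: dict = field(default_factory=dict)
    motion: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _summary_dict(s: xlmap.DistanceSummary) -> dict:
    return {
        "histogram": {f"{k:g}": v for k, v in sorted(s.histogram.items())},
        "bin_width": s.bin_width,
        "n_unique": s.n_unique,
        "n_overlength": s.n_overlength,
        "n_self": s.n_self,
        "n_unmapped": s.n_unmapped,
        "mean_distance": round(s.mean_distance, 6),
        "unmapped_reasons": s.unmapped_reasons,
    }


def _mapped_frame(mapped: list[xlmap.MappedLink]) -> pd.DataFrame:
    rows = []
    for m in mapped:
        l = m.link
        rows.append({
            "protein_a": l.protein_a, "pos_a": l.pos_a,
            "protein_b": l.protein_b, "pos_b": l.pos_b,
            "csm_count": l.csm_count,
            "shortest_distance": round(m.distance, 4) if m.is_mapped else "",
            "chain_a": m.shortest[0] if m.is_mapped else "",
            "chain_b": m.shortest[1] if m.is_mapped else "",
            "n_assignments": len(m.assignments),
            "overlength": m.overlength,
            "self_link": m.is_self,
            "unmapped_reason": m.unmapped_reason or "",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages and return the run manifest.

    Stage dependencies are validated before any work: ``map`` needs a
    structure and a cross-link table (from config paths or the simulate
    stage of the same run); ``dock`` needs mapped links plus fixed/mobile
    domain ranges; ``motion`` needs two structure paths and domain ranges.
    Outputs land under ``config.output_dir``; the manifest is written last.
    """
    stages = list(stages or STAGES[:3])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s) {unknown}; choose from {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- upfront validation of stage dependencies
    will_simulate = "simulate" in stages
    if "map" in stages and not will_simulate and not config.structure_path:
        raise ValidationError("map stage needs 'structure_path' (or the simulate stage)")
    if "map" in stages and not will_simulate and not config.crosslink_path:
        raise ValidationError("map stage needs 'crosslink_path' (or the simulate stage)")
    if "summarize" in stages and "map" not in stages:
        raise ValidationError("summarize stage needs the map stage")
    if "dock" in stages:
        for key in ("fixed_domain", "mobile_domain"):
            if key not in config.dock:
                raise ValidationError(f"dock stage needs dock.{key} = [start, end]")
        if "map" not in stages and not config.crosslink_path:
            raise ValidationError("dock stage needs mapped links (map stage or crosslink_path)")
        if not will_simulate and not config.structure_path:
            raise ValidationError("dock stage needs a structure")
    if "motion" in stages:
        for key in ("structure_ref", "structure_alt", "anchor_domain", "moving_domain"):
            if key not in config.motion:
                raise ValidationError(f"motion stage needs motion.{key}")

    manifest: dict = {
        "config": asdict(config),
        "stages": stages,
        "seed": config.seed,
        "counts": {},
        "outputs": {},
    }

    structure = None
    table: CrossLinkTable | None = None
    mapped = None
    acfg = AnalysisConfig(**config.analysis)

    if "simulate" in stages:
        spec = SimSpec(seed=config.seed, **config.simulate)
        structure = synthetic.make_ring_oligomer(spec)
        table, truth = synthetic.simulate_crosslinks(structure, spec)
        p_structure = structio.write_structure(structure, outdir / "simulated.pdb")
        p_links = structio.export_links(table, outdir / "simulated_links.tsv", "tsv")
        truth_frame = pd.DataFrame(
            [{"protein_a": k[0], "pos_a": k[1], "protein_b": k[2], "pos_b": k[3],
              "min_distance": round(t.min_distance, 4),
              "is_decoy": t.is_decoy,
              "n_replicates_detected": len(t.replicates)}
             for t in truth for k in [t.key]])
        truth_frame.to_csv(outdir / "simulated_truth.tsv", sep="\t", index=False)
        manifest["counts"]["simulate"] = {
            "n_chains": structure.n_chains,
            "n_planted_links": len(truth),
            "n_observations": len(table),
            "n_decoys_planted": int(sum(t.is_decoy for t in truth)),
        }
        manifest["outputs"]["simulate"] = [p.name for p in
                                           (p_structure, p_links,
                                            outdir / "simulated_truth.tsv")]

    if "map" in stages:
        if table is None:
            table = read_crosslink_table(config.crosslink_path, config.dialect)
        if structure is None:
            chain_proteins = config.chain_proteins
            accessions = {p for k in table.unique_keys() for p in (k[0], k[2])}
            if chain_proteins is None and len(accessions) == 1:
                # single-protein table: every chain carries that protein
                chain_proteins = accessions.pop()
                manifest.setdefault("notes", []).append(
                    f"chain->protein map defaulted to {chain_proteins!r} "
                    "(single accession in the table)")
            structure = read_structure(config.structure_path,
                                       chain_proteins=chain_proteins)
        n_in = len(table)
        filtered = xlmap.deduplicate_and_filter(table, acfg)
        mapped = xlmap.map_table(filtered, structure, acfg,
                                 offsets=config.offsets)
        frame = _mapped_frame(mapped)
        frame.to_csv(outdir / "links_mapped.tsv", sep="\t", index=False)
        manifest["counts"]["map"] = {
            "n_rows_in": n_in,
            "n_unique_after_filter": len(filtered.unique_keys()),
            "n_mapped": sum(1 for m in mapped if m.is_mapped),
            "n_unmapped": sum(1 for m in mapped if not m.is_mapped),
            "n_overlength": sum(1 for m in mapped if m.overlength),
        }
        manifest["outputs"]["map"] = ["links_mapped.tsv"]

    if "summarize" in stages:
        summary = xlmap.distance_summary(mapped, acfg)
        _write_json(_summary_dict(summary), outdir / "distance_summary.json")
        hist = pd.DataFrame(
            sorted(summary.histogram.items()),
            columns=["bin_left", "count"])
        hist["bin_right"] = hist["bin_left"] + summary.bin_width
        hist[["bin_left", "bin_right", "count"]].to_csv(
            outdir / "distance_histogram.tsv", sep="\t", index=False)
        manifest["counts"]["summarize"] = {
            "n_unique": summary.n_unique,
            "n_overlength": summary.n_overlength,
            "mean_distance": round(summary.mean_distance, 4),
        }
        manifest["outputs"]["summarize"] = ["distance_summary.json",
                                            "distance_histogram.tsv"]

    if "dock" in stages:
        fixed_def = DomainDefinition("fixed", [tuple(config.dock["fixed_domain"])])
        mobile_def = DomainDefinition("mobile", [tuple(config.dock["mobile_domain"])])
        if mapped is not None:
            link_keys = {m.link.key for m in mapped if m.is_mapped}
        else:
            link_keys = read_crosslink_table(
                config.crosslink_path, config.dialect).unique_keys()
        restraints, excluded = build_restraints(
            link_keys, fixed_def, mobile_def, **config.restraints)
        fixed = Body.from_structure(structure, fixed_def)
        mobile = Body.from_structure(structure, mobile_def)
        scan = accessible_interaction_scan(
            fixed, mobile, restraints,
            n_orientations=config.dock.get("n_orientations", 576),
            grid_spacing=config.dock.get("grid_spacing", 2.0),
            clash_dist=config.dock.get("clash_dist", 3.0),
        )
        pd.DataFrame({"k": np.arange(len(scan.n_consistent)),
                      "n_poses": scan.n_consistent}).to_csv(
            outdir / "scan_nk.tsv", sep="\t", index=False)
        dock = rigid_dock(fixed, mobile, restraints,
                          scan.best_poses[:config.dock.get("n_starts", 8)],
                          clash_dist=config.dock.get("clash_dist", 3.0))
        pose_rows = [{"rank": i,
                      "restraint_energy": round(p.restraint_energy, 6),
                      "n_satisfied": p.n_satisfied,
                      "clash_count": p.clash_count}
                     for i, p in enumerate(dock.poses)]
        pd.DataFrame(pose_rows).to_csv(outdir / "dock_poses.tsv",
                                       sep="\t", index=False)
        manifest["counts"]["dock"] = {
            "n_restraints": len(restraints),
            "n_intra_body_excluded": len(excluded),
            "n_clash_free_poses": scan.n_clash_free,
            "n_clusters": len(dock.clusters),
            "best_energy": round(dock.poses[0].restraint_energy, 6),
        }
        manifest["outputs"]["dock"] = ["scan_nk.tsv", "dock_poses.tsv"]

    if "motion" in stages:
        mcfg = config.motion
        ref = read_structure(mcfg["structure_ref"])
        alt = read_structure(mcfg["structure_alt"])
        anchor = DomainDefinition("anchor", [tuple(mcfg["anchor_domain"])])
        moving = DomainDefinition("moving", [tuple(mcfg["moving_domain"])])
        angle, disp = interdomain_motion(ref, alt, anchor, moving)
        rows = [{"anchor": "anchor", "moving": "moving",
                 "angle_deg": round(angle, 4),
                 "displacement_A": round(disp, 4)}]
        if "linker_residues" in mcfg:
            fe = linker_feasibility(
                np.zeros(3), np.array([disp, 0.0, 0.0]),
                int(mcfg["linker_residues"]))
            rows[0].update({"linker_contour_min_A": fe.contour_min,
                            "linker_contour_max_A": fe.contour_max,
                            "linker_feasible": fe.feasible})
        pd.DataFrame(rows).to_csv(outdir / "motion.tsv", sep="\t", index=False)
        manifest["counts"]["motion"] = {"angle_deg": round(angle, 4),
                                        "displacement_A": round(disp, 4)}
        manifest["outputs"]["motion"] = ["motion.tsv"]

    _write_json(manifest, outdir / "manifest.json")
    return manifest


def render_report(outdir: str | Path, plots: bool = False) -> list[Path]:
    """Regenerate derived tables (and optionally plots) from a run directory.

    Deterministic: the same archived outputs always produce the same file
    set.  Plots are optional and headless-safe (Agg backend).
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest.json in {outdir}; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    produced: list[Path] = []

    summary_path = outdir / "distance_summary.json"
    if summary_path.exists():
        with open(summary_path) as fh:
            summary = json.load(fh)
        hist = pd.DataFrame(
            sorted(((float(k), v) for k, v in summary["histogram"].items())),
            columns=["bin_left", "count"])
        hist["bin_right"] = hist["bin_left"] + summary["bin_width"]
        p = outdir / "report_histogram.tsv"
        hist[["bin_left", "bin_right", "count"]].to_csv(p, sep="\t", index=False)
        produced.append(p)
        if plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.bar(hist["bin_left"], hist["count"],
                   width=summary["bin_width"], align="edge",
                   edgecolor="black", color="#88aacc")
            ax.axvline(30.0, color="red", linestyle="--", linewidth=1)
            ax.set_xlabel("shortest Cα–Cα distance (Å)")
            ax.set_ylabel("unique cross-links")
            fig.tight_layout()
            p = outdir / "report_histogram.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            produced.append(p)

    counts_path = outdir / "report_counts.tsv"
    rows = [{"stage": stage, **{k: v for k, v in counts.items()}}
            for stage, counts in manifest.get("counts", {}).items()]
    if rows:
        pd.DataFrame(rows).to_csv(counts_path, sep="\t", index=False)
        produced.append(counts_path)
    if not produced:
        raise PipelineError(f"no stage outputs found under {outdir}")
    return produced
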