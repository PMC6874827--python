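"""End-to-end orchestration: simulate -> stats -> anchoring -> subgenomes ->
synteny -> Ks clock -> SNP tree -> repeat landscape.

A single flat key-value config (YAML) drives every stage; the global seed
fans out to per-stage seeds by stable hashing of stage names, so adding a
stage never perturbs earlier stages' randomness. Outputs are deterministic
under a fixed config and are listed in a manifest with checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import (
    assembly_stats,
    ks_clock,
    marker_linkage,
    repeat_landscape,
    simulate,
    snp_phylo,
    subgenome,
    synteny,
)
from .errors import ValidationError
from .seq import read_fasta, write_fasta

log = logging.getLogger("oatcompass")

_SIM_FIELDS = {f.name for f in fields(simulate.SimulationConfig)}


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unknown keys are rejected."""

    outdir: str = "compass_out"
    seed: int = 0
    simulate: bool = True
    genome_a: str | None = None  # inputs when simulate=False
    markers: str | None = None
    # per-stage parameters (module defaults)
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig
    node_age_years: float = 44.3e6
    bootstrap: int = 1000
    outgroup: str | None = None
    repeat_window_bp: int = 50_000
    ld_window_bp: int = 500_000
    ld_r2: float = 0.1
    max_het_fraction: float = 0.05
    min_maf: float = 0.1
    ks_bin_width: float = 0.005

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        cfg = cls()
        sim: dict = {}
        for key, value in raw.items():
            if key.startswith("sim."):
                name = key[4:]
                if name not in _SIM_FIELDS:
                    raise ValidationError(f"unknown simulation key {key!r}")
                sim[name] = value
            elif key in known:
                setattr(cfg, key, value)
            else:
                raise ValidationError(f"unknown config key {key!r}")
        cfg.sim = sim
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the global seed."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest {file: sha256} plus stage summaries."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries: dict = {}
    produced: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        produced.append(path)
        return path

    # --- simulate (or load) -------------------------------------------------
    if config.simulate:
        sim_cfg = simulate.SimulationConfig(
            seed=stage_seed(config.seed, "simulate"), **config.sim
        )
        log.info("simulate: seed=%d", sim_cfg.seed)
        bundle = simulate.simulate_truth_set(sim_cfg)
        markers, marker_truth = simulate.simulate_linkage_panel(bundle, sim_cfg)
        paths = simulate.write_bundle(bundle, outdir)
        produced.extend(paths.values())
        mpath = outdir / "linkage_markers.tsv"
        simulate.write_marker_tsv(markers, mpath)
        produced.append(mpath)
        genome_a = bundle.genome_A
    else:
        if not config.genome_a or not Path(config.genome_a).exists():
            raise FileNotFoundError(f"input FASTA not found: {config.genome_a}")
        if not config.markers or not Path(config.markers).exists():
            raise FileNotFoundError(f"marker TSV not found: {config.markers}")
        bundle = None
        sim_cfg = None
        genome_a = read_fasta(config.genome_a)
        markers = simulate.read_marker_tsv(config.markers)

    # --- assembly stats -----------------------------------------------------
    stats = assembly_stats.compute_assembly_stats(genome_a)
    spath = outdir / "assembly_stats.tsv"
    spath.write_text(assembly_stats.stats_report(stats))
    produced.append(spath)
    summaries["assembly"] = {"n50_bp": stats.n50_bp, "l50": stats.l50}

    # --- marker placement, LG assignment, merging ---------------------------
    placements, rejects = marker_linkage.place_markers(markers, genome_a)
    save_df(placements, "placements.tsv")
    save_df(rejects, "placement_rejects.tsv")
    assignment = marker_linkage.assign_linkage_groups(placements, markers)
    save_df(assignment.table, "lg_assignment.tsv")
    plan = marker_linkage.infer_merge_plan(assignment, placements, markers)
    if plan.evidence is not None and not plan.evidence.empty:
        save_df(plan.evidence, "merge_plan.tsv")
    if plan.entries:
        merged = marker_linkage.apply_merge(genome_a, plan)
        mfa = outdir / "merged.fasta"
        write_fasta(mfa, merged)
        produced.append(mfa)
    summaries["anchoring"] = {
        "placed": len(placements),
        "rejected": len(rejects),
        "mismatch": assignment.summary() if len(assignment.table) else {},
    }

    # --- subgenome deconvolution (needs the simulated hexaploid panel) -----
    if config.simulate:
        panel = simulate.simulate_hexaploid_panel(sim_cfg)
        plc_a, _ = marker_linkage.place_markers(panel.markers, panel.bundle.genome_A)
        plc_c, _ = marker_linkage.place_markers(panel.markers, panel.bundle.genome_C)
        mat_a = subgenome.build_contingency(plc_a, panel.markers, "A")
        mat_c = subgenome.build_contingency(plc_c, panel.markers, "C")
        save_df(mat_a.counts.reset_index(), "contingency_A.tsv")
        save_df(mat_c.counts.reset_index(), "contingency_C.tsv")
        assignments = subgenome.call_subgenomes(mat_a, mat_c)
        save_df(assignments.reset_index(), "subgenome_assignments.tsv")
        calls = subgenome.detect_translocations(plc_a, plc_c, panel.markers)
        save_df(
            pd.DataFrame(
                [
                    {
                        "lg": c.lg,
                        "kind": c.kind,
                        "breakpoint_lo_cm": c.breakpoint_interval[0],
                        "breakpoint_hi_cm": c.breakpoint_interval[1],
                        "segment_chromosome": c.segment_2[1],
                        "n_segment_markers": c.n_segment_markers,
                    }
                    for c in calls
                ],
                columns=[
                    "lg",
                    "kind",
                    "breakpoint_lo_cm",
                    "breakpoint_hi_cm",
                    "segment_chromosome",
                    "n_segment_markers",
                ],
            ),
            "translocations.tsv",
        )
        summaries["subgenome"] = {
            "labels": assignments["label"].value_counts().to_dict(),
            "translocations": len(calls),
        }

        # --- synteny orthology ---------------------------------------------
        blocks = simulate.simulate_synteny_blocks(panel.bundle)
        save_df(blocks, "synteny_blocks.tsv")
        ortho_calls, fractions = synteny.call_orthologs(blocks)
        save_df(fractions, "synteny_fractions.tsv")
        save_df(
            pd.DataFrame([c.__dict__ for c in ortho_calls]),
            "ortholog_calls.tsv",
        )
        r2, degenerate = synteny.block_size_correlation(blocks)
        summaries["synteny"] = {
            "orthologs": sum(c.status == "ortholog" for c in ortho_calls),
            "block_size_r2": r2,
            "degenerate": degenerate,
        }

        # --- Ks clock -------------------------------------------------------
        pair_set = simulate.simulate_ks_pairs(sim_cfg)
        ks_vals = pair_set.truth["ks"].dropna().to_numpy()
        save_df(pair_set.truth, "ks_pairs.tsv")
        peak = ks_clock.ks_peak(ks_vals, bin_width=config.ks_bin_width)
        rate = ks_clock.calibrate_rate(peak, config.node_age_years)
        summaries["ks_clock"] = {
            "peak": peak,
            "rate_per_site_per_year": rate,
            "divergence_time_core_rate_years": ks_clock.divergence_time(
                peak, ks_clock.CORE_EUKARYOTE_RATE
            ),
        }

        # --- SNP filtering and phylogeny ------------------------------------
        matrix, truth_tree = simulate.simulate_genotypes(sim_cfg)
        snp_phylo.write_genotype_tsv(matrix, outdir / "genotypes.tsv")
        produced.append(outdir / "genotypes.tsv")
        snp_phylo.write_vcf(matrix, outdir / "genotypes.vcf")
        produced.append(outdir / "genotypes.vcf")
        filtered, report = snp_phylo.filter_sites(
            matrix,
            max_het_fraction=config.max_het_fraction,
            min_maf=config.min_maf,
        )
        save_df(pd.DataFrame([report.__dict__]), "filter_report.tsv")
        pruned, _ = snp_phylo.ld_prune(
            filtered, window_bp=config.ld_window_bp, r2_threshold=config.ld_r2
        )
        outgroup = config.outgroup or matrix.accessions[-1]
        tree = snp_phylo.build_tree(
            pruned,
            outgroup_id=outgroup,
            n_bootstrap=config.bootstrap,
            seed=stage_seed(config.seed, "bootstrap"),
        )
        tpath = outdir / "tree.nwk"
        tpath.write_text(tree.newick + "\n")
        produced.append(tpath)
        (outdir / "truth_tree.nwk").write_text(truth_tree + "\n")
        produced.append(outdir / "truth_tree.nwk")
        summaries["snp_phylo"] = {
            "sites_after_filter": filtered.n_sites,
            "sites_after_prune": pruned.n_sites,
            "min_support": min(tree.supports.values()) if tree.supports else None,
        }

        # --- repeat landscape -----------------------------------------------
        monomers = repeat_landscape.find_tandem_monomers(bundle.genome_A)
        if monomers:
            top = monomers[0]
            write_fasta(
                outdir / "top_monomer.fasta", {"monomer_rank1": top.monomer}
            )
            produced.append(outdir / "top_monomer.fasta")
            cen_tracks = repeat_landscape.density_track(
                bundle.genome_A, top.monomer, window_bp=config.repeat_window_bp
            )
            tel_tracks = repeat_landscape.density_track(
                bundle.genome_A,
                bundle.telomere_monomer,
                window_bp=config.repeat_window_bp,
            )
            for label, tracks in (("cen", cen_tracks), ("tel", tel_tracks)):
                path = outdir / f"{label}_density.bedgraph"
                path.write_text("".join(t.to_bedgraph() for t in tracks))
                produced.append(path)
            cen_calls, tel_report = repeat_landscape.call_centromeres_telomeres(
                cen_tracks, tel_tracks, bundle.chromosome_lengths("A")
            )
            save_df(pd.DataFrame([c.__dict__ for c in cen_calls]), "centromeres.tsv")
            save_df(tel_report, "telomere_report.tsv")
            summaries["repeats"] = {
                "top_monomer_bp": top.length,
                "morphologies": [c.morphology for c in cen_calls],
            }
        ssrs = repeat_landscape.scan_ssrs(bundle.genome_A)
        save_df(pd.DataFrame([s.__dict__ for s in ssrs]), "ssrs.tsv")

    manifest = {
        "seed": config.seed,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(produced))},
        "summaries": summaries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
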