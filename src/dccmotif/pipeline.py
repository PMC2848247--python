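"""End-to-end orchestration: simulate a data bundle, then run
profiling -> binding-region calling -> consensus -> intersection ->
matrix scanning -> density/spacing/sliding statistics -> conservation
test -> codon analysis, writing every intermediate artifact plus a
checksummed manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .intervals import GenomicRegion, complement_regions, total_length
from .profiling import (
    ProfilingConfig,
    call_specific_regions,
    count_kmers,
    profile_target,
)
from .chip import (
    BindingCallConfig,
    ConsensusConfig,
    call_binding_regions,
    consensus_regions,
    overlap_statistics,
)
from .motif import (
    FrequencyMatrix,
    MatrixScanConfig,
    build_frequency_matrix,
    default_matrix,
    scan_sequence,
)
from .density import (
    DensityConfig,
    gene_relative_positions,
    region_centers,
    site_density,
    sliding_density_profile,
    spacing_distribution,
    uniformity_test,
)
from .conservation import (
    ConservationConfig,
    aggregate_counts,
    conservation_hypergeometric_test,
    identity_percentages,
    partition_alignment,
)
from .codons import (
    class_frequency_table,
    compare_class_proportions,
    map_sites_to_codons,
)
from .synthetic import (
    BACKGROUND_CHROM,
    TARGET_CHROM,
    SimulationConfig,
    generate_gene_models,
    generate_genome_pair,
    generate_ortholog_pairs,
    generate_probe_track,
)
from . import io as dio

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "simulate_bundle",
    "run_full_pipeline",
    "intersect_regions",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths plus the per-stage parameter blocks.

    Every default equals the original analysis' value: k=13, R=5, specificity
    cutoff 6.8, probe signal 2, gap 1 kb, consensus min length 1000,
    scan cutoff 0.90, window 500, flank 100.
    """

    genome_fasta: str = ""
    target_id: str = TARGET_CHROM
    background_id: str = BACKGROUND_CHROM
    probe_tracks: list[str] = field(default_factory=list)
    genes_gff: str | None = None
    pairs_fasta: str | None = None
    motif_seqs_fasta: str | None = None
    outdir: str = "results"
    seed: int = 0
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    binding: BindingCallConfig = field(default_factory=BindingCallConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    scan: MatrixScanConfig = field(default_factory=MatrixScanConfig)
    density: DensityConfig = field(default_factory=DensityConfig)
    conservation: ConservationConfig = field(default_factory=ConservationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sub = {
            "profiling": ProfilingConfig,
            "binding": BindingCallConfig,
            "consensus": ConsensusConfig,
            "scan": MatrixScanConfig,
            "density": DensityConfig,
            "conservation": ConservationConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write the full synthetic input bundle.

    Writes genome FASTA (target + background records), truth BEDs,
    probe TSV, gene GFF3 and site+/-flank ortholog alignments; returns
    the path map.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome_pair(config)
    probes = generate_probe_track(genome.regions, config)
    genes = generate_gene_models(
        config.target_length, config.gene_count, config.seed
    )
    pairs = generate_ortholog_pairs(
        [s for s in genome.planted_sites if s.chrom == TARGET_CHROM],
        genome.target,
        flank=100,
        site_rate=config.site_sub_rate,
        flank_rate=config.flank_sub_rate,
        seed=config.seed,
    )
    paths = {
        "genome": out / "genome.fa",
        "regions_truth": out / "regions_truth.bed",
        "sites_truth": out / "sites_truth.bed",
        "probes": out / "probes.tsv",
        "genes": out / "genes.gff3",
        "pairs": out / "pairs.fa",
        "sim_config": out / "sim_config.yaml",
    }
    dio.write_fasta(paths["genome"], genome.sequences())
    dio.write_bed(paths["regions_truth"], genome.regions)
    dio.write_bed(paths["sites_truth"], genome.planted_sites)
    dio.write_probe_tsv(paths["probes"], probes)
    dio.write_gene_models(paths["genes"], genes)
    dio.write_ortholog_pairs(paths["pairs"], pairs)
    with open(paths["sim_config"], "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def intersect_regions(
    x_regions: list[GenomicRegion],
    binding_regions: list[GenomicRegion],
    genome: dict[str, str],
) -> tuple[list[tuple[str, int, GenomicRegion]], list[GenomicRegion]]:
    """Sequences of specific regions that overlap binding regions.

    Returns (deduplicated sequences, overlapping regions): each entry of
    the first list is (sequence, multiplicity, representative region);
    exact duplicate sequences collapse onto their first occurrence.
    """
    overlapping: list[GenomicRegion] = []
    j = 0
    for r in x_regions:
        hit = any(
            b.chrom == r.chrom and b.start < r.end and r.start < b.end
            for b in binding_regions
        )
        if hit:
            overlapping.append(r)
    seen: dict[str, int] = {}
    reps: dict[str, GenomicRegion] = {}
    for r in overlapping:
        seq = genome[r.chrom][r.start : r.end]
        if seq in seen:
            seen[seq] += 1
        else:
            seen[seq] = 1
            reps[seq] = r
    unique = [(seq, mult, reps[seq]) for seq, mult in seen.items()]
    return unique, overlapping


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts + manifest under outdir.

    Returns the manifest (also written as JSON).  Re-running with the
    same inputs and seed produces byte-identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "profiling": asdict(config.profiling),
            "binding": asdict(config.binding),
            "consensus": asdict(config.consensus),
            "scan": asdict(config.scan),
            "density": asdict(config.density),
            "conservation": asdict(config.conservation),
        },
        "inputs": {},
        "artifacts": {},
        "summary": {},
    }

    def record_input(name: str, path: str | None) -> None:
        if path:
            manifest["inputs"][name] = {
                "path": str(path), "sha256": _sha256(Path(path))
            }

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    # ---------------------------------------------------------- inputs
    stage = "load"
    try:
        genome = dio.read_fasta(config.genome_fasta)
        record_input("genome", config.genome_fasta)
        target = genome[config.target_id]
        background = genome.get(config.background_id, "")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------- profiling
    stage = "profiling"
    try:
        if not background:
            raise ValueError("profiling needs a background sequence")
        t1 = count_kmers(target, config.profiling.k, config.profiling.both_strands)
        t2 = count_kmers(
            background, config.profiling.k, config.profiling.both_strands
        )
        profile = profile_target(
            target, t1, t2, config.profiling, target_id=config.target_id
        )
        x_regions = call_specific_regions(profile, config.profiling.threshold)
        p = out / "profile.tsv"
        profile.to_frame().to_csv(p, sep="\t", index=False)
        artifact("profile", p)
        p = out / "x_specific.bed"
        dio.write_bed(p, x_regions)
        artifact("x_specific", p)
        manifest["summary"]["n_x_specific_regions"] = len(x_regions)
        if x_regions:
            manifest["summary"]["mean_x_region_length"] = float(
                np.mean([len(r) for r in x_regions])
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------- region calling
    stage = "call_binding"
    try:
        per_track = []
        for track_path in config.probe_tracks:
            record_input(f"probe_track:{track_path}", track_path)
            probes = dio.read_probe_tsv(track_path)
            per_track.append(call_binding_regions(probes, config.binding))
        binding = per_track[0] if per_track else []
        p = out / "dcc_regions.bed"
        dio.write_bed(p, binding)
        artifact("dcc_regions", p)
        consensus = consensus_regions(per_track, config.consensus) if per_track else []
        p = out / "consensus.bed"
        dio.write_bed(p, consensus)
        artifact("consensus", p)
        manifest["summary"]["n_binding_regions"] = len(binding)
        manifest["summary"]["n_consensus_regions"] = len(consensus)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------- intersect
    stage = "intersect"
    try:
        unique, overlapping = intersect_regions(x_regions, binding, genome)
        p = out / "intersect_overlaps.bed"
        dio.write_bed(p, overlapping)
        artifact("intersect_overlaps", p)
        p = out / "intersect_sequences.fa"
        with open(p, "w") as fh:
            for i, (seq, mult, rep) in enumerate(unique):
                fh.write(
                    f">xr{i + 1:05d} {rep.chrom}:{rep.start}-{rep.end} "
                    f"multiplicity={mult}\n{seq}\n"
                )
        artifact("intersect_sequences", p)
        n_over, n_pos, mean_per, frac = overlap_statistics(x_regions, binding)
        manifest["summary"].update(
            {
                "n_x_regions_in_binding": n_over,
                "n_unique_intersect_sequences": len(unique),
                "fraction_binding_with_x_region": frac,
                "mean_x_regions_per_positive_binding": mean_per,
            }
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---------------------------------------------------------- matrix
    stage = "matrix"
    try:
        if config.motif_seqs_fasta:
            record_input("motif_seqs", config.motif_seqs_fasta)
            seqs = list(dio.read_fasta(config.motif_seqs_fasta).values())
            matrix = build_frequency_matrix(seqs)
        else:
            matrix = default_matrix()
        p = out / "matrix.tsv"
        p.write_text(matrix.to_tsv())
        artifact("matrix", p)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------------ scan
    stage = "scan"
    try:
        sites = scan_sequence(target, matrix, config.scan, chrom=config.target_id)
        bg_sites = (
            scan_sequence(
                background, matrix, config.scan, chrom=config.background_id
            )
            if background
            else []
        )
        p = out / "sites.bed"
        dio.sites_to_bed(p, sites + bg_sites)
        artifact("sites", p)
        manifest["summary"]["n_sites_target"] = len(sites)
        manifest["summary"]["n_sites_background"] = len(bg_sites)
        if sites:
            manifest["summary"]["mean_site_length"] = float(
                np.mean([len(s) for s in sites])
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------------- density
    stage = "density"
    try:
        rows = []
        regions_for_density = consensus or binding
        if regions_for_density:
            d_in, se_in = site_density(sites, regions_for_density, config.density)
            rest = complement_regions(
                regions_for_density, config.target_id, len(target)
            )
            d_out, se_out = site_density(sites, rest, config.density)
            rows.append(("binding_regions", d_in, se_in))
            rows.append(("rest_of_target", d_out, se_out))
            manifest["summary"]["density_binding"] = d_in
            manifest["summary"]["density_rest"] = d_out
        if background:
            whole_bg = [
                GenomicRegion(config.background_id, 0, len(background))
            ]
            d_bg, se_bg = site_density(bg_sites, whole_bg, config.density)
            rows.append(("background", d_bg, se_bg))
            manifest["summary"]["density_background"] = d_bg
        p = out / "density.tsv"
        with open(p, "w") as fh:
            fh.write("partition\tdensity_per_mb\tse\n")
            for name, d, se in rows:
                fh.write(f"{name}\t{d:.6g}\t{se:.6g}\n")
        artifact("density", p)

        spacing = spacing_distribution([s for s in sites])
        p = out / "spacing.tsv"
        with open(p, "w") as fh:
            fh.write("gap\n")
            for g in spacing.gaps:
                fh.write(f"{g}\n")
        artifact("spacing", p)
        manifest["summary"]["median_gap"] = spacing.median
        manifest["summary"]["fraction_gaps_below_1kb"] = spacing.fraction_below

        if regions_for_density:
            anchors = region_centers(regions_for_density)
            profile_sw = sliding_density_profile(
                sites, anchors, config.density,
                chrom_lengths={config.target_id: len(target)},
            )
            p = out / "sliding_profile.tsv"
            with open(p, "w") as fh:
                fh.write("offset\tmean_density\tn_anchors\n")
                for o, m, n in zip(
                    profile_sw.offsets, profile_sw.mean_density,
                    profile_sw.n_anchors,
                ):
                    fh.write(f"{o}\t{m:.6g}\t{n}\n")
            artifact("sliding_profile", p)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -------------------------------------------------- gene positions
    stage = "gene_positions"
    genes = []
    try:
        if config.genes_gff:
            record_input("genes", config.genes_gff)
            genes = dio.read_gene_models(config.genes_gff)
            values = gene_relative_positions(sites, genes)
            p = out / "gene_positions.tsv"
            with open(p, "w") as fh:
                fh.write("relative_position\n")
                for v in values:
                    fh.write(f"{v:.6g}\n")
            artifact("gene_positions", p)
            if len(values) >= 5:
                ks, pval = uniformity_test(values)
                manifest["summary"]["gene_position_ks"] = ks
                manifest["summary"]["gene_position_ks_p"] = pval
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ----------------------------------------------------- conservation
    stage = "conservation"
    try:
        if config.pairs_fasta:
            record_input("pairs", config.pairs_fasta)
            pairs = dio.read_ortholog_pairs(config.pairs_fasta)
            counts = aggregate_counts(partition_alignment(p) for p in pairs)
            site_pct, flank_pct = identity_percentages(counts)
            pval = conservation_hypergeometric_test(counts)
            p = out / "conservation.tsv"
            with open(p, "w") as fh:
                fh.write(
                    "# provenance: homology search thresholds "
                    f"E<={config.conservation.blast_evalue_max:g}, "
                    f"homology>={config.conservation.blast_min_homology}nt\n"
                )
                fh.write("N_total\tK_site\tn_diff\tk_site_diff\t"
                         "site_identity_pct\tflank_identity_pct\tp_value\n")
                fh.write(
                    f"{counts.N_total}\t{counts.K_site}\t{counts.n_diff}\t"
                    f"{counts.k_site_diff}\t{site_pct:.4f}\t{flank_pct:.4f}\t"
                    f"{pval:.6g}\n"
                )
            artifact("conservation", p)
            manifest["summary"]["conservation_p"] = pval
            manifest["summary"]["site_identity_pct"] = site_pct
            manifest["summary"]["flank_identity_pct"] = flank_pct
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ----------------------------------------------------------- codons
    stage = "codons"
    try:
        if genes:
            assignments = map_sites_to_codons(
                sites, genes, genome, binding_regions=regions_for_density
            )
            table = class_frequency_table(assignments)
            p = out / "codon_classes.tsv"
            table.to_csv(p, sep="\t")
            artifact("codon_classes", p)
            focal = "(CG)NG"
            n_in = int(table.loc[focal, "inside"])
            tot_in = int(table["inside"].sum())
            n_out = int(table.loc[focal, "outside"])
            tot_out = int(table["outside"].sum())
            if tot_in and tot_out:
                chi2, pval, _ = compare_class_proportions(
                    (n_in, tot_in), (n_out, tot_out)
                )
                manifest["summary"]["codon_class_chi2"] = chi2
                manifest["summary"]["codon_class_p"] = pval
            manifest["summary"]["n_codon_assignments"] = len(assignments)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --------------------------------------------------------- manifest
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
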