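"""End-to-end orchestration: synthesis -> training -> scanning ->
densities -> composites -> conservation -> association meta-analysis.

Every stage is a pure function of (inputs, config, seed); rerunning with
the same seed reproduces the same report bundle. Stage outputs are
written as plain-text tables (BED/TSV/FASTA/GFF3) plus one machine-
readable ``summary.json`` holding the per-variant tallies, percentages
and influence verdicts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, association, composites, conservation, motiga
from . import opwm as opwm_mod
from . import sequence_core, sitega, synthetic

logger = logging.getLogger(__name__)

CONSENSUS_VARIANTS = ("TGTCTC", "TGTCGG", "TGTSTSBC")

STAGES = (
    "synth", "train", "scan", "regions", "composites", "conserve", "assoc",
)


@dataclass
class PipelineConfig:
    """Run-level constants and generator settings for one pipeline run."""

    seed: int = 1
    outdir: str = "results/pipeline"
    opwm_threshold: float = 0.78
    sitega_threshold: float = 0.936
    alpha: float = 0.05
    fc_threshold: float = 1.5
    min_experiments: int | None = None  # None -> binomial-tail resolution
    min_block_length: int = 101
    region: str = "prox_utr"
    critical_p: float = 0.005
    n_motifs: int = 3
    calibrate_target: float | None = 0.32  # None keeps fixed thresholds
    n_genes: int = 120
    chrom_length: int = 700_000
    gc_content: float = 0.36
    plant_probability: float = 0.6
    plant_pattern: str = "TGTCTC"
    coupling_pattern: str = "TCTCCTYT"
    sitega_ga: dict = field(
        default_factory=lambda: {"population": 60, "generations": 60}
    )
    motiga_ga: dict = field(
        default_factory=lambda: {"population": 60, "generations": 60}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: PipelineConfig, stop_after: str = "assoc") -> dict:
    """Run the pipeline up to ``stop_after`` and write the report bundle.

    Returns the summary dictionary (also written to summary.json when the
    association stage runs).
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    last = STAGES.index(stop_after)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 8)
    summary: dict = {"seed": config.seed, "config": dataclasses.asdict(config)}

    # ----- synth ----------------------------------------------------------
    logger.info("stage synth: seed=%d", seeds[0])
    gen_cfg = synthetic.GeneratorConfig(
        seed=seeds[0],
        n_genes=config.n_genes,
        chrom_length=config.chrom_length,
        gc_content=config.gc_content,
    )
    genome = synthetic.generate_genome(gen_cfg)
    rules = [
        synthetic.PlantingRule(
            pattern=config.plant_pattern,
            motif_id="planted_AuxRE",
            region="promoter_prox",
            probability=config.plant_probability,
            coupling_pattern=config.coupling_pattern,
            coupling_id="planted_coupling",
            coupling_side="5p",
            coupling_spacer_class="short",
        )
    ]
    genome = synthetic.plant_sites(genome, rules, seed=seeds[1])
    alignment, train_truth = synthetic.generate_training_set(
        planted_couplings=[(config.coupling_pattern, "5p", 4)], seed=seeds[2]
    )
    element_truth = genome.truth.genes_with("planted_AuxRE")
    experiments = synthetic.generate_expression_panel(
        genome.genes, element_truth, gen_cfg.expression, seed=seeds[3],
        truth=genome.truth,
    )
    blocks = synthetic.generate_alignment_blocks(
        genome, gen_cfg.conservation, seed=seeds[4]
    )

    records = [
        sequence_core.SequenceRecord(c, s) for c, s in genome.chroms.items()
    ]
    sequence_core.write_fasta(records, out / "genome.fasta")
    (out / "genes.gff3").write_text(annotation.genes_to_gff3(genome.genes))
    (out / "training.fasta").write_text(
        "".join(
            f">site_{i + 1}\n{r}\n" for i, r in enumerate(alignment.records)
        )
    )
    (out / "blocks.tsv").write_text(conservation.blocks_to_tsv(blocks))
    (out / "panel_design.tsv").write_text(
        synthetic.panel_design_tsv(experiments)
    )
    for exp in experiments:
        exp.matrix.round(4).to_csv(out / f"expr_{exp.id}.tsv", sep="\t")
    truth_frame = genome.truth.sites_to_frame()
    truth_frame.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    summary["synth"] = {
        "n_genes": len(genome.genes),
        "genome_length": sum(genome.chrom_lengths.values()),
        "n_planted_sites": len(genome.truth.planted_sites),
        "n_experiments": len(experiments),
        "n_blocks": len(blocks),
    }
    if last < STAGES.index("train"):
        return summary

    # ----- train ----------------------------------------------------------
    logger.info("stage train")
    pwm = opwm_mod.train_opwm(alignment, seed=seeds[5])
    frames = sitega.training_frames(alignment)
    sga = sitega.train_sitega(
        frames, ga_params={**config.sitega_ga, "seed": seeds[6]}
    )
    masked = motiga.mask_core(alignment)
    motifs = motiga.discover_coupling_motifs(
        masked, n_motifs=config.n_motifs,
        ga_params={**config.motiga_ga, "seed": seeds[7]},
    )
    for mat in motifs:
        motiga.assign_motif_hits(mat, masked, config.critical_p)
    t_pwm, t_sga = config.opwm_threshold, config.sitega_threshold
    if config.calibrate_target is not None:
        # emulate the positive-set calibration: promoter regions of the
        # planted genes stand in for the proven auxin-regulated promoters
        positives = []
        spec = annotation.REGION_SPECS["promoter_ext"]
        for g in genome.genes:
            if g.gene_id not in element_truth:
                continue
            _, seq = annotation.extract_region(
                g, spec, genome.chrom_lengths[g.chrom],
                genome.chroms[g.chrom],
            )
            if seq:
                positives.append(
                    sequence_core.SequenceRecord(g.gene_id, seq)
                )
        if positives:
            t_pwm, t_sga = sitega.calibrate_joint_thresholds(
                pwm, sga, positives, config.calibrate_target
            )
    pwm.threshold, sga.threshold = t_pwm, t_sga
    (out / "opwm_model.json").write_text(pwm.to_json())
    (out / "opwm_model.meme").write_text(pwm.to_meme_text())
    (out / "sitega_model.json").write_text(sga.to_json())
    (out / "sitega_model.tsv").write_text(sga.to_tsv())
    for mat in motifs:
        (out / f"{mat.motif_id}.meme").write_text(mat.to_meme_text())
    summary["train"] = {
        "opwm_window_length": pwm.window_length,
        "opwm_threshold": t_pwm,
        "sitega_threshold": t_sga,
        "sitega_n_features": len(sga.features),
        "coupling_motifs": {
            m.motif_id: {"consensus": m.consensus, "kdic": m.kdic}
            for m in motifs
        },
    }
    if last < STAGES.index("scan"):
        return summary

    # ----- scan -----------------------------------------------------------
    logger.info("stage scan")
    hits: dict[str, list] = {v: [] for v in CONSENSUS_VARIANTS}
    hits["AuxRE_P&S"] = []
    for rec in records:
        for variant in CONSENSUS_VARIANTS:
            hits[variant].extend(
                sequence_core.scan_consensus(
                    rec, sequence_core.parse_iupac(variant),
                    model_id=variant,
                )
            )
        hits["AuxRE_P&S"].extend(
            sitega.predict_auxre_ps(rec, pwm, sga, (t_pwm, t_sga))
        )
    coupling_hits: dict[str, list] = {}
    for mat in motifs:
        threshold = mat.score_threshold
        found = []
        for rec in records:
            found.extend(scan_motif_matrix(rec, mat, threshold))
        coupling_hits[mat.motif_id] = found
    for variant, hs in {**hits, **coupling_hits}.items():
        safe = variant.replace("&", "_").replace("/", "_")
        sequence_core.write_bed(hs, out / f"hits_{safe}.bed")
    summary["scan"] = {
        "hit_counts": {v: len(h) for v, h in hits.items()},
        "coupling_hit_counts": {v: len(h) for v, h in coupling_hits.items()},
    }
    if last < STAGES.index("regions"):
        return summary

    # ----- regions / densities / profiles ----------------------------------
    logger.info("stage regions")
    chrom_lengths = genome.chrom_lengths
    partition = annotation.partition_genome(genome.genes, chrom_lengths)
    region_sets = {}
    for name in ("promoter_ext", "promoter_prox", "ext_utr", "prox_utr"):
        spec = annotation.REGION_SPECS[name]
        region_sets[name] = [
            annotation.extract_region(g, spec, chrom_lengths[g.chrom])[0]
            for g in genome.genes
        ]
    density_frames = []
    for variant, hs in hits.items():
        df = annotation.density_and_abundance(hs, partition, region_sets)
        df.insert(0, "variant", variant)
        density_frames.append(df)
    densities = pd.concat(density_frames, ignore_index=True)
    densities.to_csv(out / "densities.tsv", sep="\t", index=False)
    profiles = []
    for variant, hs in hits.items():
        prof = annotation.tss_profile(hs, genome.genes, chrom_lengths,
                                      bin_size=250)
        prof.insert(0, "variant", variant)
        profiles.append(prof)
    pd.concat(profiles, ignore_index=True).to_csv(
        out / "tss_profiles.tsv", sep="\t", index=False
    )
    summary["regions"] = {
        "class_lengths": partition.class_lengths(),
        "genome_length": partition.genome_length,
    }
    if last < STAGES.index("composites"):
        return summary

    # ----- composites -------------------------------------------------------
    logger.info("stage composites")
    gene_by_id = {g.gene_id: g for g in genome.genes}
    analysis_regions = region_sets[config.region]
    variant_gene_sets: dict[str, set[str]] = {}
    for variant, hs in hits.items():
        variant_gene_sets[variant] = {
            r.gene_id
            for r in analysis_regions
            if annotation.hits_in_region(hs, r)
        }
    all_composites = []
    gene_classes = []
    for r in analysis_regions:
        gene = gene_by_id[r.gene_id]
        anchors = composites.orient_hits(
            annotation.hits_in_region(hits["AuxRE_P&S"], r), gene
        )
        gene_classes.append(
            composites.classify_gene_elements(gene.gene_id, anchors)
        )
        for mid, chits in coupling_hits.items():
            coup = composites.orient_hits(
                annotation.hits_in_region(chits, r), gene
            )
            all_composites.extend(
                composites.find_composite_elements(anchors, coup)
            )
    comp_frame = composites.composites_to_frame(all_composites)
    comp_frame.to_csv(out / "composites.tsv", sep="\t", index=False)
    class_frame = pd.DataFrame(
        [vars(c) for c in gene_classes]
    )
    class_frame.to_csv(out / "gene_element_classes.tsv", sep="\t",
                       index=False)
    mult_counts = class_frame["multiplicity"].value_counts().to_dict()
    summary["composites"] = {
        "n_composites": len(all_composites),
        "multiplicity_counts": mult_counts,
        "spacer_class_counts": comp_frame["spacer_class"]
        .value_counts().to_dict() if len(comp_frame) else {},
    }
    if last < STAGES.index("conserve"):
        return summary

    # ----- conservation -----------------------------------------------------
    logger.info("stage conserve")
    filtered = conservation.filter_blocks(blocks, config.min_block_length)
    cons_calls = {}
    for variant, hs in hits.items():
        cons_calls[variant] = [
            conservation.call_site_conservation(h, filtered) for h in hs
        ]
    baseline_genes = conservation.regulatory_conservation_baseline(
        analysis_regions, filtered
    )
    rows = []
    for variant, hs in hits.items():
        for h, c in zip(hs, cons_calls[variant]):
            rows.append(
                {
                    "variant": variant, "chrom": h.seq_id, "start": h.start,
                    "strand": h.strand, "in_block": c.in_block,
                    "conserved": c.conserved,
                }
            )
    pd.DataFrame(rows).to_csv(out / "conservation_calls.tsv", sep="\t",
                              index=False)
    summary["conserve"] = {
        "n_filtered_blocks": len(filtered),
        "baseline_genes_with_conserved_nt": len(baseline_genes),
        "conserved_fraction": {
            v: (
                sum(c.conserved for c in calls) / len(calls)
                if calls else float("nan")
            )
            for v, calls in cons_calls.items()
        },
    }
    if last < STAGES.index("assoc"):
        return summary

    # ----- association ------------------------------------------------------
    logger.info("stage assoc")
    calls = []
    for exp in experiments:
        c = association.call_regulation(
            exp, config.fc_threshold, config.alpha
        )
        calls.append((exp.id, c))
    valid = {eid: association.validate_experiment(c) for eid, c in calls}
    min_exp = config.min_experiments
    if min_exp is None:
        min_exp = association.resolve_min_experiments(
            len(calls), config.alpha
        )
    up_genes, down_genes = association.consensus_regulated_genes(
        [c for _, c in calls], min_exp
    )
    # conserved-variant gene sets for the Table-1-style Y column
    conserved_gene_sets: dict[str, set[str]] = {}
    for variant, hs in hits.items():
        conserved_hits = [
            h
            for h, c in zip(hs, cons_calls[variant])
            if c.conserved
        ]
        conserved_gene_sets[variant] = {
            r.gene_id
            for r in analysis_regions
            if annotation.hits_in_region(conserved_hits, r)
        }
    table1 = {}
    metas = {}
    for variant, gene_set in variant_gene_sets.items():
        Z = len(gene_set)
        X_up = len(gene_set & up_genes)
        Y_up = len(gene_set & up_genes & conserved_gene_sets[variant])
        X_down = len(gene_set & down_genes)
        Y_down = len(gene_set & down_genes & conserved_gene_sets[variant])
        if Z:
            s = association.summarize_association(Z, X_up, Y_up, X_down,
                                                  Y_down)
            table1[variant] = dataclasses.asdict(s)
            meta = association.meta_association(
                gene_set, calls, config.alpha, min_exp, element_id=variant
            )
            metas[variant] = meta
            table1[variant]["n_significant_experiments"] = meta.n_significant
            table1[variant]["influential"] = meta.influential
        else:
            table1[variant] = {"Z": 0}
    assoc_rows = []
    for variant, meta in metas.items():
        for eid, res in zip(meta.experiment_ids, meta.results):
            assoc_rows.append(
                {
                    "variant": variant, "experiment": eid, "p1": res.p1,
                    "p2": res.p2, "n1": res.n1, "n2": res.n2,
                    "z": res.z_statistic, "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
    pd.DataFrame(assoc_rows).to_csv(out / "association_tests.tsv", sep="\t",
                                    index=False)
    (out / "consensus_up.txt").write_text(
        "\n".join(sorted(up_genes)) + "\n" if up_genes else ""
    )
    (out / "consensus_down.txt").write_text(
        "\n".join(sorted(down_genes)) + "\n" if down_genes else ""
    )
    summary["assoc"] = {
        "min_experiments": min_exp,
        "binomial_tail_at_threshold": association.binomial_tail(
            len(calls), min_exp, config.alpha
        ),
        "valid_experiments": valid,
        "n_consensus_up": len(up_genes),
        "n_consensus_down": len(down_genes),
        "table1": table1,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=str))
    return summary


def scan_motif_matrix(record, matrix, min_score: float):
    """All-offset scan of a coupling-motif matrix, both strands."""
    from .sequence_core import SiteHit

    w = matrix.width
    seq = record.seq
    hits = []
    for start in range(len(seq) - w + 1):
        win = seq[start : start + w]
        if "N" in win:
            continue
        if matrix.word_score(win) >= min_score:
            hits.append(
                SiteHit(record.id, start, w, "+", 1.0, matrix.motif_id)
            )
        rc = sequence_core.reverse_complement(win)
        if matrix.word_score(rc) >= min_score:
            hits.append(
                SiteHit(record.id, start, w, "-", 1.0, matrix.motif_id)
            )
    return hits
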