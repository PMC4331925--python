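"""Synthetic inputs with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: a genome with
gene structure (FASTA + GFF3), planted motif instances at controlled
densities/orientations/spacers, a 25 x 106-nt core-centred training set,
a 16-experiment log2 expression panel in which element-carrying genes are
preferentially up-regulated, and multi-species alignment blocks with
controlled core conservation. Every generator is deterministic given the
config seed, and a truth table records exactly what was planted so tests
can round-trip predictions against it.

Defaults mirror the study conditions the analysis was designed for:
25 training sites with 50-nt flanks; sixteen expression experiments (one
single-replicate) with up-regulation effect log2(3) at responder
probability 0.8 vs background 0.05; alignment blocks longer than 100 nt
over a configurable fraction of regulatory regions with per-column
substitution rate mu in non-reference species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import REGION_SPECS, GeneModel, extract_region
from .association import ExpressionExperiment
from .composites import round_half_up
from .conservation import AlignmentBlock
from .opwm import CORE_WIDTH, TrainingAlignment, build_training_alignment
from .sequence_core import IUPAC_CODES, parse_iupac, reverse_complement

LETTERS = "ACGT"


@dataclass
class PlantingRule:
    """Plant one motif instance per gene (with probability) in a region.

    ``orientation_direct_prob`` is the chance the instance lies on the
    gene's coding strand. An optional coupling partner is planted at a
    center-to-center distance drawn from the configured spacer class.
    """

    pattern: str  # IUPAC
    motif_id: str
    region: str = "promoter_prox"
    probability: float = 1.0
    orientation_direct_prob: float = 1.0
    coupling_pattern: str | None = None
    coupling_id: str | None = None
    coupling_side: str = "5p"  # 5p | 3p
    coupling_spacer_class: str = "short"  # overlapped | short | long
    coupling_direct_prob: float = 1.0


@dataclass
class ExpressionRules:
    n_experiments: int = 16
    replicates: int = 3
    baseline_mean: float = 8.0
    baseline_gene_sd: float = 1.0
    noise_sd: float = 0.2
    delta: float = math.log2(3)
    pi: float = 0.8  # responder probability for element-carrying genes
    pi0: float = 0.05  # background responder probability
    n_single_replicate: int = 1


@dataclass
class ConservationRules:
    coverage: float = 0.7  # fraction of regulatory regions with a block
    mu: float = 0.05  # per-column substitution rate per species
    core_protection: bool = True
    n_other_species: int = 4
    region: str = "ext_utr"


@dataclass
class GeneratorConfig:
    seed: int
    n_chroms: int = 1
    chrom_length: int = 200_000
    n_genes: int = 40
    gc_content: float = 0.36
    utr5_range: tuple[int, int] = (30, 300)
    utr3_range: tuple[int, int] = (100, 250)
    cds_exon_range: tuple[int, int] = (100, 300)
    intron_range: tuple[int, int] = (80, 200)
    n_cds_exons_range: tuple[int, int] = (1, 4)
    promoter_margin: int = 2100
    planting_rules: list[PlantingRule] = field(default_factory=list)
    expression: ExpressionRules = field(default_factory=ExpressionRules)
    conservation: ConservationRules = field(default_factory=ConservationRules)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class PlantedSite:
    gene_id: str
    chrom: str
    start: int
    strand: str
    motif_id: str
    pattern: str
    word: str
    role: str = "anchor"  # anchor | coupling
    partner_start: int | None = None
    side: str | None = None
    spacer_class: str | None = None
    center_distance: int | None = None


@dataclass
class TruthTable:
    planted_sites: list[PlantedSite] = field(default_factory=list)
    responders: dict = field(default_factory=dict)  # exp id -> set of genes
    skipped_genes: list[str] = field(default_factory=list)

    def sites_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.planted_sites])

    def genes_with(self, motif_id: str) -> set[str]:
        return {
            s.gene_id for s in self.planted_sites if s.motif_id == motif_id
        }


@dataclass
class SyntheticGenome:
    chroms: dict  # chrom -> sequence string
    genes: list[GeneModel]
    truth: TruthTable

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(
        np.array(list(LETTERS))[rng.choice(4, size=n, p=probs)]
    )


def sample_word(rng: np.random.Generator, pattern: str) -> str:
    """Sample one concrete word matching an IUPAC pattern uniformly."""
    out = []
    for ch in pattern.upper():
        allowed = sorted(IUPAC_CODES[ch])
        out.append(allowed[rng.integers(len(allowed))])
    return "".join(out)


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: GeneratorConfig) -> SyntheticGenome:
    """Background genome + non-overlapping structured genes + GFF3 truth.

    Genes alternate strands randomly; each keeps a promoter margin clear
    so the [-2000;-1] region never crosses a neighbouring gene.
    """
    rng = np.random.default_rng(config.seed)
    chroms = {}
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = list(random_dna(rng, config.chrom_length, config.gc_content))
        pos = config.promoter_margin
        for _ in range(per_chrom[ci]):
            strand = "+" if rng.random() < 0.5 else "-"
            utr5 = int(rng.integers(*config.utr5_range))
            utr3 = int(rng.integers(*config.utr3_range))
            n_cds = int(rng.integers(config.n_cds_exons_range[0],
                                     config.n_cds_exons_range[1] + 1))
            cds_lens = [int(rng.integers(*config.cds_exon_range))
                        for _ in range(n_cds)]
            intron_lens = [int(rng.integers(*config.intron_range))
                           for _ in range(n_cds - 1)]
            glen = utr5 + sum(cds_lens) + sum(intron_lens) + utr3
            if pos + glen + config.promoter_margin > config.chrom_length:
                raise ValueError(
                    f"genes do not fit chromosome {chrom}: increase "
                    f"chrom_length or reduce n_genes"
                )
            # transcript-order segments: 5'UTR, CDS/intron alternation, 3'UTR
            segs = [("utr5", utr5)]
            for k, cl in enumerate(cds_lens):
                segs.append(("cds", cl))
                if k < len(intron_lens):
                    segs.append(("intron", intron_lens[k]))
            segs.append(("utr3", utr3))
            if strand == "-":
                segs = segs[::-1]
            cursor = pos
            utr5_iv = utr3_iv = None
            cds_ivs, intron_ivs = [], []
            for kind, ln in segs:
                iv = (cursor, cursor + ln)
                cursor += ln
                if kind == "utr5":
                    utr5_iv = iv
                elif kind == "utr3":
                    utr3_iv = iv
                elif kind == "cds":
                    cds_ivs.append(iv)
                else:
                    intron_ivs.append(iv)
            gid = f"G{gi + 1:04d}"
            gi += 1
            tss = pos if strand == "+" else pos + glen - 1
            genes.append(
                GeneModel(
                    gene_id=gid, chrom=chrom, strand=strand, start=pos,
                    end=pos + glen, tss=tss, utr5=utr5_iv,
                    cds_exons=tuple(sorted(cds_ivs)),
                    introns=tuple(sorted(intron_ivs)),
                    utr3=utr3_iv,
                )
            )
            pos += glen + config.promoter_margin + int(rng.integers(0, 500))
        chroms[chrom] = "".join(seq)
    return SyntheticGenome(chroms=chroms, genes=genes, truth=TruthTable())


# ---------------------------------------------------------------------------
# site planting


def _write_word(seq: list, start: int, word: str, genomic_strand: str) -> None:
    text = word if genomic_strand == "+" else reverse_complement(word)
    seq[start : start + len(text)] = list(text)


def _spacer_distance(rng: np.random.Generator, cls: str) -> int:
    lo, hi = {"overlapped": (0, 5), "short": (6, 25), "long": (26, 50)}[cls]
    return int(rng.integers(lo, hi + 1))


def _merge_patterns(
    anchor: str, a_start: int, a_strand: str,
    coupling: str, c_start: int, c_strand: str,
) -> dict | None:
    """Per-position allowed sets on the plus strand for both patterns;
    None if the overlap is unsatisfiable."""
    constraint: dict[int, frozenset] = {}

    def add(pattern, start, strand):
        m = parse_iupac(pattern)
        allowed = m.allowed if strand == "+" else tuple(
            frozenset(reverse_complement(c) for c in s)
            for s in m.allowed[::-1]
        )
        for i, s in enumerate(allowed):
            pos = start + i
            cur = constraint.get(pos)
            constraint[pos] = s if cur is None else (cur & s)

    add(anchor, a_start, a_strand)
    add(coupling, c_start, c_strand)
    if any(not s for s in constraint.values()):
        return None
    return constraint


def plant_sites(
    genome: SyntheticGenome,
    rules: list[PlantingRule],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SyntheticGenome:
    """Plant motif instances per the rules, recording truth.

    Independent plantings never overlap one another; an anchor and its
    composite coupling partner may overlap (overlapped spacer class) and
    are then written from the intersection of their IUPAC constraints.
    Genes with no legal offset after 1000 tries are skipped with a truth
    record.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    seqs = {c: list(s) for c, s in genome.chroms.items()}
    occupied: dict[str, set[int]] = {c: set() for c in seqs}

    for rule in rules:
        spec = REGION_SPECS[rule.region]
        w_a = len(rule.pattern)
        for gene in genome.genes:
            if rng.random() >= rule.probability:
                continue
            region, _ = extract_region(
                gene, spec, len(seqs[gene.chrom])
            )
            if len(region) < w_a:
                genome.truth.skipped_genes.append(gene.gene_id)
                continue
            placed = False
            for _ in range(1000):
                a_start = int(rng.integers(region.start,
                                           region.end - w_a + 1))
                direct = rng.random() < rule.orientation_direct_prob
                a_strand = gene.strand if direct else (
                    "-" if gene.strand == "+" else "+"
                )
                span = set(range(a_start, a_start + w_a))
                c_start = None
                if rule.coupling_pattern:
                    w_c = len(rule.coupling_pattern)
                    d = _spacer_distance(rng, rule.coupling_spacer_class)
                    a_center = a_start + (w_a - 1) / 2
                    # side is in transcript orientation
                    sign = -1 if rule.coupling_side == "5p" else +1
                    if gene.strand == "-":
                        sign = -sign
                    c_center = a_center + sign * d
                    c_start = round_half_up(c_center - (w_c - 1) / 2)
                    c_direct = rng.random() < rule.coupling_direct_prob
                    c_strand = gene.strand if c_direct else (
                        "-" if gene.strand == "+" else "+"
                    )
                    if c_start < 0 or c_start + w_c > len(seqs[gene.chrom]):
                        continue
                    span |= set(range(c_start, c_start + w_c))
                if span & occupied[gene.chrom]:
                    continue
                if rule.coupling_pattern:
                    merged = _merge_patterns(
                        rule.pattern, a_start, a_strand,
                        rule.coupling_pattern, c_start, c_strand,
                    )
                    if merged is None:
                        continue
                    for pos, allowed in sorted(merged.items()):
                        choices = sorted(allowed)
                        seqs[gene.chrom][pos] = choices[
                            rng.integers(len(choices))
                        ]
                    a_word = "".join(
                        seqs[gene.chrom][a_start : a_start + w_a]
                    )
                    if a_strand == "-":
                        a_word = reverse_complement(a_word)
                    c_word = "".join(
                        seqs[gene.chrom][c_start : c_start + w_c]
                    )
                    if c_strand == "-":
                        c_word = reverse_complement(c_word)
                    genome.truth.planted_sites.append(
                        PlantedSite(
                            gene.gene_id, gene.chrom, a_start, a_strand,
                            rule.motif_id, rule.pattern, a_word,
                            role="anchor", partner_start=c_start,
                            side=rule.coupling_side,
                            spacer_class=rule.coupling_spacer_class,
                            center_distance=d,
                        )
                    )
                    genome.truth.planted_sites.append(
                        PlantedSite(
                            gene.gene_id, gene.chrom, c_start, c_strand,
                            rule.coupling_id or "coupling",
                            rule.coupling_pattern, c_word, role="coupling",
                            partner_start=a_start, side=rule.coupling_side,
                            spacer_class=rule.coupling_spacer_class,
                            center_distance=d,
                        )
                    )
                else:
                    word = sample_word(rng, rule.pattern)
                    _write_word(seqs[gene.chrom], a_start, word, a_strand)
                    genome.truth.planted_sites.append(
                        PlantedSite(
                            gene.gene_id, gene.chrom, a_start, a_strand,
                            rule.motif_id, rule.pattern, word,
                        )
                    )
                occupied[gene.chrom] |= span
                placed = True
                break
            if not placed:
                genome.truth.skipped_genes.append(gene.gene_id)
    genome.chroms = {c: "".join(s) for c, s in seqs.items()}
    return genome


# ---------------------------------------------------------------------------
# training set


def generate_training_set(
    n: int = 25,
    flank: int = 50,
    gc: float = 0.36,
    planted_couplings: list[tuple[str, str, int]] | None = None,
    seed: int = 0,
) -> tuple[TrainingAlignment, list[dict]]:
    """Core-centred 106-nt training records with optional planted flanking
    octamers.

    ``planted_couplings`` entries are (pattern, side, offset) with offset
    = distance in nt from the core edge to the instance start on that
    flank (5p offsets count back from the core start). Returns the
    alignment and a per-record truth list of planted instance offsets.
    """
    rng = np.random.default_rng(seed)
    sites = []
    truth = []
    for _ in range(n):
        core = "TGTC" + sample_word(rng, "NN")
        left = random_dna(rng, flank + 10, gc)
        right = random_dna(rng, flank + 10, gc)
        seq = left + core + right
        core_start = len(left)
        rec_truth = {}
        if planted_couplings:
            for pattern, side, offset in planted_couplings:
                word = sample_word(rng, pattern)
                if side == "5p":
                    start = core_start - offset - len(word)
                else:
                    start = core_start + CORE_WIDTH + offset
                seq = seq[:start] + word + seq[start + len(word) :]
                # offset within the final 2*flank+6 record
                rec_truth[pattern] = start - (core_start - flank)
        sites.append((seq, core_start))
        truth.append(rec_truth)
    return build_training_alignment(sites, flank=flank), truth


# ---------------------------------------------------------------------------
# expression panel


def generate_expression_panel(
    genes: list,  # GeneModel objects or bare gene-id strings
    element_genes: set[str],
    rules: ExpressionRules,
    seed: int = 0,
    truth: TruthTable | None = None,
) -> list[ExpressionExperiment]:
    """Log2 expression panel with element-linked up-regulation.

    Element-carrying genes respond (treatment arm shifted by +delta)
    with probability pi per experiment, all others with probability pi0.
    The last ``n_single_replicate`` experiments have one sample per arm.
    """
    if rules.replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id if hasattr(g, "gene_id") else str(g) for g in genes]
    experiments = []
    for e in range(rules.n_experiments):
        exp_id = f"EXP{e + 1:02d}"
        single = e >= rules.n_experiments - rules.n_single_replicate
        reps = 1 if single else rules.replicates
        baseline = rng.normal(rules.baseline_mean, rules.baseline_gene_sd,
                              size=len(gene_ids))
        is_element = np.array([g in element_genes for g in gene_ids])
        u = rng.random(len(gene_ids))
        responder = np.where(is_element, u < rules.pi, u < rules.pi0)
        treat = baseline[:, None] + rng.normal(
            0, rules.noise_sd, size=(len(gene_ids), reps)
        )
        treat[responder] += rules.delta
        ctrl = baseline[:, None] + rng.normal(
            0, rules.noise_sd, size=(len(gene_ids), reps)
        )
        t_ids = [f"{exp_id}_T{k + 1}" for k in range(reps)]
        c_ids = [f"{exp_id}_C{k + 1}" for k in range(reps)]
        mat = pd.DataFrame(
            np.hstack([treat, ctrl]), index=gene_ids, columns=t_ids + c_ids
        )
        experiments.append(
            ExpressionExperiment(
                id=exp_id, matrix=mat, treatment=t_ids, control=c_ids,
                replicated=not single,
            )
        )
        if truth is not None:
            truth.responders[exp_id] = {
                g for g, r in zip(gene_ids, responder) if r
            }
    return experiments


def panel_design_tsv(experiments: list[ExpressionExperiment]) -> str:
    lines = ["sample_id\texperiment_id\tarm"]
    for exp in experiments:
        for s in exp.treatment:
            lines.append(f"{s}\t{exp.id}\ttreatment")
        for s in exp.control:
            lines.append(f"{s}\t{exp.id}\tcontrol")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# alignment blocks


def generate_alignment_blocks(
    genome: SyntheticGenome,
    rules: ConservationRules,
    seed: int = 0,
) -> list[AlignmentBlock]:
    """Blocks over a fraction of regulatory regions, mutated per species.

    Each covered gene's region becomes one gap-free block; non-reference
    rows are substituted i.i.d. at rate mu except (with core protection)
    at the TGTC core columns of planted sites, which stay identical.
    """
    rng = np.random.default_rng(seed)
    spec = REGION_SPECS[rules.region]
    protected: dict[str, set[int]] = {c: set() for c in genome.chroms}
    if rules.core_protection:
        for s in genome.truth.planted_sites:
            # TGTC core: first 4 site-orientation bases
            if s.strand == "+":
                core = range(s.start, s.start + 4)
            else:
                core = range(s.start + len(s.word) - 4,
                             s.start + len(s.word))
            protected[s.chrom].update(core)
    blocks = []
    species = ["ref"] + [f"sp{k + 1}" for k in range(rules.n_other_species)]
    for gene in genome.genes:
        if rng.random() >= rules.coverage:
            continue
        region, _ = extract_region(
            gene, spec, len(genome.chroms[gene.chrom])
        )
        if len(region) < 101:
            continue
        ref_row = genome.chroms[gene.chrom][region.start : region.end]
        rows = {"ref": ref_row}
        for sp in species[1:]:
            chars = list(ref_row)
            for i in range(len(chars)):
                gpos = region.start + i
                if gpos in protected[gene.chrom]:
                    continue
                if rng.random() < rules.mu:
                    alternatives = [c for c in LETTERS if c != chars[i]]
                    chars[i] = alternatives[rng.integers(3)]
            rows[sp] = "".join(chars)
        blocks.append(
            AlignmentBlock(
                chrom=gene.chrom, start=region.start, end=region.end,
                species=tuple(species), rows=rows,
            )
        )
    return blocks
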