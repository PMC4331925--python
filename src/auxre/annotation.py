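"""Gene models, TSS-relative regulatory regions, genome partition and
site-density statistics.

Internally every interval is 0-based half-open on the plus strand; GFF3
input (1-based closed) is converted on load. Region bounds follow the
biology-style closed TSS-relative convention without a position 0: -1 is
the base immediately 5' of the TSS and +1 is the TSS base itself, so
[-300;+1] spans 301 bases. The named regions used throughout the analysis:

    promoter_ext   [-2000;-1]      extended promoter
    promoter_prox  [-300;+1]       proximal promoter
    ext_utr        [-1500;5'UTR]   extended regulatory region
    prox_utr       [-300;5'UTR]    proximal regulatory region
    tss_window     [-2000;+250]    TSS profiling window

Regions whose end is "5'UTR" run to the last base of the annotated 5'UTR;
genes without one use the TSS base as the end. Promoters are not truncated
at neighbouring genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_core import SiteHit, reverse_complement

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """One gene with its representative transcript structure.

    ``tss`` is the 0-based genomic position of the 5'-most transcribed
    base. Intervals are genomic 0-based half-open, ordered by genomic
    coordinate.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    utr5: Interval | None = None
    cds_exons: tuple[Interval, ...] = ()
    introns: tuple[Interval, ...] = ()
    utr3: Interval | None = None


@dataclass(frozen=True)
class RegionSpec:
    """A TSS-relative region; ``hi`` is an int or the string '5utr'."""

    name: str
    lo: int
    hi: object  # int | "5utr"


REGION_SPECS = {
    "promoter_ext": RegionSpec("promoter_ext", -2000, -1),
    "promoter_prox": RegionSpec("promoter_prox", -300, +1),
    "ext_utr": RegionSpec("ext_utr", -1500, "5utr"),
    "prox_utr": RegionSpec("prox_utr", -300, "5utr"),
    "tss_window": RegionSpec("tss_window", -2000, +250),
}


@dataclass(frozen=True)
class Region:
    """A genomic interval attributed to a gene, oriented with the gene."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    name: str

    def __len__(self) -> int:
        return max(0, self.end - self.start)


def _rel_offset(x: int) -> int:
    """Offset from the TSS base for a biology-style coordinate (no 0)."""
    if x == 0:
        raise ValueError("TSS-relative position 0 does not exist")
    return x - 1 if x > 0 else x


def extract_region(
    gene: GeneModel,
    spec: RegionSpec,
    chrom_length: int,
    chrom_seq: str | None = None,
) -> tuple[Region, str | None]:
    """Map a TSS-relative spec to genomic coordinates, strand-aware.

    Returns the (possibly chromosome-edge-truncated, possibly empty)
    region and, when ``chrom_seq`` is given, its sequence 5'->3' of the
    gene.
    """
    lo_off = _rel_offset(spec.lo)
    if spec.hi == "5utr":
        if gene.strand == "+":
            end3 = gene.utr5[1] if gene.utr5 else gene.tss + 1
        else:
            end3 = gene.utr5[0] if gene.utr5 else gene.tss
    else:
        hi_off = _rel_offset(int(spec.hi))
        end3 = None
    if gene.strand == "+":
        g_start = gene.tss + lo_off
        g_end = end3 if end3 is not None else gene.tss + hi_off + 1
    else:
        g_end = gene.tss - lo_off + 1
        g_start = end3 if end3 is not None else gene.tss - hi_off
    g_start = max(0, g_start)
    g_end = min(chrom_length, g_end)
    if g_end < g_start:
        g_end = g_start
    region = Region(gene.chrom, g_start, g_end, gene.strand, gene.gene_id,
                    spec.name)
    seq = None
    if chrom_seq is not None:
        seq = chrom_seq[g_start:g_end]
        if gene.strand == "-":
            seq = reverse_complement(seq)
    return region, seq


# ---------------------------------------------------------------------------
# GFF3 I/O


def load_genome_annotation(fasta_path, gff3_path) -> list[GeneModel]:
    """Load gene models from FASTA + GFF3 via gffutils.

    The representative transcript is the one with the 5'-most TSS.
    Transcripts without exons are skipped with a warning; coordinates
    outside the chromosome raise.
    """
    import gffutils

    from .sequence_core import read_fasta

    chrom_lengths = {r.id: len(r) for r in read_fasta(fasta_path)}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.seqid not in chrom_lengths:
            raise ValueError(f"gene {g.id} on unknown chromosome {g.seqid}")
        if g.end > chrom_lengths[g.seqid] or g.start < 1:
            raise ValueError(f"gene {g.id} outside chromosome bounds")
        transcripts = list(db.children(g, featuretype="mRNA"))
        if not transcripts:
            transcripts = [g]  # gene acts as its own transcript container
        best = None
        for t in transcripts:
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
            )
            if not exons:
                warnings.warn(f"transcript {t.id} has no exons; skipped")
                continue
            tss = exons[0][0] if g.strand == "+" else exons[-1][1] - 1
            key = tss if g.strand == "+" else -tss
            if best is None or key < best[0]:
                best = (key, t, exons, tss)
        if best is None:
            warnings.warn(f"gene {g.id} has no usable transcript; skipped")
            continue
        _, t, exons, tss = best
        utr5s = sorted(
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="five_prime_UTR")
        )
        utr3s = sorted(
            (f.start - 1, f.end)
            for f in db.children(t, featuretype="three_prime_UTR")
        )
        cds = tuple(
            sorted((f.start - 1, f.end) for f in db.children(t, featuretype="CDS"))
        )
        introns = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=exons[0][0],
                end=exons[-1][1],
                tss=tss,
                utr5=(utr5s[0][0], utr5s[-1][1]) if utr5s else None,
                cds_exons=cds,
                introns=introns,
                utr3=(utr3s[0][0], utr3s[-1][1]) if utr3s else None,
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.start))
    return genes


def genes_to_gff3(genes: Sequence[GeneModel]) -> str:
    """Emit gene models as GFF3 (single representative mRNA per gene)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.chrom}\tauxre\tgene\t{g.start + 1}\t{g.end}\t.\t"
            f"{g.strand}\t.\t{attrs}"
        )
        mrna_id = f"{g.gene_id}.1"
        lines.append(
            f"{g.chrom}\tauxre\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
            f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}"
        )
        # exons = gene span minus introns
        exons = []
        pos = g.start
        for ist, ien in g.introns:
            exons.append((pos, ist))
            pos = ien
        exons.append((pos, g.end))
        for i, (s, e) in enumerate(exons, 1):
            lines.append(
                f"{g.chrom}\tauxre\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id}.exon{i};Parent={mrna_id}"
            )
        if g.utr5:
            lines.append(
                f"{g.chrom}\tauxre\tfive_prime_UTR\t{g.utr5[0] + 1}\t"
                f"{g.utr5[1]}\t.\t{g.strand}\t.\tID={mrna_id}.utr5;"
                f"Parent={mrna_id}"
            )
        for i, (s, e) in enumerate(g.cds_exons, 1):
            lines.append(
                f"{g.chrom}\tauxre\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={mrna_id}.cds{i};Parent={mrna_id}"
            )
        if g.utr3:
            lines.append(
                f"{g.chrom}\tauxre\tthree_prime_UTR\t{g.utr3[0] + 1}\t"
                f"{g.utr3[1]}\t.\t{g.strand}\t.\tID={mrna_id}.utr3;"
                f"Parent={mrna_id}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genome partition and densities

CLASS_INTERGENIC = 0
CLASS_UTR5 = 1
CLASS_UTR3 = 2
CLASS_CDS = 3
CLASS_INTRON = 4
CLASS_NAMES = {
    CLASS_INTERGENIC: "intergenic",
    CLASS_UTR5: "five_prime_UTR",
    CLASS_UTR3: "three_prime_UTR",
    CLASS_CDS: "cds_exon",
    CLASS_INTRON: "intron",
}


@dataclass
class GenomePartition:
    """Every genomic position assigned to exactly one feature class."""

    arrays: dict  # chrom -> np.int8 array

    def class_lengths(self) -> dict[str, int]:
        out = {name: 0 for name in CLASS_NAMES.values()}
        for arr in self.arrays.values():
            counts = np.bincount(arr, minlength=5)
            for code, name in CLASS_NAMES.items():
                out[name] += int(counts[code])
        return out

    @property
    def genome_length(self) -> int:
        return sum(len(a) for a in self.arrays.values())

    def class_at(self, chrom: str, pos: int) -> str:
        return CLASS_NAMES[int(self.arrays[chrom][pos])]


def partition_genome(
    genes: Sequence[GeneModel], chrom_lengths: dict[str, int]
) -> GenomePartition:
    """Assign every position a single class with priority
    5'UTR > 3'UTR > CDS exon > intron > intergenic."""
    arrays = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_lengths.items()}
    # paint in increasing priority so higher classes overwrite
    for g in genes:
        arr = arrays[g.chrom]
        for s, e in g.introns:
            arr[s:e] = CLASS_INTRON
    for g in genes:
        arr = arrays[g.chrom]
        for s, e in g.cds_exons:
            arr[s:e] = CLASS_CDS
    for g in genes:
        if g.utr3:
            arrays[g.chrom][g.utr3[0] : g.utr3[1]] = CLASS_UTR3
    for g in genes:
        if g.utr5:
            arrays[g.chrom][g.utr5[0] : g.utr5[1]] = CLASS_UTR5
    return GenomePartition(arrays)


def hit_center_position(hit: SiteHit) -> int:
    """Integer genomic position of a hit's core center (round half-up)."""
    return int(math.floor(hit.center + 0.5))


def _merge_intervals(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def density_and_abundance(
    hits: Sequence[SiteHit],
    partition: GenomePartition,
    regions: dict[str, Sequence[Region]] | None = None,
) -> pd.DataFrame:
    """Site density per feature class (and optional named region sets).

    density = hits / tested positions; abundance = density / genome
    density, so the whole-genome abundance is exactly 1. Both strands'
    hits share one tested-position universe.
    """
    rows = []
    genome_hits = len(hits)
    genome_positions = partition.genome_length
    genome_density = genome_hits / genome_positions if genome_positions else 0.0

    class_hits = {name: 0 for name in CLASS_NAMES.values()}
    for h in hits:
        pos = hit_center_position(h)
        if h.seq_id in partition.arrays and 0 <= pos < len(
            partition.arrays[h.seq_id]
        ):
            class_hits[partition.class_at(h.seq_id, pos)] += 1
    lengths = partition.class_lengths()
    rows.append(
        {
            "region_class": "genome",
            "hits": genome_hits,
            "positions": genome_positions,
            "density": genome_density,
            "abundance": 1.0 if genome_density else float("nan"),
        }
    )
    for name in CLASS_NAMES.values():
        n = lengths[name]
        if n == 0:
            warnings.warn(f"class {name} has zero tested positions; omitted")
            continue
        d = class_hits[name] / n
        rows.append(
            {
                "region_class": name,
                "hits": class_hits[name],
                "positions": n,
                "density": d,
                "abundance": d / genome_density if genome_density else
                float("nan"),
            }
        )
    if regions:
        for rname, regs in regions.items():
            by_chrom: dict[str, list[Interval]] = {}
            for r in regs:
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            merged = {c: _merge_intervals(v) for c, v in by_chrom.items()}
            npos = sum(e - s for v in merged.values() for s, e in v)
            if npos == 0:
                warnings.warn(f"region set {rname} empty; omitted")
                continue
            count = 0
            starts = {
                c: np.array([s for s, _ in v]) for c, v in merged.items()
            }
            ends = {c: np.array([e for _, e in v]) for c, v in merged.items()}
            for h in hits:
                if h.seq_id not in merged:
                    continue
                pos = hit_center_position(h)
                i = np.searchsorted(starts[h.seq_id], pos, side="right") - 1
                if i >= 0 and pos < ends[h.seq_id][i]:
                    count += 1
            d = count / npos
            rows.append(
                {
                    "region_class": rname,
                    "hits": count,
                    "positions": npos,
                    "density": d,
                    "abundance": d / genome_density if genome_density else
                    float("nan"),
                }
            )
    return pd.DataFrame(rows)


def tss_profile(
    hits: Sequence[SiteHit],
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    window: tuple[int, int] = (-2000, 250),
    bin_size: int = 50,
) -> pd.DataFrame:
    """TSS-relative hit density per bin, normalised by genome density.

    Each hit's core center is mapped to a TSS-relative coordinate for
    every gene whose window covers it (strand-aware; a hit may count for
    several genes). Uniform random hits give a flat profile of ~1.
    """
    lo_off = _rel_offset(window[0])
    hi_off = _rel_offset(window[1])
    span = hi_off - lo_off + 1
    if span % bin_size:
        raise ValueError("bin size must divide the window length")
    nbins = span // bin_size
    counts = np.zeros(nbins)

    centers: dict[str, np.ndarray] = {}
    for c in chrom_lengths:
        cc = sorted(hit_center_position(h) for h in hits if h.seq_id == c)
        centers[c] = np.array(cc, dtype=int)
    for g in genes:
        cc = centers.get(g.chrom)
        if cc is None or cc.size == 0:
            continue
        if g.strand == "+":
            glo, ghi = g.tss + lo_off, g.tss + hi_off
        else:
            glo, ghi = g.tss - hi_off, g.tss - lo_off
        i0 = np.searchsorted(cc, glo, side="left")
        i1 = np.searchsorted(cc, ghi, side="right")
        for pos in cc[i0:i1]:
            rel = pos - g.tss if g.strand == "+" else g.tss - pos
            counts[(rel - lo_off) // bin_size] += 1

    genome_len = sum(chrom_lengths.values())
    genome_density = len(hits) / genome_len if genome_len else 0.0
    bin_density = counts / (bin_size * max(len(genes), 1))
    norm = bin_density / genome_density if genome_density else bin_density
    return pd.DataFrame(
        {
            "bin_start": [lo_off + i * bin_size for i in range(nbins)],
            "bin_end": [lo_off + (i + 1) * bin_size for i in range(nbins)],
            "hits": counts.astype(int),
            "normalized_density": norm,
        }
    )


def hits_in_region(hits: Iterable[SiteHit], region: Region) -> list[SiteHit]:
    """Hits whose core center lies inside the region."""
    return [
        h
        for h in hits
        if h.seq_id == region.chrom
        and region.start <= hit_center_position(h) < region.end
    ]
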