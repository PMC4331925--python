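"""Phylogenetic footprinting: conserved alignment blocks and TGTC cores.

Only continuous alignment fragments longer than 100 nt that include all
required species enter the analysis. A site counts as conserved when its
4-nt TGTC core (strand-aware) lies entirely inside one filtered block and
every species' aligned characters at the core columns are identical to
the reference — a gap or substitution at any core column breaks the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotation import Region
from .sequence_core import SiteHit

CORE_LEN = 4  # the TGTC core of the TGTCNN hexamer


@dataclass
class AlignmentBlock:
    """One multi-species alignment block anchored on the reference genome.

    ``rows`` maps species name to its gapped row; the first entry of
    ``species`` is the reference, whose degapped row spans
    [start, end) on ``chrom``.
    """

    chrom: str
    start: int
    end: int
    species: tuple[str, ...]
    rows: dict

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("aligned rows differ in length")
        ref = self.rows[self.species[0]]
        if len(ref.replace("-", "")) != self.end - self.start:
            raise ValueError(
                "reference row degapped length does not match interval"
            )

    @property
    def ref_species(self) -> str:
        return self.species[0]

    def columns_for(self, ref_positions: range) -> list[int]:
        """Alignment columns corresponding to reference genomic positions."""
        ref = self.rows[self.ref_species]
        cols = []
        pos = self.start
        for col, ch in enumerate(ref):
            if ch == "-":
                continue
            if pos in ref_positions:
                cols.append(col)
            pos += 1
            if pos >= ref_positions.stop:
                break
        return cols


@dataclass(frozen=True)
class ConservationCall:
    in_block: bool
    core_conserved: bool

    @property
    def conserved(self) -> bool:
        return self.in_block and self.core_conserved


def filter_blocks(
    blocks: Sequence[AlignmentBlock],
    min_length: int = 101,
    required_species: Sequence[str] | None = None,
) -> list[AlignmentBlock]:
    """Keep blocks spanning >= min_length reference nt with all species."""
    out = []
    for b in blocks:
        if b.end - b.start < min_length:
            continue
        if required_species and not set(required_species) <= set(b.species):
            continue
        out.append(b)
    return out


def core_interval(site: SiteHit) -> tuple[int, int]:
    """Plus-strand interval of the 4-nt TGTC core of a TGTCNN site.

    For a '-' strand site the core occupies the last 4 plus-strand bases
    of the 6-nt window.
    """
    if site.strand == "+":
        return site.start, site.start + CORE_LEN
    return site.start + site.width - CORE_LEN, site.start + site.width


def call_site_conservation(
    site: SiteHit, blocks: Sequence[AlignmentBlock]
) -> ConservationCall:
    """Conservation call for one site against filtered blocks.

    in_block requires the whole core inside a single block; a site
    spanning two blocks is not in_block.
    """
    lo, hi = core_interval(site)
    block = None
    for b in blocks:
        if b.chrom == site.seq_id and b.start <= lo and hi <= b.end:
            block = b
            break
    if block is None:
        return ConservationCall(False, False)
    cols = block.columns_for(range(lo, hi))
    ref = block.rows[block.ref_species]
    for col in cols:
        ref_ch = ref[col].upper()
        for sp in block.species[1:]:
            ch = block.rows[sp][col].upper()
            if ch == "-" or ch != ref_ch:
                return ConservationCall(True, False)
    return ConservationCall(True, True)


def regulatory_conservation_baseline(
    regions: Sequence[Region], blocks: Sequence[AlignmentBlock]
) -> set[str]:
    """Genes whose regulatory region overlaps any filtered block >= 1 nt."""
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = set()
    for r in regions:
        for b in by_chrom.get(r.chrom, ()):
            if r.start < b.end and b.start < r.end:
                out.add(r.gene_id)
                break
    return out


# ---------------------------------------------------------------------------
# I/O: simple block TSV and MAF


def blocks_to_tsv(blocks: Sequence[AlignmentBlock]) -> str:
    """block_id, chrom, start, end, species, gapped row — one row per line."""
    lines = ["block\tchrom\tstart\tend\tspecies\trow"]
    for i, b in enumerate(blocks):
        for sp in b.species:
            lines.append(
                f"{i}\t{b.chrom}\t{b.start}\t{b.end}\t{sp}\t{b.rows[sp]}"
            )
    return "\n".join(lines) + "\n"


def blocks_from_tsv(text: str) -> list[AlignmentBlock]:
    groups: dict[str, list] = {}
    order: list[str] = []
    for line in text.strip().splitlines()[1:]:
        bid, chrom, start, end, sp, row = line.split("\t")
        if bid not in groups:
            groups[bid] = []
            order.append(bid)
        groups[bid].append((chrom, int(start), int(end), sp, row))
    blocks = []
    for bid in order:
        rows = groups[bid]
        chrom, start, end = rows[0][0], rows[0][1], rows[0][2]
        species = tuple(r[3] for r in rows)
        blocks.append(
            AlignmentBlock(
                chrom=chrom, start=start, end=end, species=species,
                rows={r[3]: r[4] for r in rows},
            )
        )
    return blocks


def read_maf(path, reference: str | None = None) -> list[AlignmentBlock]:
    """Read MAF alignment blocks (reference = first row unless named)."""
    from Bio import AlignIO

    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = {}
        species = []
        meta = {}
        for rec in aln:
            rows[rec.id] = str(rec.seq)
            species.append(rec.id)
            meta[rec.id] = rec.annotations
        ref = reference if reference in rows else species[0]
        species = [ref] + [s for s in species if s != ref]
        ann = meta[ref]
        start = int(ann.get("start", 0))
        size = int(ann.get("size", len(rows[ref].replace("-", ""))))
        blocks.append(
            AlignmentBlock(
                chrom=ref.split(".", 1)[-1] if "." in ref else ref,
                start=start,
                end=start + size,
                species=tuple(species),
                rows=rows,
            )
        )
    return blocks
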