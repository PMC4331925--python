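"""Composite AuxRE elements: orientation, multiplicity and spacer classes.

A composite element is an anchor AuxRE plus a coupling motif (Y-patch,
ABRE-like or AuxRE-like) within 50 nt center-to-center. The spacer class
follows the center distance d (rounded half-up to integer nt):
overlapped d <= 5, short 6 <= d <= 25, long 26 <= d <= 50. The coupling
motif's side is 5' when its center lies upstream of the anchor center in
transcript orientation (ties break to 5'). Orientation of a hit is
"direct" (+) when it lies on the gene's coding strand, "reverse" (-)
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotation import GeneModel
from .sequence_core import SiteHit

SPACER_OVERLAPPED_MAX = 5
SPACER_SHORT_MAX = 25
SPACER_LONG_MAX = 50


@dataclass(frozen=True)
class OrientedHit:
    """A site hit expressed in the gene's transcript orientation."""

    hit: SiteHit
    gene_id: str
    orientation: str  # '+' direct, '-' reverse
    center: float  # TSS-relative, transcript orientation (nt)


@dataclass(frozen=True)
class GeneElementClass:
    gene_id: str
    multiplicity: str  # none | single | multiple
    orientation_class: str | None  # '+' | '-' | 'mixed' | None


@dataclass(frozen=True)
class CompositeHit:
    anchor: OrientedHit
    coupling: OrientedHit
    side: str  # 5p | 3p
    center_distance: int
    spacer_class: str  # overlapped | short | long
    orientation_pair: tuple[str, str]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def orient_hits(hits: Sequence[SiteHit], gene: GeneModel) -> list[OrientedHit]:
    """Attach gene-relative orientation and center to each hit.

    The center coordinate is measured from the TSS along the transcript
    (positive downstream), so mirroring a whole locus leaves orientations
    and centers invariant.
    """
    out = []
    for h in hits:
        orientation = "+" if h.strand == gene.strand else "-"
        rel = h.center - gene.tss if gene.strand == "+" else gene.tss - h.center
        out.append(OrientedHit(h, gene.gene_id, orientation, rel))
    return out


def classify_gene_elements(
    gene_id: str, oriented: Sequence[OrientedHit]
) -> GeneElementClass:
    """Single/multiple and all-direct/all-reverse/mixed classification."""
    if not oriented:
        return GeneElementClass(gene_id, "none", None)
    orientations = {oh.orientation for oh in oriented}
    ocl = orientations.pop() if len(orientations) == 1 else "mixed"
    mult = "single" if len(oriented) == 1 else "multiple"
    return GeneElementClass(gene_id, mult, ocl)


def spacer_class(distance: int) -> str | None:
    """Spacer class for an integer center distance; None beyond 50 nt."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance <= SPACER_OVERLAPPED_MAX:
        return "overlapped"
    if distance <= SPACER_SHORT_MAX:
        return "short"
    if distance <= SPACER_LONG_MAX:
        return "long"
    return None


def find_composite_elements(
    anchors: Sequence[OrientedHit],
    couplings: Sequence[OrientedHit],
    max_distance: int = SPACER_LONG_MAX,
) -> list[CompositeHit]:
    """All (anchor, coupling) pairs within ``max_distance`` nt of centers.

    Every qualifying pair is emitted exactly once; a coupling hit may
    pair with several anchors. Coincident centers class as overlapped
    with side 5' by tie-break.
    """
    out = []
    for a in anchors:
        for c in couplings:
            delta = c.center - a.center
            d = round_half_up(abs(delta))
            if d > max_distance:
                continue
            cls = spacer_class(d)
            if cls is None:
                continue
            side = "5p" if delta <= 0 else "3p"
            out.append(
                CompositeHit(
                    anchor=a,
                    coupling=c,
                    side=side,
                    center_distance=d,
                    spacer_class=cls,
                    orientation_pair=(a.orientation, c.orientation),
                )
            )
    return out


def composites_to_frame(composites: Sequence[CompositeHit]) -> pd.DataFrame:
    rows = []
    for ce in composites:
        rows.append(
            {
                "gene_id": ce.anchor.gene_id,
                "anchor_start": ce.anchor.hit.start,
                "anchor_strand": ce.anchor.hit.strand,
                "anchor_orientation": ce.anchor.orientation,
                "coupling_id": ce.coupling.hit.model_id,
                "coupling_start": ce.coupling.hit.start,
                "coupling_strand": ce.coupling.hit.strand,
                "coupling_orientation": ce.coupling.orientation,
                "side": ce.side,
                "center_distance": ce.center_distance,
                "spacer_class": ce.spacer_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "anchor_start", "anchor_strand", "anchor_orientation",
            "coupling_id", "coupling_start", "coupling_strand",
            "coupling_orientation", "side", "center_distance", "spacer_class",
        ],
    )
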