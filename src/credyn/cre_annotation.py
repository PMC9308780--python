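"""Assign peaks to genes and lineages by nearest TSS within 50 kb.

Distance is measured from the peak midpoint. Assignment is "within" at
<= 50,000 bp; proximal is strict < 5,000 bp (the two boundary conventions
differ deliberately). Equidistant ties go to the lexicographically smaller
gene id for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genomic_io import GeneModel, Peak

DEFAULT_MAX_DIST = 50_000
DEFAULT_PROX_DIST = 5_000


@dataclass
class CreAssignment:
    peak: Peak
    gene_id: str | None
    distance_bp: int | None
    locality: str | None = None  # proximal / distal, set when assigned
    lineage: str = "none"


def assign_nearest_tss(
    peak: Peak,
    genes: Sequence[GeneModel],
    max_dist: int = DEFAULT_MAX_DIST,
) -> CreAssignment:
    """Single nearest-TSS gene on the same chromosome, if within max_dist."""
    mid = peak.midpoint
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(mid - g.tss)
        if d > max_dist:
            continue
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return CreAssignment(peak=peak, gene_id=None, distance_bp=None)
    d, gid = best
    a = CreAssignment(peak=peak, gene_id=gid, distance_bp=d)
    a.locality = classify_locality(a)
    return a


def classify_locality(assignment: CreAssignment, prox_dist: int = DEFAULT_PROX_DIST) -> str:
    """proximal iff distance < prox_dist (strict); requires an assigned gene."""
    if assignment.gene_id is None or assignment.distance_bp is None:
        raise ValueError("cannot classify locality of an unassigned peak")
    return "proximal" if assignment.distance_bp < prox_dist else "distal"


def label_lineage(
    assignment: CreAssignment,
    epi_genes: Iterable[str],
    pre_genes: Iterable[str],
) -> str:
    """Lineage of the assigned gene: Epi, PrE, or none."""
    epi, pre = set(epi_genes), set(pre_genes)
    shared = epi & pre
    if shared:
        raise ValueError(f"gene sets overlap: {sorted(shared)[:5]}")
    if assignment.gene_id in pre:
        return "PrE"
    if assignment.gene_id in epi:
        return "Epi"
    return "none"


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    epi_genes: Iterable[str] = (),
    pre_genes: Iterable[str] = (),
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[CreAssignment]:
    """Full annotation of a peak list: nearest TSS, locality, lineage."""
    epi, pre = set(epi_genes), set(pre_genes)
    out = []
    for p in peaks:
        a = assign_nearest_tss(p, genes, max_dist=max_dist)
        if a.gene_id is not None:
            a.lineage = label_lineage(a, epi, pre)
        out.append(a)
    return out
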