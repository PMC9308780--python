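"""Peak taxonomies across the differentiation time course.

Two classifications:

* GATA6 peaks over a union universe of top-ranked peaks: ``early`` if present
  in the top-N ranked set at any of 2/4/8 h, ``late`` if present only at
  48 h; early peaks split by 0 h accessibility into ``early_open_0h`` /
  ``early_closed_0h``.
* NANOG 2 h peaks: pre-existing (cluster 1), de novo on open chromatin
  (cluster 2), de novo at closed sites (cluster 3).

"Present in" a ranked set means overlapping (>= 1 bp) any member of it;
cross-timepoint peak identity is the union-merge of the ranked sets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .genomic_io import Peak, PeakIndex, merge_peaks

DEFAULT_TOP_N_GATA6 = 10_000
DEFAULT_TOP_N_NANOG = 15_000

EARLY_TIMEPOINTS = (2, 4, 8)
LATE_TIMEPOINT = 48

CATEGORY_EARLY_OPEN = "early_open_0h"
CATEGORY_EARLY_CLOSED = "early_closed_0h"
CATEGORY_LATE = "late"
CATEGORY_UNCLASSIFIED = "unclassified"

CLUSTER_PREEXISTING = "c1_preexisting"
CLUSTER_DENOVO_OPEN = "c2_denovo_open"
CLUSTER_DENOVO_CLOSED = "c3_denovo_closed"


def top_n_by_q(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """The n peaks with smallest q-value; ties by (score desc, chrom, start)."""
    missing = [p for p in peaks if p.qvalue is None]
    if missing:
        raise ValueError(f"{len(missing)} peaks lack q-values")
    ranked = sorted(peaks, key=lambda p: (p.qvalue, -p.score, p.chrom, p.start))
    return ranked[:n]


def classify_gata6_peaks(
    ranked: Mapping[int, Sequence[Peak]],
    atac0: Sequence[Peak],
) -> list[tuple[Peak, str]]:
    """Early/late x open/closed taxonomy over the merged peak universe."""
    required = set(EARLY_TIMEPOINTS) | {LATE_TIMEPOINT}
    missing = required - set(ranked)
    if missing:
        raise ValueError(f"missing ranked peak sets for timepoints: {sorted(missing)}")
    universe = merge_peaks([p for t in sorted(required) for p in ranked[t]])
    early_idx = [PeakIndex(ranked[t]) for t in EARLY_TIMEPOINTS]
    late_idx = PeakIndex(ranked[LATE_TIMEPOINT])
    atac0_idx = PeakIndex(atac0)

    out: list[tuple[Peak, str]] = []
    for peak in universe:
        is_early = any(ix.overlaps_peak(peak) for ix in early_idx)
        if is_early:
            cat = CATEGORY_EARLY_OPEN if atac0_idx.overlaps_peak(peak) else CATEGORY_EARLY_CLOSED
        elif late_idx.overlaps_peak(peak):
            cat = CATEGORY_LATE
        else:  # unreachable for a universe built from these sets; kept for safety
            cat = CATEGORY_UNCLASSIFIED
        peak.labels.add(cat)
        out.append((peak, cat))
    return out


def classify_nanog_2h(
    n0: Sequence[Peak],
    n2: Sequence[Peak],
    atac0: Sequence[Peak],
) -> list[tuple[Peak, str]]:
    """Cluster each 2 h NANOG peak: c1 if bound at 0 h, else c2 if the site
    was accessible at 0 h, else c3."""
    n0_idx = PeakIndex(n0)
    atac0_idx = PeakIndex(atac0)
    out: list[tuple[Peak, str]] = []
    for peak in n2:
        if n0_idx.overlaps_peak(peak):
            cluster = CLUSTER_PREEXISTING
        elif atac0_idx.overlaps_peak(peak):
            cluster = CLUSTER_DENOVO_OPEN
        else:
            cluster = CLUSTER_DENOVO_CLOSED
        peak.labels.add(cluster)
        out.append((peak, cluster))
    return out
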