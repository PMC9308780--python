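"""Transgene quantification, lineage gene lists, DE time course, and
bulk-on-single-cell staging via group-residual PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_stats import CountTable, DiffResult, classify_features, size_factors_median_of_ratios

RNA_LFC_MIN = 2.0
RNA_PADJ_MAX = 0.1


# ---------------------------------------------------------------------------
# Transgene T/E


@dataclass
class TransgeneQuant:
    cds_norm: pd.Series  # per-sample reads per million per kb over the CDS segment
    utr_norm: pd.Series
    t: pd.Series  # transgene expression: cds_norm - utr_norm
    e: float  # endogenous expression: mean utr_norm over reference samples
    ratio: pd.Series  # t / e
    negative_t_samples: list[str]


def transgene_ratio(
    segment_counts: pd.DataFrame,  # rows: segment kinds; columns: samples
    library_sizes: pd.Series,
    segment_lengths: Mapping[str, int],
    reference_samples: Sequence[str],
    cds_kind: str = "CDS_last_exon",
    utr_kind: str = "UTR3",
) -> TransgeneQuant:
    """T/E quantification from CDS-last-exon and 3'UTR segment counts.

    norm(x) = x / (library_size / 1e6) / (length / 1000). T = CDS - UTR per
    sample; E = mean UTR over the reference samples; ratio = T / E.
    """
    for kind in (cds_kind, utr_kind):
        if kind not in segment_counts.index:
            raise ValueError(f"segment counts lack a {kind!r} row")
    if len(reference_samples) == 0:
        raise ValueError("reference_samples must be non-empty")

    def norm(kind: str) -> pd.Series:
        return (
            segment_counts.loc[kind]
            / (library_sizes / 1e6)
            / (segment_lengths[kind] / 1000)
        )

    cds_norm = norm(cds_kind)
    utr_norm = norm(utr_kind)
    t = cds_norm - utr_norm
    e = float(utr_norm[list(reference_samples)].mean())
    if e == 0:
        raise ValueError("endogenous reference expression E is zero; ratio undefined")
    negative = [str(s) for s in t.index[t < 0]]
    return TransgeneQuant(
        cds_norm=cds_norm,
        utr_norm=utr_norm,
        t=t,
        e=e,
        ratio=t / e,
        negative_t_samples=negative,
    )


# ---------------------------------------------------------------------------
# Lineage gene lists


def intersect_lineage_genes(
    de_a: DiffResult,
    de_b: DiffResult,
    lfc_min: float = RNA_LFC_MIN,
    fdr_max: float = RNA_PADJ_MAX,
) -> tuple[list[str], list[str]]:
    """(epi_ids, pre_ids): PrE genes are up in both tables, Epi down in both.

    Both tables must be oriented as PrE vs Epi; genes changing in only one
    table or in conflicting directions are excluded.
    """
    cls_a = classify_features(de_a, lfc_min, fdr_max)
    cls_b = classify_features(de_b, lfc_min, fdr_max)
    shared = cls_a.index.intersection(cls_b.index)
    pre = [g for g in shared if cls_a[g] == "up" and cls_b[g] == "up"]
    epi = [g for g in shared if cls_a[g] == "down" and cls_b[g] == "down"]
    return epi, pre


def de_timecourse(
    vs_zero: Mapping[object, DiffResult],
    vs_previous: Mapping[object, DiffResult],
    lfc_min: float = RNA_LFC_MIN,
    padj_max: float = RNA_PADJ_MAX,
) -> pd.DataFrame:
    """Earliest timepoint at which a gene changes in either contrast.

    Returns a frame indexed by gene with columns first_change (timepoint or
    NaN) and direction (up/down/none), the direction taken from whichever
    contrast fired first (vs-0h wins ties).
    """
    timepoints = sorted(set(vs_zero) | set(vs_previous))
    genes = None
    for res in list(vs_zero.values()) + list(vs_previous.values()):
        genes = res.table.index if genes is None else genes.union(res.table.index)
    first_change: dict[str, object] = {g: np.nan for g in genes}
    direction = {g: "none" for g in genes}
    for t in timepoints:
        for source in (vs_zero, vs_previous):
            if t not in source:
                continue
            cls = classify_features(source[t], lfc_min, padj_max)
            for g in cls.index[cls != "stable"]:
                if direction[g] == "none":
                    first_change[g] = t
                    direction[g] = cls[g]
    return pd.DataFrame({"first_change": pd.Series(first_change),
                         "direction": pd.Series(direction)})


# ---------------------------------------------------------------------------
# Bulk <-> single-cell staging


@dataclass
class StageMap:
    residuals: pd.DataFrame  # samples x genes
    pcs: pd.DataFrame  # samples x components
    assignments: pd.DataFrame  # per bulk sample: nearest cluster, distance


def _cluster_means_log1p_cpm(sc_counts: pd.DataFrame, cell_clusters: pd.Series,
                             cluster_merge: Mapping[str, str] | None) -> pd.DataFrame:
    """Per-cell CPM -> log1p -> mean within (merged) cluster. Rows = clusters."""
    cpm = sc_counts / sc_counts.sum(axis=0) * 1e6
    log = np.log1p(cpm)
    merged = cell_clusters.map(lambda c: (cluster_merge or {}).get(c, c))
    return log.T.groupby(merged.reindex(log.columns)).mean()


def stage_bulk_on_sc(
    bulk: CountTable,
    sc_counts: pd.DataFrame,  # genes x cells
    cell_clusters: pd.Series,  # cell -> cluster label
    cluster_merge: Mapping[str, str] | None = None,
    n_components: int = 2,
) -> StageMap:
    """Map bulk samples onto single-cell cluster centroids.

    Single-cell side: CPM, log1p, cluster means (after merging). Bulk side:
    log2(median-of-ratios-normalized + 1). Per gene, a two-group (bulk vs sc)
    least-squares fit removes the platform offset; PCA of the residuals puts
    both on common axes, and each bulk sample maps to the nearest cluster
    centroid in the first ``n_components`` PCs.
    """
    sc_means = _cluster_means_log1p_cpm(sc_counts, cell_clusters, cluster_merge)
    if bulk.size_factors is None:
        bulk.size_factors = size_factors_median_of_ratios(bulk)
    bulk_log = np.log2(bulk.normalized() + 1.0).T  # samples x genes

    genes = bulk_log.columns.intersection(sc_means.columns)
    if len(genes) == 0:
        raise ValueError("no genes shared between bulk and single-cell matrices")
    bulk_log = bulk_log[genes]
    sc_means = sc_means[genes]

    combined = pd.concat([bulk_log, sc_means])
    group = np.array(["bulk"] * len(bulk_log) + ["sc"] * len(sc_means))
    residuals = combined.copy()
    for label in ("bulk", "sc"):
        sel = group == label
        residuals.iloc[sel] = combined.iloc[sel] - combined.iloc[sel].mean(axis=0)

    # residuals are column-centered (each group's mean removed), PCA via SVD
    mat = residuals.values
    if not np.any(mat):
        raise ValueError("all residuals are zero; PCA and mapping are undefined")
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    n_keep = min(len(s), max(n_components, 2))
    pcs = pd.DataFrame(u[:, :n_keep] * s[:n_keep], index=residuals.index,
                       columns=[f"PC{i + 1}" for i in range(n_keep)])

    bulk_pcs = pcs.iloc[group == "bulk", :n_components]
    sc_pcs = pcs.iloc[group == "sc", :n_components]
    rows = []
    for sample in bulk_pcs.index:
        d = np.sqrt(((sc_pcs - bulk_pcs.loc[sample]) ** 2).sum(axis=1))
        rows.append({"sample": sample, "cluster": d.idxmin(), "distance": float(d.min())})
    assignments = pd.DataFrame(rows).set_index("sample")
    return StageMap(residuals=residuals, pcs=pcs, assignments=assignments)
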