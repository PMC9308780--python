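"""Signal quantification over peak classes and redistribution scoring.

The redistribution score for a cluster is the median over its peaks of
log2((s(t1) + 1) / (s(t0) + 1)); redistribution is detected when the
pre-existing cluster drops by at least delta while the de-novo-closed
cluster gains by at least delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import Peak, SignalTrack, track_stat

DEFAULT_FLANK = 500
DEFAULT_DELTA = 0.5
LOG_PSEUDOCOUNT = 1.0


def signal_matrix(
    peaks: Sequence[Peak],
    tracks: Mapping[tuple[str, object], SignalTrack],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Rows = peaks, columns = (assay, timepoint); entry = mean signal over
    [midpoint - flank, midpoint + flank)."""
    columns = sorted(tracks, key=str)
    data = np.zeros((len(peaks), len(columns)))
    for j, key in enumerate(columns):
        track = tracks[key]
        for i, p in enumerate(peaks):
            mid = p.midpoint
            window = Peak(p.chrom, max(mid - flank, 0), mid + flank)
            data[i, j] = track_stat(track, window, "mean")
    idx = pd.Index([f"{p.chrom}:{p.start}-{p.end}" for p in peaks], name="peak")
    return pd.DataFrame(data, index=idx, columns=pd.Index(columns))


@dataclass
class RedistributionReport:
    scores: dict[str, float]  # cluster -> median log2 ratio
    detected: bool
    delta: float
    per_peak: dict[str, np.ndarray]


def redistribution_score(
    matrix: pd.DataFrame,
    clusters: Mapping[str, Sequence[int]],
    assay: str,
    t0,
    t1,
    delta: float = DEFAULT_DELTA,
    lose_cluster: str = "c1_preexisting",
    gain_cluster: str = "c3_denovo_closed",
) -> RedistributionReport:
    """Median per-peak log2 signal ratio per cluster between two timepoints.

    ``clusters`` maps cluster name to row positions in ``matrix``. Detection
    requires the lose-cluster score <= -delta and gain-cluster >= +delta.
    """
    for key in ((assay, t0), (assay, t1)):
        if key not in matrix.columns:
            raise ValueError(f"column {key} missing from signal matrix")
    scores: dict[str, float] = {}
    per_peak: dict[str, np.ndarray] = {}
    for name, rows in clusters.items():
        if len(rows) == 0:
            raise ValueError(f"cluster {name!r} is empty")
        s0 = matrix[(assay, t0)].values[list(rows)]
        s1 = matrix[(assay, t1)].values[list(rows)]
        ratios = np.log2((s1 + LOG_PSEUDOCOUNT) / (s0 + LOG_PSEUDOCOUNT))
        per_peak[name] = ratios
        scores[name] = float(np.median(ratios))
    detected = (
        lose_cluster in scores
        and gain_cluster in scores
        and scores[lose_cluster] <= -delta
        and scores[gain_cluster] >= delta
    )
    return RedistributionReport(scores=scores, detected=detected, delta=delta,
                                per_peak=per_peak)


def meta_profile(
    track: SignalTrack,
    centers: Sequence[tuple[str, int]],
    flank: int,
    n_bins: int,
) -> np.ndarray:
    """Mean signal around centers, resampled to n_bins over [-flank, +flank)."""
    if len(centers) == 0:
        raise ValueError("meta_profile requires at least one center")
    width = 2 * flank / n_bins
    profile = np.zeros(n_bins)
    for chrom, mid in centers:
        for b in range(n_bins):
            lo = int(round(mid - flank + b * width))
            hi = int(round(mid - flank + (b + 1) * width))
            profile[b] += track_stat(track, Peak(chrom, lo, hi), "mean")
    return profile / len(centers)
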