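"""Capture-C sliding-window differential interactions and Hi-C A/B
compartments with switch calling.

Compartments: coverage normalization, observed/expected by diagonal, Pearson
correlation matrix, leading eigenvector by deterministic power iteration,
sign oriented by a per-bin activity reference. Switches: a bin switches when
the Pearson correlation of its correlation-matrix row between conditions
falls below 0.4 (strict), with direction read off the eigenvalue signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .count_stats import CountTable, DiffResult, bh_adjust, nb_wald_test

DEFAULT_WINDOW = 5_000
DEFAULT_STEP = 500
DEFAULT_PADJ = 0.01
DEFAULT_R_MAX = 0.4
DEFAULT_COMPARTMENT_BIN = 250_000
VIEWPOINT_BIN = 1_000


# ---------------------------------------------------------------------------
# Capture-C


@dataclass
class ViewpointProfile:
    """1 kb-binned interaction signal around one viewpoint, per replicate
    per condition: signal[condition] is an (n_replicates, n_bins) array."""

    viewpoint_id: str
    chrom: str
    start: int
    end: int
    signal: dict[str, np.ndarray]
    bin_size: int = VIEWPOINT_BIN

    def __post_init__(self) -> None:
        n_bins = (self.end - self.start) // self.bin_size
        for cond, arr in self.signal.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[1] != n_bins:
                raise ValueError(
                    f"{self.viewpoint_id}/{cond}: expected {n_bins} bins, got {arr.shape[1]}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{self.viewpoint_id}/{cond}: negative signal")
            self.signal[cond] = arr


def window_grid(region_length: int, win: int, step: int) -> list[tuple[int, int]]:
    """Offsets of overlapping windows: [step*i, step*i + win) while fitting."""
    if region_length < win:
        raise ValueError(f"region length {region_length} shorter than window {win}")
    n = (region_length - win) // step + 1
    return [(i * step, i * step + win) for i in range(n)]


@dataclass
class WindowDifferential:
    result: DiffResult
    windows: list[tuple[int, int]]  # genomic coordinates
    significant: list[tuple[int, int]]  # merged runs of significant windows


def window_differential(
    profile: ViewpointProfile,
    contrast: tuple[str, str],
    win: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    padj_max: float = DEFAULT_PADJ,
) -> WindowDifferential:
    """NB test of summed window signal between two conditions, BH over
    windows; significant windows are union-merged into maximal runs."""
    length = profile.end - profile.start
    offsets = window_grid(length, win, step)
    bs = profile.bin_size
    cond_a, cond_b = contrast
    reps = {c: profile.signal[c] for c in (cond_a, cond_b)}
    counts: dict[str, list[float]] = {}
    for cond in (cond_a, cond_b):
        for r in range(reps[cond].shape[0]):
            counts[f"{cond}_rep{r + 1}"] = [
                float(np.round(reps[cond][r, lo // bs : hi // bs].sum()))
                for lo, hi in offsets
            ]
    frame = pd.DataFrame(counts, index=[f"win_{lo}_{hi}" for lo, hi in offsets])
    conditions = pd.Series({s: s.rsplit("_rep", 1)[0] for s in frame.columns})
    table = CountTable(counts=frame.astype(int), conditions=conditions)
    res = nb_wald_test(table, (cond_a, cond_b))

    genomic = [(profile.start + lo, profile.start + hi) for lo, hi in offsets]
    sig = [w for w, padj in zip(genomic, res["padj"]) if padj < padj_max]
    return WindowDifferential(result=res, windows=genomic, significant=_merge_runs(sig))


def _merge_runs(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge overlapping or adjacent significant windows."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# Hi-C compartments


@dataclass
class CompartmentProfile:
    bin_size: int
    eigenvalues: np.ndarray  # per-bin signed eigenvector entries (nan = masked)
    correlation: np.ndarray  # bin x bin Pearson correlation matrix
    masked: np.ndarray  # boolean, True for all-zero bins


def _observed_expected(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    oe = np.zeros_like(matrix, dtype=float)
    for d in range(n):
        idx = np.arange(n - d)
        diag = matrix[idx, idx + d]
        mean = diag.mean()
        if mean > 0:
            oe[idx, idx + d] = diag / mean
            oe[idx + d, idx] = oe[idx, idx + d]
    return oe


def compartment_eigen(
    matrix: np.ndarray,
    reference: np.ndarray,
    bin_size: int = DEFAULT_COMPARTMENT_BIN,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> CompartmentProfile:
    """Leading eigenvector of the O/E Pearson correlation matrix.

    The matrix is coverage-normalized (entry ij divided by the product of
    row sums, rescaled), O/E'd by diagonal means, correlated, and the
    leading eigenvector found by power iteration from an all-ones start.
    Sign is oriented so the eigenvector correlates positively with the
    per-bin activity ``reference``. All-zero bins are masked (NaN).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("contact matrix must be non-negative")
    n = m.shape[0]
    rows = m.sum(axis=1)
    masked = rows == 0
    keep = ~masked
    sub = m[np.ix_(keep, keep)]
    r = sub.sum(axis=1)
    # coverage normalization preserving the overall scale
    cov = sub / np.outer(r, r) * r.mean() ** 2
    oe = _observed_expected(cov)
    corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)

    # power iteration, deterministic all-ones start; correlation matrices are
    # PSD so this converges to the leading eigenvector
    v = np.ones(corr.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = corr @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            v = w
            break
        v = w

    ref = np.asarray(reference, dtype=float)[keep]
    if np.std(ref) > 0 and np.std(v) > 0:
        if np.corrcoef(v, ref)[0, 1] < 0:
            v = -v

    eig = np.full(n, np.nan)
    eig[keep] = v
    corr_full = np.full((n, n), np.nan)
    corr_full[np.ix_(keep, keep)] = corr
    return CompartmentProfile(bin_size=bin_size, eigenvalues=eig,
                              correlation=corr_full, masked=masked)


@dataclass
class SwitchCall:
    bin_index: int
    r: float
    switched: bool
    direction: str  # "A->B", "B->A", "none"


def compartment_switches(
    a: CompartmentProfile,
    b: CompartmentProfile,
    r_max: float = DEFAULT_R_MAX,
) -> list[SwitchCall]:
    """Per-bin switch calls: r = Pearson correlation between the bin's
    correlation-matrix rows in the two conditions; switch iff r < r_max."""
    if a.correlation.shape != b.correlation.shape or a.bin_size != b.bin_size:
        raise ValueError("compartment profiles are on different bin grids")
    n = a.correlation.shape[0]
    calls = []
    for i in range(n):
        if a.masked[i] or b.masked[i]:
            continue
        valid = ~(np.isnan(a.correlation[i]) | np.isnan(b.correlation[i]))
        row_a, row_b = a.correlation[i, valid], b.correlation[i, valid]
        r = float(np.corrcoef(row_a, row_b)[0, 1])
        switched = r < r_max
        if switched:
            direction = "A->B" if a.eigenvalues[i] > 0 else "B->A"
        else:
            direction = "none"
        calls.append(SwitchCall(bin_index=i, r=r, switched=switched, direction=direction))
    return calls


def write_viewpoint_tsv(profile: ViewpointProfile, path: str | Path) -> None:
    """Profile table: chrom/start/end per bin plus one column per
    condition_repN signal vector."""
    bs = profile.bin_size
    n_bins = (profile.end - profile.start) // bs
    data = {
        "chrom": [profile.chrom] * n_bins,
        "start": [profile.start + i * bs for i in range(n_bins)],
        "end": [profile.start + (i + 1) * bs for i in range(n_bins)],
    }
    for cond, reps in profile.signal.items():
        for r in range(reps.shape[0]):
            data[f"{cond}_rep{r + 1}"] = reps[r]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_viewpoint_tsv(path: str | Path, viewpoint_id: str = "vp") -> ViewpointProfile:
    frame = pd.read_csv(path, sep="\t")
    chrom = frame["chrom"].iloc[0]
    start = int(frame["start"].iloc[0])
    end = int(frame["end"].iloc[-1])
    bin_size = int(frame["end"].iloc[0] - frame["start"].iloc[0])
    signal: dict[str, list[np.ndarray]] = {}
    for col in frame.columns:
        if "_rep" not in col:
            continue
        cond = col.rsplit("_rep", 1)[0]
        signal.setdefault(cond, []).append(frame[col].values.astype(float))
    return ViewpointProfile(
        viewpoint_id=viewpoint_id,
        chrom=chrom,
        start=start,
        end=end,
        signal={c: np.vstack(v) for c, v in signal.items()},
        bin_size=bin_size,
    )


def read_contact_matrix(path: str | Path) -> np.ndarray:
    """Dense TSV contact matrix with a header row of bin labels."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.values.astype(float)


def write_contact_matrix(matrix: np.ndarray, path: str | Path,
                         bin_size: int = DEFAULT_COMPARTMENT_BIN) -> None:
    labels = [f"bin_{i * bin_size}" for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")
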