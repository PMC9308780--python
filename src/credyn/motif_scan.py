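"""PWM scanning with exact null p-values, motif density and strength.

Scores are log2 odds of a pseudocounted position probability matrix against
a 0-order background. Scores are integer-scaled (resolution 1e-3) and the
exact null distribution of the integer score is built by dynamic programming
over positions, so window p-values are exact sums of background word
probabilities — testable against brute-force enumeration for short motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genomic_io import Peak
from .count_stats import bh_adjust

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SCORE_RESOLUTION = 1e-3
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass
class MotifModel:
    """Position probability matrix with background and pseudocount."""

    motif_id: str
    ppm: np.ndarray  # k x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("PPM must be k x 4")
        if self.ppm.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PPM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.ppm.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.ppm.argmax(axis=1))

    def with_background(self, background: np.ndarray) -> "MotifModel":
        return MotifModel(self.motif_id, self.ppm, np.asarray(background, float),
                          self.pseudocount)

    def log_odds(self) -> np.ndarray:
        """k x 4 matrix of log2((W + eps*q) / ((1 + eps) * q))."""
        q = self.background
        eps = self.pseudocount
        return np.log2((self.ppm + eps * q[None, :]) / ((1.0 + eps) * q[None, :]))

    def int_scores(self) -> np.ndarray:
        """Integer-scaled log-odds at resolution 1e-3."""
        return np.round(self.log_odds() / SCORE_RESOLUTION).astype(np.int64)


def read_jaspar(path: str | Path) -> list[MotifModel]:
    """Parse JASPAR-style PFM text (one or more motifs) into PPMs."""
    motifs: list[MotifModel] = []
    motif_id = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, motif_id
        if motif_id is None:
            return
        if set(rows) != set(ALPHABET):
            raise ValueError(f"motif {motif_id}: need one row per base, got {sorted(rows)}")
        counts = np.array([rows[b] for b in ALPHABET], dtype=float).T  # k x 4
        ppm = counts / counts.sum(axis=1, keepdims=True)
        motifs.append(MotifModel(motif_id, ppm))
        rows = {}
        motif_id = None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].strip()
            else:
                base, rest = line[0].upper(), line[1:]
                values = rest.replace("[", " ").replace("]", " ").split()
                rows[base] = [float(v) for v in values]
    flush()
    return motifs


@dataclass
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    p: float
    q: float
    matched: str
    motif_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"hit p-value {self.p} outside (0, 1]")


def exact_score_distribution(motif: MotifModel) -> tuple[np.ndarray, int]:
    """Exact pmf of the integer window score under the background model.

    Returns (pmf, min_score): pmf[i] = P(score == min_score + i) for a
    random word drawn i.i.d. from the background.
    """
    ints = motif.int_scores()
    q = motif.background
    # DP over positions: convolve the 4-point distribution of each column
    pmf = np.array([1.0])
    lo = 0
    for i in range(motif.width):
        col = ints[i]
        col_lo = int(col.min())
        new = np.zeros(len(pmf) + int(col.max()) - col_lo)
        for b in range(4):
            shift = int(col[b]) - col_lo
            new[shift : shift + len(pmf)] += q[b] * pmf
        pmf = new
        lo += col_lo
    return pmf, lo


def score_pvalue_table(motif: MotifModel) -> tuple[np.ndarray, int]:
    """Survival function of the exact score distribution.

    Returns (sf, min_score): sf[i] = P(score >= min_score + i).
    """
    pmf, lo = exact_score_distribution(motif)
    sf = np.cumsum(pmf[::-1])[::-1]
    # guard against negative rounding; P over the whole support is exactly 1
    sf = np.minimum(np.maximum(sf, 0.0), 1.0)
    return sf, lo


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order base composition of the scanned set, symmetrized over strands
    (A/T and C/G averaged) so scanning is reverse-complement invariant;
    unit pseudocount per base, uniform fallback."""
    counts = np.ones(4)
    for seq in sequences:
        s = seq.upper()
        for i, b in enumerate(ALPHABET):
            counts[i] += s.count(b)
    at = (counts[0] + counts[3]) / 2.0
    cg = (counts[1] + counts[2]) / 2.0
    sym = np.array([at, cg, cg, at])
    return sym / sym.sum()


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0-3, anything else (incl. N) to -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def scan(
    sequences: Mapping[str, str],
    motif: MotifModel,
    p_max: float = 1e-3,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan both strands of each sequence; return hits with exact p <= p_max.

    Windows containing non-ACGT characters are skipped. q-values are BH over
    the total number of scanned windows (both strands), FIMO-style.
    """
    seqs = {name: s.upper() for name, s in sequences.items()}
    if background is None:
        background = estimate_background(seqs.values())
    m = motif.with_background(background)
    k = m.width
    ints = m.int_scores()
    sf, lo = score_pvalue_table(m)
    hi = lo + len(sf) - 1

    hits: list[MotifHit] = []
    n_windows = 0
    for name, seq in seqs.items():
        if len(seq) < k:
            continue
        enc = _encode(seq)
        valid = enc >= 0
        # window is scannable iff it contains no invalid base
        ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
        n_windows += int(ok.sum()) * 2
        positions = np.nonzero(ok)[0]
        if positions.size == 0:
            continue
        # integer score of every valid window on both strands
        idx = positions[:, None] + np.arange(k)[None, :]
        words = enc[idx]  # n x k
        fwd = ints[np.arange(k)[None, :], words].sum(axis=1)
        rc_words = 3 - words[:, ::-1]
        rev = ints[np.arange(k)[None, :], rc_words].sum(axis=1)
        for strand, scores, word_arr in (("+", fwd, words), ("-", rev, rc_words)):
            pvals = sf[np.clip(scores, lo, hi) - lo]
            keep = pvals <= p_max
            for j in np.nonzero(keep)[0]:
                pos = int(positions[j])
                matched = seq[pos : pos + k]
                if strand == "-":
                    matched = reverse_complement(matched)
                hits.append(
                    MotifHit(
                        chrom=name,
                        start=pos,
                        end=pos + k,
                        strand=strand,
                        score=float(scores[j]) * SCORE_RESOLUTION,
                        p=float(pvals[j]),
                        q=1.0,
                        matched=matched,
                        motif_id=m.motif_id,
                    )
                )
    _assign_qvalues(hits, n_windows)
    return hits


def _assign_qvalues(hits: list[MotifHit], n_windows: int) -> None:
    """BH over the scanned-window universe: every unreported window has a
    larger p than every reported hit, so hit ranks are their global ranks."""
    if not hits:
        return
    order = sorted(range(len(hits)), key=lambda i: hits[i].p)
    qs = [hits[i].p * n_windows / (rank + 1) for rank, i in enumerate(order)]
    running = 1.0
    for rank in range(len(qs) - 1, -1, -1):
        running = min(running, qs[rank])
        hits[order[rank]].q = min(running, 1.0)


def brute_force_pvalue(motif: MotifModel, score_int: int) -> float:
    """Enumeration oracle: P(integer score >= score_int) summed over all 4^k
    words under the background. Only sensible for small k."""
    ints = motif.int_scores()
    q = motif.background
    k = motif.width
    total = 0.0
    for word in np.ndindex(*(4,) * k):
        s = int(ints[np.arange(k), list(word)].sum())
        if s >= score_int:
            prob = 1.0
            for b in word:
                prob *= q[b]
            total += prob
    return total


def motif_density(peaks: Sequence[Peak], hits: Sequence[MotifHit]) -> np.ndarray:
    """Per-peak count of hits fully contained within the peak interval."""
    counts = np.zeros(len(peaks), dtype=np.int64)
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    for i, p in enumerate(peaks):
        for h in by_chrom.get(p.chrom, []):
            if h.start >= p.start and h.end <= p.end:
                counts[i] += 1
    return counts


def density_by_class(peaks: Sequence[Peak], counts: np.ndarray,
                     classes: Sequence[str]) -> dict[str, np.ndarray]:
    """Split the per-peak density vector by peak label."""
    out: dict[str, np.ndarray] = {}
    for cls in classes:
        sel = [counts[i] for i, p in enumerate(peaks) if cls in p.labels]
        out[cls] = np.array(sel, dtype=np.int64)
    return out


def motif_strength(
    peaks: Sequence[Peak],
    hits: Sequence[MotifHit],
    classes: Sequence[str],
) -> dict:
    """Per-class distributions of hit q-values plus a rank-sum comparison.

    A hit contributes to a class when it is contained in a peak carrying the
    class label. Classes with < 2 hits are reported but excluded from the
    Mann-Whitney test (degenerate, with a warning flag).
    """
    qvals: dict[str, list[float]] = {cls: [] for cls in classes}
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for h in hits:
        for p in by_chrom.get(h.chrom, []):
            if h.start >= p.start and h.end <= p.end:
                for cls in classes:
                    if cls in p.labels:
                        qvals[cls].append(h.q)
    result: dict = {
        "qvalues": {cls: np.array(v) for cls, v in qvals.items()},
        "medians": {cls: (float(np.median(v)) if v else float("nan"))
                    for cls, v in qvals.items()},
        "test": None,
        "warning": None,
    }
    testable = [cls for cls in classes if len(qvals[cls]) >= 2]
    if len(testable) >= 2:
        a, b = testable[0], testable[1]
        stat, p = sps.mannwhitneyu(qvals[a], qvals[b], alternative="two-sided")
        result["test"] = {"classes": (a, b), "statistic": float(stat), "p": float(p)}
    else:
        result["warning"] = "fewer than two classes with >= 2 hits; test skipped"
    return result


def write_hits(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tchrom\tstart\tend\tstrand\tscore\tp\tq\tmatched\n")
        for h in hits:
            fh.write(
                f"{h.motif_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.score:.3f}\t{h.p:.6g}\t{h.q:.6g}\t{h.matched}\n"
            )
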