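"""Readers/writers for on-disk genomic formats and interval/signal primitives.

Coordinates follow the BED convention throughout: 0-based, half-open.
Supported text formats: BED3/BED6, ENCODE narrowPeak (10 columns),
bedGraph (4 columns), FASTA (via pyfaidx), TSV tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np


class FormatError(ValueError):
    """Raised on malformed input records; message names the offending line."""


# ---------------------------------------------------------------------------
# Peaks


@dataclass
class Peak:
    """A genomic interval with optional score/q-value and free-form labels."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    qvalue: float | None = None
    labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got {self.chrom}:{self.start}-{self.end}")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue {self.qvalue} outside [0, 1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: Peak, b: Peak) -> bool:
    """True iff the two intervals share >= 1 bp under half-open semantics."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def read_peaks(path: str | Path, format: Literal["bed", "narrowPeak"] = "bed") -> list[Peak]:
    """Parse a BED or ENCODE narrowPeak file into a list of :class:`Peak`.

    narrowPeak column 9 carries -log10(q); it is converted to
    ``qvalue = 10 ** -col9`` (a sentinel of -1 maps to qvalue None).
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format: {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if format == "narrowPeak":
                    if len(cols) < 10:
                        raise ValueError("narrowPeak requires 10 columns")
                    neglog_q = float(cols[8])
                    qvalue = None if neglog_q < 0 else min(1.0, 10.0 ** -neglog_q)
                    peaks.append(
                        Peak(
                            chrom=cols[0],
                            start=int(cols[1]),
                            end=int(cols[2]),
                            name=cols[3],
                            score=float(cols[6]),
                            qvalue=qvalue,
                        )
                    )
                else:
                    if len(cols) < 3:
                        raise ValueError("BED requires at least 3 columns")
                    peaks.append(
                        Peak(
                            chrom=cols[0],
                            start=int(cols[1]),
                            end=int(cols[2]),
                            name=cols[3] if len(cols) > 3 else ".",
                            score=float(cols[4]) if len(cols) > 4 else 0.0,
                        )
                    )
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path,
                format: Literal["bed", "narrowPeak"] = "bed") -> None:
    """Write peaks as BED6 or narrowPeak; inverse of :func:`read_peaks`."""
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format: {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            if format == "narrowPeak":
                neglog_q = -1.0 if p.qvalue is None else -np.log10(max(p.qvalue, 1e-300))
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                    f"{p.score:.6g}\t-1\t{neglog_q:.6g}\t-1\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.6g}\t.\n")


class PeakIndex:
    """Sorted-interval index answering 'does this interval overlap the set'."""

    def __init__(self, peaks: Sequence[Peak]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[Peak]] = {}
        for p in peaks:
            grouped.setdefault(p.chrom, []).append(p)
        for chrom, plist in grouped.items():
            plist.sort(key=lambda p: p.start)
            starts = np.array([p.start for p in plist], dtype=np.int64)
            # running max of ends makes the overlap test correct for nested
            # intervals without a tree
            ends = np.maximum.accumulate(np.array([p.end for p in plist], dtype=np.int64))
            self._by_chrom[chrom] = (starts, ends)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, cummax_ends = entry
        i = int(np.searchsorted(starts, end, side="left"))  # peaks with start < end
        if i == 0:
            return False
        return bool(cummax_ends[i - 1] > start)

    def overlaps_peak(self, peak: Peak) -> bool:
        return self.overlaps_any(peak.chrom, peak.start, peak.end)


def merge_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Union-merge overlapping intervals into a non-overlapping universe."""
    merged: list[Peak] = []
    for chrom in sorted({p.chrom for p in peaks}):
        plist = sorted((p for p in peaks if p.chrom == chrom), key=lambda p: p.start)
        cur_start, cur_end = plist[0].start, plist[0].end
        for p in plist[1:]:
            if p.start < cur_end:
                cur_end = max(cur_end, p.end)
            else:
                merged.append(Peak(chrom, cur_start, cur_end))
                cur_start, cur_end = p.start, p.end
        merged.append(Peak(chrom, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# Signal tracks


@dataclass
class SignalTrack:
    """Fixed-bin per-chromosome coverage with windowed mean/sum queries."""

    bin_size: int
    values: dict[str, np.ndarray]
    normalization_tag: str = "none"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"track values for {chrom} must be finite and >= 0")
            self.values[chrom] = arr

    def extent(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size


def track_stat(track: SignalTrack, interval: Peak, stat: Literal["mean", "sum"]) -> float:
    """Stat over bins overlapping the interval, partial bins weighted by overlap."""
    if stat not in ("mean", "sum"):
        raise ValueError(f"unknown stat: {stat!r}")
    if interval.chrom not in track.values:
        raise ValueError(f"interval chromosome {interval.chrom!r} not in track")
    vals = track.values[interval.chrom]
    bs = track.bin_size
    if interval.start < 0 or interval.end > len(vals) * bs:
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} outside track extent"
        )
    first, last = interval.start // bs, (interval.end - 1) // bs
    # bp-weighted accumulation: a bin contributes value * overlap_bp
    total = 0.0
    for b in range(first, last + 1):
        ov = min(interval.end, (b + 1) * bs) - max(interval.start, b * bs)
        total += vals[b] * ov
    if stat == "sum":
        return total
    return total / (interval.end - interval.start)


def read_bedgraph(path: str | Path, bin_size: int,
                  normalization_tag: str = "none",
                  chrom_sizes: dict[str, int] | None = None) -> SignalTrack:
    """Read a 4-column bedGraph whose records lie on a fixed ``bin_size`` grid.

    bedGraph omits zero runs, so pass ``chrom_sizes`` (bp) to pad each
    chromosome to its full extent.
    """
    chrom_vals: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}, line {lineno}: bedGraph requires 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if start % bin_size != 0 or (end - start) % bin_size != 0:
                raise FormatError(
                    f"{path}, line {lineno}: record not aligned to {bin_size} bp grid"
                )
            d = chrom_vals.setdefault(chrom, {})
            for b in range(start // bin_size, end // bin_size):
                d[b] = value
    if chrom_sizes:
        for chrom in chrom_sizes:
            chrom_vals.setdefault(chrom, {})
    values = {}
    for chrom, d in chrom_vals.items():
        n = max(d) + 1 if d else 0
        if chrom_sizes and chrom in chrom_sizes:
            n = max(n, -(-chrom_sizes[chrom] // bin_size))
        arr = np.zeros(n)
        for b, v in d.items():
            arr[b] = v
        values[chrom] = arr
    return SignalTrack(bin_size=bin_size, values=values, normalization_tag=normalization_tag)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            # run-length encode constant stretches, bedGraph-style
            i = 0
            while i < len(vals):
                j = i
                while j + 1 < len(vals) and vals[j + 1] == vals[i]:
                    j += 1
                if vals[i] != 0.0:
                    fh.write(f"{chrom}\t{i * bs}\t{(j + 1) * bs}\t{vals[i]:.6g}\n")
                i = j + 1


# ---------------------------------------------------------------------------
# Fragments


@dataclass
class FragmentSet:
    """Sequenced fragments as (chrom, start, end); length is end - start."""

    fragments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.fragments:
            if end <= start:
                raise ValueError(f"fragment end must exceed start: {chrom}:{start}-{end}")

    def lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.fragments], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.fragments)


_FRAGMENT_FILTERS = {
    "tf": lambda length: length < 120,
    "histone": lambda length: length > 150,
    "nucleosomal_atac": lambda length: length > 180,
}


def filter_fragments(frags: FragmentSet,
                     mode: Literal["tf", "histone", "nucleosomal_atac"]) -> FragmentSet:
    """Size-select fragments: tf < 120 bp, histone > 150 bp, nucleosomal > 180 bp."""
    try:
        keep = _FRAGMENT_FILTERS[mode]
    except KeyError:
        raise ValueError(f"unknown fragment filter mode: {mode!r}") from None
    return FragmentSet([f for f in frags.fragments if keep(f[2] - f[1])])


def read_fragments(path: str | Path) -> FragmentSet:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}, line {lineno}: need 3 columns")
            records.append((cols[0], int(cols[1]), int(cols[2])))
    return FragmentSet(records)


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in frags.fragments:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """Gene with TSS, strand, lineage label and optional CDS/UTR segments."""

    gene_id: str
    chrom: str
    tss: int
    strand: Literal["+", "-"]
    lineage: Literal["Epi", "PrE", "other"] = "other"
    segments: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        segs = sorted(self.segments, key=lambda s: s[1])
        for (_, _, e1), (_, s2, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segments in gene {self.gene_id}")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene table: gene_id, chrom, tss, strand, lineage
    [, segment records as kind:start-end separated by commas]."""
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            try:
                segments = []
                if "segments" in idx and len(cols) > idx["segments"] and cols[idx["segments"]]:
                    for seg in cols[idx["segments"]].split(","):
                        kind, span = seg.split(":")
                        s, e = span.split("-")
                        segments.append((kind, int(s), int(e)))
                genes.append(
                    GeneModel(
                        gene_id=cols[idx["gene_id"]],
                        chrom=cols[idx["chrom"]],
                        tss=int(cols[idx["tss"]]),
                        strand=cols[idx["strand"]],
                        lineage=cols[idx["lineage"]] if "lineage" in idx else "other",
                        segments=segments,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tlineage\tsegments\n")
        for g in genes:
            segs = ",".join(f"{k}:{s}-{e}" for k, s, e in g.segments)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.lineage}\t{segs}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
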