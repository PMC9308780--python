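"""Synthetic multi-omic time course with planted ground truth.

Generates, from one root seed, a toy genome with planted TF motif instances,
per-timepoint peak calls and signal tracks for five assays, fragment-length
mixtures, RNA counts (including a transgene segment table), a single-cell
matrix with labelled clusters plus matching bulk counts, viewpoint
interaction profiles with planted gains, and two-compartment contact
matrices with a minority of switching bins. Every generated feature is
traceable to a ground-truth record.

All signal effect sizes are free synthetic parameters (the emulated study
reports the corresponding effects qualitatively); defaults are chosen so the
planted structure is comfortably recoverable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .chromatin_3d import ViewpointProfile
from .count_stats import CountTable
from .genomic_io import (
    FragmentSet,
    GeneModel,
    Peak,
    SignalTrack,
    write_bedgraph,
    write_fasta,
    write_fragments,
    write_genes,
    write_peaks,
)
from .motif_scan import MotifModel

DEFAULT_TIMEPOINTS = (0, 2, 4, 8, 16, 24, 32, 40, 48)
ASSAYS = ("GATA6", "NANOG", "SOX2", "ATAC", "H3K27ac")

CLASS_EPI = "Epi"
CLASS_PRE_EARLY_OPEN = "PrE_early_open"
CLASS_PRE_EARLY_CLOSED = "PrE_early_closed"
CLASS_PRE_LATE = "PrE_late"
CLASS_BACKGROUND = "background"

CRE_WIDTH = 400
PEAK_CALL_MIN = 2.0  # planted mean signal needed to emit a peak call
TRACK_BIN = 100

# GATA-like position probability matrix (width 8, consensus AGATAAGA)
_GATA_CONSENSUS = "AGATAAGA"
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def gata6_motif(strength: float = 0.85) -> MotifModel:
    ppm = np.full((len(_GATA_CONSENSUS), 4), (1.0 - strength) / 3.0)
    for i, b in enumerate(_GATA_CONSENSUS):
        ppm[i, _BASE_INDEX[b]] = strength
    return MotifModel("GATA6_synthetic", ppm)


@dataclass
class SimConfig:
    seed: int = 1
    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    n_epi_cres: int = 200
    n_pre_cres_early: int = 200  # split half open / half closed at 0 h
    n_pre_cres_late: int = 100
    n_background_peaks: int = 200
    n_decoy_genes: int = 10
    n_stable_genes: int = 400  # RNA-only constant features; keep normalization honest
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    motif_density_epi: float = 1.5
    motif_density_pre: float = 4.0
    motif_strength_epi: float = 0.25  # per-base mutation rate of planted copies
    motif_strength_pre: float = 0.02
    depth: float = 200.0
    relocation_strength: float = 6.0  # NANOG amplitude planted on closed PrE CREs
    amp_sigma: float = 0.25  # per-CRE log-normal amplitude spread
    transgene_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        tps = tuple(self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("n_chroms", "chrom_length_bp", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.timepoints = tps

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        return cls(**raw)


def substream(config_seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the root seed."""
    return np.random.default_rng([config_seed, zlib.crc32(name.encode())])


def planted_counts(mean: float, dispersion: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """NB draws with variance mean + dispersion * mean^2 (Poisson at 0)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=n).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=n)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Signal trajectories (arbitrary units; shapes are logistic rises/decays and
# a single-bump pulse so planted orderings are exact)


def _pulse(t: float, amplitude: float, peak_time: float = 2.0) -> float:
    if t <= 0:
        return 0.0
    x = t / peak_time
    return amplitude * x * np.exp(1.0 - x)


def _rise(t: float, amplitude: float, center: float, slope: float) -> float:
    return amplitude / (1.0 + np.exp(-(t - center) / slope))


def _decay(t: float, amplitude: float, center: float, slope: float) -> float:
    return amplitude / (1.0 + np.exp((t - center) / slope))


_TRAJECTORIES: dict[tuple[str, str], Callable[[float], float]] = {
    (CLASS_EPI, "NANOG"): lambda t: _decay(t, 12.0, 1.0, 1.3),
    (CLASS_EPI, "SOX2"): lambda t: _decay(t, 11.0, 1.0, 1.3),
    (CLASS_EPI, "GATA6"): lambda t: _pulse(t, 6.0),
    (CLASS_EPI, "ATAC"): lambda t: _decay(t, 8.0, 8.0, 3.0),
    (CLASS_EPI, "H3K27ac"): lambda t: _decay(t, 7.0, 8.0, 3.0),
    (CLASS_PRE_EARLY_OPEN, "GATA6"): lambda t: _rise(t, 8.0, 3.0, 1.5),
    (CLASS_PRE_EARLY_OPEN, "NANOG"): lambda t: _pulse(t, 6.0),
    (CLASS_PRE_EARLY_OPEN, "SOX2"): lambda t: _pulse(t, 5.0),
    (CLASS_PRE_EARLY_OPEN, "ATAC"): lambda t: 6.0 + _rise(t, 2.0, 8.0, 3.0),
    (CLASS_PRE_EARLY_OPEN, "H3K27ac"): lambda t: _rise(t, 7.0, 16.0, 4.0),
    (CLASS_PRE_EARLY_CLOSED, "GATA6"): lambda t: _rise(t, 8.0, 3.0, 1.5),
    (CLASS_PRE_EARLY_CLOSED, "ATAC"): lambda t: _rise(t, 8.0, 6.0, 2.0),
    (CLASS_PRE_EARLY_CLOSED, "H3K27ac"): lambda t: _rise(t, 7.0, 16.0, 4.0),
    (CLASS_PRE_LATE, "GATA6"): lambda t: _rise(t, 7.0, 44.0, 2.0),
    (CLASS_PRE_LATE, "ATAC"): lambda t: _rise(t, 6.0, 40.0, 3.0),
    (CLASS_PRE_LATE, "H3K27ac"): lambda t: _rise(t, 5.0, 44.0, 3.0),
    (CLASS_BACKGROUND, "ATAC"): lambda t: 5.0,
    (CLASS_BACKGROUND, "H3K27ac"): lambda t: 4.0,
}


def class_signal(cls: str, assay: str, t: float, config: SimConfig | None = None) -> float:
    """Planted mean signal for a CRE class at time t (before amplitude noise).

    NANOG on closed PrE CREs is the planted redistribution: a 2 h pulse whose
    amplitude scales with the accessibility gain, controlled by
    ``relocation_strength``.
    """
    if cls == CLASS_PRE_EARLY_CLOSED and assay == "NANOG":
        strength = config.relocation_strength if config else 6.0
        return _pulse(t, strength)
    fn = _TRAJECTORIES.get((cls, assay))
    return fn(t) if fn else 0.0


# ---------------------------------------------------------------------------
# Ground truth layout


@dataclass
class GroundTruth:
    cres: pd.DataFrame  # cre_id, chrom, start, end, cls, gene_id, tss, ...
    genes: list[GeneModel]
    amplitudes: pd.DataFrame  # per-CRE per-assay log-normal factors
    extras: dict = field(default_factory=dict)

    def cre_class(self, cre_id: str) -> str:
        return self.cres.loc[cre_id, "cls"]


def _expected_nanog_cluster(cls: str) -> str:
    if cls == CLASS_EPI:
        return "c1_preexisting"
    if cls == CLASS_PRE_EARLY_OPEN:
        return "c2_denovo_open"
    if cls == CLASS_PRE_EARLY_CLOSED:
        return "c3_denovo_closed"
    return "none"


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Place CREs, genes and planted motifs; no signal or sequence yet."""
    rng = substream(config.seed, "layout")
    n_open = config.n_pre_cres_early // 2
    n_closed = config.n_pre_cres_early - n_open
    classes = (
        [CLASS_EPI] * config.n_epi_cres
        + [CLASS_PRE_EARLY_OPEN] * n_open
        + [CLASS_PRE_EARLY_CLOSED] * n_closed
        + [CLASS_PRE_LATE] * config.n_pre_cres_late
        + [CLASS_BACKGROUND] * config.n_background_peaks
    )
    n_sites = len(classes)

    slot = 25_000
    margin = 60_000  # keep everything clear of chromosome ends
    slots_per_chrom = (config.chrom_length_bp - 2 * margin) // slot
    total_slots = slots_per_chrom * config.n_chroms
    if n_sites + config.n_decoy_genes > total_slots:
        raise ValueError("genome too small for requested number of CREs")
    chosen = rng.choice(total_slots, size=n_sites + config.n_decoy_genes, replace=False)
    rng.shuffle(classes)

    motif_rng = substream(config.seed, "motifs")
    records = []
    genes: list[GeneModel] = []
    for i, (slot_idx, cls) in enumerate(zip(chosen[:n_sites], classes)):
        chrom = f"chr{slot_idx // slots_per_chrom + 1}"
        slot_start = margin + (slot_idx % slots_per_chrom) * slot
        start = slot_start + int(rng.integers(0, slot - CRE_WIDTH - 12_000))
        end = start + CRE_WIDTH
        cre_id = f"cre_{i:05d}"

        gene_id, tss = "", -1
        if cls != CLASS_BACKGROUND:
            gene_id = f"gene_{i:05d}"
            offset = int(rng.integers(1_000, 10_000)) * (1 if rng.random() < 0.5 else -1)
            tss = max((start + end) // 2 + offset, 0)
            lineage = "Epi" if cls == CLASS_EPI else "PrE"
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, tss=tss,
                                   strand="+" if rng.random() < 0.5 else "-",
                                   lineage=lineage))

        if cls == CLASS_EPI:
            density, mut = config.motif_density_epi, config.motif_strength_epi
        elif cls in (CLASS_PRE_EARLY_OPEN, CLASS_PRE_EARLY_CLOSED, CLASS_PRE_LATE):
            density, mut = config.motif_density_pre, config.motif_strength_pre
        else:
            density, mut = 0.0, 0.0
        width = len(_GATA_CONSENSUS)
        max_slots = CRE_WIDTH // (width * 4)
        n_motifs = int(min(motif_rng.poisson(density), max_slots)) if density > 0 else 0
        offsets = sorted(
            motif_rng.choice(max_slots, size=n_motifs, replace=False) * width * 4
            + width
        ) if n_motifs else []
        positions = [start + off for off in offsets]

        records.append(
            {
                "cre_id": cre_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "cls": cls,
                "gene_id": gene_id,
                "tss": tss,
                "n_motifs": n_motifs,
                "motif_positions": ",".join(map(str, positions)),
                "motif_mutation_rate": mut,
                "nanog_cluster": _expected_nanog_cluster(cls),
            }
        )

    for j, slot_idx in enumerate(chosen[n_sites:]):
        chrom = f"chr{slot_idx // slots_per_chrom + 1}"
        tss = margin + (slot_idx % slots_per_chrom) * slot + int(rng.integers(0, slot))
        genes.append(GeneModel(gene_id=f"decoy_{j:03d}", chrom=chrom, tss=tss,
                               strand="+", lineage="other"))

    cres = pd.DataFrame(records).set_index("cre_id")
    amp_rng = substream(config.seed, "amplitudes")
    amplitudes = pd.DataFrame(
        np.exp(amp_rng.normal(0.0, config.amp_sigma, size=(len(cres), len(ASSAYS)))),
        index=cres.index,
        columns=list(ASSAYS),
    )
    return GroundTruth(cres=cres, genes=genes, amplitudes=amplitudes)


# ---------------------------------------------------------------------------
# Genome sequence


def genome_sequences(config: SimConfig, truth: GroundTruth) -> dict[str, str]:
    """i.i.d. uniform background with planted (mutated) consensus copies."""
    rng = substream(config.seed, "genome")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {}
    for c in range(config.n_chroms):
        arr = bases[rng.integers(0, 4, size=config.chrom_length_bp)]
        seqs[f"chr{c + 1}"] = arr.copy()
    mut_rng = substream(config.seed, "motif_mutations")
    consensus = np.frombuffer(_GATA_CONSENSUS.encode(), dtype=np.uint8)
    for cre_id, row in truth.cres.iterrows():
        if not row["motif_positions"]:
            continue
        rate = row["motif_mutation_rate"]
        for pos in map(int, row["motif_positions"].split(",")):
            copy = consensus.copy()
            for i in range(len(copy)):
                if mut_rng.random() < rate:
                    alt = bases[mut_rng.integers(0, 4)]
                    while alt == copy[i]:
                        alt = bases[mut_rng.integers(0, 4)]
                    copy[i] = alt
            seqs[row["chrom"]][pos : pos + len(copy)] = copy
    return {name: arr.tobytes().decode() for name, arr in seqs.items()}


# ---------------------------------------------------------------------------
# Peaks and tracks


def planted_signal(config: SimConfig, truth: GroundTruth, cre_id: str,
                   assay: str, t: float) -> float:
    row = truth.cres.loc[cre_id]
    base = class_signal(row["cls"], assay, t, config)
    return base * truth.amplitudes.loc[cre_id, assay]


def build_peaks(config: SimConfig, truth: GroundTruth, assay: str, t: float) -> list[Peak]:
    """Peak calls at planted sites whose mean signal clears the call floor."""
    peaks = []
    for cre_id, row in truth.cres.iterrows():
        v = planted_signal(config, truth, cre_id, assay, t)
        if v >= PEAK_CALL_MIN:
            q = 10.0 ** -(1.0 + v)
            peaks.append(Peak(row["chrom"], int(row["start"]), int(row["end"]),
                              name=cre_id, score=float(v), qvalue=q))
    return peaks


def build_track(config: SimConfig, truth: GroundTruth, assay: str, t: float) -> SignalTrack:
    """Flat-bump signal track: each CRE contributes its planted value over
    its interval. Amplitude noise is per CRE (constant across timepoints) so
    planted temporal orderings hold exactly on the tracks."""
    n_bins = config.chrom_length_bp // TRACK_BIN
    values = {f"chr{c + 1}": np.zeros(n_bins) for c in range(config.n_chroms)}
    for cre_id, row in truth.cres.iterrows():
        v = planted_signal(config, truth, cre_id, assay, t)
        if v <= 0:
            continue
        lo, hi = int(row["start"]) // TRACK_BIN, (int(row["end"]) - 1) // TRACK_BIN + 1
        values[row["chrom"]][lo:hi] += v
    return SignalTrack(bin_size=TRACK_BIN, values=values,
                       normalization_tag=f"{assay}_{t}h_synthetic")


def build_fragments(config: SimConfig, n_fragments: int = 5_000) -> FragmentSet:
    """Bimodal fragment-length mixture: subnucleosomal (~80 bp) and
    nucleosomal (~200 bp) components."""
    rng = substream(config.seed, "fragments")
    is_nuc = rng.random(n_fragments) < 0.5
    lengths = np.where(
        is_nuc,
        rng.normal(200.0, 20.0, n_fragments),
        rng.normal(80.0, 15.0, n_fragments),
    )
    lengths = np.clip(np.round(lengths), 25, 500).astype(int)
    chroms = rng.integers(1, config.n_chroms + 1, n_fragments)
    starts = rng.integers(0, config.chrom_length_bp - 600, n_fragments)
    return FragmentSet(
        [(f"chr{c}", int(s), int(s + l)) for c, s, l in zip(chroms, starts, lengths)]
    )


# ---------------------------------------------------------------------------
# RNA counts


def _expression(cls: str, t: float) -> float:
    if cls == CLASS_EPI:
        return 0.1 + _decay(t, 1.9, 10.0, 4.0)
    if cls in (CLASS_PRE_EARLY_OPEN, CLASS_PRE_EARLY_CLOSED):
        return 0.1 + _rise(t, 1.9, 8.0, 4.0)
    if cls == CLASS_PRE_LATE:
        return 0.1 + _rise(t, 1.9, 36.0, 4.0)
    return 1.0


def rna_counts(config: SimConfig, truth: GroundTruth) -> CountTable:
    """Gene-level NB counts along the time course (genes with a CRE plus
    decoys at constant expression)."""
    rng = substream(config.seed, "rna")
    lineage_of = {row["gene_id"]: row["cls"] for _, row in truth.cres.iterrows()
                  if row["gene_id"]}
    gene_ids = [g.gene_id for g in truth.genes]
    gene_ids += [f"stable_{i:04d}" for i in range(config.n_stable_genes)]
    samples, conditions = [], {}
    for t in config.timepoints:
        for r in range(1, config.n_replicates + 1):
            s = f"t{t}h_rep{r}"
            samples.append(s)
            conditions[s] = f"t{t}h"
    data = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for i, gid in enumerate(gene_ids):
        cls = lineage_of.get(gid, CLASS_BACKGROUND)
        for j, s in enumerate(samples):
            t = float(conditions[s][1:-1])
            mean = config.depth * _expression(cls, t)
            data[i, j] = planted_counts(mean, config.nb_dispersion, 1, rng)[0]
    counts = pd.DataFrame(data, index=gene_ids, columns=samples)
    return CountTable(counts=counts, conditions=pd.Series(conditions))


# ---------------------------------------------------------------------------
# Transgene segment counts


def transgene_tables(
    config: SimConfig,
    noiseless: bool = True,
    coverage: float = 1_000.0,
    n_induced: int = 4,
    n_reference: int = 4,
    dispersion: float | None = None,
) -> dict:
    """Segment count table for the T/E computation.

    Segments: CDS_last_exon (1000 bp) and UTR3 (500 bp). Reference (96 h)
    samples express only the endogenous locus; induced samples add the
    transgene at ``config.transgene_ratio`` times the endogenous level over
    the CDS. Noise, when enabled, is per-base NB aggregated over the segment
    (dispersion defaults to config.nb_dispersion).
    """
    rng = substream(config.seed, "transgene")
    lengths = {"CDS_last_exon": 1_000, "UTR3": 500}
    lib = 1e6
    endo = 1.0  # endogenous expression rate, normalized units
    ratio = config.transgene_ratio
    samples = [f"induced_{i + 1}" for i in range(n_induced)] + [
        f"96h_{i + 1}" for i in range(n_reference)
    ]
    disp = config.nb_dispersion if dispersion is None else dispersion
    per_base = {s: {} for s in samples}
    counts = pd.DataFrame(0.0, index=list(lengths), columns=samples)
    for s in samples:
        induced = s.startswith("induced")
        for kind, length in lengths.items():
            rate = endo
            if induced and kind == "CDS_last_exon":
                rate = endo * (1.0 + ratio)
            # counts scale with both rate and segment length so the per-kb
            # normalization recovers `rate` in common units
            mean_total = coverage * rate * (length / 1000.0)
            if noiseless:
                counts.loc[kind, s] = mean_total
            else:
                per_base_mean = mean_total / length
                counts.loc[kind, s] = int(
                    planted_counts(per_base_mean, disp, length, rng).sum()
                )
    # library size that makes normalized(utr, reference) == coverage units
    library_sizes = pd.Series(lib, index=samples)
    return {
        "counts": counts,
        "library_sizes": library_sizes,
        "segment_lengths": lengths,
        "reference_samples": [s for s in samples if s.startswith("96h")],
        "planted_ratio": ratio,
    }


# ---------------------------------------------------------------------------
# Single-cell / bulk staging pair


def staging_pair(
    config: SimConfig,
    n_genes: int = 300,
    n_cells_per_cluster: int = 40,
    stage_timepoints: Sequence[int] = (0, 16, 48),
    signature_size: int = 30,
    signature_effect: float = 3.0,
) -> dict:
    """Matched bulk and single-cell matrices with planted correspondence.

    Each staging timepoint gets one cluster with a disjoint signature gene
    set; the 16 h cluster is split into two sub-clusters to exercise cluster
    merging. Bulk samples at a timepoint share the cluster's profile, so
    residual PCA must map them onto that cluster.
    """
    rng = substream(config.seed, "staging")
    genes = [f"sg_{i:04d}" for i in range(n_genes)]
    base = rng.normal(3.0, 0.5, n_genes)  # log-scale baseline
    profiles = {}
    for k, t in enumerate(stage_timepoints):
        prof = base.copy()
        sig = slice(k * signature_size, (k + 1) * signature_size)
        prof[sig] += signature_effect
        profiles[t] = prof

    # single-cell side: Poisson counts per cell around exp(profile)
    cells, cell_clusters = {}, {}
    cluster_merge = {}
    for t in stage_timepoints:
        sub_labels = [f"E_{t}h:a", f"E_{t}h:b"] if t == stage_timepoints[1] else [f"E_{t}h"]
        for sub in sub_labels:
            if ":" in sub:
                cluster_merge[sub] = f"E_{t}h"
            n_cells = n_cells_per_cluster // len(sub_labels)
            for i in range(n_cells):
                name = f"cell_{sub}_{i:03d}"
                depth_factor = rng.uniform(0.5, 1.5)
                cells[name] = rng.poisson(np.exp(profiles[t]) * depth_factor)
                cell_clusters[name] = sub
    sc_counts = pd.DataFrame(cells, index=genes)

    # bulk side: NB counts around the same profiles with a platform offset
    platform = rng.normal(0.0, 0.3, n_genes)
    samples, conditions, cols = [], {}, {}
    truth_cluster = {}
    for t in stage_timepoints:
        for r in range(1, config.n_replicates + 1):
            s = f"bulk_t{t}h_rep{r}"
            samples.append(s)
            conditions[s] = f"t{t}h"
            mean = np.exp(profiles[t] + platform)
            cols[s] = [planted_counts(m, 0.02, 1, rng)[0] for m in mean]
            truth_cluster[s] = f"E_{t}h"
    bulk = CountTable(counts=pd.DataFrame(cols, index=genes),
                      conditions=pd.Series(conditions))
    return {
        "bulk": bulk,
        "sc_counts": sc_counts,
        "cell_clusters": pd.Series(cell_clusters),
        "cluster_merge": cluster_merge,
        "truth": truth_cluster,
    }


# ---------------------------------------------------------------------------
# Viewpoint profiles


def simulate_viewpoint(
    config: SimConfig,
    fold: float = 3.0,
    region_length: int = 50_000,
    gain_span: tuple[int, int] = (15_000, 21_000),
    base_depth: float = 300.0,
    dispersion: float = 0.001,
    name: str = "vp1",
    seed_offset: int = 0,
) -> dict:
    """One viewpoint profile pair (0 h vs 48 h) with a planted fold gain
    over ``gain_span`` (region-relative coordinates) at 48 h."""
    rng = substream(config.seed + seed_offset, f"viewpoint_{name}")
    bin_size = 1_000
    n_bins = region_length // bin_size
    centre = n_bins // 2
    dist = np.abs(np.arange(n_bins) - centre)
    mean = base_depth / (1.0 + dist / 8.0) + 20.0
    gain = np.ones(n_bins)
    lo, hi = gain_span[0] // bin_size, gain_span[1] // bin_size
    gain[lo:hi] = fold
    signal = {}
    for cond, factor in (("0h", np.ones(n_bins)), ("48h", gain)):
        reps = np.zeros((config.n_replicates, n_bins))
        for r in range(config.n_replicates):
            for b in range(n_bins):
                reps[r, b] = planted_counts(mean[b] * factor[b], dispersion, 1, rng)[0]
        signal[cond] = reps
    start = 1_000_000
    profile = ViewpointProfile(
        viewpoint_id=name,
        chrom="chr1",
        start=start,
        end=start + region_length,
        signal=signal,
        bin_size=bin_size,
    )
    return {
        "profile": profile,
        "gain_interval": (start + gain_span[0], start + gain_span[1]),
        "fold": fold,
    }


# ---------------------------------------------------------------------------
# Contact matrices


def simulate_contacts(
    config: SimConfig,
    n_bins: int = 40,
    n_switch: int = 2,
    base: float = 2_000.0,
    checker: float = 0.5,
    sample_noise: bool = True,
) -> dict:
    """Two-block compartment toy matrices; ``n_switch`` bins flip block
    between conditions. Returns matrices, planted compartment vectors, and
    per-condition activity references."""
    rng = substream(config.seed, "contacts")
    comp_a = np.where(np.arange(n_bins) < n_bins // 2, 1.0, -1.0)
    switch_bins = sorted(
        rng.choice(n_bins, size=n_switch, replace=False).tolist()
    )
    comp_b = comp_a.copy()
    comp_b[switch_bins] *= -1.0

    def build(comp: np.ndarray) -> np.ndarray:
        d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
        decay = 1.0 / (1.0 + d / 10.0)
        m = base * decay * (1.0 + checker * np.outer(comp, comp))
        if sample_noise:
            upper = rng.poisson(m)
            m = np.triu(upper) + np.triu(upper, 1).T
        return m.astype(float)

    return {
        "matrix_a": build(comp_a),
        "matrix_b": build(comp_b),
        "comp_a": comp_a,
        "comp_b": comp_b,
        "reference_a": comp_a.copy(),  # activity score, positive in A
        "reference_b": comp_b.copy(),
        "switch_bins": switch_bins,
    }


# ---------------------------------------------------------------------------
# Full simulation to disk


def simulate(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Write the complete synthetic data set and return the ground truth."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    truth = make_ground_truth(config)

    write_fasta(genome_sequences(config, truth), out / "genome.fa")
    for assay in ASSAYS:
        for t in config.timepoints:
            peaks = build_peaks(config, truth, assay, t)
            write_peaks(peaks, out / f"peaks_{assay}_{t}h.narrowPeak", format="narrowPeak")
            write_bedgraph(build_track(config, truth, assay, t),
                           out / f"track_{assay}_{t}h.bedgraph")
    write_fragments(build_fragments(config), out / "fragments.bed")
    write_genes(truth.genes, out / "genes.tsv")

    rna = rna_counts(config, truth)
    rna.counts.to_csv(out / "rna_counts.tsv", sep="\t")
    pd.DataFrame({"condition": rna.conditions}).to_csv(out / "rna_meta.tsv", sep="\t")

    tg = transgene_tables(config, noiseless=True)
    tg["counts"].to_csv(out / "transgene_segment_counts.tsv", sep="\t")

    stage = staging_pair(config)
    stage["bulk"].counts.to_csv(out / "bulk_stage_counts.tsv", sep="\t")
    pd.DataFrame({"condition": stage["bulk"].conditions}).to_csv(
        out / "bulk_stage_meta.tsv", sep="\t")
    stage["sc_counts"].to_csv(out / "sc_counts.tsv", sep="\t")
    pd.DataFrame({"cluster": stage["cell_clusters"]}).to_csv(out / "sc_clusters.tsv", sep="\t")
    with open(out / "cluster_merge.yaml", "w") as fh:
        yaml.safe_dump(stage["cluster_merge"], fh)

    from .chromatin_3d import write_contact_matrix, write_viewpoint_tsv

    vp = simulate_viewpoint(config)
    write_viewpoint_tsv(vp["profile"], out / f"viewpoint_{vp['profile'].viewpoint_id}.tsv")

    contacts = simulate_contacts(config)

    write_contact_matrix(contacts["matrix_a"], out / "contacts_0h.tsv")
    write_contact_matrix(contacts["matrix_b"], out / "contacts_48h.tsv")

    truth.extras = {
        "transgene": {"planted_ratio": tg["planted_ratio"]},
        "staging_truth": stage["truth"],
        "viewpoint": {"gain_interval": vp["gain_interval"], "fold": vp["fold"]},
        "switch_bins": contacts["switch_bins"],
    }
    truth.cres.to_csv(out / "ground_truth_cres.tsv", sep="\t")
    pd.DataFrame(
        {"bulk_sample": list(stage["truth"]), "cluster": list(stage["truth"].values())}
    ).to_csv(out / "ground_truth_staging.tsv", sep="\t", index=False)
    pd.DataFrame({"switch_bin": contacts["switch_bins"]}).to_csv(
        out / "ground_truth_switches.tsv", sep="\t", index=False)
    with open(out / "sim_config.yaml", "w") as fh:
        cfg = asdict(config)
        cfg["timepoints"] = list(cfg["timepoints"])
        yaml.safe_dump(cfg, fh)
    return truth
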