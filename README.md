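# credyn

Toolkit for analysing cis-regulatory element (CRE) dynamics across a
TF-induced differentiation time course, exercised end to end on a synthetic
multi-omic data generator with planted ground truth. It covers:

- **genomic_io** — BED/narrowPeak/bedGraph/FASTA/TSV readers and writers,
  interval overlap, binned signal tracks, fragment-size selection
  (TF < 120 bp, histone > 150 bp, nucleosomal ATAC > 180 bp).
- **synthetic_data** — deterministic generator for a 9-timepoint
  (0–48 h) time course: planted Epi/PrE CREs with class-specific signal
  trajectories for GATA6/NANOG/SOX2/ATAC/H3K27ac, planted GATA6 motif
  copies (denser and closer to consensus at PrE CREs), negative-binomial
  replicate counts, fragment-length mixtures, a transgene segment table,
  matched bulk and single-cell matrices, viewpoint interaction profiles
  with planted gains, and two-compartment toy contact matrices with
  switching bins. All effect sizes are synthetic free parameters.
- **count_stats** — median-of-ratios size factors, an unshrunk NB Wald
  test (method-of-moments dispersion pooled within conditions, small-sample
  t reference), BH-FDR, and up/stable/down classification.
- **cre_annotation** — nearest-TSS peak-to-gene assignment within 50 kb,
  proximal/distal split at 5 kb (strict), Epi/PrE lineage labelling.
- **peak_dynamics** — top-N peak ranking by q-value; GATA6
  early/late × open/closed taxonomy; NANOG 2 h cluster assignment
  (pre-existing / de novo open / de novo closed).
- **signal_redistribution** — peak-by-(assay, timepoint) signal matrices,
  median log-ratio redistribution scoring with a detection rule, and
  meta-profiles around reference points.
- **motif_scan** — PWM scanning of both strands with exact p-values
  (dynamic programming over integer-scaled log-odds scores), FIMO-style
  q-values over the scanned-window universe, per-peak motif density and
  per-class motif strength comparison (Mann–Whitney).
- **transcriptomics** — transgene T/E quantification from CDS/3'UTR
  segment counts, lineage gene-list intersection of two DE tables, DE
  time-course first-change calling, and bulk↔single-cell staging via
  per-gene group-residual PCA with nearest-centroid mapping.
- **chromatin_3d** — Capture-C sliding-window differential interactions
  (5 kb windows, 500 bp step, padj < 0.01) and Hi-C A/B compartment
  eigenvectors (250 kb bins) with correlation-based switch calling
  (r < 0.4, strict).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(motif exact-p oracle, taxonomy/redistribution/staging recovery on planted
data, null calibration of the differential test, Capture-C window
detection, compartment switch calling, and threshold-boundary fidelity).

The acceptance report script (this artifact defines no numeric targets, so
the report is an empty JSON object):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## CLI

The package installs a single `cre` entry point:

```sh
cre simulate --config sim.yaml --out simdir/      # synthetic data set
cre io validate simdir/peaks_GATA6_2h.narrowPeak
cre diff --counts rna_counts.tsv --meta rna_meta.tsv \
    --contrast t48h,t0h --lfc 2 --padj 0.1 --out diff.tsv
cre annotate --peaks peaks.bed --genes genes.tsv --out assign.tsv
cre taxonomy gata6 --t2 ... --t4 ... --t8 ... --t48 ... --atac0 ... --out tax.tsv
cre taxonomy nanog2h --n0 ... --n2 ... --atac0 ... --out clusters.tsv
cre motif scan --fasta genome.fa --peaks peaks.bed --pwm gata6.pfm --out hits.tsv
cre transgene --counts transgene_segment_counts.tsv \
    --ref-samples 96h_1,96h_2,96h_3,96h_4
cre stage --bulk bulk.tsv --bulk-meta meta.tsv --sc sc.tsv \
    --cells clusters.tsv --merge merge.yaml --out stage.tsv
cre capture diff --profile viewpoint_vp1.tsv --out runs.bed
cre hic compartments --matrix-a contacts_0h.tsv --matrix-b contacts_48h.tsv \
    --reference ref.tsv --out switches.tsv
cre run --config run.yaml                         # full pipeline
```

`cre run` simulates a data set and executes every stage, writing per-stage
outputs, `summary.json` (deterministic for a fixed seed), and a run log
with version and config hash. All thresholds are surfaced in the run config
with the published analysis values as defaults (50 kb assignment window,
5 kb proximal cut, top 10,000/15,000 peaks, ATAC padj 1e-4 / RNA FDR 0.1
with |log2FC| ≥ 2, motif p/q 1e-3, 5 kb/500 bp windows at padj 0.01,
250 kb compartment bins, switch r < 0.4).

## Ground truth schema

`cre simulate` writes `ground_truth_cres.tsv` with one row per planted CRE:
`cre_id, chrom, start, end, cls` (Epi / PrE_early_open / PrE_early_closed /
PrE_late / background), `gene_id, tss`, `n_motifs, motif_positions`
(comma-separated genomic starts), `motif_mutation_rate`, and the expected
`nanog_cluster`. Additional truth tables cover staging
(`ground_truth_staging.tsv`) and compartment switches
(`ground_truth_switches.tsv`); the full simulation config is echoed to
`sim_config.yaml`.
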