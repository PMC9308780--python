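import itertools

import numpy as np
import pytest

from credyn.genomic_io import Peak
from credyn.motif_scan import (
    MotifHit,
    MotifModel,
    density_by_class,
    estimate_background,
    exact_score_distribution,
    motif_density,
    motif_strength,
    read_jaspar,
    reverse_complement,
    scan,
    score_pvalue_table,
    write_hits,
)
from credyn.synthetic_data import gata6_motif


def random_motif(k, seed, conc=0.5):
    rng = np.random.default_rng(seed)
    return MotifModel(f"rand{k}", rng.dirichlet(np.ones(4) * conc, size=k))


def enumeration_survival(motif):
    """Independent oracle: exact survival function by enumerating 4^k words."""
    ints = motif.int_scores()
    q = motif.background
    k = motif.width
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=k):
        scores.append(sum(int(ints[i, b]) for i, b in enumerate(word)))
        p = 1.0
        for b in word:
            p *= q[b]
        probs.append(p)
    scores = np.array(scores)
    probs = np.array(probs)
    return lambda s: probs[scores >= s].sum()


class TestJasparParsing:
    JASPAR = """>MA0000.1 TESTY
A  [ 10  0  0 10 ]
C  [  0 10  0  0 ]
G  [  0  0 10  0 ]
T  [  0  0  0  0 ]
"""

    def test_parse(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(self.JASPAR)
        motifs = read_jaspar(p)
        assert len(motifs) == 1
        assert motifs[0].width == 4
        assert motifs[0].consensus() == "ACGA"
        np.testing.assert_allclose(motifs[0].ppm.sum(axis=1), 1.0)


class TestModelInvariants:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotifModel("bad", np.full((5, 4), 0.3))

    def test_minimum_width(self):
        with pytest.raises(ValueError, match="width"):
            MotifModel("short", np.full((3, 4), 0.25))


class TestExactPValues:
    @pytest.mark.parametrize("k,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_dp_matches_enumeration(self, k, seed):
        motif = random_motif(k, seed)
        rng = np.random.default_rng(seed + 100)
        background = rng.dirichlet(np.ones(4) * 5)
        m = motif.with_background(background)
        sf, lo = score_pvalue_table(m)
        oracle = enumeration_survival(m)
        achievable = sorted(set(
            int(s) for s in (m.int_scores()[range(k), w].sum()
                             for w in itertools.product(range(4), repeat=k))
        )) if k <= 5 else [lo, lo + len(sf) // 3, lo + 2 * len(sf) // 3, lo + len(sf) - 1]
        for s in achievable:
            expected = oracle(s)
            got = sf[s - lo]
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)

    def test_survival_at_minimum_is_one(self):
        m = random_motif(6, 9)
        sf, lo = score_pvalue_table(m)
        assert sf[0] == pytest.approx(1.0, abs=1e-12)

    def test_pmf_sums_to_one(self):
        m = random_motif(8, 11)
        pmf, _ = exact_score_distribution(m)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_consensus_pvalue_is_max_probability_product(self):
        # uniform background, distinct column maxima: P(score >= max score)
        # equals the product over positions of the max-cell background mass
        m = gata6_motif().with_background(np.full(4, 0.25))
        sf, lo = score_pvalue_table(m)
        max_score = int(m.int_scores().max(axis=1).sum())
        assert sf[max_score - lo] == pytest.approx(0.25 ** m.width, rel=1e-10)


class TestScan:
    def planted_sequence(self, seed=0, n=2_000):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), n))
        motif = gata6_motif()
        cons = motif.consensus()
        return seq[:900] + cons + seq[900 + len(cons):], motif

    def test_finds_planted_consensus(self):
        seq, motif = self.planted_sequence()
        hits = scan({"chr1": seq}, motif, p_max=1e-3)
        assert any(h.start == 900 and h.strand == "+" for h in hits)

    def test_specificity_on_random_sequence(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 5_000))
        hits = scan({"chr1": seq}, gata6_motif(), p_max=1e-7)
        assert len(hits) == 0

    def test_reverse_complement_symmetry(self):
        seq, motif = self.planted_sequence(seed=3)
        fwd = scan({"chr1": seq}, motif, p_max=1e-3)
        rev = scan({"chr1": reverse_complement(seq)}, motif, p_max=1e-3)
        n = len(seq)
        mirrored = {(n - h.end, n - h.start, {"+": "-", "-": "+"}[h.strand])
                    for h in rev}
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored

    def test_n_windows_skipped(self):
        seq, motif = self.planted_sequence()
        seq = seq[:900] + "N" + seq[901:]  # break the planted copy
        hits = scan({"chr1": seq}, motif, p_max=1e-3)
        assert not any(h.start <= 900 < h.end for h in hits)

    def test_short_sequence_empty(self):
        assert scan({"c": "ACG"}, gata6_motif(), p_max=1.0) == []

    def test_scan_pvalues_match_enumeration(self):
        seq, _ = self.planted_sequence(seed=7)
        motif = random_motif(5, 42)
        background = estimate_background([seq])
        m = motif.with_background(background)
        oracle = enumeration_survival(m)
        hits = scan({"chr1": seq}, motif, p_max=0.05)
        assert hits
        for h in hits[:50]:
            s = int(round(h.score / 1e-3))
            assert h.p == pytest.approx(oracle(s), rel=1e-10)

    def test_qvalues_bounded_by_windows(self):
        seq, motif = self.planted_sequence()
        hits = scan({"chr1": seq}, motif, p_max=1e-2)
        for h in hits:
            assert h.q >= h.p - 1e-15
            assert 0 < h.q <= 1


class TestDensityStrength:
    def make_hit(self, start, chrom="chr1", q=0.01):
        return MotifHit(chrom, start, start + 8, "+", 5.0, 1e-4, q, "AGATAAGA")

    def test_contained_hits_counted(self):
        peaks = [Peak("chr1", 100, 500)]
        hits = [self.make_hit(150), self.make_hit(200), self.make_hit(496)]
        counts = motif_density(peaks, hits)
        assert counts[0] == 2  # the hit straddling the edge (496+8 > 500) is excluded

    def test_edge_straddling_excluded(self):
        peaks = [Peak("chr1", 100, 500)]
        assert motif_density(peaks, [self.make_hit(495)])[0] == 0

    def test_empty_hits_zero(self):
        assert motif_density([Peak("chr1", 0, 100)], [])[0] == 0

    def test_translation_invariance(self):
        peaks = [Peak("chr1", 100, 500)]
        hits = [self.make_hit(150), self.make_hit(300)]
        shift = 10_000
        peaks2 = [Peak("chr1", 100 + shift, 500 + shift)]
        hits2 = [self.make_hit(150 + shift), self.make_hit(300 + shift)]
        np.testing.assert_array_equal(motif_density(peaks, hits),
                                      motif_density(peaks2, hits2))

    def test_density_by_class(self):
        peaks = [Peak("chr1", 0, 100, labels={"Epi"}),
                 Peak("chr1", 200, 300, labels={"PrE"})]
        counts = np.array([1, 3])
        by = density_by_class(peaks, counts, ["Epi", "PrE"])
        assert by["Epi"].tolist() == [1] and by["PrE"].tolist() == [3]

    def test_strength_identical_classes(self):
        peaks = [Peak("chr1", 0, 1000, labels={"A"}),
                 Peak("chr1", 2000, 3000, labels={"B"})]
        hits = [self.make_hit(s, q=q) for s, q in
                [(10, 0.1), (50, 0.2), (90, 0.3), (2010, 0.1), (2050, 0.2), (2090, 0.3)]]
        res = motif_strength(peaks, hits, ["A", "B"])
        assert res["medians"]["A"] == res["medians"]["B"]
        assert res["test"]["p"] > 0.5

    def test_single_hit_class_skipped_with_warning(self):
        peaks = [Peak("chr1", 0, 100, labels={"A"}), Peak("chr1", 200, 300, labels={"B"})]
        res = motif_strength(peaks, [self.make_hit(10)], ["A", "B"])
        assert res["test"] is None
        assert "skipped" in res["warning"]


class TestSyntheticMotifContrast:
    def test_pre_motifs_denser_and_stronger_than_epi(self, small_config, small_truth):
        from credyn.synthetic_data import genome_sequences

        genome = genome_sequences(small_config, small_truth)
        peaks, seqs = [], {}
        for cre_id, row in small_truth.cres.iterrows():
            if row["cls"] == "background" or row["cls"] == "PrE_late":
                continue
            label = "Epi" if row["cls"] == "Epi" else "PrE"
            key = cre_id
            seqs[key] = genome[row["chrom"]][row["start"]:row["end"]]
            peaks.append(Peak(key, 0, int(row["end"] - row["start"]), labels={label}))
        hits = scan(seqs, gata6_motif(), p_max=1e-3)
        counts = motif_density(peaks, hits)
        by = density_by_class(peaks, counts, ["Epi", "PrE"])
        assert by["PrE"].mean() > by["Epi"].mean()
        strength = motif_strength(peaks, hits, ["Epi", "PrE"])
        assert strength["medians"]["PrE"] <= strength["medians"]["Epi"]

    def test_planted_motif_positions_recovered(self, small_config, small_truth):
        from credyn.synthetic_data import genome_sequences

        genome = genome_sequences(small_config, small_truth)
        # strong-motif CREs: every planted position should yield a hit
        sub = small_truth.cres[(small_truth.cres["cls"] == "PrE_early_open")
                               & (small_truth.cres["n_motifs"] > 0)].head(10)
        for cre_id, row in sub.iterrows():
            seq = genome[row["chrom"]][row["start"]:row["end"]]
            hits = scan({cre_id: seq}, gata6_motif(), p_max=1e-3)
            starts = {h.start + row["start"] for h in hits}
            planted = set(map(int, row["motif_positions"].split(",")))
            # mutated copies may fall below threshold; near-consensus rate is
            # 0.02/base so the vast majority must be found
            assert len(planted & starts) >= len(planted) - 1


def test_write_hits_roundtrip_columns(tmp_path):
    hits = [MotifHit("chr1", 5, 13, "+", 9.1, 1e-5, 1e-3, "AGATAAGA", "m1")]
    out = tmp_path / "hits.tsv"
    write_hits(hits, out)
    header = out.read_text().splitlines()[0].split("\t")
    assert header == ["motif", "chrom", "start", "end", "strand", "score", "p", "q",
                      "matched"]
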