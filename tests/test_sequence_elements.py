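"""Motif models, exact p-values, window scans and processing-motif
profiles."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest

from divtx import sequence_elements as se
from divtx.genomic_io import InMemoryGenome, revcomp


class TestMotifModel:
    def test_consensus_expansion_rows_sum_to_one(self):
        for m in se.default_core_promoter_motifs():
            assert np.allclose(m.matrix.sum(axis=1), 1.0)

    def test_scores_along_matches_per_word_scoring(self):
        m = se.MotifModel.from_consensus("TATA", "TATAWAWR")
        seq = "GGTATAAAAGG"
        scores = m.scores_along(seq)
        for i, s in enumerate(scores):
            assert s == pytest.approx(m.score(seq[i:i + len(m)]))

    def test_meme_round_trip(self, tmp_path):
        motifs = se.default_core_promoter_motifs()
        path = str(tmp_path / "motifs.meme")
        se.write_meme(motifs, path)
        back = se.read_meme(path)
        assert [m.name for m in back] == [m.name for m in motifs]
        for a, b in zip(motifs, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)


class TestPvalues:
    def test_length_one_unique_base(self):
        m = se.MotifModel("x", np.array([[0.97, 0.01, 0.01, 0.01]]))
        grid, pvals = se.motif_pvalue_table(m)
        # only 'A' attains the max score; p = P(A) = 0.25
        assert se.score_pvalue(m.max_score, grid, pvals) == pytest.approx(
            0.25)

    def test_min_score_has_pvalue_one(self):
        m = se.MotifModel.from_consensus("Inr", "TCAGTY")
        grid, pvals = se.motif_pvalue_table(m)
        assert se.score_pvalue(m.min_score, grid, pvals) == pytest.approx(1.0)

    @pytest.mark.parametrize("consensus,background", [
        ("CACGTG", None),
        ("RGWYVT", None),
        ("AWTAAA", np.array([0.3, 0.2, 0.2, 0.3])),
    ])
    def test_dp_matches_exhaustive_enumeration(self, consensus, background):
        """For motifs of length <= 6 the DP null distribution matches a
        brute-force enumeration over all 4^L words within 1e-6 (on the
        shared score discretization)."""
        res = 0.01
        m = se.MotifModel.from_consensus("m", consensus, background)
        grid, pvals = se.motif_pvalue_table(m, resolution=res)
        bg = m.background
        int_scores = np.round(m.log_odds / res).astype(int)
        exact_tail = {}
        for w in itertools.product(range(4), repeat=len(m)):
            s = sum(int_scores[i, b] for i, b in enumerate(w))
            p = float(np.prod([bg[b] for b in w]))
            exact_tail[s] = exact_tail.get(s, 0.0) + p
        scores = sorted(exact_tail, reverse=True)
        running = 0.0
        for s in scores:
            running += exact_tail[s]
            dp = se.score_pvalue(s * res, grid, pvals, resolution=res)
            assert dp == pytest.approx(running, abs=1e-6)

    def test_dp_tail_probability_decreases(self):
        m = se.MotifModel.from_consensus("DRE", "WATCGATW")
        grid, pvals = se.motif_pvalue_table(m)
        assert (np.diff(pvals) <= 1e-12).all()


def genome_with(seq_center, flank_seq="C", total=401):
    """Genome of C's with *seq_center* centered at position 200."""
    left = flank_seq * (200 - len(seq_center) // 2)
    seq = (left + seq_center).ljust(total, flank_seq)
    return InMemoryGenome({"c": seq})


class TestScan:
    def summits(self, strand="+", role="major"):
        return pd.DataFrame([{"dhs_id": "d0", "strand_role": role,
                              "chrom": "c", "summit": 200,
                              "strand": strand}])

    def test_planted_tata_found_at_offset(self):
        g = InMemoryGenome({"c": "C" * 401})
        g.plant("c", 170, "TATAAAAA")  # offset -30 from summit 200
        hits = se.scan_windows(g, self.summits(), [
            se.MotifModel.from_consensus("TATA", "TATAWAWR")])
        hit = hits.iloc[0]
        assert hit["offset"] == -30
        assert hit["significant"]

    def test_random_sequence_no_hits_at_tiny_threshold(self):
        rng = np.random.default_rng(0)
        g = InMemoryGenome(
            {"c": "".join(rng.choice(list("ACGT"), 401))})
        hits = se.scan_windows(g, self.summits(),
                               se.default_core_promoter_motifs(),
                               p_threshold=1e-9)
        assert not hits["significant"].any()

    def test_minus_strand_scan_equals_revcomp_plus_scan(self):
        """Strand symmetry: a motif planted in antisense orientation is
        found on the minus-strand scan at the same offset."""
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 401))
        motif = se.MotifModel.from_consensus("DRE", "TATCGATA")
        g_plus = InMemoryGenome({"c": base})
        g_plus.plant("c", 180, "TATCGATA")
        hits_plus = se.scan_windows(g_plus, self.summits("+"), [motif])
        g_minus = InMemoryGenome({"c": revcomp(base)})
        # same sequence viewed from the other strand; summit mirrors to
        # position len-1-200 = 200
        g_minus.plant("c", 401 - 188, revcomp("TATCGATA"))
        hits_minus = se.scan_windows(g_minus, self.summits("-"), [motif])
        assert hits_plus.iloc[0]["offset"] == hits_minus.iloc[0]["offset"]
        assert hits_plus.iloc[0]["score"] == pytest.approx(
            hits_minus.iloc[0]["score"])

    def test_truncated_window_flagged(self):
        g = InMemoryGenome({"c": "ACGT" * 20})
        s = pd.DataFrame([{"dhs_id": "d", "strand_role": "major",
                           "chrom": "c", "summit": 10, "strand": "+"}])
        hits = se.scan_windows(g, s, [se.MotifModel.from_consensus(
            "Ebox_Ohler5", "CACGTG")])
        assert hits.iloc[0]["truncated"]


class TestPositionalProfile:
    def test_all_hits_at_one_offset(self):
        hits = pd.DataFrame([
            {"dhs_id": f"d{i}", "strand_role": "major", "motif": "TATA",
             "offset": -30, "score": 9.0, "p_value": 1e-5,
             "significant": True} for i in range(5)])
        prof = se.positional_profile(hits, n_dhs=5)
        at = prof[(prof["offset"] == -30)]
        assert at["fraction"].iloc[0] == 1.0
        assert prof[prof["offset"] != -30]["fraction"].sum() == 0.0

    def test_no_hits_gives_empty_profile(self):
        hits = pd.DataFrame(columns=["dhs_id", "strand_role", "motif",
                                     "offset", "score", "p_value",
                                     "significant"])
        prof = se.positional_profile(hits, n_dhs=5)
        assert len(prof) == 0 or (prof["fraction"] == 0).all()

    def test_planted_offsets_recovered(self, default_dataset, default_run):
        """Core promoter elements planted by the generator are recovered
        at their planted offsets."""
        hits = default_run.motif_hits
        truth = default_dataset.truth_motifs
        truth_cp = truth[truth["motif"].isin(se.CORE_PROMOTER_CONSENSUS)]
        merged = truth_cp.merge(
            hits[hits["significant"]],
            on=["dhs_id", "strand_role", "motif"], how="inner")
        recall = len(merged) / len(truth_cp)
        assert recall >= 0.8
        # significant rediscovered hits sit at the planted offset
        frac_at_offset = (merged["offset_x"] == merged["offset_y"]).mean()
        assert frac_at_offset >= 0.9


class TestCorePromoterClustering:
    def test_two_regimes_separate_perfectly(self):
        rng = np.random.default_rng(3)
        a = np.column_stack([rng.normal(8, 0.3, 30),
                             rng.normal(-6, 0.3, 30)])
        b = np.column_stack([rng.normal(-6, 0.3, 30),
                             rng.normal(8, 0.3, 30)])
        mat = pd.DataFrame(
            np.vstack([a, b]), columns=["m1", "m2"],
            index=pd.MultiIndex.from_tuples(
                [(f"d{i}", "major") for i in range(60)]))
        clusters = se.cluster_core_promoters(mat, k=2)
        assert clusters.iloc[:30].nunique() == 1
        assert clusters.iloc[30:].nunique() == 1
        assert clusters.iloc[0] != clusters.iloc[-1]

    def test_fully_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((20, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            se.cluster_core_promoters(mat, k=2)

    def test_enrichment_zero_for_representative_class(self):
        """A class distributed like the whole set has log2 enrichment 0."""
        clusters = pd.Series([1] * 40 + [2] * 60)
        classes = pd.Series((["x"] * 2 + ["y"] * 2) * 25)
        enr = se.core_promoter_enrichment(clusters, classes)
        assert np.allclose(enr["log2_enrichment"], 0.0)


class TestProcessingProfiles:
    def test_polya_counts_match_regex_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 60))
            oracle = len(re.findall(r"(?=A[AT]TAAA)", seq))
            assert se.count_polya_hexamers(seq) == oracle

    def test_all_c_downstream_is_minus_background(self):
        g = InMemoryGenome({"c": "C" * 2100, "bg": "AATAAA" * 350})
        summits = pd.DataFrame([{"chrom": "c", "summit": 50,
                                 "strand": "+"}])
        background = pd.DataFrame([{"chrom": "bg", "summit": 50,
                                    "strand": "+"}])
        prof = se.downstream_processing_profile(
            g, summits, "polyA_AWTAAA", background, max_window=500,
            step=100)
        assert (prof["sites_per_bp"] == 0).all()
        assert (prof["above_background"] <= 0).all()
        assert (prof["background_per_bp"] > 0).all()

    def test_planted_hexamer_rate(self):
        # one AWTAAA planted 50 bp downstream of the summit
        g = InMemoryGenome({"c": "C" * 1100, "bg": "C" * 1100})
        g.plant("c", 100, "AATAAA")
        summits = pd.DataFrame([{"chrom": "c", "summit": 50,
                                 "strand": "+"}])
        background = pd.DataFrame([{"chrom": "bg", "summit": 50,
                                    "strand": "+"}])
        prof = se.downstream_processing_profile(
            g, summits, "polyA_AWTAAA", background, max_window=500,
            step=100)
        w100 = prof[prof["window"] == 100].iloc[0]
        assert w100["sites_per_bp"] == pytest.approx(1 / 100)
        assert w100["above_background"] == pytest.approx(1 / 100)

    def test_five_prime_ss_enriched_downstream_of_stable_majors(
            self, default_dataset, default_run):
        """Planted donor sites downstream of stable major strands produce
        an above-background 5'SS profile."""
        ds = default_dataset
        stable = ds.truth[ds.truth["class"].str.contains("stable")
                          & ~ds.truth["class"].str.contains("unstable")]
        summits = pd.DataFrame({
            "chrom": stable["chrom"],
            "summit": stable["summit_major"],
            "strand": stable["major_strand"]}).head(60)
        rng = np.random.default_rng(0)
        chrom = ds.genome.chroms[0]
        background = pd.DataFrame({
            "chrom": chrom,
            "summit": rng.integers(1000, ds.chrom_lengths[chrom] - 1000, 60),
            "strand": rng.choice(["+", "-"], 60)})
        prof = se.downstream_processing_profile(
            ds.genome, summits, se.splice_donor_motif(), background,
            max_window=300, step=100)
        assert prof["above_background"].iloc[-1] > 0
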