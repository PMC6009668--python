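"""STARR-seq fold-change calls, class enrichments, binned associations,
binary-mark proportions and footprints."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, pearsonr

from divtx import enhancer_potential as ep
from divtx.genomic_io import GenomicInterval, SignalTrack


def track(spans):
    return SignalTrack.from_spans(spans)


class TestStarrCall:
    def test_lfc_formula(self):
        dhs = GenomicInterval("c", 800, 1200, id="d")
        sig = track([("c", 900, 1100, 12.0)])
        inp = track([("c", 0, 2000, 3.0)])
        call = ep.starr_call(dhs, sig, sig, inp)
        assert call.hkCP_lfc == pytest.approx(np.log2(13 / 4))
        assert call.active_hkCP  # 1.700 >= 1.5

    def test_signal_equal_input_is_inactive(self):
        dhs = GenomicInterval("c", 800, 1200, id="d")
        t = track([("c", 0, 2000, 5.0)])
        call = ep.starr_call(dhs, t, t, t)
        assert call.hkCP_lfc == 0.0 and not call.active_hkCP

    def test_summit_matches_brute_force_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            values = rng.integers(0, 50, 41)
            spans = [("c", 800 + 10 * i, 810 + 10 * i, float(v))
                     for i, v in enumerate(values)]
            sig = track(spans)
            dhs = GenomicInterval("c", 900, 1100, id="d")
            half = 401 // 2
            lo, hi = dhs.center - half, dhs.center + half + 1
            # oracle: dense per-base argmax over the window
            dense = np.zeros(hi - lo)
            for c, s, e, v in spans:
                a, b = max(s, lo), min(e, hi)
                if a < b:
                    dense[a - lo:b - lo] = v
            oracle_pos = lo + int(np.argmax(dense))
            pos, val = sig.argmax_over("c", lo, hi)
            assert pos == oracle_pos and val == dense.max()

    def test_lfc_monotone_in_signal(self):
        dhs = GenomicInterval("c", 800, 1200, id="d")
        inp = track([("c", 0, 2000, 3.0)])
        prev = -np.inf
        for v in (1.0, 5.0, 25.0, 125.0):
            sig = track([("c", 900, 1100, v)])
            lfc = ep.starr_call(dhs, sig, sig, inp).hkCP_lfc
            assert lfc > prev
            prev = lfc


class TestEnrichmentStats:
    def test_all_inactive_single_column(self):
        assigns = pd.DataFrame({"dhs_id": ["a", "b"], "class": ["x", "y"],
                                "removed": [False, False]})
        calls = pd.DataFrame({"dhs_id": ["a", "b"],
                              "hkCP_lfc": [0.0, 0.0], "dCP_lfc": [0.0, 0.0],
                              "active_hkCP": [False, False],
                              "active_dCP": [False, False]})
        tab = ep.class_starr_enrichment(assigns, calls)
        assert tab["inactive"].sum() == 2
        assert tab[["hkCP_only", "dCP_only", "both"]].to_numpy().sum() == 0

    def test_fisher_matches_hypergeometric_brute_force(self):
        table = [[10, 90], [50, 850]]
        odds, p = ep.fisher_2x2(table, alternative="greater")
        assert odds == pytest.approx((10 * 850) / (90 * 50))  # 1.889
        assert odds == pytest.approx(1.889, abs=1e-3)
        # brute-force hypergeometric tail: P(X >= 10)
        M, n, N = 1000, 100, 60  # population, successes, draws
        expected = hypergeom.sf(9, M, n, N)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_planted_coupling_recovered(self, default_dataset, default_run):
        """hkCP enhancers enrich in stable classes; dCP in (non-weak-uni)
        unstable classes — the planted qualitative pattern."""
        tab = default_run.starr_crosstab
        frac_hk = (tab["hkCP_only"] + tab["both"]) / \
            tab[ep.STARR_CATEGORIES].sum(axis=1)
        assert frac_hk["bidirectional_stable"] > \
            frac_hk["weak_bidirectional_unstable"]
        frac_dcp = (tab["dCP_only"] + tab["both"]) / \
            tab[ep.STARR_CATEGORIES].sum(axis=1)
        assert frac_dcp["weak_bidirectional_unstable"] > \
            frac_dcp["unidirectional_stable"]


class TestBinnedAssociation:
    def test_identity_gives_rho_one(self):
        x = np.arange(100, dtype=float)
        _, rho, _ = ep.binned_association(x, x)
        assert rho == pytest.approx(1.0)

    def test_null_has_small_rho(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        _, rho, _ = ep.binned_association(x, y)
        assert abs(rho) < 0.1

    def test_rho_matches_rank_pearson_with_ties(self):
        """Spearman equals Pearson on average ranks (20-point fixture
        with ties)."""
        x = np.array([1, 2, 2, 3, 3, 3, 4, 5, 5, 6,
                      7, 7, 8, 9, 9, 10, 10, 10, 11, 12], dtype=float)
        y = np.array([2, 1, 3, 2, 5, 4, 4, 6, 7, 6,
                      8, 9, 8, 11, 10, 12, 11, 13, 12, 14], dtype=float)

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        expected = pearsonr(avg_ranks(x), avg_ranks(y))[0]
        _, rho, _ = ep.binned_association(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_x_gives_nan_rho(self):
        x = np.ones(50)
        y = np.arange(50, dtype=float)
        _, rho, _ = ep.binned_association(x, y)
        assert np.isnan(rho)

    def test_truncation_bounds(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        tab, _, _ = ep.binned_association(x, x, n_bins=5)
        lo, hi = np.percentile(x, [1, 99])
        assert tab["x_lo"].iloc[0] == pytest.approx(lo)
        assert tab["x_hi"].iloc[-1] == pytest.approx(hi)

    def test_planted_starr_expression_pattern(self, default_run):
        """Planted hkCP strength rises with expression (rho >= +0.3) and
        dCP strength falls with it (rho negative)."""
        assert default_run.starr_rho["hkCP"][0] >= 0.3
        assert default_run.starr_rho["dCP"][0] <= -0.1


class TestMarks:
    def summits(self):
        return pd.DataFrame({"dhs_id": ["d1", "d2"], "chrom": ["c", "c"],
                             "summit": [1000, 5000]})

    def assigns(self):
        return pd.DataFrame({"dhs_id": ["d1", "d2"], "class": ["x", "x"],
                             "removed": [False, False]})

    def test_mark_on_summit_present(self):
        marks = {"m": [GenomicInterval("c", 990, 1010)]}
        tab = ep.mark_proportions(self.assigns(), marks, self.summits())
        assert tab.loc["x", "m"] == 0.5

    def test_mark_just_outside_flank_absent(self):
        # summit 1000, flank 100: window [900, 1101); mark at 1101 misses
        marks = {"m": [GenomicInterval("c", 1101, 1151)]}
        tab = ep.mark_proportions(self.assigns(), marks, self.summits())
        assert tab.loc["x", "m"] == 0.0

    def test_proportions_match_hand_counts(self):
        summits = pd.DataFrame({
            "dhs_id": [f"d{i}" for i in range(12)],
            "chrom": ["c"] * 12,
            "summit": [1000 * (i + 1) for i in range(12)]})
        assigns = pd.DataFrame({
            "dhs_id": [f"d{i}" for i in range(12)],
            "class": ["x"] * 6 + ["y"] * 6,
            "removed": [False] * 12})
        # marks covering summits of d0,d1,d2 (class x) and d6 (class y)
        marks = {"m": [GenomicInterval("c", 1000 * (i + 1) - 10,
                                       1000 * (i + 1) + 10)
                       for i in (0, 1, 2, 6)]}
        tab = ep.mark_proportions(assigns, marks, summits)
        assert tab.loc["x", "m"] == pytest.approx(3 / 6)
        assert tab.loc["y", "m"] == pytest.approx(1 / 6)


class TestFootprint:
    def test_marks_everywhere_profile_one(self):
        marks = [GenomicInterval("c", 0, 20_000)]
        summits = pd.DataFrame({"dhs_id": ["d"], "chrom": ["c"],
                                "summit": [10_000]})
        prof = ep.footprint_profile(marks, summits, [], {"c": 20_000},
                                    max_dist=1000, n_randomizations=2)
        assert (prof["presence"] == 1.0).all()

    def test_no_marks_profile_zero(self):
        summits = pd.DataFrame({"dhs_id": ["d"], "chrom": ["c"],
                                "summit": [10_000]})
        prof = ep.footprint_profile([], summits, [], {"c": 20_000},
                                    max_dist=1000, n_randomizations=2)
        assert (prof["presence"] == 0.0).all()
        assert (prof["background_mean"] == 0.0).all()

    def test_neighboring_dhs_masks_bins(self):
        """A DHS 120 bp away masks the overlapping distance bins on that
        side (bins are NaN when no site contributes)."""
        summits = pd.DataFrame({"dhs_id": ["d1"], "chrom": ["c"],
                                "summit": [10_000]})
        other = [GenomicInterval("c", 10_120, 10_220, id="d2"),
                 GenomicInterval("c", 9_900, 10_100, id="d1")]
        marks = [GenomicInterval("c", 0, 20_000)]
        prof = ep.footprint_profile(marks, summits, other, {"c": 20_000},
                                    bin_size=50, max_dist=300,
                                    n_randomizations=1)
        # bins [100,150), [150,200), [200,250) overlap d2 -> masked
        masked = prof[(prof["distance"] >= 100) & (prof["distance"] < 250)]
        assert masked["presence"].isna().all()
        # own interval d1 does not mask
        own = prof[(prof["distance"] >= -100) & (prof["distance"] < 0)]
        assert (own["presence"] == 1.0).all()

    def test_background_converges_to_global_density(self):
        """With many randomizations the background band approaches the
        global mark density."""
        rng = np.random.default_rng(0)
        length = 100_000
        marks = [GenomicInterval("c", int(s), int(s) + 100)
                 for s in rng.integers(0, length - 100, 50)]
        density_per_bin = 1 - (1 - 150 / length) ** 50  # P(bin hit)
        summits = pd.DataFrame({"dhs_id": [f"d{i}" for i in range(10)],
                                "chrom": ["c"] * 10,
                                "summit": rng.integers(20_000, 80_000, 10)})
        prof = ep.footprint_profile(marks, summits, [], {"c": length},
                                    max_dist=2000, n_randomizations=30,
                                    seed=4)
        assert prof["background_mean"].mean() == pytest.approx(
            density_per_bin, rel=0.25)
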