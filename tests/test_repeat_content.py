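"""Interval accounting, repeat fractions, and the exact signed-rank test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from utr3evo import repeat_content as rc
from utr3evo import synthetic_data as sd
from oracles import signed_rank_oracle as _signed_rank_oracle


class TestMergeIntervals:
    def test_overlapping_merge(self):
        assert rc.merge_intervals([(10, 20), (15, 30)]) == [(10, 30)]

    def test_disjoint_unchanged(self):
        ivs = [(0, 5), (10, 15)]
        assert rc.merge_intervals(ivs) == ivs

    def test_inverted_interval_errors(self):
        with pytest.raises(ValueError):
            rc.merge_intervals([(10, 5)])

    def test_covered_bases_match_bitmap_oracle(self, rng):
        for _ in range(10):
            ivs = []
            for _ in range(100):
                a = int(rng.integers(0, 9900))
                ivs.append((a, a + int(rng.integers(1, 120))))
            merged = rc.merge_intervals(ivs)
            bitmap = np.zeros(10**4 + 200, dtype=bool)
            for a, b in ivs:
                bitmap[a:b] = True
            assert sum(b - a for a, b in merged) == int(bitmap.sum())
            assert all(b > a for a, b in merged)
            assert all(b1 < a2 for (_, b1), (a2, _) in zip(merged, merged[1:]))

    def test_intersect_size_matches_bitmap(self, rng):
        a = [(int(x), int(x) + 30) for x in rng.integers(0, 900, size=40)]
        b = [(int(x), int(x) + 25) for x in rng.integers(0, 900, size=40)]
        bm_a = np.zeros(1000, dtype=bool)
        bm_b = np.zeros(1000, dtype=bool)
        for lo, hi in a:
            bm_a[lo:hi] = True
        for lo, hi in b:
            bm_b[lo:hi] = True
        assert rc.intersect_size(a, b) == int((bm_a & bm_b).sum())


class TestRepeatFraction:
    def test_simple_quarter_overlap(self):
        rep = rc.repeat_fraction(
            {"utr3": [("c", 0, 100)]},
            [("c", 0, 25)],
            {"c": 1000},
        )
        assert rep.fractions["utr3"] == 0.25
        assert rep.fractions["genome"] == 0.025

    def test_no_repeats_zero_fraction(self):
        rep = rc.repeat_fraction({"utr3": [("c", 0, 100)]}, [], {"c": 1000})
        assert rep.fractions["utr3"] == 0.0

    def test_empty_feature_reported_missing(self):
        rep = rc.repeat_fraction({"utr5": []}, [("c", 0, 10)], {"c": 1000})
        assert math.isnan(rep.fractions["utr5"])

    def test_invariant_to_splitting_features(self):
        repeats = [("c", 40, 160)]
        whole = rc.repeat_fraction({"f": [("c", 0, 200)]}, repeats, {"c": 500})
        split = rc.repeat_fraction(
            {"f": [("c", 0, 70), ("c", 70, 130), ("c", 130, 200)]},
            repeats,
            {"c": 500},
        )
        assert whole.fractions["f"] == split.fractions["f"]

    def test_planted_densities_recovered(self, default_config):
        cfg = default_config
        lengths = sd.floor_lengths(
            sd.simulate_traits(*sd.make_default_tree(cfg), 1.0, 1.0, 1500.0, 60, 5),
            cfg.min_utr3,
        )
        genome = sd.build_genomes(lengths, cfg)[cfg.species[0]]
        genome, bed = sd.plant_repeats(genome, cfg.repeat_densities, seed=5)
        rep = rc.repeat_fraction(
            {
                cls: [(genome.chrom, a, b) for a, b in ivs]
                for cls, ivs in genome.feature_intervals.items()
                if cls != "intergenic"
            },
            [(c, a, b) for c, a, b, _ in bed.itertuples(index=False)],
            {genome.chrom: len(genome.sequence)},
        )
        for cls in ("utr3", "utr5", "cds"):
            assert rep.fractions[cls] == pytest.approx(
                cfg.repeat_densities[cls], abs=0.02
            )


class TestPairedSignedRank:
    def test_nine_pairs_all_lower_gives_two_in_512(self):
        pairs = [(0.30 + 0.01 * i, 0.10 + 0.01 * i) for i in range(9)]
        assert rc.paired_signed_rank(pairs) == pytest.approx(2 / 512)
        assert round(rc.paired_signed_rank(pairs), 3) == 0.004

    def test_single_pair_degenerate(self):
        assert rc.paired_signed_rank([(0.3, 0.1)]) == 1.0

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            rc.paired_signed_rank([(0.2, 0.2), (0.5, 0.5)])

    def test_mixed_signs_match_enumeration(self, rng):
        for _ in range(10):
            diffs = rng.normal(0, 1, size=6)
            pairs = [(0.0, float(d)) for d in diffs]
            assert rc.paired_signed_rank(pairs) == pytest.approx(
                _signed_rank_oracle(diffs)
            )

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            diffs = rng.normal(0, 1, size=10)
            pairs = [(0.0, float(d)) for d in diffs]
            ref = stats.wilcoxon(diffs, alternative="two-sided", mode="exact")
            assert rc.paired_signed_rank(pairs) == pytest.approx(ref.pvalue)

    def test_tied_ranks_match_enumeration(self):
        diffs = [1.0, -1.0, 2.0, 2.0, -3.0, 0.5]
        pairs = [(0.0, d) for d in diffs]
        assert rc.paired_signed_rank(pairs) == pytest.approx(
            _signed_rank_oracle(diffs)
        )

    @pytest.mark.parametrize("n", [3, 8, 12])
    def test_exact_distribution_sums_to_one_and_matches_enumeration(self, n):
        ranks = list(range(1, n + 1))
        dist = rc.signed_rank_distribution([float(r) for r in ranks])
        assert sum(dist.values()) == pytest.approx(1.0)
        counts = {}
        for signs in itertools.product([0, 1], repeat=n):
            w = 2 * sum(r for s, r in zip(signs, ranks) if s)
            counts[w] = counts.get(w, 0) + 1
        enum = {w: c / 2**n for w, c in counts.items()}
        assert dist.keys() == enum.keys()
        for w in enum:
            assert dist[w] == pytest.approx(enum[w])


class TestRepeatMaskerParsing:
    RM_OUT = """   SW   perc perc perc  query      position in query     matching repeat
score   div. del. ins.  sequence   begin  end   (left)   repeat class/family
  463   12.6  4.5  0.0  chr1          11    60  (940) +  SINE2-1  SINE/tRNA
  239    8.0  0.0  0.0  chr1         101   160  (840) C  L1-2     LINE/L1
"""

    def test_fixed_columns_and_coordinate_shift(self):
        df = rc.read_repeatmasker_out(self.RM_OUT)
        assert len(df) == 2
        assert df.iloc[0]["start"] == 10 and df.iloc[0]["end"] == 60
        assert df.iloc[1]["chrom"] == "chr1"

    def test_bed_round_trip(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t10\t60\tSINE\nchr1\t100\t160\tLINE\n")
        df = rc.read_bed(str(p))
        assert df["start"].tolist() == [10, 100]
        assert df["family"].tolist() == ["SINE", "LINE"]
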