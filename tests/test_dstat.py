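"""D-statistic pattern counting, jackknife, f-hat and decay profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import islandmix as im
from islandmix.dstat import (block_counts, count_patterns, d_decay,
                             d_statistic, f_hat, weighted_jackknife)

from conftest import build_calls


def quartet_calls(patterns, length=1000, spacing=10):
    """CallMatrix for (I1, I2, I3, O) from a list of 4-allele site patterns."""
    pos = [i * spacing for i in range(len(patterns))]
    return build_calls({"s": (pos, patterns)}, ["i1", "i2", "i3", "o"],
                       {"s": length})


TAXA = ("i1", "i2", "i3", "o")


class TestCountPatterns:
    def test_hand_built_counts(self):
        """Eight usable sites: 3 ABBA, 1 BABA, 4 uninformative."""
        patterns = [
            [0, 1, 1, 0],  # ABBA
            [0, 1, 1, 0],  # ABBA
            [0, 1, 1, 0],  # ABBA
            [1, 0, 1, 0],  # BABA
            [0, 0, 0, 0],  # monomorphic
            [1, 1, 0, 0],  # derived in I1+I2 only
            [1, 1, 1, 0],  # all derived
            [0, 0, 1, 0],  # derived in I3 only
        ]
        assert count_patterns(quartet_calls(patterns), TAXA) == (3, 1, 8)

    def test_identical_i1_i2_no_discordance(self):
        patterns = [[a, a, b, c] for a in (0, 1) for b in (0, 1)
                    for c in (0, 1)]
        calls = quartet_calls(patterns)
        nA, nB, _ = count_patterns(calls, TAXA)
        assert nA == nB == 0

    def test_swap_i1_i2_swaps_counts(self):
        patterns = [[0, 1, 1, 0]] * 5 + [[1, 0, 1, 0]] * 2
        calls = quartet_calls(patterns)
        nA, nB, _ = count_patterns(calls, TAXA)
        nA2, nB2, _ = count_patterns(calls, ("i2", "i1", "i3", "o"))
        assert (nA, nB) == (5, 2)
        assert (nA2, nB2) == (nB, nA)

    def test_missing_data_excluded(self):
        patterns = [[0, 1, 1, 0], [0, -1, 1, 0], [0, 1, 1, -1]]
        nA, nB, used = count_patterns(quartet_calls(patterns), TAXA)
        assert (nA, nB, used) == (1, 0, 1)

    def test_three_allele_sites_excluded(self):
        patterns = [[0, 2, 2, 0],   # ABBA with allele symbol 2
                    [1, 2, 2, 0],   # three alleles: excluded
                    [1, 2, 3, 0]]   # four alleles: excluded
        nA, nB, used = count_patterns(quartet_calls(patterns), TAXA)
        assert (nA, nB) == (1, 0)
        assert used == 1

    def test_duplicate_individuals_rejected(self):
        with pytest.raises(ValueError):
            count_patterns(quartet_calls([[0, 1, 1, 0]]),
                           ("i1", "i1", "i3", "o"))

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.tuples(*[st.integers(0, 1)] * 4),
                    min_size=4, max_size=60))
    def test_antisymmetric_under_exchange(self, rows):
        """D(I1, I2, ...) = -D(I2, I1, ...) and counts are invariant under
        relabeling allele symbols."""
        patterns = [list(r) for r in rows]
        calls = quartet_calls(patterns)
        nA, nB, _ = count_patterns(calls, TAXA)
        nA2, nB2, _ = count_patterns(calls, ("i2", "i1", "i3", "o"))
        assert (nA2, nB2) == (nB, nA)
        flipped = quartet_calls([[1 - v for v in r] for r in patterns])
        assert count_patterns(flipped, TAXA)[:2] == (nA, nB)


class TestDStatistic:
    def test_pooled_d_arithmetic(self):
        blocks = pd.DataFrame({"nABBA": [2, 1], "nBABA": [1, 0],
                               "used": [10, 10]})
        r = d_statistic(blocks)
        assert r.D == pytest.approx((3 - 1) / (3 + 1))

    def test_balanced_blocks_give_zero_z(self):
        blocks = pd.DataFrame({"nABBA": [4, 2], "nBABA": [4, 2],
                               "used": [20, 20]})
        r = d_statistic(blocks)
        assert r.D == 0.0
        assert r.Z == 0.0

    def test_all_zero_counts_flagged(self):
        blocks = pd.DataFrame({"nABBA": [0], "nBABA": [0], "used": [5]})
        r = d_statistic(blocks)
        assert np.isnan(r.D)
        assert r.SE is None

    def test_single_block_has_no_se(self):
        blocks = pd.DataFrame({"nABBA": [3], "nBABA": [1], "used": [10]})
        r = d_statistic(blocks)
        assert r.D == 0.5
        assert r.SE is None

    def test_jackknife_matches_delete_one_oracle(self):
        """The reported SE equals an independent delete-one recomputation
        with the weighted pseudovalue formula, on random <=20-block data."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            B = int(rng.integers(3, 21))
            nA = rng.integers(0, 40, B) + 1
            nB = rng.integers(0, 40, B) + 1
            blocks = pd.DataFrame({"nABBA": nA, "nBABA": nB,
                                   "used": nA + nB})
            r = d_statistic(blocks)
            # oracle: explicit pooling with each block removed
            A, C = nA.sum(), nB.sum()
            theta = (A - C) / (A + C)
            w = (nA + nB).astype(float)
            n = w.sum()
            h = n / w
            theta_del = np.array([
                ((A - nA[j]) - (C - nB[j])) / ((A - nA[j]) + (C - nB[j]))
                for j in range(B)])
            theta_J = B * theta - np.sum((1 - 1 / h) * theta_del)
            tau = h * theta - (h - 1) * theta_del
            var = np.sum((tau - theta_J) ** 2 / (h - 1)) / B
            assert r.SE == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_equal_weights_reduce_to_classic_jackknife(self):
        theta_del = np.array([0.1, 0.2, 0.15, 0.05])
        w = np.full(4, 25.0)
        se = weighted_jackknife(0.12, theta_del, w)
        classic = np.sqrt(3 / 4 * np.sum((theta_del - theta_del.mean()) ** 2))
        assert se == pytest.approx(classic)

    def test_d_increases_with_pulse_fraction(self, bear_calls):
        """D rises monotonically with the introgressed fraction."""
        ds = []
        for f in (0.0, 0.04, 0.08, 0.12):
            if f == 0.0:
                calls = bear_calls
            else:
                calls = im.apply_pulse(bear_calls, im.PulseSpec(
                    donor="polar3", recipient="brown2", fraction=f,
                    tract_length=20_000, restrict_to="X"), seed=17).calls
            r = im.dstat(calls, ("brown1", "brown2", "polar1", "black"),
                         chrom_class="X", block_span=1_000_000)
            ds.append(r.D)
        assert all(d1 < d2 for d1, d2 in zip(ds, ds[1:]))


class TestFHat:
    def test_full_ancestry_is_one(self, bear_calls):
        """When I2 is the second donor individual itself, f-hat = 1."""
        r = f_hat(bear_calls, "brown1", "polar2", "polar1", "polar2", "black")
        assert r.value == pytest.approx(1.0)

    def test_null_is_zero_within_se(self, bear_calls):
        r = f_hat(bear_calls, "brown1", "brown2", "polar1", "polar2", "black",
                  chrom_class="autosome", block_span=1_000_000)
        assert r.SE is not None
        assert abs(r.value) < 2.5 * r.SE

    def test_recovers_pulse_fraction(self, bear_calls_admixed):
        r = f_hat(bear_calls_admixed, "brown1", "brown2", "polar1", "polar2",
                  "black", chrom_class="X", block_span=1_000_000)
        assert r.value == pytest.approx(0.065, abs=0.035)

    def test_negative_denominator_flagged(self):
        patterns = [[1, 0, 1, 0]] * 3  # BABA-only: S < 0 in denominator
        calls = quartet_calls(patterns)
        r = f_hat(calls, "i1", "i2", "i3", "i2", "o")
        assert np.isnan(r.value) or r.denominator <= 0


class TestDDecay:
    def test_bad_offsets_rejected(self, bear_calls):
        with pytest.raises(ValueError):
            d_decay(bear_calls, ("brown1", "brown2", "polar1", "black"),
                    max_offset=500, bin_width=1000)

    def test_tract_data_biased_toward_focal_class(self, bear_calls_admixed):
        """Downstream of an ABBA site inside a donor tract, D stays high at
        offsets well below the 20 kb tract length."""
        taxa = ("brown1", "brown2", "polar1", "black")
        prof = d_decay(bear_calls_admixed, taxa, max_offset=10_000,
                       bin_width=5_000, chrom_class="X")
        overall = im.dstat(bear_calls_admixed, taxa, chrom_class="X").D
        near_abba = prof[(prof["focal"] == "ABBA")
                         & (prof["offset_lo"] == 0)]["D"].iloc[0]
        near_baba = prof[(prof["focal"] == "BABA")
                         & (prof["offset_lo"] == 0)]["D"].iloc[0]
        assert near_abba > overall
        assert near_baba < near_abba

    def test_unlinked_oracle_is_flat(self, bear_calls_admixed):
        """Destroying position structure (random permutation of site order)
        flattens the profile to the genome-wide D."""
        taxa = ("brown1", "brown2", "polar1", "black")
        calls = bear_calls_admixed.copy()
        rng = np.random.default_rng(8)
        for name in calls.scaffold_names("X"):
            perm = rng.permutation(calls.alleles[name].shape[0])
            calls.alleles[name] = calls.alleles[name][perm]
        overall = im.dstat(calls, taxa, chrom_class="X").D
        prof = d_decay(calls, taxa, max_offset=10_000, bin_width=5_000,
                       chrom_class="X")
        for _, row in prof.iterrows():
            if row["nABBA"] + row["nBABA"] > 200:
                se = 1 / np.sqrt(row["nABBA"] + row["nBABA"])
                assert abs(row["D"] - overall) < 5 * se
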