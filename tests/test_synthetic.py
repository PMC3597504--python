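"""Generator: distance calibration, pulse tracts, tract-length clock."""

import numpy as np
import pandas as pd
import pytest

import islandmix as im
from islandmix.callmatrix import Scaffold
from islandmix.synthetic import (PulseSpec, SpeciesTreeSpec, apply_pulse,
                                 place_tracts, tract_length_from_time)
from islandmix.seeds import derive_rng


def pairwise_distance(calls, a, b):
    ia, ib = calls.sample_index(a), calls.sample_index(b)
    diff = tot = 0
    for name in calls.scaffold_names():
        al = calls.alleles[name]
        diff += int(np.sum(al[:, ia] != al[:, ib]))
        tot += calls.layout[name].length
    return diff / tot


class TestSimulateSites:
    def test_distance_ratios_match_tree(self, bear_calls):
        """Pairwise distances reproduce the scaled tree ratios at 26 Mb."""
        d_ref = pairwise_distance(bear_calls, "brown1", "black")
        targets = {
            ("polar1", "polar2"): 0.1,
            ("brown1", "brown2"): 0.43,
            ("polar1", "brown1"): 0.6,
            ("polar1", "black"): 1.0,
        }
        for (a, b), scaled in targets.items():
            obs = pairwise_distance(bear_calls, a, b) / d_ref
            assert obs == pytest.approx(scaled, rel=0.05), (a, b)

    def test_absolute_polar_diversity(self, bear_calls):
        d = pairwise_distance(bear_calls, "polar1", "polar2") * 1e4
        assert d == pytest.approx(4.0, rel=0.05)

    def test_identical_twin_preset(self):
        """Zero within-diversity taxon: two samples differ nowhere."""
        tree = SpeciesTreeSpec(
            taxa=("twin", "other"),
            split_depths={("other", "twin"): 4e-3},
            within_diversity={"twin": 0.0},
            ancestral_ne=80_000.0)
        layout = im.test_scale_layout(n_auto=1, auto_len=2_000_000, n_x=0)
        calls = im.simulate_sites(tree, layout, {"twin": 2}, seed=5)
        al = calls.alleles["scaffold1"]
        assert np.array_equal(al[:, 0], al[:, 1])

    def test_null_symmetric_d(self, bear_calls):
        """Without admixture, |D| for a conspecific pair stays within 3 SE."""
        r = im.dstat(bear_calls, ("polar1", "polar2", "brown1", "black"),
                     chrom_class="autosome", block_span=2_000_000)
        assert r.SE is not None
        assert abs(r.Z) < 3

    def test_unknown_taxon_errors(self):
        layout = im.test_scale_layout(n_auto=1, n_x=0)
        with pytest.raises(KeyError):
            im.simulate_sites(im.bear_species_tree(), layout,
                              {"yeti": 2}, seed=1)

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError):
            im.GenomeLayout(())

    def test_nonpositive_scaffold_rejected(self):
        with pytest.raises(ValueError):
            Scaffold("s", 0)


class TestApplyPulse:
    def test_fraction_zero_is_identity(self, bear_calls):
        res = apply_pulse(bear_calls, PulseSpec(
            donor="polar1", recipient="brown1", fraction=0.0,
            tract_length=20_000), seed=3)
        assert res.realized_fraction == 0.0
        assert len(res.tracts) == 0
        for name in bear_calls.scaffold_names():
            assert np.array_equal(res.calls.alleles[name],
                                  bear_calls.alleles[name])

    def test_fraction_one_copies_donor(self, bear_calls):
        res = apply_pulse(bear_calls, PulseSpec(
            donor="polar1", recipient="brown1", fraction=1.0,
            tract_length=20_000, restrict_to="X"), seed=3)
        assert res.realized_fraction == 1.0
        di = bear_calls.sample_index("polar1")
        ri = bear_calls.sample_index("brown1")
        for name in bear_calls.scaffold_names("X"):
            al = res.calls.alleles[name]
            assert np.array_equal(al[:, ri], al[:, di])

    def test_only_recipient_rows_change(self, bear_calls):
        res = apply_pulse(bear_calls, PulseSpec(
            donor="polar1", recipient="brown2", fraction=0.1,
            tract_length=20_000, restrict_to="X"), seed=7)
        ri = bear_calls.sample_index("brown2")
        for name in bear_calls.scaffold_names():
            assert np.array_equal(res.calls.positions[name],
                                  bear_calls.positions[name])
            assert np.array_equal(res.calls.callable_intervals[name],
                                  bear_calls.callable_intervals[name])
            other = [j for j in range(len(bear_calls.samples)) if j != ri]
            assert np.array_equal(res.calls.alleles[name][:, other],
                                  bear_calls.alleles[name][:, other])

    def test_tract_count_and_expected_coverage(self):
        """f=0.065, L=10 Mb, l=20 kb places 33 tracts; mean unique coverage
        matches the closed form 1-(1-l/L)^33 ~ 6.4%."""
        layout = im.test_scale_layout(n_auto=2, n_x=0)
        L, ell = 10_000_000, 20_000
        n_expected = 33
        fractions = []
        for s in range(40):
            rng = derive_rng(s, "coverage-oracle")
            tracts = place_tracts(layout, 0.065, ell, rng)
            assert len(tracts) == n_expected
            covered = 0
            for _, grp in tracts.groupby("scaffold"):
                iv = sorted(zip(grp["start"], grp["end"]))
                cur_s, cur_e = iv[0]
                for s0, e0 in iv[1:]:
                    if s0 > cur_e:
                        covered += cur_e - cur_s
                        cur_s, cur_e = s0, e0
                    else:
                        cur_e = max(cur_e, e0)
                covered += cur_e - cur_s
            fractions.append(covered / L)
        closed_form = 1 - (1 - ell / L) ** n_expected
        assert np.mean(fractions) == pytest.approx(closed_form, rel=0.03)

    def test_unplaceable_tract_errors(self, bear_calls):
        with pytest.raises(ValueError):
            apply_pulse(bear_calls, PulseSpec(
                donor="polar1", recipient="brown1", fraction=1e-9,
                tract_length=20_000), seed=1)


class TestTractLengthClock:
    @pytest.mark.parametrize("t_years, r, gen, expected", [
        (50_000, 1e-8, 10, 20_000),    # the 20 kb tracts at ~50 kya
        (100_000, 1e-8, 10, 10_000),
        (7.0, 1e-8, 7.0, 1e8),         # one generation: 1/r
    ])
    def test_closed_form(self, t_years, r, gen, expected):
        assert tract_length_from_time(t_years, r, gen) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tract_length_from_time(-1, 1e-8, 10)
        with pytest.raises(ValueError):
            tract_length_from_time(50_000, 0, 10)


class TestSpecValidation:
    def test_within_cannot_exceed_between(self):
        with pytest.raises(ValueError):
            SpeciesTreeSpec(taxa=("a", "b"),
                            split_depths={("a", "b"): 1e-4},
                            within_diversity={"a": 5e-4})

    def test_non_ultrametric_rejected(self):
        tree = SpeciesTreeSpec(
            taxa=("a", "b", "c"),
            split_depths={("a", "b"): 1e-3, ("a", "c"): 5e-3,
                          ("b", "c"): 2e-3},
            within_diversity={})
        with pytest.raises(ValueError):
            im.simulate_sites(tree, im.test_scale_layout(n_auto=1, n_x=0),
                              {"a": 1, "b": 1, "c": 1}, seed=1)
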