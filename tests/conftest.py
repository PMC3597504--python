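import numpy as np
import pytest

import islandmix as im
from islandmix.callmatrix import CallMatrix, GenomeLayout, Scaffold

PANEL = {"polar": 3, "brown": 2, "black": 1}
PULSE_F_X = 0.065
TRACT = 20_000


def build_calls(alleles_by_scaffold, samples, lengths, classes=None,
                ancestral=None, callable_intervals=None):
    """Hand-build a CallMatrix from per-scaffold (positions, allele-matrix)."""
    classes = classes or {}
    scafs = tuple(Scaffold(n, lengths[n], classes.get(n, "autosome"))
                  for n in lengths)
    positions = {n: np.asarray(p, dtype=np.int64)
                 for n, (p, _) in alleles_by_scaffold.items()}
    alleles = {n: np.asarray(a, dtype=np.int8)
               for n, (_, a) in alleles_by_scaffold.items()}
    kwargs = {}
    if ancestral is not None:
        kwargs["ancestral"] = {n: np.asarray(v, dtype=np.int8)
                               for n, v in ancestral.items()}
    if callable_intervals is not None:
        kwargs["callable_intervals"] = {
            n: np.asarray(v, dtype=np.int64) for n, v in callable_intervals.items()}
    return CallMatrix(samples=list(samples), layout=GenomeLayout(scafs),
                      positions=positions, alleles=alleles, **kwargs)


@pytest.fixture(scope="session")
def bear_calls():
    """Synthetic bear panel: 4 x 5 Mb autosomes + 3 x 2 Mb X, no admixture."""
    layout = im.test_scale_layout(n_auto=4, n_x=3)
    return im.simulate_sites(im.bear_species_tree(), layout, PANEL, seed=1234)


@pytest.fixture(scope="session")
def bear_calls_admixed(bear_calls):
    """The same panel with a polar -> brown2 pulse: 6.5% of the X and
    0.75% of the autosomes in 20 kb tracts (the island scenario)."""
    res = im.apply_pulse(bear_calls, im.PulseSpec(
        donor="polar3", recipient="brown2", fraction=PULSE_F_X,
        tract_length=TRACT, restrict_to="X"), seed=99)
    res = im.apply_pulse(res.calls, im.PulseSpec(
        donor="polar3", recipient="brown2", fraction=0.0075,
        tract_length=TRACT, restrict_to="autosome"), seed=99)
    return res.calls


@pytest.fixture(scope="session")
def panda_calls():
    """Small panel including the deep outgroup, for outgroup-choice checks."""
    layout = im.x_layout(3, 2_000_000)
    return im.simulate_sites(
        im.bear_species_tree(), layout,
        {"polar": 3, "brown": 2, "black": 1, "panda": 1}, seed=77)
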