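import numpy as np
import pytest

from derivchrom.fixture import load_fixture
from derivchrom.insert_size import estimate_insert_profile, thresholds_for_categorization
from derivchrom.mapping import categorize_pair, dedupe, map_pairs
from derivchrom.pipeline import _reads_near_clusters, default_libraries, demo_plan
from derivchrom.simulate import build_derivative, make_composite_reference, simulate_pairs
from derivchrom.svcalls import cluster_events, screen_discordant


@pytest.fixture(scope="session")
def corpus():
    return load_fixture()


class SmallSim:
    """A 200 kb graft + 50 kb diploid host simulation shared across tests.

    The demo rearrangement plan plants a deletion (with a 12 bp flanking
    deletion), an inversion with a 10 bp insertion, and a tandem
    duplication, joined by 0-3 bp micro-homology junctions; five libraries
    (three small-, two large-insert) are simulated at roughly 25x pair
    coverage so that every junction is supported in all libraries.
    """

    def __init__(self, seed=3):
        self.seed = seed
        ref = make_composite_reference(200_000, {"hostA": 50_000}, seed=seed)
        self.plan = demo_plan(200_000)
        self.deriv = build_derivative(ref, self.plan)
        self.libraries = default_libraries(4000, 1500)
        genome = {**self.deriv.reference.host, "derivative": self.deriv.derivative}
        copies = {n: 2 for n in self.deriv.reference.host}
        copies["derivative"] = 1
        self.reads = simulate_pairs(genome, copies, self.libraries, seed=seed + 1)
        self.records = dedupe(map_pairs(self.reads.pairs, self.deriv.reference))
        self.profiles = {
            lib.name: estimate_insert_profile(self.records, lib.name)
            for lib in self.libraries
        }
        thresholds = thresholds_for_categorization(self.profiles)
        self.records = [categorize_pair(r, thresholds) for r in self.records]
        self.discordant = screen_discordant(self.records, self.profiles)
        self.clusters = cluster_events(self.discordant, self.profiles)
        self.zone_reads = _reads_near_clusters(
            self.reads, self.records, self.clusters, window=4000
        )
        self.read_length = 75

    @property
    def reference(self):
        return self.deriv.reference


@pytest.fixture(scope="session")
def small_sim():
    return SmallSim()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
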