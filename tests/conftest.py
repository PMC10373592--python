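import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

import ampledit as a

_hyp_settings.register_profile("ci", derandomize=True, deadline=None)
_hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def locus():
    return a.demo_locus(seed=1)


@pytest.fixture(scope="session")
def sg1(locus):
    return locus.target("sgRNA1")


@pytest.fixture(scope="session")
def sg2(locus):
    return locus.target("sgRNA2")


def insert_at(seq, pos, bases):
    return seq[:pos] + bases + seq[pos:]


def delete_at(seq, start, size):
    return seq[:start] + seq[start + size:]


def substitute_at(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1:]


@pytest.fixture(scope="session")
def edited_pool(locus):
    """Deterministic 2000-read pool at true edited fraction 0.58 at sgRNA2
    (1160 edited NHEJ + 500 target-variant + 340 WT reads)."""
    cfg = a.SimConfig(seed=3, cut_prob=0.73, n_reads=2000, allocation="exact",
                      dosage={"copy1": 25, "copy2": 25, "copy4": 25, "copy6": 25})
    rng = np.random.default_rng(cfg.seed)
    lineages = a.simulate_lineages(cfg, locus, rng)
    reads, truth = a.generate_reads(lineages, cfg, locus, rng)
    return reads, truth
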