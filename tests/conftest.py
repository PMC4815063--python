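import numpy as np
import pytest

from taumap.domain_scan import annotate_core_columns
from taumap.phmm import build_phmm
from taumap.seqio import subalignment_by_group
from taumap.synthetic_data import (map_family_default, simulate_clade_alignments,
                                   simulate_family)


@pytest.fixture(scope="session")
def default_family():
    """The default simulated MAP family: 12 species, divergence 0.2, seed 7,
    with the icefish-like expansion."""
    return simulate_family(map_family_default(n_species=12, divergence=0.2,
                                              seed=7))


@pytest.fixture(scope="session")
def class_models(default_family):
    """Per-class (paralog x repeat) profile HMMs built from the clustered
    repeat alignment, with core columns annotated."""
    aln = default_family.repeat_alignment
    return [annotate_core_columns(
                build_phmm(subalignment_by_group(aln, label), name=label))
            for label in sorted(aln.group_labels())]


@pytest.fixture(scope="session")
def clade_profiles():
    """Three simulated clade profiles; clade 0 carries two private motifs at
    columns 60-71 and 105-116."""
    alns = simulate_clade_alignments(seed=0)
    return [build_phmm(a, name=f"clade{i}") for i, a in enumerate(alns)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
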