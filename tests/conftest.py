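import numpy as np
import pytest

from metadefense.core_io import SequenceRecord
from metadefense.crispr_detect import CrisprArray
from metadefense.synthetic import SPECIES_TAXIDS, SampleConfig, simulate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_array(contig_id="c1", repeat="ACGTACGTACGTACGTACGTACGTACGTACGT",
               spacers=("A" * 36, "C" * 36), start=1001, validated=True):
    """Hand-build a CrisprArray with consistent coordinates."""
    rep_len = len(repeat)
    repeats = []
    spacer_segs = []
    pos = start
    for i in range(len(spacers) + 1):
        repeats.append((pos, pos + rep_len - 1, repeat))
        pos += rep_len
        if i < len(spacers):
            sp = spacers[i]
            spacer_segs.append((pos, pos + len(sp) - 1, sp))
            pos += len(sp)
    return CrisprArray(contig_id=contig_id, start=start, end=pos - 1,
                       repeats=tuple(repeats), spacers=tuple(spacer_segs),
                       consensus_repeat=repeat, validated=validated)


@pytest.fixture
def planted_sample():
    """A feature-rich sponge-like sample used by several integration tests."""
    cfg = SampleConfig(
        sample_id="sp1", n_contigs=8, contig_len_min=9000, contig_len_max=16000,
        n_arrays=4, cas_fraction=0.5, n_single_spacer_decoys=2,
        rms_pairs={"II": 2}, n_rms_decoys=2, taxon_pool=SPECIES_TAXIDS)
    return simulate_sample(cfg, seed=7)


@pytest.fixture
def random_contig(rng):
    from metadefense.synthetic import random_dna
    return SequenceRecord("rand1", random_dna(rng, 5000))
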