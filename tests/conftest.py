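import numpy as np
import pytest

from marpipe import AnchorSet, GenomeSpec, ProfileGrid, TagDataset


def random_scenario(seed, max_tags=2000, max_anchors=50):
    """A random genome + tags + anchors scenario for oracle comparisons.

    Includes mixed tag and anchor strands and edge-adjacent anchors; grid
    and shift are drawn from small sets.
    """
    rng = np.random.default_rng(seed)
    sizes = {
        f"chr{i + 1}": int(rng.integers(2_000, 20_000))
        for i in range(int(rng.integers(1, 4)))
    }
    genome = GenomeSpec(sizes)
    chrom_names = list(sizes)

    n_tags = int(rng.integers(0, max_tags + 1))
    t_chrom = rng.choice(chrom_names, size=n_tags)
    t_pos = np.array(
        [rng.integers(0, sizes[c]) for c in t_chrom], dtype=np.int64
    )
    t_strand = rng.choice(["+", "-"], size=n_tags)
    tags = TagDataset(t_chrom.astype(object), t_pos, t_strand, label=f"scenario{seed}")

    n_anchors = int(rng.integers(1, max_anchors + 1))
    a_chrom = rng.choice(chrom_names, size=n_anchors)
    a_pos = []
    for c in a_chrom:
        if rng.random() < 0.3:  # force edge-adjacent anchors
            a_pos.append(rng.integers(0, 600))
        else:
            a_pos.append(rng.integers(0, sizes[c]))
    anchors = AnchorSet(
        a_chrom.astype(object),
        np.array(a_pos, dtype=np.int64),
        rng.choice(["+", "-"], size=n_anchors),
    )

    window = int(rng.choice([50, 100]))
    half_span = window * int(rng.choice([4, 5, 10]))
    shift = int(rng.choice([0, 0, 35, 73]))
    return genome, tags, anchors, ProfileGrid(half_span, window), shift


@pytest.fixture
def small_genome():
    return GenomeSpec({"chr1": 10_000, "chr2": 8_000})
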