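import numpy as np
import pytest

import marpipe as m
from marpipe.errors import ConfigurationError, DegenerateInputError, ValidationError
from _oracles import brute_force_profile
from conftest import random_scenario


def profile_of(genome, tags, anchors, grid, shift=0):
    return m.count_tags_in_bins(tags, anchors, grid, genome, tag_shift=shift)


# ---------------------------------------------------------------------------
# count_tags_in_bins
# ---------------------------------------------------------------------------

def test_grid_invariants():
    with pytest.raises(ConfigurationError):
        m.ProfileGrid(half_span=450, window=100)
    with pytest.raises(ConfigurationError):
        m.ProfileGrid(half_span=0, window=100)
    assert m.ProfileGrid(5000, 100).n_bins == 100


def test_no_tags_gives_zero_counts_full_coverage(small_genome):
    tags = m.TagDataset(np.empty(0, object), np.empty(0, np.int64), np.empty(0, "U1"))
    anchors = m.AnchorSet(["chr1", "chr2"], [5000, 4000], ["+", "-"])
    profile = profile_of(small_genome, tags, anchors, m.ProfileGrid(1000, 100))
    assert profile.raw_count.sum() == 0
    assert np.all(profile.anchors_covering == 2)  # both anchors interior


def test_documented_binning_example():
    genome = m.GenomeSpec({"chr1": 10_000})
    tags = m.TagDataset(
        ["chr1"] * 5, [4850, 4950, 5050, 5150, 5250], ["+"] * 5
    )
    grid = m.ProfileGrid(200, 100)
    plus = profile_of(genome, tags, m.AnchorSet(["chr1"], [5000], ["+"]), grid)
    assert list(plus.raw_count) == [1, 1, 1, 1]  # tag at 5250 excluded
    minus = profile_of(genome, tags, m.AnchorSet(["chr1"], [5000], ["-"]), grid)
    assert list(minus.raw_count) == [1, 1, 1, 1]  # mirrored offsets


def test_tag_shift_moves_strands_oppositely():
    genome = m.GenomeSpec({"chr1": 10_000})
    anchors = m.AnchorSet(["chr1"], [5000], ["+"])
    grid = m.ProfileGrid(200, 100)
    tags = m.TagDataset(["chr1", "chr1"], [4990, 5010], ["+", "-"])
    shifted = profile_of(genome, tags, anchors, grid, shift=20)
    # + tag 4990 -> 5010 (bin [0,100)); - tag 5010 -> 4990 (bin [-100,0))
    assert list(shifted.raw_count) == [0, 1, 1, 0]


@pytest.mark.parametrize("seed", range(10))
def test_matches_brute_force_loop(seed):
    """Vectorised counting equals the per-tag × per-anchor loop exactly."""
    genome, tags, anchors, grid, shift = random_scenario(seed)
    profile = profile_of(genome, tags, anchors, grid, shift)
    raw, cov = brute_force_profile(
        list(zip(tags.chrom, tags.pos, tags.strand)),
        list(zip(anchors.chrom, anchors.pos, anchors.strand)),
        genome.sizes, grid.half_span, grid.window, shift,
    )
    assert list(profile.raw_count) == raw
    assert list(profile.anchors_covering) == cov


def test_strand_flip_reverses_profile_bit_exactly():
    genome, tags, anchors, grid, shift = random_scenario(101)
    fwd = profile_of(genome, tags, anchors, grid, shift)
    rev = profile_of(genome, tags, anchors.flipped(), grid, shift)
    assert np.array_equal(fwd.raw_count, rev.raw_count[::-1])
    assert np.array_equal(fwd.anchors_covering, rev.anchors_covering[::-1])


def test_translation_invariance():
    genome = m.GenomeSpec({"chr1": 100_000})
    rng = np.random.default_rng(5)
    pos = rng.integers(20_000, 40_000, 500)
    strands = rng.choice(["+", "-"], 500)
    anchors = m.AnchorSet(["chr1"] * 2, [25_000, 33_000], ["+", "-"])
    grid = m.ProfileGrid(2000, 100)
    base = profile_of(genome, m.TagDataset(["chr1"] * 500, pos, strands), anchors, grid)
    delta = 17_123
    moved = profile_of(
        genome,
        m.TagDataset(["chr1"] * 500, pos + delta, strands),
        m.AnchorSet(["chr1"] * 2, [25_000 + delta, 33_000 + delta], ["+", "-"]),
        grid,
    )
    assert np.array_equal(base.raw_count, moved.raw_count)


def test_adding_a_tag_is_monotone():
    genome = m.GenomeSpec({"chr1": 100_000})
    anchors = m.AnchorSet(["chr1"], [50_000], ["+"])
    grid = m.ProfileGrid(1000, 100)
    tags = m.TagDataset(["chr1"] * 3, [49_500, 50_050, 50_500], ["+"] * 3)
    before = m.fold_change_over_genome(profile_of(genome, tags, anchors, grid))
    more = m.TagDataset(["chr1"] * 4, [49_500, 50_050, 50_060, 50_500], ["+"] * 4)
    after = m.fold_change_over_genome(profile_of(genome, more, anchors, grid))
    target_bin = grid.n_bins // 2  # offsets [0, 100)
    assert after.raw_count[target_bin] == before.raw_count[target_bin] + 1
    assert after.fold_vs_genome[target_bin] > before.fold_vs_genome[target_bin]


def test_empty_anchor_set_rejected(small_genome):
    tags = m.TagDataset(["chr1"], [5], ["+"])
    empty = m.AnchorSet(np.empty(0, object), np.empty(0, np.int64), np.empty(0, "U1"))
    with pytest.raises(ValidationError):
        m.count_tags_in_bins(tags, empty, m.ProfileGrid(1000, 100), small_genome)


# ---------------------------------------------------------------------------
# fold_change_over_genome
# ---------------------------------------------------------------------------

def test_genome_lambda_and_fold_arithmetic():
    genome = m.GenomeSpec({"chr1": 1_000_000})
    rng = np.random.default_rng(1)
    tags = m.TagDataset(
        ["chr1"] * 1000, rng.integers(0, 1_000_000, 1000), ["+"] * 1000
    )
    anchors = m.AnchorSet(["chr1"], [500_000], ["+"])
    profile = profile_of(genome, tags, anchors, m.ProfileGrid(5000, 100))
    assert profile.genome_lambda == pytest.approx(0.1)  # 1000 * 100 / 1e6
    out = m.fold_change_over_genome(profile)
    i = int(np.argmax(out.raw_count))
    assert out.fold_vs_genome[i] == pytest.approx(
        out.raw_count[i] / (out.anchors_covering[i] * 0.1)
    )


def test_uniform_tags_give_unit_fold():
    genome = m.GenomeSpec({"chr1": 100_000})
    pos = np.arange(0, 100_000, 10)  # exactly one tag every 10 bp
    tags = m.TagDataset(["chr1"] * len(pos), pos, ["+"] * len(pos))
    anchors = m.AnchorSet(["chr1"] * 2, [30_000, 70_000], ["+", "-"])
    out = m.fold_change_over_genome(
        profile_of(genome, tags, anchors, m.ProfileGrid(5000, 100))
    )
    np.testing.assert_allclose(out.fold_vs_genome, 1.0, atol=1e-9)


def test_zero_total_tags_is_degenerate(small_genome):
    tags = m.TagDataset(np.empty(0, object), np.empty(0, np.int64), np.empty(0, "U1"))
    anchors = m.AnchorSet(["chr1"], [5000], ["+"])
    profile = profile_of(small_genome, tags, anchors, m.ProfileGrid(1000, 100))
    with pytest.raises(DegenerateInputError):
        m.fold_change_over_genome(profile)


# ---------------------------------------------------------------------------
# normalize_to_input
# ---------------------------------------------------------------------------

def _profiles_for_norm(seed=11, n=20_000):
    genome = m.GenomeSpec({"chr1": 1_000_000})
    rng = np.random.default_rng(seed)
    tags = m.TagDataset(
        ["chr1"] * n, rng.integers(0, 1_000_000, n), rng.choice(["+", "-"], n)
    )
    anchors = m.AnchorSet(["chr1"] * 3, [100_000, 500_000, 900_000], ["+"] * 3)
    grid = m.ProfileGrid(5000, 100)
    return genome, tags, anchors, grid


def test_self_normalization_is_identity():
    genome, tags, anchors, grid = _profiles_for_norm()
    a = profile_of(genome, tags, anchors, grid)
    b = profile_of(genome, tags, anchors, grid)
    out = m.normalize_to_input(a, b)
    assert out.k_factor == 1.0
    nonzero = out.raw_count > 0
    np.testing.assert_allclose(out.fold_vs_input[nonzero], 1.0, atol=1e-9)


def test_depth_only_difference_cancels_through_k():
    genome, tags, anchors, grid = _profiles_for_norm()
    doubled = m.TagDataset(
        np.concatenate([tags.chrom, tags.chrom]),
        np.concatenate([tags.pos, tags.pos]),
        np.concatenate([tags.strand, tags.strand]),
    )
    treat = profile_of(genome, doubled, anchors, grid)
    inp = profile_of(genome, tags, anchors, grid)
    out = m.normalize_to_input(treat, inp)
    assert out.k_factor == 2.0
    nonzero = inp.raw_count > 0
    np.testing.assert_allclose(out.fold_vs_input[nonzero], 1.0, atol=1e-9)


def test_zero_input_bins_get_floored_and_flagged():
    genome = m.GenomeSpec({"chr1": 1_000_000})
    anchors = m.AnchorSet(["chr1"], [500_000], ["+"])
    grid = m.ProfileGrid(500, 100)
    treat_tags = m.TagDataset(["chr1"] * 10, [500_050] * 10, ["+"] * 10)
    input_tags = m.TagDataset(["chr1"], [499_950], ["+"])  # empty center bin
    treat = profile_of(genome, treat_tags, anchors, grid)
    inp = profile_of(genome, input_tags, anchors, grid)
    out = m.normalize_to_input(treat, inp)
    center = grid.n_bins // 2
    assert out.input_low_confidence[center]
    # corrected count floored at eps = 1 -> fold equals the raw treatment count
    assert out.fold_vs_input[center] == pytest.approx(10.0)


def test_mismatched_grids_or_anchors_rejected():
    genome, tags, anchors, grid = _profiles_for_norm()
    a = profile_of(genome, tags, anchors, grid)
    b = profile_of(genome, tags, anchors, m.ProfileGrid(5000, 50))
    with pytest.raises(ValidationError):
        m.normalize_to_input(a, b)
    other = m.AnchorSet(["chr1"] * 2, [100_000, 500_000], ["+"] * 2)
    c = profile_of(genome, tags, other, grid)
    with pytest.raises(ValidationError):
        m.normalize_to_input(a, c)


def test_normalization_factors_values():
    genome, tags, anchors, grid = _profiles_for_norm()
    a = profile_of(genome, tags, anchors, grid)
    factors = m.normalization_factors(a, a)
    assert factors.k == 1.0
    assert factors.lam == pytest.approx(a.genome_lambda)
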