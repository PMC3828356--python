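import numpy as np
import pytest
from scipy import stats

import marpipe as m
from marpipe.errors import CapacityError, ValidationError


# ---------------------------------------------------------------------------
# make_genome_with_mars
# ---------------------------------------------------------------------------

def test_plain_genome_without_mars():
    genome, seqs, intervals, truth = m.make_genome_with_mars(2, 10_000, 0, seed=1)
    assert intervals == [] and truth.core_centers == []
    assert set(seqs) == {"chr1", "chr2"}
    assert all(len(s) == 10_000 for s in seqs.values())


def test_same_seed_is_byte_identical():
    a = m.make_genome_with_mars(1, 30_000, 3, seed=42)
    b = m.make_genome_with_mars(1, 30_000, 3, seed=42)
    assert a[1] == b[1]
    assert a[3].core_centers == b[3].core_centers
    c = m.make_genome_with_mars(1, 30_000, 3, seed=43)
    assert c[1] != a[1]


def test_intervals_disjoint_and_cores_at_truth():
    genome, seqs, intervals, truth = m.make_genome_with_mars(1, 100_000, 10, 200, 900, seed=2)
    starts = [iv.start for iv in intervals]
    ends = [iv.end for iv in intervals]
    assert all(e <= s for e, s in zip(ends, starts[1:]))  # non-overlapping
    for iv, (chrom, center) in zip(intervals, truth.core_centers):
        assert iv.start + 900 + 100 == center
        core = seqs[chrom][center - 100 : center + 100]
        at = (core.count("A") + core.count("T")) / 200
        assert at > 0.9  # (AT)n with 5% substitutions


def test_capacity_error_when_intervals_do_not_fit():
    with pytest.raises(CapacityError):
        m.make_genome_with_mars(1, 5_000, 10, 200, 900, seed=0)


def test_truth_file_round_trip(tmp_path):
    *_, truth = m.make_genome_with_mars(1, 50_000, 4, seed=3)
    truth.template_ratio = 16.0
    path = tmp_path / "truth.txt"
    truth.save(path)
    loaded = m.synthetic.load_truth(path) if hasattr(m, "synthetic") else None
    from marpipe.synthetic import load_truth
    loaded = load_truth(path)
    centers = [int(x) for x in loaded["core_centers"].split(",")]
    assert centers == [p for _, p in truth.core_centers]
    assert float(loaded["template_ratio"]) == 16.0


# ---------------------------------------------------------------------------
# simulate_tags
# ---------------------------------------------------------------------------

def _flat_model(seed=0, **kw):
    return m.TagSignalModel(rho=0.05, amplitude=1.0, sigma=300.0, core_dip=1.0,
                            seed=seed, **kw)


def test_tags_deterministic_under_seed():
    genome = m.GenomeSpec({"chr1": 200_000})
    anchors = m.AnchorSet(["chr1"], [100_000], ["+"])
    model = m.TagSignalModel(seed=5)
    a = m.simulate_tags(genome, anchors, model)
    b = m.simulate_tags(genome, anchors, model)
    assert np.array_equal(a.pos, b.pos) and np.array_equal(a.strand, b.strand)


def test_homogeneous_background_is_poisson():
    """With a = 1, d = 1 the per-window counts follow Poisson(ρ·w)."""
    genome = m.GenomeSpec({"chr1": 1_000_000})
    anchors = m.AnchorSet(["chr1"], [500_000], ["+"])
    tags = m.simulate_tags(genome, anchors, _flat_model(seed=8))
    w = 100
    counts = np.bincount(tags.pos // w, minlength=10_000)
    mu = 0.05 * w
    kmax = int(stats.poisson.ppf(0.999, mu))
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    pmf = stats.poisson.pmf(np.arange(kmax + 1), mu)
    pmf[kmax] = 1 - pmf[:kmax].sum()
    expected = pmf * len(counts)
    keep = expected >= 5
    chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    p = stats.chi2.sf(chi2, keep.sum() - 1)
    assert p > 0.01


def test_target_total_concentration():
    genome = m.GenomeSpec({"chr1": 2_000_000})
    anchors = m.AnchorSet(["chr1"], [1_000_000], ["+"])
    target = 100_000
    tags = m.simulate_tags(genome, anchors,
                           m.TagSignalModel(amplitude=3.0, seed=9), n_tags=target)
    assert abs(tags.total_tags - target) < 3 * np.sqrt(target)


def test_enrichment_and_depletion_shapes():
    genome = m.GenomeSpec({"chr1": 4_000_000})
    pos = np.arange(20_000, 4_000_000 - 20_000, 40_000)
    anchors = m.AnchorSet(["chr1"] * len(pos), pos, ["+"] * len(pos))
    grid = m.ProfileGrid(5000, 100)
    for amp in (3.0, 0.4):
        tags = m.simulate_tags(
            genome, anchors,
            m.TagSignalModel(rho=0.05, amplitude=amp, sigma=300.0, seed=10))
        profile = m.fold_change_over_genome(
            m.count_tags_in_bins(tags, anchors, grid, genome))
        center = grid.n_bins // 2
        expected = m.expected_fold_vs_genome(
            grid, genome, anchors, m.TagSignalModel(amplitude=amp))
        assert profile.fold_vs_genome[center] == pytest.approx(
            expected[center], rel=0.12)


def test_core_dip_suppresses_input_counts_over_cores():
    genome = m.GenomeSpec({"chr1": 2_000_000})
    pos = np.arange(20_000, 2_000_000 - 20_000, 20_000)
    anchors = m.AnchorSet(["chr1"] * len(pos), pos, ["+"] * len(pos))
    cores = [("chr1", int(p) - 100, int(p) + 100) for p in pos]
    flat = m.simulate_tags(genome, anchors, _flat_model(seed=11))
    dipped = m.simulate_tags(genome, anchors,
                             m.TagSignalModel(amplitude=1.0, core_dip=0.6, seed=11),
                             core_windows=cores)
    grid = m.ProfileGrid(1000, 100)
    pf = m.count_tags_in_bins(flat, anchors, grid, genome)
    pd_ = m.count_tags_in_bins(dipped, anchors, grid, genome)
    center = grid.n_bins // 2
    ratio = pd_.raw_count[center] / pf.raw_count[center]
    assert ratio == pytest.approx(0.6, rel=0.1)
    edge_ratio = pd_.raw_count[0] / pf.raw_count[0]
    assert edge_ratio == pytest.approx(1.0, rel=0.1)


def test_invalid_models_rejected():
    with pytest.raises(ValidationError):
        m.TagSignalModel(rho=0.0)
    with pytest.raises(ValidationError):
        m.TagSignalModel(core_dip=0.0)
    with pytest.raises(ValidationError):
        m.TagSignalModel(core_dip=1.5)


# ---------------------------------------------------------------------------
# simulate_qpcr / simulate_cytometry
# ---------------------------------------------------------------------------

def test_qpcr_noiseless_infinite_cap_is_exact_exponential():
    curve = m.simulate_qpcr(1.9, 1.0, 20, noise_sd=0.0, seed=0,
                            baseline=0.0, cap=np.inf)
    np.testing.assert_allclose(curve.fluorescence, 1.9 ** curve.cycles)
    assert m.estimate_efficiency(curve) == pytest.approx(1.9, abs=1e-9)


def test_qpcr_same_seed_identical():
    a = m.simulate_qpcr(1.9, 1e-2, 40, noise_sd=0.05, seed=12)
    b = m.simulate_qpcr(1.9, 1e-2, 40, noise_sd=0.05, seed=12)
    assert np.array_equal(a.fluorescence, b.fluorescence)


def test_qpcr_template_ratio_recovered_through_pipeline():
    ratio = 16.0
    e = 1.95
    ct_ref = m.call_ct(m.simulate_qpcr(e, 1e-3, 40, 0.0, 0), 500.0)
    ct_tgt = m.call_ct(m.simulate_qpcr(e, 1e-3 * ratio, 40, 0.0, 0), 500.0)
    recovered = m.relative_quantity(e, ct_tgt, e, ct_ref)
    assert recovered == pytest.approx(ratio, rel=0.15)


def test_cytometry_single_component_and_determinism():
    # component centred in the gate with spread small enough not to leak
    events = m.simulate_cytometry([0, 0, 1.0, 0], [3, 30, 300, 3000],
                                  log_sd=0.25, n=5000, seed=13)
    frac = m.classify_events(events)
    assert frac["medium"] == 1.0
    again = m.simulate_cytometry([0, 0, 1.0, 0], [3, 30, 300, 3000],
                                 log_sd=0.25, n=5000, seed=13)
    assert np.array_equal(events.values, again.values)


def test_cytometry_fraction_validation():
    with pytest.raises(ValidationError):
        m.simulate_cytometry([0.5, 0.4], [3, 500], n=10, seed=0)
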