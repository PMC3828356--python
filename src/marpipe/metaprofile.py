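"""Anchor-centred tag aggregation and fold-change normalisation.

Tags are counted in consecutive windows (default 100 bp) across a span of
±``half_span`` (default 5 kb) around every anchor, summed over the anchor
collection.  Two normalisations are provided:

* fold change over the genome-wide average tag count per window,
  λ = total_tags · w / G; and
* fold change over a depth-corrected non-precipitated (input) profile,
  where the input bin counts are first multiplied by the depth factor
  K = total_tags(treatment) / total_tags(input).

Coordinate conventions
----------------------
For a plus-strand anchor at ``c`` a tag at effective position ``p``
contributes to bin ``floor((p − c)/w)``.  For a minus-strand anchor the
relative offset is ``c − p − 1``: for integer offsets
``floor((−o − 1)/w) = −1 − floor(o/w)`` holds identically, so flipping every
anchor strand reverses the bin vector bit-exactly.  Bins whose genomic
footprint extends beyond a chromosome end are excluded for that anchor and
its per-bin coverage (``anchors_covering``) decremented, so edge-truncated
anchors do not bias averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anchors import AnchorSet
from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .genomic_io import GenomeSpec, TagDataset


@dataclass(frozen=True)
class ProfileGrid:
    """Symmetric anchor-relative binning grid.

    Bin ``k`` covers relative offsets ``[k·w, (k+1)·w)`` for
    ``k ∈ {−L/w, …, L/w − 1}``; L must be divisible by w.
    """

    half_span: int = 5000
    window: int = 100

    def __post_init__(self):
        if self.half_span <= 0 or self.window <= 0:
            raise ConfigurationError("half_span and window must be positive")
        if self.half_span % self.window != 0:
            raise ConfigurationError(
                f"half_span {self.half_span} not divisible by window {self.window}"
            )

    @property
    def n_bins(self) -> int:
        return 2 * self.half_span // self.window

    def bin_edges(self) -> np.ndarray:
        """Left edges of all bins, anchor-relative."""
        return np.arange(-self.half_span, self.half_span, self.window, dtype=np.int64)

    def bin_centers(self) -> np.ndarray:
        return self.bin_edges() + self.window / 2.0


@dataclass
class BinnedProfile:
    """Aggregated anchor-relative tag counts with optional fold tracks."""

    grid: ProfileGrid
    raw_count: np.ndarray
    anchors_covering: np.ndarray
    n_anchors: int
    label: str
    total_tags: int
    genome_length: int
    fold_vs_genome: np.ndarray | None = None
    fold_vs_input: np.ndarray | None = None
    input_low_confidence: np.ndarray | None = None
    k_factor: float | None = None

    @property
    def genome_lambda(self) -> float:
        """Expected tags per window under the genome-wide average rate."""
        return self.total_tags * self.grid.window / self.genome_length


@dataclass(frozen=True)
class NormalizationFactors:
    """Depth factor K and genome-wide per-window rate λ."""

    k: float
    lam: float

    def __post_init__(self):
        if self.k <= 0 or self.lam <= 0:
            raise ValidationError("normalization factors must be positive")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_tags_in_bins(
    tags: TagDataset,
    anchors: AnchorSet,
    grid: ProfileGrid,
    genome: GenomeSpec,
    tag_shift: int = 0,
) -> BinnedProfile:
    """Count tags in anchor-relative bins, summed over all anchors.

    Each tag's effective position is its 5′ position shifted ``tag_shift`` bp
    downstream on its own strand (minus-strand tags shift toward smaller
    coordinates).  A tag near several anchors is counted once per anchor.
    """
    if len(anchors) == 0:
        raise ValidationError("anchor set is empty")
    if tag_shift < 0:
        raise ConfigurationError("tag_shift must be >= 0")
    L, w, nb = grid.half_span, grid.window, grid.n_bins
    nb2 = nb // 2

    # Effective, sorted tag positions per chromosome.
    eff_by_chrom: dict[str, np.ndarray] = {}
    for chrom, (pos, strand) in tags.by_chromosome().items():
        if chrom not in genome:
            raise ValidationError(f"tags on unknown chromosome {chrom!r}")
        eff = np.where(strand == "+", pos + tag_shift, pos - tag_shift)
        eff_by_chrom[chrom] = np.sort(eff)

    raw = np.zeros(nb, dtype=np.int64)
    cov = np.zeros(nb, dtype=np.int64)
    ks = np.arange(-nb2, nb2, dtype=np.int64)
    empty = np.empty(0, dtype=np.int64)

    for chrom, c, strand in zip(anchors.chrom, anchors.pos, anchors.strand):
        chrom = str(chrom)
        if chrom not in genome:
            raise ValidationError(f"anchor on unknown chromosome {chrom!r}")
        clen = genome[chrom]
        c = int(c)
        # Genomic footprint of bin k: [c + k·w, c + (k+1)·w) for "+";
        # the mirror [c − (k+1)·w, c − k·w) for "-", i.e. the "+" mask reversed.
        covered = (c + ks * w >= 0) & (c + (ks + 1) * w <= clen)
        if strand == "-":
            covered = covered[::-1]
        cov += covered

        arr = eff_by_chrom.get(chrom, empty)
        i0 = np.searchsorted(arr, c - L, side="left")
        i1 = np.searchsorted(arr, c + L, side="left")
        if i1 > i0:
            window_tags = arr[i0:i1]
            rel = window_tags - c if strand == "+" else c - window_tags - 1
            bins = rel // w + nb2
            bins = bins[covered[bins]]
            if len(bins):
                raw += np.bincount(bins, minlength=nb)

    return BinnedProfile(
        grid=grid,
        raw_count=raw,
        anchors_covering=cov,
        n_anchors=len(anchors),
        label=tags.label,
        total_tags=tags.total_tags,
        genome_length=genome.total_length,
    )


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def fold_change_over_genome(
    profile: BinnedProfile,
    tags: TagDataset | None = None,
    genome: GenomeSpec | None = None,
) -> BinnedProfile:
    """Per-bin fold change over the genome-wide average tag count.

    λ = total_tags · w / G and ``fold[bin] = raw / (anchors_covering · λ)``;
    bins covered by no anchor are marked absent (NaN).  ``tags`` and
    ``genome`` are optional cross-checks against the totals recorded in the
    profile at counting time.
    """
    if tags is not None and tags.total_tags != profile.total_tags:
        raise ValidationError("tag dataset does not match the profile's totals")
    if genome is not None and genome.total_length != profile.genome_length:
        raise ValidationError("genome does not match the profile's genome length")
    if profile.total_tags == 0:
        raise DegenerateInputError("cannot normalize a profile built from 0 tags")
    lam = profile.genome_lambda
    cov = profile.anchors_covering
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(cov > 0, profile.raw_count / (cov * lam), np.nan)
    return replace(profile, fold_vs_genome=fold)


def normalization_factors(
    treatment: BinnedProfile, input_profile: BinnedProfile
) -> NormalizationFactors:
    """K = total_tags(treatment)/total_tags(input); λ of the input dataset."""
    if input_profile.total_tags == 0:
        raise DegenerateInputError("input dataset has 0 total tags")
    return NormalizationFactors(
        k=treatment.total_tags / input_profile.total_tags,
        lam=input_profile.genome_lambda,
    )


def normalize_to_input(
    treatment: BinnedProfile, input_profile: BinnedProfile
) -> BinnedProfile:
    """Fold change of a treatment profile over the K-corrected input profile.

    The input bin counts are multiplied by K = total(treatment)/total(input)
    before division, cancelling sequencing-depth differences.  Bins with zero
    input count receive the expected corrected count
    ``max(K · λ_input · anchors_covering, 1)`` and are flagged low-confidence
    in ``input_low_confidence``; bins covered by no anchor are NaN.
    """
    if treatment.grid != input_profile.grid:
        raise ValidationError("treatment and input profiles use different grids")
    if treatment.n_anchors != input_profile.n_anchors or not np.array_equal(
        treatment.anchors_covering, input_profile.anchors_covering
    ):
        raise ValidationError("treatment and input profiles use different anchor sets")
    factors = normalization_factors(treatment, input_profile)
    k = factors.k
    corrected = k * input_profile.raw_count.astype(float)
    zero_input = input_profile.raw_count == 0
    cov = treatment.anchors_covering
    floor = np.maximum(k * factors.lam * cov, 1.0)
    corrected = np.where(zero_input, floor, corrected)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(cov > 0, treatment.raw_count / corrected, np.nan)
    return replace(
        treatment,
        fold_vs_input=fold,
        input_low_confidence=zero_input & (cov > 0),
        k_factor=k,
    )
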