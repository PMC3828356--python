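"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data classes the pipeline
consumes:

* genomes with MAR-like intervals whose centre is a planted AT-dinucleotide
  core (flank + (AT)n-with-substitutions core + flank);
* strand-aware tag datasets from an inhomogeneous Poisson model whose per-bp
  intensity is ``ρ · (1 + (a − 1) · Σ_anchors exp(−(x − c)² / 2σ²))``,
  optionally multiplied by a low-complexity dip factor ``d ∈ (0, 1]`` over
  core windows — ``a > 1`` gives a Pol II-like enrichment, ``a < 1`` a
  histone-like depletion, ``a = 1`` a flat input;
* exponential-then-plateau qPCR amplification curves with known efficiency
  and template quantity;
* log-normal mixture fluorescence distributions with known category
  fractions.

Every generator is a pure function of its parameters and seed.  The core
dip models a shared sequence artifact: it applies to every dataset simulated
with core windows supplied (treatment and input alike), which is exactly the
situation input normalisation with the depth factor K is meant to rescue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .anchors import AnchorSet
from .errors import CapacityError, ValidationError
from .genomic_io import GenomeSpec, GenomicInterval, TagDataset
from .metaprofile import ProfileGrid

_SQRT2PI = math.sqrt(2.0 * math.pi)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TagSignalModel:
    """Parameters of the planted tag-intensity model.

    rho: background rate, tags per bp.  amplitude: multiplicative fold at
    the anchor centre (enrichment > 1, depletion < 1, flat = 1).
    sigma: Gaussian peak width in bp.  core_dip: multiplicative factor in
    (0, 1] applied over core windows.  seed: RNG seed.
    """

    rho: float = 0.05
    amplitude: float = 3.0
    sigma: float = 300.0
    core_dip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.rho <= 0 or self.amplitude <= 0 or self.sigma <= 0:
            raise ValidationError("rho, amplitude and sigma must be positive")
        if not (0 < self.core_dip <= 1):
            raise ValidationError("core_dip must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth recorded beside each generated dataset."""

    core_centers: list[tuple[str, int]] = field(default_factory=list)
    true_fold_per_bin: np.ndarray | None = None
    template_ratio: float | None = None
    category_fractions: tuple[float, ...] | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.core_centers:
            out["core_chroms"] = ",".join(c for c, _ in self.core_centers)
            out["core_centers"] = ",".join(str(p) for _, p in self.core_centers)
        if self.true_fold_per_bin is not None:
            out["true_fold_per_bin"] = ",".join(
                f"{v:.8g}" for v in self.true_fold_per_bin
            )
        if self.template_ratio is not None:
            out["template_ratio"] = f"{self.template_ratio:g}"
        if self.category_fractions is not None:
            out["category_fractions"] = ",".join(
                f"{v:g}" for v in self.category_fractions
            )
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key}={value}\n")


def load_truth(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                key, _, value = line.rstrip("\n").partition("=")
                out[key] = value
    return out


# ---------------------------------------------------------------------------
# Genome with planted AT cores
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _planted_core(rng: np.random.Generator, core_len: int, sub_rate: float) -> np.ndarray:
    core = np.tile(np.frombuffer(b"AT", dtype=np.uint8), core_len // 2 + 1)[:core_len]
    core = core.copy()
    sub = rng.random(core_len) < sub_rate
    core[sub] = _BASES[rng.integers(0, 4, size=int(sub.sum()))]
    return core


def make_genome_with_mars(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_mars: int = 50,
    core_len: int = 200,
    flank_len: int = 900,
    seed: int = 0,
    sub_rate: float = 0.05,
) -> tuple[GenomeSpec, dict[str, str], list[GenomicInterval], SyntheticTruth]:
    """Random genome with non-overlapping MAR-like intervals.

    Background sequence is i.i.d. uniform ACGT; each interval is
    flank + core + flank where the core is an (AT) repeat with ``sub_rate``
    random substitutions.  The truth records the exact core centres.
    """
    if n_chrom <= 0 or chrom_length <= 0:
        raise ValidationError("need a positive number of chromosomes and length")
    rng = np.random.default_rng(seed)
    interval_len = core_len + 2 * flank_len
    per_chrom = [
        n_mars // n_chrom + (1 if i < n_mars % n_chrom else 0) for i in range(n_chrom)
    ]
    genome = GenomeSpec({f"chr{i + 1}": chrom_length for i in range(n_chrom)})
    sequences: dict[str, str] = {}
    intervals: list[GenomicInterval] = []
    truth = SyntheticTruth()
    mar_index = 0
    for i, chrom in enumerate(genome.chromosomes):
        seq = _random_sequence(rng, chrom_length)
        k = per_chrom[i]
        if k > 0:
            slack = chrom_length - k * interval_len
            if slack < 0:
                raise CapacityError(
                    f"{k} intervals of {interval_len} bp do not fit in "
                    f"{chrom_length} bp of {chrom}"
                )
            starts = np.sort(rng.integers(0, slack + 1, size=k))
            starts = starts + np.arange(k, dtype=np.int64) * interval_len
            for s in starts:
                s = int(s)
                core_start = s + flank_len
                seq[core_start : core_start + core_len] = _planted_core(
                    rng, core_len, sub_rate
                )
                mar_index += 1
                intervals.append(
                    GenomicInterval(chrom, s, s + interval_len, f"MAR_{mar_index}")
                )
                truth.core_centers.append((chrom, core_start + core_len // 2))
        sequences[chrom] = seq.tobytes().decode("ascii")
    return genome, sequences, intervals, truth


def core_windows_from_truth(
    truth: SyntheticTruth, core_len: int
) -> list[tuple[str, int, int]]:
    """Half-open (chrom, start, end) core windows centred on the truth centres."""
    half = core_len // 2
    return [(c, p - half, p - half + core_len) for c, p in truth.core_centers]


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def _group_positions(anchors: AnchorSet) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom in np.unique(anchors.chrom.astype(str)):
        out[str(chrom)] = np.sort(anchors.pos[anchors.chrom == chrom])
    return out


def _core_bounds(core_windows, genome: GenomeSpec) -> dict[str, np.ndarray]:
    """Flattened sorted [start, end, start, end, ...] core boundaries per chrom."""
    per: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in core_windows or []:
        per.setdefault(chrom, []).append((max(0, int(start)), min(genome[chrom], int(end))))
    return {
        chrom: np.array(sorted(ws), dtype=np.int64).ravel() for chrom, ws in per.items()
    }


def _in_core(pos: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    if bounds is None or len(bounds) == 0:
        return np.zeros(len(pos), dtype=bool)
    return np.searchsorted(bounds, pos, side="right") % 2 == 1


def _intensity_integral(
    genome: GenomeSpec,
    anchor_pos: dict[str, np.ndarray],
    model: TagSignalModel,
    cores: dict[str, np.ndarray],
) -> float:
    """∫ (1 + (a − 1)·S(x)) · D(x) dx over the genome, per unit ρ."""
    a, sigma, d = model.amplitude, model.sigma, model.core_dip
    total = float(genome.total_length)
    for bounds in cores.values():
        lengths = bounds[1::2] - bounds[0::2]
        total -= (1.0 - d) * float(lengths.sum())
    peak = 0.0
    for chrom, clen in genome.sizes.items():
        centers = anchor_pos.get(chrom)
        if centers is None or len(centers) == 0:
            continue
        mass = _SQRT2PI * sigma * (ndtr((clen - centers) / sigma) - ndtr(-centers / sigma))
        bounds = cores.get(chrom)
        if bounds is not None and d < 1.0:
            starts, ends = bounds[0::2], bounds[1::2]
            # mass of each anchor's Gaussian inside each core window
            in_core = ndtr(
                (ends[None, :] - centers[:, None]) / sigma
            ) - ndtr((starts[None, :] - centers[:, None]) / sigma)
            mass = mass - (1.0 - d) * _SQRT2PI * sigma * in_core.sum(axis=1)
        peak += float(mass.sum())
    return total + (a - 1.0) * peak


def simulate_tags(
    genome: GenomeSpec,
    anchors: AnchorSet,
    model: TagSignalModel,
    n_tags: int | None = None,
    core_windows=None,
    label: str = "synthetic_tags",
) -> TagDataset:
    """Draw tags from the inhomogeneous Poisson intensity of ``model``.

    When ``n_tags`` is given the background rate is rescaled so the realised
    total is ``n_tags`` in expectation; otherwise ``model.rho`` is used as
    is.  Strands are assigned uniformly.  Enrichment (a ≥ 1) is sampled as a
    background-plus-Gaussian-components mixture; depletion (a < 1) by
    thinning a homogeneous background; the core dip is applied by a second
    thinning pass wherever core windows are supplied.
    """
    rng = np.random.default_rng(model.seed)
    a, sigma, d = model.amplitude, model.sigma, model.core_dip
    anchor_pos = _group_positions(anchors) if len(anchors) else {}
    cores = _core_bounds(core_windows, genome) if core_windows else {}

    integral = _intensity_integral(genome, anchor_pos, model, cores)
    if not np.isfinite(integral) or integral <= 0:
        raise ValidationError("tag intensity integral is not positive and finite")
    rho = model.rho if n_tags is None else n_tags / integral

    all_chrom: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    for chrom, clen in genome.sizes.items():
        centers = anchor_pos.get(chrom, np.empty(0, dtype=np.int64))
        if a >= 1.0:
            n_bg = rng.poisson(rho * clen)
            parts = [rng.integers(0, clen, size=n_bg)]
            if a > 1.0:
                per_peak = rho * (a - 1.0) * _SQRT2PI * sigma
                for c in centers:
                    n_pk = rng.poisson(per_peak)
                    pk = np.floor(c + sigma * rng.standard_normal(n_pk)).astype(np.int64)
                    parts.append(pk[(pk >= 0) & (pk < clen)])
            pos = np.concatenate(parts)
        else:
            n_cand = rng.poisson(rho * clen)
            cand = np.sort(rng.integers(0, clen, size=n_cand))
            shape = np.zeros(len(cand))
            span = 8.0 * sigma
            for c in centers:
                lo = np.searchsorted(cand, c - span)
                hi = np.searchsorted(cand, c + span)
                dx = cand[lo:hi] - c
                shape[lo:hi] += np.exp(-(dx * dx) / (2.0 * sigma * sigma))
            accept = np.clip(1.0 + (a - 1.0) * shape, 0.0, 1.0)
            pos = cand[rng.random(len(cand)) < accept]
        bounds = cores.get(chrom)
        if bounds is not None and d < 1.0 and len(pos):
            in_core = _in_core(pos, bounds)
            drop = in_core & (rng.random(len(pos)) >= d)
            pos = pos[~drop]
        pos = np.sort(pos)
        all_pos.append(pos)
        all_chrom.append(np.full(len(pos), chrom, dtype=object))

    pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    chroms = np.concatenate(all_chrom) if all_chrom else np.empty(0, dtype=object)
    strands = np.where(rng.random(len(pos)) < 0.5, "+", "-").astype("U1")
    return TagDataset(chroms, pos.astype(np.int64), strands, label=label)


# ---------------------------------------------------------------------------
# Analytic expectations for planted profiles
# ---------------------------------------------------------------------------

def gaussian_bin_weights(grid: ProfileGrid, sigma: float) -> np.ndarray:
    """Average single-anchor Gaussian weight over each anchor-relative bin."""
    edges = grid.bin_edges().astype(float)
    w = grid.window
    return _SQRT2PI * sigma / w * (ndtr((edges + w) / sigma) - ndtr(edges / sigma))


def expected_fold_vs_input(
    grid: ProfileGrid,
    genome: GenomeSpec,
    anchors: AnchorSet,
    treatment: TagSignalModel,
    input_model: TagSignalModel,
    core_windows=None,
) -> np.ndarray:
    """Expected input-normalised fold per bin under the planted model.

    Single-anchor approximation (anchors assumed well separated relative to
    σ).  The core-dip shape cancels bin-by-bin between treatment and input
    when both carry the same dip, as the generators enforce; what survives
    is the Gaussian shape ratio times the total-count (K) correction.
    """
    t_shape = 1.0 + (treatment.amplitude - 1.0) * gaussian_bin_weights(grid, treatment.sigma)
    i_shape = 1.0 + (input_model.amplitude - 1.0) * gaussian_bin_weights(
        grid, input_model.sigma
    )
    anchor_pos = _group_positions(anchors)
    cores = _core_bounds(core_windows, genome) if core_windows else {}
    t_int = _intensity_integral(genome, anchor_pos, treatment, cores)
    i_int = _intensity_integral(genome, anchor_pos, input_model, cores)
    return (t_shape / i_shape) * (i_int / t_int)


def expected_fold_vs_genome(
    grid: ProfileGrid,
    genome: GenomeSpec,
    anchors: AnchorSet,
    model: TagSignalModel,
    core_windows=None,
    core_len: int | None = None,
) -> np.ndarray:
    """Expected genome-average fold per bin, including the core-dip distortion."""
    shape = 1.0 + (model.amplitude - 1.0) * gaussian_bin_weights(grid, model.sigma)
    if core_len is not None and model.core_dip < 1.0:
        half = core_len / 2.0
        edges = grid.bin_edges().astype(float)
        overlap = np.clip(
            np.minimum(edges + grid.window, half) - np.maximum(edges, -half), 0.0, None
        )
        shape = shape * (1.0 - (1.0 - model.core_dip) * overlap / grid.window)
    anchor_pos = _group_positions(anchors)
    cores = _core_bounds(core_windows, genome) if core_windows else {}
    integral = _intensity_integral(genome, anchor_pos, model, cores)
    return shape * genome.total_length / integral


# ---------------------------------------------------------------------------
# qPCR and cytometry simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_e: float,
    template: float,
    n_cycles: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 50.0,
    cap: float = 1e5,
    well: str = "",
    gene: str = "",
):
    """Exponential-then-plateau amplification curve with known parameters.

    F(c) = baseline + cap·t·E^c / (cap + t·E^c), with multiplicative
    log-normal noise of standard deviation ``noise_sd`` on the amplification
    term.  ``cap = inf`` gives a pure exponential.
    """
    from .qpcr import AmplificationCurve

    if not (1.0 < true_e <= 2.2):
        raise ValidationError(f"true efficiency {true_e} outside (1, 2.2]")
    if template <= 0:
        raise ValidationError("template quantity must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    growth = template * true_e**cycles
    amp = growth if np.isinf(cap) else cap * growth / (cap + growth)
    if noise_sd > 0:
        amp = amp * np.exp(noise_sd * rng.standard_normal(n_cycles))
    return AmplificationCurve(cycles, baseline + amp, well=well, gene=gene)


def simulate_cytometry(
    fractions,
    modes,
    log_sd: float = 0.35,
    n: int = 100_000,
    seed: int = 0,
    label: str = "synthetic_events",
):
    """Log-normal mixture of fluorescence values with known fractions.

    Each component's median equals its mode parameter (values are
    ``mode · exp(log_sd · z)``); the multinomial component assignment is the
    recorded truth.
    """
    from .cytometry import EventTable

    fractions = np.asarray(fractions, dtype=float)
    modes = np.asarray(modes, dtype=float)
    if len(fractions) != len(modes):
        raise ValidationError("fractions and modes must have equal length")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError(f"fractions sum to {fractions.sum()}, expected 1")
    if np.any(fractions < 0) or np.any(modes <= 0):
        raise ValidationError("fractions must be >= 0 and modes positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, fractions)
    parts = [
        mode * np.exp(log_sd * rng.standard_normal(count))
        for mode, count in zip(modes, counts)
    ]
    values = np.concatenate(parts) if parts else np.empty(0)
    values = values[rng.permutation(len(values))]
    return EventTable(values, label=label)
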