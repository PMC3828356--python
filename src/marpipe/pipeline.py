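"""End-to-end orchestration: anchors → profiles → normalisation; qPCR plates.

A :class:`RunConfig` may be populated from a flat YAML file, from CLI flags,
or programmatically; flags override file values.  Each run writes its
outputs plus a manifest (parameters, seeds, totals, K, λ) sufficient to
reproduce it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import anchors as _anchors
from . import cytometry as _cyt
from . import genomic_io as gio
from . import metaprofile as mp
from . import qpcr as _qpcr
from .errors import ConfigurationError, ValidationError

log = logging.getLogger("marpipe")


@dataclass
class RunConfig:
    """Flat configuration mirroring the CLI flags."""

    # profile analysis
    tags: str | None = None
    input_tags: str | None = None
    anchors: str | None = None
    intervals: str | None = None
    fasta: str | None = None
    genome: str | None = None
    span: int = 5000
    window: int = 100
    shift: int = 0
    core_window: int = 200
    at_mode: str = "dinucleotide"
    out: str | None = None
    # quant analysis
    curves: str | None = None
    sheet: str | None = None
    target: str = "GFP"
    reference: str = "GAPDH"
    threshold: float = 500.0
    control: str | None = None
    # cytometry
    events: list[str] = field(default_factory=list)
    gates: tuple[float, float, float] = (10.0, 100.0, 1000.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) in (None, [])]
        if missing:
            raise ConfigurationError(f"missing required settings: {missing}")


def _write_manifest(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def resolve_anchors(config: RunConfig, genome: gio.GenomeSpec) -> _anchors.AnchorSet:
    """Anchor set from an anchor BED, or derived from intervals (+ FASTA)."""
    if config.anchors:
        ivs = gio.read_bed(config.anchors, genome)
        return _anchors.AnchorSet(
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.strand if iv.strand in "+-" else "+" for iv in ivs],
            label=str(config.anchors),
        )
    if config.intervals:
        ivs = gio.read_bed(config.intervals, genome)
        return _anchors.anchors_from_intervals(
            ivs,
            genome,
            sequences=config.fasta,
            core_window_bp=config.core_window,
            mode=config.at_mode,
        )
    raise ConfigurationError("provide either 'anchors' or 'intervals'")


def run_profile_analysis(config: RunConfig) -> mp.BinnedProfile:
    """Anchors → treatment/input profiles → genome and input normalisation.

    Writes the profile TSV to ``config.out`` and a ``<out>.manifest.yaml``
    beside it; returns the normalised treatment profile.
    """
    config.require("tags", "genome", "out")
    genome = gio.read_chrom_sizes(config.genome)
    grid = mp.ProfileGrid(config.span, config.window)
    anchor_set = resolve_anchors(config, genome)
    log.info("profile: %d anchors, grid ±%d/%d", len(anchor_set), grid.half_span, grid.window)

    treatment_tags = gio.read_tags(config.tags, genome)
    profile = mp.count_tags_in_bins(
        treatment_tags, anchor_set, grid, genome, tag_shift=config.shift
    )
    profile = mp.fold_change_over_genome(profile)
    manifest = {
        "tags": str(config.tags),
        "genome": str(config.genome),
        "span": grid.half_span,
        "window": grid.window,
        "shift": config.shift,
        "n_anchors": len(anchor_set),
        "total_tags": profile.total_tags,
        "genome_length": profile.genome_length,
        "lambda": profile.genome_lambda,
        "seed": config.seed,
    }
    if config.input_tags:
        input_tags = gio.read_tags(config.input_tags, genome)
        input_profile = mp.count_tags_in_bins(
            input_tags, anchor_set, grid, genome, tag_shift=config.shift
        )
        profile = mp.normalize_to_input(profile, input_profile)
        manifest["input_tags"] = str(config.input_tags)
        manifest["input_total_tags"] = input_profile.total_tags
        manifest["k_factor"] = profile.k_factor
        log.info("K factor = %.4f", profile.k_factor)
    gio.write_profile(profile, config.out)
    _write_manifest(Path(str(config.out) + ".manifest.yaml"), manifest)
    return profile


def run_quant_analysis(config: RunConfig):
    """qPCR curves + sample sheet → per-condition relative quantities.

    Writes a tidy TSV to ``config.out``; returns the result list.
    """
    config.require("curves", "sheet", "out")
    curves = _qpcr.read_curves(config.curves)
    sheet = _qpcr.read_sample_sheet(config.sheet)
    results = _qpcr.quantify_plate(
        curves,
        sheet,
        target=config.target,
        reference=config.reference,
        threshold=config.threshold,
        control_condition=config.control,
    )
    table = _qpcr.results_table(results)
    table.to_csv(config.out, sep="\t", index=False)
    _write_manifest(
        Path(str(config.out) + ".manifest.yaml"),
        {
            "curves": str(config.curves),
            "sheet": str(config.sheet),
            "target": config.target,
            "reference": config.reference,
            "threshold": config.threshold,
            "control": config.control,
            "n_conditions": len(results),
        },
    )
    return results


def run_facs_analysis(config: RunConfig):
    """Event tables → category fractions and mean-fluorescence folds."""
    config.require("events", "out")
    gates = _cyt.GateConfig(*config.gates)
    tables = {
        Path(p).stem: _cyt.read_events(p, label=Path(p).stem) for p in config.events
    }
    control = config.control if config.control in tables else None
    if config.control and control is None:
        raise ValidationError(f"control population {config.control!r} not among events")
    df = _cyt.summary_table(tables, gates, control=control)
    df.to_csv(config.out, sep="\t", index=False)
    return df
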