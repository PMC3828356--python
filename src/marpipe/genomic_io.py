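"""Genomic file I/O with fixed coordinate conventions.

All coordinates are 0-based half-open throughout the package: an interval
``[start, end)`` has length ``end - start``.  The module reads and writes the
small text formats the pipeline touches — BED (3–6 columns), ``chrom.sizes``,
FASTA (writing; reading is delegated to pyfaidx in :mod:`marpipe.anchors`),
BED-like tag files, and the anchor-relative profile TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError

_STRANDS = {"+", "-", "."}
_TAG_STRANDS = {"+", "-"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome name → length (bp) map.

    The total genome length ``G`` is the denominator of the genome-wide
    average tag rate used by :func:`marpipe.metaprofile.fold_change_over_genome`.
    """

    sizes: dict[str, int]

    def __post_init__(self):
        if not self.sizes:
            raise ValidationError("genome must contain at least one chromosome")
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED annotations."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TagDataset:
    """A ChIP-Seq experiment as strand-aware 5′ tag positions.

    ``chrom``/``pos``/``strand`` are parallel arrays; ``pos`` is the mapped
    5′ base of each read (plus strand → start, minus strand → end − 1).
    """

    chrom: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype="U1")
        if not (len(self.chrom) == len(self.pos) == len(self.strand)):
            raise ValidationError("tag arrays must have equal length")

    @property
    def total_tags(self) -> int:
        return int(len(self.pos))

    def by_chromosome(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Group tags by chromosome, preserving file order within each group."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in np.unique(self.chrom.astype(str)):
            m = self.chrom == c
            out[str(c)] = (self.pos[m], self.strand[m])
        return out


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeSpec:
    """Read a two-column whitespace-separated chromosome size file.

    Duplicate chromosome names are an error: silently overwriting one length
    with another hides data bugs.
    """
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError("expected 2 columns", path, lineno)
            name, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise ParseError(f"non-integer length {raw_len!r}", path, lineno) from None
            if name in sizes:
                raise ParseError(f"duplicate chromosome {name!r}", path, lineno)
            if length <= 0:
                raise ParseError(f"non-positive length {length}", path, lineno)
            sizes[name] = length
    if not sizes:
        raise ParseError("empty chrom.sizes file", path)
    return GenomeSpec(sizes)


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith(("#", "track", "browser"))


def _parse_bed_fields(fields, path, lineno):
    if len(fields) < 3:
        raise ParseError("expected at least 3 columns", path, lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError("non-integer coordinates", path, lineno) from None
    if start < 0 or start >= end:
        raise ParseError(f"invalid coordinates [{start},{end})", path, lineno)
    name = fields[3] if len(fields) > 3 else ""
    score = 0.0
    if len(fields) > 4:
        try:
            score = float(fields[4])
        except ValueError:
            raise ParseError(f"non-numeric score {fields[4]!r}", path, lineno) from None
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in _STRANDS:
        raise ParseError(f"invalid strand {strand!r}", path, lineno)
    return chrom, start, end, name, score, strand


def read_bed(path, genome: GenomeSpec | None = None) -> list[GenomicInterval]:
    """Read a 3–6 column BED file into intervals, in file order.

    ``track``/``browser``/comment lines are tolerated; columns beyond the
    sixth are ignored.  When a genome is supplied, records on unknown
    chromosomes or out of bounds are rejected with a :class:`ValidationError`.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            chrom, start, end, name, score, strand = _parse_bed_fields(
                line.split(), path, lineno
            )
            if genome is not None:
                if chrom not in genome:
                    raise ValidationError(
                        f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                    )
                if end > genome[chrom]:
                    raise ValidationError(
                        f"{path}: line {lineno}: interval end {end} exceeds "
                        f"{chrom} length {genome[chrom]}"
                    )
            intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return intervals


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Tags
# ---------------------------------------------------------------------------

def read_tags(path, genome: GenomeSpec, label: str | None = None) -> TagDataset:
    """Read a 6-column BED-like tag file, reducing each record to its 5′ base.

    Plus-strand records map to ``start``, minus-strand records to ``end − 1``.
    The strand column is mandatory and must be ``+`` or ``-``.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError("tag records need a strand in column 6", path, lineno)
            chrom, start, end, _name, _score, strand = _parse_bed_fields(
                fields, path, lineno
            )
            if strand not in _TAG_STRANDS:
                raise ParseError(f"tag strand must be + or -, got {strand!r}", path, lineno)
            if chrom not in genome:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                )
            pos = start if strand == "+" else end - 1
            if pos >= genome[chrom]:
                raise ValidationError(
                    f"{path}: line {lineno}: tag position {pos} outside {chrom}"
                )
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
    return TagDataset(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(strands, dtype="U1"),
        label=label if label is not None else str(path),
    )


def write_tags(tags: TagDataset, path) -> None:
    """Write tags as 1-bp 6-column BED records (round-trips through read_tags)."""
    with open(path, "w") as fh:
        for c, p, s in zip(tags.chrom, tags.pos, tags.strand):
            fh.write(f"{c}\t{p}\t{p + 1}\tt\t0\t{s}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Profile TSV
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = (
    "bin_center_offset",
    "raw_count",
    "anchors_covering",
    "fold_vs_genome",
    "fold_vs_input",
)


def _fmt_fold(values, i) -> str:
    if values is None:
        return ""
    v = values[i]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    return f"{v:.6g}"


def write_profile(profile, path) -> None:
    """Write a BinnedProfile as TSV: one row per bin, header first.

    Metadata needed to reconstruct the profile (label, anchor count, tag
    totals, genome length, K) is stored in leading ``#``-comment lines; a
    round trip through :func:`read_profile` reproduces all values to 6
    significant digits.
    """
    grid = profile.grid
    with open(path, "w") as fh:
        fh.write(f"# label={profile.label}\n")
        fh.write(f"# half_span={grid.half_span}\n")
        fh.write(f"# window={grid.window}\n")
        fh.write(f"# n_anchors={profile.n_anchors}\n")
        fh.write(f"# total_tags={profile.total_tags}\n")
        fh.write(f"# genome_length={profile.genome_length}\n")
        if profile.k_factor is not None:
            fh.write(f"# k_factor={profile.k_factor:.6g}\n")
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        centers = grid.bin_centers()
        for i in range(grid.n_bins):
            fh.write(
                f"{centers[i]:g}\t{int(profile.raw_count[i])}\t"
                f"{int(profile.anchors_covering[i])}\t"
                f"{_fmt_fold(profile.fold_vs_genome, i)}\t"
                f"{_fmt_fold(profile.fold_vs_input, i)}\n"
            )


def read_profile(path):
    """Read a profile TSV written by :func:`write_profile`."""
    from .metaprofile import BinnedProfile, ProfileGrid  # local import: avoid cycle

    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                continue
            if line.startswith(_PROFILE_COLUMNS[0]):
                continue
            if line.strip():
                rows.append(line.rstrip("\n").split("\t"))
    grid = ProfileGrid(int(meta["half_span"]), int(meta["window"]))
    if len(rows) != grid.n_bins:
        raise ParseError(f"expected {grid.n_bins} bin rows, found {len(rows)}", path)
    raw = np.array([int(r[1]) for r in rows], dtype=np.int64)
    cov = np.array([int(r[2]) for r in rows], dtype=np.int64)

    def _col(idx):
        vals = [r[idx] if len(r) > idx else "" for r in rows]
        if all(v == "" for v in vals):
            return None
        return np.array([float(v) if v != "" else np.nan for v in vals])

    k = meta.get("k_factor")
    return BinnedProfile(
        grid=grid,
        raw_count=raw,
        anchors_covering=cov,
        n_anchors=int(meta["n_anchors"]),
        label=meta.get("label", ""),
        total_tags=int(meta["total_tags"]),
        genome_length=int(meta["genome_length"]),
        fold_vs_genome=_col(3),
        fold_vs_input=_col(4),
        k_factor=float(k) if k else None,
    )
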