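"""AT-rich core detection and anchor-point derivation.

Matrix attachment regions carry a central core dominated by alternating A/T
(the (ATAT)n microsatellite).  Meta-profiles are aligned on the centre of
that core, so this module finds, inside each candidate interval, the
fixed-length window with the highest AT score and reports its centre as the
anchor.  Transcription start site (TSS) anchors are derived from gene
intervals and oriented by gene strand; MAR anchors are unoriented ("+").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .genomic_io import GenomeSpec, GenomicInterval

_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass(frozen=True)
class ATCoreCall:
    """Best-scoring AT window within one sequence.

    Coordinates are local to the scanned sequence; ``center`` is
    ``floor((start + end) / 2)`` and ``at_score`` the AT fraction
    (composition mode) or AT/TA adjacent-pair fraction (dinucleotide mode)
    of the reported window.
    """

    start: int
    end: int
    center: int
    at_score: float


@dataclass
class AnchorSet:
    """Oriented points that profiles are centred on (parallel arrays)."""

    chrom: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype="U1")
        if not (len(self.chrom) == len(self.pos) == len(self.strand)):
            raise ValidationError("anchor arrays must have equal length")

    def __len__(self) -> int:
        return int(len(self.pos))

    def flipped(self) -> "AnchorSet":
        """The same anchors with every strand reversed."""
        flip = np.where(self.strand == "+", "-", "+")
        return AnchorSet(self.chrom.copy(), self.pos.copy(), flip, self.label)

    def to_intervals(self) -> list[GenomicInterval]:
        """Anchors as 1-bp intervals (exportable as 6-column BED)."""
        return [
            GenomicInterval(str(c), int(p), int(p) + 1, f"anchor_{i}", 0.0, str(s))
            for i, (c, p, s) in enumerate(zip(self.chrom, self.pos, self.strand))
        ]


def _rolling_int_sum(x: np.ndarray, width: int) -> np.ndarray:
    c = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return c[width:] - c[:-width]


def find_at_core(
    sequence: str, core_window_bp: int, mode: str = "dinucleotide"
) -> ATCoreCall:
    """Find the fixed-length window maximising the AT score.

    composition mode scores a window by (#A + #T) / window length;
    dinucleotide mode by the number of adjacent AT or TA pairs divided by
    (window length − 1).  Ties are broken by the leftmost window, N (and any
    non-ACGT base) counts as non-AT.  Scoring uses integer counts, so the
    leftmost-maximum tie-break is exact.
    """
    w = int(core_window_bp)
    if w <= 0:
        raise ValidationError(f"core window must be positive, got {w}")
    if len(sequence) < w:
        raise ValidationError(
            f"sequence length {len(sequence)} shorter than core window {w}"
        )
    if mode not in ("composition", "dinucleotide"):
        raise ValidationError(f"unknown AT scoring mode {mode!r}")

    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_a = arr == _A
    is_t = arr == _T
    if mode == "composition":
        counts = _rolling_int_sum(is_a | is_t, w)
        denom = w
    else:
        pair = (is_a[:-1] & is_t[1:]) | (is_t[:-1] & is_a[1:])
        counts = _rolling_int_sum(pair, w - 1) if w > 1 else np.zeros(len(arr), np.int64)
        denom = max(w - 1, 1)
    start = int(np.argmax(counts))  # argmax returns the first (leftmost) maximum
    return ATCoreCall(
        start=start,
        end=start + w,
        center=start + w // 2,
        at_score=float(counts[start]) / denom,
    )


def _fetch_sequence(source, chrom: str, start: int, end: int) -> str:
    try:
        record = source[chrom]
    except KeyError:
        raise ValidationError(f"chromosome {chrom!r} missing from sequence source") from None
    return str(record[start:end])


def anchors_from_intervals(
    intervals: list[GenomicInterval],
    genome: GenomeSpec | None = None,
    sequences=None,
    core_window_bp: int = 200,
    mode: str = "dinucleotide",
    label: str = "mar_cores",
) -> AnchorSet:
    """One unoriented anchor per interval, at the detected AT-core centre.

    ``sequences`` may be a dict of chromosome → sequence, a ``pyfaidx.Fasta``
    object, or a FASTA path; when absent (or an interval is shorter than the
    core window) the interval midpoint is used instead.  Strand is "+"
    throughout: profiles over MARs are unoriented.
    """
    if isinstance(sequences, (str, bytes)) or hasattr(sequences, "__fspath__"):
        import pyfaidx

        sequences = pyfaidx.Fasta(str(sequences))
    chroms, positions = [], []
    for iv in intervals:
        if genome is not None:
            if iv.chrom not in genome:
                raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > genome[iv.chrom]:
                raise ValidationError(
                    f"interval {iv.chrom}:[{iv.start},{iv.end}) exceeds chromosome"
                )
        if sequences is None or iv.length < core_window_bp:
            pos = iv.midpoint
        else:
            seq = _fetch_sequence(sequences, iv.chrom, iv.start, iv.end)
            call = find_at_core(seq, core_window_bp, mode=mode)
            pos = iv.start + call.center
        chroms.append(iv.chrom)
        positions.append(pos)
    return AnchorSet(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.full(len(chroms), "+", dtype="U1"),
        label=label,
    )


def anchors_from_tss(gene_intervals: list[GenomicInterval], label: str = "tss") -> AnchorSet:
    """TSS anchors oriented by gene strand.

    Plus-strand gene → anchor at ``start`` on "+"; minus-strand gene → anchor
    at ``end − 1`` on "-".  Unstranded genes are rejected.
    """
    chroms, positions, strands = [], [], []
    for iv in gene_intervals:
        if iv.strand == "+":
            pos = iv.start
        elif iv.strand == "-":
            pos = iv.end - 1
        else:
            raise ValidationError(
                f"gene {iv.name or iv.chrom}:[{iv.start},{iv.end}) has no strand"
            )
        chroms.append(iv.chrom)
        positions.append(pos)
        strands.append(iv.strand)
    return AnchorSet(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(strands, dtype="U1"),
        label=label,
    )
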