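"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised implementations: plain
Python loops over tags × anchors and over candidate windows, written
directly from the counting and scoring definitions.
"""

from __future__ import annotations


def brute_force_profile(tag_records, anchor_records, sizes, half_span, window, shift=0):
    """Per-tag × per-anchor loop replicating the binning contract.

    tag_records: iterable of (chrom, pos, strand); anchor_records: iterable
    of (chrom, center, strand); sizes: chrom → length.  Returns
    (raw_counts, anchors_covering) as plain lists.
    """
    L, w = half_span, window
    nb = 2 * L // w
    nb2 = nb // 2
    raw = [0] * nb
    cov = [0] * nb
    for achrom, c, astrand in anchor_records:
        clen = sizes[achrom]
        covered = [False] * nb
        for i in range(nb):
            k = i - nb2
            if astrand == "+":
                lo, hi = c + k * w, c + (k + 1) * w
            else:
                lo, hi = c - (k + 1) * w, c - k * w
            if lo >= 0 and hi <= clen:
                covered[i] = True
                cov[i] += 1
        for tchrom, p, tstrand in tag_records:
            if tchrom != achrom:
                continue
            eff = p + shift if tstrand == "+" else p - shift
            rel = eff - c if astrand == "+" else c - eff - 1
            if -L <= rel < L:
                i = rel // w + nb2
                if covered[i]:
                    raw[i] += 1
    return raw, cov


def brute_force_at_core(sequence, window, mode):
    """Exhaustive scan over all fixed-length windows; leftmost maximum."""
    s = sequence.upper()
    best_count, best_start = -1, 0
    for start in range(len(s) - window + 1):
        win = s[start : start + window]
        if mode == "composition":
            count = win.count("A") + win.count("T")
        else:
            count = sum(1 for i in range(window - 1) if win[i : i + 2] in ("AT", "TA"))
        if count > best_count:
            best_count, best_start = count, start
    denom = window if mode == "composition" else max(window - 1, 1)
    return best_start, best_count / denom
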