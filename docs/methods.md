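# Methods

## Meta-profile model

A ChIP-Seq experiment is reduced to strand-aware 5′ tag positions (plus
strand → record start; minus strand → record end − 1; all coordinates
0-based half-open). Given a set of anchors, tags are counted in consecutive
windows of width `w` (default 100 bp) across ±`L` (default 5 kb) around each
anchor and summed over anchors. An optional `tag_shift` moves each tag
downstream on its own strand before counting (default 0: the counting
position used upstream of this package is not standardised, so the shift is
exposed rather than assumed).

For a plus-strand anchor at `c`, a tag at effective position `p` falls in
bin `floor((p − c)/w)`. For a minus-strand anchor the relative offset is
`c − p − 1`; because `floor((−o − 1)/w) = −1 − floor(o/w)` for integers,
flipping every anchor strand reverses the bin vector *bit-exactly*. The
more obvious mirrored offset `c − p` does not have this property at bin
boundaries (offsets at exact multiples of `w` change bins), which would
make strand symmetry only approximate; exactness is worth the 1 bp
asymmetry in the offset definition, and the convention is validated against
an independent per-tag × per-anchor brute-force loop.

Bins whose genomic footprint extends beyond a chromosome end are excluded
for that anchor only, and the per-bin anchor coverage `anchors_covering` is
decremented, so edge-truncated anchors do not dilute averages. A tag lying
near two anchors is counted once per anchor (per-anchor cumulative
counting). Both the raw sums and per-bin coverage are retained, so
sum-then-normalise and average-per-anchor readings are both available.

Two normalisations:

* **Genome-wide average**: λ = N·w/G with N the dataset's total tags and G
  the total genome length; `fold_vs_genome = raw / (anchors_covering · λ)`.
  G is the full assembly length, not a mappability-masked length — no
  mappability track is part of the model; this is a documented caveat for
  real data.
* **Input normalisation**: the input profile's bin counts are multiplied by
  the depth factor K = N_treatment/N_input before division. Bins with zero
  input count get the expected corrected count `max(K · λ_input ·
  anchors_covering, 1)` and are flagged low-confidence instead of being
  dropped or divided by zero — AT cores are exactly where input coverage
  dips, so those bins must stay visible.

## AT-core anchors

The anchor of a MAR interval is the centre of the fixed-length window
(default 200 bp, the size scale of a compact AT core) maximising either the
AT fraction (`composition`) or the fraction of adjacent AT/TA dinucleotide
pairs (`dinucleotide`, the default — the core signature is the alternating
(AT)n microsatellite, which composition scoring cannot distinguish from
poly-A). Scores are integer window counts, so the leftmost-maximum
tie-break is exact; N and any non-ACGT base scores zero (conservative for
assembly gaps). A fixed-length maximiser rather than a maximal-scoring
segment keeps the centre well defined and brute-force checkable; on
sequences ≤ 10 kb the implementation is verified against an exhaustive
scan. Without sequence data the interval midpoint is the fallback anchor.
MAR anchors are unoriented ("+"); TSS anchors take the gene strand (plus →
interval start, minus → end − 1).

## qPCR quantification

Relative quantity is E_B^Ct_B / E_A^Ct_A (A = target, B = reference),
which under a common true E estimates the target:reference template ratio;
fold versus a designated control condition sets the control to exactly 1,
and per-copy expression is the mRNA fold divided by the copy-number fold.

Efficiency estimation is a deterministic window-of-linearity variant:

* baseline = mean of cycles 1–5 **when** those cycles form a plateau
  (relative spread < 0.5); otherwise no baseline is subtracted. Baseline
  subtraction is only meaningful where an early plateau exists, and this
  rule keeps a pure exponential curve exact (E recovered to ~1e-15).
* candidate windows are 4–6 consecutive cycles with corrected fluorescence
  strictly positive, at least 20× the early-cycle noise (s.d. of cycles
  1–5) and at most 2% of the plateau amplitude. The 2% ceiling comes from
  the saturating-chemistry model F ∝ cap·g/(cap+g): at a fraction q of the
  plateau the log-slope is depressed by ≈ q, so q ≤ 2% keeps the bias in E
  below ~1%. If no window qualifies the ceiling is dropped before declaring
  no amplification.
* among candidates the window maximising R² of log10(corrected) vs cycle
  wins, ties broken by larger window then earlier start; E = 10^slope,
  required to lie in (1, 2.2].

Ct is the first crossing of a fluorescence threshold, interpolated linearly
on the log10 scale between the bracketing cycles, computed on the raw
curve (thresholds are conventionally placed well above baseline, and
avoiding subtraction keeps closed-form test cases exact). In the plate
workflow, efficiencies are estimated per well and averaged per gene
(efficiency is an amplicon property), while replicate Cts are averaged per
condition before the ratio — replicate wells are not paired.

## Cytometry scoring

Gates are half-open `[lower, upper)`: an event exactly at a gate belongs to
the upper category, which makes "silent = RFU strictly below 10" exact and
scoring deterministic. Counts are integers and fractions exact rationals,
so the four fractions sum to 1 identically. Only the silent gate (10 RFU,
the background of non-transfected cells) is empirically anchored; the
low/medium boundaries (defaults 100 and 1000 RFU) are configuration
placeholders that four-category analyses must set. Mean fluorescence is
provided both over all events and over non-silent events only, since
either convention is defensible for fold-change reporting.

## Synthetic data: what it emulates, and what it does not

Tag datasets are drawn from an inhomogeneous Poisson process with per-bp
intensity ρ·(1 + (a − 1)·Σ exp(−(x − c)²/2σ²)), optionally multiplied by a
dip factor d ∈ (0, 1] over planted core windows. The Gaussian term is
multiplicative so the expected fold tracks have closed forms
(`expected_fold_vs_input`, `expected_fold_vs_genome`, single-anchor
approximation valid when anchors are well separated relative to σ).
Enrichment (a ≥ 1) is sampled exactly as background plus per-anchor
Gaussian components with edge truncation; depletion (a < 1) by thinning;
the dip by a second thinning pass. With `n_tags` set, the rate is rescaled
so the realised total Poisson-matches the target in expectation.

The core dip models low-complexity undercounting as a property of the
*sequence*, so it is applied to whichever datasets are simulated with core
windows — treatment and input alike. That is the configuration in which
input normalisation is informative: the dip cancels in the ratio while the
genome-average fold stays distorted by a factor ≈ d at the core, and the
K factor absorbs the residual total-count difference. A dip confined to
the input alone would instead *create* a spurious enrichment of 1/d in the
normalised profile.

Default constants — ρ = 0.05 tags/bp, σ = 300 bp, a = 3 (Pol II-like),
a = 0.4 (histone-like), d = 0.6, core 200 bp inside 2 kb MAR intervals with
5% substitution noise, 10⁵ cytometry events with a 30%/70% silent/medium
mixture, qPCR plateau curves with baseline 50, capacity 10⁵ and 2%
multiplicative noise — are fixture choices defining the test conditions,
not estimates of any particular experiment. The reference profile scenario
uses 1000 anchors on a 4×10⁷ bp genome at 2×10⁶ tags per library: the
planted center fold is attenuated by the K-correction factor
1 + (a−1)·σ√(2π)·n_anchors/G (≈ 3% here), so the genome must be large
relative to the total peak mass for the planted amplitude to be
recoverable; sizes were fixed from that analysis.

Not modelled: read length and sequencing error, fragment-size distributions,
GC bias beyond the core dip, mappability, chromatin contamination in the
input, pipetting/plate effects in qPCR, autofluorescence spillover or
doublets in cytometry. Passing tests therefore demonstrate correctness of
the *computations* under a clean generative model, not robustness to every
real-data artifact.

## Numerical and design notes

* Coordinates are validated at parse time with line-numbered errors;
  duplicate chromosomes in chrom.sizes are an error rather than a silent
  overwrite.
* Bin arithmetic is integer throughout; fold tracks are float64 with NaN
  marking bins covered by no anchor.
* All generators are pure functions of (parameters, seed) via
  `numpy.random.default_rng`; repeat calls are byte-identical, and every
  CLI `simulate` subcommand requires `--seed`.
* Profile TSVs round-trip to 6 significant digits; run manifests record
  parameters, totals, K and λ, and suffice to reproduce a run.
* Degenerate inputs (zero total tags, empty event tables, constant qPCR
  curves, zero controls) raise typed errors rather than returning NaN.

## Known limitations

* The AT-core "centre" is this package's operationalisation (fixed-window
  maximiser); other tools may define the centre of curvature-predicted
  cores differently, shifting anchors by tens of bp.
* Efficiency estimation assumes an early-cycle plateau or a clean
  exponential; curves already rising at cycle 1 with a large hidden
  baseline will bias E.
* `fold_vs_genome` uses total assembly length; on masked or incomplete
  assemblies λ is underestimated and folds inflated accordingly.
* FCS binary parsing is out of scope; events arrive as delimited text.
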