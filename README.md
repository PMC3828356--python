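# marpipe

Matrix attachment regions (MARs) are AT-rich genomic elements that anchor
chromatin loops, block the spread of heterochromatin and boost transgene
expression. Characterising them computationally involves three very
different measurements that this package implements as one tested pipeline:

1. **Anchor-centred ChIP-Seq meta-profiles.** Candidate MAR intervals are
   reduced to the centre of their AT-dinucleotide-rich core, tags from a
   ChIP-Seq experiment are counted in 100 bp windows across ±5 kb around
   every anchor, and the aggregate is expressed as a fold change over the
   genome-wide average tag count, λ = N·w/G, and over a depth-corrected
   non-precipitated input profile. The input bin counts are first multiplied
   by the depth factor **K = N<sub>treatment</sub>/N<sub>input</sub>**, so
   fold<sub>input</sub>(bin) = n<sub>treat</sub>(bin) / (K·n<sub>input</sub>(bin)).
   Input normalisation matters because AT cores are low-complexity sequence
   with depressed tag counts in every library; dividing by the input cancels
   that artifact where the genome-average fold does not. Transcription start
   site (TSS) profiles use the same machinery with anchors oriented by gene
   strand.
2. **qPCR relative quantification.** Per-curve amplification efficiency E is
   estimated from the window of linearity of log10(fluorescence) after
   baseline subtraction; Ct is interpolated on the log scale; relative
   transgene copy number and mRNA level follow
   **E<sub>B</sub><sup>Ct<sub>B</sub></sup> / E<sub>A</sub><sup>Ct<sub>A</sub></sup>**
   with gene A the target (GFP) and gene B the endogenous reference (GAPDH
   for DNA, eEF1A for mRNA), expressed as fold change versus a control
   condition set to 1, and optionally per transgene copy
   (mRNA fold / copy fold).
3. **Cytometry silencing scores.** Reporter-fluorescence event tables are
   gated half-open into silent (< 10 RFU, the non-transfected background),
   low, medium and high categories; the silent fraction quantifies
   transgene silencing, and mean-fluorescence fold changes versus a control
   population quantify transcriptional augmentation.

A synthetic-data module generates every input with known ground truth —
genomes with planted AT cores, inhomogeneous-Poisson tag sets with Gaussian
enrichment (Pol II-like), depletion (histone-like) and a core coverage dip,
plateauing qPCR curves, log-normal fluorescence mixtures — so the whole
pipeline is testable without external datasets.

The package is for computational biologists who need reproducible
meta-region profiling around sequence-defined anchors, and for labs doing
MAR/transgene work who want the bookkeeping (K factors, efficiencies,
gates) pinned down and tested.

## Worked example

```python
import marpipe as mp

genome, seqs, mars, truth = mp.make_genome_with_mars(
    n_chrom=1, chrom_length=2_000_000, n_mars=50,
    core_len=200, flank_len=900, seed=1)
anchors = mp.anchors_from_intervals(mars, genome, sequences=seqs, core_window_bp=200)
cores = mp.core_windows_from_truth(truth, 200)

polII = mp.TagSignalModel(rho=0.05, amplitude=3.0, sigma=300, core_dip=0.6, seed=2)
chromatin_input = mp.TagSignalModel(rho=0.05, amplitude=1.0, sigma=300, core_dip=0.6, seed=3)
treat = mp.simulate_tags(genome, anchors, polII, n_tags=100_000, core_windows=cores)
inp = mp.simulate_tags(genome, anchors, chromatin_input, n_tags=100_000, core_windows=cores)

grid = mp.ProfileGrid(half_span=5000, window=100)
tp = mp.fold_change_over_genome(mp.count_tags_in_bins(treat, anchors, grid, genome))
norm = mp.normalize_to_input(tp, mp.count_tags_in_bins(inp, anchors, grid, genome))
center = grid.n_bins // 2
print(f"K factor                  = {norm.k_factor:.3f}")
print(f"fold vs genome at core    = {norm.fold_vs_genome[center]:.2f}")
print(f"fold vs input at core     = {norm.fold_vs_input[center]:.2f}")

e = mp.estimate_efficiency(mp.simulate_qpcr(1.90, 5e-3, 40, noise_sd=0.02, seed=4))
ct_gfp = mp.call_ct(mp.simulate_qpcr(1.90, 5e-3 * 16, 40, noise_sd=0.02, seed=5), 500.0)
ct_ref = mp.call_ct(mp.simulate_qpcr(1.90, 5e-3, 40, noise_sd=0.02, seed=6), 500.0)
print(f"estimated efficiency E    = {e:.3f}")
print(f"relative copy number      = {mp.relative_quantity(e, ct_gfp, e, ct_ref):.1f}")

events = mp.simulate_cytometry([0.30, 0, 0.70, 0], [3, 30, 500, 5000], n=100_000, seed=7)
frac = mp.classify_events(events, mp.GateConfig(10, 100, 1000))
print(f"silent-cell fraction      = {frac['silent']:.3f}")
```

prints

```
K factor                  = 1.003
fold vs genome at core    = 1.80
fold vs input at core     = 3.26
estimated efficiency E    = 1.909
relative copy number      = 15.9
silent-cell fraction      = 0.300
```

Reading the numbers: a 3-fold Pol II-like enrichment was planted at the
anchors, together with a 0.6× low-complexity coverage dip shared by
treatment and input. The genome-average fold (1.80 ≈ 3 × 0.6) is corrupted
by the dip; the input-normalised fold recovers ≈ 3 because the dip cancels
and K corrects the residual depth difference. The qPCR block plants a 16:1
target:reference template ratio at true E = 1.90 and recovers both; the
cytometry block plants a 30% silent population and recovers it.

The same analyses are available from the shell via the `marpipe` command
(`profile`, `quant`, `facs`, `anchors` and `simulate` subcommands); run
`marpipe --help` for the flags, all of which can also be supplied through a
flat YAML `--config` file.

## Layout

| module | contents |
| --- | --- |
| `marpipe.genomic_io` | BED / chrom.sizes / tag / FASTA / profile-TSV I/O, 0-based half-open throughout |
| `marpipe.anchors` | AT-core detection (composition and dinucleotide scores), MAR and TSS anchors |
| `marpipe.metaprofile` | anchor-relative binning, genome-average and K-corrected input normalisation |
| `marpipe.qpcr` | efficiency, Ct, E^Ct ratios, fold vs control, per-copy expression, plate workflow |
| `marpipe.cytometry` | half-open gating, category fractions, mean-fluorescence folds |
| `marpipe.synthetic` | ground-truth generators for all of the above |
| `marpipe.pipeline`, `marpipe.cli` | YAML-configurable runs, manifests, `marpipe` console script |

See `docs/methods.md` for the models, parameter choices and limitations.
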