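# Methods

## Quantification model

A barcoded promoter screen measures, per tissue β and promoter α, two
barcode count vectors: gDNA (how many vector genomes of construct α
reached the tissue) and cDNA (how many reporter transcripts it
produced). Counts are converted to proportions over *assigned* reads
only; ambiguous and unassigned reads are excluded from the denominator
so that assignment failures, which are promoter-independent, do not
distort composition.

Normalized expression is `R_αβ = (P_αβ(cDNA)/P_αβ(gDNA)) · C_β`. The
ratio of proportions is per-copy transcriptional output up to a
tissue-level constant; multiplying by the bulk reporter expression
`C_β = 2^−ΔCt` (measured against a housekeeper on whole-tissue cDNA)
removes that constant so that values are comparable across tissues.
Efficiency scores renormalize R within a tissue
(`E_αβ = 100·R_αβ/Σ_α R_αβ`), so any per-tissue factor — including
`C_β` itself — cancels; specificity scores renormalize across tissues
(`S_αβ = 100·R_αβ/Σ_β R_αβ`) and therefore *do* depend on `C_β` and on
tissue biodistribution. Both invariances are asserted in the test
suite. Scores are computed per animal and aggregated as mean ± sample
SD with per-cell n; a pooled mode is deliberately absent from the
default path because replicate variance is part of the result.

For individually injected constructs, `Q_αβ = C_αβ/G_αβ` replaces R,
with `G_αβ = eyfp/(Rpp30/2)` from ddPCR. Because G is a ratio of two
channels from the same well, DNA input mass cancels; no input-mass
correction is applied (the reduced liver input of typical protocols is
therefore irrelevant to G). Specificity is computed per animal from
that animal's Q across tissues; efficiency uses the per-construct mean
Q* across its replicate animals, because in a single-vector cohort each
promoter has its own animals and per-animal cross-promoter ratios do
not exist.

## Zero handling and masking

No pseudocounts are used anywhere: pseudocounts silently bias ratios of
proportions, and the gDNA proportion sits in a denominator where small
counts are explosive rather than merely noisy. Instead, promoters with
fewer than 10 assigned gDNA reads in a sample (configurable) are masked
for that sample; masked cells are NaN and excluded from every
downstream sum, and the score invariants (sum to 100 within 1e-9, all
values in [0, 100]) are enforced over unmasked entries. Undetermined
qPCR Ct values are treated as missing rather than imputed at a cycle
ceiling, which would fabricate expression values; technical duplicates
are averaged on the Ct (log) scale, the standard ΔCt practice, and
duplicate spreads beyond 1 cycle are flagged but not discarded.

## Barcode extraction and assignment

Reads are single-end 84 nt with the 15-nt barcode flanked by constant
amplicon sequence. The 5′ anchor is placed at its best-scoring
(fewest-substitution) offset, leftmost on ties, allowing at most
`max_anchor_mismatch` (default 1) substitutions; the barcode is the
following 15 bases, and when a 3′ anchor is configured it must follow
immediately within the same allowance. Observed barcodes are assigned
to the unique nearest library barcode within `max_bc_mismatch`
(default 1) substitutions; ties are counted as ambiguous and excluded
rather than fractionally split, which would correlate noise across
promoters. Indels are not modeled — anchored extraction plus
substitution-only Hamming matching is a known limitation, acceptable
for short fixed-length barcodes. Every read is accounted for exactly
once (assigned / no-anchor / unassigned / ambiguous), an invariant
checked on every sample.

The amplicon's barcode-flanking constants depend on the library design
and are required configuration, not package constants; the simulator
ships an arbitrary fixed pair of realistic length (20 and 15 nt) for
self-contained testing. Barcode maps are TSV with required columns
`promoter_id` and `barcode`; the loader validates length-15 ACGT
barcodes, uniqueness of ids and barcodes, and reports (but does not
enforce) the set's minimum pairwise Hamming distance, since the
tolerable separation depends on the downstream mismatch settings.
Fresh barcode sets are drawn by seeded rejection sampling with a retry
cap (default 1e6 draws) — simple, reproducible, and adequate for
library sizes up to a few hundred.

## Synthetic screens

The generator emulates the study design: 53 constructs pooled
equimolarly, 16 tissues, 6 animals, ~1e5 reads per sample. Per animal,
the effective pool is a Dirichlet perturbation of the nominal
proportions (concentration 5000·L), modelling injection and
biodistribution jitter with realistic inter-animal variance; the
concentration is a chosen parameter, not an estimate from data. gDNA
counts are multinomial draws from the animal's pool; cDNA counts are
multinomial with probabilities proportional to the *realized* gDNA
proportions times the true activity matrix A — transcription is
conditioned on the genomes actually delivered, the causal structure
the R ratio assumes. Bulk expression is
`C_β = c0 · Σ_α pool_α·A_αβ·D_β` with lognormal noise (σ = 0.2), where
`D_β` is true vector copies per diploid genome. FASTQ reads are
anchor + barcode + anchor + filler padded to 84 nt with i.i.d.
substitution errors (default 0.005/base); output bytes are
reproducible for a fixed seed (gzip mtime pinned). Single-vector
readouts draw ddPCR channel counts with lognormal noise around the
true dose and Ct values with Gaussian noise (σ = 0.25 cycles) around
the ΔCt implied by A and the delivered dose.

The default activity matrix has lognormal promoter strengths (σ = 1),
lognormal tissue modulation (σ = 0.5), and a 20× "home-tissue" boost
for ~40% of promoters; biodistribution is lognormal around 1 VG/DG
with a 10× liver excess, the signature tropism of systemically
injected AAV9. These are plausible synthetic defaults: the generator
reproduces equimolar pooling, per-tissue biodistribution, multinomial
sampling noise and readout noise, but not PCR jackpotting/duplicates,
GC bias, index hopping, or mechanistic capsid tropism — so passing
tests demonstrate correctness of the arithmetic and robustness to
sampling noise, not robustness to every real-data artifact.

Two exact modes support fixed-point testing. `expected_screen` returns
the infinite-depth, noise-free limit of the library screen as exact
proportion tables (integer count tables cannot represent this limit at
finite depth), and `simulate_single_vector(exact=True)` disables all
readout noise. Composed with the pipeline, both reproduce the true
within-tissue activity shares to floating-point accuracy, and the two
paths' within-tissue rankings agree exactly (Kendall τ = 1).

## Reporting choices

Pearson correlations are computed on untransformed 0–100 scores with
listwise deletion of masked pairs and are reported as undefined below
n = 3 or at zero variance. Heatmap matrices are rescaled to natural
logarithms with ε = half the smallest positive entry standing in for
zeros (monotone on positive values), then row/column ordered by
agglomerative clustering — euclidean distance, complete linkage by
default, with scipy's deterministic lowest-index tie-breaking; an
all-constant matrix keeps input order with a notice. PCA centers
columns without variance scaling by default (matching the common
default of R's `prcomp`), exposes scaling as a flag, and orients each
component so its largest-magnitude loading is positive, making signs
stable across runs and implementations.

## Problem sizes and numerical notes

The test suite and acceptance script run the full study-scale recovery
(53 × 16 × 6 at depth 1e5) directly from multinomial count tables —
this is fast because read-level simulation is only needed where
extraction itself is under test (1e4-read FASTQ fixtures there).
Score sums are exact to ~1e-13 relative; the enforced tolerance is
1e-9. The demultiplexer is verified read-for-read against exhaustive
brute-force oracles (every anchor offset, every barcode, full Hamming
scan) at both strict (0,0) and default (1,1) mismatch settings.

## Known limitations

- Substitution-only matching; indel-bearing reads are lost (tallied,
  not misassigned).
- `C_β` may be supplied per animal or as per-tissue means broadcast to
  all animals; the broadcast loses inter-animal expression variance in
  specificity scores.
- The simulator's inter-animal variance structure (Dirichlet
  concentration) is a free parameter; real screens may be over- or
  under-dispersed relative to it.
- No differential-activity hypothesis testing: the pipeline produces
  descriptive scores with replicate SDs, not p-values.
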