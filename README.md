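# promoscreen

Quantification pipeline for barcoded AAV promoter-library screens.

## The problem

Choosing a promoter for an AAV gene-therapy vector means knowing two
things that are expensive to measure one construct at a time: how
*strong* the promoter is in a given tissue, and how *specific* its
activity is to that tissue. Barcoded library screens solve this in a
single animal cohort: every promoter drives the same reporter, tagged
with a unique 15-nt DNA barcode in the 3′ UTR, all constructs are
packaged, pooled equimolarly and injected systemically. Sequencing the
barcode region of each tissue's genomic DNA (vector delivery) and cDNA
(transcription) then reads out every promoter's performance at once.

`promoscreen` implements the complete downstream analysis:

* barcode extraction and counting from amplicon FASTQ reads
  (anchored, bounded-mismatch, with full read bookkeeping);
* the normalization cascade from counts to promoter×tissue scores;
* the single-vector validation arithmetic (ΔCt qPCR and ddPCR);
* comparison artifacts (Pearson correlations, clustered log-score
  matrices, PCA);
* a synthetic-screen generator with known ground truth, so every stage
  is testable end to end without any sequencing data.

## The model

For promoter α in tissue β, with `P_αβ(cDNA)` and `P_αβ(gDNA)` the
barcode proportions in cDNA and gDNA and `C_β` the bulk relative
reporter expression of the tissue (qPCR, `2^−ΔCt` vs. a housekeeper),
normalized expression is

```
R_αβ = ( P_αβ(cDNA) / P_αβ(gDNA) ) · C_β
```

The cDNA/gDNA ratio cancels biodistribution; `C_β` restores each
tissue's absolute expression scale. `R` is deconstructed into

```
efficiency   E_αβ = 100 · R_αβ / Σ_α R_αβ    (sums to 100 per tissue)
specificity  S_αβ = 100 · R_αβ / Σ_β R_αβ    (sums to 100 per promoter)
```

computed per animal and then averaged (mean ± SD) over replicates.

For individually injected constructs the same scores are built from
`Q_αβ = C_αβ / G_αβ`, where `C_αβ = 2^−ΔCt` is relative expression and
`G_αβ = eyfp copies / (Rpp30 copies / 2)` is the ddPCR vector dose in
vector genomes per diploid genome (Rpp30 is a two-copy autosomal gene).

## Worked example

Simulate a full screen (53 promoters × 16 tissues × 6 animals, 10⁵
reads/sample) and quantify it:

```python
import promoscreen as ps

truth, bc_map = ps.default_truth(n_promoters=53, n_animals=6,
                                 depth=100_000, seed=7)
ds = ps.simulate_counts(truth)
r = ps.quantify_screen(ds.counts, ds.samples, ds.bulk)
eff = ps.aggregate_replicates(ps.efficiency_scores(r))
spec = ps.aggregate_replicates(ps.specificity_scores(r))

print(eff.mean["liver"].sort_values(ascending=False).head(3).round(2))
best = eff.mean["liver"].idxmax()
print(spec.mean.loc[best].sort_values(ascending=False).head(3).round(2))
report = ps.recovery_report(eff.mean, truth)
print(f"Spearman rho vs truth: {report.mean_spearman:.3f}; "
      f"top promoter recovered in {report.top1_agreement}/16 tissues")
```

prints

```
P08    39.09
P47    17.25
P06     8.59
Name: liver, dtype: float64
liver    94.38
ovary     1.20
gut       0.59
Name: P08, dtype: float64
Spearman rho vs truth: 0.999; top promoter recovered in 16/16 tissues
```

P08 is the screen's strongest liver promoter (efficiency 39 of 100,
i.e. 39% of all liver expression), and it is liver-*specific*: 94% of
its total activity across the 16 tissues is hepatic. The recovery
report confirms the pipeline's estimates rank promoters essentially
identically to the simulator's ground truth.

The same steps are available from the shell:

```
promoscreen simulate --promoters 53 --animals 6 --depth 100000 --seed 7 --out-dir run/
promoscreen quantify --counts-dir run/counts --samples run/samples.csv \
    --bulk run/bulk_expression.csv --out run/quant
promoscreen recover --est run/quant/efficiency_mean.tsv --truth run/truth.json
```

plus `promoscreen count` (FASTQ → counts), `promoscreen validate`
(qPCR/ddPCR → Q and scores), `promoscreen barcodes
generate|validate`, and `promoscreen report` (heatmap / PCA /
correlations).

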