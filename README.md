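# paralogdose

Quantitative "paralog dose" analysis for the STAT5A/STAT5B transcription
factor pair in T cells.

STAT5A and STAT5B are duplicated genes whose combined dose — allele count
and expression level — shapes cytokine-driven transcription in CD4+ T
cells. Comparing wild-type cells with *Stat5a*- and *Stat5b*-deficient
cells asks, per transcript, *which paralog matters more, and by how much*.
`paralogdose` implements that analysis as a tested, reusable pipeline:

- **Expression core** — RPKM matrix ingestion, pseudo-count offset
  normalization (the second quartile of the dataset, typically 0.2–0.3),
  most-abundant-fragment collapsing, the RPKM < 1 expression filter, and
  fold-change/p-value thresholding (regulated ⇔ >1.5-fold, p < 0.05) with a
  pooled-variance t-test on log2 values as the small-sample test (variance
  floor s₀ = 0.05); precomputed DE tables load verbatim.
- **Paralog preference** — per gene and KO-vs-WT contrast, a paralog score
  `s = |FC| × max(RPKM_WT, RPKM_KO)`; the preference is
  `log2(s_B / s_A)`, positive when the transcript is more impacted by loss
  of STAT5B. Preferences are summarized as a 12-bin histogram (bin 1 below
  −5, unit bins, bin 12 at +5 and above) plus the median, and arbitrary
  gene sets can be projected onto the scale.
- **Paralog specificity** — pan-STAT5 vs STAT5A-/STAT5B-specific calls:
  specific ⇔ the two knockouts differ directly (>1.5-fold, p < 0.05),
  regulated vs WT in one contrast (>1.5-fold, p < 0.05) and essentially
  unchanged in the other (<1.2-fold); opposite-direction transcripts are
  excluded.
- **Paralog abundance** — % of total STAT5 per paralog from mRNA ratios or
  from total-STAT5 MFI measured across the *Stat5* allele series (fold
  changes vs WT, ratios within the one- and three-allele pairs, averaged).
- **ChIP-seq integration** — peak retention (>3-fold enrichment,
  p < 5e-5), symmetric overlap counts between genotypes (maximum one-to-one
  matching of intervals), peak-to-TSS distance histograms in 10 kb bins,
  ±10 kb peak-to-gene assignment, and the occupancy hierarchy relating how
  deeply a gene's binding persists across WT → het → A-KO → B-KO to its WT
  peak height and expression dysregulation.
- **Synthetic data** — a generator planting all of the structure above
  (lognormal baselines, pan effects with a B/A asymmetry ratio r such that
  |log2FC_B| = |log2FC_A| + log2 r, paralog-specific genes,
  height-thresholded peak retention, an MFI allele series) with full
  ground-truth records, so every stage is testable without sequencing data.

## Worked example

Run the fully simulated pipeline:

```bash
paralogdose run --simulate --seed 7 --out report.json
```

With the default simulation (1000 genes, 3 replicates per genotype, 30%
pan genes at asymmetry r = 2, 6% paralog-specific genes, log2 noise 0.4)
the report contains, among other things:

```
offset            0.2261
n_input 1000 | analyzed 286 | pooled 117
median preference 0.745
labels            {'pan': 43, 'a_specific': 8, 'b_specific': 6,
                   'excluded_opposite': 0, 'unclassified': 60}
peak counts       {'WT': 213, 'het': 163, 'A-KO': 88, 'B-KO': 18}
occupancy groups  mean WT heights 8.7 < 17.9 < 36.1 < 72.1
abundance         mRNA: 66.7% STAT5B  protein: 61.9% STAT5B
```

Reading these: the offset lands in the expected 0.2–0.3 band; 286 of 1000
genes are expressed (≥1 RPKM in some genotype); 117 are STAT5-regulated.
The median preference of +0.745 recovers the planted B-dominance
(log2 2 = 1, attenuated by noise and the specific genes in the pool); 12%
of regulated genes are called paralog-specific. Peak counts fall along the
genotype series, and the mean WT peak height rises strictly with sharing
depth — high-affinity sites are the ones preserved when STAT5 dose drops.
The MFI allele series (unit contributions B = 2A) yields STAT5B carrying
61.9% of total protein, matching the hand-computed closed form.

Every stage is also available separately (`paralogdose simulate`, `de`,
`preference`, `specificity`, `abundance`, `chip`) on TSV/BED/JSON files,
or as library functions (`paralogdose.compute_de`,
`build_preference_records`, `classify_specificity`, …).

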