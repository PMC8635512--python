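# rbprofiler

Profiling RNA-binding protein (RBP) expression across human B- and
T-lymphocyte differentiation.

RBPs steer post-transcriptional gene regulation — RNA splicing,
stability, transport, modification and translation — and their
relative abundance shifts as naive lymphocytes differentiate into
memory and effector cells. `rbprofiler` is a reusable pipeline for
cataloguing that landscape from bulk RNA-seq, quantitative proteomics
and single-cell RNA-seq tables. It is aimed at immunologists and
computational biologists who have gene-level quantification matrices
in hand and want the cataloguing, differential-expression and
cytotoxicity-scoring stages as tested, scriptable components.

## What it computes

**Reference catalogue.** Experimentally identified RBPs (RNA-interactome
capture) are merged with computationally predicted ones; histones,
known affinity-purification contaminants and mitochondrial RBPs are
flagged and removed. Entries carry RNA-binding-domain (RBD)
annotations (canonical = RRM, KH, DEAD, zinc fingers, dsRBD, ... —
the packaged list is editable) and membership in five RNA-process
function classes.

**Bulk expression.** TPM normalisation
(`tpm_g = 10^6 (c_g/ℓ_g) / Σ_j (c_j/ℓ_j)`), detection calling
(mean TPM > 0.1, copy number > 1; strict), expression ranking,
Venn-region overlap counts, RNA–protein concordance (Pearson r of
log₁₀ abundances per gene group) and PCA of the most variable genes.

**Differential expression.**

* RNA: per-gene negative-binomial Wald test on raw counts —
  median-of-ratios size factors, method-of-moments dispersion with
  across-gene moderation, LFC = log₂((μ̂₂+ε)/(μ̂₁+ε)),
  Var(ln μ̂ₖ) ≈ (1/μ̂ₖ + α̂)/nₖ — with normal-prior shrinkage of the
  LFCs (posterior mean `lfc·τ²/(τ²+se²)`) and Benjamini–Hochberg
  adjustment. DE call: |LFC| > 0.5 and adjusted p < 0.01 (strict).
* Protein: empirical-Bayes moderated t on log₂ LFQ intensities
  (`s²_post = (d₀s₀² + d s²_g)/(d₀+d)` with moment-matched prior),
  thresholds |LFC| > 0.5, adjusted p < 0.05.
* Single cell: two-part hurdle test (binomial detection + Gaussian
  continuous component, combined likelihood ratio on 1–2 df).

DE genes are intersected with the curated catalogue, clustered
hierarchically on row-z-scored profiles, and each cluster is
summarised by its function-class distribution with Fisher-exact
overrepresentation tests.

**Cytotoxicity.** In single-cell data, naive T cells (high
CCR7/LEF1/SELL) are excluded by two-means on a marker Z-score; a
signature is built from the anchor FGFBP2 plus the 7 genes most
correlated with it; each cell's cytotoxic score is the mean of the
signature genes' Z-scored log-normalised expression; cells are binned
into bottom-10% / middle / top-10% score groups, the hurdle test
contrasts the extreme bins, and RBPs moving consistently in CD8⁺ and
CD4⁺ T cells form the shared cytotoxic repertoire.

Every stage is exercised end-to-end on synthetic data with recorded
ground truth (`rbprofiler.simulate`): NB bulk counts with planted
fold changes, protein abundances at calibrated RNA–protein
correlations, and sparse single-cell counts with a planted
anchor-correlated cytotoxic module and naive-marker module.

## Worked example

```python
import rbprofiler as rb

# curated reference catalogue (synthetic fixture mirroring the
# published curation arithmetic)
fix = rb.make_reference_fixture(seed=1)
catalog = rb.compile_catalog(fix["experimental"], fix["predicted"], fix["flags"])
print(f"merged {catalog.n_merged}, flagged {catalog.n_flagged}, "
      f"curated {catalog.n_curated}")

# single-cell cytotoxicity stage on synthetic T cells
sc, truth = rb.simulate_sc(seed=1)
scorer = rb.CytotoxicScorer().fit(sc)
print("signature:", ", ".join(scorer.signature_))
bins = scorer.bins_
res = rb.hurdle_de_test(scorer.scored_, bins[bins.isin(["low", "high"])],
                        reference="low")
print(res[res["de_flag"]][["lfc_raw", "padj"]].round(3))
```

prints

```
merged 3333, flagged 100, curated 3233
signature: FGFBP2, NKG7, GNLY, CX3CR1, GZMH, ADGRG1, GZMB, PRF1
        lfc_raw  padj
symbol
CX3CR1    4.124   0.0
ADGRG1    4.030   0.0
FGFBP2    3.997   0.0
PRF1      3.992   0.0
GNLY      3.961   0.0
GZMH      3.946   0.0
NKG7      3.912   0.0
GZMB      3.790   0.0
```

The catalogue line is the curation arithmetic (3,333 merged putative
RBPs, 100 flagged, 3,233 kept). The signature is the anchor FGFBP2
plus the seven genes most correlated with it — here exactly the
planted cytotoxic module — and the hurdle test between the top-10%
and bottom-10% score bins recovers all eight signature genes as
upregulated in high-score cells (600 of 2,000 cells were excluded as
naive; the per-cell score tracks the planted activity at Spearman
ρ = 0.97).

A command-line interface mirrors the library
(`rbprofiler simulate|catalog|detect|de|cluster|classes|cytotox|cytotox-de`);
run `rbprofiler --help`.

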