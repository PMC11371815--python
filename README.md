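# fibretmt

Analysis pipeline for **pooled single-fibre TMT proteomics** of human
skeletal muscle: normalisation across multi-plex isobaric-label batches,
moderated-t differential expression between fibre types and across
training, and — the part that changes conclusions — **mitochondrial-content
correction**, which separates "type I fibres have more mitochondria" from
"type I mitochondria are built differently".

It is written for muscle and exercise physiologists analysing
fibre-type-pooled TMT reporter matrices (proteins × samples), and ships a
synthetic-cohort generator with known ground truth so every claim the
pipeline makes can be checked against a planted answer.

## The analysis in brief

Reporter intensities are modelled as lognormal with log2-additive effects.
For protein *g* in sample *s* (fibre type *f*, timepoint *t*, training
group *c*, plex *b*):

    log2 x_gs = mu_g + beta_fibre_g·[f = II] + beta_train_gc·[t = POST]
                + log2 m(f,t,c)·[g mitochondrial] + gamma_bg + eps·delta_bg
                + log2 l_s

where `m` is a *global mitochondrial-content multiplier*, `gamma/delta`
are plex location/scale batch effects and `l_s` is channel loading.

The pipeline stages:

1. **Clean-up** — keep proteins with high identification confidence, no
   contaminant flag and > 1 unique peptide; drop proteins missing in more
   than 30% of all samples; impute the rest by a protein-neighbour kNN
   average on the log2 scale (k = 10).
2. **Normalisation** — sample loading (equal total signal per channel
   within a plex) → TMM (trimmed mean of M-values, precision-weighted)
   → log2 → ComBat (parametric empirical-Bayes location/scale batch
   adjustment, biological covariates preserved).
3. **Differential expression** — per-protein least squares with
   participant blocking; empirical-Bayes variance moderation
   (s²_post = (d₀s₀² + d·s²)/(d₀ + d), moderated t on d₀ + d df);
   Benjamini–Hochberg adjustment; significance is `p_adj < 0.05`, the
   ±0.2 log2FC bound only colours direction labels.
4. **Fusion scoring** — for paired training contrasts,
   π = |log2FC|·(−log10 p) with a within-pair sign-flip permutation null
   (exhaustive up to 12 pairs).
5. **Mitochondrial correction** — MPE (share of total intensity from
   mitochondrial proteins, a content proxy) and *mitochondria-corrected
   relative abundance*: the mitochondrial subset is re-normalised from
   the raw scale with the same chain, removing any global content
   multiplier by construction.
6. **Profiles & enrichment** — Δ mean z-score of functional groups
   (OXPHOS complexes CI–CV, TCA, β-oxidation, mitochondrial ribosome,
   dynamics, …) with paired t-tests, UPGMA heatmap ordering, and one-sided
   Fisher's exact enrichment over user-supplied term maps.

## Worked example

`examples/mito_content_correction.py` simulates a cohort in which type I
fibres carry exactly **2×** the mitochondrial content of type II fibres
and *no* mitochondrial protein is individually remodelled, then runs the
fibre-type contrast before and after subset renormalisation:

```
mitochondrial proteins analysed: 249
significant with standard normalisation:  242 (97.2%)
significant after content correction:     0 (0.0%)
```

Every one of the 242 calls under standard normalisation is a content
artefact — the planted truth contains no per-protein difference — and the
corrected analysis returns to the nominal false-positive rate. The other
example scripts cover cohort simulation (`simulate_cohort.py`), the full
orchestrated run with manifest (`run_full_pipeline.py`) and the
sensitivity/error-control trade-off between fusion scoring and BH
adjustment (`fusion_vs_bh.py`).

A thin CLI mirrors the stages (`fibretmt simulate | preprocess |
normalise | de | mitonorm | profiles | run-all`); re-running `run-all`
with the same config and seed reproduces every output byte for byte.

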