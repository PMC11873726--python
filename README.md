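# ithkit

Multiregion tumor transcriptome, microenvironment and immune-repertoire
coevolution analysis, with a synthetic cohort generator for end-to-end
verification.

The toolkit implements, as tested reusable components:

- **Expression distances and I-TED** — 1 − Pearson r over the cohort's
  top-variable genes, per-patient intratumor expression distance
  (median of all primary–primary pair distances), and a bootstrap
  inter-/intra-tumor heterogeneity ratio with percentile CIs.
- **Phylogeny-aware quantities** — minimum edge-count clonal distances
  between samples (zero when a clone is shared), distance to the MRCA,
  terminal-clone identification, metastasis seeding classification, and
  clone-level expression/TME profiles from monoclonal regions.
- **A pairwise-difference gene regression framework** — per gene, a
  linear mixed-effects model of expression differences between
  within-patient sample pairs on copy-number, epigenetic-driver,
  9p-loss and purity differences (plus random baseline covariates),
  with patient and WGD-status random intercepts and BH-FDR per
  covariate; 9p-arm genes have their CN difference masked.
- **I-TED variance decomposition** — sequential (type-I)
  sum-of-squares shares of nine clinico-genomic covariates, plus the
  driver-CNA swap variant.
- **TME layer** — a from-scratch ssGSEA running-sum implementation
  (rank-weighted, deterministic tie-breaks), signature Z-scores,
  antitumor/immunosuppressive classification, directional transition
  counting with a chi-squared test against a 0.5-transition null, and
  3-group infiltration clustering (Manhattan distance, complete
  linkage).
- **Immune repertoires** — Morisita–Horn overlap, Gini clonality,
  clonotype-sharing reports, and overlap-vs-clonal-distance
  mixed-model association.
- **Synthetic cohorts** — clone trees grown by uniform attachment,
  cumulatively inherited genotypes (arm losses/gains, driver
  mutations), purity-admixed expression with gene-dosage effects and
  Brownian drift along tree edges, driver-linked immune shifts,
  Dirichlet TME fractions, lineage-coupled repertoires, and a full
  ground-truth record.

## CLI

Every stage reads a cohort directory (as written by `simulate`, or
assembled from real data in the same text formats) and writes TSV
tables:

```sh
ithkit simulate --seed 7 --out-dir cohort/
ithkit ited        --cohort cohort/ --out-dir results/ --top-k 500
ithkit distances   --cohort cohort/ --out-dir results/
ithkit clone-expr  --cohort cohort/ --out-dir results/
ithkit gene-model  --cohort cohort/ --out-dir results/
ithkit tme         --cohort cohort/ --out-dir results/
ithkit transitions --cohort cohort/ --out-dir results/ \
    --classification results/tme_classification.tsv
ithkit repertoire  --cohort cohort/ --out-dir results/
ithkit report      --cohort cohort/ --out-dir results/
```

Fixed `--seed` and configuration reproduce every output byte-for-byte.

### Formats

Expression/CN/TME matrices: gene × sample TSV or MatrixMarket triplet
with `.rownames`/`.colnames` sidecars; clone trees: edge-list JSON (with
genotypes) or Newick; gene sets: GMT; clonotypes: AIRR-style TSV
(`sample_id`, `chain`, `clonotype_key`, `count`); metadata: TSV;
configuration: YAML (`AnalysisConfig`).

The package accepts an already-normalized expression matrix (the
original analysis used DESeq2 VST); `ithkit.io.normalize_log2_cpm`
provides a clearly-labelled non-VST fallback.

## Acceptance

`tests/test_acceptance.py` holds the property-based acceptance suite:
brute-force oracle equivalence for every statistic, dosage-slope and
trans-effect recovery against simulator truth, type-I calibration of the
mixed-model layers, drift-induced distance monotonicity and seeding
directionality, TME classification fidelity, I-TED region-count bias
control, and seeded determinism.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The reference study's headline numbers derive from a controlled-access
cohort, so there are no recomputable numeric targets; the script runs an
end-to-end smoke pass and emits an empty JSON report by design.
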