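# phosphoprio

Prioritization of functionally important phosphosites from quantitative
phosphoproteomics.

Deep phosphoproteome surveys routinely quantify tens of thousands of
phosphosites, but only a small minority of them matter functionally, and
wet-lab follow-up is expensive. `phosphoprio` implements the computational
stack for turning a stable-isotope (e.g. ¹⁴N/¹⁵N metabolic labeling)
phosphoproteomics experiment into a short, ranked list of candidate
functional sites:

1. **Differential calling** (`diffquant`) — phosphoisoforms are compared
   between a test genotype and a control using replicate light/heavy
   ratios. After per-replicate median normalization, the population spread
   of log₂ fold changes is summarized robustly by the normalized
   interquartile range, NIQ = 0.7413·(Q₃ − Q₁) (a consistent estimate of σ
   for Gaussian data). An isoform is called hyper- or hypo-phosphorylated
   by a two-tier flexible filter: |log₂FC − median| beyond 1.5·NIQ with
   one-tailed Wilcoxon rank-sum p < 0.05, or beyond 1.0·NIQ with two-tailed
   p < 0.05.
2. **Feature encoding** (`features`, `conservation`) — each site is encoded
   into six features (eight numeric columns): the number of distinct
   upstream kinase families predicted to target it (UKF); a phosphorylation
   conservation score RCS = MBL × Np/N, where MBL is the longest patristic
   distance on a species tree between organisms carrying a conserved
   phosphoacceptor and Np/N is the conserved fraction within the spanning
   clade; the interaction-partner count of the domains containing the site
   (IDM); an acetylation co-occurrence flag within ±15 residues (ASC);
   predicted relative surface accessibility (RSA); and the three
   secondary-structure probabilities (helix/strand/coil).
3. **Scoring** (`model`) — a binary logistic regression is trained on a
   small positive set of literature-curated functional sites against
   negatives sampled at a configurable ratio (default 1:5) from the
   remaining sites; ten benchmark sets are drawn, each evaluated by
   stratified 10-fold cross-validation (AUC on pooled out-of-fold scores),
   and the model refit on the best benchmark is kept. Raw scores are
   normalized onto [0, 1] by a fence-clipped min-max map with Tukey-style
   fences at Q₁ − 3·IQ and Q₃ + 3·IQ.
4. **Prioritization & enrichment** (`model`, `enrichment`) — the top 5%
   highest-scoring sites are intersected with the differentially regulated
   sites to give the final candidates; kinases and pathways with regulated
   targets over-represented against the full background are flagged by the
   one-sided hypergeometric test with E-ratio = (m/M)/(n/N) > 1 and
   p < 0.05.

A first-class synthetic-data generator (`synthetic`) emulates every input
with planted ground truth, so the whole workflow runs and is testable with
no external downloads.

## Worked example

Generate a 200-site synthetic study (30 designated functional sites,
planted two-fold changes in a tenth of the isoforms, one kinase enriched
among the hypo-phosphorylated sites) and run the full pipeline:

```bash
phosphoprio simulate --out fix --seed 1
cat > config.yaml <<'EOF'
seed: 1
outdir: out
inputs:
  sites: fix/sites.tsv
  quant: fix/quant.tsv
  annotations: fix/annotations
  msa_dir: fix/msa
  tree: fix/tree.nwk
  positives: fix/positives.txt
  pathways: fix/pathways.tsv
params:
  n_bootstrap: 2000
EOF
phosphoprio run --config config.yaml
```

This run prints `pipeline complete; 11 outputs in out` and produces, among
others:

* `out/model.json` — cross-validated AUC of the selected model 0.8016
  (95% bootstrap CI 0.6889–0.8911) over ten benchmark draws whose AUCs
  ranged 0.783–0.802: the scorer separates the planted functional class
  well but not trivially;
* `out/regulated_sites.tsv` — 27 sites called differentially
  phosphorylated;
* `out/lirp.tsv` — the final candidates, i.e. regulated sites that also
  rank in the top 5% of normalized scores:

  ```
    site_id direction   log2fc isoform_id  conflict    score
   P039:T40     hyper 1.083066   P039:T40     False 1.000000
   P002:S18     hyper 0.203613   P002:S18     False 0.946974
  P031:S106     hyper 0.822303  P031:S106     False 0.777249
  ```

* `out/kinase_enrichment.tsv` — the planted kinase is recovered among the
  hypo-phosphorylated sites (`KF01`, E-ratio 3.08, p = 1.5×10⁻⁵), with no
  spurious hits at this seed.

Every output carries its SHA-256 in `out/manifest.json`; re-running the
same config reproduces the hashes byte for byte.

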