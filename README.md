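# coexsig

Blood-transcriptome biomarker pipeline for recessive loss-of-function
disease, built around weighted gene co-expression network analysis
(WGCNA-style): derive co-expression modules from case/control RNA-seq
counts, identify disease-associated modules, classify individual samples
by module-eigengene statistics, and test biomarker specificity across
datasets with permutation module preservation and hypergeometric gene-set
overlap.

The package is aimed at researchers who want a transcriptional signature
from accessible tissue (peripheral blood) as a functional proxy for loss
of a gene's activity — e.g. to support pathogenicity assessment of
variants of uncertain significance — and who need every stage of that
analysis to be reproducible and testable.  A first-class synthetic-data
generator produces count cohorts with known module structure, so the
entire pipeline can be validated against ground truth without any
external download.

## The model

**Network.** For genes *i, j* with expression profiles *x_i, x_j*, the
unsigned adjacency is *a_ij = |cor(x_i, x_j)|^β*, with the soft power β
chosen as the smallest value whose connectivity distribution fits a
scale-free topology (signed R² ≥ 0.8) — or set explicitly (β = 4 for the
blood network convention).  Adjacency is converted to the topological
overlap matrix

    ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_u a_iu a_uj,  k_i = Σ_u a_iu,

and genes are clustered by average linkage on 1 − ω with a dynamic tree
cut (minimum module size 50, deep split 2).  Each module is summarized by
its **eigengene** (ME): the first principal component of the module's
standardized expression, one value per sample, sign-aligned with mean
module expression.

**Disease association.** A module is disease-associated when the Pearson
correlation of its eigengene with the 0/1 case indicator has unadjusted
p < 0.05 (t distribution, n − 2 df).

**Classifier.** For a sample *s* and module *m*, a one-sample two-sided
t-test compares the training controls' ME distribution against μ₀ = ME_s:

    t = (mean_ctrl − ME_s) / (sd_ctrl / √n),  df = n − 1,

and the sample is called positive when p < α (default 0.05) *and* ME_s
lies on the patient side of the control mean.  Module combinations use an
OR rule; a depth-≤2 Gini decision tree over two module MEs is available
as an independently derived rule.  Sensitivity and specificity are
reported with exact Clopper–Pearson 95% intervals at individual or family
level (a family is positive iff any affected member is positive), and
classifiers are compared with Fisher's exact test.

**Preservation.** Whether a module's structure recurs in another dataset
is scored by permutation Z statistics (mean intra-module adjacency,
cross-dataset correlation of intra-module connectivity, and of the
gene–gene correlation pattern; 50 permutations, seeded), with
Zsummary ≥ 2 taken as preserved.  The composite biomarker rule calls a
module positive in a test dataset only when it is preserved there *and*
its most-equivalent test module (minimal hypergeometric overlap p) is
disease-associated in that dataset.

## Worked example

```bash
coexsig simulate --outdir sim --seed 7      # 11 cases / 35 controls, 3 modules + grey
cat > config.yaml <<EOF
counts: sim/counts.tsv
annotation: sim/gene_annotation.tsv
metadata: sim/sample_metadata.tsv
outdir: out
power: 4
EOF
coexsig run --config config.yaml
```

prints

```
individual-level performance (95% CI, clopper-pearson)
  sensitivity 73% [39%-94%]  (8/11)
  specificity 63% [45%-79%]  (22/35)
modules: out/modules.tsv
eigengenes: out/eigengenes.tsv
classification: out/classification.json
performance: out/performance.json
edges: out/edges.tsv
```

The pipeline normalized the counts, built the β = 4 network, recovered
the planted modules, flagged the disease-associated one, fit the
single-module eigengene classifier on the training cohort and called
every sample: 8 of the 11 affected samples match the disease expression
profile (73%, exact 95% CI 39–94%), while 22 of 35 controls are called
negative.  The specificity sits near its analytic value for this rule —
the t statistic scales the deviation by the standard *error* of the
control mean, so any sample more than about 0.34 control-SD toward the
patient side is flagged at α = 0.05; module choice and combination
ranking (specificity first) are what make the final biomarker specific.
The same objects are available programmatically:

```python
from coexsig import EigengeneClassifier
model = EigengeneClassifier(eigengenes, status, disease_modules=[1],
                            family_id=families)
results = model.fit(rule="single")
print(results.summary())
report = results.performance(level="family", sides=("sensitivity",))
```

## Layout

- `src/coexsig/simulate.py` — synthetic cohorts with known module structure
- `src/coexsig/normalize.py` — zero-gene filter, log2 FPKM, GC/length
  correction + quantile normalization, covariate regression, sex/outlier QC
- `src/coexsig/network.py` — soft threshold, adjacency, TOM, dynamic tree
  cut, module merging, edge export
- `src/coexsig/modules.py` — eigengenes, disease association,
  hypergeometric overlap, Welch-t differential-expression screen
- `src/coexsig/classify.py` — eigengene classifier (model/results API),
  exact binomial CIs, Fisher comparison, combination search, decision tree
- `src/coexsig/preserve.py` — permutation module preservation and the
  composite biomarker rule
- `src/coexsig/{io,pipeline,cli}.py` — TSV/JSON formats, end-to-end
  pipeline, `coexsig` command-line interface

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
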