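# ptcnmf

NMF metagene deconvolution and immune-based subtyping of papillary thyroid
carcinoma (PTC) expression cohorts.

Bulk PTC transcriptomes mix a driver program (BRAF-V600E-like versus
RAS-like) with an immune program driven by infiltrating leukocytes. This
package factorizes a nonnegative expression matrix `V` (genes x samples)
into metagene signatures,

    V ~ W H,   W, H >= 0,

selects the number of signatures by the cophenetic stability of consensus
clustering across seeded restarts, and — at k = 3 (RAS, Immune, BRAF
signatures) — derives the four clusters **RAS-IR, RAS-ID, BRAF-IR,
BRAF-ID** (IR/ID = immunoreactive/immunodeficient, the high/low
immune-signature subgroup within each driver side; NMF1–NMF4 in the fixed
order above). It also:

* projects the learned basis onto external cohorts via the Moore–Penrose
  pseudoinverse with nonnegativity enforced (`classify.project_metagenes`);
* computes expression-based immunoprofiling: cytolytic activity
  (geometric mean of GZMA and PRF1), gene-set signature scores, NNLS immune
  cell fractions against a reference profile, signature–feature Pearson
  correlations, and pre-ranked enrichment of metagene weights
  (`immune`);
* reproduces recurrence-association statistics: 2x2 odds ratios with Wald
  intervals, univariate→multivariate logistic risk-factor tables,
  chi-square/Fisher tests, Kaplan–Meier, log-rank and Cox models
  (`clinical`);
* ships a synthetic-cohort generator with planted rank-3 structure,
  cluster-linked recurrence and ground-truth labels, so every stage can be
  validated against known truth (`simulate`).

It is intended for computational biologists analysing bulk thyroid (or
similar driver-plus-immune) expression cohorts, and as a self-contained,
testable reference for the consensus-NMF subtyping workflow.

## Worked example

Generate a cohort with planted structure, factorize, and label the
clusters:

```python
import ptcnmf as p

cohort = p.generate_cohort(p.SyntheticConfig(n_genes=1000, n_samples=300,
                                             noise_sd=0.2, seed=11))
W, H = p.nmf_factorize(cohort.expression, k=3, seed=1)
ann = p.annotate_signatures(H, cohort.driver_label,
                            p.cyt_score(cohort.expression))
labels = p.label_clusters(p.cluster_samples(H, 4), ann, H)
print(ann.roles)
print(labels.to_frame()["label"].value_counts().to_dict())
print("accuracy:",
      (labels.to_frame()["cluster"].values == cohort.true_cluster.values).mean())
```

prints

```
{'signature2': 'RAS', 'signature1': 'Immune', 'signature3': 'BRAF'}
{'BRAF-ID': 99, 'BRAF-IR': 98, 'RAS-ID': 63, 'RAS-IR': 40}
accuracy: 0.99
```

i.e. the three fitted signatures are identified with the RAS, immune and
BRAF programs from the driver contrast, the four named clusters have the
expected proportions (BRAF side largest), and 99% of samples receive
their planted cluster. The same workflow runs from the shell:

```bash
ptcnmf simulate --n-genes 1000 --n-samples 300 --seed 11 --outdir cohort/
ptcnmf nmf --expression cohort/expression.tsv --rank 3 --seed 1 --no-log --out fit/
ptcnmf classify --model fit/ --expression cohort/expression.tsv \
    --drivers cohort/clinical.csv --out labels.csv
ptcnmf assoc --clinical cohort/clinical.csv --labels labels.csv --out table2.csv
```

`ptcnmf run --config pipeline.yaml` executes the full
preprocess → survey → fit → classify → immune → association pipeline and
writes a manifest with seeds and output checksums; reruns under the same
config are byte-identical.

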