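# refharm

Platform-agnostic harmonization of gene expression profiles.

Public repositories hold millions of human expression profiles, but
values measured on different platforms — competing microarray designs,
RNA-sequencing — are not directly comparable: each platform imposes its
own scale, dynamic-range compression, and gene-specific probe effects.
Ordinary normalization (quantile normalization, count size factors)
equalizes scales *within* a platform but leaves gene-level platform
artifacts intact, so pooled analyses cluster by platform instead of by
biology.  `refharm` is for anyone who needs to place profiles from many
platforms — however many datasets, however few samples each — into one
comparable space: every profile is calibrated individually against a
fixed auxiliary dataset **P0** and transformed into the distributional
frame of a fixed reference dataset **Q**.

## The model

Each profile *i* is column-bound to P0, jointly quantile-normalized with
it (giving the dataset P), log2-transformed, and mapped into Q's frame
under a shared partially linear block model

```
x_gs = A[α(g), β(s)] · b_g + c_g + σ_g · ε_gs
```

where α clusters genes (K groups, stochastic k-means), β clusters
samples (L groups, joint *spherical* — cosine-based — k-means over the
P and Q columns), A holds block means, b/c are per-gene slope and
offset (mean(b)=1, mean(c)=0 within each gene cluster), and σ is the
per-gene residual scale.  The transform keeps the profile's standardized
residual and substitutes Q's systematic structure and noise scale:

```
x* = A_Q[α(g), β(s)] · b_Q + c_Q + σ_Q · (x − A_P[α(g), β(s)] · b_P − c_P) / σ_P
```

Q never changes; only P moves.  The output averages this transform over
`n_repeats` independent clustering draws, and only column *i* of the
result is kept.  Because a profile's only companions are the fixed P0
and Q, harmonization is independent per profile: any number of
platforms, any dataset sizes, order- and batch-invariant by
construction.  See `docs/methods.md` for the full account, including the
baselines (quantile normalization, median-of-ratios size factors), the
per-gene negative-binomial goodness-of-fit screen, and the
clustering-based evaluation protocol.

## Worked example

The package ships a synthetic multi-platform benchmark — four
reference-RNA sample types (A; B; C = 3:1 and D = 1:3 mixtures of A:B)
profiled in five replicates on three simulated microarray platforms,
plus synthetic P0 (39 heterogeneous profiles) and Q (100 profiles, 10
tissues) stand-ins:

```python
import refharm as rh
from refharm.benchmark import run_study_benchmark

scores = run_study_benchmark(include_sequencing=False, algorithm_seed=0)
for key in ("ari_bio_harmonized", "ari_platform_harmonized",
            "ari_platform_qn", "ari_platform_sizefactor",
            "max_ks_to_reference_harmonized"):
    print(f"{key}: {scores[key]:.3f}")
```

prints (about four minutes on one CPU):

```
ari_bio_harmonized: 1.000
ari_platform_harmonized: 0.131
ari_platform_qn: 1.000
ari_platform_sizefactor: 1.000
max_ks_to_reference_harmonized: 0.034
```

Read: after harmonization, cutting the sample dendrogram (Euclidean,
average linkage) at two clusters recovers the biological split {A,C}
versus {B,D} perfectly (adjusted Rand index 1.0) and platform labels
explain almost nothing (0.13 at k = 3); the same data pooled under
quantile normalization or size-factor normalization clusters purely by
platform (1.0).  Every harmonized sample's value distribution sits
within Kolmogorov–Smirnov distance 0.034 of the reference's mean
quantile profile — all platforms now share one shape.

The same workflow is available from the shell:

```
refharm simulate --outdir data --seed 1
refharm harmonize --input data/array1.tsv --input data/array2.tsv \
    --input data/array3.tsv --metadata data/metadata.tsv \
    --p0 data/p0.tsv --q data/q.tsv --seed 0 --out harmonized.tsv
refharm evaluate --input harmonized.tsv --metadata data/metadata.tsv \
    --q data/q.tsv --out report.json
```

plus `refharm normalize qn|sizefactors`, `refharm nbgof` (the
negative-binomial screen) and `refharm pipeline` for a one-config run.
Expression matrices are plain TSV (genes × samples, symbols in the first
column; GCT 1.2 accepted); drop in your own `p0.tsv`/`q.tsv` to
harmonize real data against real references.

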