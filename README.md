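# phenodiv

Phenotypic diversity evaluation of crop germplasm panels, built around the
workflow used to characterize 1,558 foxtail millet (*Setaria italica*)
accessions on 25 traits (11 quantitative, 14 integer-coded qualitative):

1. **Descriptive variability** — per-trait mean, sample SD (n−1), range and
   coefficient of variation CV = 100·S/X̄.
2. **Shannon-Wiener diversity** — H′ = −Σ pᵢ ln pᵢ, with continuous traits
   first stratified into 10 classes on the mean/SD grid: class 1 is
   x ≤ X̄ − 2S, class 10 is x ≥ X̄ + 2S, and the interior classes are
   half-open 0.5 S intervals. Qualitative traits use their category
   frequencies directly.
3. **Correlation and PCA** — Pearson correlations (with t-transform
   p-values) over all 25 standardized traits, then eigendecomposition of
   the correlation matrix. Loadings are vᵢ√λᵢ, score coefficients are the
   unit eigenvector elements (loading/√λ), contribution rates are
   100·λᵢ/25, and components are retained while λ > 0.95 (max 10).
4. **Composite F scoring** — weights wᵢ = rateᵢ/Σrates over the retained
   components, F = Σ wᵢFᵢ per accession, dense ranking by descending F.
5. **Hierarchical clustering** — Ward linkage on Euclidean distances over
   z-scored traits, cut into k = 5 phenotype groups with per-cluster trait
   profiles.

Because the original accession-level data are not public, the package ships
a seedable synthetic-cohort generator whose defaults reproduce the
published marginal distributions (trait means/SDs/ranges and qualitative
class frequencies of the 1,558-accession panel), optionally with injected
inter-trait correlations. It is aimed at genebank curators and breeders who
need a reproducible multi-trait evaluation pipeline, and at method
developers who need a faithful test bed.

## Worked example

```bash
phenodiv simulate --n 1558 --seed 42 --out cohort.csv
phenodiv diversity --in cohort.csv --out-dir results
phenodiv pca      --in cohort.csv --out-dir results
phenodiv score    --in cohort.csv --top 3 --out-dir results
phenodiv cluster  --in cohort.csv --k 5 --out-dir results
```

`results/table3.csv` starts:

```
trait,abbreviation,mean,sd,max,min,range,cv_percent,shannon_index,n
seedling-to-spike period,STC,73.73,6.58,95.95,58.2,37.75,8.93,2.1,1558
growth period,GP,111.99,4.67,125.83,102.01,23.82,4.17,2.09,1558
main spike length,MPL,28.87,5.24,47.12,13.14,33.98,18.17,2.09,1558
```

The simulated panel recovers the published targets: STC was generated to
mean 73.56 / SD 6.63 (CV 9.02 %), and the 10-class H′ of ≈ 2.1 is what a
near-normal trait yields (the exact-normal value is 2.088). The scoring
stage prints the top accessions with their composite F and quantitative
trait values (`results/table7.csv`):

```
rank,accession_id,accession_name,F,STC,GP,MPL,MTL,ST,SSW,SGW,TGW,L,a,b
1,ACC0356,ACC0356,1.313,81.882,110.147,24.606,135.708,9.087,101.662,...
2,ACC0783,ACC0783,0.999,70.746,114.542,33.104,123.059,8.764,91.89,...
```

and `phenodiv pca` reports `retained 10 components (cumulative 45.38%)` —
lower than the 64.30 % seen on the real panel because the default synthetic
cohort draws traits independently; inject correlations (see
`phenodiv.cohort.injected_correlation`) to move the spectrum toward the
field data. Clustering at the same seed splits the panel into groups of
sizes 1138/187/164/61/8; with planted centroids (see the test suite) the
five groups are recovered essentially exactly.

The same functionality is available as a library
(`phenodiv.diversity_report`, `phenodiv.pca`, `phenodiv.score_pipeline`,
`phenodiv.hierarchical_cluster`), and `phenodiv run --config run.yaml`
drives the whole pipeline into one reproducible output bundle with a
manifest.

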