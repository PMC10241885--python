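# snpscreen

Feature screening for case-control SNP data based on sample-size-adjusted
trend statistics.

For each SNP, summarised as a 2×3 case/control genotype count table, the
package computes the Cochran-Armitage trend statistic `Z` under the
recessive `(0,0,1)`, additive `(0,1/2,1)` and dominant `(0,1,1)` score
vectors, its adjusted version `omega = Z/sqrt(n)` (a correlation-scale
measure bounded by 1), and the model-robust maximum `nu = max |omega|`
over the three scores.  Ranking SNPs by `|omega|` or `nu` yields the
screening procedures **REC-SIS**, **ADD-SIS**, **DOM-SIS** and
**MAX-SIS** (plus a Pearson chi-square comparator, **PC-SIS**), with the
top-`d` rule (`d = ⌊n/log n⌋` by default) or a threshold rule
`c0·n^(−τ)`.

The package also includes:

* a trinomial **simulator** for four genetic models (recessive, additive,
  dominant and their mixture) with Hardy-Weinberg controls, configurable
  sample size, case:control ratio, minor allele frequency and effect size;
* an **evaluation** harness computing the per-SNP selection proportion
  `P_s^k` and the all-selected proportion `P_a` over replications, for
  single cells or whole parameter grids;
* **I/O** for genotype matrices (TSV or VCF) with a binary phenotype file,
  including the missingness filter (> 1% removed), the two-genotype filter
  and minor-allele-as-risk orientation.

## Library quick start

```python
import snpscreen as ss

cfg = ss.SimulationConfig(model="I", m=10_000, n=4500, w=1, alpha=0.45, seed=1)
data = ss.simulate_counts(cfg)
result = ss.screen_counts(data, ss.ScreeningConfig("max", d=ss.default_d(4500)))
print(result.selected[:10])

summary = ss.evaluate_method(cfg, ss.ScreeningConfig("max", d=534), reps=100)
print(summary.all_selected_proportion)
```

## Command line

```sh
# simulate count tables (or a sample-level matrix with --format matrix)
snpscreen simulate --model IV --m 10000 --n 3000 --alpha 0.25 --seed 1 \
    --out counts.tsv

# rank and select SNPs; writes all four statistics per SNP
snpscreen screen --counts counts.tsv --method max --d 374 --out ranked.tsv

# real-data path: filters + allele orientation are applied automatically
snpscreen screen --genotypes geno.tsv --phenotypes pheno.tsv \
    --method max --out ranked.tsv

# replicated grid evaluation from a YAML config
snpscreen evaluate --config grid.yaml --seed 1 --out results.tsv
```

A grid config lists `models`, `n`, `w`, `alpha` plus optional `methods`,
`m`, `reps`, `d`.

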