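# mitonuclear

Analysis toolkit for **mitonuclear epistasis** in factorial mtDNA-exchange
(cybrid) strain collections, modeled on high-density colony-array phenotyping
of *Saccharomyces cerevisiae*.

When every nuclear background of a k-isolate panel is paired with every
mitochondrial haplotype (mitotype), the resulting k² genotypes let you ask
directly how much phenotypic variation comes from the mtDNA, the nuclear
genome, and their interaction — and whether original (coadapted)
mtDNA–nucleus pairings outperform synthetic ones. The package covers the
whole workflow:

1. **Design** (`design`): the k × k factorial, clade-scoped enumeration of
   pairwise mtDNA exchanges, replicate/balance validation.
2. **Simulation** (`simulate`): seeded colony-array datasets with known
   ground-truth variance structure — genotype fitness drawn from
   `f = μ + mt_i + n_j + (mt×n)_ij + e_k + …` and rendered as logistic
   colony growth on plates with reference spots, edge rings, and QC failures.
3. **Growth → fitness** (`growth`): circularity/edge filtering, per-spot
   logistic fits `y(t) = y_min + (y_max−y_min)/(1+exp(−r(t−t_mid)))`,
   median±4·MAD outlier removal, normalization to reference-strain spots per
   plate, technical-replicate balancing. Fitness is the fitted span
   `y_max − y_min`, normalized.
4. **Variance decomposition** (`varcomp`): crossed random-effects model
   `y_ijr = μ + mt_i + n_j + (mt×n)_ij + ε_ijr` (plus environment
   interactions across conditions), estimated by closed-form expected mean
   squares on balanced data and by non-negative REML in general; term tests
   by boundary-corrected likelihood-ratio tests.
5. **Per-exchange epistasis** (`epistasis`): for each mtDNA exchange between
   strains i and j, a fixed-effect 2×2 ANOVA on the four genotypes and the
   effect size `ΔΔ = |(y_ij − y_ii) − (y_jj − y_ji)|` (the absolute 2×2
   interaction contrast), with within- vs between-clade comparisons of
   significance frequency (χ²/Fisher) and effect size (Mann–Whitney).
6. **Coadaptation** (`coadapt`): one-way ANOVAs per nuclear background in a
   niche-matched environment, classifying each original-vs-foreign contrast
   as advantage / disadvantage / ns.
7. **SNP association** (`association`): SNPs and nucleotide diversity π from
   a gapped mitochondrial coding-sequence alignment, per-SNP one-way ANOVA
   against a per-mitotype phenotype with a Bonferroni threshold α/m.

## Worked example

```python
import mitonuclear as mn

panel = mn.example_panel()                      # 15 isolates, 4 clades + mosaics
print(len(mn.enumerate_genotypes(panel)))       # 225
print(mn.count_clade_exchanges(panel, exclude=("SK1",))[:2])   # (11, 25)

params = mn.SimulationParams(seed=1, media=("CSM",), temperatures=(30,))
params = params.with_variance_proportions(0.0, 0.4, 0.2, 0.4)  # mt, n, mt×n, resid
truth = mn.simulate_true_fitness(params, panel)
ts = mn.simulate_colony_timeseries(truth, params, panel)
fitness, qc = mn.fitness_from_timeseries(ts, "DAU2", seed=1)

vd = mn.reml_varcomp(fitness)
print({k: round(v, 3) for k, v in vd.proportions.items()})
# {'mt': 0.001, 'n': 0.366, 'mt:n': 0.237, 'resid': 0.396}

res = mn.lrt_term(fitness, "mt:n")
print(round(res.statistic, 1), res.p_value)     # 123.8 4.78e-29
```

The decomposition recovers the generating variance shares: essentially no
marginal mtDNA effect, a large nuclear effect, and a mitonuclear interaction
near the simulated 20% of phenotypic variance, detected decisively by the
likelihood-ratio test.

A command-line front end mirrors the library
(`mitonuclear simulate|fit-growth|varcomp|epistasis|coadapt|assoc|all`),
reading a shared YAML config and writing seeded, diff-stable TSV outputs
plus a JSON manifest.

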