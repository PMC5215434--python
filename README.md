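# ubiqevo

Evolutionary conservation analysis of human protein ubiquitination sites.

Ubiquitination — covalent attachment of ubiquitin to lysine residues —
regulates protein degradation, trafficking, and signalling. A natural
question is whether the modified lysines are under stronger purifying
selection than their sequence neighbourhood, and when in evolutionary
history each modified site appeared. `ubiqevo` answers both questions from
pairwise alignments of human proteins against orthologs in a ladder of
organisms ordered by divergence time, and ships a calibrated synthetic-data
generator so every statistical procedure can be validated against a known
ground truth.

## What it computes

**Site vs flank conservation.** For each organism, substitutions at
ubiquitinated lysine positions and at their flanking positions (±5 residues
by default) are counted across all aligned proteins. The observed
difference proportion `p = n_diff / n_total` is corrected for multiple
hits with the Poisson distance

```
d = −ln(1 − p),        Var(d) = p(1 − p) / (n (1 − p)²)
```

Sites and flanks are contrasted with a two-sample z statistic
`z = (d_s − d_f) / √(Var_s + Var_f)`; evidence across all organisms is
combined as `Σ z²  ~  χ²(df = #organisms)`.

**Functional groups.** Protein groups (annotation categories, tissue
specificity classes, interaction-network hubs) are compared on the
*relative* distance `r = d_sites / d_flanks`, with a delta-method variance,
so groups with different overall divergence remain comparable.

**Tissue specificity (TSPS).** For an expression profile over `N` tissues,
`TSPS = Σ_j p_j log2(p_j N)` — the relative entropy against uniform
expression, in bits. It is 0 for uniform expression and `log2 N` for
expression confined to one tissue. Proteins below 1 bit are classed as
*facilitators* (broadly expressed), at or above 1 bit as *specifiers*.

**Gain timing and enrichment.** Each site's lysine presence/absence
profile along the organism ladder dates the gain of the site to an epoch
(human-lineage, primate, mammalian, vertebrate, animal, eukaryote, …).
Per-epoch gains are tested for functional-category enrichment with the
hypergeometric test, Bonferroni-corrected.

The API follows the statsmodels convention: a `Model` object holds data
and configuration, `Model.fit()` returns a `Results` object carrying point
estimates, variances, combined tests, `summary()`, and plotting helpers.

## Worked example

Simulate a dataset in which modified sites evolve at half the flank rate,
then fit the conservation model:

```python
from ubiqevo import ConservationModel, SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(
    n_proteins=50, site_rate_multiplier=0.5, seed=7,
))
res = ConservationModel.from_dataset(ds).fit()
print(res.summary())
```

Output:

```
Ubiquitination-site conservation: Poisson distance of sites vs flanking background
organisms (nearest first): G. gorilla, M. mulatta, R. norvegicus, M. musculus, G. gallus, X. tropicalis, D. rerio, D. melanogaster, A. gambiae, C. elegans, K. lactis, S. cerevisiae, N. crassa, S. pombe
gap counted as difference: True

group           organism            d_sites d_flanks       z          p  sig
all             G. gorilla           0.0134   0.0461   -2.96    0.00304  **
all             M. mulatta           0.0478   0.0762   -1.46      0.145  
all             R. norvegicus        0.1203   0.1500   -0.96      0.338  
all             M. musculus          0.0907   0.1737   -3.01    0.00258  **
all             G. gallus            0.1354   0.2863   -4.37   1.22e-05  ***
all             X. tropicalis        0.1664   0.3971   -5.89   3.96e-09  ***
all             D. rerio             0.2231   0.5982   -7.96   1.66e-15  ***
all             D. melanogaster      0.3857   0.8439   -7.22   5.21e-13  ***
all             A. gambiae           0.5563   1.0031   -5.71   1.13e-08  ***
all             C. elegans           0.6162   1.3149   -8.06   7.55e-16  ***
all             K. lactis            0.8518   1.7091   -7.83   5.04e-15  ***
all             S. cerevisiae        0.8059   1.9808  -10.52   6.71e-26  ***
all             N. crassa            1.0217   1.9906   -7.64   2.25e-14  ***
all             S. pombe             1.3997   2.3340   -5.73   1.03e-08  ***
all             COMBINED                               -5.67  1.47e-108  *** (chi2=550.89, df=14)
```

Sites planted at half the background rate come out less diverged than
their flanks in every organism, with a decisive combined test.

The same analysis runs end to end from the command line:

```bash
ubiq-evo run --seed 7 --out-dir scratch/run   # full pipeline, TSV outputs
ubiq-evo report --out-dir scratch/run          # print the run summary
```

or stage by stage (`ubiq-evo simulate | align | conserve | tsps | hubs |
gains | enrich`). Provided-data mode (`mode: provided` in a YAML config)
reads the same TSV/FASTA/YAML bundle layout the simulator writes, so real
datasets drop in without code changes.

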