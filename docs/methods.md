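# Methods

## Model and assumptions

The analysis treats each aligned human↔ortholog residue pair as an
independent Bernoulli trial: identical or different. For a group of
positions (all ubiquitinated lysines, or all their flanking positions)
compared against one organism, the difference proportion is
`p = n_diff / n_total`. Assumptions:

- **Independence across positions.** Substitutions at distinct alignment
  columns are treated as independent; linkage and local rate
  autocorrelation are ignored.
- **Poisson substitution process.** Multiple hits at one position are
  corrected with the Poisson distance `d = −ln(1 − p)`. This assumes a
  memoryless substitution process with a site-independent rate within each
  region class; it does not model among-site rate variation (no gamma
  rates) or a full amino-acid exchange matrix.
- **Large-sample normality.** With thousands of pooled positions per
  region and organism, `p̂` is treated as normal;
  `Var(d) = Var(p) / (1 − p)² = p(1 − p) / (n (1 − p)²)` by the delta
  method.

### Test statistics

Site vs flank within one organism:
`z = (d_s − d_f) / √(Var(d_s) + Var(d_f))`, two-sided normal p-value.
Evidence across organisms is combined as `X² = Σ_o z_o²` referred to a
chi-square distribution with `df = #organisms`. Under the null the `z_o`
are independent standard normals, so `X²` is exactly chi-square
distributed; the test is two-sided per organism and direction-agnostic
in combination (the reported mean z conveys direction). Significance
stars: `*` < 0.05, `**` < 0.01, `***` < 0.001.

Group comparisons use the **relative distance** `r = d_sites / d_flanks`
with delta-method variance
`Var(r) = Var(d_s)/d_f² + d_s² Var(d_f)/d_f⁴`, which removes the
group-level divergence scale before contrasting two groups with a
two-sample z. A degenerate background (`d_flanks ≤ 0`) is a hard error,
not a silent NaN.

### Tissue specificity

`TSPS(x) = Σ_j p_j log2(p_j N)` with `p_j = x_j / Σ x`, tissues with
`x_j = 0` contributing 0. This is the Kullback–Leibler divergence from
the uniform distribution, in bits: 0 for uniform expression, `log2 N`
(5 bits for N = 32) for single-tissue expression. Floating-point
round-off can produce tiny negative sums for near-uniform profiles, so
the score is clamped at 0. Proteins with all-zero expression are
excluded with a warning. The facilitator/specifier threshold is 1 bit.

### Network hubs

Degree counts *distinct* interaction partners; self-loops and duplicate
edges are removed at read time. A hub is a protein with degree strictly
greater than 20.

### Gain timing

For one site, the ladder profile is the ortholog residue at the site
column in each organism, nearest first. In `first_appearance` mode the
gain boundary is placed just beyond the most distant organism that
retains a lysine; organisms with no ortholog (MISSING) are skipped.
`strict` mode additionally requires every organism inside the boundary
to carry a lysine: profiles with an interior non-lysine (a candidate
secondary loss) are returned as *unresolved* rather than dated. If all
organisms beyond the deepest lysine are MISSING, the event is flagged
`low_coverage`. By construction the inferred boundary is monotone: adding
a deeper lysine-bearing organism can only move the gain earlier.

### Enrichment

Per epoch, gained proteins are tested against a background (all proteins
with sites, unless a custom background is supplied) with the
hypergeometric distribution. Both tails are computed — upper
`P(X ≥ k)` and lower `P(X ≤ k)` — and the smaller tail is reported
together with its direction (enriched/depleted). The expected count is
`nK/N`. Correction is Bonferroni across the categories tested within one
epoch: `p_corr = min(1, m·p)`.

## Synthetic data generator

The generator produces a full analysis bundle (sequences, sites,
ortholog alignments, annotations, expression, interaction edges,
organism ladder) with recorded ground truth, so every inference step can
be checked against what was planted.

**Substitution model.** Each residue draws `Poisson(depth × multiplier)`
substitution events; each event replaces the current residue with one of
the 19 alternatives uniformly. Because events can revert a residue, the
expected observable difference proportion after rate `λ` is

```
P(diff) = (19/20) · (1 − exp(−20λ/19))
```

which the test suite verifies against an independently coded Markov
chain. This back-substitution is exactly what the Poisson distance is
designed to correct, making the generator a proper end-to-end check of
the estimator (the estimator assumes the slightly different pure-Poisson
observable, so a small model-mismatch bias remains at large depths; the
site-vs-flank contrast is insensitive to it because both regions share
the same process).

**Defaults** (all rates in expected substitutions per residue):

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 200 | enough pooled positions (~10⁵ flank observations) for stable per-organism estimates |
| `protein_length_range` | (200, 400) | typical globular protein lengths |
| `sites_per_protein` | 3 | sites spaced ≥ 2·half_width+1 apart so flank windows never overlap a neighbouring site |
| `organisms` | 14-rung ladder, depths 0.05 → 2.8 | see below |
| `site/flank/background_rate_multiplier` | 1.0 | null configuration; studies set sites to 0.5 (conserved) or 2.0 (relaxed) |
| `flank_half_width` | 5 | ±5 residues, the window also used by the analysis |
| `indel_rate` | 0.0 | indels are opt-in; when enabled, planted site columns are protected from deletion |
| `n_tissues` | 32 | gives an interpretable 5-bit TSPS maximum |
| `expression_concentration` | facilitator 5.0, specifier 0.05 | Dirichlet concentrations producing near-uniform vs near-single-tissue profiles |
| `hub_degree_range` / threshold | (25, 60) vs > 20 | planted hubs sit clearly above the hub cutoff |
| `gain_loss_rate` | 0.0 | secondary losses are opt-in |
| `missing_ortholog_rate` | 0.0 | missing orthologs are opt-in |

**Divergence depths.** The ladder depths (0.05 for *G. gorilla* up to
2.8 for *S. pombe*) were fixed a priori from a power calculation: at the
default dataset size, a 2× rate contrast gives a per-organism
`|z| ≈ 15.8 √λ`, so even the shallowest rung (λ = 0.05) is expected to
carry signal while the deepest rungs approach but do not reach
saturation (`p → 0.95`). They are calibration constants of the
generator, not estimates of real species divergence.

**Secondary losses.** When `gain_loss_rate > 0`, a planted gain may have
its lysine knocked out in one organism *inside* the gain boundary. Losses
are planted only at interior rungs because a loss at the deepest
lysine-bearing rung is observationally identical to a younger gain — no
method can distinguish the two from presence/absence data alone. With
this convention, `first_appearance` mode still recovers the planted
epoch (the deepest lysine is intact), and `strict` mode flags exactly
the lossy profiles as unresolved.

**What the generator does not emulate:** domain architecture and
structural constraints, among-site rate heterogeneity within a region
class, alignment error (alignments are exact by construction unless
indels are enabled, in which case they are still the true alignments),
correlated evolution between interacting proteins, gene duplication and
paralogy, and annotation noise.

## Numerical choices

- **Saturation clamp.** `p = 1` makes `d = −ln(0)` infinite; the
  estimator clamps to `p = (n − 0.5)/n` with a warning. A strict mode
  (`clamp_p1=False`) raises instead, for pipelines that prefer failure
  over clamped estimates.
- **Gaps.** An alignment gap at a scored position is counted as a
  difference by default (`gap_as_diff=True`): a deleted site cannot be
  modified, so a gap is evidence of non-conservation. Setting it to
  False drops gapped positions from both counts.
- **Flank lysines.** Flanking positions that are themselves lysines in
  the human sequence can be excluded (`exclude_flank_lysines=True`) to
  avoid contaminating the background with potentially modified residues;
  the default keeps them, since unannotated lysines are part of the
  honest background.
- **Aligner.** Pairwise global alignment uses an affine-gap
  (Gotoh three-state) dynamic program with BLOSUM62, gap open 10, gap
  extend 1 (a gap of length L costs 10 + (L−1)·1). Traceback ties
  prefer match over a gap in the ortholog over a gap in the human
  sequence, giving a deterministic single optimum. Scores are verified
  in the test suite against Biopython's `PairwiseAligner` and, for short
  sequences, an exhaustive recursion.
- **Determinism.** All randomness flows from one
  `numpy.random.default_rng(seed)`; derived seeds are drawn below 2³¹.
  TSV outputs use a fixed float format (`%.10g`), so a pipeline run is
  byte-reproducible from its configuration.

## Limitations

- The Poisson correction ignores among-site rate variation and the
  amino-acid exchange structure; absolute distances at large depths are
  underestimates. All headline tests are *contrasts* between regions or
  groups under the same model, which cancels most of this bias.
- Pooling positions across proteins assumes exchangeability within a
  region class; protein-level random effects are not modelled.
- Gain dating from presence/absence cannot separate a deep loss from a
  young gain (see the interior-loss convention above), and parsimony
  with a single allowed loss is a simplification of real site turnover.
- Bonferroni correction is conservative when categories overlap.
- The hub threshold and the 1-bit TSPS threshold are conventions, not
  estimated quantities; conclusions near the thresholds are sensitive to
  them.
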