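# Methods

This note records the models, parameter choices and numerical decisions
behind `tcsoil`. Equations use the notation of the study the toolkit
reanalyses: eight treatment variants crossing tetracycline (Tc, 100 mg
kg⁻¹), grass compost (G, 4 % w/w) and maize sowing (Zm), sampled on days
25 and 50.

## 1. Culture indices

For a 10-day colony emergence series with `Nₖ` colonies first visible on
day `k` and `N = Σ Nₖ`:

- **Colony development index** `CD = 100 · Σₖ (Nₖ/N)/k`, bounded in
  [10, 100]: 100 when all colonies emerge on day 1 (r-strategists), 10
  when all emerge on day 10 (K-strategists).
- **Ecophysiological diversity** `EP = −Σₖ pₖ·log₁₀ pₖ` with
  `pₖ = Nₖ/N` and `0·log 0 = 0`; the base-10 logarithm makes the uniform
  10-day distribution score exactly 1.

Both are undefined when `N = 0`; the toolkit returns NaN and flags the
series rather than silently dropping it. Culturable counts are scaled to
CFU per kg dry matter as `colonies × dilution / dry_mass`.

## 2. Impact factors and derived chemistry

The effect of factor `F` on quantity `q` is
`IF_F = mean(treated)/mean(control) − 1`, computed on replicate means per
day within each stratum of the other two factors (so `IF_Tc` has four
strata: ±Zm × ±G, and so on). A missing control level (e.g. plant
quantities for `IF_Zm`, which exist only in sown pots) causes the cell to
be omitted with a logged warning, never imputed. Two-day summary values
are arithmetic means of the per-day IFs, displayed half-up at 3 decimals.

Soil chemistry: cation exchange capacity `CEC = EBC + HAC` and alkaline
cation saturation `ACS = 100·EBC/CEC`, where EBC is the exchangeable base
content and HAC the hydrolytic acidity, both in cmol(+) kg⁻¹.

## 3. Community diversity

Lineages follow the GreenGenes convention
(`k__…; p__…; c__…; o__…; f__…; g__…`); a seventh `s__` field is
tolerated and dropped, more fields are rejected, and an empty field
buckets the taxon as "unclassified" at that rank. Relative abundances are
percentages per sample and rank; the display filter keeps taxa at or above
a threshold (default 1 %, inclusive; a strict flag excludes exact ties)
and pools the rest into `other`. Shannon–Wiener diversity is
`H′ = −Σ p·ln p` on the unfiltered rank profile. Genus-set analysis takes
the above-threshold genus sets per variant (unclassified excluded); the
*core* is their intersection and a variant's *unique* genera are its set
minus the union of the others, computed separately for the non-sown and
sown scopes.

Note the entropy-refinement property (H′ non-decreasing from phylum to
genus) holds only for fully specified nested lineages: empty intermediate
ranks merge taxa into one unclassified bucket, which is a coarsening, not
a refinement. The test suite therefore checks it on constructed nested
lineages.

Proportion differences between two samples use a STAMP-style battery: a
Yates-corrected G-test (observed counts shrunk 0.5 toward expectation,
clamped at the expectation; equivalent to scipy's
`chi2_contingency(correction=True, lambda_="log-likelihood")`), Fisher's
exact test, and a Newcombe hybrid-score confidence interval for the
difference of proportions.

## 4. Group statistics

Replicated values per (variant, day) group are gated by a Shapiro–Wilk
test on the pooled within-group residuals (α = 0.05). Degenerate inputs
(fewer than 3 residuals, or constant residuals) fall back to the
rank-based path.

- **Parametric path**: type-II two-way ANOVA (factor A = variant, B =
  day; the interaction is dropped without replication), then Duncan's
  multiple range test. The critical range for a span of `p` ordered means
  is `R_p = q(1−α_p, p, df)·√(MSE/n_h)` with `α_p = 1−(1−α)^(p−1)`,
  studentized-range quantile `q`, and harmonic mean group size `n_h`;
  a non-significant span blocks all pairs inside it.
- **Rank-based path**: Dunn's test with tie-corrected standard errors and
  Bonferroni adjustment (capped at 1).

Either path's pairwise decisions are rendered as a compact letter display
by insert-and-absorb: two groups share a letter if and only if they were
not declared different. This clique-cover property is verified
exhaustively against all decision matrices for up to 6 groups.

## 5. Synthetic-data generator

The generator produces the full factorial dataset with recorded ground
truth so estimators can be validated:

- **Design**: 8 variants × days {25, 50} × replicates (4 for counts, 3
  for enzyme/plant quantities). Plant quantities exist only in sown pots
  and (for yields/SPAD) on day 50.
- **Measurements**: each value is `baseline × Π multipliers × ε` where
  `ε` is lognormal with mean 1 — `μ = −σ²/2`, `σ = √ln(1+cv²)` — so the
  expected impact factor equals `multiplier − 1` exactly. Default
  `cv_noise = 0.05`. Day-50 modifiers can attenuate a factor's effect
  over time.
- **Emergence series**: multinomial draws over per-group 10-day emergence
  probability vectors.
- **Taxon table**: a 20-genus panel plus an unclassified bucket. Factor
  effects act as log-fold changes on the base composition (softmax
  renormalized); the sample composition is drawn from a Dirichlet with
  concentration `dispersion × mean` and counts from a multinomial at
  `otu_depth` (default 70,000; tests use smaller depths purely for
  speed — depth only sets multinomial resolution, not the analysis
  logic). Three core genera stay above 1 % everywhere; two
  tetracycline-responders sit just below 1 % at baseline and cross it
  only under Tc.
- **Reproducibility**: each stage uses its own
  `np.random.default_rng([seed, stage])` stream, so adding a stage never
  perturbs another stage's draws. Equal seeds give byte-identical output
  bundles; the pipeline manifest records a SHA-256 over all products.
  File header comments echo only analytic parameters (not output paths),
  so the bundle hash is location-independent.

Defaults were chosen once from the published baseline table and held
fixed; they were never adjusted in response to test outcomes.

## 6. Numerical choices

- **Display rounding** is half-up (commercial), not banker's, to match
  the published tables. Implemented with `decimal.Decimal` on `repr(x)`
  with a guard-digit pre-quantization at `ndigits + 6`: binary floats
  like `(0.916 + 1.021)/2 = 0.96849999…` must display as `0.969`, which
  naive half-up on the float representation would miss.
- Statistical primitives come from scipy/statsmodels where a standard
  implementation exists (Shapiro–Wilk, Fisher exact, studentized range,
  ANOVA, Newcombe CI); the study-specific constructs (CD, EP, IF,
  Yates-corrected G-test, Duncan ranges, Dunn adjustment, letter display,
  generator) are implemented here and checked against independent oracles
  in the tests (exhaustive hypergeometric enumeration, projection-matrix
  ANOVA decomposition, clique-cover check, Monte-Carlo effect recovery
  and familywise-error bounds).

## 7. Limitations

- The generator emulates the experiment's statistical structure, not its
  biology: no temporal autocorrelation, no between-quantity correlation,
  and factor effects are multiplicative and stratum-homogeneous.
- Heat-map-only quantities in the source material (per-variant OTU
  totals) are not reproducible from printed numbers and are out of scope.
- Duncan's test is implemented against the classical definition; with no
  R `agricolae` available in the environment, its oracle is an
  independent in-test re-derivation (pairwise span logic) rather than a
  third-party implementation.
- Taxonomic lineages are taken from the input table verbatim, including
  any unconventional assignments; no taxonomy correction is applied.
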