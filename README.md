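# tcsoil

Analysis toolkit for a factorial soil-microcosm experiment on tetracycline
toxicity and its mitigation by grass-compost fertilization and maize
(*Zea mays*) cultivation.

## The problem

Tetracycline reaching arable soil (through manure from treated livestock)
suppresses parts of the soil microbiome and soil enzyme activity. Two
agronomic countermeasures are of interest: organic fertilization with grass
compost, and phytoremediation by growing maize. The experiment crosses
three binary factors — tetracycline (Tc), grass compost (G) and maize
sowing (Zm) — into eight treatment variants (`C`, `CTc`, `CG`, `CTcG`,
`Zm`, `ZmTc`, `ZmG`, `ZmTcG`), sampled on days 25 and 50, and asks how each
factor shifts:

- culturable counts of organotrophic, copiotrophic and oligotrophic
  bacteria and actinomycetes (CFU per kg dry soil), with 10-day colony
  emergence series;
- dehydrogenase and catalase activities;
- maize biomass and SPAD leaf-greenness readings;
- 16S community composition at phylum through genus rank.

The package implements the study's analytical machinery:

- **Culture indices** — the colony development index
  `CD = 100 · Σₖ (Nₖ/N)/k` over the 10 observation days (range 10–100;
  high = fast-growing r-strategists) and the ecophysiological diversity
  index `EP = −Σ p·log₁₀ p` (1 = perfectly even emergence).
- **Impact factors** — `IF_F = mean(treated)/mean(control) − 1` for each
  factor, computed per quantity, day and stratum of the other two factors,
  with derived soil chemistry (`CEC = EBC + HAC`, `ACS = 100·EBC/CEC`).
- **Community diversity** — rank-wise relative abundance with a ≥1 %
  threshold and pooled "other" bucket, Shannon–Wiener `H′ = −Σ p·ln p`,
  and core/unique genus-set analysis across variants.
- **Group statistics** — a Shapiro–Wilk normality gate routing each
  quantity to two-way ANOVA + Duncan's multiple range test (parametric) or
  Dunn's test with Bonferroni correction (rank-based), rendered as compact
  letter displays.
- **Synthetic data** — a seeded generator producing the full factorial
  dataset with known ground-truth effect sizes (lognormal measurement noise
  with mean 1; Dirichlet-multinomial taxon counts with log-fold
  compositional effects), so every estimator can be validated against a
  recorded truth.

## Worked example

Run the numbered stages (each writes TSV/JSON into `results/` by default):

```bash
python analysis/01_simulate.py --seed 0 --out results
python analysis/02_culture_indices.py
python analysis/03_effect_indices.py
python analysis/04_community_diversity.py
python analysis/05_group_stats.py
```

or equivalently run everything through the CLI: `tcsoil report --seed 0 --out results`.

Output excerpts (seed 0):

```
$ head -4 results/culture_indices.tsv
sample_id   organism_group  cd                  ep                  total_colonies
C_d25_r1    Org             31.31984126984127   0.8630639247338925  200
C_d25_r1    Act             26.695833333333336  0.9333173025782667  200
C_d25_r2    Org             32.07936507936508   0.8556512407968998  200

$ head -4 results/if_Tc.tsv
factor  quantity  day  stratum_sown  stratum_compost_dose  value                  n_treated  n_control
Tc      Cat       25   False         0.0                   -0.004635313232831062  3          3
Tc      Cat       25   False         4.0                    0.019768715131864623  3          3
Tc      Cat       25   True          0.0                   -0.012792871505648118  3          3

$ head -6 results/letters_cfu_Org.tsv
group       mean              sd              letters
ZmG_d50     128259497943.166  2903261096.199  a
ZmG_d25     123150348310.532  5702105016.333  a
Zm_d50      81245778256.158   2984323089.026  abc
Zm_d25      80809095371.690   1218411985.028  ac
ZmTcG_d25   72162681384.741   2744121466.082  abcd
```

Groups sharing a letter are not significantly different at the chosen
alpha. `set_report.json` lists, per scope (non-sown / maize-sown soils),
the core genera above 1 % in every variant and the genera unique to each.

## Layout

- `src/tcsoil/` — the library (design, lineage parsing, tables, culture
  indices, effect indices, diversity, group statistics, simulator,
  pipeline, CLI).
- `analysis/` — numbered driver scripts, one per stage.
- `scripts/acceptance.py` — summary-value recomputation.
- `docs/methods.md` — model, parameters, numerical choices, limitations.
- `tests/` — unit, property and acceptance tests (oracle-based where an
  independent check exists).
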