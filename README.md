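# abundrare

Biogeography of abundant and rare bacterioplankton taxa: a tested,
reusable pipeline for partitioning an OTU table into abundant, rare and
intermediate subcommunities and asking which ecological processes —
environmental selection or neutral dispersal — structure each of them.

The package is aimed at microbial ecologists working with 16S rRNA OTU
count tables from spatially structured surveys (e.g. stations in several
bays along a coastline, sampled at two depth layers, with a panel of
physico-chemical covariates per station).

## What it computes

**Dual-threshold classification.** An OTU is *abundant* when its relative
abundance is ≥ 1% in at least one sample (local criterion) **and** its
mean relative abundance over all samples, zeros included, is ≥ 0.1%
(regional criterion). It is *rare* when it is < 0.01% in at least one
sample and its regional mean is < 0.001%. Everything else is
intermediate. Regional thresholds are the local ones divided by 10.

**Diversity and structure.** Observed richness, Chao1 (± SE), ACE,
Shannon–Wiener H, Gini–Simpson 1 − Σp², Pielou J = H/ln S, Good's
coverage 1 − F₁/N, analytic rarefaction curves, species accumulation,
Mann–Whitney U comparisons; Bray–Curtis dissimilarity on √-transformed
abundances, NMDS (SMACOF with isotonic regression, Kruskal stress-1),
ANOSIM, Mantel and partial Mantel tests.

**Space vs. environment.** Great-circle distances, PCNM spatial
eigenfunctions from a truncated geographic distance matrix, distance-decay
regressions, DCA gradient-length gating between RDA and CCA, VIF
filtering (> 20), permutation forward selection (P < 0.05), and
variation partitioning on the adjusted-R² scale,

    pure E|S = adjR²(E∪S) − adjR²(S),   pure S|E = adjR²(E∪S) − adjR²(E),
    shared   = adjR²(E) + adjR²(S) − adjR²(E∪S),   residual = 1 − adjR²(E∪S).

**Sloan neutral community model.** The detection frequency of a taxon
with regional mean abundance p under drift + immigration is governed by a
Beta(Nm·p, Nm·(1 − p)) local-abundance law; `fit_ncm` estimates the single
parameter Nm by least squares of observed occurrence frequencies and
reports m = Nm/N and the fit R².

**Synthetic metacommunities.** `simulate_metacommunity` generates count
tables with tunable niche (`w_env`) and dispersal-limitation (`w_space`)
structure over a clustered coastline design, so every statistic above can
be validated against known ground truth; `simulate_neutral_assembly`
produces exactly neutral communities for NCM parameter recovery.

## Worked example

```python
from abundrare import (SimulationConfig, simulate_metacommunity,
    relative_abundance, classify_otus, partition_summary, bray_curtis,
    anosim, haversine_matrix, distance_decay, fit_ncm)

cfg = SimulationConfig(n_otus=5000, n_samples=22, n_clusters=3,
                       depth=5000, seed=42)
cm, meta, truth = simulate_metacommunity(cfg)
ra = relative_abundance(cm)
print(partition_summary(classify_otus(ra), cm).to_string(index=False))

bc = bray_curtis(ra)
an = anosim(bc, meta.groups("bay"), n_perm=999, seed=1)
print(f"ANOSIM R = {an.R:.3f} (p = {an.p:.3f})")
decay, slope = distance_decay(bc, haversine_matrix(meta), n_perm=999, seed=1)
print(f"distance-decay Spearman r = {decay.r:.3f} (p = {decay.p:.3f})")
fit = fit_ncm(cm)
print(f"NCM: Nm = {fit.Nm:.0f}, m = {fit.m:.3f}, R2 = {fit.r_squared:.3f}")
```

prints

```
       label  otu_n  otu_pct  seq_n  seq_pct
    abundant     54     1.08  61249    55.68
        rare   2910    58.20    668     0.61
intermediate   2036    40.72  48083    43.71
         all   5000   100.00 110000   100.00
ANOSIM R = 0.815 (p = 0.001)
distance-decay Spearman r = 0.754 (p = 0.001)
NCM: Nm = 4727, m = 0.945, R2 = 0.882
```

Read top to bottom: 54 of 5,000 OTUs (1.08%) are abundant yet carry
55.68% of all reads, while 2,910 rare OTUs (58.20%) carry only 0.61% — the
classic asymmetry between the dominant few and the rare biosphere. The
three simulated bays separate cleanly (ANOSIM R = 0.815), community
dissimilarity increases with geographic distance (Spearman r = 0.754,
both p = 0.001), and the neutral model fits the occurrence-frequency
spectrum well (R² = 0.88) because this simulation mixes moderate
selection with strong sampling drift.

The same workflow runs from the shell: `abundrare simulate`, `classify`,
`diversity`, `ordinate`, `decay`, `select`, `varpart`, `ncm`, or
`abundrare all config.yaml` for the full orchestration (rarefy → classify
→ per-subcommunity diversity, ordination, distance-decay, forward
selection, variation partitioning, plus a whole-community neutral fit),
writing every result as a labelled TSV.

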