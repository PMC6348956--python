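# groomtrade

Grooming-market analysis of matrilineal primate groups: from
focal-observation event logs to dominance hierarchies, grooming networks,
partner-choice diversity, reciprocity indices and biological-markets
hypothesis tests.

## The scientific problem

In female kin-bonded Old World monkeys, grooming is both a bond and a
currency: biological-markets theory predicts that grooming is traded for
itself and for rank-contingent commodities (social tolerance, infant
access), that low-ranking females direct grooming up the hierarchy, and
that partner choice tracks each partner's market value.  Testing these
predictions in a small captive matriline — half a dozen females observed in
15-minute focal samples across separate periods — requires a specific
statistical toolkit, because every quantity is dyadic and actors' rows are
not independent.  `groomtrade` packages that toolkit for behavioural
ecologists:

- **Bout segmentation** — grooming episodes of a dyad belong to one bout
  while no more than 30 s pass without grooming between the pair (the gap
  is measured from the end of the last episode, in either direction); the
  first groomer is the *Groomer*, a bout with both directions is
  *reciprocated*.
- **Dominance** — each female's average dominance index,
  `ADI_i = mean_j wins_ij / (wins_ij + wins_ji)` over opponents actually
  met, orders the hierarchy; under a fully consistent hierarchy the female
  at rank *i* of *n* scores exactly `(n−i)/(n−1)`.  Kinship comes from the
  recursive tabular (numerator relationship) method on the pedigree.
- **Networks** — degree, reach centrality `1 + Σ_j 1/d(i,j)`, unnormalised
  geodesic betweenness and unit-norm eigenvector centrality; Newman
  leading-eigenvector community division (structure flagged at Q > 0.30);
  average-linkage dendrograms with the cophenetic correlation coefficient
  (faithful above 0.80).
- **tau-Kr** — the rowwise Kendall matrix correlation
  `tauKr = Σ_i S_i / Σ_i D_i` with permutation inference that conserves
  each actor's outgoing value multiset; exact (enumerated) null for small
  groups, sampled otherwise.
- **Market statistics** — standardised Shannon–Weaver partner diversity
  `H′ = −Σ p_i ln p_i / ln(n−1)`; the grooming reciprocity index
  `gRI = 1 − |gAB − gBA| / (gAB + gBA)`; the weighted log-log within-bout
  reciprocity regression; observed-vs-expected grooming up the hierarchy
  with exact Wilcoxon signed-rank tests; GR/GG versus rank; grooming ×
  agonism (tolerance) and gRI × rank-distance correlations; cross-period
  partner-choice stability.
- **A seeded synthetic generator** that emulates the whole observation
  protocol (continuous clock sliced into rotating focal samples), with
  every market effect switchable by one parameter, so the full pipeline is
  testable without field data.

## Worked example

The package bundles the published partner lists and rank orders of a
captive mandrill matriline observed in two periods.  Rebuilding period
two's directed network from the partner lists alone:

```python
from groomtrade import datasets, classify_dyads, symmetrize
from groomtrade.network import centrality_table

b2 = datasets.partner_matrix("two")
c = classify_dyads(b2)
print(f"period two: {c.grooming_dyads}/{c.possible_dyads} dyads "
      f"({c.percent_grooming}%), {c.unidirectional} unidirectional")
print(centrality_table(symmetrize(b2)).round(3)[["degree", "reach", "betweenness"]])
```

prints

```
period two: 9/21 dyads (42.86%), 3 unidirectional
           degree  reach  betweenness
Camila          4  5.500          4.0
Limbe           3  5.000          0.0
Lisala          4  5.500          1.5
Lolaya          2  4.333          0.0
Mirinda         1  3.833          0.0
Nefertari       0  1.000          0.0
Tania           4  5.500          1.5
```

Nine of twenty-one possible dyads groomed, three of them one-way; the
isolated bottom-ranking female (reach exactly 1.000, degree 0) is socially
excluded, while the alpha female bridges the most pairs (betweenness 4.0).

A fully synthetic period with the default study-scale parameters:

```python
from groomtrade import SyntheticConfig, generate_group, simulate_period
from groomtrade import segment_bouts, effort_matrix, reciprocity_test

cfg = SyntheticConfig(n_females=7, obs_hours_per_female=16.0, seed=42)
group = generate_group(cfg)
log = simulate_period(group, cfg, "one")
bouts = segment_bouts(log)
eff = effort_matrix(bouts, list(group.individuals))
res = reciprocity_test(eff, n_perm=10_000, seed=42)
print(f"{len(bouts)} bouts, {eff.data.to_numpy().sum():.0f} s of grooming")
print(f"reciprocity: tauKr = {res.tau_kr:.3f}, p = {res.p_two_tailed:.4f}")
```

prints

```
212 bouts, 10863 s of grooming
reciprocity: tauKr = 0.646, p = 0.0003
```

— grooming given and received are strongly concordant, as expected with
the generator's default within-bout reciprocation switched on.

The same pipeline is scriptable from the shell:

```bash
groomtrade simulate --seed 42 --out log.csv
groomtrade analyze config.yaml --out results/
groomtrade report results/report.json
```

where `config.yaml` names the event logs (or a simulation block), the
pedigree, seeds and permutation counts; see `groomtrade analyze --help`.

## Layout

- `groomtrade.obslog` — event-log I/O, validation, bout segmentation
- `groomtrade.synthetic` — seeded generator of focal-observation logs
- `groomtrade.dominance` — ADI, rank distance, pedigree kinship
- `groomtrade.matrices` — effort/frequency/agonism matrices and dyad accounting
- `groomtrade.network` — centrality, modularity, clustering, rank tests
- `groomtrade.taukr` — tau-Kr statistic and permutation tests
- `groomtrade.market` — H′, gRI, regression, up-hierarchy and trade tests
- `groomtrade.pipeline` / `groomtrade.cli` — orchestration and CLI
- `groomtrade.datasets` — bundled published partner lists, ranks, pedigree

See `docs/methods.md` for the statistical conventions and their rationale.
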