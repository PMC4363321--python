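# relca

Comparative product carbon footprints (PCFs) with statistical support.

Point-value carbon footprints of near-identical products routinely differ by
less than their own uncertainty, so "product A emits less than product B"
claims need a hypothesis test, not a pair of numbers.  `relca` is a small
engine for exactly that workflow, aimed at LCA practitioners comparing
product alternatives (the bundled example: catfish from small family-owned
vs large corporate farms, per tonne of live fish):

1. **Quantify** — attach a distribution to every unit-process parameter
   (fit by maximum likelihood + Anderson–Darling selection over lognormal /
   normal / triangular / uniform, or supply specs directly) and to every
   GWP characterization factor (σ back-calculated from published 90% ranges
   as σ = (P95 − P05) / (2·1.645); CO₂ fixed at 1 with no uncertainty).
2. **Propagate** — matrix-based LCI: solve **A·s = f**, form **g = B·s**,
   characterize **h = q·g**, over N Monte Carlo runs.  Sampling is
   *dependent* across alternatives: each shared parameter (the common
   background supply chain, the GWPs) is drawn once per run and reused by
   every alternative, so shared uncertainty cancels out of the per-run
   differences Δₖ = h_{A,k} − h_{B,k} ("relative results").  Independent
   sampling is available for contrast but its results are refused for
   run-by-run comparison.
3. **Test** — Shapiro–Wilk gate, then the one-sample Wilcoxon signed-rank
   test (exact null by sign enumeration up to n = 25) or the paired t-test
   on the differences; Friedman plus post-hoc clustering (pairwise
   Wilcoxon + Holm, or blocked ANOVA + Tukey) for three or more
   alternatives.
4. **Report** — distribution-free order-statistic confidence interval for
   the median difference, box-plot percentiles, and traffic-light cluster
   labels.

## Worked example

The bundled synthetic case mirrors a two-farm-type aquaculture comparison:
a shared background supply chain (electricity, commercial and farm-made
feed, transport) consumed in different quantities, unshared direct pond
CH₄/N₂O emissions, and a constructed central-value footprint difference of
824 kg CO₂-eq per tonne of fish.

```sh
relca demo --seed 1 -o demo-out
```

prints

```text
kg CO2-eq per tonne of fish (1000 dependent MC runs):
    small-farm:  p10   3774.4  p25   4110.5  median   4517.2  p75   4977.2  p90   5393.9
    large-farm:  p10   2971.4  p25   3291.5  median   3651.6  p75   4126.1  p90   4560.5
median difference (small-farm - large-farm): 848.9 kg CO2-eq, 95% CI [810.6, 896.8]
wilcoxon_signed_rank: statistic 492243.0, p = 1.29e-154 -> reject H0 (median difference = 0.0) at alpha = 0.05
```

Read this as: the absolute footprints overlap heavily (the small-farm p10
is far below the large-farm p90), so point values or independent confidence
intervals could not separate the two products — but the *paired* per-run
differences, in which the shared supply-chain and GWP draws cancel, show a
median difference of ≈ 849 kg CO₂-eq whose 95% CI excludes zero, and the
signed-rank test rejects equality decisively.  The same pipeline runs on
your own data via the CSV/YAML dialect:

```sh
relca fit samples.csv -o specs.csv        # distributions from raw observations
relca compare comparison.yaml -o out/     # MC + statistical ladder
relca report out/results.csv              # re-run the ladder on saved results
```

Library use mirrors the CLI:

```python
import relca

case = relca.generate_case()                      # or build_system(...) from CSVs
design = relca.ComparisonDesign(case.systems, case.characterization,
                                n_runs=1000, mode="dependent", master_seed=1)
res = relca.run_comparison(design)
diffs = relca.relative_results(res, "small-farm", "large-farm")
print(relca.wilcoxon_signed_rank(diffs).to_dict())
```

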