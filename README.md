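# sipriming

Analysis pipeline for **¹³C stable-isotope-probing (SIP) incubation
experiments** that quantify the *priming effect* — the acceleration of
refractory organic-matter degradation when labile material is added — in
marine sediment slurries. The package targets the classic design in which
97 atom% ¹³C-labelled lignocellulose (a proxy for terrestrial particulate
organic carbon) is incubated with and without unlabelled diatom detritus,
and the label is traced into respired CO₂ and into phospholipid fatty acid
(PLFA) biomarkers of the microbial community.

It is written for biogeochemists and microbial ecologists who have per-vial
measurement tables (headspace CO₂ + dissolved inorganic carbon with δ¹³C,
and PLFA concentration/δ¹³C profiles) and want a tested, reproducible route
from raw measurements to mineralisation rates, biomarker incorporation and
multivariate community fingerprints.

## What it computes

**Tracer mass balance.** Isotope values convert between δ-notation,
isotope ratio and atom fraction:

    R = (δ¹³C/1000 + 1) · R_VPDB,   R_VPDB = 0.0112372
    F = R / (R + 1)

Total-CO₂ δ¹³C is the concentration-weighted mean of headspace and
dissolved phases (with a configurable +1 ‰ gas-phase fractionation
correction). Excess ¹³C against time-matched unlabelled controls,
E = F_sample − F_background, attributes carbon to the labelled substrate:

    substrate-derived C = E · C_total / F_substrate        (F_substrate = 0.97)

**Mineralisation series.** Treatment × time means ± SE of total and
substrate-derived CO₂ (μg C mL⁻¹ wet sediment), per-interval rates, and the
cumulative percentage of the added substrate respired.

**PLFA incorporation.** Per-PLFA incorporation I_PLFA = E · conc /
F_substrate, bacterial vs microeukaryote biomarker-group totals,
proportional enrichment profiles I_PLFA/I_total, a mean-enrichment < 0.001
filter and the empirical logit transform ln((p+0.1)/(1−p+0.1)).

**Statistics.** Sequential (type-1) two-way ANOVA with interaction and
Tukey HSD post-hocs (studentized-range based), residual diagnostics, and a
from-scratch NIPALS PLS2 with per-component explained variance and biplot
coordinates — used both for treatment/time structure in enrichment profiles
and for comparison against a genus-level PLFA reference database.

**Synthetic experiments.** A forward simulator of the whole incubation
(three carbon pools, two-phase partitioning, destructive sampling,
measurement noise) with named scenarios whose ground truths are the
published rates and cumulative fractions, so every pipeline stage is
testable end to end without raw data.

## Worked example

```
$ sipriming run-all --scenario rates-paper --seed 3 --outdir out
{
 "cumulative_fraction_pct": {
  "LC": 6.953333333333332,
  "LC1D": 7.186666666666668,
  "LC2D": 9.1
 },
 "interval_rate_0_7": {
  "LC": 0.62,
  "LC1D": 1.0499999999999998,
  "LC2D": 1.28
 },
 "pls_explained_y_pct": [99.91304840079377, 0.0869515992062337],
 ...
}
```

Reading the output: in the first week the lignocellulose mineralisation
rate rises step-wise with diatom dose (0.62 → 1.05 → 1.28 μg C mL⁻¹ d⁻¹ for
the lignocellulose-only control, low-diatom and high-diatom treatments) —
the priming signal — and over 28 days 7–9 % of the added lignocellulose
carbon is respired. The first PLS axis separates the treatments' PLFA
enrichment fingerprints (here it captures ~99.9 % of profile variance
because the synthetic truth is noise-free). All stage tables
(`mineralisation.tsv`, `anova.tsv`, `tukey_treatment.tsv`,
`pls_*.tsv`, …), a run manifest and this summary are written to `out/`.

The same stages are importable as a library:

```python
from sipriming import paper_scenario, simulate_experiment, substrate_series

sim = simulate_experiment(paper_scenario("cumulative-paper"), seed=1)
series = substrate_series(sim.vials)
```

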