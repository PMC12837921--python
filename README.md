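# felicoex

Statistical tooling for studying how a dominant and a subordinate forest
felid — think leopard (*Panthera pardus*, ~43 kg) and African golden cat
(*Caracal aurata*, ~9 kg) sharing Central African rainforest — coexist along
the three classical niche axes: space, time, and food. It is aimed at
camera-trap and scat-diet practitioners who want the full analysis chain as
reproducible, tested code, from raw detection records to density estimates,
co-occurrence models and diet-partitioning statistics.

Because location data for threatened carnivores are usually withheld, the
package includes a first-class synthetic-data generator that reproduces the
statistical structure of such surveys (nested camera grid, sex-structured
capture histories, two-species time-stamped detections with diel rhythms,
small scat samples), so every stage of the pipeline is testable end to end.

## What it computes

**Spatial capture–recapture (SCR).** Individual activity centers form a
homogeneous Poisson process of density *D* over a habitat mask; detection at
a trap on a daily occasion is Bernoulli with half-normal probability
*g*(d) = *g*₀·exp(−d²/2σ²). The full (Poisson-*N*) likelihood carries a
two-class sex mixture with female fraction *pmix* (unknown-sex individuals
enter through both classes). The module provides the RPSV-based mask buffer,
the classical capture-span closure test with exact span moments, AIC ranking
of the {null, g₀×sex, σ×sex, both} model set, a likelihood-ratio test of
*pmix* = ½, and HRCIW = 100·(UCL−LCL)/(2·D̂) as a monitoring-precision
summary.

**Continuous-time two-species occupancy.** Station states follow a
log-linear model ψ_z ∝ exp(z₁f₁ + z₂f₂ + z₁z₂f₁₂) with covariates on the
natural parameters f₁, f₂, f₁₂; detections at occupied stations are a
temporal Poisson process with log intensity α + two-harmonic Fourier series
in time of day, plus an optional η·u(t) term for the subordinate species,
u(t) being the capped time since the last dominant-species detection.
Midpoint quadrature (60 min), two-stage AIC selection, Wald intervals, and
bootstrap prediction curves (marginal/co-occurrence occupancy vs. distance,
diel activity, 3-h detection shares).

**Scat diets.** Frequency of occurrence (FO), corrected FO (CFO), and
relative biomass consumed (RBC) via the asymptotic biomass-per-scat model
y = a − b·e^(−c·x), x = prey/predator mass; group and size-class
aggregation; Levins standardized breadth, Pianka overlap, and Brillouin
accumulation curves for sampling adequacy.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Simulate a scat dataset at the subordinate-felid preset and summarize it:

```sh
felicoex simulate scats --preset nnnp --seed 7 --out demo
felicoex diet summary --scats demo/scats.csv --iterations 1000 --seed 1
```

```
wrote scats.csv (22 items) to demo
golden_cat: 16 scats, 22 items (mean 1.38/scat)
```

16 scats yielding 22 prey items (1.38 items per scat on average) — the
sample size and multiplicity the generator is calibrated to. In Python, the
same machinery applied to the packaged diet tables:

```python
from felicoex import diet

traits = diet.load_prey_traits()
scats = diet.load_scat_reconstruction("leopard")
profile = diet.diet_profile(scats, traits, "leopard")
print(profile.taxa[["taxon", "fo", "cfo", "rbc"]].round(1))
```

```
                     taxon    fo   cfo   rbc
0   Cephalophus callipygus  11.1   3.7   3.8
1  Cephalophus sylvicultor  11.1  11.1  12.5
2   Cercopithecus pogonias  11.1   3.7   2.0
3      Civettictis civetta  11.1   3.7   3.3
4          Colobus guereza  11.1  11.1   8.4
5      Lophocebus albigena  11.1  11.1   8.1
6     Potamochoerus porcus  55.6  55.6  62.1
```

Reading: over half the scats contain red river hog (*P. porcus*), and after
weighting by body mass it accounts for ~62% of the biomass consumed —
the dominant felid feeds mainly on large ungulates, while the subordinate's
profile (swap in `"golden_cat"`) is dominated by murid rodents and the
smallest duiker, which is why their dietary overlap (Pianka's index on
FO-derived proportions) comes out near 0.04.

Density estimation on synthetic captures:

```sh
felicoex simulate scr --preset nnnp --seed 5 --out demo
felicoex scr fit --captures demo/captures.csv --traps demo/traps.csv \
    --buffer-mult 4.5 --spacing-km 1 --models null,sigsex
```

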