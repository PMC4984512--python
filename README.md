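# islesar

Small-island-effect detection and nestedness analysis for island
biogeography data.

Species richness *S* usually grows with island area *A* as the power
law *S = cA^z* (a line in log–log space), but on sufficiently small
islands richness often decouples from area — the **small island effect
(SIE)** — and on very large islands in situ speciation can steepen the
curve again. `islesar` detects these regime changes by fitting five
candidate species–area models in log₁₀ *S* space and selecting among
them with AIC:

1. left-horizontal, one threshold:
   log *S* = *c*₁ + [log *A* > *T*₁] *z*₁(log *A* − *T*₁)
2. two-slope:
   log *S* = [log *A* ≤ *T*₁](*c*₁ + *z*₁ log *A*) + [log *A* > *T*₁](*c*₂ + *z*₂ log *A*)
3. left-horizontal, two thresholds:
   log *S* = *c*₁ + [*T*₁ < log *A* ≤ *T*₂] *z*₁(log *A* − *T*₁) + [log *A* > *T*₂](*c*₂ + *z*₂ log *A*)
4. three-slope:
   log *S* = [log *A* ≤ *T*₁](*c*₁ + *z*₁ log *A*) + [*T*₁ < log *A* ≤ *T*₂](*c*₂ + *z*₂ log *A*) + [log *A* > *T*₂](*c*₃ + *z*₃ log *A*)
5. power (linear in log–log):
   log *S* = *c*₁ + *z*₁ log *A*

Bracketed conditions are 0/1 indicators. Break points *T*ᵢ (log₁₀ km²)
are estimated by minimum residual sum of squares: continuous hinges on
a fine grid (step 0.001), discontinuous breaks over the observed
log-areas. Models are compared by AIC = 2*K* − 2 log *L* with the
Gaussian profile likelihood and *K* counting coefficients + thresholds
+ the error variance (so the five forms have *K* = 4, 6, 7, 9, 3
respectively), plus ΔAIC and Akaike weights ω.

The companion half of the package quantifies community **nestedness**
with NODF (nestedness metric based on overlap and decreasing fill,
0–100), tests it against the EE (equiprobable), CC (probabilistic
intermediate) and FF (fixed row/column totals, curveball-sampled) null
models, and characterises nestedness of *portions* of a system by
scoring NODF on random island subsets.

A synthetic-data module generates island tables and presence–absence
matrices with known ground truth (areas spanning ten orders of
magnitude, richness from any of the five forms, matrices from
perfectly nested to checkerboard), so the whole pipeline is testable
without external data.

## Worked example

`examples/sie_model_selection.py` simulates 500 islands from a
three-segment truth (*z* = 0.080/0.297/0.421, *T* = −0.603/0.946,
σ = 0.05 in log *S*) and re-detects the regime structure:

```
            model     c1    c2    c3    z1    z2    z3     T1    T2    rss  K    logL       AIC  delta_AIC  weight
            power  0.549   NaN   NaN 0.229   NaN   NaN    NaN   NaN 23.868  3  51.047   -96.095   1447.131     0.0
        two_slope  0.276 0.055   NaN 0.092 0.413   NaN  0.639   NaN  1.852  6 690.122 -1368.243    174.983     0.0
left_horizontal_1  0.041   NaN   NaN 0.373   NaN   NaN -0.387   NaN  4.104  4 491.196  -974.391    568.834     0.0
      three_slope  0.250 0.280 0.023 0.083 0.287 0.422 -0.663 0.918  1.290  9 780.613 -1543.226      0.000     1.0
left_horizontal_2 -0.082 0.137   NaN 0.096 0.413   NaN -3.774 0.639  1.832  7 692.807 -1371.614    171.611     0.0

best model: three_slope (Akaike weight 1.000)
estimated break points (log10 km^2): [-0.663, 0.918]
```

The three-slope form wins decisively (ΔAIC = 0, ω = 1.00) and recovers
both break points within 0.06 log₁₀ units of the generating values:
below *T*₁ ≈ −0.66 (about 0.2 km²) richness barely responds to area
(*z*₁ = 0.083, the SIE); above *T*₂ ≈ 0.92 the slope jumps to 0.42, the
signature of the speciation-dominated regime. The other examples run
the nestedness half: `nestedness_significance.py` (NODF against the
three null models) and `portion_sampling.py` (portion-level NODF,
sampled vs exhaustively enumerated).

A thin CLI wraps the same library calls:

```bash
islesar simulate sar --form three_slope --out sim --seed 1
islesar sie --islands sim/islands.csv --out results --seed 1
islesar nodf --matrix matrix.csv --null FF,CC --ensemble 1000 --out results --seed 1
islesar portions --matrix matrix.csv --iters 10000 --out results --seed 1
```

Every command writes JSON results plus a run manifest (settings, seed,
versions) making stochastic runs reproducible from their outputs.

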