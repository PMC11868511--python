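# dcvwalk

Heterogeneous random-walk analysis of dynein-driven dense-core-vesicle (DCV)
transport in neurons.

## The problem

Time-lapse recordings of GFP-labelled DCVs in the *C. elegans* ALA neuron
show retrograde (dynein-driven) cargo moving with a displacement variance
that grows roughly like *t*² — far faster than the linear growth a standard
random walk allows.  `dcvwalk` implements the statistical model that explains
this superdiffusive behaviour through *population heterogeneity*, together
with everything needed to apply it to kymograph-tracker output: trajectory
cleaning and classification, maximum-likelihood fitting, first-passage-time
analysis, a trajectory simulator, and a labelled synthetic-data generator.
It is aimed at anyone doing single-particle-tracking statistics of directed
intracellular transport.

## The model

A vesicle advances by one lattice step *a* = 0.092 µm per step time
τ = 0.01563 s with probability *p*, or pauses with probability 1 − *p*.
Each track keeps its own *p*, drawn once from a beta density
*f*(*p*) = *B*⁻¹(α, β) *p*^(α−1) (1 − *p*)^(β−1).  Marginalizing over *p*:

* the displacement *k* = *x*/*a* after *n* = *t*/τ steps is **beta-binomial**,

  P(k | n) = C(n, k) · B(k + α, n − k + β) / B(α, β),

  with mean ⟨x⟩ = α/(α+β) · a·n and variance
  var(x) = a²·n·αβ/[(α+β)(1+α+β)] + a²·n²·αβ/[(α+β)²(1+α+β)] —
  the *n*² term is the heterogeneity signature that makes the walk
  ballistic at late times;

* the first-passage step count *n* to reach a threshold of *k* steps is
  **beta-negative-binomial (BNB)**,

  F(n | k) = C(n−1, k−1) · B(k + α, n − k + β) / B(α, β),

  with mean ⟨t⟩ = τ·k·(α+β−1)/(α−1) for α > 1 and variance
  var(t) = τ²·k·β·(k+α−1)(α+β−1)/[(α−2)(α−1)²] for α > 2,

  **with the same (α, β) as the displacement law** — the model's key
  testable self-consistency prediction.

Shape parameters fitted to the three recorded strains ship as presets:
wild-type *ida-1::gfp* (α = 8.19, β = 12.95), *klc-1(−)* (α = 3.18,
β = 4.15) and *klc-2(rf)* (α = 5.12, β = 12.87).

## Worked example

Generate a synthetic wild-type-like dataset, run the track pipeline, and fit
the displacement law:

```bash
dcvwalk generate --preset wild_type --seed 1 --out tracks.csv
# wrote 1702 tracks ({'retrograde': 851, 'stationary': 596, 'anterograde': 255}) to tracks.csv

dcvwalk analyze --input tracks.csv --outdir analysis --no-plots
# analyzed 1702 tracks (847 retrograde) -> analysis

dcvwalk fit --displacements analysis/displacements.csv --strain wild_type --out fit.json
# alpha=7.493 (SE 0.430), beta=11.812 (SE 0.685), nll=3283.7, n=846 -> fit.json
```

`analysis/moments.csv` holds the empirical displacement moments:

```
lag_s,mean_um,var_um2,n_tracks
1.563,3.5706741986777026,1.1878924140017668,846
3.126,7.1421827830927835,4.24347368952572,833
```

At the 1.563 s lag the 846 surviving retrograde tracks moved 3.57 µm on
average with variance 1.19 µm² — close to the generating model's 3.56 µm and
1.10 µm².  The fitted shapes (α̂ = 7.49 ± 0.43, β̂ = 11.81 ± 0.69) sit near
the generating (8.19, 12.95); the shortfall is the selection effect of the
mean-speed track filter, discussed in `docs/methods.md`.  The reported
goodness of fit (χ² p = 0.64, total-variation distance 0.090) says the
beta-binomial describes the selected sample well.  Dropping `--no-plots`
additionally writes displacement, moment and first-passage figures with the
fitted overlays.

The same workflow runs on real kymograph-tracker exports: any CSV with
columns `track_id, frame, x_px` (one row per track point) is accepted, with
pixel size, frame interval, direction convention and speed threshold set via
`--config` YAML or command-line flags.

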