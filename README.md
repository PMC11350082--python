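# stemflux

Partitioning of net stem CO₂ efflux into its component processes —
**respiration**, **bark photosynthesis** and **sap-transport** — from paired
dark/transparent chamber measurements on tree stems, with a synthetic-data
generator that provides known ground truth for end-to-end validation.

Stem CO₂ efflux is a major but composite term in forest carbon budgets: CO₂
produced by stem respiration partly escapes radially, is partly refixed by
chlorophyll-containing bark tissue under light, and is partly carried up or
delivered by the transpiration stream as dissolved CO₂. `stemflux` is aimed at
ecophysiologists running continuous stem gas-exchange campaigns (dynamic
flow-through chambers plus thermal-dissipation sap-flow probes) who want a
tested, reproducible implementation of the chamber-difference partitioning
workflow rather than ad-hoc scripts.

## The model

With the sign convention that net flux `FCO2 < 0` when CO₂ leaves the stem,
the chamber mass balance is

```
-R + P + T = FCO2
```

and the three processes are parameterised per tree and calendar month as

```
R' = R0 · exp(b · temp)                       exponential temperature response
P' = Pmax · f · PPFD / (f · PPFD + Pmax)      rectangular-hyperbola light response
T' = e · J                                    linear in sap flux density
```

where `temp` is xylem temperature (°C), `PPFD` the photosynthetic photon flux
density (µmol m⁻² s⁻¹) and `J` the sap flux density. `R0` is respiration at
0 °C, `b` the temperature sensitivity (`Q10 = exp(10 b)`), `Pmax` the
light-saturation point, `f` the quantum yield, and `e` the slope linking
transport to sap flow (it measures the axial CO₂ concentration gradient).

The partitioning procedure: fit `R'` on dark-chamber data restricted to
near-zero sap flow (`J < 5 g m⁻² h⁻¹`, where the transport term vanishes);
extend `R'` over the whole record via xylem temperature; take the transport
residual `T = dFCO2 + R'` and the chamber difference `P = tFCO2 - dFCO2`
(daytime); then fit `P'` and `T'`. QC is flag-then-drop: a technical check,
a 3-standard-deviation outlier filter, and removal of records measured at
relative humidity above 85 %. All fits report standard errors, `t = est/SE`,
and 95 % confidence intervals; validation uses a random 8:2 train/test split
and regresses measured transparent-chamber flux on the reconstructed
`-R' + P' + T'`.

## Worked example

```bash
python examples/04_partition_season.py
```

simulates a June–September season at 30-min resolution with chamber noise
sd 0.1 µmol m⁻² s⁻¹, runs QC and the monthly fits, and prints (abridged):

```
aligned rows: 5846; low-sap-flow rows per month: {6: 270, 7: 303, 8: 469, 9: 688}

fitted parameters (estimate +/- SE, all p < 0.001):
  month 6  r0       0.8315 +/- 0.0154   (n=270)
  month 6  b        0.0727 +/- 0.0012   (n=270)
  ...
  month 9  pmax     0.5038 +/- 0.0116   (n=746)
  month 9  f        0.0061 +/- 0.0008   (n=746)
  month 6  e        0.0197 +/- 0.0002   (n=1440)
  ...
max |relative error| vs truth: 6.314%
```

The generator's June truth was `R0 = 0.80`, `b = 0.075`, `e = 0.020`: every
estimate sits within a few SE of truth, and the largest relative error is on
the September quantum yield, the hardest parameter (small `P`, low light).
The other examples cover driver simulation, closure-trace flux inversion,
Granier sap-flux conversion, and holdout validation with the contribution
figures. A thin CLI wraps the same pipeline:
`stemflux run --out run1 --seed 1 --noise-sd 0.1`.

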