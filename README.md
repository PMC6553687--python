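# phyllosim

Inhibitory-field models of phyllotaxis — the self-organized positioning of
leaf primordia around the shoot apical meristem (SAM).  The package
implements the two classical Douady–Couder-type models and their expansions
with primordial-age-dependent inhibitory power, which are the minimal
setting in which **orixate phyllotaxis** (the tetrastichous divergence-angle
cycle 180°, 90°, −180°, −90°, named after *Orixa japonica*) arises as a
stable pattern.  It is aimed at plant developmental biologists and
modelers who want to simulate, classify, and map phyllotactic patterns
across parameter space.

## Models

Every existing primordium *m* (azimuth θ_m, radius r_m = R0·e^(t−t_m) under
exponential apex growth; lengths in units of R0, times standardized by
V0/R0) contributes to an inhibitory field on the formation circle *M*:

* **DC1** (planar apex, one primordium per plastochron *T*):
  I(θ) = Σ_m k·d_m(θ)^(−η), with d_m the planar distance and
  G ≡ V0·T/R0 = ln(r_m/r_{m+1}).  The new primordium takes the global
  minimum of I.  Parameters: η, G.
* **DC2** (conical apex, flatness N = sin(ψ/2); threshold dynamics):
  I(θ) = Σ_m E(d_m(θ)/d0) with
  E(x) = Es·(coth(αx) − 1)/(coth(α) − 1), Es = 1, Γ ≡ d0/(R0·N).
  Whenever I drops below Es somewhere on *M*, a primordium is inserted
  there immediately — simultaneous insertions (whorls) included.
  Parameters: α, Γ, N.
* **EDC1 / EDC2** multiply each contribution by a logistic age factor
  F(age) = 1/(1 + e^(−a(age−b))) (EDC1, age in plastochrons, η = 2) or
  1/(1 + e^(−A(age−B))) (EDC2, standardized age).  A slow, late rise of
  the inhibitory power is what stabilizes orixate patterns.

On top of the simulators the package provides divergence-angle /
plastochron series extraction, the pattern taxonomy (regular, two-cycle,
tetrastichous four-cycle, x-cycle, decussate, tricussate, …) with its HSL
color legend, 1–2 parameter sweep maps, and fixed-arrangement stability
analyses of normal orixate phyllotaxis (stationarity curves of the EDC1
condition dI/dθ = 0 and a numerical impossibility scan for plain DC1).

## Worked example

Reproduce the distorted tetrastichous DC1 pattern at G = 0.3, η = 1.5:

```sh
$ phyllosim simulate --model dc1 -p G=0.3 -p eta=1.5 --out dc1_trace.csv
dc1: 100 primordia -> four_cycle_alternate
cycle angles: 90.7, 164.7, 90.8, 164.7
```

After 100 primordia the divergence angle cycles through p, q, −p, −q with
|p| ≈ 165° and |q| ≈ 91° — a four-ranked alternate pattern whose larger
angle is well short of the 180° of true orixate phyllotaxis (the angle
ratio |q|/|p| ≈ 0.55 instead of 0.5 with orthogonal ranks).  The same in
Python:

```python
from phyllosim import DC1Params, run_dc1, classify
pc = classify(run_dc1(DC1Params(eta=1.5, G=0.3)))
pc.category             # 'four_cycle_alternate'
pc.representative_angles  # (90.7, 164.65, 90.75, 164.65)
```

The EDC1 parameters compatible with *normal* orixate geometry come from
intersecting the stationarity curves of the two arrangement situations:

```sh
$ phyllosim solve-orixate --g 0.5 --a-min 1.0 --a-max 2.0 --a-step 0.1 --out curves.csv
G=0.5: 4 intersection(s) (a=1.509, b=8.530), (a=1.507, b=12.531), (a=1.505, b=16.531), (a=1.513, b=4.517)
```

The lowest-b crossing (a ≈ 1.51, b ≈ 4.52) lies inside the parameter
window where EDC1 simulations actually produce orixate patterns.

Other subcommands: `sweep` (classified parameter-grid CSV + color-map
PNG), `classify` (re-classify a written trace), `landscape` (field profile
of an artificial normal-orixate arrangement).

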