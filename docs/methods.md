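# Methods

## Model structure

Five classes of point agents — melanophores (M), loose/dense xanthophores
(Xl/Xd) and loose/dense iridophores (Il/Id) — interact on a rectangular
patch of skin that is periodic lengthwise (x) and bounded dorsoventrally
(y). The patch starts at 2000 × 1000 μm at 21 days post-fertilization
(dpf), covering the full body height and about a third of the patterned
body length, and grows 38 μm/day in length and 27 μm/day in height;
each day every coordinate is multiplied by the day's scale factors
(uniform epithelial stretching). One simulated day consists of:

1. scheduled perturbations (choker seeding, ablation), applied to the
   state entering the day;
2. growth and stretching;
3. migration — 10 synchronous forward-Euler substeps of 0.1 day;
4. one synchronous rule pass: every birth, death and form-flip decision is
   computed from the post-migration snapshot and applied together, so no
   rule observes another rule's same-day outcome.

Melanophores are the only cells that die; xanthophores and iridophores
change form but never disappear. Within 50 μm of the top or bottom edge,
outward vertical velocity is zeroed (no flux); neighbourhoods truncate at
those edges rather than mirroring.

## Forces

The force a source cell at A exerts on a target cell at B is
`-R·(1/2 + 1/2·tanh((r − ‖A−B‖)/δ))·(A−B)/‖A−B‖`: a smoothed contact
step of signed strength R (μm/day; positive repels, the single attractive
term draws dense xanthophores toward dense iridophores) and range r, with
δ = 5 μm. Forces are truncated beyond `r_max + 5δ` (tanh tail < 1e-4 of
R); coincident cells exert no force (the direction is undefined; daughters
separate through other neighbours within a day). Interaction terms exist
only where the biology motivates them — e.g. melanophores and loose
iridophores share stripes in different skin layers and do not repel.

## Rules

All rules are inequalities on the numbers of cells inside closed disks of
radius 45, 75, 82 (the melanophore–xanthophore boundary distance) and
90 μm, or a closed 210–250 μm annulus, with the focal cell included when
it belongs to the counted class. The printed constants are: melanophore
birth `α = 3`, `β = 3.5`, empty-neighbourhood birth rate 1% at `γ = 0`;
death `μ = 1.25`, `ξ = 2`, `ν = 3`, `p_death = 0.0333/day`; xanthophore
form `a = 2`, `b = 1`, Bernoulli mean `p = 0.5`; iridophore network
`c = f = e = 3`, `d = 9`, `g = 5`, `h = 2`. Mechanism toggles replace a
threshold with ±10⁹, which disables or satisfies a single clause of the
compound iridophore rules without touching rule code; presets map these
sentinel settings to the reduced networks ([Ã&C̃], [C̃], [A||B], [B] and
the six wild-type reductions).

## Calibrated constants

Interaction strengths/ranges, the daily candidate counts (`n_diff`,
`n_rand`), the crowding caps (`η`, `φ`, `ψ`, `ρ`) and the initial-condition
densities are not fixed by printed values; they ship as calibrated
defaults (flagged in `RuleParams.calibrated` and the parameter-YAML
metadata) chosen against the published measurement envelopes: mean
nearest-neighbour distances 36–82 μm per class with M–M ≈ 50 μm at stage
J+, melanophore migration on the order of 100 μm/week, the wild-type
milestone schedule, and a high rate of unbroken interstripes.

Two lessons fixed the final values. First, the tanh force saturates at
short range, so if a division cap permits a density above the packing
density of the force range, crowded regions jam into clusters with
near-zero internal restoring force; every cap is therefore set so that its
implied hexagonal spacing exceeds the corresponding force range
(`φ = 8`, `ψ = 4`, `ρ = 9` cells per 82 μm disk). Second, melanophore
density is limited by the long-range birth signal rather than by the local
cap, so the M–M spacing tracks the dense-cell densities; `η = 6` and
`n_diff = 600` candidates/day place it at ~52 μm. With these defaults a
wild-type run takes ~14 s on one CPU, and ensembles of 20 runs are used
where the original study used 100 — the statistics reported here
(success rate, spacing means) are computed at that reduced ensemble size.
Measured melanophore speeds are ~63 μm/week, slightly below the 80–100
envelope; raising the M–M strength recovers speed but disorders the
spacing, and the slower value was kept.

The initial condition is a jittered 30 μm grid of dense iridophores in a
100 μm tall central band (the "faint strip" over the horizontal
myoseptum) plus larval/loose xanthophores on a jittered 85 μm grid —
about 230 and 270 cells respectively.

`calibrate_unknowns()` exposes the search itself: random draws over the
documented ranges scored by squared deviation from the spacing envelopes
on short wild-type runs. The shipped defaults are the product of this
procedure plus manual refinement on the full timeline.

## Randomness

Every stochastic decision draws from a counter-based stream (Philox) keyed
by `(root seed, day, purpose tag)` and indexed by entity — cell id for
per-cell coins (death, the Eq.-2 Bernoulli, daughter placement), candidate
index for location draws. Streams are independent across keys and
reproducible regardless of consumption order, so the daily update is
bit-exactly invariant to the storage order of cells; populations are also
re-sorted by id each day so floating-point summation order is canonical.

## Metrics

Interstripe bands are maximal y-intervals where the smoothed (20 μm bins,
3-bin moving average) dense-cell density exceeds half the central-band
peak; breaks are runs of ≥ 100 μm of empty 50 μm columns along a band,
with seam-crossing voids counted once. Pattern success means X0, X1D and
X1V all detected with zero breaks. Nearest-neighbour statistics use the
periodic-in-x metric and exclude the focal cell for same-class queries;
CV = 100·SD/mean of melanophore neighbour distances. The
horizontal-banding (anisotropy) index contrasts the coefficients of
variation of the y- and x-marginal density profiles: ≈ +0.8 for wild-type
stripes, ≈ 0 for the labyrinthine choker pattern. Developmental stages
(PB 21 dpf, PR 30, SP 39, SA 44, J 51, J+ 70) interpolate the standard
staging table.

## Known limitations

* The model omits L-iridophores, intermediate xanthophore forms and
  larval-to-adult melanophore transitions; it addresses body (not fin)
  patterning from 21 dpf onward.
* The simulated *nacre* (no melanophores) ends as a uniform dense
  iridophore+xanthophore sheet rather than a widened central interstripe
  over a loose-iridophore background. The dense-xanthophore state is
  self-propagating through the loose-xanthophore lattice via the
  `P·Xd75` term of the form rule; without melanophores nothing opposes
  the wave, and whether loose iridophores nucleate at the expanding front
  first is a race decided by density constants that the quantitative
  envelopes pin differently. Within those envelopes the nucleation loses,
  so this phenotype is reported as a known mismatch rather than tuned
  around.
* Synthetic patterns lack many features of real skin: three-dimensional
  layering is collapsed to one plane, cell sizes and shapes are ignored,
  and communication is instantaneous at fixed radii. Passing tests show
  the rule network reproduces the pattern-level phenomenology at realistic
  densities, not that parameter values transfer to real fish.
* Band detection assumes horizontal banding when locating X0/X1D/X1V;
  strongly disordered patterns (choker) are instead quantified by the
  anisotropy index and windowed band counts.
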