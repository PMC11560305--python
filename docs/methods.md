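# Methods

## Model

One rigid cubic lattice (default 40×40×20 sites, spacing l = 0.2 μm)
represents a patch of cell: the z = 1 plane is the plasma membrane, z ∈ [2,
nz] the cytosol. x and y are periodic; the top surface and the membrane are
closed, which stands in for steric hindrance at those surfaces. A fixed
number of YAP molecules (total conserved — production/degradation operate on
hour timescales, far slower than the simulated seconds-to-minutes) occupy at
most one site each.

Integrin adhesions are rectangular footprints of binding sites on the
membrane plane. Cytosolic YAP one site above a free binding site may bind
(jump z = 2 → z = 1) at rate R_b; bound YAP is phosphorylated at R_p or
released unphosphorylated at R_u,YAP; bound pYAP is released at R_u,pYAP or
when its adhesion disassembles. Cytosolic pYAP is dephosphorylated at
R_deph; bound pYAP is protected. pYAP never rebinds. Bound molecules do not
diffuse (d_i = 0), mimicking crowding inside adhesions.

The stochastic dynamics are a per-molecule next-event scheme: molecule i
holds an absolute time τ_i = t − log(rand)/(r_i + d_i); the globally
earliest event fires, a second uniform draw picks reaction
(probability r_i/(r_i+d_i)) vs. diffusion, a third picks the channel
(proportional to rate) or one of six hop directions (uniform), and only the
executed molecule's clock is redrawn — the other clocks stay valid by
memorylessness. Diffusion is a hopping reaction at total rate d = 6D/l²,
which reproduces Fickian diffusion with per-axis MSD 2Dt.

## Parameters

| parameter | meaning | default | studied range |
|---|---|---|---|
| D (μm²/s) | cytosolic diffusion coefficient | 0.8 | 0.8–19 |
| R_b (s⁻¹) | binding from z = 2 onto a free site | 50 | 5–100 |
| R_p (s⁻¹) | phosphorylation of bound YAP | 200 | fixed |
| R_u,YAP (s⁻¹) | release of bound YAP | 0.1 | 0.02–0.2 |
| R_u,pYAP (s⁻¹) | release of bound pYAP | 0.1 | 0.001–0.2 |
| R_deph (s⁻¹) | cytosolic dephosphorylation | 0.035 | 0.035–0.56 |
| n_YAP | total molecules (1.62 nM in the default box) | 250 | 150–800 |
| N × footprint | adhesion count × size (sites) | 9 × (3×3) | 1–9; 3×3–9×9 |
| r | confinement fraction of the membrane | 1 | 0.09–1 |
| lifetime (s) | adhesion turnover period | none | 60–135 |

R_p ≫ R_u,YAP, so a bound YAP is far more likely to be phosphorylated than
to leave unmodified; this is why doubling R_u,YAP barely moves the pYAP
ratio while R_b moves it strongly.

## Event-loop semantics and numerical choices

- **Rejection kinetics.** Hops into occupied sites or across closed
  boundaries, and releases under an occupied z = 2 site, are rejected but
  still consume the event (time advances, clock redrawn). This keeps the hop
  rate at the constant 6D/l² that the diffusion calibration assumes.
- **Lazy rate re-evaluation.** Other molecules' actions can change a
  molecule's eligible channels (a binding site frees or fills) without its
  clock being redrawn. Rates are therefore recomputed from the current grid
  at execution time, so an illegal channel is never executed; the event time
  itself keeps the originally drawn value.
- **Tie-breaking.** A scheduled adhesion disassembly beats a molecule event
  at exactly equal times; equal molecule clocks resolve to the lowest id.
  Ties have probability zero; the rules only pin down reproducibility.
- **Turnover.** Each adhesion initially carries a uniform random age
  tl ∈ [0, lifetime] and disassembles at lifetime − tl, desynchronizing the
  population; afterwards disassemblies recur every lifetime. On disassembly
  every bound molecule is released to z = 2 above its site — if occupied, to
  the first free cytosolic site scanning outward in Chebyshev distance with
  sorted-coordinate tie-break (release never fails, so mass is conserved) —
  and a same-size footprint is placed at a fresh random admissible position.
- **Placement.** "Not clumped" is operationalized as ≥ 1 empty site between
  footprint perimeters (toroidal metric); no metric is standard, and this is
  the weakest constraint that forbids contiguous super-adhesions. Footprints
  may wrap across the periodic edges when placed on the whole membrane but
  never across a confinement-region boundary, which is a literal sub-area.
  Placement is rejection sampling with whole-layout restarts (the confined
  9-in-12×12 case jams sequential sampling occasionally).
- **Equal-total-area sweep.** 81 total sites split over N = 2 or 4 equal
  squares is not realizable on an integer lattice (40.5, 20.25 sites); the
  preset uses two 5×8 and four 4×5 rectangles (80 sites, −1.2 % total area)
  and records the realized area in every output row.
- **Pairwise distance.** The spatial-dispersion metric is the mean plain
  Euclidean distance between all unordered binding-site pairs, computed on
  the stored (wrapped) coordinates without a minimum-image convention; a
  footprint that happens to wrap therefore contributes split coordinates.
  Layouts are placed without wrap in all preset scenarios that report it.
- **z = 1 outside footprints** is inaccessible: binding is a reaction
  channel, not a hop, and no event list exists for free molecules on the
  membrane, so cytosolic molecules live strictly in z ≥ 2.
- **Steady state.** Counts are sampled every 10³ events; a run's
  steady-state ratio is the mean over the last 50 % of samples (burn-in
  fraction configurable). Headline uncertainty is the SD over ≥ 3 replicate
  runs with fresh random adhesion positions and seeds base+i; the within-run
  fluctuation is also reported.
- **Budgets.** Desk-scale runs use 10⁶ events per replicate (tens of
  seconds of simulated time at D = 0.8), chosen so a full sweep runs in
  minutes; presets expose a 10⁷ budget via `--full`, and runs at D = 19 get
  8× more events since hops dominate the event count there and comparable
  simulated time needs proportionally more events. The saturation and
  turnover analyses use 3–5×10⁶ events (the slow scales there are site
  filling and the 60–135 s lifetimes).
- **RNG.** One seeded `numpy` Generator drives placement, initialization and
  turnover; the compiled kernel uses its own stream seeded from the same
  seed via `SeedSequence`. Identical seeds give bitwise identical outputs.

## Validation oracles

For a single molecule the model is a finite CTMC whose states are (site,
phosphorylation, bound) and whose transition rates are read directly off the
engine's channel-rate function; `oracle.stationary_distribution` solves
πQ = 0 (restricted to the unique closed communicating class, with rejected
hops omitted — self-loops do not change the stationary law). Engine
time-weighted state frequencies on a 3×3×3-cytosol, one-binding-site model
agree with π within batch-mean standard errors. Free-diffusion runs with all
reaction rates zero reproduce the per-axis MSD 2Dt within a few percent
(walkers start in a central slab so the closed z boundaries stay unreached
over the measurement window; occupancy at 0.4 % density contributes < 1 %
rejection bias).

## What the simulations do and do not emulate

The simulator *is* the study system: all inputs are parameter sets, and all
test fixtures are generated programmatically. The scaled-down scenario
budgets (10⁶-event runs vs. 10⁷–5×10⁷ for production figures) reproduce
orderings and sign contrasts with separations measured against replicate
SDs, not converged plateau values; quantitative plateau ratios require the
`--full` budget. Not modeled: adhesion growth, merging or
stiffness-dependent size selection (adhesion size is an input);
gamma-distributed lifetimes (all adhesions share one fixed lifetime);
spatially varying D near adhesions; pYAP rebinding; downstream S127/Hippo
signaling and nuclear translocation.

## Known limitations

- With R_u,pYAP = 0 and no turnover, bound pYAP is absorbing; the engine
  marks such molecules inert (clock = +∞), and a run where *every* molecule
  becomes inert terminates early by design.
- The Hill fit is an empirical summary; k₂ is poorly constrained when the
  sampled R_b grid sits entirely on the plateau.
- Batch-mean standard errors in the CTMC comparison assume batches longer
  than the chain's mixing time; the shipped tiny models mix in ≪ 1 batch.
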