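# Model and methods

`osteosim` is a centre-based, off-lattice agent-based model of *in vitro*
intramembranous osteogenesis in a virtual culture dish. It simulates the
full cascade from a handful of colony-forming mesenchymal precursor cells
to a mineralised bone nodule: monolayer growth to confluence, stochastic
commitment to the pre-osteoblastic lineage, migration to a skeletogenic
focal point, condensation growth in 3D, differentiation into polarised
osteoblasts, osteoid deposition, mineralisation, and the terminal
entrapment of osteoblasts as osteocytes. Its purpose is hypothesis
testing: four alternative rules for how osteoblasts acquire their
deposition direction (polarity) — and hence how they become entrapped —
can be swapped while everything else stays fixed.

## Agents and environment

Every agent is a non-deformable sphere of diameter 20 µm in a
300 × 300 × 300 µm³ dish with hard walls. Six kinds exist: precursor,
pre-osteoblast, osteoblast, osteoid, mineralised osteoid and osteocyte.
Cells are mobile; matrix (osteoid, mineralised osteoid), once placed,
never moves. One engine iteration corresponds to 20 minutes of physical
time (72 iterations per day); simulated days post-confluence ("pc") are
counted in 72-iteration blocks from the first iteration at which the
precursor monolayer is confluent. Each osteoid agent stands for an
arbitrary quantum of homogeneous bone matrix; its fibrous/ground-substance
composition is not resolved.

## Physical interactions

Overlap is detected and corrected once per iteration by an explicit
scheme: each cell is displaced, from the previous iteration's positions
only, by the sum over in-range neighbours j of

    F_c,ij = s_ij · c_c,i · O_ij ,   s_ij = 1/d_ij ,   c_c,i = α (c_j − c_i)

per axis c ∈ {x, y, z}, where O_ij = d_ij − (r_i + r_j) is the signed gap
and α = 0.4 when the pair overlaps (O_ij < 0) or 0.06 when it is separated
within the 10-µm vicinity band (pairs farther apart do not interact). The
signs make a single formula cover both regimes: overlap repels hard,
in-band separation is drawn softly back toward contact, so an isolated
pair relaxes to touching. The soft branch acts as cell–cell cohesion and
produces the tight aggregates characteristic of condensations; an
all-repulsive variant was tried and inflates the packing until the
entrapment criterion (below) becomes geometrically unsatisfiable.
Residual overlaps may persist within a step but shrink geometrically
across steps. Coincident centres receive a seeded 0.1-µm jitter. After
displacement, positions are clamped into the dish and precursors are
re-pinned to the monolayer plane (z = 10 µm).

Neighbour queries run through a `scipy.spatial.cKDTree`; the test-suite
keeps a brute-force O(n²) scan as the independent oracle.

## Rules

All gates refer to the **condensation height**: the maximum z-top of any
condensation agent (every kind except precursors, with z-top above one
monolayer diameter) over the dish floor.

* **Proliferation.** Precursors and pre-osteoblasts attempt division at
  strictly periodic intervals (default every 12 h; the timer is redrawn
  whether or not the attempt succeeds). Precursors place the daughter
  in-plane and are contact-inhibited at 4 planar neighbours (separation
  band 0 < gap ≤ 10 µm among precursors); they probe a few directions per
  attempt so the monolayer reliably fills the dish. Pre-osteoblasts divide
  in a uniformly random 3D direction, only after arriving at the
  skeletogenic site, only below a condensation height of 90 µm, and are
  contact-inhibited at 6 neighbouring *cells* (touching included; matrix
  constrains them through the daughter-placement check instead — in the
  cohesive equilibrium cells rest at gap ≈ 0, where the strict separation
  band systematically under-counts). A daughter needs a free site
  (no agent within one diameter less a 1-µm tolerance).
* **Confluence.** The monolayer is confluent when every precursor either
  has its critical planar neighbour count or cannot fit a daughter along
  any compass direction. Confluence sets the day-0 pc origin and triggers
  the one-shot stochastic precursor → pre-osteoblast conversion (fraction
  0.55 of precursors; a calibration parameter, see below). Losing
  confluence (e.g. cells leaving for the condensation) lets the remaining
  precursors regrow the monolayer.
* **Migration.** Pre-osteoblasts move in-plane at constant speed toward
  the dish-centre focal point — 2 µm per iteration regardless of distance
  (an effective speed; the nominal 0.2 µm/s taken literally would cross
  the dish in minutes, while aggregation is observed to take of order a
  day) — and stop permanently on reaching one diameter of the focal point
  or on touching an already-arrived cell, seeding a growing aggregate.
* **Differentiation (pre-osteoblast → osteoblast).** Gated at 50 µm.
  Eligible are pre-osteoblasts *ensconced within* the condensation —
  z-top below 80 µm, at least 20 µm below the growing top surface, 20 µm
  inside the lateral rim, and above the basal monolayer — or in touching
  contact with more than four osteoblasts. Eligible cells convert with
  probability 0.007 per iteration (instantaneous conversion exhausts the
  proliferative pool and stalls growth); converts acquire their polarity
  on creation. Osteoblasts that end up on the lateral periphery revert to
  pre-osteoblasts, using the same geometry snapshot to avoid oscillation.
* **Osteoid deposition.** Gated to heights 70–110 µm; each osteoblast
  deposits at strictly periodic intervals (default every 18 h). A deposit
  extends the osteoblast's matrix *seam*: it lands on the first available
  site along the polarity ray, in steps of one diameter, up to 7 diameters
  out. A site is available when no other matrix overlaps it (matrix packs
  at ≥ 11.5 µm centre spacing — denser than cells, as befits amorphous
  matrix) and no cell core sits within 5 µm; cells merely nearby do not
  block, so osteoid wedges into the interstices of the cellular fabric and
  the overlap mechanics relaxes the crowding. This is how osteoblasts end
  up caged without being displaced out of the nodule. If the whole ray is
  saturated, the deposit overflows to the first free site vertically above
  the cell — secreted matrix cannot vanish — which is what ultimately
  pushes the roof of the nodule through the 100/110-µm gates.
* **Polarity (the four entrapment hypotheses).**
  H1: a fresh random direction at every deposition (apolar secretion).
  H2: one random direction per osteoblast, immutable until it
  differentiates or dies (cell-autonomous polarity, self-burial).
  H3: one direction per 20-µm z-layer (regions 10–30, 30–50, 50–70,
  70–90 µm), drawn once per run — polarity as a property of a cell layer,
  so younger layers bury their predecessors.
  H4: as H3, but osteoblast secretion switches off stochastically (below).
  The default direction set ("tilted") draws a uniform azimuth at a fixed
  climb — z-component 0.15/0.3/0.5/0.5 for the four regions, deep layers
  depositing nearly laterally onto the substrate, upper layers toward the
  growing front — with a ±0.7-rad per-cell azimuth scatter around the
  layer direction ("roughly, not exactly, the same direction"), which
  interleaves neighbouring seams and completes the cages. Isotropic
  sphere/hemisphere and axis-aligned sets are available in the
  configuration; the tilted set is the calibrated default because fully
  random layer directions make whole runs fail to reach the
  mineralisation gate whenever no layer happens to point upward.
* **H4 secretion switch-off.** From a configurable onset iteration, every
  osteoblast is switched off with a per-iteration probability equal to
  the population fraction, for the configured period (24 h, 48 h, or
  indefinite), fresh draws refreshing the window. The steady-state
  silenced fraction is 1 − exp(−q·period); 30%/indefinite silences
  everyone almost immediately, 2%/24 h silences ~76% and is the only
  regime that still produces osteocytes — reproducing the reported
  phenotype grid. With fraction 0 the rule is inert and H4 is exactly H3.
* **Mineralisation.** Gated at 100 µm. Each osteoid agent must pass two
  sequential Bernoulli gates (p = 0.03 per gate per iteration, one gate
  per iteration), so conversion takes at least 2 iterations and on
  average 2/p ≈ 67 iterations (~0.9 days).
* **Entrapment (osteoblast → osteocyte).** Gated at 100 µm. An osteoblast
  whose contact set (touching or within the 10-µm vicinity band, i.e.
  centres within 30 µm) holds at least 6 mineralised matrix agents
  terminally differentiates; the sensitivity variant S4 lowers the
  threshold to 4.
* **Apoptosis.** Once the nodule has acquired its maximum height
  (110 µm), each undifferentiated osteoblast dies with probability 0.002
  per iteration, freeing its space.

## Engine

Phases run in a fixed order each iteration — migration, division,
precursor differentiation (at confluence), pre-osteoblast
differentiation + periphery reversal, H4 switch-off, deposition,
mineralisation, entrapment, apoptosis, overlap resolution — with
within-phase agent order shuffled from the run's RNG. All randomness
derives from one root seed through named PCG64 substreams (one per
stochastic phase), so a (config, seed) pair determines the trajectory
bitwise, and toggling one rule does not perturb another's draws.
Snapshots (CSV + JSON sidecar, full float precision) optionally carry the
substream states, making a resumed run identical to an uninterrupted one.

## Parameters

Stated by the study design (Tables of the experimental grid):

| parameter | default | varied in |
|---|---|---|
| division interval | 12 h | S1 ±3 h, S2 ±1 h, S3 8 h, S8/r2 18 h |
| deposition interval | 18 h | S5 6 h, S6 ±3 h, S7/r1 1 h, r2 36 h |
| entrapment threshold | 6 mineralised contacts | S4: 4 |
| critical neighbours | 4 (2D), 6 (3D) | — |
| height gates | 50/70/80/90/100/110 µm | — |
| dish, agent size | 300³ µm³, Ø 20 µm | — |
| iteration | 20 min | — |

Unstated in the source system and therefore calibrated **once** on the h3
baseline (target: maturation ≈ day 9 pc, ≈ 86 osteocytes at day 12 pc),
then frozen for every other experiment:

| parameter | value | role |
|---|---|---|
| precursor → pre-osteoblast fraction | 0.55 | size of the migratory pool |
| mineralisation gate p | 0.03 /iter | sets the ~1-day mineralisation lag |
| apoptosis rate | 0.002 /iter | attrition of unentombed osteoblasts |
| polarity direction set | tilted (0.15/0.3/0.5/0.5; ±0.7 rad) | cage completion + roof reliability |

Structural constants fixed during the same calibration: migration step
2 µm/iter, osteoblast differentiation rate 0.007/iter, seam reach 7
diameters, matrix packing 11.5 µm, deposition cell clearance 5 µm.
With these, the baseline over 8 seeds gives 82 ± 16 osteocytes at day 12
pc and median maturation day 9.

## What the model does and does not capture

The simulated dish assumes optimal, spatially uniform concentrations of
nutrients and osteogenic factors: there are no morphogen fields, no
chemotaxis beyond the fixed focal point, no mechanics-driven polarity,
no osteoclasts (resorption is an imposed perturbation, not a process),
and a single nodule per dish. Matrix is homogeneous and immobile. Passing
tests therefore demonstrate internal consistency of the rule set and
agreement with the reference system's aggregate readouts (census,
maturation timing, arrangement regularity), not predictive power for any
particular culture.

Known quantitative limitations, measured and left uncorrected:

* The response of the osteocyte census to the *matrix deposition rate* is
  flatter than in the reference system. Moderately faster deposition
  (6 h) depresses the count too much, and extreme rates (1 h, alone or
  with slowed division) not enough, because interstitial seam deposition
  couples deposition rate to roof growth roughly linearly; the reference
  behaviour suggests surface apposition whose height growth saturates
  with rate. The interval-jitter variant (18 ± 3 h) is reproduced only
  directionally.
* After the resorption challenge the baseline mechanism regrows a
  qualitatively normal but smaller nodule: the surviving cell pool below
  the 40-µm cut is small, and the regrown spike reaches the global
  height gates before the nodule has re-widened. The mechanism ordering
  (h3 recovers best; matrix overproduction and low vigour recover fewer
  osteocytes; H4 none) is reproduced; statistical equivalence of the h3
  recovery with the unchallenged baseline is not.

## Numerical choices

Placement tolerance 1 µm (a daughter may overlap by up to 1 µm; the
mechanics absorbs it); degenerate pairs jittered at 0.1 µm from the
mechanics substream; condensation membership requires z-top strictly
above 20 µm; maturation day is ⌈(first-osteocyte iteration −
confluence)/72⌉ with day 0 for osteocytes already present at confluence;
Gaussian-mixture cluster counts use full covariances, 3 seeded restarts,
reg_covar 1e-4, k ≤ 8 (a nodule of ~90 osteocytes does not support more
interpretable clusters), argmin-BIC; the Kruskal–Wallis test is
asymptotic (chi-square) with tie correction, with an exact-permutation
enumeration retained as an oracle for tiny samples; Dunn's post-hoc z
uses the pooled-rank variance with tie correction and multiplies raw p by
the number of comparisons in the family.
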