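# Methods

## Model

`trenshsim` represents a plexiform brain arteriovenous malformation (bAVM)
and its feeding/draining circulation as a directed vessel graph solved as an
electrical network. Each vessel is a rigid cylindrical conduit carrying
incompressible, laminar, Newtonian flow, so the Hagen–Poiseuille law

    Q = ΔP / R_v,    R_v = 8 L μ / (π r⁴)

plays the role of Ohm's law (blood viscosity μ fixed at 3.5 cP). Pressure
drops at junctions, pulsatility, vessel compliance and autoregulation are
all neglected; flow is steady-state. Internally everything is computed in
CGS units (cm, poise, dyn/cm², cm³/s); mmHg (1 mmHg = 1333.22 dyn/cm²) and
mL/min appear only at API boundaries.

### Extranidal template

The fixed extranidal tree runs from the aortic root through the carotid /
subclavian / vertebral trunks and the cerebral arteries (MCA, ACA, PCA, plus
a transosseous feeding artery) to four arterial feeders AF1–AF4; venous
return runs from three draining veins DV1–DV3 through the dural sinus and
vena cava. AF1/AF2 are major low-resistance feeders, AF3/AF4 minor
high-resistance ones; AF2 carries the most flow. Each cerebral branch also
carries a lumped *normal-territory runoff* vessel to the systemic veins,
representing the capillary bed of normal brain. These runoff branches form a
perfusion-pressure divider at the feeder origins: the feeders' stall
pressure (the pressure a retrograde injection must exceed before a feeder
reverses) is the divider value, well below the systemic mean. Without this
element a retrograde venous injection would flood the nidus even at
normotension; with it, flooding becomes possible only when systemic pressure
is lowered — the central mechanism of TRENSH.

Nine electromotive forces drive the circuit: ESP (systemic mean pressure,
realized as the pinned aortic-root pressure), one EMF per feeder (EAF1–4)
and per draining vein (EDV1–3, ideal sources in series with their vessel;
zero at baseline), and ECVP (central venous pressure, the pinned vena-cava
outlet and the absolute-pressure reference). A retrograde injection adds its
pressure (10/20/30 mmHg in the standard grid) to the injected DV's EMF with
retrograde polarity; nothing else changes. Temporary balloon occlusion (TBO)
of a feeder removes that edge from the graph and never touches an EMF.

### Stochastic nidus generator

A nidus is organized into C horizontal compartments and K columns:

* C ~ round(Normal(4.5, 1)) truncated by rejection to [3, 6];
  K ~ round(Normal(5, 1)) truncated to [3, 7].
* Each (compartment, column) cell holds a uniform number of nodes — 30–34
  in the end columns, 36–40 in interior columns. Counts are per cell; the
  alternative reading (totals per column split across compartments) is
  available via `NidusParams.counts_per_compartment=False` but produces a
  mean vessel count (~310) far below the ~950–980 of the per-cell reading,
  which matches the reference aggregate targeted by the acceptance check.
* Intracompartmental vessels guarantee every node one incoming vessel from
  the previous column of its compartment and one outgoing vessel to the
  next: first each node draws one predecessor uniformly from the previous
  cell, then any node still lacking an outgoing vessel draws one successor
  uniformly from the next cell.
* Exactly 2·C·K intercompartmental vessels: uniform random start node; end
  compartment uniform over the others; end column a rounded
  Normal(start, 2) redrawn until it lands in [1, K] and differs from the
  start column; end node uniform within the cell.
* A single intranidal fistula of larger radius runs from AF2 through one
  random node of each column of the middle compartment (index ⌈C/2⌉ for
  even C) to DV2.
* Layout: columns at integer x, compartments stacked in y, nodes evenly
  spaced within their cell; AF terminals at x = 0, DV terminals at
  x = K + 1, evenly spread over the stack. First/last-column nodes attach to
  the nearest AF/DV terminal by Euclidean distance (ties to the lower
  index); a terminal left unattached (possible only for a peripheral feeder
  such as AF4) is joined to its nearest intranidal node.

All draws happen in a fixed, documented order from one `numpy` Generator, so
a seed fully determines the architecture. Batch runs give architecture *i*
the seed `master + i`.

### Flow solver

The solver assembles a grounded-Laplacian nodal system in sparse form:
unknown node pressures, pinned aortic-root/vena-cava nodes, series EMFs
moved to the right-hand side. One LU factorization (SuperLU) serves all
pressure sets that share a topology — the 320-set standard grid factors four
topologies (no TBO, AF1, AF2, AF3) and solves 80 right-hand sides each in
one block. Both Kirchhoff laws can be verified post hoc with
`kirchhoff_residuals`, which walks a computed cycle basis (parallel edges
contribute explicit two-edge cycles) and evaluates node imbalance and
Σ(R_v Q − EMF) per cycle; residuals are at machine precision (≤ 1e-9
required, ~1e-12 typical). The test suite additionally checks the solver
against an independent dense least-squares solve of the flow-variable
formulation (one conservation row per node, one voltage row per basis
cycle, one source-path row).

Flows with |Q| < 1e-12 cm³/s are treated as zero wherever a direction is
needed.

### Scenario grids

The standard grid holds 320 pressure sets per architecture: 4 hypotension
levels (systemic mean 74 / 70 / 50 / 25 mmHg for normo / mild / moderate /
profound) × 2 CVP levels (6 / 12 mmHg) × 4 TBO states (none, AF1, AF2, AF3;
AF4 is never occludable) × (no injection + 3 DV sites × 3 injection
pressures). Fine sweeps cover 20–30 mmHg in 1-mmHg steps. Cardiac phases
scale the arterial-side EMFs by ±10 % (diastole −, systole +, intermediate
= mean; the fraction is configurable since intranidal pulse pressure is
shallow); the risk parameter P_min stays fixed at 4 mmHg, the minimum CVP
across the sets.

### Sclerosant filling

Filling is pure reachability on the flow-oriented graph — no transport
physics. During injection (*ingress*), every vessel is oriented by the sign
of its solved flow; an intranidal vessel is filled iff its flow-origin node
is reachable from the injected DV's nidus-boundary junction along
flow-oriented vessels. Traversable edges are the intranidal vessels
(plexiform + fistula), the injected DV's own boundary branches (the way
in), and — only while a feeder's net flow is retrograde or the feeder is
balloon-occluded — that feeder's boundary branches, modelling sclerosant
spilling into a stagnant feeder stump and re-entering through its other
branchlets. Branches of non-injected DVs are pure outflow and never
traversable. After the injection stops (*egress*), flow reverts to the
baseline profile and the set is closed antegradely to a fixed point: a
vessel joins iff its baseline-flow origin node is the head of a vessel
already in the set. Reported filling is the egress-closed set (the ingress
set is also emitted); the percentage denominator is the intranidal vessel
count including the fistula.

Animations replay this frame by frame: one ingress frame per integer mmHg
from 0 to the target, then exit frames in which a vessel is colored iff a
vessel pointing at its entry node was colored in the previous frame, until
the coloring empties or repeats.

### Rupture risk

Each intranidal vessel's exposure pressure P_exp is the magnitude of its
hemodynamic pressure difference R_v·Q (configurable alternative: mean of the
endpoint node pressures). Risk is the normalized logarithm

    Risk = ln(P_exp / P_min) / ln(P_max / P_min) × 100 %

clamped to [0, 100], with P_min = 4 mmHg and P_max = 74 mmHg. The ΔP
reading is the default because it reproduces the reference baseline
maximum-risk aggregate (~32 %) that the acceptance suite checks; the
endpoint-pressure reading would saturate near the feeder pressure and yield
~80 %.

## Default parameter table

The vessel dimension table (`DEFAULT_DIMENSIONS`) is the package's own
construction: trunk vessels use textbook-scale dimensions, and the free
radii (feeders, draining veins, runoff, boundary pedicles, plexiform and
fistula vessels) were calibrated once against the reference baseline
aggregates of this model family — mean total nidal flow ≈ 367 mL/min at
normotension and ≈ 105 mL/min at profound hypotension, a feeder → nidus →
vein pressure cascade of roughly 74 → 45 → 17 → 6 mmHg, and a mean
per-architecture maximum rupture risk ≈ 32 %. Two structural consequences
matter:

* most of the nidus-to-vein drop sits in the draining-vein pedicle branches
  (intranidal pressures remain high, as measured in vivo in AVM nidi);
* the feeder stall pressures scale with systemic pressure through the
  runoff divider, so a 30-mmHg venous injection is sub-threshold at
  normotension but supra-threshold at profound hypotension.

Every entry is overridable through `SimulationConfig` or a YAML file; the
simulation results are meaningful only relative to a stated table.

## What the generator does and does not emulate

The synthetic architectures capture compartmentalization, column-graded
connectivity, a dominant intranidal fistula, stochastic vessel counts
spanning roughly 300–1900, and feeder/vein asymmetry. They do not capture
anatomical tortuosity, vessel tapering, perinidal angiogenesis, flow-related
remodelling, or any biological response to the sclerosant; filling is
reachability, not transport. Passing tests therefore demonstrate internal
consistency of the hemodynamic machinery and reproduction of family-level
aggregates, not patient-level predictive validity.

## Numerical choices

* Sparse LU with shared factorization per topology; batched right-hand
  sides; batched and single solves agree to 1e-12.
* Zero-flow threshold 1e-12 cm³/s for all direction-dependent logic.
* Truncated integer draws by rejection (not clipping), so boundary mass is
  not inflated.
* Euclidean attachment ties break to the lower-index terminal.
* Degenerate inputs raise typed errors (`InvalidGeometryError`,
  `SingularSystemError` for open or disconnected circuits, `ParameterError`
  for bad ranges) rather than returning NaNs.

## Known limitations

* The 20-mmHg injection regime is the model's weakest point: with
  scenario-independent resistances and zero-baseline feeder/vein EMFs, the
  transition between "penetrates partially" and "floods the nidus" is
  softer than the reference aggregates suggest, so intermediate-pressure
  filling is overestimated (and, correspondingly, the incremental benefit
  of feeder occlusion at 20 mmHg is underestimated). Scheduling the nine
  EMF values per scenario — supported by the configuration — is the natural
  refinement.
* Because the injection-adjacent pressure drops fall mostly on the
  boundary pedicle vessels, which are excluded from the intranidal risk
  statistic, mean rupture risk during deep-hypotension injections is near
  zero rather than a small positive percentage.
* Sensitivity analysis perturbs lengths/radii by ±10 % uniformly and
  independently per vessel; correlated (e.g. whole-tree) perturbations are
  not modelled.
* No pulsatile flow, compliance, autoregulation, or sclerosant chemistry.
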