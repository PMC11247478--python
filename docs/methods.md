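# Methods

This note documents the models, conventions and numerical choices behind
`reaxtrack`, and what the synthetic test bed does and does not establish
about real reactive-MD data.

## Input model

The package consumes the LAMMPS `fix reaxff/bonds` text dialect: per frame,
a `# Timestep` comment block followed by one row per atom listing its
neighbours and the fractional bond order to each.  Every bond appears in
both atoms' rows; the parser reconciles the two listings into a single
`(lo, hi)` entry and keeps the value from the lower atom id's row, logging a
warning when the mirror differs by more than 0.05.  This rule is a
convention of this package — dump producers do not document how mirrored
orders can diverge — chosen because it is deterministic and independent of
row order.  Atom ids are 1-based throughout; elements come from a
user-supplied type→element map because the dump stores numeric types only.
Times are kept in femtoseconds internally and printed in picoseconds.

The reference cadence is a 0.25 fs integration step with output every 1000
steps (250 fs), 4000 frames for a 1 ns production run; the ramp protocol is
linear, 300→3500 K over 800 ps (4 K/ps).  Per-frame temperatures are
computed from that schedule rather than read from thermostat output, which
the bonds dialect does not carry.

## Species identification

A pair of atoms is bonded iff its order is **≥** the cutoff (closed bound,
so boundary values count as bonded — documented so results reproduce
bit-for-bit).  Species are connected components, computed with
`scipy.sparse.csgraph` (equivalent to breadth-first traversal; the test
suite checks it against an independent transitive-closure oracle on
hundreds of random frames).  Species identity for counting and ranking is
the canonical Hill formula — carbon first, hydrogen second, the rest
alphabetical, and purely alphabetical when no carbon is present (hence
"H2O", not "OH2").  Structural isomers are therefore pooled; exact atom-id
sets are retained so instances can still be followed individually.

The default cutoff is 0.5.  `cutoff_selection` reproduces the
distinct-species-vs-cutoff analysis that motivates it: distinct formulas
are pooled over every 10th frame per replicate (the sampling stride is a
convention of this package and is configurable), then averaged across
replicates.  Selection is purely count-based — the grid point with minimal
mean, ties toward the smaller cutoff — with manual override; scoring the
chemical plausibility of species is out of scope.

## Lifetime filtering

A species instance is an exact atom-id set; gaining or losing any atom
starts a new instance.  Its lifetime is **cumulative** occupancy over the
whole run (a longest-contiguous-run mode is available behind a flag), and a
formula survives the filter iff at least one instance reaches the
threshold, closed at the boundary: 50 frames × 0.25 ps = 12.5 ps passes,
49 frames does not.  The default threshold of 12.5 ps corresponds to 50
output frames at the reference cadence and is deliberately shared with the
event-persistence rule below.

## Product ranking and intermediates

Prevalence is the mean instance count over the trailing window (default
100 ps), computed per replicate and then averaged across replicates, with
lexicographic tie-breaks; the default report keeps the top 10.  Feed
species (reactant, O₂) are kept by default and can be excluded with a flag.
Intermediates of a product are all species that ever shared at least one
atom with a final product instance, lifetime-filtered, deduplicated by
formula with first/last appearance times.

## Bond events

Labeled reactant bonds are bound to concrete atom pairs by element-labeled
subgraph isomorphism (networkx VF2) against the species partition of the
first frame; molecules already reacted at frame 0 are left unlabeled, with
a warning when the copy count misses the expectation.  For symmetric
molecules the isomorphism is not unique (ring swap, methyl hydrogens); the
first VF2 match with nodes inserted in ascending-id order is used, which is
deterministic for a given frame, and reports can aggregate the primed /
unprimed ring labels.

Order series are discretised at 0.5 and 1.5 — the midpoints of the nominal
orders 0, 1, 2 — into absent/single/double; the lower threshold equals the
species cutoff for consistency.  A state change is committed as an event
only when the new state persists 50 consecutive frames, mirroring the
lifetime filter; this hysteresis keeps bond-order vibration out of the
event stream, at the cost of missing events within 50 frames of the end of
a run.  The event time is the first frame of the new state.  New
(non-template) bonds are found by scanning all frames for pairs above the
state threshold that belong to no template copy and applying the same
persistence rule; a watch list of unordered element pairs can restrict the
report.

## Pathway aggregation

For each final instance of a product, every atom's containing species is
recorded in every frame; the union of those species' atoms is the traced
set, which deliberately includes transient partners (the H atom eliminated
early and captured late belongs to the hydroperoxide's history).  The
instance's sequence is every committed event whose pair intersects the
traced set, time-ordered with lexicographic tie-breaks.  Aggregation
across instances and replicates orders step descriptors by median event
time and attaches a support fraction; for every step pair, the pairwise
precedence majority is computed over co-occurrences, and pairs whose
majority contradicts the median order are reported as conflicts instead of
being forced into a total order.  This formal aggregation replaces
by-inspection pathway identification and is an explicit methodological
choice of this package.

## Degradation onset

Intactness is graph-isomorphism to the reactant template at the operating
cutoff — a formula match is insufficient, since a formula-preserving
rearrangement is no longer the reactant; verdicts are cached per distinct
component edge set, so unreacted copies cost one test per run.  The count
series is fitted by unweighted least squares to a plateau plus shifted
exponential,

    N(T) = N0                      for T <= T0
    N(T) = N0 exp(-(T - T0)/s)     for T >  T0,

with N₀ fixed at the initial count and T₀ initialised at the first drop.
The tail of this curve has no physical meaning — it only reflects the
finite molecule count — but the fit localises where decay begins.  The
reported onset operationalises "first molecule lost": the temperature
where the fitted curve equals N₀ − 1, i.e. T₀ + s·ln(N₀/(N₀−1)).
Replicates are aggregated as arithmetic mean ± sample standard deviation
(undefined below two fits and reported as absent).

Recovery properties, measured by the test suite and the acceptance script:
on noiseless model-generated series the fit returns T₀ to well under 1 K;
under binomial survival noise at N₀ = 50 the three-replicate-mean estimator
carries a systematic error of a few kelvin (bounded below 5 K when averaged
over 20 seeded ensembles), while a single three-replicate mean scatters
with a standard deviation near 6 K — an intrinsic limit of 50-molecule
counting statistics, not of the fit.

## Synthetic trajectories

The generator emulates the reference systems — 50 reactant copies plus 300
O₂ (3200 atoms for the monomer system, 3800 for the dimer), 250 fs frames
over 1 ns — as bond-order book-keeping only: no forces, geometry or
thermostats.  Orders are step functions at scripted event frames plus
Gaussian noise of sd 0.05 (chosen so the 0.5 cutoff separates states by
ten standard deviations; the true noise of a reactive force field is
system-dependent), clipped at zero.  Two transient channels exercise the
filters: flicker bonds with orders in [0.5, 0.7] lasting 1–5 frames, which
briefly fuse species and must be removed by the lifetime filter, and weak
contacts with orders in [0.1, 0.45], invisible at the operating cutoff but
responsible for the low-cutoff rise of the distinct-species curve.  Every
change is recorded in a ground-truth log (species intervals, events,
flickers), exact by construction, against which census, event detection
and pathway recovery are scored.

Scripted mechanism presets cover the three headline products: on the
monomer, ethyl elimination (4A) → ester C–O single-to-double (3A) → C–C
scission (2A) yielding CO₂, and phenolic H loss (1A) → ethyl elimination
(4A) → ethyl–O₂ C–O formation → H–O formation yielding C₂H₆O₂; on the
dimer, phenolic O–H scission (1B/1B′) and side-chain C–O scission (4B/4B′)
followed by HO–H formation yielding H₂O, run on both rings of each
reacting copy.  Scheduled events are spaced ≥ 50 frames so the persistence
rule commits them.  Ramp runs dissociate each intact molecule independently
with the per-frame hazard of the shifted-exponential survival law and break
one uniformly random template bond.

What passing these tests shows — and does not.  The generator's step-function
orders, independent per-bond noise and scripted timing are idealisations:
real trajectories have correlated order fluctuations, recrossing events
slower than 50 frames, genuinely ambiguous near-cutoff bonds and competing
unscripted chemistry.  Ground-truth recovery therefore validates the
book-keeping, thresholds and aggregation logic, not the chemical fidelity
of any particular MD data set; cutoff and persistence defaults should be
re-examined per force field.

## Problem sizes

Default test and acceptance scenarios use scaled boxes (5–8 reactant
copies, 400 frames) for the mechanism analyses, the full 50-copy boxes for
assembly and bond-mapping checks, 200 random ≤ 60-atom frames for the
partition oracle, and 801-point ramps (4 K resolution) for onset recovery;
these sizes were chosen as the smallest that exercise every code path with
unambiguous statistics.
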