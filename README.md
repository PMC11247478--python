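# reaxtrack

Tracking reaction products and pathways in reactive molecular dynamics
output — species census, bond-event detection, pathway reconstruction and
degradation-onset fitting for ReaxFF bond-order trajectories.

## The problem

Reactive MD (ReaxFF) simulations of thermo-oxidation — for example of
modified lignin model compounds such as a hydrogenated/esterified/butylated
monomer C₁₉H₃₀O₃ or the corresponding biphenyl dimer C₂₆H₃₄O₄ in an O₂-rich
box — produce thousands of frames of fractional bond orders for thousands
of atoms.  Turning that into chemistry (which products form, through which
intermediates, by which ordered bond events, and at what temperature
degradation begins) is a data-analysis problem.  `reaxtrack` implements
that analysis, plus a synthetic-trajectory generator with exact ground
truth so every step is testable without running any MD.

## Method

1. **Species identification.**  A frame's atoms are connected wherever the
   bond order *BO ≥ c*; species are the connected components of that graph
   (breadth-first traversal), named by canonical Hill formula.  The
   operating cutoff *c* = 0.5 sits at the minimum of the distinct-species
   vs cutoff curve: below it, weak transient contacts fuse molecules; above
   it, intact molecules fragment (`cutoff-sweep` reproduces the curve).
2. **Lifetime filter.**  A species instance is an exact atom-id set; its
   cumulative lifetime is (frames present) × (frame interval).  Formulas
   whose every instance lives < 12.5 ps (50 frames at 250 fs output) are
   discarded as bond-order flicker.
3. **Product ranking.**  Mean instance count over the trailing 100 ps of
   each run, averaged across replicates; top-10 reported.
4. **Bond events.**  Each labeled reactant bond (1A = phenolic O–H, 2A =
   C–C to the ester carbonyl, 3A = ester C–O, 4A = O–ethyl; 1B–4B and
   primed equivalents on the dimer's two rings) is bound to concrete atoms
   by element-labeled subgraph matching at frame 0 and its order series is
   discretised into states (absent < 0.5 ≤ single < 1.5 ≤ double).  A state
   change becomes a committed event — dissociation, formation,
   single↔double — only after persisting 50 frames (hysteresis).  New
   non-template bonds (e.g. ethyl-C–O, HO–H) are detected the same way.
5. **Pathways.**  Every final product instance is traced backwards through
   the per-frame species partitions; all committed events touching its
   traced atoms form its event sequence.  Sequences are aggregated across
   molecules and replicates into a dominant pathway: steps ordered by
   median event time, each with its support fraction, with pairwise
   precedence conflicts reported rather than hidden.
6. **Degradation onset.**  For linear temperature ramps (300→3500 K at
   4 K/ps) the intact-molecule count *N(T)* — intact meaning graph-isomorphic
   to the reactant template — is fitted by least squares to a plateau with
   shifted-exponential decay, N(T) = N₀ for T ≤ T₀ and
   N₀·exp(−(T−T₀)/s) beyond; the onset is read off where the fitted curve
   equals N₀ − 1 (first molecule lost): T₀ + s·ln(N₀/(N₀−1)).

## Worked example

Generate the packaged monomer scenario (8 copies of C₁₉H₃₀O₃ + 20 O₂,
400 frames at 250 fs; three copies scripted to the carbon-dioxide mechanism
and three to the ethyl-hydroperoxide mechanism), then rank products and
reconstruct a pathway:

```bash
reaxtrack synth trajectory --preset a --frames 400 --seed 11 --out a.bonds
reaxtrack rank --bonds a.bonds --window-ps 25 \
    --exclude-feed C19H30O3 --exclude-feed O2 --out rank.csv
reaxtrack pathways --bonds a.bonds --template A --product C2H6O2 --out pathway.csv
```

prints

```
         C16H25O  3.000
        C17H24O3  3.000
            C2H5  3.000
          C2H6O2  3.000
             CO2  3.000
```

— the three CO₂ and three ethyl-hydroperoxide product molecules, alongside
their co-products (C₁₆H₂₅O and the ethyl radical left by the CO₂ route,
C₁₇H₂₄O₃ left by the hydroperoxide route), each averaged over the final
25 ps — and, for the hydroperoxide pathway,

```
t=   20.50 ps        1A dissociation     support=1.00
t=   35.50 ps        4A dissociation     support=1.00
t=   50.50 ps       C-O formation        support=1.00
t=   65.50 ps       H-O formation        support=1.00
```

i.e. phenolic H loss, ethyl elimination, O₂ capture by the ethyl radical
and H transfer onto the peroxy oxygen — every one of the three product
instances followed that order.  Other subcommands: `census`,
`cutoff-sweep`, `events`, `onset`, and `synth ramp` for temperature-ramp
scenarios with a known onset.

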