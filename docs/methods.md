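# Methods

## The coordinate model

`cvkmap` places a compound entirely by its molecular formula. Three
unitless ratios are derived from the element counts: H:C, O:C, and a
weighted heteroatom ratio

NOPS:C = (14·nN + 16·nO + 31·nP + 32·nS) / (12·nC),

where the weights are **nominal integer masses** (mass numbers), held in
an explicit `MassTable` with defaults H=1, C=12, N=14, O=16, P=31, S=32.
Using mass numbers rather than atomic numbers keeps the metric consistent
with its isotope extension: an isotope-qualified atom (`[13C]`, `D`, `T`,
`[18O]`, …) counts toward its base element's atom tally but contributes
its own mass to the weighted numerator (and, for carbon isotopes, the
denominator). The table is overridable, so exact monoisotopic masses can
be substituted without code changes.

Two consequences of the definition are load-bearing and tested as
invariants: NOPS:C ≥ (16/12)·O:C and NOPS:C ≥ (14/12)·N:C for any
non-isotopic formula (each heteroatom term is nonnegative), and every
ratio is invariant under scaling all counts by a positive integer.

Carbon-free compounds (water, phosphate, ammonia) have no coordinate.
`compute_ratios` raises a typed `CarbonFreeError` rather than returning
infinities; the pathway reader excludes such compounds with a logged
warning and a count in the graph metadata, and treats a reaction edge
touching an excluded compound as an integrity error, since silently
dropping the edge would misrepresent the pathway.

## Formula grammar

The parser accepts Hill-style strings with parenthesized groups
(`Ca(NO3)2`), implicit count 1, isotope brackets (`[13C]6H12O6`) and the
hydrogen shorthands `D`/`T`, underscore and whitespace decoration
(`C_26_H_43_NO_5_`, as markup and model exports produce), and one
trailing charge annotation. The charge rule is deliberately narrow — a
single digit directly before a trailing sign is the charge magnitude
(`Ca2+`, `SO42-`) — because longer digit runs are inherently ambiguous
with element counts; neutral formulas should simply omit the sign.
Hydrate dots and adduct notation (`·H2O`, `[M+H]+`) are rejected so the
grammar stays unambiguous; adduct normalization belongs upstream.
Serialization is Hill notation (C, then H, then alphabetical; pure
alphabetical when carbon-free; isotopes directly after their base
element, lightest first), and parse ∘ serialize is the identity on
element counts — a property the suite tests over a wide random alphabet.

## Polar projection

The angle is a linear map of H:C onto the circle:

theta = theta_origin + direction · 2π · min(hc, hc_max)/hc_max, reduced to [0, 2π).

Defaults: `hc_max = 4.0` (saturated CH4 closes the full turn; biological
H:C distributions lie well inside), `theta_origin = 0` (east),
`direction = +1` (counterclockwise) — the standard mathematical polar
convention, both configurable. A **fixed, data-independent full scale is
essential**: it is what makes the coordinate of a compound identical
across maps and datasets. H:C above the full scale saturates at the
full-scale angle and is flagged (`hc_saturated`) instead of wrapping, so
wrapping can never alias two distinct compounds; note the full-scale
angle itself coincides with the origin after reduction mod 2π, which is
the one unavoidable seam of a closed angular scale. The radius is the
selected ratio (NOPS:C by default, O:C by option), optionally clipped at
`r_max` with a `clipped` flag. The outer boundary circle is `r_max` when
configured, else the maximum radius present.

## Overlap resolution

Isomers ("cohabitant" compounds) share a formula and therefore coincide.
The resolver groups nodes closer than `min_sep · r_max` (transitive
closure of the pairwise test, connected components of the proximity
graph) and fans each cluster symmetrically around its original angle:
members are ordered by compound id, assigned centered offsets
(i − (k−1)/2)·Δφ, where Δφ subtends a chord equal to the separation
threshold at the cluster's smallest radius (inflated by a 1e-9 relative
margin so resolved distances clear the threshold despite rounding).

Properties of this scheme, all asserted in tests:

- **radii are preserved exactly** — only the angle moves, so the radial
  coordinate keeps its chemical meaning;
- a coincident pair moves ±Δφ/2; its angular midpoint is the original
  angle and each displacement is about half the threshold;
- pairwise separation within a resolved cluster is at least the
  threshold; the worst-case per-node displacement grows as
  ceil((k−1)/2) thresholds for k coincident nodes. This growth is
  geometrically unavoidable: points confined to a fixed-radius arc
  within one threshold of a common origin can hold at most three
  mutually separated nodes, so guaranteed separation was chosen over a
  uniform displacement cap — separation is the purpose of the step;
- the procedure is a deterministic function of the layout and config
  (id-sorted processing, no randomness; the `seed` field is reserved for
  pluggable stochastic strategies), so figures are reproducible and
  order-invariant under permutation of the input rows;
- clusters at radius ≈ 0 (pure hydrocarbons on the NOPS:C axis) cannot
  be separated angularly; they are left in place and counted in
  `residual_collisions`, never fatal. The pass iterates up to `max_iter`
  times to absorb knock-on collisions between clusters.

`min_sep` defaults to 0.01 (1 % of the outer radius): small enough to
keep positions chemistry-faithful, large enough to separate default-size
markers at typical figure sizes.

## Rendering

Matplotlib draws the scene; SVG is the canonical output (PNG is a
rasterization of the same scene). Determinism is enforced by a fixed
`svg.hashsalt`, text kept as text, and suppressed Date metadata, making
byte-identity across runs a testable contract. Every artist carries a
stable SVG group id (`node-<compound>`, `edge-<reaction>`,
`label-<compound>`, `boundary`), so tests parse the output rather than
eyeball it. Edges are straight chords between node positions (an
optional curved style is config-gated), with one arrowhead, or two for
reversible reactions. Signed numeric overlays use a diverging palette
with limits symmetric about the zero point (the standard for log fold
changes); categorical overlays map sorted labels onto a discrete
palette. Labels offset radially outward and are suppressed (and counted)
when they would leave the axes. Panels lay out several pathways with one
shared angular convention and one shared boundary radius so positions
are comparable across subplots. Every render returns a `RenderReport`
whose counts reconcile exactly with the input tables
(nodes drawn + carbon-free exclusions = compound rows).

## Synthetic data

The generators produce the structures the projection is designed to
reveal, not simulated measurements:

- **demethylation chains** remove one CH2-equivalent (C−1, H−2) per
  step, the motif of xanthine alkaloid degradation. Whether H:C falls
  along the chain depends on the start (removing CH2 lowers H:C exactly
  when H:C < 2), so the trend is computed and recorded in metadata, never
  assumed.
- **homologous series** add a CH2 unit per member, the fatty-acid
  elongation motif; H:C approaches the polymethylene limit 2
  monotonically from either side (a head at exactly H:C = 2, e.g. a
  saturated fatty acid CnH2nO2, is the fixed point and stays at 2), while
  O:C decreases strictly.
- **random graphs** draw formulas constrained to H ≤ 2C+2 and each
  heteroatom ≤ C — plausible elemental ranges — with seeded, reproducible
  edges; duplicate formulas arise naturally and exercise the resolver.

Two hand-curated demo pathways (caffeine degradation, 14 compounds /
17 reactions; aminosugar–UDP-GlcNAc, 12/12) use textbook formulas and
are labeled illustrative. What passing tests on these fixtures show is
that the geometry, accounting and determinism contracts hold on
realistic topologies; they say nothing about measurement noise,
missing-identification rates, or cofactor conventions in real model
exports (hub metabolites are rendered exactly as supplied — cofactor
filtering is the caller's decision).

## Numerical and design choices

- Ratios are stored at full double precision; 3-decimal rounding is
  display-only (CLI `ratios` default, configurable).
- The weighted-sum numerator and denominator are integer arithmetic with
  a single final division, so the oracle-equivalence test can assert
  exact float equality.
- Angle reduction uses Python's modulo into [0, 2π) with a guard at the
  seam; coordinates of an undisplaced compound are bit-identical across
  graphs, not merely close, and the tests assert `==`.
- Reversible reactions are stored once with a flag and drawn
  double-headed; the default is irreversible.
- Compounds sharing a formula remain distinct nodes (identity matters
  for overlays); coincidence is a layout concern only.
- Duplicate reaction ids are rejected; parallel reactions under distinct
  ids are allowed, as they occur biologically.
- Problem sizes in the test and acceptance runs (200 coordinate probes,
  1000 ratio draws, 500 round-trip formulas, clusters up to k = 10,
  pathways up to ~30 nodes) were chosen as the smallest sizes that
  exercise every contract over a representative range.

## Known limitations

- Coordinates are formula-resolved: stereo- and structural isomers
  coincide by design and are only separated cosmetically. A pie-chart
  composite node for cohabitant molecules would be the structured
  alternative and is left for a future version.
- The density of a global, database-scale map eventually exceeds what a
  static 2-D figure can carry; interactive rendering is out of scope.
- No SBML/genome-scale-model ingestion, stoichiometry, cofactor or
  gene–protein–reaction handling: the two-table format is the contract.
- Label placement has no global overlap optimizer; labels that would
  leave the axes are suppressed and counted instead.
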