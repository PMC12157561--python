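# cvkmap — circular van Krevelen maps for metabolic pathways

Metabolic maps drawn by hand cannot keep up with the scale of modern
metabolomics: genome-scale models hold thousands of compounds and compound
databases hundreds of thousands, and newly discovered metabolites have no
place on a fixed, manually curated chart. `cvkmap` lays pathways out on a
coordinate system computed from chemistry alone, so that **every compound
has a fixed coordinate determined by its molecular formula** — adding a new
metabolite to a map never moves any other node, and two groups drawing the
same pathway get the same picture.

It is aimed at metabolomics and exposomics researchers who need automated,
reproducible pathway figures: pathway maps with reaction arrows, overlays
of differential abundance or dataset-of-origin, and comparable
small-multiple panels.

## The coordinate system

For a formula with atom counts $n_C, n_H, n_N, n_O, n_P, n_S$:

- **H:C ratio** $= n_H / n_C$ — high for saturated aliphatics (→ 2),
  low for aromatics;
- **O:C ratio** $= n_O / n_C$ — the classic van Krevelen y-axis;
- **NOPS:C ratio**, a heteroatom axis weighted by nominal integer masses:

$$\mathrm{NOPS{:}C} = \frac{14\,n_N + 16\,n_O + 31\,n_P + 32\,n_S}{12\,n_C}$$

The weighted ratio spreads biological molecules over a broader range than
O:C, which improves space utilisation, and extends naturally to isotope
labels (a `[13C]` atom counts as carbon but weighs 13).

The **circular map** projects these onto polar coordinates: H:C maps
linearly onto the angle (default full scale H:C = 4, counterclockwise from
east) and NOPS:C (or O:C) is the radius. The outer boundary circle bounds
a constant space, compounds of equal H:C line up on radial spokes that act
as landmarks, and reaction edges become short chords instead of long
connectors. Isomers share a formula and hence a coordinate; a
deterministic resolver fans such collision clusters apart by small angular
offsets that preserve every radius exactly.

## Worked example

The ratios of a single formula (here C26H43NO5):

```python
>>> import cvkmap as cv
>>> r = cv.compute_ratios(cv.parse_formula("C26H43NO5"))
>>> print(f"H:C={r.hc:.3f}  O:C={r.oc:.3f}  NOPS:C={r.nops_c:.3f}")
H:C=1.654  O:C=0.192  NOPS:C=0.301
```

H:C = 43/26 = 1.654 fixes the angle (2π·1.654/4 ≈ 2.598 rad) and
NOPS:C = (1·14 + 5·16)/(26·12) = 0.301 the radius of this compound on
every circular map drawn with the default configuration.

A full pathway map from the bundled caffeine-degradation demo:

```python
>>> from cvkmap import fixtures
>>> g = fixtures.caffeine_demo()
>>> g, _ = cv.attach_overlay(g, fixtures.demo_overlay("caffeine"))
>>> lay = cv.resolve_overlaps(cv.polar_layout(g))
>>> report = cv.render_map(g, lay, out="caffeine.svg")
>>> print(report.nodes_drawn, report.edges_drawn, report.residual_collisions)
14 17 0
```

14 metabolites are drawn with 17 directed reaction arrows; the three
dimethylxanthine isomers (one shared formula C7H8N4O2) were fanned apart
with zero residual collisions, and the overlay colors the recently
identified dihydrourate metabolite differently from the known ones.

The same pipeline from the shell:

```bash
cvkmap demo caffeine --out-dir demo
cvkmap plot demo/caffeine.compounds.tsv demo/caffeine.reactions.tsv --out caffeine.svg
# -> wrote caffeine.svg: 14 nodes, 17 edges, 0 labels
cvkmap ratios formulas.tsv          # (compound_id, formula) -> ratio table
cvkmap layout compounds.tsv reactions.tsv --mode polar --out coords.tsv
```

Input is deliberately plain: a compound table (`id`, `name`, `formula`)
and a reaction table (`id`, `substrate`, `product`[, `reversible`]),
tab-separated with a header row, plus optional overlay tables
(`compound_id`, `value`) holding numbers (diverging palette, symmetric
about zero for signed data) or labels (categorical palette).

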