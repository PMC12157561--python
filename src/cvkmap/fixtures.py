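"""Synthetic pathway generators with the chemistry the maps are built to show.

Three generators cover the structural motifs that make van Krevelen
layouts informative:

* **demethylation chains** — successive loss of a CH2-equivalent (one C,
  two H per step), as in xanthine alkaloid degradation, which walks H:C
  downward step by step;
* **homologous series** — repeated addition of a chain unit (CH2 by
  default), as in fatty acid elongation, which drives H:C monotonically
  toward the CH2 limit of 2 and traces a regular arc on the circular map;
* **random graphs** — seeded, biologically plausible formulas
  (H <= 2C+2, each heteroatom <= C) for property tests.

Two hand-curated demo pathways ship as data: human caffeine degradation
(textbook metabolite formulas; illustrative, not a curated database
export) and an aminosugar/UDP-GlcNAc pathway.  Both emit the same
two-table TSV format the pathway reader consumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .chem import ElementCount
from .pathway import OverlayTable, PathwayGraph, write_pathway

__all__ = [
    "DEMO_NAMES",
    "caffeine_demo",
    "aminosugar_demo",
    "demo_graph",
    "demo_overlay",
    "make_demethylation_chain",
    "make_homologous_series",
    "make_random_graph",
    "write_demo",
]

CH2 = ElementCount({"C": 1, "H": 2})


def make_demethylation_chain(
    start_counts: ElementCount,
    n_steps: int,
    id_prefix: str = "M",
    name: str = "demethylation chain",
) -> PathwayGraph:
    """Chain of n_steps+1 compounds, each losing one C and two H.

    Step i has counts (C - i, H - 2i) relative to the start; edges point
    along degradation.  Whether H:C actually decreases along the chain
    depends on the start composition (removing CH2 lowers H:C exactly when
    the start has H:C < 2), so the trend is computed, never assumed: it is
    recorded in ``metadata['hc_monotone_decreasing']`` together with the
    full H:C sequence.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if start_counts.total("C") < n_steps + 1 or start_counts.total("H") < 2 * n_steps + 1:
        raise ValueError(
            f"start compound lacks {n_steps} removable CH2 units "
            f"(needs C >= {n_steps + 1}, H >= {2 * n_steps + 1})"
        )
    graph = PathwayGraph(metadata={"name": name, "kind": "demethylation_chain"})
    ids = []
    for i in range(n_steps + 1):
        counts = start_counts.subtract({"C": i, "H": 2 * i})
        cid = f"{id_prefix}{i:02d}"
        graph.add_compound(cid, counts, name=f"step {i}")
        ids.append(cid)
    for i in range(n_steps):
        graph.add_reaction(f"R{i:02d}", ids[i], ids[i + 1])
    hc_seq = [graph.get_compound(cid).ratios.hc for cid in ids]
    graph.metadata["hc_sequence"] = hc_seq
    graph.metadata["hc_monotone_decreasing"] = all(
        a > b for a, b in zip(hc_seq, hc_seq[1:])
    )
    return graph


def make_homologous_series(
    head_counts: ElementCount,
    n_members: int,
    unit: ElementCount = CH2,
    id_prefix: str = "S",
    name: str = "homologous series",
) -> PathwayGraph:
    """Series of n_members compounds, member j = head + j*unit, chained
    by elongation edges.  With a CH2 unit, H:C moves monotonically toward
    the polymethylene limit of 2, tracing a regular arc on a polar map.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if unit.total("C") < 1:
        raise ValueError("unit must contain carbon")
    graph = PathwayGraph(metadata={"name": name, "kind": "homologous_series"})
    ids = []
    for j in range(n_members):
        counts = head_counts
        for _ in range(j):
            counts = counts.add(unit)
        cid = f"{id_prefix}{j:02d}"
        graph.add_compound(cid, counts, name=f"member {j}")
        ids.append(cid)
    for j in range(n_members - 1):
        graph.add_reaction(f"E{j:02d}", ids[j], ids[j + 1])
    return graph


def make_random_graph(
    n_compounds: int,
    n_edges: int,
    carbon_range: tuple[int, int] = (2, 30),
    seed: int = 0,
    id_prefix: str = "N",
) -> PathwayGraph:
    """Seeded random pathway over C/H/N/O/P/S with plausible formulas.

    Formulas satisfy 1 <= H <= 2C+2 and each heteroatom count <= C, so
    ratios stay in biologically sensible ranges.  Edges are a uniform
    sample of simple directed pairs (no self-loops); the complete digraph
    is reachable at n_edges = n*(n-1).  Deterministic for a fixed seed.
    Duplicate formulas across compounds are possible and intended — they
    exercise collision resolution.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if n_edges > n_compounds * (n_compounds - 1):
        raise ValueError("n_edges exceeds the simple-digraph maximum")
    rng = np.random.default_rng(seed)
    graph = PathwayGraph(
        metadata={"name": f"random graph (seed {seed})", "kind": "random_graph"}
    )
    ids = [f"{id_prefix}{i:03d}" for i in range(n_compounds)]
    for cid in ids:
        c = int(rng.integers(carbon_range[0], carbon_range[1] + 1))
        counts = {
            "C": c,
            "H": int(rng.integers(1, 2 * c + 3)),
        }
        for elem, p in (("N", 0.5), ("O", 0.8), ("P", 0.15), ("S", 0.15)):
            if rng.random() < p:
                counts[elem] = int(rng.integers(1, max(2, c + 1)))
        graph.add_compound(cid, ElementCount(counts), name=cid)
    pairs = [(i, j) for i in range(n_compounds) for j in range(n_compounds) if i != j]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    for k, idx in enumerate(sorted(int(i) for i in chosen)):
        i, j = pairs[idx]
        graph.add_reaction(f"{id_prefix}R{k:04d}", ids[i], ids[j])
    return graph


# ---------------------------------------------------------------------------
# Hand-curated demo pathways (illustrative textbook chemistry)
# ---------------------------------------------------------------------------

# Human caffeine degradation: trimethylxanthine demethylated/oxidized through
# dimethyl- and monomethylxanthines to xanthine and urates.
_CAFFEINE_COMPOUNDS = [
    ("caffeine", "Caffeine", "C8H10N4O2"),
    ("paraxanthine", "Paraxanthine", "C7H8N4O2"),
    ("theobromine", "Theobromine", "C7H8N4O2"),
    ("theophylline", "Theophylline", "C7H8N4O2"),
    ("mx1", "1-Methylxanthine", "C6H6N4O2"),
    ("mx3", "3-Methylxanthine", "C6H6N4O2"),
    ("mx7", "7-Methylxanthine", "C6H6N4O2"),
    ("xanthine", "Xanthine", "C5H4N4O2"),
    ("mu1", "1-Methyluric acid", "C6H6N4O3"),
    ("dmu17", "1,7-Dimethyluric acid", "C7H8N4O3"),
    ("tmu", "1,3,7-Trimethyluric acid", "C8H10N4O3"),
    ("tmdhu", "1,3,7-Trimethyldihydrouric acid", "C8H12N4O3"),
    ("afmu", "AFMU", "C8H10N4O4"),
    ("urate", "Uric acid", "C5H4N4O3"),
]

_CAFFEINE_REACTIONS = [
    ("r01", "caffeine", "paraxanthine"),
    ("r02", "caffeine", "theobromine"),
    ("r03", "caffeine", "theophylline"),
    ("r04", "caffeine", "tmu"),
    ("r05", "caffeine", "tmdhu"),
    ("r06", "paraxanthine", "mx1"),
    ("r07", "paraxanthine", "mx7"),
    ("r08", "paraxanthine", "afmu"),
    ("r09", "paraxanthine", "dmu17"),
    ("r10", "theobromine", "mx3"),
    ("r11", "theobromine", "mx7"),
    ("r12", "theophylline", "mx1"),
    ("r13", "theophylline", "mx3"),
    ("r14", "mx1", "mu1"),
    ("r15", "mx7", "xanthine"),
    ("r16", "mx3", "xanthine"),
    ("r17", "xanthine", "urate"),
]

# Aminosugar / UDP-GlcNAc biosynthesis with the sialic acid branch.
_AMINOSUGAR_COMPOUNDS = [
    ("glc", "Glucose", "C6H12O6"),
    ("g6p", "Glucose 6-phosphate", "C6H13O9P"),
    ("f6p", "Fructose 6-phosphate", "C6H13O9P"),
    ("glcn6p", "Glucosamine 6-phosphate", "C6H14NO8P"),
    ("glcnac6p", "N-Acetylglucosamine 6-phosphate", "C8H16NO9P"),
    ("glcnac1p", "N-Acetylglucosamine 1-phosphate", "C8H16NO9P"),
    ("udpglcnac", "UDP-N-acetylglucosamine", "C17H27N3O17P2"),
    ("glcnac", "N-Acetylglucosamine", "C8H15NO6"),
    ("glcn", "Glucosamine", "C6H13NO5"),
    ("manac", "N-Acetylmannosamine", "C8H15NO6"),
    ("manac6p", "N-Acetylmannosamine 6-phosphate", "C8H16NO9P"),
    ("neu5ac", "N-Acetylneuraminate", "C11H19NO9"),
]

_AMINOSUGAR_REACTIONS = [
    ("a01", "glc", "g6p"),
    ("a02", "g6p", "f6p", True),
    ("a03", "f6p", "glcn6p"),
    ("a04", "glcn6p", "glcnac6p"),
    ("a05", "glcnac6p", "glcnac1p", True),
    ("a06", "glcnac1p", "udpglcnac"),
    ("a07", "udpglcnac", "glcnac"),
    ("a08", "glcnac", "glcn"),
    ("a09", "udpglcnac", "manac"),
    ("a10", "manac", "manac6p"),
    ("a11", "manac6p", "neu5ac"),
    ("a12", "glcn", "glcn6p"),
]


def _build_demo(name: str, compounds, reactions) -> PathwayGraph:
    from .chem import parse_formula

    graph = PathwayGraph(metadata={"name": name, "kind": "demo"})
    for cid, cname, formula in compounds:
        graph.add_compound(cid, parse_formula(formula), name=cname)
    for rxn in reactions:
        rid, sub, prod = rxn[:3]
        reversible = bool(rxn[3]) if len(rxn) > 3 else False
        graph.add_reaction(rid, sub, prod, reversible)
    return graph


def caffeine_demo() -> PathwayGraph:
    """Human caffeine degradation pathway (14 compounds, 17 reactions)."""
    return _build_demo("Caffeine metabolism", _CAFFEINE_COMPOUNDS, _CAFFEINE_REACTIONS)


def aminosugar_demo() -> PathwayGraph:
    """Aminosugar / UDP-GlcNAc pathway (12 compounds, 12 reactions)."""
    return _build_demo(
        "Aminosugar metabolism", _AMINOSUGAR_COMPOUNDS, _AMINOSUGAR_REACTIONS
    )


def fatty_acid_series_demo() -> PathwayGraph:
    """Fatty-acid elongation series from a C12 head, 8 members."""
    graph = make_homologous_series(
        ElementCount({"C": 12, "H": 24, "O": 2}),
        n_members=8,
        id_prefix="FA",
        name="Fatty acid elongation",
    )
    return graph


DEMO_NAMES = ("caffeine", "aminosugar", "fatty-acids")

_DEMOS = {
    "caffeine": caffeine_demo,
    "aminosugar": aminosugar_demo,
    "fatty-acids": fatty_acid_series_demo,
}


def demo_graph(name: str) -> PathwayGraph:
    """Named demo pathway; names in :data:`DEMO_NAMES`."""
    try:
        return _DEMOS[name]()
    except KeyError:
        raise ValueError(f"unknown demo {name!r}; choose from {DEMO_NAMES}") from None


def demo_overlay(name: str) -> OverlayTable:
    """Illustrative overlay for a demo: highlights the recently identified
    dihydrourate metabolite on the caffeine map; a signed fold-change-style
    overlay elsewhere."""
    if name == "caffeine":
        values: dict[str, float | str] = {
            cid: "known" for cid, _, _ in _CAFFEINE_COMPOUNDS
        }
        values["tmdhu"] = "new"
        return OverlayTable(values=values)
    graph = demo_graph(name)
    ids = graph.compound_ids
    return OverlayTable(
        values={cid: float(i - len(ids) // 2) for i, cid in enumerate(ids)}
    )


def write_demo(name: str, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a demo pathway as (compounds.tsv, reactions.tsv) under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cpath = out_dir / f"{name}.compounds.tsv"
    rpath = out_dir / f"{name}.reactions.tsv"
    write_pathway(demo_graph(name), cpath, rpath)
    return cpath, rpath
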