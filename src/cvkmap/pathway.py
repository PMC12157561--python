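"""Pathway graphs: compounds as nodes, reactions as directed edges.

The input format is deliberately minimal — two tab-separated tables, one of
compounds (id, name, formula) and one of reactions (id, substrate, product
[, reversible]) — so that any pathway source (a genome-scale model export,
a hand-written table, a fixture generator) can feed the layout engine.
Carbon-free compounds (water, phosphate, ...) have no van Krevelen
coordinate and are excluded on read with a logged warning; an edge touching
an excluded compound is an integrity error, surfacing the exclusion rather
than silently dropping the reaction.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .chem import (
    CarbonFreeError,
    ElementCount,
    FormulaError,
    MassTable,
    RatioSet,
    compute_ratios,
    parse_formula,
    to_hill_notation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "FormatError",
    "IntegrityError",
    "MergeError",
    "OverlayReport",
    "OverlayTable",
    "PathwayError",
    "PathwayGraph",
    "Reaction",
    "attach_overlay",
    "merge_graphs",
    "origin_overlay",
    "read_overlay",
    "read_pathway",
    "write_pathway",
]


class PathwayError(ValueError):
    """Base class for pathway construction and I/O errors."""


class FormatError(PathwayError):
    """An input table is missing required columns or is malformed."""


class IntegrityError(PathwayError):
    """Referential integrity violated (dangling endpoints, duplicates)."""


class MergeError(PathwayError):
    """Two graphs disagree about a shared compound id."""


@dataclass(frozen=True)
class Compound:
    id: str
    counts: ElementCount
    ratios: RatioSet
    name: str = ""

    @property
    def formula(self) -> str:
        return to_hill_notation(self.counts)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrate_id: str
    product_id: str
    reversible: bool = False


class PathwayGraph:
    """A validated directed graph of compounds and reactions.

    Invariants maintained by construction: unique compound and reaction
    ids, both reaction endpoints resolve to compounds, no self-loops, and
    every compound carries ratios computed with the graph's mass table.
    """

    def __init__(
        self,
        masses: MassTable | None = None,
        metadata: dict | None = None,
    ):
        self.masses = masses if masses is not None else MassTable()
        self.metadata: dict = dict(metadata or {})
        self._compounds: dict[str, Compound] = {}
        self._reactions: dict[str, Reaction] = {}
        #: compound id -> overlay value (numeric or categorical), see attach_overlay
        self.overlay: dict[str, float | str] = {}
        #: compound/reaction id -> dataset-of-origin labels, set by merge_graphs
        self.origin: dict[str, tuple[str, ...]] = {}
        self.edge_origin: dict[str, tuple[str, ...]] = {}

    # -- construction -------------------------------------------------------

    def add_compound(
        self, compound_id: str, counts: ElementCount, name: str = ""
    ) -> Compound:
        compound_id = str(compound_id)
        if compound_id in self._compounds:
            raise IntegrityError(f"duplicate compound id {compound_id!r}")
        ratios = compute_ratios(counts, self.masses)  # CarbonFreeError propagates
        compound = Compound(id=compound_id, counts=counts, ratios=ratios, name=name)
        self._compounds[compound_id] = compound
        return compound

    def add_reaction(
        self,
        reaction_id: str,
        substrate_id: str,
        product_id: str,
        reversible: bool = False,
    ) -> Reaction:
        reaction_id = str(reaction_id)
        if reaction_id in self._reactions:
            raise IntegrityError(f"duplicate reaction id {reaction_id!r}")
        if substrate_id == product_id:
            raise IntegrityError(
                f"reaction {reaction_id!r} is a self-loop on {substrate_id!r}"
            )
        dangling = [e for e in (substrate_id, product_id) if e not in self._compounds]
        if dangling:
            raise IntegrityError(
                f"reaction {reaction_id!r} references unknown compounds: {dangling}"
            )
        reaction = Reaction(
            id=reaction_id,
            substrate_id=str(substrate_id),
            product_id=str(product_id),
            reversible=bool(reversible),
        )
        self._reactions[reaction_id] = reaction
        return reaction

    # -- access --------------------------------------------------------------

    @property
    def compounds(self) -> list[Compound]:
        return [self._compounds[cid] for cid in sorted(self._compounds)]

    @property
    def reactions(self) -> list[Reaction]:
        return [self._reactions[rid] for rid in sorted(self._reactions)]

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self._compounds)

    def get_compound(self, compound_id: str) -> Compound:
        return self._compounds[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._compounds

    def __len__(self) -> int:
        return len(self._compounds)

    @property
    def n_reactions(self) -> int:
        return len(self._reactions)

    def copy(self) -> "PathwayGraph":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Re-check referential integrity; raises IntegrityError on violation."""
        offenders = []
        for rxn in self._reactions.values():
            for endpoint in (rxn.substrate_id, rxn.product_id):
                if endpoint not in self._compounds:
                    offenders.append((rxn.id, endpoint))
            if rxn.substrate_id == rxn.product_id:
                offenders.append((rxn.id, "self-loop"))
        if offenders:
            raise IntegrityError(f"integrity violations: {offenders}")

    def to_networkx(self) -> nx.DiGraph:
        """Export as a networkx DiGraph with compound/reaction attributes."""
        g = nx.DiGraph(**self.metadata)
        for c in self.compounds:
            g.add_node(
                c.id,
                name=c.name,
                formula=c.formula,
                hc=c.ratios.hc,
                oc=c.ratios.oc,
                nc=c.ratios.nc,
                nops_c=c.ratios.nops_c,
            )
        for r in self.reactions:
            g.add_edge(
                r.substrate_id, r.product_id, reaction_id=r.id, reversible=r.reversible
            )
        return g


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y"}


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: cannot read table ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return df.fillna("")


def read_pathway(
    compound_table: str | Path,
    reaction_table: str | Path,
    masses: MassTable | None = None,
) -> PathwayGraph:
    """Read a pathway from compound and reaction TSV tables.

    The compound table needs columns (id, name, formula); the reaction
    table (id, substrate, product) with an optional ``reversible`` column.
    Carbon-free compounds are excluded with a warning; the exclusion count
    and ids are recorded in ``graph.metadata``.  Reactions referencing
    unknown (or excluded) compounds raise :class:`IntegrityError` listing
    every offender.
    """
    cdf = _read_table(compound_table, {"id", "name", "formula"})
    rdf = _read_table(reaction_table, {"id", "substrate", "product"})

    graph = PathwayGraph(masses=masses)
    excluded: list[str] = []
    for i, rec in enumerate(cdf.itertuples(index=False), start=2):
        try:
            counts = parse_formula(rec.formula)
        except FormulaError as exc:
            raise FormatError(
                f"{compound_table}, line {i}: compound {rec.id!r}: {exc}"
            ) from exc
        try:
            graph.add_compound(rec.id, counts, name=rec.name)
        except CarbonFreeError:
            logger.warning(
                "excluding carbon-free compound %r (%s)", rec.id, rec.formula
            )
            excluded.append(str(rec.id))
    graph.metadata["carbon_free_excluded"] = len(excluded)
    graph.metadata["excluded_ids"] = excluded
    graph.metadata["compound_rows"] = len(cdf)

    dangling: list[tuple[str, str]] = []
    for i, rec in enumerate(rdf.itertuples(index=False), start=2):
        reversible = (
            str(getattr(rec, "reversible", "")).strip().lower() in _TRUTHY
        )
        for endpoint in (rec.substrate, rec.product):
            if endpoint not in graph:
                dangling.append((str(rec.id), str(endpoint)))
        if any(d[0] == str(rec.id) for d in dangling):
            continue
        try:
            graph.add_reaction(rec.id, rec.substrate, rec.product, reversible)
        except IntegrityError as exc:
            raise IntegrityError(f"{reaction_table}, line {i}: {exc}") from exc
    if dangling:
        notes = [
            f"{rid} -> {cid}" + (" (excluded carbon-free)" if cid in excluded else "")
            for rid, cid in dangling
        ]
        raise IntegrityError(
            f"{reaction_table}: reactions reference unknown compounds: {notes}"
        )
    return graph


def write_pathway(
    graph: PathwayGraph,
    compound_table: str | Path,
    reaction_table: str | Path,
) -> None:
    """Write a graph back to the two-table TSV format (UTF-8, header row)."""
    pd.DataFrame(
        [{"id": c.id, "name": c.name, "formula": c.formula} for c in graph.compounds]
    ).to_csv(compound_table, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "substrate": r.substrate_id,
                "product": r.product_id,
                "reversible": int(r.reversible),
            }
            for r in graph.reactions
        ],
        columns=["id", "substrate", "product", "reversible"],
    ).to_csv(reaction_table, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Overlays
# ---------------------------------------------------------------------------


@dataclass
class OverlayTable:
    """Per-compound annotation: numeric (fold change) or categorical labels."""

    values: dict[str, float | str] = field(default_factory=dict)

    @property
    def is_numeric(self) -> bool:
        return bool(self.values) and all(
            isinstance(v, (int, float)) and not isinstance(v, bool)
            for v in self.values.values()
        )


def read_overlay(path: str | Path) -> OverlayTable:
    """Read a (compound_id, value) TSV; numeric detection is by parse."""
    df = _read_table(path, {"compound_id", "value"})
    values: dict[str, float | str] = {}
    for rec in df.itertuples(index=False):
        raw = str(rec.value).strip()
        try:
            values[str(rec.compound_id)] = float(raw)
        except ValueError:
            values[str(rec.compound_id)] = raw
    return OverlayTable(values=values)


@dataclass
class OverlayReport:
    matched: int
    unmatched_keys: list[str]
    unannotated_ids: list[str]

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched_keys)


def attach_overlay(
    graph: PathwayGraph, overlay: OverlayTable
) -> tuple[PathwayGraph, OverlayReport]:
    """Attach overlay values to a copy of the graph; mismatches are reported.

    Unmatched overlay keys and unannotated compounds are counted, never
    silently dropped.  Values keep their sign and magnitude exactly.
    """
    if not overlay.values:
        raise ValueError("overlay is empty")
    annotated = graph.copy()
    matched = {k: v for k, v in overlay.values.items() if k in annotated}
    unmatched = sorted(k for k in overlay.values if k not in annotated)
    annotated.overlay.update(matched)
    report = OverlayReport(
        matched=len(matched),
        unmatched_keys=unmatched,
        unannotated_ids=sorted(set(annotated.compound_ids) - set(annotated.overlay)),
    )
    annotated.metadata["overlay_unmatched"] = len(unmatched)
    if unmatched:
        logger.warning("overlay keys not found in graph: %s", unmatched)
    return annotated, report


# ---------------------------------------------------------------------------
# Merging pathways (comparative maps)
# ---------------------------------------------------------------------------


def _labels_for(graph: PathwayGraph, registry: dict, key: str, default: str):
    return registry.get(key, (default,))


def merge_graphs(
    a: PathwayGraph,
    b: PathwayGraph,
    label_a: str = "a",
    label_b: str = "b",
) -> PathwayGraph:
    """Union of two pathways with dataset-of-origin labels on every element.

    Compounds sharing an id must agree on the formula (else
    :class:`MergeError`); the shared node carries both labels.  Reactions
    sharing an id must agree on endpoints.  Graphs already carrying origin
    labels (from a previous merge) keep them, so merging is associative up
    to label sets.
    """
    if a.masses != b.masses:
        raise MergeError("cannot merge graphs with different mass tables")
    merged = PathwayGraph(masses=a.masses)
    merged.metadata["merged_from"] = (label_a, label_b)

    for graph, label in ((a, label_a), (b, label_b)):
        for comp in graph.compounds:
            labels = _labels_for(graph, graph.origin, comp.id, label)
            if comp.id in merged:
                existing = merged.get_compound(comp.id)
                if existing.counts != comp.counts:
                    raise MergeError(
                        f"compound {comp.id!r} has conflicting formulas: "
                        f"{existing.formula} vs {comp.formula}"
                    )
                merged.origin[comp.id] = tuple(
                    sorted(set(merged.origin[comp.id]) | set(labels))
                )
            else:
                merged.add_compound(comp.id, comp.counts, name=comp.name)
                merged.origin[comp.id] = tuple(sorted(set(labels)))
        for rxn in graph.reactions:
            labels = _labels_for(graph, graph.edge_origin, rxn.id, label)
            if rxn.id in {r.id for r in merged.reactions}:
                existing = next(r for r in merged.reactions if r.id == rxn.id)
                if (existing.substrate_id, existing.product_id) != (
                    rxn.substrate_id,
                    rxn.product_id,
                ):
                    raise MergeError(
                        f"reaction {rxn.id!r} has conflicting endpoints"
                    )
                merged.edge_origin[rxn.id] = tuple(
                    sorted(set(merged.edge_origin[rxn.id]) | set(labels))
                )
            else:
                merged.add_reaction(
                    rxn.id, rxn.substrate_id, rxn.product_id, rxn.reversible
                )
                merged.edge_origin[rxn.id] = tuple(sorted(set(labels)))
        merged.overlay.update(graph.overlay)
    return merged


def origin_overlay(graph: PathwayGraph) -> OverlayTable:
    """Categorical overlay from merge origin labels ('a', 'b', 'a+b')."""
    return OverlayTable(
        values={cid: "+".join(labels) for cid, labels in sorted(graph.origin.items())}
    )
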