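"""Compartment-profile ranking of candidates from MITAB-style interaction
tables and gene->compartment annotation sets."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import networkx as nx
import pandas as pd

__all__ = ["InteractionGraph", "parse_interactions", "load_annotations",
           "EnrichmentProfile", "interactor_profile", "screen_baseline"]

_ALIAS_RE = re.compile(r"^[\w .\-/]+:(?P<value>[^(|]+)")


@dataclass
class InteractionGraph:
    """Simple undirected gene graph with parse bookkeeping."""

    graph: nx.Graph
    n_duplicates: int = 0
    n_self_loops: int = 0
    n_malformed: int = 0

    @property
    def nodes(self) -> List[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> List[tuple]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def neighbors(self, gene: str) -> Set[str]:
        return set(self.graph.neighbors(gene)) if gene in self.graph else set()


def _symbol_from_field(field: str) -> str | None:
    """First usable gene symbol from a MITAB identifier/alias field.

    Fields look like ``entrez gene/locuslink:TP53(gene name)|...``; the
    first alias whose value is non-numeric wins, otherwise the first value.
    """
    if not field or field == "-":
        return None
    first_value = None
    for part in field.split("|"):
        m = _ALIAS_RE.match(part.strip())
        if not m:
            continue
        value = m.group("value").strip().strip('"')
        if not value:
            continue
        if first_value is None:
            first_value = value
        if not value.isdigit():
            return value.upper()
    return first_value.upper() if first_value else None


def _row_symbols(cols: Sequence[str]) -> tuple:
    """(gene_a, gene_b) for one MITAB row, preferring alias columns 4/5,
    then alt-id columns 2/3, then the primary identifiers."""
    for ia, ib in ((4, 5), (2, 3), (0, 1)):
        if len(cols) > ib:
            a = _symbol_from_field(cols[ia])
            b = _symbol_from_field(cols[ib])
            if a and b and not (a.isdigit() or b.isdigit()):
                return a, b
    if len(cols) >= 2:
        return _symbol_from_field(cols[0]), _symbol_from_field(cols[1])
    return None, None


def parse_interactions(source) -> InteractionGraph:
    """Parse a MITAB-style TSV into a simple undirected graph.

    ``source`` is a path or an iterable of lines.  Duplicate edges
    (A-B == B-A) are merged, self-loops dropped, malformed rows skipped;
    counts of each are kept on the returned graph.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = list(source)

    g = nx.Graph()
    n_dup = n_self = n_bad = 0
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            n_bad += 1
            continue
        a, b = _row_symbols(cols)
        if not a or not b:
            n_bad += 1
            continue
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed interaction rows")
    return InteractionGraph(graph=g, n_duplicates=n_dup, n_self_loops=n_self,
                            n_malformed=n_bad)


def load_annotations(source) -> Dict[str, Set[str]]:
    """compartment<TAB>gene TSV -> {compartment: set of genes} (symbols
    uppercased)."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    out: Dict[str, Set[str]] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        comp, gene = line.split("\t")[:2]
        out.setdefault(comp, set()).add(gene.upper())
    return out


@dataclass
class EnrichmentProfile:
    candidate: str
    n_interactors: int
    pct_per_compartment: Dict[str, float] = dc_field(default_factory=dict)
    baseline_pct: Dict[str, float] = dc_field(default_factory=dict)
    flagged: bool = False

    def to_row(self) -> Dict:
        row = {"candidate": self.candidate,
               "n_interactors": self.n_interactors, "flagged": self.flagged}
        row.update({f"pct_{c}": v for c, v in self.pct_per_compartment.items()})
        return row


def interactor_profile(graph: InteractionGraph, candidate: str,
                       annotations: Mapping[str, Iterable[str]],
                       ) -> EnrichmentProfile:
    """Percentage of the candidate's direct interactors annotated to each
    compartment.  Candidates absent from the graph (or with degree 0) are
    flagged with no percentages."""
    candidate = candidate.upper()
    interactors = graph.neighbors(candidate)
    if not interactors:
        warnings.warn(f"candidate {candidate!r} has no interactors; "
                      "profile undefined")
        return EnrichmentProfile(candidate=candidate, n_interactors=0,
                                 flagged=True)
    pct = {}
    for comp, genes in annotations.items():
        genes = {g.upper() for g in genes}
        pct[comp] = 100.0 * len(interactors & genes) / len(interactors)
    return EnrichmentProfile(candidate=candidate,
                             n_interactors=len(interactors),
                             pct_per_compartment=pct)


def screen_baseline(graph: InteractionGraph, screened_genes: Sequence[str],
                    annotations: Mapping[str, Iterable[str]],
                    ) -> Dict[str, float]:
    """Unweighted mean of per-gene compartment percentages over all
    screened genes with at least one interactor."""
    profiles = []
    for gene in screened_genes:
        if graph.degree(gene.upper()) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profiles.append(interactor_profile(graph, gene, annotations))
    if not profiles:
        raise ValueError("no screened gene has any interactors")
    comps = sorted({c for p in profiles for c in p.pct_per_compartment})
    return {c: float(pd.Series([p.pct_per_compartment.get(c, 0.0)
                                for p in profiles]).mean())
            for c in comps}
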