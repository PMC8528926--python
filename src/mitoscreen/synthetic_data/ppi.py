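"""Random PPI testbeds with brute-force-recomputable compartment profiles."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

__all__ = ["PPITestbed", "generate_ppi_testbed", "testbed_to_mitab",
           "testbed_annotation_tsv"]


@dataclass
class PPITestbed:
    edges: List[Tuple[str, str]]
    annotations: Dict[str, Set[str]]          # gene -> compartment labels
    planted_profiles: Dict[str, Dict[str, float]]  # gene -> compartment -> %

    def compartment_sets(self) -> Dict[str, Set[str]]:
        """Invert gene->compartments into compartment->genes (the
        orientation the profiling code consumes)."""
        out: Dict[str, Set[str]] = {}
        for gene, comps in self.annotations.items():
            for c in comps:
                out.setdefault(c, set()).add(gene)
        return out

    @property
    def genes(self) -> List[str]:
        seen = []
        for a, b in self.edges:
            for g in (a, b):
                if g not in seen:
                    seen.append(g)
        return seen


def _brute_profiles(edges, annotations) -> Dict[str, Dict[str, float]]:
    neigh: Dict[str, Set[str]] = {}
    for a, b in edges:
        neigh.setdefault(a, set()).add(b)
        neigh.setdefault(b, set()).add(a)
    compartments = sorted({c for s in annotations.values() for c in s})
    profiles = {}
    for g, ns in neigh.items():
        if not ns:
            continue
        profiles[g] = {
            c: 100.0 * sum(1 for n in ns if c in annotations.get(n, set())) / len(ns)
            for c in compartments
        }
    return profiles


def generate_ppi_testbed(
    n_genes: int,
    n_edges: int,
    compartments: Sequence[str],
    seed: int,
    annotation_prob: float = 0.3,
) -> PPITestbed:
    """Simple undirected random graph plus random compartment sets.

    ``planted_profiles`` are computed by brute-force neighbour counting, so
    any downstream profiling code can be checked against them exactly.
    """
    max_edges = n_genes * (n_genes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_genes} genes (max {max_edges})")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    chosen: Set[Tuple[int, int]] = set()
    while len(chosen) < n_edges:
        i, j = rng.integers(0, n_genes, size=2)
        if i == j:
            continue
        chosen.add((min(i, j), max(i, j)))
    edges = sorted((genes[i], genes[j]) for i, j in sorted(chosen))
    annotations = {
        g: {c for c in compartments if rng.random() < annotation_prob}
        for g in genes
    }
    return PPITestbed(edges=edges, annotations=annotations,
                      planted_profiles=_brute_profiles(edges, annotations))


def testbed_to_mitab(testbed: PPITestbed) -> str:
    """Serialize edges as a minimal MITAB 2.5-style table (15 columns)."""
    buf = io.StringIO()
    for a, b in testbed.edges:
        cols = [f"entrez gene/locuslink:{hash(a) % 99999}",
                f"entrez gene/locuslink:{hash(b) % 99999}",
                f"biogrid:{a}", f"biogrid:{b}",
                f"entrez gene/locuslink:{a}(gene name)",
                f"entrez gene/locuslink:{b}(gene name)"]
        cols += ["-"] * 9
        buf.write("\t".join(cols) + "\n")
    return buf.getvalue()


def testbed_annotation_tsv(testbed: PPITestbed) -> str:
    lines = []
    for gene in sorted(testbed.annotations):
        for comp in sorted(testbed.annotations[gene]):
            lines.append(f"{comp}\t{gene}")
    return "\n".join(lines) + ("\n" if lines else "")
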