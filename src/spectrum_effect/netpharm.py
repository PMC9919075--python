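"""Offline network statistics for the target-prediction stage.

Consumes user-supplied exports (target id lists, protein-protein
interaction edge lists, term-membership tables) as delimited text and
computes: target-set intersection with Venn counts, interaction-graph
degree statistics and rankings, hypergeometric term enrichment with
Benjamini-Hochberg correction, and assembly of the
component-target-pathway-disease network.  No live database is queried.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TargetSets",
    "intersect_targets",
    "graph_stats",
    "top_degree",
    "hypergeom_enrich",
    "build_ctpd_network",
    "read_id_set",
    "read_edge_list",
    "read_term_membership",
    "write_sif",
]


def _norm(ids: Iterable[str]) -> set[str]:
    return {str(i).strip() for i in ids if str(i).strip()}


@dataclass(frozen=True)
class TargetSets:
    """Drug-target and disease-target sets with their intersection."""

    drug_targets: frozenset[str]
    disease_targets: frozenset[str]

    @property
    def intersection(self) -> frozenset[str]:
        return self.drug_targets & self.disease_targets

    @property
    def venn_counts(self) -> tuple[int, int, int]:
        """(drug-only, disease-only, both)."""
        both = len(self.intersection)
        return (len(self.drug_targets) - both, len(self.disease_targets) - both, both)


def intersect_targets(drug: Iterable[str], disease: Iterable[str]) -> TargetSets:
    """Normalized (case/whitespace-trimmed) set intersection with Venn counts."""
    d, s = _norm(drug), _norm(disease)
    import warnings

    if not d or not s:
        warnings.warn("empty input target set: intersection is empty")
    return TargetSets(frozenset(d), frozenset(s))


def graph_stats(g: nx.Graph) -> dict:
    """Node/edge counts, degree map and average degree (2E/N, 1 decimal)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n, e = g.number_of_nodes(), g.number_of_edges()
    avg = 2 * e / n
    return {
        "n_nodes": n,
        "n_edges": e,
        "degree": dict(g.degree()),
        "average_degree": avg,
        "average_degree_1dp": round(avg, 1),
    }


def top_degree(g: nx.Graph, k: int) -> list[str]:
    """Top-k nodes by degree, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g.number_of_nodes():
        import warnings

        warnings.warn(f"k={k} exceeds node count {g.number_of_nodes()}; returning all nodes")
        k = g.number_of_nodes()
    ordered = sorted(g.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    return [str(n) for n, _ in ordered[:k]]


def hypergeom_enrich(
    study: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    use_adjusted: bool = True,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH correction.

    For each term of size K in a universe of size N, with study size n
    and k study hits, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    Rows are sorted by ascending p; by default only terms with adjusted
    p below ``alpha`` are kept (set ``use_adjusted=False`` to filter on
    the raw p, ``keep_all=True`` to disable filtering).
    """
    uni = _norm(universe)
    stu = _norm(study)
    offenders = sorted(stu - uni)
    if offenders:
        raise ValueError(f"study ids outside the universe: {offenders}")
    N, n = len(uni), len(stu)
    rows = []
    for term, members in terms.items():
        mem = _norm(members)
        if not mem <= uni:
            raise ValueError(f"term {term!r} has members outside the universe")
        K = len(mem)
        k = len(mem & stu)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    if not keep_all:
        key = "p_adj" if use_adjusted else "p"
        df = df[df[key] < alpha].reset_index(drop=True)
    return df


def build_ctpd_network(
    component: str,
    targets: Iterable[str],
    degree: Mapping[str, int],
    enrichment: pd.DataFrame,
    pathway_members: Mapping[str, Iterable[str]],
    pathway_diseases: Mapping[str, Iterable[str]] | None = None,
    top_pathways: int = 20,
) -> nx.Graph:
    """Component-target-pathway-disease network.

    Keeps targets whose interaction degree is strictly above the average
    degree, and the ``top_pathways`` enriched pathways by ascending p.
    Edges: component-target; target-pathway (membership);
    pathway-disease (supplied map).  Node attribute ``kind`` is one of
    component/target/pathway/disease.
    """
    import warnings

    targets = _norm(targets)
    if not degree:
        raise ValueError("empty degree map")
    avg = sum(degree.values()) / len(degree)
    selected = sorted(t for t in targets if degree.get(t, 0) > avg)
    if enrichment.empty:
        chosen_paths: list[str] = []
    else:
        chosen_paths = list(enrichment.sort_values(["p", "term"], kind="mergesort")["term"].head(top_pathways))

    g = nx.Graph()
    g.add_node(component, kind="component")
    for t in selected:
        g.add_node(t, kind="target")
        g.add_edge(component, t)
    members = {p: _norm(m) for p, m in pathway_members.items()}
    for p in chosen_paths:
        g.add_node(p, kind="pathway")
        mem = members.get(p)
        if mem is None:
            warnings.warn(f"no membership annotation for pathway {p!r}")
            continue
        for t in selected:
            if t in mem:
                g.add_edge(t, p)
    for p in chosen_paths:
        for d in _norm((pathway_diseases or {}).get(p, ())):
            g.add_node(d, kind="disease")
            g.add_edge(p, d)
    return g


# ---------------------------------------------------------------------------
# delimited-text IO

def read_id_set(path: str | Path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_edge_list(path: str | Path, sep: str = "\t") -> nx.Graph:
    """Two-column tab-delimited edge list -> simple undirected graph
    (self-loops and duplicate edges dropped)."""
    g = nx.Graph()
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    for a, b in df.iloc[:, :2].itertuples(index=False):
        a, b = str(a).strip(), str(b).strip()
        if a and b and a != b:
            g.add_edge(a, b)
    return g


def read_term_membership(path: str | Path, sep: str = "\t") -> dict[str, set[str]]:
    """term-id, member-id pairs -> term -> member-set map."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    out: dict[str, set[str]] = {}
    for t, m in df.iloc[:, :2].itertuples(index=False):
        out.setdefault(str(t).strip(), set()).add(str(m).strip())
    return out


def write_sif(g: nx.Graph, path: str | Path, relation: str = "link") -> None:
    """Simple interaction format: source relation target, one edge per line."""
    lines = [f"{a}\t{relation}\t{b}" for a, b in sorted(map(lambda e: tuple(map(str, e)), g.edges()))]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export (node attributes such as ``kind`` are preserved)."""
    nx.write_graphml(g, str(path))
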