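"""Feature-based MS/MS molecular networking.

Spectral similarity is the *modified cosine*: fragment ions of two
precursors are matched either at equal m/z or offset by the precursor
m/z difference (so a homolog's shifted fragment series still aligns),
each peak participates in at most one matched pair, and the cosine is
computed on (by default square-root transformed) intensities.  Edges
require a minimum score and minimum number of matched fragment ions, and
each node keeps at most ``max_neighbors`` neighbours (an edge survives
only if it ranks in the top-k of BOTH endpoints).  The graph exports to
GraphML for Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .spectra import FragmentSpectrum

__all__ = [
    "SimilarityResult",
    "NetworkEdge",
    "modified_cosine",
    "build_network",
    "export_graphml",
    "export_edge_table",
    "export_node_table",
]


@dataclass(frozen=True)
class SimilarityResult:
    """Modified-cosine score between two spectra."""

    score: float
    n_matched: int
    pairs: Tuple[Tuple[int, int], ...] = ()


@dataclass(frozen=True)
class NetworkEdge:
    a: str
    b: str
    score: float
    n_matched: int


def _weights(intensity: np.ndarray, transform: str) -> np.ndarray:
    if transform == "sqrt":
        return np.sqrt(intensity)
    if transform == "raw":
        return intensity.astype(float)
    raise ValueError(f"unknown intensity transform: {transform!r}")


def modified_cosine(
    a: FragmentSpectrum,
    b: FragmentSpectrum,
    tol_ppm: float = 5.0,
    tol_da: float = 0.003,
    transform: str = "sqrt",
) -> SimilarityResult:
    """Modified cosine with precursor-shifted fragment matching.

    Candidate pairs (i, j) satisfy |mz_i - mz_j| <= tol OR
    |(mz_i - mz_j) - (prec_a - prec_b)| <= tol, with tol =
    max(``tol_ppm`` at the larger fragment m/z, ``tol_da``).  A pair
    satisfying both conditions is counted once.  A one-to-one assignment
    is chosen greedily by descending weight product (weights are sqrt- or
    raw intensities), and the score is the matched weight dot product
    normalised by the two weight-vector norms, so self-similarity is
    exactly 1.  Empty spectra score 0.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        return SimilarityResult(score=0.0, n_matched=0)
    wa = _weights(a.intensity, transform)
    wb = _weights(b.intensity, transform)
    shift = a.precursor_mz - b.precursor_mz

    cands: List[Tuple[float, int, int]] = []
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            d = a.mz[i] - b.mz[j]
            tol = max(tol_ppm * 1e-6 * max(a.mz[i], b.mz[j]), tol_da)
            if abs(d) <= tol or abs(d - shift) <= tol:
                cands.append((wa[i] * wb[j], i, j))
    if not cands:
        return SimilarityResult(score=0.0, n_matched=0)
    # greedy one-to-one by descending weight product; index tie-break
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set = set()
    used_b: set = set()
    pairs: List[Tuple[int, int]] = []
    total = 0.0
    for w, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        total += w
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    score = total / norm if norm > 0 else 0.0
    return SimilarityResult(score=min(score, 1.0), n_matched=len(pairs), pairs=tuple(pairs))


def _dedup_by_feature(spectra: Sequence[FragmentSpectrum]) -> List[FragmentSpectrum]:
    """Keep one spectrum per feature: the one with the largest base peak."""
    best: Dict[str, FragmentSpectrum] = {}
    for s in spectra:
        key = s.feature_id or s.spectrum_id
        cur = best.get(key)
        if cur is None or s.base_peak_intensity > cur.base_peak_intensity:
            best[key] = s
    return [best[k] for k in sorted(best)]


def build_network(
    spectra: Sequence[FragmentSpectrum],
    score_min: float = 0.7,
    min_matched: int = 5,
    max_neighbors: int = 10,
    tol_ppm: float = 5.0,
    tol_da: float = 0.003,
    transform: str = "sqrt",
    node_attrs: Optional[Dict[str, dict]] = None,
) -> nx.Graph:
    """All-pairs modified-cosine network with thresholds and degree cap.

    Edges must reach ``score_min`` and ``min_matched`` matched fragment
    ions; the neighbour cap keeps an edge only if it ranks within the
    top ``max_neighbors`` by (score desc, n_matched desc, lexicographic
    partner id) for BOTH endpoints.  The result is an undirected simple
    graph without self-loops whose nodes carry precursor m/z, RT and any
    extra attributes supplied per feature id.
    """
    if not (0.0 <= score_min <= 1.0):
        raise ValueError("score_min must lie in [0, 1]")
    if min_matched < 1 or max_neighbors < 1:
        raise ValueError("min_matched and max_neighbors must be >= 1")
    uniq = _dedup_by_feature(spectra)
    g = nx.Graph()
    for s in uniq:
        key = s.feature_id or s.spectrum_id
        attrs = {"mz": float(s.precursor_mz), "rt": float(s.precursor_rt)}
        if node_attrs and key in node_attrs:
            attrs.update(node_attrs[key])
        g.add_node(key, **attrs)

    edges: List[NetworkEdge] = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            sim = modified_cosine(
                uniq[i], uniq[j], tol_ppm=tol_ppm, tol_da=tol_da, transform=transform
            )
            if sim.score >= score_min and sim.n_matched >= min_matched:
                ida = uniq[i].feature_id or uniq[i].spectrum_id
                idb = uniq[j].feature_id or uniq[j].spectrum_id
                a, b = sorted((ida, idb))
                edges.append(NetworkEdge(a=a, b=b, score=sim.score, n_matched=sim.n_matched))

    # per-node ranking for the top-k neighbour cap
    ranks: Dict[Tuple[str, str, str], int] = {}
    by_node: Dict[str, List[NetworkEdge]] = {}
    for e in edges:
        by_node.setdefault(e.a, []).append(e)
        by_node.setdefault(e.b, []).append(e)
    for node, node_edges in by_node.items():
        node_edges.sort(
            key=lambda e: (-e.score, -e.n_matched, e.b if e.a == node else e.a)
        )
        for r, e in enumerate(node_edges):
            ranks[(node, e.a, e.b)] = r
    for e in edges:
        if (
            ranks[(e.a, e.a, e.b)] < max_neighbors
            and ranks[(e.b, e.a, e.b)] < max_neighbors
        ):
            g.add_edge(e.a, e.b, score=round(e.score, 6), n_matched=e.n_matched)
    return g


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """Write the network as GraphML (Cytoscape-importable)."""
    nx.write_graphml(g, str(path))


def export_edge_table(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": a, "target": b, "score": d.get("score"), "n_matched": d.get("n_matched")}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "score", "n_matched"]).to_csv(
        path, index=False
    )


def export_node_table(g: nx.Graph, path: str | Path) -> None:
    rows = []
    for n, d in sorted(g.nodes(data=True)):
        row = {"feature_id": n}
        row.update(d)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
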