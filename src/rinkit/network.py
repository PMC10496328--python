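"""Assemble the residue interaction network, serialize it, and analyse it.

The RIN is a networkx MultiGraph: one node per prepared residue (isolated
residues included), one edge per surviving contact, typed multi-edges
permitted. GraphML and the node/edge CSV pair encode identical graphs.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import networkx as nx
import numpy as np

from rinkit.chemistry import annotate_chemistry
from rinkit.detectors import Contact, detect_contacts
from rinkit.errors import InputError, RinkitError
from rinkit.params import BondParams, SPECIFIC_BONDS
from rinkit.structure import PreparedModel, PrepOptions, Structure, prepare_model

logger = logging.getLogger("rinkit.network")

NODE_FIELDS = ("node_id", "chain", "seq", "icode", "residue", "degree")
EDGE_FIELDS = ("source", "target", "bond_type", "atom_a", "atom_b", "distance", "angle", "energy")


def build_rin(model: PreparedModel, contacts: list[Contact],
              structure_id: str = "", params: BondParams | None = None) -> nx.MultiGraph:
    """Build the attributed residue interaction network for one model."""
    rin = nx.MultiGraph(
        structure_id=structure_id,
        model=model.index,
        params_fingerprint=params.fingerprint() if params is not None else "",
    )
    for res in model.residues:
        rin.add_node(res.node_id, chain=res.chain_id, seq=res.seq_num,
                     icode=res.icode, residue=res.name)
    for c in contacts:
        id_a = model.residues[c.idx_a].node_id
        id_b = model.residues[c.idx_b].node_id
        if id_a not in rin or id_b not in rin:
            raise RinkitError(f"contact references unknown residue {id_a} / {id_b}")
        attrs = {
            "bond_type": c.bond_type,
            "atom_a": ";".join(c.atoms_a),
            "atom_b": ";".join(c.atoms_b),
            "distance": float(c.distance),
            "energy": float(c.energy),
        }
        if c.angle is not None:
            attrs["angle"] = float(c.angle)
        for k, v in c.extra.items():
            if k != "sigma":
                attrs[k] = str(v)
        rin.add_edge(id_a, id_b, **attrs)
    for node in rin.nodes:
        rin.nodes[node]["degree"] = rin.degree(node)
    return rin


def write_graphml(rin: nx.MultiGraph, path) -> None:
    """Write well-formed GraphML (undirected; numeric attributes typed as such)."""
    try:
        nx.write_graphml(rin, str(path), infer_numeric_types=False)
    except OSError as exc:
        raise InputError(f"cannot write GraphML to {path}: {exc}") from exc


def write_csv(rin: nx.MultiGraph, nodes_path, edges_path) -> None:
    """Write the node and edge tables as RFC-4180 CSV with deterministic order."""
    try:
        with open(nodes_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(NODE_FIELDS)
            for node in sorted(rin.nodes):
                d = rin.nodes[node]
                writer.writerow([node, d.get("chain", ""), d.get("seq", ""),
                                 d.get("icode", ""), d.get("residue", ""),
                                 d.get("degree", rin.degree(node))])
        with open(edges_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(EDGE_FIELDS)
            rows = []
            for u, v, d in rin.edges(data=True):
                src, tgt = sorted((u, v))
                angle = d.get("angle")
                rows.append([src, tgt, d.get("bond_type", ""), d.get("atom_a", ""),
                             d.get("atom_b", ""), repr(float(d["distance"])),
                             "" if angle is None else repr(float(angle)),
                             repr(float(d["energy"]))])
            rows.sort()
            writer.writerows(rows)
    except OSError as exc:
        raise InputError(f"cannot write CSV to {nodes_path}/{edges_path}: {exc}") from exc


def read_rin(path) -> nx.MultiGraph:
    """Read a RIN back from GraphML or from an edges CSV file."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read RIN file: {path}")
    if path.suffix.lower() == ".csv":
        rin = nx.MultiGraph()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                attrs = {k: row[k] for k in ("bond_type", "atom_a", "atom_b") if k in row}
                for k in ("distance", "angle", "energy"):
                    if row.get(k):
                        attrs[k] = float(row[k])
                rin.add_edge(row["source"], row["target"], **attrs)
        return rin
    return nx.MultiGraph(nx.read_graphml(str(path)))


def run_model(model, prep: PrepOptions, params: BondParams,
              which=SPECIFIC_BONDS, structure_id: str = "") -> nx.MultiGraph:
    """Prepare one model, run the selected detectors and assemble its RIN."""
    prepared = prepare_model(model, prep)
    chem = annotate_chemistry(prepared)
    contacts = detect_contacts(prepared, chem, params, which=which)
    counts: dict[str, int] = {}
    for c in contacts:
        counts[c.bond_type] = counts.get(c.bond_type, 0) + 1
    logger.info("model %d: %d residues, %d contacts (%s)", prepared.index,
                len(prepared.residues), len(contacts),
                ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none")
    return build_rin(prepared, contacts, structure_id=structure_id, params=params)


def run_all_models(structure: Structure, prep: PrepOptions, params: BondParams,
                   out_dir, fmt: str = "graphml", which=SPECIFIC_BONDS) -> list[Path]:
    """One RIN output per model, written into ``out_dir``; returns the file list.

    A model that fails is skipped with a logged warning rather than aborting
    the batch.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    failures = 0
    for model in structure.models:
        try:
            rin = run_model(model, prep, params, which=which, structure_id=structure.id)
            stem = f"{structure.id}_model{model.index}"
            if fmt == "csv":
                nodes_path = out_dir / f"{stem}_nodes.csv"
                edges_path = out_dir / f"{stem}_edges.csv"
                write_csv(rin, nodes_path, edges_path)
                produced.extend([nodes_path, edges_path])
            else:
                path = out_dir / f"{stem}.graphml"
                write_graphml(rin, path)
                produced.append(path)
        except Exception as exc:
            failures += 1
            logger.warning("model %d failed and was skipped: %s", model.index, exc)
    if failures:
        logger.warning("%d model(s) failed during batch output", failures)
    return produced


# ---------------------------------------------------------------------------
# Graph statistic


def betweenness(rin: nx.Graph, variant: str = "ratio") -> dict:
    """Betweenness per node.

    ``variant="ratio"``: for each node v, the number of shortest paths (over
    all unordered pairs {s, t}, s != t != v) passing through v as an interior
    vertex, divided by the total number of shortest paths between all
    unordered pairs in the graph. Disconnected pairs contribute no paths.
    Values lie in [0, 1].

    ``variant="brandes"``: the standard pair-normalized betweenness
    centrality, for comparability with common graph libraries.

    Multi-edges are collapsed to a simple unweighted graph before counting.
    """
    simple = nx.Graph(rin)
    nodes = list(simple.nodes)
    if not nodes:
        return {}
    if variant == "brandes":
        return dict(nx.betweenness_centrality(simple, normalized=True))
    if variant != "ratio":
        raise ValueError(f"unknown betweenness variant {variant!r}")

    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        # BFS computing geodesic counts from s
        frontier = [si]
        adj = simple.adj
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[nodes[u]]:
                    wi = index[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(wi)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, u]
            frontier = nxt
            d += 1

    finite = np.isfinite(dist)
    off = ~np.eye(n, dtype=bool)
    total_paths = sigma[np.triu(finite & off)].sum()
    values: dict = {}
    for v in nodes:
        vi = index[v]
        if total_paths == 0:
            values[v] = 0.0
            continue
        dv = dist[:, vi][:, None] + dist[vi, :][None, :]
        on_path = finite & (dv == dist) & off
        on_path[vi, :] = False
        on_path[:, vi] = False
        np.fill_diagonal(on_path, False)
        through = (sigma[:, vi][:, None] * sigma[vi, :][None, :])[on_path].sum() / 2.0
        values[v] = float(through / total_paths)
    return values
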