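"""Contig connectivity: the contig-read string graph, the contig overlay
graph, graph surgery and extension-candidate extraction.

Only reads whose alignments touch an end window of some contig enter the
string graph, which keeps it small; the contig graph then records one edge
per read-path connection between a contig's right end and another contig's
left start, weighted by coverage depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core_io import Alignment, SeqRecord, find_matches, reverse_complement
from .signal_detector import CoverageProfile

__all__ = [
    "ContigReadStringGraph",
    "ExtensionCandidate",
    "build_contig_read_graph",
    "condense_to_contig_graph",
    "transitive_reduction",
    "contract_edges",
    "find_extension_candidates",
    "write_dot",
    "write_edge_list",
]

END_SLACK = 300  # how close to a contig end an alignment must reach to dangle
MIN_OVERHANG = 50  # bases a read must extend past a contig end to connect


@dataclass
class ContigReadStringGraph:
    """String graph over contig-end anchors and endpoint-proximal reads.

    Nodes: ("S", contig_id) left-start ports, ("E", contig_id) right-end
    ports, and ("R", read_id, orient) oriented reads.  Edges carry the
    overlap length.
    """

    graph: nx.DiGraph
    read_seqs: dict[tuple[str, str], str] = field(default_factory=dict)

    def read_nodes(self):
        return [n for n in self.graph.nodes if n[0] == "R"]


def _oriented(al: Alignment, read_len: int):
    """Map an alignment into contig-forward space.

    Returns (orient, oqs, oqe): orient '+' keeps the read, '-' means its
    reverse complement aligns forward; (oqs, oqe) are the matching
    coordinates on the oriented read.
    """
    if al.strand == "+":
        return "+", al.qstart, al.qend
    return "-", read_len - al.qend, read_len - al.qstart


def build_contig_read_graph(
    contigs: list[SeqRecord],
    reads: list[SeqRecord],
    alignments: list[Alignment],
    end_window: int = 5000,
) -> ContigReadStringGraph:
    """Keep reads whose alignments touch within *end_window* of a contig
    end; connect contig-end ports to dangling reads and overlapping reads
    head-to-tail."""
    if end_window <= 0:
        raise ValueError("end_window must be positive")
    clen = {c.id: len(c) for c in contigs}
    rlen = {r.id: len(r) for r in reads}
    rseq = {r.id: r.seq for r in reads}
    g = nx.DiGraph()
    for c in contigs:
        g.add_node(("S", c.id))
        g.add_node(("E", c.id))
    read_seqs: dict[tuple[str, str], str] = {}
    by_contig: dict[str, list] = {}
    dangling: set[tuple[str, str]] = set()
    for al in alignments:
        if al.target_id not in clen or al.query_id not in rlen:
            continue
        L = clen[al.target_id]
        near_end = al.tend > L - end_window
        near_start = al.tstart < end_window
        if not (near_end or near_start):
            continue
        orient, oqs, oqe = _oriented(al, rlen[al.query_id])
        rnode = ("R", al.query_id, orient)
        overhang_right = (rlen[al.query_id] - oqe) - (L - al.tend)
        overhang_left = oqs - al.tstart
        dangles_right = al.tend > L - END_SLACK and overhang_right > MIN_OVERHANG
        dangles_left = al.tstart < END_SLACK and overhang_left > MIN_OVERHANG
        if rnode not in g:
            g.add_node(rnode)
            read_seqs[rnode[1:]] = (
                rseq[al.query_id] if orient == "+" else reverse_complement(rseq[al.query_id])
            )
        if dangles_right:
            g.add_edge(("E", al.target_id), rnode, overlap=al.tend - al.tstart)
            dangling.add(rnode[1:])
        if dangles_left:
            g.add_edge(rnode, ("S", al.target_id), overlap=al.tend - al.tstart)
            dangling.add(rnode[1:])
        by_contig.setdefault(al.target_id, []).append((al.tstart, al.tend, rnode))
    min_olap = max(200, MIN_OVERHANG)
    # head-to-tail overlaps inferred from co-alignment to a shared contig:
    # two reads whose projected intervals overlap by >= min_olap dovetail
    for _cid, hits in by_contig.items():
        hits.sort()
        for i, (s1, e1, n1) in enumerate(hits):
            for s2, e2, n2 in hits[i + 1 :]:
                if s2 >= e1 - min_olap:
                    break
                if n1 == n2:
                    continue
                if s1 < s2 and e1 < e2:
                    g.add_edge(n1, n2, overlap=e1 - s2)
                elif s2 < s1 and e2 < e1:
                    g.add_edge(n2, n1, overlap=e1 - s2)
    # overlaps whose shared region lies beyond every contig end (gap
    # bridging) need actual alignment; only dangling reads can take part
    if dangling:
        recs = [
            SeqRecord(f"{rid}|{orient}", read_seqs[(rid, orient)])
            for rid, orient in sorted(dangling)
        ]
        for al in find_matches(
            recs,
            recs,
            min_len=min_olap,
            min_identity=0.65,
            max_hits_per_query=12,
            strands="+",
        ):
            if al.query_id == al.target_id:
                continue
            qkey = tuple(al.query_id.rsplit("|", 1))
            tkey = tuple(al.target_id.rsplit("|", 1))
            qlen = len(read_seqs[qkey])
            tlen = len(read_seqs[tkey])
            # suffix of query matches prefix of target, target extends right
            if (
                qlen - al.qend < END_SLACK
                and al.tstart < END_SLACK
                and (tlen - al.tend) > (qlen - al.qend) + MIN_OVERHANG
            ):
                g.add_edge(("R", *qkey), ("R", *tkey), overlap=al.qend - al.qstart)
    return ContigReadStringGraph(graph=g, read_seqs=read_seqs)


def condense_to_contig_graph(
    g: ContigReadStringGraph,
    coverage: CoverageProfile | None = None,
    max_hops: int = 5,
    max_paths: int = 50,
) -> nx.DiGraph:
    """Contig overlay graph: edge (u, v) iff a read path links u's right
    end to v's left start; node weight = mean coverage depth of u."""
    sg = g.graph
    contigs = sorted({n[1] for n in sg.nodes if n[0] in "SE"})
    out = nx.DiGraph()
    for cid in contigs:
        weight = coverage.mean_depth(cid) if coverage is not None else 0.0
        length = len(coverage.depth[cid]) if coverage is not None and cid in coverage.depth else 0
        out.add_node(cid, weight=float(weight), length=int(length))
    for u in contigs:
        start = ("E", u)
        if start not in sg:
            continue
        # breadth-first over read nodes; each read expands once, so the
        # search is linear even in dense overlap neighbourhoods.  Each
        # read adjacent to a contig start contributes one supporting path.
        found: dict[str, list[tuple]] = {}
        first_path = {start: ()}
        frontier = [start]
        hops = 0
        while frontier and hops <= max_hops:
            nxt_frontier = []
            for node in frontier:
                path = first_path[node]
                for nxt in sorted(sg.successors(node)):
                    if nxt[0] == "S":
                        v = nxt[1]
                        if v != u and path:
                            found.setdefault(v, [])
                            if len(found[v]) < max_paths:
                                found[v].append(tuple(n[1] for n in path))
                    elif nxt[0] == "R" and nxt not in first_path:
                        first_path[nxt] = path + (nxt,)
                        nxt_frontier.append(nxt)
            frontier = nxt_frontier
            hops += 1
        for v, paths in sorted(found.items()):
            out.add_edge(u, v, paths=sorted(set(paths)))
    return out


def transitive_reduction(g: nx.DiGraph, hints=()) -> nx.DiGraph:
    """Remove edges u->v implied by a surviving two-step path u->w->v.

    *hints* are (u, w) or (w, v) edges to add before reduction when a short
    contig w would otherwise leave the triangle incomplete.  Edges are
    examined in sorted order and removed one at a time with the witness
    path checked against the current graph, so reachability is preserved.
    """
    h = g.copy()
    for u, v in hints:
        if u in h and v in h and not h.has_edge(u, v):
            h.add_edge(u, v, paths=[], inferred=True)
    changed = True
    while changed:
        changed = False
        for u, v in sorted(h.edges):
            if any(h.has_edge(u, w) and h.has_edge(w, v) for w in h.nodes if w not in (u, v)):
                h.remove_edge(u, v)
                changed = True
                break
    return h


def _length_weight_merge(g: nx.DiGraph, u, v):
    lu = g.nodes[u].get("length", 0)
    lv = g.nodes[v].get("length", 0)
    wu = g.nodes[u].get("weight", 0.0)
    wv = g.nodes[v].get("weight", 0.0)
    total = lu + lv
    if total == 0:
        return (wu + wv) / 2.0, 0
    return (wu * lu + wv * lv) / total, total


def contract_edges(g: nx.DiGraph, veto=None) -> nx.DiGraph:
    """Merge u->v whenever outdeg(u) == indeg(v) == 1, unless vetoed.

    *veto* is an optional predicate (u, v) -> bool implementing the repeat
    guard (another contig read-linked near u's right end or v's left end).
    Merged nodes are named "u+v"; weight is the length-weighted mean.
    """
    h = g.copy()
    changed = True
    while changed:
        changed = False
        for u, v in sorted(h.edges):
            if u == v:
                continue
            if h.out_degree(u) == 1 and h.in_degree(v) == 1:
                if veto is not None and veto(u, v):
                    continue
                w, total = _length_weight_merge(h, u, v)
                new = f"{u}+{v}"
                joins = (
                    h.nodes[u].get("joins", [])
                    + [(u, v, h.edges[u, v].get("paths", []))]
                    + h.nodes[v].get("joins", [])
                )
                h.add_node(new, weight=w, length=total, joins=joins)
                for p, _ in list(h.in_edges(u)):
                    h.add_edge(p, new, **h.edges[p, u])
                for _, s in list(h.out_edges(v)):
                    h.add_edge(new, s, **h.edges[v, s])
                h.remove_node(u)
                h.remove_node(v)
                changed = True
                break
    return h


@dataclass(frozen=True)
class ExtensionCandidate:
    incoming: frozenset
    outgoing: frozenset
    repeat_node: str | None = None
    spanning_reads: tuple = ()  # ((a, b, (read ids, ...)), ...)

    def __post_init__(self):
        if not self.incoming or not self.outgoing:
            raise ValueError("candidate needs non-empty incoming and outgoing sets")
        if self.incoming & self.outgoing:
            raise ValueError("incoming and outgoing sets must be disjoint")

    def spanning(self) -> dict:
        return {(a, b): list(reads) for a, b, reads in self.spanning_reads}


def _direct_spanning(g: nx.DiGraph, pairs) -> tuple:
    out = []
    for a, b in sorted(pairs):
        if g.has_edge(a, b):
            reads = sorted({rid for path in g.edges[a, b].get("paths", []) for rid in path})
            out.append((a, b, tuple(reads)))
    return tuple(out)


def find_extension_candidates(g: nx.DiGraph, veto=None) -> list[ExtensionCandidate]:
    """Local merge patterns: contractable pairs, repeat stars, and pure
    bipartite groups of competing contigs."""
    cands: list[ExtensionCandidate] = []
    claimed: set = set()
    # repeat stars: a middle node with traffic on both sides and branching
    for r in sorted(g.nodes):
        preds = set(g.predecessors(r)) - {r}
        succs = set(g.successors(r)) - {r}
        if preds and succs and len(preds) + len(succs) >= 3 and not (preds & succs):
            pairs = [(a, b) for a in preds for b in succs if a != b]
            cands.append(
                ExtensionCandidate(
                    incoming=frozenset(preds),
                    outgoing=frozenset(succs),
                    repeat_node=r,
                    spanning_reads=_direct_spanning(g, pairs),
                )
            )
            claimed |= {(a, r) for a in preds} | {(r, b) for b in succs}
    # contractable pairs
    for u, v in sorted(g.edges):
        if (u, v) in claimed or u == v:
            continue
        if g.out_degree(u) == 1 and g.in_degree(v) == 1:
            if veto is not None and veto(u, v):
                continue
            cands.append(
                ExtensionCandidate(
                    incoming=frozenset([u]),
                    outgoing=frozenset([v]),
                    repeat_node=None,
                    spanning_reads=_direct_spanning(g, [(u, v)]),
                )
            )
            claimed.add((u, v))
    # bipartite competing groups (no explicit repeat node)
    seen_nodes = {n for c in cands for n in c.incoming | c.outgoing}
    if any(c.repeat_node for c in cands):
        seen_nodes |= {c.repeat_node for c in cands if c.repeat_node}
    for comp in nx.weakly_connected_components(g):
        comp = set(comp)
        if len(comp) < 3 or comp & seen_nodes:
            continue
        sources = {n for n in comp if g.in_degree(n) == 0 and g.out_degree(n) > 0}
        sinks = {n for n in comp if g.out_degree(n) == 0 and g.in_degree(n) > 0}
        if sources and sinks and sources | sinks == comp:
            pairs = [(a, b) for a in sources for b in sinks]
            cands.append(
                ExtensionCandidate(
                    incoming=frozenset(sources),
                    outgoing=frozenset(sinks),
                    repeat_node=None,
                    spanning_reads=_direct_spanning(g, pairs),
                )
            )
    return cands


def make_end_veto(
    contigs: list[SeqRecord],
    alignments: list[Alignment],
    end_window: int = 5000,
):
    """Repeat guard: veto contraction of u->v when a third contig is
    read-linked near u's right end or v's left end."""
    clen = {c.id: len(c) for c in contigs}
    read_targets: dict[str, set[str]] = {}
    near_right: dict[str, set[str]] = {}
    near_left: dict[str, set[str]] = {}
    for al in alignments:
        if al.target_id not in clen:
            continue
        read_targets.setdefault(al.query_id, set()).add(al.target_id)
        if al.tend > clen[al.target_id] - end_window:
            near_right.setdefault(al.target_id, set()).add(al.query_id)
        if al.tstart < end_window:
            near_left.setdefault(al.target_id, set()).add(al.query_id)

    def veto(u: str, v: str) -> bool:
        linked: set[str] = set()
        for rid in near_right.get(u, set()) | near_left.get(v, set()):
            linked |= read_targets.get(rid, set())
        return bool(linked - {u, v})

    return veto


def write_dot(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph contigs {\n")
        for n, data in g.nodes(data=True):
            fh.write(f'  "{n}" [label="{n}\\n{data.get("weight", 0):.1f}X"];\n')
        for u, v in g.edges:
            fh.write(f'  "{u}" -> "{v}";\n')
        fh.write("}\n")


def write_edge_list(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\tn_paths\n")
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{v}\t{len(data.get('paths', []))}\n")
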