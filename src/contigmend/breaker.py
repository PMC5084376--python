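"""Break decisions: chimera fixing, the break graph, and coverage tests.

The pipeline is: fix palindromic chimeras, cut contigs at repeat endpoints
to build a fully contracted segment graph over both strands, choose a
minimum *sufficient breaking set* of junctions (so the broken contigs are
consistent with every feasible ground truth), and finally keep only the
junctions at which an exact conditional Poisson test confirms a coverage
change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import SeqRecord, reverse_complement
from .signal_detector import (
    CoverageProfile,
    PalindromeSignal,
    RepeatEndpoint,
)

__all__ = [
    "BreakGraph",
    "BreakSet",
    "Junction",
    "fix_chimeric_contigs",
    "build_break_graph",
    "locate_potential_misassemblies",
    "is_sufficient_breaking_set",
    "enumerate_ground_truths",
    "remove_redundant",
    "c_test",
    "iterative_c_test",
    "confirm_break_points",
]


# ---------------------------------------------------------------------------
# chimeric contig fixing
# ---------------------------------------------------------------------------


def _contained(piece: str, host: str) -> bool:
    if len(piece) > len(host):
        return False
    return piece in host or reverse_complement(piece) in host


def fix_chimeric_contigs(
    contigs: list[SeqRecord], palindromes: list[PalindromeSignal]
) -> list[SeqRecord]:
    """Split flagged palindromic contigs at their wrapping boundary.

    Pieces that are contained in another output contig (up to reverse
    complement) are dropped as redundant; unflagged contigs pass through.
    """
    by_id = {c.id: c for c in contigs}
    for sig in palindromes:
        if sig.contig_id not in by_id:
            raise KeyError(f"palindrome refers to unknown contig {sig.contig_id!r}")
        if not (0 < sig.split_pos < len(by_id[sig.contig_id])):
            raise ValueError(
                f"split position {sig.split_pos} outside contig {sig.contig_id!r}"
            )
    flagged = {s.contig_id: s for s in palindromes}
    kept: list[SeqRecord] = []
    pieces: list[SeqRecord] = []
    for contig in contigs:
        sig = flagged.get(contig.id)
        if sig is None:
            kept.append(contig)
        else:
            left = contig.seq[: sig.split_pos]
            right = contig.seq[sig.split_pos :]
            if left:
                pieces.append(SeqRecord(f"{contig.id}_p0", left))
            if right:
                pieces.append(SeqRecord(f"{contig.id}_p1", right))
    # greedy redundancy removal: longest pieces first, a piece survives only
    # if it is not contained (up to rc) in an already-accepted contig
    out = list(kept)
    for piece in sorted(pieces, key=lambda p: (-len(p.seq), p.id)):
        if not any(_contained(piece.seq, h.seq) for h in out):
            out.append(piece)
    return out


# ---------------------------------------------------------------------------
# break graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakEdge:
    eid: str
    u: str
    v: str
    junction: object  # (contig_id, pos) for sequence graphs, eid otherwise
    mirror: str | None = None  # eid of the reverse-strand twin


class BreakGraph:
    """Directed multigraph of repeat-flanked segments.

    Every edge corresponds to one feasible break point (a contig
    junction); strand-mirrored edges share the same junction.
    """

    def __init__(self, edges: list[BreakEdge], vertices: set[str] | None = None):
        self.edges = list(edges)
        self.by_id = {e.eid: e for e in self.edges}
        if len(self.by_id) != len(self.edges):
            raise ValueError("duplicate edge ids")
        self.vertices = set(vertices or set())
        for e in self.edges:
            self.vertices.add(e.u)
            self.vertices.add(e.v)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "BreakGraph":
        """Build from (u, v) pairs; parallel edges get numeric suffixes and
        each edge is its own junction (used in tests and benchmarks)."""
        counts: dict[tuple[str, str], int] = {}
        edges = []
        for u, v in pairs:
            counts[(u, v)] = counts.get((u, v), 0) + 1
        seen: dict[tuple[str, str], int] = {}
        for u, v in pairs:
            if counts[(u, v)] > 1:
                seen[(u, v)] = seen.get((u, v), 0) + 1
                eid = f"{u}{v}{seen[(u, v)]}"
            else:
                eid = f"{u}{v}"
            edges.append(BreakEdge(eid, u, v, junction=eid))
        return cls(edges)

    def in_edges(self, v: str) -> list[BreakEdge]:
        return [e for e in self.edges if e.v == v]

    def out_edges(self, v: str) -> list[BreakEdge]:
        return [e for e in self.edges if e.u == v]

    def predecessors(self, v: str) -> set[str]:
        return {e.u for e in self.edges if e.v == v}

    def successors(self, v: str) -> set[str]:
        return {e.v for e in self.edges if e.u == v}

    def sources(self) -> list[str]:
        return sorted(v for v in self.vertices if not self.in_edges(v) and self.out_edges(v))

    def sinks(self) -> list[str]:
        return sorted(v for v in self.vertices if not self.out_edges(v) and self.in_edges(v))

    def is_fully_contracted(self) -> bool:
        for e in self.edges:
            if e.u != e.v and len(self.out_edges(e.u)) == 1 and len(self.in_edges(e.v)) == 1:
                return False
        return True

    def qualifying_vertices(self) -> list[str]:
        """Vertices with >= 2 distinct predecessors and >= 2 successors."""
        return sorted(
            v
            for v in self.vertices
            if len(self.predecessors(v)) >= 2 and len(self.successors(v)) >= 2
        )

    def weak_components(self) -> list[list[BreakEdge]]:
        parent: dict[str, str] = {v: v for v in self.vertices}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in self.edges:
            ru, rv = find(e.u), find(e.v)
            if ru != rv:
                parent[max(ru, rv)] = min(ru, rv)
        groups: dict[str, list[BreakEdge]] = {}
        for e in self.edges:
            groups.setdefault(find(e.u), []).append(e)
        return [groups[k] for k in sorted(groups)]


@dataclass(frozen=True)
class BreakSet:
    edges: frozenset  # edge ids
    junctions: frozenset  # (contig_id, pos) pairs (or edge ids for test graphs)


def build_break_graph(
    contigs: list[SeqRecord], repeat_endpoints: list[RepeatEndpoint]
) -> BreakGraph:
    """Cut contigs at repeat endpoints and assemble the doubled segment graph.

    Both strands of every contig are laid down; segments with identical
    sequence share a vertex, so repeat copies collapse into one vertex per
    family and orientation.  Mirrored edges (same physical junction seen on
    the two strands) reference each other and share a junction.  The
    result is fully contracted.
    """
    cuts: dict[str, set[int]] = {c.id: set() for c in contigs}
    for ep in repeat_endpoints:
        if ep.contig_id not in cuts:
            raise KeyError(f"repeat endpoint on unknown contig {ep.contig_id!r}")
        L = len(next(c for c in contigs if c.id == ep.contig_id))
        if 0 < ep.pos < L:
            cuts[ep.contig_id].add(ep.pos)

    vid_of: dict[str, str] = {}

    def vid(seq: str) -> str:
        if seq not in vid_of:
            vid_of[seq] = f"v{len(vid_of)}"
        return vid_of[seq]

    edges: list[BreakEdge] = []
    eid_at: dict[tuple[str, int, str], str] = {}
    for contig in contigs:
        L = len(contig)
        pos = sorted(cuts[contig.id])
        for strand in "+-":
            seq = contig.seq if strand == "+" else reverse_complement(contig.seq)
            spos = pos if strand == "+" else [L - p for p in reversed(pos)]
            bounds = [0] + spos + [L]
            seg_ids = [vid(seq[bounds[i] : bounds[i + 1]]) for i in range(len(bounds) - 1)]
            for i, cut in enumerate(spos):
                fwd_pos = cut if strand == "+" else L - cut
                eid = f"{contig.id}:{fwd_pos}:{strand}"
                eid_at[(contig.id, fwd_pos, strand)] = eid
                edges.append(
                    BreakEdge(
                        eid,
                        seg_ids[i],
                        seg_ids[i + 1],
                        junction=(contig.id, fwd_pos),
                        mirror=None,
                    )
                )
    # wire mirrors
    wired: list[BreakEdge] = []
    for e in edges:
        cid, p, strand = e.eid.rsplit(":", 2)
        mirror = eid_at.get((cid, int(p), "-" if strand == "+" else "+"))
        wired.append(BreakEdge(e.eid, e.u, e.v, e.junction, mirror))
    graph = BreakGraph(wired)
    return _contract(graph)


def _contract(graph: BreakGraph) -> BreakGraph:
    """Remove every edge whose tail has out-degree 1 and head in-degree 1,
    merging the endpoints; the corresponding junctions stop being feasible."""
    parent: dict[str, str] = {v: v for v in graph.vertices}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = list(graph.edges)
    changed = True
    while changed:
        changed = False
        outdeg: dict[str, int] = {}
        indeg: dict[str, int] = {}
        for e in edges:
            outdeg[find(e.u)] = outdeg.get(find(e.u), 0) + 1
            indeg[find(e.v)] = indeg.get(find(e.v), 0) + 1
        for e in edges:
            u, v = find(e.u), find(e.v)
            if u != v and outdeg.get(u) == 1 and indeg.get(v) == 1:
                parent[v] = u
                edges = [x for x in edges if x.eid != e.eid]
                changed = True
                break
    merged = [
        BreakEdge(e.eid, find(e.u), find(e.v), e.junction, e.mirror) for e in edges
    ]
    vertices = {find(v) for v in graph.vertices}
    return BreakGraph(merged, vertices)


def _junction_key(j: object) -> tuple:
    if not isinstance(j, tuple):
        return (str(j), 0)
    # (contig_id, pos) junctions: compare positions numerically
    return tuple((x, 0) if isinstance(x, (int, float)) else (str(x), 0) for x in j)


def _solve_component(
    edges: list[BreakEdge], graph: BreakGraph, exhaust_limit: int
) -> tuple[set, set[str]]:
    """Minimum-junction side choice for one weak component."""
    comp_vertices = {e.u for e in edges} | {e.v for e in edges}
    qual = [v for v in graph.qualifying_vertices() if v in comp_vertices]
    if not qual:
        return set(), set()
    comp_eids = {e.eid for e in edges}
    side_sets: list[tuple[list[BreakEdge], list[BreakEdge]]] = []
    for v in qual:
        ins = [e for e in graph.in_edges(v) if e.eid in comp_eids]
        outs = [e for e in graph.out_edges(v) if e.eid in comp_eids]
        side_sets.append((ins, outs))

    def cost(chosen: list[list[BreakEdge]]):
        junctions = {e.junction for side in chosen for e in side}
        eids = sorted({e.eid for side in chosen for e in side})
        return (len(junctions), sorted(_junction_key(j) for j in junctions), eids), junctions, eids

    if len(edges) <= exhaust_limit:
        best = None
        for combo in itertools.product(*side_sets):
            key, junctions, eids = cost(list(combo))
            if best is None or key < best[0]:
                best = (key, junctions, eids)
        assert best is not None
        return best[1], set(best[2])
    # feasible fallback: smaller side per qualifying vertex
    junctions: set = set()
    eids: set[str] = set()
    for ins, outs in side_sets:
        ji = {e.junction for e in ins}
        jo = {e.junction for e in outs}
        if (len(ji), sorted(_junction_key(j) for j in ji)) <= (
            len(jo),
            sorted(_junction_key(j) for j in jo),
        ):
            pick = ins
        else:
            pick = outs
        junctions |= {e.junction for e in pick}
        eids |= {e.eid for e in pick}
    return junctions, eids


def locate_potential_misassemblies(
    graph: BreakGraph, exhaust_limit: int = 20
) -> BreakSet:
    """Choose break-point edges so that either all in-edges or all out-edges
    are taken at every vertex with >= 2 predecessors and >= 2 successors.

    Components small enough are minimized exhaustively over the per-vertex
    side choices (counting physical junctions, mirrored edges collapse);
    larger components get the feasible smaller-side-per-vertex choice.
    Mirror components (reverse-strand copies) are solved once.
    """
    if not graph.is_fully_contracted():
        raise ValueError("break graph is not fully contracted")
    components = graph.weak_components()
    seen_junction_sets: set[frozenset] = set()
    all_junctions: set = set()
    all_eids: set[str] = set()
    for comp in components:
        jset = frozenset(e.junction for e in comp)
        if jset in seen_junction_sets:
            continue  # mirror twin of a component already solved
        seen_junction_sets.add(jset)
        junctions, eids = _solve_component(comp, graph, exhaust_limit)
        all_junctions |= junctions
        all_eids |= eids
    # include mirror edges of every chosen edge so Phi holds on both strands
    for eid in list(all_eids):
        m = graph.by_id[eid].mirror
        if m is not None:
            all_eids.add(m)
    return BreakSet(edges=frozenset(all_eids), junctions=frozenset(all_junctions))


def satisfies_phi(graph: BreakGraph, edge_ids: frozenset) -> bool:
    """Direct check of the side-choice constraint at qualifying vertices."""
    for v in graph.qualifying_vertices():
        ins = {e.eid for e in graph.in_edges(v)}
        outs = {e.eid for e in graph.out_edges(v)}
        if not (ins <= edge_ids or outs <= edge_ids):
            return False
    return True


# ---------------------------------------------------------------------------
# ground-truth enumeration oracle
# ---------------------------------------------------------------------------


class EnumerationLimit(RuntimeError):
    pass


def enumerate_ground_truths(
    graph: BreakGraph, limit: int = 5000
) -> list[tuple[tuple[str, ...], ...]]:
    """All edge-disjoint source-to-sink trail partitions, as sorted tuples
    of edge-id sequences.  Raises EnumerationLimit past *limit* results."""
    sources = []
    for v in sorted(graph.vertices):
        excess = len(graph.out_edges(v)) - len(graph.in_edges(v))
        sources.extend([v] * max(0, excess))
    out_by_vertex: dict[str, list[BreakEdge]] = {}
    for e in graph.edges:
        out_by_vertex.setdefault(e.u, []).append(e)
    for lst in out_by_vertex.values():
        lst.sort(key=lambda e: e.eid)

    results: set[tuple[tuple[str, ...], ...]] = set()

    def rec(src_idx: int, used: set[str], trails: list[tuple[str, ...]], cur: list[str], head: str | None):
        if len(results) > limit:
            raise EnumerationLimit(f"more than {limit} ground truths")
        if head is None:
            if src_idx == len(sources):
                if len(used) == len(graph.edges):
                    results.add(tuple(sorted(trails)))
                return
            rec(src_idx + 1, used, trails, [], sources[src_idx])
            return
        nxt = [e for e in out_by_vertex.get(head, []) if e.eid not in used]
        if not nxt:
            rec(src_idx, used, trails + [tuple(cur)], [], None)
            return
        for e in nxt:
            rec(src_idx, used | {e.eid}, trails, cur + [e.eid], e.v)

    rec(0, set(), [], [], None)
    return sorted(results)


def ground_truths_as_vertex_trails(graph: BreakGraph, limit: int = 5000) -> list:
    """Feasible ground truths viewed as multisets of vertex sequences
    (parallel-edge choices collapse, matching hand counts)."""
    out = {
        tuple(sorted(_trail_vertices(graph, t) for t in gt))
        for gt in enumerate_ground_truths(graph, limit)
    }
    return sorted(out)


def _trail_vertices(graph: BreakGraph, trail: tuple[str, ...]) -> tuple[str, ...]:
    verts = [graph.by_id[trail[0]].u]
    for eid in trail:
        verts.append(graph.by_id[eid].v)
    return tuple(verts)


def _split_trail(
    graph: BreakGraph, trail: tuple[str, ...], removed: frozenset
) -> list[tuple[str, ...]]:
    """Vertex-sequence pieces of a trail after removing edges in *removed*;
    single-vertex pieces are kept."""
    verts = _trail_vertices(graph, trail)
    pieces: list[tuple[str, ...]] = []
    cur = [verts[0]]
    for i, eid in enumerate(trail):
        if eid in removed:
            pieces.append(tuple(cur))
            cur = [verts[i + 1]]
        else:
            cur.append(verts[i + 1])
    pieces.append(tuple(cur))
    return pieces


def _is_subtrail(x: tuple[str, ...], y: tuple[str, ...]) -> bool:
    if len(x) > len(y):
        return False
    return any(y[i : i + len(x)] == x for i in range(len(y) - len(x) + 1))


def _consistent(t1: set[tuple[str, ...]], t2: set[tuple[str, ...]]) -> bool:
    return all(any(_is_subtrail(x, y) for y in t2) for x in t1) and all(
        any(_is_subtrail(x, y) for y in t1) for x in t2
    )


def is_sufficient_breaking_set(
    graph: BreakGraph, removed_edges, limit: int = 5000
) -> bool:
    """Enumeration oracle: true iff for every pair of feasible ground
    truths, the broken trail sets are mutually consistent."""
    removed = frozenset(removed_edges)
    gts = enumerate_ground_truths(graph, limit=limit)
    broken = [
        {piece for trail in gt for piece in _split_trail(graph, trail, removed)}
        for gt in gts
    ]
    for i in range(len(broken)):
        for j in range(i + 1, len(broken)):
            if not _consistent(broken[i], broken[j]):
                return False
    return True


def remove_redundant(trails) -> list:
    """Minimal subset with no trail contained (as a contiguous sub-trail)
    in another; deterministic."""
    uniq = sorted(set(tuple(t) for t in trails))
    kept = [
        t
        for t in uniq
        if not any(u != t and _is_subtrail(t, u) for u in uniq)
    ]
    return kept


# ---------------------------------------------------------------------------
# coverage confirmation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Junction:
    contig_id: str
    pos: int
    left_len: int
    right_len: int
    left_starts: int
    right_starts: int

    def __post_init__(self):
        if self.left_len < 1 or self.right_len < 1:
            raise ValueError("segment lengths must be >= 1")
        if self.left_starts < 0 or self.right_starts < 0:
            raise ValueError("counts must be >= 0")


def c_test(x1: int, x2: int, l1: int, l2: int, alpha: float = 0.05) -> tuple[bool, float]:
    """Exact conditional test of equal Poisson rates per unit length.

    Conditioned on n = x1 + x2, x1 ~ Binomial(n, l1/(l1+l2)) under H0.
    The two-sided p-value sums all outcome probabilities not exceeding the
    observed outcome's probability (ties included).
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if l1 < 1 or l2 < 1:
        raise ValueError("lengths must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    n = x1 + x2
    if n == 0:
        return False, 1.0
    p = l1 / (l1 + l2)
    pval = float(stats.binomtest(x1, n, p, alternative="two-sided").pvalue)
    pval = min(1.0, pval)
    return pval < alpha, pval


def _segments_from_junctions(junctions: list[Junction]):
    lengths = [junctions[0].left_len] + [j.right_len for j in junctions]
    counts = [junctions[0].left_starts] + [j.right_starts for j in junctions]
    for a, b in zip(junctions, junctions[1:]):
        if (a.right_len, a.right_starts) != (b.left_len, b.left_starts):
            raise ValueError("inconsistent segment data between adjacent junctions")
    return lengths, counts


def iterative_c_test(junctions: list[Junction], alpha: float = 0.05) -> list[Junction]:
    """Repeat the conditional test, merging non-rejected segments, until
    the surviving junction set is stable.  Output is a subset of the input
    and non-increasing across iterations."""
    if not junctions:
        return []
    lengths, counts = _segments_from_junctions(junctions)
    alive = list(range(len(junctions)))  # junction i sits after segment i
    while True:
        # current merged segments: boundaries at alive junctions
        bounds = [0] + [i + 1 for i in alive] + [len(lengths)]
        seg_len = [sum(lengths[bounds[i] : bounds[i + 1]]) for i in range(len(bounds) - 1)]
        seg_cnt = [sum(counts[bounds[i] : bounds[i + 1]]) for i in range(len(bounds) - 1)]
        keep = []
        for si, ji in enumerate(alive):
            reject, _p = c_test(
                seg_cnt[si], seg_cnt[si + 1], seg_len[si], seg_len[si + 1], alpha
            )
            if reject:
                keep.append(ji)
        if keep == alive:
            return [junctions[i] for i in alive]
        alive = keep
        if not alive:
            return []


def junctions_from_coverage(
    contig: SeqRecord,
    positions: list[int],
    coverage: CoverageProfile,
    merge_dist: int = 100,
) -> list[Junction]:
    """Build Junction records from candidate positions and read-start
    counts; candidates closer than *merge_dist* are merged to their
    midpoint."""
    L = len(contig)
    pos = sorted(p for p in positions if 0 < p < L)
    merged: list[int] = []
    cluster: list[int] = []
    for p in pos:
        if cluster and p - cluster[-1] < merge_dist:
            cluster.append(p)
        else:
            if cluster:
                merged.append(int(round(sum(cluster) / len(cluster))))
            cluster = [p]
    if cluster:
        merged.append(int(round(sum(cluster) / len(cluster))))
    if not merged:
        return []
    starts = coverage.starts.get(contig.id)
    if starts is None:
        starts = np.zeros(L, dtype=np.int64)
    bounds = [0] + merged + [L]
    seg_counts = [int(starts[bounds[i] : bounds[i + 1]].sum()) for i in range(len(bounds) - 1)]
    seg_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
    return [
        Junction(
            contig.id,
            merged[i],
            seg_lens[i],
            seg_lens[i + 1],
            seg_counts[i],
            seg_counts[i + 1],
        )
        for i in range(len(merged))
    ]


def split_contig(contig: SeqRecord, positions: list[int]) -> list[SeqRecord]:
    pos = sorted(p for p in positions if 0 < p < len(contig))
    if not pos:
        return [contig]
    bounds = [0] + pos + [len(contig)]
    return [
        SeqRecord(f"{contig.id}_p{i}", contig.seq[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]


def confirm_break_points(
    contigs: list[SeqRecord],
    break_set: BreakSet,
    coverage: CoverageProfile,
    alpha: float = 0.05,
    merge_dist: int = 100,
    require_confirmation: bool = True,
    report: list | None = None,
) -> list[SeqRecord]:
    """Split contigs at candidate junctions confirmed by the iterative
    conditional test.  With *require_confirmation* false (no read data),
    all candidates are applied.  If *report* is a list, rows of
    (contig_id, pos, decision) are appended to it."""
    by_contig: dict[str, list[int]] = {}
    ids = {c.id for c in contigs}
    for j in break_set.junctions:
        if not isinstance(j, tuple) or len(j) != 2:
            continue
        cid, p = j
        if cid not in ids:
            raise KeyError(f"break junction on unknown contig {cid!r}")
        by_contig.setdefault(cid, []).append(int(p))
    out: list[SeqRecord] = []
    for contig in contigs:
        cand = by_contig.get(contig.id, [])
        if not cand:
            out.append(contig)
            continue
        if require_confirmation:
            juncs = junctions_from_coverage(contig, cand, coverage, merge_dist)
            confirmed = [j.pos for j in iterative_c_test(juncs, alpha)]
            if report is not None:
                for j in juncs:
                    decision = "break" if j.pos in confirmed else "keep"
                    report.append((contig.id, j.pos, decision))
        else:
            confirmed = cand
            if report is not None:
                report.extend((contig.id, p, "break") for p in sorted(confirmed))
        out.extend(split_contig(contig, confirmed))
    return out
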