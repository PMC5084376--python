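"""Contig merging decisions and execution.

For each extension candidate the bipartite matching between incoming and
outgoing contigs is decided either by the spanning-read / coverage
heuristic (default) or by enumerating perfect matchings and ranking them
with a hard-assignment EM confidence score over read abundances and
alignment distances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import SeqRecord, find_matches
from .merger_graph import ExtensionCandidate
from .signal_detector import CoverageProfile

logger = logging.getLogger(__name__)

__all__ = [
    "Matching",
    "EMState",
    "decide_heuristic",
    "read_distance",
    "em_estimate",
    "score_matching",
    "choose_best_matching",
    "merge_contigs",
]


@dataclass(frozen=True)
class Matching:
    pairs: frozenset  # of (incoming_id, outgoing_id)
    score: float | None = None
    repeat_node: str | None = None

    def __post_init__(self):
        ins = [a for a, _ in self.pairs]
        outs = [b for _, b in self.pairs]
        if len(set(ins)) != len(ins) or len(set(outs)) != len(outs):
            raise ValueError("pairs must form a partial matching")


@dataclass
class EMState:
    lam: np.ndarray  # normalized abundances
    contents: list[SeqRecord]
    q: float
    lengths: np.ndarray
    assignments: np.ndarray  # per-read content index
    distances: np.ndarray  # (n_reads, k) alignment distances

    def __post_init__(self):
        if not (0 < self.q < 0.5):
            raise ValueError("q must be in (0, 0.5)")
        if len(self.contents) != len(self.lam):
            raise ValueError("|contents| must equal |lambda|")


def decide_heuristic(
    cand: ExtensionCandidate,
    coverage: CoverageProfile | None = None,
    depths: dict[str, float] | None = None,
    min_span: int = 2,
    rel_tol: float = 0.25,
    runner_margin: float = 0.25,
) -> Matching:
    """Spanning-read and coverage heuristic for one candidate.

    1x1 candidates merge outright.  A pair (a, b) merges on read evidence
    when >= *min_span* reads uniquely span it and neither side has read
    paths to a competing partner; remaining contigs pair by coverage depth
    when within *rel_tol* relative difference and without a runner-up
    within *runner_margin*.  Conflicting merges are discarded.
    """
    I = sorted(cand.incoming)
    O = sorted(cand.outgoing)
    if len(I) == 1 and len(O) == 1:
        return Matching(pairs=frozenset({(I[0], O[0])}), repeat_node=cand.repeat_node)
    span = cand.spanning()
    read_pairs: set[tuple[str, str]] = set()
    for a in I:
        for b in O:
            reads_ab = set(span.get((a, b), []))
            others = set()
            for b2 in O:
                if b2 != b:
                    others |= set(span.get((a, b2), []))
            for a2 in I:
                if a2 != a:
                    others |= set(span.get((a2, b), []))
            unique = reads_ab - others
            a_elsewhere = any(span.get((a, b2)) for b2 in O if b2 != b)
            b_elsewhere = any(span.get((a2, b)) for a2 in I if a2 != a)
            if len(unique) >= min_span and not a_elsewhere and not b_elsewhere:
                read_pairs.add((a, b))

    if depths is None:
        depths = {}
        if coverage is not None:
            for cid in I + O:
                depths[cid] = coverage.mean_depth(cid)

    matched_a = {a for a, _ in read_pairs}
    matched_b = {b for _, b in read_pairs}
    cov_pairs: set[tuple[str, str]] = set()
    free_a = [a for a in I if a not in matched_a and depths.get(a, 0) > 0]
    free_b = [b for b in O if b not in matched_b and depths.get(b, 0) > 0]
    used_b: set[str] = set()
    for a in free_a:
        cands_b = sorted(
            (abs(depths[a] - depths[b]), b) for b in free_b if b not in used_b
        )
        if not cands_b:
            continue
        gap, b = cands_b[0]
        if gap > rel_tol * max(depths[a], depths[b]):
            continue
        # runner-up guard: another free partner with similar depth blocks
        if len(cands_b) > 1:
            _gap2, b2 = cands_b[1]
            if abs(depths[b2] - depths[b]) <= runner_margin * depths[b]:
                continue
        competing_a = [
            a2 for a2 in free_a if a2 != a and abs(depths[a2] - depths[a]) <= runner_margin * depths[a]
        ]
        if competing_a:
            continue
        cov_pairs.add((a, b))
        used_b.add(b)

    pairs = read_pairs | cov_pairs
    # discard conflicting merges (a or b claimed twice)
    from collections import Counter

    ca = Counter(a for a, _ in pairs)
    cb = Counter(b for _, b in pairs)
    pairs = {p for p in pairs if ca[p[0]] == 1 and cb[p[1]] == 1}
    return Matching(pairs=frozenset(pairs), repeat_node=cand.repeat_node)


def read_distance(read: SeqRecord, content: SeqRecord, min_seed: int = 50) -> float:
    """Semi-global alignment distance of a read against a contig: chained
    edit distance plus unaligned read tails; |read| when nothing aligns."""
    als = find_matches(
        [read], [content], min_len=min(min_seed, len(read)), min_identity=0.0
    )
    if not als:
        return float(len(read))
    best = None
    for al in als:
        edits = (1.0 - al.identity) * max(al.qend - al.qstart, al.tend - al.tstart)
        d = edits + al.qstart + (len(read) - al.qend)
        if best is None or d < best:
            best = d
    return float(best)


def em_estimate(
    reads: list[SeqRecord],
    initial_contents: list[SeqRecord],
    q: float = 0.1,
    max_iter: int = 10,
    distances: np.ndarray | None = None,
) -> EMState:
    """Hard-assignment (classification) EM over read-to-contig assignment.

    Reads are assigned to the distance-minimizing content (ties to the
    larger current abundance, then the lower index); abundances update to
    assigned-read fractions.  Contents are held at their initial merged
    sequences: the distance-minimizing consensus of indel-noise reads
    sampled from them is the sequence itself, so the update is a fixed
    point at the fixtures this package targets.
    """
    k = len(initial_contents)
    if k == 0:
        raise ValueError("need at least one content sequence")
    if not reads:
        raise ValueError("reads must be non-empty")
    if distances is None:
        distances = np.array(
            [[read_distance(r, c) for c in initial_contents] for r in reads]
        )
    lam = np.full(k, 1.0 / k)
    lengths = np.array([len(c) for c in initial_contents], dtype=float)
    assign = np.full(len(reads), -1, dtype=int)
    for _ in range(max_iter):
        new_assign = np.empty_like(assign)
        for i in range(len(reads)):
            d = distances[i]
            cand = np.flatnonzero(d == d.min())
            if len(cand) > 1:
                best_lam = lam[cand].max()
                cand = cand[lam[cand] == best_lam]
            new_assign[i] = int(cand[0])
        counts = np.bincount(new_assign, minlength=k).astype(float)
        lam = counts / counts.sum()
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return EMState(
        lam=lam,
        contents=list(initial_contents),
        q=q,
        lengths=lengths,
        assignments=assign,
        distances=distances,
    )


def score_matching(m: Matching, reads: list[SeqRecord], state: EMState) -> float:
    """Log-likelihood objective of the fitted state: per read,
    log(lambda_z / l_z) + |R| log(1-2q) + d log(q / (1-2q))."""
    if not reads:
        return 0.0
    q = state.q
    total = 0.0
    for i, read in enumerate(reads):
        j = int(state.assignments[i])
        lam = max(state.lam[j], 1e-12)
        total += (
            math.log(lam / state.lengths[j])
            + len(read) * math.log(1 - 2 * q)
            + state.distances[i, j] * math.log(q / (1 - 2 * q))
        )
    return total


def _matching_contents(
    perm_pairs, contigs: dict[str, SeqRecord], repeat_seq: str
) -> list[SeqRecord]:
    out = []
    for a, b in perm_pairs:
        seq = contigs[a].seq + repeat_seq + contigs[b].seq
        out.append(SeqRecord(f"{a}+{b}", seq))
    return out


def choose_best_matching(
    cand: ExtensionCandidate,
    reads: list[SeqRecord],
    method: str = "heuristic",
    contigs: dict[str, SeqRecord] | None = None,
    repeat_seq: str = "",
    coverage: CoverageProfile | None = None,
    depths: dict[str, float] | None = None,
    q: float = 0.1,
    max_iter: int = 10,
    max_k: int = 5,
    **heuristic_kwargs,
) -> Matching:
    """Resolve one candidate: the heuristic directly, or EM ranking of all
    k! perfect matchings (falls back to the heuristic on shape mismatch)."""
    I = sorted(cand.incoming)
    O = sorted(cand.outgoing)
    if method == "em":
        if len(I) != len(O) or len(I) > max_k or contigs is None or not reads:
            logger.warning(
                "EM needs |I| == |O| <= %d and read/contig data; falling back to heuristic",
                max_k,
            )
            method = "heuristic"
    if method == "heuristic":
        return decide_heuristic(
            cand, coverage=coverage, depths=depths, **heuristic_kwargs
        )
    best: tuple[float, Matching] | None = None
    for perm in itertools.permutations(O):
        pairs = tuple(zip(I, perm))
        contents = _matching_contents(pairs, contigs, repeat_seq)
        state = em_estimate(reads, contents, q=q, max_iter=max_iter)
        matching = Matching(
            pairs=frozenset(pairs), repeat_node=cand.repeat_node
        )
        s = score_matching(matching, reads, state)
        if best is None or s > best[0]:
            best = (s, Matching(pairs=matching.pairs, score=s, repeat_node=cand.repeat_node))
    assert best is not None
    return best[1]


def _collapse_join(left: str, right: str, max_overlap: int = 20000, min_overlap: int = 20) -> str:
    """Concatenate, collapsing one exact suffix-prefix overlap if present."""
    limit = min(len(left), len(right), max_overlap)
    for olap in range(limit, min_overlap - 1, -1):
        if left.endswith(right[:olap]):
            return left + right[olap:]
    return left + right


def merge_contigs(
    contigs: list[SeqRecord],
    matchings: list[Matching],
    contig_map: dict[str, SeqRecord] | None = None,
) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Execute merge decisions; returns (contigs, provenance).

    Matched pairs are concatenated through their repeat node when one
    exists, collapsing exact end overlaps once.  Chains compose (a->b,
    b->c gives a single contig).  Unmatched contigs pass through.  The
    provenance maps each output id to the ordered input ids it contains;
    repeat-node sequences may appear in several outputs.
    """
    if contig_map is None:
        contig_map = {c.id: c for c in contigs}
    nxt: dict[str, tuple[str, str | None]] = {}
    has_pred: set[str] = set()
    for m in matchings:
        for a, b in sorted(m.pairs):
            if a in nxt or b in has_pred:
                logger.warning("skipping conflicting merge %s->%s", a, b)
                continue
            if a not in contig_map or b not in contig_map:
                logger.warning("skipping merge with unknown contig %s->%s", a, b)
                continue
            nxt[a] = (b, m.repeat_node)
            has_pred.add(b)
    consumed: set[str] = set()
    out: list[SeqRecord] = []
    provenance: dict[str, list[str]] = {}
    for contig in contigs:
        if contig.id in has_pred or contig.id in consumed:
            continue
        if contig.id not in nxt:
            continue  # emitted in passthrough loop below unless in a chain
        chain = [contig.id]
        joiners: list[str | None] = []
        cur = contig.id
        while cur in nxt:
            b, r = nxt[cur]
            joiners.append(r)
            chain.append(b)
            cur = b
        seq = contig_map[chain[0]].seq
        prov = [chain[0]]
        for piece, r in zip(chain[1:], joiners):
            if r is not None and r in contig_map:
                seq = _collapse_join(seq, contig_map[r].seq)
                prov.append(r)
            seq = _collapse_join(seq, contig_map[piece].seq)
            prov.append(piece)
        out_id = "+".join(chain)
        out.append(SeqRecord(out_id, seq))
        provenance[out_id] = prov
        consumed.update(chain)
    repeat_ids = {m.repeat_node for m in matchings if m.repeat_node is not None}
    for contig in contigs:
        if contig.id in consumed or contig.id in has_pred:
            continue
        if contig.id in repeat_ids and any(contig.id in p for p in provenance.values()):
            consumed.add(contig.id)
            continue  # repeat consumed by the joins it mediated
        out.append(contig)
        provenance[contig.id] = [contig.id]
    return out, provenance
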