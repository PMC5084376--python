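"""Mis-assembly signal collection.

Three signals are gathered from the contigs and the original reads:

* palindromes — a contig that is the concatenation of a wrapping pair,
  the footprint left by adapter-skipped chimeric reads;
* repeat endpoints — boundaries of long (approximate) maximal repeats
  within and across contigs, on both strands;
* the coverage profile — per-base read depth and read-start counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Alignment, SeqRecord, find_matches, reverse_complement

__all__ = [
    "PalindromeSignal",
    "RepeatEndpoint",
    "CoverageProfile",
    "wrapping_length",
    "detect_palindromes",
    "detect_repeats",
    "compute_coverage",
    "best_alignments_per_read",
]


@dataclass(frozen=True)
class PalindromeSignal:
    contig_id: str
    wrap_len: int
    split_pos: int  # 0-based position where the wrapping pair abuts


@dataclass(frozen=True)
class RepeatEndpoint:
    contig_id: str
    pos: int  # 0-based inter-base junction
    side: str  # "start" | "end"
    repeat_id: int


@dataclass
class CoverageProfile:
    """Per-contig read depth and read-start counts."""

    depth: dict[str, np.ndarray] = field(default_factory=dict)
    starts: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_depth(self, contig_id: str) -> float:
        d = self.depth.get(contig_id)
        if d is None or len(d) == 0:
            return 0.0
        return float(np.mean(d))

    def trimmed_mean_depth(self, contig_id: str, trim: int) -> float:
        """Mean depth ignoring *trim* bases at each end (capped at a
        quarter of the contig), where junction-straddling reads depress
        the profile."""
        d = self.depth.get(contig_id)
        if d is None or len(d) == 0:
            return 0.0
        t = min(trim, len(d) // 4)
        return float(np.mean(d[t : len(d) - t])) if len(d) > 2 * t else float(np.mean(d))

    def robust_depth(self, contig_id: str, trim: int) -> float:
        """Median depth of the end-trimmed profile; robust both to
        junction dips and to local read-sampling pile-ups."""
        d = self.depth.get(contig_id)
        if d is None or len(d) == 0:
            return 0.0
        t = min(trim, len(d) // 4)
        core = d[t : len(d) - t] if len(d) > 2 * t else d
        return float(np.median(core))

    def total_reads(self) -> int:
        return int(sum(arr.sum() for arr in self.starts.values()))


def wrapping_length(x: str) -> int:
    """Maximum over wrapping-pair decompositions x = a+b of min(|a|, |b|).

    (a, b) is a wrapping pair when reverse_complement(a) is a prefix of b
    or reverse_complement(b) is a suffix of a.  Returns 0 when no
    decomposition qualifies.
    """
    n = len(x)
    if n < 2:
        raise ValueError("wrapping_length needs |x| >= 2")
    rc = reverse_complement(x)
    # rc(x)[n-i:] == rc(x[:i]) and rc(x)[:n-i] == rc(x[i:])
    best = 0
    for i in range(1, n):
        a, b = x[:i], x[i:]
        rca = rc[n - i :]
        rcb = rc[: n - i]
        if b.startswith(rca) or a.endswith(rcb):
            best = max(best, min(i, n - i))
    return best


def _self_minus_matches(contig: SeqRecord, min_len: int) -> list[Alignment]:
    return [
        al
        for al in find_matches([contig], [contig], min_len=min_len, min_identity=0.8)
        if al.strand == "-"
    ]


def detect_palindromes(
    contigs: list[SeqRecord], min_wrap: int = 1000
) -> list[PalindromeSignal]:
    """Flag contigs whose approximate wrapping length reaches *min_wrap*.

    Palindromes are found by aligning each contig against itself and
    keeping reverse-strand self-matches whose two footprints mirror each
    other around a common center.
    """
    if min_wrap <= 0:
        raise ValueError("min_wrap must be positive")
    signals: list[PalindromeSignal] = []
    for contig in contigs:
        n = len(contig)
        best: PalindromeSignal | None = None
        for al in _self_minus_matches(contig, min_len=min_wrap):
            lo = min(al.qstart, al.tstart)
            hi = max(al.qend, al.tend)
            # a reverse-strand self-match of a palindrome is (near) symmetric
            # about its center; require the two footprints to overlap the
            # mirrored layout rather than being a distant inverted repeat
            if al.qstart > al.tstart:
                continue  # mirror duplicate of a hit already seen
            gap = al.tstart - al.qend
            if gap > 0.2 * (hi - lo):
                continue
            split = (lo + hi) // 2
            wrap = min(split - lo, hi - split)
            if wrap >= min_wrap and 0 < split < n:
                if best is None or wrap > best.wrap_len:
                    best = PalindromeSignal(contig.id, wrap, split)
        if best is not None:
            signals.append(best)
    return signals


def _cluster_intervals(
    copies: list[tuple[str, int, int]], tol: float = 0.1
) -> list[int]:
    """Union-find grouping of near-identical intervals on the same contig."""
    parent = list(range(len(copies)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_contig: dict[str, list[int]] = {}
    for idx, (cid, _s, _e) in enumerate(copies):
        by_contig.setdefault(cid, []).append(idx)
    for idxs in by_contig.values():
        for ii, i in enumerate(idxs):
            _, si, ei = copies[i]
            for j in idxs[ii + 1 :]:
                _, sj, ej = copies[j]
                inter = min(ei, ej) - max(si, sj)
                shorter = min(ei - si, ej - sj)
                if inter > 0 and inter >= (1 - tol) * shorter and abs(si - sj) <= tol * shorter:
                    union(i, j)
    return [find(i) for i in range(len(copies))]


def detect_repeats(
    contigs: list[SeqRecord],
    min_repeat_len: int = 1000,
    min_identity: float = 0.9,
    alignments: list[Alignment] | None = None,
) -> list[RepeatEndpoint]:
    """Endpoints of maximal repeats of length >= *min_repeat_len*.

    Repeats are discovered by all-vs-all (including self) contig alignment
    on both strands; approximate copies are grouped under one repeat_id.
    Precomputed *alignments* (e.g. from an external aligner) may be
    supplied instead.
    """
    if min_repeat_len <= 0:
        raise ValueError("min_repeat_len must be positive")
    if alignments is None:
        alignments = find_matches(
            contigs, contigs, min_len=min_repeat_len, min_identity=min_identity
        )
    pair_edges: list[tuple[int, int]] = []
    copies: list[tuple[str, int, int]] = []
    copy_key: dict[tuple[str, int, int], int] = {}

    def copy_idx(cid: str, s: int, e: int) -> int:
        key = (cid, s, e)
        if key not in copy_key:
            copy_key[key] = len(copies)
            copies.append(key)
        return copy_key[key]

    for al in alignments:
        if al.length < min_repeat_len or al.identity < min_identity:
            continue
        if (
            al.query_id == al.target_id
            and al.strand == "+"
            and al.qstart == al.tstart
            and al.qend == al.tend
        ):
            continue
        i = copy_idx(al.query_id, al.qstart, al.qend)
        j = copy_idx(al.target_id, al.tstart, al.tend)
        if i != j:
            pair_edges.append((i, j))

    if not copies:
        return []

    roots = _cluster_intervals(copies)
    # merge clusters linked by an alignment (copies of the same repeat)
    parent = list(range(len(copies)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx, r in enumerate(roots):
        ri, rj = find(idx), find(r)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    for i, j in pair_edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    family_of: dict[int, int] = {}
    out: list[RepeatEndpoint] = []
    seen: set[tuple[str, int, str, int]] = set()
    for idx, (cid, s, e) in enumerate(copies):
        root = find(idx)
        fam = family_of.setdefault(root, len(family_of))
        for pos, side in ((s, "start"), (e, "end")):
            key = (cid, pos, side, fam)
            if key not in seen:
                seen.add(key)
                out.append(RepeatEndpoint(cid, pos, side, fam))
    return sorted(out, key=lambda ep: (ep.contig_id, ep.pos, ep.side, ep.repeat_id))


def best_alignments_per_read(alignments: list[Alignment]) -> list[Alignment]:
    """One alignment per read: highest identity*length, ties broken by
    lowest target id, forward strand first, then leftmost target start."""
    best: dict[str, Alignment] = {}
    for al in alignments:
        cur = best.get(al.query_id)
        if cur is None:
            best[al.query_id] = al
            continue
        score = (al.identity * al.length, )
        cur_score = (cur.identity * cur.length, )
        if score > cur_score or (
            score == cur_score
            and (al.target_id, al.strand, al.tstart)
            < (cur.target_id, cur.strand, cur.tstart)
        ):
            best[al.query_id] = al
    return [best[q] for q in sorted(best)]


def compute_coverage(
    contigs: list[SeqRecord],
    reads: list[SeqRecord],
    alignments: list[Alignment],
) -> CoverageProfile:
    """Depth and read-start counts per contig base.

    Each read contributes through its single best alignment; depth[i]
    counts alignments covering base i, starts[i] alignments beginning at
    base i (on the forward strand of the contig).
    """
    known = {c.id: len(c) for c in contigs}
    profile = CoverageProfile(
        depth={c.id: np.zeros(len(c), dtype=np.int64) for c in contigs},
        starts={c.id: np.zeros(len(c), dtype=np.int64) for c in contigs},
    )
    for al in best_alignments_per_read(alignments):
        if al.target_id not in known:
            raise KeyError(f"alignment references unknown contig {al.target_id!r}")
        n = known[al.target_id]
        ts, te = max(0, al.tstart), min(n, al.tend)
        if ts >= te:
            continue
        d = profile.depth[al.target_id]
        d[ts:te] += 1
        profile.starts[al.target_id][ts] += 1
    return profile


def write_signals(path, palindromes, repeats) -> None:
    """Tab-separated dump of the collected signals for inspection."""
    with open(path, "w") as fh:
        fh.write("contig_id\tpos\tkind\taux\n")
        for p in palindromes:
            fh.write(f"{p.contig_id}\t{p.split_pos}\tpalindrome\twrap={p.wrap_len}\n")
        for r in repeats:
            fh.write(f"{r.contig_id}\t{r.pos}\trepeat\t{r.side},family={r.repeat_id}\n")
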