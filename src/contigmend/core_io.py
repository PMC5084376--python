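"""Sequence records, FASTA/FASTQ I/O and a pluggable overlap finder.

The internal aligner is an exact k-mer seed-and-extend local aligner: shared
k-mers are merged into maximal exact runs along diagonals, runs are chained
within a diagonal band, and the gaps between chained runs are closed with a
small edit-distance DP.  An adapter for the tabular output of an external
aligner (``show-coords -r -c -l -T``) is provided so the two sources of
overlap information are interchangeable downstream: everything after this
module consumes only :class:`Alignment`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SeqRecord",
    "Alignment",
    "read_fasta",
    "read_fastq",
    "read_seqs",
    "write_fasta",
    "reverse_complement",
    "edit_distance",
    "find_matches",
    "parse_show_coords",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code; N deliberately absent (k-mers containing N are skipped)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


class FastaParseError(ValueError):
    """Raised when a sequence file cannot be parsed."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (contig, read or genome)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"SeqRecord {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """A local match between a query and a target sequence.

    Coordinates are 0-based half-open on the forward strand of each
    sequence.  ``strand == "-"`` means the query matches the reverse
    complement of the target interval.
    """

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    identity: float
    length: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError(f"bad query interval [{self.qstart},{self.qend})")
        if not (0 <= self.tstart < self.tend):
            raise ValueError(f"bad target interval [{self.tstart},{self.tend})")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def reverse_complement(s: str) -> str:
    """Watson-Crick complement, reversed; N maps to N."""
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file into records.

    Sequences are uppercased and line wraps joined.  A parse error names
    the offending line number.
    """
    records: list[SeqRecord] = []
    name = None
    chunks: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(SeqRecord(name, "".join(chunks).upper()))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    if name is not None:
        records.append(SeqRecord(name, "".join(chunks).upper()))
    return records


def read_fastq(path) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTQ file; quality lines are discarded."""
    records: list[SeqRecord] = []
    with _open_maybe_gzip(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) % 4 != 0:
        raise FastaParseError(f"{path}: FASTQ record count is not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, _qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FastaParseError(f"{path}: malformed FASTQ record near line {i + 1}")
        records.append(SeqRecord(head[1:].split()[0], seq.upper()))
    return records


def read_seqs(path) -> list[SeqRecord]:
    """Dispatch on extension: .fq/.fastq (optionally .gz) as FASTQ, else FASTA."""
    stem = str(path)
    if stem.endswith(".gz"):
        stem = stem[: -len(".gz")]
    if stem.endswith((".fq", ".fastq")):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SeqRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# internal aligner
# ---------------------------------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit costs), Myers' bit-parallel algorithm.

    Python integers are unbounded, so the bit vectors work for any pattern
    length; cost is O(|b| * |a|/64).
    """
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) > len(b):
        a, b = b, a
    m = len(a)
    peq: dict[str, int] = {}
    for i, c in enumerate(a):
        peq[c] = peq.get(c, 0) | (1 << i)
    mask = (1 << m) - 1
    last = 1 << (m - 1)
    vp = mask
    vn = 0
    score = m
    for c in b:
        x = peq.get(c, 0) | vn
        d0 = (((x & vp) + vp) ^ vp) | x
        hn = vp & d0
        hp = vn | (~(d0 | vp) & mask)
        if hp & last:
            score += 1
        elif hn & last:
            score -= 1
        x = ((hp << 1) | 1) & mask
        vn = x & d0
        vp = ((hn << 1) | (~(x | d0) & mask)) & mask
    return score


def _edit_distance_scalar(a: str, b: str) -> int:
    """Plain O(nm) DP; reference implementation used for small gaps."""
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ai != b[j - 1]),
            )
        prev = cur
    return prev[m]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of all k-mers; -1 where the window contains N."""
    x = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(x)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = x != 255
    xi = np.where(valid, x, 0).astype(np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for i in range(k):
        codes |= xi[i : n - k + 1 + i] << (2 * i)
        ok &= valid[i : n - k + 1 + i]
    codes[~ok] = -1
    return codes


class _SortedKmerIndex:
    """Sorted (code, position) arrays; lookups via binary search."""

    __slots__ = ("codes", "positions")

    def __init__(self, codes: np.ndarray, positions: np.ndarray):
        self.codes = codes
        self.positions = positions


def _index_kmers(seq: str, k: int) -> _SortedKmerIndex:
    codes = _kmer_codes(seq, k)
    if codes.size == 0:
        return _SortedKmerIndex(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    keep = sorted_codes >= 0
    return _SortedKmerIndex(sorted_codes[keep], order[keep].astype(np.int64))


def _anchors(query: str, index: "_SortedKmerIndex", k: int) -> np.ndarray:
    """(qpos, tpos) pairs of shared k-mers, as an (n, 2) int array."""
    codes = _kmer_codes(query, k)
    if codes.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    lo = np.searchsorted(index.codes, codes, side="left")
    hi = np.searchsorted(index.codes, codes, side="right")
    counts = hi - lo
    counts[codes < 0] = 0
    total = int(counts.sum())
    if total == 0:
        return np.empty((0, 2), dtype=np.int64)
    qpos = np.repeat(np.arange(len(codes), dtype=np.int64), counts)
    # gather target positions run by run, fully vectorized:
    # idx = concat(arange(s_i, s_i + n_i)) built from a global cumsum
    starts = lo[counts > 0]
    lens = counts[counts > 0]
    step = np.ones(total, dtype=np.int64)
    head = np.r_[0, np.cumsum(lens)[:-1]]
    step[head[0]] = starts[0]
    if len(starts) > 1:
        step[head[1:]] = starts[1:] - (starts[:-1] + lens[:-1] - 1)
    idx = np.cumsum(step)
    tpos = index.positions[idx]
    return np.column_stack([qpos, tpos])


def _merge_runs(anchors: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Merge same-diagonal consecutive/overlapping anchors into
    (q, t, length) runs, vectorized."""
    if anchors.shape[0] == 0:
        return []
    diag = anchors[:, 0] - anchors[:, 1]
    order = np.lexsort((anchors[:, 0], diag))
    q = anchors[order, 0]
    t = anchors[order, 1]
    d = diag[order]
    # a new run starts where the diagonal changes or the q-step exceeds k
    new_run = np.ones(len(q), dtype=bool)
    if len(q) > 1:
        new_run[1:] = (d[1:] != d[:-1]) | (q[1:] - q[:-1] > k)
    starts = np.flatnonzero(new_run)
    ends_idx = np.r_[starts[1:] - 1, len(q) - 1]
    rq = q[starts]
    rt = t[starts]
    rlen = q[ends_idx] + k - rq
    return list(zip(rq.tolist(), rt.tolist(), rlen.tolist()))


def _chain_runs(
    runs: list[tuple[int, int, int]], band: int, max_gap: int
) -> list[list[tuple[int, int, int]]]:
    """Group exact runs into co-linear chains.

    Runs are bucketed by diagonal (split where consecutive diagonals differ
    by more than *band*), then ordered by query position with backwards
    steps dropped.  Within a bucket a chain breaks where the query gap
    exceeds *max_gap*.
    """
    if not runs:
        return []
    runs = sorted(runs, key=lambda r: (r[0] - r[1], r[0]))
    buckets: list[list[tuple[int, int, int]]] = [[runs[0]]]
    for r in runs[1:]:
        if (r[0] - r[1]) - (buckets[-1][-1][0] - buckets[-1][-1][1]) > band:
            buckets.append([r])
        else:
            buckets[-1].append(r)
    chains: list[list[tuple[int, int, int]]] = []
    for bucket in buckets:
        bucket.sort(key=lambda r: (r[0], r[1]))
        cur: list[tuple[int, int, int]] = []
        for r in bucket:
            if not cur:
                cur = [r]
                continue
            pq, pt, plen = cur[-1]
            if r[0] >= pq + plen and r[1] >= pt + plen:
                if r[0] - (pq + plen) > max_gap:
                    chains.append(cur)
                    cur = [r]
                else:
                    cur.append(r)
            elif r[0] - pq > 0 and r[1] - pt > 0 and r[2] > plen:
                cur[-1] = r  # overlapping alternative, keep the longer run
        if cur:
            chains.append(cur)
    return chains


def _extend_exact(query: str, target: str, qs, qe, ts, te):
    """Greedy exact extension of a chain span in both directions."""
    while qs > 0 and ts > 0 and query[qs - 1] == target[ts - 1]:
        qs -= 1
        ts -= 1
    n, m = len(query), len(target)
    while qe < n and te < m and query[qe] == target[te]:
        qe += 1
        te += 1
    return qs, qe, ts, te


def _chain_to_alignment(
    query: str, target: str, chain: list[tuple[int, int, int]], max_gap: int
):
    """Turn one chain into (qs, qe, ts, te, edits) with gap DPs, or None."""
    qs, ts = chain[0][0], chain[0][1]
    qe = chain[-1][0] + chain[-1][2]
    te = chain[-1][1] + chain[-1][2]
    qs, qe, ts, te = _extend_exact(query, target, qs, qe, ts, te)
    edits = 0
    for (pq, pt, plen), (nq, nt, _nl) in zip(chain, chain[1:]):
        gq = query[pq + plen : nq]
        gt = target[pt + plen : nt]
        if len(gq) > max_gap or len(gt) > max_gap:
            return None
        if len(gq) <= 4 or len(gt) <= 4:
            # cheap upper bound, exact for pure-indel gaps
            edits += max(len(gq), len(gt))
        else:
            edits += edit_distance(gq, gt)
    return qs, qe, ts, te, edits


class _TargetIndex:
    """k-mer index over the concatenation of all targets (both strands),
    with N separators so no k-mer spans a boundary."""

    def __init__(self, targets: Sequence[SeqRecord], k: int, strands: str = "+-"):
        self.k = k
        parts: list[str] = []
        meta: list[tuple[str, str, int]] = []  # (target_id, strand, target_len)
        offsets: list[int] = []
        pos = 0
        for t in targets:
            both = (("+", t.seq), ("-", reverse_complement(t.seq)))
            for strand, seq in both:
                if strand not in strands:
                    continue
                parts.append(seq)
                meta.append((t.id, strand, len(seq)))
                offsets.append(pos)
                pos += len(seq) + 1
        self.cat = "N".join(parts)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.ends = self.offsets + np.array([m[2] for m in meta], dtype=np.int64)
        self.meta = meta
        self.index = _index_kmers(self.cat, k)
        self.seqs = parts

    def block_of(self, tpos: int) -> int:
        return int(np.searchsorted(self.offsets, tpos, side="right") - 1)


def find_matches(
    set_a: Sequence[SeqRecord],
    set_b: Sequence[SeqRecord],
    min_len: int = 300,
    min_identity: float = 0.7,
    k: int = 15,
    band: int = 400,
    max_gap: int = 500,
    max_hits_per_query: int | None = None,
    strands: str = "+-",
) -> list[Alignment]:
    """Local alignments between every query in *set_a* and target in *set_b*.

    Both strands are searched.  Trivial self-identity hits (same record id,
    same coordinates, forward strand) are suppressed so the function can be
    used for self-repeat discovery.  *max_hits_per_query* keeps only the
    chains with the most anchor support before the (expensive) gap closing
    — useful for dense read-vs-read overlap queries.  Results are sorted
    by (query_id, qstart, target_id, tstart, strand).
    """
    k = max(2, min(k, min_len))
    tindex = _TargetIndex(set_b, k, strands=strands)
    out: list[Alignment] = []
    for a in set_a:
        anchors = _anchors(a.seq, tindex.index, k)
        if anchors.shape[0] == 0:
            continue
        # split anchors by target block so chains never cross targets
        blocks = np.searchsorted(tindex.offsets, anchors[:, 1], side="right") - 1
        pending: list[tuple[int, int, list]] = []  # (-anchor_bases, blk, chain)
        for blk in np.unique(blocks):
            sub = anchors[blocks == blk].copy()
            sub[:, 1] -= int(tindex.offsets[blk])
            for chain in _chain_runs(_merge_runs(sub, k), band, max_gap):
                support = sum(r[2] for r in chain)
                pending.append((-support, int(blk), chain))
        if max_hits_per_query is not None and len(pending) > max_hits_per_query:
            pending.sort(key=lambda x: x[0])
            pending = pending[:max_hits_per_query]
        for _sup, blk, chain in pending:
            tid, strand, tlen = tindex.meta[blk]
            tseq = tindex.seqs[blk]
            res = _chain_to_alignment(a.seq, tseq, chain, max_gap)
            if res is None:
                continue
            qs, qe, ts, te, edits = res
            if qe - qs < min_len:
                continue
            span = max(qe - qs, te - ts)
            identity = 1.0 - edits / span
            if identity < min_identity:
                continue
            if strand == "-":
                ts, te = tlen - te, tlen - ts
            if a.id == tid and strand == "+" and qs == ts and qe == te:
                continue  # trivial identity diagonal
            out.append(
                Alignment(
                    query_id=a.id,
                    target_id=tid,
                    qstart=qs,
                    qend=qe,
                    tstart=ts,
                    tend=te,
                    strand=strand,
                    identity=identity,
                    length=qe - qs,
                )
            )
    dedup = {
        (al.query_id, al.target_id, al.qstart, al.qend, al.tstart, al.tend, al.strand): al
        for al in out
    }
    return sorted(
        dedup.values(),
        key=lambda al: (al.query_id, al.qstart, al.target_id, al.tstart, al.strand),
    )


# ---------------------------------------------------------------------------
# external aligner adapter
# ---------------------------------------------------------------------------


def parse_show_coords(path_or_lines) -> list[Alignment]:
    """Parse ``show-coords -r -c -l -T`` tabular output into Alignments.

    The external tool prints 1-based inclusive coordinates; reverse-strand
    hits have a descending second coordinate pair.  All coordinates are
    converted to the internal 0-based half-open convention here, at the
    boundary.
    """
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    out: list[Alignment] = []
    for line in lines:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9:
            continue
        try:
            s1, e1, s2, e2 = (int(p) for p in parts[0:4])
            len1 = int(parts[4])
            idy = float(parts[6])
        except ValueError:
            continue  # header / separator lines
        ref_id, qry_id = parts[-2], parts[-1]
        strand = "+" if s2 <= e2 else "-"
        if strand == "-":
            s2, e2 = e2, s2
        out.append(
            Alignment(
                query_id=qry_id,
                target_id=ref_id,
                qstart=s2 - 1,
                qend=e2,
                tstart=s1 - 1,
                tend=e1,
                strand=strand,
                identity=idy / 100.0,
                length=len1,
            )
        )
    return sorted(
        out, key=lambda al: (al.query_id, al.qstart, al.target_id, al.tstart, al.strand)
    )
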