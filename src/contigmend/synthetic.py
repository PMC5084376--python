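"""Synthetic fixtures: random communities sharing a long repeat, indel-noise
long reads at chosen abundances, artificially swapped (mis-assembled)
contigs, Markov-switching Poisson count tracks, and a small truth-based
assembly evaluator.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import SeqRecord, find_matches

__all__ = [
    "CommunitySpec",
    "SegSimSpec",
    "CommunityTruth",
    "generate_community",
    "sample_reads",
    "make_misassembled_contigs",
    "simulate_markov_poisson",
    "evaluate_against_truth",
    "n_statistic",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    genome_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    abundances: tuple[float, ...] = (2 / 7, 5 / 7)
    repeat_len: int = 12_000
    read_len: int = 6_000
    coverages: tuple[float, ...] = (20.0, 50.0)
    indel_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        k = len(self.genome_lengths)
        if len(self.abundances) != k or len(self.coverages) != k:
            raise ValueError("genome_lengths, abundances, coverages must align")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if self.repeat_len < 0 or self.repeat_len >= min(self.genome_lengths):
            raise ValueError("repeat_len must be < min genome length")
        if any(c <= 0 for c in self.coverages):
            raise ValueError("coverages must be positive")
        if not (0 <= self.indel_rate < 0.5):
            raise ValueError("indel_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class SegSimSpec:
    n: int = 100
    means: tuple[float, float] = (20.0, 50.0)
    p_switch: float = 0.1
    rounds: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if any(m <= 0 for m in self.means):
            raise ValueError("means must be positive")
        if not (0 < self.p_switch < 1):
            raise ValueError("p_switch must be in (0, 1)")


@dataclass
class CommunityTruth:
    """Repeat coordinates per genome: (repeat_start, repeat_end)."""

    repeat: str
    junctions: dict[str, tuple[int, int]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def generate_community(spec: CommunitySpec) -> tuple[list[SeqRecord], CommunityTruth]:
    """Genomes g_i = x_i + r + y_i with independent random flanks and one
    shared repeat r placed centrally; truth records the repeat coordinates."""
    rng = np.random.default_rng(spec.seed)
    repeat = _random_seq(rng, spec.repeat_len) if spec.repeat_len else ""
    genomes: list[SeqRecord] = []
    truth = CommunityTruth(repeat=repeat)
    for gi, glen in enumerate(spec.genome_lengths):
        flank = glen - spec.repeat_len
        left = flank // 2
        right = flank - left
        seq = _random_seq(rng, left) + repeat + _random_seq(rng, right)
        name = f"g{gi + 1}"
        genomes.append(SeqRecord(name, seq))
        truth.junctions[name] = (left, left + spec.repeat_len)
    return genomes, truth


def _corrupt(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per base: deletion with rate/2, random single-base insertion after
    the base with rate/2."""
    if rate <= 0:
        return seq
    x = np.frombuffer(seq.encode(), dtype=np.uint8)
    u = rng.random(len(x))
    keep = u >= rate / 2
    insert = u >= 1 - rate / 2
    pieces: list[bytes] = []
    ins_pos = np.flatnonzero(insert)
    ins_base = _BASES[rng.integers(0, 4, size=len(ins_pos))]
    out = []
    prev = 0
    for p, b in zip(ins_pos, ins_base):
        out.append(x[prev : p + 1][keep[prev : p + 1]])
        out.append(np.array([b], dtype=np.uint8))
        prev = p + 1
    out.append(x[prev:][keep[prev:]])
    return np.concatenate(out).tobytes().decode()


def sample_reads(
    genomes: list[SeqRecord], spec: CommunitySpec, random_strand: bool = False
) -> list[SeqRecord]:
    """Uniform start positions; read count = coverage * length / read_len
    per genome, rounded up; indel corruption at spec.indel_rate."""
    rng = np.random.default_rng(spec.seed + 1)
    reads: list[SeqRecord] = []
    for genome, cov in zip(genomes, spec.coverages):
        glen = len(genome)
        if spec.read_len > glen:
            raise ValueError("read_len exceeds genome length")
        n_reads = int(np.ceil(cov * glen / spec.read_len))
        starts = rng.integers(0, glen - spec.read_len + 1, size=n_reads)
        for i, s in enumerate(sorted(starts.tolist())):
            sub = genome.seq[s : s + spec.read_len]
            sub = _corrupt(rng, sub, spec.indel_rate)
            if random_strand and rng.random() < 0.5:
                from .core_io import reverse_complement

                sub = reverse_complement(sub)
            reads.append(SeqRecord(f"{genome.id}_r{i}", sub))
    return reads


def make_misassembled_contigs(
    genomes: list[SeqRecord], truth: CommunityTruth
) -> list[SeqRecord]:
    """Swap the post-repeat tails of the first two genomes:
    c1 = x1 r y2, c2 = x2 r y1."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to swap")
    g1, g2 = genomes[0], genomes[1]
    for g in (g1, g2):
        if g.id not in truth.junctions:
            raise KeyError(f"truth lacks repeat coordinates for {g.id!r}")
    s1, e1 = truth.junctions[g1.id]
    s2, e2 = truth.junctions[g2.id]
    c1 = g1.seq[:e1] + g2.seq[e2:]
    c2 = g2.seq[:e2] + g1.seq[e1:]
    return [SeqRecord("c1", c1), SeqRecord("c2", c2)]


def simulate_markov_poisson(spec: SegSimSpec, round_index: int = 0):
    """One replicate of the two-state Markov-switching Poisson track.

    Returns (counts, true_junctions): counts[i] ~ Poisson(mean of state i),
    true junctions are the positions i (1-based segment boundaries,
    junction i separates counts[i-1] and counts[i]) where the hidden state
    switches.  Initial state uniform.
    """
    rng = np.random.default_rng((spec.seed, round_index))
    states = np.empty(spec.n, dtype=np.int64)
    states[0] = rng.integers(0, 2)
    flips = rng.random(spec.n - 1) < spec.p_switch
    for i in range(1, spec.n):
        states[i] = states[i - 1] ^ int(flips[i - 1])
    means = np.asarray(spec.means)[states]
    counts = rng.poisson(means)
    junctions = [i for i in range(1, spec.n) if states[i] != states[i - 1]]
    return counts, junctions


def n_statistic(lengths, fraction: float) -> int:
    """Smallest length L such that contigs >= L cover *fraction* of the
    total assembly length (N50 at fraction=0.5)."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    total = sum(ls)
    if total == 0:
        return 0
    acc = 0
    for L in ls:
        acc += L
        if acc >= fraction * total:
            return L
    return ls[-1]


def evaluate_against_truth(
    contigs: list[SeqRecord],
    genomes: list[SeqRecord],
    min_anchor: int = 1000,
    max_dist: int = 1000,
):
    """Minimal truth-based evaluation: (n_contigs, misjoins, N50, N75,
    genome_fractions).

    Each contig is tiled with its alignments to the truth genomes; an
    adjacency between consecutive tiles mapping to different genomes, or to
    discordant loci (> *max_dist* apart, wrong order or orientation), is a
    misjoin.  genome_fractions maps genome id -> fraction of its bases
    covered by any contig alignment.
    """
    # namespace query ids so a contig named like a genome (e.g. evaluating
    # the truth against itself) keeps its identity diagonal
    queries = [SeqRecord(f"q::{c.id}", c.seq) for c in contigs]
    als = find_matches(queries, genomes, min_len=min_anchor, min_identity=0.7)
    als = [
        al.__class__(**{**al.__dict__, "query_id": al.query_id[3:]}) for al in als
    ]
    misjoins = 0
    cover: dict[str, np.ndarray] = {g.id: np.zeros(len(g), dtype=bool) for g in genomes}
    for al in als:
        cover[al.target_id][al.tstart : al.tend] = True
    for contig in contigs:
        hits = sorted(
            (al for al in als if al.query_id == contig.id),
            key=lambda al: (al.qstart, -(al.qend - al.qstart)),
        )
        # greedy tiling: keep hits that extend query coverage
        tiles = []
        qcov = 0
        for al in hits:
            if al.qend > qcov + min_anchor // 2:
                tiles.append(al)
                qcov = max(qcov, al.qend)
        for a, b in zip(tiles, tiles[1:]):
            if a.target_id != b.target_id or a.strand != b.strand:
                misjoins += 1
                continue
            gap_q = b.qstart - a.qend
            if a.strand == "+":
                gap_t = b.tstart - a.tend
            else:
                gap_t = a.tstart - b.tend
            if abs(gap_t - gap_q) > max_dist or gap_t < -max_dist:
                misjoins += 1
    lengths = [len(c) for c in contigs]
    fractions = {g.id: float(cover[g.id].mean()) for g in genomes}
    return (
        len(contigs),
        misjoins,
        n_statistic(lengths, 0.5),
        n_statistic(lengths, 0.75),
        fractions,
    )


def write_counts(path, counts) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(int(c)) for c in counts) + "\n")


def write_truth(path, truth: CommunityTruth) -> None:
    with open(path, "w") as fh:
        fh.write("genome\trepeat_start\trepeat_end\n")
        for gid, (s, e) in sorted(truth.junctions.items()):
            fh.write(f"{gid}\t{s}\t{e}\n")
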