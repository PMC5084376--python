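"""End-to-end orchestration of the break and merge stages."""

from __future__ import annotations

import logging

from .breaker import (
    _contained,
    build_break_graph,
    confirm_break_points,
    fix_chimeric_contigs,
    locate_potential_misassemblies,
)
from .config import PipelineConfig
from .contig_extender import choose_best_matching, merge_contigs
from .core_io import SeqRecord, find_matches
from .merger_graph import (
    build_contig_read_graph,
    condense_to_contig_graph,
    find_extension_candidates,
    make_end_veto,
    transitive_reduction,
)
from .signal_detector import (
    CoverageProfile,
    compute_coverage,
    detect_palindromes,
    detect_repeats,
)

logger = logging.getLogger(__name__)

__all__ = ["break_stage", "merge_stage", "run_pipeline"]


def _map_reads(reads, contigs, cfg: PipelineConfig):
    if not reads or not contigs:
        return []
    return find_matches(
        reads, contigs, min_len=cfg.read_min_len, min_identity=cfg.read_min_identity
    )


def break_stage(
    contigs: list[SeqRecord],
    reads: list[SeqRecord],
    cfg: PipelineConfig,
    alignments=None,
):
    """Palindrome fixing, repeat-graph break-point selection and coverage
    confirmation.  Returns (contigs, report rows)."""
    report: list[tuple] = []
    if not contigs:
        logger.warning("empty contig set")
        return [], report
    palindromes = detect_palindromes(contigs, cfg.min_wrap)
    for p in palindromes:
        report.append((p.contig_id, p.split_pos, "palindrome"))
    fixed = fix_chimeric_contigs(contigs, palindromes)
    repeats = detect_repeats(
        fixed, cfg.min_repeat_len, cfg.repeat_identity, alignments=alignments
    )
    graph = build_break_graph(fixed, repeats)
    break_set = locate_potential_misassemblies(graph, cfg.exhaust_limit)
    for j in sorted(break_set.junctions, key=str):
        report.append((*j, "candidate"))
    if reads:
        read_als = _map_reads(reads, fixed, cfg)
        coverage = compute_coverage(fixed, reads, read_als)
        out = confirm_break_points(
            fixed,
            break_set,
            coverage,
            alpha=cfg.alpha,
            merge_dist=cfg.merge_dist,
            report=report,
        )
    else:
        out = confirm_break_points(
            fixed,
            break_set,
            CoverageProfile(),
            require_confirmation=False,
            report=report,
        )
    return out, report


def _drop_contained(contigs: list[SeqRecord]) -> list[SeqRecord]:
    """Remove contigs exactly contained (up to rc) in a longer contig;
    duplicate repeat pieces from breaking collapse here."""
    out: list[SeqRecord] = []
    for c in sorted(contigs, key=lambda c: (-len(c.seq), c.id)):
        if not any(_contained(c.seq, h.seq) for h in out):
            out.append(c)
    order = {c.id: i for i, c in enumerate(contigs)}
    return sorted(out, key=lambda c: order[c.id])


def merge_stage(
    contigs: list[SeqRecord],
    reads: list[SeqRecord],
    cfg: PipelineConfig,
):
    """String-graph connectivity, graph surgery, matching decisions and
    merge execution.  Returns (contigs, report rows)."""
    report: list[tuple] = []
    if not contigs:
        logger.warning("empty contig set")
        return [], report
    contigs = _drop_contained(contigs)
    if not reads:
        return list(contigs), report
    read_als = _map_reads(reads, contigs, cfg)
    coverage = compute_coverage(contigs, reads, read_als)
    sgraph = build_contig_read_graph(contigs, reads, read_als, cfg.end_window)
    cgraph = condense_to_contig_graph(sgraph, coverage)
    cgraph = transitive_reduction(cgraph)
    veto = make_end_veto(contigs, read_als, cfg.end_window)
    candidates = find_extension_candidates(cgraph, veto=veto)
    contig_map = {c.id: c for c in contigs}
    depths = {c.id: coverage.robust_depth(c.id, cfg.end_window) for c in contigs}
    best_by_read: dict[str, set[str]] = {}
    for al in read_als:
        best_by_read.setdefault(al.query_id, set()).add(al.target_id)
    matchings = []
    for cand in candidates:
        if cfg.method == "em":
            members = set(cand.incoming) | set(cand.outgoing)
            if cand.repeat_node:
                members.add(cand.repeat_node)
            sub_reads = [
                r for r in reads if best_by_read.get(r.id, set()) & members
            ]
            repeat_seq = (
                contig_map[cand.repeat_node].seq
                if cand.repeat_node and cand.repeat_node in contig_map
                else ""
            )
            m = choose_best_matching(
                cand,
                sub_reads,
                method="em",
                contigs=contig_map,
                repeat_seq=repeat_seq,
                coverage=coverage,
                depths=depths,
                q=cfg.q,
                max_iter=cfg.em_max_iter,
                min_span=cfg.min_span,
                rel_tol=cfg.rel_tol,
                runner_margin=cfg.runner_margin,
            )
        else:
            m = choose_best_matching(
                cand,
                reads,
                method="heuristic",
                coverage=coverage,
                depths=depths,
                min_span=cfg.min_span,
                rel_tol=cfg.rel_tol,
                runner_margin=cfg.runner_margin,
            )
        matchings.append(m)
        for a, b in sorted(m.pairs):
            report.append(
                (a, b, cfg.method, cand.repeat_node or "-", m.score if m.score is not None else "-")
            )
    merged, provenance = merge_contigs(contigs, matchings, contig_map)
    return merged, report


def run_pipeline(contigs, reads, cfg: PipelineConfig):
    """break_stage followed by merge_stage on its output."""
    broken, break_report = break_stage(contigs, reads, cfg)
    merged, merge_report = merge_stage(broken, reads, cfg)
    return merged, break_report, merge_report
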