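"""The three-step HGT scan.

Step 1: cut the host genome into sliding 5 kb windows (1 kb step) and the
host + reference genomes into non-overlapping 5 kb training fragments.

Step 2: train one joint BLSOM on all training fragments, label every lattice
node by which training sources reached it — host only (host territory),
references only (prokaryote territory), both (mixed), none (empty) — and map
each host window to its best-matching node.  Windows landing on prokaryote
territory are HGT candidate segments; their putative phylum is the most
abundant reference phylum at that node.  A contig is assigned to a phylum
when the top phylum accounts for more than 40% of its candidate segments
(strictly; the denominator is configurable to all of the contig's segments).

Step 3: candidate segments are mapped again on per-phylum maps trained only
on that phylum's reference fragments, whose nodes are labelled by majority
genus, giving a genus-rank call where the references resolve that far.

Mixed nodes never produce candidates; node-level ties in the majority label
leave the rank unassigned rather than picking arbitrarily.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import blsom
from .blsom import Lattice, TrainingConfig
from .composition import (
    DegenerateKmerIndex,
    Segment,
    SequenceRecord,
    SourceClass,
    build_index,
    fragment_training,
    segment_sliding,
)

logger = logging.getLogger("blsomhgt")

UNASSIGNED = "Unassigned"


class Territory(IntEnum):
    EMPTY = 0
    HOST = 1
    PROKARYOTE = 2
    MIXED = 3


class PipelineError(RuntimeError):
    pass


@dataclass
class TerritoryMap:
    """Per-node training-fragment tallies and derived territory classes.

    ``phyla`` indexes the first axis of ``ref_counts``; ``node_phylum`` holds
    the most abundant reference phylum at each prokaryote node (None on ties
    or elsewhere).
    """

    phyla: tuple[str, ...]
    host_count: np.ndarray      # (I, J) int
    ref_counts: np.ndarray      # (n_phyla, I, J) int
    territory: np.ndarray       # (I, J) Territory values
    node_phylum: np.ndarray     # (I, J) object (str or None)


@dataclass
class GenusMap:
    """Per-phylum lattice with nodes labelled by majority genus class.

    Reference fragments lacking a genus keep their coarser supplied rank
    label (the phylum string) as their class, so a node dominated by them is
    reported at that coarser rank rather than dropped.
    """

    phylum: str
    lattice: Lattice
    classes: tuple[str, ...]
    counts: np.ndarray          # (n_classes, I, J) int
    node_genus: np.ndarray      # (I, J) object (str or None)


@dataclass
class SegmentAssignment:
    segment: Segment
    node: tuple[int, int]
    territory: Territory
    is_hgt_candidate: bool
    phylum: Optional[str] = None
    genus: Optional[str] = None


@dataclass
class ContigAssignment:
    contig_id: str
    n_segments_total: int          # mapped (non-omitted) sliding segments
    n_candidate_segments: int
    phylum_counts: dict[str, int]  # candidate segments per phylum
    top_fraction: float
    assigned_phylum: Optional[str] = None
    assigned_genus: Optional[str] = None


def _majority(labels: Sequence[str], counts_by_label: dict[str, int]) -> Optional[str]:
    """Label with the strictly largest count, or None on a tie/empty."""
    if not counts_by_label:
        return None
    best = max(counts_by_label.values())
    winners = [l for l in labels if counts_by_label.get(l, 0) == best]
    return winners[0] if len(winners) == 1 else None


def _tally(
    lattice: Lattice, comps: np.ndarray, labels: Sequence[Optional[str]], classes: Sequence[str]
) -> np.ndarray:
    counts = np.zeros((len(classes), lattice.I, lattice.J), dtype=np.int64)
    if len(comps) == 0:
        return counts
    class_idx = {c: n for n, c in enumerate(classes)}
    flat = blsom.bmus(comps, lattice)
    for lab, f in zip(labels, flat):
        i, j = divmod(int(f), lattice.J)
        counts[class_idx[lab], i, j] += 1
    return counts


def label_territories(
    lattice: Lattice,
    host_comps: np.ndarray,
    ref_comps: np.ndarray,
    ref_phyla: Sequence[str],
) -> TerritoryMap:
    """Tally training-fragment BMUs on a trained lattice and classify nodes."""
    phyla = tuple(sorted(set(ref_phyla)))
    host_count = _tally(lattice, host_comps, ["host"] * len(host_comps), ("host",))[0]
    ref_counts = _tally(lattice, ref_comps, list(ref_phyla), phyla)
    ref_total = ref_counts.sum(axis=0)
    territory = np.full((lattice.I, lattice.J), int(Territory.EMPTY), dtype=np.int8)
    territory[host_count > 0] = Territory.HOST
    territory[(host_count == 0) & (ref_total > 0)] = Territory.PROKARYOTE
    territory[(host_count > 0) & (ref_total > 0)] = Territory.MIXED
    node_phylum = np.full((lattice.I, lattice.J), None, dtype=object)
    for i, j in zip(*np.nonzero(territory == Territory.PROKARYOTE)):
        counts_here = {p: int(ref_counts[n, i, j]) for n, p in enumerate(phyla)
                       if ref_counts[n, i, j] > 0}
        node_phylum[i, j] = _majority(phyla, counts_here)
    return TerritoryMap(phyla, host_count, ref_counts, territory, node_phylum)


def build_joint_map(
    host_fragments: Sequence[Segment],
    ref_fragments: Sequence[tuple[Segment, str]],
    config: TrainingConfig = TrainingConfig(),
    I: Optional[int] = None,  # noqa: E741
) -> tuple[Lattice, TerritoryMap]:
    """Train the joint host+reference map and derive its territories.

    ``ref_fragments`` pairs each reference training fragment with its phylum.
    Omitted fragments are ignored.
    """
    host = [s for s in host_fragments if not s.omitted]
    ref = [(s, p) for s, p in ref_fragments if not s.omitted]
    if not host or not ref:
        raise PipelineError("both host and reference fragment sets must be nonempty")
    host_comps = np.vstack([s.composition for s in host])
    ref_comps = np.vstack([s.composition for s, _ in ref])
    pooled = np.vstack([host_comps, ref_comps])
    lattice = blsom.pca_initialize(pooled, I=I, config=config)
    lattice = blsom.train(lattice, pooled, config)
    tmap = label_territories(lattice, host_comps, ref_comps, [p for _, p in ref])
    return lattice, tmap


def assign_segments(
    segments: Sequence[Segment], lattice: Lattice, territories: TerritoryMap
) -> list[SegmentAssignment]:
    """Map host sliding windows to their BMUs and flag prokaryote-territory hits."""
    live = [s for s in segments if not s.omitted]
    out: list[SegmentAssignment] = []
    if not live:
        return out
    flat = blsom.bmus(np.vstack([s.composition for s in live]), lattice)
    for seg, f in zip(live, flat):
        i, j = divmod(int(f), lattice.J)
        terr = Territory(int(territories.territory[i, j]))
        cand = terr == Territory.PROKARYOTE
        out.append(
            SegmentAssignment(
                segment=seg,
                node=(i, j),
                territory=terr,
                is_hgt_candidate=cand,
                phylum=territories.node_phylum[i, j] if cand else None,
            )
        )
    return out


def call_contigs(
    assignments: Sequence[SegmentAssignment],
    threshold: float = 0.4,
    min_candidates: int = 1,
    denominator: str = "candidates",
) -> list[ContigAssignment]:
    """Contig-level phylum calls by the >threshold (default >40%) rule.

    A contig with at least ``min_candidates`` candidate segments is reported;
    it is assigned to its top phylum only when that phylum's candidate count,
    divided by the contig's candidate segments (or all its mapped segments
    when ``denominator='total'``), strictly exceeds ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if denominator not in ("candidates", "total"):
        raise ValueError("denominator must be 'candidates' or 'total'")
    by_contig: dict[str, list[SegmentAssignment]] = defaultdict(list)
    for a in assignments:
        by_contig[a.segment.contig_id].append(a)
    calls: list[ContigAssignment] = []
    for contig_id in sorted(by_contig):
        segs = by_contig[contig_id]
        cands = [a for a in segs if a.is_hgt_candidate]
        if len(cands) < max(min_candidates, 1):
            continue
        counts: dict[str, int] = defaultdict(int)
        for a in cands:
            if a.phylum is not None:
                counts[a.phylum] += 1
        denom = len(cands) if denominator == "candidates" else len(segs)
        top = _majority(sorted(counts), dict(counts))
        top_count = max(counts.values()) if counts else 0
        frac = top_count / denom if denom else 0.0
        assigned = top if (top is not None and frac > threshold) else None
        calls.append(
            ContigAssignment(
                contig_id=contig_id,
                n_segments_total=len(segs),
                n_candidate_segments=len(cands),
                phylum_counts=dict(counts),
                top_fraction=frac,
                assigned_phylum=assigned,
            )
        )
    return calls


def build_genus_maps(
    ref_fragments: Sequence[tuple[Segment, str, Optional[str]]],
    config: TrainingConfig = TrainingConfig(),
    I: Optional[int] = None,  # noqa: E741
) -> dict[str, GenusMap]:
    """One map per phylum, trained on that phylum's fragments only.

    ``ref_fragments`` rows are (fragment, phylum, genus-or-None).  Phyla with
    fewer than 3 usable fragments are skipped with a warning.
    """
    groups: dict[str, list[tuple[Segment, Optional[str]]]] = defaultdict(list)
    for seg, phylum, genus in ref_fragments:
        if not seg.omitted:
            groups[phylum].append((seg, genus))
    maps: dict[str, GenusMap] = {}
    for phylum in sorted(groups):
        rows = groups[phylum]
        if len(rows) < 3:
            logger.warning("phylum %s: only %d fragments, genus map skipped", phylum, len(rows))
            continue
        comps = np.vstack([s.composition for s, _ in rows])
        # genus-less fragments keep the coarser rank (the phylum string) as class
        classes_per_frag = [g if g is not None else phylum for _, g in rows]
        classes = tuple(sorted(set(classes_per_frag)))
        lattice = blsom.pca_initialize(comps, I=I, config=config)
        lattice = blsom.train(lattice, comps, config)
        counts = _tally(lattice, comps, classes_per_frag, classes)
        node_genus = np.full((lattice.I, lattice.J), None, dtype=object)
        occupied = counts.sum(axis=0) > 0
        for i, j in zip(*np.nonzero(occupied)):
            here = {c: int(counts[n, i, j]) for n, c in enumerate(classes)
                    if counts[n, i, j] > 0}
            node_genus[i, j] = _majority(classes, here)
        maps[phylum] = GenusMap(phylum, lattice, classes, counts, node_genus)
    return maps


def refine_to_genus(
    assignments: Sequence[SegmentAssignment],
    genus_maps: dict[str, GenusMap],
    contig_calls: Optional[Sequence[ContigAssignment]] = None,
    threshold: float = 0.4,
) -> None:
    """Map phylum-assigned candidates onto their phylum's genus map (in place).

    A segment's genus is the majority genus class of its BMU node (absent on
    ties or empty nodes); a contig's genus is then called with the same
    strict >threshold rule over its genus-labelled candidate segments of the
    assigned phylum.
    """
    by_phylum: dict[str, list[SegmentAssignment]] = defaultdict(list)
    for a in assignments:
        if a.is_hgt_candidate and a.phylum is not None:
            by_phylum[a.phylum].append(a)
    for phylum, group in sorted(by_phylum.items()):
        gm = genus_maps.get(phylum)
        if gm is None:
            logger.warning(
                "no genus map for phylum %s; %d segments stay at phylum rank",
                phylum, len(group),
            )
            continue
        comps = np.vstack([a.segment.composition for a in group])
        flat = blsom.bmus(comps, gm.lattice)
        for a, f in zip(group, flat):
            i, j = divmod(int(f), gm.lattice.J)
            a.genus = gm.node_genus[i, j]
    if contig_calls is None:
        return
    by_contig: dict[str, list[SegmentAssignment]] = defaultdict(list)
    for a in assignments:
        by_contig[a.segment.contig_id].append(a)
    for call in contig_calls:
        if call.assigned_phylum is None:
            continue
        labelled = [
            a for a in by_contig[call.contig_id]
            if a.is_hgt_candidate and a.phylum == call.assigned_phylum and a.genus is not None
        ]
        counts: dict[str, int] = defaultdict(int)
        for a in labelled:
            counts[a.genus] += 1
        top = _majority(sorted(counts), dict(counts))
        if top is not None and counts[top] / len(labelled) > threshold:
            call.assigned_genus = top


def summarize(
    contig_calls: Sequence[ContigAssignment],
    assignments: Sequence[SegmentAssignment],
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Phylum- and genus-level contig count tables plus headline statistics.

    The phylum table lists contigs per assigned phylum with an Unassigned row
    and a Total row equal to the number of candidate-bearing contigs.  The
    genus table lists phylum/genus contig counts for phylum-assigned contigs
    (genus Unassigned where refinement did not resolve one).  Stats include
    the candidate-segment count and its fraction of all mapped segments.
    """
    phylum_counts: dict[str, int] = defaultdict(int)
    for c in contig_calls:
        phylum_counts[c.assigned_phylum or UNASSIGNED] += 1
    rows = [
        {"phylum": p, "n_contigs": phylum_counts[p]}
        for p in sorted(phylum_counts, key=lambda p: (p == UNASSIGNED, p))
        if p != UNASSIGNED
    ]
    rows.append({"phylum": UNASSIGNED, "n_contigs": phylum_counts.get(UNASSIGNED, 0)})
    rows.append({"phylum": "Total", "n_contigs": len(contig_calls)})
    phylum_table = pd.DataFrame(rows, columns=["phylum", "n_contigs"])

    genus_counts: dict[tuple[str, str], int] = defaultdict(int)
    for c in contig_calls:
        if c.assigned_phylum is not None:
            genus_counts[(c.assigned_phylum, c.assigned_genus or UNASSIGNED)] += 1
    genus_table = pd.DataFrame(
        [
            {"phylum": p, "genus": g, "n_contigs": n}
            for (p, g), n in sorted(genus_counts.items())
        ],
        columns=["phylum", "genus", "n_contigs"],
    )
    n_candidates = sum(a.is_hgt_candidate for a in assignments)
    stats = {
        "n_segments_mapped": len(assignments),
        "n_candidate_segments": int(n_candidates),
        "candidate_segment_fraction": n_candidates / len(assignments) if assignments else 0.0,
        "n_candidate_contigs": len(contig_calls),
        "n_assigned_contigs": sum(c.assigned_phylum is not None for c in contig_calls),
    }
    return phylum_table, genus_table, stats


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class PipelineResult:
    index: DegenerateKmerIndex
    lattice: Lattice
    territories: TerritoryMap
    genus_maps: dict[str, GenusMap]
    segments: list[Segment]                  # all sliding windows, incl. omitted
    assignments: list[SegmentAssignment]     # non-omitted sliding windows
    contig_calls: list[ContigAssignment]
    phylum_table: pd.DataFrame
    genus_table: pd.DataFrame
    stats: dict
    exclusions: dict = field(default_factory=dict)


def run_pipeline(
    host_records: Sequence[SequenceRecord],
    ref_records: Sequence[SequenceRecord],
    cfg,
) -> PipelineResult:
    """Run the full scan: train, map, call at phylum rank, refine to genus.

    ``cfg`` is a RunConfig (see blsomhgt.io); its training sub-config drives
    both the joint and the per-phylum maps.
    """
    index = build_index(cfg.k)
    tc = cfg.training_config()

    host_train: list[Segment] = []
    n_short_host = 0
    for rec in host_records:
        if len(rec) < cfg.min_contig:
            n_short_host += 1
            continue
        host_train.extend(
            fragment_training(rec, index, cfg.window, n_fraction_max=cfg.n_fraction_max)
        )
    ref_train: list[tuple[Segment, str, Optional[str]]] = []
    n_short_ref = 0
    for rec in ref_records:
        if rec.source_class != SourceClass.REFERENCE:
            raise PipelineError(f"record {rec.id!r} is not a reference record")
        frags = fragment_training(
            rec, index, cfg.window, min_total=cfg.min_reference_total,
            n_fraction_max=cfg.n_fraction_max,
        )
        if not frags:
            n_short_ref += 1
            continue
        ref_train.extend((f, rec.phylum, rec.genus) for f in frags)

    lattice, tmap = build_joint_map(
        host_train, [(f, p) for f, p, _ in ref_train], config=tc, I=cfg.lattice_width
    )
    genus_maps = build_genus_maps(ref_train, config=tc)

    segments: list[Segment] = []
    for rec in host_records:
        if len(rec) < cfg.min_contig:
            continue
        segments.extend(
            segment_sliding(rec, index, cfg.window, cfg.step, n_fraction_max=cfg.n_fraction_max)
        )
    assignments = assign_segments(segments, lattice, tmap)
    contig_calls = call_contigs(
        assignments,
        threshold=cfg.contig_threshold,
        min_candidates=cfg.min_candidates,
        denominator=cfg.contig_denominator,
    )
    refine_to_genus(assignments, genus_maps, contig_calls, threshold=cfg.contig_threshold)
    phylum_table, genus_table, stats = summarize(contig_calls, assignments)

    n_omitted = sum(s.omitted for s in segments)
    exclusions = {
        "short_host_contigs": n_short_host,
        "short_reference_records": n_short_ref,
        "omitted_segments": int(n_omitted),
        "tied_prokaryote_nodes": int(
            sum(
                1
                for i, j in zip(*np.nonzero(tmap.territory == Territory.PROKARYOTE))
                if tmap.node_phylum[i, j] is None
            )
        ),
    }
    for key, n in exclusions.items():
        if n:
            logger.info("excluded/unresolved: %s = %d", key, n)
    stats["n_segments_total"] = len(segments)
    stats["n_segments_omitted"] = int(n_omitted)
    return PipelineResult(
        index=index,
        lattice=lattice,
        territories=tmap,
        genus_maps=genus_maps,
        segments=segments,
        assignments=assignments,
        contig_calls=contig_calls,
        phylum_table=phylum_table,
        genus_table=genus_table,
        stats=stats,
        exclusions=exclusions,
    )
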