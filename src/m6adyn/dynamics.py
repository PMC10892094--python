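"""Replicate consensus, condition classification and transcript assignment.

High-confidence peaks are those supported by all three biological
replicates of a condition; comparing the two conditions' consensus sets
partitions peaks into stress-enriched / control-enriched / shared, and
assigning peaks to overlapping transcripts yields per-transcript category
labels and the non-coding biotype breakdown.

Overlap criterion everywhere: >= 1 nt on the same strand, optionally
tightened to a fraction of the shorter interval via ``min_overlap_frac``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, Peak, TranscriptModel, overlap
from .core import NONCODING_BIOTYPES

log = logging.getLogger("m6adyn")

CATEGORIES = ("stress-enriched", "control-enriched", "shared")


@dataclass
class ConsensusPeak:
    """A peak supported by one member from every replicate of a condition."""

    interval: GenomicInterval
    members: tuple[str, ...]  # member peak names, one per replicate
    condition: str

    def to_peak(self, name: str | None = None) -> Peak:
        iv = self.interval
        return Peak(iv, len(iv) // 2, 0.0, 0.0, name or "|".join(self.members))


def _required_overlap(a: GenomicInterval, b: GenomicInterval, frac: float) -> int:
    if frac <= 0.0:
        return 1
    return max(1, int(frac * min(len(a), len(b))))


def _overlaps(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    return overlap(a, b, same_strand=True) >= _required_overlap(a, b, frac)


def consensus(
    replicate_peaks: list[list[Peak]],
    condition: str = "",
    min_overlap_frac: float = 0.0,
) -> list[ConsensusPeak]:
    """Group mutually overlapping peaks, one from each replicate.

    Candidate groups are examined in coordinate order (first replicate's
    peaks sorted by chrom/strand/start) and members are consumed greedily,
    so each member peak joins at most one consensus.  The consensus interval
    is the union (hull) of its members.
    """
    if len(replicate_peaks) < 2:
        raise ValueError("consensus needs at least two replicates")
    n_reps = len(replicate_peaks)
    used = [set() for _ in range(n_reps)]
    sorted_reps = [
        sorted(reps, key=lambda p: (p.interval.chrom, p.interval.strand,
                                    p.interval.start, p.interval.end, p.name))
        for reps in replicate_peaks
    ]
    out: list[ConsensusPeak] = []
    for i0, a in enumerate(sorted_reps[0]):
        group = [(0, i0, a)]
        ok = True
        for r in range(1, n_reps):
            found = None
            for ir, b in enumerate(sorted_reps[r]):
                if ir in used[r]:
                    continue
                if all(
                    _overlaps(b.interval, g.interval, min_overlap_frac)
                    for _, _, g in group
                ):
                    found = (r, ir, b)
                    break
            if found is None:
                ok = False
                break
            group.append(found)
        if not ok:
            continue
        for r, ir, _ in group:
            used[r].add(ir)
        ivs = [g.interval for _, _, g in group]
        hull = GenomicInterval(
            ivs[0].chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            ivs[0].strand,
        )
        out.append(
            ConsensusPeak(hull, tuple(g.name for _, _, g in group), condition)
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.strand, c.interval.start))
    return out


def classify(
    control_consensus: list[ConsensusPeak],
    stress_consensus: list[ConsensusPeak],
    min_overlap_frac: float = 0.0,
) -> tuple[list[ConsensusPeak], list[ConsensusPeak], list[ConsensusPeak]]:
    """Partition consensus peaks into (stress-enriched, control-enriched, shared).

    A stress peak overlapping any control peak (and vice versa) is shared;
    shared peaks are reported once, with the stress-side coordinates.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in control_consensus:
        iv = c.interval
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(iv.start, iv.end, c)
    stress_enriched, shared = [], []
    control_hit = set()
    for s in stress_consensus:
        iv = s.interval
        hits = [
            h.data
            for h in trees.get((iv.chrom, iv.strand), IntervalTree()).overlap(iv.start, iv.end)
            if _overlaps(iv, h.data.interval, min_overlap_frac)
        ]
        if hits:
            shared.append(s)
            control_hit.update(id(h) for h in hits)
        else:
            stress_enriched.append(s)
    control_enriched = [c for c in control_consensus if id(c) not in control_hit]
    return stress_enriched, control_enriched, shared


# ----------------------------------------------------------------------
# transcript assignment
# ----------------------------------------------------------------------
@dataclass
class TranscriptAssignment:
    """Peak->transcript assignment and per-transcript category labels."""

    table: pd.DataFrame  # transcript_id, gene_id, biotype, category
    peaks: dict  # category -> list[Peak]
    peak_hosts: dict  # (category, peak name) -> list of transcript_ids
    intergenic: list = field(default_factory=list)

    def transcripts_in(self, category: str) -> list[str]:
        t = self.table
        return list(t.loc[t["category"] == category, "transcript_id"])


def _exon_trees(annotation: list[TranscriptModel]) -> dict:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in annotation:
        for e in t.exons:
            trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
                e.start, e.end, t
            )
    return trees


def assign_to_transcripts(
    peaks_by_category: dict[str, list[Peak]],
    annotation: list[TranscriptModel],
) -> TranscriptAssignment:
    """Assign peaks to every same-strand exon-overlapping transcript and
    label transcripts by category with precedence stress > control > shared.

    Peaks overlapping no transcript are retained in an intergenic bucket
    with a logged count.
    """
    trees = _exon_trees(annotation)
    by_id = {t.transcript_id: t for t in annotation}
    hosts: dict[tuple[str, str], list[str]] = {}
    transcript_cats: dict[str, set] = {}
    intergenic = []
    for cat, plist in peaks_by_category.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        for p in plist:
            iv = p.interval
            tree = trees.get((iv.chrom, iv.strand))
            tids = sorted(
                {h.data.transcript_id for h in tree.overlap(iv.start, iv.end)}
            ) if tree is not None else []
            if not tids:
                intergenic.append(p)
                continue
            hosts[(cat, p.name)] = tids
            for tid in tids:
                transcript_cats.setdefault(tid, set()).add(cat)
    if intergenic:
        log.info("%d peaks overlapped no transcript (intergenic bucket)", len(intergenic))
    rows = []
    for tid in sorted(transcript_cats):
        cats = transcript_cats[tid]
        for cat in CATEGORIES:  # precedence order
            if cat in cats:
                label = cat
                break
        t = by_id[tid]
        rows.append(
            dict(transcript_id=tid, gene_id=t.gene_id, biotype=t.biotype, category=label)
        )
    table = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype", "category"])
    return TranscriptAssignment(table, dict(peaks_by_category), hosts, intergenic)


def ncrna_breakdown(assignment: TranscriptAssignment) -> pd.DataFrame:
    """Counts of unique non-coding transcripts per biotype x category.

    Rows: ncRNA biotypes (sorted by total, descending); columns: the three
    categories plus a total.
    """
    t = assignment.table
    nc = t[t["biotype"].isin(NONCODING_BIOTYPES)]
    if nc.empty:
        return pd.DataFrame(columns=[*CATEGORIES, "total"])
    pivot = (
        nc.pivot_table(
            index="biotype", columns="category", values="transcript_id",
            aggfunc="nunique", fill_value=0,
        )
        .reindex(columns=CATEGORIES, fill_value=0)
    )
    pivot["total"] = pivot.sum(axis=1)
    pivot = pivot.sort_values("total", ascending=False)
    pivot.columns.name = None
    return pivot
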