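"""Metagene density profiles, per-nucleotide m6A frequency, feature breakdown.

Three views of where m6A sits along transcripts:

* a binned read-density metagene over 5'UTR / CDS / 3'UTR (fixed bin count
  per region with fractional-nt weighting, so variable-length UTRs share a
  common axis);
* the per-nucleotide methylation frequency around the start or stop codon:
  frequency(p) = (# unique peaks of the category overlapping transcript
  position p) / (# methylated transcripts in the category), max-normalised
  over the +-flank window;
* the percent breakdown of peaks per category by the transcript feature
  their summit falls in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Peak, TranscriptModel
from .dynamics import CATEGORIES, TranscriptAssignment
from .peaks import WindowTrack

log = logging.getLogger("m6adyn")

METAGENE_REGIONS = ("5'UTR", "CDS", "3'UTR")
BREAKDOWN_FEATURES = ("5'UTR", "start_codon", "CDS", "stop_codon", "3'UTR", "other")


@dataclass
class MetageneProfile:
    regions: tuple
    n_bins: int
    density: np.ndarray  # shape (3, n_bins); mean normalized density
    n_transcripts: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, region in enumerate(self.regions):
            for b in range(self.n_bins):
                rows.append(dict(region=region, bin=b, density=self.density[r, b]))
        return pd.DataFrame(rows)

    def argmax_region(self) -> str:
        """Region containing the global maximum bin."""
        r, _ = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return self.regions[r]


def _per_nt_coverage(tracks: list[WindowTrack]) -> dict:
    """Summed per-nt coverage arrays keyed by (chrom, strand).

    Window counts are spread uniformly over their window.
    """
    cov: dict[tuple[str, str], np.ndarray] = {}
    for tr in tracks:
        arr = np.repeat(tr.counts.astype(float) / tr.window_size, tr.window_size)
        key = (tr.chrom, tr.strand)
        if key in cov:
            a, b = cov[key], arr
            if len(a) < len(b):
                a, b = b, a
            a[: len(b)] += b
            cov[key] = a
        else:
            cov[key] = arr
    return cov


def _transcript_coverage(t: TranscriptModel, cov: dict) -> np.ndarray:
    arr = cov.get((t.chrom, t.strand))
    out = np.zeros(t.length)
    if arr is None:
        return out
    pos = 0
    for e in t.exons:  # exons are in transcript orientation
        seg = arr[e.start : min(e.end, len(arr))]
        if len(seg) < len(e):
            seg = np.concatenate([seg, np.zeros(len(e) - len(seg))])
        if t.strand == "-":
            seg = seg[::-1]
        out[pos : pos + len(e)] = seg
        pos += len(e)
    return out


def _binned_density(cov: np.ndarray, lo: int, hi: int, n_bins: int) -> np.ndarray:
    """Per-nt density in n_bins equal fractions of [lo, hi) with fractional
    edge weighting (integral over the bin divided by the bin width)."""
    cum = np.concatenate([[0.0], np.cumsum(cov)])
    edges = lo + (hi - lo) * np.arange(n_bins + 1) / n_bins
    integ = np.interp(edges, np.arange(len(cum)), cum)
    widths = np.diff(edges)
    return np.diff(integ) / widths


def metagene_density(
    tracks: list[WindowTrack],
    annotation: list[TranscriptModel],
    n_bins: int = 20,
) -> MetageneProfile:
    """Mean normalized read-density profile over 5'UTR / CDS / 3'UTR.

    Each region of each coding transcript is divided into ``n_bins`` bins;
    per-bin per-nt densities are normalized by the transcript's total
    density and averaged across transcripts.  Transcripts missing a region
    are excluded with a logged count.
    """
    cov = _per_nt_coverage(tracks)
    total = np.zeros((3, n_bins))
    n_used = n_excluded = 0
    for t in annotation:
        if not t.is_coding:
            n_excluded += 1
            continue
        lens = t.region_lengths()
        if min(lens.values()) < 1:
            n_excluded += 1
            continue
        c = _transcript_coverage(t, cov)
        prof = np.vstack(
            [
                _binned_density(c, 0, t.cds_t_start, n_bins),
                _binned_density(c, t.cds_t_start, t.cds_t_end, n_bins),
                _binned_density(c, t.cds_t_end, t.length, n_bins),
            ]
        )
        s = prof.sum()
        if s <= 0:
            n_excluded += 1
            continue
        total += prof / s
        n_used += 1
    if n_excluded:
        log.info("metagene: %d transcripts excluded", n_excluded)
    density = total / n_used if n_used else total
    return MetageneProfile(METAGENE_REGIONS, n_bins, density, n_used, n_excluded)


# ----------------------------------------------------------------------
# per-nucleotide frequency around start / stop codons
# ----------------------------------------------------------------------
@dataclass
class FrequencyProfile:
    anchor: str  # start_codon | stop_codon
    offsets: np.ndarray  # -flank .. +flank
    raw: dict  # category -> np.ndarray in [0,1]
    normalized: dict  # category -> np.ndarray, max 1 when any raw > 0
    denominators: dict  # category -> # methylated transcripts used

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in self.raw:
            for i, off in enumerate(self.offsets):
                rows.append(
                    dict(category=cat, offset=int(off),
                         raw=self.raw[cat][i], normalized=self.normalized[cat][i])
                )
        return pd.DataFrame(rows)


def positional_frequency(
    assignment: TranscriptAssignment,
    annotation: list[TranscriptModel],
    anchor: str = "start_codon",
    flank: int = 100,
) -> FrequencyProfile:
    """Per-position methylation frequency per category around an anchor.

    For each transcript-coordinate position p in [anchor-flank, anchor+flank],
    raw(p) = (# unique peaks of the category overlapping p on the category's
    transcripts) / (# coding methylated transcripts in the category);
    normalized(p) = raw(p) / max over the window.  Empty categories yield an
    all-zero, flagged profile (no division by zero).
    """
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError("anchor must be start_codon or stop_codon")
    by_id = {t.transcript_id: t for t in annotation}
    offsets = np.arange(-flank, flank + 1)
    raw: dict[str, np.ndarray] = {}
    normalized: dict[str, np.ndarray] = {}
    denominators: dict[str, int] = {}
    for cat in CATEGORIES:
        tids = [
            tid for tid in assignment.transcripts_in(cat) if by_id[tid].is_coding
        ]
        denom = len(tids)
        hit_sets: list[set] = [set() for _ in offsets]
        tid_set = set(tids)
        for p in assignment.peaks.get(cat, []):
            for tid in assignment.peak_hosts.get((cat, p.name), []):
                if tid not in tid_set:
                    continue
                t = by_id[tid]
                span = t.genomic_to_transcript_span(p.interval)
                if span is None:
                    continue
                a = t.cds_t_start if anchor == "start_codon" else t.cds_t_end - 3
                lo = max(span[0] - a, -flank)
                hi = min(span[1] - a, flank + 1)
                for off in range(lo, hi):
                    hit_sets[off + flank].add(p.name)
        counts = np.array([len(s) for s in hit_sets], dtype=float)
        r = counts / denom if denom else np.zeros(len(offsets))
        m = r.max()
        if m <= 0:
            log.info("frequency: category %s has no overlaps (flagged zero profile)", cat)
            normalized[cat] = np.zeros(len(offsets))
        else:
            normalized[cat] = r / m
        raw[cat] = r
        denominators[cat] = denom
    return FrequencyProfile(anchor, offsets, raw, normalized, denominators)


# ----------------------------------------------------------------------
# feature breakdown (summit rule)
# ----------------------------------------------------------------------
def feature_breakdown(
    assignment: TranscriptAssignment,
    annotation: list[TranscriptModel],
    codon_flank: int = 0,
    multi_vote: bool = False,
) -> pd.DataFrame:
    """Percent of peaks per category by overlapped transcript feature.

    Default: each peak votes once, with the feature its summit falls in on
    its (longest) host transcript; summits not exonic in any host land in
    "other".  ``multi_vote=True`` lets a peak vote once for every feature
    its full span overlaps.  Percentages per category sum to 100.
    """
    by_id = {t.transcript_id: t for t in annotation}
    rows = {}
    for cat, plist in assignment.peaks.items():
        votes = {f: 0.0 for f in BREAKDOWN_FEATURES}
        for p in plist:
            tids = assignment.peak_hosts.get((cat, p.name), [])
            hosts = sorted(
                (by_id[t] for t in tids), key=lambda t: (-t.length, t.transcript_id)
            )
            feats: set[str] = set()
            if multi_vote:
                for h in hosts:
                    span = h.genomic_to_transcript_span(p.interval)
                    if span is None or not h.is_coding:
                        continue
                    feats.update(
                        h.region_of(tp, codon_flank) for tp in range(span[0], span[1])
                    )
            else:
                for h in hosts:
                    tp = h.genome_to_transcript(p.summit)
                    if tp is None:
                        continue
                    feats = {h.region_of(tp, codon_flank) if h.is_coding else "other"}
                    break
            if not feats:
                feats = {"other"}
            feats = {f if f in BREAKDOWN_FEATURES else "other" for f in feats}
            for f in feats:
                votes[f] += 1.0 / len(feats)
        n = sum(votes.values())
        rows[cat] = {f: 100.0 * v / n if n else 0.0 for f, v in votes.items()}
    df = pd.DataFrame(rows).T.reindex(columns=list(BREAKDOWN_FEATURES))
    df.index.name = "category"
    return df


def plot_metagene(profiles: dict, path: str) -> None:  # pragma: no cover
    """Line plot of one or more metagene profiles (label -> MetageneProfile)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for label, prof in profiles.items():
        ax.plot(prof.density.ravel(), label=label)
    nb = next(iter(profiles.values())).n_bins
    for x in (nb, 2 * nb):
        ax.axvline(x, color="grey", lw=0.5)
    ax.set_xticks([nb / 2, 1.5 * nb, 2.5 * nb])
    ax.set_xticklabels(METAGENE_REGIONS)
    ax.set_ylabel("mean normalized density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
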