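"""Core genomic data model.

All coordinates are 0-based half-open (BED convention) internally; GTF/GFF3
1-based inclusive coordinates are converted at the I/O boundary.  Strand is a
single character ``+`` or ``-`` and is honoured by every overlap operation
downstream: m6A-IP libraries are stranded and peaks are called per strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

STRANDS = ("+", "-")

#: biotypes recognised by the annotation reader; everything non-coding and
#: unlabelled collapses to "ncRNA"
BIOTYPES = ("mRNA", "lncRNA", "miRNA_precursor", "snoRNA", "ncRNA")
NONCODING_BIOTYPES = ("lncRNA", "miRNA_precursor", "snoRNA", "ncRNA")

#: transcript regions used by metagene / feature-breakdown analyses
REGIONS = ("5'UTR", "start_codon", "CDS", "stop_codon", "3'UTR")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlap(a: GenomicInterval, b: GenomicInterval, same_strand: bool = True) -> int:
    """Length (nt) of the intersection of two intervals.

    Returns 0 for disjoint intervals, different chromosomes, or — when
    ``same_strand`` is set — different strands.  Half-open convention: an
    abutting pair like [100,200) / [200,300) does not overlap.
    """
    if a.chrom != b.chrom:
        return 0
    if same_strand and a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class Peak:
    """A stranded enrichment peak (NarrowPeak-compatible).

    summit_offset is the summit position relative to interval.start;
    score is the IP/input enrichment fold; pvalue is the raw (not -log10)
    Poisson p-value of the best window.
    """

    interval: GenomicInterval
    summit_offset: int
    score: float
    pvalue: float
    name: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.summit_offset < len(self.interval):
            raise ValueError("summit_offset outside peak")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue must lie in [0,1]")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def summit(self) -> int:
        """Genomic position of the summit."""
        return self.interval.start + self.summit_offset


class TranscriptModel:
    """A transcript's exon structure with genome<->transcript coordinate maps.

    Parameters
    ----------
    exons
        Exon intervals; stored sorted 5'->3' in transcript orientation
        (genomically descending for minus-strand transcripts).
    cds_start, cds_end
        Genomic half-open CDS span (``None`` for non-coding transcripts).
        The stop codon is the last 3 nt of the CDS.
    """

    def __init__(
        self,
        transcript_id: str,
        gene_id: str,
        biotype: str,
        exons: list[GenomicInterval],
        cds_start: int | None = None,
        cds_end: int | None = None,
    ):
        if not exons:
            raise ValueError(f"transcript {transcript_id} has no exons")
        if biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {biotype!r}")
        chrom = exons[0].chrom
        strand = exons[0].strand
        if any(e.chrom != chrom or e.strand != strand for e in exons):
            raise ValueError("exons must share chrom and strand")
        exons = sorted(exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {transcript_id}")
        if strand == "-":
            exons = exons[::-1]  # 5'->3' in transcript orientation
        self.transcript_id = transcript_id
        self.gene_id = gene_id
        self.biotype = biotype
        self.exons = exons
        self.cds_start = cds_start
        self.cds_end = cds_end
        self.interval = GenomicInterval(
            chrom,
            min(e.start for e in exons),
            max(e.end for e in exons),
            strand,
        )
        # cumulative transcript offset of each exon's 5' end
        self._cum = [0]
        for e in exons:
            self._cum.append(self._cum[-1] + len(e))
        self.length = self._cum[-1]
        if (cds_start is None) != (cds_end is None):
            raise ValueError("cds_start/cds_end must be given together")
        if cds_start is not None:
            ts = self.genome_to_transcript(cds_start)
            te = self.genome_to_transcript(cds_end - 1)
            if ts is None or te is None:
                raise ValueError(f"CDS outside exons in {transcript_id}")
            self.cds_t_start, self.cds_t_end = min(ts, te), max(ts, te) + 1
        else:
            self.cds_t_start = self.cds_t_end = None

    # ------------------------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TranscriptModel({self.transcript_id}, {self.biotype}, "
            f"{self.chrom}:{self.interval.start}-{self.interval.end}"
            f"{self.strand}, {len(self.exons)} exons)"
        )

    # ------------------------------------------------------------------
    def genome_to_transcript(self, pos: int) -> int | None:
        """Spliced transcript-orientation offset of a genomic position.

        Returns ``None`` for intronic or outside positions.
        """
        for i, e in enumerate(self.exons):
            if e.start <= pos < e.end:
                if self.strand == "+":
                    return self._cum[i] + (pos - e.start)
                return self._cum[i] + (e.end - 1 - pos)
        return None

    def transcript_to_genome(self, tpos: int) -> int:
        """Genomic position of a transcript offset (inverse of the above)."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} outside [0,{self.length})")
        i = bisect.bisect_right(self._cum, tpos) - 1
        off = tpos - self._cum[i]
        e = self.exons[i]
        return e.start + off if self.strand == "+" else e.end - 1 - off

    def transcript_blocks(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Genomic exon blocks of the transcript-coordinate span [t_start, t_end).

        Blocks are returned 5'->3' in transcript orientation; a span crossing
        an exon junction yields multiple blocks.
        """
        if not 0 <= t_start < t_end <= self.length:
            raise ValueError("span outside transcript")
        blocks = []
        for i, e in enumerate(self.exons):
            lo = max(t_start, self._cum[i])
            hi = min(t_end, self._cum[i + 1])
            if lo >= hi:
                continue
            if self.strand == "+":
                blocks.append(
                    GenomicInterval(self.chrom, e.start + (lo - self._cum[i]),
                                    e.start + (hi - self._cum[i]), "+")
                )
            else:
                blocks.append(
                    GenomicInterval(self.chrom, e.end - (hi - self._cum[i]),
                                    e.end - (lo - self._cum[i]), "-")
                )
        return blocks

    def genomic_to_transcript_span(self, iv: GenomicInterval) -> tuple[int, int] | None:
        """Transcript-coordinate hull [t_start, t_end) of a genomic interval.

        Only exonic bases contribute; returns ``None`` when the interval does
        not touch any exon on the same strand/chromosome.
        """
        if iv.chrom != self.chrom or iv.strand != self.strand:
            return None
        tpos = []
        for i, e in enumerate(self.exons):
            lo, hi = max(iv.start, e.start), min(iv.end, e.end)
            if lo >= hi:
                continue
            tpos.append(self.genome_to_transcript(lo))
            tpos.append(self.genome_to_transcript(hi - 1))
        if not tpos:
            return None
        return min(tpos), max(tpos) + 1

    # ------------------------------------------------------------------
    def region_lengths(self) -> dict[str, int]:
        """Lengths (nt) of 5'UTR / CDS / 3'UTR in transcript coordinates.

        Non-coding transcripts have a single implicit region equal to the
        whole transcript; this raises for them.
        """
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        return {
            "5'UTR": self.cds_t_start,
            "CDS": self.cds_t_end - self.cds_t_start,
            "3'UTR": self.length - self.cds_t_end,
        }

    def region_of(self, tpos: int, codon_flank: int = 0) -> str:
        """Feature label of a transcript position.

        The start/stop codon features are the 3-nt codons themselves,
        optionally widened by ``codon_flank`` nt on each side.  Start codon
        takes precedence over stop when windows touch (degenerate CDS).
        """
        if not self.is_coding:
            return "ncRNA"
        if self.cds_t_start - codon_flank <= tpos < self.cds_t_start + 3 + codon_flank:
            return "start_codon"
        if self.cds_t_end - 3 - codon_flank <= tpos < self.cds_t_end + codon_flank:
            return "stop_codon"
        if tpos < self.cds_t_start:
            return "5'UTR"
        if tpos < self.cds_t_end:
            return "CDS"
        return "3'UTR"


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str  # control | copper
    assay: str  # rna | polysome | ip | input
    replicate: int


class CountMatrix:
    """Features x samples non-negative integer counts with sample metadata."""

    def __init__(
        self,
        feature_ids: list[str],
        samples: list[SampleInfo],
        counts: np.ndarray,
        library_size: np.ndarray | None = None,
    ):
        counts = np.asarray(counts)
        if counts.shape != (len(feature_ids), len(samples)):
            raise ValueError("counts shape must be (n_features, n_samples)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("feature_ids must be unique")
        self.feature_ids = list(feature_ids)
        self.samples = list(samples)
        self.counts = counts.astype(np.int64)
        if library_size is None:
            library_size = self.counts.sum(axis=0).astype(float)
        self.library_size = np.asarray(library_size, dtype=float)
        if (self.library_size <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def columns(self, condition: str | None = None, assay: str | None = None) -> list[int]:
        return [
            j
            for j, s in enumerate(self.samples)
            if (condition is None or s.condition == condition)
            and (assay is None or s.assay == assay)
        ]

    def subset(self, condition: str | None = None, assay: str | None = None) -> "CountMatrix":
        cols = self.columns(condition, assay)
        return CountMatrix(
            self.feature_ids,
            [self.samples[j] for j in cols],
            self.counts[:, cols],
            self.library_size[cols],
        )

    def rpm(self) -> np.ndarray:
        """Reads-per-million matrix: count * 1e6 / library_size."""
        return self.counts * 1e6 / self.library_size


def longest_per_gene(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Pick one representative transcript per gene: the longest isoform.

    Ties break on transcript_id for determinism.
    """
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None or (t.length, cur.transcript_id) > (cur.length, t.transcript_id):
            best[t.gene_id] = t
    return sorted(best.values(), key=lambda t: t.transcript_id)


def make_peak(chrom: str, start: int, end: int, strand: str,
              summit_offset: int | None = None, score: float = 0.0,
              pvalue: float = 1.0, name: str = ".") -> Peak:
    """Convenience constructor (summit defaults to the midpoint)."""
    iv = GenomicInterval(chrom, start, end, strand)
    if summit_offset is None:
        summit_offset = (end - start) // 2
    return Peak(iv, summit_offset, score, pvalue, name)
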