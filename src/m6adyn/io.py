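"""Readers and writers for the standard formats the pipeline touches.

GTF/GFF3 parsing goes through :mod:`gffutils`; FASTA access through
:mod:`pyfaidx`.  NarrowPeak / BedGraph / count-matrix TSV are simple
line formats written and read directly.  All conversion between 1-based
inclusive (GTF) and the internal 0-based half-open convention happens here.
"""

from __future__ import annotations

import logging
import math
import os

import gffutils
import numpy as np
import pandas as pd
import pyfaidx

from .core import (
    BIOTYPES,
    CountMatrix,
    GenomicInterval,
    Peak,
    SampleInfo,
    TranscriptModel,
)

log = logging.getLogger("m6adyn")


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------
def read_annotation(path: str) -> list[TranscriptModel]:
    """Read a GTF/GFF3 file into TranscriptModels.

    Records with malformed coordinates (end < start) are rejected with a
    logged warning; a transcript without exons raises.  Biotype is taken
    from a ``biotype``/``transcript_biotype``/``gene_biotype`` attribute,
    defaulting to mRNA when a CDS is present, else ncRNA.
    """
    kept, dropped = [], 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 5:
                try:
                    if int(f[4]) < int(f[3]):
                        dropped += 1
                        log.warning("rejecting malformed record (end < start): %s",
                                    line.strip())
                        continue
                except ValueError:
                    dropped += 1
                    log.warning("rejecting unparseable record: %s", line.strip())
                    continue
            kept.append(line)
    db = gffutils.create_db(
        "".join(kept),
        ":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for t in db.features_of_type(("transcript", "mRNA")):
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(t, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ValueError(f"transcript {t.id} has no exons")
        cds = list(db.children(t, featuretype="CDS", order_by="start"))
        cds_start = cds_end = None
        if cds:
            cds_start = min(c.start for c in cds) - 1
            cds_end = max(c.end for c in cds)
        biotype = None
        for key in ("biotype", "transcript_biotype", "gene_biotype"):
            if key in t.attributes:
                biotype = t.attributes[key][0]
                break
        if biotype is None:
            biotype = "mRNA" if cds else "ncRNA"
        if biotype not in BIOTYPES:
            biotype = "mRNA" if cds else "ncRNA"
        gene_id = t.attributes.get("gene_id", [t.id])[0]
        tid = t.attributes.get("transcript_id", [t.id])[0]
        out.append(TranscriptModel(tid, gene_id, biotype, exons, cds_start, cds_end))
    out.sort(key=lambda t: t.transcript_id)
    return out


def write_gtf(transcripts: list[TranscriptModel], path: str) -> None:
    """Write transcripts as GTF (gene/transcript/exon/CDS records)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda x: (x.chrom, x.interval.start, x.transcript_id)):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'biotype "{t.biotype}";'
            )
            rows = [("gene", t.interval.start, t.interval.end),
                    ("transcript", t.interval.start, t.interval.end)]
            for e in sorted(t.exons, key=lambda e: e.start):
                rows.append(("exon", e.start, e.end))
            if t.is_coding:
                rows.append(("CDS", t.cds_start, t.cds_end))
            for feat, s, e in rows:
                frame = "0" if feat == "CDS" else "."
                fh.write(
                    f"{t.chrom}\tm6adyn\t{feat}\t{s + 1}\t{e}\t.\t{t.strand}\t{frame}\t{attrs}\n"
                )


# ----------------------------------------------------------------------
# NarrowPeak (ENCODE BED6+4)
# ----------------------------------------------------------------------
def write_narrowpeak(peaks: list[Peak], path: str) -> None:
    """Write peaks as ENCODE NarrowPeak.

    Column 7 carries the enrichment fold, column 8 the -log10 p-value
    (full float precision so that files round-trip), column 9 is -1
    (no q-value at this stage), column 10 the summit offset.
    """
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            neglog = -math.log10(p.pvalue) if p.pvalue > 0 else 9999.0
            score_int = int(min(1000, round(10 * neglog)))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{score_int}\t{iv.strand}\t"
                f"{p.score:.17g}\t{neglog:.17g}\t-1\t{p.summit_offset}\n"
            )


def read_narrowpeak(path: str) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 10:
                raise ValueError(
                    f"{path}:{ln}: NarrowPeak needs 10 columns, got {len(f)}"
                )
            neglog = float(f[7])
            pval = 0.0 if neglog >= 9999.0 else 10.0 ** (-neglog)
            peaks.append(
                Peak(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    summit_offset=int(f[9]),
                    score=float(f[6]),
                    pvalue=min(1.0, pval),
                    name=f[3],
                )
            )
    return peaks


# ----------------------------------------------------------------------
# BedGraph window tracks
# ----------------------------------------------------------------------
def write_bedgraph(path: str, chrom_counts: dict[str, np.ndarray], window_size: int) -> None:
    """Write per-window counts as BedGraph (one fixed-width interval per window)."""
    with open(path, "w") as fh:
        for chrom in sorted(chrom_counts):
            counts = chrom_counts[chrom]
            for i, c in enumerate(counts):
                fh.write(f"{chrom}\t{i * window_size}\t{(i + 1) * window_size}\t{int(c)}\n")


def read_bedgraph(path: str, window_size: int) -> dict[str, np.ndarray]:
    """Read a fixed-window BedGraph back into per-chromosome count arrays."""
    per_chrom: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{ln}: BedGraph needs 4 columns, got {len(f)}")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if start % window_size or end - start != window_size:
                raise ValueError(
                    f"{path}:{ln}: interval not on the {window_size}-nt window grid"
                )
            per_chrom.setdefault(chrom, {})[start // window_size] = value
    out = {}
    for chrom, d in per_chrom.items():
        arr = np.zeros(max(d) + 1)
        for i, v in d.items():
            arr[i] = v
        out[chrom] = arr
    return out


# ----------------------------------------------------------------------
# count matrices
# ----------------------------------------------------------------------
def _parse_sample_id(sample_id: str) -> SampleInfo:
    """Parse ``{assay}_{condition}_rep{i}`` sample ids."""
    parts = sample_id.split("_")
    if len(parts) != 3 or not parts[2].startswith("rep"):
        raise ValueError(
            f"sample id {sample_id!r} must look like 'rna_control_rep1'"
        )
    return SampleInfo(sample_id, parts[1], parts[0], int(parts[2][3:]))


def write_counts_tsv(cm: CountMatrix, path: str) -> None:
    df = pd.DataFrame(
        cm.counts, index=cm.feature_ids, columns=[s.sample_id for s in cm.samples]
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [_parse_sample_id(c) for c in df.columns]
    return CountMatrix(list(df.index), samples, df.to_numpy())


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------
def read_fasta(path: str) -> pyfaidx.Fasta:
    return pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)


def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    # drop any stale index so pyfaidx reindexes the new file
    fai = path + ".fai"
    if os.path.exists(fai):
        os.remove(fai)
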