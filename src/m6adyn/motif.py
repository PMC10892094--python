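"""k-mer motif enrichment in peak sequences vs shuffled background.

A simplified de novo motif stage: peak sequences (spliced,
transcript-orientation) are scanned for all k-mers (k = 4..6 by default)
and each k-mer's foreground occurrence count is tested against the rate in
a composition-matched background built from dinucleotide-preserving
shuffles (Altschul-Erickson) of the same sequences.  Dinucleotide shuffling
keeps mono- and di-nucleotide composition exactly, so enrichment reflects
higher-order structure — such as a planted UGUA (DNA: TGTA) methylation
motif — rather than base composition.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Peak, TranscriptModel
from .dynamics import _exon_trees

log = logging.getLogger("m6adyn")

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ----------------------------------------------------------------------
# peak sequence extraction
# ----------------------------------------------------------------------
def _chrom_seq(source, chrom: str, start: int, end: int) -> str:
    seq = source[chrom]
    if isinstance(seq, np.ndarray):
        return seq[start:end].tobytes().decode()
    return str(seq[start:end]).upper()


def extract_peak_sequences(
    peaks: list[Peak],
    annotation: list[TranscriptModel],
    sequences,
) -> list[str]:
    """Spliced transcript-orientation sequences of peak regions.

    ``sequences`` may be a pyfaidx.Fasta or a dict of per-chromosome
    sequences.  Each peak is spliced through its (longest) host transcript,
    so a peak spanning an exon junction yields the junction sequence with
    length equal to its exonic overlap.  Minus-strand peaks are
    reverse-complemented.  Peaks outside any exon are skipped with a warning.
    """
    trees = _exon_trees(annotation)
    out = []
    n_skipped = 0
    for p in peaks:
        iv = p.interval
        tree = trees.get((iv.chrom, iv.strand))
        hosts = sorted(
            {h.data for h in tree.overlap(iv.start, iv.end)},
            key=lambda t: (-t.length, t.transcript_id),
        ) if tree is not None else []
        seq = None
        for host in hosts:
            span = host.genomic_to_transcript_span(iv)
            if span is None:
                continue
            parts = [
                _chrom_seq(sequences, b.chrom, b.start, b.end)
                for b in host.transcript_blocks(*span)
            ]
            if host.strand == "-":
                parts = [revcomp(s) for s in parts]
            seq = "".join(parts)
            break
        if seq is None:
            n_skipped += 1
            continue
        out.append(seq)
    if n_skipped:
        log.warning("%d peaks outside exons skipped during sequence extraction",
                    n_skipped)
    return out


# ----------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)
# ----------------------------------------------------------------------
def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact mono- and di-nucleotide counts.

    Implements the Altschul-Erickson Euler-walk construction: pick a random
    "last edge" per vertex, accept when those edges form a tree into the
    terminal character, then walk the remaining edges in random order.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    verts = list(edges)
    for _ in range(200):
        # reserve a random last out-edge for every vertex except the terminal one
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in verts
            if v != last
        }
        # those reserved edges must form a tree pointing into `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        order = {}
        for v in verts:
            rest = list(edges[v])
            if v in last_edge:
                rest.remove(last_edge[v])
            perm = [rest[i] for i in rng.permutation(len(rest))]
            if v in last_edge:
                perm.append(last_edge[v])
            order[v] = perm
        # Euler walk from the first character
        idx = {v: 0 for v in verts}
        out = [seq[0]]
        cur = seq[0]
        for _ in range(len(seq) - 1):
            nxt = order[cur][idx[cur]]
            idx[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    log.warning("dinucleotide shuffle failed to converge; returning input")
    return seq  # pragma: no cover


# ----------------------------------------------------------------------
# k-mer counting and enrichment
# ----------------------------------------------------------------------
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def kmer_counts(seqs: list[str], k: int) -> np.ndarray:
    """Occurrence counts of all 4^k k-mers over sliding windows of ``seqs``."""
    if not seqs:
        return np.zeros(4**k, dtype=np.int64)
    # concatenate with a separator that poisons any window crossing it
    cat = ("N" * k).join(seqs)
    codes = _CODE[np.frombuffer(cat.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        idx = idx * 4 + np.where(c >= 0, c, 0)
        valid &= c >= 0
    return np.bincount(idx[valid], minlength=4**k)


def _kmer_strings(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def kmer_enrichment(
    fg: list[str],
    k_range: tuple[int, ...] = (4, 5, 6),
    n_shuffles: int = 100,
    seed: int = 0,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Ranked k-mer enrichment of foreground sequences vs shuffled background.

    Background: ``n_shuffles`` dinucleotide-preserving shuffles of every
    foreground sequence.  Per k-mer, p is the binomial upper tail of the
    foreground count over foreground positions with the background rate as
    success probability; BH-adjusted across all k-mers.  Ranking: p-value,
    then enrichment fold (descending), then k-mer lexicographic — fully
    deterministic under a fixed seed.
    """
    fg = [s.upper() for s in fg if s]
    if not fg:
        raise ValueError("foreground sequence set is empty")
    rng = np.random.default_rng(seed)
    bg = [dinucleotide_shuffle(s, rng) for s in fg for _ in range(n_shuffles)]
    frames = []
    for k in k_range:
        usable_fg = [s for s in fg if len(s) >= k]
        usable_bg = [s for s in bg if len(s) >= k]
        if not usable_fg:
            continue
        fg_counts = kmer_counts(usable_fg, k)
        bg_counts = kmer_counts(usable_bg, k)
        n_fg = sum(len(s) - k + 1 for s in usable_fg)
        n_bg = sum(len(s) - k + 1 for s in usable_bg)
        bg_rate = np.maximum(bg_counts, 0.5) / n_bg  # floor avoids p=0 rates
        pvals = stats.binom.sf(fg_counts - 1, n_fg, np.minimum(bg_rate, 1.0))
        enr = (fg_counts / n_fg) / bg_rate
        frames.append(
            pd.DataFrame(
                dict(
                    kmer=_kmer_strings(k), k=k,
                    fg_count=fg_counts, bg_count=bg_counts,
                    fg_rate=fg_counts / n_fg, bg_rate=bg_rate,
                    enrichment=enr, pvalue=pvals,
                )
            )
        )
    res = pd.concat(frames, ignore_index=True)
    res["padj"] = multipletests(res["pvalue"], method=adjust)[1]
    res = res.sort_values(
        ["pvalue", "enrichment", "kmer"], ascending=[True, False, True]
    ).reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return res
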