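"""Synthetic transcriptome, planted m6A peaks, and count simulation.

The generator builds a toy multi-chromosome genome with spliced, stranded
transcripts, plants m6A peaks (150-200 nt, single-exon) with class-dependent
positional bias, inserts a sense-strand motif into peak sequences, and
simulates negative-binomial windowed IP/input tracks plus RNA-seq and
polysome-seq count matrices with known per-transcript effect sizes.  The
emitted :class:`SyntheticTruth` is the recovery oracle for every downstream
stage.

Randomness: every stage owns an independent stream spawned from
``cfg.seed`` so each public function is deterministic on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PEAK_CLASSES, BIAS_REGIONS, SimulationConfig
from .core import CountMatrix, GenomicInterval, Peak, SampleInfo, TranscriptModel
from .peaks import WindowTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONDITIONS = ("control", "copper")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and Var = mean + dispersion*mean^2.

    ``dispersion`` is the inverse size parameter; 0 gives the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


# ======================================================================
# transcriptome
# ======================================================================
def generate_transcriptome(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptModel], dict[str, np.ndarray]]:
    """Build annotation and genome sequence.

    Returns the transcript models and per-chromosome sequences as uint8
    arrays of ASCII bases (mutable so that motif planting can edit them).
    ~``noncoding_frac`` of transcripts are non-coding with biotypes drawn
    from ``biotype_shares`` (lncRNA gets the largest share).
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_transcripts

    n_nc = int(round(n * cfg.noncoding_frac))
    nc_idx = set(rng.choice(n, size=n_nc, replace=False).tolist())
    nc_biotypes = list(cfg.biotype_shares)
    nc_probs = np.array([cfg.biotype_shares[b] for b in nc_biotypes])

    cursors = {f"chr{i + 1}": 0 for i in range(cfg.n_chroms)}
    transcripts: list[TranscriptModel] = []
    min_len = cfg.peak_len_max + 50
    for i in range(n):
        chrom = f"chr{(i * cfg.n_chroms) // n + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = i not in nc_idx
        if coding:
            u5 = max(60, int(rng.gamma(4.0, cfg.utr5_len / 4.0)))
            cds = 3 * max(100, int(rng.gamma(4.0, cfg.cds_len / 4.0)) // 3)
            u3 = max(120, int(rng.gamma(4.0, cfg.utr3_len / 4.0)))
            length = u5 + cds + u3
            biotype = "mRNA"
        else:
            length = max(300, int(rng.gamma(4.0, cfg.noncoding_len / 4.0)))
            biotype = nc_biotypes[int(rng.choice(len(nc_biotypes), p=nc_probs))]
        if length < min_len:
            raise ValueError("transcript too short to host a peak")

        # split into exon pieces, each long enough to host a peak
        min_piece = cfg.peak_len_max + 10
        k = int(rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3]))
        while k > 1 and length < min_piece * k:
            k -= 1
        pieces = [length // k] * k
        pieces[-1] += length % k
        for j in range(k - 1):
            shift = int(rng.integers(-50, 51))
            if pieces[j] + shift >= min_piece and pieces[j + 1] - shift >= min_piece:
                pieces[j] += shift
                pieces[j + 1] -= shift

        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        pos = cursors[chrom] + gap
        exons = []
        for j, plen in enumerate(pieces):
            if j:
                pos += int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + plen, strand))
            pos += plen
        cursors[chrom] = pos

        tid, gid = f"t{i:05d}", f"g{i:05d}"
        if coding:
            skeleton = TranscriptModel(tid, gid, "mRNA", exons)
            blocks = skeleton.transcript_blocks(u5, u5 + cds)
            cds_start = min(b.start for b in blocks)
            cds_end = max(b.end for b in blocks)
            transcripts.append(
                TranscriptModel(tid, gid, "mRNA", exons, cds_start, cds_end)
            )
        else:
            transcripts.append(TranscriptModel(tid, gid, biotype, exons))

    sequences = {
        chrom: _BASES[rng.integers(0, 4, size=end + 100)]
        for chrom, end in sorted(cursors.items())
    }
    return transcripts, sequences


# ======================================================================
# planted peaks + motif
# ======================================================================
@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator.

    planted: one row per planted peak (genomic interval, class, host,
    transcript-coordinate span, motif offset within the peak or -1).
    transcripts: per-transcript biotype, methylation class and true effect
    sizes (log2 abundance shift, log2 occupancy shift).
    """

    planted: pd.DataFrame
    transcripts: pd.DataFrame

    def peaks_by_class(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {c: [] for c in PEAK_CLASSES}
        for row in self.planted.itertuples():
            iv = GenomicInterval(row.chrom, row.start, row.end, row.strand)
            out[row.peak_class].append(
                Peak(iv, row.summit - row.start, 0.0, 0.0, row.peak_id)
            )
        return out

    def peaks_active_in(self, condition: str) -> list[Peak]:
        keep = {"shared", "stress-only" if condition == "copper" else "control-only"}
        return [
            p
            for cls, plist in self.peaks_by_class().items()
            if cls in keep
            for p in plist
        ]


def _write_motif(seqs, t: TranscriptModel, tpos: int, motif: str) -> None:
    # sense-strand motif: on minus-strand transcripts each genomic base gets
    # the complement, so the reference carries the reverse complement
    for j, base in enumerate(motif):
        g = t.transcript_to_genome(tpos + j)
        b = base if t.strand == "+" else _COMP[base]
        seqs[t.chrom][g] = ord(b)


def plant_peaks(
    annotation: list[TranscriptModel],
    sequences: dict[str, np.ndarray],
    cfg: SimulationConfig,
) -> SyntheticTruth:
    """Plant one m6A peak per methylated transcript and insert motifs.

    Shared peaks follow the 3'UTR-biased positional vector; stress-only and
    control-only peaks the 5'UTR/start-shifted vector.  Peaks are 150-200 nt
    and constrained to a single exon so every planted peak lies within its
    host's exons.  The motif is written into the peak sequence (sense
    strand) at rate ``motif_rate_in_peaks`` and into background exonic
    sequence at ``motif_rate_background`` per ~175 nt.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    n = len(annotation)
    m = int(round(n * cfg.frac_methylated))
    meth = rng.permutation(np.sort(rng.choice(n, size=m, replace=False)))
    n_stress = int(round(m * cfg.frac_stress_only))
    n_control = int(round(m * cfg.frac_control_only))
    classes = {}
    for j, idx in enumerate(meth):
        if j < n_stress:
            classes[int(idx)] = "stress-only"
        elif j < n_stress + n_control:
            classes[int(idx)] = "control-only"
        else:
            classes[int(idx)] = "shared"

    mlen = len(cfg.motif)
    rows = []
    t_rows = []
    for i, t in enumerate(annotation):
        cls = classes.get(i)
        if cls is not None:
            L = int(rng.integers(cfg.peak_len_min, cfg.peak_len_max + 1))
            if t.length < L:
                raise ValueError(f"{t.transcript_id} too short for a {L} nt peak")
            t_start = _place_peak(rng, t, cls, L, cfg)
            blocks = t.transcript_blocks(t_start, t_start + L)
            assert len(blocks) == 1, "planted peaks are single-exon by construction"
            block = blocks[0]
            summit_g = t.transcript_to_genome(t_start + L // 2)
            motif_off = -1
            if rng.random() < cfg.motif_rate_in_peaks:
                motif_off = int(rng.integers(0, L - mlen + 1))
                _write_motif(sequences, t, t_start + motif_off, cfg.motif)
            rows.append(
                dict(
                    peak_id=f"planted_{t.transcript_id}",
                    transcript_id=t.transcript_id,
                    peak_class=cls,
                    chrom=block.chrom,
                    start=block.start,
                    end=block.end,
                    strand=block.strand,
                    summit=summit_g,
                    t_start=t_start,
                    length=L,
                    motif_offset=motif_off,
                )
            )
            # background motif instances outside the peak
            n_bg = rng.binomial(max(1, t.length // 175), cfg.motif_rate_background)
            for _ in range(n_bg):
                for _try in range(10):
                    off = int(rng.integers(0, t.length - mlen + 1))
                    if off + mlen <= t_start or off >= t_start + L:
                        _write_motif(sequences, t, off, cfg.motif)
                        break
        else:
            n_bg = rng.binomial(max(1, t.length // 175), cfg.motif_rate_background)
            for _ in range(n_bg):
                off = int(rng.integers(0, t.length - mlen + 1))
                _write_motif(sequences, t, off, cfg.motif)

        if cls == "stress-only":
            lfc = (
                cfg.lfc_shift_lncrna_stress
                if t.biotype == "lncRNA"
                else cfg.lfc_shift_stress_enriched
            )
            occ = cfg.occupancy_shift_stress_enriched
        elif cls == "control-only":
            lfc, occ = cfg.lfc_shift_control_enriched, 0.0
        else:
            lfc, occ = 0.0, 0.0
        t_rows.append(
            dict(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                biotype=t.biotype,
                methylated=cls is not None,
                peak_class=cls if cls is not None else "none",
                true_lfc=lfc,
                true_occ_shift=occ,
            )
        )

    planted = pd.DataFrame(
        rows,
        columns=[
            "peak_id", "transcript_id", "peak_class", "chrom", "start", "end",
            "strand", "summit", "t_start", "length", "motif_offset",
        ],
    )
    return SyntheticTruth(planted, pd.DataFrame(t_rows))


def _place_peak(rng, t: TranscriptModel, cls: str, L: int, cfg: SimulationConfig) -> int:
    """Pick a transcript-coordinate start so the peak sits in one exon with
    its center in the class-sampled region."""
    flank = cfg.start_stop_flank
    for _ in range(60):
        region_span = None  # set for pure-region classes to keep the peak inside
        if t.is_coding:
            region = BIAS_REGIONS[
                int(rng.choice(5, p=np.asarray(cfg.positional_bias[cls])))
            ]
            if region == "5'UTR":
                center = int(rng.integers(0, t.cds_t_start))
                region_span = (0, t.cds_t_start)
            elif region == "start":
                center = int(
                    rng.integers(max(0, t.cds_t_start - flank),
                                 min(t.length, t.cds_t_start + flank + 1))
                )
            elif region == "CDS":
                center = int(rng.integers(t.cds_t_start, t.cds_t_end))
                region_span = (t.cds_t_start, t.cds_t_end)
            elif region == "stop":
                center = int(
                    rng.integers(max(0, t.cds_t_end - 3 - flank),
                                 min(t.length, t.cds_t_end - 3 + flank + 1))
                )
            else:
                center = int(rng.integers(t.cds_t_end, t.length))
                region_span = (t.cds_t_end, t.length)
        else:
            center = int(rng.integers(0, t.length))
        # exon piece holding the center
        i = next(
            j for j in range(len(t.exons)) if t._cum[j] <= center < t._cum[j + 1]
        )
        lo, hi = t._cum[i], t._cum[i + 1]
        if hi - lo < L:
            continue
        # keep region-class peaks inside their region when it is long enough,
        # so a "3'UTR peak" does not bleed across the stop codon
        if region_span is not None:
            rlo, rhi = max(lo, region_span[0]), min(hi, region_span[1])
            if rhi - rlo >= L:
                lo, hi = rlo, rhi
        start = int(np.clip(center - L // 2, lo, hi - L))
        return start
    raise ValueError(f"could not place a {L} nt peak on {t.transcript_id}")


# ======================================================================
# windowed IP / input tracks
# ======================================================================
def _coverage_rates(
    annotation: list[TranscriptModel],
    truth: SyntheticTruth,
    sequences: dict[str, np.ndarray],
    cfg: SimulationConfig,
) -> tuple[dict, dict]:
    """Per-(chrom,strand) per-nt input rate and per-condition peak extra rate."""
    per_nt = cfg.depth / cfg.window_size
    base: dict[tuple[str, str], np.ndarray] = {}
    extra: dict[str, dict[tuple[str, str], np.ndarray]] = {
        c: {} for c in CONDITIONS
    }
    for chrom, seq in sequences.items():
        for strand in "+-":
            base[(chrom, strand)] = np.zeros(len(seq))
            for c in CONDITIONS:
                extra[c][(chrom, strand)] = np.zeros(len(seq))
    for t in annotation:
        arr = base[(t.chrom, t.strand)]
        if t.is_coding:
            # region multipliers per transcript-coordinate nt, mapped per exon
            mult = np.empty(t.length)
            mult[: t.cds_t_start] = cfg.region_rate_utr5
            mult[t.cds_t_start : t.cds_t_end] = cfg.region_rate_cds
            mult[t.cds_t_end :] = cfg.region_rate_utr3
        else:
            mult = np.ones(t.length)
        for i, e in enumerate(t.exons):  # exons in transcript orientation
            seg = mult[t._cum[i] : t._cum[i + 1]]
            if t.strand == "-":
                seg = seg[::-1]
            arr[e.start : e.end] += per_nt * seg
    for row in truth.planted.itertuples():
        conds = (
            ("control", "copper")
            if row.peak_class == "shared"
            else (("copper",) if row.peak_class == "stress-only" else ("control",))
        )
        for c in conds:
            arr = extra[c][(row.chrom, row.strand)]
            arr[row.start : row.end] += (cfg.ip_enrichment - 1.0) * base[
                (row.chrom, row.strand)
            ][row.start : row.end]
    return base, extra


def simulate_ip_counts(
    truth: SyntheticTruth,
    annotation: list[TranscriptModel],
    sequences: dict[str, np.ndarray],
    cfg: SimulationConfig,
) -> dict[tuple[str, str, int], list[WindowTrack]]:
    """Simulate stranded windowed count tracks for {control,copper} x {ip,input} x reps.

    Input counts are NB with mean = coverage rate per window; IP counts
    inside a peak active in that condition have their mean multiplied by
    ``ip_enrichment``.  Each sample gets its own library-scale factor; the
    reported library size is the realised total count.
    """
    rng = _rng(cfg, 2)
    base, extra = _coverage_rates(annotation, truth, sequences, cfg)
    W = cfg.window_size

    def window_means(per_nt: np.ndarray) -> np.ndarray:
        n = len(per_nt)
        nw = -(-n // W)
        padded = np.zeros(nw * W)
        padded[:n] = per_nt
        return padded.reshape(nw, W).sum(axis=1)

    samples: dict[tuple[str, str, int], list[WindowTrack]] = {}
    lo, hi = cfg.library_factor_range
    for cond in CONDITIONS:
        for assay in ("ip", "input"):
            for rep in range(1, cfg.n_ip_reps + 1):
                f = rng.uniform(lo, hi)
                tracks = []
                for chrom in sorted(sequences):
                    for strand in "+-":
                        mean = window_means(base[(chrom, strand)])
                        if assay == "ip":
                            mean = mean + window_means(extra[cond][(chrom, strand)])
                        counts = sample_nb(rng, mean * f, cfg.window_dispersion)
                        tracks.append(
                            WindowTrack(chrom, strand, W, counts, 1.0)
                        )
                total = float(sum(tr.counts.sum() for tr in tracks))
                for tr in tracks:
                    tr.library_size = total
                samples[(cond, assay, rep)] = tracks
    return samples


# ======================================================================
# expression / polysome counts
# ======================================================================
def simulate_expression(
    truth: SyntheticTruth,
    cfg: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix]:
    """Simulate the RNA-seq (3x2) and polysome-seq (2x2) count matrices.

    Copper abundance means are shifted by the per-transcript true log2 fold
    change; copper polysome means additionally by the true occupancy shift,
    so that log2(polysome RPM / RNA RPM) changes by exactly the planted
    occupancy effect in expectation.
    """
    rng = _rng(cfg, 3)
    tdf = truth.transcripts
    nt = len(tdf)
    base = rng.lognormal(np.log(cfg.expr_mean) - cfg.expr_sigma**2 / 2.0,
                         cfg.expr_sigma, size=nt)
    lfc = tdf["true_lfc"].to_numpy()
    occ = tdf["true_occ_shift"].to_numpy()
    lo, hi = cfg.library_factor_range

    def matrix(assay: str, n_reps: int) -> CountMatrix:
        cols, infos = [], []
        for cond in CONDITIONS:
            shift = lfc if cond == "copper" else 0.0
            extra = occ if (cond == "copper" and assay == "polysome") else 0.0
            mean = base * 2.0 ** (shift + extra)
            for rep in range(1, n_reps + 1):
                f = rng.uniform(lo, hi)
                cols.append(sample_nb(rng, mean * f, cfg.dispersion))
                infos.append(SampleInfo(f"{assay}_{cond}_rep{rep}", cond, assay, rep))
        return CountMatrix(list(tdf["transcript_id"]), infos, np.column_stack(cols))

    return matrix("rna", cfg.n_rna_reps), matrix("polysome", cfg.n_poly_reps)


# ======================================================================
# one-call simulation + file output
# ======================================================================
@dataclass
class SimulationResult:
    cfg: SimulationConfig
    annotation: list
    sequences: dict
    truth: SyntheticTruth
    tracks: dict
    rna: CountMatrix
    polysome: CountMatrix


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    annotation, sequences = generate_transcriptome(cfg)
    truth = plant_peaks(annotation, sequences, cfg)
    tracks = simulate_ip_counts(truth, annotation, sequences, cfg)
    rna, poly = simulate_expression(truth, cfg)
    return SimulationResult(cfg, annotation, sequences, truth, tracks, rna, poly)


def write_simulation(res: SimulationResult, outdir: str) -> None:
    """Write annotation (GTF), genome (FASTA), tracks (BedGraph), count
    matrices and truth tables (TSV) under ``outdir``; deterministic layout."""
    import os

    from . import io as mio

    os.makedirs(outdir, exist_ok=True)
    tracks_dir = os.path.join(outdir, "tracks")
    os.makedirs(tracks_dir, exist_ok=True)
    mio.write_gtf(res.annotation, os.path.join(outdir, "annotation.gtf"))
    mio.write_fasta(
        os.path.join(outdir, "genome.fa"),
        {c: res.sequences[c].tobytes().decode() for c in sorted(res.sequences)},
    )
    lib_rows = []
    for (cond, assay, rep), tracks in sorted(res.tracks.items()):
        for strand, tag in (("+", "plus"), ("-", "minus")):
            chrom_counts = {
                tr.chrom: tr.counts for tr in tracks if tr.strand == strand
            }
            mio.write_bedgraph(
                os.path.join(tracks_dir, f"{cond}_{assay}_rep{rep}_{tag}.bedgraph"),
                chrom_counts,
                res.cfg.window_size,
            )
        lib_rows.append(
            dict(condition=cond, assay=assay, replicate=rep,
                 library_size=int(tracks[0].library_size))
        )
    pd.DataFrame(lib_rows).to_csv(
        os.path.join(outdir, "library_sizes.tsv"), sep="\t", index=False
    )
    mio.write_counts_tsv(res.rna, os.path.join(outdir, "rna_counts.tsv"))
    mio.write_counts_tsv(res.polysome, os.path.join(outdir, "polysome_counts.tsv"))
    res.truth.planted.to_csv(
        os.path.join(outdir, "truth_peaks.tsv"), sep="\t", index=False
    )
    res.truth.transcripts.to_csv(
        os.path.join(outdir, "truth_transcripts.tsv"), sep="\t", index=False
    )
    res.cfg.to_yaml(os.path.join(outdir, "config.yaml"))
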