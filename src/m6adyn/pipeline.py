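"""End-to-end pipeline: simulate -> call peaks -> dynamics -> profiles ->
quantification -> motif -> report.

``run_analysis`` performs every analysis stage on a simulated (or loaded)
dataset and returns the intermediate objects; ``write_report`` serialises
them; ``run_all`` wires simulation, analysis and report together and is
deterministic under a fixed config seed.

Report directory layout:

    sim/                 synthetic annotation, genome, tracks, counts, truth
    peaks/               per-replicate NarrowPeak files
    consensus_<cond>.tsv high-confidence peaks per condition
    peak_categories.tsv  stress-enriched / control-enriched / shared peaks
    transcript_categories.tsv, ncrna_breakdown.tsv
    metagene_<cond>_<assay>.tsv, frequency_<anchor>.tsv, feature_breakdown.tsv
    fold_change.tsv, occupancy.tsv, comparisons_<metric>.tsv
    motifs.tsv
    summary.json         headline numbers of the run
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import dynamics, io, metagene, motif, quantify
from .config import SimulationConfig
from .dynamics import CATEGORIES
from .peaks import call_peaks_tracks
from .simulate import CONDITIONS, SimulationResult, run_simulation, write_simulation

log = logging.getLogger("m6adyn")


def consensus_df(cps) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=c.interval.chrom, start=c.interval.start, end=c.interval.end,
                strand=c.interval.strand, condition=c.condition,
                members=",".join(c.members),
            )
            for c in cps
        ],
        columns=["chrom", "start", "end", "strand", "condition", "members"],
    )


@dataclass
class PipelineResult:
    """All intermediate objects of one end-to-end analysis."""

    sim: SimulationResult
    rep_peaks: dict  # condition -> list per replicate of list[Peak]
    consensus: dict  # condition -> list[ConsensusPeak]
    peaks_by_cat: dict  # category -> list[Peak]
    assignment: dynamics.TranscriptAssignment
    ncrna: pd.DataFrame
    profiles: dict  # (condition, assay) -> MetageneProfile
    frequency: dict  # anchor -> FrequencyProfile
    feature_breakdown: pd.DataFrame
    fold_change: pd.DataFrame
    occupancy: pd.DataFrame
    comparisons: dict  # metric -> DataFrame
    motifs: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_analysis(res: SimulationResult) -> PipelineResult:
    """Run every analysis stage on a simulated dataset."""
    cfg = res.cfg

    log.info("stage=callpeaks")
    rep_peaks: dict[str, list] = {c: [] for c in CONDITIONS}
    for cond in CONDITIONS:
        for rep in range(1, cfg.n_ip_reps + 1):
            rep_peaks[cond].append(
                call_peaks_tracks(
                    res.tracks[(cond, "ip", rep)],
                    res.tracks[(cond, "input", rep)],
                    name_prefix=f"{cond}_rep{rep}",
                )
            )

    log.info("stage=dynamics")
    cons = {
        cond: dynamics.consensus(rep_peaks[cond], condition=cond)
        for cond in CONDITIONS
    }
    stress_e, control_e, shared = dynamics.classify(cons["control"], cons["copper"])
    peaks_by_cat = {
        "stress-enriched": [c.to_peak(f"stress_{i + 1}") for i, c in enumerate(stress_e)],
        "control-enriched": [c.to_peak(f"control_{i + 1}") for i, c in enumerate(control_e)],
        "shared": [c.to_peak(f"shared_{i + 1}") for i, c in enumerate(shared)],
    }
    assignment = dynamics.assign_to_transcripts(peaks_by_cat, res.annotation)
    ncrna = dynamics.ncrna_breakdown(assignment)

    log.info("stage=metagene")
    # profiles are drawn over the transcripts detected as m6A-containing
    # (hosts of consensus peaks), the population an IP library represents
    detected = set(assignment.table["transcript_id"])
    meta_annotation = [t for t in res.annotation if t.transcript_id in detected]
    profiles = {}
    for cond in CONDITIONS:
        for assay in ("ip", "input"):
            tracks = [
                t
                for rep in range(1, cfg.n_ip_reps + 1)
                for t in res.tracks[(cond, assay, rep)]
            ]
            profiles[(cond, assay)] = metagene.metagene_density(tracks, meta_annotation)
    freq = {
        anchor: metagene.positional_frequency(assignment, res.annotation, anchor)
        for anchor in ("start_codon", "stop_codon")
    }
    fb = metagene.feature_breakdown(assignment, res.annotation)

    log.info("stage=quant")
    fc = quantify.log2_fold_change(res.rna)
    occ = quantify.polysome_occupancy(res.polysome, res.rna)
    cat_map = assignment.table.set_index("transcript_id")["category"]
    bio_map = assignment.table.set_index("transcript_id")["biotype"]
    mrna_ids = set(bio_map[bio_map == "mRNA"].index)
    fc_idx = fc.set_index("transcript_id")
    occ_idx = occ.set_index("transcript_id")
    comparisons = {
        "lfc": quantify.category_comparison(
            fc_idx.loc[[i for i in fc_idx.index if i in mrna_ids], "log2fc"],
            cat_map, test="wilcoxon",
        ),
        "occupancy": quantify.category_comparison(
            occ_idx.loc[[i for i in occ_idx.index if i in mrna_ids], "occupancy_change"],
            cat_map, test="wilcoxon",
        ),
    }
    stress_mrna = [
        t for t in assignment.transcripts_in("stress-enriched") if t in mrna_ids
    ]
    n_up, n_down = quantify.threshold_counts(fc, stress_mrna)

    log.info("stage=motif")
    all_peaks = [p for plist in peaks_by_cat.values() for p in plist]
    seqs = motif.extract_peak_sequences(all_peaks, res.annotation, res.sequences)
    motifs = motif.kmer_enrichment(seqs, seed=cfg.seed)

    def medians(df, col):
        out = {}
        for cat in CATEGORIES:
            ids = [i for i in assignment.transcripts_in(cat) if i in mrna_ids]
            vals = df.loc[df.index.intersection(ids), col]
            out[cat] = float(vals.median()) if len(vals) else None
        return out

    summary = {
        "n_transcripts": cfg.n_transcripts,
        "seed": cfg.seed,
        "peaks_per_replicate": {
            cond: [len(r) for r in rep_peaks[cond]] for cond in CONDITIONS
        },
        "consensus_peaks": {cond: len(cons[cond]) for cond in CONDITIONS},
        "peak_categories": {cat: len(v) for cat, v in peaks_by_cat.items()},
        "transcripts_per_category": {
            cat: len(assignment.transcripts_in(cat)) for cat in CATEGORIES
        },
        "intergenic_peaks": len(assignment.intergenic),
        "metagene_max_region": {
            f"{cond}_{assay}": profiles[(cond, assay)].argmax_region()
            for cond in CONDITIONS
            for assay in ("ip", "input")
        },
        "median_log2fc": medians(fc_idx, "log2fc"),
        "median_occupancy_change": medians(occ_idx, "occupancy_change"),
        "comparison_pvalues": {
            metric: {f"{r.group1}_vs_{r.group2}": r.pvalue for r in df.itertuples()}
            for metric, df in comparisons.items()
        },
        "stress_mrna_threshold_counts": {"increase": n_up, "decrease": n_down},
        "top_motifs": motifs.head(5)["kmer"].tolist(),
        "n_de_transcripts": int((fc["padj"] < 0.05).sum()),
    }
    return PipelineResult(
        res, rep_peaks, cons, peaks_by_cat, assignment, ncrna, profiles, freq,
        fb, fc, occ, comparisons, motifs, summary,
    )


def write_report(pr: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    peaks_dir = os.path.join(outdir, "peaks")
    os.makedirs(peaks_dir, exist_ok=True)
    for cond in CONDITIONS:
        for rep, called in enumerate(pr.rep_peaks[cond], 1):
            io.write_narrowpeak(
                called, os.path.join(peaks_dir, f"{cond}_rep{rep}.narrowPeak")
            )
        consensus_df(pr.consensus[cond]).to_csv(
            os.path.join(outdir, f"consensus_{cond}.tsv"), sep="\t", index=False
        )
    cat_rows = [
        dict(chrom=p.interval.chrom, start=p.interval.start, end=p.interval.end,
             strand=p.interval.strand, category=cat, name=p.name)
        for cat, plist in pr.peaks_by_cat.items()
        for p in plist
    ]
    pd.DataFrame(cat_rows).to_csv(
        os.path.join(outdir, "peak_categories.tsv"), sep="\t", index=False
    )
    pr.assignment.table.to_csv(
        os.path.join(outdir, "transcript_categories.tsv"), sep="\t", index=False
    )
    pr.ncrna.to_csv(os.path.join(outdir, "ncrna_breakdown.tsv"), sep="\t")
    for (cond, assay), prof in pr.profiles.items():
        prof.to_frame().to_csv(
            os.path.join(outdir, f"metagene_{cond}_{assay}.tsv"), sep="\t", index=False
        )
    for anchor, fp in pr.frequency.items():
        fp.to_frame().to_csv(
            os.path.join(outdir, f"frequency_{anchor}.tsv"), sep="\t", index=False
        )
    pr.feature_breakdown.to_csv(os.path.join(outdir, "feature_breakdown.tsv"), sep="\t")
    pr.fold_change.to_csv(os.path.join(outdir, "fold_change.tsv"), sep="\t", index=False)
    pr.occupancy.to_csv(os.path.join(outdir, "occupancy.tsv"), sep="\t", index=False)
    for metric, df in pr.comparisons.items():
        df.to_csv(os.path.join(outdir, f"comparisons_{metric}.tsv"), sep="\t", index=False)
    pr.motifs.head(50).to_csv(os.path.join(outdir, "motifs.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(pr.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(cfg: SimulationConfig, outdir: str, write_files: bool = True) -> dict:
    """Run the full pipeline on one simulated dataset; returns the summary."""
    log.info("stage=simulate seed=%d n=%d", cfg.seed, cfg.n_transcripts)
    res = run_simulation(cfg)
    if write_files:
        write_simulation(res, os.path.join(outdir, "sim"))
    pr = run_analysis(res)
    if write_files:
        write_report(pr, outdir)
    return pr.summary
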