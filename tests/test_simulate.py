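"""Synthetic-data generator: determinism, planted structure, count models."""

import filecmp
import os

import numpy as np
import pytest
from scipy import stats

from m6adyn.config import SimulationConfig
from m6adyn.core import NONCODING_BIOTYPES, overlap
from m6adyn.simulate import (
    generate_transcriptome,
    plant_peaks,
    run_simulation,
    sample_nb,
    simulate_expression,
    simulate_ip_counts,
    write_simulation,
)


class TestDeterminism:
    def test_identical_outputs_under_fixed_seed(self, tmp_path):
        """Two runs with the same seed produce byte-identical files."""
        dirs = []
        for name in ("a", "b"):
            res = run_simulation(SimulationConfig(n_transcripts=100, seed=7))
            d = tmp_path / name
            write_simulation(res, str(d))
            dirs.append(d)
        for root, _, files in os.walk(dirs[0]):
            rel = os.path.relpath(root, dirs[0])
            for f in files:
                if f.endswith(".fai"):
                    continue
                a = os.path.join(root, f)
                b = os.path.join(dirs[1], rel, f)
                assert filecmp.cmp(a, b, shallow=False), f"{rel}/{f} differs"

    def test_different_seeds_differ(self):
        a = run_simulation(SimulationConfig(n_transcripts=50, seed=1))
        b = run_simulation(SimulationConfig(n_transcripts=50, seed=2))
        assert not np.array_equal(a.rna.counts, b.rna.counts)


class TestTranscriptome:
    def test_lncrna_has_largest_noncoding_share(self, default_sim):
        counts = (
            default_sim.truth.transcripts.query("biotype != 'mRNA'")["biotype"]
            .value_counts()
        )
        assert set(counts.index) <= set(NONCODING_BIOTYPES)
        assert counts.idxmax() == "lncRNA"
        assert counts["lncRNA"] > counts.drop("lncRNA").max()

    def test_mean_utr3_length_tracks_config(self, default_sim):
        """Law of large numbers: mean 3'UTR length within 10% at n=2000."""
        lens = [
            t.region_lengths()["3'UTR"]
            for t in default_sim.annotation
            if t.is_coding
        ]
        target = default_sim.cfg.utr3_len
        assert abs(np.mean(lens) - target) / target < 0.10

    def test_exons_within_chromosomes_and_sorted(self, default_sim):
        for t in default_sim.annotation[:200]:
            assert t.interval.end <= len(default_sim.sequences[t.chrom])


class TestPlantedPeaks:
    def test_degenerate_bias_puts_all_shared_peaks_in_utr3(self):
        cfg = SimulationConfig(
            n_transcripts=200, seed=3, noncoding_frac=0.0,
            positional_bias={
                "shared": (0, 0, 0, 0, 1.0),
                "stress-only": (0.2, 0.2, 0.25, 0.1, 0.25),
                "control-only": (0.2, 0.2, 0.25, 0.1, 0.25),
            },
        )
        ann, seqs = generate_transcriptome(cfg)
        truth = plant_peaks(ann, seqs, cfg)
        by_id = {t.transcript_id: t for t in ann}
        for row in truth.planted.query("peak_class == 'shared'").itertuples():
            t = by_id[row.transcript_id]
            utr3 = t.transcript_blocks(t.cds_t_end, t.length)
            iv = type(utr3[0])(row.chrom, row.start, row.end, row.strand)
            assert any(overlap(iv, b) >= 1 for b in utr3)

    def test_peak_lengths_within_bounds(self, default_sim):
        lens = default_sim.truth.planted["length"]
        assert lens.between(150, 200).all()

    def test_stress_peaks_more_5utr_start_biased_than_shared(self, default_sim):
        """Condition-specific peaks sit in the 5'UTR/start region more often."""
        by_id = {t.transcript_id: t for t in default_sim.annotation}

        def frac_5p(cls):
            rows = default_sim.truth.planted.query("peak_class == @cls")
            hits = total = 0
            for r in rows.itertuples():
                t = by_id[r.transcript_id]
                if not t.is_coding:
                    continue
                total += 1
                mid = r.t_start + r.length // 2
                if t.region_of(mid, codon_flank=50) in ("5'UTR", "start_codon"):
                    hits += 1
            return hits / total

        assert frac_5p("stress-only") > frac_5p("shared")

    def test_peaks_lie_within_host_exons(self, default_sim):
        by_id = {t.transcript_id: t for t in default_sim.annotation}
        for r in default_sim.truth.planted.itertuples():
            t = by_id[r.transcript_id]
            exonic = sum(
                min(r.end, e.end) - max(r.start, e.start)
                for e in t.exons
                if min(r.end, e.end) > max(r.start, e.start)
            )
            assert exonic == r.end - r.start

    def test_classes_partition_planted_peaks(self, default_sim):
        vc = default_sim.truth.planted["peak_class"].value_counts()
        assert vc.sum() == len(default_sim.truth.planted)
        assert set(vc.index) == {"stress-only", "control-only", "shared"}

    def test_motif_written_into_sequence(self, default_sim):
        by_id = {t.transcript_id: t for t in default_sim.annotation}
        planted = default_sim.truth.planted.query("motif_offset >= 0").head(50)
        for r in planted.itertuples():
            t = by_id[r.transcript_id]
            tpos = r.t_start + r.motif_offset
            sense = "".join(
                chr(default_sim.sequences[t.chrom][t.transcript_to_genome(tpos + j)])
                if t.strand == "+"
                else {"A": "T", "C": "G", "G": "C", "T": "A"}[
                    chr(default_sim.sequences[t.chrom][t.transcript_to_genome(tpos + j)])
                ]
                for j in range(4)
            )
            assert sense == default_sim.cfg.motif


class TestWindowCounts:
    def test_null_enrichment_gives_equal_ip_and_input_means(self):
        cfg = SimulationConfig(n_transcripts=150, seed=5, ip_enrichment=1.0,
                               library_factor_range=(1.0, 1.0))
        ann, seqs = generate_transcriptome(cfg)
        truth = plant_peaks(ann, seqs, cfg)
        tracks = simulate_ip_counts(truth, ann, seqs, cfg)
        ip = np.concatenate([t.counts for t in tracks[("copper", "ip", 1)]])
        inp = np.concatenate([t.counts for t in tracks[("copper", "input", 1)]])
        assert abs(ip.mean() - inp.mean()) / inp.mean() < 0.02

    def test_poisson_limit_variance_mean_ratio(self, rng):
        draws = sample_nb(rng, np.full(20000, 30.0), dispersion=0.0)
        assert abs(draws.var() / draws.mean() - 1.0) < 0.05

    def test_enrichment_fold_recovered_inside_peaks(self, default_sim):
        """Mean IP coverage inside planted peaks / outside ~= ip_enrichment."""
        cfg = default_sim.cfg
        W = cfg.window_size
        tracks = {
            (t.chrom, t.strand): t for t in default_sim.tracks[("copper", "ip", 1)]
        }
        inputs = {
            (t.chrom, t.strand): t for t in default_sim.tracks[("copper", "input", 1)]
        }
        in_peak, in_bg = [], []
        for r in default_sim.truth.planted.itertuples():
            active = r.peak_class in ("shared", "stress-only")
            ws, we = r.start // W + 1, r.end // W - 1  # fully covered windows
            if we <= ws:
                continue
            ip = tracks[(r.chrom, r.strand)].counts[ws:we]
            inp = inputs[(r.chrom, r.strand)].counts[ws:we]
            (in_peak if active else in_bg).append((ip.sum(), inp.sum()))
        # ratio of (IP/input) inside peaks to (IP/input) in inactive peak
        # regions cancels library-scale factors and region-coverage bias
        peak_ratio = sum(a for a, _ in in_peak) / sum(b for _, b in in_peak)
        bg_ratio = sum(a for a, _ in in_bg) / sum(b for _, b in in_bg)
        assert peak_ratio / bg_ratio == pytest.approx(cfg.ip_enrichment, rel=0.10)

    def test_nb_marginal_goodness_of_fit(self, rng):
        """Sampler matches the NB(mean, dispersion) pmf (chi-square, alpha=0.01)."""
        for disp in (0.005, 0.05):
            mean, n = 30.0, 10000
            draws = sample_nb(rng, np.full(n, mean), disp)
            size = 1.0 / disp
            p = size / (size + mean)
            hi = int(stats.nbinom.ppf(0.999, size, p))
            edges = np.arange(0, hi + 2)
            obs, _ = np.histogram(draws, bins=np.append(edges, np.inf))
            pmf = stats.nbinom.pmf(edges, size, p)
            pmf[-1] += stats.nbinom.sf(hi, size, p)
            exp = pmf * n
            keep = exp >= 5
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            pval = stats.chi2.sf(chi2, keep.sum() - 1)
            assert pval > 0.01


class TestExpression:
    def test_replicate_layout(self, default_sim):
        assert len(default_sim.rna.samples) == 6
        assert len(default_sim.polysome.samples) == 4
        for cond in ("control", "copper"):
            assert len(default_sim.rna.columns(condition=cond)) == 3
            assert len(default_sim.polysome.columns(condition=cond)) == 2

    def test_zero_shifts_give_null_category_differences(self):
        cfg = SimulationConfig(
            n_transcripts=2000, seed=9,
            lfc_shift_stress_enriched=0.0, lfc_shift_control_enriched=0.0,
            lfc_shift_lncrna_stress=0.0, occupancy_shift_stress_enriched=0.0,
        )
        ann, seqs = generate_transcriptome(cfg)
        truth = plant_peaks(ann, seqs, cfg)
        rna, _ = simulate_expression(truth, cfg)
        norm = rna.counts / (rna.counts.sum(0) / rna.counts.sum(0).mean())
        lfc = np.log2(
            (norm[:, rna.columns(condition="copper")].mean(1) + 1)
            / (norm[:, rna.columns(condition="control")].mean(1) + 1)
        )
        cls = truth.transcripts["peak_class"].to_numpy()
        a, b = lfc[cls == "stress-only"], lfc[cls == "shared"]
        t = stats.ttest_ind(a, b, equal_var=False).statistic
        assert abs(t) < 3

    def test_planted_shift_recovered(self):
        """+0.5 log2 on stress hosts shows up as the category mean log2FC."""
        cfg = SimulationConfig(n_transcripts=1000, seed=13, frac_methylated=1.0,
                               frac_stress_only=0.3, frac_control_only=0.3,
                               noncoding_frac=0.0)
        ann, seqs = generate_transcriptome(cfg)
        truth = plant_peaks(ann, seqs, cfg)
        rna, _ = simulate_expression(truth, cfg)
        norm = rna.counts / (rna.counts.sum(0) / rna.counts.sum(0).mean())
        lfc = np.log2(
            (norm[:, rna.columns(condition="copper")].mean(1) + 1)
            / (norm[:, rna.columns(condition="control")].mean(1) + 1)
        )
        cls = truth.transcripts["peak_class"].to_numpy()
        assert lfc[cls == "stress-only"].mean() == pytest.approx(0.5, abs=0.1)
        assert lfc[cls == "control-only"].mean() == pytest.approx(-0.5, abs=0.1)
        assert lfc[cls == "shared"].mean() == pytest.approx(0.0, abs=0.1)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_transcripts=123, seed=5, depth=12.5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        back = SimulationConfig.from_yaml(str(path))
        assert back == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"frac_methylated": 1.5})
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"unknown_key": 1})
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"ip_enrichment": 0.5})
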