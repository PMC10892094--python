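"""Consensus, classification, transcript assignment: examples + oracles."""

import numpy as np
import pandas as pd
import pytest

from m6adyn.core import GenomicInterval, TranscriptModel, make_peak
from m6adyn.dynamics import (
    assign_to_transcripts,
    classify,
    consensus,
    ncrna_breakdown,
)


def peak(start, end, strand="+", chrom="chr1", name="p"):
    return make_peak(chrom, start, end, strand, name=name)


# ----------------------------------------------------------------------
# per-base oracles (independent of the interval arithmetic under test)
# ----------------------------------------------------------------------
def base_set(p):
    return (p.interval.chrom, p.interval.strand, set(range(p.interval.start, p.interval.end)))


def bases_overlap(a, b):
    ca, sa, ba = base_set(a)
    cb, sb, bb = base_set(b)
    return ca == cb and sa == sb and len(ba & bb) >= 1


def consensus_oracle(replicate_peaks):
    """Greedy coordinate-order grouping using per-base overlap tests."""
    sorted_reps = [
        sorted(reps, key=lambda p: (p.interval.chrom, p.interval.strand,
                                    p.interval.start, p.interval.end, p.name))
        for reps in replicate_peaks
    ]
    used = [set() for _ in replicate_peaks]
    out = []
    for a in sorted_reps[0]:
        group = [a]
        ok = True
        for r in range(1, len(sorted_reps)):
            found = None
            for i, b in enumerate(sorted_reps[r]):
                if i in used[r]:
                    continue
                if all(bases_overlap(b, g) for g in group):
                    found = (i, b)
                    break
            if found is None:
                ok = False
                break
            group.append(found[1])
        if not ok:
            continue
        for r in range(1, len(sorted_reps)):
            used[r].add(next(i for i, b in enumerate(sorted_reps[r]) if b is group[r]))
        union = set()
        for g in group:
            union |= base_set(g)[2]
        out.append((group[0].interval.chrom, group[0].interval.strand,
                    min(union), max(union) + 1))
    return sorted(out)


def classify_oracle(control, stress):
    s_only, shared = [], []
    for s in stress:
        if any(bases_overlap(s, c) for c in control):
            shared.append(s)
        else:
            s_only.append(s)
    c_only = [c for c in control if not any(bases_overlap(c, s) for s in stress)]
    return s_only, c_only, shared


def random_peaks(rng, n, name_prefix):
    out = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, 3000))
        out.append(peak(start, start + int(rng.integers(50, 250)), strand,
                        name=f"{name_prefix}_{i}"))
    return out


class TestConsensus:
    def test_identical_peaks_in_all_replicates(self):
        reps = [[peak(100, 300, name=f"r{i}")] for i in range(3)]
        got = consensus(reps)
        assert len(got) == 1
        assert (got[0].interval.start, got[0].interval.end) == (100, 300)
        assert len(got[0].members) == 3

    def test_peak_in_two_of_three_replicates_dropped(self):
        """High confidence requires support from all three replicates."""
        reps = [[peak(100, 300)], [peak(150, 320)], []]
        assert consensus(reps) == []

    def test_staggered_mutually_overlapping_peaks_union(self):
        reps = [[peak(100, 260)], [peak(150, 310)], [peak(200, 360)]]
        got = consensus(reps)
        assert len(got) == 1
        assert (got[0].interval.start, got[0].interval.end) == (100, 360)

    def test_chained_but_not_mutual_overlap_rejected(self):
        # a-b overlap and b-c overlap but a-c do not: no 3-way consensus
        reps = [[peak(100, 200)], [peak(180, 300)], [peak(280, 400)]]
        assert consensus(reps) == []

    def test_strand_respected(self):
        reps = [[peak(100, 300, "+")], [peak(100, 300, "-")], [peak(100, 300, "+")]]
        assert consensus(reps) == []

    def test_member_joins_at_most_one_consensus(self):
        # two rep-1 peaks both overlap the single rep-2/3 peaks
        reps = [
            [peak(100, 200, name="a1"), peak(150, 260, name="a2")],
            [peak(120, 240, name="b1")],
            [peak(130, 250, name="c1")],
        ]
        got = consensus(reps)
        assert len(got) == 1  # b1/c1 are consumed by the first group

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(30):
            reps = [random_peaks(rng, int(rng.integers(3, 25)), f"r{j}")
                    for j in range(3)]
            got = sorted(
                (c.interval.chrom, c.interval.strand, c.interval.start, c.interval.end)
                for c in consensus(reps)
            )
            assert got == consensus_oracle(reps)


class TestClassify:
    def c(self, start, end, strand="+", cond="x"):
        from m6adyn.dynamics import ConsensusPeak

        return ConsensusPeak(GenomicInterval("chr1", start, end, strand), ("m",), cond)

    def test_disjoint_sets_all_condition_specific(self):
        ctrl = [self.c(0, 100)]
        stress = [self.c(500, 600)]
        s, c, sh = classify(ctrl, stress)
        assert (len(s), len(c), len(sh)) == (1, 1, 0)

    def test_identical_sets_all_shared(self):
        ctrl = [self.c(0, 100), self.c(500, 600)]
        stress = [self.c(0, 100), self.c(500, 600)]
        s, c, sh = classify(ctrl, stress)
        assert (len(s), len(c), len(sh)) == (0, 0, 2)
        # shared reported once, with stress-side coordinates
        assert all(x in stress for x in sh)

    def test_partition_and_symmetry_on_random_sets(self, rng):
        from m6adyn.dynamics import ConsensusPeak

        def rand_cons(n, cond):
            return [
                ConsensusPeak(
                    GenomicInterval(
                        "chr1", int(s := rng.integers(0, 3000)),
                        int(s + rng.integers(50, 250)),
                        "+" if rng.random() < 0.5 else "-",
                    ),
                    (f"{cond}{i}",), cond,
                )
                for i in range(n)
            ]

        for _ in range(20):
            ctrl = rand_cons(int(rng.integers(5, 40)), "ctl")
            stress = rand_cons(int(rng.integers(5, 40)), "cu")
            s, c, sh = classify(ctrl, stress)
            # partition: every peak counted exactly once, shared on stress side
            assert len(s) + len(sh) == len(stress)
            assert len(c) == len(ctrl) - sum(
                1 for x in ctrl if any(bases_overlap(x, y) for y in stress)
            )
            # oracle equivalence
            os_, oc, osh = classify_oracle(
                [x.to_peak() for x in ctrl], [x.to_peak() for x in stress]
            )
            assert len(s) == len(os_) and len(c) == len(oc) and len(sh) == len(osh)
            # symmetry: swapping conditions swaps the specific sets
            s2, c2, sh2 = classify(stress, ctrl)
            assert {id(x) for x in s2} == {id(x) for x in [y for y in ctrl if y in c]}
            assert len(c2) == len(s)


class TestAssignment:
    @pytest.fixture()
    def annotation(self):
        mk = lambda tid, start, end, strand="+", biotype="mRNA", cds=None: TranscriptModel(
            tid, f"g_{tid}", biotype,
            [GenomicInterval("chr1", start, end, strand)],
            *(cds or (start + 50, end - 50) if biotype == "mRNA" else (None, None)),
        )
        return [
            mk("tA", 0, 1000),
            mk("tB", 2000, 3000),
            mk("tC", 4000, 5000, biotype="lncRNA"),
            mk("tD", 6000, 7000, biotype="ncRNA"),
        ]

    def test_precedence_stress_over_shared(self, annotation):
        cats = {
            "stress-enriched": [peak(100, 300, name="s1")],
            "control-enriched": [],
            "shared": [peak(500, 700, name="sh1")],
        }
        a = assign_to_transcripts(cats, annotation)
        row = a.table.set_index("transcript_id").loc["tA"]
        assert row["category"] == "stress-enriched"

    def test_transcript_without_peaks_absent(self, annotation):
        cats = {"stress-enriched": [peak(100, 300)], "control-enriched": [], "shared": []}
        a = assign_to_transcripts(cats, annotation)
        assert "tB" not in set(a.table["transcript_id"])

    def test_intergenic_bucket(self, annotation, caplog):
        cats = {
            "stress-enriched": [],
            "control-enriched": [],
            "shared": [peak(1200, 1400, name="nowhere")],
        }
        with caplog.at_level("INFO", logger="m6adyn"):
            a = assign_to_transcripts(cats, annotation)
        assert len(a.intergenic) == 1
        assert a.table.empty

    def test_strand_respected_in_assignment(self, annotation):
        cats = {
            "stress-enriched": [peak(100, 300, strand="-")],
            "control-enriched": [],
            "shared": [],
        }
        a = assign_to_transcripts(cats, annotation)
        assert len(a.intergenic) == 1  # tA is on +

    def test_ncrna_breakdown_counts_and_conservation(self, annotation):
        cats = {
            "stress-enriched": [peak(4100, 4300, name="s1")],
            "control-enriched": [peak(6100, 6300, name="c1")],
            "shared": [peak(4500, 4700, name="sh1"), peak(100, 300, name="sh2")],
        }
        a = assign_to_transcripts(cats, annotation)
        table = ncrna_breakdown(a)
        assert table.loc["lncRNA", "stress-enriched"] == 1
        assert table.loc["ncRNA", "control-enriched"] == 1
        # mRNA tA not counted; row sums equal methylated ncRNA transcripts
        assert table["total"].sum() == 2

    def test_empty_annotation_gives_empty_breakdown(self):
        cats = {"stress-enriched": [], "control-enriched": [], "shared": []}
        a = assign_to_transcripts(cats, [])
        assert ncrna_breakdown(a).empty


class TestEndToEndRecall:
    def test_category_recall_against_truth(self, default_sim, default_analysis):
        """Full chain (call -> consensus -> classify -> assign) recovers the
        planted per-transcript classes at >= 95% for every category."""
        truth = default_sim.truth.transcripts.query("methylated")
        truth_map = {
            "stress-only": "stress-enriched",
            "control-only": "control-enriched",
            "shared": "shared",
        }
        got = default_analysis.assignment.table.set_index("transcript_id")["category"]
        for cls, cat in truth_map.items():
            tids = truth.query("peak_class == @cls")["transcript_id"]
            hit = sum(1 for t in tids if t in got.index and got[t] == cat)
            assert hit / len(tids) >= 0.95, (cls, hit, len(tids))

    def test_partition_of_consensus_peaks(self, default_analysis):
        s = default_analysis.summary
        n_cats = sum(s["peak_categories"].values())
        n_stress_side = s["consensus_peaks"]["copper"]
        n_control_side = s["consensus_peaks"]["control"]
        # stress-enriched + shared = copper consensus; control-enriched is the rest
        assert (
            s["peak_categories"]["stress-enriched"] + s["peak_categories"]["shared"]
            == n_stress_side
        )
        assert n_cats == s["peak_categories"]["control-enriched"] + n_stress_side
        assert s["peak_categories"]["control-enriched"] <= n_control_side

    def test_lncrna_largest_in_synthetic_breakdown(self, default_analysis):
        table = default_analysis.ncrna
        assert table["total"].idxmax() == "lncRNA"
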