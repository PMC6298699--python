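"""Three-letter alignment, call extraction, aggregation, labelling."""

import numpy as np
import pandas as pd
import pytest

from methyltarget import (
    PlasmidSpec,
    aggregate_report,
    align_reads,
    build_plasmid,
    estimate_frequencies,
    extract_calls,
    label_cis_trans,
    make_truth,
    quantify_reads,
    simulate_bisulfite_reads,
    three_letter_align,
)
from methyltarget.bsquant import (
    Call,
    brute_force_align,
    count_calls_batch,
    default_max_mismatch,
    estimated_background,
)
from methyltarget.simdata import revcomp


def _window(plasmid, start1, n, strand="+"):
    L = plasmid.length
    w = "".join(plasmid.sequence[(start1 - 1 + o) % L] for o in range(n))
    return w if strand == "+" else revcomp(w)


class TestAlignment:
    def test_exact_converted_copy_places_at_origin(self, small_plasmid):
        w = _window(small_plasmid, 50, 70).replace("C", "T")
        p = three_letter_align(w, small_plasmid)
        assert (p.position, p.strand, p.mismatches, p.valid) == (50, "+", 0, True)

    def test_minus_strand_read_round_trips(self, small_plasmid):
        w = _window(small_plasmid, 50, 70, strand="-").replace("C", "T")
        p = three_letter_align(w, small_plasmid)
        assert (p.position, p.strand, p.valid) == (50, "-", True)

    def test_read_spanning_the_origin_wraps(self, small_plasmid):
        L = small_plasmid.length
        w = _window(small_plasmid, L - 10, 40).replace("C", "T")
        p = three_letter_align(w, small_plasmid)
        assert (p.position, p.strand, p.valid) == (L - 10, "+", True)

    def test_mismatch_budget_and_no_hit(self, small_plasmid, rng):
        w = _window(small_plasmid, 100, 60).replace("C", "T")
        # corrupt more than the budget allows
        budget = default_max_mismatch(60)
        corrupt = list(w)
        pos = rng.choice(60, size=budget + 4, replace=False)
        for i in pos:
            corrupt[i] = {"A": "G", "G": "A", "T": "A", "C": "A"}[corrupt[i]]
        p = three_letter_align("".join(corrupt), small_plasmid)
        assert not p.valid and p.reason == "no_hit"

    def test_ambiguous_read_from_duplicated_region_dropped(self):
        # hand-built circular reference with an exact 40 bp duplication
        block = "ATTGATAGGATTAGTTAGGATATTAGATTGAGATTAGGAT"
        filler1 = "TTAGGATTTAATTGGTATTA" * 3
        filler2 = "AGGATTAAATTGATTAGGTA" * 3
        seq = block + filler1 + block + filler2
        plasmid = PlasmidSpec(
            name="dup", sequence=seq, protospacer_start=41, protospacer_strand="+",
            pam_end=63, target_cpg_pos=70, gap=6, nontarget_cpg_positions=(),
            restriction_sites=(),
        )
        p = three_letter_align(block[:35], plasmid)
        assert not p.valid and p.reason == "ambiguous"

    def test_batch_equals_brute_force_oracle(self, small_plasmid, small_truth):
        rs = simulate_bisulfite_reads(
            small_plasmid, small_truth, coverage=14, read_length=80,
            error_rate=0.01, seed=21,
        )
        res = align_reads(rs.bases, small_plasmid)
        for i in range(rs.n_reads):
            bf = brute_force_align(rs.sequence(i), small_plasmid)
            assert bf.valid == bool(res["valid"][i])
            if bf.valid:
                assert bf.position - 1 == res["position0"][i]
                assert (bf.strand == "-") == bool(res["minus"][i])
                assert bf.mismatches == res["mismatches"][i]

    def test_strand_separation(self, small_plasmid, small_truth):
        rs = simulate_bisulfite_reads(small_plasmid, small_truth, 30, 80, seed=3)
        res = align_reads(rs.bases, small_plasmid)
        ok = res["valid"]
        assert np.array_equal(res["minus"][ok], (rs.origin_strand == "-")[ok])


class TestCalls:
    def test_plus_read_calls(self, small_plasmid):
        w = _window(small_plasmid, 1, 80)
        # unconverted copy: every reference C is a methylated call
        p = three_letter_align(w.replace("C", "T"), small_plasmid)
        calls = extract_calls(p, w, small_plasmid)
        assert all(c.methylated for c in calls)
        assert all(c.strand == "+" for c in calls)
        n_c = w.count("C")
        assert len(calls) == n_c
        # fully converted copy: every call unmethylated
        calls_u = extract_calls(p, w.replace("C", "T"), small_plasmid)
        assert len(calls_u) == n_c and not any(c.methylated for c in calls_u)

    def test_contexts_come_from_reference_trinucleotide(self, small_plasmid):
        w = _window(small_plasmid, small_plasmid.target_cpg_pos - 2, 30)
        p = three_letter_align(w.replace("C", "T"), small_plasmid)
        calls = extract_calls(p, w, small_plasmid)
        at_target = [c for c in calls if c.pos == small_plasmid.target_cpg_pos]
        assert len(at_target) == 1
        assert at_target[0].context == "CpG"
        assert at_target[0].trinucleotide.startswith("CG")

    def test_calls_match_sidecar_without_noise(self, small_plasmid, small_truth):
        rs = simulate_bisulfite_reads(
            small_plasmid, small_truth, coverage=12, read_length=80,
            conversion_rate=1.0, error_rate=0.0, seed=17,
        )
        sidecar = rs.sidecar_frame().set_index(["read_id", "pos", "strand"])
        res = align_reads(rs.bases, small_plasmid)
        checked = 0
        for i in range(rs.n_reads):
            if not res["valid"][i]:
                continue
            pl = brute_force_align(rs.sequence(i), small_plasmid, read_id=rs.read_id(i))
            for c in extract_calls(pl, rs.sequence(i), small_plasmid):
                if c.context != "CpG":
                    continue
                truth_state = sidecar.loc[(rs.read_id(i), c.pos, pl.strand), "methylated"]
                assert bool(truth_state) == c.methylated
                checked += 1
        assert checked > 50

    def test_batch_counting_equals_per_read_composition(self, small_plasmid, small_truth):
        rs = simulate_bisulfite_reads(small_plasmid, small_truth, 5, 70, seed=23)
        res = align_reads(rs.bases, small_plasmid)
        batch = count_calls_batch(rs.bases, res, small_plasmid)
        calls = []
        for i in range(rs.n_reads):
            if res["valid"][i]:
                pl = brute_force_align(rs.sequence(i), small_plasmid)
                calls.extend(extract_calls(pl, rs.sequence(i), small_plasmid))
        ref = aggregate_report(calls)
        merged = batch.merge(ref, on=["pos", "strand"], suffixes=("_b", "_r"))
        assert len(merged) == len(batch) == len(ref)
        assert (merged["count_methylated_b"] == merged["count_methylated_r"]).all()
        assert (merged["count_unmethylated_b"] == merged["count_unmethylated_r"]).all()


class TestAggregation:
    def test_empty_calls_empty_report(self):
        assert aggregate_report([]).empty

    def test_counts_conserved(self):
        calls = [Call(10, "+", "CpG", "CGA", True)] * 5 + [
            Call(10, "+", "CpG", "CGA", False)
        ] * 5
        rep = aggregate_report(calls)
        assert len(rep) == 1
        assert rep.loc[0, "count_methylated"] == 5
        assert rep.loc[0, "count_unmethylated"] == 5
        total = rep["count_methylated"].sum() + rep["count_unmethylated"].sum()
        assert total == len(calls)


class TestFrequenciesAndLabels:
    def _report(self, rows):
        return pd.DataFrame(
            rows,
            columns=["pos", "strand", "context", "trinucleotide",
                     "count_methylated", "count_unmethylated"],
        )

    def test_frequency_arithmetic(self):
        rep = self._report([(5, "+", "CpG", "CGT", 5, 5), (9, "-", "CpG", "CGA", 0, 20)])
        t = estimate_frequencies(rep, min_coverage=1)
        assert t["freq"].tolist() == [0.5, 0.0]

    def test_low_coverage_flagged_missing_not_zero(self):
        rep = self._report([(5, "+", "CpG", "CGT", 1, 2)])
        t = estimate_frequencies(rep, min_coverage=10)
        assert t["missing"].iloc[0]
        assert np.isnan(t["freq"].iloc[0])

    def test_conversion_correction_formula(self):
        rep = self._report([(5, "+", "CpG", "CGT", 5, 995)])
        t = estimate_frequencies(rep, min_coverage=1, conversion_rate=0.995)
        assert t["freq_corrected"].iloc[0] == pytest.approx(0.0)

    def test_target_dyad_labels(self, small_plasmid):
        t = small_plasmid.target_cpg_pos
        rep = self._report(
            [(t, "+", "CpG", "CGC", 3, 7), (t + 1, "-", "CpG", "CGC", 2, 8),
             (50, "+", "CpG", "CGA", 0, 10)]
        )
        lab = label_cis_trans(estimate_frequencies(rep, 1), small_plasmid)
        by = lab.set_index(["pos", "strand"])
        assert by.loc[(t, "+"), "cis_trans"] == "cis" and by.loc[(t, "+"), "target"]
        assert by.loc[(t + 1, "-"), "cis_trans"] == "trans" and by.loc[(t + 1, "-"), "target"]
        assert not by.loc[(50, "+"), "target"]

    def test_labels_invariant_under_plasmid_rotation(self, small_plasmid):
        p = small_plasmid
        L = p.length
        k = 123

        def shift(pos):
            return (pos - 1 - k) % L + 1

        rotated = PlasmidSpec(
            name=p.name, sequence=p.sequence[k:] + p.sequence[:k],
            protospacer_start=shift(p.protospacer_start),
            protospacer_strand=p.protospacer_strand,
            pam_end=shift(p.pam_end), target_cpg_pos=shift(p.target_cpg_pos),
            gap=p.gap,
            nontarget_cpg_positions=tuple(sorted(shift(q) for q in p.nontarget_cpg_positions)),
            restriction_sites=tuple((n, shift(s), st) for n, s, st in p.restriction_sites),
        )
        t = p.target_cpg_pos
        rep = self._report(
            [(t, "+", "CpG", "CGC", 3, 7), (t + 1, "-", "CpG", "CGC", 2, 8)]
        )
        rep_rot = rep.assign(pos=rep["pos"].map(shift))
        lab = label_cis_trans(rep, p).set_index("strand")
        lab_rot = label_cis_trans(rep_rot, rotated).set_index("strand")
        for s in ("+", "-"):
            assert lab.loc[s, "cis_trans"] == lab_rot.loc[s, "cis_trans"]
            assert lab.loc[s, "target"] == lab_rot.loc[s, "target"]

    def test_unknown_position_raises(self, small_plasmid):
        rep = self._report([(10_000, "+", "CpG", "CGT", 1, 1)])
        with pytest.raises(ValueError):
            label_cis_trans(rep, small_plasmid)


class TestEndToEndRecovery:
    def test_estimates_within_three_se_of_truth(self, small_plasmid, linker15):
        truth = make_truth(small_plasmid, linker15, seed=5)
        rs = simulate_bisulfite_reads(
            small_plasmid, truth, coverage=600, read_length=80,
            conversion_rate=1.0, error_rate=0.0, seed=31,
        )
        _, sites = quantify_reads(rs, small_plasmid)
        merged = sites.merge(truth, on=["pos", "strand"], suffixes=("", "_true"))
        assert len(merged) == len(truth)
        for _, r in merged.iterrows():
            se = np.sqrt(max(r.freq_true * (1 - r.freq_true), 1e-4) / r.coverage)
            assert abs(r.freq - r.freq_true) <= 3.5 * se

    def test_unmethylated_plasmid_background_near_nonconversion(
        self, small_plasmid, linker15
    ):
        truth = make_truth(small_plasmid, linker15, seed=5)
        truth["freq"] = 0.0
        rs = simulate_bisulfite_reads(
            small_plasmid, truth, coverage=400, read_length=80,
            conversion_rate=0.995, error_rate=0.0, seed=37,
        )
        rep, sites = quantify_reads(rs, small_plasmid, conversion_rate=0.995)
        raw = (sites["count_methylated"].sum()
               / (sites["count_methylated"] + sites["count_unmethylated"]).sum())
        assert raw == pytest.approx(0.005, abs=0.002)
        assert sites["freq_corrected"].mean() == pytest.approx(0.0, abs=0.002)
        assert estimated_background(rep) == pytest.approx(0.005, abs=0.002)
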