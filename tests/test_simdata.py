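"""Plasmid layout, condition profiles, off-target baseline, read simulator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methyltarget import (
    build_plasmid,
    condition_profile,
    count_cpg_dyads,
    get_condition,
    load_conditions,
    make_truth,
    sample_offtarget_frequencies,
    simulate_bisulfite_reads,
)
from methyltarget.simdata import LayoutError, revcomp


def brute_force_cpg_count(seq: str) -> int:
    """Independent circular substring scan."""
    n = len(seq)
    return sum(1 for i in range(n) if seq[i] == "C" and seq[(i + 1) % n] == "G")


class TestBuildPlasmid:
    @pytest.mark.parametrize(
        "length,n_cpg,gap,seed",
        [(4000, 0, 12, 7), (4000, 241, 12, 1), (600, 8, 11, 3), (1500, 30, 2, 9)],
    )
    def test_cpg_dyad_count_matches_independent_scan(self, length, n_cpg, gap, seed):
        p = build_plasmid(length, n_cpg, gap, seed)
        assert count_cpg_dyads(p.sequence) == n_cpg + 1
        assert brute_force_cpg_count(p.sequence) == n_cpg + 1
        assert len(p.nontarget_cpg_positions) == n_cpg

    def test_gap_convention_and_pam(self, small_plasmid):
        p = small_plasmid
        assert p.target_cpg_pos - p.pam_end - 1 == p.gap
        pam = p.sequence[p.pam_end - 3 : p.pam_end]
        assert pam[1:] == "GG"  # NGG
        # target CpG really is a CG on the cis (plus) strand
        assert p.sequence[p.target_cpg_pos - 1 : p.target_cpg_pos + 1] == "CG"

    def test_target_embedded_in_fspi_site(self, small_plasmid):
        p = small_plasmid
        start = p.target_cpg_pos - 3  # 0-based site start is target-2
        assert p.sequence[start : start + 6] == "TGCGCA"

    def test_deterministic_given_seed(self):
        a = build_plasmid(800, 10, 12, seed=42)
        b = build_plasmid(800, 10, 12, seed=42)
        assert a == b

    def test_infeasible_layouts_raise(self):
        with pytest.raises(LayoutError):
            build_plasmid(4000, 241, 1, seed=0)  # site 1 would overlap PAM
        with pytest.raises(LayoutError):
            build_plasmid(300, 200, 12, seed=0)  # no room for 200 dyads
        with pytest.raises(ValueError):
            build_plasmid(100, 5, 12, seed=0)


class TestConditionProfile:
    def test_packaged_anchor_values(self):
        p15 = get_condition("linker15")
        assert condition_profile(p15, p15.peak_gap["trans"], "trans") == pytest.approx(0.367)
        assert condition_profile(p15, 2, "trans") == p15.baseline  # below g_min=8
        p4 = get_condition("linker4")
        assert condition_profile(p4, 11, "trans") == pytest.approx(0.524)
        p25 = get_condition("linker25")
        assert condition_profile(p25, p25.optimal_gap, "trans") == pytest.approx(0.55)
        s291f = get_condition("S291F")
        assert condition_profile(s291f, 12, "trans") == pytest.approx(0.21)
        assert condition_profile(s291f, 12, "cis") == pytest.approx(0.022)

    def test_all_conditions_load_with_valid_invariants(self):
        conds = load_conditions()
        assert {"linker4", "linker15", "linker25", "Y305F", "T313A", "S291F", "S317A"} <= set(conds)
        for c in conds.values():
            assert 0 <= c.baseline <= min(c.amplitude.values())
            assert c.support[0] <= c.support[1]
            assert c.period_T > 0

    @given(k=st.integers(-3, 3), dg=st.floats(0, 5.5))
    @settings(max_examples=40, deadline=None)
    def test_periodic_and_symmetric_about_peak_inside_unbounded_support(self, k, dg):
        p15 = get_condition("linker15")
        prof = dataclasses.replace(p15, support=(0, 10_000))
        peak = prof.peak_gap["trans"]
        g = peak + dg + k * prof.period_T
        if g < 0:
            return
        ref = condition_profile(prof, peak + dg, "trans")
        assert condition_profile(prof, g, "trans") == pytest.approx(ref, abs=1e-12)
        if peak - dg >= 0:
            assert condition_profile(prof, peak - dg, "trans") == pytest.approx(ref, abs=1e-12)


class TestOfftargetBaseline:
    def test_empirical_median_matches_parameterisation(self):
        draws = sample_offtarget_frequencies(10_000, 0.006, 1.0, seed=3)
        assert draws.size == 20_000
        assert np.median(draws) == pytest.approx(0.006, rel=0.10)

    def test_large_dispersion_degenerates_to_median(self):
        draws = sample_offtarget_frequencies(500, 0.006, 1e6, seed=4)
        assert np.allclose(draws, 0.006, atol=5e-4)

    def test_invalid_median_raises(self):
        with pytest.raises(ValueError):
            sample_offtarget_frequencies(10, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            sample_offtarget_frequencies(10, 1.5, 1.0, seed=0)


class TestReadSimulator:
    def test_full_conversion_no_methylation_gives_all_T(self, small_plasmid, linker15):
        truth = make_truth(small_plasmid, linker15, seed=5)
        truth["freq"] = 0.0
        rs = simulate_bisulfite_reads(
            small_plasmid, truth, coverage=100, read_length=80,
            conversion_rate=1.0, error_rate=0.0, seed=2,
        )
        L = small_plasmid.length
        seq = small_plasmid.sequence
        for i in range(0, rs.n_reads, 37):
            start0 = rs.origin_pos[i] - 1
            window = "".join(seq[(start0 + o) % L] for o in range(rs.read_length))
            expect = window.replace("C", "T")
            if rs.origin_strand[i] == "-":
                expect = revcomp(window).replace("C", "T")
            assert rs.sequence(i) == expect

    def test_full_methylation_keeps_all_cpg_C(self, small_plasmid, linker15):
        truth = make_truth(small_plasmid, linker15, seed=5)
        truth["freq"] = 1.0
        rs = simulate_bisulfite_reads(
            small_plasmid, truth, coverage=50, read_length=80,
            conversion_rate=1.0, error_rate=0.0, seed=2,
        )
        # sidecar must agree: every CpG cytosine of every molecule methylated
        assert rs.sidecar_meth.all()

    def test_observed_fraction_converges_to_truth(self, small_plasmid, linker15):
        truth = make_truth(small_plasmid, linker15, seed=5)
        truth.loc[truth.target, "freq"] = 0.5
        rs = simulate_bisulfite_reads(
            small_plasmid, truth, coverage=2000, read_length=80,
            conversion_rate=1.0, error_rate=0.0, seed=6,
        )
        t = small_plasmid.target_cpg_pos
        sel = (rs.sidecar_pos == t) & (rs.sidecar_strand == "+")
        n = int(sel.sum())
        frac = rs.sidecar_meth[sel].mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_deterministic_given_seed(self, small_plasmid, small_truth):
        a = simulate_bisulfite_reads(small_plasmid, small_truth, 20, 60, seed=11)
        b = simulate_bisulfite_reads(small_plasmid, small_truth, 20, 60, seed=11)
        assert np.array_equal(a.bases, b.bases)
        assert np.array_equal(a.sidecar_meth, b.sidecar_meth)

    def test_sidecar_covers_cpg_cytosines_of_each_molecule(self, small_plasmid, small_truth):
        rs = simulate_bisulfite_reads(small_plasmid, small_truth, 10, 100, seed=13)
        # every sidecar position is a CpG cytosine on its strand
        seq = small_plasmid.sequence
        L = small_plasmid.length
        for pos, strand in zip(rs.sidecar_pos[:200], rs.sidecar_strand[:200]):
            i = pos - 1
            if strand == "+":
                assert seq[i] == "C" and seq[(i + 1) % L] == "G"
            else:
                assert seq[i] == "G" and seq[i - 1] == "C"

    def test_truth_table_shape(self, small_plasmid, small_truth):
        assert len(small_truth) == 2 * (len(small_plasmid.nontarget_cpg_positions) + 1)
        assert small_truth["freq"].between(0, 1).all()
        assert small_truth["target"].sum() == 2
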