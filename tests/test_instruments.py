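"""Instrument selection: significance filter, clumping, screens, proxies, strength."""

import itertools

import pytest
from hypothesis import given, strategies as st

from tsmr.harmonize import HarmonizedSet, HarmonizedSnp, harmonize, orient_positive_exposure
from tsmr.instruments import (
    SelectionConfig,
    clump,
    filter_significant,
    instrument_strength,
    screen_confounders,
    screen_outcome_association,
    substitute_proxies,
)
from tsmr.summary_data import LDReference, SnpRecord, SummaryStats, builtin_fixture


def _rec(snp, pval, beta=0.05, eaf=0.3, chrom=None, pos=None):
    return SnpRecord(snp, "A", "G", beta=beta, se=0.01, pval=pval,
                     eaf=eaf, chrom=chrom, pos=pos)


def _table(records, label="t", trait_type="quantitative"):
    return SummaryStats(records, trait_label=label, trait_type=trait_type)


class TestFilterSignificant:
    def test_all_printed_instruments_pass_genome_wide_threshold(self, chinese_tables):
        exposure, _ = chinese_tables
        kept = filter_significant(exposure, 5e-8)
        assert kept.ids == exposure.ids  # max p = 3.62e-8 < 5e-8

    def test_stringent_threshold_keeps_only_strongest(self, chinese_tables):
        # at 1e-16 only rs79105258 (4.76e-17) and rs56129017 (2.18e-96) pass
        exposure, _ = chinese_tables
        kept = filter_significant(exposure, 1e-16)
        assert kept.ids == ["rs79105258", "rs56129017"]

    def test_strict_inequality_at_boundary(self):
        stats = _table([_rec("rs1", 5e-8)])
        assert len(filter_significant(stats, 5e-8)) == 0

    def test_empty_input_and_idempotence(self, chinese_tables):
        assert len(filter_significant(_table([]), 5e-8)) == 0
        once = filter_significant(chinese_tables[0], 5e-8)
        assert filter_significant(once, 5e-8).ids == once.ids


def _brute_force_clump(pvals, r2, threshold):
    """Literal restatement of the greedy procedure on index lists."""
    remaining = sorted(range(len(pvals)), key=lambda i: (pvals[i], i))
    index = []
    while remaining:
        head = remaining.pop(0)
        index.append(head)
        remaining = [j for j in remaining
                     if r2.get(frozenset((head, j)), 0.0) <= threshold]
    return index


class TestClump:
    def test_three_snp_worked_example(self):
        stats = _table([_rec("rs1", 1e-10), _rec("rs2", 1e-9), _rec("rs3", 1e-8)])
        ld = LDReference({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.0, ("rs2", "rs3"): 0.0})
        kept = clump(stats, ld)
        assert kept.ids == ["rs1", "rs3"]

    def test_independent_snps_all_survive(self):
        stats = _table([_rec(f"rs{i}", 10.0**-(8 + i)) for i in range(4)])
        ld = LDReference({(f"rs{i}", f"rs{j}"): 0.0
                          for i in range(4) for j in range(i + 1, 4)})
        assert set(clump(stats, ld).ids) == set(stats.ids)

    def test_perfect_ld_keeps_smaller_p(self):
        stats = _table([_rec("rs_weak", 1e-9), _rec("rs_strong", 1e-12)])
        ld = LDReference({("rs_weak", "rs_strong"): 1.0})
        assert clump(stats, ld).ids == ["rs_strong"]

    def test_unknown_r2_policy(self):
        stats = _table([_rec("rs1", 1e-12), _rec("rs2", 1e-9)])
        ld = LDReference()
        conservative = SelectionConfig(missing_ld_policy="conservative")
        permissive = SelectionConfig(missing_ld_policy="permissive")
        assert clump(stats, ld, conservative).ids == ["rs1"]
        assert set(clump(stats, ld, permissive).ids) == {"rs1", "rs2"}

    def test_window_limits_pruning(self):
        near = _rec("rs_near", 1e-9, chrom="1", pos=1_000_000)
        far = _rec("rs_far", 1e-8, chrom="1", pos=200_000_000)
        head = _rec("rs_head", 1e-12, chrom="1", pos=500_000)
        stats = _table([head, near, far])
        ld = LDReference({("rs_head", "rs_near"): 0.9, ("rs_head", "rs_far"): 0.9})
        kept = clump(stats, ld)  # window auto-enforced: positions present
        assert kept.ids == ["rs_head", "rs_far"]

    def test_window_enforcement_without_positions_errors(self):
        stats = _table([_rec("rs1", 1e-9), _rec("rs2", 1e-8)])
        with pytest.raises(ValueError, match="chrom/pos"):
            clump(stats, LDReference(), enforce_window=True)

    def test_result_independent_of_row_order(self):
        records = [_rec("rs1", 1e-10), _rec("rs2", 1e-9), _rec("rs3", 1e-8)]
        ld = LDReference({("rs1", "rs2"): 0.5, ("rs2", "rs3"): 0.7})
        forward = clump(_table(records), ld).ids
        reversed_ = clump(_table(records[::-1]), ld).ids
        assert sorted(forward) == sorted(reversed_)

    @given(st.data())
    def test_greedy_oracle_equivalence_up_to_six_snps(self, data):
        n = data.draw(st.integers(min_value=1, max_value=6))
        pvals = data.draw(
            st.lists(
                st.floats(min_value=1e-30, max_value=1e-8, allow_nan=False),
                min_size=n, max_size=n, unique=True,
            )
        )
        r2 = {}
        for i, j in itertools.combinations(range(n), 2):
            r2[frozenset((i, j))] = data.draw(
                st.sampled_from([0.0, 0.0005, 0.002, 0.5, 1.0])
            )
        threshold = 0.001
        stats = _table([_rec(f"rs{i:02d}", pvals[i]) for i in range(n)])
        ld = LDReference({(f"rs{i:02d}", f"rs{j:02d}"): r2[frozenset((i, j))]
                          for i, j in itertools.combinations(range(n), 2)})
        expected = [f"rs{i:02d}" for i in _brute_force_clump(pvals, r2, threshold)]
        got = clump(stats, ld, SelectionConfig(clump_r2=threshold)).ids
        assert got == expected


class TestScreens:
    def test_printed_instruments_survive_outcome_screen(self, chinese_tables):
        exposure, outcome = chinese_tables
        kept, log = screen_outcome_association(exposure, outcome, 5e-8)
        assert kept.ids == exposure.ids and not log  # min outcome p = 0.164

    def test_outcome_associated_snp_removed(self):
        stats = _table([_rec("rs1", 1e-10), _rec("rs2", 1e-10)])
        outcome = _table([_rec("rs1", 1e-9), _rec("rs2", 0.5)], trait_type="binary")
        kept, log = screen_outcome_association(stats, outcome, 5e-8)
        assert kept.ids == ["rs2"]
        assert log[0].reason == "outcome_associated"

    def test_threshold_one_removes_everything(self, chinese_tables):
        exposure, outcome = chinese_tables
        kept, log = screen_outcome_association(exposure, outcome, 1.0)
        assert len(kept) == 0 and len(log) == 5

    def test_confounder_screen_names_the_confounder(self):
        stats = _table([_rec("rs1", 1e-10), _rec("rs2", 1e-10)])
        hypertension = _table([_rec("rs1", 1e-12)], label="hypertension")
        kept, log = screen_confounders(stats, [hypertension], 5e-8)
        assert kept.ids == ["rs2"]
        assert log[0].reason == "confounder_associated"
        assert "hypertension" in log[0].detail

    def test_empty_confounder_list_is_identity(self, chinese_tables):
        exposure, _ = chinese_tables
        kept, log = screen_confounders(exposure, [], 5e-8)
        assert kept.ids == exposure.ids and not log

    def test_instrument_absent_from_tables_retained(self):
        stats = _table([_rec("rs1", 1e-10)])
        other = _table([_rec("rs9", 1e-12)], label="bmi")
        kept, _ = screen_confounders(stats, [other], 5e-8)
        assert kept.ids == ["rs1"]


class TestSubstituteProxies:
    def test_printed_proxy_mapping_reproduced(self, japanese_tables):
        _, outcome = japanese_tables
        ld = LDReference({
            ("rs13329271", "rs3825845"): 0.91,
            ("rs56129017", "rs12151139"): 0.95,
        })
        mapping, unresolved = substitute_proxies(
            ["rs13329271", "rs56129017", "rs79105258"], outcome, ld, 0.8
        )
        assert mapping["rs13329271"] == ("rs3825845", 0.91)
        assert mapping["rs56129017"] == ("rs12151139", 0.95)
        assert unresolved == ["rs79105258"]  # no qualifying proxy exists

    def test_low_r2_candidate_unresolved(self):
        outcome = _table([_rec("rs_proxy", 0.5)], trait_type="binary")
        ld = LDReference({("rs_lost", "rs_proxy"): 0.5})
        mapping, unresolved = substitute_proxies(["rs_lost"], outcome, ld, 0.8)
        assert not mapping and unresolved == ["rs_lost"]

    def test_r2_tie_broken_by_outcome_p(self):
        outcome = _table(
            [_rec("rs_a", 0.9), _rec("rs_b", 0.1)], trait_type="binary"
        )
        ld = LDReference({("rs_lost", "rs_a"): 0.9, ("rs_lost", "rs_b"): 0.9})
        mapping, _ = substitute_proxies(["rs_lost"], outcome, ld, 0.8)
        assert mapping["rs_lost"][0] == "rs_b"


class TestInstrumentStrength:
    def test_single_snp_r2_formula(self):
        hset = HarmonizedSet([
            HarmonizedSnp("rs56129017", beta_x=0.131, se_x=0.006,
                          beta_y=-0.122, se_y=0.088, eaf=0.260)
        ])
        strength = instrument_strength(hset, n=72655, sd=1.0)
        assert strength.per_snp_r2["rs56129017"] == pytest.approx(
            2 * 0.26 * 0.74 * 0.131**2, rel=1e-12
        )

    def test_published_f_statistic_from_stated_r2(self):
        # the study's variance explained (0.36%) with N = 72,655 and k = 5
        # gives F = 52.5 by the stated formula
        r2, n, k = 0.0036, 72655, 5
        f = ((n - k - 1) / k) * (r2 / (1 - r2))
        assert f == pytest.approx(52.5, abs=0.05)

    def test_f_monotone_in_r2_and_k(self, chinese_set):
        full = instrument_strength(chinese_set, n=72655)
        fewer = instrument_strength(chinese_set.without("rs78277894"), n=72655)
        assert fewer.r2_total < full.r2_total
        # direct monotonicity of the formula
        def f(r2, k, n=72655.0):
            return ((n - k - 1) / k) * (r2 / (1 - r2))
        assert f(0.004, 5) > f(0.003, 5)
        assert f(0.0036, 4) > f(0.0036, 5)

    def test_missing_eaf_and_small_n_error(self):
        hset = HarmonizedSet([
            HarmonizedSnp("rs1", beta_x=0.1, se_x=0.01, beta_y=0.1, se_y=0.1)
        ])
        with pytest.raises(ValueError, match="rs1"):
            instrument_strength(hset, n=1000)
        hset_eaf = HarmonizedSet([
            HarmonizedSnp("rs1", beta_x=0.1, se_x=0.01, beta_y=0.1, se_y=0.1, eaf=0.3)
        ])
        with pytest.raises(ValueError, match="exceed"):
            instrument_strength(hset_eaf, n=2)


def test_selection_config_validation():
    with pytest.raises(ValueError, match="clump_r2"):
        SelectionConfig(clump_r2=0.9, proxy_r2_floor=0.8)
    with pytest.raises(ValueError, match="missing_ld_policy"):
        SelectionConfig(missing_ld_policy="bogus")
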