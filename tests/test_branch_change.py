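"""Per-branch change metrics, 5% coding, cross-tabs and sign test."""

import math

import numpy as np
import pytest

from renschkit import (
    BMSimConfig,
    asr_bm,
    branch_changes,
    code_branches,
    crosstab,
    rate_difference_regression,
    sign_binomial_test,
    simulate_bm_bivariate,
    simulate_yule_tree,
    ssd_range_from_reconstructions,
)
from renschkit.branch_change import BranchChangeRecord, single_sex_ssd_counts


def _rec(branch, initial, final, duration, trait="male_length"):
    dw = (
        abs(math.log(final / initial)) / duration
        if initial > 0 and final > 0 and duration > 0
        else None
    )
    return BranchChangeRecord(
        branch=branch, trait=trait, initial=initial, final=final,
        change=final - initial, abs_change=abs(final - initial),
        darwins=dw, duration=duration,
    )


@pytest.fixture
def reconstructed_changes(tree50):
    male, female, _ = simulate_bm_bivariate(tree50, BMSimConfig(seed=21))
    am = asr_bm(tree50, {t: male[t] for t in tree50.tip_labels}, trait="male_length")
    af = asr_bm(tree50, {t: female[t] for t in tree50.tip_labels}, trait="female_length")
    return am, af, branch_changes(tree50, am), branch_changes(tree50, af)


class TestBranchChanges:
    def test_darwin_unit_identity(self):
        """initial 1.0 -> final e over 1 My is exactly one darwin."""
        from renschkit import AncestralReconstruction, Phylogeny

        t = Phylogeny.from_newick("(A:1);")
        rec = AncestralReconstruction(
            trait="m",
            estimates={t.root_id: 1.0, "A": math.e},
            ci={t.root_id: (1.0, 1.0), "A": (math.e, math.e)},
            sigma2=0.0,
        )
        (br,) = branch_changes(t, rec)
        assert br.darwins == pytest.approx(1.0, abs=1e-15)

    def test_hand_arithmetic(self):
        rec = _rec("b", 1.2, 1.5, 2.0)
        assert rec.change == pytest.approx(0.3)
        assert rec.darwins == pytest.approx(abs(math.log(1.25)) / 2, abs=1e-9)
        assert rec.darwins == pytest.approx(0.111572, abs=1e-6)

    def test_records_cover_every_branch(self, tree50, reconstructed_changes):
        _, _, rm, _ = reconstructed_changes
        assert len(rm) == 2 * tree50.n_tips - 2

    def test_darwins_invariant_to_unit_rescale(self, tree50, reconstructed_changes):
        am, _, rm, _ = reconstructed_changes
        micro = type(am)(
            trait=am.trait,
            estimates={k: v * 1000.0 for k, v in am.estimates.items()},
            ci={k: (lo * 1000, hi * 1000) for k, (lo, hi) in am.ci.items()},
            sigma2=am.sigma2 * 1e6,
        )
        rm_micro = branch_changes(tree50, micro)
        for a, b in zip(rm, rm_micro):
            assert b.darwins == pytest.approx(a.darwins, rel=1e-9)

    def test_telescoping_sum_of_changes(self, tree50, reconstructed_changes):
        am, _, rm, _ = reconstructed_changes
        by_child = {r.branch: r for r in rm}
        root = tree50.root_id
        for tip in tree50.tip_labels[:10]:
            node = tree50.node(tip)
            total = 0.0
            while node.parent_node is not None:
                total += by_child[node._node_id].change
                node = node.parent_node
            assert total == pytest.approx(
                am.estimates[tip] - am.estimates[root], abs=1e-9
            )

    def test_missing_node_value_errors(self, tree50, reconstructed_changes):
        am = reconstructed_changes[0]
        broken = type(am)(
            trait=am.trait,
            estimates={k: v for k, v in am.estimates.items() if k != tree50.root_id},
            ci=am.ci, sigma2=am.sigma2,
        )
        with pytest.raises(ValueError, match=tree50.root_id):
            branch_changes(tree50, broken)

    def test_zero_duration_darwins_undefined(self):
        rec = _rec("b", 1.0, 2.0, 0.0)
        assert rec.darwins is None
        assert rec.change == pytest.approx(1.0)


class TestCoding:
    def test_five_percent_rule_on_sizes(self):
        m4 = [_rec("b", 1.00, 1.04, 1.0)]
        m10 = [_rec("b", 1.00, 1.10, 1.0)]
        f = [_rec("b", 1.00, 1.00, 1.0, trait="female_length")]
        assert code_branches(m4, f, ssd_range=0.5)[0].code_male == "="
        assert code_branches(m10, f, ssd_range=0.5)[0].code_male == "+"

    def test_ssd_threshold_fraction_of_range(self):
        f = [_rec("b", 1.00, 1.00, 1.0, trait="female_length")]
        near = code_branches([_rec("b", 1.00, 1.02, 1.0)], f, ssd_range=0.5)
        assert near[0].code_ssd == "="  # |0.02| < 0.025
        down = code_branches([_rec("b", 1.00, 0.96, 1.0)], f, ssd_range=0.5)
        assert down[0].code_ssd == "-"  # |-0.04| >= 0.025

    def test_all_changes_mode_has_no_equals_for_nonzero_change(self):
        m = [_rec("b", 1.00, 1.001, 1.0)]
        f = [_rec("b", 1.00, 0.999, 1.0, trait="female_length")]
        c = code_branches(m, f, ssd_range=0.5, all_changes=True)[0]
        assert (c.code_male, c.code_female, c.code_ssd) == ("+", "-", "+")

    def test_coding_is_monotone_in_change_size(self):
        f = [_rec("b", 1.00, 1.00, 1.0, trait="female_length")]
        codes = [
            code_branches([_rec("b", 1.0, 1.0 + d, 1.0)], f, ssd_range=1.0)[0].code_male
            for d in np.linspace(0, 0.2, 21)
        ]
        seen_plus = False
        for c in codes:
            if c == "+":
                seen_plus = True
            assert not (seen_plus and c == "=")

    def test_zero_ssd_range_codes_all_equal(self):
        m = [_rec("b", 1.50, 1.60, 1.0)]
        f = [_rec("b", 1.45, 1.55, 1.0, trait="female_length")]
        assert code_branches(m, f, ssd_range=0.0)[0].code_ssd == "="

    def test_misaligned_branch_sets_error(self):
        m = [_rec("b1", 1.0, 1.1, 1.0)]
        f = [_rec("b2", 1.0, 1.1, 1.0, trait="female_length")]
        with pytest.raises(ValueError, match="different branch sets"):
            code_branches(m, f, ssd_range=0.5)


class TestCrosstabAndSignTest:
    def test_single_cell(self):
        m = [_rec(f"b{i}", 1.0, 1.2, 1.0) for i in range(10)]
        f = [_rec(f"b{i}", 1.0, 1.05, 1.0, trait="female_length") for i in range(10)]
        tab = crosstab(code_branches(m, f, ssd_range=0.5, all_changes=True))
        assert len(tab) == 1
        assert tab["count"].iloc[0] == 10

    def test_counts_conserved(self, reconstructed_changes):
        am, af, rm, rf = reconstructed_changes
        rng_ = ssd_range_from_reconstructions(am, af)
        codes = code_branches(rm, rf, ssd_range=rng_)
        assert crosstab(codes)["count"].sum() == len(codes)

    def test_male_driven_regime_fills_male_cells(self, tree50):
        male, female, _ = simulate_bm_bivariate(
            tree50, BMSimConfig(sigma_male=0.15, sigma_female=0.015, rho=0.0, seed=33)
        )
        am = asr_bm(tree50, {t: male[t] for t in tree50.tip_labels}, trait="m")
        af = asr_bm(tree50, {t: female[t] for t in tree50.tip_labels}, trait="f")
        codes = code_branches(
            branch_changes(tree50, am), branch_changes(tree50, af),
            ssd_range=ssd_range_from_reconstructions(am, af),
        )
        n_m, n_f = single_sex_ssd_counts(codes)
        assert n_m > n_f

    def test_exact_binomial_values(self):
        # oracle: 2 * sum_{k=24}^{31} C(31,k) / 2^31
        exact = 2 * sum(math.comb(31, k) for k in range(24, 32)) / 2**31
        assert sign_binomial_test(24, 7) == pytest.approx(exact, abs=1e-12)
        assert sign_binomial_test(5, 5) == pytest.approx(1.0)
        assert sign_binomial_test(7, 24) == pytest.approx(exact, abs=1e-12)

    def test_sign_test_input_validation(self):
        with pytest.raises(ValueError):
            sign_binomial_test(0, 0)
        with pytest.raises(ValueError):
            sign_binomial_test(-1, 3)


class TestRateDifferenceRegression:
    def test_female_zero_gives_identity_on_male(self):
        m = [_rec(f"b{i}", 1.0, 1.0 + 0.1 * i, 1.0) for i in range(1, 8)]
        f = [
            BranchChangeRecord(f"b{i}", "f", 1.0, 1.0, 0.0, 0.0, 0.0, 1.0)
            for i in range(1, 8)
        ]
        fit = rate_difference_regression(m, f, metric="darwins")
        male_row = fit[fit.predictor == "male"].iloc[0]
        assert male_row.slope == pytest.approx(1.0)
        assert male_row.r2 == pytest.approx(1.0)

    def test_replicated_rows_leave_slope_unchanged(self):
        rng = np.random.default_rng(44)
        m = [_rec(f"b{i}", 1.0, 1.0 + abs(rng.normal()) * 0.2, 1.0) for i in range(10)]
        f = [
            _rec(f"b{i}", 1.0, 1.0 + abs(rng.normal()) * 0.1, 1.0, trait="f")
            for i in range(10)
        ]
        base = rate_difference_regression(m, f, metric="absolute")
        m2 = m + [_rec(f"c{i}", r.initial, r.final, r.duration) for i, r in enumerate(m)]
        f2 = f + [
            _rec(f"c{i}", r.initial, r.final, r.duration, trait="f")
            for i, r in enumerate(f)
        ]
        doubled = rate_difference_regression(m2, f2, metric="absolute")
        np.testing.assert_allclose(doubled.slope.values, base.slope.values, rtol=1e-9)

    def test_undefined_darwins_rows_dropped(self):
        m = [_rec(f"b{i}", 1.0, 1.1 + 0.02 * i, 1.0) for i in range(5)] + [
            _rec("bz", 1.0, 1.1, 0.0)
        ]
        f = [_rec(f"b{i}", 1.0, 1.05, 1.0, trait="f") for i in range(5)] + [
            _rec("bz", 1.0, 1.02, 0.0, trait="f")
        ]
        fit = rate_difference_regression(m, f, metric="darwins")
        assert (fit.n == 5).all()

    def test_too_few_branches_error(self):
        m = [_rec("b1", 1.0, 1.1, 1.0)]
        f = [_rec("b1", 1.0, 1.0, 1.0, trait="f")]
        with pytest.raises(ValueError, match="3 usable"):
            rate_difference_regression(m, f)
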