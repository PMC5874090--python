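"""Friedman test, Conover post-hoc and the comparison suite."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from pancmotion.pipeline import cohort_motion_records
from pancmotion.stats import (
    BlockDesign,
    build_comparison_suite,
    conover_posthoc,
    friedman,
    render_symbol_table,
)


def test_all_equal_values_give_zero_statistic():
    res = friedman(BlockDesign(np.ones((4, 3))))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_perfect_ordering_closed_form():
    res = friedman(BlockDesign(np.array([[1.0, 2.0, 3.0]] * 3)))
    assert res.statistic == pytest.approx(6.0, abs=1e-12)
    assert res.dof == 2


def test_matches_scipy_without_ties():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(8, 4))
    res = friedman(BlockDesign(vals))
    stat, p = sps.friedmanchisquare(*vals.T)
    assert res.statistic == pytest.approx(stat, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def _brute_stat(v):
    r = np.apply_along_axis(sps.rankdata, 1, v)
    b, k = v.shape
    rs = r.sum(axis=0)
    a1, c1 = (r**2).sum(), b * k * (k + 1) ** 2 / 4.0
    ss = ((rs - b * (k + 1) / 2.0) ** 2).sum()
    return 0.0 if a1 == c1 else (k - 1) * ss / (a1 - c1)


def test_exact_p_matches_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(4, 3)).round(2)
    res = friedman(BlockDesign(vals), method="exact")
    obs = _brute_stat(vals)
    count = total = 0
    for rows in itertools.product(
        *[list(itertools.permutations(row)) for row in vals]
    ):
        total += 1
        count += _brute_stat(np.array(rows)) >= obs - 1e-12
    assert res.p_value == pytest.approx(count / total, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(arrays(float, (5, 3), elements=st.floats(-5, 5)))
def test_statistic_invariant_under_within_block_monotone_transform(vals):
    vals = np.round(vals, 2)  # keep value gaps well above float rounding
    base = friedman(BlockDesign(vals)).statistic
    transformed = friedman(BlockDesign(vals**3 + 2.0 * vals)).statistic
    assert base == pytest.approx(transformed, abs=1e-9)


def test_conover_matches_anova_on_ranks_lsd():
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(5, 4)).round(2)
    post = conover_posthoc(BlockDesign(vals))
    # independent oracle: Fisher LSD from the two-way ANOVA on within-block ranks
    ranks = np.apply_along_axis(sps.rankdata, 1, vals)
    b, k = ranks.shape
    grand = ranks.mean()
    sse = ((ranks - grand) ** 2).sum() - b * ((ranks.mean(axis=0) - grand) ** 2).sum()
    dof = (b - 1) * (k - 1)
    mse = sse / dof
    for i in range(k):
        for j in range(i + 1, k):
            t = abs(ranks[:, i].mean() - ranks[:, j].mean()) / np.sqrt(2 * mse / b)
            p = 2 * sps.t.sf(t, dof)
            assert post.pairwise_p[i, j] == pytest.approx(p, abs=1e-12)


def test_identical_treatments_form_single_group():
    with pytest.warns(UserWarning, match="degenerate"):
        post = conover_posthoc(BlockDesign(np.ones((4, 3))))
    assert post.n_groups == 1
    assert np.all(post.pairwise_p == 1.0)


def test_dominant_treatment_isolated_in_own_group():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(6, 4))
    vals[:, 2] += 100.0 * vals.std()
    post = conover_posthoc(BlockDesign(vals))
    assert post.groups[2].isdisjoint(post.groups[0] | post.groups[1] | post.groups[3])


def test_grouping_realises_exactly_the_nonsignificant_pairs():
    rng = np.random.default_rng(7)
    for _ in range(10):
        vals = rng.normal(size=(6, 5)) + rng.normal(0, 1.5, size=5)
        post = conover_posthoc(BlockDesign(vals), alpha=0.05)
        k = vals.shape[1]
        for i in range(k):
            assert post.groups[i], "every treatment needs a symbol"
            for j in range(i + 1, k):
                share = bool(post.groups[i] & post.groups[j])
                assert share == (post.pairwise_p[i, j] >= 0.05)


def test_design_validation():
    with pytest.raises(ValueError):
        BlockDesign(np.ones((1, 3)))
    with pytest.raises(ValueError):
        BlockDesign(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError):
        friedman(BlockDesign(np.ones((2, 2))), method="banana")


def _identical_motion_records(n_datasets=2):
    """Every setup and structure shows literally the same displacement."""
    import pandas as pd

    from pancmotion.motion import motion_records
    from pancmotion.phantom import PhantomConfig, generate_phantom

    ph = generate_phantom(PhantomConfig(seed=0), with_intensity=False)
    recs = []
    for d in range(n_datasets):
        for position in ("prone", "supine"):
            for device in ("vacuum", "mask", "compressor"):
                structures = {
                    s: ph.masks.masks for s in ("pancreas", "head", "body", "tail")
                }
                recs.append(
                    motion_records(
                        structures, ph.masks.spacing_mm, f"P{d + 1}",
                        position, device, ref_phase=ph.reference_phase,
                    )
                )
    return pd.concat(recs, ignore_index=True)


def test_identical_motion_cohort_is_fully_homogeneous():
    suite = build_comparison_suite(_identical_motion_records())
    for r in suite:
        assert r.testable
        assert r.friedman.statistic == 0.0 and r.friedman.p_value == 1.0
        assert r.posthoc is None  # omnibus quiet -> no post-hoc run


def test_missing_setup_drops_blocks_and_stays_testable():
    rec = cohort_motion_records(
        n_datasets=1, seed=4, com_noise_sd_mm=0.3,
        drop=(("P1", "supine", "compressor"),),
    )
    suite = build_comparison_suite(rec, pooled=False)
    pos = [r for r in suite if r.comparison == "prone_vs_supine"][0]
    assert pos.testable
    assert pos.n_blocks_dropped > 0  # compressor blocks lack the supine arm


def test_symbol_table_blank_when_homogeneous():
    suite = build_comparison_suite(_identical_motion_records(), pooled=False)
    table = render_symbol_table(suite)
    assert (table.to_numpy() == "").all()


def test_symbol_table_marks_structure_split():
    rec = cohort_motion_records(
        n_datasets=3, seed=0, tail_head_si_ratio=2.0, com_noise_sd_mm=0.3
    )
    suite = build_comparison_suite(rec)
    table = render_symbol_table(suite)
    col = ("all", "SI")
    head = table.loc["structures:head", col]
    tail = table.loc["structures:tail", col]
    assert head and tail and set(head).isdisjoint(set(tail))
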