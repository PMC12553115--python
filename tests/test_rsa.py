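"""Pattern-similarity constructs against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

from psmem import GeneratorParams, generate_design, generate_patterns
from psmem.rsa import (SimilarityMatrix, average_within_session, build_pair_table,
                       incongruent_category_mean, mds_embed, ps_change,
                       reorganization, spearman_z, within_day_matrix, CLIP)
from psmem.scoring import score_behavior
from psmem.behavior_sim import generate_behavior


# ---------------------------------------------------------------------------
# spearman_z

def test_spearman_z_examples():
    assert spearman_z([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(np.arctanh(0.8))
    # identity correlates at 1, clipped before atanh
    assert spearman_z([1, 2, 3], [10, 20, 30]) == pytest.approx(np.arctanh(CLIP))
    assert spearman_z([1, 2, 3], [3, 2, 1]) == pytest.approx(-np.arctanh(CLIP))


def test_spearman_z_constant_input_is_missing():
    assert np.isnan(spearman_z([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def test_spearman_z_matches_scipy(rng):
    for _ in range(50):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        expected = np.arctanh(np.clip(spearmanr(a, b).statistic, -CLIP, CLIP))
        assert spearman_z(a, b) == pytest.approx(expected, abs=1e-12)


def test_spearman_z_handles_ties_with_average_ranks(rng):
    a = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
    b = rng.standard_normal(6)
    ra, rb = rankdata(a), rankdata(b)
    expected = np.arctanh(np.clip(np.corrcoef(ra, rb)[0, 1], -CLIP, CLIP))
    assert spearman_z(a, b) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_spearman_z_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(20)
    b = rng.standard_normal(20)
    base = spearman_z(a, b)
    assert spearman_z(a**3, b) == pytest.approx(base, abs=1e-10)
    assert spearman_z(a, np.exp(b)) == pytest.approx(base, abs=1e-10)
    assert spearman_z(np.exp(a), b**3) == pytest.approx(base, abs=1e-10)


# ---------------------------------------------------------------------------
# averaging and matrices

def test_average_within_session(rng):
    p = rng.standard_normal((6, 15))
    np.testing.assert_allclose(average_within_session(p), p.mean(axis=0), atol=1e-12)
    one = rng.standard_normal(15)
    np.testing.assert_array_equal(average_within_session(one[None, :]), one)
    np.testing.assert_allclose(
        average_within_session(np.stack([one, -one])), np.zeros(15), atol=1e-12)
    with pytest.raises(ValueError):
        average_within_session(p, usable=np.zeros(6, bool))


def test_within_day_matrix_against_double_loop_oracle(rng):
    s1 = rng.standard_normal((8, 25))
    s2 = rng.standard_normal((8, 25))
    mat = within_day_matrix(s1, s2, day="pre")
    for i in range(8):
        for j in range(8):
            if i == j:
                assert np.isnan(mat.values[i, j])
                continue
            zij = np.arctanh(np.clip(spearmanr(s1[i], s2[j]).statistic, -CLIP, CLIP))
            zji = np.arctanh(np.clip(spearmanr(s1[j], s2[i]).statistic, -CLIP, CLIP))
            assert mat.values[i, j] == pytest.approx((zij + zji) / 2, abs=1e-12)
    # symmetry by construction
    off = ~np.eye(8, dtype=bool)
    np.testing.assert_allclose(mat.values[off], mat.values.T[off], atol=1e-14)


def test_within_day_matrix_pair_count(pattern_set):
    mat = within_day_matrix(pattern_set.sessions["pre1"],
                            pattern_set.sessions["pre2"], day="pre")
    pairs = mat.pair_values()
    assert len(pairs) == 276
    assert pairs["z"].notna().all()


@pytest.mark.parametrize("n", [2, 5, 12, 24])
def test_pair_count_formula(n, rng):
    s = rng.standard_normal((n, 10))
    mat = within_day_matrix(s, rng.standard_normal((n, 10)), day="pre")
    assert len(mat.pair_values()) == n * (n - 1) // 2


def test_orthogonal_noiseless_sessions_give_near_zero_offdiagonal():
    # rows of an orthogonal design: identical across sessions, uncorrelated
    rng = np.random.default_rng(0)
    base = rng.standard_normal((6, 500))
    mat = within_day_matrix(base, base, day="pre")
    off = mat.pair_values()["z"]
    assert np.abs(off).max() < 0.2


def test_ps_change_oracle(rng):
    s = [rng.standard_normal((5, 12)) for _ in range(4)]
    pre = within_day_matrix(s[0], s[1], day="pre")
    post = within_day_matrix(s[2], s[3], day="post")
    change = ps_change(pre, post)
    np.testing.assert_allclose(change.values, post.values - pre.values, atol=1e-14)
    zero = ps_change(pre, pre)
    off = ~np.eye(5, dtype=bool)
    np.testing.assert_allclose(zero.values[off], 0.0, atol=1e-14)
    with pytest.raises(ValueError):
        ps_change(pre, SimilarityMatrix(values=np.zeros((4, 4)), day="post"))


# ---------------------------------------------------------------------------
# reorganization

def test_reorganization_identical_sessions_hits_clip_maximum(rng):
    x = rng.standard_normal((6, 30))
    table = reorganization((x, x), (x, x))
    np.testing.assert_allclose(table["reorg_z"], np.arctanh(CLIP), atol=1e-10)


def test_reorganization_independent_days_near_zero():
    vals = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        pre = (rng.standard_normal((4, 40)), rng.standard_normal((4, 40)))
        post = (rng.standard_normal((4, 40)), rng.standard_normal((4, 40)))
        vals.extend(reorganization(pre, post)["reorg_z"])
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals)) < 3 * se


def test_reorganization_matches_bruteforce_and_session_swap(rng):
    s = [rng.standard_normal((5, 20)) for _ in range(4)]
    table = reorganization((s[0], s[1]), (s[2], s[3]))
    for i in range(5):
        crossings = [
            np.arctanh(np.clip(spearmanr(p[i], q[i]).statistic, -CLIP, CLIP))
            for p in (s[0], s[1]) for q in (s[2], s[3])
        ]
        assert table["reorg_z"][i] == pytest.approx(np.mean(crossings), abs=1e-12)
    swapped = reorganization((s[1], s[0]), (s[3], s[2]))
    np.testing.assert_allclose(table["reorg_z"], swapped["reorg_z"], atol=1e-14)


def test_reorganization_closed_loop_congruence_direction():
    """Generator closed loop: the larger incongruent gap shows up as lower
    cross-day self-similarity for incongruent objects over 100 participants."""
    inc, con = [], []
    for seed in range(100):
        design = generate_design(seed)
        pats = generate_patterns(design, GeneratorParams(seed=seed, n_voxels=60))
        t = reorganization((pats.sessions["pre1"], pats.sessions["pre2"]),
                           (pats.sessions["post1"], pats.sessions["post2"]), design)
        inc.append(t.loc[~t["congruent"], "reorg_z"].mean())
        con.append(t.loc[t["congruent"], "reorg_z"].mean())
    assert np.mean(inc) < np.mean(con)


# ---------------------------------------------------------------------------
# pair table and condition means

@pytest.fixture(scope="module")
def scored_behavior():
    design = generate_design(7)
    params = GeneratorParams(seed=7)
    return design, score_behavior(generate_behavior(design, params), design=design)


def test_pair_table_counts(pattern_set, scored_behavior):
    design, beh = scored_behavior
    pre = within_day_matrix(pattern_set.sessions["pre1"],
                            pattern_set.sessions["pre2"], day="pre")
    post = within_day_matrix(pattern_set.sessions["post1"],
                             pattern_set.sessions["post2"], day="post")
    all_rec = beh.assign(recognized=True)
    table = build_pair_table(pre, post, design, all_rec)
    assert len(table) == 276
    assert not table["excluded"].any()
    assert table[["object_i", "object_j"]].drop_duplicates().shape[0] == 276
    # exactly two unrecognized objects flag 2*23 - 1 = 45 pairs
    two_miss = beh.assign(recognized=~beh["object_id"].isin([3, 11]))
    t2 = build_pair_table(pre, post, design, two_miss)
    assert t2["excluded"].sum() == 2 * 23 - 1
    assert (~t2["excluded"]).sum() == 231


def test_pair_table_distances_and_confidence(pattern_set, scored_behavior):
    design, beh = scored_behavior
    pre = within_day_matrix(pattern_set.sessions["pre1"],
                            pattern_set.sessions["pre2"], day="pre")
    post = within_day_matrix(pattern_set.sessions["post1"],
                             pattern_set.sessions["post2"], day="post")
    table = build_pair_table(pre, post, design, beh)
    b = beh.set_index("object_id")
    row = table.iloc[17]
    i, j = int(row["object_i"]), int(row["object_j"])
    expect = np.hypot(b.loc[i, "retrieved_x"] - b.loc[j, "retrieved_x"],
                      b.loc[i, "retrieved_y"] - b.loc[j, "retrieved_y"])
    assert row["retrieved_distance"] == pytest.approx(expect)
    assert row["mean_confidence"] == pytest.approx(
        (b.loc[i, "confidence"] + b.loc[j, "confidence"]) / 2)
    same_pos = beh.copy()
    same_pos["retrieved_x"] = 5.0
    same_pos["retrieved_y"] = 5.0
    t0 = build_pair_table(pre, post, design, same_pos)
    np.testing.assert_allclose(t0["retrieved_distance"], 0.0, atol=1e-12)


def test_incongruent_category_mean_structure(scored_behavior):
    design, beh = scored_behavior
    c = 0.37
    uniform = SimilarityMatrix(values=np.full((24, 24), c), day="post")
    out = incongruent_category_mean(uniform, design, "relevance")
    # 6 task-relevant and 6 task-irrelevant incongruent objects, all means = c
    assert sorted(out["n_objects"]) == [6, 6]
    np.testing.assert_allclose(out["mean_z"], c, atol=1e-12)
    # each incongruent object has exactly 4 congruent same-category partners
    for obj in design.objects:
        if not obj.congruent:
            partners = [o for o in design.objects
                        if o.congruent and o.category == obj.category]
            assert len(partners) == 4


def test_incongruent_category_mean_room_choice_split(scored_behavior):
    design, beh = scored_behavior
    rng = np.random.default_rng(0)
    values = rng.standard_normal((24, 24))
    mat = SimilarityMatrix(values=(values + values.T) / 2, day="post")
    out = incongruent_category_mean(mat, design, "room_choice", beh)
    assert set(out["condition"]) == {"correct", "semantic"}
    assert out["n_objects"].sum() <= 12  # unrelated sortings drop out
    # an empty cell yields a missing mean, not an error
    all_unrelated = beh.copy()
    all_unrelated["room_choice"] = "unrelated"
    empty = incongruent_category_mean(mat, design, "room_choice", all_unrelated)
    assert empty["mean_z"].isna().all()
    assert (empty["n_objects"] == 0).all()


# ---------------------------------------------------------------------------
# MDS

def test_mds_equilateral_triangle():
    z = np.arctanh(np.full((3, 3), 0.5))
    np.fill_diagonal(z, np.nan)
    coords = mds_embed(SimilarityMatrix(values=z, day="pre"))
    d01 = np.linalg.norm(coords[0] - coords[1])
    d02 = np.linalg.norm(coords[0] - coords[2])
    d12 = np.linalg.norm(coords[1] - coords[2])
    assert d01 == pytest.approx(d02, abs=1e-8)
    assert d01 == pytest.approx(d12, abs=1e-8)


def test_mds_recovers_planted_configuration(rng):
    pts = rng.standard_normal((10, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d /= d.max() * 1.5  # keep dissimilarities in the tanh range
    np.fill_diagonal(d, np.nan)
    z = np.arctanh(1.0 - d)
    np.fill_diagonal(d, 0.0)
    coords = mds_embed(SimilarityMatrix(values=z, day="pre"))
    rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.testing.assert_allclose(rec, d, atol=1e-6)


def test_mds_duplicate_objects_coincide(rng):
    pts = rng.standard_normal((5, 2)) * 0.1
    pts[4] = pts[0]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    z = np.arctanh(np.clip(1.0 - d, -CLIP, CLIP))
    np.fill_diagonal(z, np.nan)
    coords = mds_embed(SimilarityMatrix(values=z, day="pre"))
    assert np.linalg.norm(coords[0] - coords[4]) < 1e-8


def test_mds_orientation_convention(pattern_set):
    mat = within_day_matrix(pattern_set.sessions["pre1"],
                            pattern_set.sessions["pre2"], day="pre")
    coords = mds_embed(mat)
    assert coords.shape == (24, 2)
    assert coords[0, 0] >= 0 and coords[0, 1] >= 0
    np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-10)
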