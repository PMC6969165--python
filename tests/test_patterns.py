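"""Grouped matrices, weighted NMF, consensus merging and marker assignment."""

import numpy as np
import pandas as pd
import pytest

import pdpatterns.patterns as pat

from conftest import make_longitudinal, make_normalized_panel


def toy_gm(D, S=None):
    D = np.asarray(D, dtype=float)
    cols = pd.MultiIndex.from_product(
        [[f"g{i}" for i in range(D.shape[1] // 3)], ["week0", "week4", "week16"]],
        names=["subgroup", "visit"])
    S = np.ones_like(D) if S is None else np.asarray(S, dtype=float)
    return pat.GroupedMeanMatrix(
        D=pd.DataFrame(D, columns=cols),
        S=pd.DataFrame(S, columns=cols),
        n=pd.Series(10, index=cols),
    )


def toy_run(P_rows, A=None, seed=0):
    P = np.asarray(P_rows, dtype=float)
    P = P / np.linalg.norm(P, axis=1, keepdims=True)
    K, m = P.shape
    A = np.ones((4, K)) if A is None else np.asarray(A, dtype=float)
    cols = pd.MultiIndex.from_product(
        [[f"g{i}" for i in range(m // 3)], ["week0", "week4", "week16"]],
        names=["subgroup", "visit"])
    return pat.PatternRun(
        A=pd.DataFrame(A, index=[f"A{i:03d}" for i in range(A.shape[0])]),
        P=pd.DataFrame(P, columns=cols),
        chi2=0.0, seed=seed, n_iterations=1,
    )


# --- grouped matrix ---------------------------------------------------------

def grouped_setup(rng):
    effects = {f"A{i}": {"AR": (0.0, 0.0), "ANR": (0.0, 0.0)} for i in range(3)}
    panel, meta = make_longitudinal(rng, 20, effects)
    groups = {"AR": sorted(meta.loc[meta.response == "AR", "subject"].unique()),
              "ANR": sorted(meta.loc[meta.response == "ANR", "subject"].unique())}
    return panel, meta, groups


def test_grouped_matrix_hand_arithmetic():
    values = np.array([[1.0], [3.0]])
    panel = make_normalized_panel(values, analytes=["A0"],
                                  samples=["S0_week4", "S1_week4"])
    meta = pd.DataFrame({"subject": ["S0", "S1"], "visit": "week4"},
                        index=panel.samples)
    gm = pat.build_grouped_matrix(panel, meta, {"g": ["S0", "S1"]},
                                  visits=("week4",))
    assert gm.D.iloc[0, 0] == 2.0
    assert gm.S.iloc[0, 0] == pytest.approx(1.0)   # sd sqrt(2) / sqrt(2)


def test_grouped_matrix_shape_and_order(rng):
    panel, meta, groups = grouped_setup(rng)
    gm = pat.build_grouped_matrix(panel, meta, groups,
                                  visits=("week4", "week16"))
    assert list(gm.D.columns) == [("AR", "week4"), ("AR", "week16"),
                                  ("ANR", "week4"), ("ANR", "week16")]
    assert (gm.S.to_numpy() > 0).all()


def test_grouped_matrix_subject_order_invariance(rng):
    panel, meta, groups = grouped_setup(rng)
    gm1 = pat.build_grouped_matrix(panel, meta, groups, visits=("week4", "week16"))
    shuffled = {g: list(reversed(s)) for g, s in groups.items()}
    perm = panel.values.sample(frac=1.0, random_state=1)
    panel2 = make_normalized_panel(perm.to_numpy(), analytes=perm.columns,
                                   samples=perm.index)
    gm2 = pat.build_grouped_matrix(panel2, meta, shuffled,
                                   visits=("week4", "week16"))
    pd.testing.assert_frame_equal(gm1.D, gm2.D)
    pd.testing.assert_frame_equal(gm1.S, gm2.S)


def test_grouped_matrix_rejects_single_subject_cell(rng):
    panel, meta, groups = grouped_setup(rng)
    groups["AR"] = groups["AR"][:1]
    with pytest.raises(ValueError, match="AR"):
        pat.build_grouped_matrix(panel, meta, groups, visits=("week4", "week16"))


# --- weighted NMF -----------------------------------------------------------

def test_nmf_validation():
    gm = toy_gm(np.ones((4, 6)))
    with pytest.raises(ValueError, match="K"):
        pat.fit_weighted_nmf(gm, K=7)
    with pytest.raises(ValueError, match="non-negative"):
        pat.fit_weighted_nmf(toy_gm(-np.ones((4, 6))), K=2)
    with pytest.raises(ValueError, match="n_iterations"):
        pat.fit_weighted_nmf(gm, K=2, n_iterations=0)


def test_nmf_contract_and_reproducibility(rng):
    D = rng.uniform(1, 10, (12, 6))
    gm = toy_gm(D, S=rng.uniform(0.1, 0.5, (12, 6)))
    r1 = pat.fit_weighted_nmf(gm, 2, 500, seed=4)
    r2 = pat.fit_weighted_nmf(gm, 2, 500, seed=4)
    r3 = pat.fit_weighted_nmf(gm, 2, 500, seed=5)
    assert (r1.A.to_numpy() >= 0).all() and (r1.P.to_numpy() >= 0).all()
    assert np.allclose(np.linalg.norm(r1.P.to_numpy(), axis=1), 1.0, atol=1e-9)
    pd.testing.assert_frame_equal(r1.P, r2.P)
    assert r1.chi2 == r2.chi2
    assert not np.allclose(r1.P.to_numpy(), r3.P.to_numpy())
    # stored chi2 matches recomputation
    assert r1.chi2 == pytest.approx(
        pat.weighted_chi2(gm.D, gm.S, r1.A, r1.P), abs=1e-9)


def test_nmf_overcomplete_basis_reaches_near_zero(rng):
    D = rng.uniform(1, 5, (4, 6))
    gm = toy_gm(D)
    run = pat.fit_weighted_nmf(gm, K=4, n_iterations=20000, seed=0)
    assert run.chi2 < 1e-4 * D.size


def test_chi2_quarters_when_s_doubles(rng):
    D = rng.uniform(1, 5, (5, 6))
    A = rng.uniform(0, 1, (5, 2))
    P = rng.uniform(0, 1, (2, 6))
    S = rng.uniform(0.2, 1.0, (5, 6))
    assert pat.weighted_chi2(D, 2 * S, A, P) == pytest.approx(
        pat.weighted_chi2(D, S, A, P) / 4.0, rel=1e-12)


def test_select_iterations_prefers_converged_batch(rng):
    A0 = rng.uniform(0, 1, (10, 2))
    P0 = rng.uniform(0, 1, (2, 6))
    gm = toy_gm(A0 @ P0)
    chosen, table = pat.select_iterations(gm, K=2, candidates=(5, 2000),
                                          n_runs=5, seed=0)
    assert chosen == 2000
    assert table.loc[2000, "mean_chi2"] < table.loc[5, "mean_chi2"]


def test_select_iterations_single_candidate(rng):
    gm = toy_gm(rng.uniform(1, 2, (6, 6)))
    chosen, table = pat.select_iterations(gm, K=2, candidates=(100,), n_runs=2)
    assert chosen == 100 and len(table) == 1


def test_select_iterations_mean_chi2_nonincreasing(rng):
    A0 = rng.uniform(0, 1, (10, 2))
    P0 = rng.uniform(0, 1, (2, 6))
    gm = toy_gm(A0 @ P0 + rng.normal(0, 0.01, (10, 6)).clip(-0.5))
    _, table = pat.select_iterations(gm, K=2, candidates=(10, 100, 1000),
                                     n_runs=6, seed=3)
    mean = table["mean_chi2"].to_numpy()
    slack = 2 * table["sd_chi2"].to_numpy() / np.sqrt(table["n_runs"].to_numpy())
    assert np.all(np.diff(mean) <= slack[:-1] + slack[1:])


# --- merging ----------------------------------------------------------------

def test_merge_identical_runs_collapse_to_k_patterns():
    P = [[1, 2, 3, 1, 1, 1], [3, 1, 1, 2, 2, 2]]
    runs = [toy_run(P, seed=s) for s in range(10)]
    merged = pat.merge_patterns(runs)
    assert len(merged.centroids) == 2
    assert all(len(m) == 10 for m in merged.members.values())
    assert np.allclose(np.linalg.norm(merged.centroids.to_numpy(), axis=1), 1.0)


def test_merge_separates_planted_families(rng):
    fam1 = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    fam2 = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 1.0])
    runs = []
    for s in range(20):
        jitter = rng.normal(0, 0.003, 6)
        runs.append(toy_run([fam1 + abs(jitter), fam2 + abs(jitter[::-1])], seed=s))
    merged = pat.merge_patterns(runs)
    assert len(merged.centroids) == 2
    # no cross-contamination: each group holds one pattern index throughout
    for members in merged.members.values():
        assert len({k for _, k in members}) == 1


def test_merge_zero_tolerance_keeps_everything_apart(rng):
    runs = [toy_run(rng.uniform(0.1, 1.0, (2, 6)), seed=s) for s in range(5)]
    merged = pat.merge_patterns(runs, tol=0.0)
    assert len(merged.centroids) == 10


def test_merge_rejects_inconsistent_runs():
    r1 = toy_run([[1, 2, 3, 1, 1, 1]])
    with pytest.raises(ValueError, match="at least two"):
        pat.merge_patterns([r1])
    r2 = toy_run([[1, 2, 3, 1, 1, 1], [1, 1, 1, 1, 2, 1]])
    with pytest.raises(ValueError, match="K"):
        pat.merge_patterns([r1, r2])


# --- marker assignment ------------------------------------------------------

def test_assign_pure_marker_zero_distance():
    A = np.array([[0.0, 5.0, 0.0], [2.0, 2.0, 2.0], [0.0, 0.0, 0.0]])
    run = toy_run(np.eye(3, 6) + 0.1, A=A)
    out = pat.assign_markers(run)
    assert out.assignment["A000"] == 1
    assert out.distances.loc["A000", 1] == pytest.approx(0.0)
    # uniform loadings tie -> lowest index, flagged ambiguous
    assert out.assignment["A001"] == 0
    assert "A001" in out.ambiguous
    # all-zero row -> unassigned
    assert out.assignment["A002"] == -1
    assert "A002" in out.unassigned


def test_assign_recovers_planted_markers_under_noise(rng):
    correct = total = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        K, per = 3, 10
        A = np.zeros((K * per, K))
        for k in range(K):
            A[k * per:(k + 1) * per, k] = 1.0
        A = np.abs(A + r.normal(0, 0.05, A.shape))
        run = toy_run(r.uniform(0.2, 1.0, (K, 6)), A=A)
        out = pat.assign_markers(run)
        for i in range(K * per):
            total += 1
            if out.assignment[f"A{i:03d}"] == i // per:
                correct += 1
    assert correct / total >= 0.95


def test_consensus_frequency_strictly_above_half():
    fam1 = [1.0, 0.0, 0.0, 1.0, 0.0, 0.0]
    fam2 = [0.0, 0.0, 1.0, 0.0, 0.0, 1.0]
    runs = []
    for s in range(100):
        # analyte A000 loads on fam1's pattern in exactly half the runs
        a_row = [5.0, 0.1] if s < 50 else [0.1, 5.0]
        A = np.array([a_row, [4.0, 0.1], [0.1, 4.0], [3.0, 0.2]])
        runs.append(toy_run([fam1, fam2], A=A, seed=s))
    merged = pat.consensus_assignment(runs, pat.merge_patterns(runs))
    freq = merged.frequencies
    assert freq.loc["A000"].max() == pytest.approx(0.5)
    assert "A000" not in merged.assignment.index       # 50% is NOT "exceeds 50%"
    assert merged.frequencies.loc["A001"].max() == 1.0
    assert merged.assignment["A001"] == merged.frequencies.loc["A001"].idxmax()
    # frequencies for one analyte sum to at most 1
    assert (freq.sum(axis=1) <= 1.0 + 1e-12).all()


# --- pharmacodynamic follow-up ---------------------------------------------

def test_top_decliners_forced_ranking(rng):
    declines = {"A0": -1.0, "A1": -0.8, "A2": -0.5, "A3": -0.3, "A4": -0.1,
                "A5": 0.4}
    effects = {a: {"AR": (0.0, d), "ANR": (0.0, d)} for a, d in declines.items()}
    panel, meta = make_longitudinal(rng, 40, effects, subject_sd=0.05,
                                    resid_sd=0.05)
    top = pat.top_decliners(list(declines), panel, meta, n_top=4)
    assert list(top.index) == ["A0", "A1", "A2", "A3"]
    with pytest.warns(UserWarning, match="decline"):
        few = pat.top_decliners(["A4", "A5"], panel, meta, n_top=4)
    assert list(few.index) == ["A4"]


def test_top_decliners_subject_order_invariance(rng):
    effects = {f"A{i}": {"AR": (0.0, -0.2 * i), "ANR": (0.0, -0.2 * i)}
               for i in range(4)}
    panel, meta = make_longitudinal(rng, 30, effects)
    top1 = pat.top_decliners(list(effects), panel, meta, n_top=3)
    perm = panel.values.sample(frac=1.0, random_state=2)
    panel2 = make_normalized_panel(perm.to_numpy(), analytes=perm.columns,
                                   samples=perm.index)
    top2 = pat.top_decliners(list(effects), panel2, meta, n_top=3)
    pd.testing.assert_frame_equal(top1, top2)


def test_responder_decline_no_separation_gives_large_p(rng):
    effects = {"A0": {"AR": (0.0, -0.5), "ANR": (0.0, -0.5)}}
    panel, meta = make_longitudinal(rng, 40, effects, subject_sd=0.3,
                                    resid_sd=0.3)
    out = pat.responder_decline_test(["A0"], panel, meta)
    assert out.p > 0.05


def test_responder_single_analyte_matches_direct_mwu(rng):
    from scipy import stats as sstats

    effects = {"A0": {"AR": (0.0, -0.8), "ANR": (0.0, -0.2)}}
    panel, meta = make_longitudinal(rng, 30, effects)
    out = pat.responder_decline_test(["A0"], panel, meta)
    # independent oracle: per-subject deltas then Mann-Whitney
    deltas = {}
    for subject, grp in meta.groupby("subject"):
        s4 = grp.index[grp["visit"] == "week4"][0]
        s16 = grp.index[grp["visit"] == "week16"][0]
        deltas[subject] = (panel.values.loc[s16, "A0"]
                           - panel.values.loc[s4, "A0"])
    ar = [d for s, d in deltas.items()
          if meta.loc[f"{s}_week4", "response"] == "AR"]
    anr = [d for s, d in deltas.items()
          if meta.loc[f"{s}_week4", "response"] == "ANR"]
    ref = sstats.mannwhitneyu(ar, anr, alternative="two-sided",
                              method="asymptotic")
    assert out.p == pytest.approx(ref.pvalue, rel=1e-9)
    assert out.U == pytest.approx(ref.statistic)
    assert out.geometric_mean_fold["AR"] < out.geometric_mean_fold["ANR"] < 1.0
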