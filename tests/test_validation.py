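"""Split designs, relatedness scoring (against an exhaustive pair oracle),
out-of-sample R^2, and the experiment driver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgpred import (
    ExperimentConfig,
    LeakageError,
    MCMCConfig,
    Pedigree,
    SimConfig,
    SplitPlan,
    expected_r2_from_accuracy,
    make_split,
    r2_val,
    relatedness_scores,
    run_experiment,
    score_group,
    simulate_cohort,
    simulate_pedigree,
)
from conftest import random_pedigree


def pair_weight(ped: Pedigree, a: str, b: str) -> float:
    """Direct rule: 1 for parent-offspring or full sibs, 0.5 for half sibs."""
    parents = {r["individual_id"]: (r["sire_id"], r["dam_id"])
               for _, r in ped.table.iterrows()}
    pa, pb = parents[a], parents[b]
    if a in pb or b in pa:
        return 1.0
    shared = len({p for p in pa if p is not None} & {p for p in pb if p is not None})
    if shared == 2:
        return 1.0
    if shared == 1:
        return 0.5
    return 0.0


def test_implied_r2_of_an_accurate_predictor():
    assert expected_r2_from_accuracy(0.7, 0.8) == pytest.approx(0.392)
    assert expected_r2_from_accuracy(1.0, 0.8) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        expected_r2_from_accuracy(0.7, 1.2)


# -- split plans ------------------------------------------------------------

def test_kfold_sizes_match_large_cohort_geometry():
    ids = np.array([f"i{k}" for k in range(5117)], dtype=object)
    plan = make_split("kfold", ids, n_folds=10, seed=1)
    trn_sizes = sorted(len(trn) for trn, _ in plan.folds)
    assert set(trn_sizes) <= {4605, 4606}
    tested = sorted(i for _, tst in plan.folds for i in tst)
    assert tested == sorted(ids)


def test_two_generation_split_uses_cohort_labels():
    cfg = SimConfig(n_founders=1493, n_offspring=3624, n_markers=5, seed=2)
    ped = simulate_pedigree(cfg)
    plan = make_split("two_generation", ped.ids, pedigree=ped)
    assert plan.n_folds == 1
    trn, tst = plan.folds[0]
    assert len(trn) == 1493 and len(tst) == 3624
    cohorts = ped.table.set_index("individual_id")["cohort"]
    assert (cohorts.loc[list(trn)] == "original").all()
    assert (cohorts.loc[list(tst)] == "offspring").all()


def test_random_split_has_fixed_trn_size_and_independent_replicates():
    ids = np.array([f"i{k}" for k in range(200)], dtype=object)
    plan = make_split("random_split", ids, n_train=60, n_replicates=5, seed=3)
    assert all(len(trn) == 60 for trn, _ in plan.folds)
    trn_sets = [frozenset(trn) for trn, _ in plan.folds]
    assert len(set(trn_sets)) > 1


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), n=st.integers(20, 300), k=st.integers(2, 10))
def test_kfold_partition_property(seed, n, k):
    ids = np.array([f"i{j}" for j in range(n)], dtype=object)
    plan = make_split("kfold", ids, n_folds=min(k, n), seed=seed)
    tested = [i for _, tst in plan.folds for i in tst]
    assert sorted(tested) == sorted(ids)
    sizes = [len(t) for _, t in plan.folds]
    assert max(sizes) - min(sizes) <= 1


def test_split_plan_invariants_enforced():
    ids = np.array(list("abcdef"), dtype=object)
    with pytest.raises(LeakageError):
        SplitPlan("kfold", [(ids[:4], ids[3:])], seed=0)
    with pytest.raises(ValueError, match="one replicate"):
        SplitPlan("two_generation", [(ids[:3], ids[3:]), (ids[:3], ids[3:])], seed=0)
    with pytest.raises(ValueError, match="fixed"):
        SplitPlan("random_split", [(ids[:2], ids[2:]), (ids[:3], ids[3:])], seed=0)
    with pytest.raises(ValueError, match="cohort"):
        make_split("two_generation", ids)


# -- relatedness scores -----------------------------------------------------

def test_relatedness_hand_counts():
    rows = [
        {"individual_id": p, "sire_id": None, "dam_id": None, "sex": s,
         "generation": 0, "cohort": "original"}
        for p, s in [("pa", "M"), ("ma", "F"), ("px", "M"), ("mx", "F")]
    ]
    def child(cid, sire, dam):
        return {"individual_id": cid, "sire_id": sire, "dam_id": dam,
                "sex": "M", "generation": 1, "cohort": "offspring"}
    rows += [child("c1", "pa", "ma"), child("c2", "pa", "ma"),
             child("h1", "pa", "mx"), child("lone", "px", "mx")]
    ped = Pedigree(pd.DataFrame(rows))

    # c1 tested with both parents and a full sib in training: s = 3
    plan = SplitPlan("random_split", [(np.array(["pa", "ma", "c2"], dtype=object),
                                       np.array(["c1", "px"], dtype=object))], seed=0)
    scores = relatedness_scores(plan, ped).set_index("individual_id")
    assert scores.loc["c1", "s"] == 3.0 and scores.loc["c1", "group"] == "s>=3"
    # px has no close relative in training (spouse does not count)
    assert scores.loc["px", "s"] == 0.0 and scores.loc["px", "group"] == "s=0"

    # half sib only: s = 0.5, grouped down into s=0
    plan2 = SplitPlan("random_split", [(np.array(["c1"], dtype=object),
                                        np.array(["h1"], dtype=object))], seed=0)
    s2 = relatedness_scores(plan2, ped).set_index("individual_id")
    assert s2.loc["h1", "s"] == 0.5 and s2.loc["h1", "group"] == "s=0"


def test_score_grouping_rounds_fractions_down():
    assert score_group(0.0) == "s=0"
    assert score_group(0.5) == "s=0"
    assert score_group(1.0) == "s=1"
    assert score_group(1.5) == "s=1"
    assert score_group(2.5) == "s=2"
    assert score_group(3.0) == "s>=3"
    assert score_group(7.5) == "s>=3"


@pytest.mark.parametrize("seed", range(10))
def test_relatedness_matches_exhaustive_pair_oracle(seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n_founders=rng.integers(6, 20),
                          n_offspring=rng.integers(10, 60))
    ids = ped.ids
    perm = rng.permutation(len(ids))
    cut = len(ids) // 2
    trn, tst = ids[perm[:cut]], ids[perm[cut:]]
    plan = SplitPlan("random_split", [(trn, tst)], seed=0)
    scores = relatedness_scores(plan, ped).set_index("individual_id")
    for i in tst:
        oracle = sum(pair_weight(ped, i, j) for j in trn)
        assert scores.loc[i, "s"] == pytest.approx(oracle)


# -- out-of-sample R^2 ------------------------------------------------------

def test_r2_val_trivial_cases():
    obs = np.array([1.0, 2.0, 4.0, 3.0])
    assert r2_val(obs, obs) == pytest.approx(1.0)
    assert r2_val(np.full(4, 2.5), obs) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        r2_val(obs, np.full(4, 1.0))


def test_r2_val_rejects_leakage():
    obs = np.array([1.0, 2.0, 3.0])
    with pytest.raises(LeakageError):
        r2_val(obs, obs, trn_ids=["a", "b"], tst_ids=["b", "c"])


# -- experiment driver ------------------------------------------------------

def test_experiment_bookkeeping(small_cohort):
    cfg = ExperimentConfig(
        models=("GY",), marker_counts=(60, 120), designs=("kfold",),
        n_folds=4, mcmc=MCMCConfig(n_iter=600, burn_in=200, thin=2), seed=5,
    )
    report = run_experiment(small_cohort, cfg)
    assert len(report.cells) == 2
    assert set(report.cells["n_markers"]) == {60, 120}
    assert (report.replicates.groupby("n_markers")["fold"].count() == 4).all()
    assert not report.by_group.empty
    assert set(report.by_group["group"]) <= {"s=0", "s=1", "s=2", "s>=3"}
    table = report.table_by_markers("kfold")
    assert table.shape[0] == 2
    # training fit exceeds validation fit in every cell
    assert (report.cells["r2_trn"] > report.cells["r2_val"]).all()


def test_experiment_is_deterministic(small_cohort):
    cfg = ExperimentConfig(models=("GY",), marker_counts=(80,), designs=("kfold",),
                           n_folds=3, mcmc=MCMCConfig(n_iter=400, burn_in=100, thin=2),
                           seed=7)
    a = run_experiment(small_cohort, cfg)
    b = run_experiment(small_cohort, cfg)
    pd.testing.assert_frame_equal(a.cells, b.cells)


def test_report_serialization(tmp_path, small_cohort):
    cfg = ExperimentConfig(models=("GY",), marker_counts=(80,), designs=("kfold",),
                           n_folds=3, mcmc=MCMCConfig(n_iter=400, burn_in=100, thin=2))
    report = run_experiment(small_cohort, cfg)
    path = tmp_path / "report.json"
    report.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert "cells" in payload and "by_group" in payload
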