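"""SART scheduling, signal-detection scoring and contrast tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ammod import behavior, synth
from ammod.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

# ------------------------------------------------------------------ schedule


def test_six_block_preset_layout():
    s = behavior.generate_schedule(seed=3, **behavior.SCHEDULE_PRESETS["exp1"])
    assert s.n_trials == 1200 and s.trials_per_block == 200
    assert s.n_targets == 120
    assert s.onset_asynchrony_s == pytest.approx(1.150)
    onsets = s.trials["onset_s"].to_numpy()
    assert np.allclose(np.diff(onsets), 1.150)


def test_four_block_preset_layout():
    s = behavior.generate_schedule(seed=3, **behavior.SCHEDULE_PRESETS["exp4"])
    assert s.n_trials == 1080 and s.trials_per_block == 270
    assert s.n_targets == 108


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    n_blocks=st.sampled_from([1, 2, 4, 6]),
    per_block=st.integers(30, 200),
    seed=st.integers(0, 2**20),
)
def test_schedule_exact_targets_and_no_adjacent(n_blocks, per_block, seed):
    n = n_blocks * per_block
    s = behavior.generate_schedule(n, n_blocks=n_blocks, seed=seed)
    tgt = s.trials["is_target"].to_numpy()
    assert tgt.sum() == round(0.10 * n)
    assert not np.any(tgt[1:] & tgt[:-1])
    digits = s.trials.loc[~s.trials["is_target"], "digit"]
    assert digits.between(1, 9).all()


def test_schedule_seed_reproducibility():
    a = behavior.generate_schedule(600, n_blocks=3, seed=9)
    b = behavior.generate_schedule(600, n_blocks=3, seed=9)
    pd.testing.assert_frame_equal(a.trials, b.trials)


def test_schedule_edge_cases():
    all_go = behavior.generate_schedule(100, target_prop=0.0, n_blocks=1, seed=0)
    assert all_go.all_go and all_go.n_targets == 0
    # prop just below 0.5 still packs non-adjacently (alternating layout)
    dense = behavior.generate_schedule(100, target_prop=0.49, n_blocks=1, seed=0)
    tgt = dense.trials["is_target"].to_numpy()
    assert not np.any(tgt[1:] & tgt[:-1])
    with pytest.raises(InvalidParameterError):
        behavior.generate_schedule(100, target_prop=0.6, n_blocks=1, seed=0)


# ------------------------------------------------------------------- scoring


def _perfect_log(schedule):
    pressed = ~schedule.trials["is_target"].to_numpy()
    rt = np.where(pressed, 0.4, np.nan)
    return pd.DataFrame({"pressed": pressed, "rt_s": rt})


def test_perfect_responder_corrected_dprime():
    """180 go / 20 no-go with perfect behavior: log-linear correction gives
    z(180.5/181) - z(0.5/21) = 4.7555 (verified against R's qnorm)."""
    s = behavior.generate_schedule(200, n_blocks=1, seed=0)
    summary = behavior.score_responses(s, _perfect_log(s))
    assert summary.overall_dprime == pytest.approx(4.7555, abs=1e-3)
    row = summary.table.iloc[0]
    assert (row.hits, row.misses, row.fas, row.crs) == (180, 0, 0, 20)


def test_all_press_responder_symmetry():
    """With both rates at ceiling the log-linear correction cancels exactly
    only when go and no-go counts match; on the SART's 9:1 ratio the
    residual is the difference of the two corrected z's."""
    assert behavior.dprime(hits=100, misses=0, fas=100, crs=0) == pytest.approx(0.0)
    s = behavior.generate_schedule(200, n_blocks=1, seed=0)
    log = pd.DataFrame({"pressed": np.ones(200, bool)})
    expected = norm.ppf(180.5 / 181) - norm.ppf(20.5 / 21)
    assert behavior.score_responses(s, log).overall_dprime == pytest.approx(expected)


def test_coin_flip_responder_is_unbiased():
    """Null agent: mean corrected d' over seeds is ~0 (se ~ 0.03 at 100
    seeds on a 200-trial block)."""
    s = behavior.generate_schedule(200, n_blocks=1, seed=0)
    ds = []
    for seed in range(100):
        r = np.random.default_rng(seed)
        log = pd.DataFrame({"pressed": r.random(200) < 0.5})
        ds.append(behavior.score_responses(s, log).overall_dprime)
    assert abs(np.mean(ds)) < 0.1


def test_counts_conserve_per_block():
    s = behavior.generate_schedule(400, n_blocks=2, seed=1)
    r = np.random.default_rng(0)
    log = pd.DataFrame({"pressed": r.random(400) < 0.8})
    table = behavior.score_responses(s, log).table
    assert (table[["hits", "misses", "fas", "crs"]].sum(axis=1) == 200).all()


def test_score_length_mismatch():
    s = behavior.generate_schedule(100, n_blocks=1, seed=0)
    with pytest.raises(InvalidInputError):
        behavior.score_responses(s, pd.DataFrame({"pressed": [True] * 99}))


# -------------------------------------------------------------- rt variability


def test_rt_cv_constant_and_hand_computed():
    log = pd.DataFrame({"rt_s": [0.4] * 20})
    assert np.allclose(behavior.rt_variability(log), 0.0)
    # window of {0.3, 0.5}: sample SD = 0.1*sqrt(2), mean 0.4
    rts = [0.3, 0.5] + [np.nan] * 8
    cv = behavior.rt_variability(pd.DataFrame({"rt_s": rts}))
    assert cv[0] == pytest.approx(0.1 * np.sqrt(2) / 0.4, abs=1e-9)


def test_rt_cv_sparse_windows():
    rts = [0.4] + [np.nan] * 9 + [0.3, 0.5] + [np.nan] * 8
    cv = behavior.rt_variability(pd.DataFrame({"rt_s": rts}))
    assert np.isnan(cv[0]) and np.isfinite(cv[1])
    with pytest.raises(InsufficientDataError):
        behavior.rt_variability(pd.DataFrame({"rt_s": [np.nan] * 20}))


# --------------------------------------------------- condition/block summary


def _dprime_table(values):
    rows = []
    for (subj, cond, block), d in values.items():
        rows.append({"subject": subj, "condition": cond, "block": block, "dprime": d})
    return pd.DataFrame(rows)


def test_identical_conditions_give_zero_deltas():
    vals = {
        (s, c, b): 2.0 + 0.1 * s
        for s in range(4) for c in ("none", 8, 16) for b in (0, 1)
    }
    delta, group = behavior.condition_block_summary(_dprime_table(vals), "none")
    assert np.allclose(delta["delta_dprime"], 0.0)
    assert np.allclose(group["within_subject_sem"], 0.0)


def test_within_subject_sem_matches_morey_identity(rng):
    """Cousineau-Morey SEM = SEM of subject-mean-centered data times
    sqrt(m/(m-1)) — checked against an independent re-implementation."""
    data = rng.normal(size=(10, 4)) + rng.normal(size=(10, 1))  # subject offsets
    pivot = pd.DataFrame(data)
    sem = behavior.within_subject_sem(pivot)
    centered = data - data.mean(axis=1, keepdims=True) + data.mean()
    expected = centered.std(axis=0, ddof=1) / np.sqrt(10) * np.sqrt(4 / 3)
    np.testing.assert_allclose(sem.to_numpy(), expected, rtol=1e-12)


def test_missing_baseline_raises():
    vals = {(0, 8, 0): 1.0, (0, 16, 0): 1.2}
    with pytest.raises(InvalidInputError):
        behavior.condition_block_summary(_dprime_table(vals), "none")


def test_cohort_mean_effect_recovery():
    """Designed +0.3 d' offset in one condition is recovered by the group
    mean within 2 within-subject SEMs (moderate-sensitivity regime where
    the log-linear correction bias is negligible)."""
    effects = synth.EffectMap(
        baseline_dprime=1.5, criterion=0.5, condition_offsets={16: 0.3}
    )
    table, profiles = synth.synth_cohort_counts(
        80, n_go=900, n_nogo=100, effects=effects, seed=4
    )
    delta, group = behavior.condition_block_summary(table, "none")
    g16 = group[group["condition"] == 16]
    est = g16["mean_delta_dprime"].mean()
    sem = g16["within_subject_sem"].mean()
    assert est == pytest.approx(0.3, abs=2 * sem + 0.02)


# --------------------------------------------------------- interaction contrast


def test_zero_deltas_give_null_contrast():
    rows = [
        {"subject": s, "condition": c, "block": b, "delta_dprime": 0.0}
        for s in range(10) for c in (8, 16, 32) for b in (0, 1)
    ]
    profiles = pd.DataFrame({"subject": range(10), "asrs_score": range(20, 30)})
    res = behavior.interaction_contrast(pd.DataFrame(rows), profiles,
                                        n_perm=200, seed=0)
    assert res.slope == 0.0
    assert res.p_perm == pytest.approx(1.0)


def test_designed_interaction_recovered_with_power():
    """+0.4 interaction coefficient (16 Hz benefit growing over blocks,
    scaled by ASRS): positive slope with permutation p < 0.05 in >= 80% of
    cohorts at n = 82."""
    effects = synth.EffectMap(condition_offsets={16: 0.2}, asrs_interaction=0.4)
    wins = 0
    n_cohorts = 20
    for k in range(n_cohorts):
        table, profiles = synth.synth_cohort_counts(
            82, n_go=121, n_nogo=14, effects=effects, seed=1000 + k
        )
        delta, _ = behavior.condition_block_summary(table, "none")
        res = behavior.interaction_contrast(delta, profiles, n_perm=399, seed=k)
        if res.slope > 0 and res.p_perm < 0.05:
            wins += 1
    assert wins >= 0.8 * n_cohorts


def test_incomplete_subjects_excluded_with_warning():
    rows = [
        {"subject": s, "condition": c, "block": b, "delta_dprime": 0.1}
        for s in range(6) for c in (8, 16, 32) for b in (0, 1)
    ]
    df = pd.DataFrame(rows)
    df = df[~((df.subject == 5) & (df.condition == 32))]
    profiles = pd.DataFrame({"subject": range(6), "asrs_score": [20, 25, 30, 35, 40, 45]})
    with pytest.warns(UserWarning, match="excluding"):
        res = behavior.interaction_contrast(df, profiles, n_perm=100, seed=0)
    assert res.n_subjects == 5


def test_dprime_antisymmetry():
    """Swapping press behavior between go and no-go trials flips the sign
    of d' when go and no-go counts are equal."""
    a = behavior.dprime(hits=45, misses=5, fas=10, crs=40)
    b = behavior.dprime(hits=10, misses=40, fas=45, crs=5)
    assert a == pytest.approx(-b)
    assert a == pytest.approx(
        norm.ppf(45.5 / 51) - norm.ppf(10.5 / 51), abs=1e-12
    )
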