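"""Outcome proportions, propensities, fit statistics, and smoothers."""

import math

import numpy as np
import pandas as pd
import pytest

from trustgames.games import OUTCOME_CLASSES
from trustgames.metrics import (
    FitResult,
    compare_frames,
    fit_per_outcome_mean,
    fit_statistics,
    game_outcome_series,
    propensity_difference,
    proportion_profile,
    repetition_propensity,
    smooth,
    steiger_z,
    transfer_test,
)
from trustgames.synthetic import archetype_runs, mixture_runs


def test_profile_all_cooperators():
    frame = archetype_runs({"CC": 10}, rounds=20)
    prof = proportion_profile(frame)
    assert prof.shape == (20, 5)
    assert (prof["CC"] == 1.0).all()
    assert prof[["CD", "DC", "DD", "ALT"]].to_numpy().sum() == 0


def test_profile_perfect_alternators():
    frame = archetype_runs({"ALT": 8}, rounds=30)
    prof = proportion_profile(frame)
    assert (prof.loc[2:, "ALT"] == 1.0).all()
    assert prof.loc[1, "CD"] == 1.0  # round 1 cannot alternate


def test_profile_matches_tally_oracle():
    frame = mixture_runs({"CC": 0.4, "CD": 0.1, "DC": 0.2, "DD": 0.3},
                         n_runs=12, rounds=15, seed=4)
    prof = proportion_profile(frame)
    # Brute-force tally, independent of the pivot implementation.
    for rnd in (1, 7, 15):
        sub = frame[frame["round"] == rnd]
        for cls in OUTCOME_CLASSES:
            assert prof.loc[rnd, cls] == pytest.approx(
                (sub["outcome_class"] == cls).mean())
    assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-12)


def test_profile_rows_sum_to_one(small_experiment_frame):
    prof = proportion_profile(small_experiment_frame, 2)
    assert prof.shape[0] == 100  # both games on a continuous axis
    assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-12)


def test_profile_requires_single_condition(small_experiment_frame):
    with pytest.raises(ValueError):
        proportion_profile(small_experiment_frame)


def test_propensity_constant_defectors():
    frame = archetype_runs({"DD": 6}, rounds=10)
    prop = repetition_propensity(frame)
    assert (prop["DD"].dropna() == 1.0).all()
    # Other conditioning outcomes never occurred: undefined.
    assert prop[["CC", "CD", "DC"]].isna().all().all()


def test_propensity_half_switchers():
    # 3 runs stay mutual defectors; 3 runs alternate (switch every
    # round after a DD start is impossible, so build CD vs ALT mix):
    # 2 constant-CC runs repeat B after CC; 2 ALT runs switch after
    # their unilateral outcomes.
    frame = archetype_runs({"CC": 2, "ALT": 2}, rounds=12)
    prop = repetition_propensity(frame)
    assert (prop["CC"].dropna() == 1.0).all()
    # Alternators never repeat after their unilateral rounds.
    assert (prop[["CD", "DC"]].stack().dropna() == 0.0).all()


def test_propensity_matches_tally_oracle():
    frame = mixture_runs({"CC": 0.3, "CD": 0.2, "DC": 0.2, "DD": 0.3},
                         n_runs=15, rounds=10, seed=9)
    prop = repetition_propensity(frame)
    # Oracle: direct loop over runs.
    runs = {rid: g.sort_values("round")
            for rid, g in frame.groupby("run_id")}
    for rnd in (2, 5, 10):
        tallies = {k: [] for k in ("CC", "CD", "DC", "DD")}
        for g in runs.values():
            prev = g.iloc[rnd - 2]
            cur = g.iloc[rnd - 1]
            key = ("C" if prev.focal_move == "B" else "D") + \
                  ("C" if prev.agent_move == "B" else "D")
            tallies[key].append(cur.focal_move == prev.focal_move)
        for key, vals in tallies.items():
            if vals:
                assert prop.loc[rnd, key] == pytest.approx(np.mean(vals))
            else:
                assert math.isnan(prop.loc[rnd, key])


def test_propensity_difference_sign_and_shape():
    human = archetype_runs({"CC": 4}, rounds=8)
    model = archetype_runs({"CC": 2, "ALT": 2}, rounds=8)
    ph, pm = repetition_propensity(human), repetition_propensity(model)
    diff = propensity_difference(ph, pm)
    # Humans always repeat after CC, the model half the time overall --
    # but per CC-conditioned cell the model's CC runs also repeat, so
    # the CC cell difference is 0; unilateral cells are undefined for
    # the humans.
    assert (diff["CC"].dropna() == 0.0).all()
    assert diff[["CD", "DC"]].isna().all().all()
    ident = propensity_difference(ph, ph)
    assert (ident.fillna(0) == 0).all().all()
    with pytest.raises(ValueError):
        propensity_difference(ph, pm.iloc[:-1])


def _manual_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def test_fit_statistics_trivial_cases():
    a = proportion_profile(archetype_runs({"CC": 3, "DD": 2}, rounds=10))
    res = fit_statistics(a, a)
    assert res.r == pytest.approx(1.0) and res.rmsd == 0.0
    shifted = a + 0.1
    res = fit_statistics(a, shifted)
    assert res.r == pytest.approx(1.0)
    assert res.rmsd == pytest.approx(0.1)


def test_fit_statistics_matches_textbook_formulas():
    a = pd.DataFrame({"CC": [0.2, 0.5, 0.9], "DD": [0.8, 0.5, 0.1]})
    b = pd.DataFrame({"CC": [0.1, 0.6, 0.7], "DD": [0.9, 0.4, 0.3]})
    res = fit_statistics(a, b)
    x, y = a.to_numpy().ravel(), b.to_numpy().ravel()
    assert res.r == pytest.approx(_manual_pearson(x, y))
    assert res.rmsd == pytest.approx(math.sqrt(np.mean((x - y) ** 2)))
    assert res.n == 6
    # Symmetry in both statistics.
    swapped = fit_statistics(b, a)
    assert swapped.r == pytest.approx(res.r)
    assert swapped.rmsd == pytest.approx(res.rmsd)


def test_fit_statistics_constant_vector_flagged():
    a = pd.DataFrame({"CC": [0.5, 0.5], "DD": [0.5, 0.5]})
    b = pd.DataFrame({"CC": [0.2, 0.4], "DD": [0.8, 0.6]})
    res = fit_statistics(a, b)
    assert not res.r_defined
    assert res.rmsd > 0


def test_pooled_fit_equals_concatenation():
    a1 = pd.DataFrame({"CC": [0.2, 0.4], "DD": [0.8, 0.6]})
    b1 = pd.DataFrame({"CC": [0.3, 0.3], "DD": [0.7, 0.7]})
    a2 = pd.DataFrame({"CC": [0.9, 0.1], "DD": [0.1, 0.9]})
    b2 = pd.DataFrame({"CC": [0.8, 0.2], "DD": [0.2, 0.8]})
    pooled = fit_statistics([a1, a2], [b1, b2])
    concat = fit_statistics(pd.concat([a1, a2]), pd.concat([b1, b2]))
    assert pooled.r == pytest.approx(concat.r)
    assert pooled.rmsd == pytest.approx(concat.rmsd)


def test_per_outcome_mean_option():
    a = pd.DataFrame({"CC": [0.2, 0.4, 0.6], "DD": [0.8, 0.6, 0.4]})
    b = pd.DataFrame({"CC": [0.25, 0.35, 0.65], "DD": [0.75, 0.65, 0.35]})
    res = fit_per_outcome_mean(a, b)
    per = [fit_statistics(a[[c]], b[[c]]) for c in a.columns]
    assert res.r == pytest.approx(np.mean([p.r for p in per]))
    assert res.rmsd == pytest.approx(np.mean([p.rmsd for p in per]))


def _manual_paired_t(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    return float(d.mean() / (d.std(ddof=1) / math.sqrt(d.size)))


def test_transfer_test_against_formula_oracle():
    first = [0.30, 0.42, 0.55, 0.48, 0.61]
    second = [0.22, 0.40, 0.46, 0.40, 0.50]
    res = transfer_test(first, second)
    assert res.t == pytest.approx(_manual_paired_t(first, second))
    assert res.df == 4
    assert res.mean_first_pct == pytest.approx(100 * np.mean(first))
    assert res.sd_second_pct == pytest.approx(100 * np.std(second, ddof=1))
    assert 0 < res.p < 0.05  # uniformly lower second series


def test_transfer_test_sign_and_degenerate():
    same = transfer_test([0.1, 0.4, 0.2], [0.1, 0.4, 0.2])
    assert same.t == 0.0
    rising = transfer_test([0.1, 0.2, 0.3], [0.3, 0.4, 0.5])
    assert rising.t < 0  # second > first gives negative t
    with pytest.raises(ValueError):
        transfer_test([0.1], [0.2])
    with pytest.raises(ValueError):
        transfer_test([0.1, 0.2], [0.2])


def test_transfer_test_pair_order_invariance():
    first = np.array([0.3, 0.5, 0.2, 0.6])
    second = np.array([0.1, 0.4, 0.3, 0.5])
    perm = [2, 0, 3, 1]
    a = transfer_test(first, second)
    b = transfer_test(first[perm], second[perm])
    assert a.t == pytest.approx(b.t)


def _manual_steiger(r1, r2, r12, n):
    z1, z2 = math.atanh(r1), math.atanh(r2)
    rbar = (r1 + r2) / 2
    psi = r12 * (1 - 2 * rbar ** 2) \
        - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r12 ** 2)
    c = psi / (1 - rbar ** 2) ** 2
    return (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * c))


def test_steiger_z():
    assert steiger_z(0.4, 0.4, 0.3, 50) == 0.0
    got = steiger_z(0.5, 0.3, 0.2, 100)
    assert got == pytest.approx(_manual_steiger(0.5, 0.3, 0.2, 100))
    assert got > 0
    # |Z| grows with n at fixed correlations.
    assert abs(steiger_z(0.5, 0.3, 0.2, 400)) > abs(got)
    with pytest.raises(ValueError):
        steiger_z(1.0, 0.3, 0.2, 100)
    with pytest.raises(ValueError):
        steiger_z(0.5, 0.3, 0.2, 3)


def test_smooth_preserves_constant_and_linear():
    const = np.full(40, 0.7)
    assert np.allclose(smooth(const), const, atol=1e-9)
    linear = np.linspace(0, 1, 40)
    assert np.allclose(smooth(linear), linear, atol=1e-6)


def test_smooth_denoises_sine():
    rng = np.random.default_rng(0)
    x = np.linspace(0, 2 * np.pi, 100)
    clean = np.sin(x)
    noisy = clean + rng.normal(0, 0.3, x.size)
    smoothed = smooth(noisy, span=0.25)
    assert np.mean((smoothed - clean) ** 2) < np.mean((noisy - clean) ** 2) / 2


def test_smooth_interpolates_gaps():
    y = np.linspace(0, 1, 20)
    gappy = y.copy()
    gappy[5] = np.nan
    out = smooth(gappy, span=0.5)
    assert np.isfinite(out).all()
    with pytest.raises(ValueError):
        smooth(y, span=0.0)


def test_transfer_report_finds_mixed_order_pairs():
    import trustgames as tg

    cfg = tg.ExperimentConfig(n_runs=3, rounds_per_game=10, master_seed=4)
    frame = tg.runs_to_frame(tg.run_experiment(
        cfg, [tg.get_condition(2), tg.get_condition(3)]))  # PDCG + CGPD T4T HT
    from trustgames.metrics import transfer_report

    reports = transfer_report(frame)
    # Both PD (CC) and CG (ALT) first-vs-second comparisons exist.
    assert {(r["game"], r["outcome"]) for r in reports} == \
        {("PD", "CC"), ("CG", "ALT")}
    assert all(r["df"] == 9 for r in reports)


def test_compare_frames_and_game_series(small_experiment_frame):
    frame = small_experiment_frame
    fits = compare_frames(frame, frame)
    assert fits["overall"].r == pytest.approx(1.0)
    assert fits["overall"].rmsd == 0.0
    assert set(fits["per_condition"]) == {2, 13}
    series = game_outcome_series(frame, 2, 1, "CC")
    prof = proportion_profile(frame, 2)
    assert np.allclose(series, prof.loc[1:50, "CC"])
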