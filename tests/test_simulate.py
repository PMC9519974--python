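"""Synthetic cohort generator: determinism, trait effects, calibration structure."""

import numpy as np
import pandas as pd
import pytest

from psycop.scoring import (
    LightCycle, SprtConfig, nocturnality_score, ppi_percent,
    sprt_trials_to_criterion,
)
from psycop.simulate import (
    CohortDesign, EffectSpec, MouseLatentTraits, Phase, generate_cohort,
    sample_traits, simulate_intellicage_events, simulate_summary_tests,
    simulate_trial_sequences, simulate_reversal_auc_table, _build_schedule,
)

SMALL = CohortDesign(group_sizes=(3, 3, 3, 3), seed=11,
                     phases=(Phase("acclimatization", "free", 1.0),
                             Phase("place_learning", "learning", 1.0),
                             Phase("reversal1", "learning", 1.0),
                             Phase("reversal2", "learning", 1.0),
                             Phase("sucrose", "sucrose", 0.5)))


def test_same_seed_identical_dataset(tmp_path):
    a = generate_cohort(SMALL, seed=5)
    b = generate_cohort(SMALL, seed=5)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.summaries, b.summaries)
    pd.testing.assert_frame_equal(a.arms, b.arms)
    a.save(tmp_path / "a")
    b.save(tmp_path / "b")
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_different_seed_differs():
    a = generate_cohort(SMALL, seed=5)
    b = generate_cohort(SMALL, seed=6)
    assert not a.events.equals(b.events)


def test_invalid_designs_rejected():
    with pytest.raises(ValueError):
        CohortDesign(group_sizes=(1, 5, 5, 5))
    with pytest.raises(ValueError):
        CohortDesign(group_sizes=(5, 5, 5))
    with pytest.raises(ValueError):
        Phase("x", "free", 0.0)
    with pytest.raises(ValueError):
        Phase("x", "weird", 1.0)


def test_unknown_trait_in_effects_rejected():
    with pytest.raises(ValueError, match="unknown trait"):
        EffectSpec({"not_a_trait": {"S": 1.0}})
    with pytest.raises(ValueError, match="terms"):
        EffectSpec({"learning_rate": {"SxB": 1.0}})


def test_effect_shift_moves_cell_means(rng):
    eff = EffectSpec({"learning_rate": {"S": 0.8}})
    lo = [sample_traits(rng, -1.0, -1.0, eff).learning_rate for _ in range(300)]
    hi = [sample_traits(rng, 1.0, -1.0, eff).learning_rate for _ in range(300)]
    assert np.mean(hi) > np.mean(lo) * 1.5


def _one_mouse_events(traits, days=4.0, seed=0):
    design = CohortDesign(group_sizes=(2, 2, 2, 2), seed=seed,
                          phases=(Phase("acclimatization", "free", days),))
    rng = np.random.default_rng(seed)
    schedule = _build_schedule(design, ["M001"], rng)
    return simulate_intellicage_events(traits, schedule, "M001", rng)


class TestCircadianStructure:
    def test_zero_amplitude_symmetric_day_night(self):
        traits = MouseLatentTraits(circadian_amplitude=0.0, base_visit_rate=8.0)
        ev = _one_mouse_events(traits, days=5.0)
        assert len(ev) >= 500
        s = nocturnality_score(ev["t_start"].to_numpy(), LightCycle())
        assert abs(s) < 0.05

    def test_strong_amplitude_nocturnal(self):
        traits = MouseLatentTraits(circadian_amplitude=0.95, base_visit_rate=8.0)
        ev = _one_mouse_events(traits, days=5.0)
        s = nocturnality_score(ev["t_start"].to_numpy(), LightCycle())
        assert s > 0.5

    def test_visits_sorted_nonoverlapping(self):
        traits = MouseLatentTraits(base_visit_rate=10.0)
        ev = _one_mouse_events(traits, days=2.0)
        t0 = ev["t_start"].to_numpy()
        t1 = ev["t_end"].to_numpy()
        assert (t1 >= t0).all()
        assert (t0[1:] >= t1[:-1]).all()


def test_zero_learning_rate_stays_at_chance():
    """With no value updating, corner choice stays uniform and the SPRT
    criterion is (almost) never reached within a one-day phase."""
    phases = (Phase("reversal1", "learning", 1.0),)
    cfg = SprtConfig()
    censored = 0
    n_mice = 60
    rng = np.random.default_rng(99)
    for _ in range(n_mice):
        traits = MouseLatentTraits(learning_rate=0.0, base_visit_rate=4.0)
        seqs = simulate_trial_sequences(traits, phases, {"reversal1": 2}, rng)
        _, cens = sprt_trials_to_criterion(seqs["reversal1"], cfg)
        censored += cens
    assert censored >= 0.95 * n_mice


def test_learning_rate_monotonically_speeds_criterion():
    phases = (Phase("place_learning", "learning", 2.0),)
    rng = np.random.default_rng(7)
    medians = []
    for lr in (0.05, 0.15, 0.4):
        traits = MouseLatentTraits(learning_rate=lr, base_visit_rate=4.0,
                                   choice_temperature=0.3)
        crits = []
        for _ in range(80):
            seqs = simulate_trial_sequences(traits, phases, {"place_learning": 1}, rng)
            crits.append(sprt_trials_to_criterion(seqs["place_learning"])[0])
        medians.append(np.median(crits))
    assert medians[0] > medians[1] > medians[2]


class TestSummaryTests:
    def test_no_attenuation_gives_zero_ppi(self):
        rng = np.random.default_rng(3)
        traits = MouseLatentTraits(ppi_attenuation=0.0)
        vals = []
        for _ in range(1000):
            _, st = simulate_summary_tests(traits, rng)
            base = st.loc[st["condition"] == "baseline", "amplitude"]
            pp = st.loc[st["condition"] == "pp75", "amplitude"]
            vals.append(ppi_percent(base, pp))
        assert abs(np.mean(vals)) < 2.0

    def test_sixty_percent_attenuation_recovered(self):
        rng = np.random.default_rng(4)
        traits = MouseLatentTraits(ppi_attenuation=0.6,
                                   ppi_level_offsets=(0.0, 0.0, 0.0))
        vals = []
        for _ in range(1000):
            _, st = simulate_summary_tests(traits, rng)
            base = st.loc[st["condition"] == "baseline", "amplitude"]
            pp = st.loc[st["condition"] == "pp75", "amplitude"]
            vals.append(ppi_percent(base, pp))
        assert np.mean(vals) == pytest.approx(60.0, abs=3.0)

    def test_zero_freeze_propensity_always_zero_seconds(self):
        rng = np.random.default_rng(5)
        traits = MouseLatentTraits(freeze_baseline=0.0, freeze_cue=0.0,
                                   freeze_ctx=0.0)
        for _ in range(20):
            summ, _ = simulate_summary_tests(traits, rng)
            assert summ["BsF"] == 0.0 and summ["Cue"] == 0.0 and summ["Ctx"] == 0.0


def test_cohort_layout_and_validity():
    c = generate_cohort(SMALL, seed=2)
    assert len(c.design) == 12
    assert set(c.events["mouse_tag"]) <= set(c.design.index)
    from psycop.io import validate_event_table
    assert validate_event_table(c.events) == []
    # reversal assignment switches for every mouse
    r1 = c.schedule.assigned_corners("reversal1")
    r2 = c.schedule.assigned_corners("reversal2")
    assert all(r1[t] != r2[t] for t in r1)


def test_fast_path_null_pvalues_uniform():
    """With zero effects the SxA p-values over replicate cohorts are U(0,1)."""
    from psycop.stats import two_way_anova_type2
    import scipy.stats as sps
    design = CohortDesign(group_sizes=(6, 6, 8, 8), seed=0)
    ps = []
    for i in range(120):
        tab = simulate_reversal_auc_table(design, seed=20_000 + i)
        res = two_way_anova_type2(tab["SrL"].to_numpy(), tab[["S", "A"]])
        ps.append(res.table.loc["SxA", "p"])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_reversal_auc_table_columns():
    tab = simulate_reversal_auc_table(SMALL, seed=1)
    assert {"RvL", "SrL", "S", "A"} <= set(tab.columns)
    assert tab["SrL"].notna().all()
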