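"""Rank tests against enumeration oracles, BH arithmetic, and the cascade."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from motifdms import scoring, stat_filters as sf, synthetic_data as sd

# --------------------------------------------------------------------------
# Enumeration oracle for the Mann-Whitney U test (tie-free samples)
# --------------------------------------------------------------------------


def mw_enumeration_p(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating every labeling of the pooled data."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    total = len(us)
    p_le = (us <= u_obs).sum() / total
    p_ge = (us >= u_obs).sum() / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_le, p_ge))


def test_mw_exact_matches_enumeration_for_all_small_sizes():
    """Tie-free samples with n_x + n_y <= 10: exact p equals enumeration."""
    rng = np.random.default_rng(99)
    for nx in range(1, 6):
        for ny in range(1, 6):
            for _ in range(3):
                pooled = rng.permutation(rng.normal(size=nx + ny))
                x, y = pooled[:nx], pooled[nx:]
                for alt in ("two-sided", "greater", "less"):
                    _, p = sf.mann_whitney_u(x, y, alt)
                    assert p == pytest.approx(mw_enumeration_p(x, y, alt), abs=1e-12)


def test_mw_textbook_example():
    """x below y with n = 3 + 3: U = 0 and exact two-sided p = 2/20."""
    u, p = sf.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)


def test_mw_identical_samples_and_symmetry():
    x = [1.0, 2.0, 3.0, 4.0]
    _, p = sf.mann_whitney_u(x, x)
    assert p == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=6), rng.normal(size=9)
    assert sf.mann_whitney_u(a, b)[1] == pytest.approx(sf.mann_whitney_u(b, a)[1])
    with pytest.raises(ValueError):
        sf.mann_whitney_u([], [1.0])


def test_bh_hand_computed_step_up():
    """(0.01, 0.02, 0.03, 0.04) all adjust to 0.04 under the step-up."""
    adj = sf.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert sf.bh_fdr([0.2]) == pytest.approx([0.2])
    with pytest.raises(ValueError):
        sf.bh_fdr([0.5, 1.2])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_bh_monotone_in_rank_order(ps):
    adj = sf.bh_fdr(ps)
    order = np.argsort(ps, kind="stable")
    assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
    assert ((adj >= 0) & (adj <= 1)).all()


def test_bh_controls_fdr_in_null_simulation():
    """Observed FDR over pure-null batches stays near/below alpha."""
    rng = np.random.default_rng(12)
    alpha = 0.05
    false_rates = []
    for _ in range(300):
        p = rng.uniform(size=40)
        rejected = sf.bh_fdr(p) < alpha
        false_rates.append(rejected.mean() > 0)  # any false discovery
    # P(any rejection) <= alpha under independence for BH
    assert np.mean(false_rates) <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / 300)


def test_welch_and_student_t():
    t, p = sf.welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0.0 and p == pytest.approx(1.0)
    t, _ = sf.student_t_test([2, 3, 4], [4, 5, 6])
    assert t == pytest.approx(-2.449, abs=0.001)
    with pytest.raises(ValueError):
        sf.welch_t_test([1.0], [1, 2])


# --------------------------------------------------------------------------
# Filter steps on constructed score tables
# --------------------------------------------------------------------------


def _control_scores(n_nonsense=20, reps=6, outlier=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_nonsense):
        center = 0.5 if i == outlier else -1.0
        for r in range(1, reps + 1):
            rows.append({"bait": "Sho1", "condition": "MTX", "replicate": r,
                         "variant_id": f"n{i}", "variant_class": "nonsense",
                         "aa_change_key": f"n{i}",
                         "scaled_score": rng.normal(center, 0.05),
                         "pass_count_filter": True})
    return pd.DataFrame(rows)


def test_control_outlier_flags_the_planted_outlier():
    """The displaced control is flagged; false flags stay near the 5%
    type-I rate of the unadjusted test."""
    flags = sf.flag_control_outliers(_control_scores(outlier=7))
    flagged = flags.loc[flags["flagged"], "variant_id"].tolist()
    assert "n7" in flagged
    assert len(flagged) <= 3  # ~alpha * 20 false flags expected at most


def test_control_outlier_type_one_rate_is_near_alpha():
    """With all controls from one distribution the flag rate is ~5%."""
    rates = []
    for seed in range(30):
        flags = sf.flag_control_outliers(_control_scores(seed=seed))
        rates.append(flags["flagged"].mean())
    assert np.mean(rates) == pytest.approx(0.05, abs=0.04)


def test_control_outlier_single_variant_class_untested():
    flags = sf.flag_control_outliers(_control_scores(n_nonsense=1))
    assert flags.empty


def test_control_condition_defect_rule():
    """Missense similar to nonsense in the control -> removed; distinct -> kept."""
    rng = np.random.default_rng(1)
    rows = []
    for i in range(30):
        for r in range(1, 4):
            rows.append({"bait": "Sho1", "condition": "noMTX", "replicate": r,
                         "variant_id": f"n{i}", "variant_class": "nonsense",
                         "aa_change_key": f"stop{i}",
                         "scaled_score": rng.normal(-1.0, 0.05),
                         "pass_count_filter": True})
    for name, center in [("good", 0.0), ("bad", -1.0)]:
        for r in range(1, 7):
            rows.append({"bait": "Sho1", "condition": "noMTX", "replicate": r,
                         "variant_id": name, "variant_class": "missense",
                         "aa_change_key": name,
                         "scaled_score": rng.normal(center, 0.05),
                         "pass_count_filter": True})
    flags = sf.flag_control_condition_defects(pd.DataFrame(rows))
    by = flags.set_index("aa_change_key")["flagged"]
    assert not by["good"]
    assert by["bad"]


def test_classification_of_constructed_mutants():
    rng = np.random.default_rng(2)
    rows = []
    for r in range(24):
        rows.append({"bait": "Sho1", "condition": "MTX", "replicate": r % 3 + 1,
                     "variant_id": f"wt{r}", "variant_class": "silent",
                     "aa_change_key": f"wt{r}",
                     "scaled_score": rng.normal(0.0, 0.05),
                     "pass_count_filter": True})
    specs = {"up": [0.8, 0.9, 1.0, 0.85], "down": [-0.7, -0.8, -0.75, -0.9],
             "flat": list(rng.normal(0.0, 0.05, 4))}
    for name, vals in specs.items():
        for r, v in enumerate(vals, start=1):
            rows.append({"bait": "Sho1", "condition": "MTX", "replicate": r,
                         "variant_id": name, "variant_class": "missense",
                         "aa_change_key": name, "scaled_score": v,
                         "pass_count_filter": True})
    cls = sf.classify_mutants(pd.DataFrame(rows))
    by = cls.set_index("aa_change_key")["classification"]
    assert by["up"] == "stronger"
    assert by["down"] == "weaker"
    assert by["flat"] == "not_different"


def test_proliferation_test_welch():
    rng = np.random.default_rng(4)
    rows = [{"aa_change_key": "WT", "s": v} for v in rng.normal(0, 0.005, 6)]
    rows += [{"aa_change_key": "neutral", "s": v} for v in rng.normal(0, 0.005, 6)]
    rows += [{"aa_change_key": "stop", "s": v} for v in rng.normal(-0.2, 0.005, 6)]
    res = sf.proliferation_test(pd.DataFrame(rows))
    by = res.set_index("aa_change_key")["significant"]
    assert by["stop"]
    assert not by["neutral"]


# --------------------------------------------------------------------------
# End-to-end cascade on simulated data
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def cascade_run():
    design = sd.example_design("NNK", (85, 100))
    params = sd.SimulationParams(seed=8, read_depth=100_000, n_replicates=3,
                                 conditions=("MTX+sorbitol", "noMTX"),
                                 baits=("Sho1", "Hog1"),
                                 couple_abundance_to_growth=True)
    effects = sd.EffectModel.classes(design, seed=8, frac_abundance=0.10)
    scores = scoring.score_counts(sd.simulate_counts(design, params, effects), design)
    return design, effects, scores, sf.run_cascade(scores)


def test_cascade_catches_abundance_mutants_not_binding_mutants(cascade_run):
    from conftest import planted_keys

    design, effects, _, result = cascade_run
    flagged = set(result.abundance_flags.loc[result.abundance_flags["flagged"],
                                             "aa_change_key"])
    ab = planted_keys(design, effects.abundance, lambda v: v != 0)
    b_only = planted_keys(design, effects.binding, lambda v: v != 0) - ab
    assert len(ab & flagged) / len(ab) >= 0.95
    assert len(b_only & flagged) / len(b_only) <= 0.05


def test_cascade_classification_recovers_planted_fractions(cascade_run):
    from conftest import planted_keys

    design, effects, _, result = cascade_run
    cls = result.classification
    cls = cls[cls["condition"] == "MTX+sorbitol"].set_index("aa_change_key")
    stronger = planted_keys(design, effects.binding, lambda v: v > 0)
    weaker = planted_keys(design, effects.binding, lambda v: v < 0)
    got_stronger = set(cls.index[cls["classification"] == "stronger"])
    got_weaker = set(cls.index[cls["classification"] == "weaker"])
    present = set(cls.index)
    # planted directions are recovered for the mutants that survive filtering
    assert len(stronger & present & got_stronger) / max(1, len(stronger & present)) > 0.8
    assert len(weaker & present & got_weaker) / max(1, len(weaker & present)) > 0.8
    # and classified mutants rarely land on the wrong side
    assert len(got_stronger & weaker) == 0
    assert len(got_weaker & stronger) == 0


def test_cascade_rescaling_still_anchored_after_outlier_removal(cascade_run):
    _, _, _, result = cascade_run
    surv = result.scores
    nonsense = surv[(surv["variant_class"] == "nonsense") & surv["pass_count_filter"]]
    med = nonsense.groupby(["condition", "replicate"])["scaled_score"].median()
    mtx = med.loc["MTX+sorbitol"]
    assert np.allclose(mtx.to_numpy(), -1.0, atol=1e-12)


def test_cascade_rerun_is_stable(cascade_run):
    """Re-running the cascade on its own survivors barely changes anything:
    the unadjusted 5% outlier test may flag a few fresh borderline
    controls, but the retained records and classifications are stable."""
    _, _, _, result = cascade_run
    again = sf.run_cascade(result.scores)
    n_first = len(result.scores)
    assert len(again.scores) >= 0.97 * n_first
    first = result.classification
    first = first[first["condition"] == "MTX+sorbitol"] \
        .set_index("aa_change_key")["classification"]
    second = again.classification
    second = second[second["condition"] == "MTX+sorbitol"] \
        .set_index("aa_change_key")["classification"]
    shared = first.index.intersection(second.index)
    assert len(shared) >= 0.97 * len(first)
    assert (first.loc[shared] == second.loc[shared]).mean() >= 0.97
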