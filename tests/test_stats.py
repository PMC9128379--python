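"""Group comparisons, the gated Bonferroni ladder, and partial correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dynreconf import (
    bonferroni,
    compare_groups,
    longitudinal_change,
    partial_correlation,
    run_test_ladder,
)
from dynreconf.datatypes import DynreconfError
from dynreconf.stats import GroupComparison


def make_cohort(rng, n_per_group=30, groups=("HC", "CP", "MCI", "CI")):
    n = n_per_group * len(groups)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": np.repeat(groups, n_per_group),
            "age": rng.normal(50, 10, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.integers(0, 2, n),
        }
    )


# ------------------------------------------------------------- OLS layer
def test_noise_free_contrast_recovered_exactly(rng):
    df = make_cohort(rng)
    df["y"] = (
        0.3 * (df.group == "CI")
        + 0.02 * df.age
        - 0.1 * df.sex
        + 0.05 * df.education
    )
    res = compare_groups(df, "y", divisor=2)
    ci_cp = res.contrasts.set_index("contrast").loc["CI - CP", "estimate"]
    assert ci_cp == pytest.approx(0.3, abs=1e-8)
    hc_ci = res.contrasts.set_index("contrast").loc["CI - HC", "estimate"]
    assert hc_ci == pytest.approx(0.3, abs=1e-8)
    assert res.p_adjusted <= 1e-8


def test_adjustment_recovers_confounded_contrast(rng):
    """When age differs by group and drives y, adjustment recovers the planted 0.5."""
    df = make_cohort(rng, n_per_group=200, groups=("CP", "CI"))
    df["age"] = df["age"] + 10.0 * (df.group == "CI")
    df["y"] = 0.5 * (df.group == "CI") + 0.05 * df.age + rng.normal(0, 0.3, len(df))
    adjusted = compare_groups(df, "y").contrasts["estimate"].iloc[0]
    unadjusted = (
        df.loc[df.group == "CI", "y"].mean() - df.loc[df.group == "CP", "y"].mean()
    )
    assert abs(adjusted - 0.5) < abs(unadjusted - 0.5)
    assert adjusted == pytest.approx(0.5, abs=0.1)


def test_compare_groups_requires_two_groups(rng):
    df = make_cohort(rng, groups=("CP",))
    df["y"] = rng.normal(size=len(df))
    with pytest.raises(DynreconfError):
        compare_groups(df, "y")


def test_bonferroni_adjustment_bounds():
    assert bonferroni(0.03, 2) == pytest.approx(0.06)
    assert bonferroni(0.8, 7) == 1.0
    for p in (0.001, 0.2, 0.9):
        for d in (1, 2, 7):
            assert bonferroni(p, d) >= p


# ------------------------------------------------------- longitudinal layer
def _long_cohort(rng, slope_declining=0.0, noise=0.05):
    rows = []
    for i in range(40):
        group = "declining" if i < 20 else "stable"
        level = rng.normal(0, 1)
        age = rng.normal(50, 8)
        sex = int(rng.random() < 0.5)
        edu = int(rng.random() < 0.5)
        for t, tp in enumerate(["baseline", "followup"]):
            y = level + (slope_declining * t if group == "declining" else 0.0)
            y += rng.normal(0, noise)
            rows.append(
                dict(subject_id=f"s{i}", group=group, timepoint=tp, age=age,
                     sex=sex, education=edu, y=y)
            )
    return pd.DataFrame(rows)


def test_identical_timepoints_give_zero_time_effect(rng):
    df = _long_cohort(rng, slope_declining=0.0, noise=0.0)
    df["y"] = df.groupby("subject_id")["y"].transform("first")  # exactly repeated
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = longitudinal_change(df, "y", group_order=("stable", "declining"))
    assert np.all(np.abs(res["time_effect"]) < 1e-6)


def test_planted_slope_only_in_declining_group(rng):
    df = _long_cohort(rng, slope_declining=1.0, noise=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = longitudinal_change(df, "y", group_order=("stable", "declining")).set_index("group")
    assert res.loc["declining", "time_effect"] == pytest.approx(1.0, abs=0.1)
    assert abs(res.loc["stable", "time_effect"]) < 0.1
    assert res.loc["declining", "interaction_p"] < 0.01


def test_estimates_invariant_to_row_permutation(rng):
    df = _long_cohort(rng, slope_declining=0.6, noise=0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = longitudinal_change(df, "y", group_order=("stable", "declining"))
        b = longitudinal_change(
            df.sample(frac=1.0, random_state=5), "y", group_order=("stable", "declining")
        )
    pd.testing.assert_frame_equal(a, b, atol=1e-6, rtol=1e-5)


# --------------------------------------------------------- partial correlation
def test_partial_correlation_identity(rng):
    x = rng.normal(size=60)
    cov = pd.DataFrame({"age": rng.normal(size=60), "sex": rng.integers(0, 2, 60)})
    r, p = partial_correlation(x, x, cov)
    assert r == pytest.approx(1.0)
    assert p == 0.0


def test_partial_matches_plain_with_orthogonal_covariates(rng):
    n = 500
    x = rng.standard_normal(n)
    y = 0.4 * x + rng.standard_normal(n)
    cov = rng.standard_normal((n, 3))  # independent of both
    r_partial, _ = partial_correlation(x, y, cov)
    r_plain = np.corrcoef(x, y)[0, 1]
    assert r_partial == pytest.approx(r_plain, abs=0.02)


def test_partial_null_is_centred(rng):
    rs = []
    for _ in range(200):
        z = rng.standard_normal(50)
        x = 0.5 * z + rng.standard_normal(50)
        y = 0.5 * z + rng.standard_normal(50)
        r, _ = partial_correlation(x, y, z)
        rs.append(r)
    assert abs(np.mean(rs)) < 0.05


def test_partial_correlation_against_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    n = 80
    df = pd.DataFrame(
        {
            "x": rng.standard_normal(n),
            "y": rng.standard_normal(n),
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n),
        }
    )
    df["y"] += 0.5 * df["x"] + 0.3 * df["a"]
    r, p = partial_correlation(df.x, df.y, df[["a", "b"]])
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_partial_correlation_degenerate_inputs(rng):
    x = rng.normal(size=30)
    c = rng.normal(size=30)
    with pytest.raises(DynreconfError):
        partial_correlation(x, c.copy(), c)  # y fully explained by the covariate
    with pytest.raises(DynreconfError):
        partial_correlation(x[:4], x[:4], np.ones((4, 3)))


# ------------------------------------------------------------------ ladder
def _fake_compare_factory(p_by_outcome):
    def fake(df, outcome, covariates=None, divisor=1, **kw):
        p = p_by_outcome[outcome.split("_")[0]]
        return GroupComparison(
            outcome=outcome,
            omnibus_stat=1.0,
            omnibus_df=(3.0, 100.0),
            p_raw=p,
            p_adjusted=bonferroni(p, divisor),
            divisor=divisor,
            contrasts=pd.DataFrame(),
        )

    return fake


def _metric_tables():
    glob = pd.DataFrame({"promiscuity": [0.0], "flexibility": [0.0],
                         "cohesion": [0.0], "disjointedness": [0.0]})
    nets = pd.DataFrame({f"{m}@{n}": [0.0] for m in ("cohesion", "promiscuity")
                         for n in ("DMN", "FPN")})
    return glob, nets


def test_ladder_gates_stage2_on_flexibility():
    glob, nets = _metric_tables()
    # flexibility not significant after its divisor-2 correction -> no stage 2
    fake = _fake_compare_factory(
        {"promiscuity": 0.5, "flexibility": 0.04, "cohesion": 0.001, "disjointedness": 0.5}
    )
    res = run_test_ladder(glob, glob, network_metrics=nets, compare=fake)
    assert not res.gates["stage2"]
    assert set(res.table["stage"]) == {1}


def test_ladder_runs_stage2_and_descends_to_networks():
    glob, nets = _metric_tables()
    fake = _fake_compare_factory(
        {"promiscuity": 0.9, "flexibility": 0.001, "cohesion": 0.002, "disjointedness": 0.9}
    )
    res = run_test_ladder(glob, glob, network_metrics=nets, compare=fake)
    assert res.gates["stage2"]
    stage2 = res.table[res.table.stage == 2]
    assert set(stage2["outcome"]) == {"cohesion", "disjointedness"}
    stage3 = res.table[res.table.stage == 3]
    # only cohesion survived stage 2, so only its networks are tested (divisor 7)
    assert set(o.split("_")[0] for o in stage3["outcome"]) == {"cohesion"}
    assert np.allclose(stage3["p_adjusted"], np.minimum(1.0, stage3["p_raw"] * 7))
    # flexibility itself is replaced by its differentiation at stage 3
    assert "flexibility" not in {o.split("_")[0] for o in stage3["outcome"]}


def test_ladder_adjusted_p_never_below_raw():
    glob, nets = _metric_tables()
    fake = _fake_compare_factory(
        {"promiscuity": 0.01, "flexibility": 0.01, "cohesion": 0.01, "disjointedness": 0.01}
    )
    res = run_test_ladder(glob, glob, network_metrics=nets, compare=fake)
    assert np.all(res.table["p_adjusted"] >= res.table["p_raw"])
    assert np.all(res.table["p_adjusted"] <= 1.0)
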