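import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronode import (
    CountExperiment,
    SimulationConfig,
    TreatDE,
    bh_adjust,
    call_targets,
    estimate_dispersions,
    generate_counts,
    tmm_factors,
    treat_test,
)
from chronode.detest import expression_floor
from conftest import make_experiment
from oracles import bh_stepup


@pytest.fixture(scope="module")
def null_poisson():
    cfg = SimulationConfig(
        n_genes=2000, seed=10, dispersion=0.0, archetype_fractions={"null": 1.0},
        baseline_log2cpm_range=(3.0, 8.0),
    )
    experiment, _ = generate_counts(cfg)
    return experiment


@pytest.fixture(scope="module")
def null_nb():
    cfg = SimulationConfig(
        n_genes=2000, seed=11, dispersion=0.2, archetype_fractions={"null": 1.0},
        baseline_log2cpm_range=(3.0, 8.0),
    )
    experiment, _ = generate_counts(cfg)
    return experiment


# ---------------------------------------------------------------------------
# dispersion estimation


def test_common_dispersion_near_zero_for_poisson_data(null_poisson):
    fac = tmm_factors(null_poisson)
    disp = estimate_dispersions(null_poisson, fac)
    assert disp.common < 0.05


def test_common_dispersion_recovers_planted_value(null_nb):
    fac = tmm_factors(null_nb)
    disp = estimate_dispersions(null_nb, fac)
    assert 0.15 <= disp.common <= 0.25


def test_tagwise_shrinks_toward_common(null_nb):
    fac = tmm_factors(null_nb)
    weak = estimate_dispersions(null_nb, fac, prior_df=1.0)
    strong = estimate_dispersions(null_nb, fac, prior_df=200.0)
    spread_weak = np.log(weak.tagwise / weak.common).abs().median()
    spread_strong = np.log(strong.tagwise / strong.common).abs().median()
    assert spread_strong < spread_weak


def test_single_replicate_rejected():
    counts = np.random.default_rng(0).poisson(50, size=(20, 8))
    exp = make_experiment(counts, n_rep=1)
    fac = tmm_factors(exp)
    with pytest.raises(ValueError, match="replicates"):
        estimate_dispersions(exp, fac)


# ---------------------------------------------------------------------------
# TREAT threshold test


def balanced_experiment(y_treated: int, y_control: int, n_filler: int = 200):
    """One test gene (first row) with the given per-arm counts on a large
    constant filler background, so normalization cannot absorb the contrast."""
    counts = np.full((n_filler + 1, 24), 100, dtype=int)
    template = make_experiment(counts)
    arm = template.design["arm"].to_numpy()
    counts[0, arm == "treated"] = y_treated
    counts[0, arm == "control"] = y_control
    return make_experiment(counts)


def test_p_is_one_at_zero_log2fc():
    exp = balanced_experiment(50, 50)
    fac = tmm_factors(exp)
    disp = estimate_dispersions(exp, fac)
    res = treat_test(exp, fac, disp, 4, tau=1.5)
    assert np.allclose(res["log2FC"], 0.0)
    assert np.allclose(res["p"], 1.0)


def test_tau_to_one_limit_recovers_two_sided_wald():
    exp = balanced_experiment(120, 50)
    fac = tmm_factors(exp)
    disp = estimate_dispersions(exp, fac)
    res = treat_test(exp, fac, disp, 4, tau=1.0 + 1e-12)
    # reconstruct the two-sided Wald p from the reported statistic
    from scipy.stats import norm

    eff = fac.effective
    t_cols = exp.samples_at(4, "treated")
    c_cols = exp.samples_at(4, "control")
    phi = disp.tagwise.to_numpy()
    rate_t = (exp.counts[t_cols].sum(axis=1).to_numpy() + 0.5) / eff[t_cols].sum()
    rate_c = (exp.counts[c_cols].sum(axis=1).to_numpy() + 0.5) / eff[c_cols].sum()
    mu_t = rate_t[:, None] * eff[t_cols].to_numpy()
    mu_c = rate_c[:, None] * eff[c_cols].to_numpy()
    info_t = (mu_t / (1 + phi[:, None] * mu_t)).sum(axis=1)
    info_c = (mu_c / (1 + phi[:, None] * mu_c)).sum(axis=1)
    se = np.sqrt(1 / info_t + 1 / info_c) / np.log(2)
    expected = 2 * norm.sf(np.abs(res["log2FC"]) / se)
    assert np.allclose(res["p"], expected, rtol=1e-6)


def test_p_monotone_in_effect_size():
    """Larger |log2FC| at fixed depth gives smaller TREAT p."""
    ps = []
    for y_treated in (60, 100, 200, 400):
        exp = balanced_experiment(y_treated, 50)
        fac = tmm_factors(exp)
        disp = estimate_dispersions(exp, fac)
        ps.append(treat_test(exp, fac, disp, 4, tau=1.5)["p"].iloc[0])
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_interior_of_null_region_keeps_p_above_half():
    exp = balanced_experiment(60, 50)  # |FC| = 1.2 < tau
    fac = tmm_factors(exp)
    disp = estimate_dispersions(exp, fac)
    res = treat_test(exp, fac, disp, 4, tau=1.5)
    assert (res["p"] >= 0.5).all()


def test_null_simulation_type_i_error(null_nb):
    """All-null NB data: raw p < 0.05 at most at the nominal rate (conservative)."""
    fac = tmm_factors(null_nb)
    disp = estimate_dispersions(null_nb, fac)
    res = treat_test(null_nb, fac, disp, 4, tau=1.5)
    frac = (res["p"] < 0.05).mean()
    mc_se = np.sqrt(0.05 * 0.95 / len(res))
    assert frac <= 0.05 + 3 * mc_se


def test_power_simulation_strong_effect():
    """Planted log2FC = 3 at CPM ~100, phi = 0.1: p < 0.01 for >= 95% of genes."""
    fractions = {"null": 0.8, "direct_up": 0.2}
    cfg = SimulationConfig(
        n_genes=1500, seed=12, dispersion=0.1, archetype_fractions=fractions,
        effect_log2_range=(3.0, 3.0), baseline_log2cpm_range=(6.6, 6.7),
    )
    experiment, truth = generate_counts(cfg)
    fac = tmm_factors(experiment)
    disp = estimate_dispersions(experiment, fac)
    planted = truth.index[(truth["archetype"] == "direct_up") & (truth["onset_h"] <= 8)]
    res = treat_test(experiment, fac, disp, 8, tau=2.0).set_index("gene")
    assert (res.loc[planted, "p"] < 0.01).mean() >= 0.95


def test_arm_swap_negates_log2fc_and_keeps_p(small_dataset):
    _, experiment, _ = small_dataset
    fac = tmm_factors(experiment)
    disp = estimate_dispersions(experiment, fac)
    res = treat_test(experiment, fac, disp, 24, tau=2.0)
    swapped_design = experiment.design.copy()
    swapped_design["arm"] = swapped_design["arm"].map(
        {"treated": "control", "control": "treated"}
    )
    swapped = CountExperiment(experiment.counts, swapped_design)
    res_sw = treat_test(swapped, fac, disp, 24, tau=2.0)
    assert np.allclose(res["log2FC"], -res_sw["log2FC"])
    assert np.allclose(res["p"], res_sw["p"])


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_example():
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_degenerate_cases():
    assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
    assert bh_adjust([0.037]).tolist() == [0.037]
    out = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()
    with pytest.raises(ValueError):
        bh_adjust([1.5])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_stepup_oracle(p):
    assert np.allclose(bh_adjust(p), bh_stepup(p), rtol=1e-12, atol=1e-12)


# ---------------------------------------------------------------------------
# target calling


def test_floor_rule_excludes_low_expression_hits():
    de = pd.DataFrame(
        {"gene": ["g1", "g2"], "time_h": [24, 8], "fdr": [0.01, 0.04]}
    )
    floor = pd.Series({"g1": 10.0, "g2": 200.0})
    sets, union = call_targets(de, floor, alpha=0.05, cpm_floor=25.0)
    assert sets == {24: set(), 8: {"g2"}}
    assert union == ["g2"]


def test_call_targets_matches_enumeration_oracle():
    rng = np.random.default_rng(13)
    genes = [f"g{i}" for i in range(50)]
    rows = []
    for t in (4, 8, 24, 48):
        for g in genes:
            rows.append({"gene": g, "time_h": t, "fdr": rng.uniform(0, 0.2)})
    de = pd.DataFrame(rows)
    floor = pd.Series(rng.uniform(0, 50, size=50), index=genes)
    sets, union = call_targets(de, floor, alpha=0.05, cpm_floor=25.0)
    expected_union = set()
    for t in (4, 8, 24, 48):
        expected = {
            r["gene"]
            for _, r in de[de["time_h"] == t].iterrows()
            if r["fdr"] < 0.05 and floor[r["gene"]] > 25.0
        }
        assert sets[t] == expected
        expected_union |= expected
    assert set(union) == expected_union


def test_fdr_never_below_p_within_time_point(small_dataset):
    _, experiment, _ = small_dataset
    results = TreatDE(experiment).fit()
    assert (results.table["fdr"] >= results.table["p"] - 1e-12).all()
    # summary renders and reports the union size
    assert f"union of target genes: {len(results.targets)}" in results.summary()


def test_expression_floor_is_sum_of_per_time_means(small_dataset):
    _, experiment, _ = small_dataset
    fac = tmm_factors(experiment)
    from chronode import cpm

    floor = expression_floor(experiment, fac)
    mat = cpm(experiment, fac)
    gene = experiment.genes[0]
    expected = sum(
        mat.loc[gene, experiment.samples_at(t)].mean() for t in (4, 8, 24, 48)
    )
    assert floor[gene] == pytest.approx(expected)
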