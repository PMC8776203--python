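import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from chronode import (
    TreatDE,
    axis_contingency,
    cpm,
    kmeans_cluster,
    label_clusters,
    standardize,
    tmm_factors,
)
from chronode.trajcluster import StandardizedTrajectories
from oracles import best_bipartition_wcss, fisher_two_sided


def as_trajectories(x: np.ndarray) -> StandardizedTrajectories:
    cols = pd.MultiIndex.from_product([(4, 8, 24, 48), ("control", "treated")],
                                      names=["time_h", "arm"])
    genes = pd.Index([f"g{i}" for i in range(x.shape[0])], name="gene")
    df = pd.DataFrame(x, index=genes, columns=cols)
    return StandardizedTrajectories(
        values=df, mean=pd.Series(0.0, index=genes), sd=pd.Series(1.0, index=genes),
        excluded=[],
    )


# ---------------------------------------------------------------------------
# standardization


def test_standardize_rows_have_zero_mean_unit_sd(small_dataset):
    _, experiment, _ = small_dataset
    fac = tmm_factors(experiment)
    traj = standardize(cpm(experiment, fac, log2=True), experiment.design)
    z = traj.values.to_numpy()
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(z.std(axis=1), 1.0, atol=1e-6)
    assert traj.values.shape[1] == 8  # 4 time points x 2 arms


def test_standardize_location_and_scale_invariance(small_dataset):
    _, experiment, _ = small_dataset
    fac = tmm_factors(experiment)
    log2cpm = cpm(experiment, fac, log2=True)
    base = standardize(log2cpm, experiment.design)
    shifted = standardize(log2cpm + 3.0, experiment.design)
    scaled = standardize(log2cpm * 5.0, experiment.design)
    assert np.allclose(base.values, shifted.values, atol=1e-9)
    assert np.allclose(base.values, scaled.values, atol=1e-9)


def test_standardize_excludes_constant_rows():
    design = pd.DataFrame(
        {
            "time_h": [4, 4, 8, 8],
            "arm": ["control", "treated", "control", "treated"],
            "replicate": [1, 1, 1, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    log2cpm = pd.DataFrame(
        {"s1": [1.0, 2.0], "s2": [1.0, 3.0], "s3": [1.0, 4.0], "s4": [1.0, 5.0]},
        index=pd.Index(["flat", "varies"], name="gene"),
    )
    with pytest.warns(UserWarning, match="constant-profile"):
        traj = standardize(log2cpm, design)
    assert traj.excluded == ["flat"]
    assert list(traj.values.index) == ["varies"]


# ---------------------------------------------------------------------------
# k-means


def test_k1_centroid_is_column_mean():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(20, 8))
    traj = as_trajectories(x)
    res = kmeans_cluster(traj, k=1, seed=0)
    assert np.allclose(res.centroids.to_numpy()[0], x.mean(axis=0))
    assert (res.assignments == 0).all()


def test_separated_blobs_recovered_exactly():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 0.1, size=(30, 8))
    b = rng.normal(10, 0.1, size=(25, 8))
    traj = as_trajectories(np.vstack([a, b]))
    res = kmeans_cluster(traj, k=2, seed=0)
    labels = res.assignments.to_numpy()
    assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
    assert labels[0] != labels[-1]


def test_wcss_equals_exhaustive_bipartition_minimum():
    """8 points, k = 2: the restarted k-means solution attains the global WCSS."""
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 8))
        traj = as_trajectories(x)
        res = kmeans_cluster(traj, k=2, n_restarts=200, seed=seed)
        assert res.wcss == pytest.approx(best_bipartition_wcss(x), rel=1e-9)


def test_restart_monotonicity():
    rng = np.random.default_rng(3)
    x = np.vstack([rng.normal(i, 1.0, size=(10, 8)) for i in range(4)])
    traj = as_trajectories(x)
    best_many = kmeans_cluster(traj, k=4, n_restarts=25, seed=0).wcss
    singles = [kmeans_cluster(traj, k=4, n_restarts=1, seed=s).wcss for s in range(5)]
    assert best_many <= min(singles) + 1e-9


def test_k_larger_than_n_genes_errors():
    traj = as_trajectories(np.random.default_rng(0).normal(size=(3, 8)))
    with pytest.raises(ValueError, match="exceeds"):
        kmeans_cluster(traj, k=4)


# ---------------------------------------------------------------------------
# cluster labeling


def centroid_frame(rows: list[list[float]]) -> pd.DataFrame:
    cols = pd.MultiIndex.from_product([(4, 8, 24, 48), ("control", "treated")],
                                      names=["time_h", "arm"])
    df = pd.DataFrame(rows, columns=cols.sortlevel(0)[0])
    df.index.name = "cluster"
    return df


def test_label_treated_rise_is_direct_up():
    # columns: (4,c),(4,t),(8,c),(8,t),(24,c),(24,t),(48,c),(48,t)
    rows = [[0, 0, 0, 0.7, 0, 1.4, 0, 2.0]]
    labels = label_clusters(centroid_frame(rows))
    assert labels.loc[0, "mechanism"] == "direct"
    assert labels.loc[0, "direction"] == "up"


def test_label_control_rise_is_indirect_up():
    # control drifts up while treatment holds the gene flat
    rows = [[0, 0, 0.7, 0, 1.4, 0, 2.0, 0]]
    labels = label_clusters(centroid_frame(rows))
    assert labels.loc[0, "mechanism"] == "indirect"
    assert labels.loc[0, "direction"] == "up"  # reports the suppressed drift


def test_label_control_fall_is_indirect_down():
    rows = [[0, 0, -0.7, 0, -1.4, 0, -2.0, 0]]
    labels = label_clusters(centroid_frame(rows))
    assert labels.loc[0, "mechanism"] == "indirect"
    assert labels.loc[0, "direction"] == "down"


def test_label_tie_is_conservative_indirect():
    rows = [[0.0] * 8]
    with pytest.warns(UserWarning, match="tie"):
        labels = label_clusters(centroid_frame(rows))
    assert labels.loc[0, "mechanism"] == "indirect"


def test_labels_invariant_to_cluster_permutation():
    rows = [
        [0, 0, 0, 0.7, 0, 1.4, 0, 2.0],
        [0, 0, -0.7, 0, -1.4, 0, -2.0, 0],
    ]
    fwd = label_clusters(centroid_frame(rows))
    rev = label_clusters(centroid_frame(rows[::-1]))
    assert fwd.loc[0].tolist() == rev.loc[1].tolist()
    assert fwd.loc[1].tolist() == rev.loc[0].tolist()


# ---------------------------------------------------------------------------
# contingency analysis


@pytest.mark.parametrize(
    "table,expected_p",
    [
        ([[3, 1], [1, 3]], 0.4857),
        ([[10, 10], [10, 10]], 1.0),
        ([[5, 0], [0, 5]], 0.0079),
    ],
)
def test_fisher_reference_values(table, expected_p):
    assert fisher_exact(table)[1] == pytest.approx(expected_p, abs=5e-5)
    assert fisher_two_sided(table) == pytest.approx(expected_p, abs=5e-5)


def test_axis_contingency_reports_or_rr_and_excludes_mixed():
    cls = pd.DataFrame(
        {
            "direction": ["down"] * 20 + ["up"] * 20 + ["mixed"] * 5,
            "mechanism": ["indirect"] * 15 + ["direct"] * 5
            + ["indirect"] * 5 + ["direct"] * 15 + ["direct"] * 5,
        },
        index=[f"g{i}" for i in range(45)],
    )
    out = axis_contingency(cls, pairs=[("direction", "mechanism")])
    assert len(out) == 1
    row = out.iloc[0]
    assert row[["n00", "n01", "n10", "n11"]].sum() == 40  # mixed dropped
    table = [[row["n00"], row["n01"]], [row["n10"], row["n11"]]]
    assert row["p"] == pytest.approx(fisher_two_sided(table), rel=1e-9)
    # down genes are 3x as often indirect as up genes: the direct-rate RR is 1/3
    assert row["relative_risk"] == pytest.approx((5 / 20) / (15 / 20))
    assert 1.0 / row["relative_risk"] == pytest.approx(3.0)


def test_axis_contingency_haldane_correction_on_zero_cell():
    cls = pd.DataFrame(
        {
            "direction": ["down"] * 10 + ["up"] * 10,
            "mechanism": ["indirect"] * 10 + ["direct"] * 10,
        }
    )
    out = axis_contingency(cls, pairs=[("direction", "mechanism")])
    assert np.isfinite(out["odds_ratio"].iloc[0])


def test_axis_contingency_skips_degenerate_margin():
    cls = pd.DataFrame({"direction": ["down"] * 10, "mechanism": ["direct"] * 10})
    with pytest.warns(UserWarning, match="degenerate"):
        out = axis_contingency(cls, pairs=[("direction", "mechanism")])
    assert len(out) == 0


def test_mechanism_recovery_on_planted_mixture(strong_dataset):
    """Planted direct vs culture-driven genes get the right mechanism label."""
    _, experiment, truth = strong_dataset
    fac = tmm_factors(experiment)
    results = TreatDE(experiment, factors=fac).fit()
    traj = standardize(cpm(experiment, fac, log2=True), experiment.design,
                       genes=results.targets)
    res = kmeans_cluster(traj, k=4, n_restarts=25, seed=17)
    mech = res.assignments.map(res.labels["mechanism"])
    t = truth[truth["expected_target"]]
    common = mech.index.intersection(t.index)
    agree = (mech.loc[common] == t.loc[common, "expected_mechanism"]).mean()
    assert agree >= 0.8
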