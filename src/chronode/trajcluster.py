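"""Trajectory clustering: direct (treatment-driven) vs indirect (culture-driven) targets.

Target genes are clustered on their z-score standardized log2CPM profiles
over the 8 condition means (4 time points x 2 arms; replicates collapsed to
the condition mean so replicate noise does not dominate the shape).  k-means
(Lloyd's algorithm with k-means++ seeding, best of 25 restarts, up to 1000
iterations) recovers the canonical four clusters: directly up-/down-regulated
genes (treated arm moves, control flat) and genes whose control arm drifts
up/down while treatment stabilizes them (indirect targets).

Cluster labels are assigned automatically from the centroids: the arm with
the larger temporal range is the driving arm (treated -> direct, control ->
indirect), and the direction is the treated-vs-control offset for direct
clusters or the control-arm drift for indirect ones.

The module also provides the two-sided Fisher contingency analysis between
classification axes (e.g. direction x mechanism), with BH correction across
all tables of a run.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans

from .detest import bh_adjust
from .prep import CountExperiment

logger = logging.getLogger(__name__)


@dataclass
class StandardizedTrajectories:
    """Row-standardized condition-mean profiles plus the per-gene mean/SD used."""

    values: pd.DataFrame  # genes x (time_h, arm) MultiIndex columns
    mean: pd.Series
    sd: pd.Series
    excluded: list[str]  # constant-profile genes dropped


def standardize(
    log2cpm: pd.DataFrame,
    design: pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> StandardizedTrajectories:
    """Collapse replicates to (time, arm) means and z-score each gene's profile.

    Genes whose condition-mean profile is constant (zero variance) cannot be
    standardized; they are excluded with a warning.
    """
    if genes is not None:
        log2cpm = log2cpm.loc[list(genes)]
    cols = pd.MultiIndex.from_frame(design[["time_h", "arm"]])
    mat = log2cpm.copy()
    mat.columns = cols
    cond = mat.T.groupby(level=["time_h", "arm"]).mean().T
    cond = cond.sort_index(axis=1)
    mean = cond.mean(axis=1)
    sd = cond.std(axis=1, ddof=0)
    constant = sd <= 1e-12
    excluded = cond.index[constant].tolist()
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} constant-profile gene(s) from standardization",
            stacklevel=2,
        )
    keep = ~constant
    z = cond.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return StandardizedTrajectories(values=z, mean=mean[keep], sd=sd[keep], excluded=excluded)


@dataclass
class ClusterResult:
    """k-means partition of standardized trajectories with automatic labels."""

    k: int
    assignments: pd.Series  # gene -> cluster id (0-based)
    centroids: pd.DataFrame  # cluster x (time_h, arm)
    wcss: float
    labels: pd.DataFrame  # cluster -> mechanism, direction
    seed: int | None
    n_restarts: int

    def gene_mechanism(self) -> pd.Series:
        """Per-gene mechanism label inherited from the gene's cluster."""
        return self.assignments.map(self.labels["mechanism"])

    def gene_direction(self) -> pd.Series:
        return self.assignments.map(self.labels["direction"])


def kmeans_cluster(
    trajectories: StandardizedTrajectories,
    k: int = 4,
    n_restarts: int = 25,
    max_iter: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Best-of-``n_restarts`` k-means on the standardized profiles.

    Deterministic for a given seed.  Raises when k exceeds the number of
    genes (an empty cluster would be unavoidable).
    """
    z = trajectories.values
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({z.shape[0]})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(z.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=z.columns)
    centroids.index.name = "cluster"
    labels = label_clusters(centroids)
    return ClusterResult(
        k=k,
        assignments=pd.Series(km.labels_, index=z.index, name="cluster"),
        centroids=centroids,
        wcss=float(km.inertia_),
        labels=labels,
        seed=seed,
        n_restarts=n_restarts,
    )


def label_clusters(centroids: pd.DataFrame) -> pd.DataFrame:
    """Mechanism and direction per cluster, from the centroid's arm trajectories.

    The arm with the larger temporal range (max minus min over time) drives
    the cluster: treated -> direct, control -> indirect (ties are called
    indirect, conservatively, with a warning).  Direction is the sign of the
    treated-minus-control offset averaged over time points after the first
    (direct clusters), or of the control-arm drift relative to its first
    time point (indirect clusters — the drift that treatment suppresses).
    """
    rows = []
    times = sorted({t for t, _ in centroids.columns})
    for cl in centroids.index:
        treated = np.array([centroids.loc[cl, (t, "treated")] for t in times])
        control = np.array([centroids.loc[cl, (t, "control")] for t in times])
        range_t = treated.max() - treated.min()
        range_c = control.max() - control.min()
        if range_t > range_c:
            mechanism = "direct"
            signal = float(np.mean(treated[1:] - control[1:]))
        else:
            if range_t == range_c:
                warnings.warn(
                    f"cluster {cl}: treated and control ranges tie; labeled indirect",
                    stacklevel=2,
                )
            mechanism = "indirect"
            signal = float(np.mean(control[1:] - control[0]))
        rows.append(
            {"cluster": cl, "mechanism": mechanism, "direction": "up" if signal > 0 else "down"}
        )
    return pd.DataFrame(rows).set_index("cluster")


def axis_contingency(
    classification: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = (("direction", "mechanism"),),
    exclude: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """2x2 Fisher tables between pairs of binary classification axes.

    For each (axis_a, axis_b) pair the two most frequent levels of each axis
    form the table; levels listed in ``exclude`` (by default ``mixed`` on the
    direction axis) are dropped first.  Reports the two-sided Fisher exact p,
    the sample odds ratio (Haldane 0.5 correction when a cell is zero), the
    relative risk, and BH-corrected p across all tables of the call.
    Degenerate tables (an empty row or column) are skipped with a warning.
    """
    if exclude is None:
        exclude = {"direction": ["mixed"]}
    rows = []
    for axis_a, axis_b in pairs:
        df = classification[[axis_a, axis_b]].copy()
        for axis in (axis_a, axis_b):
            drop = set(exclude.get(axis, ()))
            df = df[~df[axis].isin(drop)]
        lev_a = df[axis_a].value_counts().index[:2].tolist()
        lev_b = df[axis_b].value_counts().index[:2].tolist()
        if len(lev_a) < 2 or len(lev_b) < 2:
            warnings.warn(
                f"contingency {axis_a} x {axis_b}: degenerate margin, skipped", stacklevel=2
            )
            continue
        lev_a, lev_b = sorted(lev_a), sorted(lev_b)
        tab = np.array(
            [
                [int(((df[axis_a] == a) & (df[axis_b] == b)).sum()) for b in lev_b]
                for a in lev_a
            ]
        )
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            warnings.warn(
                f"contingency {axis_a} x {axis_b}: degenerate margin, skipped", stacklevel=2
            )
            continue
        _, p = fisher_exact(tab, alternative="two-sided")
        a, b, c, d = tab.ravel().astype(float)
        if min(a, b, c, d) == 0:
            a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a2, b2, c2, d2 = a, b, c, d
        odds = (a2 * d2) / (b2 * c2)
        rr = (a / (a + b)) / (c / (c + d))
        rows.append(
            {
                "axis_a": axis_a,
                "axis_b": axis_b,
                "levels_a": "|".join(lev_a),
                "levels_b": "|".join(lev_b),
                "n00": int(tab[0, 0]),
                "n01": int(tab[0, 1]),
                "n10": int(tab[1, 0]),
                "n11": int(tab[1, 1]),
                "odds_ratio": odds,
                "relative_risk": rr,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "axis_a", "axis_b", "levels_a", "levels_b",
            "n00", "n01", "n10", "n11", "odds_ratio", "relative_risk", "p",
        ],
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out
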