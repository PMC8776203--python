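"""Negative-binomial differential expression against a fold-change threshold.

Model
-----
Counts for gene g in sample i follow NB(mu_gi, phi_g) with
Var = mu + phi * mu**2 and mu_gi = r_{g,c(i)} * N_i, where c(i) is the
(time, arm) group of sample i, N_i its effective (TMM-scaled) library size
and r the group expression rate.

Dispersion is estimated in two stages on a log-spaced grid:

* a **common** dispersion maximizing the across-gene mean of the Cox–Reid
  adjusted profile likelihood (APL; the adjustment is -0.5 log det of the
  Fisher information of the fitted group means, correcting the downward
  bias of plugging in estimated means);
* **tagwise** dispersions by weighted-likelihood shrinkage: each gene
  maximizes its own APL plus ``prior_df`` times the across-gene mean APL,
  pulling poorly informed genes toward the common value.

The per-time-point test is a Wald analogue of the threshold test (TREAT):
the null is |log2FC| <= log2(tau), and the p-value is the sum of the upper
tails of the Wald statistic at the two boundary nulls,

    p = min(1, Q((|L| - c)/se) + Q((|L| + c)/se)),   c = log2(tau),

with Q the standard normal survival function.  At tau -> 1 this is the
ordinary two-sided Wald test; for |L| <= c it is >= 0.5 by construction, and
at L = 0 it is exactly 1.  Standard errors come from the NB Fisher
information of the two group log-rates with the tagwise dispersion.

Significance follows the two-part rule used for time-course target calling:
BH-adjusted p (per time point) below alpha, plus an expression floor — the
sum over time points of the cross-arm mean CPM must exceed ``cpm_floor``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .prep import CountExperiment, NormFactors, cpm, tmm_factors

logger = logging.getLogger(__name__)

DEFAULT_TAUS = {4: 1.5, 8: 1.5, 24: 2.0, 48: 2.0}

_GRID = np.concatenate([[1e-6], np.logspace(-4.0, 1.0, 41)])


@dataclass
class DispersionEstimate:
    """Common and tagwise NB dispersions plus the shrinkage prior df."""

    common: float
    tagwise: pd.Series
    prior_df: float

    def __post_init__(self) -> None:
        if self.common < 0 or (self.tagwise < 0).any():
            raise ValueError("dispersions must be >= 0")
        if not np.isfinite(self.tagwise.to_numpy()).all():
            raise ValueError("tagwise dispersions must be finite")


# ---------------------------------------------------------------------------
# likelihood machinery


def _group_indicator(group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    ind = np.zeros((group_idx.size, n_groups))
    ind[np.arange(group_idx.size), group_idx] = 1.0
    return ind


def _fit_group_rates(
    y: np.ndarray,
    offsets: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    phi: np.ndarray | float,
    n_iter: int = 12,
) -> np.ndarray:
    """NB maximum-likelihood group rates (genes x groups), Fisher scoring on log-rate."""
    ind = _group_indicator(group_idx, n_groups)
    tot_n = offsets @ ind
    r = np.maximum((y @ ind) / tot_n, 1e-12)
    phi = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float))[:, None], y.shape) \
        if np.ndim(phi) > 0 else np.full_like(y, float(phi), dtype=float)
    for _ in range(n_iter):
        mu = r[:, group_idx] * offsets
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom) @ ind
        info = (mu / denom) @ ind
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        r = np.maximum(r * np.exp(step), 1e-12)
        if np.abs(step).max() < 1e-10:
            break
    return r


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; Poisson branch for tiny phi."""
    if phi < 1e-8:
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        k = 1.0 / phi
        ll = (
            gammaln(y + k)
            - gammaln(k)
            - gammaln(y + 1.0)
            + k * np.log(k / (k + mu))
            + y * np.log(mu / (k + mu))
        )
    return ll.sum(axis=1)


def _adjusted_profile_loglik(
    y: np.ndarray,
    offsets: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    phi: float,
) -> np.ndarray:
    """Cox–Reid adjusted profile log-likelihood of phi, per gene."""
    r = _fit_group_rates(y, offsets, group_idx, n_groups, phi)
    mu = r[:, group_idx] * offsets
    ll = _nb_loglik(y, mu, phi)
    ind = _group_indicator(group_idx, n_groups)
    info = (mu / (1.0 + phi * mu)) @ ind
    cr = 0.5 * np.log(np.maximum(info, 1e-300)).sum(axis=1)
    return ll - cr


def _interp_argmax(log_grid: np.ndarray, values: np.ndarray) -> float:
    """Grid argmax with parabolic refinement in log-dispersion space."""
    j = int(np.argmax(values))
    if j == 0 or j == len(log_grid) - 1:
        return float(np.exp(log_grid[j]))
    x0, x1, x2 = log_grid[j - 1 : j + 2]
    y0, y1, y2 = values[j - 1 : j + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if denom >= -1e-12:  # not concave; keep grid point
        return float(np.exp(x1))
    x = x1 + 0.5 * (y0 - y2) / denom * (x1 - x0)
    x = float(np.clip(x, x0, x2))
    return float(np.exp(x))


def estimate_dispersions(
    experiment: CountExperiment,
    factors: NormFactors,
    prior_df: float = 10.0,
    grid: Sequence[float] | None = None,
) -> DispersionEstimate:
    """Common + weighted-likelihood-shrunk tagwise NB dispersions.

    Requires at least two replicates in every (time, arm) group — with a
    single replicate the group mean saturates the data and the dispersion
    is unidentifiable.
    """
    sizes = experiment.group_sizes()
    if (sizes < 2).any():
        raise ValueError("dispersion estimation requires >= 2 replicates per (time, arm) group")
    grid_arr = _GRID if grid is None else np.asarray(grid, dtype=float)
    y = experiment.counts.to_numpy(dtype=float)
    offsets = factors.effective.reindex(experiment.samples).to_numpy(dtype=float)
    groups = experiment.design.groupby(["time_h", "arm"], observed=True, sort=True).ngroup()
    group_idx = groups.to_numpy()
    n_groups = int(group_idx.max()) + 1
    apl = np.column_stack(
        [_adjusted_profile_loglik(y, offsets, group_idx, n_groups, p) for p in grid_arr]
    )
    mean_apl = apl.mean(axis=0)
    log_grid = np.log(grid_arr)
    common = _interp_argmax(log_grid, mean_apl)
    score = apl + prior_df * mean_apl[None, :]
    tagwise = np.array([_interp_argmax(log_grid, score[g]) for g in range(y.shape[0])])
    logger.info("common dispersion %.4g (grid %d points)", common, grid_arr.size)
    return DispersionEstimate(
        common=common,
        tagwise=pd.Series(tagwise, index=experiment.genes),
        prior_df=prior_df,
    )


# ---------------------------------------------------------------------------
# TREAT-style threshold test


def treat_test(
    experiment: CountExperiment,
    factors: NormFactors,
    dispersions: DispersionEstimate,
    time_h: int,
    tau: float,
) -> pd.DataFrame:
    """Per-gene threshold Wald test treated-vs-control at one time point.

    Returns a DataFrame with columns gene, time_h, log2FC, logCPM, p, tau.
    log2FC is the log-ratio of offset-adjusted group mean rates with a 0.5
    count guard per group; the guard enters the reported fold change and the
    Wald plug-in rates, not any likelihood.
    """
    if tau <= 1.0:
        raise ValueError("tau must be > 1")
    design = experiment.design
    treated = design.index[(design["time_h"] == time_h) & (design["arm"] == "treated")]
    control = design.index[(design["time_h"] == time_h) & (design["arm"] == "control")]
    if len(treated) == 0 or len(control) == 0:
        raise ValueError(f"time point {time_h} h is missing an arm")
    eff = factors.effective
    y_t = experiment.counts[treated].to_numpy(dtype=float)
    y_c = experiment.counts[control].to_numpy(dtype=float)
    n_t = eff[treated].to_numpy(dtype=float)
    n_c = eff[control].to_numpy(dtype=float)
    rate_t = (y_t.sum(axis=1) + 0.5) / n_t.sum()
    rate_c = (y_c.sum(axis=1) + 0.5) / n_c.sum()
    log2fc = np.log2(rate_t / rate_c)

    phi = dispersions.tagwise.reindex(experiment.genes).to_numpy()
    mu_t = rate_t[:, None] * n_t
    mu_c = rate_c[:, None] * n_c
    info_t = (mu_t / (1.0 + phi[:, None] * mu_t)).sum(axis=1)
    info_c = (mu_c / (1.0 + phi[:, None] * mu_c)).sum(axis=1)
    se = np.sqrt(1.0 / info_t + 1.0 / info_c) / np.log(2.0)

    c = np.log2(tau)
    absl = np.abs(log2fc)
    p = np.minimum(1.0, norm.sf((absl - c) / se) + norm.sf((absl + c) / se))

    at_time = design.index[design["time_h"] == time_h]
    log2cpm_t = cpm(experiment, factors, log2=True)[at_time].mean(axis=1)
    return pd.DataFrame(
        {
            "gene": experiment.genes,
            "time_h": time_h,
            "log2FC": log2fc,
            "logCPM": log2cpm_t.to_numpy(),
            "p": p,
            "tau": tau,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR; NaNs propagate and are excluded from ranking."""
    p_arr = np.asarray(p, dtype=float)
    ok = ~np.isnan(p_arr)
    if ((p_arr[ok] < 0) | (p_arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p_arr.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p_arr[ok], method="fdr_bh")[1]
    return out


def expression_floor(
    experiment: CountExperiment, factors: NormFactors
) -> pd.Series:
    """Per-gene floor statistic: sum over time points of cross-arm mean CPM."""
    cpm_mat = cpm(experiment, factors, log2=False)
    design = experiment.design
    total = pd.Series(0.0, index=experiment.genes)
    for t in experiment.time_points:
        cols = design.index[design["time_h"] == t]
        total += cpm_mat[cols].mean(axis=1)
    return total


def call_targets(
    de_table: pd.DataFrame,
    floor_stat: pd.Series,
    alpha: float = 0.05,
    cpm_floor: float = 25.0,
) -> tuple[dict[int, set[str]], list[str]]:
    """Per-time significant gene sets and their union (the target catalogue).

    A gene is significant at time t iff FDR_t < alpha and its summed
    mean-CPM floor statistic exceeds ``cpm_floor``.
    """
    passed = floor_stat > cpm_floor
    sets: dict[int, set[str]] = {}
    for t, sub in de_table.groupby("time_h"):
        sig = sub.loc[(sub["fdr"] < alpha) & sub["gene"].map(passed).fillna(False), "gene"]
        sets[int(t)] = set(sig)
    union = sorted(set().union(*sets.values())) if sets else []
    return sets, union


# ---------------------------------------------------------------------------
# model / results


class TreatDE:
    """Threshold differential-expression model for a two-arm time course.

    Parameters
    ----------
    experiment
        Filtered :class:`~chronode.prep.CountExperiment`.
    taus
        Fold-change thresholds per time point; defaults to 1.5 at 4/8 h and
        2.0 at 24/48 h (any time point missing from the mapping gets 1.5).
    factors
        TMM factors; computed from the experiment when omitted.

    Examples
    --------
    >>> model = TreatDE(experiment)                      # doctest: +SKIP
    >>> res = model.fit()                                # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(
        self,
        experiment: CountExperiment,
        taus: Mapping[int, float] | None = None,
        factors: NormFactors | None = None,
    ) -> None:
        self.experiment = experiment
        self.factors = factors if factors is not None else tmm_factors(experiment)
        if taus is None:
            taus = {t: DEFAULT_TAUS.get(t, 1.5) for t in experiment.time_points}
        self.taus = dict(taus)
        missing = set(experiment.time_points) - set(self.taus)
        if missing:
            raise ValueError(f"no fold-change threshold for time point(s) {sorted(missing)}")

    @classmethod
    def from_files(cls, counts_path, design_path, **kwargs) -> "TreatDE":
        from .prep import read_experiment

        return cls(read_experiment(counts_path, design_path), **kwargs)

    def fit(
        self,
        prior_df: float = 10.0,
        alpha: float = 0.05,
        cpm_floor: float = 25.0,
        dispersions: DispersionEstimate | None = None,
    ) -> "TreatDEResults":
        if dispersions is None:
            dispersions = estimate_dispersions(self.experiment, self.factors, prior_df=prior_df)
        frames = []
        for t in self.experiment.time_points:
            frame = treat_test(self.experiment, self.factors, dispersions, t, self.taus[t])
            frame["fdr"] = bh_adjust(frame["p"].to_numpy())  # BH within each time point
            frames.append(frame)
        table = pd.concat(frames, ignore_index=True)
        floor_stat = expression_floor(self.experiment, self.factors)
        sets, union = call_targets(table, floor_stat, alpha=alpha, cpm_floor=cpm_floor)
        sig = np.zeros(len(table), dtype=bool)
        for t, genes in sets.items():
            sig |= (table["time_h"] == t).to_numpy() & table["gene"].isin(genes).to_numpy()
        table["significant"] = sig
        return TreatDEResults(
            model=self,
            table=table,
            dispersions=dispersions,
            floor_stat=floor_stat,
            significant_sets=sets,
            targets=union,
            alpha=alpha,
            cpm_floor=cpm_floor,
        )


@dataclass
class TreatDEResults:
    """Fitted threshold-DE results: tidy per-gene-per-time table plus target calls."""

    model: TreatDE
    table: pd.DataFrame
    dispersions: DispersionEstimate
    floor_stat: pd.Series
    significant_sets: dict[int, set[str]]
    targets: list[str]
    alpha: float
    cpm_floor: float

    def log2fc_matrix(self) -> pd.DataFrame:
        """Genes x time points matrix of log2 fold changes."""
        return self.table.pivot(index="gene", columns="time_h", values="log2FC")

    def significant_times(self) -> dict[str, set[int]]:
        """Per target gene, the set of time points at which it is significant."""
        out: dict[str, set[int]] = {g: set() for g in self.targets}
        for t, genes in self.significant_sets.items():
            for g in genes:
                out[g].add(t)
        return out

    def summary(self) -> str:
        lines = [
            "Threshold differential expression (treated vs control)",
            f"  genes tested: {self.model.experiment.n_genes}"
            f"   common dispersion: {self.dispersions.common:.4f}",
            f"  alpha: {self.alpha}   CPM floor: {self.cpm_floor}",
            "  time_h   tau   significant      up    down",
        ]
        for t in self.model.experiment.time_points:
            genes = self.significant_sets.get(t, set())
            sub = self.table[(self.table["time_h"] == t) & self.table["gene"].isin(genes)]
            n_up = int((sub["log2FC"] > 0).sum())
            n_down = int((sub["log2FC"] < 0).sum())
            lines.append(
                f"  {t:>6}  {self.model.taus[t]:>4}   {len(genes):>11}  {n_up:>6}  {n_down:>6}"
            )
        lines.append(f"  union of target genes: {len(self.targets)}")
        return "\n".join(lines)
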