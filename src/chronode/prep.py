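"""Count-experiment container, low-expression filtering, TMM normalization, CPM and MDS.

The container couples a genes x samples integer count matrix with a sample
design table (time point in hours, arm, replicate).  Everything downstream —
dispersion estimation, the fold-change-threshold test, trajectory clustering —
consumes this pair.

Normalization follows the trimmed-mean-of-M-values (TMM) scheme: per-sample
scaling factors computed from doubly trimmed, precision-weighted log-ratios
against a reference sample, renormalized to geometric mean one.  Expression is
reported as counts per million (CPM) over effective library sizes, optionally
log2 with a library-size-scaled prior count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

ARMS = ("control", "treated")


@dataclass
class CountExperiment:
    """Integer count matrix (genes x samples) plus the sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, non-negative
        integers.
    design
        DataFrame indexed by sample id with columns ``time_h`` (int),
        ``arm`` (``"treated"`` or ``"control"``) and ``replicate`` (int).
        Sample order must match the count columns.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("design rows must match count columns (same order)")
        for col in ("time_h", "arm", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design is missing required column {col!r}")
        bad_arms = set(self.design["arm"]) - set(ARMS)
        if bad_arms:
            raise ValueError(f"unknown arm labels: {sorted(bad_arms)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        if self.design.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")

    # -- convenience ---------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    @property
    def time_points(self) -> list[int]:
        return sorted(self.design["time_h"].unique())

    def group_sizes(self) -> pd.Series:
        """Replicate count per (time_h, arm) cell."""
        return self.design.groupby(["time_h", "arm"], observed=True).size()

    def subset_genes(self, genes: Sequence[str]) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(genes)], self.design)

    def samples_at(self, time_h: int, arm: str | None = None) -> pd.Index:
        mask = self.design["time_h"] == time_h
        if arm is not None:
            mask &= self.design["arm"] == arm
        return self.design.index[mask]


def read_experiment(counts_path: str | Path, design_path: str | Path) -> CountExperiment:
    """Read ``counts.tsv`` / ``design.tsv`` as written by :func:`chronode.simulate.write_experiment`."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return CountExperiment(counts, design)


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean one)."""

    library_size: pd.Series
    factor: pd.Series

    @property
    def effective(self) -> pd.Series:
        """Effective library size = raw library size x TMM factor."""
        return self.library_size * self.factor


class FilterResult(NamedTuple):
    experiment: CountExperiment
    n_kept: int
    n_removed: int


def filter_low_expression(
    experiment: CountExperiment,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> FilterResult:
    """Drop genes not reaching ``min_cpm`` (raw-library CPM) in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest (time, arm) group size, so a gene
    expressed in only one complete replicate group survives.  The boundary is
    inclusive: CPM exactly equal to ``min_cpm`` counts.
    """
    if min_samples is None:
        min_samples = int(experiment.group_sizes().min())
    if min_samples > len(experiment.samples):
        raise ValueError("min_samples exceeds the number of samples")
    lib = experiment.library_sizes.to_numpy()
    raw_cpm = experiment.counts.to_numpy(dtype=float) / lib * 1e6
    keep = (raw_cpm >= min_cpm).sum(axis=1) >= min_samples
    n_kept = int(keep.sum())
    n_removed = experiment.n_genes - n_kept
    if n_kept == 0:
        warnings.warn("filtering removed every gene", stacklevel=2)
    logger.info("expression filter: kept %d genes, removed %d", n_kept, n_removed)
    filtered = CountExperiment(experiment.counts.loc[keep], experiment.design)
    return FilterResult(filtered, n_kept, n_removed)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M (binomial sampling in each library)
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.allclose(m, 0.0, atol=1e-10):
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    experiment: CountExperiment,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values normalization factors.

    The reference sample is, unless given, the one whose upper-quartile
    count fraction is closest to the across-sample mean upper quartile.
    Genes with a zero count in either member of a pair are excluded from
    that pair's M/A computation; the M values are doubly trimmed (30% on M,
    5% on A by default) and combined with inverse-variance weights.
    Returned factors are renormalized to geometric mean one.
    """
    counts = experiment.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = experiment.samples[lib == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    samples = list(experiment.samples)
    if reference_sample is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(len(samples))])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = samples.index(reference_sample)
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_j:
            continue
        factors[j] = _tmm_pair(counts[:, j], counts[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        library_size=pd.Series(lib, index=experiment.samples),
        factor=pd.Series(factors, index=experiment.samples),
    )


def cpm(
    experiment: CountExperiment,
    factors: NormFactors | None = None,
    log2: bool = False,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """Counts per million over effective library sizes.

    With ``log2=True`` a prior count (scaled per sample by relative effective
    library size, as in standard log-CPM practice) keeps zero counts finite.
    """
    if factors is None:
        lib = experiment.library_sizes
        eff = lib.to_numpy(dtype=float)
    else:
        eff = factors.effective.reindex(experiment.samples).to_numpy(dtype=float)
    y = experiment.counts.to_numpy(dtype=float)
    if not log2:
        out = y / eff * 1e6
    else:
        prior = prior_count * eff / eff.mean()
        out = np.log2((y + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(out, index=experiment.genes, columns=experiment.samples)


def mds_distances(log2cpm: pd.DataFrame, top_n: int = 500) -> pd.DataFrame:
    """Pairwise sample distances: RMS of the ``top_n`` largest absolute log2 differences.

    For every sample pair a different top-gene set is selected (largest
    |log2CPM difference| for that pair), so the triangle inequality is not
    guaranteed — the matrix is symmetric with zero diagonal only.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    x = log2cpm.to_numpy(dtype=float)
    samples = log2cpm.columns
    n = len(samples)
    k = min(top_n, x.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            if k < diff2.size:
                top = np.partition(diff2, diff2.size - k)[-k:]
            else:
                top = diff2
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    return pd.DataFrame(d, index=samples, columns=samples)
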