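"""Negative-binomial count simulator with planted trajectory archetypes.

Emulates a two-arm (treated vs solvent control) time-course experiment:
4 time points x 2 arms x 3 replicates = 24 libraries over ~12,000 filtered
protein-coding genes.  Each gene is assigned one trajectory archetype:

``null``
    flat and equal in both arms.
``direct_up`` / ``direct_down``
    control flat; treated carries a step fold change from the onset time
    onward (treatment-driven response).
``indirect_up`` / ``indirect_down``
    treated flat; the *control* arm drifts up/down from the onset onward
    (ex vivo culture response that treatment stabilizes).  Note the DE
    contrast treated-vs-control therefore has the opposite sign.
``transient``
    treated-arm up-effect at the early time points (onset through 8 h) only.
``discontinuous``
    treated-arm effect at 8 h and 48 h with none at 24 h.
``mixed``
    treated-arm effect up at 4/8 h, down at 24/48 h.

Counts are drawn NB(mean, dispersion) with variance = mu + phi * mu**2;
phi = 0 degenerates to Poisson.  Each gene draws from its own deterministic
substream so adding genes never perturbs earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prep import CountExperiment

ARCHETYPES = (
    "null",
    "direct_up",
    "direct_down",
    "indirect_up",
    "indirect_down",
    "transient",
    "discontinuous",
    "mixed",
)

#: target genes are ~5.5% of expressed genes, split so that treatment-driven
#: (direct-like) and culture-driven (indirect) responses are both common and
#: indirect slightly dominates, as observed in mixed immune-cell time courses.
DEFAULT_FRACTIONS: dict[str, float] = {
    "null": 0.945,
    "direct_up": 0.012,
    "direct_down": 0.010,
    "indirect_up": 0.012,
    "indirect_down": 0.013,
    "transient": 0.004,
    "discontinuous": 0.002,
    "mixed": 0.002,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated experiment.

    ``library_sizes`` may be None, in which case 24 sizes are drawn
    log-normally (10% CV) around 5e6 from the experiment seed.
    Effect magnitudes are drawn log-uniform-ish (uniform in log2FC) over
    ``effect_log2_range``; baselines uniform in log2CPM over
    ``baseline_log2cpm_range`` so the expression filter boundary is exercised.
    """

    n_genes: int = 12000
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    baseline_log2cpm_range: tuple[float, float] = (-2.0, 9.0)
    effect_log2_range: tuple[float, float] = (0.8, 3.0)
    dispersion: float = 0.1
    library_sizes: tuple[float, ...] | None = None
    mean_library_size: float = 5e6
    n_replicates: int = 3
    time_points_h: tuple[int, ...] = (4, 8, 24, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in fractions: {sorted(unknown)}")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions sum to {total}, not 1")
        if any(v < 0 for v in self.archetype_fractions.values()):
            raise ValueError("archetype fractions must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n_samples = 2 * self.n_replicates * len(self.time_points_h)
        if self.library_sizes is not None:
            if len(self.library_sizes) != n_samples:
                raise ValueError(
                    f"library_sizes must have {n_samples} entries, got {len(self.library_sizes)}"
                )
            if any(s <= 0 for s in self.library_sizes):
                raise ValueError("library sizes must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def _onset_choices(archetype: str, time_points: Sequence[int]) -> tuple[int, ...]:
    early = tuple(t for t in time_points if t <= 8)
    if archetype == "null":
        return (time_points[0],)
    if archetype == "transient":
        return early  # effect must vanish after 8 h, so it must start by 8 h
    if archetype == "discontinuous":
        return (8,)  # effect hard-coded at 8 and 48 h
    if archetype == "mixed":
        return (time_points[0],)  # sign flip spans the whole course
    if archetype.startswith("indirect"):
        # culture drift must develop inside the observed window: a drift already
        # at full effect at the first time point is indistinguishable from a
        # direct effect of the opposite sign (both arms flat, constant offset),
        # so the planted mechanism would not be a recoverable ground truth
        return tuple(t for t in time_points if t > time_points[0])
    return tuple(time_points)


def archetype_mean(
    archetype: str,
    arm: str,
    time_h: int,
    baseline_mu: float,
    effect_log2: float,
    onset_h: int = 4,
    time_points_h: Sequence[int] = (4, 8, 24, 48),
) -> float:
    """Expected count mean (linear scale) for one arm at one time point.

    ``effect_log2`` is the planted magnitude (>= 0); the archetype determines
    which arm carries it, from when, and with which sign.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    if baseline_mu <= 0:
        raise ValueError("baseline_mu must be positive")
    if time_h not in time_points_h:
        raise ValueError(f"time {time_h} not in configured grid {tuple(time_points_h)}")
    e = abs(effect_log2)
    shift = 0.0
    if archetype == "direct_up" and arm == "treated" and time_h >= onset_h:
        shift = e
    elif archetype == "direct_down" and arm == "treated" and time_h >= onset_h:
        shift = -e
    elif archetype == "indirect_up" and arm == "control" and time_h >= onset_h:
        shift = e
    elif archetype == "indirect_down" and arm == "control" and time_h >= onset_h:
        shift = -e
    elif archetype == "transient" and arm == "treated" and onset_h <= time_h <= 8:
        shift = e
    elif archetype == "discontinuous" and arm == "treated" and time_h in (8, 48):
        shift = e
    elif archetype == "mixed" and arm == "treated" and time_h >= onset_h:
        shift = e if time_h <= 8 else -e
    return baseline_mu * 2.0**shift


def expected_labels(archetype: str, onset_h: int) -> dict[str, str | bool]:
    """Deterministic ground-truth labels from (archetype, onset).

    ``expected_direction`` is the sign of the treated-vs-control DE contrast
    (so an ``indirect_up`` gene — control drifts up — is expected *down*).
    """
    if archetype == "null":
        return {
            "expected_target": False,
            "expected_timing": "",
            "expected_mechanism": "",
            "expected_direction": "",
        }
    timing = "primary" if onset_h <= 8 else "secondary"
    mechanism = "indirect" if archetype.startswith("indirect") else "direct"
    direction = {
        "direct_up": "up",
        "direct_down": "down",
        "indirect_up": "down",
        "indirect_down": "up",
        "transient": "up",
        "discontinuous": "up",
        "mixed": "mixed",
    }[archetype]
    return {
        "expected_target": True,
        "expected_timing": timing,
        "expected_mechanism": mechanism,
        "expected_direction": direction,
    }


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for t in config.time_points_h:
        for arm in ("control", "treated"):
            for r in range(1, config.n_replicates + 1):
                rows.append((f"t{t}_{arm}_r{r}", t, arm, r))
    return pd.DataFrame(
        rows, columns=["sample", "time_h", "arm", "replicate"]
    ).set_index("sample")


def generate_counts(config: SimulationConfig) -> tuple[CountExperiment, pd.DataFrame]:
    """Draw one experiment and its ground-truth table.

    Returns the count experiment and a truth DataFrame (one row per gene:
    archetype, effect_log2, onset_h, expected labels).  Identical config and
    seed give bit-identical output.
    """
    design = _sample_table(config)
    n_samples = len(design)
    root = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.library_sizes is not None:
        lib = np.asarray(config.library_sizes, dtype=float)
    else:
        lib = config.mean_library_size * np.exp(root.normal(0.0, 0.1, size=n_samples))
    arm = design["arm"].to_numpy()
    time_h = design["time_h"].to_numpy()

    names = [a for a in ARCHETYPES if config.archetype_fractions.get(a, 0.0) > 0]
    cum = np.cumsum([config.archetype_fractions[a] for a in names])
    cum[-1] = 1.0  # guard rounding

    lo_b, hi_b = config.baseline_log2cpm_range
    lo_e, hi_e = config.effect_log2_range
    phi = config.dispersion

    children = np.random.SeedSequence(config.seed).spawn(config.n_genes)
    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    truth_rows = []
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    for i in range(config.n_genes):
        rng = np.random.default_rng(children[i])
        u = rng.uniform()
        archetype = names[int(np.searchsorted(cum, u, side="left"))]
        base_log2cpm = rng.uniform(lo_b, hi_b)
        effect = 0.0 if archetype == "null" else rng.uniform(lo_e, hi_e)
        onsets = _onset_choices(archetype, config.time_points_h)
        onset = int(onsets[rng.integers(len(onsets))]) if len(onsets) > 1 else int(onsets[0])
        base_rate = 2.0**base_log2cpm / 1e6  # per-read rate; scaled by library size
        mu = np.array(
            [
                archetype_mean(
                    archetype, arm[j], int(time_h[j]), base_rate * lib[j], effect,
                    onset_h=onset, time_points_h=config.time_points_h,
                )
                for j in range(n_samples)
            ]
        )
        if phi == 0.0:
            counts[i] = rng.poisson(mu)
        else:
            k = 1.0 / phi
            counts[i] = rng.negative_binomial(k, k / (k + mu))
        row = {"gene": gene_ids[i], "archetype": archetype,
               "effect_log2": effect, "onset_h": onset}
        row.update(expected_labels(archetype, onset))
        truth_rows.append(row)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                             columns=design.index)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return CountExperiment(counts_df, design), truth


def write_experiment(
    experiment: CountExperiment, truth: pd.DataFrame | None, directory: str | Path
) -> dict[str, Path]:
    """Write counts.tsv / design.tsv (and truth.tsv) into an existing directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    paths = {
        "counts": directory / "counts.tsv",
        "design": directory / "design.tsv",
    }
    experiment.counts.to_csv(paths["counts"], sep="\t", lineterminator="\n")
    experiment.design.to_csv(paths["design"], sep="\t", lineterminator="\n")
    if truth is not None:
        paths["truth"] = directory / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    return paths
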