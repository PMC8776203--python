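"""End-to-end orchestration: simulate/read -> prep -> DE -> classify -> cluster -> enrich -> coloc.

A single flat configuration document drives the whole run; a single seed
fans out deterministically to the simulator and to k-means, so two runs with
the same configuration produce byte-identical TSV outputs.  Defaults
reproduce the standard analysis settings: fold-change thresholds 1.5 at
4/8 h and 2 at 24/48 h, alpha 0.05, CPM floor 25, direction threshold 1.5,
k = 4 with 25 restarts, minimum 5 significant genes per enriched term and a
1 Mb colocalization window.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .classify import classify_targets, venn_counts
from .detest import TreatDE
from .enrich import enrich_with_direction, read_gmt
from .genomics import colocalize, read_bed, write_bed
from .prep import (
    CountExperiment,
    cpm,
    filter_low_expression,
    mds_distances,
    read_experiment,
    tmm_factors,
)
from .simulate import SimulationConfig, generate_counts, write_experiment
from .trajcluster import axis_contingency, kmeans_cluster, standardize

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration; unknown keys are an error."""

    # inputs (either a counts/design pair or simulate: true)
    counts: str | None = None
    design: str | None = None
    gmt: str | None = None
    genes_bed: str | None = None
    peaks_bed: str | None = None
    simulate: bool = False
    # simulation overrides
    n_genes: int = 12000
    dispersion: float = 0.1
    mean_library_size: float = 5e6
    # thresholds
    min_cpm: float = 1.0
    tau4: float = 1.5
    tau8: float = 1.5
    tau24: float = 2.0
    tau48: float = 2.0
    alpha: float = 0.05
    cpm_floor: float = 25.0
    fc_threshold: float = 1.5
    k: int = 4
    restarts: int = 25
    min_sig: int = 5
    window_bp: int = 1_000_000
    mds_top_n: int = 500
    prior_df: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.simulate and (self.counts is None or self.design is None):
            raise ValueError("config needs either simulate: true or counts+design paths")
        for name in ("tau4", "tau8", "tau24", "tau48", "fc_threshold"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k < 1 or self.restarts < 1 or self.min_sig < 0 or self.window_bp <= 0:
            raise ValueError("k, restarts >= 1; min_sig >= 0; window_bp > 0")

    @property
    def taus(self) -> dict[int, float]:
        return {4: self.tau4, 8: self.tau8, 24: self.tau24, 48: self.tau48}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index, lineterminator="\n")


def summarize(
    de_table: pd.DataFrame,
    significant_sets: dict[int, set[str]],
    classification: pd.DataFrame,
    cluster_sizes: dict[int, int] | None = None,
    mechanism_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Headline summary table; marginal consistency is hard-asserted.

    Rows: per-time-point significant counts and up/down percentages, union
    size, timing/direction/profile counts, cluster sizes and mechanism counts.
    """
    rows: list[tuple[str, float]] = []
    union = len(set().union(*significant_sets.values())) if significant_sets else 0
    for t in sorted(significant_sets):
        genes = significant_sets[t]
        rows.append((f"significant_{t}h", len(genes)))
        sub = de_table[(de_table["time_h"] == t) & de_table["gene"].isin(genes)]
        n = len(sub)
        up = int((sub["log2FC"] > 0).sum())
        rows.append((f"pct_up_{t}h", 100.0 * up / n if n else 0.0))
        rows.append((f"pct_down_{t}h", 100.0 * (n - up) / n if n else 0.0))
    rows.append(("targets_union", union))
    timing = classification["timing"].value_counts() if len(classification) else pd.Series(dtype=int)
    direction = (
        classification["direction"].value_counts() if len(classification) else pd.Series(dtype=int)
    )
    profile = (
        classification["profile"].value_counts() if len(classification) else pd.Series(dtype=int)
    )
    assert int(timing.sum()) == union, "timing counts must sum to the union"
    assert int(direction.sum()) == union, "direction counts must sum to the union"
    assert int(profile.sum()) == union, "profile counts must sum to the union"
    for label in ("primary", "secondary"):
        rows.append((f"n_{label}", int(timing.get(label, 0))))
    for label in ("up", "down", "mixed"):
        rows.append((f"n_{label}", int(direction.get(label, 0))))
    for label in ("persistent", "transient", "discontinuous"):
        rows.append((f"n_{label}", int(profile.get(label, 0))))
    if cluster_sizes is not None:
        total = sum(cluster_sizes.values())
        for cl in sorted(cluster_sizes):
            rows.append((f"cluster_{cl}_size", cluster_sizes[cl]))
        rows.append(("n_clustered", total))
    if mechanism_counts is not None:
        n_mech = sum(mechanism_counts.values())
        assert cluster_sizes is None or n_mech == sum(cluster_sizes.values()), (
            "mechanism counts must sum to the clustered-gene count"
        )
        for label in ("direct", "indirect"):
            rows.append((f"n_{label}", int(mechanism_counts.get(label, 0))))
    return pd.DataFrame(rows, columns=["metric", "value"]).set_index("metric")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage, writing all outputs under ``outdir``.

    Returns a bundle with the in-memory stage results (experiment, DE
    results, classification, cluster result, summary, ...).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("chronode")
    root.addHandler(fh)
    old_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        logger.info("chronode %s  seed=%d  thresholds=%s alpha=%s floor=%s",
                    __version__, config.seed, config.taus, config.alpha, config.cpm_floor)
        bundle: dict[str, Any] = {"config": config}

        # --- input / simulation ------------------------------------------
        truth = None
        if config.simulate:
            sim = SimulationConfig(
                n_genes=config.n_genes,
                dispersion=config.dispersion,
                mean_library_size=config.mean_library_size,
                seed=config.seed,
            )
            experiment, truth = generate_counts(sim)
            write_experiment(experiment, truth, outdir)
        else:
            experiment = read_experiment(config.counts, config.design)
        bundle["truth"] = truth

        # --- prep ---------------------------------------------------------
        filtered, n_kept, n_removed = filter_low_expression(experiment, min_cpm=config.min_cpm)
        logger.info("filter: kept %d removed %d", n_kept, n_removed)
        factors = tmm_factors(filtered)
        _write(
            pd.DataFrame(
                {"library_size": factors.library_size, "tmm_factor": factors.factor,
                 "effective_size": factors.effective}
            ),
            outdir / "normfactors.tsv",
        )
        log2cpm = cpm(filtered, factors, log2=True)
        _write(cpm(filtered, factors, log2=False), outdir / "cpm.tsv")
        _write(mds_distances(log2cpm, top_n=config.mds_top_n), outdir / "mds.tsv")
        bundle["experiment"] = filtered
        bundle["factors"] = factors

        # --- differential expression --------------------------------------
        model = TreatDE(filtered, taus={t: config.taus[t] for t in filtered.time_points},
                        factors=factors)
        results = model.fit(prior_df=config.prior_df, alpha=config.alpha,
                            cpm_floor=config.cpm_floor)
        _write(results.table, outdir / "de_results.tsv", index=False)
        _write(pd.DataFrame({"gene": results.targets}), outdir / "targets.tsv", index=False)
        bundle["de"] = results
        logger.info("targets: %d", len(results.targets))

        # --- classification ------------------------------------------------
        classification = classify_targets(
            results.significant_times(), results.log2fc_matrix(), config.fc_threshold
        )
        _write(classification, outdir / "classification.tsv")
        _write(venn_counts(results.significant_sets), outdir / "venn.tsv", index=False)
        bundle["classification"] = classification

        # --- trajectory clustering -----------------------------------------
        cluster_result = None
        if len(results.targets) >= config.k:
            traj = standardize(log2cpm, filtered.design, genes=results.targets)
            cluster_result = kmeans_cluster(
                traj, k=config.k, n_restarts=config.restarts, seed=config.seed
            )
            clusters_df = pd.DataFrame(
                {
                    "cluster": cluster_result.assignments,
                    "mechanism": cluster_result.gene_mechanism(),
                    "direction": cluster_result.gene_direction(),
                }
            ).sort_index()
            _write(clusters_df, outdir / "clusters.tsv")
            cent = cluster_result.centroids.copy()
            cent.columns = [f"t{t}_{arm}" for t, arm in cent.columns]
            _write(cent, outdir / "centroids.tsv")
            merged = classification.join(clusters_df[["mechanism"]], how="left")
            tables = axis_contingency(
                merged.dropna(subset=["mechanism"]),
                pairs=[("direction", "mechanism"), ("timing", "mechanism")],
            )
            _write(tables, outdir / "contingency.tsv", index=False)
            bundle["contingency"] = tables
        else:
            logger.warning("clustering skipped: %d targets < k=%d",
                           len(results.targets), config.k)
        bundle["clusters"] = cluster_result

        # --- enrichment -----------------------------------------------------
        if config.gmt is not None and len(classification):
            collection = read_gmt(config.gmt)
            enrichment = enrich_with_direction(
                classification, filtered.genes, collection, min_sig=config.min_sig
            )
            _write(enrichment, outdir / "enrichment.tsv", index=False)
            bundle["enrichment"] = enrichment
        else:
            logger.info("enrichment skipped (no GMT collection configured)")
            bundle["enrichment"] = None

        # --- colocalization --------------------------------------------------
        if config.genes_bed is not None and config.peaks_bed is not None:
            loci = read_bed(config.genes_bed)
            target_set = set(results.targets)
            target_loci = [iv for iv in loci if iv.name in target_set]
            write_bed(target_loci, outdir / "targets.bed")
            peaks = read_bed(config.peaks_bed)
            coloc = colocalize(target_loci, peaks, window_bp=config.window_bp)
            _write(coloc, outdir / "colocalization.tsv", index=False)
            bundle["colocalization"] = coloc
        else:
            logger.info("colocalization skipped (no gene/peak BED configured)")
            bundle["colocalization"] = None

        # --- summary ----------------------------------------------------------
        cluster_sizes = mech_counts = None
        if cluster_result is not None:
            cluster_sizes = cluster_result.assignments.value_counts().sort_index().to_dict()
            mech_counts = cluster_result.gene_mechanism().value_counts().to_dict()
        summary = summarize(
            results.table, results.significant_sets, classification, cluster_sizes, mech_counts
        )
        _write(summary, outdir / "summary.tsv")
        bundle["summary"] = summary
        logger.info("pipeline complete: %d stage outputs in %s", len(bundle), outdir)
        return bundle
    finally:
        root.setLevel(old_level)
        root.removeHandler(fh)
        fh.close()
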