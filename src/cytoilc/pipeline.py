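"""End-to-end orchestration: simulate/load -> gate -> stats -> cluster -> report.

A :class:`PipelineConfig` (YAML-loadable) drives the full analysis path:
pregate -> merge-then-logicle-transform -> hierarchical ILC gate -> subset
frequencies and stage t-test -> t-SNE of the ILC pool -> BIC-selected
Gaussian-mixture clustering -> cluster composition and per-marker Duncan
contrasts.  Every stage writes CSV artifacts; a manifest records config,
seeds and versions so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel_io import Cohort, EventMatrix, PanelConfig, default_panel, \
    load_panel, read_events
from .transform import transform_cohort
from .pregating import PregateConfig, pregate_and_subsample, pool
from .ilc_gating import GatingConfig, classify_events, \
    frequencies_from_pooled
from .group_stats import marker_contrasts, unpaired_ttest
from .embed_cluster import ClusterAssignment, EmbeddingConfig, bic_select, \
    cluster_composition, cluster_stage_association, \
    per_sample_cluster_fractions, tsne_embed
from .synthetic_data import SyntheticSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's configuration; exactly one of files / simulate."""

    input_files: list[str] = field(default_factory=list)
    simulate: bool = True
    panel_path: str | None = None
    master_seed: int = 0
    out_dir: str = "results"
    subsample_n: int = 5000
    cd45_threshold: float = 1.0
    positivity_threshold: float = 1.0
    perplexity: float = 30.0
    tsne_iterations: int = 1000
    g_max: int = 9
    mrt_alpha: float = 0.05
    contrast_markers: list[str] = field(default_factory=list)
    synthetic: dict = field(default_factory=dict)
    make_plots: bool = True

    def __post_init__(self) -> None:
        if bool(self.input_files) == bool(self.simulate):
            raise ValueError(
                "config must select exactly one input mode: "
                "input_files XOR simulate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _load_cohort(cfg: PipelineConfig, panel: PanelConfig) -> Cohort:
    if cfg.simulate:
        spec = SyntheticSpec(seed=cfg.master_seed, **cfg.synthetic)
        cohort, _ = generate_cohort(spec, panel)
        return cohort
    samples = [read_events(p, panel) for p in cfg.input_files]
    return Cohort(samples=samples, panel=panel)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the result bundle (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(cfg.panel_path) if cfg.panel_path else default_panel()
    bundle: dict = {"out_dir": str(out)}
    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("input")
        cohort = _load_cohort(cfg, panel)

        stage("pregate")
        pre_cfg = PregateConfig(cd45_threshold=cfg.cd45_threshold,
                                subsample_n=cfg.subsample_n,
                                seed=cfg.master_seed)
        gated, retention = pregate_and_subsample(cohort, pre_cfg)
        retention.to_csv(out / "retention.csv", index=False)

        stage("transform")
        transformed, params = transform_cohort(gated, return_params=True)
        params.to_csv(out / "logicle_params.csv", index=False)

        stage("gate")
        gate_cfg = GatingConfig(
            positivity_threshold=cfg.positivity_threshold)
        classified = Cohort(
            samples=[classify_events(s, gate_cfg)
                     for s in transformed.samples],
            panel=panel)
        pooled = pool(classified)
        freqs = frequencies_from_pooled(pooled)
        freqs.to_csv(out / "frequencies.csv", index=False)
        bundle["frequencies"] = freqs
        bundle["n_pooled"] = int(pooled.n_events)

        stage("stage_ttest")
        per_sample = freqs[freqs.sample_id != "__pooled__"]
        stage_tests = []
        for col in ("pct_ILC1", "pct_ILC2", "pct_ILC3_NKp44pos",
                    "pct_ILC3_NKp44neg"):
            a = per_sample.loc[per_sample.stage == "T2", col]
            b = per_sample.loc[per_sample.stage.isin(["T3", "T4"]), col]
            if len(a) >= 2 and len(b) >= 2:
                r = unpaired_ttest(a, b)
                stage_tests.append({
                    "subset": col, "t": r.t_statistic, "df": r.df,
                    "p_value": r.p_value, "mean_T2": r.mean_a,
                    "mean_T3plus": r.mean_b})
        stage_df = pd.DataFrame(stage_tests)
        stage_df.to_csv(out / "stage_ttest.csv", index=False)
        bundle["stage_ttest"] = stage_df

        stage("embed")
        ilc_mask = (pooled.annotations["phenotype"] != "nonILC").to_numpy()
        ilc = pooled.take(np.flatnonzero(ilc_mask))
        emb_cfg = EmbeddingConfig(perplexity=cfg.perplexity,
                                  n_iterations=cfg.tsne_iterations,
                                  seed=cfg.master_seed)
        coords = tsne_embed(ilc, emb_cfg)

        stage("cluster")
        best, bic_table = bic_select(coords, range(1, cfg.g_max + 1),
                                     seed=cfg.master_seed)
        assign = ClusterAssignment(best.predict(coords), best)
        bic_table.to_csv(out / "bic_table.csv", index=False)
        coords_df = pd.DataFrame({
            "x": coords[:, 0], "y": coords[:, 1],
            "cluster": assign.cluster_id,
            "phenotype": ilc.annotations["phenotype"].to_numpy(),
            "sample_id": ilc.annotations["sample_id"].to_numpy(),
        })
        coords_df.to_csv(out / "tsne_coordinates.csv", index=False)
        comp = cluster_composition(
            assign, ilc.annotations["phenotype"].to_numpy())
        comp.to_csv(out / "cluster_composition.csv")
        bundle.update(best_model=best, bic_table=bic_table,
                      composition=comp, coords=coords_df)

        stage("cluster_stage")
        fracs = per_sample_cluster_fractions(
            assign, ilc.annotations["sample_id"].to_numpy())
        stages = (per_sample.set_index("sample_id")["stage"]
                  .reindex(fracs.index))
        try:
            cs = cluster_stage_association(fracs, stages)
        except ValueError as exc:
            logger.warning("cluster-stage association skipped: %s", exc)
            cs = pd.DataFrame()
        cs.to_csv(out / "cluster_stage_ttest.csv", index=False)
        bundle["cluster_stage"] = cs

        stage("marker_mrt")
        markers = cfg.contrast_markers or [
            "RORgt", "Tbet", "GATA-3", "IFN-g", "IL-13", "IL-17A", "IL-22",
            "perforin", "NKp30", "NKp46", "CD69", "PD-1", "Tim3",
        ]
        mrt_rows = []
        for grouping in ("ilc_type", "cluster"):
            source = ilc if grouping == "ilc_type" else EventMatrix(
                data=ilc.data, sample_id="ilc", scale_state="transformed",
                annotations=ilc.annotations.assign(
                    cluster=assign.cluster_id))
            results, means = marker_contrasts(
                source, markers, grouping=grouping, alpha=cfg.mrt_alpha)
            for m, res in results.items():
                for _, row in res.pairs_table().iterrows():
                    mrt_rows.append({"grouping": grouping, "marker": m,
                                     **row.to_dict()})
            means.to_csv(out / f"group_means_{grouping}.csv", index=False)
        mrt_df = pd.DataFrame(mrt_rows)
        mrt_df.to_csv(out / "marker_mrt.csv", index=False)
        bundle["marker_mrt"] = mrt_df

        if cfg.make_plots:
            stage("plots")
            _plots(out, coords_df, freqs)

        stage("manifest")
        from . import __version__ as pkg_version
        manifest = {
            "version": pkg_version,
            "master_seed": cfg.master_seed,
            "n_samples": len(cohort.samples),
            "n_pooled": bundle["n_pooled"],
            "n_ilc": int(ilc.n_events),
            "selected_G": int(best.G),
            "selected_family": best.family,
            "config": {k: v for k, v in asdict(cfg).items()},
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()[:16]
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']!r}: {exc}"
        ) from exc
    return bundle


def _plots(out: Path, coords: pd.DataFrame, freqs: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for key, ax in zip(("cluster", "phenotype"), axes):
        for val, grp in coords.groupby(key):
            ax.scatter(grp.x, grp.y, s=4, label=str(val))
        ax.set_title(f"t-SNE by {key}")
        ax.legend(fontsize=6, markerscale=2)
    fig.tight_layout()
    fig.savefig(out / "tsne.png", dpi=120)
    plt.close(fig)

    per_sample = freqs[freqs.sample_id != "__pooled__"]
    fig, ax = plt.subplots(figsize=(6, 4))
    cols = ["pct_ILC1", "pct_ILC2", "pct_ILC3_NKp44pos", "pct_ILC3_NKp44neg"]
    ax.boxplot([per_sample[c] for c in cols], tick_labels=cols)
    ax.set_ylabel("% of CD45+ events")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out / "frequencies.png", dpi=120)
    plt.close(fig)


def make_report(bundle: dict) -> str:
    """Render the result bundle as a Markdown report (also written to disk).

    One section per figure analogue: subset frequencies & stage association,
    marker contrasts, cluster structure, per-cluster profiles.
    """
    for key in ("frequencies", "stage_ttest", "bic_table", "composition"):
        if key not in bundle:
            raise ValueError(f"bundle is missing {key!r}")
    freqs: pd.DataFrame = bundle["frequencies"]
    pooled = freqs[freqs.sample_id == "__pooled__"].iloc[0]
    lines = [
        "# ILC analysis report", "",
        "## Subset frequencies and stage association", "",
        f"Pooled CD45+ events: {int(bundle['n_pooled'])}", "",
        f"- ILC1: {pooled.pct_ILC1:.2f}% of CD45+",
        f"- ILC2: {pooled.pct_ILC2:.2f}% of CD45+",
        f"- NKp44+ ILC3: {pooled.pct_ILC3_NKp44pos:.2f}% of CD45+",
        f"- NKp44- ILC3: {pooled.pct_ILC3_NKp44neg:.2f}% of CD45+", "",
        bundle["stage_ttest"].to_markdown(index=False)
        if len(bundle["stage_ttest"]) else "_no stage test (too few samples)_",
        "",
        "## Marker contrasts across ILC subsets", "",
        bundle["marker_mrt"].query("grouping == 'ilc_type'")
        .head(40).to_markdown(index=False)
        if len(bundle.get("marker_mrt", [])) else "_no contrasts_",
        "",
        "## Model-based clustering", "",
    ]
    comp = bundle["composition"]
    if len(comp) == 0:
        lines.append("_no clusters_")
    else:
        best = bundle["best_model"]
        lines += [
            f"Selected model: G = {best.G}, family = {best.family}, "
            f"BIC = {best.bic:.1f}", "",
            comp.to_markdown(),
        ]
    lines += ["", "## Per-cluster marker profiles", ""]
    mrt = bundle.get("marker_mrt")
    if mrt is not None and len(mrt):
        lines.append(mrt.query("grouping == 'cluster'")
                     .head(40).to_markdown(index=False))
    else:
        lines.append("_no per-cluster contrasts_")
    text = "\n".join(lines) + "\n"
    out_dir = bundle.get("out_dir")
    if out_dir:
        Path(out_dir, "report.md").write_text(text)
    return text
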