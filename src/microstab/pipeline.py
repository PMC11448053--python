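"""End-to-end orchestration of the full analysis on real or synthetic inputs.

Stage order: rarefaction -> alpha diversity -> CLR/Aitchison -> group distance
summaries -> PERMANOVA + PermDisp -> stability regression -> PRC (taxa in
single-group mode; metabolites per group with cross-comparison and top-bin
selection) -> correlation screens -> networks + rewiring. All randomness
flows from one root seed via per-stage derived seeds (CRC32 of the stage
name), so adding stages never perturbs existing ones. Results are written
under the output directory; the report JSON carries full provenance.
"""

from __future__ import annotations

import json
import logging
import sys
import time as _time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, compositional, diversity, networks, ordination, prc, stability
from .io import (
    FeatureTable,
    SampleMetadata,
    read_feature_table,
    read_metadata,
    read_newick,
    write_distance_matrix,
    write_feature_table,
    write_metadata,
    write_newick,
)
from .simulate import TrialConfig, simulate_trial, config_to_dict

log = logging.getLogger("microstab")

__all__ = ["AnalysisConfig", "run_full_analysis", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the root seed and the stage name."""
    return (zlib.crc32(stage.encode()) ^ (root_seed * 2654435761)) % (2**31)


@dataclass
class AnalysisConfig:
    # exactly one of (asv_path ...) or simulate must be given
    asv_path: str | None = None
    metabolite_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    simulate: TrialConfig | None = None
    pseudocount: float = 1.0
    rarefaction_depth: int = 25_000
    n_permutations: int = 1000
    prc_transform: str = "chord"  # taxa PRC; metabolites use log-centred values
    n_bins: int = 10
    n_top_bins: int = 2
    network_method: str = "pearson"
    network_threshold: float = 0.75
    correlation_method: str = "pearson"
    seed: int = 0
    output_dir: str = "microstab_out"

    def validate(self) -> None:
        has_paths = self.asv_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("exactly one of input paths or a simulate block is required")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline; returns the report dict (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config": _config_dict(config),
        },
        "sections": {},
    }
    manifest: list[str] = []

    def stage(name):
        def deco(fn):
            t0 = _time.perf_counter()
            log.info("stage %s ...", name)
            try:
                report["sections"][name] = _jsonable(fn())
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                _write_report(report, manifest, out)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest.append(name)
            log.info("stage %s done (%.2fs)", name, _time.perf_counter() - t0)

        return deco

    # ---- inputs -------------------------------------------------------
    if config.simulate is not None:
        trial = simulate_trial(config.simulate)
        asv, metab, metadata, tree = (
            trial.asv_table,
            trial.metabolite_table,
            trial.metadata,
            trial.tree,
        )
        report["sections"]["truth"] = _jsonable(trial.truth)
        write_feature_table(asv, out / "asv_counts.tsv")
        write_feature_table(metab, out / "metabolite_abundance.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_newick(tree, out / "tree.nwk")
    else:
        asv = read_feature_table(config.asv_path, kind="counts")
        metadata = read_metadata(config.metadata_path)
        metab = (
            read_feature_table(config.metabolite_path, kind="abundance")
            if config.metabolite_path
            else None
        )
        tree = read_newick(config.tree_path) if config.tree_path else None

    depth = min(config.rarefaction_depth, int(asv.values.sum(axis=0).min()))

    @stage("rarefaction")
    def _():
        nonlocal asv
        res = compositional.rarefy(asv, depth, stage_seed(config.seed, "rarefaction"))
        asv = res.table
        return {"depth": res.depth, "dropped": res.dropped, "n_samples": len(asv.sample_ids)}

    @stage("alpha_diversity")
    def _():
        alpha = diversity.alpha_diversity_table(asv, tree=tree)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        merged = alpha.join(metadata.samples[["group", "day"]])
        return {
            "group_day_means": merged.groupby(["group", "day"]).mean().reset_index().to_dict("records")
        }

    dist_holder = {}

    @stage("aitchison_distance")
    def _():
        dist = compositional.aitchison_distance(asv, config.pseudocount)
        dist_holder["dist"] = dist
        write_distance_matrix(dist, out / "aitchison_distance.tsv")
        return {"n_samples": len(dist.ids)}

    @stage("group_distance_summary")
    def _():
        summary = ordination.group_distance_summary(dist_holder["dist"], metadata)
        return {
            f"{g}.day{d}": {"mean": float(v.mean()), "n_pairs": len(v)}
            for (g, d), v in summary.items()
        }

    @stage("permanova")
    def _():
        dist = dist_holder["dist"]
        groups = [metadata.group_of(s) for s in dist.ids]
        res = ordination.permanova(
            dist, groups, config.n_permutations, stage_seed(config.seed, "permanova")
        )
        return asdict(res)

    @stage("permdisp")
    def _():
        # dispersion on post-baseline days, mirroring the pooled 7/14/78 design
        days = sorted(metadata.samples["day"].unique())
        late = metadata.samples[metadata.samples["day"].isin(days[1:])]
        ids = [s for s in dist_holder["dist"].ids if s in set(late.index)]
        dist = dist_holder["dist"].filter(ids)
        groups = [metadata.group_of(s) for s in ids]
        res = ordination.permdisp(
            dist, groups, config.n_permutations, stage_seed(config.seed, "permdisp")
        )
        return asdict(res)

    @stage("stability_regression")
    def _():
        records = compositional.stability_series(dist_holder["dist"], metadata)
        pct = metadata.percent_serum_change()
        subj = metadata.subject_table()
        treated = subj.index[subj["group"] == "treatment"]
        res = stability.fit_stability_regression(
            [r for r in records if r.subject_id in set(treated)], pct.loc[treated]
        )
        summary = compositional.subject_stability_summary(records)
        summary.to_csv(out / "stability_by_subject.tsv", sep="\t")
        return {"treatment_arm": asdict(res)}

    @stage("prc_taxa")
    def _():
        # single-group mode on the treatment arm, first day as baseline
        treated = metadata.samples[metadata.samples["group"] == "treatment"]
        sub = asv.select_samples([s for s in asv.sample_ids if s in set(treated.index)])
        if config.prc_transform == "chord":
            mat = compositional.chord_transform(sub).T
        else:
            mat = compositional.clr_transform(sub, config.pseudocount).T
        days = treated.loc[mat.index, "day"].to_numpy()
        res = prc.fit_prc(mat, days)
        res.species_scores.to_csv(out / "prc_taxa_scores.tsv", sep="\t", header=["species_score"])
        return {
            "baseline_day": int(res.baseline_level),
            "canonical_coefficients": {
                str(lv[0]): float(c) for lv, c in zip(res.condition_levels, res.canonical_coefficients)
            },
            "explained_variance_fraction": res.explained_variance_fraction,
            "top_taxa": res.species_scores.abs().sort_values(ascending=False).head(8).index.tolist(),
        }

    met_norm_holder = {}
    comparison_holder = {}

    @stage("prc_metabolites")
    def _():
        if metab is None:
            return {"skipped": "no metabolite table provided"}
        norm = compositional.normalize_metabolites(metab, metadata)
        met_norm_holder["norm"] = norm
        scores = {}
        for group in ("placebo", "treatment"):
            rows = metadata.samples[metadata.samples["group"] == group]
            cols = [s for s in norm.columns if s in set(rows.index)]
            mat = norm[cols].T
            days = rows.loc[cols, "day"].to_numpy()
            fit = prc.fit_prc(mat, days)
            scores[group] = prc.standardize_scores(fit.species_scores)
        comp = prc.compare_groups(scores["placebo"], scores["treatment"])
        comparison_holder["comp"] = comp
        comp.table.to_csv(out / "prc_metabolite_comparison.tsv", sep="\t", index_label="feature_id")
        annotated = pd.Series(True, index=comp.table.index)
        selected = prc.select_top_bins(comp, annotated, config.n_bins, config.n_top_bins)
        return {
            "n_features": len(comp.table),
            "selected": selected,
            "n_selected": len(selected),
            "quadrant_counts": comp.table["quadrant"].value_counts().to_dict(),
        }

    @stage("correlation_screen")
    def _():
        clr = compositional.clr_transform(asv, config.pseudocount)
        treated = metadata.samples[metadata.samples["group"] == "treatment"]
        sub_meta = SampleMetadata(treated.copy(), metadata.subjects)
        baseline_day = int(metadata.samples["day"].min())
        changes = association.clr_change(clr, sub_meta, baseline_day)
        pct = metadata.percent_serum_change()
        cov = pd.Series(
            [pct[subj] for subj, _ in changes.index], index=changes.index
        )
        results = association.correlate_with_covariate(
            changes, cov, method=config.correlation_method
        )
        df = pd.DataFrame([asdict(r) for r in results]).sort_values("q_value")
        df.to_csv(out / "taxa_serum_correlations.tsv", sep="\t", index=False)
        sig = df[df["q_value"] <= 0.05]
        return {
            "method": config.correlation_method,
            "n_tested": int(df["p_value"].notna().sum()),
            "n_significant_q05": int(len(sig)),
            "top": df.head(10).to_dict("records"),
        }

    @stage("networks")
    def _():
        if metab is None:
            return {"skipped": "no metabolite table provided"}
        clr = compositional.clr_transform(asv, config.pseudocount)
        norm = met_norm_holder["norm"]
        nets = {}
        for group in ("placebo", "treatment"):
            rows = metadata.samples[metadata.samples["group"] == group]
            cols = [s for s in clr.columns if s in set(rows.index) and s in set(norm.columns)]
            coeffs = networks.pairwise_correlation(
                clr[cols], norm[cols], method=config.network_method
            )
            nets[group] = networks.build_network(coeffs, config.network_threshold)
            networks.write_edge_list(nets[group], out / f"network_{group}.tsv")
        overlap = networks.network_overlap(nets["placebo"], nets["treatment"])
        dn = networks.dn_rewiring(nets["placebo"], nets["treatment"])
        dn.to_csv(out / "dn_rewiring.tsv", sep="\t")
        return {
            "overlap": asdict(overlap),
            "mean_dn": float(dn["dn"].mean()) if len(dn) else None,
            "n_rewired_nodes": int((dn["dn"] > 0).sum()),
        }

    _write_report(report, manifest, out)
    return report


def _config_dict(config: AnalysisConfig) -> dict:
    d = asdict(config)
    if config.simulate is not None:
        d["simulate"] = config_to_dict(config.simulate)
    return d


def _write_report(report: dict, manifest: list[str], out: Path) -> None:
    report["manifest"] = manifest
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(message)s",
    )
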