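"""End-to-end pipeline: simulate -> call -> QC/map -> scan -> association.

Each stage writes its artifacts as TSV into the output directory and appends
to a marker-count log shaped like a filtering-cascade table (one row per
step, counts monotone non-increasing from the calling stage onward).  A
stage failure raises ``PipelineError`` naming the stage; artifacts written
by earlier stages are left in place.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import association, io, linkage, mixture, qtl
from .errors import Gras2QtlError
from .simulate import (
    DefaultCaller,
    DepthModel,
    QTLEffect,
    SimConfig,
    simulate_dataset,
)

log = logging.getLogger("gras2qtl")


class PipelineError(Gras2QtlError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def sim_config_from_dict(d: dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a (possibly nested) plain dict, e.g. from YAML."""
    d = dict(d)
    if seed is not None:
        d["seed"] = seed
    if "depth_model" in d:
        d["depth_model"] = DepthModel(**d["depth_model"])
    if "default_caller" in d:
        d["default_caller"] = DefaultCaller(**d["default_caller"])
    for key in ("qtl_spec", "flowering_qtl_spec"):
        if key in d:
            d[key] = tuple(
                q if isinstance(q, QTLEffect) else QTLEffect(*q) for q in d[key]
            )
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise Gras2QtlError(f"unknown simulate config keys {sorted(unknown)}")
    return SimConfig(**d)


def _call_and_filter(
    depths: mixture.DepthMatrix,
    default_dominant: pd.DataFrame,
    family: str,
    consensus_threshold: float,
) -> tuple[mixture.MarkerSet, float]:
    ms, _ = mixture.call_markers(depths, family)
    ms = mixture.consensus_filter(ms, default_dominant, threshold=consensus_threshold)
    ms = mixture.parental_consistency_filter(ms)
    mean_consensus = float(ms.info["consensus_pct"].mean()) if ms.n_markers else float("nan")
    return ms, mean_consensus


def run_pipeline(config: io.RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline under one seed; returns the artifact dictionary."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    counts_log: list[tuple[str, int]] = []
    artifacts: dict = {"out_dir": out, "counts_log": counts_log}
    config.to_yaml(out / "resolved_config.yaml")

    stage = "simulate"
    try:
        sim_cfg = sim_config_from_dict(config.simulate, seed=seed)
        data = simulate_dataset(sim_cfg)
        io.write_depth_matrix(data.depths, out / "depths.tsv", seed)
        io.write_genotype_matrix(data.truth.genotypes, out / "true_genotypes.tsv", seed)
        io.write_genotype_matrix(data.default_dominant, out / "default_dominant.tsv", seed)
        io.write_genotype_matrix(data.default_codominant, out / "default_codominant.tsv", seed)
        io.write_phenotypes(data.phenotypes, out / "phenotypes.tsv", seed)
        io.write_map(data.truth.map, out / "true_map.tsv", seed)
        artifacts["dataset"] = data
        log.info("simulated %d markers x %d individuals", len(data.depths.counts),
                 len(data.depths.counts.columns))
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, e) from e

    stage = "call"
    try:
        thr = float(config.call.get("consensus_threshold", 95.0))
        default_set = mixture.marker_set_from_calls(
            data.default_codominant, "default", data.depths.source_parent
        )
        gamma_set, gamma_consensus = _call_and_filter(
            data.depths, data.default_dominant, "gamma", thr
        )
        normal_set, normal_consensus = _call_and_filter(
            data.depths, data.default_dominant, "normal", thr
        )
        merged = mixture.priority_merge(default_set, gamma_set, normal_set)
        gamma_acc = mixture.codominant_accuracy(gamma_set.calls, data.default_codominant)[1] \
            if len(gamma_set.calls.index.intersection(data.default_codominant.index)) else float("nan")
        artifacts.update(
            merged=merged, gamma_set=gamma_set, normal_set=normal_set,
            gamma_consensus=gamma_consensus, normal_consensus=normal_consensus,
            gamma_codominant_accuracy=gamma_acc,
        )
        calls = pd.concat([merged.calls, data.morphological.to_frame().T])
        counts_log.append(("called_markers", len(calls)))
        io.write_genotype_matrix(merged.calls, out / "called_genotypes.tsv", seed)
        io.write_table(merged.info.reset_index(names="marker"), out / "marker_qc.tsv", seed)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "map"
    try:
        calls, dup_report = linkage.collapse_duplicate_markers(calls)
        counts_log.append(("after_duplicate_removal", len(calls)))
        alpha = float(config.map.get("distortion_alpha", 0.001))
        calls, dist_report = linkage.segregation_distortion_filter(calls, alpha=alpha)
        counts_log.append(("after_distortion_filter", len(calls)))
        gmap = linkage.build_map(
            calls,
            r_max=float(config.map.get("r_max", 0.35)),
            lod_min=float(config.map.get("lod_min", 3.0)),
            runs=int(config.map.get("runs", 50)),
            seed=seed,
        )
        gmap, gap_log = linkage.gap_filter(gmap, max_gap=float(config.map.get("max_gap", 20.0)))
        counts_log.append(("after_gap_filter", gmap.n_markers))
        summary = linkage.summarize_map(gmap)
        artifacts.update(map=gmap, map_summary=summary, distortion_report=dist_report,
                         duplicate_report=dup_report, gap_log=gap_log, mapped_calls=calls)
        io.write_map(gmap, out / "map.tsv", seed)
        io.write_table(pd.DataFrame([summary]), out / "map_summary.tsv", seed)
        log.info("map: %s", summary)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "scan"
    try:
        scan_cfg = config.scan
        model = str(scan_cfg.get("model", "cim"))
        n_perm = int(scan_cfg.get("n_perm", 1000))
        alpha = float(scan_cfg.get("alpha", 0.05))
        censor_policy = str(scan_cfg.get("censor_policy", "include"))
        pheno = data.phenotypes.frame.set_index("individual")
        mapped = calls.loc[[m for m in calls.index if m in set(gmap.marker_ids)]]
        scans = {}
        for trait in ("maturity_time", "flowering_time"):
            y = pheno[trait].copy()
            if trait == "maturity_time" and censor_policy == "exclude":
                y = y[~pheno["censored"]]
            res = qtl.scan_with_permutations(
                gmap, mapped, y, model=model, n_perm=n_perm, alpha=alpha,
                seed=seed, n_cofactors=int(scan_cfg.get("n_cofactors", 5)),
                window=float(scan_cfg.get("window", 10.0)),
            )
            scans[trait] = res
            io.write_table(res.scan, out / f"scan_{trait}.tsv", seed)
            io.write_table(res.peaks, out / f"peaks_{trait}.tsv", seed)
        artifacts["scans"] = scans
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    stage = "assoc"
    try:
        pheno = data.phenotypes.frame.set_index("individual")
        policy = str(config.assoc.get("censor_policy", "exclude"))
        kept_ids = pheno.index[~pheno["censored"]] if policy == "exclude" else pheno.index
        summaries = []
        for _, peak in scans["maturity_time"].peaks.iterrows():
            proxy = peak["marker_left"] or peak["marker_right"]
            if proxy is None or proxy not in calls.index:
                continue
            cs = association.class_summary(
                calls.loc[proxy].reindex(kept_ids),
                pheno.loc[kept_ids, "maturity_time"],
                marker=str(proxy),
            )
            summaries.append(cs)
        corr = association.phenotype_correlation(
            pheno["flowering_time"], pheno["maturity_time"], pheno["censored"],
            censor_policy=str(config.assoc.get("censor_policy", "exclude")),
        )
        artifacts.update(class_summaries=summaries, flowering_maturity_r=corr)
        if summaries:
            rows = []
            for cs in summaries:
                for c in cs.classes.index:
                    rows.append((cs.marker, c, *cs.classes.loc[c]))
            io.write_table(
                pd.DataFrame(rows, columns=["marker", "class", "n", "mean", "sd"]),
                out / "association_classes.tsv", seed,
            )
            io.write_table(
                pd.concat(
                    [cs.contrasts.assign(marker=cs.marker) for cs in summaries]
                ),
                out / "association_contrasts.tsv", seed,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    io.write_table(
        pd.DataFrame(counts_log, columns=["step", "n_markers"]),
        out / "filter_counts.tsv", seed,
    )
    return artifacts
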