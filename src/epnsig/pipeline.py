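"""Pipeline orchestration: composable stages driven by one YAML config.

Stages run in the fixed order ``simulate -> select_markers -> normalize ->
classify -> stats``; each stage reads/writes files under the output
directory through :mod:`epnsig.io`, so a config plus seed reproduces
byte-identical artifacts.  A ``report.json`` bundle records provenance
(config hash, seed, package version) and the stats blocks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from . import __version__
from .classify import (SignaturePanel, assign_by_reference, assign_pf,
                       assign_pfa_subgroup, classify_nell2_lama2, cluster_samples)
from .io import (load_table2, read_clinical_table, read_expression_matrix,
                 read_rcc_batch, write_assignments, write_clinical_table,
                 write_expression_matrix, write_rcc_batch, ExpressionMatrix)
from .markers import (SelectionRule, quantile_normalize, resampled_ttest_scores,
                      select_markers, variance_filter)
from .nanostring import normalize_lanes
from .simulate import (CohortDesign, NanoDesign, SurvivalDesign, SurvivalGroup,
                       simulate_microarray_cohort, simulate_nanostring_run,
                       simulate_survival)
from .stats import (fisher_exact_two_sided, fusion_concordance, km_estimate,
                    logrank_test, survivor_count)

logger = logging.getLogger("epnsig")

STAGE_ORDER = ("simulate", "select_markers", "normalize", "classify", "stats")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _nano_design_from_config(cfg: Mapping[str, Any], seed: int) -> NanoDesign:
    groups = [(name, int(n)) for name, n in cfg["groups"].items()]
    sigs = cfg.get("signature_sets")
    if sigs is None:
        defaults = {**SignaturePanel.posterior_fossa().groups,
                    **SignaturePanel.supratentorial().groups,
                    **SignaturePanel.pfa_subgroups().groups}
        sigs = {}
        for name, _ in groups:
            if name not in defaults:
                raise PipelineError(
                    f"simulate: group {name!r} has no default signature set; "
                    "provide signature_sets"
                )
            sigs[name] = list(defaults[name])
    kwargs = {k: cfg[k] for k in
              ("signature_fold", "lane_scale_sd", "dispersion", "baseline_mean",
               "hk_mean", "neg_mean") if k in cfg}
    return NanoDesign(groups=groups, signature_sets=sigs, seed=seed, **kwargs)


def _survival_design_from_config(cfg: Mapping[str, Any], seed: int) -> SurvivalDesign:
    groups = [SurvivalGroup(**g) for g in cfg["groups"]]
    window = tuple(cfg.get("censor_window_months", (24.0, 120.0)))
    return SurvivalDesign(groups=groups, censor_window_months=window, seed=seed)


def _cohort_design_from_config(cfg: Mapping[str, Any], seed: int) -> CohortDesign:
    kwargs = {k: cfg[k] for k in
              ("n_probes", "baseline_log2_mean", "baseline_log2_sd", "noise_sd")
              if k in cfg}
    entities = [(name, int(n)) for name, n in cfg["entities"].items()]
    plan = [tuple(m) for m in cfg.get("marker_plan", [])]
    return CohortDesign(entities=entities, marker_plan=plan, seed=seed, **kwargs)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the report bundle (also written
    to ``report.json`` under ``out_dir``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    seed = config.get("seed")
    if "simulate" in stages and seed is None:
        raise PipelineError("simulate: config must set a seed for stochastic stages")

    report: dict[str, Any] = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "epnsig_version": __version__,
        },
        "stages": {},
    }

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else out_dir / path

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        cfg = stages[stage] or {}
        t0 = time.perf_counter()
        try:
            block = _run_stage(stage, cfg, seed, resolve)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage context added
            raise PipelineError(f"{stage}: {exc}") from exc
        report["stages"][stage] = block
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _run_stage(stage: str, cfg: Mapping[str, Any], seed: Optional[int], resolve) -> dict:
    if stage == "simulate":
        block: dict[str, Any] = {}
        if "nanostring" in cfg:
            design = _nano_design_from_config(cfg["nanostring"], seed)
            lanes = simulate_nanostring_run(design)
            rcc_dir = resolve(cfg["nanostring"].get("out", "rcc"))
            write_rcc_batch(lanes, rcc_dir)
            block["nanostring"] = {"n_lanes": len(lanes), "out": cfg["nanostring"].get("out", "rcc")}
        if "microarray" in cfg:
            design = _cohort_design_from_config(cfg["microarray"], seed)
            matrix = simulate_microarray_cohort(design)
            mpath = resolve(cfg["microarray"].get("out", "matrix_linear.tsv"))
            write_expression_matrix(matrix, mpath, mpath.with_suffix(".labels.tsv"))
            block["microarray"] = {"n_probes": len(matrix.probe_ids),
                                   "n_samples": len(matrix.sample_ids),
                                   "out": mpath.name}
        if "survival" in cfg:
            design = _survival_design_from_config(cfg["survival"], seed)
            records = simulate_survival(design)
            cpath = resolve(cfg["survival"].get("out", "clinical.csv"))
            write_clinical_table(records, cpath)
            block["survival"] = {"n_patients": len(records), "out": cpath.name}
        if not block:
            raise PipelineError("simulate: nothing to simulate "
                                "(need nanostring/microarray/survival)")
        return block

    if stage == "select_markers":
        matrix = read_expression_matrix(resolve(cfg["matrix"]),
                                        resolve(cfg["labels"]))
        rule = SelectionRule(
            min_fold=cfg.get("min_fold", 5.0),
            max_rank=cfg.get("top", 20),
            n_iterations=cfg.get("iterations", 100),
            variance_threshold=cfg.get("variance_threshold", 0.25),
        )
        log2 = quantile_normalize(matrix).to_log2()
        filtered = variance_filter(log2, rule.variance_threshold)
        scores = resampled_ttest_scores(filtered, cfg["target"],
                                        n_iterations=rule.n_iterations,
                                        seed=seed if seed is not None else 0)
        selected = select_markers(scores, rule)
        spath = resolve(cfg.get("out", "marker_scores.tsv"))
        with spath.open("w") as fh:
            fh.write("probe_id\tmean_p\tmean_fold\tmax_fold\trank\tselected\n")
            for s in scores:
                fh.write(f"{s.probe_id}\t{s.mean_p:.6g}\t{s.mean_fold:.6g}\t"
                         f"{s.max_fold:.6g}\t{s.significance_rank}\t"
                         f"{int(s.probe_id in selected)}\n")
        return {"target": cfg["target"], "n_selected": len(selected),
                "selected": selected, "out": spath.name}

    if stage == "normalize":
        lanes = read_rcc_batch(resolve(cfg["rcc_dir"]))
        hk = cfg.get("hk", ["ACTB", "GAPDH", "TBP"])
        norm = normalize_lanes(lanes, hk_genes=hk,
                               subtract_background=cfg.get("subtract_background", False))
        mpath = resolve(cfg.get("out", "normalized.tsv"))
        write_expression_matrix(
            ExpressionMatrix(norm.data, scale="log2"), mpath)
        flagged = {s: sorted(f) for s, f in norm.qc_flags.items() if f}
        return {"n_lanes": len(lanes), "qc_flags": flagged, "out": mpath.name}

    if stage == "classify":
        matrix = read_expression_matrix(resolve(cfg["matrix"]))
        compartment = cfg.get("compartment", "PF")
        panel = SignaturePanel(
            {g: tuple(genes) for g, genes in cfg["panel"].items()}
        ) if "panel" in cfg else None
        if compartment == "PF":
            assignments = assign_pf(matrix.data, panel)
            pfa = [a.sample_id for a in assignments if a.label == "PFA"]
            subgroup_genes = SignaturePanel.pfa_subgroups().all_genes
            if len(pfa) >= 3 and all(g in matrix.data.index for g in subgroup_genes):
                assignments += assign_pfa_subgroup(matrix.data[pfa])
            assignments += classify_nell2_lama2(matrix.data)
        elif compartment == "ST":
            refs_cfg = cfg.get("references")
            if refs_cfg is None:
                raise PipelineError("classify: ST compartment needs references")
            if isinstance(refs_cfg, str):
                refs = {}
                for line in resolve(refs_cfg).read_text().splitlines():
                    if not line.strip() or line.startswith("sample"):
                        continue
                    sid, group = line.split("\t")[:2]
                    refs[sid] = group
            else:
                refs = dict(refs_cfg)
            use_panel = panel or SignaturePanel.supratentorial()
            cut = cluster_samples(matrix.data, use_panel.all_genes)
            assignments = assign_by_reference(cut, matrix.data, refs, use_panel)
        else:
            raise PipelineError(f"classify: unknown compartment {compartment!r}")
        apath = resolve(cfg.get("out", "assignments.tsv"))
        write_assignments(assignments, apath)
        counts: dict[str, int] = {}
        for a in assignments:
            counts[a.label] = counts.get(a.label, 0) + 1
        return {"label_counts": counts, "out": apath.name}

    if stage == "stats":
        source = cfg.get("clinical", "packaged:table2")
        if source == "packaged:table2":
            records = load_table2()
        else:
            records = read_clinical_table(resolve(source))
        block: dict[str, Any] = {"n_patients": len(records)}
        if cfg.get("fusion_concordance", True):
            table = fusion_concordance(records)
            block["fusion_concordance"] = {
                "table": [[table.a, table.b], [table.c, table.d]],
                "fisher_p": fisher_exact_two_sided(table),
            }
        if "survivor_count" in cfg:
            sc = cfg["survivor_count"]
            block["survivor_count"] = survivor_count(
                records, sc["group"], sc["min_months"])
        endpoint = cfg.get("endpoint", "OS")
        groups = sorted({r.group_label for r in records})
        km_block = {}
        for g in groups:
            recs = [r for r in records if r.group_label == g]
            try:
                curve = km_estimate(recs, endpoint)
            except ValueError:
                continue
            km_block[g] = {
                "times": curve.times.tolist(),
                "survival": curve.survival.tolist(),
                "n_events": curve.n_events,
            }
        block[f"km_{endpoint}"] = km_block
        if cfg.get("logrank") and len(groups) > 1:
            chi2, p = logrank_test(records, endpoint=endpoint)
            block["logrank"] = {"chi2": chi2, "p": p}
        return block

    raise PipelineError(f"unknown stage {stage!r}")
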