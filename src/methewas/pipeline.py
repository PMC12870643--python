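"""Orchestration of the full study flow from one configuration file.

Stages: simulate -> qc -> deconvolve -> technical PCs -> primary EWAS ->
sensitivity / never-smoker EWAS -> annotation summaries -> MRS threshold
sweep -> external replication -> (optional) enrichment. Every stage
consumes and produces plain files in the run directory, so any stage can
be re-run in place, and a machine-readable ``run_manifest.json`` records
inputs, outputs, parameters and row counts per stage. All randomness is
seeded from the configuration; rerunning a config reproduces every
numeric output bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    SimulationConfig,
    annotate,
    enrichment,
    ewas,
    io as mio,
    mrs,
    qc as qcmod,
    simulate,
)
from .deconv import estimate_fractions

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


DEFAULTS = {
    "qc": {
        "fail_alpha": 0.05,
        "max_fail_fraction": 0.10,
        "pass_alpha": 0.05,
        "min_pass_fraction": 0.96,
    },
    "ewas": {
        "n_technical_pcs": 5,
        "n_ancestry_pcs": 10,
        "use_computed_ews_threshold": False,
        "ews_alpha": ewas.EWS_ALPHA,
        "min_cases_sensitivity": 50,
    },
    "mrs": {
        "discovery_fraction": 0.75,
        "r_cutoff": 0.3,
        "stratify": False,
        "n_bootstrap": 1000,
    },
    "replication": {"n_samples": 0, "n_cases": 0, "attenuation": 1.0},
    "enrichment": {"gene_sets": None, "relaxed_threshold": 5e-05},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise PipelineError("pipeline config must be a mapping")
    if "seed" not in cfg:
        raise PipelineError("pipeline config must set an explicit 'seed'")
    merged = {k: dict(v) for k, v in DEFAULTS.items()}
    for key, val in cfg.items():
        if key in merged and isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    merged.setdefault("simulate", {})
    return merged


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Execute every stage; returns the run manifest (also written as JSON)."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(config), "stages": []}
    seed = int(config["seed"])

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                info = fn()
            except Exception as exc:  # halt with stage name, keep partials
                manifest["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
                _write_manifest(manifest, out)
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            info = info or {}
            info.update({"stage": name, "status": "ok", "seconds": round(time.time() - t0, 3)})
            manifest["stages"].append(info)
            logger.info("stage %s: %s", name, {k: v for k, v in info.items() if k != "stage"})
            return info

        return deco

    state: dict = {}

    @stage("simulate")
    def _sim():
        sim_cfg = SimulationConfig(**{**config.get("simulate", {}), "seed": seed})
        ds = simulate.generate_dataset(sim_cfg)
        paths = simulate.write_dataset(ds, out / "data")
        state["ds"] = ds
        return {"outputs": paths, "n_samples": ds.beta.shape[1], "n_probes": ds.beta.shape[0]}

    @stage("qc")
    def _qc():
        ds = state["ds"]
        q = config["qc"]
        report = qcmod.run_qc(
            ds.detection_p,
            fail_alpha=q["fail_alpha"],
            max_fail_fraction=q["max_fail_fraction"],
            pass_alpha=q["pass_alpha"],
            min_pass_fraction=q["min_pass_fraction"],
        )
        blocklist = mio.read_blocklist(q["blocklist"]) if q.get("blocklist") else []
        beta = qcmod.apply_qc(ds.beta, report, blocklist)
        mio.write_matrix(beta, out / "beta_qc.tsv")
        qcmod.report_to_frame(report).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        state["beta"] = beta
        return {
            "probes_retained": beta.shape[0],
            "samples_retained": beta.shape[1],
            "probes_excluded": len(report.excluded_probes),
            "samples_excluded": len(report.excluded_samples),
        }

    @stage("deconvolve")
    def _deconv():
        ds = state["ds"]
        beta = state["beta"]
        markers = [p for p in ds.reference_panel.marker_probes if p in beta.index]
        panel = ds.reference_panel
        if len(markers) < len(panel.marker_probes):
            panel = type(panel)(panel.profiles.loc[markers])
        fracs = estimate_fractions(beta, panel)
        samples = ds.samples.loc[beta.columns].join(fracs)
        mio.write_sample_table(samples, out / "samples_with_fractions.tsv")
        state["samples"] = samples
        state["cell_cols"] = fracs.columns.tolist()
        return {"cell_types": fracs.columns.tolist()}

    @stage("technical_pcs")
    def _tpcs():
        ds = state["ds"]
        k = config["ewas"]["n_technical_pcs"]
        tpcs = ewas.compute_technical_pcs(ds.control_probes[state["beta"].columns], k=k)
        state["samples"] = state["samples"].join(tpcs)
        state["tpc_cols"] = tpcs.columns.tolist()
        return {"k": k}

    @stage("ewas_primary")
    def _primary():
        beta, samples = state["beta"], state["samples"]
        e = config["ewas"]
        pc_cols = [f"pc{i+1}" for i in range(e["n_ancestry_pcs"])]
        covs = ["age", "sex", "scanner_id"] + state["cell_cols"] + pc_cols + state["tpc_cols"]
        state["covariates"] = covs
        res = ewas.run_ewas(beta, samples, covariates=covs, bacon_seed=seed)
        state["primary"] = res
        alpha = (
            ewas.ews_threshold(beta.shape[0])
            if e["use_computed_ews_threshold"]
            else e["ews_alpha"]
        )
        state["alpha"] = alpha
        ewas.result_to_frame(res, state["ds"].annotation.probes).to_csv(
            out / "ewas_primary.tsv", sep="\t"
        )
        hits = res.significant(alpha)
        return {
            "lambda": res.lambda_,
            "n_cases": res.n_cases,
            "ews_alpha": alpha,
            "n_significant": len(hits),
        }

    @stage("ewas_sensitivity")
    def _sens():
        beta, samples = state["beta"], state["samples"]
        e = config["ewas"]
        try:
            res = ewas.sensitivity_ewas(
                beta, samples, covariates=state["covariates"],
                min_cases=e["min_cases_sensitivity"], bacon_seed=seed + 1,
            )
        except ewas.EwasError as exc:
            return {"skipped": str(exc)}
        ewas.result_to_frame(res, state["ds"].annotation.probes).to_csv(
            out / "ewas_sensitivity.tsv", sep="\t"
        )
        state["sensitivity"] = res
        return {"lambda": res.lambda_, "n_significant": len(res.significant(state["alpha"]))}

    @stage("ewas_never_smokers")
    def _never():
        beta, samples = state["beta"], state["samples"]
        e = config["ewas"]
        try:
            res = ewas.never_smoker_ewas(
                beta, samples, covariates=state["covariates"],
                min_cases=e["min_cases_sensitivity"], bacon_seed=seed + 2,
            )
        except ewas.EwasError as exc:
            return {"skipped": str(exc)}
        ewas.result_to_frame(res, state["ds"].annotation.probes).to_csv(
            out / "ewas_never_smokers.tsv", sep="\t"
        )
        return {"lambda": res.lambda_, "n_significant": len(res.significant(state["alpha"]))}

    @stage("annotate")
    def _ann():
        res = state["primary"]
        ds = state["ds"]
        hits = res.significant(state["alpha"])
        summary = annotate.direction_summary(hits["coefficient"])
        if len(hits):
            relation = ds.annotation.classify(hits.index.tolist())
            summary["island_relation_counts"] = relation.value_counts().to_dict()
            summary["genes"] = annotate.map_sites_to_genes(hits.index.tolist(), ds.annotation)
        with open(out / "significant_sites_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        return {"direction": {k: summary[k] for k in ("hypo", "hyper", "zero")}}

    @stage("mrs_sweep")
    def _sweep():
        beta, samples = state["beta"], state["samples"]
        mcfg = config["mrs"]
        disc, valid = mrs.split_cohort(
            samples.index,
            phenotype=samples["phenotype"].to_numpy(),
            discovery_fraction=mcfg["discovery_fraction"],
            seed=seed,
            stratify_by_phenotype=mcfg["stratify"],
        )
        disc_res = ewas.run_ewas(
            beta[disc], samples.loc[disc], covariates=state["covariates"], bacon_seed=seed + 3
        )
        sweep = mrs.threshold_sweep(
            disc_res,
            beta[disc],
            beta[valid],
            samples.loc[valid, "phenotype"].to_numpy(),
            r_cutoff=mcfg["r_cutoff"],
            n_bootstrap=mcfg["n_bootstrap"],
            seed=seed,
        )
        sweep.to_csv(out / "mrs_sweep.tsv", sep="\t", index=False)
        state["discovery_result"] = disc_res
        state["discovery_ids"] = disc
        state["beta_discovery"] = beta[disc]
        return {"n_discovery": len(disc), "n_validation": len(valid)}

    @stage("replication")
    def _repl():
        r = config["replication"]
        if not r["n_samples"]:
            return {"skipped": "no replication cohort configured"}
        ds = state["ds"]
        rep = simulate.generate_replication_cohort(
            ds.truth, r["n_samples"], r["n_cases"], seed=seed + 10,
            attenuation=r["attenuation"],
        )
        rows = []
        for thr in (0.05, 0.01, 0.005, 0.001):
            sel = mrs.select_sites(state["primary"], thr)
            if sel.empty:
                rows.append({"p_threshold": thr, "n_sites": 0, "auc": np.nan})
                continue
            kept = mrs.prune_comethylated(
                state["beta"], sel.index.tolist(), config["mrs"]["r_cutoff"]
            )
            model = mrs.MrsModel(thr, sel.loc[kept, ["weight"]], config["mrs"]["r_cutoff"])
            scores = mrs.compute_mrs(rep.beta, model)
            auc = mrs.evaluate_mrs_auc(scores, rep.samples["phenotype"].to_numpy())
            rows.append({"p_threshold": thr, "n_sites": len(kept), "auc": auc})
        pd.DataFrame(rows).to_csv(out / "replication_auc.tsv", sep="\t", index=False)
        return {"n_samples": r["n_samples"], "aucs": [round(x["auc"], 4) for x in rows if x["n_sites"]]}

    @stage("enrichment")
    def _enrich():
        ecfg = config["enrichment"]
        if not ecfg.get("gene_sets"):
            return {"skipped": "no gene-set collection configured"}
        gene_sets = mio.read_gmt(ecfg["gene_sets"])
        ds = state["ds"]
        background = annotate.map_sites_to_genes(
            state["beta"].index.tolist(), ds.annotation
        )
        genes = enrichment.relaxed_gene_set(
            state["primary"], ds.annotation, threshold=ecfg["relaxed_threshold"]
        )
        genes = [g for g in genes if g in set(background)]
        if not genes:
            return {"skipped": "no genes below the relaxed threshold"}
        table = enrichment.enrich(genes, gene_sets, background)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return {"n_query_genes": len(genes), "n_sets": len(gene_sets)}

    _write_manifest(manifest, out)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
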