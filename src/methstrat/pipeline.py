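"""End-to-end orchestration: simulate → preprocess → cluster → classify →
distill → outcome statistics → differential testing.

A single declarative YAML config drives the run; every stage writes its
outputs under the run directory and the manifest records per-stage files
with content hashes, so a run is auditable and reproducible: identical
config and seed give byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classification, clustering, differential, outcome_stats, preprocessing
from .synthetic_data import (
    SimConfig,
    generate_cohort,
    generate_expression,
    generate_gene_models,
    write_cohort,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "cluster",
    "classify",
    "distill",
    "outcome_stats",
    "differential",
)

_DEPENDS = {
    "preprocess": ("simulate",),
    "cluster": ("preprocess",),
    "classify": ("cluster",),
    "distill": ("classify",),
    "outcome_stats": ("classify",),
    "differential": ("preprocess", "classify"),
}

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "simulate": {
        "discovery": {"cluster_sizes": [15, 11, 13],
                      "event_rates": [1 / 15, 5 / 11, 8 / 13],
                      "control_n": 22},
        "validation": {"cluster_sizes": [12, 11, 17],
                       "event_rates": [1 / 12, 4 / 11, 13 / 17],
                       "control_n": 0},
    },
    "thresholds": {
        "sd_threshold": 0.25,
        "k": 3,
        "k_min": 5,
        "k_max": 200,
        "k_step": 5,
        "p_threshold": 0.05,
        "delta_beta_min": 0.1,
        "detection_threshold": 0.01,
    },
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``DEFAULT_CONFIG`` for keys)."""

    seed: int = 0
    stages: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG["stages"]))
    simulate: dict = field(default_factory=lambda: DEFAULT_CONFIG["simulate"])
    thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFIG["thresholds"])
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"seed", "stages", "simulate", "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.stages.update(raw.get("stages", {}))
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        for cohort, block in (raw.get("simulate") or {}).items():
            cfg.simulate.setdefault(cohort, {}).update(block or {})
        cfg.thresholds.update(raw.get("thresholds", {}))
        th = cfg.thresholds
        if not 0 < th["detection_threshold"] < 1 or not 0 < th["p_threshold"] < 1:
            raise ValueError("p-value thresholds must lie in (0, 1)")
        if th["k"] < 1 or th["k_min"] < 1 or th["k_max"] < th["k_min"]:
            raise ValueError("invalid cluster count or distillation grid")
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_dependencies(stages: dict) -> None:
    for stage, needs in _DEPENDS.items():
        if stages.get(stage):
            for dep in needs:
                if not stages.get(dep):
                    raise ValueError(
                        f"stage '{stage}' is enabled but its dependency "
                        f"'{dep}' is disabled"
                    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest (also written to ``manifest.json``): seed,
    thresholds, and per-stage output files with SHA-256 hashes.  Any stage
    failure raises with the stage name attached.
    """
    _check_dependencies(config.stages)
    os.makedirs(outdir, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "thresholds": dict(config.thresholds),
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage):
            continue
        runner = globals()[f"_stage_{stage}"]
        try:
            outputs = runner(config, outdir, state)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            os.path.basename(p): _sha256(p) for p in outputs
        }
        logger.info("stage %s: %d output(s)", stage, len(outputs))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _sim_config(block: dict, name: str, seed: int) -> SimConfig:
    kwargs = dict(block)
    kwargs.setdefault("cohort_name", name)
    kwargs.setdefault("sample_prefix", name[0].upper())
    kwargs.setdefault("seed", seed)
    if "cluster_sizes" in kwargs:
        kwargs["cluster_sizes"] = tuple(kwargs["cluster_sizes"])
    if "event_rates" in kwargs:
        kwargs["event_rates"] = tuple(kwargs["event_rates"])
    if "cluster_mean_beta" in kwargs:
        kwargs["cluster_mean_beta"] = tuple(kwargs["cluster_mean_beta"])
    return SimConfig(**kwargs)


def _stage_simulate(config, outdir, state):
    outputs = []
    for i, (name, block) in enumerate(sorted(config.simulate.items())):
        cohort = generate_cohort(_sim_config(block, name, config.seed + i))
        state[f"cohort_{name}"] = cohort
        outputs.extend(write_cohort(cohort, outdir).values())
    return sorted(set(outputs))


def _stage_preprocess(config, outdir, state):
    th = config.thresholds
    outputs = []
    for key in list(state):
        if not key.startswith("cohort_"):
            continue
        cohort = state[key]
        filtered = preprocessing.filter_probes(
            cohort.beta, cohort.annotation,
            detection_threshold=th["detection_threshold"],
        )
        state[f"filtered_{key.removeprefix('cohort_')}"] = filtered
        path = os.path.join(outdir, f"beta_filtered_{cohort.config.cohort_name}.tsv")
        preprocessing.write_beta_tsv(filtered, path)
        outputs.append(path)
    return outputs


def _stage_cluster(config, outdir, state):
    th = config.thresholds
    cohort = state["cohort_discovery"]
    beta = state["filtered_discovery"][cohort.patient_ids]
    model = clustering.fit_cluster_model(
        beta, sd_threshold=th["sd_threshold"], k=th["k"]
    )
    state["model"] = model
    path = os.path.join(outdir, "model.json")
    model.to_json(path)
    return [path]


def _stage_classify(config, outdir, state):
    model = state["model"]
    cohort = state["cohort_validation"]
    beta = state["filtered_validation"].loc[
        model.signature_probes, cohort.patient_ids
    ]
    calls = classification.classify_nearest_centroid(beta, model.centroids)
    state["calls"] = calls
    path = os.path.join(outdir, "calls.tsv")
    calls.to_csv(path, sep="\t", index_label="sample_id")
    return [path]


def _stage_distill(config, outdir, state):
    th = config.thresholds
    model = state["model"]
    disc = state["cohort_discovery"]
    val = state["cohort_validation"]
    curve = classification.distill_signature(
        state["filtered_discovery"].loc[model.signature_probes, disc.patient_ids],
        model.labels,
        state["filtered_validation"].loc[model.signature_probes, val.patient_ids],
        k_min=th["k_min"], k_max=th["k_max"], step=th["k_step"],
    )
    state["curve"] = curve
    path = os.path.join(outdir, "curve.tsv")
    curve.to_frame().to_csv(path, sep="\t", index=False)
    return [path]


def _stage_outcome_stats(config, outdir, state):
    model = state["model"]
    disc = state["cohort_discovery"]
    val = state["cohort_validation"]

    results = {}
    for name, labels, samples in (
        ("discovery", model.labels, disc.samples),
        ("validation", state["calls"]["label"], val.samples),
    ):
        events = samples["event_4yr"].reindex(labels.index)
        summary = outcome_stats.cluster_event_summary(labels, events)
        tab = pd.DataFrame({"cluster": labels, "event": events})
        full = outcome_stats.logistic_fit_formula(tab, "event", ["cluster"])
        km = outcome_stats.kaplan_meier(
            samples.loc[labels.index, "followup_months"], events
        )
        results[name] = {
            "summary": summary.reset_index().to_dict(orient="records"),
            "lrt_p": full.lrt_p["cluster"],
            "km": km.to_dict(orient="list"),
        }
    path = os.path.join(outdir, "results.json")
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, default=float)
    state["stats"] = results
    return [path]


def _stage_differential(config, outdir, state):
    th = config.thresholds
    disc = state["cohort_discovery"]
    val = state["cohort_validation"]
    beta = pd.concat(
        [
            state["filtered_discovery"][disc.patient_ids],
            state["filtered_validation"][val.patient_ids],
        ],
        axis=1,
        join="inner",
    )
    events = pd.concat(
        [disc.samples["event_4yr"], val.samples["event_4yr"]]
    ).reindex(beta.columns)
    mvals = preprocessing.beta_to_m(beta)
    res = differential.moderated_two_group_test(mvals, events, beta=beta)
    dmps = differential.call_dmps(
        res, p_threshold=th["p_threshold"], delta_beta_min=th["delta_beta_min"]
    )

    genes = generate_gene_models(disc.annotation, seed=config.seed)
    mapping = preprocessing.annotate_promoters(disc.annotation, genes)
    meth_genes = differential.project_to_promoter_genes(dmps, mapping)

    # expression arm: a small RNA subset of the discovery cohort
    rna_ids = list(disc.patient_ids[:8])
    rna_samples = disc.samples.loc[rna_ids]
    de_truth = list(genes["gene_id"][: len(genes) // 8])
    expr = generate_expression(
        rna_samples, genes["gene_id"], de_genes=de_truth, seed=config.seed
    )
    expr = differential.drop_all_zero_genes(expr)
    if rna_samples["event_4yr"].nunique() == 2 and min(
        rna_samples["event_4yr"].value_counts()
    ) >= 2:
        de_res = differential.moderated_two_group_test(
            expr, rna_samples["event_4yr"]
        )
        de_genes = list(differential.call_de_genes(de_res, th["p_threshold"]))
    else:  # too unbalanced to test
        de_genes = []
    overlap = differential.overlap_gene_lists(meth_genes, de_genes)

    path = os.path.join(outdir, "differential.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "n_dmps": int(len(dmps)),
                "d0": res.d0,
                "s0_sq": res.s0_sq,
                "meth_genes": meth_genes,
                "de_genes": de_genes,
                "overlap_genes": overlap,
            },
            fh,
            indent=1,
        )
    state["differential"] = {"dmps": dmps, "overlap": overlap}
    return [path]


def summary_report(outdir) -> pd.DataFrame:
    """Assemble the headline table from a completed run directory.

    One row per cohort x cluster with n, events, event proportion and its
    exact 95% CI, plus the cohort-level cluster-association p-value and the
    smallest signature size whose validation calls disagree with the full
    signature at most once.
    """
    with open(os.path.join(outdir, "results.json")) as fh:
        results = json.load(fh)
    curve = pd.read_csv(os.path.join(outdir, "curve.tsv"), sep="\t")
    ok = curve[curve["errors"] <= 1]
    min_k = int(ok["k"].iloc[0]) if len(ok) else None

    rows = []
    for cohort, block in results.items():
        for rec in block["summary"]:
            rows.append(
                {
                    "cohort": cohort,
                    "cluster": rec["cluster"],
                    "n": rec["n"],
                    "events": rec["events"],
                    "proportion": rec["proportion"],
                    "pct": rec["pct"],
                    "ci_low_pct": rec["ci_low_pct"],
                    "ci_high_pct": rec["ci_high_pct"],
                    "cluster_lrt_p": block["lrt_p"],
                    "min_recapitulating_k": min_k,
                }
            )
    report = pd.DataFrame(rows)
    report.to_csv(os.path.join(outdir, "report.tsv"), sep="\t", index=False)
    return report
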