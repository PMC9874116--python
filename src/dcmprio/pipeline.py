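"""End-to-end orchestration: simulate -> preprocess -> deg -> train ->
weights -> evaluate -> immune, with a JSON run manifest.

Every stage writes plain TSV/JSON artifacts into the output directory and
the manifest records the config snapshot, per-stage seeds and a SHA-256
digest of every file, so a rerun with the same config and seed can be
verified byte for byte (candidate lists and weight tables are
deterministic given the seed).
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as dio
from .degs import deg_table, select_degs
from .diagnostics import evaluate_candidates
from .immune import correlate, significance_filter
from .models import FAMILIES, fit_all_models
from .preprocess import preprocess_pipeline
from .synthetic import default_config, generate_dataset, generate_fractions, SynthConfig
from .weighting import normalize_weights, select_candidates, weight_table_report

_STAGES = ("simulate", "preprocess", "deg", "train", "weights",
           "evaluate", "immune")


def default_pipeline_config() -> dict:
    return {
        "seed": 0,
        "synthetic": {"n_genes": 500},
        "preprocess": {"ratio": 5.0, "linear_scale": False},
        "deg": {"logfc": 1.0, "fdr": 0.001, "method": "welch_t"},
        "train": {"families": list(FAMILIES), "compute_cv": True},
        "weights": {"threshold": 1.0},
        "immune": {"enabled": True, "n_cell_types": 22,
                   "linked": [["G0010", 0, 0.6]], "alpha": 0.05},
    }


def _stage_seeds(seed: int) -> dict:
    # independent 31-bit seeds per stage, all derived from the global seed
    states = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {s: int(v % (2 ** 31)) for s, v in zip(_STAGES, states)}


def _synth_config_from(section: dict, seed: int) -> SynthConfig:
    section = dict(section)
    if "samples_per_batch" in section or "planted" in section:
        section.setdefault("n_genes", 500)
        section["samples_per_batch"] = tuple(
            tuple(p) for p in section["samples_per_batch"]
        )
        section["planted"] = tuple(tuple(p) for p in section.get("planted", ()))
        section["seed"] = seed
        return SynthConfig(**section)
    return default_config(seed=seed, n_genes=int(section.get("n_genes", 500)))


def run_all(config: dict, out_dir, seed=None) -> dict:
    """Run the whole pipeline; returns the manifest dictionary.

    ``seed`` overrides ``config['seed']``. With no differentially
    expressed genes the pipeline stops gracefully before model training
    and records the reason in the manifest.
    """
    cfg = copy.deepcopy(default_pipeline_config())
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    seeds = _stage_seeds(int(cfg["seed"]))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    def _save(name, writer):
        path = out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        files.append(path)
        return path

    manifest = {
        "version": __version__,
        "config": cfg,
        "seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stopped_at": None,
        "message": "",
    }

    # --- simulate or load ------------------------------------------------
    if "input" in cfg and cfg["input"]:
        matrix, probe_to_gene = dio.read_probe_matrix(cfg["input"]["matrix"])
        annotation = dio.read_annotation(cfg["input"]["annotation"])
        fractions_path = cfg["input"].get("fractions")
        fractions = dio.read_fractions(fractions_path) if fractions_path else None
    else:
        synth = _synth_config_from(cfg.get("synthetic") or {}, seeds["simulate"])
        ds = generate_dataset(synth)
        matrix, probe_to_gene, annotation = ds.matrix, ds.probe_to_gene, ds.annotation
        fractions = None
        _save("matrix.tsv", lambda p: dio.write_probe_matrix(matrix, probe_to_gene, p))
        _save("annotation.tsv", lambda p: dio.write_annotation(annotation, p))
        _save("truth.tsv", lambda p: pd.DataFrame(
            ds.truth, columns=["gene_id", "log2_effect"]).to_csv(p, sep="\t", index=False))

    # --- preprocess -------------------------------------------------------
    pp = cfg["preprocess"]
    gene_matrix, annotation = preprocess_pipeline(
        matrix, probe_to_gene, annotation, ratio=float(pp.get("ratio", 5.0)),
        linear_scale=bool(pp.get("linear_scale", False)),
        seed=seeds["preprocess"],
    )
    _save("expression_preprocessed.tsv",
          lambda p: dio.write_gene_matrix(gene_matrix, p))
    _save("annotation_split.tsv", lambda p: dio.write_annotation(annotation, p))

    # --- differential expression -----------------------------------------
    dcfg = cfg["deg"]
    train_cols = annotation.index[annotation["split"] == "train"]
    records = deg_table(gene_matrix[train_cols], annotation,
                        logfc_threshold=float(dcfg.get("logfc", 1.0)),
                        fdr_threshold=float(dcfg.get("fdr", 0.001)),
                        method=dcfg.get("method", "welch_t"))
    degs = select_degs(records)
    _save("degs.tsv", lambda p: degs.to_csv(p, sep="\t", index_label="gene_id"))
    _save("deg_records.tsv",
          lambda p: records.to_csv(p, sep="\t", index_label="gene_id"))

    if degs.empty:
        manifest["stopped_at"] = "train"
        manifest["message"] = (
            "no gene passed the differential-expression thresholds; "
            "model training and downstream stages were skipped"
        )
        return _finish(manifest, files, out_dir)

    # --- model suite -------------------------------------------------------
    tcfg = cfg["train"]
    deg_matrix = gene_matrix.loc[degs.index]
    fitted, importances, performance = fit_all_models(
        deg_matrix, annotation, families=tuple(tcfg.get("families", FAMILIES)),
        seed=seeds["train"], compute_cv=bool(tcfg.get("compute_cv", True)),
    )
    raw = pd.DataFrame({f: iv.weights for f, iv in importances.items()})
    _save("importances.tsv", lambda p: raw.to_csv(p, sep="\t", index_label="gene_id"))
    _save("performance.tsv", lambda p: performance.to_csv(p, sep="\t"))

    # --- overall weighting -------------------------------------------------
    wcfg = cfg["weights"]
    table = normalize_weights(importances)
    candidates = select_candidates(table, threshold=float(wcfg.get("threshold", 1.0)))
    display, full = weight_table_report(table)
    _save("overall_weights.tsv",
          lambda p: display.to_csv(p, sep="\t", index_label="gene_id"))
    _save("overall_weights_full.tsv",
          lambda p: full.to_csv(p, sep="\t", index_label="gene_id"))
    _save("candidates.txt",
          lambda p: p.write_text("".join(f"{g}\n" for g in candidates.index)))

    # --- diagnostic evaluation ----------------------------------------------
    roc, curves, group_tests = evaluate_candidates(
        gene_matrix, annotation, list(candidates.index))
    _save("roc.tsv", lambda p: roc.to_csv(p, sep="\t", index=False))
    _save("group_tests.tsv",
          lambda p: group_tests.to_csv(p, sep="\t", index=False))
    for (g, split), curve in curves.items():
        _save(f"roc_curves/{g}_{split}.tsv", lambda p, c=curve: pd.DataFrame(
            c, columns=["fpr", "tpr"]).to_csv(p, sep="\t", index=False))

    # --- immune correlation --------------------------------------------------
    icfg = cfg["immune"]
    if icfg.get("enabled", True) and not candidates.empty:
        if fractions is None:
            linked = [tuple(l) for l in icfg.get("linked", [])
                      if l and l[0] in gene_matrix.index]
            fractions = generate_fractions(
                gene_matrix, annotation,
                n_cell_types=int(icfg.get("n_cell_types", 22)),
                linked=linked, seed=seeds["immune"],
            )
            _save("fractions.tsv", lambda p: dio.write_fractions(fractions, p))
        correlations = correlate(gene_matrix, fractions, list(candidates.index))
        significant = significance_filter(correlations,
                                          alpha=float(icfg.get("alpha", 0.05)))
        _save("immune_correlation.tsv",
              lambda p: correlations.to_csv(p, sep="\t", index=False))
        _save("immune_correlation_significant.tsv",
              lambda p: significant.to_csv(p, sep="\t", index=False))

    return _finish(manifest, files, out_dir)


def _finish(manifest: dict, files, out_dir: Path) -> dict:
    manifest["files"] = {
        str(p.relative_to(out_dir)): dio.sha256_file(p) for p in files
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
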