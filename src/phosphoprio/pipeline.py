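"""End-to-end orchestration: diffcall -> conserve/features -> train ->
score -> prioritize -> enrich, from a single structured config.

Stages communicate only via files (TSV/JSON) so any stage can be re-run or
inspected independently.  Every run writes a manifest listing the config
snapshot, the seed, and the SHA-256 of every output file; re-running an
unchanged config reproduces identical hashes (the manifest deliberately
carries no wall-clock timestamps so it is itself byte-reproducible).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, diffquant, enrichment, features, model
from .conservation import read_alignment_fasta, residue_conservation_score

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "test_genotype": "daf-2",
    "control_genotype": "WT",
    "auxiliary_genotypes": ["daf-16", "daf-16;daf-2"],
    "alpha": 0.05,
    "min_quant": 3,
    "ratio": 5,
    "n_benchmark_sets": 10,
    "cv_folds": 10,
    "top_fraction": 0.05,
    "n_bootstrap": 10000,
    "reference_species": "ref",
    "missing_policy": "impute-zero",
    "strict_residue": False,
}


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, output hashes, warnings."""

    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # name -> sha256
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = Path(path).parent
    cfg.setdefault("params", {})
    cfg["params"] = {**DEFAULT_PARAMS, **cfg["params"]}
    # resolve input paths relative to the config file
    cfg["inputs"] = {
        k: str((base / v)) if not Path(v).is_absolute() else v
        for k, v in cfg["inputs"].items()
    }
    if not Path(cfg["outdir"]).is_absolute():
        cfg["outdir"] = str(base / cfg["outdir"])
    return cfg


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, name: str) -> None:
    core_io.write_tsv(df.round(10), path)
    manifest.outputs[name] = _sha256(path)


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Run every stage of the prioritization workflow.

    ``config`` is a dict (or path to a YAML file) with keys ``inputs``
    (sites, quant, annotations, msa_dir, tree, positives, pathways),
    ``params`` and ``outdir`` plus ``seed``.  The terminal artifact is the
    table of regulated sites that also rank in the top score fraction.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    inputs = config["inputs"]
    seed = int(config.get("seed", model.DEFAULT_SEED))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={**config, "params": params}, seed=seed)

    # --- stage 1: differential calling -----------------------------------
    quant_df = core_io.read_tsv(inputs["quant"])
    quant_df = diffquant.normalize_quant_frame(quant_df)
    norm_path = outdir / "quant_normalized.tsv"
    _write(quant_df, norm_path, manifest, "quant_normalized")
    isoforms = core_io.read_quant_table(norm_path)
    calls, spread = diffquant.call_differential(
        isoforms,
        test_genotype=params["test_genotype"],
        control_genotype=params["control_genotype"],
        auxiliary_genotypes=params["auxiliary_genotypes"],
        min_quant=params["min_quant"],
        alpha=params["alpha"],
    )
    _write(calls, outdir / "diffcalls.tsv", manifest, "diffcalls")
    regulated = diffquant.expand_to_sites(calls)
    _write(regulated, outdir / "regulated_sites.tsv", manifest, "regulated_sites")
    if regulated["conflict"].any():
        manifest.warnings.append(
            f"{int(regulated['conflict'].sum())} site rows with conflicting directions"
        )

    # --- stage 2: conservation + feature encoding ------------------------
    sites, proteins = core_io.read_site_table(inputs["sites"])
    tree = core_io.read_newick(inputs["tree"])
    msa_dir = Path(inputs["msa_dir"])
    rcs: dict[str, float] = {}
    for site in sites:
        msa_path = msa_dir / f"{site.accession}.fasta"
        if not msa_path.exists():
            continue  # treated as missing annotation under the policy
        aln = read_alignment_fasta(msa_path, params["reference_species"])
        score = residue_conservation_score(
            aln, tree, site, strict_residue=params["strict_residue"]
        )
        rcs[site.site_id] = score.rcs
    cons_df = pd.DataFrame(sorted(rcs.items()), columns=["site_id", "rcs"])
    _write(cons_df, outdir / "conservation.tsv", manifest, "conservation")

    bundle = core_io.read_annotations(inputs["annotations"])
    core_io.validate_annotations(bundle, proteins, strict=True)
    table = features.assemble_feature_table(
        sites, bundle, rcs, missing_policy=params["missing_policy"]
    )
    _write(table.reset_index(), outdir / "features.tsv", manifest, "features")

    # --- stage 3: training and scoring -----------------------------------
    positive_ids = [
        line.strip()
        for line in Path(inputs["positives"]).read_text().splitlines()
        if line.strip()
    ]
    unknown = set(positive_ids) - set(table.index)
    if unknown:
        raise ValueError(f"positive sites absent from feature table: {sorted(unknown)[:5]}")
    positives = table.loc[positive_ids]
    pool = table.drop(index=positive_ids)
    benchmarks = model.build_benchmarks(
        positives, pool, ratio=params["ratio"],
        n_sets=params["n_benchmark_sets"], seed=seed,
    )
    final, aucs = model.select_final_model(
        benchmarks, k=params["cv_folds"], seed=seed
    )
    best_cv = model.cross_validate(
        benchmarks[final.benchmark_index], k=params["cv_folds"], seed=seed
    )
    ci = model.bootstrap_auc_ci(
        best_cv.oof_scores, best_cv.labels,
        n_boot=params["n_bootstrap"], seed=seed,
    )
    _write(best_cv.sn_sp, outdir / "cv_report.tsv", manifest, "cv_report")

    raw = final.decision_scores(table)
    normalizer = model.fit_normalizer(raw)
    norm = normalizer.normalize(raw)
    scores = pd.DataFrame(
        {"site_id": table.index, "raw_score": raw, "score": norm}
    ).sort_values("score", ascending=False, kind="mergesort")
    _write(scores, outdir / "scores.tsv", manifest, "scores")

    model_path = outdir / "model.json"
    model_blob = {
        "model": final.to_dict(),
        "normalizer": normalizer.to_dict(),
        "cv_auc_per_benchmark": [float(a) for a in aucs],
        "cv_auc_best": float(final.cv_auc),
        "auc_ci95": [float(ci[0]), float(ci[1])],
    }
    model_path.write_text(json.dumps(model_blob, indent=2, sort_keys=True))
    manifest.outputs["model"] = _sha256(model_path)

    # --- stage 4: prioritization ------------------------------------------
    score_series = pd.Series(
        scores["score"].to_numpy(), index=scores["site_id"]
    )
    prioritized = model.prioritize_top_fraction(
        score_series, fraction=params["top_fraction"]
    )
    lirp = model.intersect_lirp(prioritized, regulated, score_series)
    _write(lirp, outdir / "lirp.tsv", manifest, "lirp")

    # --- stage 5: enrichment ----------------------------------------------
    regulated_by_dir = {
        direction: set(sub["site_id"])
        for direction, sub in regulated.groupby("direction")
    }
    kin = enrichment.enrich_kinases(
        [s.site_id for s in sites],
        regulated_by_dir,
        bundle.kinase_edges,
        alpha=params["alpha"],
    )
    _write(kin, outdir / "kinase_enrichment.tsv", manifest, "kinase_enrichment")

    pathways = core_io.read_tsv(inputs["pathways"])
    background_genes = {s.accession for s in sites}
    regulated_genes = {sid.split(":", 1)[0] for sid in set(regulated["site_id"])}
    pw = enrichment.enrich_pathways(
        background_genes, regulated_genes, pathways, alpha=params["alpha"]
    )
    _write(pw, outdir / "pathway_enrichment.tsv", manifest, "pathway_enrichment")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True)
    )
    return manifest
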