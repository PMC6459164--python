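"""End-to-end composition: filter -> deconvolve -> DEG -> DCGP -> localization
-> evaluation, with a machine-readable run manifest."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd

import hdcn
from hdcn import io as hio
from hdcn._log import get_logger
from hdcn.containers import ExpressionMatrix
from hdcn.de import call_degs
from hdcn.deconvolution import (
    estimate_proportions,
    filter_variable_genes,
    fit_reference,
)
from hdcn.evaluation import nb_cv_auc, pca_explained_variance
from hdcn.localization import (
    detect_changes,
    features_from_expression,
    predict_profiles,
    summarize_compartment_changes,
    train_localization_classifier,
)
from hdcn.mic import call_dcgps, mic_matrix

log = get_logger("hdcn.pipeline")

DEFAULTS = {
    "cv_threshold": 0.5,
    "fc_threshold": 1.25,
    "p_threshold": 0.01,
    "n_perm": 1000,
    "delta_mic": 0.4,
    "top_k": 10000,
    "n_folds": 10,
    "n_repeats": 500,
    "quantile": 0.95,
    "n_null": 100,
    "seed": 0,
}

_REQUIRED_PATHS = ("matrix", "groups", "network", "annotations", "out_dir")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict) -> dict:
    """Run the full expression pipeline from a flat configuration mapping.

    Required keys: matrix, groups, network, annotations, out_dir. Stage
    parameters default to the pipeline's standard values (CV > 0.5,
    FC > 1.25, p < 0.01, 1000 permutations, delta MIC > 0.4, 10-fold CV).
    Any stage error aborts with the stage name; outputs written so far are
    retained. Returns the manifest.
    """
    missing = [k for k in _REQUIRED_PATHS if k not in config]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    params = {
        k: type(v)(config.get(k, v)) for k, v in DEFAULTS.items()
    }
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(params["seed"])
    manifest: dict = {
        "package": "hdcn",
        "version": hdcn.__version__,
        "python": sys.version.split()[0],
        "parameters": params,
        "stages": {},
    }

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        rec = stage("load")
        matrix = hio.read_expression_matrix(config["matrix"], config["groups"])
        network, annotations = hio.read_network_and_annotations(
            config["network"], config["annotations"]
        )
        rec.update(
            n_genes=len(matrix.gene_ids),
            n_samples=len(matrix.sample_ids),
            n_edges=network.number_of_edges(),
        )

        rec = stage("filter")
        genes = filter_variable_genes(matrix, params["cv_threshold"])
        rec.update(n_variable_genes=len(genes))

        rec = stage("deconvolve")
        ref_params = fit_reference(matrix, genes)
        result = estimate_proportions(matrix, genes, ref_params)
        result.pi_hat.rename_axis("sample_id").reset_index().to_csv(
            out_dir / "proportions.tsv", sep="\t", index=False
        )
        hio.write_expression_matrix(
            result.purified,
            out_dir / "purified.tsv",
            out_dir / "purified_groups.tsv",
        )
        rec.update(converged=result.converged, n_iter=result.n_iter)

        rec = stage("deg")
        reference = matrix.subset(genes, matrix.reference_samples)
        degs = call_degs(
            result.purified,
            reference,
            fc_threshold=params["fc_threshold"],
            p_threshold=params["p_threshold"],
            n_perm=params["n_perm"],
            seed=seed,
        )
        degs.to_csv(out_dir / "degs.tsv", sep="\t")
        rec.update(
            n_up=int((degs["call"] == "up").sum()),
            n_down=int((degs["call"] == "down").sum()),
        )

        rec = stage("dcgp")
        gene_set = set(genes)
        pairs = [
            (a, b)
            for a, b in network.edges()
            if a in gene_set and b in gene_set
        ]
        mics = mic_matrix(matrix, pairs) if pairs else pd.DataFrame(
            columns=["gene_a", "gene_b", "mic_mixed", "mic_reference", "self_pair"]
        )
        dcgps = call_dcgps(mics, params["delta_mic"])
        dcgps.to_csv(out_dir / "dcgps.tsv", sep="\t", index=False)
        rec.update(
            n_pairs=len(dcgps),
            n_up=int((dcgps["call"] == "up").sum()) if len(dcgps) else 0,
            n_down=int((dcgps["call"] == "down").sum()) if len(dcgps) else 0,
        )

        rec = stage("localize")
        mixed_expr = matrix.subset(samples=matrix.mixed_samples)
        ref_expr = matrix.subset(samples=matrix.reference_samples)
        feats_mixed = features_from_expression(mixed_expr, network, annotations)
        feats_ref = features_from_expression(ref_expr, network, annotations)
        classifier, cv_acc = train_localization_classifier(
            feats_ref, annotations, seed=seed
        )
        profile = predict_profiles(classifier, feats_mixed, feats_ref)
        changed, threshold, _ = detect_changes(
            profile,
            classifier,
            network,
            annotations,
            mixed_expr,
            ref_expr,
            threshold_quantile=params["quantile"],
            n_null=params["n_null"],
            seed=seed,
        )
        prof_rows = []
        for cond, probs in (
            ("mixed", profile.probs_mixed),
            ("reference", profile.probs_reference),
        ):
            block = probs.copy()
            block.insert(0, "condition", cond)
            prof_rows.append(block.rename_axis("protein").reset_index())
        pd.concat(prof_rows).to_csv(out_dir / "profiles.tsv", sep="\t", index=False)
        changes = pd.DataFrame(
            {
                "protein": list(profile.change_score.index),
                "change_score": profile.change_score.values,
                "top_mixed": profile.top_mixed.values,
                "top_reference": profile.top_reference.values,
                "changed": [p in changed for p in profile.change_score.index],
            }
        )
        changes.to_csv(out_dir / "localization_changes.tsv", sep="\t", index=False)
        summary = summarize_compartment_changes(changed, profile)
        summary.to_csv(out_dir / "compartment_summary.tsv", sep="\t", index=False)
        rec.update(
            cv_accuracy=cv_acc,
            n_changed=len(changed),
            null_threshold=threshold,
        )

        rec = stage("evaluate")
        deg_genes = list(degs.index[degs["call"] != "none"])
        combined = ExpressionMatrix(
            pd.concat(
                [result.purified.values, reference.values], axis=1
            ),
            {**result.purified.groups, **reference.groups},
        )
        if len(deg_genes) >= 2:
            pca = pca_explained_variance(combined, deg_genes, k=3)
            auc_mean, auc_sd = nb_cv_auc(
                combined,
                deg_genes,
                n_folds=params["n_folds"],
                n_repeats=params["n_repeats"],
                seed=seed,
            )
            rec.update(
                pca_proportions=[float(p) for p in pca],
                auc_mean=auc_mean,
                auc_sd=auc_sd,
            )
        else:
            log.warning("fewer than 2 DEGs; skipping evaluation stage metrics")
            rec.update(pca_proportions=None, auc_mean=None, auc_sd=None)
    except Exception as exc:  # abort with stage context, keep partial outputs
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(failed, exc) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["run_pipeline", "StageError", "DEFAULTS"]
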