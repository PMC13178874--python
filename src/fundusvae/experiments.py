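"""Canonical desk-scale replication experiment.

One experiment = the full benchmark (simulate, train four models, evaluate
disentanglement, perturbation locality, genetic association) repeated over a
small set of seeds; the aggregate summarizes the comparisons the framework is
designed around:

* dedicated-block disentanglement of each structure stream vs the monolithic
  baseline, on identical PCA-orthogonalized factor targets;
* left/right-eye consistency of the block disentanglement scores;
* vessel-stream traversal locality vs the monolithic model;
* causal-SNP recovery and stream attribution in the toy association scan,
  plus null calibration (type-I error, min-P family-wise error rate, false
  loci under the global null).

Problem sizes are chosen so the whole experiment runs on a single CPU in
minutes: 120 training subjects (paired eyes, 32 x 32 px), 10 epochs per
stream, 250 evaluation subjects with 10 resampling iterations of n = 400,
and 2,000 single-eye subjects with 200 independent SNPs for the association
stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .pipeline import (
    AssociationSettings,
    EvaluationSettings,
    PerturbationSettings,
    PipelineConfig,
    SimulationSettings,
    TrainingSettings,
    run_benchmark,
)

__all__ = ["replication_config", "smoke_config", "run_replication", "aggregate_reports"]


def replication_config(seed: int) -> PipelineConfig:
    """The canonical study conditions for one replication seed."""
    return PipelineConfig(
        seed=seed,
        simulation=SimulationSettings(n_subjects=120, eval_subjects=250, resolution=32),
        training=TrainingSettings(epochs=10),
        evaluation=EvaluationSettings(resample_iters=10, resample_n=400),
        perturbation=PerturbationSettings(n_base_images=16, steps=7),
        association=AssociationSettings(n_subjects=2000, n_snps=200),
    )


def smoke_config(seed: int) -> PipelineConfig:
    """A minutes-scale configuration exercising every stage end to end."""
    return PipelineConfig(
        seed=seed,
        simulation=SimulationSettings(n_subjects=40, eval_subjects=60, resolution=32),
        training=TrainingSettings(epochs=2),
        evaluation=EvaluationSettings(resample_iters=2, resample_n=100),
        perturbation=PerturbationSettings(n_base_images=4, steps=5),
        association=AssociationSettings(
            n_subjects=300, n_snps=40, null_scans=2, fwer_replicates=50
        ),
    )


def run_replication(seeds: Sequence[int], verbose: bool = False) -> list[dict]:
    """Run the canonical benchmark once per seed."""
    return [run_benchmark(replication_config(s), verbose=verbose) for s in seeds]


def aggregate_reports(reports: Sequence[dict]) -> dict:
    """Seed-level pass counts and cross-seed means of the headline quantities."""
    n = len(reports)

    def mean(path):
        vals = []
        for r in reports:
            v = r
            for k in path:
                v = v[k]
            vals.append(float(v))
        return float(np.mean(vals))

    agg: dict = {"n_seeds": n}
    for st in ("background", "disc_cup", "vessel"):
        agg[f"block_D_{st}"] = mean(("dci", "blocks", st, "block_D"))
        agg[f"block_superior_{st}"] = sum(
            r["dci"]["blocks"][st]["superior"] for r in reports
        )
        agg[f"interocular_diff_{st}"] = mean(("interocular", st, "abs_diff"))
        agg[f"interocular_ok_{st}"] = sum(
            r["interocular"][st]["within_tolerance"] for r in reports
        )
    agg["mono_D"] = mean(("dci", "mono_D", "mean"))
    agg["savae_D"] = mean(("dci", "savae_D", "mean"))
    agg["savae_I"] = mean(("dci", "savae_I", "mean"))
    agg["mono_I"] = mean(("dci", "mono_I", "mean"))
    agg["savae_MIG"] = mean(("dci", "savae_MIG", "mean"))
    agg["mono_MIG"] = mean(("dci", "mono_MIG", "mean"))
    agg["locality_vessel"] = mean(("locality", "vessel"))
    agg["locality_monolithic"] = mean(("locality", "monolithic"))
    agg["locality_superior"] = sum(r["locality"]["superior"] for r in reports)
    agg["savae_recovery_rate"] = mean(("association", "savae_recovery_rate"))
    agg["monolithic_recovery_rate"] = mean(("association", "monolithic_recovery_rate"))
    agg["attribution_accuracy"] = mean(("association", "attribution_accuracy"))
    agg["recovery_ge_monolithic"] = sum(
        r["association"]["savae_recovery_rate"] >= r["association"]["monolithic_recovery_rate"]
        for r in reports
    )
    agg["type_i_error"] = mean(("association", "type_i_error"))
    agg["minp_fwer"] = mean(("association", "minp_fwer"))
    agg["null_loci_strict_total"] = int(
        sum(r["association"]["null_loci_strict"] for r in reports)
    )
    agg["null_loci_analog_first"] = int(reports[0]["association"]["null_loci_total"])
    for st in ("background", "disc_cup", "vessel", "monolithic"):
        agg[f"val_ssim_{st}"] = mean(("training", st, "val_ssim"))
        agg[f"recon_ssim_{st}"] = mean(("reconstruction", st, "SSIM", "mean"))
        agg[f"recon_psnr_{st}"] = mean(("reconstruction", st, "PSNR", "mean"))
    return agg
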