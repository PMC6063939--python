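"""End-to-end orchestration: simulate -> qc -> pca -> assoc -> prs -> evaluate.

``run_all`` drives the whole comparison from one config and writes every
stage hand-off to plain files in the run directory, along with a manifest
recording the config, derived per-stage seeds, row/variant counts and
sha256 checksums — re-running with the same config reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import logistic_assoc, pca
from .evaluation import (
    billing_count_sweep,
    compare_channels,
    fold_statistics,
    overlap_report,
    summarize,
)
from .genotype_qc import run_qc
from .prs_model import cross_validated_scores, default_grid, make_folds
from .synthetic_cohort import ChannelSpec, SimConfig, simulate_cohort, write_cohort

__all__ = ["load_config", "run_all", "sha256_file"]

log = logging.getLogger("phenoscore")


def load_config(path: str | os.PathLike) -> dict:
    """Load the flat YAML run config (SimConfig fields + pipeline settings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return raw


def config_from_dict(raw: dict) -> tuple[SimConfig, dict]:
    """Split a raw config mapping into a SimConfig and pipeline settings."""
    raw = dict(raw)
    pipeline_keys = {
        "pcs": 2,
        "folds": 5,
        "grid_min": 5e-5,
        "grid_max": 0.1,
        "grid_n": 12,
        "maf_min": 0.01,
        "callrate_min": 0.90,
        "hwe_alpha": 1e-6,
        "prune_window": 50,
        "prune_step": 5,
        "prune_vif_max": 10.0,
        "billing_sweep": True,
    }
    settings = {k: raw.pop(k, v) for k, v in pipeline_keys.items()}
    if "channels" in raw:
        chans = raw["channels"]
        if not isinstance(chans, (list, tuple)) or len(chans) == 0:
            raise ValueError("config field 'channels' must be a non-empty list")
        parsed = []
        for c in chans:
            missing = {"name", "sensitivity", "specificity"} - set(c)
            if missing:
                raise ValueError(
                    f"channel block {c!r} missing field(s): {sorted(missing)}"
                )
            parsed.append(
                ChannelSpec(c["name"], c["sensitivity"], c["specificity"])
            )
        raw["channels"] = tuple(parsed)
    if "billing_count_params" in raw:
        raw["billing_count_params"] = tuple(raw["billing_count_params"])
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return SimConfig(**raw), settings


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _channel_spec_dict(c: ChannelSpec) -> dict:
    return {"name": c.name, "sensitivity": c.sensitivity, "specificity": c.specificity}


def run_all(
    config: dict | SimConfig,
    out_dir: str | os.PathLike,
    seed: int | None = None,
    settings: dict | None = None,
) -> Path:
    """Run the full channel-comparison pipeline into *out_dir*.

    Returns the run directory.  Any stage failure propagates with the stage
    named in the log; partial outputs are left in place for debugging.
    """
    t0 = time.time()
    if isinstance(config, SimConfig):
        sim_cfg, defaults = config, config_from_dict({})[1]
        settings = {**defaults, **(settings or {})}
    else:
        sim_cfg, parsed = config_from_dict(config)
        settings = {**parsed, **(settings or {})}
    if seed is not None:
        sim_cfg = SimConfig(**{**asdict_sim(sim_cfg), "seed": int(seed)})

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "package_version": __version__,
        "seed": sim_cfg.seed,
        "config": {
            **asdict_sim(sim_cfg),
            "channels": [_channel_spec_dict(c) for c in sim_cfg.channels],
        },
        "settings": settings,
        "stages": {},
        "checksums": {},
    }

    def _stage(name):
        log.info("stage %s: start", name)
        return time.time()

    def _done(name, t, **counts):
        log.info("stage %s: done in %.1fs %s", name, time.time() - t, counts)
        manifest["stages"][name] = {"seconds": round(time.time() - t, 2), **counts}

    try:
        # ---------------------------------------------------------- simulate
        t = _stage("simulate")
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, out / "cohort")
        pheno = cohort.phenotype_frame()
        _done(
            "simulate",
            t,
            n_samples=cohort.genotypes.n_samples,
            n_variants=cohort.genotypes.n_variants,
            n_true_cases=int(cohort.true_status.sum()),
        )

        # ---------------------------------------------------------------- qc
        t = _stage("qc")
        gm, qc_report = run_qc(
            cohort.genotypes,
            maf_min=settings["maf_min"],
            callrate_min=settings["callrate_min"],
            hwe_alpha=settings["hwe_alpha"],
            window=settings["prune_window"],
            step=settings["prune_step"],
            vif_max=settings["prune_vif_max"],
        )
        qc_report.to_tsv(out / "qc_report.tsv")
        _done("qc", t, n_retained=qc_report.n_retained)

        # --------------------------------------------------------------- pca
        t = _stage("pca")
        k = int(settings["pcs"])
        pcs = pca(gm, k)
        if k > 0:
            pd.DataFrame(
                pcs.components,
                columns=[f"PC{i + 1}" for i in range(k)],
            ).assign(sample_id=gm.sample_ids).to_csv(
                out / "pcs.tsv", sep="\t", index=False
            )
        covariates = pcs.components if k > 0 else None
        _done("pca", t, k=k)

        # ------------------------------------------------------------- assoc
        # full-cohort association per channel, for lambda_gc diagnostics
        t = _stage("assoc")
        channel_names = list(cohort.labels.columns)
        lambdas = {}
        for name in channel_names:
            labels = pheno[name].to_numpy()
            assoc = logistic_assoc(gm, labels, covariates=covariates)
            assoc.to_tsv(out / f"assoc_{name}.tsv")
            lambdas[name] = assoc.lambda_gc
        _done("assoc", t, lambda_gc=lambdas)

        # --------------------------------------------------------------- prs
        t = _stage("prs")
        grid = default_grid(
            settings["grid_min"], settings["grid_max"], int(settings["grid_n"])
        )
        plan = make_folds(
            cohort.labels, k=int(settings["folds"]), seed=sim_cfg.seed
        )
        pd.DataFrame(
            {"sample_id": gm.sample_ids, "fold": plan.assignments}
        ).to_csv(out / "folds.tsv", sep="\t", index=False)
        cv_results = {}
        score_frames = []
        for name in channel_names:
            labels = pheno[name].to_numpy()
            cv = cross_validated_scores(
                gm, labels, covariates, grid, plan, channel=name
            )
            cv_results[name] = cv
            score_frames.append(cv.to_frame(gm.sample_ids))
            for fold, assoc in enumerate(cv.fold_assoc):
                assoc.to_tsv(out / f"assoc_{name}_fold{fold}.tsv")
        pd.concat(score_frames, ignore_index=True).to_csv(
            out / "scores.tsv", sep="\t", index=False, float_format="%.10g"
        )
        _done(
            "prs",
            t,
            best_thresholds={n: cv_results[n].best_threshold for n in channel_names},
        )

        # ---------------------------------------------------------- evaluate
        t = _stage("evaluate")
        summaries = {}
        for name in channel_names:
            cv = cv_results[name]
            labels = pheno[name].to_numpy()
            stats_df = fold_statistics(cv.scores_at_best(), labels, plan)
            summaries[name] = summarize(
                stats_df, name, labels, threshold=cv.best_threshold
            )
        ranking = compare_channels(
            summaries, plans={n: id(plan) for n in channel_names}
        )
        ranking.to_csv(out / "report.tsv", sep="\t", index=False)

        if len(channel_names) >= 2:
            ov = overlap_report(cohort.labels)
            ov.by_degree.to_csv(out / "overlap.tsv", sep="\t", index=False)

        sweep_rows = []
        if settings["billing_sweep"] and "billing" in channel_names:
            sweep = billing_count_sweep(
                gm, cohort.billing_counts, covariates, grid, plan
            )
            sweep_rows = [s.to_row() for s in sweep.values()]
            pd.DataFrame(sweep_rows).to_csv(
                out / "billing_sweep.tsv", sep="\t", index=False
            )

        with open(out / "ranking.txt", "w") as fh:
            fh.write(render_ranking(ranking, lambdas))
        _done("evaluate", t, n_channels=len(channel_names))

    except Exception as exc:  # noqa: BLE001 - re-raised after logging the stage
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in ("manifest.json", "run.log"):
            manifest["checksums"][f.name] = sha256_file(f)
    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def asdict_sim(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["channels"] = tuple(
        ChannelSpec(**c) if isinstance(c, dict) else c for c in cfg.channels
    )
    d["billing_count_params"] = tuple(cfg.billing_count_params)
    return d


def render_ranking(ranking: pd.DataFrame, lambdas: dict[str, float]) -> str:
    lines = [
        "Channel ranking by cross-validated PRS AUC",
        "(statistics are fold means with sample SDs; each channel is",
        " evaluated against its own labels on held-out folds)",
        "",
    ]
    for _, r in ranking.iterrows():
        tie = " (tied)" if r.get("tied", False) else ""
        lines.append(
            f"{int(r['rank'])}. {r['channel']}{tie}: "
            f"AUC {r['auc']:.4f} ({r['auc_sd']:.4f}), "
            f"mean diff {r['mean_diff']:.5f} ({r['mean_diff_sd']:.5f}), "
            f"OR/SD {r['or_per_sd']:.3f} ({r['or_per_sd_sd']:.3f}), "
            f"cases {int(r['n_cases'])}, controls {int(r['n_controls'])}"
        )
    lines.append("")
    lines.append("Genomic inflation (full-cohort association, PC-adjusted):")
    for name, lam in lambdas.items():
        lines.append(f"  lambda_gc[{name}] = {lam:.4f}")
    lines.append("")
    return "\n".join(lines)
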