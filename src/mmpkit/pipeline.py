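"""End-to-end orchestration: simulate -> rates -> mmp -> stability ->
predict -> absorb, with plain-file handoff and a reproducibility manifest.

Every stage reads and writes declared TSV/JSON files only, so deleting
intermediates and re-running with the same config regenerates
byte-identical outputs for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mmpkit import __version__
from mmpkit.absorption import (
    GAMMA_CACO,
    GAMMA_DIALYSIS,
    predict_cohort_absorption,
)
from mmpkit.community import (
    filter_low_depth,
    rarefy,
    relative_abundance,
    train_high_low_classifier,
)
from mmpkit.data_io import OtuTable, read_otu_table, read_scfa_table, write_scfa_table, write_otu_table
from mmpkit.mmp import (
    MmpMatrix,
    binarize_high_low,
    build_mmp_matrix,
    stability_test,
    upgma_cluster,
    zscore_columns,
)
from mmpkit.rates import rate_table, replicate_cv
from mmpkit.simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rates", "mmp", "stability", "predict", "absorb")


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record(self, stage: str, outputs: list[Path]) -> None:
        digests = {}
        for p in outputs:
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages.append({"stage": stage, "outputs": digests})

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "package_version": self.package_version,
                    "stages": self.stages,
                    "elapsed_s": round(time.time() - self.started, 3),
                },
                indent=2,
            )
        )


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the enabled stages in order; abort naming the failing stage.

    ``config`` keys: ``seed``, ``stages`` (subset of STAGES), ``dialect``,
    ``simulate`` (CohortConfig overrides), ``scfa_table``/``otu_table``
    (paths, when the simulate stage is disabled), ``min_reads``,
    ``gamma_source`` (``dialysis``/``caco``), ``tau``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    dialect = config.get("dialect", "A")
    manifest = RunManifest(
        config_hash=_hash_config(config), seed=seed, package_version=__version__
    )

    paths = {
        "scfa_v1": out / "scfa_visit1.tsv",
        "scfa_v2": out / "scfa_visit2.tsv",
        "otus": out / "otu_table.tsv",
        "rates_v1": out / "rates_visit1.tsv",
        "rates_v2": out / "rates_visit2.tsv",
        "zmatrix": out / "zmatrix.tsv",
        "clusters": out / "clusters.tsv",
        "qc": out / "replicate_qc.tsv",
        "stability": out / "stability.json",
        "report": out / "classifier_report.json",
        "absorb": out / "absorption.tsv",
    }

    for stage in stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                sim_over = dict(config.get("simulate", {}))
                cohort = generate_cohort(CohortConfig(seed=seed, **sim_over))
                write_scfa_table(cohort.series[1], paths["scfa_v1"], dialect)
                write_scfa_table(cohort.series[2], paths["scfa_v2"], dialect)
                write_otu_table(
                    OtuTable(
                        sample_ids=list(cohort.otu_counts.index),
                        otu_ids=list(cohort.otu_counts.columns),
                        counts=cohort.otu_counts.to_numpy(),
                        taxonomy=cohort.taxonomy,
                    ),
                    paths["otus"],
                )
                manifest.record(stage, [paths["scfa_v1"], paths["scfa_v2"], paths["otus"]])
            elif stage == "rates":
                src1 = Path(config.get("scfa_table", paths["scfa_v1"]))
                if not src1.exists():
                    raise StageError(f"rates stage: input {src1} missing")
                series1 = read_scfa_table(src1, dialect)
                rate_table(series1).to_csv(paths["rates_v1"], sep="\t", index=False)
                qc = replicate_cv(series1)
                qc.per_pair.to_csv(paths["qc"], sep="\t", index=False)
                outputs = [paths["rates_v1"], paths["qc"]]
                if paths["scfa_v2"].exists():
                    series2 = read_scfa_table(paths["scfa_v2"], dialect)
                    rate_table(series2).to_csv(paths["rates_v2"], sep="\t", index=False)
                    outputs.append(paths["rates_v2"])
                logger.info("overall replicate CV: %.1f%%", qc.overall_cv)
                manifest.record(stage, outputs)
            elif stage == "mmp":
                rates = pd.read_csv(paths["rates_v1"], sep="\t")
                z = zscore_columns(build_mmp_matrix(rates))
                z.values.to_csv(paths["zmatrix"], sep="\t")
                _, labels = upgma_cluster(z, k=int(config.get("clusters", 2)))
                labels.to_csv(paths["clusters"], sep="\t")
                manifest.record(stage, [paths["zmatrix"], paths["clusters"]])
            elif stage == "stability":
                if not paths["rates_v2"].exists():
                    raise StageError("stability stage: no visit-2 rates available")
                z1 = zscore_columns(build_mmp_matrix(pd.read_csv(paths["rates_v1"], sep="\t")))
                z2 = zscore_columns(build_mmp_matrix(pd.read_csv(paths["rates_v2"], sep="\t")))
                ct, p = stability_test(binarize_high_low(z1), binarize_high_low(z2))
                paths["stability"].write_text(
                    json.dumps(
                        {"table": ct.table.tolist(), "n_cells": ct.n_cells,
                         "fisher_p_two_tailed": p},
                        indent=2,
                    )
                )
                manifest.record(stage, [paths["stability"]])
            elif stage == "predict":
                otu_path = Path(config.get("otu_table", paths["otus"]))
                if not otu_path.exists():
                    raise StageError(f"predict stage: OTU table {otu_path} missing")
                table = read_otu_table(otu_path)
                table, dropped = filter_low_depth(table, int(config.get("min_reads", 5000)))
                rel = relative_abundance(table)
                z = zscore_columns(build_mmp_matrix(pd.read_csv(paths["rates_v1"], sep="\t")))
                target = config.get("target_column", "inulin:propionate")
                labels = binarize_high_low(z)[target]
                labels = labels.loc[[d for d in labels.index if d in rel.values.index]]
                report = train_high_low_classifier(rel, labels, seed=seed)
                paths["report"].write_text(
                    json.dumps(
                        {"target": target, "dropped_samples": dropped,
                         "fold_aucs": report.fold_aucs, "mean_auc": report.mean_auc,
                         "top_importances": report.importances.head(10).to_dict(),
                         "seed": seed, **report.metadata},
                        indent=2,
                    )
                )
                manifest.record(stage, [paths["report"]])
            elif stage == "absorb":
                rates = pd.read_csv(paths["rates_v1"], sep="\t")
                raw = build_mmp_matrix(rates)
                gamma = GAMMA_CACO if config.get("gamma_source") == "caco" else GAMMA_DIALYSIS
                df = predict_cohort_absorption(
                    raw, gamma=gamma, tau=float(config.get("tau", 12.0))
                )
                df.to_csv(paths["absorb"], sep="\t", index=False)
                manifest.record(stage, [paths["absorb"]])
            else:
                raise StageError(f"unknown stage {stage!r}")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2f s", stage, time.time() - t0)

    manifest.write(out / "manifest.json")
    return manifest


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
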