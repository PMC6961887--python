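"""End-to-end workflow: calibrate → quantify → (correct, aggregate) → test.

Each stage writes its intermediate table and appends structured entries to
a JSON report, so every excluded taxon, QC flag and fallback is auditable.
Outputs are deterministic given identical inputs (no timestamps are
written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as qio
from .calibration import fit_standard_curve
from .qmp import (
    aggregate_rank,
    copy_number_correct,
    estimate_absolute,
    prevalence_filter,
    relative_abundances,
)
from .stats import ModelSelectionRule, test_taxa

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and completed artifacts."""

    def __init__(self, stage: str, message: str, artifacts: dict[str, str]):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.artifacts = artifacts


@dataclass
class RunConfig:
    """Paths and options steering one pipeline run.

    ``design_path`` (sample_id + binary ``intervention`` column) enables
    the per-taxon testing stage; without it the pipeline stops after
    quantification.
    """

    counts_path: str
    standards_path: str
    plate_path: str
    metadata_path: str
    out_dir: str
    copy_number_path: str | None = None
    design_path: str | None = None
    total_assay: str = "total_bacteria"
    prevalence_threshold: float | None = 1e-4  # None disables the filter
    cn_fallback: str = "table_mean"
    rank: str | None = None
    test_space: str = "absolute"
    spread_limit: float = 0.5
    outlier_k: float = 2.0
    zero_fraction_threshold: float = 0.3
    dispersion_test_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("counts_path", "standards_path", "plate_path", "metadata_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for name in ("copy_number_path", "design_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns result objects and artifact paths.

    Stages: (1) fit standard curves and calibrate the plate to per-sample
    total load; (2) count table → relative abundances → absolute
    abundances, with optional prevalence filtering, copy-number correction
    and rank aggregation; (3) optional per-taxon differential-abundance
    tests.  Any stage error aborts with the stage name and the paths of
    artifacts already written.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    report: dict = {"stages": [], "exclusions": [], "warnings": []}
    stage = "calibrate"
    try:
        standards = qio.read_standards(config.standards_path)
        curves = {a: fit_standard_curve(pts, assay_id=a) for a, pts in standards.items()}
        replicates = qio.read_qpcr_plate(
            config.plate_path,
            spread_limit=config.spread_limit,
            outlier_k=config.outlier_k,
        )
        meta = qio.read_metadata(config.metadata_path)
        from .calibration import calibrate_samples

        load_frame = calibrate_samples(replicates, curves, meta)
        load_path = out_dir / "load.tsv"
        qio.write_total_load(load_frame, load_path)
        artifacts["load"] = str(load_path)
        for _, row in load_frame.iterrows():
            if row["qc_flags"]:
                report["warnings"].append(
                    {"stage": stage, "sample": row["sample_id"],
                     "assay": row["assay_id"], "qc_flags": row["qc_flags"]}
                )
        report["stages"].append(
            {
                "name": stage,
                "assays": {
                    a: {
                        "slope": c.slope,
                        "intercept": c.intercept,
                        "r_squared": c.r_squared,
                        "efficiency_percent": (
                            c.efficiency_percent if c.valid else None
                        ),
                        "valid": c.valid,
                    }
                    for a, c in curves.items()
                },
            }
        )

        stage = "quantify"
        counts = qio.read_count_table(config.counts_path)
        if config.prevalence_threshold is not None:
            counts, dropped = prevalence_filter(counts, config.prevalence_threshold)
            for t in dropped:
                report["exclusions"].append(
                    {"stage": stage, "taxon": t, "reason": "prevalence_below_threshold"}
                )
        rel = relative_abundances(counts)
        loads = qio.read_total_load(load_path, assay_id=config.total_assay)
        qmp = estimate_absolute(rel, loads)
        if config.copy_number_path is not None:
            cn = qio.read_copy_number_table(config.copy_number_path)
            import warnings as _warnings

            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                qmp = copy_number_correct(qmp, cn, fallback=config.cn_fallback)
            for w in caught:
                report["warnings"].append({"stage": stage, "message": str(w.message)})
        if config.rank is not None:
            qmp = aggregate_rank(qmp, config.rank)
        qmp_path = out_dir / "qmp.tsv"
        qio.write_qmp_table(qmp, qmp_path)
        artifacts["qmp"] = str(qmp_path)
        report["stages"].append(
            {"name": stage, "n_taxa": int(len(qmp.taxa)),
             "n_samples": int(len(qmp.samples)), "units": qmp.unit_state}
        )

        if config.design_path is not None:
            stage = "test"
            design = pd.read_csv(config.design_path, sep="\t")
            if not {"sample_id", "intervention"} <= set(design.columns):
                raise ValueError(
                    "design file needs columns: sample_id, intervention"
                )
            design = design.set_index("sample_id").reindex(qmp.samples)
            if design["intervention"].isna().any():
                missing = list(design.index[design["intervention"].isna()])
                raise ValueError(f"design missing samples: {missing}")
            covariate = design["intervention"].to_numpy(float)
            rule = ModelSelectionRule(
                zero_fraction_threshold=config.zero_fraction_threshold,
                dispersion_test_alpha=config.dispersion_test_alpha,
            )
            results = test_taxa(
                qmp.data, covariate,
                space="absolute" if config.test_space == "absolute" else "counts",
                rule=rule,
            )
            res_path = out_dir / "results.tsv"
            results.to_csv(res_path, sep="\t", index=False, na_rep="NA")
            artifacts["results"] = str(res_path)
            report["stages"].append(
                {"name": stage, "space": config.test_space,
                 "n_tested": int(len(results))}
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc), artifacts) from exc

    report_path = out_dir / "report.json"
    with report_path.open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["report"] = str(report_path)
    return {"artifacts": artifacts, "report": report}
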