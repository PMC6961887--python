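"""Shared fixtures: a small synthetic qPCR + sequencing study.

All fixture files are generated programmatically so tests carry no data
payload.  The study is internally consistent: plate Ct values are derived
by inverting the standard curve at known per-sample loads, so calibration
must recover those loads exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from qmprofiler import io as qio
from qmprofiler.calibration import SampleMeta, StandardPoint
from qmprofiler.simulate import SimConfig, counts_to_table, simulate_dataset

# perfect-doubling slope: one cycle per factor of 2
SLOPE_100 = -1.0 / math.log10(2.0)


@pytest.fixture(scope="session")
def sim_config():
    # small dimensions keep pipeline fixtures quick; statistics elsewhere
    # use the full presets
    return SimConfig(
        n_taxa=6, n_subjects=4, timepoints=(0, 1, 2, 3),
        intervention_window=(2, 3), effect_size=3.0, depth=20_000, seed=7,
    )


@pytest.fixture(scope="session")
def sim_counts(sim_config):
    return counts_to_table(simulate_dataset(sim_config, replicate=0))


@pytest.fixture()
def study_files(tmp_path, sim_counts, sim_config):
    """Write a coherent study to disk; returns a dict of paths + truths."""
    samples = list(sim_counts.samples)
    rng = np.random.default_rng(11)
    loads = pd.Series(
        10 ** rng.uniform(10.5, 11.5, len(samples)), index=samples
    )
    meta = {
        s: SampleMeta(
            sample_id=s, feces_mass_g=0.125, dna_yield_ng=5000.0, template_ng=0.5
        )
        for s in samples
    }
    slope, intercept = -3.4, 39.0
    std_rows, plate_rows = [], []
    for assay in ("total_bacteria",):
        for k in range(2, 8):
            for rep in range(3):
                std_rows.append(
                    {"assay_id": assay, "copies": 10.0 ** k, "replicate": rep,
                     "ct": intercept + slope * k}
                )
    for s in samples:
        m = meta[s]
        copies_rxn = loads[s] * m.feces_mass_g * m.template_ng / m.dna_yield_ng
        ct = intercept + slope * math.log10(copies_rxn)
        for rep in range(3):
            plate_rows.append(
                {"sample_id": s, "assay_id": "total_bacteria",
                 "replicate": rep, "ct": ct}
            )
    paths = {
        "counts": tmp_path / "counts.tsv",
        "standards": tmp_path / "standards.csv",
        "plate": tmp_path / "plate.csv",
        "meta": tmp_path / "meta.tsv",
        "cn": tmp_path / "cn.tsv",
        "design": tmp_path / "design.tsv",
        "out_dir": tmp_path / "out",
    }
    qio.write_count_table(sim_counts, paths["counts"])
    qio.write_standards(pd.DataFrame(std_rows), paths["standards"])
    qio.write_qpcr_plate(pd.DataFrame(plate_rows), paths["plate"])
    qio.write_metadata(meta, paths["meta"])
    cn = pd.DataFrame(
        {
            "taxon": [f"taxon_{j}" for j in range(sim_config.n_taxa)],
            "rank": "genus",
            "copy_number": rng.integers(1, 8, sim_config.n_taxa).astype(float),
        }
    )
    cn.to_csv(paths["cn"], sep="\t", index=False)
    in_window = {
        s: int(int(s.split("_T")[1]) in (2, 3)) for s in samples
    }
    pd.DataFrame(
        {"sample_id": samples, "intervention": [in_window[s] for s in samples]}
    ).to_csv(paths["design"], sep="\t", index=False)
    return {"paths": paths, "loads": loads, "slope": slope, "intercept": intercept}


@pytest.fixture(scope="session")
def standard_points_perfect():
    return [
        StandardPoint(copies=10.0 ** k, ct=38.0 + SLOPE_100 * k) for k in range(2, 8)
    ]
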