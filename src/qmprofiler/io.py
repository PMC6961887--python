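"""Readers and writers for the package's plain-text formats.

All files are UTF-8 TSV/CSV with header rows, ``.`` decimal separator and
``NA`` (or an empty field) for missing values — declared explicitly because
qPCR instrument exports vary.  Every writer emits files its paired reader
parses back to equal in-memory values.

Formats
-------
count table TSV
    First column ``taxon`` holding a greengenes-style lineage
    ``k__...;p__...;c__...;o__...;f__...;g__...;s__...``; one integer
    column per sample.  The taxon's display name is its finest classified
    rank label.
qPCR plate CSV
    ``sample_id, assay_id, replicate, ct``; missing Ct = non-detect.
standards CSV
    ``assay_id, copies, replicate, ct``.
metadata TSV
    ``sample_id, feces_mass_g, dna_yield_ng, template_ng``.
copy-number TSV
    ``taxon, rank, copy_number`` (rrnDB-style flat table).
total-load TSV
    ``sample_id, copies_per_g`` (+ QC columns when written by calibrate).
QMP TSV
    Like the count table but float abundances; the unit state is recorded
    in a leading ``# units: copies_per_g|genomes_per_g`` comment so
    downstream consumers cannot confuse copies with genome equivalents.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ReplicateSet, SampleMeta, StandardPoint, aggregate_replicates
from .qmp import RANKS, CopyNumberTable, CountTable, QmpTable

__all__ = [
    "FormatError",
    "read_count_table", "write_count_table",
    "read_qmp_table", "write_qmp_table",
    "read_qpcr_plate", "write_qpcr_plate",
    "read_standards", "write_standards",
    "read_metadata", "write_metadata",
    "read_copy_number_table", "write_copy_number_table",
    "read_total_load", "write_total_load",
]

_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


def _parse_lineage(text: str, path, lineno: int) -> tuple[str, dict]:
    fields = [f.strip() for f in text.split(";")]
    lineage: dict[str, object] = {r: np.nan for r in RANKS}
    name = None
    for f in fields:
        if not f:
            continue
        for rank, prefix in zip(RANKS, _PREFIXES):
            if f.startswith(prefix):
                label = f[len(prefix):]
                if label:
                    lineage[rank] = label
                break
        else:
            raise FormatError(
                f"{path}:{lineno}: lineage field {f!r} lacks a rank prefix "
                f"({'/'.join(_PREFIXES)})"
            )
    for rank in reversed(RANKS):
        if isinstance(lineage[rank], str):
            name = lineage[rank]
            break
    if name is None:
        raise FormatError(f"{path}:{lineno}: lineage {text!r} has no classified rank")
    return name, lineage


def _format_lineage(row: pd.Series) -> str:
    parts = []
    for rank, prefix in zip(RANKS, _PREFIXES):
        val = row.get(rank)
        parts.append(f"{prefix}{val}" if isinstance(val, str) and val else prefix)
    return ";".join(parts)


def read_count_table(path) -> CountTable:
    """Parse a lineage-keyed integer count TSV into a CountTable.

    Rejects duplicate taxon names, duplicate sample IDs and non-integer
    counts, reporting the offending line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0] != "taxon":
            raise FormatError(f"{path}:1: first column must be 'taxon', got {header[:1]}")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise FormatError(f"{path}:1: duplicate sample IDs: {dupes}")
        names, lineages, rows = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(samples) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(row)}"
                )
            name, lineage = _parse_lineage(row[0], path, lineno)
            counts = []
            for s, v in zip(samples, row[1:]):
                v = v.strip()
                try:
                    iv = int(v)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: count for sample {s!r} is not an "
                        f"integer: {v!r}"
                    ) from None
                counts.append(iv)
            names.append(name)
            lineages.append(lineage)
            rows.append(counts)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicate taxon names: {dupes}")
    data = pd.DataFrame(rows, index=pd.Index(names, name="taxon"), columns=samples)
    lineage = pd.DataFrame(lineages, index=data.index)
    return CountTable(data, lineage=lineage)


def write_count_table(table: CountTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon", *table.samples])
        for taxon in table.taxa:
            writer.writerow(
                [_format_lineage(table.lineage.loc[taxon]),
                 *(int(v) for v in table.data.loc[taxon])]
            )


def read_qmp_table(path) -> QmpTable:
    """Parse an abundance TSV with a leading ``# units:`` comment."""
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline().strip()
        if not first.startswith("# units:"):
            raise FormatError(f"{path}:1: missing '# units:' header comment")
        unit_state = first.split(":", 1)[1].strip()
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "taxon":
            raise FormatError(f"{path}:2: first column must be 'taxon'")
        samples = header[1:]
        names, lineages, rows = [], [], []
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            name, lineage = _parse_lineage(row[0], path, lineno)
            names.append(name)
            lineages.append(lineage)
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric abundance") from None
    data = pd.DataFrame(rows, index=pd.Index(names, name="taxon"), columns=samples)
    lineage = pd.DataFrame(lineages, index=data.index)
    return QmpTable(data, unit_state=unit_state, lineage=lineage)


def write_qmp_table(table: QmpTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# units: {table.unit_state}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon", *table.samples])
        for taxon in table.taxa:
            writer.writerow(
                [_format_lineage(table.lineage.loc[taxon]),
                 *(repr(float(v)) for v in table.data.loc[taxon])]
            )


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")


def read_qpcr_plate(
    path, spread_limit: float = 0.5, outlier_k: float = 2.0
) -> list[ReplicateSet]:
    """Read a plate CSV and aggregate replicates per (sample, assay).

    Empty or ``NA`` Ct fields are non-detects: excluded from the average
    and counted in the ReplicateSet.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False)
    _require_columns(df, ["sample_id", "assay_id", "replicate", "ct"], path)
    out = []
    for (sample, assay), grp in df.groupby(["sample_id", "assay_id"], sort=True):
        cts = [float(c) if pd.notna(c) else float("nan") for c in grp["ct"]]
        out.append(
            aggregate_replicates(
                cts, spread_limit=spread_limit, outlier_k=outlier_k,
                sample_id=str(sample), assay_id=str(assay),
            )
        )
    return out


def write_qpcr_plate(rows: pd.DataFrame, path) -> None:
    """Write raw plate rows (``sample_id, assay_id, replicate, ct``)."""
    rows.to_csv(path, index=False, na_rep="NA")


def read_standards(path) -> dict[str, list[StandardPoint]]:
    """Read a standard-series CSV into per-assay dilution points."""
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False)
    _require_columns(df, ["assay_id", "copies", "ct"], path)
    df = df[pd.notna(df["ct"])]
    out: dict[str, list[StandardPoint]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["assay_id"]), []).append(
            StandardPoint(copies=float(row["copies"]), ct=float(row["ct"]))
        )
    return out


def write_standards(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False, na_rep="NA")


def read_metadata(path) -> dict[str, SampleMeta]:
    """Read per-sample extraction metadata (validates invariants)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["sample_id", "feces_mass_g", "dna_yield_ng", "template_ng"], path
    )
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate sample IDs: {dupes}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = SampleMeta(
            sample_id=str(row["sample_id"]),
            feces_mass_g=float(row["feces_mass_g"]),
            dna_yield_ng=float(row["dna_yield_ng"]),
            template_ng=float(row["template_ng"]),
        )
    return out


def write_metadata(meta: dict[str, SampleMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "feces_mass_g": m.feces_mass_g,
                "dna_yield_ng": m.dna_yield_ng,
                "template_ng": m.template_ng,
            }
            for m in meta.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_copy_number_table(path) -> CopyNumberTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["taxon", "rank", "copy_number"], path)
    return CopyNumberTable(df[["taxon", "rank", "copy_number"]].copy())


def write_copy_number_table(cn: CopyNumberTable, path) -> None:
    cn.table.to_csv(path, sep="\t", index=False)


def read_total_load(path, assay_id: str | None = None) -> pd.Series:
    """Read per-sample total load (copies/g) from a calibrate output TSV.

    When the file carries multiple assays, ``assay_id`` selects the one
    providing total bacterial load.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "copies_per_g"], path)
    if "assay_id" in df.columns and assay_id is not None:
        df = df[df["assay_id"] == assay_id]
        if df.empty:
            raise FormatError(f"{path}: no rows for assay {assay_id!r}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(
            f"{path}: multiple load rows per sample {dupes}; pass assay_id"
        )
    return pd.Series(
        df["copies_per_g"].to_numpy(float), index=df["sample_id"].astype(str)
    )


def write_total_load(frame: pd.DataFrame, path) -> None:
    """Write a calibrate result frame (sample_id, ..., copies_per_g, ...)."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
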