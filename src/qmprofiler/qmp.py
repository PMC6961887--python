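"""Quantitative microbiome profiling: relative → absolute abundance tables.

The central transformation scales NGS-derived relative abundances r_st
(taxon t, sample s) by an independently measured total bacterial load T_s
(16S copies per gram of wet feces, typically from universal-primer qPCR):

    A_st = r_st * T_s        [16S copies / g]

and optionally divides by each taxon's genomic 16S copy number c_t
(rrnDB-style table) to approximate genome equivalents:

    G_st = A_st / c_t        [genome equivalents / g]

Unit states are tracked explicitly so copies/g and genomes/g cannot be
mixed silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "CountTable",
    "RelativeTable",
    "QmpTable",
    "CopyNumberTable",
    "relative_abundances",
    "prevalence_filter",
    "estimate_absolute",
    "copy_number_correct",
    "aggregate_rank",
    "functional_group_sum",
]

logger = logging.getLogger(__name__)

#: Taxonomic ranks, coarsest to finest, matching greengenes-style
#: ``k__;p__;c__;o__;f__;g__;s__`` lineage strings.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))


def _check_lineage(lineage: pd.DataFrame, taxa: pd.Index) -> pd.DataFrame:
    if lineage is None:
        lineage = pd.DataFrame(index=taxa, columns=list(RANKS), dtype=object)
    lineage = lineage.reindex(index=taxa, columns=list(RANKS))
    return lineage


@dataclass
class CountTable:
    """Integer sequencing reads per (taxon, sample) with lineage metadata.

    ``data`` holds taxa as rows and samples as columns; ``lineage`` maps
    each taxon to its name at every rank (NaN where unclassified).
    """

    data: pd.DataFrame
    lineage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.lineage = _check_lineage(self.lineage, self.data.index)

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class RelativeTable:
    """Per-sample fractions; each sample column sums to 1."""

    data: pd.DataFrame
    lineage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.lineage = _check_lineage(self.lineage, self.data.index)
        sums = self.data.sum(axis=0)
        if not np.allclose(sums, 1.0, rtol=1e-9, atol=1e-12):
            bad = sums[~np.isclose(sums, 1.0, rtol=1e-9, atol=1e-12)]
            raise ValueError(
                f"relative abundances must sum to 1 per sample; offending "
                f"samples: {list(bad.index)}"
            )

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


@dataclass
class QmpTable:
    """Absolute abundances per (taxon, sample).

    ``unit_state`` is ``"copies_per_g"`` (16S copies / g wet feces) or,
    after copy-number correction, ``"genomes_per_g"``.
    """

    data: pd.DataFrame
    unit_state: str = "copies_per_g"
    lineage: pd.DataFrame | None = None

    _UNITS = ("copies_per_g", "genomes_per_g")

    def __post_init__(self) -> None:
        if self.unit_state not in self._UNITS:
            raise ValueError(f"unknown unit_state {self.unit_state!r}")
        if (self.data.values < 0).any():
            raise ValueError("absolute abundances must be non-negative")
        self.lineage = _check_lineage(self.lineage, self.data.index)

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class CopyNumberTable:
    """Mean genomic 16S copy number per taxon name, per rank (rrnDB-style)."""

    table: pd.DataFrame  # columns: taxon, rank, copy_number

    def __post_init__(self) -> None:
        required = {"taxon", "rank", "copy_number"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"copy-number table missing columns: {sorted(missing)}")
        if (self.table["copy_number"] < 1).any():
            bad = self.table.loc[self.table["copy_number"] < 1, "taxon"].tolist()
            raise ValueError(f"16S copy numbers must be >= 1; offending taxa: {bad}")
        # case-insensitive exact lookup keyed by (rank, lower-cased name)
        self._lookup = {
            (str(r).lower(), str(t).lower()): float(c)
            for t, r, c in self.table[["taxon", "rank", "copy_number"]].itertuples(
                index=False
            )
        }

    def get(self, name: str, rank: str) -> float | None:
        return self._lookup.get((rank.lower(), str(name).lower()))

    def mean_copy_number(self) -> float:
        return float(self.table["copy_number"].mean())


def relative_abundances(counts: CountTable) -> RelativeTable:
    """Divide each sample's counts by its total reads.

    Raises
    ------
    ValueError
        Naming any sample with zero total reads (rejected, not imputed).
    """
    totals = counts.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"samples with zero reads cannot be normalized: {list(zero.index)}"
        )
    rel = counts.data.astype(float).div(totals, axis=1)
    return RelativeTable(rel, lineage=counts.lineage)


def prevalence_filter(
    counts: CountTable, min_prevalence: float = 1e-4
) -> tuple[CountTable, list[str]]:
    """Drop taxa whose share of the grand-total reads is below a threshold.

    Reads of very low overall prevalence are likely sequencing errors; the
    default threshold 1e-4 (0.01%) removes a taxon when
    ``total reads of taxon / grand total < min_prevalence`` (strictly
    below — a taxon exactly at the threshold is retained).

    Returns the filtered table and the list of dropped taxon names.
    """
    grand_total = counts.data.values.sum()
    if grand_total == 0:
        return counts, []
    prevalence = counts.data.sum(axis=1) / grand_total
    keep = prevalence >= min_prevalence
    dropped = list(counts.taxa[~keep])
    if dropped:
        logger.info(
            "prevalence_filter: dropped %d taxa below %.3g: %s",
            len(dropped),
            min_prevalence,
            dropped,
        )
    filtered = CountTable(
        counts.data.loc[keep].copy(),
        lineage=counts.lineage.loc[keep].copy(),
    )
    return filtered, dropped


def estimate_absolute(
    rel: RelativeTable, total_load: Mapping[str, float] | pd.Series
) -> QmpTable:
    """Scale relative abundances by per-sample total bacterial load.

    ``A_st = r_st * T_s`` with T_s in 16S copies/g wet feces; the output
    conserves the load: each sample's column sums to T_s.
    """
    loads = pd.Series(total_load, dtype=float)
    missing = [s for s in rel.samples if s not in loads.index]
    if missing:
        raise ValueError(f"no total load for samples: {missing}")
    bad = loads.reindex(rel.samples)
    if (bad <= 0).any() or bad.isna().any():
        raise ValueError(
            f"total loads must be positive: "
            f"{list(bad.index[(bad <= 0) | bad.isna()])}"
        )
    data = rel.data.mul(loads.reindex(rel.samples), axis=1)
    return QmpTable(data, unit_state="copies_per_g", lineage=rel.lineage)


def _taxon_rank(lineage_row: pd.Series, taxon_name: str) -> str:
    """Finest rank at which the taxon is classified; species by default."""
    for rank in reversed(RANKS):
        val = lineage_row.get(rank)
        if isinstance(val, str) and val:
            return rank
    return "species"


def copy_number_correct(
    qmp: QmpTable,
    cn: CopyNumberTable,
    fallback: str = "table_mean",
) -> QmpTable:
    """Divide taxon abundances by genomic 16S copy numbers.

    Converts 16S copies/g into genome equivalents/g, ``G_st = A_st / c_t``.
    Matching is by case-insensitive exact name at the taxon's finest
    classified rank.  Taxa absent from the table are resolved per
    ``fallback``:

    - ``"error"``: raise, listing the missing taxa;
    - ``"table_mean"`` (default): divide by the table-wide mean copy number
      (logged warning) — silent omission would bias community sums;
    - ``"ancestor"``: walk up the lineage to the nearest rank with an
      entry, then table mean if none.
    """
    if fallback not in ("error", "table_mean", "ancestor"):
        raise ValueError(f"unknown fallback policy {fallback!r}")
    if qmp.unit_state != "copies_per_g":
        raise ValueError(
            f"copy-number correction needs copies_per_g input, got "
            f"{qmp.unit_state!r}"
        )
    divisors = {}
    missing = []
    for taxon in qmp.taxa:
        lin = qmp.lineage.loc[taxon]
        rank = _taxon_rank(lin, taxon)
        c = cn.get(str(taxon), rank)
        if c is None and fallback == "ancestor":
            for up in reversed(RANKS[: RANKS.index(rank)]):
                anc = lin.get(up)
                if isinstance(anc, str) and anc:
                    c = cn.get(anc, up)
                    if c is not None:
                        break
        if c is None:
            missing.append(str(taxon))
            c = cn.mean_copy_number()
        divisors[taxon] = c
    if missing:
        if fallback == "error":
            raise KeyError(f"taxa missing from copy-number table: {missing}")
        warnings.warn(
            f"copy-number correction: {len(missing)} taxa missing from table, "
            f"using table mean {cn.mean_copy_number():.3g}: {missing}",
            stacklevel=2,
        )
    div = pd.Series(divisors).reindex(qmp.taxa)
    return QmpTable(
        qmp.data.div(div, axis=0),
        unit_state="genomes_per_g",
        lineage=qmp.lineage,
    )


def aggregate_rank(table: CountTable | QmpTable, rank: str):
    """Sum abundances over taxa sharing a label at the requested rank.

    Taxa unclassified at that rank are grouped under
    ``"unclassified_<parent>"`` where parent is the nearest classified
    ancestor label.  Per-sample totals are conserved.  Returns a table of
    the same kind as the input.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for taxon in table.taxa:
        lin = table.lineage.loc[taxon]
        val = lin.get(rank)
        if isinstance(val, str) and val:
            labels.append(val)
        else:
            parent = "root"
            for up in reversed(RANKS[: RANKS.index(rank)]):
                anc = lin.get(up)
                if isinstance(anc, str) and anc:
                    parent = anc
                    break
            labels.append(f"unclassified_{parent}")
    grouped = table.data.groupby(pd.Index(labels, name="taxon"), sort=True).sum()
    # lineage of an aggregate: ranks down to the aggregation rank, first
    # member's values (identical within group by construction for the
    # classified ones)
    keep_ranks = list(RANKS[: RANKS.index(rank) + 1])
    lin_rows = {}
    for lab, taxon in zip(labels, table.taxa):
        if lab not in lin_rows:
            row = pd.Series(index=list(RANKS), dtype=object)
            if not lab.startswith("unclassified_"):
                row[keep_ranks] = table.lineage.loc[taxon, keep_ranks]
                row[rank] = lab
            lin_rows[lab] = row
    new_lineage = pd.DataFrame(lin_rows).T.reindex(grouped.index)
    if isinstance(table, CountTable):
        return CountTable(grouped, lineage=new_lineage)
    return QmpTable(grouped, unit_state=table.unit_state, lineage=new_lineage)


def functional_group_sum(
    qmp: QmpTable, members: Iterable[str]
) -> tuple[pd.Series, list[str]]:
    """Per-sample summed abundance of a named set of taxa.

    Used e.g. to total the dominant butyrate-producing genera for
    comparison against a butyryl-CoA:acetate CoA-transferase qPCR assay.
    Matching is case-insensitive exact; returns the per-sample sums and the
    list of member names that matched nothing (raising if none matched).
    """
    members = list(members)
    if not members:
        raise ValueError("functional group must have at least one member")
    by_lower = {str(t).lower(): t for t in qmp.taxa}
    matched, unmatched = [], []
    for m in members:
        t = by_lower.get(str(m).lower())
        (matched if t is not None else unmatched).append(t if t is not None else m)
    if not matched:
        raise KeyError(f"no functional-group member matches any taxon: {members}")
    if unmatched:
        logger.warning("functional_group_sum: unmatched members: %s", unmatched)
    sums = qmp.data.loc[matched].sum(axis=0)
    sums.name = "abundance"
    return sums, unmatched
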