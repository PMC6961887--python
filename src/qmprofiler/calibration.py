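"""qPCR standard-curve calibration and absolute quantification.

Converts raw threshold-cycle (Ct) measurements into estimates of target gene
copies per gram of wet feces.  The workflow mirrors routine qPCR practice:

1. fit a standard curve (Ct vs log10 copies) from a dilution series of a
   reference amplicon,
2. aggregate replicate Ct values with outlier removal and spread QC,
3. interpolate sample Ct on the curve to copies per reaction,
4. scale by the DNA-extraction stoichiometry (template ng, total yield ng,
   feces wet mass) to copies per gram.

Relative quantification of functional genes via the comparative-Ct (ΔΔCt)
method is also provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scistats

__all__ = [
    "CalibrationError",
    "StandardPoint",
    "StandardCurve",
    "ReplicateSet",
    "SampleMeta",
    "fit_standard_curve",
    "amplification_efficiency",
    "aggregate_replicates",
    "ct_to_copies",
    "copies_per_gram",
    "comparative_ct_fold",
    "calibrate_samples",
]

#: Floor (in Ct units) on the standard deviation used in the replicate
#: outlier rule.  Deviations within the acceptable triplicate spread are
#: never "clear outliers", so the floor equals the default spread limit;
#: without it two near-identical replicates would eject any third point.
SD_FLOOR_CT = 0.5


class CalibrationError(ValueError):
    """Raised when qPCR calibration inputs are unusable."""


@dataclass(frozen=True)
class StandardPoint:
    """One point of a dilution series: known input copies and measured Ct."""

    copies: float
    ct: float

    def __post_init__(self) -> None:
        if not (self.copies > 0):
            raise CalibrationError(f"standard copies must be > 0, got {self.copies}")
        if not math.isfinite(self.ct):
            raise CalibrationError(f"standard Ct must be finite, got {self.ct}")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit Ct = intercept + slope * log10(copies).

    ``efficiency`` is the per-cycle amplification gain minus one,
    ``10**(-1/slope) - 1``; 1.0 means perfect doubling each cycle.  A curve
    with non-negative slope is physically invalid and carries
    ``valid=False`` rather than being silently dropped.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int = 0
    assay_id: str | None = None
    valid: bool = True

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


@dataclass
class ReplicateSet:
    """Replicate Ct measurements for one (sample, assay) with QC outcome."""

    sample_id: str
    assay_id: str
    cts: list[float]
    qc_spread_flag: bool = False
    removed_indices: list[int] = field(default_factory=list)
    mean_ct: float | None = None
    n_nondetect: int = 0

    @property
    def surviving_cts(self) -> list[float]:
        return [c for i, c in enumerate(self.cts) if i not in self.removed_indices]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample extraction/assay quantities linking reaction to feces.

    feces_mass_g : wet mass of feces extracted (g)
    dna_yield_ng : total DNA eluted from that mass (ng)
    template_ng  : DNA template loaded per qPCR reaction (ng)
    """

    sample_id: str
    feces_mass_g: float
    dna_yield_ng: float
    template_ng: float

    def __post_init__(self) -> None:
        for name in ("feces_mass_g", "dna_yield_ng", "template_ng"):
            if not (getattr(self, name) > 0):
                raise ValueError(
                    f"{self.sample_id}: {name} must be > 0, got {getattr(self, name)}"
                )
        if self.template_ng > self.dna_yield_ng:
            raise ValueError(
                f"{self.sample_id}: template_ng ({self.template_ng}) exceeds "
                f"dna_yield_ng ({self.dna_yield_ng})"
            )


def fit_standard_curve(
    points: list[StandardPoint], assay_id: str | None = None
) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies) over a dilution series.

    Parameters
    ----------
    points
        Dilution-series measurements; at least two distinct copy levels.

    Returns
    -------
    StandardCurve
        With slope (Ct per decade), intercept (Ct at one copy), R², and
        amplification efficiency.  A non-negative slope yields a curve with
        ``valid=False`` and an emitted warning.

    Raises
    ------
    CalibrationError
        If fewer than two distinct concentrations are supplied.
    """
    if len(points) < 2:
        raise CalibrationError("standard curve needs at least 2 points")
    log_copies = np.array([math.log10(p.copies) for p in points])
    cts = np.array([p.ct for p in points])
    if np.unique(log_copies).size < 2:
        raise CalibrationError(
            "standard curve needs at least 2 distinct copy concentrations"
        )
    res = _scistats.linregress(log_copies, cts)
    slope, intercept = float(res.slope), float(res.intercept)
    r_squared = float(res.rvalue) ** 2
    if slope < 0:
        eff = amplification_efficiency(slope)
        valid = True
    else:
        warnings.warn(
            f"standard curve for assay {assay_id!r} has non-negative slope "
            f"({slope:.4g}); curve flagged invalid",
            stacklevel=2,
        )
        eff = float("nan")
        valid = False
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        efficiency=eff,
        n_points=len(points),
        assay_id=assay_id,
        valid=valid,
    )


def amplification_efficiency(slope: float) -> float:
    """Per-cycle amplification efficiency from a standard-curve slope.

    ``E = 10**(-1/slope) - 1``; a slope of −1/log10(2) ≈ −3.3219 gives
    E = 1 (perfect doubling).  Requires ``slope < 0``.
    """
    if not (slope < 0):
        raise CalibrationError(f"efficiency undefined for slope {slope} (need < 0)")
    return 10.0 ** (-1.0 / slope) - 1.0


def aggregate_replicates(
    cts: list[float],
    spread_limit: float = 0.5,
    outlier_k: float = 2.0,
    sample_id: str = "",
    assay_id: str = "",
) -> ReplicateSet:
    """Average replicate Ct values after outlier removal and spread QC.

    Non-finite entries (NaN — non-detects) are dropped first and counted.
    A replicate is removed as a clear outlier when it deviates from the
    mean of the remaining replicates by more than ``outlier_k`` times their
    standard deviation (floored at 0.5 Ct, the acceptable spread, so
    ordinary triplicate scatter never triggers removal); at most one
    replicate is removed, and
    removal needs at least three finite replicates so the "others" define a
    spread.  After removal, ``qc_spread_flag`` is set when the surviving
    range exceeds ``spread_limit`` (default 0.5 Ct).  Flagged sets keep
    their mean: the flag propagates downstream as a warning, not an
    exclusion.
    """
    if len(cts) == 0:
        raise ValueError("aggregate_replicates: empty replicate list")
    finite_idx = [i for i, c in enumerate(cts) if c is not None and math.isfinite(c)]
    n_nondetect = len(cts) - len(finite_idx)
    rs = ReplicateSet(
        sample_id=sample_id,
        assay_id=assay_id,
        cts=list(cts),
        n_nondetect=n_nondetect,
    )
    rs.removed_indices = [i for i in range(len(cts)) if i not in finite_idx]
    survivors = [cts[i] for i in finite_idx]
    if not survivors:
        rs.qc_spread_flag = True
        rs.mean_ct = None
        return rs
    if len(survivors) >= 3:
        # leave-one-out screen: worst offender removed if it clears the bar
        worst = None
        for j, i in enumerate(finite_idx):
            others = [cts[k] for k in finite_idx if k != i]
            mu = float(np.mean(others))
            sd = max(float(np.std(others, ddof=1)), SD_FLOOR_CT)
            dev = abs(cts[i] - mu)
            if dev > outlier_k * sd and (worst is None or dev > worst[1]):
                worst = (i, dev)
        if worst is not None:
            rs.removed_indices.append(worst[0])
            survivors = [cts[i] for i in finite_idx if i != worst[0]]
    rs.removed_indices.sort()
    rs.mean_ct = float(np.mean(survivors))
    rs.qc_spread_flag = (max(survivors) - min(survivors)) > spread_limit
    return rs


def ct_to_copies(curve: StandardCurve, ct: float) -> float:
    """Invert a standard curve: Ct → copies per reaction.

    ``copies = 10**((ct - intercept) / slope)``, strictly decreasing in Ct
    for a valid (negative-slope) curve.
    """
    if not curve.valid or not (curve.slope < 0):
        raise CalibrationError(
            f"cannot quantify on invalid standard curve (assay {curve.assay_id!r})"
        )
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copies_per_gram(copies_rxn: float, meta: SampleMeta) -> float:
    """Scale copies per reaction to copies per gram of wet feces.

    The reaction contains ``template_ng`` of a DNA pool of ``dna_yield_ng``
    extracted from ``feces_mass_g`` grams, so

    ``copies/g = copies_rxn * (dna_yield_ng / template_ng) / feces_mass_g``.

    Assumes the eluate represents the whole aliquot (no extraction-efficiency
    correction).
    """
    return copies_rxn * (meta.dna_yield_ng / meta.template_ng) / meta.feces_mass_g


def comparative_ct_fold(
    ct_target: float, ct_reference: float, efficiency: float = 1.0
) -> float:
    """Relative quantification by the comparative-Ct method.

    ``fold = (1 + E) ** (ct_reference - ct_target)``: each cycle earlier
    than the reference multiplies abundance by the per-cycle gain (1+E).
    """
    if not (efficiency > 0):
        raise CalibrationError(f"efficiency must be > 0, got {efficiency}")
    return (1.0 + efficiency) ** (ct_reference - ct_target)


def calibrate_samples(
    replicate_sets: list[ReplicateSet],
    curves: dict[str, StandardCurve],
    meta: dict[str, SampleMeta],
) -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Quantify a plate of aggregated replicates against per-assay curves.

    Returns a tidy frame with one row per (sample, assay):
    ``sample_id, assay_id, mean_ct, copies_per_reaction, copies_per_g,
    qc_flags``.  QC flags are semicolon-joined codes (``spread``,
    ``replicate_removed``, ``nondetect``, ``no_signal``); flagged rows are
    reported, never dropped.
    """
    import pandas as pd

    rows = []
    for rs in replicate_sets:
        if rs.assay_id not in curves:
            raise CalibrationError(f"no standard curve for assay {rs.assay_id!r}")
        if rs.sample_id not in meta:
            raise CalibrationError(f"no metadata for sample {rs.sample_id!r}")
        curve = curves[rs.assay_id]
        flags = []
        if rs.qc_spread_flag:
            flags.append("spread")
        if any(
            math.isfinite(rs.cts[i])
            for i in rs.removed_indices
            if rs.cts[i] is not None
        ):
            flags.append("replicate_removed")
        if rs.n_nondetect:
            flags.append("nondetect")
        if rs.mean_ct is None:
            flags.append("no_signal")
            cpr = cpg = float("nan")
        else:
            cpr = ct_to_copies(curve, rs.mean_ct)
            cpg = copies_per_gram(cpr, meta[rs.sample_id])
        rows.append(
            {
                "sample_id": rs.sample_id,
                "assay_id": rs.assay_id,
                "mean_ct": rs.mean_ct if rs.mean_ct is not None else float("nan"),
                "copies_per_reaction": cpr,
                "copies_per_g": cpg,
                "qc_flags": ";".join(flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "assay_id",
            "mean_ct",
            "copies_per_reaction",
            "copies_per_g",
            "qc_flags",
        ],
    )
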