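"""Simulated interventions on absolute abundances and their relative view.

The generative model operates in *absolute* abundance: each taxon j has a
lognormal baseline, each subject a log-scale random effect, and each
observation residual log-normal noise,

    A[s, t, j] = exp(b_j + u_sj + e_stj) * (F if j = target and t in window)

where F is a multiplicative intervention effect on a single target taxon
during an intervention window.  Sequencing is emulated by row-normalizing
to relative abundances and drawing multinomial read counts at a fixed
depth.  Because relative abundances are compositional, raising one taxon's
absolute abundance *forces* every other taxon's share down — the
false-positive experiment quantifies how often unaffected taxa are then
"detected" when tested in relative/count space versus absolute space.

Defaults model a repeated-measures intervention cohort: 20 subjects, six
timepoints (two pre, two during, two post), 50,000 reads/sample, lognormal
baselines spanning roughly three decades around 1e9 copies/g, subject SD
0.5 and residual SD 0.3 on the log scale.  Presets: a complex gut-like
community (91 taxa) and a simple low-diversity community (10 taxa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats
from .qmp import RANKS, CountTable

__all__ = ["SimConfig", "SimResult", "FpSummary", "simulate_community",
           "to_relative_and_counts", "run_fp_experiment", "counts_to_table"]

PRESETS = {"complex": 91, "simple": 10}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated single-taxon intervention."""

    n_taxa: int = 10
    n_subjects: int = 20
    timepoints: tuple = (0, 1, 2, 3, 4, 5)
    intervention_window: tuple = (2, 3)  # inclusive (start, end) timepoints
    target_taxon: int = 0
    effect_size: float = 4.0
    baseline_log_mean: float = float(np.log(1e9))
    baseline_log_sd: float = 1.0
    target_log_mean_offset: float = 0.0
    subject_sd: float = 0.5
    noise_sd: float = 0.3
    depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not (self.effect_size > 0):
            raise ValueError("effect_size must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        lo, hi = self.intervention_window
        if lo > hi or lo not in self.timepoints or hi not in self.timepoints:
            raise ValueError(
                f"intervention window {self.intervention_window} outside "
                f"timepoints {self.timepoints}"
            )
        if not (0 <= self.target_taxon < self.n_taxa):
            raise ValueError(f"target taxon index {self.target_taxon} out of range")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimConfig":
        """``"complex"`` (91 taxa, gut-like) or ``"simple"`` (10 taxa)."""
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {list(PRESETS)}")
        return cls(n_taxa=PRESETS[name], **overrides)

    @property
    def in_window(self) -> np.ndarray:
        lo, hi = self.intervention_window
        return np.array([lo <= t <= hi for t in self.timepoints])


@dataclass
class SimResult:
    """One simulated dataset in absolute, relative and count form."""

    config: SimConfig
    absolute: np.ndarray  # (subjects, timepoints, taxa)
    relative: np.ndarray
    counts: np.ndarray


@dataclass
class FpSummary:
    """False-positive experiment outcome over replicates.

    Rates are per-test over non-target taxa pooled across replicates
    (unadjusted p < alpha); ``negative_effect_fraction`` is the share of
    non-target effect estimates that are negative in relative/count space.
    """

    n_reps: int
    alpha: float
    fp_rate_absolute: float
    fp_rate_relative: float
    detection_rate_absolute: float
    detection_rate_relative: float
    negative_effect_fraction_relative: float
    negative_effect_fraction_absolute: float
    n_tests_per_space: int
    n_fit_failures: int
    per_taxon: pd.DataFrame | None = None


def _rng_for(config: SimConfig, *stream) -> np.random.Generator:
    # sub-streams derived from the root seed by fixed offsets, so each
    # replicate is reproducible independently of execution order
    return np.random.default_rng([int(config.seed) % (2**31), *map(int, stream)])


def simulate_community(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw absolute abundances (subjects × timepoints × taxa).

    Deterministic given ``config.seed``; the intervention multiplies the
    target taxon's abundance by ``effect_size`` during the window.
    """
    if rng is None:
        rng = _rng_for(config, 0)
    S, T, J = config.n_subjects, len(config.timepoints), config.n_taxa
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=J)
    baselines[config.target_taxon] += config.target_log_mean_offset
    subject_eff = rng.normal(0.0, config.subject_sd, size=(S, J))
    noise = rng.normal(0.0, config.noise_sd, size=(S, T, J))
    log_abund = baselines[None, None, :] + subject_eff[:, None, :] + noise
    abund = np.exp(log_abund)
    abund[:, config.in_window, config.target_taxon] *= config.effect_size
    return abund


def to_relative_and_counts(
    absolute: np.ndarray,
    depth: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize to relative abundances and draw multinomial reads.

    Each (subject, timepoint) cell is one sequencing library of ``depth``
    reads distributed multinomially over taxa by their relative shares.
    """
    absolute = np.asarray(absolute, dtype=float)
    totals = absolute.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("each (subject, timepoint) needs positive total abundance")
    relative = absolute / totals
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    flat = relative.reshape(-1, relative.shape[-1])
    counts = np.stack([rng.multinomial(depth, p) for p in flat])
    return relative, counts.reshape(relative.shape)


def simulate_dataset(config: SimConfig, replicate: int = 0) -> SimResult:
    """Full draw for one replicate: absolute, relative and count views."""
    abund = simulate_community(config, _rng_for(config, replicate, 0))
    rel, counts = to_relative_and_counts(
        abund, config.depth, _rng_for(config, replicate, 1)
    )
    return SimResult(config=config, absolute=abund, relative=rel, counts=counts)


def _long_design(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Observation-level intervention indicator and subject dummy columns."""
    S, T = config.n_subjects, len(config.timepoints)
    interv = np.tile(config.in_window.astype(float), S)
    subj = np.repeat(np.arange(S), T)
    dummies = np.column_stack([(subj == k).astype(float) for k in range(1, S)])
    return interv, dummies


def analyze_dataset(
    result: SimResult,
    alpha: float = 0.05,
    rule: _stats.ModelSelectionRule = _stats.ModelSelectionRule(),
) -> dict[str, pd.DataFrame]:
    """Test every taxon for an intervention effect in both spaces.

    Absolute space: log abundances by ordinary least squares.  Relative /
    count space: Poisson quasi-likelihood on the multinomial reads with a
    log-depth offset and cluster-robust (by subject) standard errors — the
    sandwich variance stays valid under the overdispersion and
    within-subject correlation the repeated-measures design induces,
    where a maximum-likelihood dispersion estimate alongside the subject
    fixed effects would not.  Both spaces adjust for subject as fixed
    effects.  Returns ``{"absolute": frame, "relative": frame}``.
    """
    cfg = result.config
    interv, dummies = _long_design(cfg)
    subjects = np.repeat(np.arange(cfg.n_subjects), len(cfg.timepoints))
    J = cfg.n_taxa
    taxa = [f"taxon_{j}" for j in range(J)]
    abs_tab = pd.DataFrame(
        result.absolute.reshape(-1, J).T, index=taxa
    )
    cnt_tab = pd.DataFrame(result.counts.reshape(-1, J).T, index=taxa)
    res_abs = _stats.test_taxa(
        abs_tab, interv, space="absolute", extra_covariates=dummies
    )
    offsets = np.full(abs_tab.shape[1], np.log(cfg.depth))
    res_rel = _stats.test_taxa(
        cnt_tab, interv, space="counts", rule=rule, model="poisson",
        offset=offsets, extra_covariates=dummies, groups=subjects,
    )
    return {"absolute": res_abs, "relative": res_rel}


def run_fp_experiment(
    config: SimConfig,
    n_reps: int = 200,
    alpha: float = 0.05,
    keep_per_taxon: bool = False,
) -> FpSummary:
    """Monte Carlo false-positive experiment over independent replicates.

    Each replicate simulates a dataset, tests every taxon in absolute and
    in relative/count space, and records unadjusted p < alpha calls.
    Non-target calls are false positives (their absolute abundances are
    untouched by the intervention); target calls measure detection power.
    Replicates whose fits fail are counted and excluded test-wise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    n_failures = 0
    for rep in range(n_reps):
        res = simulate_dataset(config, replicate=rep)
        tests = analyze_dataset(res, alpha=alpha)
        for space, frame in tests.items():
            n_failures += int((~frame["converged"]).sum())
            for j, r in frame.iterrows():
                rows.append(
                    {
                        "rep": rep,
                        "space": space,
                        "taxon": r["taxon"],
                        "is_target": j == config.target_taxon,
                        "effect_estimate": r["effect_estimate"],
                        "p_value": r["p_value"],
                        "converged": r["converged"],
                    }
                )
    frame = pd.DataFrame(rows)
    ok = frame[frame["converged"] & frame["p_value"].notna()]
    nt = ok[~ok["is_target"]]
    tg = ok[ok["is_target"]]

    def rate(df, space):
        d = df[df["space"] == space]
        return float((d["p_value"] < alpha).mean()) if len(d) else float("nan")

    def neg_frac(df, space):
        d = df[df["space"] == space]
        return float((d["effect_estimate"] < 0).mean()) if len(d) else float("nan")

    return FpSummary(
        n_reps=n_reps,
        alpha=alpha,
        fp_rate_absolute=rate(nt, "absolute"),
        fp_rate_relative=rate(nt, "relative"),
        detection_rate_absolute=rate(tg, "absolute"),
        detection_rate_relative=rate(tg, "relative"),
        negative_effect_fraction_relative=neg_frac(nt, "relative"),
        negative_effect_fraction_absolute=neg_frac(nt, "absolute"),
        n_tests_per_space=len(nt[nt["space"] == "absolute"]),
        n_fit_failures=n_failures,
        per_taxon=frame if keep_per_taxon else None,
    )


def counts_to_table(result: SimResult) -> CountTable:
    """Reshape simulated counts into the package's CountTable.

    Samples are named ``S<subject>_T<timepoint>``; taxa get a minimal
    synthetic lineage (all in one family, distinct genera) so rank
    aggregation and TSV round trips work on simulated fixtures.
    """
    cfg = result.config
    J = cfg.n_taxa
    samples = [
        f"S{s}_T{t}"
        for s in range(cfg.n_subjects)
        for t in range(len(cfg.timepoints))
    ]
    taxa = [f"taxon_{j}" for j in range(J)]
    data = pd.DataFrame(
        result.counts.reshape(-1, J).T, index=taxa, columns=samples
    )
    lineage = pd.DataFrame(index=taxa, columns=list(RANKS), dtype=object)
    lineage["kingdom"] = "Bacteria"
    lineage["phylum"] = "SimPhylum"
    lineage["class"] = "SimClass"
    lineage["order"] = "SimOrder"
    lineage["family"] = [f"family_{j % 3}" for j in range(J)]
    lineage["genus"] = taxa
    return CountTable(data, lineage=lineage)
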