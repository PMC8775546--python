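"""Cohort aggregation and the left/right asymmetry statistical battery.

The unit of analysis is the participant x dance mean: per-recording ApEn and
mean-angle values are averaged within (participant, group, dance, joint,
measure, side), and each aggregate is one datapoint in the contrasts.  For
every group and joint-measure the pipeline tests left vs right ApEn and left
vs right mean angle with a two-sided unpaired test: Welch's t by default,
falling back to Mann-Whitney when either side fails Shapiro-Wilk normality.
Assumption evidence (Shapiro-Wilk, Brown-Forsythe Levene, Tukey-fence
outliers) is reported alongside every contrast; outliers are flagged but
never removed.  Group-level descriptives (recording length, selected delay,
ACF at the delay) are compared PD vs OA with Welch's t, and across dance
types with one-way ANOVA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import ApEnConfig, analyze_series
from .errors import (
    ConstantSeriesError,
    InsufficientEmbeddingError,
    TauNotFoundError,
)
from .io import LOWER_LIMB, CohortLoadResult, Recording, load_cohort

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AssumptionReport",
    "ComparisonResult",
    "AnalysisReport",
    "analyze_recordings",
    "aggregate",
    "check_assumptions",
    "compare_sides",
    "compare_groups",
    "compare_across_dances",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the cohort analysis.

    alpha: significance level reported with every contrast.
    alpha_normality: Shapiro-Wilk level that triggers the nonparametric path.
    apen: single-series analysis parameters.
    channels: (joint, measure) allow-list; defaults to the lower limb.
    holm: apply a Holm step-down adjustment across the side contrasts
        (off by default: per-contrast p-values are reported unadjusted).
    """

    alpha: float = 0.05
    alpha_normality: float = 0.05
    apen: ApEnConfig = field(default_factory=ApEnConfig)
    channels: tuple[tuple[str, str], ...] = LOWER_LIMB
    holm: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.alpha_normality < 1:
            raise ValueError("alpha levels must be in (0, 1)")


@dataclass(frozen=True)
class OutlierFlag:
    value: float
    severity: str  # "outlier" (1.5 IQR) or "extreme" (3 IQR)
    side: str


@dataclass(frozen=True)
class AssumptionReport:
    shapiro_left: tuple[float, float]  # (W, p)
    shapiro_right: tuple[float, float]
    levene: tuple[float, float]  # Brown-Forsythe (statistic, p)
    outliers: tuple[OutlierFlag, ...]
    decision: str  # "parametric" | "nonparametric"
    alpha_normality: float


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    test: str  # welch_t | mann_whitney | anova_oneway
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    n: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    mean_diff: float | None = None  # mean(right) - mean(left) for side contrasts
    assumptions: AssumptionReport | None = None
    flags: tuple[str, ...] = ()

    def to_row(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df1, df2 = df
        else:
            df1, df2 = df, None
        row = {
            "label": self.label,
            "test": self.test,
            "statistic": self.statistic,
            "df1": df1,
            "df2": df2,
            "p_value": self.p_value,
            "n": "/".join(str(k) for k in self.n),
            "means": "/".join(f"{v:.6g}" for v in self.means),
            "sds": "/".join(f"{v:.6g}" for v in self.sds),
            "mean_diff": self.mean_diff,
            "flags": ";".join(self.flags),
        }
        if self.assumptions is not None:
            row["shapiro_p_left"] = self.assumptions.shapiro_left[1]
            row["shapiro_p_right"] = self.assumptions.shapiro_right[1]
            row["levene_p"] = self.assumptions.levene[1]
            row["n_outliers"] = len(self.assumptions.outliers)
            row["decision"] = self.assumptions.decision
        return row


# ---------------------------------------------------------------------------
# per-recording analysis and aggregation


def analyze_recordings(
    recordings: list[Recording], config: PipelineConfig
) -> pd.DataFrame:
    """Run the single-series chain on every allowed channel of every recording.

    Returns the QC table: one row per (recording, channel) with tau, ACF at
    tau, tolerance r, ApEn, mean angle and a status column; failed series
    carry their failure reason and are excluded from aggregation downstream.
    """
    allowed = set(config.channels)
    rows = []
    for rec in recordings:
        for name in sorted(rec.channels):
            ch = rec.channels[name]
            if (ch.joint, ch.measure) not in allowed:
                continue
            row = {
                "recording_id": rec.recording_id,
                "participant_id": rec.participant_id,
                "group": rec.group,
                "dance": rec.dance,
                "joint": ch.joint,
                "measure": ch.measure,
                "side": ch.side,
                "n": ch.n,
                "duration_min": rec.duration_min,
                "tau": np.nan,
                "acf_at_tau": np.nan,
                "r": np.nan,
                "apen": np.nan,
                "mean_angle": np.nan,
                "status": "ok",
                "message": "",
            }
            try:
                res = analyze_series(ch.values, config.apen)
            except ConstantSeriesError as exc:
                row.update(status="constant_series", message=str(exc))
            except TauNotFoundError as exc:
                row.update(status="tau_not_found", message=str(exc))
            except InsufficientEmbeddingError as exc:
                row.update(status="insufficient_embedding", message=str(exc))
            else:
                row.update(
                    tau=res.tau.tau,
                    acf_at_tau=res.tau.acf_at_tau,
                    r=res.apen.r,
                    apen=res.apen.apen,
                    mean_angle=res.mean_angle,
                )
                if res.apen.notes:
                    row["message"] = "; ".join(res.apen.notes)
            rows.append(row)
    return pd.DataFrame(rows)


_AGG_KEY = ["participant_id", "group", "dance", "joint", "measure", "side"]


def aggregate(qc: pd.DataFrame) -> pd.DataFrame:
    """Participant x dance means of ApEn and mean angle per channel and side.

    Only rows with status == "ok" contribute.  The sum of ``n_recordings``
    over the result equals the number of successfully analyzed
    (recording, channel) pairs.
    """
    if qc.empty:
        raise ValueError("no per-series results to aggregate")
    ok = qc[qc["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successfully analyzed series to aggregate")
    agg = (
        ok.groupby(_AGG_KEY, as_index=False)
        .agg(
            mean_apen=("apen", "mean"),
            mean_angle=("mean_angle", "mean"),
            n_recordings=("apen", "size"),
        )
        .sort_values(_AGG_KEY, kind="mergesort")
        .reset_index(drop=True)
    )
    return agg


# ---------------------------------------------------------------------------
# assumption checks and statistical contrasts


def _tukey_flags(values: np.ndarray, side: str) -> list[OutlierFlag]:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear-interpolation quantiles
    iqr = q3 - q1
    flags = []
    for v in values:
        if v < q1 - 3.0 * iqr or v > q3 + 3.0 * iqr:
            flags.append(OutlierFlag(value=float(v), severity="extreme", side=side))
        elif v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr:
            flags.append(OutlierFlag(value=float(v), severity="outlier", side=side))
    return flags


def check_assumptions(
    left, right, alpha_normality: float = 0.05
) -> AssumptionReport:
    """Shapiro-Wilk per side, Brown-Forsythe Levene, Tukey-fence outliers.

    The parametric/nonparametric decision is nonparametric iff either side's
    Shapiro p falls below ``alpha_normality``.  Outliers are flagged per side
    (1.5 IQR "outlier", 3 IQR "extreme") and always kept.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size < 3 or right.size < 3:
        raise ValueError(
            f"insufficient sample for assumption checks (n={left.size}/{right.size})"
        )
    sw_l = _shapiro_safe(left)
    sw_r = _shapiro_safe(right)
    if np.ptp(left) == 0 and np.ptp(right) == 0:
        levene = (0.0, 1.0)
    else:
        lv = stats.levene(left, right, center="median")
        levene = (float(lv.statistic), float(lv.pvalue))
    outliers = tuple(_tukey_flags(left, "left") + _tukey_flags(right, "right"))
    nonparam = sw_l[1] < alpha_normality or sw_r[1] < alpha_normality
    return AssumptionReport(
        shapiro_left=sw_l,
        shapiro_right=sw_r,
        levene=levene,
        outliers=outliers,
        decision="nonparametric" if nonparam else "parametric",
        alpha_normality=alpha_normality,
    )


def _shapiro_safe(v: np.ndarray) -> tuple[float, float]:
    if np.ptp(v) == 0:
        return (1.0, 1.0)  # degenerate: treat as no evidence against normality
    w, p = stats.shapiro(v)
    return (float(w), float(p))


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p for a vs b."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_sides(
    left, right, assumptions: AssumptionReport | None = None,
    *, label: str = "left_vs_right", alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Two-sided unpaired left-vs-right contrast.

    Parametric path: Welch's t (unequal variances, Welch-Satterthwaite
    fractional df).  Nonparametric path (triggered by the assumption report):
    two-sided Mann-Whitney, exact when both n <= 20 and there are no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.  The reported effect direction is mean(right) - mean(left);
    the t statistic is signed as left - right, so swapping the labels flips
    its sign and leaves p unchanged.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if assumptions is None:
        assumptions = check_assumptions(left, right, alpha_normality)
    n = (left.size, right.size)
    means = (float(np.mean(left)), float(np.mean(right)))
    sds = (
        float(np.std(left, ddof=1)) if left.size > 1 else 0.0,
        float(np.std(right, ddof=1)) if right.size > 1 else 0.0,
    )
    mean_diff = means[1] - means[0]
    if np.ptp(left) == 0 and np.ptp(right) == 0 and means[0] == means[1]:
        return ComparisonResult(
            label=label, test="welch_t", statistic=0.0, df=float(sum(n) - 2),
            p_value=1.0, n=n, means=means, sds=sds, mean_diff=0.0,
            assumptions=assumptions, flags=("degenerate",),
        )
    if assumptions.decision == "nonparametric":
        ties = (
            np.unique(np.concatenate([left, right])).size < left.size + right.size
        )
        method = "exact" if (max(n) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(
            left, right, alternative="two-sided", method=method,
            use_continuity=True,
        )
        return ComparisonResult(
            label=label, test="mann_whitney", statistic=float(res.statistic),
            df=None, p_value=float(res.pvalue), n=n, means=means, sds=sds,
            mean_diff=mean_diff, assumptions=assumptions,
            flags=(f"mw_{method}",),
        )
    t, df, p = _welch(left, right)
    return ComparisonResult(
        label=label, test="welch_t", statistic=t, df=df, p_value=p, n=n,
        means=means, sds=sds, mean_diff=mean_diff, assumptions=assumptions,
    )


def compare_groups(a, b, *, label: str = "group_a_vs_b") -> ComparisonResult:
    """Welch's t for two independent groups (demographics-style comparison)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    n = (a.size, b.size)
    means = (float(np.mean(a)), float(np.mean(b)))
    sds = (float(np.std(a, ddof=1)), float(np.std(b, ddof=1)))
    if np.ptp(a) == 0 and np.ptp(b) == 0 and means[0] == means[1]:
        return ComparisonResult(
            label=label, test="welch_t", statistic=0.0, df=float(sum(n) - 2),
            p_value=1.0, n=n, means=means, sds=sds, flags=("degenerate",),
        )
    t, df, p = _welch(a, b)
    return ComparisonResult(
        label=label, test="welch_t", statistic=t, df=df, p_value=p, n=n,
        means=means, sds=sds, mean_diff=means[1] - means[0],
    )


def compare_across_dances(
    values_by_dance: dict[str, np.ndarray], *, label: str = "across_dances"
) -> ComparisonResult:
    """One-way fixed-effects ANOVA over dance types, df = (k-1, N-k)."""
    if len(values_by_dance) < 2:
        raise ValueError("need at least 2 dance groups")
    groups = []
    for dance in sorted(values_by_dance):
        v = np.asarray(values_by_dance[dance], dtype=float)
        if v.size < 2:
            raise ValueError(f"dance group {dance!r} has n < 2")
        groups.append(v)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df = (float(k - 1), float(n_total - k))
    grand = np.mean(np.concatenate(groups))
    ss_between = sum(g.size * (np.mean(g) - grand) ** 2 for g in groups)
    if ss_between == 0.0:
        f_stat, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*groups)
        f_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        label=label, test="anova_oneway", statistic=f_stat, df=df, p_value=p,
        n=tuple(g.size for g in groups),
        means=tuple(float(np.mean(g)) for g in groups),
        sds=tuple(float(np.std(g, ddof=1)) for g in groups),
    )


# ---------------------------------------------------------------------------
# whole-cohort driver


@dataclass
class SkippedContrast:
    label: str
    reason: str


@dataclass
class AnalysisReport:
    """Everything run_pipeline produces, with deterministic serialization."""

    qc: pd.DataFrame
    aggregates: pd.DataFrame
    contrasts: list[ComparisonResult]
    group_tests: list[ComparisonResult]
    dance_anovas: list[ComparisonResult]
    skipped: list[SkippedContrast]
    exclusions: list[tuple]
    config: PipelineConfig

    def contrasts_frame(self) -> pd.DataFrame:
        rows = [c.to_row() for c in self.contrasts + self.group_tests + self.dance_anovas]
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        def _num(v):
            if v is None:
                return None
            v = float(v)
            return None if np.isnan(v) else v

        comparisons = {}
        for c in self.contrasts + self.group_tests + self.dance_anovas:
            row = c.to_row()
            comparisons[c.label] = {
                "test": c.test,
                "statistic": _num(row["statistic"]),
                "df1": _num(row["df1"]),
                "df2": _num(row["df2"]),
                "p_value": _num(c.p_value),
                "mean_diff": _num(c.mean_diff),
                "n": list(c.n),
                "flags": list(c.flags),
            }
        return {
            "n_recordings": int(self.qc["recording_id"].nunique()),
            "n_series_ok": int((self.qc["status"] == "ok").sum()),
            "n_series_failed": int((self.qc["status"] != "ok").sum()),
            "n_excluded_files": len(self.exclusions),
            "n_aggregates": int(len(self.aggregates)),
            "comparisons": comparisons,
            "skipped": {s.label: s.reason for s in self.skipped},
            "config": {
                "alpha": self.config.alpha,
                "alpha_normality": self.config.alpha_normality,
                "m": self.config.apen.m,
                "r_factor": self.config.apen.r_factor,
                "acf_threshold": self.config.apen.acf_threshold,
                "max_shift_fraction": self.config.apen.max_shift_fraction,
                "signed_threshold": self.config.apen.signed_threshold,
                "channels": ["_".join(c) for c in self.config.channels],
                "holm": self.config.holm,
            },
        }

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.qc.to_csv(out_dir / "qc.csv", index=False, lineterminator="\n")
        self.aggregates.to_csv(
            out_dir / "results.csv", index=False, lineterminator="\n"
        )
        self.contrasts_frame().to_csv(
            out_dir / "contrasts.csv", index=False, lineterminator="\n"
        )
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def get(self, label: str) -> ComparisonResult | None:
        for c in self.contrasts + self.group_tests + self.dance_anovas:
            if c.label == label:
                return c
        return None


def _side_contrasts(
    agg: pd.DataFrame, metric: str, config: PipelineConfig
) -> tuple[list[ComparisonResult], list[SkippedContrast]]:
    results: list[ComparisonResult] = []
    skipped: list[SkippedContrast] = []
    for group in sorted(agg["group"].unique()):
        g = agg[agg["group"] == group]
        for (joint, measure), sub in g.groupby(["joint", "measure"], sort=True):
            label = f"{group}:{joint}_{measure}:{metric}:left_vs_right"
            wide = sub.pivot_table(
                index=["participant_id", "dance"], columns="side",
                values=metric, aggfunc="first",
            )
            if "left" not in wide.columns or "right" not in wide.columns:
                skipped.append(SkippedContrast(label, "missing one side entirely"))
                continue
            one_sided = int(wide["left"].isna().sum() + wide["right"].isna().sum())
            if one_sided:
                log.info(
                    "%s: %d participant x dance keys present on one side only; "
                    "excluded from the contrast", label, one_sided,
                )
            both = wide.dropna()
            left = both["left"].to_numpy()
            right = both["right"].to_numpy()
            if left.size < 3:
                skipped.append(
                    SkippedContrast(label, f"insufficient datapoints (n={left.size})")
                )
                continue
            results.append(
                compare_sides(
                    left, right, label=label,
                    alpha_normality=config.alpha_normality,
                )
            )
    return results, skipped


def run_pipeline(
    manifest_path, config: PipelineConfig = PipelineConfig()
) -> AnalysisReport:
    """Load a cohort, analyze every series, aggregate, and run every contrast.

    Fully deterministic given the input files: no randomness enters the
    pipeline.  Contrasts without enough data are reported as skipped.
    """
    loaded: CohortLoadResult = load_cohort(manifest_path)
    qc = analyze_recordings(loaded.recordings, config)
    agg = aggregate(qc)

    contrasts: list[ComparisonResult] = []
    skipped: list[SkippedContrast] = []
    for metric in ("mean_apen", "mean_angle"):
        res, skip = _side_contrasts(agg, metric, config)
        contrasts.extend(res)
        skipped.extend(skip)

    if config.holm and contrasts:
        order = np.argsort([c.p_value for c in contrasts])
        m = len(contrasts)
        adj = {}
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * contrasts[idx].p_value))
            adj[idx] = running
        contrasts = [
            ComparisonResult(
                **{**c.__dict__, "flags": c.flags + (f"holm_p={adj[i]:.6g}",)}
            )
            for i, c in enumerate(contrasts)
        ]

    ok = qc[qc["status"] == "ok"]
    group_tests: list[ComparisonResult] = []
    per_rec = ok.drop_duplicates("recording_id")
    pd_rec = per_rec[per_rec["group"] == "PD"]
    oa_rec = per_rec[per_rec["group"] == "OA"]
    group_metrics = [
        ("duration_min", per_rec, pd_rec, oa_rec),
        ("tau", ok, ok[ok["group"] == "PD"], ok[ok["group"] == "OA"]),
        ("acf_at_tau", ok, ok[ok["group"] == "PD"], ok[ok["group"] == "OA"]),
    ]
    for metric, _all, a, b in group_metrics:
        label = f"PD_vs_OA:{metric}"
        if len(a) < 2 or len(b) < 2:
            skipped.append(SkippedContrast(label, "a group has n < 2"))
            continue
        group_tests.append(
            compare_groups(a[metric].to_numpy(), b[metric].to_numpy(), label=label)
        )

    dance_anovas: list[ComparisonResult] = []
    for metric, frame in (("duration_min", per_rec), ("tau", ok)):
        label = f"across_dances:{metric}"
        by_dance = {
            d: sub[metric].to_numpy()
            for d, sub in frame.groupby("dance")
            if len(sub) >= 2
        }
        if len(by_dance) < 2:
            skipped.append(SkippedContrast(label, "fewer than 2 dances with n >= 2"))
            continue
        dance_anovas.append(compare_across_dances(by_dance, label=label))

    return AnalysisReport(
        qc=qc, aggregates=agg, contrasts=contrasts, group_tests=group_tests,
        dance_anovas=dance_anovas, skipped=skipped,
        exclusions=loaded.exclusions, config=config,
    )
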