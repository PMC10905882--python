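"""Count-based field evaluation of the sensor against manual inspection.

Field performance is scored per collection cycle from *aggregate* counts, not
per-event matching: a trained entomologist counts the frozen catch-bag
contents (the manual count, taken as reference) and the sensor reports its
own per-class counts.  For a positive class,

    TP = min(sensor, manual)
    FP = max(sensor − manual, 0)
    FN = max(manual − sensor, 0)
    TN = manual negatives − FP   (floored at 0, flagged if FP exceeds them)

and balanced accuracy BA = (Se + Sp)/2 with Se = TP/(TP+FN),
Sp = TN/(TN+FP).  BA weights positives and negatives equally, which matters
because field catches are heavily imbalanced (non-target insects usually
dominate).  Per-trial performance is summarized by the mean, median, IQR and
quartiles of the per-cycle BAs, plus Pearson correlation and ordinary
least-squares regression of sensor on manual counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import TARGET_CLASSES, ClassLabel

__all__ = [
    "CycleCounts",
    "ConfusionCounts",
    "CycleMetrics",
    "SummaryStats",
    "CorrelationResult",
    "RegressionResult",
    "count_confusion",
    "balanced_accuracy",
    "evaluate_target_detection",
    "evaluate_genus_sex",
    "pearson_correlation",
    "linear_regression",
    "compute_activity_profile",
    "summarize",
    "read_cycle_counts",
    "write_cycle_counts",
]

_CLASS_COLS = {
    ClassLabel.AEDES_F: "AeF",
    ClassLabel.AEDES_M: "AeM",
    ClassLabel.CULEX_F: "CxF",
    ClassLabel.CULEX_M: "CxM",
}


@dataclass
class CycleCounts:
    """Per-cycle sensor and manual counts (one row of the count table)."""

    cycle_id: str
    start: Optional[datetime]
    end: Optional[datetime]
    manual: dict[ClassLabel, int]
    manual_nontarget: int
    sensor: Optional[dict[ClassLabel, int]] = None
    sensor_target_total: Optional[int] = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        for c in TARGET_CLASSES:
            self.manual.setdefault(c, 0)
        vals = list(self.manual.values()) + [self.manual_nontarget]
        if self.sensor is not None:
            vals += list(self.sensor.values())
        if self.sensor_target_total is not None:
            vals.append(self.sensor_target_total)
        if any(v < 0 for v in vals):
            raise ValueError(f"cycle {self.cycle_id}: counts must be non-negative")

    @property
    def manual_target_total(self) -> int:
        return sum(self.manual[c] for c in TARGET_CLASSES)


@dataclass(frozen=True)
class ConfusionCounts:
    """Count-based confusion for one positive class in one cycle."""

    tp: int
    fp: int
    fn: int
    tn: int
    fp_exceeds_negatives: bool = False


@dataclass(frozen=True)
class CycleMetrics:
    """Sensitivity, specificity and balanced accuracy (proportions in [0,1]).

    Components are ``None`` when undefined (no positives for Se, no
    negatives for Sp).  When only one component is defined, BA equals it and
    ``partial`` is set; when neither is defined BA is ``None`` and the cycle
    is dropped from averages.
    """

    se: Optional[float]
    sp: Optional[float]
    ba: Optional[float]
    partial: bool = False

    @property
    def ba_pct(self) -> Optional[float]:
        return None if self.ba is None else 100.0 * self.ba


@dataclass(frozen=True)
class SummaryStats:
    """Mean/median/IQR/quartiles of per-cycle balanced accuracies, in %."""

    mean: float
    median: float
    iqr: float
    q1: float
    q3: float
    n: int

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "SummaryStats":
        v = np.asarray([x for x in values if x is not None and np.isfinite(x)], float)
        if v.size == 0:
            raise ValueError("no defined values to summarize")
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear ("type 7") quantiles
        return cls(
            mean=float(v.mean()),
            median=float(med),
            iqr=float(q3 - q1),
            q1=float(q1),
            q3=float(q3),
            n=int(v.size),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "median": self.median,
            "iqr": self.iqr,
            "q1": self.q1,
            "q3": self.q3,
            "n": self.n,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def count_confusion(
    sensor_pos: int, manual_pos: int, manual_neg: int
) -> ConfusionCounts:
    """Derive TP/FP/FN/TN from aggregate per-cycle counts.

    TP is the minimum common value of sensor and manual count; the signed
    excess/deficit becomes FP/FN; TN is the manual negative count minus FP.
    """
    if sensor_pos < 0 or manual_pos < 0 or manual_neg < 0:
        raise ValueError("counts must be non-negative")
    tp = min(sensor_pos, manual_pos)
    fp = max(sensor_pos - manual_pos, 0)
    fn = max(manual_pos - sensor_pos, 0)
    flag = fp > manual_neg
    tn = max(manual_neg - fp, 0)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, fp_exceeds_negatives=flag)


def balanced_accuracy(c: ConfusionCounts) -> CycleMetrics:
    """Se/Sp/BA from count-based confusion, handling undefined components.

    Cycles without positives contribute only specificity (and vice versa);
    the BA then equals the defined component and is flagged ``partial``.
    """
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    if se is not None and sp is not None:
        return CycleMetrics(se=se, sp=sp, ba=(se + sp) / 2.0)
    if se is not None or sp is not None:
        only = se if se is not None else sp
        return CycleMetrics(se=se, sp=sp, ba=only, partial=True)
    return CycleMetrics(se=None, sp=None, ba=None, partial=True)


def _active(cycles: Sequence[CycleCounts]) -> list[CycleCounts]:
    kept = [c for c in cycles if not c.excluded]
    if not kept:
        raise ValueError("all cycles are excluded")
    for c in kept:
        if c.sensor_target_total is None and c.sensor is None:
            raise ValueError(f"cycle {c.cycle_id}: no sensor counts")
    return kept


def _sensor_total(c: CycleCounts) -> int:
    if c.sensor_target_total is not None:
        return c.sensor_target_total
    return sum(c.sensor.get(k, 0) for k in TARGET_CLASSES)


def evaluate_target_detection(
    cycles: Sequence[CycleCounts],
) -> tuple[pd.DataFrame, SummaryStats]:
    """Per-cycle target-detection metrics and their summary.

    Positives are target mosquitoes (sensor vs manual target totals);
    negatives are the manually counted non-target insects.  Excluded cycles
    (depredation, connectivity loss) are dropped first.
    """
    rows = []
    for c in _active(cycles):
        conf = count_confusion(_sensor_total(c), c.manual_target_total, c.manual_nontarget)
        m = balanced_accuracy(conf)
        rows.append(
            {
                "cycle_id": c.cycle_id,
                "sensor": _sensor_total(c),
                "manual": c.manual_target_total,
                "manual_nontarget": c.manual_nontarget,
                "tp": conf.tp,
                "fp": conf.fp,
                "fn": conf.fn,
                "tn": conf.tn,
                "se": m.se,
                "sp": m.sp,
                "ba_pct": m.ba_pct,
                "partial": m.partial,
            }
        )
    df = pd.DataFrame(rows)
    return df, SummaryStats.from_values(df["ba_pct"])


def evaluate_genus_sex(
    cycles: Sequence[CycleCounts],
) -> tuple[pd.DataFrame, dict[ClassLabel, SummaryStats], SummaryStats, float]:
    """One-vs-rest per-class evaluation of genus × sex classification.

    For each target class the negatives are the manual counts of the other
    three classes.  Returns the per-cycle-per-class table, per-class
    summaries, the summary of all cycle × class BAs pooled (the distribution
    reported per trial), and the overall BA: the unweighted mean over the
    four classes of the per-class mean BAs.
    """
    rows = []
    for c in _active(cycles):
        if c.sensor is None:
            raise ValueError(f"cycle {c.cycle_id}: per-class sensor counts required")
        for cls in TARGET_CLASSES:
            neg = c.manual_target_total - c.manual[cls]
            conf = count_confusion(c.sensor.get(cls, 0), c.manual[cls], neg)
            m = balanced_accuracy(conf)
            rows.append(
                {
                    "cycle_id": c.cycle_id,
                    "class": cls.value,
                    "sensor": c.sensor.get(cls, 0),
                    "manual": c.manual[cls],
                    "tp": conf.tp,
                    "fp": conf.fp,
                    "fn": conf.fn,
                    "tn": conf.tn,
                    "se": m.se,
                    "sp": m.sp,
                    "ba_pct": m.ba_pct,
                    "partial": m.partial,
                }
            )
    df = pd.DataFrame(rows)
    per_class: dict[ClassLabel, SummaryStats] = {}
    for cls in TARGET_CLASSES:
        sub = df.loc[df["class"] == cls.value, "ba_pct"].dropna()
        per_class[cls] = SummaryStats.from_values(sub)
    pooled = SummaryStats.from_values(df["ba_pct"].dropna())
    overall = float(np.mean([per_class[c].mean for c in TARGET_CLASSES]))
    return df, per_class, pooled, overall


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value (n − 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue))


def linear_regression(
    response: Sequence[float], predictor: Sequence[float]
) -> RegressionResult:
    """OLS of ``response`` on ``predictor`` with intercept.

    The reporting convention is response = sensor count, predictor = manual
    count, so a slope below one reads "the sensor undercounts"; both
    orientations are worth inspecting since scatter plots in the field
    literature are drawn both ways.
    """
    y = np.asarray(response, float)
    x = np.asarray(predictor, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    ss_res = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=float(res.pvalue),
    )


def compute_activity_profile(
    events: pd.DataFrame,
    trial_start: datetime,
    trial_end: datetime,
) -> pd.DataFrame:
    """Average hourly sensor count per month per genus.

    ``events`` needs columns ``timestamp`` (datetime) and ``genus``.  For
    each (month, genus, hour-of-day) the value is the total count in that
    hour over the month divided by the number of days of that month that
    fall inside [trial_start, trial_end] — i.e. the mean count per hour slot
    per day.  Returns a tidy frame with columns month, genus, hour,
    mean_count; months with no trial coverage are absent.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["month", "genus", "hour", "mean_count"])
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    ev = ev[(ev["timestamp"] >= trial_start) & (ev["timestamp"] <= trial_end)]
    ev["month"] = ev["timestamp"].dt.month
    ev["hour"] = ev["timestamp"].dt.hour

    days_per_month: dict[int, float] = {}
    day = trial_start.date()
    while day <= trial_end.date():
        days_per_month[day.month] = days_per_month.get(day.month, 0) + 1
        day = day + pd.Timedelta(days=1)

    out = []
    for (month, genus), grp in ev.groupby(["month", "genus"]):
        counts = grp.groupby("hour").size()
        days = days_per_month.get(month)
        if not days:
            continue
        for hour in range(24):
            out.append(
                {
                    "month": int(month),
                    "genus": genus,
                    "hour": hour,
                    "mean_count": float(counts.get(hour, 0)) / days,
                }
            )
    return pd.DataFrame(out)


def summarize(values: Iterable[float]) -> SummaryStats:
    """Convenience alias for :meth:`SummaryStats.from_values`."""
    return SummaryStats.from_values(values)


# ---------------------------------------------------------------------------
# CSV schema mirroring the published per-cycle count table, so a real file
# can be dropped in: cycle_id, start, end, sensor_AeF..sensor_CxM,
# sensor_target_total, manual_AeF..manual_CxM, manual_nontarget, excluded,
# exclusion_reason.

def write_cycle_counts(cycles: Sequence[CycleCounts], path: Union[str, Path]) -> None:
    rows = []
    for c in cycles:
        row = {
            "cycle_id": c.cycle_id,
            "start": c.start.isoformat() if c.start else "",
            "end": c.end.isoformat() if c.end else "",
        }
        for cls, short in _CLASS_COLS.items():
            row[f"sensor_{short}"] = (c.sensor or {}).get(cls, 0)
        row["sensor_target_total"] = (
            c.sensor_target_total
            if c.sensor_target_total is not None
            else (sum((c.sensor or {}).values()) if c.sensor else 0)
        )
        for cls, short in _CLASS_COLS.items():
            row[f"manual_{short}"] = c.manual[cls]
        row["manual_nontarget"] = c.manual_nontarget
        row["excluded"] = int(c.excluded)
        row["exclusion_reason"] = c.exclusion_reason
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cycle_counts(path: Union[str, Path]) -> list[CycleCounts]:
    df = pd.read_csv(path, keep_default_na=False)
    cycles = []
    for _, row in df.iterrows():
        sensor = {cls: int(row[f"sensor_{s}"]) for cls, s in _CLASS_COLS.items()}
        manual = {cls: int(row[f"manual_{s}"]) for cls, s in _CLASS_COLS.items()}
        cycles.append(
            CycleCounts(
                cycle_id=str(row["cycle_id"]),
                start=datetime.fromisoformat(row["start"]) if row["start"] else None,
                end=datetime.fromisoformat(row["end"]) if row["end"] else None,
                manual=manual,
                manual_nontarget=int(row["manual_nontarget"]),
                sensor=sensor,
                sensor_target_total=int(row["sensor_target_total"]),
                excluded=bool(int(row["excluded"])),
                exclusion_reason=str(row["exclusion_reason"]),
            )
        )
    return cycles
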