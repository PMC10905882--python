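"""Published summary tables and headline counts of the two-trial field study.

The real recording dataset behind the surveillance system is unpublished,
but the study's aggregate tables are public: the manual taxonomic
composition of the field catches (two Mediterranean sites near Barcelona,
trial 1 in 2021 with 24-h collection cycles, trial 2 in 2022 with 24–72-h
cycles), the laboratory dataset bookkeeping, and the sample accounting.
These numbers serve two roles here: desk-checkable arithmetic (totals,
proportions, rejection rate, cycle accounting) and the default intensities
of the synthetic field scenarios, so simulations reproduce the reported
catch sizes and class mix.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from importlib import resources

import numpy as np
import pandas as pd

from .types import ClassLabel, CollectionCycle, FieldScenario

__all__ = [
    "STUDY_COUNTS",
    "CLASS_SHARE_OF_TARGETS",
    "field_composition",
    "mosquito_totals",
    "target_totals",
    "nontarget_totals",
    "target_proportion_pct",
    "cleaning_rejection_rate_pct",
    "cycles_analyzed",
    "reference_field_scenarios",
]

#: Headline bookkeeping counts reported for the study.
STUDY_COUNTS: dict[str, int] = {
    "lab_flights_recorded": 15208,
    "lab_flights_valid": 14067,
    "lab_test_set_size": 1000,
    "samples_collected_trial1": 32,
    "samples_collected_trial2": 21,
    "samples_excluded_depredation": 7,
    "samples_excluded_connectivity": 2,
    "cycles_analyzed_trial1": 29,
    "cycles_analyzed_trial2": 15,
}

#: Within-target genus × sex composition of the field catches (fractions).
CLASS_SHARE_OF_TARGETS: dict[int, dict[ClassLabel, float]] = {
    1: {
        ClassLabel.CULEX_F: 0.766,
        ClassLabel.AEDES_F: 0.150,
        ClassLabel.AEDES_M: 0.046,
        ClassLabel.CULEX_M: 0.038,
    },
    2: {
        ClassLabel.CULEX_F: 0.671,
        ClassLabel.AEDES_F: 0.189,
        ClassLabel.AEDES_M: 0.092,
        ClassLabel.CULEX_M: 0.048,
    },
}


def field_composition() -> pd.DataFrame:
    """Manual-inspection composition of the field catches, per trial."""
    with resources.files("trapsense.data").joinpath("field_composition.csv").open() as fh:
        return pd.read_csv(fh)


def mosquito_totals() -> dict[int, int]:
    """Manually classified mosquitoes (culicids) per trial."""
    df = field_composition()
    mosq = df[df["category"] == "mosquito"]
    return {1: int(mosq["trial1"].sum()), 2: int(mosq["trial2"].sum())}


def target_totals() -> dict[int, int]:
    """Target (*Aedes* + *Culex*) mosquitoes per trial."""
    df = field_composition()
    tgt = df[df["group"] == "target"]
    return {1: int(tgt["trial1"].sum()), 2: int(tgt["trial2"].sum())}


def nontarget_totals() -> dict[int, int]:
    """Non-target insects (incl. non-target culicids) per trial."""
    df = field_composition()
    non = df[df["group"] == "non_target"]
    return {1: int(non["trial1"].sum()), 2: int(non["trial2"].sum())}


def target_proportion_pct(trial: int) -> float:
    """Share of target mosquitoes among all insects in the catch, in %."""
    t, n = target_totals()[trial], nontarget_totals()[trial]
    return 100.0 * t / (t + n)


def cleaning_rejection_rate_pct() -> float:
    """Fraction of laboratory recordings rejected during cleaning, in %."""
    rec = STUDY_COUNTS["lab_flights_recorded"]
    return 100.0 * (rec - STUDY_COUNTS["lab_flights_valid"]) / rec


def cycles_analyzed() -> dict[str, int]:
    """Sample accounting: collected minus excluded equals analyzed cycles."""
    collected = (
        STUDY_COUNTS["samples_collected_trial1"]
        + STUDY_COUNTS["samples_collected_trial2"]
    )
    analyzed = (
        collected
        - STUDY_COUNTS["samples_excluded_depredation"]
        - STUDY_COUNTS["samples_excluded_connectivity"]
    )
    return {
        "collected": collected,
        "analyzed": analyzed,
        "trial1": STUDY_COUNTS["cycles_analyzed_trial1"],
        "trial2": STUDY_COUNTS["cycles_analyzed_trial2"],
    }


def reference_field_scenarios(
    diel_profiles: dict[str, np.ndarray],
) -> dict[int, FieldScenario]:
    """Synthetic two-trial design matching the reported study layout.

    Trial 1: 32 collected 24-h cycles (Jul–Oct), 3 excluded; trial 2: 21
    collected 48-h cycles (Jun–Sep), 6 excluded — leaving the 29 + 15 = 44
    analyzed cycles.  Per-class Poisson intensities are normalized so the
    *expected* catch per trial equals the published totals with the reported
    genus × sex mix; a mild mid-summer seasonal peak modulates all classes.
    """
    seasonal = {6: 0.9, 7: 1.2, 8: 1.2, 9: 0.75, 10: 0.35}

    def build(
        trial: int,
        n_cycles: int,
        cycle_hours: float,
        first_start: datetime,
        spacing_days: float,
        excluded: dict[str, str],
    ) -> FieldScenario:
        cycles = []
        for i in range(n_cycles):
            start = first_start + timedelta(days=spacing_days * i)
            cycles.append(
                CollectionCycle(
                    cycle_id=f"T{trial}C{i + 1:02d}",
                    start=start,
                    end=start + timedelta(hours=cycle_hours),
                )
            )
        # normalize intensities so expected totals hit the published counts
        weight = sum(
            seasonal.get(c.start.month, 1.0)
            * (c.end - c.start).total_seconds()
            / 86400.0
            for c in cycles
        )
        tgt_total = target_totals()[trial]
        intensities = {
            cls: share * tgt_total / weight
            for cls, share in CLASS_SHARE_OF_TARGETS[trial].items()
        }
        intensities[ClassLabel.NON_TARGET] = nontarget_totals()[trial] / weight
        return FieldScenario(
            cycles=cycles,
            class_intensities=intensities,
            diel_profile=diel_profiles,
            seasonal_trend=seasonal,
            excluded_cycles=excluded,
        )

    trial1 = build(
        1,
        n_cycles=32,
        cycle_hours=24.0,
        first_start=datetime(2021, 7, 5, 9, 0),
        spacing_days=3.3,
        excluded={
            "T1C07": "depredation",
            "T1C18": "depredation",
            "T1C26": "depredation",
        },
    )
    trial2 = build(
        2,
        n_cycles=21,
        cycle_hours=48.0,
        first_start=datetime(2022, 6, 6, 9, 0),
        spacing_days=5.4,
        excluded={
            "T2C03": "depredation",
            "T2C08": "depredation",
            "T2C11": "depredation",
            "T2C15": "depredation",
            "T2C17": "connectivity",
            "T2C20": "connectivity",
        },
    )
    return {1: trial1, 2: trial2}
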