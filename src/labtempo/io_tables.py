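"""Tab-separated event tables for raw cohort data.

Four tables move raw synthetic cohorts between pipeline stages:
administrations (patient_id, day), lab observations (patient_id,
parameter_id, day, value), reference intervals (patient_id,
parameter_id, lower, upper) and the planted ground truth (patient_id,
first_day, parameter_id, effect, amplitude, lag_days, sign).
"""

from __future__ import annotations

import os

import pandas as pd

from labtempo.model import AdministrationEvent, LabObservation, ReferenceInterval
from labtempo.synth import PlantedEffect


def write_administrations(events: list[AdministrationEvent], path) -> None:
    pd.DataFrame(
        [(e.patient_id, e.day) for e in events], columns=["patient_id", "day"]
    ).to_csv(path, sep="\t", index=False)


def read_administrations(path) -> list[AdministrationEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return [AdministrationEvent(r.patient_id, int(r.day)) for r in df.itertuples()]


def write_observations(observations: list[LabObservation], path) -> None:
    pd.DataFrame(
        [(o.patient_id, o.parameter_id, o.day, o.value) for o in observations],
        columns=["patient_id", "parameter_id", "day", "value"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_observations(path) -> list[LabObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "parameter_id": str})
    return [
        LabObservation(r.patient_id, r.parameter_id, int(r.day), float(r.value))
        for r in df.itertuples()
    ]


def write_intervals(intervals: list[ReferenceInterval], path) -> None:
    pd.DataFrame(
        [(i.patient_id, i.parameter_id, i.lower, i.upper) for i in intervals],
        columns=["patient_id", "parameter_id", "lower", "upper"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_intervals(path) -> list[ReferenceInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "parameter_id": str})
    return [
        ReferenceInterval(r.patient_id, r.parameter_id, float(r.lower), float(r.upper))
        for r in df.itertuples()
    ]


def write_truth(truth: dict[tuple[str, int, str], PlantedEffect], path) -> None:
    rows = [
        (pid, day, param, int(t.effect), t.amplitude, t.lag_days, t.sign)
        for (pid, day, param), t in sorted(truth.items())
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "first_day",
            "parameter_id",
            "effect",
            "amplitude",
            "lag_days",
            "sign",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_truth(path) -> dict[tuple[str, int, str], PlantedEffect]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "parameter_id": str})
    return {
        (r.patient_id, int(r.first_day), r.parameter_id): PlantedEffect(
            effect=bool(r.effect),
            amplitude=float(r.amplitude),
            lag_days=int(r.lag_days),
            sign=int(r.sign),
        )
        for r in df.itertuples()
    }
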