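"""Simplified dose estimators for later therapy cycles.

Three shortcuts replace full multi-time-point dosimetry after cycle 1:

* **SM1** — single-time-point rescaling: assume the pharmacokinetics of
  cycle 1, scale the cycle-1 fitted TAC by the ratio of the measured
  activity at one imaging time point to the cycle-1 curve at that time,
  and integrate (equivalently, scale the cycle-1 TIA by that ratio).
* **SM2** — activity extrapolation from cycle 1:
  ``D_i = (D_1 / A_1) * A_i``.
* **SM3** — activity extrapolation from the mean normalized dose of
  cycles 1 and 2: ``D_i = ((D_1/A_1 + D_2/A_2) / 2) * A_i``.

SM2/SM3 are only valid for organs at risk: tumor uptake declines over
cycles, which a pure activity scaling cannot represent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .dose import RECORD_COLUMNS, make_record, run_reference_dosimetry
from .errors import DomainError, FitError
from .fitting import TACFit
from .physics import LU177, Radionuclide, SourceRegion, self_dose_factor

log = logging.getLogger(__name__)

#: single-time-point labels: early post-injection scan, 24 h, 48 h, and the
#: cycle's own (variable) last scan between 72 and 168 h
TP_LABELS = ("2-4h", "24h", "48h", "72-168h")
#: latest admissible single observation time, hours
MAX_SINGLE_TP_H = 400.0

METHODS = ("RM", "SM1", "SM2", "SM3")


@dataclass(frozen=True)
class SingleTimePointObservation:
    """One measured activity used by SM1 in a cycle >= 2."""

    patient: str
    cycle: int
    region_id: str
    t_single_h: float
    measured_MBq: float
    injected_MBq: float
    tp_label: str

    def __post_init__(self) -> None:
        if self.cycle < 2:
            raise DomainError("SM1 observations apply to cycles 2 and later")
        if not 0 < self.t_single_h <= MAX_SINGLE_TP_H:
            raise DomainError(f"observation time must be in (0, {MAX_SINGLE_TP_H}] h")
        if self.measured_MBq < 0:
            raise DomainError("measured activity must be non-negative")


def sm1_dose(
    ref_fit: TACFit,
    ref_tia_MBqh: float,
    obs: SingleTimePointObservation,
    region: SourceRegion,
    nuclide: Radionuclide = LU177,
) -> dict:
    """SM1 dose record from the cycle-1 fit and one later-cycle measurement.

    The cycle-1 fitted curve is evaluated at the observation time; the
    cycle-1 TIA is scaled by ``measured / curve`` and converted to dose as
    in the reference method.  The effective half-life is inherited from
    cycle 1.  A trapezoid-tail reference fit is evaluated through its tail
    mono-exponential (logged as a warning).
    """
    if ref_fit.model == "trapezoid_tail":
        log.warning(
            "SM1 reference fit for %s %s is trapezoid-tail; "
            "evaluating its tail mono-exponential at %.1f h",
            obs.patient, obs.region_id, obs.t_single_h,
        )
    ref_activity = float(ref_fit.predict(obs.t_single_h))
    if ref_activity <= 0:
        raise DomainError("cycle-1 curve is non-positive at the observation time")
    scale = obs.measured_MBq / ref_activity
    return make_record(
        patient=obs.patient,
        cycle=obs.cycle,
        region=region,
        method="SM1",
        tia_MBqh=scale * ref_tia_MBqh,
        injected_MBq=obs.injected_MBq,
        t_eff_h=ref_fit.t_eff_h,
        fit_model=f"sm1[{ref_fit.model}]",
        nuclide=nuclide,
        tp_label=obs.tp_label,
    )


def sm2_dose(D1_mGy: float, A1_MBq: float, Ai_MBq: float) -> float:
    """Extrapolate the cycle-i dose from cycle 1: ``(D1/A1) * Ai``."""
    if not A1_MBq > 0:
        raise DomainError("cycle-1 injected activity must be positive")
    return D1_mGy / A1_MBq * Ai_MBq


def sm3_dose(D1_mGy: float, A1_MBq: float, D2_mGy: float, A2_MBq: float, Ai_MBq: float) -> float:
    """Extrapolate from the mean normalized dose of cycles 1 and 2."""
    if not (A1_MBq > 0 and A2_MBq > 0):
        raise DomainError("cycle-1 and cycle-2 injected activities must be positive")
    return 0.5 * (D1_mGy / A1_MBq + D2_mGy / A2_MBq) * Ai_MBq


def observation_time(cycle_schedule_h: np.ndarray, tp_label: str) -> float:
    """Scan time within a cycle's schedule for a single-TP label."""
    sched = np.asarray(cycle_schedule_h, dtype=float)
    if tp_label == "2-4h":
        return float(sched[0])
    if tp_label == "24h":
        return 24.0
    if tp_label == "48h":
        return 48.0
    if tp_label == "72-168h":
        return float(sched[-1])
    raise DomainError(f"unknown time-point label {tp_label!r}; use one of {TP_LABELS}")


def _copied(rm_rows: pd.DataFrame, method: str) -> pd.DataFrame:
    out = rm_rows.copy()
    out["method"] = method
    out["fit_model"] = "copied_rm"
    return out


def run_simplified(
    cohort: Cohort,
    rm_records: pd.DataFrame,
    method: str,
    tp_label: str | None = None,
    nuclide: Radionuclide = LU177,
    cycle1_fits: dict | None = None,
    include_lesions: bool | None = None,
) -> pd.DataFrame:
    """Apply a simplified method to every eligible patient/region.

    SM1 produces records for cycles 2..n at the chosen time point (for the
    72-168 h label, each cycle's own last scan time) for organs and
    lesions alike.  SM2/SM3 extrapolate organ doses only; requesting them
    for lesions raises, because declining tumor uptake invalidates pure
    activity scaling.  For SM2 (SM3) the cycle-1 (cycles-1/2) records are
    copied from the reference method so cumulated totals are comparable.

    ``cycle1_fits`` may carry ``{(patient, cycle, region): (TACFit, tia)}``
    from ``run_reference_dosimetry(..., return_fits=True)`` to avoid
    refitting cycle 1 for SM1.
    """
    if method not in ("SM1", "SM2", "SM3"):
        raise DomainError(f"unknown simplified method {method!r}")
    n_cycles = max(len(p.cycles) for p in cohort.patients)

    if method == "SM1":
        if tp_label not in TP_LABELS:
            raise DomainError(f"SM1 needs a time-point label from {TP_LABELS}")
        if include_lesions is None:
            include_lesions = True
        if cycle1_fits is None:
            _, cycle1_fits = run_reference_dosimetry(cohort, nuclide, return_fits=True)
        rows = []
        for p in cohort.patients:
            for rid, region in p.regions.items():
                if region.kind.is_lesion and not include_lesions:
                    continue
                key = (p.patient_id, 1, rid)
                if key not in cycle1_fits:
                    continue
                ref_fit, ref_tia = cycle1_fits[key]
                for cyc in p.cycles[1:n_cycles]:
                    data = cyc.measurements.get(rid)
                    if data is None:
                        continue
                    t_obs = observation_time(data.times_h, tp_label)
                    idx = np.flatnonzero(np.isclose(data.times_h, t_obs))
                    if idx.size == 0:
                        raise FitError(
                            f"no measurement at {t_obs} h for {p.patient_id} "
                            f"cycle {cyc.index} region {rid}"
                        )
                    obs = SingleTimePointObservation(
                        patient=p.patient_id,
                        cycle=cyc.index,
                        region_id=rid,
                        t_single_h=t_obs,
                        measured_MBq=float(data.activities_MBq[idx[0]]),
                        injected_MBq=cyc.injected_MBq,
                        tp_label=tp_label,
                    )
                    rows.append(sm1_dose(ref_fit, ref_tia, obs, region, nuclide))
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    # SM2 / SM3
    if include_lesions:
        raise DomainError(
            f"{method} cannot be applied to tumor lesions: uptake declines from "
            "cycle to cycle, so extrapolation by injected activity alone is invalid"
        )
    organs = rm_records[~rm_records["kind"].str.startswith("lesion")]
    base_cycles = (1,) if method == "SM2" else (1, 2)
    missing = [c for c in base_cycles if c not in set(organs["cycle"])]
    if missing:
        raise DomainError(f"{method} needs reference records for cycle(s) {missing}")
    copied = _copied(organs[organs["cycle"].isin(base_cycles)], method)
    rows = []
    for p in cohort.patients:
        base = organs[organs["patient"] == p.patient_id]
        for rid, region in p.regions.items():
            if region.kind.is_lesion:
                continue
            ref = base[base["region"] == rid].set_index("cycle")
            if any(c not in ref.index for c in base_cycles):
                continue
            d1, a1 = float(ref.loc[1, "dose_mGy"]), float(ref.loc[1, "injected_MBq"])
            if method == "SM3":
                d2, a2 = float(ref.loc[2, "dose_mGy"]), float(ref.loc[2, "injected_MBq"])
            for cyc in p.cycles:
                if cyc.index in base_cycles or cyc.index > n_cycles:
                    continue
                ai = cyc.injected_MBq
                dose = (
                    sm2_dose(d1, a1, ai) if method == "SM2" else sm3_dose(d1, a1, d2, a2, ai)
                )
                # the extrapolation defines the dose directly; the implied
                # TIA (dose / S) keeps the record schema consistent
                rows.append(
                    make_record(
                        patient=p.patient_id,
                        cycle=cyc.index,
                        region=region,
                        method=method,
                        tia_MBqh=dose / self_dose_factor(region, nuclide),
                        injected_MBq=ai,
                        t_eff_h=float("nan"),
                        fit_model="extrapolation",
                        nuclide=nuclide,
                    )
                )
    out = pd.concat([copied, pd.DataFrame(rows, columns=RECORD_COLUMNS)], ignore_index=True)
    return out.sort_values(["patient", "region", "cycle"]).reset_index(drop=True)


def fill_from_reference(
    sm_records: pd.DataFrame, rm_records: pd.DataFrame, cycles: tuple[int, ...] = (1,)
) -> pd.DataFrame:
    """Prepend reference-method records for the given cycles (relabelled).

    Used to cumulate SM1 totals over all cycles: cycle 1 has no simplified
    estimate, so its reference dose participates in the total.
    """
    if sm_records.empty:
        return sm_records
    method = sm_records["method"].iloc[0]
    keys = sm_records[["patient", "region"]].drop_duplicates()
    rm = rm_records[rm_records["cycle"].isin(cycles)].merge(keys, on=["patient", "region"])
    return pd.concat([_copied(rm, method), sm_records], ignore_index=True)
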