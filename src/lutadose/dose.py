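"""Reference dosimetry: TIA -> absorbed dose -> normalized dose, and totals.

The reference method (RM) fits every measured TAC with the selection
cascade of :mod:`lutadose.fitting`, integrates analytically to infinity
(or trapezoid-with-tail where no exponential fits), and converts TIA to
absorbed dose with the sphere-model self-dose factor.  Doses are reported
per cycle as mGy and normalized to the injected activity (mGy/MBq), and
cumulated over cycles in Gy with safety flags against proposed organ
dose limits (28 Gy kidneys, 35 Gy salivary glands).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DomainError, FitError
from .fitting import TAC, TACFit, select_fit, tia_of
from .physics import (
    GLAND_LIMIT_GY,
    KIDNEY_LIMIT_GY,
    LU177,
    Radionuclide,
    RegionKind,
    SourceRegion,
    self_dose_factor,
)

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "patient", "cycle", "region", "kind", "method", "tp_label",
    "mass_g", "injected_MBq", "tia_MBqh", "dose_mGy",
    "norm_dose_mGy_per_MBq", "t_eff_h", "fit_model",
]


def absorbed_dose(tia_MBqh: float, region: SourceRegion, nuclide: Radionuclide = LU177) -> float:
    """Self-dose absorbed dose in mGy for a given TIA (MBq*h)."""
    if tia_MBqh < 0:
        raise DomainError("TIA must be non-negative")
    return tia_MBqh * self_dose_factor(region, nuclide)


def make_record(
    *,
    patient: str,
    cycle: int,
    region: SourceRegion,
    method: str,
    tia_MBqh: float,
    injected_MBq: float,
    t_eff_h: float,
    fit_model: str,
    nuclide: Radionuclide = LU177,
    tp_label: str = "",
) -> dict:
    dose = absorbed_dose(tia_MBqh, region, nuclide)
    return {
        "patient": patient,
        "cycle": cycle,
        "region": region.region_id,
        "kind": region.kind.value,
        "method": method,
        "tp_label": tp_label,
        "mass_g": region.mass_g,
        "injected_MBq": injected_MBq,
        "tia_MBqh": tia_MBqh,
        "dose_mGy": dose,
        "norm_dose_mGy_per_MBq": dose / injected_MBq,
        "t_eff_h": t_eff_h,
        "fit_model": fit_model,
    }


def run_reference_dosimetry(
    cohort: Cohort,
    nuclide: Radionuclide = LU177,
    return_fits: bool = False,
):
    """Run the reference method over every (patient, cycle, region).

    Returns a DataFrame of dose records (one per patient/cycle/region with
    a successful fit; failures are logged and omitted, never silent).
    With ``return_fits=True`` also returns ``{(patient, cycle, region):
    (TACFit, tia)}`` for reuse by the simplified methods.
    """
    rows: list[dict] = []
    fits: dict[tuple[str, int, str], tuple[TACFit, float]] = {}
    for p, cyc, region, data in cohort.iter_records():
        tac = TAC(data.times_h, data.activities_MBq, region.region_id, p.patient_id, cyc.index)
        try:
            fit = select_fit(tac)
            tia = tia_of(tac, fit)
        except FitError as exc:
            log.warning(
                "fit failed for %s cycle %d region %s: %s",
                p.patient_id, cyc.index, region.region_id, exc,
            )
            continue
        fits[(p.patient_id, cyc.index, region.region_id)] = (fit, tia)
        rows.append(
            make_record(
                patient=p.patient_id,
                cycle=cyc.index,
                region=region,
                method="RM",
                tia_MBqh=tia,
                injected_MBq=cyc.injected_MBq,
                t_eff_h=fit.t_eff_h,
                fit_model=fit.model,
                nuclide=nuclide,
            )
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return (df, fits) if return_fits else df


def fits_frame(fits: dict) -> pd.DataFrame:
    """Tidy table of fitted TAC parameters, one row per patient/cycle/region.

    ``fits`` is the mapping returned by ``run_reference_dosimetry(...,
    return_fits=True)``.
    """
    rows = []
    for (patient, cycle, region), (fit, tia) in fits.items():
        rows.append(
            {
                "patient": patient,
                "cycle": cycle,
                "region": region,
                "model": fit.model,
                "amplitude_MBq": fit.amplitude_MBq,
                "clearance_rate_h": fit.clearance_rate_h,
                "uptake_rate_h": fit.uptake_rate_h,
                "t_eff_h": fit.t_eff_h,
                "tail_points_used": fit.tail_points_used,
                "fit_residual_rms_MBq": fit.fit_residual_rms,
                "flagged": fit.flagged,
                "tia_MBqh": tia,
            }
        )
    return pd.DataFrame(rows)


def cumulate_doses(records: pd.DataFrame, n_cycles: int = 4) -> pd.DataFrame:
    """Cumulative dose per patient/region over cycles 1..n_cycles, in Gy.

    A missing cycle marks the total as ``partial``.  Kidney totals at or
    above 28 Gy and salivary-gland totals at or above 35 Gy are flagged
    against the proposed absorbed-dose limits.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["patient", "region", "kind", "method", "total_Gy",
                     "n_cycles_present", "partial", "flag_limit"]
        )
    methods = records["method"].unique()
    if len(methods) > 1:
        raise DomainError(f"cumulate_doses expects a single method, got {sorted(methods)}")
    sub = records[records["cycle"] <= n_cycles]
    rows = []
    for (patient, region), g in sub.groupby(["patient", "region"], sort=True):
        kind = RegionKind(g["kind"].iloc[0])
        total_gy = float(g["dose_mGy"].sum()) / 1000.0
        flag = ""
        if kind is RegionKind.KIDNEY and total_gy >= KIDNEY_LIMIT_GY:
            flag = "kidney_28_40Gy"
        elif kind in (RegionKind.PAROTID, RegionKind.SUBMANDIBULAR) and total_gy >= GLAND_LIMIT_GY:
            flag = "glands_35Gy"
        rows.append(
            {
                "patient": patient,
                "region": region,
                "kind": kind.value,
                "method": methods[0],
                "total_Gy": total_gy,
                "n_cycles_present": int(g["cycle"].nunique()),
                "partial": int(g["cycle"].nunique()) < n_cycles,
                "flag_limit": flag,
            }
        )
    return pd.DataFrame(rows)


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of normalized dose and T_eff by region kind and cycle."""
    if records.empty:
        return pd.DataFrame()
    g = records.groupby(["kind", "cycle"])
    out = g.agg(
        n=("norm_dose_mGy_per_MBq", "size"),
        norm_dose_mean=("norm_dose_mGy_per_MBq", "mean"),
        norm_dose_sd=("norm_dose_mGy_per_MBq", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
        t_eff_mean=("t_eff_h", "mean"),
        t_eff_sd=("t_eff_h", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
    ).reset_index()
    return out
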