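"""Synthetic virtual-patient cohort emulating a Lu-177 PSMA therapy study.

The generator works backwards from published summary statistics: for each
patient, cycle and source region it draws a *target* normalized absorbed
dose (mGy/MBq) and effective half-life (h) from log-normal distributions
around per-cycle population means, inverts the forward dosimetry map to
obtain true kinetics (amplitude and clearance rate), and simulates noisy
activity measurements at the imaging schedule.  Running the reference
dosimetry pipeline on the generated cohort should therefore recover the
configured population means up to Monte-Carlo and fit error — the basis
of all round-trip tests.

Default settings emulate a 16-patient, 4-cycle study: ~6.2 GBq injected
per cycle, imaging at 2/24/48 h plus a variable last time point between
72 and 168 h (mean 130 h), organ kinetics for kidneys and salivary
glands, and 90 tumor lesions (70 bone, 19 lymph node, 1 local recurrence)
with declining uptake and progressive dropout (90/87/79/67 analysable
lesions in cycles 1-4).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import truncnorm

from .errors import ConfigError, DomainError
from .fitting import TAC
from .physics import LU177, Radionuclide, RegionKind, SourceRegion, make_region, self_dose_factor

__all__ = [
    "TrueKinetics",
    "OrganKineticsSpec",
    "LesionTypeSpec",
    "LesionPlan",
    "CohortConfig",
    "Cohort",
    "Patient",
    "Cycle",
    "RegionCycleData",
    "kinetics_from_targets",
    "simulate_tac",
    "generate_cohort",
]


# --------------------------------------------------------------------------
# true kinetics and the inverse calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueKinetics:
    """Ground-truth kinetic model of one region in one cycle."""

    model: str  # "monoexp" | "uptake_biexp"
    amplitude_MBq: float
    clearance_rate_h: float
    uptake_rate_h: float | None = None

    def __post_init__(self) -> None:
        if not self.amplitude_MBq > 0:
            raise DomainError("amplitude must be positive")
        if not self.clearance_rate_h > 0:
            raise DomainError("clearance rate must be positive")
        if self.model == "uptake_biexp" and (
            self.uptake_rate_h is None or self.uptake_rate_h <= self.clearance_rate_h
        ):
            raise DomainError("uptake rate must exceed clearance rate")

    @property
    def t_eff_h(self) -> float:
        return math.log(2.0) / self.clearance_rate_h

    def activity(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "uptake_biexp":
            return self.amplitude_MBq * (
                np.exp(-self.clearance_rate_h * t) - np.exp(-self.uptake_rate_h * t)
            )
        return self.amplitude_MBq * np.exp(-self.clearance_rate_h * t)

    @property
    def tia_MBqh(self) -> float:
        if self.model == "uptake_biexp":
            return self.amplitude_MBq * (
                1.0 / self.clearance_rate_h - 1.0 / self.uptake_rate_h
            )
        return self.amplitude_MBq / self.clearance_rate_h


def kinetics_from_targets(
    norm_dose_mGy_per_MBq: float,
    t_eff_h: float,
    injected_MBq: float,
    region: SourceRegion,
    nuclide: Radionuclide = LU177,
    model: str = "monoexp",
    uptake_half_life_h: float = 1.0,
) -> TrueKinetics:
    """Invert the forward dosimetry map.

    Solves for the amplitude such that ``TIA * S(m) / A_inj`` equals the
    requested normalized dose, with ``TIA = A0/lam`` (mono-exponential) or
    ``TIA = A0*(1/lam_eff - 1/lam_up)`` (uptake bi-exponential).
    """
    if min(norm_dose_mGy_per_MBq, t_eff_h, injected_MBq) <= 0:
        raise DomainError("targets must be positive")
    s = self_dose_factor(region, nuclide)
    tia = norm_dose_mGy_per_MBq * injected_MBq / s
    lam = math.log(2.0) / t_eff_h
    if model == "monoexp":
        return TrueKinetics("monoexp", tia * lam, lam)
    lam_up = math.log(2.0) / uptake_half_life_h
    denom = 1.0 / lam - 1.0 / lam_up
    if denom <= 0:
        raise DomainError("requested dose unreachable: uptake slower than clearance")
    return TrueKinetics("uptake_biexp", tia / denom, lam, uptake_rate_h=lam_up)


def simulate_tac(
    kin: TrueKinetics,
    schedule_h: Sequence[float],
    noise_cv: float,
    seed: int | np.random.Generator = 0,
) -> TAC:
    """Simulate measured activities at the imaging schedule.

    Measurements are the true curve times i.i.d. log-normal multiplicative
    noise with mean 1 and the given coefficient of variation; ``noise_cv=0``
    returns the exact curve.  Deterministic under a fixed seed.
    """
    t = np.asarray(schedule_h, dtype=float)
    if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise DomainError("schedule must be non-empty, positive, strictly increasing")
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    a = kin.activity(t)
    if noise_cv > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        a = a * _lognormal_mean1(rng, noise_cv, t.shape)
    return TAC(t, a)


def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Log-normal deviates with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=size)


def _ln_effect(z: float, cv: float) -> float:
    """Mean-1 log-normal factor with the given CV from a standard-normal z."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.exp(sigma * z - 0.5 * sigma * sigma)


# --------------------------------------------------------------------------
# configuration (defaults are the emulated study conditions)
# --------------------------------------------------------------------------

class OrganKineticsSpec(BaseModel):
    """Per-cycle population targets for one organ kind.

    ``norm_dose`` / ``t_eff`` are per-cycle means; the ``*_cv`` lists are
    the per-cycle between-patient coefficients of variation (table SD /
    mean row by row).  They are realised through one patient-level
    standard-normal effect shared across cycles and scaled to each
    cycle's log-normal spread, so per-cycle means and CVs match the
    configured rows while patients stay internally consistent.
    """

    model_config = ConfigDict(extra="forbid")

    norm_dose_mGy_per_MBq: list[float]
    norm_dose_cv: list[float]
    t_eff_h: list[float]
    t_eff_cv: list[float]


class LesionTypeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    count: int = Field(ge=0)
    norm_dose_cycle1_mGy_per_MBq: float = Field(gt=0)
    norm_dose_cv: float = Field(ge=0)
    t_eff_h: float = Field(gt=0)
    t_eff_cv: float = Field(ge=0)
    volume_ml_mean: float = Field(gt=0)
    volume_ml_cv: float = Field(ge=0)


class LesionPlan(BaseModel):
    """Cohort-wide tumor-lesion plan.

    ``cycle_counts`` are the numbers of analysable lesions per cycle
    (dropout removes lesions, never adds); they are scaled proportionally
    if the type counts change.  ``decline_factors`` multiply each lesion's
    cycle-1 normalized-dose target; effective half-life targets are held
    constant across cycles.
    """

    model_config = ConfigDict(extra="forbid")

    bone: LesionTypeSpec = LesionTypeSpec(
        count=70,
        norm_dose_cycle1_mGy_per_MBq=2.91,
        norm_dose_cv=2.52 / 2.91,
        t_eff_h=55.5,
        t_eff_cv=19.2 / 55.5,
        volume_ml_mean=5.0,
        volume_ml_cv=0.8,
    )
    soft: LesionTypeSpec = LesionTypeSpec(
        count=19,
        norm_dose_cycle1_mGy_per_MBq=7.18,
        norm_dose_cv=3.94 / 7.18,
        t_eff_h=52.2,
        t_eff_cv=13.5 / 52.2,
        volume_ml_mean=8.0,
        volume_ml_cv=0.8,
    )
    n_local_recurrence: int = Field(default=1, ge=0)
    decline_factors: list[float] = [1.00, 0.61, 0.53, 0.52]
    cycle_counts: list[int] = [90, 87, 79, 67]
    max_per_patient: int = Field(default=10, ge=1)

    @property
    def total(self) -> int:
        return self.bone.count + self.soft.count + self.n_local_recurrence


_DEFAULT_ORGANS: dict[str, OrganKineticsSpec] = {
    "kidney": OrganKineticsSpec(
        norm_dose_mGy_per_MBq=[0.67, 0.73, 0.75, 0.67],
        norm_dose_cv=[0.30 / 0.67, 0.29 / 0.73, 0.33 / 0.75, 0.36 / 0.67],
        t_eff_h=[39.3, 38.0, 36.3, 36.7],
        t_eff_cv=[13.7 / 39.3, 14.6 / 38.0, 13.6 / 36.3, 16.3 / 36.7],
    ),
    "parotid": OrganKineticsSpec(
        norm_dose_mGy_per_MBq=[0.30, 0.28, 0.31, 0.25],
        norm_dose_cv=[0.18 / 0.30, 0.06 / 0.28, 0.10 / 0.31, 0.09 / 0.25],
        t_eff_h=[36.4, 32.6, 37.3, 39.4],
        t_eff_cv=[13.0 / 36.4, 8.2 / 32.6, 16.7 / 37.3, 18.2 / 39.4],
    ),
    "submandibular": OrganKineticsSpec(
        norm_dose_mGy_per_MBq=[0.23, 0.23, 0.23, 0.20],
        norm_dose_cv=[0.11 / 0.23, 0.08 / 0.23, 0.08 / 0.23, 0.06 / 0.20],
        t_eff_h=[41.6, 47.7, 44.6, 34.3],
        t_eff_cv=[17.3 / 41.6, 19.8 / 47.7, 19.5 / 44.6, 8.5 / 34.3],
    ),
}


class CohortConfig(BaseModel):
    """Full specification of the synthetic study population."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=16, ge=1)
    n_cycles: int = Field(default=4, ge=1)
    # injected activity: truncated normal, MBq
    activity_MBq_centre: float = 6200.0
    activity_MBq_sd: float = 500.0
    activity_MBq_range: tuple[float, float] = (5000.0, 6700.0)
    # imaging schedule
    early_schedule_h: list[float] = [2.0, 24.0, 48.0]
    last_tp_choices_h: list[float] = [72.0, 96.0, 120.0, 144.0, 168.0]
    last_tp_weights: list[float] = [0.125, 0.15, 0.2, 0.225, 0.3]
    # the last scan time varies mostly between patients and only partly
    # within a patient: each cycle redraws it with this probability
    last_tp_redraw_prob: float = Field(default=0.25, ge=0, le=1)
    # kinetics
    organs: dict[str, OrganKineticsSpec] = Field(
        default_factory=lambda: {k: v.model_copy() for k, v in _DEFAULT_ORGANS.items()}
    )
    lesion_plan: LesionPlan = Field(default_factory=LesionPlan)
    lesion_model: str = "monoexp"  # or "uptake_biexp"
    lesion_uptake_half_life_h: float = 1.0
    intercycle_cv: float = Field(default=0.10, ge=0)
    noise_cv: float = Field(default=0.05, ge=0)
    # anatomy
    kidney_volume_ml_mean: float = 300.0  # both kidneys combined
    kidney_volume_ml_cv: float = 0.15
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        sched = list(self.early_schedule_h)
        if any(b <= a for a, b in zip(sched, sched[1:])) or any(t <= 0 for t in sched):
            raise ValueError("early schedule must be positive, strictly increasing")
        if len(self.last_tp_choices_h) != len(self.last_tp_weights):
            raise ValueError("last-TP choices and weights must have equal length")
        if min(self.last_tp_choices_h) <= max(sched):
            raise ValueError("last time point must come after the early schedule")
        if abs(sum(self.last_tp_weights) - 1.0) > 1e-9:
            raise ValueError("last-TP weights must sum to 1")
        for name, spec in self.organs.items():
            fields = (spec.norm_dose_mGy_per_MBq, spec.norm_dose_cv, spec.t_eff_h, spec.t_eff_cv)
            if any(len(f) < self.n_cycles for f in fields):
                raise ValueError(f"organ {name!r}: need per-cycle targets/CVs for every cycle")
            if any(cv < 0 for f in (spec.norm_dose_cv, spec.t_eff_cv) for cv in f):
                raise ValueError(f"organ {name!r}: CVs must be non-negative")
        lp = self.lesion_plan
        if lp.total > self.n_patients * lp.max_per_patient:
            raise ValueError(
                f"infeasible lesion plan: {lp.total} lesions exceed "
                f"{self.n_patients} patients x {lp.max_per_patient}"
            )
        if len(lp.decline_factors) < self.n_cycles or len(lp.cycle_counts) < self.n_cycles:
            raise ValueError("lesion plan needs decline factors and counts for every cycle")
        if any(b > a for a, b in zip(lp.cycle_counts, lp.cycle_counts[1:])):
            raise ValueError("lesion cycle counts must be non-increasing")
        return self

    @property
    def mean_last_tp_h(self) -> float:
        return float(np.dot(self.last_tp_choices_h, self.last_tp_weights))


# --------------------------------------------------------------------------
# cohort containers
# --------------------------------------------------------------------------

@dataclass
class RegionCycleData:
    kinetics: TrueKinetics | None
    times_h: np.ndarray
    activities_MBq: np.ndarray
    norm_dose_true: float | None = None


@dataclass
class Cycle:
    index: int  # 1-based
    injected_MBq: float
    schedule_h: np.ndarray
    measurements: dict[str, RegionCycleData] = field(default_factory=dict)


@dataclass
class Patient:
    patient_id: str
    regions: dict[str, SourceRegion]
    cycles: list[Cycle] = field(default_factory=list)


@dataclass
class Cohort:
    config: CohortConfig | None
    patients: list[Patient]

    def iter_records(self):
        for p in self.patients:
            for cyc in p.cycles:
                for rid, data in cyc.measurements.items():
                    yield p, cyc, p.regions[rid], data

    def tac(self, patient_id: str, cycle: int, region_id: str) -> TAC:
        p = next(pt for pt in self.patients if pt.patient_id == patient_id)
        data = p.cycles[cycle - 1].measurements[region_id]
        return TAC(data.times_h, data.activities_MBq, region_id, patient_id, cycle)

    def lesion_count(self, cycle: int | None = None) -> int:
        n = 0
        for p in self.patients:
            cycles = p.cycles if cycle is None else [p.cycles[cycle - 1]]
            if cycle is None:
                ids = {r for r in p.regions if p.regions[r].kind.is_lesion}
                n += len(ids)
            else:
                n += sum(
                    1 for r in cycles[0].measurements if p.regions[r].kind.is_lesion
                )
        return n

    # -- tidy I/O ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per measurement (tidy long format)."""
        rows = []
        for p, cyc, region, data in self.iter_records():
            for t, a in zip(data.times_h, data.activities_MBq):
                rows.append(
                    {
                        "patient": p.patient_id,
                        "cycle": cyc.index,
                        "region": region.region_id,
                        "kind": region.kind.value,
                        "mass_g": region.mass_g,
                        "injected_MBq": cyc.injected_MBq,
                        "time_h": t,
                        "activity_MBq": a,
                    }
                )
        return pd.DataFrame(rows)

    def truth(self) -> dict:
        """JSON-serialisable ground truth for parameter-recovery tests."""
        out: dict = {"config": self.config.model_dump() if self.config else None, "records": []}
        for p, cyc, region, data in self.iter_records():
            kin = data.kinetics
            out["records"].append(
                {
                    "patient": p.patient_id,
                    "cycle": cyc.index,
                    "region": region.region_id,
                    "kind": region.kind.value,
                    "model": kin.model if kin else None,
                    "amplitude_MBq": kin.amplitude_MBq if kin else None,
                    "clearance_rate_h": kin.clearance_rate_h if kin else None,
                    "uptake_rate_h": kin.uptake_rate_h if kin else None,
                    "t_eff_h": kin.t_eff_h if kin else None,
                    "norm_dose_true": data.norm_dose_true,
                }
            )
        return out

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "measurements.csv"
        json_path = out / "truth.json"
        self.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        json_path.write_text(json.dumps(self.truth(), indent=1))
        return csv_path, json_path

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        """Rebuild a measurement-only cohort (no ground truth) from tidy CSV."""
        required = {"patient", "cycle", "region", "kind", "mass_g", "injected_MBq",
                    "time_h", "activity_MBq"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"measurement table missing columns: {sorted(missing)}")
        patients: list[Patient] = []
        for pid, pdf in df.groupby("patient", sort=True):
            regions: dict[str, SourceRegion] = {}
            for rid, rdf in pdf.groupby("region"):
                regions[str(rid)] = SourceRegion(
                    region_id=str(rid),
                    kind=RegionKind(rdf["kind"].iloc[0]),
                    mass_g=float(rdf["mass_g"].iloc[0]),
                )
            cycles = []
            for ci, cdf in pdf.groupby("cycle", sort=True):
                meas: dict[str, RegionCycleData] = {}
                sched = np.array([])
                for rid, rdf in cdf.groupby("region"):
                    rdf = rdf.sort_values("time_h")
                    t = rdf["time_h"].to_numpy(float)
                    meas[str(rid)] = RegionCycleData(None, t, rdf["activity_MBq"].to_numpy(float))
                    sched = t if t.size > sched.size else sched
                cycles.append(
                    Cycle(int(ci), float(cdf["injected_MBq"].iloc[0]), sched, meas)
                )
            patients.append(Patient(str(pid), regions, cycles))
        return cls(config=None, patients=patients)

    @classmethod
    def read(cls, csv_path: str | Path) -> "Cohort":
        return cls.from_frame(pd.read_csv(csv_path))


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def sample_last_tp(config: CohortConfig, rng: np.random.Generator, size=None):
    return rng.choice(config.last_tp_choices_h, size=size, p=config.last_tp_weights)


def _sample_activity(config: CohortConfig, rng: np.random.Generator) -> float:
    if config.activity_MBq_sd == 0:
        return config.activity_MBq_centre
    lo, hi = config.activity_MBq_range
    a = (lo - config.activity_MBq_centre) / config.activity_MBq_sd
    b = (hi - config.activity_MBq_centre) / config.activity_MBq_sd
    return float(
        truncnorm.rvs(
            a, b, loc=config.activity_MBq_centre, scale=config.activity_MBq_sd,
            random_state=rng,
        )
    )


def _allocate_lesions(
    config: CohortConfig, rng: np.random.Generator
) -> list[tuple[int, RegionKind, str]]:
    """Assign lesions (patient index, kind, label) respecting the per-patient cap."""
    lp = config.lesion_plan
    kinds = (
        [RegionKind.LESION_BONE] * lp.bone.count
        + [RegionKind.LESION_SOFT] * lp.soft.count
        + [RegionKind.LESION_SOFT] * lp.n_local_recurrence
    )
    labels = (
        [f"bone{i+1}" for i in range(lp.bone.count)]
        + [f"node{i+1}" for i in range(lp.soft.count)]
        + [f"local{i+1}" for i in range(lp.n_local_recurrence)]
    )
    order = rng.permutation(len(kinds))
    counts = np.zeros(config.n_patients, dtype=int)
    out = []
    for idx in order:
        open_patients = np.flatnonzero(counts < lp.max_per_patient)
        if open_patients.size == 0:
            raise ConfigError("infeasible lesion plan: all patients at capacity")
        pidx = int(rng.choice(open_patients))
        counts[pidx] += 1
        out.append((pidx, kinds[idx], labels[idx]))
    return out


def _dropout_sets(config: CohortConfig, lesion_ids: list[str], rng: np.random.Generator):
    """Per-cycle sets of surviving lesion ids with exact cohort-level counts."""
    lp = config.lesion_plan
    total = len(lesion_ids)
    if total == 0:
        return [set() for _ in range(config.n_cycles)]
    base = lp.cycle_counts[: config.n_cycles]
    targets = [min(total, int(round(c / lp.cycle_counts[0] * total))) for c in base]
    survivors = list(lesion_ids)
    sets = []
    for tgt in targets:
        n_drop = len(survivors) - tgt
        if n_drop > 0:
            dropped = rng.choice(len(survivors), size=n_drop, replace=False)
            keep = set(range(len(survivors))) - set(int(d) for d in dropped)
            survivors = [survivors[i] for i in sorted(keep)]
        sets.append(set(survivors))
    return sets


def generate_cohort(config: CohortConfig | None = None, nuclide: Radionuclide = LU177) -> Cohort:
    """Generate the full synthetic cohort (deterministic under ``config.seed``)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    lp = config.lesion_plan

    allocation = _allocate_lesions(config, rng)
    patients: list[Patient] = []
    lesion_spec = {
        RegionKind.LESION_BONE: lp.bone,
        RegionKind.LESION_SOFT: lp.soft,
    }

    # build patients and regions
    all_lesion_ids: list[str] = []
    for pidx in range(config.n_patients):
        pid = f"P{pidx + 1:02d}"
        regions: dict[str, SourceRegion] = {}
        kidney_vol = config.kidney_volume_ml_mean * _lognormal_mean1(
            rng, config.kidney_volume_ml_cv
        )
        regions["kidneys"] = make_region("kidneys", RegionKind.KIDNEY, volume_ml=float(kidney_vol))
        regions["parotid"] = make_region("parotid", RegionKind.PAROTID)
        regions["submandibular"] = make_region("submandibular", RegionKind.SUBMANDIBULAR)
        patients.append(Patient(pid, regions))
    for pidx, kind, label in allocation:
        p = patients[pidx]
        spec = lesion_spec[kind]
        vol = spec.volume_ml_mean * _lognormal_mean1(rng, spec.volume_ml_cv)
        rid = f"{p.patient_id}-{label}"
        p.regions[rid] = make_region(rid, kind, volume_ml=float(vol))
        all_lesion_ids.append(rid)

    survivor_sets = _dropout_sets(config, all_lesion_ids, rng)

    # patient-level random effects: one standard-normal draw per region and
    # quantity, shared across cycles and scaled to each cycle's CV below
    effects: dict[tuple[str, str], tuple[float, float]] = {}
    for p in patients:
        for rid in p.regions:
            effects[(p.patient_id, rid)] = (float(rng.standard_normal()),
                                            float(rng.standard_normal()))

    # cycles
    for p in patients:
        patient_last = float(sample_last_tp(config, rng))
        for ci in range(1, config.n_cycles + 1):
            injected = _sample_activity(config, rng)
            last = patient_last
            if ci > 1 and rng.random() < config.last_tp_redraw_prob:
                last = float(sample_last_tp(config, rng))
            schedule = np.array(list(config.early_schedule_h) + [last])
            cyc = Cycle(ci, injected, schedule)
            for rid, region in p.regions.items():
                kind = region.kind
                if kind.is_lesion and rid not in survivor_sets[ci - 1]:
                    continue
                z_d, z_t = effects[(p.patient_id, rid)]
                if kind.is_lesion:
                    spec = lesion_spec[kind]
                    d_mean = spec.norm_dose_cycle1_mGy_per_MBq * lp.decline_factors[ci - 1]
                    t_mean = spec.t_eff_h
                    d_cv, t_cv = spec.norm_dose_cv, spec.t_eff_cv
                    model = config.lesion_model
                else:
                    ospec = config.organs[kind.value]
                    d_mean = ospec.norm_dose_mGy_per_MBq[ci - 1]
                    t_mean = ospec.t_eff_h[ci - 1]
                    d_cv, t_cv = ospec.norm_dose_cv[ci - 1], ospec.t_eff_cv[ci - 1]
                    model = "monoexp"
                jit_d = float(_lognormal_mean1(rng, config.intercycle_cv))
                jit_t = float(_lognormal_mean1(rng, config.intercycle_cv))
                jit_u = float(_lognormal_mean1(rng, config.intercycle_cv))
                d_true = d_mean * _ln_effect(z_d, d_cv) * jit_d
                t_true = t_mean * _ln_effect(z_t, t_cv) * jit_t
                kin = kinetics_from_targets(
                    d_true, t_true, injected, region, nuclide,
                    model=model,
                    uptake_half_life_h=config.lesion_uptake_half_life_h * jit_u,
                )
                tac = simulate_tac(kin, schedule, config.noise_cv, rng)
                cyc.measurements[rid] = RegionCycleData(
                    kin, tac.times_h, tac.activities_MBq, norm_dose_true=d_true
                )
            p.cycles.append(cyc)

    return Cohort(config=config, patients=patients)
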