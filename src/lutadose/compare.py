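"""Agreement between simplified and reference dosimetry.

Bland-Altman statistics on percent differences (bias and 1.96*SD limits
of agreement), RMSE in dose units, per-cycle percent-deviation summaries,
and a seeded permutation test for a between-cycle effect (a stand-in for
a repeated-measures mixed-effects model; its p-values are its own, not a
replication of any particular mixed-model implementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    """Bland-Altman + RMSE summary for one SM-vs-RM pairing."""

    n: int
    mean_bias_pct: float
    loa_pct: float  # 1.96 * SD of percent differences
    rmse: float  # in the input dose units

    @property
    def loa_low_pct(self) -> float:
        return self.mean_bias_pct - self.loa_pct

    @property
    def loa_high_pct(self) -> float:
        return self.mean_bias_pct + self.loa_pct


def percent_difference(d_sm, d_rm, denominator: str = "rm"):
    """Percent difference of a simplified vs a reference dose.

    ``denominator="rm"`` (default) uses the reference value;
    ``"mean"`` uses the pair mean (classical Bland-Altman x-axis).
    """
    d_sm = np.asarray(d_sm, dtype=float)
    d_rm = np.asarray(d_rm, dtype=float)
    if denominator == "rm":
        denom = d_rm
    elif denominator == "mean":
        denom = 0.5 * (d_sm + d_rm)
    else:
        raise DomainError("denominator must be 'rm' or 'mean'")
    if np.any(denom <= 0):
        raise DomainError("percent difference undefined for non-positive denominator")
    return 100.0 * (d_sm - d_rm) / denom


def rmse(d_sm, d_rm) -> float:
    """Root mean square error between paired doses, in input units."""
    d_sm = np.asarray(d_sm, dtype=float)
    d_rm = np.asarray(d_rm, dtype=float)
    if d_sm.size == 0:
        raise DomainError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((d_sm - d_rm) ** 2)))


def bland_altman(d_sm, d_rm, denominator: str = "rm") -> ComparisonResult:
    """Bland-Altman bias and limits of agreement on percent differences.

    Bias is the mean percent difference; the limits of agreement are
    bias +/- 1.96 times the sample SD (ddof=1) of the percent differences,
    which contain ~95% of the data under normality.
    """
    d_sm = np.asarray(d_sm, dtype=float)
    d_rm = np.asarray(d_rm, dtype=float)
    if d_sm.size < 2:
        raise DomainError("Bland-Altman needs at least 2 pairs")
    diffs = percent_difference(d_sm, d_rm, denominator)
    return ComparisonResult(
        n=int(diffs.size),
        mean_bias_pct=float(np.mean(diffs)),
        loa_pct=float(1.96 * np.std(diffs, ddof=1)),
        rmse=rmse(d_sm, d_rm),
    )


def pair_records(
    sm_records: pd.DataFrame,
    rm_records: pd.DataFrame,
    value: str = "norm_dose_mGy_per_MBq",
) -> pd.DataFrame:
    """Inner-join SM and RM records on (patient, cycle, region).

    A ``seed`` column (present when records from several replicated
    cohorts are pooled) joins too, so replicates never cross-match.
    """
    keys = ["patient", "cycle", "region"]
    if "seed" in sm_records.columns and "seed" in rm_records.columns:
        keys = ["seed"] + keys
    sm = sm_records[keys + ["kind", value]].rename(columns={value: "d_sm"})
    rm = rm_records[keys + [value]].rename(columns={value: "d_rm"})
    return sm.merge(rm, on=keys, how="inner")


def compare_methods(
    sm_records: pd.DataFrame,
    rm_records: pd.DataFrame,
    value: str = "norm_dose_mGy_per_MBq",
    by: tuple[str, ...] = ("kind",),
    denominator: str = "rm",
    cycles: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Agreement table (one row per group): n, bias, LoA, RMSE.

    By default pools cycles and groups by region kind, mirroring an
    agreement table of bias +/- 1.96 SD and RMSE per organ/structure.
    """
    pairs = pair_records(sm_records, rm_records, value)
    if cycles is not None:
        pairs = pairs[pairs["cycle"].isin(cycles)]
    rows = []
    groups = pairs.groupby(list(by)) if by else [((), pairs)]
    for key, g in groups:
        res = bland_altman(g["d_sm"], g["d_rm"], denominator)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=res.n,
            mean_bias_pct=res.mean_bias_pct,
            loa_pct=res.loa_pct,
            loa_low_pct=res.loa_low_pct,
            loa_high_pct=res.loa_high_pct,
            rmse=res.rmse,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def patient_mean_lesion_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse individual lesions to one mean value per patient and cycle.

    Mirrors analysing lesions 'as mean absorbed dose per patient': the
    region key becomes a synthetic 'lesions-mean' region.
    """
    lesions = records[records["kind"].str.startswith("lesion")]
    if lesions.empty:
        return lesions
    g = (
        lesions.groupby(["patient", "cycle", "method", "tp_label"], as_index=False)
        .agg(norm_dose_mGy_per_MBq=("norm_dose_mGy_per_MBq", "mean"),
             dose_mGy=("dose_mGy", "mean"),
             n_lesions=("region", "size"))
    )
    g["region"] = "lesions-mean"
    g["kind"] = "lesion_mean"
    return g


def cycle_deviation_summary(rm_records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent deviation of each cycle's normalized dose from cycle 1.

    Returns (per patient/region/cycle table, across-patient means by
    region kind and cycle).  Patients/regions without a cycle-1 record
    are excluded and logged.
    """
    value = "norm_dose_mGy_per_MBq"
    rows = []
    for (patient, region), g in rm_records.groupby(["patient", "region"]):
        g = g.set_index("cycle")
        if 1 not in g.index:
            log.warning("no cycle-1 record for %s/%s; excluded", patient, region)
            continue
        base = float(g.loc[1, value])
        for cyc in sorted(g.index):
            rows.append(
                {
                    "patient": patient,
                    "region": region,
                    "kind": g.loc[cyc, "kind"],
                    "cycle": int(cyc),
                    "deviation_pct": 100.0 * (float(g.loc[cyc, value]) - base) / base,
                }
            )
    per_record = pd.DataFrame(rows)
    if per_record.empty:
        return per_record, per_record
    summary = (
        per_record.groupby(["kind", "cycle"], as_index=False)
        .agg(mean_deviation_pct=("deviation_pct", "mean"), n=("deviation_pct", "size"))
    )
    return per_record, summary


def between_cycle_test(
    rm_records: pd.DataFrame,
    region_kind: str,
    n_perm: int = 10_000,
    seed: int = 0,
    value: str = "norm_dose_mGy_per_MBq",
) -> float:
    """Permutation p-value for a cycle effect on per-patient values.

    The statistic is the variance of the cycle means of per-patient values
    (individual lesions are first averaged within patient and cycle); the
    null distribution permutes cycle labels within each patient, which
    respects the repeated-measures structure and tolerates missing cells.
    Deterministic under ``seed``.
    """
    sub = rm_records[rm_records["kind"] == region_kind]
    if region_kind in ("lesion", "lesion_all"):
        sub = rm_records[rm_records["kind"].str.startswith("lesion")]
    per_patient = (
        sub.groupby(["patient", "cycle"], as_index=False)[value].mean()
    )
    cycles = sorted(per_patient["cycle"].unique())
    if len(cycles) < 2:
        raise DomainError("between-cycle test needs at least 2 cycles")
    if per_patient["patient"].nunique() < 3:
        raise DomainError("between-cycle test needs at least 3 patients")

    cycle_pos = {c: i for i, c in enumerate(cycles)}
    by_patient = [
        (np.array([cycle_pos[c] for c in g["cycle"]]), g[value].to_numpy(float))
        for _, g in per_patient.groupby("patient")
    ]
    n_c = len(cycles)
    counts = np.zeros(n_c)
    obs_sums = np.zeros(n_c)
    for pos, vals in by_patient:
        np.add.at(counts, pos, 1.0)
        np.add.at(obs_sums, pos, vals)
    obs = float(np.var(obs_sums / counts))

    # permute cycle labels within each patient, all replicates at once
    rng = np.random.default_rng(seed)
    sums = np.zeros((n_perm, n_c))
    for pos, vals in by_patient:
        k = len(vals)
        perm = np.argsort(rng.random((n_perm, k)), axis=1)
        permuted = vals[perm]  # (n_perm, k)
        for j in range(k):
            sums[:, pos[j]] += permuted[:, j]
    stats = np.var(sums / counts, axis=1)
    hits = int(np.sum(stats >= obs - 1e-15))
    return (1 + hits) / (1 + n_perm)
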