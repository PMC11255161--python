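"""Study orchestration: seed-replicated virtual studies and summary metrics.

A *replicated study* regenerates the synthetic cohort under several seeds,
runs the reference pipeline (and optionally SM1 at chosen time points) on
each replicate, and pools the dose records.  Population summary metrics
(cohort-mean normalized doses and effective half-lives) are then simple
averages over the pooled records — the quantities a multi-time-point
dosimetry study tabulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, generate_cohort
from .dose import run_reference_dosimetry
from .simplified import run_simplified

__all__ = ["ReplicatedStudy", "replicate_study", "derive_seeds", "reference_summary_metrics"]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible per-replicate seeds (< 2**31) from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


@dataclass
class ReplicatedStudy:
    """Pooled dose records over seed replicates (``seed`` column added)."""

    rm_records: pd.DataFrame
    sm1_records: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_replicates: int = 0


def replicate_study(
    config: CohortConfig | None = None,
    n_replicates: int = 20,
    base_seed: int = 0,
    tp_labels: tuple[str, ...] = (),
) -> ReplicatedStudy:
    """Generate + analyse ``n_replicates`` cohorts; pool the records."""
    config = config or CohortConfig()
    rm_parts: list[pd.DataFrame] = []
    sm1_parts: dict[str, list[pd.DataFrame]] = {tp: [] for tp in tp_labels}
    for seed in derive_seeds(base_seed, n_replicates):
        cfg = config.model_copy(update={"seed": seed})
        cohort = generate_cohort(cfg)
        rm, fits = run_reference_dosimetry(cohort, return_fits=True)
        rm = rm.assign(seed=seed)
        rm_parts.append(rm)
        for tp in tp_labels:
            sm1 = run_simplified(cohort, rm, "SM1", tp_label=tp, cycle1_fits=fits)
            sm1_parts[tp].append(sm1.assign(seed=seed))
    return ReplicatedStudy(
        rm_records=pd.concat(rm_parts, ignore_index=True),
        sm1_records={tp: pd.concat(parts, ignore_index=True) for tp, parts in sm1_parts.items()},
        n_replicates=n_replicates,
    )


def _mean_n(series: pd.Series) -> dict:
    return {"value": float(series.mean()), "n": int(series.size)}


def reference_summary_metrics(rm_records: pd.DataFrame) -> dict[str, dict]:
    """Cohort-level summary quantities from pooled reference records.

    Keys: mean normalized doses (mGy/MBq) per organ kind pooled over
    cycles, individual-lesion means for cycles 1 and 4, and cycle-1 mean
    fitted effective half-lives (h) for kidneys and lesions.
    """
    df = rm_records
    lesions = df[df["kind"].str.startswith("lesion")]
    out = {
        "kidney_norm_dose_mGy_per_MBq": _mean_n(
            df.loc[df["kind"] == "kidney", "norm_dose_mGy_per_MBq"]
        ),
        "parotid_norm_dose_mGy_per_MBq": _mean_n(
            df.loc[df["kind"] == "parotid", "norm_dose_mGy_per_MBq"]
        ),
        "submandibular_norm_dose_mGy_per_MBq": _mean_n(
            df.loc[df["kind"] == "submandibular", "norm_dose_mGy_per_MBq"]
        ),
        "lesion_cycle1_norm_dose_mGy_per_MBq": _mean_n(
            lesions.loc[lesions["cycle"] == 1, "norm_dose_mGy_per_MBq"]
        ),
        "lesion_cycle4_norm_dose_mGy_per_MBq": _mean_n(
            lesions.loc[lesions["cycle"] == 4, "norm_dose_mGy_per_MBq"]
        ),
        "kidney_cycle1_t_eff_h": _mean_n(
            df.loc[(df["kind"] == "kidney") & (df["cycle"] == 1), "t_eff_h"]
        ),
        "lesion_cycle1_t_eff_h": _mean_n(
            lesions.loc[lesions["cycle"] == 1, "t_eff_h"]
        ),
    }
    return out
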