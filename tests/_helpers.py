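"""Shared test helpers (importable from any test module)."""

from lutadose import CohortConfig
from lutadose.cohort import LesionPlan, LesionTypeSpec, OrganKineticsSpec


def constant_kinetics_config(**overrides) -> CohortConfig:
    """Small cohort whose targets do not change across cycles.

    With noise and inter-cycle variability switched off, every cycle of a
    patient then has identical kinetics — the regime where the simplified
    single-time-point method is exact.
    """
    organs = {
        "kidney": OrganKineticsSpec(
            norm_dose_mGy_per_MBq=[0.7] * 4, norm_dose_cv=[0.4] * 4,
            t_eff_h=[39.0] * 4, t_eff_cv=[0.3] * 4,
        ),
        "parotid": OrganKineticsSpec(
            norm_dose_mGy_per_MBq=[0.28] * 4, norm_dose_cv=[0.3] * 4,
            t_eff_h=[36.0] * 4, t_eff_cv=[0.3] * 4,
        ),
        "submandibular": OrganKineticsSpec(
            norm_dose_mGy_per_MBq=[0.22] * 4, norm_dose_cv=[0.3] * 4,
            t_eff_h=[42.0] * 4, t_eff_cv=[0.3] * 4,
        ),
    }
    plan = LesionPlan(
        bone=LesionTypeSpec(
            count=6, norm_dose_cycle1_mGy_per_MBq=2.9, norm_dose_cv=0.6,
            t_eff_h=55.0, t_eff_cv=0.3, volume_ml_mean=5.0, volume_ml_cv=0.5,
        ),
        soft=LesionTypeSpec(
            count=2, norm_dose_cycle1_mGy_per_MBq=7.2, norm_dose_cv=0.5,
            t_eff_h=52.0, t_eff_cv=0.25, volume_ml_mean=8.0, volume_ml_cv=0.5,
        ),
        n_local_recurrence=0,
        decline_factors=[1.0] * 4,
        cycle_counts=[8] * 4,
    )
    base = dict(
        n_patients=4,
        n_cycles=4,
        organs=organs,
        lesion_plan=plan,
        noise_cv=0.0,
        intercycle_cv=0.0,
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)
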