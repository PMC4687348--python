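"""Tunable protocol constants.

Every threshold the decision rules use lives in one frozen-by-default
:class:`Settings` object so that a hospital can override locally (YAML file
via the CLI ``--config`` flag) without touching rule code.  The defaults are
the published protocol values; overriding them produces a *different*
protocol, which is why they are collected here rather than scattered as
magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["Settings", "DEFAULT_SETTINGS", "load_settings"]


@dataclass(frozen=True)
class Settings:
    """Protocol constants, all glucose values in mg/dL.

    Attributes
    ----------
    elderly_age_years:
        Age at or above which a patient counts as elderly for the
        dose-lowering modifier.  The protocol names the factor without a
        cutoff; 70 is the conservative geriatric convention.
    category_min, category_max:
        Clamp bounds on the insulin dose category, keeping the per-kg
        coefficient inside 0.1-0.7 u/kg.
    rapid_rule_constant, short_rule_constant:
        Numerators of the 1800 Rule (rapid-acting) and 1500 Rule
        (short-acting/regular) for the sensitivity factor.
    correction_target_mgdl:
        Anchor of the correction scale; upper edge of the 100-140 average-BG
        goal band, biased against hypoglycemia.
    correction_cap_units:
        Largest single correction dose the scale will tabulate; beyond it the
        scale says to escalate to a physician.
    stepwise_initial_bg_cutoff_mgdl:
        Initial BG below which an eating, insulin-naive/low-dose patient
        starts on the step-wise (no basal) approach.
    stepwise_low_dose_iu_per_kg:
        Outpatient total daily insulin dose per kg below which home insulin
        use still qualifies for the step-wise approach.
    avg_bg_increase_above_mgdl, avg_bg_decrease_below_mgdl:
        Titration band: average BG strictly above the first raises the
        category, strictly below the second lowers it.
    stepwise_add_basal_above_mgdl:
        Average BG strictly above which a step-wise regimen gains basal
        insulin at reassessment.
    hypoglycemia_alert_mgdl, severe_hypoglycemia_mgdl:
        Alert threshold (<70, the standard alert level) and the severity
        annotation level (<40).
    variability_hypo_mgdl, variability_hyper_mgdl:
        A window containing both a value below the first and a value above
        the second flags glycemic variability (specialist consult).
    dka_rule_out_above_mgdl:
        Any single BG strictly above this triggers the DKA rule-out message.
    bedtime_supplement_low_mgdl, bedtime_supplement_high_mgdl:
        Bedtime supplement bands: 2 units inside [low, high], 4 units above.
    nph_doses_per_day:
        2 = NPH split 2/3 morning + 1/3 evening (default); 3 = equal thirds.
    review_window_hours:
        Default titration look-back window (24-48 h allowed).
    """

    elderly_age_years: float = 70.0
    category_min: int = 2
    category_max: int = 14
    rapid_rule_constant: float = 1800.0
    short_rule_constant: float = 1500.0
    correction_target_mgdl: float = 140.0
    correction_cap_units: int = 8
    stepwise_initial_bg_cutoff_mgdl: float = 250.0
    stepwise_low_dose_iu_per_kg: float = 0.2
    avg_bg_increase_above_mgdl: float = 140.0
    avg_bg_decrease_below_mgdl: float = 100.0
    stepwise_add_basal_above_mgdl: float = 180.0
    hypoglycemia_alert_mgdl: float = 70.0
    severe_hypoglycemia_mgdl: float = 40.0
    variability_hypo_mgdl: float = 70.0
    variability_hyper_mgdl: float = 180.0
    dka_rule_out_above_mgdl: float = 250.0
    bedtime_supplement_low_mgdl: float = 250.0
    bedtime_supplement_high_mgdl: float = 350.0
    nph_doses_per_day: int = 2
    review_window_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.nph_doses_per_day not in (2, 3):
            raise ValueError("nph_doses_per_day must be 2 or 3")
        if not self.category_min <= 8 <= self.category_max:
            raise ValueError("category bounds must bracket the standard category 8")


DEFAULT_SETTINGS = Settings()

_FIELD_NAMES = {f.name for f in fields(Settings)}


def load_settings(source: str | Path | Mapping[str, Any] | None) -> Settings:
    """Build a :class:`Settings` from a YAML file or mapping of overrides.

    Unknown keys raise ``ValueError`` so that a typo in a config file cannot
    silently leave a threshold at its default.
    """
    if source is None:
        return DEFAULT_SETTINGS
    if isinstance(source, Mapping):
        data: Mapping[str, Any] = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {source} must contain a mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown settings key(s): {sorted(unknown)}")
    return replace(DEFAULT_SETTINGS, **dict(data))
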