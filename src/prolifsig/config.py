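"""Analysis thresholds shared across the pipeline.

Every cut-off used anywhere in the analysis lives here, so that no
computation path hard-codes a boundary and every threshold can be
overridden in one place (and is recorded in the run manifest).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs for tertiles, PD-L1 TPS, cold tumors and cohort eligibility.

    Attributes
    ----------
    tertile_low, tertile_high:
        Rank-scale tertile boundaries. A score ``< tertile_low`` is *low*,
        ``tertile_low <= score <= tertile_high`` is *medium* and
        ``> tertile_high`` is *high* (both boundaries belong to *medium*).
    tps_positive, tps_strong:
        PD-L1 tumor proportion score cut-offs in percent. TPS below
        ``tps_positive`` is negative, at or above ``tps_strong`` strongly
        positive, in between weakly positive.
    cd8_cold_strict, cd8_cold_tertile:
        CD8 transcript-rank cut-offs flagging immunologically "cold" tumors
        (strict arbitrary cut and lower-tertile cut; both strict ``<``).
    early_exclusion_days:
        Patients who die within this many days of the first ICI dose are
        excluded (rapid progression indistinguishable from poor performance
        status); patients alive with less follow-up and no evaluable
        response are likewise excluded.
    days_per_month:
        Conversion constant used when survival is stored in months.
    sd_dc_min_months:
        Minimum survival for stable disease to count as disease control.
    km_horizon_months:
        Kaplan-Meier curves and log-rank tests are truncated at this
        horizon (5 years).
    alpha:
        Reporting significance level for the function screen.
    dc_requires_12mo_for_cr_pr:
        If true, CR/PR additionally require ``sd_dc_min_months`` survival
        to count as disease control. Default false: the 12-month clause
        binds stable disease only.
    """

    tertile_low: float = 33.0
    tertile_high: float = 66.0
    tps_positive: float = 1.0
    tps_strong: float = 50.0
    cd8_cold_strict: float = 15.0
    cd8_cold_tertile: float = 33.0
    early_exclusion_days: float = 90.0
    days_per_month: float = 30.44
    sd_dc_min_months: float = 12.0
    km_horizon_months: float = 60.0
    alpha: float = 0.05
    dc_requires_12mo_for_cr_pr: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.tertile_low < self.tertile_high < 100.0):
            raise ValueError(
                f"tertile cuts must satisfy 0 < low < high < 100, got "
                f"{self.tertile_low}/{self.tertile_high}"
            )
        if not (0.0 < self.tps_positive < self.tps_strong <= 100.0):
            raise ValueError(
                f"TPS cuts must satisfy 0 < positive < strong <= 100, got "
                f"{self.tps_positive}/{self.tps_strong}"
            )
        if not (0.0 < self.cd8_cold_strict < self.cd8_cold_tertile < 100.0):
            raise ValueError("CD8 cold cuts must satisfy 0 < strict < tertile < 100")
        for name in ("early_exclusion_days", "days_per_month",
                     "sd_dc_min_months", "km_horizon_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def early_exclusion_months(self) -> float:
        """The 90-day exclusion expressed in months (90 / 30.44 ≈ 2.957)."""
        return self.early_exclusion_days / self.days_per_month

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_THRESHOLDS = Thresholds()
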