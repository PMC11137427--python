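"""National extrapolation of per-session savings.

The national annual session count is anchored on CMS (Centers for Medicare &
Medicaid Services) reimbursement: CMS paid for 27,691,878 telemedicine
sessions in one year and accounts for 38% of National Health Expenditures,
giving an estimated 72,873,363 sessions nationally.  Multiplying by a central
per-session net saving (median by default) yields the annual national total
in metric tons CO2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

#: CMS-reimbursed telemedicine sessions, March 2020 - February 2021.
DEFAULT_CMS_SESSIONS = 27_691_878
#: CMS share of US National Health Expenditures (2021).
DEFAULT_CMS_SHARE = 0.38
#: Sessions on the studied platform meeting inclusion criteria.
DEFAULT_PLATFORM_SESSIONS = 6_231_614


@dataclass(frozen=True)
class ExtrapolationInputs:
    cms_sessions: int = DEFAULT_CMS_SESSIONS
    cms_share: float = DEFAULT_CMS_SHARE
    platform_sessions: int = DEFAULT_PLATFORM_SESSIONS

    def __post_init__(self) -> None:
        if not (0.0 < self.cms_share <= 1.0):
            raise DomainError(f"cms_share {self.cms_share} outside (0, 1]")
        if self.cms_sessions <= 0 or self.platform_sessions <= 0:
            raise DomainError("session counts must be positive")


@dataclass(frozen=True)
class NationalEstimate:
    total_sessions: int
    per_session_net_g: float
    total_savings_metric_tons_raw: float
    total_savings_metric_tons_rounded: float
    central_estimate_kind: str


def estimate_total_sessions(
    cms_sessions: int = DEFAULT_CMS_SESSIONS, cms_share: float = DEFAULT_CMS_SHARE
) -> int:
    """National session count implied by the CMS payer share, nearest integer."""
    if not (0.0 < cms_share <= 1.0):
        raise DomainError(f"cms_share {cms_share} outside (0, 1]")
    if cms_sessions <= 0:
        raise DomainError("cms_sessions must be positive")
    return round(cms_sessions / cms_share)


def total_savings_tons(per_session_net_g: float, n_sessions: int) -> float:
    """Aggregate net savings in metric tons CO2 (grams x sessions / 1e6)."""
    if per_session_net_g < 0 or n_sessions < 0:
        raise DomainError("inputs must be non-negative")
    return per_session_net_g * n_sessions / 1e6


def round_tons(tons: float, nearest: int = 100) -> float:
    """Round an aggregate total to the reporting granularity (default 100 t)."""
    return round(tons / nearest) * nearest


def national_estimate(
    per_session_net_g: float,
    inputs: ExtrapolationInputs = ExtrapolationInputs(),
    central_estimate_kind: str = "median",
    headline_rounding: int = 100,
) -> NationalEstimate:
    """Scale a central per-session net saving to the national annual total."""
    total = estimate_total_sessions(inputs.cms_sessions, inputs.cms_share)
    raw = total_savings_tons(per_session_net_g, total)
    return NationalEstimate(
        total_sessions=total,
        per_session_net_g=per_session_net_g,
        total_savings_metric_tons_raw=raw,
        total_savings_metric_tons_rounded=round_tons(raw, headline_rounding),
        central_estimate_kind=central_estimate_kind,
    )
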