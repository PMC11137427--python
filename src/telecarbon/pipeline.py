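"""End-to-end orchestration: generate/ingest -> filter -> stratified sample
-> route -> emissions -> extrapolate -> report.

A single :class:`PipelineConfig` drives the whole run.  The master seed
spawns independent child seeds for generation and sampling, so two runs
with identical config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emissions import EmissionFactors, add_emissions_columns
from .errors import ConfigurationError
from .extrapolation import ExtrapolationInputs, national_estimate, total_savings_tons
from .ingest import (
    DEFAULT_DATE_WINDOW,
    DEFAULT_MAX_GEODESIC_MILES,
    apply_filters,
    read_sessions,
)
from .records import write_sessions_csv
from .report import distance_summary_tables, per_session_summary_table
from .sampling import allocate_proportional, assign_strata, draw_sample, stratum_census
from .synthetic import GeneratorConfig, SyntheticRouter, generate_sessions
from .travel import add_travel_columns

#: Sampling fraction of the reference study (79,904 of 6,231,614 eligible
#: sessions); used when no explicit sample size is configured.
DEFAULT_SAMPLING_FRACTION = 79_904 / 6_231_614

MODE_ADJUSTMENT_CHOICES = ("off", "per-session", "aggregate")
CENTRAL_CHOICES = ("median", "mean")


@dataclass
class RouterConfig:
    detour_factor_mean: float = 1.3
    detour_factor_sd: float = 0.1
    speed_mph: float = 40.0


@dataclass
class PipelineConfig:
    """Validated configuration of one full pipeline run."""

    generator: GeneratorConfig | None = None
    input_csv: str | None = None
    date_window: tuple[str, str] = ("2022-01-01", "2023-02-21")
    max_geodesic_miles: float = DEFAULT_MAX_GEODESIC_MILES
    sample_size: int | None = None
    seed: int = 0
    router: RouterConfig = field(default_factory=RouterConfig)
    factors: EmissionFactors = field(default_factory=EmissionFactors)
    extrapolation: ExtrapolationInputs = field(default_factory=ExtrapolationInputs)
    mode_adjustment: str = "off"
    central: str = "median"
    out_dir: str = "telecarbon_out"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_csv is None):
            raise ConfigurationError(
                "exactly one of 'generator' and 'input_csv' must be set"
            )
        if self.mode_adjustment not in MODE_ADJUSTMENT_CHOICES:
            raise ConfigurationError(
                f"mode_adjustment must be one of {MODE_ADJUSTMENT_CHOICES}"
            )
        if self.central not in CENTRAL_CHOICES:
            raise ConfigurationError(f"central must be one of {CENTRAL_CHOICES}")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ConfigurationError("sample_size must be positive when given")

    # -- construction from plain dicts / files --------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)

        def build(klass, key):
            if key not in data:
                return None
            sub = data.pop(key)
            if sub is None:
                return None
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigurationError(f"unknown {key} key(s): {sorted(unknown)}")
            if key == "generator" and "distance_params" in sub:
                sub["distance_params"] = {
                    k: tuple(v) for k, v in sub["distance_params"].items()
                }
            return klass(**sub)

        parts = {
            "generator": build(GeneratorConfig, "generator"),
            "router": build(RouterConfig, "router") or RouterConfig(),
            "factors": build(EmissionFactors, "factors") or EmissionFactors(),
            "extrapolation": build(ExtrapolationInputs, "extrapolation")
            or ExtrapolationInputs(),
        }
        if "date_window" in data:
            data["date_window"] = tuple(data["date_window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**{**data, **parts})

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def fingerprint(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir")
        canonical = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _central(values: pd.Series, kind: str) -> float:
    return float(values.median() if kind == "median" else values.mean())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; write all artifacts; return the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_gen, seed_sample = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(int(config.seed)).spawn(2)
    )

    # stage 1: obtain sessions
    malformed: dict[str, int] = {}
    if config.generator is not None:
        gen_config = dataclasses.replace(config.generator, seed=seed_gen)
        sessions = generate_sessions(gen_config)
        write_sessions_csv(sessions, out_dir / "sessions.csv")
    else:
        result = read_sessions(config.input_csv)
        sessions = result.frame
        malformed = result.malformed
    n_input = len(sessions) + sum(malformed.values())

    # stage 2: eligibility filter
    window = tuple(pd.Timestamp(t, tz="UTC") for t in config.date_window)
    retained, filter_report = apply_filters(
        sessions, date_window=window, max_geodesic_miles=config.max_geodesic_miles
    )
    filter_report.to_json(out_dir / "filter_report.json")

    # stage 3: stratify and sample
    stratified = assign_strata(retained)
    census = stratum_census(stratified)
    sample_size = config.sample_size
    if sample_size is None:
        sample_size = max(1, round(len(retained) * DEFAULT_SAMPLING_FRACTION))
    allocation = allocate_proportional(census, sample_size)
    alloc_rows = [
        {
            "region": k.region,
            "duration_class": k.duration_class,
            "day_class": k.day_class,
            "hour_class": k.hour_class,
            "population": census[k],
            "sample": allocation.counts[k],
        }
        for k in sorted(allocation.counts, key=lambda k: k.sort_index)
    ]
    pd.DataFrame(alloc_rows).to_csv(out_dir / "allocation.csv", index=False)
    sample = draw_sample(stratified, allocation, seed=seed_sample)

    # stage 4: travel
    router = SyntheticRouter(
        detour_factor_mean=config.router.detour_factor_mean,
        detour_factor_sd=config.router.detour_factor_sd,
        speed_mph=config.router.speed_mph,
        seed=seed_gen,
    )
    sample = add_travel_columns(sample, router, car_share=config.factors.car_share)

    # stage 5: emissions
    sample = add_emissions_columns(
        sample, config.factors, apply_mode_adjustment=config.mode_adjustment == "per-session"
    )
    results = sample.copy()
    results["start_utc"] = results["start_utc"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    results.to_csv(out_dir / "sample_results.csv", index=False)

    # stage 6: descriptive tables
    for dim, table in distance_summary_tables(sample).items():
        table.to_csv(out_dir / f"distance_by_{dim}.csv", index=False)
    per_session_summary_table(sample).to_csv(out_dir / "per_session_summary.csv", index=False)

    # stage 7: extrapolation
    if config.mode_adjustment == "aggregate":
        central_net = (
            _central(sample["savings_g"], config.central) * config.factors.car_share
            - _central(sample["expenditure_g"], config.central)
        )
    else:
        central_net = _central(sample["net_g"], config.central)
    estimate = national_estimate(
        central_net, config.extrapolation, central_estimate_kind=config.central
    )
    platform_tons = total_savings_tons(
        max(central_net, 0.0), config.extrapolation.platform_sessions
    )
    national = {
        "total_sessions": estimate.total_sessions,
        "per_session_net_g": estimate.per_session_net_g,
        "total_savings_metric_tons_raw": estimate.total_savings_metric_tons_raw,
        "total_savings_metric_tons_rounded": estimate.total_savings_metric_tons_rounded,
        "platform_savings_metric_tons": platform_tons,
        "central_estimate_kind": estimate.central_estimate_kind,
        "mode_adjustment": config.mode_adjustment,
    }
    (out_dir / "national_estimate.json").write_text(
        json.dumps(national, indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        "config_sha256": config.fingerprint(),
        "seed": config.seed,
        "n_input": n_input,
        "n_malformed": sum(malformed.values()),
        "n_retained": filter_report.n_retained,
        "exclusions": filter_report.exclusions,
        "sample_size": allocation.total,
        "n_sampled": len(sample),
        "national_estimate": national,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out_dir / "config_echo.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
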