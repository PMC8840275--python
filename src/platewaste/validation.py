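"""Forecast-quality metrics and synthetic plate-waste observations.

Forecasts are compared with per-school weekly plate-waste observations
grouped by lunch duration, using RMSE and MAPE.  Because field measurements
of this kind are rarely public, a synthetic-observation generator produces
format-identical records by running the simulator itself and perturbing the
means with multiplicative noise; it supports self-consistency checks of the
whole validation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulator import SimulationConfig, run_simulation

__all__ = [
    "ObservationRecord",
    "ForecastRecord",
    "ValidationReport",
    "rmse",
    "mape",
    "synthesize_observations",
    "validate",
    "observations_to_csv",
    "observations_from_csv",
]


@dataclass(frozen=True)
class ObservationRecord:
    """One school's observed weekly plate waste at one lunch duration."""

    school: str
    lunch_duration: float
    observed_weekly_waste: float
    unit: str = "fraction"  # or "g_week"
    n_children: int | None = None

    def __post_init__(self) -> None:
        if self.observed_weekly_waste < 0:
            raise ValueError("observed waste must be >= 0")
        if self.unit not in ("fraction", "g_week"):
            raise ValueError(f"unknown unit {self.unit!r}")


@dataclass(frozen=True)
class ForecastRecord:
    """Forecasted weekly plate waste for one lunch duration."""

    lunch_duration: float
    forecast_weekly_waste: float
    unit: str = "fraction"

    def __post_init__(self) -> None:
        if self.forecast_weekly_waste < 0:
            raise ValueError("forecast waste must be >= 0")


def rmse(forecasts, observations) -> float:
    """Root mean square error between paired forecasts and observations."""
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.shape != o.shape:
        raise ValueError(f"forecasts and observations differ in length: {f.shape} vs {o.shape}")
    if f.size == 0:
        raise ValueError("at least one forecast/observation pair is required")
    return float(np.sqrt(np.mean((f - o) ** 2)))


def mape(forecasts, observations) -> float:
    """Mean absolute percentage error (%), |forecast - observed| / observed."""
    f = np.asarray(forecasts, dtype=float)
    o = np.asarray(observations, dtype=float)
    if f.shape != o.shape:
        raise ValueError(f"forecasts and observations differ in length: {f.shape} vs {o.shape}")
    if f.size == 0:
        raise ValueError("at least one forecast/observation pair is required")
    if np.any(o <= 0):
        raise ValueError("MAPE requires strictly positive observations")
    return float(100.0 * np.mean(np.abs(f - o) / o))


def _forecast_value(result, unit: str) -> float:
    return result.mean_waste_fraction if unit == "fraction" else result.mean_weekly_waste_g


def synthesize_observations(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    durations=(15.0, 20.0, 25.0, 30.0),
    n_schools: int = 1,
    noise_sd: float = 0.0,
    unit: str = "fraction",
) -> list[ObservationRecord]:
    """Generate per-school weekly observations from the simulator itself.

    For each duration the simulator is run once at the walking-adjusted
    time; each school's record perturbs that mean with multiplicative
    normal noise of relative sd ``noise_sd`` (zero noise yields the
    simulator means exactly, so downstream errors reflect Monte Carlo
    variation only).
    """
    records = []
    for i, duration in enumerate(durations):
        run_cfg = replace(cfg, lunch_duration=float(duration),
                          seed=_derived_seed(cfg.seed, 7001, i))
        value = _forecast_value(run_simulation(run_cfg), unit)
        for s in range(n_schools):
            noisy = value * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd > 0 else value
            records.append(ObservationRecord(
                school=f"school_{s + 1}",
                lunch_duration=float(duration),
                observed_weekly_waste=max(0.0, float(noisy)),
                unit=unit,
            ))
    return records


def _derived_seed(base: int, salt: int, index: int) -> int:
    return int(np.random.SeedSequence([base, salt, index]).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ValidationReport:
    """RMSE/MAPE of simulator forecasts against grouped observations."""

    rmse: float
    mape: float
    n: int
    unit: str
    residuals: pd.DataFrame  # school, duration, observed, forecast, residual

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mape": self.mape,
            "n": self.n,
            "unit": self.unit,
            "residuals": self.residuals.to_dict(orient="records"),
        }


def validate(
    cfg: SimulationConfig, observations: list[ObservationRecord]
) -> ValidationReport:
    """Forecast at each observed lunch duration and score the pairing.

    One forecast per distinct duration (fresh random streams, independent
    of any synthetic-observation run) is paired with every observation at
    that duration.  Duplicate (school, duration) records are a pairing
    error; nothing is silently dropped.
    """
    if not observations:
        raise ValueError("at least one observation is required")
    units = {o.unit for o in observations}
    if len(units) > 1:
        raise ValueError(f"observations mix units: {sorted(units)}")
    unit = units.pop()
    keys = [(o.school, o.lunch_duration) for o in observations]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (school, duration) observation pairs: {dupes}")

    forecasts: dict[float, float] = {}
    for i, duration in enumerate(sorted({o.lunch_duration for o in observations})):
        run_cfg = replace(cfg, lunch_duration=duration,
                          seed=_derived_seed(cfg.seed, 7919, i))
        forecasts[duration] = _forecast_value(run_simulation(run_cfg), unit)

    rows = [
        {
            "school": o.school,
            "duration_min": o.lunch_duration,
            "observed": o.observed_weekly_waste,
            "forecast": forecasts[o.lunch_duration],
            "residual": forecasts[o.lunch_duration] - o.observed_weekly_waste,
        }
        for o in observations
    ]
    residuals = pd.DataFrame(rows)
    return ValidationReport(
        rmse=rmse(residuals["forecast"], residuals["observed"]),
        mape=mape(residuals["forecast"], residuals["observed"]),
        n=len(rows),
        unit=unit,
        residuals=residuals,
    )


def observations_to_csv(records: list[ObservationRecord], path) -> None:
    pd.DataFrame([
        {
            "school": r.school,
            "duration_min": r.lunch_duration,
            "observed_weekly_waste": r.observed_weekly_waste,
            "unit": r.unit,
            "n_children": r.n_children,
        }
        for r in records
    ]).to_csv(path, index=False)


def observations_from_csv(path) -> list[ObservationRecord]:
    df = pd.read_csv(path)
    return [
        ObservationRecord(
            school=str(row["school"]),
            lunch_duration=float(row["duration_min"]),
            observed_weekly_waste=float(row["observed_weekly_waste"]),
            unit=str(row["unit"]),
            n_children=(int(row["n_children"]) if pd.notna(row.get("n_children")) else None),
        )
        for _, row in df.iterrows()
    ]
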