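"""Alkali-trap titration to CO2-C conversion and cumulative mineralization.

During a 30-day incubation, CO2 evolved from a soil jar is trapped in NaOH;
at each sampling day the residual NaOH is back-titrated to pH 7 with HCl
after precipitating carbonate as BaCO3. Because trapping consumes 2 mol NaOH
per mol CO2 (and HCl titrates residual NaOH 1:1), the CO2-C caught between
openings is

    CO2-C (mg per kg soil) = (V_blank - V_sample) * M_HCl * 12.01 / 2 / m_soil

with volumes in mL, molarity in mol/L and soil mass in kg. Blank jars (no
soil) trap background CO2 and define V_blank per sampling day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sampling schedule (days after the start of incubation).
SAMPLING_DAYS = (1, 3, 5, 7, 10, 15, 20, 25, 30)

#: Molar mass of carbon, g/mol.
CARBON_MOLAR_MASS = 12.01


@dataclass
class TitrationTable:
    """Per-jar, per-day HCl titration volumes plus trap constants.

    ``records`` columns: jar, day, hcl_mL, is_blank. Sample jars map 1:1 to
    soil samples via ``jar_metadata`` (jar -> treatment) when available.
    """

    records: pd.DataFrame
    hcl_molarity: float = 0.4
    naoh_molarity: float = 0.5
    naoh_volume_mL: float = 20.0
    soil_mass_kg: float = 0.030
    jar_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        req = {"jar", "day", "hcl_mL", "is_blank"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"titration records missing columns: {sorted(missing)}")
        if (self.records["hcl_mL"] < 0).any():
            raise ValueError("negative titration volume")
        bad = set(self.records["day"]) - set(SAMPLING_DAYS)
        if bad:
            raise ValueError(f"days outside the sampling schedule: {sorted(bad)}")
        for day in sorted(set(self.records["day"])):
            sub = self.records[self.records["day"] == day]
            if not sub["is_blank"].any():
                raise ValueError(f"no blank jar for day {day}")

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "TitrationTable":
        rec = pd.read_csv(path, sep="\t")
        rec["is_blank"] = rec["is_blank"].astype(bool)
        return cls(records=rec, **kwargs)


@dataclass
class MineralizationSeries:
    """Interval CO2-C, daily rates and running cumulative sum per jar."""

    per_jar: pd.DataFrame  # jar, day, interval_mg_kg, daily_rate, cum
    clipped_intervals: int = 0
    jar_metadata: pd.DataFrame | None = None

    def cum_final(self) -> pd.Series:
        """Cumulative mineralization (mg CO2-C per kg soil) at day 30 per jar."""
        last = self.per_jar.sort_values("day").groupby("jar").tail(1)
        return last.set_index("jar")["cum"]

    def treatment_summary(self) -> pd.DataFrame:
        """Mean +- standard error of final Cum across jars per treatment."""
        if self.jar_metadata is None:
            raise ValueError("no jar metadata attached")
        cum = self.cum_final().rename("cum").reset_index()
        merged = cum.merge(self.jar_metadata, on="jar")
        g = merged.groupby("treatment")["cum"]
        return pd.DataFrame(
            {"mean": g.mean(), "se": g.sem(ddof=1), "n": g.size()}
        )


def titration_to_co2(
    blank_mL: float,
    sample_mL: float,
    hcl_molarity: float = 0.4,
    soil_mass_kg: float = 0.030,
    carbon_molar_mass: float = CARBON_MOLAR_MASS,
    clip_tolerance_mL: float = 0.5,
) -> float:
    """Convert a blank/sample titration volume pair to mg CO2-C per kg soil.

    A sample volume exceeding the blank (apparent negative CO2) within
    ``clip_tolerance_mL`` is clipped to 0; beyond it a warning is emitted and
    the value is still clipped to 0.
    """
    if blank_mL < 0 or sample_mL < 0:
        raise ValueError("titration volumes must be >= 0")
    if hcl_molarity <= 0 or soil_mass_kg <= 0:
        raise ValueError("molarity and soil mass must be positive")
    delta = blank_mL - sample_mL
    if delta < 0:
        if -delta > clip_tolerance_mL:
            warnings.warn(
                f"sample volume exceeds blank by {-delta:.3f} mL; clipping CO2 to 0",
                stacklevel=2,
            )
        return 0.0
    return delta * hcl_molarity * carbon_molar_mass / 2.0 / soil_mass_kg


def cumulative_mineralization(table: TitrationTable) -> MineralizationSeries:
    """Blank-corrected interval CO2-C, daily rates and cumulative sum per jar.

    Per jar and sampling day, the interval CO2-C is computed against the
    day's blank-mean volume; the daily rate divides by the days elapsed since
    the previous sampling (day 0 origin); Cum is the running sum through day
    30. Negative blank-corrected intervals are clipped to 0 with a count.
    """
    rec = table.records
    blanks = rec[rec["is_blank"]].groupby("day")["hcl_mL"].mean()
    jars = sorted(rec.loc[~rec["is_blank"], "jar"].unique())
    days = sorted(set(rec["day"]))

    rows = []
    clipped = 0
    for jar in jars:
        sub = rec[(rec["jar"] == jar) & (~rec["is_blank"])].set_index("day")["hcl_mL"]
        cum = 0.0
        prev_day = 0
        for day in days:
            if day not in sub.index:
                raise ValueError(f"jar {jar} has no titration record for day {day}")
            blank_mean = blanks[day]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = titration_to_co2(
                    blank_mean,
                    float(sub[day]),
                    hcl_molarity=table.hcl_molarity,
                    soil_mass_kg=table.soil_mass_kg,
                )
            if float(sub[day]) > blank_mean:
                clipped += 1
            cum += val
            rows.append(
                {
                    "jar": jar,
                    "day": day,
                    "interval_mg_kg": val,
                    "daily_rate": val / (day - prev_day),
                    "cum": cum,
                }
            )
            prev_day = day
    if clipped:
        warnings.warn(f"{clipped} negative blank-corrected interval(s) clipped to 0", stacklevel=2)
    return MineralizationSeries(
        per_jar=pd.DataFrame(rows),
        clipped_intervals=clipped,
        jar_metadata=table.jar_metadata,
    )
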