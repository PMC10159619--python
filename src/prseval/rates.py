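"""Age-band population incidence and all-cause mortality rate tables.

These play the role of national registry statistics: cancer incidence
``lambda_m(a)`` and all-cause mortality ``m(a)`` per person-year, on
contiguous half-open age bands [a_i, a_{i+1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RateTable", "read_rate_csv"]


@dataclass
class RateTable:
    age_low: np.ndarray
    age_high: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray

    def __post_init__(self) -> None:
        self.age_low = np.asarray(self.age_low, dtype=float)
        self.age_high = np.asarray(self.age_high, dtype=float)
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        if not (
            len(self.age_low) == len(self.age_high)
            == len(self.incidence) == len(self.mortality)
        ):
            raise ValueError("rate table columns have unequal lengths")
        if np.any(self.age_high <= self.age_low):
            raise ValueError("age bands must have positive width")
        if np.any(self.age_low[1:] != self.age_high[:-1]):
            raise ValueError("age bands must be contiguous and non-overlapping")
        if np.any(self.incidence < 0) or np.any(self.mortality < 0):
            raise ValueError("rates must be non-negative")

    @property
    def min_age(self) -> float:
        return float(self.age_low[0])

    @property
    def max_age(self) -> float:
        return float(self.age_high[-1])

    def expand_years(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand to 1-year steps (band value repeated across its years).

        Returns (ages, incidence, mortality) with one entry per integer
        year of age from min_age to max_age - 1.
        """
        ages, inc, mort = [], [], []
        for lo, hi, i, m in zip(
            self.age_low, self.age_high, self.incidence, self.mortality
        ):
            for a in range(int(lo), int(hi)):
                ages.append(a)
                inc.append(i)
                mort.append(m)
        return np.array(ages, dtype=float), np.array(inc), np.array(mort)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_low": self.age_low,
            "age_high": self.age_high,
            "incidence": self.incidence,
            "mortality": self.mortality,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_rate_csv(path) -> RateTable:
    df = pd.read_csv(path)
    return RateTable(
        age_low=df["age_low"].to_numpy(),
        age_high=df["age_high"].to_numpy(),
        incidence=df["incidence"].to_numpy(),
        mortality=df["mortality"].to_numpy(),
    )
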