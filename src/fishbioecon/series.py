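"""Annual catch–effort observations for a single stock."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CatchEffortSeries"]


@dataclass(frozen=True)
class CatchEffortSeries:
    """One species' annual catch (tonnes) and effort (boats) time series.

    CPUE (tonnes/boat) is derived as catch/effort wherever effort is
    positive and is NaN elsewhere.  Years must be strictly increasing.
    """

    years: np.ndarray
    catches: np.ndarray
    efforts: np.ndarray
    collapsed: bool = False  # set by the simulator if the stock hit its floor
    species: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "catches", np.asarray(self.catches, dtype=float))
        object.__setattr__(self, "efforts", np.asarray(self.efforts, dtype=float))
        n = len(self.years)
        if len(self.catches) != n or len(self.efforts) != n:
            raise ValueError("years, catches and efforts must have equal length")
        if n and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.catches < 0):
            raise ValueError("catches must be >= 0")
        if np.any(self.efforts < 0):
            raise ValueError("efforts must be >= 0")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def cpue(self) -> np.ndarray:
        """Catch per unit effort (tonnes/boat); NaN where effort is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.efforts > 0, self.catches / self.efforts, np.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "catch_t": self.catches,
                "effort_boats": self.efforts,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str | None = None) -> "CatchEffortSeries":
        return cls(
            years=df["year"].to_numpy(),
            catches=df["catch_t"].to_numpy(),
            efforts=df["effort_boats"].to_numpy(),
            species=species,
        )
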