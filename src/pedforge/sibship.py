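"""Generation-varying sibship-size model.

Sibship sizes (children per parent couple) are drawn from a normal
distribution whose mean and standard deviation can change across
generation ticks.  The packaged default table holds United States census
estimates for five generations (census years 1850, 1880, 1910, 1940 and
1970), so simulated families shrink over time the way the census did.

A continuous normal draw is turned into a child count by rounding to the
nearest integer and clamping below at a configurable minimum (0 by
default, so a couple may remain childless and terminate that branch).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SibshipModel:
    """Per-generation-tick (mean, sd) parameters for sibship-size draws.

    Ticks must be unique and ascending; lookups beyond the last row
    return the last row's parameters, so a short table extends naturally
    to deeper pedigrees.
    """

    ticks: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ticks:
            raise ValueError("sibship model needs at least one row")
        if len(set(self.ticks)) != len(self.ticks):
            raise ValueError("duplicate generation tick in sibship model")
        if list(self.ticks) != sorted(self.ticks):
            raise ValueError("generation ticks must be ascending")
        if any(t < 1 for t in self.ticks):
            raise ValueError("generation ticks must be >= 1")
        if any(m < 0 for m in self.means) or any(s < 0 for s in self.sds):
            raise ValueError("sibship mean and sd must be non-negative")

    def lookup(self, tick: int) -> tuple[float, float]:
        """Parameters for ``tick``; rows extend beyond the table's ends."""
        idx = int(np.searchsorted(self.ticks, tick, side="right")) - 1
        idx = max(idx, 0)
        return self.means[idx], self.sds[idx]

    @classmethod
    def from_rows(cls, rows) -> "SibshipModel":
        ticks, means, sds = zip(*((int(t), float(m), float(s)) for t, m, s in rows))
        return cls(ticks, means, sds)

    @classmethod
    def default(cls) -> "SibshipModel":
        """The packaged US-census table (five generations, 1850-1970)."""
        with resources.files("pedforge.data").joinpath("census_sibship.csv").open() as fh:
            return parse_sibship_table(fh)


def parse_sibship_table(path_or_buffer) -> SibshipModel:
    """Parse a sibship CSV with (order-insensitive) columns generation, mean, sd."""
    df = pd.read_csv(path_or_buffer)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"generation", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"sibship CSV must have columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        raise ValueError("sibship CSV has no rows")
    df = df.sort_values("generation")
    return SibshipModel.from_rows(df[["generation", "mean", "sd"]].itertuples(index=False))


def draw_sibship_size(model: SibshipModel, tick: int, rng: np.random.Generator, min_size: int = 0) -> int:
    """Draw one sibship size for a couple reproducing at ``tick``.

    Round-to-nearest of a normal(mean, sd) draw, clamped below at
    ``min_size``.
    """
    if tick < 1:
        raise ValueError("generation tick must be >= 1")
    mean, sd = model.lookup(tick)
    draw = rng.normal(mean, sd)
    return max(int(np.rint(draw)), min_size)
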