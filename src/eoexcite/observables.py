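"""Shared container for time-dependent ensemble observables."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .units import AUT_FS

__all__ = ["EnsembleObservables"]


@dataclasses.dataclass
class EnsembleObservables:
    """Time series of <R>, <dR> and state population for one ensemble.

    ``valid`` marks the times where the projected norm (or the number of
    contributing trajectories) is nonzero; mean/std entries at invalid times
    are undefined and must not be consumed silently, so they are stored as
    ``nan`` *and* flagged here.
    """

    times: np.ndarray            # au
    r_mean: np.ndarray           # bohr
    r_std: np.ndarray            # bohr
    population: np.ndarray      # fraction in the selected state
    valid: np.ndarray            # bool per time
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_fs": self.times * AUT_FS,
                "r_mean_bohr": self.r_mean,
                "r_std_bohr": self.r_std,
                "population": self.population,
                "valid": self.valid,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def interp(self, times_au) -> "EnsembleObservables":
        """Linear interpolation onto a new time grid (valid region only)."""
        t = np.asarray(times_au, dtype=float)
        tv = self.times[self.valid]
        ok = (t >= tv.min()) & (t <= tv.max())
        out = {}
        for name in ("r_mean", "r_std", "population"):
            y = getattr(self, name)[self.valid]
            arr = np.full(t.shape, np.nan)
            arr[ok] = np.interp(t[ok], tv, y)
            out[name] = arr
        return EnsembleObservables(
            times=t, valid=ok, label=self.label, **out
        )
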