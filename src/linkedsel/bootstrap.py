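"""Block bootstrap over non-overlapping genomic windows.

Windows (100 kb by default elsewhere in the package), not sites, are the
exchangeable unit: resampling whole windows preserves the local structure of
linkage disequilibrium that makes per-site resampling anticonservative. Each
replicate draws ``resample_size`` windows with replacement and recomputes
the statistic end to end; the reported uncertainty is the standard deviation
of the replicate distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BootstrapPlan", "block_bootstrap", "sem"]


@dataclass
class BootstrapPlan:
    """Replicate count, resample size, and seed for a block bootstrap.

    ``resample_size`` defaults to the number of observed windows; for F_ST
    the convention is to resample to the total autosomal window count
    instead, so it is an explicit knob.
    """

    n_replicates: int = 1000
    resample_size: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.resample_size is not None and self.resample_size < 1:
            raise ValueError("resample size must be >= 1")


def block_bootstrap(windows, statistic, plan: BootstrapPlan) -> np.ndarray:
    """Bootstrap a statistic of a window multiset.

    ``windows`` is a DataFrame (one row per window) or array; ``statistic``
    maps a resampled window set to a float. Replicates on which the
    statistic is undefined (raises ``ValueError`` or ``ZeroDivisionError``)
    are recorded as NaN. A single seed streams per-replicate sub-seeds, so
    results are reproducible and replicates are independent.
    """
    n = len(windows)
    if n == 0:
        raise ValueError("no windows to resample")
    size = plan.resample_size or n
    ss = np.random.SeedSequence(plan.seed)
    out = np.empty(plan.n_replicates)
    is_df = isinstance(windows, pd.DataFrame)
    for rep, child in enumerate(ss.spawn(plan.n_replicates)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=size)
        sample = windows.iloc[idx] if is_df else np.asarray(windows)[idx]
        try:
            out[rep] = statistic(sample)
        except (ValueError, ZeroDivisionError):
            out[rep] = np.nan
    return out


def sem(replicates) -> float:
    """Bootstrap standard error: SD (denominator n-1) of replicate values.

    Missing (NaN) replicates are excluded with a warning.
    """
    reps = np.asarray(replicates, dtype=float)
    bad = np.isnan(reps)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} of {len(reps)} bootstrap replicates undefined; excluded",
            stacklevel=2,
        )
        reps = reps[~bad]
    if len(reps) < 2:
        raise ValueError("need at least 2 defined replicates for an SEM")
    return float(np.std(reps, ddof=1))
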