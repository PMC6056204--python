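"""Diversity (pi), singleton density (psi), and divergence normalization.

Statistics are accumulated over non-overlapping 100-kb windows. A window
enters any statistic only if it carries at least 10 kb of outgroup-divergence
information (the same retained-window universe is used whether or not the
divergence normalization itself is applied, so normalized and unnormalized
estimates are comparable). Bin-level values are ratios of aggregates:
summed per-site heterozygosity over summed retained sites, divided by summed
divergence differences over summed informative bases. A per-window-mean
alternative is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import GenomeLayout, IntervalTrack, track_intersect
from .variants import AlleleCountTable

__all__ = [
    "per_site_pi",
    "window_divergence",
    "window_stats",
    "normalized_diversity",
    "relative_diversity",
    "singleton_density",
    "relative_singleton_density",
    "DiversitySummary",
]

WINDOW_SIZE = 100_000
MIN_INFORMATIVE = 10_000


def per_site_pi(x, n):
    """Proportion of chromosome pairs differing at a site: 2x(n-x)/(n(n-1))."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if (n < 2).any():
        raise ValueError("per-site pi requires at least 2 chromosomes")
    if ((x < 0) | (x > n)).any():
        raise ValueError("alt count outside [0, n]")
    return 2.0 * x * (n - x) / (n * (n - 1.0))


def window_divergence(diff_bp, informative_bp, min_informative: int = MIN_INFORMATIVE):
    """Per-window divergence fraction, or None when the window is excluded.

    Windows with fewer than ``min_informative`` aligned bases carry too
    little information and are dropped from every statistic.
    """
    if informative_bp < min_informative:
        return None
    return diff_bp / informative_bp


def _window_coverage_bp(track: IntervalTrack, size: int) -> dict:
    """bp of track coverage per (contig, window_start)."""
    cov: dict[tuple, int] = {}
    for contig in track.contigs():
        s, e, _ = track.per_contig(contig)
        for a, b in zip(s, e):
            w = (a // size) * size
            while w < b:
                hi = min(b, w + size)
                lo = max(a, w)
                cov[(contig, int(w))] = cov.get((contig, int(w)), 0) + int(hi - lo)
                w += size
    return cov


def window_stats(
    table: AlleleCountTable,
    pop: str,
    sites_track: IntervalTrack,
    divergence: pd.DataFrame,
    size: int = WINDOW_SIZE,
    min_informative: int = MIN_INFORMATIVE,
    m: int | None = None,
) -> pd.DataFrame:
    """Per-window sufficient statistics for pi and psi over a site set.

    ``sites_track`` is the retained-site universe (neutral mask intersected
    with a B bin). ``divergence`` has columns ``contig, start, informative_bp,
    diff_bp`` on the same window grid. ``m`` is the projection target for the
    singleton expectation (skipped when None).

    Returns one row per *retained* window: ``retained_bp`` (pi denominator),
    ``pi_sum``, ``psi_sites`` (psi denominator: retained sites with a
    high-confidence ancestral call), ``singleton_exp``, ``informative_bp``,
    ``diff_bp``.
    """
    div = divergence.set_index(["contig", "start"])
    keep_windows = div[div["informative_bp"] >= min_informative]
    cov = _window_coverage_bp(sites_track, size)

    rows = {}
    for (contig, start), r in keep_windows.iterrows():
        bp = cov.get((contig, int(start)), 0)
        rows[(contig, int(start))] = {
            "contig": contig,
            "start": int(start),
            "end": int(start) + size,
            "retained_bp": bp,
            "pi_sum": 0.0,
            "psi_sites": float(bp),
            "singleton_exp": 0.0,
            "informative_bp": float(r["informative_bp"]),
            "diff_bp": float(r["diff_bp"]),
        }

    in_sites = table.in_track(sites_track)
    df = table.df
    n = df[f"{pop}_n"].to_numpy(dtype=float)
    x = df[f"{pop}_x"].to_numpy(dtype=float)
    usable = in_sites & (n >= 2)
    pi_vals = np.zeros(len(df))
    pi_vals[usable] = per_site_pi(x[usable], n[usable])

    if m is not None:
        if "ancestral" not in df:
            raise ValueError("singleton density needs a polarized table")
        d = table.derived_counts(pop)
        high = df["high_conf"].to_numpy()
        s_ok = usable & high & ~np.isnan(d)
        sing = np.zeros(len(df))
        # expected singleton mass after projecting each site to m chromosomes
        pairs = pd.DataFrame({"n": n[s_ok], "d": d[s_ok]})
        if len(pairs):
            uniq = pairs.value_counts().reset_index(name="w")
            for ni, di, _w in uniq.itertuples(index=False):
                if m > ni:
                    raise ValueError(f"projection target {m} exceeds sample size {int(ni)}")
                sel = s_ok & (n == ni) & (d == di)
                sing[sel] = hypergeom.pmf(1, int(ni), int(di), m)
        low_conf_variant = usable & ~(high & ~np.isnan(d))
    else:
        sing = np.zeros(len(df))
        low_conf_variant = np.zeros(len(df), dtype=bool)

    contigs = df["contig"].to_numpy()
    wstarts = (df["pos"].to_numpy() // size) * size
    for i in np.where(usable)[0]:
        key = (contigs[i], int(wstarts[i]))
        row = rows.get(key)
        if row is None:  # window excluded by the divergence rule
            continue
        row["pi_sum"] += pi_vals[i]
        row["singleton_exp"] += sing[i]
        if low_conf_variant[i]:
            row["psi_sites"] -= 1.0

    out = pd.DataFrame(list(rows.values()))
    if len(out) == 0:
        raise ValueError("no windows retained (check divergence information)")
    return out.reset_index(drop=True)


def normalized_diversity(windows: pd.DataFrame, per_window_mean: bool = False) -> float:
    """pi / divergence over a retained-window set.

    Default is the ratio of aggregates (pool sites, pool divergence), which
    is stable for sparse windows; ``per_window_mean=True`` averages
    per-window normalized values instead.
    """
    if per_window_mean:
        w = windows[windows["retained_bp"] > 0]
        vals = (w["pi_sum"] / w["retained_bp"]) / (w["diff_bp"] / w["informative_bp"])
        return float(vals.mean())
    sites = windows["retained_bp"].sum()
    if sites == 0:
        raise ValueError("zero retained sites")
    info = windows["informative_bp"].sum()
    diff = windows["diff_bp"].sum()
    if diff == 0:
        raise ValueError("zero aggregate divergence")
    return float((windows["pi_sum"].sum() / sites) / (diff / info))


def relative_diversity(low_bin: pd.DataFrame, high_bin: pd.DataFrame, **kw) -> float:
    """pi/pi_min: normalized diversity in the strong-BGS bin over the weak-BGS bin."""
    return normalized_diversity(low_bin, **kw) / normalized_diversity(high_bin, **kw)


def singleton_density(windows: pd.DataFrame) -> float:
    """Normalized psi: expected singletons per polarizable site / divergence."""
    sites = windows["psi_sites"].sum()
    if sites <= 0:
        raise ValueError("zero retained polarizable sites")
    info = windows["informative_bp"].sum()
    diff = windows["diff_bp"].sum()
    if diff == 0:
        raise ValueError("zero aggregate divergence")
    return float((windows["singleton_exp"].sum() / sites) / (diff / info))


def relative_singleton_density(low_bin: pd.DataFrame, high_bin: pd.DataFrame) -> float:
    """psi/psi_min across the extreme B bins."""
    return singleton_density(low_bin) / singleton_density(high_bin)


@dataclass
class DiversitySummary:
    """One bin-level result row: normalized and relative statistics with SEMs."""

    population: str
    bin_label: str
    normalized_pi: float
    normalized_psi: float | None = None
    relative_pi: float | None = None
    relative_psi: float | None = None
    sem_relative_pi: float | None = None
    sem_relative_psi: float | None = None


def bin_windows(
    table: AlleleCountTable,
    pop: str,
    neutral_mask: IntervalTrack,
    bin_track: IntervalTrack,
    divergence: pd.DataFrame,
    **kw,
) -> pd.DataFrame:
    """Window stats for the site universe (neutral mask intersect B bin)."""
    sites = track_intersect([neutral_mask, bin_track])
    return window_stats(table, pop, sites, divergence, **kw)
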