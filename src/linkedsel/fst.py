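"""Hudson F_ST with ratio-of-averages combining, B-bin profiles, and the
F_ST-on-B linear regression.

Per-site numerator and denominator follow the Hudson estimator in the form
recommended by Bhatia et al. (2013):

    N_h = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_h = p1(1-p2) + p2(1-p1)

and multi-SNP estimates are Sum(N_h) / Sum(D_h) — a ratio of averages, never
an average of per-SNP ratios. SNPs may first be ascertained as polymorphic
in an outgroup panel to remove discovery bias. The genome is then divided
into disjoint equal-occupancy bins of the per-base B distribution and the
profile F_ST(B) is summarized by OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intervals import IntervalTrack, quantile_thresholds
from .variants import AlleleCountTable, OutgroupPanel

__all__ = [
    "hudson_components",
    "fst_ratio_of_averages",
    "ascertain_outgroup",
    "fst_profile_by_b",
    "ols_fst_on_b",
    "RegressionResult",
]


def hudson_components(p1, n1, p2, n2):
    """Per-site Hudson F_ST numerator and denominator (vectorized)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if ((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    if ((n1 < 2) | (n2 < 2)).any():
        raise ValueError("need at least 2 chromosomes per population")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_ratio_of_averages(num, den) -> float:
    """Sum of numerators over sum of denominators across SNPs."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    d = den.sum()
    if d == 0:
        raise ValueError("zero aggregate denominator: no informative SNPs")
    return float(num.sum() / d)


def ascertain_outgroup(panel: OutgroupPanel, table: AlleleCountTable) -> np.ndarray:
    """Keep sites polymorphic in the outgroup panel (>=1 ref and >=1 alt call)."""
    return panel.polymorphic_mask(table)


def _bin_edges(bmap: IntervalTrack, n_bins: int):
    vals = bmap.values()
    inner = quantile_thresholds(bmap, np.arange(1, n_bins) / n_bins)
    return np.concatenate([[float(vals.min())], inner, [float(vals.max())]])


def _bin_of(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Disjoint bin index with (lo, hi] convention (first bin closed below)."""
    idx = np.searchsorted(edges[1:-1], values, side="left")
    return np.clip(idx, 0, len(edges) - 2)


def fst_profile_by_b(
    table: AlleleCountTable,
    bmap: IntervalTrack,
    pairs: list[tuple[str, str]],
    n_bins: int = 50,
    ascertained: np.ndarray | None = None,
    window_size: int | None = None,
) -> pd.DataFrame:
    """Per-pair, per-B-bin Hudson F_ST (ratio of averages).

    Sites lacking a B value are dropped; sites monomorphic across both
    populations of a pair contribute nothing. The bin x-value ``b_mid`` is
    the mean of the value bounds defining the bin. When ``window_size`` is
    given the output keeps per-(bin, window) component sums so a block
    bootstrap can recompute the profile from resampled windows.
    """
    df = table.df
    b_at = np.full(len(df), np.nan)
    for contig, sub in df.groupby("contig", sort=False):
        b_at[sub.index.to_numpy()] = bmap.value_at(contig, sub["pos"].to_numpy())
    keep = ~np.isnan(b_at)
    if ascertained is not None:
        keep &= np.asarray(ascertained, dtype=bool)

    edges = _bin_edges(bmap, n_bins)
    bins = np.full(len(df), -1)
    bins[keep] = _bin_of(b_at[keep], edges)
    b_mid = (edges[:-1] + edges[1:]) / 2.0

    rows = []
    for pop1, pop2 in pairs:
        n1 = df[f"{pop1}_n"].to_numpy(dtype=float)
        n2 = df[f"{pop2}_n"].to_numpy(dtype=float)
        x1 = df[f"{pop1}_x"].to_numpy(dtype=float)
        x2 = df[f"{pop2}_x"].to_numpy(dtype=float)
        ok = keep & (n1 >= 2) & (n2 >= 2)
        poly = (x1 + x2 > 0) & (x1 + x2 < n1 + n2)
        ok &= poly
        p1 = np.divide(x1, n1, out=np.zeros_like(x1), where=n1 > 0)
        p2 = np.divide(x2, n2, out=np.zeros_like(x2), where=n2 > 0)
        num = np.zeros(len(df))
        den = np.zeros(len(df))
        num[ok], den[ok] = hudson_components(p1[ok], n1[ok], p2[ok], n2[ok])
        group_cols = [bins]
        names = ["bin"]
        if window_size is not None:
            wkey = df["contig"].astype(str) + ":" + (
                (df["pos"] // window_size) * window_size
            ).astype(str)
            group_cols.append(wkey.to_numpy())
            names.append("window")
        agg = pd.DataFrame(
            {"bin": group_cols[0], "num": np.where(ok, num, 0.0),
             "den": np.where(ok, den, 0.0), "n_snps": ok.astype(int)}
        )
        if window_size is not None:
            agg["window"] = group_cols[1]
        agg = agg[agg["bin"] >= 0]
        g = agg.groupby(names, as_index=False).sum()
        g["pair"] = f"{pop1}-{pop2}"
        g["b_mid"] = b_mid[g["bin"].to_numpy()]
        if window_size is None:
            g["fst"] = g["num"] / g["den"].where(g["den"] != 0, np.nan)
        rows.append(g)
    return pd.concat(rows, ignore_index=True)


@dataclass
class RegressionResult:
    """OLS fit of F_ST on bin-mean B: F_ST = b0 + b1 * B + eps."""

    beta0: float
    beta1: float
    r: float
    se_beta0: float
    se_beta1: float
    p_beta0: float
    p_beta1: float
    n: int

    def summary_row(self) -> dict:
        return {
            "beta0": self.beta0, "beta1": self.beta1, "r": self.r,
            "se_beta0": self.se_beta0, "se_beta1": self.se_beta1,
            "p_beta0": self.p_beta0, "p_beta1": self.p_beta1, "n_bins": self.n,
        }


def ols_fst_on_b(b_values, fst_values) -> RegressionResult:
    """Ordinary least squares of per-bin F_ST on bin-mean B.

    ``r`` is the Pearson correlation; coefficient p-values come from the
    two-sided t-test of the OLS fit.
    """
    b = np.asarray(b_values, dtype=float)
    y = np.asarray(fst_values, dtype=float)
    ok = ~(np.isnan(b) | np.isnan(y))
    b, y = b[ok], y[ok]
    X = sm.add_constant(b)
    fit = sm.OLS(y, X).fit()
    if len(b) > 1 and np.std(b) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(b, y)[0, 1])
    else:
        r = np.nan
    return RegressionResult(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        r=r,
        se_beta0=float(fit.bse[0]),
        se_beta1=float(fit.bse[1]),
        p_beta0=float(fit.pvalues[0]),
        p_beta1=float(fit.pvalues[1]),
        n=len(b),
    )
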