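"""End-to-end analyses: relative diversity, singleton density, and F_ST(B).

These drivers glue the interval, variant, statistic, and bootstrap layers
together the way the headline analyses use them: ascertain the retained
100-kb window universe, split sites into B-quantile bins, form ratio
statistics, and attach block-bootstrap standard errors in which every
replicate recomputes the statistic end to end from resampled windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapPlan, sem
from .fst import RegressionResult, fst_profile_by_b, ols_fst_on_b
from .intervals import IntervalTrack, bin_membership, track_intersect
from .popstats import WINDOW_SIZE, window_stats
from .variants import AlleleCountTable

__all__ = ["DiversityResult", "FstResult", "run_relative_diversity", "run_fst_regression"]


@dataclass
class DiversityResult:
    population: str
    relative_pi: float
    sem_pi: float | None
    relative_psi: float | None
    sem_psi: float | None
    normalized_pi_low: float
    normalized_pi_high: float
    n_windows: int


def _merged_bin_windows(table, pop, mask, low_track, high_track, divergence, m):
    low = window_stats(
        table, pop, track_intersect([mask, low_track]), divergence, m=m
    )
    high = window_stats(
        table, pop, track_intersect([mask, high_track]), divergence, m=m
    )
    key = ["contig", "start"]
    lo = low.set_index(key).add_prefix("low_")
    hi = high.set_index(key).add_prefix("high_")
    df = lo.join(hi, how="outer")
    for pre in ("low_", "high_"):
        for col in ("retained_bp", "pi_sum", "psi_sites", "singleton_exp"):
            df[pre + col] = df[pre + col].fillna(0.0)
        for col in ("informative_bp", "diff_bp"):
            df[pre + col] = df[pre + col].fillna(
                df[("high_" if pre == "low_" else "low_") + col]
            )
    return df.reset_index()


def _ratio_stat(df, num_col, den_col):
    def one(sub, pre):
        w = sub[sub[pre + den_col] > 0]
        if len(w) == 0 or w[pre + den_col].sum() == 0:
            raise ValueError("empty bin in replicate")
        val = w[pre + num_col].sum() / w[pre + den_col].sum()
        div = w[pre + "diff_bp"].sum() / w[pre + "informative_bp"].sum()
        if div == 0:
            raise ValueError("zero divergence in replicate")
        return val / div
    return one(df, "low_") / one(df, "high_")


def run_relative_diversity(
    table: AlleleCountTable,
    pop: str,
    bmap: IntervalTrack,
    neutral_mask: IntervalTrack,
    divergence: pd.DataFrame,
    low_quantile: float = 0.01,
    top_quantile: float = 0.01,
    m: int | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DiversityResult:
    """pi/pi_min (and psi/psi_min when ``m`` is given) with bootstrap SEMs."""
    bins = bin_membership(bmap, (low_quantile,), top_quantile)
    low_label = [k for k in bins if k.startswith("lowest_")][0]
    high_label = [k for k in bins if k.startswith("highest_")][0]
    df = _merged_bin_windows(
        table, pop, neutral_mask, bins[low_label], bins[high_label], divergence, m
    )
    rel_pi = _ratio_stat(df, "pi_sum", "retained_bp")
    rel_psi = _ratio_stat(df, "singleton_exp", "psi_sites") if m is not None else None

    sem_pi = sem_psi = None
    if n_boot:
        plan = BootstrapPlan(n_replicates=n_boot, seed=seed)
        reps_pi = _bootstrap_windows(df, lambda d: _ratio_stat(d, "pi_sum", "retained_bp"), plan)
        sem_pi = sem(reps_pi)
        if m is not None:
            reps_psi = _bootstrap_windows(
                df, lambda d: _ratio_stat(d, "singleton_exp", "psi_sites"), plan
            )
            sem_psi = sem(reps_psi)

    lw = df[df["low_retained_bp"] > 0]
    hw = df[df["high_retained_bp"] > 0]
    return DiversityResult(
        population=pop,
        relative_pi=rel_pi,
        sem_pi=sem_pi,
        relative_psi=rel_psi,
        sem_psi=sem_psi,
        normalized_pi_low=(lw["low_pi_sum"].sum() / lw["low_retained_bp"].sum())
        / (lw["low_diff_bp"].sum() / lw["low_informative_bp"].sum()),
        normalized_pi_high=(hw["high_pi_sum"].sum() / hw["high_retained_bp"].sum())
        / (hw["high_diff_bp"].sum() / hw["high_informative_bp"].sum()),
        n_windows=len(df),
    )


def _bootstrap_windows(df, statistic, plan):
    n = len(df)
    ss = np.random.SeedSequence(plan.seed)
    size = plan.resample_size or n
    out = np.empty(plan.n_replicates)
    values = {c: df[c].to_numpy() for c in df.columns if c not in ("contig", "start")}
    for rep, child in enumerate(ss.spawn(plan.n_replicates)):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=size)
        sub = pd.DataFrame({c: v[idx] for c, v in values.items()})
        try:
            out[rep] = statistic(sub)
        except (ValueError, ZeroDivisionError):
            out[rep] = np.nan
    return out


@dataclass
class FstResult:
    profile: pd.DataFrame  # pair, bin, b_mid, fst, sem
    regression: RegressionResult
    sem_beta0: float | None
    sem_beta1: float | None
    sem_r: float | None


def run_fst_regression(
    table: AlleleCountTable,
    bmap: IntervalTrack,
    pairs: list[tuple[str, str]],
    ascertained: np.ndarray | None = None,
    n_bins: int = 50,
    window_size: int = WINDOW_SIZE,
    n_boot: int = 1000,
    resample_size: int | None = None,
    seed: int | None = None,
) -> FstResult:
    """F_ST(B) profile over disjoint quantile bins plus the OLS summary.

    The block bootstrap resamples 100-kb windows (``resample_size`` defaults
    to the observed window count; pass the total autosomal window count to
    follow the genome-wide convention) and re-runs the per-bin ratio of
    averages and the regression in every replicate.
    """
    comp = fst_profile_by_b(
        table, bmap, pairs, n_bins=n_bins, ascertained=ascertained,
        window_size=window_size,
    )
    # point estimates
    point = comp.groupby(["pair", "bin", "b_mid"], as_index=False)[
        ["num", "den", "n_snps"]
    ].sum()
    point["fst"] = point["num"] / point["den"].where(point["den"] != 0, np.nan)
    reg = ols_fst_on_b(point["b_mid"], point["fst"])

    sem_b0 = sem_b1 = sem_r = None
    prof = point.copy()
    prof["sem"] = np.nan
    if n_boot:
        windows = sorted(comp["window"].unique())
        widx = {w: i for i, w in enumerate(windows)}
        pairs_u = sorted(comp["pair"].unique())
        pidx = {p: i for i, p in enumerate(pairs_u)}
        n_w, n_p = len(windows), len(pairs_u)
        num = np.zeros((n_w, n_p, n_bins))
        den = np.zeros((n_w, n_p, n_bins))
        wi = comp["window"].map(widx).to_numpy()
        pi_ = comp["pair"].map(pidx).to_numpy()
        bi = comp["bin"].to_numpy()
        np.add.at(num, (wi, pi_, bi), comp["num"].to_numpy())
        np.add.at(den, (wi, pi_, bi), comp["den"].to_numpy())
        b_mid_by_bin = (
            point.drop_duplicates("bin").set_index("bin")["b_mid"]
            .reindex(range(n_bins))
            .to_numpy()
        )
        size = resample_size or n_w
        ss = np.random.SeedSequence(seed)
        b0s = np.empty(n_boot)
        b1s = np.empty(n_boot)
        rs = np.empty(n_boot)
        fst_reps = np.full((n_boot, n_p, n_bins), np.nan)
        for rep, child in enumerate(ss.spawn(n_boot)):
            rng = np.random.default_rng(child)
            idx = rng.integers(0, n_w, size=size)
            nsum = num[idx].sum(axis=0)
            dsum = den[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(dsum != 0, nsum / dsum, np.nan)
            fst_reps[rep] = f
            xs = np.tile(b_mid_by_bin, n_p)
            ys = f.ravel()
            ok = ~(np.isnan(xs) | np.isnan(ys))
            if ok.sum() < 3:
                b0s[rep] = b1s[rep] = rs[rep] = np.nan
                continue
            r = ols_fst_on_b(xs[ok], ys[ok])
            b0s[rep], b1s[rep], rs[rep] = r.beta0, r.beta1, r.r
        sem_b0, sem_b1, sem_r = sem(b0s), sem(b1s), sem(rs)
        fst_sem = np.nanstd(fst_reps, axis=0, ddof=1)
        prof["sem"] = [
            fst_sem[pidx[p], b] for p, b in zip(prof["pair"], prof["bin"])
        ]
    return FstResult(
        profile=prof[["pair", "bin", "b_mid", "fst", "sem", "n_snps"]],
        regression=reg,
        sem_beta0=sem_b0,
        sem_beta1=sem_b1,
        sem_r=sem_r,
    )
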