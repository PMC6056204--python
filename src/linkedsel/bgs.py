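"""Forward Wright-Fisher simulation of background selection (BGS).

The simulated region is a neutral core (30 kb by default) flanked on both
sides by 1-Mb blocks in which a fraction ``f_del`` of sites receives
deleterious mutations. Selection coefficients come from a two-component
gamma mixture (conserved non-coding and coding distributions of fitness
effects); fitness is multiplicative across sites with heterozygote factor
``1 + h s`` and homozygote factor ``1 + s``. Neutral mutations are tracked
only in the core: flank non-deleterious positions cannot affect core
diversity and would dominate memory. Each generation performs
fitness-weighted multinomial reproduction, Poisson crossovers at a uniform
per-bp rate, Poisson mutation (infinite sites), binomial migrant exchange,
and any scheduled demographic event; samples of ``sample_size`` chromosomes
are scored for pairwise diversity (pi) and singleton density (psi) in the
core at regular intervals and at every demographic event.

Desk-scale runs use the standard rescaling by ``Q``: population sizes and
epoch durations divide by ``Q`` while mu, r, s and migration rates multiply
by ``Q``, leaving theta, rho, 2Ns and 4Nm invariant. Selection coefficients
whose rescaled magnitude exceeds 1 are clamped to lethal (s = -1).

Haplotypes are sparse mutation-id sets; identical gametes share storage, so
the per-generation cost scales with the number of mutation copies rather
than with sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .demography import ConstantModel, ThreePopModel, default_model, rescale, validate

__all__ = [
    "DFEComponent",
    "DFESpec",
    "default_dfe",
    "SimulationConfig",
    "SiteClassMap",
    "TimeSeriesResult",
    "assign_site_classes",
    "draw_s",
    "run_forward",
    "run_neutral_control",
    "relative_timeseries",
]

_EMPTY = np.empty(0, dtype=np.int32)


@dataclass
class DFEComponent:
    """One gamma component of the deleterious DFE.

    ``alpha`` and ``beta`` are the population-scaled gamma parameters with
    mean ``alpha/beta`` and variance ``alpha/beta**2`` on the 2N-scaled
    selection-coefficient axis; ``two_n_ref`` is the ancestral 2N of the
    source study, which converts scaled draws to raw ``s``. The default
    ``convention="moments"`` reads (alpha, beta) as gamma(shape, rate), per
    the stated moment relations; ``"shape"`` instead uses ``beta`` as the
    gamma shape (the parameterization common in the DFE literature) with
    the same mean.
    """

    weight: float
    alpha: float
    beta: float
    two_n_ref: float
    label: str = ""

    @property
    def mean_s(self) -> float:
        return self.alpha / (self.beta * self.two_n_ref)

    def draw_abs(self, rng: np.random.Generator, size: int, convention: str) -> np.ndarray:
        if convention == "moments":
            return rng.gamma(self.alpha, 1.0 / self.beta, size) / self.two_n_ref
        if convention == "shape":
            return rng.gamma(self.beta, self.mean_s / self.beta, size)
        raise ValueError(f"unknown DFE convention {convention!r}")


@dataclass
class DFESpec:
    """Mixture of deleterious gamma components; draws are negative."""

    components: list[DFEComponent]
    convention: str = "moments"

    def __post_init__(self):
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {w}, not 1")
        for c in self.components:
            if c.alpha <= 0 or c.beta <= 0 or c.two_n_ref <= 0:
                raise ValueError("gamma parameters must be positive")


def default_dfe() -> DFESpec:
    """Conserved non-coding (66.06%) + coding (33.94%) gamma mixture."""
    return DFESpec(
        [
            DFEComponent(
                weight=0.6606, alpha=80.11, beta=0.0415,
                two_n_ref=80.11 / 0.00515625, label="conserved_noncoding",
            ),
            DFEComponent(
                weight=0.3394, alpha=6.25, beta=0.184,
                two_n_ref=6.25 / 0.00040244, label="coding",
            ),
        ]
    )


def draw_s(dfe: DFESpec, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw selection coefficients (negative, clamped at -1) from the mixture."""
    weights = np.array([c.weight for c in dfe.components])
    comp = rng.choice(len(weights), size=size, p=weights)
    out = np.empty(size)
    for i, c in enumerate(dfe.components):
        k = int((comp == i).sum())
        if k:
            out[comp == i] = c.draw_abs(rng, k, dfe.convention)
    return -np.minimum(out, 1.0)


@dataclass
class SimulationConfig:
    """Full specification of one BGS simulation design."""

    flank_bp: int = 1_000_000
    n_flanks: int = 2
    core_bp: int = 30_000
    f_del: float = 0.2046
    dfe: DFESpec = field(default_factory=default_dfe)
    mu: float = 1.66e-8
    rec_rate: float = 8.19e-10
    demography: ThreePopModel | ConstantModel = field(default_factory=default_model)
    migration: bool = True
    sample_size: int = 100
    output_interval: float = 100.0
    replicates: int = 2000
    burn_in_factor: float = 10.0
    rescale_q: float = 1.0
    dominance: float = 0.5
    run_generations: float | None = None  # constant-size runs only
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.f_del <= 1.0:
            raise ValueError("f_del must lie in [0, 1]")
        if self.rescale_q <= 0:
            raise ValueError("rescale factor must be positive")
        if isinstance(self.demography, ThreePopModel):
            diags = validate(self.demography)
            if diags:
                raise ValueError("invalid demographic model: " + "; ".join(diags))

    @property
    def selected_bp(self) -> int:
        return self.n_flanks * self.flank_bp

    @property
    def total_bp(self) -> int:
        return self.selected_bp + self.core_bp

    @property
    def deleterious_u(self) -> float:
        """U: per-gamete deleterious mutation rate (mu x selected sites)."""
        return self.mu * self.f_del * self.selected_bp


@dataclass
class SiteClassMap:
    """Per-site class assignment over the selected flanks (fixed per replicate)."""

    classes: np.ndarray  # int8: 0 neutral, 1.. = DFE component index + 1

    @property
    def del_count(self) -> int:
        return int((self.classes > 0).sum())

    def component_counts(self, n_components: int) -> np.ndarray:
        return np.bincount(self.classes[self.classes > 0] - 1, minlength=n_components)


def assign_site_classes(config: SimulationConfig, seed=None) -> SiteClassMap:
    """i.i.d. per-site class draw over the flanks, reproducible by seed."""
    rng = np.random.default_rng(seed)
    w = np.array([c.weight for c in config.dfe.components])
    probs = np.concatenate([[1.0 - config.f_del], config.f_del * w])
    classes = rng.choice(len(probs), size=config.selected_bp, p=probs).astype(np.int8)
    return SiteClassMap(classes)


# ---------------------------------------------------------------------------
# engine internals

class _MutTable:
    """Growable registry of mutations: position, log-fitness terms."""

    def __init__(self):
        self.n = 0
        cap = 4096
        self.pos = np.empty(cap)
        self.lw_het = np.empty(cap)
        self.lw_hom = np.empty(cap)

    def _grow(self, need):
        cap = max(len(self.pos), 1024)
        if self.n + need <= len(self.pos):
            return
        while cap < self.n + need:
            cap *= 2
        for name in ("pos", "lw_het", "lw_hom"):
            arr = np.empty(cap)
            arr[: self.n] = getattr(self, name)[: self.n]
            setattr(self, name, arr)

    def add(self, pos: np.ndarray, s: np.ndarray, h: float) -> np.ndarray:
        k = len(pos)
        self._grow(k)
        sl = slice(self.n, self.n + k)
        self.pos[sl] = pos
        with np.errstate(divide="ignore"):
            self.lw_het[sl] = np.log1p(h * s)
            self.lw_hom[sl] = np.log1p(s)
        ids = np.arange(self.n, self.n + k, dtype=np.int32)
        self.n += k
        return ids

    def compact(self, keep_mask: np.ndarray) -> np.ndarray:
        """Keep flagged ids; returns old->new map (-1 for dropped)."""
        remap = np.full(self.n, -1, dtype=np.int32)
        kept = np.where(keep_mask[: self.n])[0]
        remap[kept] = np.arange(len(kept), dtype=np.int32)
        for name in ("pos", "lw_het", "lw_hom"):
            setattr(self, name, getattr(self, name)[: self.n][kept].copy())
        self.n = len(kept)
        self._grow(0)
        return remap


class _Pop:
    __slots__ = ("name", "haps_d", "haps_n")

    def __init__(self, name, haps_d, haps_n):
        self.name = name
        self.haps_d = haps_d  # deleterious mutation ids per haplotype
        self.haps_n = haps_n  # neutral (core) mutation ids per haplotype

    @property
    def n_dip(self):
        return len(self.haps_d) // 2


def _fitness(pop: _Pop, table: _MutTable) -> np.ndarray | None:
    lens = np.fromiter((h.size for h in pop.haps_d), dtype=np.int64, count=len(pop.haps_d))
    total = int(lens.sum())
    n_dip = pop.n_dip
    if total == 0:
        return None
    ids = np.concatenate(pop.haps_d)
    dip = np.repeat(np.arange(len(lens)) >> 1, lens)
    lw = np.bincount(dip, weights=table.lw_het[ids], minlength=n_dip)
    order = np.lexsort((ids, dip))
    i2, d2 = ids[order], dip[order]
    dup = (i2[1:] == i2[:-1]) & (d2[1:] == d2[:-1])
    if dup.any():
        di = i2[1:][dup]
        np.add.at(lw, d2[1:][dup], table.lw_hom[di] - 2.0 * table.lw_het[di])
    top = lw.max()
    if not np.isfinite(top):
        return None
    w = np.exp(lw - top)
    return w


def _cross_pick(arr, parity, bps, pos):
    if arr.size == 0:
        return arr
    seg = np.searchsorted(bps, pos[arr])
    return arr[(seg & 1) == parity]


def _sample_stats(pop: _Pop, n_s: int, rng, core_bp: int, context: str):
    n_hap = len(pop.haps_n)
    if n_hap < n_s:
        raise ValueError(
            f"population {pop.name} has {n_hap} chromosomes, fewer than the "
            f"requested sample of {n_s} ({context})"
        )
    idx = rng.choice(n_hap, size=n_s, replace=False)
    parts = [pop.haps_n[i] for i in idx]
    ids = np.concatenate(parts) if parts else _EMPTY
    if ids.size == 0:
        return 0.0, 0.0, 0
    _, counts = np.unique(ids, return_counts=True)
    seg = counts[counts < n_s]
    pi_sum = float((2.0 * seg * (n_s - seg)).sum()) / (n_s * (n_s - 1.0))
    singles = int((seg == 1).sum())
    return pi_sum / core_bp, singles / core_bp, int(len(seg))


def _purge(pops: list[_Pop], table: _MutTable):
    if table.n == 0:
        return
    present = np.zeros(table.n, dtype=bool)
    fixed_all = np.ones(table.n, dtype=bool)
    for pop in pops:
        arrs = pop.haps_d + pop.haps_n
        lens = np.fromiter((a.size for a in arrs), dtype=np.int64, count=len(arrs))
        if lens.sum() == 0:
            fixed_all[:] = False
            continue
        ids = np.concatenate(arrs)
        cnt = np.bincount(ids, minlength=table.n)
        present |= cnt > 0
        fixed_all &= cnt == len(pop.haps_d)
    keep = present & ~fixed_all
    remap = table.compact(keep)
    cache: dict[int, np.ndarray] = {}
    for pop in pops:
        for attr in ("haps_d", "haps_n"):
            haps = getattr(pop, attr)
            for i, arr in enumerate(haps):
                if arr.size == 0:
                    continue
                key = id(arr)
                new = cache.get(key)
                if new is None:
                    m = remap[arr]
                    new = m[m >= 0].astype(np.int32, copy=False)
                    cache[key] = new
                haps[i] = new


@dataclass
class TimeSeriesResult:
    """Per-replicate, per-population time series of core diversity statistics.

    ``df`` columns: ``rep, pop, gen`` (forward, rescaled), ``t_gens_ago``
    (unscaled generations before present), ``pi, psi`` (per core site),
    ``segsites``.
    """

    df: pd.DataFrame
    config: SimulationConfig
    site_classes: SiteClassMap | None = None

    def mean_series(self) -> pd.DataFrame:
        g = (
            self.df.groupby(["pop", "t_gens_ago"], as_index=False)[["pi", "psi"]]
            .mean()
            .sort_values(["pop", "t_gens_ago"], ascending=[True, False])
        )
        return g.reset_index(drop=True)

    def final_values(self) -> pd.DataFrame:
        t0 = self.df["t_gens_ago"].min()
        return (
            self.df[self.df["t_gens_ago"] == t0]
            .groupby("pop", as_index=False)[["pi", "psi"]]
            .mean()
        )


def _reproduce(pop, n_next, w, rng, table, par):
    """One round of fitness-weighted WF reproduction for one population."""
    (c_rate, u_del, u_neu, bps_draw, del_pos, neu_pos, del_s, h) = par
    n_dip = pop.n_dip
    n_gam = 2 * n_next
    if w is None:
        parents = rng.integers(0, n_dip, size=n_gam)
    else:
        p = w / w.sum()
        parents = rng.choice(n_dip, size=n_gam, p=p)
    which = rng.integers(0, 2, size=n_gam)
    hap_idx = (2 * parents + which).astype(np.int64)
    hd, hn = pop.haps_d, pop.haps_n
    hil = hap_idx.tolist()
    new_d = [hd[i] for i in hil]
    new_n = [hn[i] for i in hil]

    n_cross = rng.poisson(c_rate, n_gam) if c_rate > 0 else np.zeros(n_gam, dtype=np.int64)
    n_mdel = rng.poisson(u_del, n_gam) if u_del > 0 else np.zeros(n_gam, dtype=np.int64)
    n_mneu = rng.poisson(u_neu, n_gam) if u_neu > 0 else np.zeros(n_gam, dtype=np.int64)

    tot_del = int(n_mdel.sum())
    tot_neu = int(n_mneu.sum())
    if tot_del:
        s = del_s(rng, tot_del)
        ids_del = table.add(del_pos(rng, tot_del), s, h)
    if tot_neu:
        ids_neu = table.add(neu_pos(rng, tot_neu), np.zeros(tot_neu), h)

    special = np.nonzero((n_cross > 0) | (n_mdel > 0) | (n_mneu > 0))[0]
    cd = cn = 0
    pos = table.pos
    for g in special:
        d, nn = new_d[g], new_n[g]
        k = n_cross[g]
        if k:
            sib = hil[g] ^ 1
            bps = np.sort(bps_draw(rng, k))
            d = np.concatenate([_cross_pick(d, 0, bps, pos), _cross_pick(hd[sib], 1, bps, pos)])
            nn = np.concatenate([_cross_pick(nn, 0, bps, pos), _cross_pick(hn[sib], 1, bps, pos)])
        md = n_mdel[g]
        if md:
            d = np.concatenate([d, ids_del[cd: cd + md]])
            cd += md
        mn = n_mneu[g]
        if mn:
            nn = np.concatenate([nn, ids_neu[cn: cn + mn]])
            cn += mn
        new_d[g], new_n[g] = d, nn
    pop.haps_d, pop.haps_n = new_d, new_n


def _migrate(pops: dict[str, _Pop], pairs, rng):
    snap = {
        name: (list(p.haps_d), list(p.haps_n)) for name, p in pops.items()
    }
    for a, b, m in pairs:
        if m <= 0:
            continue
        for dst, src in ((a, b), (b, a)):
            if dst not in pops or src not in pops:
                continue
            n_dst = pops[dst].n_dip
            n_src = len(snap[src][0]) // 2
            if n_src == 0:
                continue
            k = rng.binomial(n_dst, min(m, 1.0))
            if k == 0:
                continue
            k = min(k, n_dst)
            targets = rng.choice(n_dst, size=k, replace=False)
            sources = rng.integers(0, n_src, size=k)
            sd, sn = snap[src]
            for t, s in zip(targets, sources):
                pops[dst].haps_d[2 * t] = sd[2 * s]
                pops[dst].haps_d[2 * t + 1] = sd[2 * s + 1]
                pops[dst].haps_n[2 * t] = sn[2 * s]
                pops[dst].haps_n[2 * t + 1] = sn[2 * s + 1]


def _founders(src: _Pop, name: str, n_dip: int, rng) -> _Pop:
    n_src = src.n_dip
    idx = rng.choice(n_src, size=n_dip, replace=n_dip > n_src)
    hd, hn = [], []
    for i in idx:
        hd += [src.haps_d[2 * i], src.haps_d[2 * i + 1]]
        hn += [src.haps_n[2 * i], src.haps_n[2 * i + 1]]
    return _Pop(name, hd, hn)


def _run_replicate(cfg: SimulationConfig, rep: int, rng, records: list, scm: SiteClassMap | None):
    q = cfg.rescale_q
    mu_q = cfg.mu * q
    r_q = cfg.rec_rate * q
    flank = cfg.flank_bp
    core = cfg.core_bp
    l_tot = cfg.total_bp
    h = cfg.dominance

    if cfg.f_del > 0 and cfg.selected_bp > 0:
        if scm is None:
            scm = assign_site_classes(cfg, rng.integers(2**31))
        m_del = scm.del_count
        comp_counts = scm.component_counts(len(cfg.dfe.components))
        frac = comp_counts / max(1, comp_counts.sum())

        def del_s(rng, k):
            out = np.empty(k)
            comp = rng.choice(len(frac), size=k, p=frac)
            for i, c in enumerate(cfg.dfe.components):
                sel = comp == i
                kk = int(sel.sum())
                if kk:
                    out[sel] = c.draw_abs(rng, kk, cfg.dfe.convention)
            return -np.minimum(out * q, 1.0)
    else:
        m_del = 0
        del_s = None
    u_del = mu_q * m_del
    u_neu = mu_q * core
    c_rate = r_q * l_tot

    half = cfg.selected_bp / 2.0

    def del_pos(rng, k):
        u = rng.uniform(0, cfg.selected_bp, k)
        return np.where(u < half, u, u + core)

    def neu_pos(rng, k):
        return rng.uniform(half, half + core, k)

    def bps_draw(rng, k):
        return rng.uniform(0, l_tot, k)

    par = (c_rate, u_del, u_neu, bps_draw, del_pos, neu_pos, del_s, h)
    table = _MutTable()

    model = cfg.demography
    if isinstance(model, ThreePopModel):
        model_r = rescale(model, q)
        t_total = int(round(model_r.t_expansion))
        g_ooa = t_total - int(round(model_r.t_ooa_split))
        g_split2 = t_total - int(round(model_r.t_eur_easn_split))
        n0 = max(2, int(round(model_r.n_anc)))
        n_afr = max(2, int(round(model_r.n_afr)))
        n_b = max(2, int(round(model_r.n_b)))
        n_eur0 = max(2, int(round(model_r.n_eur0)))
        n_easn0 = max(2, int(round(model_r.n_easn0)))
    else:
        if cfg.run_generations is None:
            raise ValueError("constant-size runs need run_generations")
        t_total = int(round(cfg.run_generations / q))
        g_ooa = g_split2 = None
        n0 = max(2, int(round(model.n / q)))
        model_r = None

    out_step = max(1, int(round(cfg.output_interval / q)))
    burn = int(round(cfg.burn_in_factor * n0))

    pops: dict[str, _Pop] = {
        "AFR": _Pop("AFR", [_EMPTY] * (2 * n0), [_EMPTY] * (2 * n0))
    }

    def step_all(sizes: dict[str, int], gen_label: str):
        for name, pop in pops.items():
            w = _fitness(pop, table) if u_del > 0 else None
            _reproduce(pop, sizes[name], w, rng, table, par)

    def record(g_forward, t_ago):
        for name, pop in pops.items():
            pi, psi, seg = _sample_stats(
                pop, cfg.sample_size, rng, core,
                f"generation {g_forward} ({name})",
            )
            records.append((rep, name, g_forward, t_ago, pi, psi, seg))

    # burn-in at the ancestral size
    for g in range(burn):
        step_all({"AFR": n0}, "burn-in")
        if (g + 1) % 32 == 0:
            _purge(list(pops.values()), table)

    if model_r is None:
        for g in range(t_total + 1):
            if g % out_step == 0 or g == t_total:
                record(g, (t_total - g) * q)
            if g == t_total:
                break
            step_all({"AFR": n0}, "constant")
            if (g + 1) % 32 == 0:
                _purge(list(pops.values()), table)
        return

    mig_rates = {
        "B": [("AFR", "B", model_r.m_afr_b)],
        "split": [
            ("AFR", "EUR", model_r.m_afr_eur),
            ("AFR", "EASN", model_r.m_afr_easn),
            ("EUR", "EASN", model_r.m_eur_easn),
        ],
    }

    for g in range(t_total + 1):
        # demographic events at this generation
        if g == g_ooa:
            pops["B"] = _founders(pops["AFR"], "B", n_b, rng)
        if g == g_split2:
            b = pops.pop("B")
            pops["EUR"] = _founders(b, "EUR", n_eur0, rng)
            pops["EASN"] = _founders(b, "EASN", n_easn0, rng)
        if g % out_step == 0 or g in (0, g_ooa, g_split2, t_total):
            record(g, (t_total - g) * q)
        if g == t_total:
            break
        # sizes of the next generation
        sizes = {"AFR": n_afr}
        if "B" in pops:
            sizes["B"] = n_b
        if "EUR" in pops:
            dt = g + 1 - g_split2
            sizes["EUR"] = max(2, int(round(n_eur0 * np.exp(model_r.r_eur * dt))))
            sizes["EASN"] = max(2, int(round(n_easn0 * np.exp(model_r.r_easn * dt))))
        step_all(sizes, f"generation {g}")
        if cfg.migration:
            if "EUR" in pops:
                _migrate(pops, mig_rates["split"], rng)
            elif "B" in pops:
                _migrate(pops, mig_rates["B"], rng)
        if (g + 1) % 32 == 0:
            _purge(list(pops.values()), table)


def run_forward(config: SimulationConfig, replicates: int | None = None) -> TimeSeriesResult:
    """Run the BGS design; returns per-replicate time series of pi and psi."""
    n_rep = replicates if replicates is not None else config.replicates
    ss = np.random.SeedSequence(config.seed)
    records: list = []
    scm = None
    for rep, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        _run_replicate(config, rep, rng, records, None)
    df = pd.DataFrame(
        records, columns=["rep", "pop", "gen", "t_gens_ago", "pi", "psi", "segsites"]
    )
    return TimeSeriesResult(df, config, scm)


def run_neutral_control(config: SimulationConfig, replicates: int | None = None) -> TimeSeriesResult:
    """Matched control: core region only, no deleterious mutation."""
    ctrl = replace(config, f_del=0.0, flank_bp=0)
    return run_forward(ctrl, replicates)


def relative_timeseries(bgs: TimeSeriesResult, control: TimeSeriesResult) -> pd.DataFrame:
    """pi/pi0 and psi/psi0 per population and time point.

    Ratios of across-replicate means at matched output generations.
    """
    a = bgs.mean_series().rename(columns={"pi": "pi_bgs", "psi": "psi_bgs"})
    b = control.mean_series().rename(columns={"pi": "pi0", "psi": "psi0"})
    out = a.merge(b, on=["pop", "t_gens_ago"], how="inner")
    out["pi_ratio"] = out["pi_bgs"] / out["pi0"]
    out["psi_ratio"] = out["psi_bgs"] / out["psi0"]
    return out
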