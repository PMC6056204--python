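"""Bi-allelic SNP ingestion, HWE filtering, polarization, and SFS machinery.

The central container is :class:`AlleleCountTable`, a thin wrapper around a
pandas DataFrame with one row per bi-allelic autosomal SNP and per-population
called-chromosome counts ``n``, alternate-allele counts ``x`` and genotype
counts. Derived-allele polarity comes from an ancestral-allele annotation
(the VCF ``AA`` tag or an external per-site map); lowercase ancestral calls
are treated as low-confidence and excluded from singleton statistics.

Unfolded site-frequency spectra are built from derived counts and projected
down to a common number of chromosomes with the hypergeometric expectation,
so populations of different sample sizes (and sites with missing genotypes)
are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AlleleCountTable",
    "SFS",
    "OutgroupPanel",
    "load_biallelic_snps",
    "hwe_exact_test",
    "hwe_filter",
    "polarize",
    "sfs_from_counts",
    "project_sfs",
]

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}


@dataclass
class AlleleCountTable:
    """Per-site, per-population allele and genotype counts.

    ``df`` columns: ``contig, pos`` (0-based), ``ref, alt, aa`` plus, for each
    population ``P``: ``P_n`` (called chromosomes), ``P_x`` (alt count),
    ``P_hom_ref, P_het, P_hom_alt, P_missing``. After :func:`polarize`, the
    columns ``ancestral`` (``"ref" | "alt" | "unknown"``) and ``high_conf``
    are present.
    """

    df: pd.DataFrame
    populations: list[str] = field(default_factory=list)

    def __post_init__(self):
        for pop in self.populations:
            n = self.df[f"{pop}_n"].to_numpy()
            x = self.df[f"{pop}_x"].to_numpy()
            if ((x < 0) | (x > n)).any():
                raise ValueError(f"alt counts outside [0, n] for population {pop}")

    def __len__(self):
        return len(self.df)

    def derived_counts(self, pop: str) -> np.ndarray:
        """Derived-allele counts; NaN where polarity is unknown."""
        if "ancestral" not in self.df:
            raise ValueError("table is not polarized; call polarize() first")
        n = self.df[f"{pop}_n"].to_numpy(dtype=float)
        x = self.df[f"{pop}_x"].to_numpy(dtype=float)
        anc = self.df["ancestral"].to_numpy()
        d = np.where(anc == "ref", x, n - x)
        d[anc == "unknown"] = np.nan
        return d

    def in_track(self, track) -> np.ndarray:
        """Boolean mask of rows whose position lies inside an IntervalTrack."""
        out = np.zeros(len(self.df), dtype=bool)
        for contig, sub in self.df.groupby("contig", sort=False):
            out[sub.index.to_numpy()] = track.contains(
                contig, sub["pos"].to_numpy()
            )
        return out


@dataclass
class SFS:
    """Unfolded site-frequency spectrum over derived-allele classes 0..n.

    ``counts`` may be real-valued (projection produces expectations); class 0
    and class n are permitted so per-site normalizations can include
    monomorphic sites.
    """

    n: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n + 1:
            raise ValueError("counts must have length n+1")
        if (self.counts < -1e-9).any():
            raise ValueError("negative SFS class counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def segregating(self) -> float:
        return float(self.counts[1:-1].sum())

    @property
    def singletons(self) -> float:
        return float(self.counts[1])


@dataclass
class OutgroupPanel:
    """Per-site ref/alt called-allele counts across an outgroup panel."""

    df: pd.DataFrame  # columns: contig, pos, ref_count, alt_count

    def polymorphic_mask(self, table: AlleleCountTable) -> np.ndarray:
        """Sites of ``table`` polymorphic within the panel (>=1 ref, >=1 alt)."""
        poly = (self.df["ref_count"].to_numpy() >= 1) & (
            self.df["alt_count"].to_numpy() >= 1
        )
        poly_sites = set(map(tuple, self.df.loc[poly, ["contig", "pos"]].values))
        keys = map(tuple, table.df[["contig", "pos"]].values)
        return np.fromiter(
            (k in poly_sites for k in keys), dtype=bool, count=len(table.df)
        )


def load_biallelic_snps(
    vcf_path,
    populations: dict[str, list[str]],
    autosomes=None,
    quality_filter_field: str | None = "FT",
) -> AlleleCountTable:
    """Read autosomal bi-allelic SNPs from a VCF into an AlleleCountTable.

    ``populations`` maps population name -> sample IDs. Missing genotypes
    reduce the called-chromosome count ``n`` per site; low-quality per-sample
    calls (a FORMAT field named by ``quality_filter_field`` that is not PASS,
    e.g. VQLOW-style flags) are likewise treated as missing. Non-SNP and
    non-bi-allelic records are dropped. ``autosomes`` optionally restricts to
    a set of contig names; by default the sex chromosomes and mitochondrion
    are excluded by name.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    sample_idx = {}
    for pop, ids in populations.items():
        idx = []
        for sid in ids:
            if sid not in samples:
                raise ValueError(f"sample {sid!r} not present in VCF")
            idx.append(samples.index(sid))
        sample_idx[pop] = np.asarray(idx, dtype=int)

    rows = []
    for var in vcf:
        if autosomes is not None:
            if var.CHROM not in autosomes:
                continue
        elif var.CHROM in _NON_AUTOSOMES:
            continue
        if len(var.ALT) != 1:
            continue
        if not var.is_snp:
            continue
        aa = var.INFO.get("AA")
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gts = np.asarray(var.gt_types)
        if quality_filter_field and quality_filter_field in (var.FORMAT or []):
            ft = var.format(quality_filter_field)
            if ft is not None:
                low = ~np.isin(np.asarray(ft).ravel(), ("PASS", ".", ""))
                gts = np.where(low[: len(gts)], 3, gts)
        row = {
            "contig": var.CHROM,
            "pos": var.POS - 1,  # 0-based internally
            "ref": var.REF,
            "alt": var.ALT[0],
            "aa": aa if aa is not None else ".",
        }
        for pop, idx in sample_idx.items():
            g = gts[idx]
            hom_ref = int((g == 0).sum())
            het = int((g == 1).sum())
            hom_alt = int((g == 2).sum())
            missing = int((g == 3).sum())
            row[f"{pop}_n"] = 2 * (hom_ref + het + hom_alt)
            row[f"{pop}_x"] = het + 2 * hom_alt
            row[f"{pop}_hom_ref"] = hom_ref
            row[f"{pop}_het"] = het
            row[f"{pop}_hom_alt"] = hom_alt
            row[f"{pop}_missing"] = missing
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        cols = ["contig", "pos", "ref", "alt", "aa"]
        for pop in populations:
            cols += [f"{pop}_{c}" for c in ("n", "x", "hom_ref", "het", "hom_alt", "missing")]
        df = pd.DataFrame(columns=cols)
    return AlleleCountTable(df, populations=list(populations))


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts no more probable than
    the observed one, under the exact distribution of heterozygotes given
    the minor-allele count. Returns a p-value in (0, 1].
    """
    hom_ref, het, hom_alt = int(hom_ref), int(het), int(hom_alt)
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(hom_ref, hom_alt) + het
    if rare == 0:
        return 1.0
    # log P(het = h | rare allele count, n) up to a constant
    hs = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([_log_hwe_weight(h, rare, n) for h in hs])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.where(hs == het)[0][0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _log_hwe_weight(het: int, rare: int, n: int) -> float:
    hom_rare = (rare - het) // 2
    hom_common = n - het - hom_rare
    return (
        het * np.log(2.0)
        + lgamma(n + 1)
        - lgamma(het + 1)
        - lgamma(hom_rare + 1)
        - lgamma(hom_common + 1)
    )


def hwe_filter(
    table: AlleleCountTable,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> np.ndarray:
    """Mask of sites passing the HWE exact test in every population.

    The threshold is ``alpha / m`` with Bonferroni ``m`` defaulting to the
    number of SNPs tested.
    """
    m = bonferroni_m if bonferroni_m is not None else max(1, len(table))
    thresh = alpha / m
    keep = np.ones(len(table), dtype=bool)
    cache: dict[tuple, float] = {}
    for pop in table.populations:
        cols = table.df[[f"{pop}_hom_ref", f"{pop}_het", f"{pop}_hom_alt"]].to_numpy()
        pvals = np.empty(len(cols))
        for i, key in enumerate(map(tuple, cols)):
            if key not in cache:
                cache[key] = hwe_exact_test(*key) if sum(key) > 0 else 1.0
            pvals[i] = cache[key]
        keep &= pvals >= thresh
    return keep


def polarize(table: AlleleCountTable, ancestral=None) -> AlleleCountTable:
    """Annotate ancestral polarity from an ancestral-allele source.

    ``ancestral`` may be ``None`` (use the table's ``aa`` column, i.e. the
    VCF ``AA`` tag) or a mapping ``(contig, pos) -> base``. Uppercase calls
    are high-confidence; lowercase calls map polarity but are flagged
    low-confidence (excluded from singleton analyses). Calls matching
    neither allele, and missing calls, are ``unknown``. Idempotent.
    """
    df = table.df.copy()
    if ancestral is None:
        aa = df["aa"].astype(str).to_numpy()
    else:
        aa = np.array(
            [ancestral.get((c, p), ".") for c, p in zip(df["contig"], df["pos"])],
            dtype=object,
        )
        df["aa"] = aa
    aa = np.asarray(aa, dtype="U8")
    ref = df["ref"].astype(str).to_numpy(dtype="U8")
    alt = df["alt"].astype(str).to_numpy(dtype="U8")
    anc = np.full(len(df), "unknown", dtype=object)
    high = np.zeros(len(df), dtype=bool)
    aa_up = np.char.upper(aa)
    is_ref = aa_up == np.char.upper(ref)
    is_alt = aa_up == np.char.upper(alt)
    anc[is_ref] = "ref"
    anc[is_alt] = "alt"
    high[(is_ref | is_alt)] = np.char.isupper(aa)[is_ref | is_alt]
    df["ancestral"] = anc
    df["high_conf"] = high
    return AlleleCountTable(df, populations=table.populations)


def sfs_from_counts(
    table: AlleleCountTable,
    pop: str,
    sites: np.ndarray | None = None,
    m: int | None = None,
    high_conf_only: bool = True,
) -> SFS:
    """Unfolded SFS over derived counts for one population.

    ``sites`` is an optional boolean row mask. When ``m`` is given, every
    site is projected to ``m`` chromosomes with the hypergeometric
    expectation, which also absorbs per-site missingness (variable ``n``);
    otherwise all retained sites must share an identical ``n``.
    """
    d = table.derived_counts(pop)
    n = table.df[f"{pop}_n"].to_numpy(dtype=float)
    keep = ~np.isnan(d)
    if high_conf_only:
        keep &= table.df["high_conf"].to_numpy()
    if sites is not None:
        keep &= np.asarray(sites, dtype=bool)
    d, n = d[keep], n[keep]
    if m is None:
        if len(n) and not (n == n[0]).all():
            raise ValueError("variable per-site n; pass a projection target m")
        m = int(n[0]) if len(n) else 0
        counts = np.bincount(d.astype(int), minlength=m + 1).astype(float)
        return SFS(m, counts[: m + 1])
    counts = np.zeros(m + 1)
    for (ni, di), w in pd.Series(1, index=pd.MultiIndex.from_arrays([n, d])).groupby(
        level=[0, 1]
    ).sum().items():
        ni, di = int(ni), int(di)
        if m > ni:
            raise ValueError(f"projection target {m} exceeds site sample size {ni}")
        j = np.arange(m + 1)
        counts += w * hypergeom.pmf(j, ni, di, m)
    return SFS(m, counts)


def project_sfs(sfs: SFS, m: int) -> SFS:
    """Expected SFS for ``m`` chromosomes subsampled from ``sfs.n``.

    Class-j mass is ``sum_i counts[i] * C(i,j) C(n-i, m-j) / C(n,m)``; total
    mass is preserved and projection composes (n -> m -> k equals n -> k).
    """
    if m > sfs.n:
        raise ValueError(f"projection target {m} exceeds sample size {sfs.n}")
    if m == sfs.n:
        return SFS(m, sfs.counts.copy())
    j = np.arange(m + 1)
    out = np.zeros(m + 1)
    for i, c in enumerate(sfs.counts):
        if c:
            out += c * hypergeom.pmf(j, sfs.n, i, m)
    return SFS(m, out)
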