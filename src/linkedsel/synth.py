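"""Synthetic cohort generator with analytically known ground truth.

Emits everything the empirical pipeline consumes — a multi-population cohort
VCF, a B bedGraph, include/exclude mask BEDs, an outgroup panel VCF, and a
per-window divergence table — from a fully parametric model, together with a
:class:`TruthManifest` recording the expectations the pipeline should
recover.

Model: the genome is tiled with constant-B segments, B ~ Beta(a, b). The
segregating-site intensity per bp is ``theta * a_n * B`` (so per-site
diversity is proportional to B, mimicking background selection), ancestral
derived-allele frequencies follow the neutral 1/p density, and population
allele frequencies follow the Balding-Nichols model with differentiation
``F(B) = f_base + f_slope * (1 - B)``: strong-BGS (low B) regions drift
more. The outgroup panel drifts independently with its own F, so some sites
fail polymorphism ascertainment. Divergence is B-independent by default
(the normalization is a no-op in expectation); ``divergence_b_coupling``
couples it to B for sensitivity runs.

Under this model:

    E[pi/pi_min]   = (B_low (1 - F(B_low))) / (B_high (1 - F(B_high)))
    E[F_ST | bin]  ~= F(mean B of bin)
    E[beta1]       ~= -f_slope   (per unit B)

all computable from the realized B map; the manifest stores them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .intervals import GenomeLayout

__all__ = ["SynthConfig", "TruthManifest", "generate", "expected_outputs"]

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Generator parameters (defaults define the standard study conditions)."""

    n_contigs: int = 5
    contig_length: int = 10_000_000
    b_segment: int = 10_000
    b_alpha: float = 2.0
    b_beta: float = 1.0
    theta: float = 1.0e-3
    pi_proportional_to_b: bool = True
    f_base: float = 0.10
    f_slope: float = 0.03
    samples: dict = field(
        default_factory=lambda: {"AFR": 100, "EUR": 100, "EASN": 85}
    )
    outgroup_n: int = 13
    outgroup_f: float = 0.05
    divergence_mean: float = 0.06
    divergence_b_coupling: float = 0.0
    informative_fraction: float = 0.8
    low_informative_windows: float = 0.02
    mask_exclude_fraction: float = 0.05
    aa_high_conf_fraction: float = 0.9
    missing_rate: float = 0.01
    window: int = 100_000
    seed: int | None = None

    def f_of_b(self, b):
        return self.f_base + self.f_slope * (1.0 - np.asarray(b, dtype=float))


@dataclass
class TruthManifest:
    """Configured parameters plus realized per-bin expectations."""

    config: dict
    mean_b_low1: float
    mean_b_high1: float
    expected_pi_pimin: float
    expected_psi_ratio: float
    bin_mean_b: list
    expected_fst_per_bin: list
    expected_beta1: float
    n_sites: int

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


def _weighted_quantile(values, weights, q):
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return v[np.searchsorted(cdf, q, side="left").clip(0, len(v) - 1)]


def _draw_neutral_p(rng, size, p_min):
    # density proportional to 1/p on [p_min, 1 - p_min]
    u = rng.uniform(size=size)
    return p_min * ((1.0 - p_min) / p_min) ** u


def _vcf_header(samples, contigs=(), length=0):
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c},length={length}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


_GT = np.array(["0/0", "0/1", "1/1", "./."])


def generate(config: SynthConfig, out_dir, seed: int | None = None):
    """Write the synthetic dataset; returns (paths dict, TruthManifest).

    Reproducible: the same config and seed give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    contigs = [f"chr{i + 1}" for i in range(config.n_contigs)]
    layout = GenomeLayout({c: config.contig_length for c in contigs})
    pops = list(config.samples)
    n_dip = {p: config.samples[p] for p in pops}
    n_chr = {p: 2 * n_dip[p] for p in pops}
    max_chr = max(n_chr.values())
    a_n = float(np.sum(1.0 / np.arange(1, max_chr)))
    p_min = 1.0 / max_chr

    # --- B map -------------------------------------------------------------
    n_seg = config.contig_length // config.b_segment
    b_rows = []
    b_vals_all = []
    for c in contigs:
        b = rng.beta(config.b_alpha, config.b_beta, size=n_seg)
        for k in range(n_seg):
            s = k * config.b_segment
            b_rows.append((c, s, s + config.b_segment, float(b[k])))
        b_vals_all.append(b)
    b_vals_all = np.concatenate(b_vals_all)
    bmap_path = out / "bmap.bedgraph"
    with open(bmap_path, "w") as fh:
        for c, s, e, v in b_rows:
            fh.write(f"{c}\t{s}\t{e}\t{v:.6f}\n")

    # --- masks -------------------------------------------------------------
    include_path = out / "accessible.bed"
    with open(include_path, "w") as fh:
        for c in contigs:
            fh.write(f"{c}\t0\t{config.contig_length}\n")
    exclude_paths = {}
    excluded = {c: [] for c in contigs}
    for name in ("repeats", "sweeps"):
        path = out / f"{name}.bed"
        with open(path, "w") as fh:
            for c in contigs:
                n_iv = int(
                    config.mask_exclude_fraction * config.contig_length / 5000
                )
                starts = np.sort(rng.integers(0, config.contig_length - 5000, n_iv))
                for s in starts:
                    e = int(s) + int(rng.integers(1000, 5000))
                    e = min(e, config.contig_length)
                    fh.write(f"{c}\t{int(s)}\t{e}\n")
                    excluded[c].append((int(s), e))
        exclude_paths[name] = path

    # --- sites -------------------------------------------------------------
    vcf_rows = []
    og_rows = []
    site_b = []
    for ci, c in enumerate(contigs):
        seg_b = b_vals_all[ci * n_seg: (ci + 1) * n_seg]
        lam = config.theta * a_n * config.b_segment * (
            seg_b if config.pi_proportional_to_b else np.full(n_seg, seg_b.mean())
        )
        counts = rng.poisson(lam)
        total = int(counts.sum())
        seg_idx = np.repeat(np.arange(n_seg), counts)
        pos = (
            seg_idx * config.b_segment
            + rng.integers(0, config.b_segment, size=total)
        )
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        seg_idx = seg_idx[order]
        # drop duplicate positions (bi-allelic SNPs only)
        keep = np.concatenate([[True], np.diff(pos) > 0])
        pos, seg_idx = pos[keep], seg_idx[keep]
        total = len(pos)
        b_site = b_vals_all[ci * n_seg + seg_idx]
        site_b.append(b_site)

        p_anc = _draw_neutral_p(rng, total, p_min)
        f_site = config.f_of_b(b_site)
        ref_is_anc = rng.uniform(size=total) < 0.5
        high_conf = rng.uniform(size=total) < config.aa_high_conf_fraction
        ref_idx = rng.integers(0, 4, size=total)
        alt_idx = (ref_idx + rng.integers(1, 4, size=total)) % 4
        ref_b = _BASES[ref_idx]
        alt_b = _BASES[alt_idx]
        anc_base = np.where(ref_is_anc, ref_b, alt_b)
        aa = np.where(high_conf, anc_base, np.char.lower(anc_base))

        gt_cols = {}
        for p in pops:
            a = p_anc * (1.0 - f_site) / f_site
            bb = (1.0 - p_anc) * (1.0 - f_site) / f_site
            p_pop = rng.beta(a, bb)
            # derived-allele frequency -> ALT frequency
            p_alt = np.where(ref_is_anc, p_pop, 1.0 - p_pop)
            g = rng.binomial(2, p_alt[:, None], size=(total, n_dip[p]))
            miss = rng.uniform(size=g.shape) < config.missing_rate
            g = np.where(miss, 3, g)
            gt_cols[p] = _GT[g]
        # outgroup panel with its own drift around the ancestral frequency
        a = p_anc * (1.0 - config.outgroup_f) / config.outgroup_f
        bb = (1.0 - p_anc) * (1.0 - config.outgroup_f) / config.outgroup_f
        p_og = rng.beta(a, bb)
        p_og_alt = np.where(ref_is_anc, p_og, 1.0 - p_og)
        g_og = rng.binomial(2, p_og_alt[:, None], size=(total, config.outgroup_n))
        og_gt = _GT[g_og]

        all_gt = np.concatenate([gt_cols[p] for p in pops], axis=1)
        for i in range(total):
            vcf_rows.append(
                f"{c}\t{pos[i] + 1}\t.\t{ref_b[i]}\t{alt_b[i]}\t.\tPASS\t"
                f"AA={aa[i]}\tGT\t" + "\t".join(all_gt[i])
            )
            og_rows.append(
                f"{c}\t{pos[i] + 1}\t.\t{ref_b[i]}\t{alt_b[i]}\t.\tPASS\t.\tGT\t"
                + "\t".join(og_gt[i])
            )
    site_b = np.concatenate(site_b) if site_b else np.zeros(0)

    sample_names = []
    pop_rows = []
    for p in pops:
        for k in range(n_dip[p]):
            name = f"{p}_{k:03d}"
            sample_names.append(name)
            pop_rows.append(f"{name}\t{p}")
    vcf_path = out / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write(_vcf_header(sample_names, contigs, config.contig_length))
        fh.write("\n".join(vcf_rows) + ("\n" if vcf_rows else ""))
    og_path = out / "outgroup.vcf"
    og_names = [f"OG_{k:02d}" for k in range(config.outgroup_n)]
    with open(og_path, "w") as fh:
        fh.write(_vcf_header(og_names, contigs, config.contig_length))
        fh.write("\n".join(og_rows) + ("\n" if og_rows else ""))
    pops_path = out / "populations.tsv"
    with open(pops_path, "w") as fh:
        fh.write("\n".join(pop_rows) + "\n")

    # --- divergence windows -------------------------------------------------
    div_path = out / "divergence.tsv"
    seg_per_win = config.window // config.b_segment
    with open(div_path, "w") as fh:
        fh.write("contig\tstart\tinformative_bp\tdiff_bp\n")
        for ci, c in enumerate(contigs):
            for w0 in range(0, config.contig_length, config.window):
                if rng.uniform() < config.low_informative_windows:
                    informative = int(rng.integers(0, 9999))
                else:
                    informative = int(
                        config.informative_fraction * config.window
                        * rng.uniform(0.9, 1.0)
                    )
                wseg = b_vals_all[
                    ci * n_seg + w0 // config.b_segment:
                    ci * n_seg + w0 // config.b_segment + seg_per_win
                ]
                d = config.divergence_mean * (
                    1.0 + config.divergence_b_coupling * (wseg.mean() - 0.5)
                )
                diff = int(rng.binomial(informative, min(max(d, 0.0), 1.0)))
                fh.write(f"{c}\t{w0}\t{informative}\t{diff}\n")

    # --- truth manifest ------------------------------------------------------
    seg_len = np.full(len(b_vals_all), float(config.b_segment))
    q_low, q_high = _weighted_quantile(b_vals_all, seg_len, np.array([0.01, 0.99]))
    low = b_vals_all[b_vals_all <= q_low]
    high = b_vals_all[b_vals_all >= q_high]
    mean_b_low = float(low.mean())
    mean_b_high = float(high.mean())
    if config.pi_proportional_to_b:
        exp_ratio = (
            mean_b_low * (1.0 - float(config.f_of_b(mean_b_low)))
        ) / (mean_b_high * (1.0 - float(config.f_of_b(mean_b_high))))
        exp_psi = mean_b_low / mean_b_high
    else:
        exp_ratio = 1.0
        exp_psi = 1.0
    edges = np.concatenate(
        [[b_vals_all.min()],
         _weighted_quantile(b_vals_all, seg_len, np.arange(1, 50) / 50.0),
         [b_vals_all.max()]]
    )
    bin_mid = ((edges[:-1] + edges[1:]) / 2.0).tolist()
    exp_fst = [float(config.f_of_b(m)) for m in bin_mid]
    manifest = TruthManifest(
        config={**asdict(config)},
        mean_b_low1=mean_b_low,
        mean_b_high1=mean_b_high,
        expected_pi_pimin=float(exp_ratio),
        expected_psi_ratio=float(exp_psi),
        bin_mean_b=bin_mid,
        expected_fst_per_bin=exp_fst,
        expected_beta1=-config.f_slope,
        n_sites=len(site_b),
    )
    manifest.save(out / "manifest.json")
    paths = {
        "vcf": vcf_path,
        "outgroup": og_path,
        "populations": pops_path,
        "bmap": bmap_path,
        "include": {"accessible": include_path},
        "exclude": exclude_paths,
        "divergence": div_path,
        "manifest": out / "manifest.json",
        "layout": layout,
    }
    return paths, manifest


def expected_outputs(manifest: TruthManifest) -> dict:
    """Closed-form pipeline expectations under the generator model."""
    return {
        "pi_pimin": manifest.expected_pi_pimin,
        "psi_ratio": manifest.expected_psi_ratio,
        "fst_per_bin": dict(
            zip(manifest.bin_mean_b, manifest.expected_fst_per_bin)
        ),
        "beta1": manifest.expected_beta1,
    }
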