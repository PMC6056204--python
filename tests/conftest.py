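import numpy as np
import pytest

from linkedsel.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """A compact synthetic dataset shared across pipeline tests."""
    cfg = SynthConfig(
        n_contigs=2,
        contig_length=2_000_000,
        samples={"AFR": 30, "EUR": 30, "EASN": 25},
        seed=11,
    )
    out = tmp_path_factory.mktemp("synth")
    paths, manifest = generate(cfg, out, seed=11)
    return cfg, paths, manifest


def write_vcf(path, records, samples):
    """Write a minimal VCF 4.2 file from (chrom, pos1, ref, alt, aa, gts) rows."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        for c in sorted({r[0] for r in records}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, aa, gts in records:
            info = f"AA={aa}" if aa else "."
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
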