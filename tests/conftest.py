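import textwrap

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

import cosegscan as cs
from cosegscan.synthetic_panel import default_config, generate_panel


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The canonical synthetic input bundle (seed 0)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_panel(default_config(seed=0), out)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A full pipeline run on the canonical bundle."""
    out = tmp_path_factory.mktemp("run")
    cfg = cs.PipelineConfig(out_dir=str(out), simulate=True, seed=0)
    manifest = cs.run_all(cfg)
    return cfg, manifest, out


def write_vcf(path, records, samples=("S1", "S2", "S3", "S4")):
    """Write a minimal VCF from (chrom, pos, vid, ref, alt, gt_strings)."""
    header = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=1,length=1000000>
        ##contig=<ID=2,length=1000000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        """)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf
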