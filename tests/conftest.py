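import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from poolscan import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 120-variety, 300-marker panel with one strong planted QTL."""
    cfg = SimConfig(
        n_varieties=120,
        n_markers=300,
        n_qtl=1,
        qtl_effects=(30.0,),
        qtl_freq_range=(0.4, 0.6),
        noise_sd=8.0,
        missing_genotype_rate=0.02,
        seed=42,
    )
    return cfg, simulate_panel(cfg)


@pytest.fixture
def toy_vcf(tmp_path):
    """Five VCF lines: three biallelic SNPs, one indel, one triallelic site."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1H,length=1000000>",
            '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference obs count">',
            '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate obs count">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tH\tL",
            "1H\t100\t.\tA\tG\t60\t.\t.\tRO:AO\t150:50\t25:75",
            "1H\t200\t.\tA\tAT\t60\t.\t.\tRO:AO\t10:10\t10:10",
            "1H\t300\t.\tC\tT,G\t60\t.\t.\tRO:AO\t10:10,5\t10:10,5",
            "1H\t400\t.\tG\tC\t49.9\t.\t.\tRO:AO\t120:30\t60:90",
            "1H\t500\t.\tT\tA\t80\t.\t.\tRO:AO\t99:0\t5000:5000",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text + "\n")
    return path
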