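"""Shared fixtures: tiny hand-written VCFs and cached simulations."""

import numpy as np
import pytest

import divscape as d

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="qual by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="fisher strand">
##INFO=<ID=MQ,Number=1,Type=Float,Description="mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="mq rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="read pos rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=50000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
"""


def write_vcf_text(path, records, header=VCF_HEADER):
    path.write_text(header + "".join(r + "\n" for r in records))
    return str(path)


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 biallelic sites, 4 samples, full INFO/GQ/DP annotations."""
    records = [
        "chr1\t100\t.\tA\tT\t50\tPASS\tQD=25.0;FS=1.0;MQ=60.0\t"
        "GT:GQ:DP\t0/0:99:30\t0/1:80:25\t1/1:70:28\t./.:0:0",
        "chr1\t200\t.\tG\tC\t50\tPASS\tQD=30.0;FS=0.5;MQ=59.0\t"
        "GT:GQ:DP\t0/1:60:22\t0/1:55:26\t0/0:90:31\t1/1:88:29",
        "chr2\t150\t.\tC\tA\t50\tPASS\tQD=28.0;FS=2.0;MQ=58.0\t"
        "GT:GQ:DP\t1/1:77:27\t0/0:66:24\t0/1:92:30\t0/0:85:33",
    ]
    return write_vcf_text(tmp_path / "tiny.vcf", records)


def small_matrix(dosages, positions=None, chrom="chr1", sample_prefix="s"):
    """Build a GenotypeMatrix directly from a dosage list-of-lists."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(1, n_sites + 1) * 10)
    return d.GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos,
        ref_allele=np.full(n_sites, "A", dtype=object),
        alt_allele=np.full(n_sites, "T", dtype=object),
        dosage=dosages,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default 2 Mb simulation shared across tests (read-only)."""
    return d.simulate_dataset(d.SimConfig(seed=1))


@pytest.fixture(scope="session")
def planted_sim():
    """5 Mb simulation with planted islands and one sweep per species."""
    cfg = d.SimConfig(
        contigs=[("chr1", 5_000_000)],
        snp_density=1 / 200,
        islands=[d.IslandSpec("chr1", 1_000_000, 1_100_000, lam=5.0),
                 d.IslandSpec("chr1", 3_500_000, 3_550_000, lam=5.0)],
        sweeps=[d.SweepSpec("sweepOT", "chr1", 2_000_000, 2_005_000, "OT"),
                d.SweepSpec("sweepOK", "chr1", 2_600_000, 2_605_000, "OK"),
                d.SweepSpec("sweepOI", "chr1", 4_200_000, 4_205_000, "OI")],
        seed=42,
    )
    return d.simulate_dataset(cfg)
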