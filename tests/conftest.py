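import numpy as np
import pytest

from parasweep.datatypes import HaplotypeBlock
from parasweep.pipeline import PipelineConfig, run_pipeline
from parasweep.simdata import SimConfig, SweepSpec, simulate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_block(alleles, positions=None, chrom="chr1"):
    """HaplotypeBlock from a (n_haps, n_sites) 0/1 array; n_haps must be even."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_haps, n_sites = alleles.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    samples = [f"S{i}" for i in range(n_haps // 2)]
    return HaplotypeBlock(chrom, np.asarray(positions), alleles, samples)


def random_block(rng, n_haps=20, n_sites=40, spacing=1000, chrom="chr1"):
    """Random block with LD-free sites at fixed spacing, all sites polymorphic."""
    while True:
        alleles = (rng.random((n_haps, n_sites)) < rng.uniform(0.2, 0.8, n_sites)).astype(np.int8)
        counts = alleles.sum(axis=0)
        if np.all((counts >= 2) & (counts <= n_haps - 2)):
            break
    positions = np.arange(1, n_sites + 1) * spacing
    return make_block(alleles, positions, chrom)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Moderate simulated cohort (2 x 3 Mb) with one PS and one DU sweep,
    exported to disk; shared across tests that need real-shaped inputs."""
    outdir = tmp_path_factory.mktemp("simbundle")
    config = SimConfig(
        chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000}, seed=11
    )
    sweeps = [
        SweepSpec("chr1", 1_500_000, ("DLW", "DU")),
        SweepSpec("chr2", 1_500_000, ("DU",)),
    ]
    paths = simulate_bundle(config, sweeps, outdir)
    return {"config": config, "sweeps": sweeps, "paths": paths}


@pytest.fixture(scope="session")
def pipeline_run(sim_bundle, tmp_path_factory):
    """One full pipeline run on the shared bundle."""
    outdir = tmp_path_factory.mktemp("pipelinerun")
    paths = sim_bundle["paths"]
    config = PipelineConfig(
        vcf=str(paths["vcf"]),
        popmap=str(paths["popmap"]),
        genes=str(paths["genes"]),
        qtls=str(paths["qtls"]),
        outdir=str(outdir),
        chrom_lengths=sim_bundle["config"].chrom_lengths,
        seed=11,
    )
    result = run_pipeline(config)
    return {"config": config, "result": result, "outdir": outdir}
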