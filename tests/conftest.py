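import pytest

from mirprecis.pipeline import GenotypeConfig, RunConfig, SimulationConfig, run_pipeline
from mirprecis.simulate import (
    LibrarySpec,
    SyntheticGenomeSpec,
    SyntheticLocusSpec,
    build_genome,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb genome with 8 planted hairpins (one mature + one star each)."""
    spec = SyntheticGenomeSpec(n_chromosomes=2, chromosome_length=10_000, seed=11)
    loci = [
        SyntheticLocusSpec(
            locus_id=f"syn-MIR{i:02d}",
            baseline_abundance=400.0,
            mature_arm="5p" if i % 2 == 0 else "3p",
            genotype_multipliers={"mut": 0.4} if i < 3 else {},
        )
        for i in range(8)
    ]
    genome, annotation, catalog = build_genome(spec, loci)
    return genome, annotation, catalog, loci


@pytest.fixture(scope="session")
def small_library(small_genome):
    """One clean WT library: no misprocessing, Poisson counts."""
    genome, annotation, _catalog, loci = small_genome
    lib = LibrarySpec(
        genotype="WT", replicate=1, depth=8_000,
        misprocessing_rate=0.0, background_24nt_fraction=0.4, seed=21,
    )
    records, truth = simulate_library(genome, annotation, lib, loci)
    return lib, records, truth


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """The full-scale default study: WT + a processing mutant (hyl1-like,
    misprocessing 0.4, 15 loci at multiplier 0.4) + an abundance-only mutant
    (snrk2-like, 15 loci at multiplier 0.4, 10 shared), 2 replicates each,
    depth 2e5, 60 loci, dispersion 0.1."""
    out = tmp_path_factory.mktemp("study")
    config = RunConfig(out_dir=str(out), seed=1)
    return run_pipeline(config, write_fastq=False)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """A fast 10-locus pipeline run for smoke/format tests."""
    out = tmp_path_factory.mktemp("tiny")
    config = RunConfig(
        out_dir=str(out),
        seed=5,
        simulation=SimulationConfig(n_loci=10, depth=10_000, chromosome_length=20_000),
        genotypes={
            "WT": GenotypeConfig(),
            "hyl1_like": GenotypeConfig(
                misprocessing_rate=0.4, multiplier=0.4, reduced_loci=[0, 1, 2]
            ),
            "snrk2_like": GenotypeConfig(multiplier=0.4, reduced_loci=[1, 2, 3]),
        },
    )
    return run_pipeline(config)


def mature_label_to_locus(label: str) -> str:
    """Map a mature catalog label (e.g. syn-MIR001-5p) to its locus id."""
    first = label.split("/")[0]
    for suffix in ("-5p", "-3p"):
        if first.endswith(suffix):
            return first[: -len(suffix)]
    return first
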