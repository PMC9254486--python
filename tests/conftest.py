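import pytest

import rloopscape as rl


def iv(chrom, start, end, strand=".", name=None):
    return rl.StrandedInterval(chrom, start, end, strand, name)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study: 2 Mb genome, 3 samples, planted markers."""
    return rl.generate_dataset(rl.SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def small_config():
    """Desk-second-scale configuration for determinism / file round trips."""
    return rl.SimulationConfig(
        seed=7,
        chrom_sizes={"chr2L": 150_000, "chr3R": 100_000, "chrM": 5_000},
        gap_regions=[("chr2L", 70_000, 72_000)],
        n_transcripts=40,
        n_background_peaks=20,
        marker_programs=[
            rl.MarkerProgram("bound_factor", rho=2.0, n_peaks=60),
            rl.MarkerProgram("independent_factor", rho=1.0, n_peaks=60),
        ],
        probe_dense_region=("chr2L", 0, 60_000),
        n_chipchip_peaks=50,
        n_skew_sites=2,
        skew_site_half_width=500,
    )


@pytest.fixture(scope="session")
def layout():
    return rl.GenomeLayout({"chr2L": 100_000, "chr3R": 50_000})
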