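import numpy as np
import pandas as pd
import pytest

import introscan as isc
from introscan.segments import encode_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """One 100 Mbp / 150 cM chromosome with 10 evenly spaced markers."""
    spec = isc.ChromosomeSpec("1H", 100_000_000, 150.0)
    bp = np.linspace(10_000_000, 100_000_000, 10)
    markers = pd.DataFrame(
        {"chrom": "1H", "bp": bp, "cM": bp * 1.5e-6},
        index=[f"m{i}" for i in range(10)],
    )
    return isc.GeneticMap([spec], markers)


@pytest.fixture(scope="session")
def tiny_study():
    """A small error-free simulated mapping cohort shared across tests."""
    return isc.simulate_mapping_study(
        20240416, n_markers_per_chromosome=120, n_transformable=8, n_non_transformable=3
    )


@pytest.fixture(scope="session")
def tiny_encoded(tiny_study):
    encoded, n_discordant = encode_genotypes(
        tiny_study.genotypes,
        tiny_study.panel["call_recurrent"],
        tiny_study.panel["call_donor"],
    )
    assert n_discordant == 0
    return encoded


def make_map(marker_bp: dict[str, list[int]], length_bp: int = 1_000, length_cM: float = 100.0):
    """Build a map from explicit per-chromosome marker positions (bp)."""
    chroms = [isc.ChromosomeSpec(c, length_bp, length_cM) for c in marker_bp]
    rows = []
    names = []
    for chrom, positions in marker_bp.items():
        for i, bp in enumerate(positions):
            names.append(f"{chrom}_m{i}")
            rows.append({"chrom": chrom, "bp": float(bp), "cM": bp * length_cM / length_bp})
    return isc.GeneticMap(chroms, pd.DataFrame(rows, index=names))
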