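import numpy as np
import pytest

from idscan import (
    PolygenicSpec, QTLSpec, SimulationConfig, simulate_population,
)


@pytest.fixture(scope="session")
def small_pop():
    """A small mixed selfed/outcross population with a polygenic
    directional-dominance trait, shared across read-only tests."""
    cfg = SimulationConfig(
        n_parents=10, n_chromosomes=2, chrom_length_cM=80,
        marker_spacing_cM=1.0, seed=42,
        selfed_family_sizes=[15] * 10,
        polygenic_spec=PolygenicSpec(n_loci=60, effect_scale=0.3,
                                     mean_dominance=0.7,
                                     freq_beta_a=1.5, freq_beta_b=4.0),
        residual_sd_by_type_year={
            ("outcrossed", "Y1"): 2.0, ("outcrossed", "Y2"): 2.0,
            ("selfed", "Y1"): 2.0, ("selfed", "Y2"): 2.0,
        },
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def qtl_pop():
    """Population carrying one private large-effect QTL (parent 2, hap 0)."""
    cfg = SimulationConfig(
        n_parents=10, n_chromosomes=2, chrom_length_cM=80, seed=5,
        selfed_family_sizes=[20] * 10,
        qtl_spec=[QTLSpec(chrom=1, cM=40.0, freq=0.05, a=-4.0, d=2.0,
                          carrier=(2, 0))],
        residual_sd_by_type_year={
            ("outcrossed", "Y1"): 3.0, ("outcrossed", "Y2"): 3.0,
            ("selfed", "Y1"): 3.0, ("selfed", "Y2"): 3.0,
        },
    )
    return simulate_population(cfg)
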