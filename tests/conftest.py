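"""Shared fixtures: study-design constants and reduced MCMC settings."""

import pytest

from isodiet import (
    DiscriminationFactor,
    MCMCSettings,
    SourceSpec,
    consumers_from_moments,
)


@pytest.fixture(scope="session")
def paper_sources():
    """Source specs for both zooplankton treatments plus mesopelagic fishes."""
    meso = SourceSpec("mesopelagic sources", -17.6, 0.8, 6.2, 1.5, n=11)
    return {
        "lipid_normalized": [
            SourceSpec("surface zooplankton", -19.7, 1.0, 7.8, 1.0, n=35),
            meso,
        ],
        "bulk": [
            SourceSpec("surface zooplankton", -20.5, 0.6, 7.8, 1.0, n=35),
            meso,
        ],
    }


@pytest.fixture(scope="session")
def paper_dtdfs():
    """The two elasmobranch DTDF sets used across the four models."""
    return {
        "large_shark": DiscriminationFactor(0.9, 0.33, 2.29, 0.22, "large_shark"),
        "leopard_shark": DiscriminationFactor(1.7, 0.5, 3.7, 0.4, "leopard_shark"),
    }


@pytest.fixture(scope="session")
def consumers75():
    """75 consumers reconstituted from the overall manta muscle moments."""
    return consumers_from_moments(-16.8, 1.1, 10.6, 1.5, 75, seed=42,
                                  species="Manta birostris")


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chains for unit tests; convergence still checked per run."""
    return MCMCSettings(chains=2, iterations=3000, burn_in=500, seed=7)
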