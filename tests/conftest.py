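"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from plexcell.synth import TissueSpec, default_phenotypes


@pytest.fixture(scope="session")
def immune_phenotypes():
    """The nine default immune phenotypes (no tumor compartment)."""
    return default_phenotypes(tumor_fraction=0.0)


@pytest.fixture(scope="session")
def noiseless_phenotypes(immune_phenotypes):
    """Immune phenotypes with zero expression variance: every cell sits
    exactly at its type's mean profile, so marker positivity is
    unambiguous."""
    return tuple(
        replace(p, marker_sds={m: 0.0 for m in p.marker_sds})
        for p in immune_phenotypes
    )


def small_spec(phenotypes, n_cells=120, density_per_mm2=1200.0, **kwargs):
    side = float(np.sqrt(n_cells / density_per_mm2) * 1000.0)
    return TissueSpec(phenotypes=phenotypes, n_cells=n_cells,
                      field_um=(side, side), **kwargs)


@pytest.fixture
def two_type_spec(immune_phenotypes):
    """Bright T cells (70%) and dim-DAPI macrophages (30%)."""
    by_name = {p.name: p for p in immune_phenotypes}
    phens = (
        replace(by_name["CD8_T"], abundance=0.7),
        replace(by_name["TAM"], abundance=0.3),
    )
    return small_spec(phens, n_cells=200, density_per_mm2=1000.0)
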