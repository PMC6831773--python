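"""Shared fixtures: hand-written micro-tables and the default simulation."""

from __future__ import annotations

import numpy as np
import pytest

import sipshift as s
from sipshift.model import Assay, FractionSample, Isotope, OtuFractionTable, Treatment


def make_samples(
    densities,
    treatment=Treatment.NH4,
    isotope=Isotope.C12,
    assay=Assay.DNA,
    column_id="column_1",
    concentrations=None,
):
    """Build a gradient's FractionSamples from a density vector (heavy first)."""
    if concentrations is None:
        concentrations = [10.0] * len(densities)
    return [
        FractionSample(
            sample_id=f"{treatment.value}_{isotope.value}_{assay.value}_{column_id}_f{i + 1:02d}",
            treatment=treatment,
            isotope=isotope,
            assay=assay,
            column_id=column_id,
            fraction_index=i + 1,
            buoyant_density=float(d),
            na_concentration=float(c),
        )
        for i, (d, c) in enumerate(zip(densities, concentrations))
    ]


def make_table(counts, densities, **kwargs) -> OtuFractionTable:
    counts = np.asarray(counts)
    return OtuFractionTable(
        otu_ids=[f"otu{i + 1}" for i in range(counts.shape[0])],
        samples=make_samples(densities, **kwargs),
        counts=counts,
    )


@pytest.fixture
def small_table() -> OtuFractionTable:
    """3 OTUs x 4 fractions, densities descending (heavy -> light)."""
    return make_table(
        [[10, 20, 10, 0], [0, 5, 5, 10], [100, 100, 100, 100]],
        [1.74, 1.72, 1.70, 1.68],
    )


@pytest.fixture(scope="session")
def default_dataset() -> s.SyntheticDataset:
    return s.simulate_experiment()


@pytest.fixture(scope="session")
def default_shifts(default_dataset) -> list[s.ShiftRecord]:
    return s.compute_shifts(default_dataset.tables)


@pytest.fixture(scope="session")
def default_cascade(default_dataset, default_shifts) -> s.CascadeResult:
    return s.run_filter_cascade(
        default_shifts, default_dataset.taxonomy, n_boot=1000, seed=7
    )
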