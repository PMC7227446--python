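"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

import gxeblup as gx


@pytest.fixture
def toy_table() -> gx.PhenotypeTable:
    """Nine records, three lines, three environments across two companies."""
    rows = []
    vals = iter(np.linspace(9.0, 12.0, 9))
    for line in ("L1", "L2", "L3"):
        for company, year, loc in (("NS", 2015, 1), ("NS", 2016, 1), ("SJ", 2015, 1)):
            rows.append({"line_id": line, "company": company, "year": year,
                         "location": loc, "protein": next(vals),
                         "test_weight": 60.0})
    return gx.PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset() -> gx.SyntheticDataset:
    """Compact end-to-end dataset: ~110 lines, 5 environments, 400 markers."""
    cfg = gx.SimulationConfig(
        n_founders=24, n_families=22, n_singleton_crosses=5, n_markers=400,
        n_chromosomes=4, selfing_generations=3,
        companies={"NS": {2015: 2, 2016: 1}, "SJ": {2015: 1, 2017: 1}},
        missing_design_fraction=0.35, seed=11,
    )
    return gx.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset) -> gx.FitResult:
    """One full-model fit reused by summary-level tests."""
    spec = gx.ModelSpec("ELGA-GxE-AxE", n_iter=1500, burn_in=400, thin=2, seed=3)
    return gx.fit_model(small_dataset.phenotypes, "protein", spec,
                        G=small_dataset.G, A=small_dataset.A)
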