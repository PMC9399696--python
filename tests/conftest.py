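"""Shared fixtures: scenario builders and small simulated plates."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from xistmelt import meltsim, pipeline
from xistmelt.meltsim import ProductSpec, SampleTruth, SimConfig, WellScenario


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def grid(config) -> np.ndarray:
    return config.grid()


@pytest.fixture(scope="session")
def make_well(config, grid):
    """Factory for a single simulated well from explicit products."""

    def _make(
        products,
        well_id: str = "W1",
        sample_id: str = "S1",
        noise_sd: float | None = None,
        seed: int = 0,
        amplified: bool = True,
        gain: float = 1.0,
    ):
        scenario = WellScenario(
            well_id=well_id,
            sample_id=sample_id,
            products=tuple(products),
            noise_sd=config.noise_sd if noise_sd is None else noise_sd,
            amplified=amplified,
            seed=seed,
            gain=gain,
        )
        return meltsim.simulate_well(scenario, grid)

    return _make


@pytest.fixture(scope="session")
def actb_product(config) -> ProductSpec:
    return ProductSpec("ACTB", config.actb_tm, config.product_width, config.actb_abundance)


@pytest.fixture(scope="session")
def xist_product(config) -> ProductSpec:
    return ProductSpec("XIST", config.xist_tm, config.product_width, config.xist_abundance)


@pytest.fixture(scope="session")
def male_curve(make_well, actb_product):
    """Noiseless single-product (ACTB-only) male well."""
    return make_well([actb_product], well_id="M1", noise_sd=0.0)


@pytest.fixture(scope="session")
def female_curve(make_well, actb_product, xist_product):
    """Noiseless duplex (ACTB + XIST) female well."""
    return make_well([actb_product, xist_product], well_id="F1", noise_sd=0.0)


def build_plate(samples: list[SampleTruth], config: SimConfig, seed: int):
    """Simulate wells/layout/metadata for an explicit sample list."""
    curves, rows = [], []
    grid = config.grid()
    for idx, sample in enumerate(samples):
        for rep in range(config.replicates):
            well_id = f"P1-{chr(ord('A') + idx)}{rep + 1:02d}"
            scenario = meltsim.make_scenario(sample, rep, config, seed=seed, well_id=well_id)
            curves.append(meltsim.simulate_well(scenario, grid))
            rows.append({"well": well_id, "sample_id": sample.sample_id, "replicate": rep + 1})
    layout = pd.DataFrame(rows)
    truth = pd.DataFrame([vars(s) for s in samples])
    return curves, layout, meltsim.truth_to_metadata(truth)


def sample(
    sample_id: str,
    sex: str,
    rna_yield: float = 70.0,
    anchor: bool = False,
    karyotype: str | None = None,
    cohort: str = "test",
) -> SampleTruth:
    karyotype = karyotype or ("XX" if sex == "female" else "XY")
    dna_sex = "male" if karyotype in ("XY", "XXY") else "female"
    return SampleTruth(
        sample_id=sample_id,
        true_sex=sex,
        karyotype=karyotype,
        rna_yield=rna_yield,
        cohort=cohort,
        known_female_anchor=anchor,
        dna_sex=dna_sex,
    )


@pytest.fixture(scope="session")
def mixed_run():
    """A small analyzed mixed-sex cohort with anchors and adequate yields."""
    cohort = meltsim.simulate_cohort(8, 0.5, "2021", seed=42, min_yield=9.0)
    metadata = meltsim.truth_to_metadata(cohort.truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.analyze_plate(cohort.curves, cohort.layout, metadata)
    return cohort, metadata, result
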