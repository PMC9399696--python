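"""Synthetic duplex RT-qPCR melt-curve simulator.

Generates plates of XIST/ACTB duplex melt curves with the signal structure
the downstream analysis assumes, together with ground-truth labels for every
well and sample:

* female (XX) wells carry two melt transitions — the XIST amplicon near
  84.0 °C and the ACTB control amplicon near 85.5 °C;
* male (XY) wells carry the ACTB transition only (optionally split into two
  closely spaced sub-transitions for ACTB-heterozygous individuals, giving
  the characteristic elevation-separating plateau);
* XXY individuals express XIST (female-like melt profile) while their
  DNA-based label is male;
* samples with low RNA yield are exposed to well-level failure modes —
  XIST dropout (a female well rendered male-like), a dominant primer-dimer
  product at low temperature, or complete non-amplification.

Each well's fluorescence is a two-state (helix/coil) melting model on a
linear dye/background baseline:

    RFU(T) = gain · (b0 + b1·T) · (residual + Σ_k a_k · θ(T; tm_k, w_k)) + ε

with θ the logistic helicity fraction and ε additive Gaussian noise scaled
to the pre-melt amplitude. Everything is deterministic given the master
seed: per-well seeds are derived by stable hashing so plates reproduce
bit-identically regardless of simulation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .plate_io import MeltCurve

__all__ = [
    "ProductSpec",
    "WellScenario",
    "SampleTruth",
    "SimConfig",
    "COHORT_PROFILES",
    "two_state_fraction",
    "simulate_well",
    "simulate_cq",
    "make_scenario",
    "simulate_cohort",
    "truth_to_metadata",
    "default_grid",
]

#: cohort RNA-yield profiles (log-normal): name -> (mean ng/µl, sigma of log)
COHORT_PROFILES: dict[str, tuple[float, float]] = {
    "pilot-2020": (5.6, 0.5),
    "optimized-2020": (55.0, 0.6),
    "2021": (71.4, 0.6),
}

_PLATE_ROWS = "ABCDEFGH"
_PLATE_COLS = 12
_PLATE_CAPACITY = len(_PLATE_ROWS) * _PLATE_COLS


@dataclass(frozen=True)
class ProductSpec:
    """One amplicon's contribution to a well's melt signal."""

    name: str
    tm: float  # melting temperature, °C
    width: float  # transition width, °C
    abundance: float  # relative fluorescence contribution, arbitrary units

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"product {self.name!r}: width must be > 0")
        if self.abundance < 0:
            raise ValueError(f"product {self.name!r}: abundance must be >= 0")


@dataclass(frozen=True)
class WellScenario:
    """Ground-truth generative parameters for a single well."""

    well_id: str
    sample_id: str
    products: tuple[ProductSpec, ...]
    baseline_intercept: float = 2600.0  # RFU
    baseline_slope: float = -20.0  # RFU / °C (dye response falls with T)
    residual_fraction: float = 0.05  # non-melting residual fluorescence
    noise_sd: float = 0.004  # additive noise, fraction of pre-melt amplitude
    template_log10: float = 0.0  # log10 relative cDNA input
    amplified: bool = True
    seed: int = 0
    gain: float = 1.0  # per-well multiplicative gain

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.residual_fraction < 0:
            raise ValueError("residual_fraction must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass(frozen=True)
class SampleTruth:
    """Per-sample ground truth, including the DNA-method label.

    ``dna_sex`` is the label a gel-based SRY/ZFX assay would report; for an
    XXY individual it is ``male`` even though XIST is expressed, which is
    exactly the discordance the validation stage must surface.
    """

    sample_id: str
    true_sex: str  # female | male
    karyotype: str  # XX | XY | XXY
    rna_yield: float  # ng µl⁻¹
    cohort: str
    known_female_anchor: bool
    dna_sex: str

    def __post_init__(self) -> None:
        if self.true_sex not in ("female", "male"):
            raise ValueError(f"unknown sex label {self.true_sex!r}")
        if self.karyotype not in ("XX", "XY", "XXY"):
            raise ValueError(f"unknown karyotype {self.karyotype!r}")
        if self.rna_yield <= 0:
            raise ValueError("rna_yield must be > 0")
        if self.karyotype == "XXY" and self.dna_sex != "male":
            raise ValueError("XXY karyotype implies dna_sex == 'male'")

    @property
    def expresses_xist(self) -> bool:
        """XIST is transcribed in any karyotype with ≥ 2 X chromosomes."""
        return self.karyotype in ("XX", "XXY")


@dataclass(frozen=True)
class SimConfig:
    """Tunable simulator parameters (all temperatures in °C).

    Defaults encode the study conditions of the assay: the ACTB control
    amplicon melts near 85.5 °C, the female-specific XIST amplicon near
    84.0 °C, the instrument reads 70–95 °C in 0.5 °C steps, and samples with
    RNA yield below ~9 ng µl⁻¹ are exposed to XIST dropout, primer-dimer and
    non-amplification failure modes.
    """

    grid_min: float = 70.0
    grid_max: float = 95.0
    grid_step: float = 0.5

    actb_tm: float = 85.5
    xist_tm: float = 84.0
    product_width: float = 0.25
    actb_abundance: float = 1.0
    xist_abundance: float = 0.55

    baseline_intercept: float = 2600.0
    baseline_slope: float = -20.0
    residual_fraction: float = 0.05
    noise_sd: float = 0.004
    gain_sigma: float = 0.1  # sigma of the per-well log-normal gain

    het_actb_prob: float = 0.10  # per-individual ACTB-heterozygosity rate
    het_actb_spacing: float = 0.35  # °C between the two ACTB sub-transitions
    het_actb_width: float = 0.25

    dropout_threshold: float = 9.0  # ng µl⁻¹; below: failure modes active
    nonamp_prob: float = 0.2
    dimer_prob: float = 0.3
    dropout_prob: float = 0.5
    dimer_tm: float = 78.0
    dimer_width: float = 0.35
    dimer_abundance: float = 0.7
    dimer_actb_abundance: float = 0.35

    xxy_prob: float = 0.0  # not observed in the study; supported for tests
    anchor_prob: float = 0.35  # chance a female is a known-female anchor
    replicates: int = 3

    cq_slope: float = 3.32  # cycles per log10 template (100% efficiency)
    cq_intercept: float = 24.0
    max_cycles: int = 45

    def grid(self) -> np.ndarray:
        """The default instrument temperature grid."""
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


def default_grid() -> np.ndarray:
    """70–95 °C at 0.5 °C — the instrument's melt-step read grid."""
    return SimConfig().grid()


def _derive_seed(master: int, label: str) -> int:
    """Stable sub-seed from (master seed, label); < 2**31 and order-free."""
    digest = hashlib.blake2b(f"{master}|{label}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31 - 1)


def two_state_fraction(
    temperature: float | np.ndarray, tm: float, width: float
) -> float | np.ndarray:
    """Helicity fraction of a two-state melting amplicon.

    θ(T) = 1 / (1 + exp((T − tm) / width)); 1 well below the transition,
    0.5 at tm, 0 well above. Monotonically non-increasing in temperature.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    arg = (np.asarray(temperature, dtype=float) - tm) / width
    out = 1.0 / (1.0 + np.exp(np.clip(arg, -700, 700)))
    if np.isscalar(temperature):
        return float(out)
    return out


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("temperature grid is empty")
    if grid.size >= 2:
        diffs = np.diff(grid)
        if not np.all(diffs > 0):
            raise ValueError("temperature grid must be ascending")
        if np.ptp(diffs) > 1e-9:
            raise ValueError("temperature grid must have a uniform step")
    return grid


def melt_signal(scenario: WellScenario, grid: np.ndarray) -> np.ndarray:
    """Noise-free expected RFU of a scenario on a grid (no gain, no noise).

    Exposes the composition structure — baseline × (residual + Σ product
    melt terms) — so tests can verify a duplex well equals the sum of its
    single-product parts.
    """
    grid = _validate_grid(grid)
    baseline = scenario.baseline_intercept + scenario.baseline_slope * grid
    melt = np.full_like(grid, scenario.residual_fraction)
    if scenario.amplified:
        for product in scenario.products:
            melt = melt + product.abundance * two_state_fraction(
                grid, product.tm, product.width
            )
    return baseline * melt


def simulate_well(scenario: WellScenario, grid: np.ndarray | None = None) -> MeltCurve:
    """Simulate one well's melt trace on ``grid`` (default 70–95 °C, 0.5 °C).

    Additive Gaussian noise is scaled by the pre-melt signal amplitude so
    ``noise_sd`` is in normalized units; the draw is reproducible from
    ``scenario.seed``.
    """
    grid = _validate_grid(default_grid() if grid is None else grid)
    signal = scenario.gain * melt_signal(scenario, grid)
    rng = np.random.default_rng(scenario.seed)
    noise = rng.standard_normal(grid.size) * (scenario.noise_sd * abs(signal[0]))
    return MeltCurve(scenario.well_id, grid, signal + noise, scenario.amplified)


def simulate_cq(
    template_log10: float,
    slope: float = 3.32,
    intercept: float = 24.0,
    max_cycles: int = 45,
) -> float | None:
    """Quantification cycle for a given log10 relative template amount.

    Cq = intercept − slope·template_log10 on a standard curve with positive
    slope (3.32 cycles/log10 at 100% efficiency). Returns ``None`` when the
    computed Cq exceeds ``max_cycles`` (the reaction never crosses threshold
    within the run — a non-amplified well). A Cq that computes negative
    (saturating template) is clamped to 0.0.
    """
    if slope <= 0:
        raise ValueError("standard-curve slope must be > 0")
    cq = intercept - slope * template_log10
    if cq > max_cycles:
        return None
    return max(cq, 0.0)


def _actb_products(config: SimConfig, heterozygous: bool) -> list[ProductSpec]:
    if not heterozygous:
        return [ProductSpec("ACTB", config.actb_tm, config.product_width, config.actb_abundance)]
    half = config.het_actb_spacing / 2.0
    return [
        ProductSpec(
            "ACTB_allele1",
            config.actb_tm - half,
            config.het_actb_width,
            config.actb_abundance / 2.0,
        ),
        ProductSpec(
            "ACTB_allele2",
            config.actb_tm + half,
            config.het_actb_width,
            config.actb_abundance / 2.0,
        ),
    ]


def make_scenario(
    sample: SampleTruth,
    replicate: int,
    config: SimConfig | None = None,
    seed: int = 0,
    well_id: str | None = None,
) -> WellScenario:
    """Build the generative scenario for one replicate well of a sample.

    Product composition follows karyotype: ACTB always; XIST whenever the
    sample has ≥ 2 X chromosomes (XX and XXY). ACTB heterozygosity is an
    individual-level trait (drawn once per sample, stable across its
    replicates). When the sample's RNA yield is below the dropout threshold
    the well is exposed, in fixed order, to mutually exclusive failure
    draws: non-amplification, a dominant primer-dimer product, then XIST
    dropout (which leaves a female well male-like).
    """
    config = config or SimConfig()
    if well_id is None:
        well_id = f"{sample.sample_id}:{replicate}"
    well_seed = _derive_seed(seed, f"well|{well_id}")
    rng = np.random.default_rng(_derive_seed(seed, f"draws|{well_id}"))
    sample_rng = np.random.default_rng(_derive_seed(seed, f"sample|{sample.sample_id}"))

    heterozygous = bool(sample_rng.random() < config.het_actb_prob)
    products = _actb_products(config, heterozygous)
    if sample.expresses_xist:
        products.append(
            ProductSpec("XIST", config.xist_tm, config.product_width, config.xist_abundance)
        )

    # fixed draw order keeps the stream stable whatever branch is taken
    u_nonamp, u_dimer, u_dropout = rng.random(3)
    gain = float(rng.lognormal(0.0, config.gain_sigma))

    amplified = True
    if sample.rna_yield < config.dropout_threshold:
        if u_nonamp < config.nonamp_prob:
            amplified = False
        elif u_dimer < config.dimer_prob:
            products = [
                ProductSpec(
                    "primer_dimer", config.dimer_tm, config.dimer_width, config.dimer_abundance
                ),
                ProductSpec(
                    "ACTB_weak", config.actb_tm, config.product_width, config.dimer_actb_abundance
                ),
            ]
        elif sample.expresses_xist and u_dropout < config.dropout_prob:
            products = [p for p in products if p.name != "XIST"]

    return WellScenario(
        well_id=well_id,
        sample_id=sample.sample_id,
        products=tuple(products),
        baseline_intercept=config.baseline_intercept,
        baseline_slope=config.baseline_slope,
        residual_fraction=config.residual_fraction,
        noise_sd=config.noise_sd,
        template_log10=float(np.log10(sample.rna_yield)) - 1.0,
        amplified=amplified,
        seed=well_seed,
        gain=gain,
    )


class CohortData(NamedTuple):
    """Bundle returned by :func:`simulate_cohort`."""

    curves: list[MeltCurve]
    layout: pd.DataFrame
    truth: pd.DataFrame
    scenarios: list[WellScenario]


def _draw_yield(
    rng: np.random.Generator, mean: float, sigma: float, min_yield: float | None
) -> float:
    mu = np.log(mean) - 0.5 * sigma**2
    for _ in range(1000):
        y = float(rng.lognormal(mu, sigma))
        if min_yield is None or y >= min_yield:
            return y
    return float(min_yield)  # pathological truncation; keep determinism


def _well_position(index: int) -> str:
    plate, offset = divmod(index, _PLATE_CAPACITY)
    row, col = divmod(offset, _PLATE_COLS)
    return f"P{plate + 1}-{_PLATE_ROWS[row]}{col + 1:02d}"


def simulate_cohort(
    n_samples: int,
    sex_ratio: float = 0.5,
    cohort_profile: str | tuple[float, float] = "2021",
    seed: int = 0,
    config: SimConfig | None = None,
    min_yield: float | None = None,
    multi_plate: bool = False,
) -> CohortData:
    """Simulate a full cohort: truth table, plate layout and melt curves.

    Parameters
    ----------
    n_samples : int
        Number of individuals (each run in ``config.replicates`` wells).
    sex_ratio : float
        Fraction of females, in [0, 1].
    cohort_profile : str or (mean, sigma)
        Named RNA-yield profile (``pilot-2020``, ``optimized-2020``,
        ``2021``) or a custom (mean ng/µl, log-sigma) pair for the
        log-normal yield distribution.
    min_yield : float, optional
        Truncate the yield draw at this floor (adequate-yield cohorts).
    multi_plate : bool
        Allow the run to span several 96-well plates; without it a cohort
        larger than one plate raises.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must be in [0, 1]")
    config = config or SimConfig()
    if isinstance(cohort_profile, str):
        if cohort_profile not in COHORT_PROFILES:
            raise ValueError(
                f"unknown cohort profile {cohort_profile!r}; "
                f"choose from {sorted(COHORT_PROFILES)} or pass (mean, sigma)"
            )
        mean, sigma = COHORT_PROFILES[cohort_profile]
        cohort_label = cohort_profile
    else:
        mean, sigma = cohort_profile
        cohort_label = "custom"

    n_wells = n_samples * config.replicates
    if n_wells > _PLATE_CAPACITY and not multi_plate:
        raise ValueError(
            f"{n_wells} wells exceed one 96-well plate; pass multi_plate=True"
        )

    rng = np.random.default_rng(_derive_seed(seed, "cohort"))
    n_female = int(round(n_samples * sex_ratio))
    sexes = ["female"] * n_female + ["male"] * (n_samples - n_female)
    rng.shuffle(sexes)

    truth_rows: list[SampleTruth] = []
    for i, sex in enumerate(sexes):
        sample_id = f"S{i + 1:03d}"
        karyotype = "XX" if sex == "female" else "XY"
        if sex == "male" and rng.random() < config.xxy_prob:
            karyotype = "XXY"
        y = _draw_yield(rng, mean, sigma, min_yield)
        anchor = sex == "female" and rng.random() < config.anchor_prob
        truth_rows.append(
            SampleTruth(
                sample_id=sample_id,
                true_sex=sex,
                karyotype=karyotype,
                rna_yield=round(y, 1),
                cohort=cohort_label,
                known_female_anchor=anchor,
                dna_sex="male" if karyotype in ("XY", "XXY") else "female",
            )
        )
    # guarantee at least one anchor whenever any female exists
    females = [i for i, s in enumerate(truth_rows) if s.true_sex == "female"]
    if females and not any(truth_rows[i].known_female_anchor for i in females):
        truth_rows[females[0]] = replace(truth_rows[females[0]], known_female_anchor=True)

    curves: list[MeltCurve] = []
    scenarios: list[WellScenario] = []
    layout_rows = []
    grid = config.grid()
    well_index = 0
    for sample in truth_rows:
        for rep in range(config.replicates):
            well_id = _well_position(well_index)
            well_index += 1
            scenario = make_scenario(sample, rep, config, seed=seed, well_id=well_id)
            scenarios.append(scenario)
            curves.append(simulate_well(scenario, grid))
            layout_rows.append(
                {"well": well_id, "sample_id": sample.sample_id, "replicate": rep + 1}
            )

    truth = pd.DataFrame([vars(s) for s in truth_rows])
    layout = pd.DataFrame(layout_rows)
    return CohortData(curves=curves, layout=layout, truth=truth, scenarios=scenarios)


def truth_to_metadata(truth: pd.DataFrame) -> pd.DataFrame:
    """Project a truth table onto the sample-metadata columns the pipeline
    consumes (dropping the generative-only ``true_sex``/``karyotype``)."""
    return truth[
        ["sample_id", "rna_yield", "dna_sex", "known_female_anchor", "cohort"]
    ].copy()
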