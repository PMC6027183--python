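import numpy as np
import pytest

from pnacid import MixtureComposition, default_coefficients


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


@pytest.fixture
def table3_mean_mixture():
    """Mixture carrying the cohort-mean species concentrations (mmol/L)."""
    return MixtureComposition(
        mixture_id="cohort-mean-species",
        volume_ml=1979.0,
        cysteine=0.4,
        methionine=12.0,
        lysine=17.0,
        arginine=18.5,
        histidine=7.2,
        phospholipid=1.5,
        acetate=29.1,
        gluconate=5.8,
    )


@pytest.fixture
def table1_mean_mixture():
    """Mixture carrying the cohort-mean covariate concentrations."""
    return MixtureComposition(
        mixture_id="cohort-mean-covariates",
        volume_ml=1979.0,
        glucose=9.1,
        lipid=2.2,
        amino_acid=3.3,
        calcium=3.0,
        phosphorus=6.1,
        sodium=51.1,
        potassium=25.2,
        magnesium=4.6,
    )


def random_full_mixture(rng: np.random.Generator, mixture_id: str = "r") -> MixtureComposition:
    """A fully populated random mixture (species supplied, not derived)."""
    return MixtureComposition(
        mixture_id=mixture_id,
        volume_ml=float(rng.uniform(500, 3000)),
        glucose=float(rng.uniform(0, 20)),
        lipid=float(rng.uniform(0, 4)),
        amino_acid=float(rng.uniform(0, 6)),
        calcium=float(rng.uniform(0, 15)),
        phosphorus=float(rng.uniform(0, 20)),
        sodium=float(rng.uniform(0, 90)),
        potassium=float(rng.uniform(0, 75)),
        magnesium=float(rng.uniform(0, 13)),
        acetate=float(rng.uniform(0, 55)),
        gluconate=float(rng.uniform(0, 27)),
        cysteine=float(rng.uniform(0, 1)),
        methionine=float(rng.uniform(0, 22)),
        lysine=float(rng.uniform(0, 31)),
        arginine=float(rng.uniform(0, 34)),
        histidine=float(rng.uniform(0, 13)),
        phospholipid=float(rng.uniform(0, 3)),
    )
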