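"""Potential renal acid load of parenteral-nutrition admixtures.

The potential metabolic acid load (PMAL) of a bag is the net amount of fixed
(non-volatile) acid that catabolism of its nutrients will produce: the sulfur
amino acids cysteine and methionine yield two protons each on oxidation of
their sulfur, the cationic amino acids lysine, histidine and arginine one
each, phospholipids contribute at one fifth weight through their phosphate,
while the organic anions acetate and gluconate are metabolised to CO2/water
and each consume one proton.  With concentrations in mmol/L and the bag
volume in mL:

    PMAL (mmol) = [2*cys + 2*met + lys + his + arg + phospholipid/5
                   - acetate - gluconate] * volume/1000

The potential total acid load is PTAL = TA + PMAL, where TA is the titratable
acidity (preformed fixed acid, mmol NaOH to pH 7.4).  One bag is infused per
day, so mmol per bag is read as mmol/day when classifying against the
clinically motivated daily-load thresholds of 50, 75 and 100 mmol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Iterable, Mapping, Sequence

from .composition import MixtureComposition, SPECIES_FIELDS

__all__ = [
    "SPECIES_WEIGHTS",
    "AcidLoadResult",
    "CohortSummary",
    "MissingSpeciesError",
    "compute_pmal",
    "compute_ptal",
    "summarize_cohort",
    "load_species_weights",
]


#: Signed per-species weights of the metabolic acid-load formula (mmol acid
#: per mmol species).  Anionic amino acids (aspartate, glutamate) would carry
#: -1 but are absent from the default because the reference amino-acid
#: product contains none; supply a custom table for formulations that do.
SPECIES_WEIGHTS: Mapping[str, float] = {
    "cysteine": 2.0,
    "methionine": 2.0,
    "lysine": 1.0,
    "histidine": 1.0,
    "arginine": 1.0,
    "phospholipid": 0.2,
    "acetate": -1.0,
    "gluconate": -1.0,
}


class MissingSpeciesError(ValueError):
    """The mixture lacks species concentrations; run derive_species first."""


def load_species_weights(path: str | Path) -> dict[str, float]:
    """Load a custom species → signed weight table from JSON."""
    data = json.loads(Path(path).read_text())
    return {str(k): float(v) for k, v in data.items()}


@dataclass(frozen=True)
class AcidLoadResult:
    """Acid-load accounting for one admixture (one bag == one day).

    ``metabolic_fraction`` is PMAL/PTAL, the share of the total load of
    metabolic (as opposed to preformed) origin; ``None`` when PTAL is zero.
    """

    mixture_id: str
    ta: float
    pmal: float
    ptal: float
    metabolic_fraction: float | None
    exceeds_50: bool
    exceeds_75: bool
    exceeds_100: bool
    ph: float | None = None


def compute_pmal(
    m: MixtureComposition, weights: Mapping[str, float] | None = None
) -> float:
    """Metabolic acid load of one bag in mmol (may be negative).

    Requires the species concentrations to be populated; raises
    :class:`MissingSpeciesError` otherwise.
    """
    weights = weights if weights is not None else SPECIES_WEIGHTS
    missing = [s for s in weights if s in SPECIES_FIELDS and getattr(m, s) is None]
    if missing:
        raise MissingSpeciesError(
            f"mixture {m.mixture_id!r} lacks species {missing}; "
            "run derive_species (or supply the concentrations) first"
        )
    per_litre = sum(w * float(getattr(m, s)) for s, w in weights.items())
    return per_litre * m.volume_ml / 1000.0


def compute_ptal(
    ta: float, pmal: float, mixture_id: str = "", ph: float | None = None
) -> AcidLoadResult:
    """Combine titratable acidity and metabolic load into the total load.

    PTAL = TA + PMAL exactly; threshold flags use strict comparison against
    50, 75 and 100 mmol/day.
    """
    if not (math.isfinite(ta) and math.isfinite(pmal)):
        raise ValueError("ta and pmal must be finite")
    ptal = ta + pmal
    return AcidLoadResult(
        mixture_id=mixture_id,
        ta=ta,
        pmal=pmal,
        ptal=ptal,
        metabolic_fraction=(pmal / ptal) if ptal != 0 else None,
        exceeds_50=ptal > 50.0,
        exceeds_75=ptal > 75.0,
        exceeds_100=ptal > 100.0,
        ph=ph,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of acid load over a cohort of admixtures."""

    n: int
    ta: Mapping[str, float]
    pmal: Mapping[str, float]
    ptal: Mapping[str, float]
    count_over_50: int
    count_over_75: int
    count_over_100: int
    pct_over_50: float
    pct_over_75: float
    pct_over_100: float
    degenerate: bool  # single-mixture cohort: SD reported as 0


def _stats(values: Sequence[float]) -> dict[str, float]:
    n = len(values)
    mu = mean(values)
    if n > 1:
        sd = math.sqrt(sum((v - mu) ** 2 for v in values) / (n - 1))
    else:
        sd = 0.0
    return {"mean": mu, "sd": sd, "min": min(values), "max": max(values)}


def summarize_cohort(results: Iterable[AcidLoadResult]) -> CohortSummary:
    """Mean/SD/min/max of TA, PMAL, PTAL and the threshold distribution."""
    results = list(results)
    if not results:
        raise ValueError("summarize_cohort requires a non-empty cohort")
    n = len(results)
    c50 = sum(r.exceeds_50 for r in results)
    c75 = sum(r.exceeds_75 for r in results)
    c100 = sum(r.exceeds_100 for r in results)
    return CohortSummary(
        n=n,
        ta=_stats([r.ta for r in results]),
        pmal=_stats([r.pmal for r in results]),
        ptal=_stats([r.ptal for r in results]),
        count_over_50=c50,
        count_over_75=c75,
        count_over_100=c100,
        pct_over_50=100.0 * c50 / n,
        pct_over_75=100.0 * c75 / n,
        pct_over_100=100.0 * c100 / n,
        degenerate=(n == 1),
    )
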