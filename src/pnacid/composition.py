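"""Data model for compounded parenteral-nutrition (PN) admixtures.

A compounded PN admixture is described by its *final* concentrations after
mixing: macronutrients in g/100 mL (glucose, lipid, amino acid) and
electrolytes in mmol/L, plus the bag volume in mL.  The acid-load formula
additionally needs the concentrations of individual chemical species — the
acid-producing amino acids, the emulsifier phospholipid, and the acid-consuming
anions acetate and gluconate — which clinical prescriptions rarely state
explicitly because they are fixed properties of the stock products used for
compounding.  :class:`StockProfile` captures those product ratios so the
species can be derived from the macronutrient and calcium totals.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MixtureComposition",
    "StockProfile",
    "MixtureValidationError",
    "MixtureParseError",
    "derive_species",
    "read_mixtures",
    "write_mixtures",
    "write_report",
    "MIXTURE_CSV_COLUMNS",
    "SPECIES_FIELDS",
]


class MixtureValidationError(ValueError):
    """A mixture field violates its physical constraints (named in message)."""


class MixtureParseError(ValueError):
    """A CSV cell or column could not be parsed; carries row/column context."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if column is not None:
            ctx.append(f"column '{column}'")
        super().__init__(f"{message} ({', '.join(ctx)})" if ctx else message)


#: Species entering the metabolic acid-load formula (mmol/L each).
SPECIES_FIELDS = (
    "acetate",
    "gluconate",
    "cysteine",
    "methionine",
    "lysine",
    "arginine",
    "histidine",
    "phospholipid",
)

#: Covariates of the linear acidity/pH predictors, in canonical order.
COVARIATE_FIELDS = (
    "glucose",
    "lipid",
    "amino_acid",
    "calcium",
    "phosphorus",
    "sodium",
    "potassium",
    "magnesium",
)


@dataclass(frozen=True)
class MixtureComposition:
    """Final composition of one compounded PN admixture.

    Units: ``volume_ml`` in mL; ``glucose``/``lipid``/``amino_acid`` in
    g/100 mL; every other concentration in mmol/L.  Species fields default to
    ``None`` (unknown) and may be filled by :func:`derive_species`.
    ``chloride`` is informational only — it enters neither the acid-load
    formula nor the predictors.
    """

    mixture_id: str
    volume_ml: float
    glucose: float = 0.0
    lipid: float = 0.0
    amino_acid: float = 0.0
    calcium: float = 0.0
    phosphorus: float = 0.0
    sodium: float = 0.0
    potassium: float = 0.0
    magnesium: float = 0.0
    acetate: float | None = None
    gluconate: float | None = None
    chloride: float | None = None
    cysteine: float | None = None
    methionine: float | None = None
    lysine: float | None = None
    arginine: float | None = None
    histidine: float | None = None
    phospholipid: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.volume_ml, (int, float)) and math.isfinite(self.volume_ml)):
            raise MixtureValidationError("volume_ml must be a finite number")
        if self.volume_ml <= 0:
            raise MixtureValidationError(
                f"volume_ml must be > 0, got {self.volume_ml!r} (mixture {self.mixture_id!r})"
            )
        for f in dataclasses.fields(self):
            if f.name in ("mixture_id", "volume_ml"):
                continue
            v = getattr(self, f.name)
            if v is None:
                continue
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise MixtureValidationError(f"{f.name} must be a finite number, got {v!r}")
            if v < 0:
                raise MixtureValidationError(
                    f"{f.name} must be >= 0, got {v!r} (mixture {self.mixture_id!r})"
                )

    @property
    def has_all_species(self) -> bool:
        """True when every species needed by the acid-load formula is set."""
        return all(getattr(self, s) is not None for s in SPECIES_FIELDS)

    def covariates(self) -> dict[str, float]:
        """The eight predictor covariates as a name → value mapping."""
        return {k: float(getattr(self, k)) for k in COVARIATE_FIELDS}


#: Table-derived amino-acid spectrum of the 10% amino-acid product used for
#: compounding: mmol/L of each species per (g/100 mL) of total amino acid.
#: These ratios are an approximation from paired cohort means; users with a
#: product datasheet should supply explicit species columns instead.
DEFAULT_AA_SPECIES_PER_AA: Mapping[str, float] = {
    "cysteine": 0.4 / 3.3,
    "methionine": 12.0 / 3.3,
    "lysine": 17.0 / 3.3,
    "arginine": 18.5 / 3.3,
    "histidine": 7.2 / 3.3,
}


@dataclass(frozen=True)
class StockProfile:
    """Per-product ratios linking macronutrient totals to species content.

    - ``acetate_per_aa``: mmol/L acetate per g/100 mL total amino acid.  The
      default 8.5 reflects an amino-acid stock stabilised with 85 mmol/L
      acetate at 10 g/100 mL.
    - ``phospholipid_per_lipid``: mmol/L per g/100 mL lipid; 0.75 reflects a
      20% emulsion carrying 15 mmol/L phospholipid.
    - ``gluconate_per_calcium``: mol gluconate per mol calcium; 2.0 is the
      calcium gluconate stoichiometry Ca(C6H11O7)2.
    - ``aa_species_per_aa``: per-species mmol/L per g/100 mL total amino acid.
    """

    acetate_per_aa: float = 8.5
    phospholipid_per_lipid: float = 0.75
    gluconate_per_calcium: float = 2.0
    aa_species_per_aa: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_SPECIES_PER_AA)
    )

    def __post_init__(self) -> None:
        for name in ("acetate_per_aa", "phospholipid_per_lipid", "gluconate_per_calcium"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise MixtureValidationError(f"{name} must be finite and >= 0, got {v!r}")
        for sp, v in self.aa_species_per_aa.items():
            if not (math.isfinite(v) and v >= 0):
                raise MixtureValidationError(f"aa_species_per_aa[{sp!r}] must be >= 0, got {v!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "StockProfile":
        data = json.loads(Path(path).read_text())
        return cls(
            acetate_per_aa=data.get("acetate_per_aa", 8.5),
            phospholipid_per_lipid=data.get("phospholipid_per_lipid", 0.75),
            gluconate_per_calcium=data.get("gluconate_per_calcium", 2.0),
            aa_species_per_aa=dict(
                data.get("aa_species_per_aa", DEFAULT_AA_SPECIES_PER_AA)
            ),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "acetate_per_aa": self.acetate_per_aa,
            "phospholipid_per_lipid": self.phospholipid_per_lipid,
            "gluconate_per_calcium": self.gluconate_per_calcium,
            "aa_species_per_aa": dict(self.aa_species_per_aa),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def derive_species(
    core: MixtureComposition, profile: StockProfile | None = None
) -> MixtureComposition:
    """Fill missing species concentrations from the stock-product ratios.

    Only fields that are ``None`` are filled; explicitly supplied values
    (e.g., from a product datasheet) are never overwritten, so the operation
    is idempotent.  Derived values: acetate from total amino acid,
    phospholipid from lipid, gluconate from calcium, and each amino-acid
    species from total amino acid.
    """
    profile = profile or StockProfile()
    updates: dict[str, float] = {}
    if core.acetate is None:
        updates["acetate"] = profile.acetate_per_aa * core.amino_acid
    if core.phospholipid is None:
        updates["phospholipid"] = profile.phospholipid_per_lipid * core.lipid
    if core.gluconate is None:
        updates["gluconate"] = profile.gluconate_per_calcium * core.calcium
    for sp in ("cysteine", "methionine", "lysine", "arginine", "histidine"):
        if getattr(core, sp) is None:
            updates[sp] = profile.aa_species_per_aa.get(sp, 0.0) * core.amino_acid
    if not updates:
        return core
    return dataclasses.replace(core, **updates)


# ---------------------------------------------------------------------------
# CSV I/O

MIXTURE_CSV_COLUMNS = (
    "mixture_id",
    "volume_ml",
    "glucose_g100ml",
    "lipid_g100ml",
    "amino_acid_g100ml",
    "calcium_mM",
    "phosphorus_mM",
    "sodium_mM",
    "potassium_mM",
    "magnesium_mM",
    # optional species block
    "acetate_mM",
    "gluconate_mM",
    "chloride_mM",
    "cysteine_mM",
    "methionine_mM",
    "lysine_mM",
    "arginine_mM",
    "histidine_mM",
    "phospholipid_mM",
)

_REQUIRED_COLUMNS = MIXTURE_CSV_COLUMNS[:10]

_COLUMN_TO_FIELD = {
    "mixture_id": "mixture_id",
    "volume_ml": "volume_ml",
    "glucose_g100ml": "glucose",
    "lipid_g100ml": "lipid",
    "amino_acid_g100ml": "amino_acid",
    "calcium_mM": "calcium",
    "phosphorus_mM": "phosphorus",
    "sodium_mM": "sodium",
    "potassium_mM": "potassium",
    "magnesium_mM": "magnesium",
    "acetate_mM": "acetate",
    "gluconate_mM": "gluconate",
    "chloride_mM": "chloride",
    "cysteine_mM": "cysteine",
    "methionine_mM": "methionine",
    "lysine_mM": "lysine",
    "arginine_mM": "arginine",
    "histidine_mM": "histidine",
    "phospholipid_mM": "phospholipid",
}
_FIELD_TO_COLUMN = {v: k for k, v in _COLUMN_TO_FIELD.items()}


def read_mixtures(path: str | Path) -> list[MixtureComposition]:
    """Read mixtures from CSV, validating every row.

    Rows are numbered from 1 (first data row).  Species columns, when present
    and non-empty, take precedence over later derivation.  Raises
    :class:`MixtureParseError` with row/column context for missing columns,
    non-numeric cells, or invariant violations.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise MixtureParseError("missing required column", column=col)
        mixtures: list[MixtureComposition] = []
        for i, row in enumerate(reader, start=1):
            kwargs: dict[str, object] = {}
            for col in header:
                fld = _COLUMN_TO_FIELD.get(col)
                if fld is None:
                    continue  # unknown columns ignored
                raw = (row.get(col) or "").strip()
                if fld == "mixture_id":
                    kwargs[fld] = raw
                    continue
                if raw == "":
                    if col in _REQUIRED_COLUMNS:
                        raise MixtureParseError("empty cell in required column", row=i, column=col)
                    continue  # optional species left unknown
                try:
                    kwargs[fld] = float(raw)
                except ValueError:
                    raise MixtureParseError(
                        f"non-numeric value {raw!r}", row=i, column=col
                    ) from None
            try:
                mixtures.append(MixtureComposition(**kwargs))  # type: ignore[arg-type]
            except MixtureValidationError as exc:
                raise MixtureParseError(str(exc), row=i) from exc
    return mixtures


def write_mixtures(mixtures: Sequence[MixtureComposition], path: str | Path) -> None:
    """Write mixtures to CSV with the canonical header (full precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MIXTURE_CSV_COLUMNS)
        for m in mixtures:
            row = []
            for col in MIXTURE_CSV_COLUMNS:
                v = getattr(m, _COLUMN_TO_FIELD[col])
                row.append("" if v is None else (v if isinstance(v, str) else repr(float(v))))
            writer.writerow(row)


def write_report(results: Iterable, path: str | Path) -> None:
    """Write an acid-load report CSV.

    One row per mixture: TA, PMAL and PTAL in mmol to 0.1 (the reporting
    precision of acid-base titration), predicted pH to 0.01 where available,
    and the three daily-load threshold flags.
    """
    results = list(results)
    if not results:
        raise ValueError("write_report requires a non-empty result list")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "mixture_id",
                "ta_mmol",
                "pmal_mmol",
                "ptal_mmol",
                "ph",
                "exceeds_50",
                "exceeds_75",
                "exceeds_100",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.mixture_id,
                    f"{r.ta:.1f}",
                    f"{r.pmal:.1f}",
                    f"{r.ptal:.1f}",
                    "" if r.ph is None else f"{r.ph:.2f}",
                    r.exceeds_50,
                    r.exceeds_75,
                    r.exceeds_100,
                ]
            )
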