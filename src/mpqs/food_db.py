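"""Food composition tables and their harmonization into an amino-acid-annotated database.

A national food-composition table (NEVO-style) carries, per food code,
protein and energy per 100 g but usually no amino-acid data.  Amino-acid
profiles come from foreign tables (keyed by their own identifiers) and are
attached to every food whose protein supplies at least a configurable share
of its energy (default 1 EN%).  When no foreign table carries the food
directly, fallbacks apply in order: the profile of the food's dominant
source protein, the profile of an explicitly mapped comparable product, or a
recipe built from the relative protein contributions of known components.
Profiles are stored internally as mg per g protein, which makes the
scaling-to-native-protein correction implicit; explicit converters to
mg per 100 g food are provided for output.

Protein digestibility is attached per food group as a consumption-frequency
weighted mean of known PDCAAS values within the group.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .config import Config, DEFAULT_CONFIG

# Unit tags for amino-acid vectors.
MG_PER_G_PROTEIN = "mg_per_g_protein"
MG_PER_100G_FOOD = "mg_per_100g_food"
MG_ABSOLUTE = "mg_absolute"
_VALID_UNITS = (MG_PER_G_PROTEIN, MG_PER_100G_FOOD, MG_ABSOLUTE)

PROVENANCES = ("native", "source_protein", "comparable_product", "recipe", "scaled")

#: Protein contents closer than this (g/100 g, relative) are treated as equal
#: when deciding whether a foreign profile had to be rescaled.
_PROTEIN_MATCH_RTOL = 1e-6


class FoodDataError(ValueError):
    """Raised for invalid food-composition data or failed harmonization steps."""


@dataclass(frozen=True)
class EAAVector:
    """Amounts of each essential amino acid, tagged with a unit.

    ``values`` maps EAA name to a non-negative amount.  Arithmetic is only
    defined between vectors with identical unit tags and identical key sets.
    """

    values: Mapping[str, float]
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _VALID_UNITS:
            raise FoodDataError(f"unknown EAA unit tag {self.unit!r}")
        vals = dict(self.values)
        for name, amount in vals.items():
            if not math.isfinite(amount) or amount < 0:
                raise FoodDataError(f"EAA amount for {name!r} must be finite and >= 0, got {amount}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def zeros(cls, eaas: Sequence[str], unit: str) -> "EAAVector":
        return cls({e: 0.0 for e in eaas}, unit)

    def __getitem__(self, eaa: str) -> float:
        return self.values[eaa]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def keys(self):
        return self.values.keys()

    def _check_compatible(self, other: "EAAVector") -> None:
        if self.unit != other.unit:
            raise FoodDataError(f"unit mismatch: {self.unit} vs {other.unit}")
        if set(self.values) != set(other.values):
            raise FoodDataError("EAA key sets differ; vectors are not compatible")

    def __add__(self, other: "EAAVector") -> "EAAVector":
        self._check_compatible(other)
        return EAAVector({e: self.values[e] + other.values[e] for e in self.values}, self.unit)

    def scale(self, factor: float) -> "EAAVector":
        if factor < 0:
            raise FoodDataError("scale factor must be non-negative")
        return EAAVector({e: v * factor for e, v in self.values.items()}, self.unit)

    def with_unit(self, unit: str) -> "EAAVector":
        return EAAVector(self.values, unit)

    def validate_keys(self, eaa_list: Sequence[str]) -> None:
        """Require keys to equal the configured EAA list exactly."""
        if set(self.values) != set(eaa_list):
            missing = sorted(set(eaa_list) - set(self.values))
            extra = sorted(set(self.values) - set(eaa_list))
            raise FoodDataError(
                f"EAA keys do not match configured list (missing={missing}, extra={extra})"
            )


@dataclass(frozen=True)
class FoodItem:
    """One food with composition per 100 g and optional amino-acid annotation."""

    code: str
    name: str
    food_group: str
    protein: float  # g per 100 g
    energy: float   # kcal (or kJ) per 100 g, per Config.energy_unit
    aa_profile: Optional[EAAVector] = None  # mg per g protein
    digestibility: Optional[float] = None   # fraction of absorbable protein, [0, 1]
    provenance: Optional[str] = None
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.code:
            raise FoodDataError("food code must be non-empty")
        if not math.isfinite(self.protein) or self.protein < 0:
            raise FoodDataError(f"{self.code}: protein must be finite and >= 0, got {self.protein}")
        if not math.isfinite(self.energy) or self.energy < 0:
            raise FoodDataError(f"{self.code}: energy must be finite and >= 0, got {self.energy}")
        if self.digestibility is not None and not (0.0 <= self.digestibility <= 1.0):
            raise FoodDataError(
                f"{self.code}: digestibility must lie in [0, 1], got {self.digestibility}"
            )
        if self.aa_profile is not None:
            if self.aa_profile.unit != MG_PER_G_PROTEIN:
                raise FoodDataError(f"{self.code}: aa_profile must be in {MG_PER_G_PROTEIN}")
            if self.provenance is None:
                raise FoodDataError(f"{self.code}: annotated item must record provenance")
        if self.provenance is not None and self.provenance not in PROVENANCES:
            raise FoodDataError(f"{self.code}: unknown provenance {self.provenance!r}")
        object.__setattr__(self, "extras", dict(self.extras))

    @property
    def is_scoreable(self) -> bool:
        return self.aa_profile is not None and self.digestibility is not None


@dataclass
class FoodTable:
    """Collection of FoodItems keyed by unique code."""

    items: dict[str, FoodItem]
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, item in self.items.items():
            if code != item.code:
                raise FoodDataError(f"table key {code!r} does not match item code {item.code!r}")

    @classmethod
    def from_items(cls, items: Iterable[FoodItem], **metadata: object) -> "FoodTable":
        table: dict[str, FoodItem] = {}
        for item in items:
            if item.code in table:
                raise FoodDataError(f"duplicate food code {item.code!r}")
            table[item.code] = item
        return cls(table, dict(metadata))

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, code: str) -> bool:
        return code in self.items

    def __getitem__(self, code: str) -> FoodItem:
        try:
            return self.items[code]
        except KeyError:
            raise FoodDataError(f"unknown food code {code!r}") from None

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self.items.values())

    def replace_item(self, item: FoodItem) -> None:
        self.items[item.code] = item


@dataclass(frozen=True)
class DigestibilityRecord:
    """A known PDCAAS value for one food, with its consumption frequency weight."""

    code: str
    pdcaas: float
    frequency: float
    food_group: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pdcaas <= 1.0):
            raise FoodDataError(f"{self.code}: pdcaas must lie in [0, 1], got {self.pdcaas}")
        if self.frequency < 0:
            raise FoodDataError(f"{self.code}: frequency must be >= 0, got {self.frequency}")


@dataclass(frozen=True)
class ForeignAARecord:
    """Amino-acid data for one food in a foreign source table (per 100 g food)."""

    key: str
    protein: float  # g per 100 g as reported by the foreign source
    aa_per_100g: EAAVector  # mg per 100 g food

    def __post_init__(self) -> None:
        if self.protein < 0:
            raise FoodDataError(f"{self.key}: foreign protein must be >= 0")
        if self.aa_per_100g.unit != MG_PER_100G_FOOD:
            raise FoodDataError(f"{self.key}: foreign AA data must be in {MG_PER_100G_FOOD}")

    def profile_per_g_protein(self) -> EAAVector:
        """Convert to mg per g protein (independent of any native protein value)."""
        if self.protein <= 0:
            raise FoodDataError(f"{self.key}: cannot derive per-protein profile, protein is 0")
        return self.aa_per_100g.scale(1.0 / self.protein).with_unit(MG_PER_G_PROTEIN)


@dataclass
class ForeignAATable:
    """One foreign amino-acid source with a name used in priority ordering."""

    name: str
    records: dict[str, ForeignAARecord]

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def __getitem__(self, key: str) -> ForeignAARecord:
        return self.records[key]


@dataclass(frozen=True)
class TableDialect:
    """Delimited-text layout of a food table: separator and column names."""

    delimiter: str = ","
    code: str = "code"
    name: str = "name"
    food_group: str = "food_group"
    protein: str = "protein"
    energy: str = "energy"
    digestibility: str = "digestibility"
    provenance: str = "provenance"
    aa_prefix: str = "aa_"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.code, self.name, self.food_group, self.protein, self.energy)


DEFAULT_DIALECT = TableDialect()


@dataclass
class RowDiagnostic:
    row: int
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row} (code {self.code!r}): {self.message}"


def _parse_float(raw: str, what: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise FoodDataError(f"malformed numeric for {what}: {raw!r}") from None
    if not math.isfinite(value):
        raise FoodDataError(f"non-finite value for {what}: {raw!r}")
    return value


def read_food_table(
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    config: Config = DEFAULT_CONFIG,
    diagnostics: Optional[list[RowDiagnostic]] = None,
) -> FoodTable:
    """Read a delimited food-composition table.

    Rows with malformed numeric fields are rejected individually and reported
    through ``diagnostics`` (if given); a duplicate code or a missing required
    column aborts the read.
    """
    path = Path(path)
    if not path.exists():
        raise FoodDataError(f"food table not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in dialect.required if c not in header]
        if missing:
            raise FoodDataError(f"missing required columns: {missing}")
        aa_cols = {
            c[len(dialect.aa_prefix):]: c
            for c in header
            if c.startswith(dialect.aa_prefix)
        }
        extra_cols = [
            c for c in header
            if c not in dialect.required
            and c not in (dialect.digestibility, dialect.provenance)
            and not c.startswith(dialect.aa_prefix)
        ]
        items: dict[str, FoodItem] = {}
        for lineno, row in enumerate(reader, start=2):
            code = (row.get(dialect.code) or "").strip()
            try:
                if not code:
                    raise FoodDataError("empty food code")
                if code in items:
                    raise FoodDataError(f"duplicate food code {code!r}")
                protein = _parse_float(row[dialect.protein], "protein")
                energy = _parse_float(row[dialect.energy], "energy")
                digest_raw = (row.get(dialect.digestibility) or "").strip()
                digestibility = _parse_float(digest_raw, "digestibility") if digest_raw else None
                prov_raw = (row.get(dialect.provenance) or "").strip()
                provenance = prov_raw or None
                profile = None
                if aa_cols:
                    raw_vals = {e: (row.get(col) or "").strip() for e, col in aa_cols.items()}
                    if any(raw_vals.values()):
                        profile = EAAVector(
                            {e: _parse_float(v, f"aa {e}") for e, v in raw_vals.items()},
                            MG_PER_G_PROTEIN,
                        )
                        profile.validate_keys(config.eaa_list)
                item = FoodItem(
                    code=code,
                    name=(row.get(dialect.name) or "").strip(),
                    food_group=(row.get(dialect.food_group) or "").strip(),
                    protein=protein,
                    energy=energy,
                    aa_profile=profile,
                    digestibility=digestibility,
                    provenance=provenance,
                    extras={c: row.get(c, "") or "" for c in extra_cols},
                )
            except FoodDataError as exc:
                if "duplicate food code" in str(exc):
                    raise
                if diagnostics is not None:
                    diagnostics.append(RowDiagnostic(lineno, code or "?", str(exc)))
                continue
            items[code] = item
    return FoodTable(items, {"source": str(path)})


def write_food_table(
    table: FoodTable,
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
    config: Config = DEFAULT_CONFIG,
) -> None:
    """Write a food table as delimited text; floats use repr so a round trip
    through :func:`read_food_table` is bit-exact."""
    path = Path(path)
    extra_cols = sorted({c for item in table for c in item.extras})
    header = list(dialect.required) + [dialect.digestibility, dialect.provenance]
    header += [dialect.aa_prefix + e for e in config.eaa_list] + extra_cols
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for item in table:
            row = [
                item.code,
                item.name,
                item.food_group,
                repr(item.protein),
                repr(item.energy),
                "" if item.digestibility is None else repr(item.digestibility),
                item.provenance or "",
            ]
            for e in config.eaa_list:
                row.append("" if item.aa_profile is None else repr(item.aa_profile[e]))
            row += [item.extras.get(c, "") for c in extra_cols]
            writer.writerow(row)


def energy_percent_protein(item: FoodItem, config: Config = DEFAULT_CONFIG) -> Optional[float]:
    """Percentage of the food's energy supplied by protein (EN%).

    Returns ``None`` for a zero-energy food: the EN% is undefined there and
    the annotation filter treats it as below any threshold.
    """
    if item.energy == 0:
        return None
    return 100.0 * item.protein * config.protein_energy_factor / item.energy


def scale_aa_to_native(
    aa_per_100g_foreign: EAAVector,
    protein_foreign: float,
    protein_native: float,
) -> EAAVector:
    """Rescale foreign per-100 g amino-acid amounts to the native protein content.

    When the foreign source reports a different total protein for the "same"
    food, its amino-acid amounts are multiplied by native/foreign protein so
    the profile is consistent with the native composition data.
    """
    if aa_per_100g_foreign.unit != MG_PER_100G_FOOD:
        raise FoodDataError(f"expected {MG_PER_100G_FOOD} input, got {aa_per_100g_foreign.unit}")
    if protein_foreign <= 0:
        raise FoodDataError(f"cannot scale: foreign protein content is {protein_foreign}")
    if protein_native < 0:
        raise FoodDataError("native protein content must be >= 0")
    return aa_per_100g_foreign.scale(protein_native / protein_foreign)


def recipe_aa_profile(
    components: Sequence[tuple[EAAVector, float]],
    config: Config = DEFAULT_CONFIG,
) -> EAAVector:
    """Profile of a composite food as the protein-fraction-weighted mean of its
    components' profiles (all mg per g protein)."""
    if not components:
        raise FoodDataError("recipe must have at least one component")
    total = sum(frac for _, frac in components)
    if any(frac < 0 for _, frac in components):
        raise FoodDataError("recipe protein fractions must be >= 0")
    if abs(total - 1.0) > config.recipe_fraction_tol:
        raise FoodDataError(f"recipe protein fractions sum to {total!r}, expected 1")
    result = EAAVector.zeros(list(components[0][0].keys()), MG_PER_G_PROTEIN)
    for profile, frac in components:
        if profile.unit != MG_PER_G_PROTEIN:
            raise FoodDataError("recipe components must be in mg per g protein")
        result = result + profile.scale(frac)
    return result


def group_digestibility(records: Sequence[DigestibilityRecord]) -> dict[str, float]:
    """Frequency-weighted mean PDCAAS per food group.

    factor(group) = sum(pdcaas * frequency) / sum(frequency) over the group's
    records; every group must carry at least one positive frequency.
    """
    if not records:
        raise FoodDataError("no digestibility records supplied")
    groups: dict[str, list[DigestibilityRecord]] = {}
    for rec in records:
        groups.setdefault(rec.food_group, []).append(rec)
    factors: dict[str, float] = {}
    for group, recs in groups.items():
        wsum = sum(r.frequency for r in recs)
        if wsum <= 0:
            raise FoodDataError(f"food group {group!r} has no record with frequency > 0")
        factors[group] = sum(r.pdcaas * r.frequency for r in recs) / wsum
    return factors


def apply_group_digestibility(table: FoodTable, factors: Mapping[str, float]) -> FoodTable:
    """Assign each item its food group's joint digestibility factor.

    Items of a group absent from ``factors`` are left untouched.
    """
    items = {}
    for item in table:
        if item.food_group in factors:
            items[item.code] = replace(item, digestibility=factors[item.food_group])
        else:
            items[item.code] = item
    return FoodTable(items, dict(table.metadata))


@dataclass(frozen=True)
class RecipeComponent:
    """One component of a recipe: where its profile comes from and the share
    of the recipe's protein it contributes."""

    foreign_key: str
    protein_fraction: float


@dataclass
class AnnotationReport:
    """Outcome of the amino-acid annotation pass over a food table."""

    annotated: list[str] = field(default_factory=list)
    below_threshold: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unresolved


def _lookup_foreign(sources: Sequence[ForeignAATable], key: str) -> Optional[ForeignAARecord]:
    for src in sources:
        if key in src:
            return src[key]
    return None


def annotate_amino_acids(
    table: FoodTable,
    sources: Sequence[ForeignAATable],
    source_protein_map: Optional[Mapping[str, str]] = None,
    comparable_map: Optional[Mapping[str, str]] = None,
    recipes: Optional[Mapping[str, Sequence[RecipeComponent]]] = None,
    config: Config = DEFAULT_CONFIG,
) -> tuple[FoodTable, AnnotationReport]:
    """Attach amino-acid profiles to every food at or above the EN% threshold.

    Resolution order per food: (a) its own code in the foreign sources, taken
    in their listed priority order; (b) the mapped source-protein key;
    (c) the mapped comparable-product key; (d) a recipe over foreign keys.
    A food whose foreign protein content differs from the native value gets
    provenance ``scaled`` — storing profiles as mg per g protein makes the
    rescaling implicit.  Foods above the threshold with no resolution path
    are listed in the report, never silently dropped.
    """
    source_protein_map = source_protein_map or {}
    comparable_map = comparable_map or {}
    recipes = recipes or {}
    report = AnnotationReport()
    items: dict[str, FoodItem] = {}

    for item in table:
        epp = energy_percent_protein(item, config)
        if epp is None or epp < config.en_threshold:
            report.below_threshold.append(item.code)
            items[item.code] = item
            continue
        if item.aa_profile is not None:
            report.annotated.append(item.code)
            items[item.code] = item
            continue

        profile: Optional[EAAVector] = None
        provenance: Optional[str] = None

        rec = _lookup_foreign(sources, item.code)
        if rec is not None:
            profile = rec.profile_per_g_protein()
            scaled = abs(rec.protein - item.protein) > _PROTEIN_MATCH_RTOL * max(
                rec.protein, item.protein, 1.0
            )
            provenance = "scaled" if scaled else "native"
        if profile is None and item.code in source_protein_map:
            rec = _lookup_foreign(sources, source_protein_map[item.code])
            if rec is not None:
                profile = rec.profile_per_g_protein()
                provenance = "source_protein"
        if profile is None and item.code in comparable_map:
            rec = _lookup_foreign(sources, comparable_map[item.code])
            if rec is not None:
                profile = rec.profile_per_g_protein()
                provenance = "comparable_product"
        if profile is None and item.code in recipes:
            components = []
            complete = True
            for comp in recipes[item.code]:
                comp_rec = _lookup_foreign(sources, comp.foreign_key)
                if comp_rec is None:
                    complete = False
                    break
                components.append((comp_rec.profile_per_g_protein(), comp.protein_fraction))
            if complete and components:
                profile = recipe_aa_profile(components, config)
                provenance = "recipe"

        if profile is None:
            report.unresolved.append(item.code)
            items[item.code] = item
            continue
        profile.validate_keys(config.eaa_list)
        items[item.code] = replace(item, aa_profile=profile, provenance=provenance)
        report.annotated.append(item.code)

    return FoodTable(items, dict(table.metadata)), report


def read_foreign_aa_table(
    path: str | Path,
    name: str,
    delimiter: str = ",",
    config: Config = DEFAULT_CONFIG,
) -> ForeignAATable:
    """Read a foreign amino-acid source: key, protein (g/100 g), then one
    ``aa_<name>`` column per configured EAA in mg per 100 g food."""
    path = Path(path)
    if not path.exists():
        raise FoodDataError(f"foreign AA table not found: {path}")
    records: dict[str, ForeignAARecord] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for required in ("key", "protein"):
            if required not in header:
                raise FoodDataError(f"{name}: missing column {required!r}")
        for row in reader:
            key = row["key"].strip()
            if key in records:
                raise FoodDataError(f"{name}: duplicate key {key!r}")
            protein = _parse_float(row["protein"], "protein")
            values = {
                e: _parse_float(row.get(f"aa_{e}", ""), f"aa {e}") for e in config.eaa_list
            }
            records[key] = ForeignAARecord(
                key=key,
                protein=protein,
                aa_per_100g=EAAVector(values, MG_PER_100G_FOOD),
            )
    return ForeignAATable(name, records)


def read_digestibility_records(
    path: str | Path, delimiter: str = ","
) -> list[DigestibilityRecord]:
    """Read PDCAAS records: columns code, food_group, pdcaas, frequency."""
    path = Path(path)
    if not path.exists():
        raise FoodDataError(f"digestibility table not found: {path}")
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for row in reader:
            records.append(
                DigestibilityRecord(
                    code=row["code"].strip(),
                    pdcaas=_parse_float(row["pdcaas"], "pdcaas"),
                    frequency=_parse_float(row["frequency"], "frequency"),
                    food_group=row["food_group"].strip(),
                )
            )
    return records
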