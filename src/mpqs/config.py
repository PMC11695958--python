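"""Global configuration for scoring and database construction.

The essential-amino-acid (EAA) list is configurable because food tables
differ in whether they pool the sulfur amino acids (methionine + cysteine)
and the aromatic amino acids (phenylalanine + tyrosine).  The default list
follows the FAO scoring-pattern convention with both pairs pooled:

    his, ile, leu, lys, saa (Met+Cys), aaa (Phe+Tyr), thr, trp, val
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

DEFAULT_EAA_LIST: tuple[str, ...] = (
    "his", "ile", "leu", "lys", "saa", "aaa", "thr", "trp", "val",
)

#: Atwater energy factor for protein, kcal per gram.
KCAL_PER_G_PROTEIN = 4.0
#: Energy factor for protein in kilojoules per gram.
KJ_PER_G_PROTEIN = 17.0


class ConfigError(ValueError):
    """Raised for an invalid or inconsistent configuration."""


@dataclass(frozen=True)
class Config:
    """Settings shared across database construction and scoring.

    Parameters
    ----------
    eaa_list:
        Ordered names of the essential amino acids carried by every profile,
        threshold and score.  Order matters: it breaks ties when reporting
        the limiting amino acid.
    kcal_per_g_protein, kj_per_g_protein:
        Protein energy-conversion factors.  Which one applies is selected by
        ``energy_unit``, matching the unit of the food table's energy column.
    energy_unit:
        ``"kcal"`` or ``"kj"``.
    en_threshold:
        Minimum energy-percent protein (EN%) a food must reach before it is
        annotated with an amino-acid profile during database construction.
    recipe_fraction_tol:
        Tolerance on protein fractions summing to 1 in recipe construction.
    day_aggregate:
        How per-meal scores combine into a whole-day figure: ``"mean"``
        (default) or ``"min"``.
    score_variant:
        ``"limiting"`` (default): 100 x the capped minimum intake/threshold
        ratio.  ``"capped_mean"``: 100 x the mean of capped ratios, offered
        for sensitivity analysis only; it does not pin the score to 0 when a
        single amino acid is absent, and the proportion-adjustment linear
        program is only valid for the limiting variant.
    """

    eaa_list: tuple[str, ...] = DEFAULT_EAA_LIST
    kcal_per_g_protein: float = KCAL_PER_G_PROTEIN
    kj_per_g_protein: float = KJ_PER_G_PROTEIN
    energy_unit: str = "kcal"
    en_threshold: float = 1.0
    recipe_fraction_tol: float = 1e-6
    day_aggregate: str = "mean"
    score_variant: str = "limiting"

    def __post_init__(self) -> None:
        if not self.eaa_list:
            raise ConfigError("eaa_list must not be empty")
        if len(set(self.eaa_list)) != len(self.eaa_list):
            raise ConfigError("eaa_list contains duplicate names")
        if self.energy_unit not in ("kcal", "kj"):
            raise ConfigError(f"energy_unit must be 'kcal' or 'kj', got {self.energy_unit!r}")
        if self.kcal_per_g_protein <= 0 or self.kj_per_g_protein <= 0:
            raise ConfigError("protein energy factors must be positive")
        if self.en_threshold < 0:
            raise ConfigError("en_threshold must be non-negative")
        if self.day_aggregate not in ("mean", "min"):
            raise ConfigError(f"day_aggregate must be 'mean' or 'min', got {self.day_aggregate!r}")
        if self.score_variant not in ("limiting", "capped_mean"):
            raise ConfigError(
                f"score_variant must be 'limiting' or 'capped_mean', got {self.score_variant!r}"
            )

    @property
    def protein_energy_factor(self) -> float:
        """Energy per gram of protein in the configured energy unit."""
        return self.kcal_per_g_protein if self.energy_unit == "kcal" else self.kj_per_g_protein

    def with_overrides(self, **kwargs: Any) -> "Config":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "Config":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        clean = dict(data)
        if "eaa_list" in clean:
            clean["eaa_list"] = tuple(clean["eaa_list"])
        return cls(**clean)


DEFAULT_CONFIG = Config()
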