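"""Participant diets from food-frequency records.

A food-frequency questionnaire reports grams/day across a hierarchy of
food items.  To turn that into exchange-flux constraints for community
modeling, the pipeline

1. maps food compounds to exchange metabolites and converts grams/day to
   mmol per gram microbiota per day (dividing by the assumed 200 g of
   colonic microbiota),
2. augments nitrogen-rich compounds that questionnaires under-report:
   purines/pyrimidines (pyrimidines are extrapolated from purines:
   thymidine+uracil together match the adenosine class, cytosine matches
   the guanosine class) and polyamines, with ornithine extrapolated at
   3.28x the summed polyamine content for food items lacking measured
   values,
3. scales every amount so each participant's diet carries the common
   reference caloric value (8799 kJ/day),
4. blends the participant diet 90/10 with a reference "Western" diet so
   that compounds missing from the questionnaire do not artificially
   starve individual strains; a handful of growth-limiting minerals keep
   their reference values outright, and
5. optionally discounts each compound by its small-intestinal absorption
   before the remainder reaches the colonic community.

All steps are linear and preserve non-negativity; a provenance log
records the compound and caloric totals after each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FoodRecord",
    "CompoundInfo",
    "CompoundMap",
    "DietSpec",
    "AugmentationTable",
    "DietError",
    "MICROBIOTA_MASS_G",
    "TARGET_KJ",
    "ORNITHINE_FACTOR",
    "RETAINED_COMPOUNDS",
    "mass_to_flux",
    "normalize_caloric",
    "augment_nucleotides",
    "augment_polyamines",
    "blend_with_reference",
    "adjust_absorption",
    "build_participant_diet",
    "read_food_records",
    "read_compound_map",
    "read_augmentation_table",
    "read_diet",
    "write_diet",
]

#: assumed total wet mass of the colonic microbiota (grams)
MICROBIOTA_MASS_G = 200.0
#: reference caloric value all participant diets are normalized to (kJ/day)
TARGET_KJ = 8799.0
#: median ornithine : total-polyamine molar ratio used for extrapolation
ORNITHINE_FACTOR = 3.28
#: minerals whose reference-diet inflow is retained unchanged during blending
RETAINED_COMPOUNDS = ("pi", "cu2", "mn2", "zn2", "fe3", "cl")


class DietError(ValueError):
    pass


@dataclass
class FoodRecord:
    participant_id: str
    food_item: str
    group_path: tuple[str, ...]
    grams_per_day: float

    def __post_init__(self) -> None:
        if self.grams_per_day < 0:
            raise DietError(
                f"{self.participant_id}/{self.food_item}: negative grams/day"
            )


@dataclass
class CompoundInfo:
    exchange_metabolite_id: str
    molecular_weight: float  # g/mol
    kj_per_gram: float = 0.0

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise DietError(
                f"{self.exchange_metabolite_id}: molecular weight must be > 0"
            )
        if self.kj_per_gram < 0:
            raise DietError(f"{self.exchange_metabolite_id}: negative kJ/gram")


CompoundMap = dict[str, CompoundInfo]


@dataclass
class DietSpec:
    """Exchange amounts (mmol/gM/d) plus the diet's caloric value (kJ/day)."""

    participant_id: str
    amounts: dict[str, float] = field(default_factory=dict)
    caloric_value_kj: float = 0.0

    def __post_init__(self) -> None:
        bad = {c: a for c, a in self.amounts.items() if a < 0}
        if bad:
            raise DietError(f"negative diet amounts: {bad}")
        if self.caloric_value_kj < 0:
            raise DietError("negative caloric value")

    def copy(self) -> "DietSpec":
        return replace(self, amounts=dict(self.amounts))

    def total(self) -> float:
        return float(sum(self.amounts.values()))


@dataclass
class AugmentationTable:
    """Per-food-item compound contents in mmol per gram of food.

    ``contents[food_item][compound]`` may be missing for individual items;
    lookups then fall back to the mean over the item's food group, walking
    the hierarchy from the most specific group outward.
    """

    contents: dict[str, dict[str, float]]
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, row in self.contents.items():
            for compound, val in row.items():
                if val < 0:
                    raise DietError(f"{item}/{compound}: negative content")

    def lookup(self, food_item: str, compound: str, group_path: Sequence[str]) -> float:
        row = self.contents.get(food_item)
        if row is not None and compound in row:
            return row[compound]
        # group-average imputation, most specific group first
        for depth in range(len(group_path), 0, -1):
            prefix = tuple(group_path[:depth])
            vals = [
                r[compound]
                for item, r in self.contents.items()
                if compound in r and self.groups.get(item, ())[:depth] == prefix
            ]
            if vals:
                return sum(vals) / len(vals)
        raise DietError(
            f"no {compound!r} data for food item {food_item!r} at any level of "
            f"group {'/'.join(group_path) or '<root>'}"
        )


# ------------------------------------------------------------------ steps

def mass_to_flux(
    grams_per_day: float, molecular_weight: float, microbiota_mass: float = MICROBIOTA_MASS_G
) -> float:
    """Convert grams/day of a compound to mmol/gM/d.

    grams -> mol via the molecular weight, mol -> mmol, then divided by
    the microbiota mass so the flux is per gram of microbiota.
    """
    if molecular_weight <= 0:
        raise DietError(f"molecular weight must be > 0, got {molecular_weight}")
    if microbiota_mass <= 0:
        raise DietError(f"microbiota mass must be > 0, got {microbiota_mass}")
    return grams_per_day / molecular_weight * 1000.0 / microbiota_mass


def normalize_caloric(diet: DietSpec, target_kj: float = TARGET_KJ) -> DietSpec:
    """Scale all amounts so the diet carries ``target_kj`` kJ/day."""
    if diet.caloric_value_kj <= 0:
        raise DietError(
            f"participant {diet.participant_id}: caloric value must be > 0 "
            f"to normalize, got {diet.caloric_value_kj}"
        )
    factor = target_kj / diet.caloric_value_kj
    return DietSpec(
        participant_id=diet.participant_id,
        amounts={c: a * factor for c, a in diet.amounts.items()},
        caloric_value_kj=target_kj,
    )


_PURINE_SPLIT = {
    # adenosine-class purines split 50/50 across the two molecular species
    "adenosine": ("adn", "dad_2"),
    "guanosine": ("gsn", "dgsn"),
}
_PYRIMIDINE_FROM_PURINE = {
    # thymidine + uracil together equal the adenosine class;
    # cytosine equals the guanosine class
    "adenosine": ("thymd", "ura"),
    "guanosine": ("csn",),
}
_POLYAMINES = ("cadaverine", "putrescine", "spermidine", "spermine")
_POLYAMINE_EXCHANGE = {
    "cadaverine": "15dap",
    "putrescine": "ptrc",
    "spermidine": "spmd",
    "spermine": "sprm",
}


def augment_nucleotides(
    diet: DietSpec,
    food_records: Iterable[FoodRecord],
    table: AugmentationTable,
    pyrimidine_split: float = 0.5,
    microbiota_mass: float = MICROBIOTA_MASS_G,
) -> DietSpec:
    """Add purines from food contents and extrapolate pyrimidines.

    The purine classes (adenosine-type, guanosine-type) are taken from the
    augmentation table (mmol per gram food, group-average imputed when an
    item is missing) and split 50/50 across their ribo/deoxyribo species.
    Pyrimidines are extrapolated: thymidine + uracil together total the
    adenosine class (``pyrimidine_split`` is the thymidine share) and
    cytosine equals the guanosine class.
    """
    if not 0 <= pyrimidine_split <= 1:
        raise DietError(f"pyrimidine_split outside [0,1]: {pyrimidine_split}")
    out = diet.copy()
    totals = {"adenosine": 0.0, "guanosine": 0.0}
    for rec in food_records:
        for purine in totals:
            content = table.lookup(rec.food_item, purine, rec.group_path)
            totals[purine] += content * rec.grams_per_day / microbiota_mass
    for purine, (ribo, deoxy) in _PURINE_SPLIT.items():
        amount = totals[purine]
        out.amounts[ribo] = out.amounts.get(ribo, 0.0) + amount / 2
        out.amounts[deoxy] = out.amounts.get(deoxy, 0.0) + amount / 2
    thymd, ura = _PYRIMIDINE_FROM_PURINE["adenosine"]
    out.amounts[thymd] = out.amounts.get(thymd, 0.0) + totals["adenosine"] * pyrimidine_split
    out.amounts[ura] = out.amounts.get(ura, 0.0) + totals["adenosine"] * (1 - pyrimidine_split)
    (csn,) = _PYRIMIDINE_FROM_PURINE["guanosine"]
    out.amounts[csn] = out.amounts.get(csn, 0.0) + totals["guanosine"]
    return out


def augment_polyamines(
    diet: DietSpec,
    food_records: Iterable[FoodRecord],
    table: AugmentationTable,
    ornithine_factor: float = ORNITHINE_FACTOR,
    microbiota_mass: float = MICROBIOTA_MASS_G,
) -> DietSpec:
    """Add polyamines from food contents; extrapolate missing ornithine.

    For a food item with a measured ornithine content that value is used;
    otherwise ornithine is taken as ``ornithine_factor`` times the item's
    total polyamine content (cadaverine + putrescine + spermidine +
    spermine).
    """
    out = diet.copy()
    for rec in food_records:
        scale = rec.grams_per_day / microbiota_mass
        poly_total = 0.0
        for compound in _POLYAMINES:
            content = table.lookup(rec.food_item, compound, rec.group_path)
            poly_total += content
            key = _POLYAMINE_EXCHANGE[compound]
            out.amounts[key] = out.amounts.get(key, 0.0) + content * scale
        row = table.contents.get(rec.food_item, {})
        if "ornithine" in row:
            orn = row["ornithine"]
        else:
            orn = ornithine_factor * poly_total
        out.amounts["orn"] = out.amounts.get("orn", 0.0) + orn * scale
    return out


def blend_with_reference(
    diet: DietSpec,
    reference: DietSpec | Mapping[str, float],
    participant_fraction: float = 0.9,
    retained_compounds: Sequence[str] = RETAINED_COMPOUNDS,
) -> DietSpec:
    """Mix the participant diet with the reference (Western) diet.

    Each compound becomes ``f*participant + (1-f)*reference`` except the
    retained minerals, which keep the reference amount unchanged.
    """
    if not 0 <= participant_fraction <= 1:
        raise DietError(f"participant_fraction must be in [0,1]: {participant_fraction}")
    ref_amounts: Mapping[str, float] = getattr(reference, "amounts", reference)
    retained = set(retained_compounds)
    out_amounts: dict[str, float] = {}
    for compound in set(diet.amounts) | set(ref_amounts):
        p = diet.amounts.get(compound, 0.0)
        r = ref_amounts.get(compound, 0.0)
        if compound in retained:
            out_amounts[compound] = r
        else:
            out_amounts[compound] = participant_fraction * p + (1 - participant_fraction) * r
    return DietSpec(
        participant_id=diet.participant_id,
        amounts=out_amounts,
        caloric_value_kj=diet.caloric_value_kj,
    )


def adjust_absorption(
    diet: DietSpec, absorbed_fraction: Mapping[str, float]
) -> DietSpec:
    """Discount each compound by its small-intestinal absorption."""
    for compound, frac in absorbed_fraction.items():
        if not 0 <= frac <= 1:
            raise DietError(f"absorbed fraction for {compound!r} outside [0,1]: {frac}")
    out = diet.copy()
    for compound, frac in absorbed_fraction.items():
        if compound in out.amounts:
            out.amounts[compound] *= 1 - frac
    return out


def build_participant_diet(
    records: Sequence[FoodRecord],
    compound_intake: Mapping[str, float],
    compound_map: CompoundMap,
    purine_table: AugmentationTable,
    polyamine_table: AugmentationTable,
    reference: DietSpec | Mapping[str, float],
    participant_fraction: float = 0.9,
    retained_compounds: Sequence[str] = RETAINED_COMPOUNDS,
    target_kj: float = TARGET_KJ,
    absorbed_fraction: Mapping[str, float] | None = None,
    microbiota_mass: float = MICROBIOTA_MASS_G,
) -> tuple[DietSpec, list[dict]]:
    """Full diet pipeline for one participant.

    ``compound_intake`` maps food compounds (keys of ``compound_map``) to
    grams/day; ``records`` carry the food-item masses used for the
    nitrogen-compound augmentation.  Pipeline order: map & convert ->
    augment nucleotides -> augment polyamines -> caloric normalization ->
    reference blending [-> absorption adjustment].  Returns the diet and a
    provenance log with per-step totals.
    """
    participant_ids = {r.participant_id for r in records}
    if len(participant_ids) > 1:
        raise DietError(f"records span several participants: {sorted(participant_ids)}")
    pid = participant_ids.pop() if participant_ids else "participant"

    amounts: dict[str, float] = {}
    caloric = 0.0
    for compound, grams in compound_intake.items():
        info = compound_map.get(compound)
        if info is None:
            raise DietError(f"compound {compound!r} missing from the compound map")
        key = info.exchange_metabolite_id
        amounts[key] = amounts.get(key, 0.0) + mass_to_flux(
            grams, info.molecular_weight, microbiota_mass
        )
        caloric += grams * info.kj_per_gram
    diet = DietSpec(participant_id=pid, amounts=amounts, caloric_value_kj=caloric)

    log: list[dict] = []

    def _log(step: str, d: DietSpec) -> None:
        log.append(
            {"step": step, "total_mmol_per_gM_d": d.total(), "caloric_kj": d.caloric_value_kj}
        )

    _log("mapped", diet)
    diet = augment_nucleotides(diet, records, purine_table, microbiota_mass=microbiota_mass)
    _log("nucleotides", diet)
    diet = augment_polyamines(diet, records, polyamine_table, microbiota_mass=microbiota_mass)
    _log("polyamines", diet)
    diet = normalize_caloric(diet, target_kj=target_kj)
    _log("caloric_normalized", diet)
    diet = blend_with_reference(
        diet, reference, participant_fraction=participant_fraction,
        retained_compounds=retained_compounds,
    )
    _log("blended", diet)
    if absorbed_fraction is not None:
        diet = adjust_absorption(diet, absorbed_fraction)
        _log("absorption_adjusted", diet)
    return diet, log


# -------------------------------------------------------------------- I/O

def read_food_records(path: str | Path) -> list[FoodRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"participant_id", "food_item", "group_path", "grams_per_day"}
    missing = required - set(df.columns)
    if missing:
        raise DietError(f"{path}: missing columns {sorted(missing)}")
    return [
        FoodRecord(
            participant_id=str(r.participant_id),
            food_item=str(r.food_item),
            group_path=tuple(str(r.group_path).split("/")),
            grams_per_day=float(r.grams_per_day),
        )
        for r in df.itertuples()
    ]


def read_compound_map(path: str | Path) -> CompoundMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r.compound): CompoundInfo(
            exchange_metabolite_id=str(r.exchange_metabolite_id),
            molecular_weight=float(r.molecular_weight),
            kj_per_gram=float(getattr(r, "kj_per_gram", 0.0)),
        )
        for r in df.itertuples()
    }


def read_augmentation_table(path: str | Path) -> AugmentationTable:
    """TSV with columns food_item, group_path, then one column per compound.

    Empty cells mean "not measured" and trigger group-average imputation.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    compounds = [c for c in df.columns if c not in ("food_item", "group_path")]
    contents: dict[str, dict[str, float]] = {}
    groups: dict[str, tuple[str, ...]] = {}
    for r in df.itertuples():
        row = {}
        for compound in compounds:
            val = getattr(r, compound)
            if pd.notna(val):
                row[compound] = float(val)
        contents[str(r.food_item)] = row
        groups[str(r.food_item)] = tuple(str(r.group_path).split("/"))
    return AugmentationTable(contents=contents, groups=groups)


def read_diet(path: str | Path, participant_id: str = "") -> DietSpec:
    df = pd.read_csv(path, sep="\t", comment="#")
    caloric = 0.0
    amounts: dict[str, float] = {}
    for r in df.itertuples():
        amounts[str(r.compound)] = float(r.amount)
    return DietSpec(
        participant_id=participant_id or Path(path).stem, amounts=amounts,
        caloric_value_kj=caloric,
    )


def write_diet(diet: DietSpec, path: str | Path, options: Mapping | None = None) -> None:
    lines = [f"# participant: {diet.participant_id}"]
    lines.append(f"# caloric_value_kj: {diet.caloric_value_kj}")
    for key, val in (options or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append("compound\tamount")
    for compound in sorted(diet.amounts):
        lines.append(f"{compound}\t{diet.amounts[compound]!r}")
    Path(path).write_text("\n".join(lines) + "\n")
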