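"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a single master seed: substreams
are derived from fixed per-generator labels, so adding a generator never
shifts another generator's stream.

What is emulated (structurally, not biochemically):

* ``make_toy_models`` — a strain panel in which a configurable subset
  carries the arginine -> agmatine route (arginine uptake, cytosolic
  decarboxylase, agmatine export and outflow) next to a glucose-fueled
  biomass core; plus a nitrogen-gated family where the achievable
  agmatine flux is proportional to the number of transferable nitrogen
  atoms of the fed compound, and a cross-feeding pair in which one
  strain secretes arginine that only the other can decarboxylate.
* ``make_cohort`` — Dirichlet-distributed relative-abundance profiles;
  in the "treated" group the producer strains' concentration parameters
  are multiplied by the effect size, planting higher producer abundance.
* ``make_ffq`` — hierarchical food-frequency records with a compound
  map, purine/polyamine content tables (with gaps that exercise
  group-average imputation) and a reference diet.
* ``make_screen`` — logistic growth curves where the drug lowers the
  carrying capacity and planted nutrients rescue it, log-normal per-worm
  reporter intensities, and ``make_interaction_design``, the long-format
  log2-response table used for the interaction-model null/power
  simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AbundanceProfile
from .core import MetabolicModel, Metabolite, Reaction, ReactionKind
from .diet import AugmentationTable, CompoundInfo, DietSpec, FoodRecord
from .screen import GrowthCurve, WormIntensitySet

__all__ = [
    "SimulationConfig",
    "make_toy_models",
    "make_producer_model",
    "make_nonproducer_model",
    "make_nitrogen_gated_model",
    "make_crossfeeding_pair",
    "make_random_network",
    "make_cohort",
    "make_ffq",
    "make_screen",
    "make_interaction_design",
    "COHORT_DIET",
    "COHORT_COUPLING_C",
]

_STREAM = {"models": 11, "cohort": 23, "ffq": 37, "screen": 41, "networks": 53}

#: diet fed to every synthetic community (mmol/gM/d): ample glucose for
#: biomass and ample arginine so that flux-biomass coupling, not substrate,
#: limits agmatine production
COHORT_DIET = {"glc": 10.0, "arg": 20.0, "nh4": 5.0}
#: coupling strength used for the synthetic cohort; weak enough that the
#: coupling bound c*f_k*v_biomass is the binding constraint, making community
#: capacity proportional to aggregate producer abundance (the planted signal)
COHORT_COUPLING_C = 10.0


@dataclass
class SimulationConfig:
    seed: int = 0
    # strain panel / cohort
    n_strains: int = 10
    producer_fraction: float = 0.4
    n_participants: int = 30          # per group
    effect_size: float = 3.0          # multiplier on producer Dirichlet weight
    # diet template
    diet_glc: float = 10.0
    diet_arg: float = 20.0
    # screen design
    n_nutrients: int = 337
    n_replicates: int = 4
    sigma: float = 0.2                # sd of log2 responses
    n_planted: int = 30
    planted_effect: float = 1.0       # log2 interaction magnitude
    drug_effect: float = -1.0         # log2 effect of drug on growth
    # worm reporter
    worms_per_well: int = 10
    worm_drug_shift: float = 1.0      # log2 upshift of reporter under drug

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_participants < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.producer_fraction <= 1:
            raise ValueError("producer_fraction must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


# ----------------------------------------------------------------- models

def _biomass_core(model: MetabolicModel) -> None:
    """Glucose uptake -> biomass, shared by every toy strain."""
    for mid, comp in (("glc_e", "e"), ("glc_c", "c"), ("biomass_c", "c")):
        model.add_metabolite(Metabolite(id=mid, compartment=comp))
    model.add_reaction(Reaction("EX_glc", {"glc_e": -1.0}, kind=ReactionKind.EXCHANGE))
    model.add_reaction(Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0,
                                ReactionKind.TRANSPORT))
    model.add_reaction(
        Reaction("BIOMASS", {"glc_c": -1.0, "biomass_c": 1.0}, 0.0, 1000.0,
                 ReactionKind.BIOMASS)
    )
    model.add_reaction(
        Reaction("BIOMASS_SINK", {"biomass_c": -1.0}, 0.0, 1000.0, ReactionKind.OUTFLOW)
    )
    model.biomass_reaction_id = "BIOMASS"


def make_producer_model(
    strain_id: str,
    cap: float = 1000.0,
    refined: bool = True,
    genus: str = "Escherichia",
    species: str = "coli",
) -> MetabolicModel:
    """A strain carrying the arginine -> agmatine route.

    ``cap`` bounds the arginine importer, setting the strain's intrinsic
    production ceiling.  With ``refined=False`` the agmatine exporter and
    outflow are left off, as in a draft reconstruction before
    homology-guided refinement.
    """
    m = MetabolicModel(id=strain_id, genus=genus, species=species)
    _biomass_core(m)
    for mid, comp in (
        ("arg_e", "e"), ("arg_c", "c"), ("agm_c", "c"), ("agm_e", "e"),
        ("co2_c", "c"), ("co2_e", "e"),
    ):
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction("EX_arg", {"arg_e": -1.0}, kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("ARGt", {"arg_e": -1.0, "arg_c": 1.0}, 0.0, cap,
                            ReactionKind.TRANSPORT))
    m.add_reaction(
        Reaction("ARGDC", {"arg_c": -1.0, "agm_c": 1.0, "co2_c": 1.0}, 0.0, 1000.0,
                 ReactionKind.INTERNAL, name="arginine decarboxylase")
    )
    m.add_reaction(Reaction("CO2t", {"co2_c": -1.0, "co2_e": 1.0}, 0.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("EX_co2", {"co2_e": -1.0}, kind=ReactionKind.EXCHANGE))
    if refined:
        m.add_reaction(Reaction("AGMt", {"agm_c": -1.0, "agm_e": 1.0}, -1000.0, 1000.0,
                                ReactionKind.TRANSPORT))
        m.add_reaction(Reaction("EX_agm", {"agm_e": -1.0}, kind=ReactionKind.EXCHANGE))
        m.add_reaction(Reaction("AGM_OUTFLOW", {"agm_e": -1.0}, 0.0, 1000.0,
                                ReactionKind.OUTFLOW))
    m.validate()
    return m


def make_nonproducer_model(
    strain_id: str, genus: str = "Faecalibacterium", species: str = "prausnitzii"
) -> MetabolicModel:
    m = MetabolicModel(id=strain_id, genus=genus, species=species)
    _biomass_core(m)
    m.validate()
    return m


def make_nitrogen_gated_model(
    strain_id: str = "N_gated",
    compounds: dict[str, int] | None = None,
    nitrogen_per_agmatine: int = 4,
) -> MetabolicModel:
    """A strain whose agmatine output is gated by transferable nitrogen.

    ``compounds`` maps compound name -> number of transferable nitrogen
    atoms (0 marks a sugar-type, carbon-only compound).  Each compound
    gets an exchange, a transporter and a deamination reaction releasing
    its nitrogen; agmatine synthesis consumes ``nitrogen_per_agmatine``
    nitrogen units (agmatine carries four N), so capacity steps with the
    nitrogen content of the fed compound.
    """
    compounds = compounds if compounds is not None else {
        "sugarX": 0, "n1cmp": 1, "n2cmp": 2, "n3cmp": 3, "n4cmp": 4,
    }
    m = MetabolicModel(id=strain_id, genus="Escherichia", species="coli")
    _biomass_core(m)
    for mid, comp in (
        ("nh4_e", "e"), ("nh4_c", "c"), ("agm_c", "c"), ("agm_e", "e"),
    ):
        m.add_metabolite(Metabolite(id=mid, compartment=comp))
    m.add_reaction(Reaction("EX_nh4", {"nh4_e": -1.0}, kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("NH4t", {"nh4_e": -1.0, "nh4_c": 1.0}, 0.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(
        Reaction(
            "AGMSYN", {"nh4_c": -float(nitrogen_per_agmatine), "agm_c": 1.0},
            0.0, 1000.0, ReactionKind.INTERNAL, name="agmatine synthesis from nitrogen pool",
        )
    )
    m.add_reaction(Reaction("AGMt", {"agm_c": -1.0, "agm_e": 1.0}, -1000.0, 1000.0,
                            ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("EX_agm", {"agm_e": -1.0}, kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("AGM_OUTFLOW", {"agm_e": -1.0}, 0.0, 1000.0,
                            ReactionKind.OUTFLOW))
    for name, n_atoms in compounds.items():
        e, c = f"{name}_e", f"{name}_c"
        m.add_metabolite(Metabolite(id=e, compartment="e"))
        m.add_metabolite(Metabolite(id=c, compartment="c"))
        m.add_reaction(Reaction(f"EX_{name}", {e: -1.0}, kind=ReactionKind.EXCHANGE))
        m.add_reaction(Reaction(f"{name}t", {e: -1.0, c: 1.0}, 0.0, 1000.0,
                                ReactionKind.TRANSPORT))
        if n_atoms > 0:
            m.add_reaction(
                Reaction(f"DEAM_{name}", {c: -1.0, "nh4_c": float(n_atoms)},
                         0.0, 1000.0, ReactionKind.INTERNAL)
            )
        else:
            # sugar: carbon skeleton feeds glycolysis, no nitrogen released
            m.add_reaction(
                Reaction(f"GLYC_{name}", {c: -1.0, "glc_c": 1.0}, 0.0, 1000.0,
                         ReactionKind.INTERNAL)
            )
    m.validate()
    return m


def make_crossfeeding_pair() -> dict[str, MetabolicModel]:
    """Two strains that only jointly produce agmatine.

    The feeder synthesizes and exports arginine from glucose but cannot
    decarboxylate it; the converter decarboxylates arginine but cannot
    make it.  On a glucose-only diet each alone has capacity 0 while the
    community is productive through lumen cross-feeding.
    """
    feeder = MetabolicModel(id="Feeder", genus="Bacteroides", species="uniformis")
    _biomass_core(feeder)
    for mid, comp in (("arg_c", "c"), ("arg_e", "e")):
        feeder.add_metabolite(Metabolite(id=mid, compartment=comp))
    feeder.add_reaction(
        Reaction("ARGSYN", {"glc_c": -1.0, "arg_c": 1.0}, 0.0, 1000.0,
                 ReactionKind.INTERNAL, name="arginine biosynthesis")
    )
    feeder.add_reaction(Reaction("ARGt", {"arg_c": -1.0, "arg_e": 1.0}, -1000.0, 1000.0,
                                 ReactionKind.TRANSPORT))
    feeder.add_reaction(Reaction("EX_arg", {"arg_e": -1.0}, kind=ReactionKind.EXCHANGE))
    feeder.validate()

    converter = make_producer_model(
        "Converter", cap=1000.0, refined=True, genus="Escherichia", species="coli"
    )
    return {"Feeder": feeder, "Converter": converter}


def make_toy_models(config: SimulationConfig, refined: bool = True) -> dict[str, MetabolicModel]:
    """The synthetic strain panel: producers (with intrinsic caps drawn
    from the model stream) and non-producers."""
    rng = config.rng("models")
    n_producers = round(config.n_strains * config.producer_fraction)
    models: dict[str, MetabolicModel] = {}
    for i in range(config.n_strains):
        if i < n_producers:
            cap = float(rng.uniform(2.0, 10.0))
            models[f"P{i:03d}"] = make_producer_model(
                f"P{i:03d}", cap=cap, refined=refined,
                genus="Escherichia", species=f"sp{i % 2}",
            )
        else:
            models[f"N{i:03d}"] = make_nonproducer_model(
                f"N{i:03d}", genus="Faecalibacterium", species=f"sp{i % 3}"
            )
    return models


def make_random_network(
    rng: np.random.Generator,
    n_reactions: int = 8,
    n_metabolites: int = 4,
) -> MetabolicModel:
    """A random small network with finite bounds (always feasible at v=0).

    Used for oracle-equivalence and invariant sweeps; coefficients are
    drawn from {-2, -1, 1, 2} with ~2 metabolites per reaction, lower
    bounds from {-b, 0} and finite positive upper bounds, so every LP is
    bounded and v = 0 is feasible.
    """
    model = MetabolicModel(id="random_net")
    for i in range(n_metabolites):
        model.add_metabolite(Metabolite(id=f"m{i}", compartment="c"))
    for j in range(n_reactions):
        k = int(rng.integers(1, min(3, n_metabolites) + 1))
        mets = rng.choice(n_metabolites, size=k, replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        stoich = {f"m{i}": float(c) for i, c in zip(mets, coefs)}
        ub = float(rng.uniform(1.0, 20.0))
        lb = float(rng.choice([0.0, -rng.uniform(1.0, 20.0)]))
        model.add_reaction(Reaction(f"r{j}", stoich, lb, ub, ReactionKind.INTERNAL))
    model.validate()
    return model


# ----------------------------------------------------------------- cohort

def make_cohort(
    config: SimulationConfig,
) -> tuple[list[AbundanceProfile], dict[str, str]]:
    """Dirichlet abundance profiles for treated vs control participants.

    Every strain has concentration parameter 1; in the treated group
    producer strains' parameters are multiplied by ``effect_size``, so
    treated communities carry systematically more producer biomass
    (exchangeable with controls when ``effect_size == 1``).
    """
    rng = config.rng("cohort")
    n_producers = round(config.n_strains * config.producer_fraction)
    strains = [f"P{i:03d}" for i in range(n_producers)] + [
        f"N{i:03d}" for i in range(n_producers, config.n_strains)
    ]
    alphas_control = np.ones(config.n_strains)
    alphas_treated = alphas_control.copy()
    alphas_treated[:n_producers] *= config.effect_size

    profiles: list[AbundanceProfile] = []
    groups: dict[str, str] = {}
    for group, alphas in (("control", alphas_control), ("treated", alphas_treated)):
        for i in range(config.n_participants):
            pid = f"{group}_{i:03d}"
            fractions = rng.dirichlet(alphas)
            profiles.append(
                AbundanceProfile(
                    participant_id=pid,
                    data_type="amplicon16S",
                    abundances=dict(zip(strains, map(float, fractions))),
                )
            )
            groups[pid] = group
    return profiles, groups


# -------------------------------------------------------------------- ffq

_FOODS = [
    # food_item, group_path, compound composition (g compound per g food)
    ("wheat_bread", ("plant", "grain"), {"starch_glc": 0.45, "protein_arg": 0.010}),
    ("apple", ("plant", "fruit"), {"starch_glc": 0.12, "protein_arg": 0.001}),
    ("beef", ("animal", "meat"), {"protein_arg": 0.018, "fat_chol": 0.002}),
    ("cheese", ("animal", "dairy"), {"protein_arg": 0.012, "fat_chol": 0.003}),
    ("beer", ("plant", "beverage"), {"starch_glc": 0.03}),
]

_COMPOUND_MAP = {
    "starch_glc": CompoundInfo("glc", molecular_weight=180.16, kj_per_gram=17.0),
    "protein_arg": CompoundInfo("arg", molecular_weight=174.20, kj_per_gram=17.0),
    "fat_chol": CompoundInfo("chol", molecular_weight=386.65, kj_per_gram=37.0),
}

# purine contents (mmol per gram food); beer left unmeasured on purpose to
# exercise group-average imputation
_PURINES = {
    "wheat_bread": {"adenosine": 2e-4, "guanosine": 1e-4},
    "apple": {"adenosine": 5e-5, "guanosine": 2e-5},
    "beef": {"adenosine": 8e-4, "guanosine": 6e-4},
    "cheese": {"adenosine": 1e-4, "guanosine": 8e-5},
    "beer": {},
}

# polyamine contents (mmol per gram food); ornithine measured only for beef
_POLYAMINES = {
    "wheat_bread": {"cadaverine": 1e-5, "putrescine": 4e-5, "spermidine": 2e-5,
                    "spermine": 1e-5},
    "apple": {"cadaverine": 0.0, "putrescine": 8e-5, "spermidine": 1e-5,
              "spermine": 0.0},
    "beef": {"cadaverine": 2e-5, "putrescine": 3e-5, "spermidine": 6e-5,
             "spermine": 5e-5, "ornithine": 4e-4},
    "cheese": {"cadaverine": 3e-4, "putrescine": 2e-4, "spermidine": 1e-5,
               "spermine": 1e-5},
    "beer": {"cadaverine": 1e-5, "putrescine": 2e-5, "spermidine": 5e-6,
             "spermine": 0.0},
}

_REFERENCE_DIET = {
    "glc": 2.0, "arg": 0.5, "chol": 0.05, "pi": 1.0, "cu2": 0.02, "mn2": 0.02,
    "zn2": 0.02, "fe3": 0.05, "cl": 1.0, "nh4": 1.0,
}


def make_ffq(config: SimulationConfig) -> dict:
    """Synthetic food-frequency data for ``2 * n_participants`` participants.

    Returns a dict with per-participant food records and compound intakes
    (grams/day), the compound map, purine and polyamine augmentation
    tables, and the reference diet.
    """
    rng = config.rng("ffq")
    records: dict[str, list[FoodRecord]] = {}
    intakes: dict[str, dict[str, float]] = {}
    for i in range(2 * config.n_participants):
        pid = f"ffq_{i:03d}"
        recs = []
        intake: dict[str, float] = {}
        for food_item, group_path, composition in _FOODS:
            grams = float(rng.gamma(shape=2.0, scale=60.0))
            recs.append(
                FoodRecord(participant_id=pid, food_item=food_item,
                           group_path=group_path, grams_per_day=grams)
            )
            for compound, frac in composition.items():
                intake[compound] = intake.get(compound, 0.0) + grams * frac
        records[pid] = recs
        intakes[pid] = intake
    groups = {item: path for item, path, _ in _FOODS}
    return {
        "records": records,
        "intakes": intakes,
        "compound_map": dict(_COMPOUND_MAP),
        "purine_table": AugmentationTable(
            contents={k: dict(v) for k, v in _PURINES.items()}, groups=dict(groups)
        ),
        "polyamine_table": AugmentationTable(
            contents={k: dict(v) for k, v in _POLYAMINES.items()}, groups=dict(groups)
        ),
        "reference_diet": DietSpec(
            participant_id="western_reference", amounts=dict(_REFERENCE_DIET),
            caloric_value_kj=8799.0,
        ),
    }


# ------------------------------------------------------------------ screen

def make_interaction_design(
    config: SimulationConfig,
    planted: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format log2 response table for the 2x2 interaction models.

    Cell means are 0 (baseline), ``drug_effect`` (drug), 0 (nutrient) and
    ``drug_effect + planted[nutrient]`` (drug + nutrient); Gaussian noise
    with sd ``sigma``; ``n_replicates`` wells per cell, with the
    no-nutrient cells shared across nutrients as on a real plate.
    ``planted`` defaults to ``planted_effect`` on the first ``n_planted``
    nutrients.
    """
    rng = config.rng("screen")
    if planted is None:
        planted = {
            f"nut{i:03d}": config.planted_effect for i in range(config.n_planted)
        }
    rows = []
    for drug in (False, True):
        mean = config.drug_effect if drug else 0.0
        for rep in range(config.n_replicates):
            rows.append(
                {"nutrient_id": "none", "drug": drug,
                 "response": mean + rng.normal(0.0, config.sigma)}
            )
    for i in range(config.n_nutrients):
        nutrient = f"nut{i:03d}"
        delta = planted.get(nutrient, 0.0)
        for drug in (False, True):
            mean = (config.drug_effect + delta) if drug else 0.0
            for rep in range(config.n_replicates):
                rows.append(
                    {"nutrient_id": nutrient, "drug": drug,
                     "response": mean + rng.normal(0.0, config.sigma)}
                )
    return pd.DataFrame(rows)


def make_screen(
    config: SimulationConfig,
    planted: dict[str, float] | None = None,
    od_noise: float = 0.0,
    times: np.ndarray | None = None,
) -> tuple[list[GrowthCurve], list[WormIntensitySet]]:
    """Logistic growth curves and per-worm reporter intensities.

    OD(t) = K / (1 + exp(-r (t - t0))) with K modulated multiplicatively
    (on the log2 scale) by drug, nutrient and planted interaction
    effects; optional Gaussian OD noise (floored at 0.001).  Worm log2
    intensities are normal around a baseline that the drug shifts up by
    ``worm_drug_shift`` and planted nutrients pull back down.
    """
    rng = config.rng("screen")
    if times is None:
        times = np.linspace(0.0, 18.0, 37)  # every 30 min over 18 h
    if planted is None:
        planted = {
            f"nut{i:03d}": config.planted_effect for i in range(config.n_planted)
        }
    r, t0, K0 = 0.6, 6.0, 1.0
    shape = 1.0 / (1.0 + np.exp(-r * (times - t0)))

    curves: list[GrowthCurve] = []
    worms: list[WormIntensitySet] = []
    nutrients = ["none"] + [f"nut{i:03d}" for i in range(config.n_nutrients)]
    for nutrient in nutrients:
        delta = planted.get(nutrient, 0.0)
        for drug_dose in (0.0, 50.0):
            drug = drug_dose > 0
            log2_K = np.log2(K0)
            if drug:
                log2_K += config.drug_effect
                if nutrient != "none":
                    log2_K += delta
            K = 2.0 ** log2_K
            for rep in range(config.n_replicates):
                od = K * shape
                if od_noise > 0:
                    od = np.maximum(od + rng.normal(0.0, od_noise, size=od.shape), 0.001)
                curves.append(
                    GrowthCurve(
                        well_id=f"{nutrient}_m{int(drug_dose)}_r{rep}",
                        nutrient_id=nutrient, metformin_mM=drug_dose,
                        replicate=rep, times=times.copy(), od=od,
                    )
                )
            # worm reporter: drug raises expression, planted nutrients suppress
            mu = 10.0 + (config.worm_drug_shift if drug else 0.0)
            if drug and nutrient != "none":
                mu -= delta * config.worm_drug_shift
            log2_int = rng.normal(mu, config.sigma, size=config.worms_per_well)
            worms.append(
                WormIntensitySet(
                    well_id=f"{nutrient}_m{int(drug_dose)}_worms",
                    nutrient_id=nutrient, metformin_mM=drug_dose,
                    intensities=2.0 ** log2_int,
                )
            )
    return curves, worms
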