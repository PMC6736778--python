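"""Join strain models into one participant community model.

The construction follows the common-compartment recipe for microbial
community FBA:

* every member model is tagged with its strain id (metabolites,
  compartments and reactions become ``<strain>__<id>``), so the union of
  member namespaces is collision-free;
* member exchange reactions become reversible transports between the
  member's own extracellular compartment and a shared lumen compartment
  ``u``; a fresh community exchange reaction ``EX_<met>_u`` is created
  for every lumen metabolite, and the diet is applied to those community
  exchanges only — members can therefore cross-feed through the lumen
  but cannot bypass the dietary boundary;
* member biomass outflows are blocked and a community biomass reaction
  consumes each member's biomass metabolite in proportion to its
  observed relative abundance f_k, enforcing the measured composition;
* coupling constraints tie the magnitude of every member reaction flux
  to that member's biomass production
  (|v_j| <= c * v_biomass,k + u_slack), so a taxon present at low
  abundance cannot act as an unbounded enzyme bag.

Relative abundances are filtered at a data-type-specific detection
cutoff (0.1% for 16S amplicon profiles, 0.01% for shotgun metagenomes)
and renormalized to sum to one before assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ReactionKind,
)
from .fba import LeqRow, apply_diet

__all__ = [
    "AbundanceProfile",
    "CommunityModel",
    "filter_and_renormalize",
    "build_community",
    "add_coupling",
    "assemble_participant",
    "read_abundance_table",
    "CUTOFF_16S",
    "CUTOFF_METAGENOME",
    "DEFAULT_COUPLING_C",
    "DEFAULT_COUPLING_SLACK",
    "COMMUNITY_BIOMASS_ID",
    "LUMEN",
]

CUTOFF_16S = 0.001         # >= 0.1% of reads
CUTOFF_METAGENOME = 0.0001  # >= 0.01% of reads
DEFAULT_COUPLING_C = 400.0
DEFAULT_COUPLING_SLACK = 0.01
#: default bounds on community biomass flux (one gut turnover per day)
DEFAULT_COMMUNITY_BIOMASS_BOUNDS = (0.4, 1.0)
LUMEN = "u"
COMMUNITY_BIOMASS_ID = "COMMUNITY_BIOMASS"
COMMUNITY_BIOMASS_OUTFLOW_ID = "EX_community_biomass"
_TAG_SEP = "__"


@dataclass
class AbundanceProfile:
    participant_id: str
    data_type: str  # "amplicon16S" or "metagenome"
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if self.data_type not in ("amplicon16S", "metagenome"):
            raise ValueError(f"unknown data_type {self.data_type!r}")
        bad = {s: a for s, a in self.abundances.items() if a < 0}
        if bad:
            raise ValueError(f"negative abundances: {bad}")

    def normalized(self) -> "AbundanceProfile":
        total = sum(self.abundances.values())
        if total <= 0:
            raise ValueError(f"{self.participant_id}: all-zero abundance profile")
        return replace(
            self, abundances={s: a / total for s, a in self.abundances.items()}
        )


@dataclass
class CommunityModel(MetabolicModel):
    """A joined multi-member model sharing the lumen compartment.

    ``members`` maps strain id to its abundance fraction; coupling
    constraints are materialized lazily by :meth:`extra_constraints` so
    the LP layer picks them up on every solve.
    """

    members: dict[str, float] = field(default_factory=dict)
    member_reaction_ids: dict[str, list[str]] = field(default_factory=dict)
    member_biomass_reaction: dict[str, str] = field(default_factory=dict)
    member_lumen_transport: dict[str, list[str]] = field(default_factory=dict)
    coupling_c: float | None = None
    coupling_slack: float = DEFAULT_COUPLING_SLACK

    def extra_constraints(self) -> list[LeqRow]:
        if self.coupling_c is None:
            return []
        rows: list[LeqRow] = []
        c = self.coupling_c
        u = self.coupling_slack
        for strain in sorted(self.members):
            bio = self.member_biomass_reaction[strain]
            for rid in self.member_reaction_ids[strain]:
                if rid == bio:
                    continue
                rows.append(({rid: 1.0, bio: -c}, u))
                rows.append(({rid: -1.0, bio: -c}, u))
        return rows

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            id=self.id,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            genus=self.genus,
            species=self.species,
            members=dict(self.members),
            member_reaction_ids={k: list(v) for k, v in self.member_reaction_ids.items()},
            member_biomass_reaction=dict(self.member_biomass_reaction),
            member_lumen_transport={
                k: list(v) for k, v in self.member_lumen_transport.items()
            },
            coupling_c=self.coupling_c,
            coupling_slack=self.coupling_slack,
        )


def filter_and_renormalize(
    profile: AbundanceProfile,
    cutoff_16s: float = CUTOFF_16S,
    cutoff_mgx: float = CUTOFF_METAGENOME,
) -> AbundanceProfile:
    """Drop strains below the detection cutoff and renormalize to 1.

    The cutoff is inclusive (a strain exactly at the threshold is kept)
    and depends on the profile's data type.
    """
    profile = profile.normalized()
    cutoff = cutoff_16s if profile.data_type == "amplicon16S" else cutoff_mgx
    kept = {s: a for s, a in profile.abundances.items() if a >= cutoff}
    if not kept:
        raise ValueError(
            f"{profile.participant_id}: no strain passes the {cutoff:g} abundance cutoff"
        )
    total = sum(kept.values())
    return replace(profile, abundances={s: a / total for s, a in kept.items()})


def _biomass_metabolite(model: MetabolicModel) -> str:
    if model.biomass_reaction_id is None:
        raise ModelValidationError(f"{model.id}: no biomass reaction designated")
    bio = model.reactions[model.biomass_reaction_id]
    products = [m for m, c in bio.stoichiometry.items() if c > 0]
    if len(products) != 1:
        raise ModelValidationError(
            f"{model.id}: biomass reaction must produce exactly one biomass "
            f"metabolite, found {products}"
        )
    return products[0]


def build_community(
    models: Mapping[str, MetabolicModel],
    profile: AbundanceProfile,
    community_biomass_bounds: tuple[float, float] = DEFAULT_COMMUNITY_BIOMASS_BOUNDS,
) -> CommunityModel:
    """Join member models into one community model.

    ``profile`` must already be filtered and renormalized.  Raises if a
    strain in the profile has no model.
    """
    missing = sorted(set(profile.abundances) - set(models))
    if missing:
        raise KeyError(f"no model for strains: {', '.join(missing)}")
    total = sum(profile.abundances.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"{profile.participant_id}: fractions sum to {total}, expected 1 "
            "(run filter_and_renormalize first)"
        )

    comm = CommunityModel(id=f"community_{profile.participant_id}")
    community_biomass_stoich: dict[str, float] = {}

    for strain in sorted(profile.abundances):
        frac = profile.abundances[strain]
        member = models[strain]
        comm.members[strain] = frac
        comm.member_reaction_ids[strain] = []
        comm.member_lumen_transport[strain] = []
        tag = strain + _TAG_SEP

        for mid in member.sorted_metabolite_ids():
            met = member.metabolites[mid]
            comm.add_metabolite(
                Metabolite(
                    id=tag + met.id,
                    name=met.name,
                    compartment=f"{strain}_{met.compartment}",
                    formula=met.formula,
                    charge=met.charge,
                )
            )

        bio_met = tag + _biomass_metabolite(member)

        for rid in member.sorted_reaction_ids():
            rxn = member.reactions[rid]
            new_id = tag + rid
            stoich = {tag + m: c for m, c in rxn.stoichiometry.items()}
            lb, ub = rxn.lower_bound, rxn.upper_bound
            kind = rxn.kind
            if rxn.kind is ReactionKind.EXCHANGE:
                # member exchange -> reversible transport into the shared lumen
                (tagged_met,) = stoich
                lumen_met = _lumen_metabolite(comm, member, rid)
                stoich = {tagged_met: -1.0, lumen_met: 1.0}
                lb, ub = -1000.0, 1000.0
                kind = ReactionKind.TRANSPORT
                comm.member_lumen_transport[strain].append(new_id)
            elif rxn.kind is ReactionKind.OUTFLOW and next(iter(rxn.stoichiometry)) == (
                _biomass_metabolite(member)
            ):
                lb, ub = 0.0, 0.0  # member biomass outflow blocked
            comm.add_reaction(
                Reaction(
                    id=new_id, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    kind=kind, name=rxn.name,
                )
            )
            comm.member_reaction_ids[strain].append(new_id)

        comm.member_biomass_reaction[strain] = tag + member.biomass_reaction_id
        community_biomass_stoich[bio_met] = -frac

    # community biomass: consume member biomasses at their fractions
    comm.add_metabolite(
        Metabolite(id=f"community_biomass_{LUMEN}", compartment=LUMEN, name="community biomass")
    )
    community_biomass_stoich[f"community_biomass_{LUMEN}"] = 1.0
    comm.add_reaction(
        Reaction(
            id=COMMUNITY_BIOMASS_ID,
            stoichiometry=community_biomass_stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            kind=ReactionKind.BIOMASS,
            name="abundance-weighted community biomass",
        )
    )
    lb, ub = community_biomass_bounds
    comm.add_reaction(
        Reaction(
            id=COMMUNITY_BIOMASS_OUTFLOW_ID,
            stoichiometry={f"community_biomass_{LUMEN}": -1.0},
            lower_bound=lb,
            upper_bound=ub,
            kind=ReactionKind.OUTFLOW,
            name="community biomass outflow",
        )
    )
    comm.biomass_reaction_id = COMMUNITY_BIOMASS_ID

    # one fresh community exchange per lumen metabolite
    for mid in comm.sorted_metabolite_ids():
        met = comm.metabolites[mid]
        if met.compartment != LUMEN or mid == f"community_biomass_{LUMEN}":
            continue
        comm.add_reaction(
            Reaction(
                id=f"EX_{mid}",
                stoichiometry={mid: -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
                kind=ReactionKind.EXCHANGE,
            )
        )
    comm.validate()
    return comm


def _lumen_metabolite(comm: CommunityModel, member: MetabolicModel, exchange_id: str) -> str:
    (met_id,) = member.reactions[exchange_id].stoichiometry
    met = member.metabolites[met_id]
    lumen_id = f"{met.base_id}_{LUMEN}"
    if lumen_id not in comm.metabolites:
        comm.add_metabolite(
            Metabolite(id=lumen_id, name=met.name, compartment=LUMEN,
                       formula=met.formula, charge=met.charge)
        )
    return lumen_id


def add_coupling(
    community: CommunityModel,
    c: float = DEFAULT_COUPLING_C,
    u_slack: float = DEFAULT_COUPLING_SLACK,
) -> CommunityModel:
    """Activate flux-biomass coupling: |v_j| <= c * v_biomass,k + u_slack."""
    if c <= 0:
        raise ValueError("coupling parameter c must be positive")
    if u_slack < 0:
        raise ValueError("coupling slack must be non-negative")
    community.coupling_c = c
    community.coupling_slack = u_slack
    return community


def assemble_participant(
    models: Mapping[str, MetabolicModel],
    profile: AbundanceProfile,
    diet: Mapping[str, float] | "object",
    coupling_c: float = DEFAULT_COUPLING_C,
    coupling_slack: float = DEFAULT_COUPLING_SLACK,
    cutoff_16s: float = CUTOFF_16S,
    cutoff_mgx: float = CUTOFF_METAGENOME,
    community_biomass_bounds: tuple[float, float] = DEFAULT_COMMUNITY_BIOMASS_BOUNDS,
) -> CommunityModel:
    """Filter, build, couple, and diet-constrain one participant community."""
    filtered = filter_and_renormalize(profile, cutoff_16s=cutoff_16s, cutoff_mgx=cutoff_mgx)
    comm = build_community(models, filtered, community_biomass_bounds=community_biomass_bounds)
    add_coupling(comm, c=coupling_c, u_slack=coupling_slack)
    comm, _skipped = apply_diet(comm, diet, inplace=True)
    return comm


def read_abundance_table(path: str | Path) -> list[AbundanceProfile]:
    """Long-format TSV: participant_id, strain_id, relative_abundance, data_type."""
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for (pid, dtype), grp in df.groupby(["participant_id", "data_type"], sort=True):
        profiles.append(
            AbundanceProfile(
                participant_id=str(pid),
                data_type=str(dtype),
                abundances={
                    str(r.strain_id): float(r.relative_abundance) for r in grp.itertuples()
                },
            )
        )
    return profiles
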