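"""Homology-guided refinement of strain models for agmatine handling.

Draft gut-bacterial reconstructions typically lack agmatine transporters
and the extracellular arm of arginine decarboxylation.  Refinement adds
them from homology evidence and then screens the refined models:

* a reversible agmatine transporter (``agm_c <-> agm_e``) for strains
  with a transporter-query hit at bitscore > 50 and query coverage >= 75%,
* an extracellular arginine decarboxylase reaction (``ARGDC_EXT``,
  ``arg_e -> agm_e + co2_e``) for strains with a speA homolog at
  bitscore > 200, copied from the strain's cytosolic ``ARGDC`` template,
* an irreversible agmatine outflow for every strain that received either,
* a growth screen (max biomass >= 0.01 mmol/gM/d on the diet) and a
  producer screen (max agmatine outflow > 0 on the diet).

Refinement is additive and idempotent: it never removes reactions or
alters existing bounds, and re-running adds nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import MetabolicModel, Metabolite, Reaction, ReactionKind
from .fba import apply_diet, fba

__all__ = [
    "HomologyHit",
    "RefinementReport",
    "parse_homology_table",
    "assign_agmatine_transport",
    "add_extracellular_argdc",
    "add_agmatine_outflow",
    "screen_growth",
    "screen_producers",
    "refine_models",
    "TRANSPORTER_BITSCORE_MIN",
    "TRANSPORTER_COVERAGE_MIN",
    "SPEA_BITSCORE_MIN",
    "GROWTH_BIOMASS_CUTOFF",
]

log = logging.getLogger(__name__)

TRANSPORTER_BITSCORE_MIN = 50.0   # strict: hits must score above this
TRANSPORTER_COVERAGE_MIN = 75.0   # inclusive: coverage >= this
SPEA_BITSCORE_MIN = 200.0         # strict
GROWTH_BIOMASS_CUTOFF = 0.01      # mmol/gM/d, inclusive

TRANSPORT_RXN_ID = "AGMt"
ARGDC_EXT_ID = "ARGDC_EXT"
OUTFLOW_RXN_ID = "AGM_OUTFLOW"
#: fallback extracellular arginine-decarboxylase stoichiometry for strains
#: with a qualifying speA hit but no cytosolic template to copy
CANONICAL_ARGDC = {"arg": -1.0, "agm": 1.0, "co2": 1.0}


@dataclass
class HomologyHit:
    query_protein: str
    target_strain: str
    bitscore: float
    query_coverage: float | None = None  # percent, 0-100

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query_protein}")
        if self.query_coverage is not None and not 0 <= self.query_coverage <= 100:
            raise ValueError(
                f"{self.query_protein}->{self.target_strain}: "
                f"coverage {self.query_coverage} outside [0, 100]"
            )


@dataclass
class RefinementReport:
    transporter_added: dict[str, bool] = field(default_factory=dict)
    argdc_ext_added: dict[str, bool] = field(default_factory=dict)
    outflow_added: dict[str, bool] = field(default_factory=dict)
    growth_pass: dict[str, bool] = field(default_factory=dict)
    producer: dict[str, bool] = field(default_factory=dict)
    #: total models entering the growth screen / models entering producer screen
    n_growth_screened: int = 0
    n_producer_screened: int = 0
    skipped_hits: list[str] = field(default_factory=list)

    @property
    def n_transporter(self) -> int:
        return sum(self.transporter_added.values())

    @property
    def n_argdc_ext(self) -> int:
        return sum(self.argdc_ext_added.values())

    @property
    def n_outflow(self) -> int:
        return sum(self.outflow_added.values())

    @property
    def n_growing(self) -> int:
        return sum(self.growth_pass.values())

    @property
    def n_producers(self) -> int:
        return sum(self.producer.values())

    def species_counts(self, models: Mapping[str, MetabolicModel]) -> pd.DataFrame:
        """Aggregate per-strain flags to species using model taxonomy."""
        rows = []
        for strain, model in models.items():
            rows.append(
                {
                    "species": f"{model.genus} {model.species}".strip() or strain,
                    "transporter": self.transporter_added.get(strain, False),
                    "argdc_ext": self.argdc_ext_added.get(strain, False),
                    "producer": self.producer.get(strain, False),
                }
            )
        df = pd.DataFrame(rows)
        return df.groupby("species").any().reset_index()

    def to_frame(self) -> pd.DataFrame:
        strains = sorted(
            set(self.transporter_added)
            | set(self.argdc_ext_added)
            | set(self.outflow_added)
            | set(self.growth_pass)
            | set(self.producer)
        )
        return pd.DataFrame(
            {
                "strain": strains,
                "transporter_added": [self.transporter_added.get(s, False) for s in strains],
                "argdc_ext_added": [self.argdc_ext_added.get(s, False) for s in strains],
                "outflow_added": [self.outflow_added.get(s, False) for s in strains],
                "growth_pass": [self.growth_pass.get(s, None) for s in strains],
                "producer": [self.producer.get(s, None) for s in strains],
            }
        )


def parse_homology_table(
    path: str | Path, query_lengths: Mapping[str, float] | None = None
) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore, optionally a 13th column with query
    coverage percent.  Without that column, coverage is computed as
    alignment-length / query-length when ``query_lengths`` is given;
    otherwise coverage stays None (and coverage-gated rules will reject
    the hit).
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: row {lineno}: expected >= 12 columns, got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                aln_length = float(fields[3])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: non-numeric field: {exc}") from exc
            coverage: float | None = None
            if len(fields) >= 13:
                coverage = float(fields[12])
            elif query_lengths and query in query_lengths:
                coverage = 100.0 * aln_length / query_lengths[query]
            hits.append(
                HomologyHit(
                    query_protein=query,
                    target_strain=subject,
                    bitscore=bitscore,
                    query_coverage=min(coverage, 100.0) if coverage is not None else None,
                )
            )
    return hits


def _ensure_metabolite(model: MetabolicModel, met_id: str, compartment: str) -> None:
    if met_id not in model.metabolites:
        model.add_metabolite(Metabolite(id=met_id, compartment=compartment))


def assign_agmatine_transport(
    models: Mapping[str, MetabolicModel],
    hits: Iterable[HomologyHit],
    report: RefinementReport | None = None,
    bitscore_min: float = TRANSPORTER_BITSCORE_MIN,
    coverage_min: float = TRANSPORTER_COVERAGE_MIN,
) -> RefinementReport:
    """Add a reversible agmatine transporter to strains with evidence.

    Evidence: at least one hit with bitscore strictly above
    ``bitscore_min`` and coverage at or above ``coverage_min``.  Models
    are modified in place; idempotent.
    """
    report = report or RefinementReport()
    qualifying: set[str] = set()
    for hit in hits:
        if hit.target_strain not in models:
            report.skipped_hits.append(f"{hit.query_protein}->{hit.target_strain}")
            log.warning("hit names unknown strain %s; skipped", hit.target_strain)
            continue
        if hit.bitscore > bitscore_min and (
            hit.query_coverage is not None and hit.query_coverage >= coverage_min
        ):
            qualifying.add(hit.target_strain)
    for strain, model in models.items():
        if strain in qualifying and TRANSPORT_RXN_ID not in model.reactions:
            _ensure_metabolite(model, "agm_c", "c")
            _ensure_metabolite(model, "agm_e", "e")
            model.add_reaction(
                Reaction(
                    id=TRANSPORT_RXN_ID,
                    stoichiometry={"agm_c": -1.0, "agm_e": 1.0},
                    lower_bound=-1000.0,
                    upper_bound=1000.0,
                    kind=ReactionKind.TRANSPORT,
                    name="agmatine transport (homology-assigned)",
                )
            )
        report.transporter_added[strain] = (
            strain in qualifying or report.transporter_added.get(strain, False)
        )
    return report


def add_extracellular_argdc(
    models: Mapping[str, MetabolicModel],
    spea_hits: Iterable[HomologyHit],
    report: RefinementReport | None = None,
    bitscore_min: float = SPEA_BITSCORE_MIN,
) -> RefinementReport:
    """Add extracellular arginine decarboxylase for strains with a speA homolog.

    Strains with a hit strictly above ``bitscore_min`` gain ``ARGDC_EXT``
    with the stoichiometric coefficients of the strain's cytosolic
    ``ARGDC`` reaction transplanted to the extracellular compartment.
    Strains lacking the cytosolic template get the canonical
    arginine -> agmatine + CO2 stoichiometry, with a warning.
    """
    report = report or RefinementReport()
    qualifying: set[str] = set()
    for hit in spea_hits:
        if hit.target_strain not in models:
            report.skipped_hits.append(f"{hit.query_protein}->{hit.target_strain}")
            continue
        if hit.bitscore > bitscore_min:
            qualifying.add(hit.target_strain)
    for strain, model in models.items():
        if strain in qualifying and ARGDC_EXT_ID not in model.reactions:
            template = model.reactions.get("ARGDC")
            if template is not None:
                stoich = {
                    _to_extracellular(model, met_id): coef
                    for met_id, coef in template.stoichiometry.items()
                }
            else:
                log.warning(
                    "%s: qualifying speA hit but no cytosolic ARGDC template; "
                    "using canonical stoichiometry", strain,
                )
                stoich = {f"{base}_e": coef for base, coef in CANONICAL_ARGDC.items()}
            for met_id in stoich:
                _ensure_metabolite(model, met_id, "e")
            model.add_reaction(
                Reaction(
                    id=ARGDC_EXT_ID,
                    stoichiometry=stoich,
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    kind=ReactionKind.INTERNAL,
                    name="extracellular arginine decarboxylase (speA homolog)",
                )
            )
        report.argdc_ext_added[strain] = (
            strain in qualifying or report.argdc_ext_added.get(strain, False)
        )
    return report


def _to_extracellular(model: MetabolicModel, met_id: str) -> str:
    met = model.metabolites[met_id]
    return f"{met.base_id}_e"


def add_agmatine_outflow(
    models: Mapping[str, MetabolicModel], report: RefinementReport
) -> RefinementReport:
    """Add an irreversible agmatine outflow wherever evidence exists.

    A strain qualifies if it received either the transporter or the
    extracellular decarboxylase.
    """
    for strain, model in models.items():
        qualifies = report.transporter_added.get(strain, False) or report.argdc_ext_added.get(
            strain, False
        )
        if qualifies and OUTFLOW_RXN_ID not in model.reactions:
            _ensure_metabolite(model, "agm_e", "e")
            model.add_reaction(
                Reaction(
                    id=OUTFLOW_RXN_ID,
                    stoichiometry={"agm_e": -1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    kind=ReactionKind.OUTFLOW,
                    name="agmatine outflow",
                )
            )
        report.outflow_added[strain] = qualifies or report.outflow_added.get(strain, False)
    return report


def screen_growth(
    models: Mapping[str, MetabolicModel],
    diet: Mapping[str, float] | "object",
    report: RefinementReport | None = None,
    biomass_cutoff: float = GROWTH_BIOMASS_CUTOFF,
) -> RefinementReport:
    """Flag strains whose max biomass on the diet reaches the cutoff."""
    report = report or RefinementReport()
    report.n_growth_screened = len(models)
    for strain, model in models.items():
        if model.biomass_reaction_id is None:
            raise ValueError(f"{strain}: no biomass reaction designated")
        constrained, _ = apply_diet(model, diet)
        sol = fba(constrained, model.biomass_reaction_id, sense="max")
        if not sol.optimal:
            log.info("%s: growth LP %s; excluded", strain, sol.status.value)
            report.growth_pass[strain] = False
        else:
            report.growth_pass[strain] = sol.primary_objective >= biomass_cutoff
    return report


def screen_producers(
    models: Mapping[str, MetabolicModel],
    diet: Mapping[str, float] | "object",
    report: RefinementReport | None = None,
    tol: float = 1e-9,
) -> RefinementReport:
    """Flag growing strains able to secrete agmatine on the diet."""
    report = report or RefinementReport()
    screened = {
        s: m for s, m in models.items() if report.growth_pass.get(s, True)
    }
    report.n_producer_screened = len(screened)
    for strain, model in models.items():
        if strain not in screened:
            report.producer[strain] = False
            continue
        if OUTFLOW_RXN_ID not in model.reactions:
            report.producer[strain] = False
            continue
        constrained, _ = apply_diet(model, diet)
        sol = fba(constrained, OUTFLOW_RXN_ID, sense="max")
        report.producer[strain] = sol.optimal and sol.primary_objective > tol
    return report


def refine_models(
    models: Mapping[str, MetabolicModel],
    transporter_hits: Iterable[HomologyHit],
    spea_hits: Iterable[HomologyHit],
    diet: Mapping[str, float] | "object",
    bitscore_min: float = TRANSPORTER_BITSCORE_MIN,
    coverage_min: float = TRANSPORTER_COVERAGE_MIN,
    spea_bitscore_min: float = SPEA_BITSCORE_MIN,
    biomass_cutoff: float = GROWTH_BIOMASS_CUTOFF,
) -> RefinementReport:
    """Full refinement pipeline: transport, ARGDC_EXT, outflow, screens."""
    report = assign_agmatine_transport(
        models, transporter_hits, bitscore_min=bitscore_min, coverage_min=coverage_min
    )
    report = add_extracellular_argdc(
        models, spea_hits, report=report, bitscore_min=spea_bitscore_min
    )
    report = add_agmatine_outflow(models, report)
    report = screen_growth(models, diet, report=report, biomass_cutoff=biomass_cutoff)
    report = screen_producers(models, diet, report=report)
    return report
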