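"""Stoichiometric network containers.

A :class:`MetabolicNetwork` is the unit of flux balance analysis and
gapfilling: a set of metabolites, a set of mass-balanced reactions with flux
bounds, boundary (exchange) reactions that connect extracellular metabolites
to the environment, and exactly one biomass reaction acting as the growth
objective.  A :class:`UniversalDB` has the same shape minus the biomass
reaction and serves as the pool of candidate reactions for gapfilling.

Conventions
-----------
* Compartments: ``"c"`` cytosol, ``"e"`` extracellular.
* An exchange reaction touches exactly one extracellular metabolite with
  coefficient -1; positive flux is secretion, negative flux is uptake.
* Flux units are toy mmol·gDW⁻¹·h⁻¹; the default magnitude bound is 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, Mapping, Optional

from .errors import ValidationError

EXTRACELLULAR = "e"
CYTOSOL = "c"
DEFAULT_BOUND = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed, positive = produced).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    is_biomass: bool = False
    name: str = ""

    def validate(self, metabolites: Optional[Mapping[str, Metabolite]] = None) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        if self.is_exchange:
            if len(self.stoichiometry) != 1:
                raise ValidationError(
                    f"exchange reaction {self.id!r} must touch exactly one metabolite"
                )
            if metabolites is not None:
                (mid,) = self.stoichiometry
                met = metabolites.get(mid)
                if met is not None and met.compartment != EXTRACELLULAR:
                    raise ValidationError(
                        f"exchange reaction {self.id!r} touches non-extracellular metabolite {mid!r}"
                    )
        if metabolites is not None:
            for mid in self.stoichiometry:
                if mid not in metabolites:
                    raise ValidationError(
                        f"reaction {self.id!r} references unknown metabolite {mid!r}"
                    )

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class _ReactionSet:
    """Shared machinery for networks and universal databases."""

    def __init__(self, id: str, metabolites: Iterable[Metabolite] = (),
                 reactions: Iterable[Reaction] = ()):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r} in {self.id!r}")
        self.reactions[rxn.id] = rxn

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.reactions

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions.values())

    def __len__(self) -> int:
        return len(self.reactions)

    @property
    def exchange_ids(self):
        return [r.id for r in self.reactions.values() if r.is_exchange]


class MetabolicNetwork(_ReactionSet):
    """A draft, true or gapfilled metabolic network with one biomass reaction."""

    def __init__(self, id: str, metabolites: Iterable[Metabolite] = (),
                 reactions: Iterable[Reaction] = (), biomass_id: Optional[str] = None):
        super().__init__(id, metabolites, reactions)
        if biomass_id is None:
            biomass = [r.id for r in self.reactions.values() if r.is_biomass]
            biomass_id = biomass[0] if len(biomass) == 1 else None
        self.biomass_id = biomass_id

    def validate(self) -> None:
        biomass = [r for r in self.reactions.values() if r.is_biomass]
        if len(biomass) != 1:
            raise ValidationError(
                f"network {self.id!r}: expected exactly one biomass reaction, found {len(biomass)}"
            )
        if self.biomass_id != biomass[0].id:
            raise ValidationError(
                f"network {self.id!r}: biomass_id {self.biomass_id!r} does not match "
                f"flagged biomass reaction {biomass[0].id!r}"
            )
        for r in self.reactions.values():
            r.validate(self.metabolites)

    def copy(self, id: Optional[str] = None) -> "MetabolicNetwork":
        return MetabolicNetwork(
            id if id is not None else self.id,
            list(self.metabolites.values()),
            [r.copy() for r in self.reactions.values()],
            biomass_id=self.biomass_id,
        )

    def without(self, reaction_id: str) -> "MetabolicNetwork":
        """Copy of the network with one reaction removed (metabolites kept)."""
        if reaction_id not in self.reactions:
            raise ValidationError(f"cannot remove unknown reaction {reaction_id!r}")
        if reaction_id == self.biomass_id:
            raise ValidationError("cannot remove the biomass reaction")
        out = self.copy()
        del out.reactions[reaction_id]
        return out

    def with_reactions(self, reactions: Iterable[Reaction],
                       metabolites: Iterable[Metabolite] = ()) -> "MetabolicNetwork":
        """Copy of the network with extra reactions (and any new metabolites)."""
        out = self.copy()
        for m in metabolites:
            out.metabolites.setdefault(m.id, m)
        for r in reactions:
            out.add_reaction(r.copy())
        return out


class UniversalDB(_ReactionSet):
    """Universal reaction database: the candidate pool for gapfilling."""

    def validate(self) -> None:
        for r in self.reactions.values():
            if r.is_biomass:
                raise ValidationError(
                    f"universal database {self.id!r} must not contain biomass reactions ({r.id!r})"
                )
            r.validate(self.metabolites)

    def check_covers(self, draft: MetabolicNetwork) -> None:
        """Verify the load-time invariant: draft non-biomass, non-exchange
        reactions are a subset of the database."""
        missing = [
            r.id for r in draft
            if not r.is_biomass and not r.is_exchange and r.id not in self.reactions
        ]
        if missing:
            raise ValidationError(
                f"draft {draft.id!r} has reactions outside database {self.id!r}: {sorted(missing)[:5]}"
            )


@dataclass(frozen=True)
class MediumCondition:
    """A growth medium: per-exchange maximum uptake fluxes, one of which is
    designated the sole nitrogen source.  Exchanges not listed are closed to
    uptake (secretion stays open)."""

    id: str
    uptake_bounds: Mapping[str, float] = field(default_factory=dict)
    nitrogen_source_id: str = ""

    def __post_init__(self):
        for ex, ub in self.uptake_bounds.items():
            if ub < 0:
                raise ValidationError(f"medium {self.id!r}: negative uptake bound for {ex!r}")

    def validate_against(self, holder: _ReactionSet) -> None:
        known = set(holder.reactions)
        for ex in self.uptake_bounds:
            if ex not in known:
                raise ValidationError(
                    f"medium {self.id!r} references unknown exchange {ex!r} in {holder.id!r}"
                )


@dataclass
class FluxDistribution:
    """Result of one FBA solve: optimal fluxes and the biomass objective.

    ``feasible`` is False when the LP was infeasible; the objective is then
    reported as 0 and ``fluxes`` is empty.
    """

    fluxes: Dict[str, float]
    objective_value: float
    feasible: bool = True
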