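"""Cost components, perspective filtering, capital annuitisation and remuneration.

Costs are tagged with the *location* where they are incurred (general
practice, private gynaecologist, hospital) and the *bearer* who pays them
(the healthcare sector or the patient).  The societal perspective counts
every component; the healthcare-sector perspective keeps only components
borne by the healthcare sector, dropping patient time and transport.

Capital items (an ultrasound scanner, a training course) are converted to a
cost per scan with the equivalent-annual-cost method: the purchase price is
annuitised over the asset's lifespan at a fixed interest rate and divided by
the annual number of scans for the indication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "GP",
    "PRIVATE_GYNAECOLOGIST",
    "HOSPITAL",
    "LOCATIONS",
    "BEARER_HEALTHCARE",
    "BEARER_PATIENT",
    "BEARERS",
    "SOCIETAL",
    "HEALTHCARE",
    "PERSPECTIVES",
    "CostComponent",
    "CostGroup",
    "Costbook",
    "AnnuitySpec",
    "Remuneration",
    "annuity_factor",
    "per_use_capital_cost",
    "visit_cost",
    "remuneration",
    "REMUNERATION_COMPONENT_IDS",
]

# Locations where care can be completed.
GP = "GP"
PRIVATE_GYNAECOLOGIST = "private_gynaecologist"
HOSPITAL = "hospital"
LOCATIONS = (GP, PRIVATE_GYNAECOLOGIST, HOSPITAL)

# Cost bearers and evaluation perspectives.
BEARER_HEALTHCARE = "healthcare"
BEARER_PATIENT = "patient"
BEARERS = (BEARER_HEALTHCARE, BEARER_PATIENT)
SOCIETAL = "societal"
HEALTHCARE = "healthcare"
PERSPECTIVES = (SOCIETAL, HEALTHCARE)

# Which alternative a component applies to.
APPLIES = ("usual_practice", "intervention", "both")


@dataclass(frozen=True)
class CostComponent:
    """A single resource-use item: ``quantity`` units at ``unit_price`` € each.

    ``range`` is an optional [low, high] interval *on the per-visit component
    cost in €* used by the deterministic and probabilistic sensitivity
    analyses; ranges stated in resource-use units (minutes, km) are converted
    at the fixed unit price before being stored here.  ``group`` names an
    optional bundle (e.g. consumable utensils) that is varied as one axis.
    """

    id: str
    location: str
    bearer: str
    quantity: float
    unit_price: float
    applies_to: str = "both"
    range: tuple[float, float] | None = None
    group: str | None = None
    psa_included: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"component {self.id!r}: quantity must be >= 0")
        if self.unit_price < 0:
            raise ValueError(f"component {self.id!r}: unit_price must be >= 0")
        if self.location not in LOCATIONS:
            raise ValueError(
                f"component {self.id!r}: unknown location {self.location!r}; "
                f"expected one of {LOCATIONS}"
            )
        if self.bearer not in BEARERS:
            raise ValueError(
                f"component {self.id!r}: unknown bearer {self.bearer!r}; "
                f"expected one of {BEARERS}"
            )
        if self.range is not None:
            object.__setattr__(self, "range", (float(self.range[0]), float(self.range[1])))
            if self.range[0] > self.range[1]:
                raise ValueError(f"component {self.id!r}: range low > high")

    @property
    def cost(self) -> float:
        """Per-visit component cost in €: quantity × unit price."""
        return self.quantity * self.unit_price


@dataclass(frozen=True)
class CostGroup:
    """A bundle of components varied as a single sensitivity axis.

    The DSA/PSA range applies to the bundle's total per-visit cost; member
    costs are scaled proportionally when the bundle is perturbed.
    """

    id: str
    members: tuple[str, ...]
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if self.range is not None:
            object.__setattr__(self, "range", (float(self.range[0]), float(self.range[1])))


@dataclass(frozen=True)
class CostAxis:
    """One sensitivity axis: a lone component or a component group."""

    id: str
    base: float
    range: tuple[float, float] | None
    psa_included: bool


@dataclass(frozen=True)
class Costbook:
    """The full set of cost components and bundles for one model."""

    components: Mapping[str, CostComponent]
    groups: Mapping[str, CostGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", MappingProxyType(dict(self.components)))
        object.__setattr__(self, "groups", MappingProxyType(dict(self.groups)))
        for gid, group in self.groups.items():
            for member in group.members:
                if member not in self.components:
                    raise KeyError(f"cost group {gid!r} references unknown component {member!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Costbook):
            return NotImplemented
        return dict(self.components) == dict(other.components) and dict(self.groups) == dict(
            other.groups
        )

    def group_base_cost(self, group_id: str) -> float:
        group = self.groups[group_id]
        return sum(self.components[m].cost for m in group.members)

    def component_cost(
        self,
        component_id: str,
        perspective: str = SOCIETAL,
        overrides: Mapping[str, float] | None = None,
    ) -> float:
        """Per-visit cost of one component under a perspective.

        ``overrides`` maps axis ids (component or group ids) to replacement
        per-visit € values; a group override scales its members
        proportionally to their base costs.
        """
        comp = self.components[component_id]
        if perspective == HEALTHCARE and comp.bearer != BEARER_HEALTHCARE:
            return 0.0
        if overrides:
            if comp.id in overrides:
                return float(overrides[comp.id])
            if comp.group is not None and comp.group in overrides:
                base_total = self.group_base_cost(comp.group)
                if base_total == 0:
                    return 0.0
                return comp.cost * float(overrides[comp.group]) / base_total
        return comp.cost

    def axes(self) -> list[CostAxis]:
        """Sensitivity axes in declaration order: grouped bundles count once."""
        axes: list[CostAxis] = []
        seen_groups: set[str] = set()
        for comp in self.components.values():
            if comp.group is not None:
                if comp.group in seen_groups:
                    continue
                seen_groups.add(comp.group)
                group = self.groups[comp.group]
                members = [self.components[m] for m in group.members]
                axes.append(
                    CostAxis(
                        id=group.id,
                        base=sum(m.cost for m in members),
                        range=group.range,
                        psa_included=all(m.psa_included for m in members),
                    )
                )
            else:
                axes.append(
                    CostAxis(id=comp.id, base=comp.cost, range=comp.range,
                             psa_included=comp.psa_included)
                )
        return axes


@dataclass(frozen=True)
class AnnuitySpec:
    """Capital item annuitised to a per-use cost.

    ``use_fraction`` is the share of the asset's use attributable to the
    indication being costed (a scanner bought for a whole practice serves
    many indications; only a fraction of its cost is charged here).
    """

    capital: float
    lifespan_years: float
    annual_rate: float
    annual_uses: float
    use_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.lifespan_years <= 0:
            raise ValueError("lifespan_years must be > 0")
        if self.annual_rate < 0:
            raise ValueError("annual_rate must be >= 0")
        if self.annual_uses <= 0:
            raise ValueError("annual_uses must be > 0")
        if not (0 < self.use_fraction <= 1):
            raise ValueError("use_fraction must be in (0, 1]")


def annuity_factor(annual_rate: float, lifespan_years: float) -> float:
    """Annuity factor (1 − (1+r)^−L) / r, the present value of €1/year for L years.

    At r = 0 the continuity limit L applies (straight-line depreciation).
    """
    if lifespan_years <= 0:
        raise ValueError("lifespan_years must be > 0")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    if annual_rate == 0:
        return float(lifespan_years)
    return (1.0 - (1.0 + annual_rate) ** -lifespan_years) / annual_rate


def per_use_capital_cost(spec: AnnuitySpec) -> float:
    """Equivalent cost per use of a capital item in €.

    capital × use_fraction / annuity_factor(rate, lifespan) / annual_uses.
    """
    factor = annuity_factor(spec.annual_rate, spec.lifespan_years)
    return spec.capital * spec.use_fraction / factor / spec.annual_uses


def visit_cost(
    location: str,
    alternative: str,
    perspective: str,
    costbook: Costbook,
) -> float:
    """Total per-visit cost at a location for one alternative and perspective.

    Sums quantity × unit price over components at the location whose
    ``applies_to`` covers the alternative; under the healthcare perspective
    only healthcare-borne components count.
    """
    if location not in LOCATIONS:
        raise ValueError(f"unknown location {location!r}; expected one of {LOCATIONS}")
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")
    total = 0.0
    for comp in costbook.components.values():
        if comp.location != location:
            continue
        if comp.applies_to not in ("both", alternative):
            continue
        total += costbook.component_cost(comp.id, perspective)
    return total


# The six add-on components a GP incurs per point-of-care scan: time,
# equipment, training, and the three consumables.
REMUNERATION_COMPONENT_IDS = (
    "gp_scan_time",
    "scanner",
    "ceclus_training",
    "wet_wipes",
    "transducer_cover",
    "gel",
)


@dataclass(frozen=True)
class Remuneration:
    """Itemised per-scan fee proposal: (label, € cost) pairs and their total."""

    components: tuple[tuple[str, float], ...]
    total: float
    complete: bool = True


def remuneration(
    costbook: Costbook,
    component_ids: tuple[str, ...] | None = None,
) -> Remuneration:
    """Compose the GP's per-scan add-on fee from the costbook.

    With the default id list the result is the proposed fee covering scanner
    depreciation, training, scanning time and utensils.  A named component
    missing from the costbook raises ``KeyError``; an explicitly empty id
    list yields total 0 flagged incomplete.
    """
    ids = REMUNERATION_COMPONENT_IDS if component_ids is None else tuple(component_ids)
    if not ids:
        return Remuneration(components=(), total=0.0, complete=False)
    items: list[tuple[str, float]] = []
    for cid in ids:
        if cid not in costbook.components:
            raise KeyError(f"remuneration component {cid!r} missing from costbook")
        items.append((cid, costbook.components[cid].cost))
    total = sum(cost for _, cost in items)
    return Remuneration(components=tuple(items), total=total, complete=True)
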