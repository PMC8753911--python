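"""Decision-tree data model, validation, and expected-cost roll-back.

The model is a rooted tree.  The root is a decision node with one named
branch per management alternative (usual practice without point-of-care
ultrasound; the intervention with it).  Interior nodes are chance nodes
whose branches carry references to probability parameters; leaves are
terminal nodes labelled with the location where clinical management
completes.  Costs accrue on branches along a path — a referral path
accumulates the GP visit's costs plus the specialist visit's costs — and
the expected cost of an alternative is the probability-weighted sum of its
path costs, computed bottom-up (roll-back).

``enumerate_paths`` is an independent path-enumeration oracle: it lists
every root-to-terminal path with its probability and accumulated cost, and
Σ probability × cost must equal the roll-back value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping, NamedTuple, Union

from .costing import LOCATIONS, PERSPECTIVES, SOCIETAL, Costbook

__all__ = [
    "PROB_TOL",
    "Branch",
    "ChanceNode",
    "TerminalNode",
    "DecisionTree",
    "ProbabilityParameter",
    "CmaModel",
    "EvaluationResult",
    "Path",
    "validate",
    "expected_cost",
    "enumerate_paths",
    "evaluate",
    "incremental_cost",
]

#: Tolerance for branch probabilities summing to one at a chance node.
PROB_TOL = 1e-9


@dataclass(frozen=True)
class Branch:
    """An edge of the tree.

    ``probability`` names a :class:`ProbabilityParameter` (``None`` only for
    the root decision branches, which are chosen, not chanced).  ``costs``
    lists the cost-component ids accrued when the branch is taken.
    """

    child: str
    probability: str | None = None
    costs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "costs", tuple(self.costs))


@dataclass(frozen=True)
class ChanceNode:
    id: str
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))


@dataclass(frozen=True)
class TerminalNode:
    """A leaf: clinical management completes at ``location``."""

    id: str
    location: str


Node = Union[ChanceNode, TerminalNode]


@dataclass(frozen=True)
class DecisionTree:
    """Root decision branches plus the node set they reach.

    ``alternatives`` preserves declaration order; the first-declared
    alternative is the comparator for incremental costs.
    """

    alternatives: tuple[tuple[str, Branch], ...]
    nodes: Mapping[str, Node]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "nodes", MappingProxyType(dict(self.nodes)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecisionTree):
            return NotImplemented
        return self.alternatives == other.alternatives and dict(self.nodes) == dict(other.nodes)

    @property
    def alternative_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.alternatives)

    def branch_for(self, alternative: str) -> Branch:
        for name, branch in self.alternatives:
            if name == alternative:
                return branch
        raise ValueError(
            f"unknown alternative {alternative!r}; valid alternatives: "
            f"{', '.join(self.alternative_names)}"
        )


@dataclass(frozen=True)
class ProbabilityParameter:
    """A branch probability with its base value and sensitivity range.

    ``complement_group`` links the two probabilities of a binary chance node
    so perturbation and sampling keep them summing to one.
    """

    id: str
    base: float
    range: tuple[float, float] | None = None
    complement_group: str | None = None
    psa_included: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if self.range is not None:
            object.__setattr__(self, "range", (float(self.range[0]), float(self.range[1])))


@dataclass(frozen=True)
class CmaModel:
    """A complete cost-minimisation model: tree, probabilities, costbook.

    Iterable, so it unpacks as ``tree, params, costbook = model``.
    """

    tree: DecisionTree
    params: Mapping[str, ProbabilityParameter]
    costbook: Costbook

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", MappingProxyType(dict(self.params)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CmaModel):
            return NotImplemented
        return (
            self.tree == other.tree
            and dict(self.params) == dict(other.params)
            and self.costbook == other.costbook
        )

    def __iter__(self) -> Iterator:
        yield self.tree
        yield self.params
        yield self.costbook

    def complement_groups(self) -> dict[str, list[str]]:
        """Complement-group id → member parameter ids, in declaration order."""
        groups: dict[str, list[str]] = {}
        for pid, param in self.params.items():
            if param.complement_group is not None:
                groups.setdefault(param.complement_group, []).append(pid)
        return groups


@dataclass(frozen=True)
class EvaluationResult:
    """Per-alternative expected costs under one perspective, in € per patient.

    ``incremental`` is the expected cost of the last-declared alternative
    minus the comparator (first-declared); negative values are savings.
    """

    perspective: str
    expected_cost_by_alternative: Mapping[str, float]
    incremental: float = field(init=False)

    def __post_init__(self) -> None:
        costs = dict(self.expected_cost_by_alternative)
        object.__setattr__(self, "expected_cost_by_alternative", MappingProxyType(costs))
        values = list(costs.values())
        inc = values[-1] - values[0] if len(values) >= 2 else 0.0
        object.__setattr__(self, "incremental", inc)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvaluationResult):
            return NotImplemented
        return self.perspective == other.perspective and dict(
            self.expected_cost_by_alternative
        ) == dict(other.expected_cost_by_alternative)


class Path(NamedTuple):
    """One root-to-terminal path: visited node ids, probability, accrued cost."""

    nodes: tuple[str, ...]
    probability: float
    cost: float


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(
    tree: DecisionTree,
    params: Mapping[str, ProbabilityParameter],
    costbook: Costbook | None = None,
) -> list[str]:
    """Check every structural invariant; return violation descriptions.

    An empty list means the model is sound: the graph is a rooted tree with
    terminal leaves, every parameter and cost reference resolves, chance-node
    probabilities sum to one, and complement groups are consistent.
    """
    violations: list[str] = []

    if not tree.alternatives:
        violations.append("decision node has no alternatives")
    names = [name for name, _ in tree.alternatives]
    for name in names:
        if names.count(name) > 1:
            violations.append(f"alternative name {name!r} is duplicated")
            break

    for nid, node in tree.nodes.items():
        if not nid:
            violations.append("empty node id")
        if node.id != nid:
            violations.append(f"node registered as {nid!r} carries id {node.id!r}")
        if isinstance(node, TerminalNode) and node.location not in LOCATIONS:
            violations.append(
                f"terminal node {nid!r}: unknown location {node.location!r}"
            )

    def check_branch(branch: Branch, owner: str, chance: bool) -> None:
        if branch.child not in tree.nodes:
            violations.append(f"{owner}: branch child {branch.child!r} is not a known node")
        if chance:
            if branch.probability is None:
                violations.append(f"{owner}: chance branch to {branch.child!r} lacks a probability")
            elif branch.probability not in params:
                violations.append(
                    f"{owner}: probability reference {branch.probability!r} does not resolve"
                )
        if costbook is not None:
            for cid in branch.costs:
                if cid not in costbook.components:
                    violations.append(
                        f"{owner}: cost reference {cid!r} does not resolve"
                    )

    # Tree shape: every node reached exactly once from exactly one root branch.
    parent_count: dict[str, int] = {nid: 0 for nid in tree.nodes}
    for name, branch in tree.alternatives:
        check_branch(branch, f"alternative {name!r}", chance=False)
        if branch.child in parent_count:
            parent_count[branch.child] += 1
    for nid, node in tree.nodes.items():
        if isinstance(node, ChanceNode):
            if not node.branches:
                violations.append(f"chance node {nid!r} has no branches (leaf must be terminal)")
            for branch in node.branches:
                check_branch(branch, f"chance node {nid!r}", chance=True)
                if branch.child in parent_count:
                    parent_count[branch.child] += 1
            probs = [
                params[b.probability].base
                for b in node.branches
                if b.probability is not None and b.probability in params
            ]
            if len(probs) == len(node.branches) and abs(sum(probs) - 1.0) > PROB_TOL:
                violations.append(
                    f"chance node {nid!r}: branch probabilities sum to "
                    f"{sum(probs):.10g}, not 1"
                )
    for nid, count in parent_count.items():
        if count == 0:
            violations.append(f"node {nid!r} is unreachable from the root")
        elif count > 1:
            violations.append(f"node {nid!r} has {count} parents (graph is not a tree)")

    for pid, param in params.items():
        if not (0.0 <= param.base <= 1.0):
            violations.append(f"parameter {pid!r}: base {param.base} outside [0, 1]")
        if param.range is not None:
            low, high = param.range
            if not (0.0 <= low <= param.base <= high <= 1.0):
                violations.append(
                    f"parameter {pid!r}: range [{low}, {high}] must satisfy "
                    f"0 <= low <= base <= high <= 1"
                )
    groups: dict[str, list[ProbabilityParameter]] = {}
    for param in params.values():
        if param.complement_group is not None:
            groups.setdefault(param.complement_group, []).append(param)
    for gid, members in groups.items():
        if len(members) != 2:
            violations.append(
                f"complement group {gid!r} has {len(members)} members; exactly 2 required"
            )
        elif abs(sum(p.base for p in members) - 1.0) > PROB_TOL:
            violations.append(
                f"complement group {gid!r}: base values sum to "
                f"{sum(p.base for p in members):.10g}, not 1"
            )

    return violations


def validate_model(model: CmaModel) -> list[str]:
    return validate(model.tree, model.params, model.costbook)


# ---------------------------------------------------------------------------
# Evaluation: roll-back and path enumeration
# ---------------------------------------------------------------------------

def _param_value(
    params: Mapping[str, ProbabilityParameter],
    pid: str,
    prob_overrides: Mapping[str, float] | None,
) -> float:
    if prob_overrides and pid in prob_overrides:
        return float(prob_overrides[pid])
    return params[pid].base


def expected_cost(
    tree: DecisionTree,
    alternative: str,
    params: Mapping[str, ProbabilityParameter],
    costbook: Costbook,
    perspective: str = SOCIETAL,
    *,
    prob_overrides: Mapping[str, float] | None = None,
    cost_overrides: Mapping[str, float] | None = None,
) -> float:
    """Expected per-patient cost of one alternative by roll-back, in €.

    The value of a branch is the cost accrued taking it plus the value of
    its child; a chance node's value is the probability-weighted sum over
    its branches; terminals are worth zero.  Full floating precision —
    rounding to whole euros happens only in reporting.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")
    root_branch = tree.branch_for(alternative)

    def branch_value(branch: Branch) -> float:
        accrued = sum(
            costbook.component_cost(cid, perspective, cost_overrides) for cid in branch.costs
        )
        return accrued + node_value(tree.nodes[branch.child])

    def node_value(node: Node) -> float:
        if isinstance(node, TerminalNode):
            return 0.0
        return sum(
            _param_value(params, b.probability, prob_overrides) * branch_value(b)
            for b in node.branches
        )

    return branch_value(root_branch)


def enumerate_paths(
    tree: DecisionTree,
    alternative: str,
    params: Mapping[str, ProbabilityParameter],
    costbook: Costbook,
    perspective: str = SOCIETAL,
    *,
    prob_overrides: Mapping[str, float] | None = None,
    cost_overrides: Mapping[str, float] | None = None,
) -> list[Path]:
    """Exhaustive root-to-terminal path listing — the roll-back oracle.

    Each path's probability is the product of its branch probabilities and
    its cost the sum of accrued component costs under the perspective;
    Σ probability × cost over the returned paths equals ``expected_cost``.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")
    root_branch = tree.branch_for(alternative)
    paths: list[Path] = []

    def walk(branch: Branch, visited: tuple[str, ...], prob: float, cost: float) -> None:
        cost += sum(
            costbook.component_cost(cid, perspective, cost_overrides) for cid in branch.costs
        )
        node = tree.nodes[branch.child]
        visited = visited + (node.id,)
        if isinstance(node, TerminalNode):
            paths.append(Path(nodes=visited, probability=prob, cost=cost))
            return
        for child_branch in node.branches:
            p = _param_value(params, child_branch.probability, prob_overrides)
            walk(child_branch, visited, prob * p, cost)

    walk(root_branch, (), 1.0, 0.0)
    return paths


def evaluate(
    model: CmaModel,
    perspective: str = SOCIETAL,
    *,
    prob_overrides: Mapping[str, float] | None = None,
    cost_overrides: Mapping[str, float] | None = None,
) -> EvaluationResult:
    """Expected cost of every alternative plus the incremental cost."""
    costs = {
        name: expected_cost(
            model.tree,
            name,
            model.params,
            model.costbook,
            perspective,
            prob_overrides=prob_overrides,
            cost_overrides=cost_overrides,
        )
        for name in model.tree.alternative_names
    }
    return EvaluationResult(perspective=perspective, expected_cost_by_alternative=costs)


def incremental_cost(result: EvaluationResult) -> float:
    """Last-declared alternative minus comparator; negative = cost-saving."""
    if len(result.expected_cost_by_alternative) < 2:
        raise ValueError(
            "incremental cost requires at least two alternatives; got "
            f"{list(result.expected_cost_by_alternative)}"
        )
    return result.incremental
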