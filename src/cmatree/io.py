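"""YAML model configuration, config emission, and result writing.

The configuration format is a single YAML document describing alternatives,
chance/terminal nodes, probability parameters, cost components (optionally
annuitised capital items), cost groups and run settings.  The reader
schema-checks every key with its path, builds the model, and runs full
structural validation; ``emit_config`` round-trips a model back to the same
format.  Reports are plain CSV (RFC-4180, two-decimal €) and JSON (full
precision), written with fixed column order so identical runs are
byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Any, Mapping

import yaml

from .costing import (
    AnnuitySpec,
    BEARERS,
    Costbook,
    CostComponent,
    CostGroup,
    LOCATIONS,
    PERSPECTIVES,
    Remuneration,
    SOCIETAL,
    per_use_capital_cost,
)
from .model import (
    Branch,
    ChanceNode,
    CmaModel,
    DecisionTree,
    EvaluationResult,
    ProbabilityParameter,
    TerminalNode,
    validate_model,
)
from .sensitivity import PsaResult

__all__ = [
    "ModelConfig",
    "ConfigError",
    "ConfigSyntaxError",
    "ConfigSchemaError",
    "ConfigValidationError",
    "read_config",
    "parse_config",
    "emit_config",
    "write_config",
    "write_report",
]


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigSyntaxError(ConfigError):
    """The file is not well-formed YAML."""


class ConfigSchemaError(ConfigError):
    """A key or value violates the configuration schema."""


class ConfigValidationError(ConfigError):
    """The parsed model fails structural validation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("model validation failed:\n  " + "\n  ".join(violations))


@dataclass(frozen=True)
class ModelConfig:
    """A parsed configuration: the model plus run settings."""

    model: CmaModel
    perspective: str = SOCIETAL
    n_draws: int = 10_000
    seed: int = 0


# ---------------------------------------------------------------------------
# Schema helpers
# ---------------------------------------------------------------------------

def _require_mapping(value: Any, path: str) -> Mapping:
    if not isinstance(value, Mapping):
        raise ConfigSchemaError(f"{path}: expected a mapping, got {type(value).__name__}")
    return value


def _check_keys(value: Mapping, path: str, allowed: set[str], required: set[str] = frozenset()) -> None:
    for key in value:
        if key not in allowed:
            raise ConfigSchemaError(f"{path}.{key}: unknown key (allowed: {sorted(allowed)})")
    for key in required:
        if key not in value:
            raise ConfigSchemaError(f"{path}: missing required key {key!r}")


def _number(value: Any, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigSchemaError(f"{path}: expected a number, got {value!r}")
    return float(value)


def _probability(value: Any, path: str) -> float:
    x = _number(value, path)
    if not (0.0 <= x <= 1.0):
        raise ConfigSchemaError(f"{path}: probability {x} outside [0, 1]")
    return x


def _range(value: Any, path: str) -> tuple[float, float]:
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise ConfigSchemaError(f"{path}: expected [low, high]")
    return (_number(value[0], f"{path}[0]"), _number(value[1], f"{path}[1]"))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_config(path: str | FsPath) -> ModelConfig:
    """Read and fully validate a YAML model configuration.

    Raises ``FileNotFoundError`` for a missing file, ``ConfigSyntaxError``
    for malformed YAML, ``ConfigSchemaError`` for schema violations (with
    the offending key path), and ``ConfigValidationError`` when the parsed
    model breaks a structural invariant.
    """
    path = FsPath(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigSyntaxError(f"{path}: malformed YAML: {exc}") from exc
    return parse_config(raw)


def parse_config(raw: Any) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from parsed YAML data."""
    doc = _require_mapping(raw, "<root>")
    _check_keys(doc, "<root>",
                {"alternatives", "nodes", "parameters", "costs", "cost_groups", "run"},
                required={"alternatives", "nodes", "parameters", "costs"})

    # parameters
    params: dict[str, ProbabilityParameter] = {}
    for pid, spec in _require_mapping(doc["parameters"], "parameters").items():
        p = f"parameters.{pid}"
        spec = _require_mapping(spec, p)
        _check_keys(spec, p, {"base", "range", "complement_group", "psa", "source"},
                    required={"base"})
        params[pid] = ProbabilityParameter(
            id=pid,
            base=_probability(spec["base"], f"{p}.base"),
            range=_range(spec["range"], f"{p}.range") if "range" in spec else None,
            complement_group=spec.get("complement_group"),
            psa_included=bool(spec.get("psa", True)),
            source=str(spec.get("source", "")),
        )

    # cost components
    components: dict[str, CostComponent] = {}
    for cid, spec in _require_mapping(doc["costs"], "costs").items():
        p = f"costs.{cid}"
        spec = _require_mapping(spec, p)
        _check_keys(spec, p,
                    {"location", "bearer", "quantity", "unit_price", "annuity",
                     "applies_to", "range", "group", "psa", "source"},
                    required={"location", "bearer"})
        if "annuity" in spec:
            a = _require_mapping(spec["annuity"], f"{p}.annuity")
            _check_keys(a, f"{p}.annuity",
                        {"capital", "lifespan_years", "annual_rate", "annual_uses",
                         "use_fraction"},
                        required={"capital", "lifespan_years", "annual_rate", "annual_uses"})
            annuity = AnnuitySpec(
                capital=_number(a["capital"], f"{p}.annuity.capital"),
                lifespan_years=_number(a["lifespan_years"], f"{p}.annuity.lifespan_years"),
                annual_rate=_number(a["annual_rate"], f"{p}.annuity.annual_rate"),
                annual_uses=_number(a["annual_uses"], f"{p}.annuity.annual_uses"),
                use_fraction=_number(a.get("use_fraction", 1.0), f"{p}.annuity.use_fraction"),
            )
            quantity, unit_price = 1.0, per_use_capital_cost(annuity)
        else:
            if "quantity" not in spec or "unit_price" not in spec:
                raise ConfigSchemaError(f"{p}: needs quantity+unit_price or annuity")
            quantity = _number(spec["quantity"], f"{p}.quantity")
            unit_price = _number(spec["unit_price"], f"{p}.unit_price")
        if spec["location"] not in LOCATIONS:
            raise ConfigSchemaError(f"{p}.location: unknown location {spec['location']!r}")
        if spec["bearer"] not in BEARERS:
            raise ConfigSchemaError(f"{p}.bearer: unknown bearer {spec['bearer']!r}")
        components[cid] = CostComponent(
            id=cid,
            location=spec["location"],
            bearer=spec["bearer"],
            quantity=quantity,
            unit_price=unit_price,
            applies_to=str(spec.get("applies_to", "both")),
            range=_range(spec["range"], f"{p}.range") if "range" in spec else None,
            group=spec.get("group"),
            psa_included=bool(spec.get("psa", True)),
            source=str(spec.get("source", "")),
        )

    groups: dict[str, CostGroup] = {}
    for gid, spec in _require_mapping(doc.get("cost_groups", {}) or {}, "cost_groups").items():
        p = f"cost_groups.{gid}"
        spec = _require_mapping(spec, p)
        _check_keys(spec, p, {"members", "range"}, required={"members"})
        members = spec["members"]
        if not isinstance(members, list):
            raise ConfigSchemaError(f"{p}.members: expected a list")
        for m in members:
            if m not in components:
                raise ConfigSchemaError(f"{p}.members: unknown component {m!r}")
        groups[gid] = CostGroup(
            id=gid, members=tuple(members),
            range=_range(spec["range"], f"{p}.range") if "range" in spec else None,
        )

    # nodes
    nodes: dict[str, Any] = {}
    for nid, spec in _require_mapping(doc["nodes"], "nodes").items():
        p = f"nodes.{nid}"
        spec = _require_mapping(spec, p)
        _check_keys(spec, p, {"kind", "location", "branches"}, required={"kind"})
        kind = spec["kind"]
        if kind == "terminal":
            _check_keys(spec, p, {"kind", "location"}, required={"kind", "location"})
            nodes[nid] = TerminalNode(nid, spec["location"])
        elif kind == "chance":
            _check_keys(spec, p, {"kind", "branches"}, required={"kind", "branches"})
            branches = []
            for i, bspec in enumerate(spec["branches"]):
                bp = f"{p}.branches[{i}]"
                bspec = _require_mapping(bspec, bp)
                _check_keys(bspec, bp, {"to", "p", "costs"}, required={"to", "p"})
                branches.append(Branch(
                    child=str(bspec["to"]),
                    probability=str(bspec["p"]),
                    costs=tuple(bspec.get("costs", ()) or ()),
                ))
            nodes[nid] = ChanceNode(nid, tuple(branches))
        else:
            raise ConfigSchemaError(f"{p}.kind: expected 'chance' or 'terminal', got {kind!r}")

    # alternatives
    alts_spec = doc["alternatives"]
    if not isinstance(alts_spec, list):
        raise ConfigSchemaError("alternatives: expected a list")
    alternatives = []
    for i, aspec in enumerate(alts_spec):
        p = f"alternatives[{i}]"
        aspec = _require_mapping(aspec, p)
        _check_keys(aspec, p, {"name", "node", "costs"}, required={"name", "node"})
        alternatives.append((
            str(aspec["name"]),
            Branch(child=str(aspec["node"]), costs=tuple(aspec.get("costs", ()) or ())),
        ))

    tree = DecisionTree(alternatives=tuple(alternatives), nodes=nodes)
    model = CmaModel(tree=tree, params=params, costbook=Costbook(components, groups))
    violations = validate_model(model)
    if violations:
        raise ConfigValidationError(violations)

    run = _require_mapping(doc.get("run", {}) or {}, "run")
    _check_keys(run, "run", {"perspective", "n_draws", "seed"})
    perspective = run.get("perspective", SOCIETAL)
    if perspective not in PERSPECTIVES:
        raise ConfigSchemaError(f"run.perspective: unknown perspective {perspective!r}")
    return ModelConfig(
        model=model,
        perspective=perspective,
        n_draws=int(run.get("n_draws", 10_000)),
        seed=int(run.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Emission (round-trip)
# ---------------------------------------------------------------------------

def emit_config(model: CmaModel, *, perspective: str = SOCIETAL,
                n_draws: int = 10_000, seed: int = 0) -> dict:
    """Model → plain-data configuration; ``parse_config`` of it round-trips."""
    doc: dict[str, Any] = {
        "alternatives": [
            {"name": name, "node": branch.child, "costs": list(branch.costs)}
            for name, branch in model.tree.alternatives
        ],
        "nodes": {},
        "parameters": {},
        "costs": {},
        "run": {"perspective": perspective, "n_draws": n_draws, "seed": seed},
    }
    for nid, node in model.tree.nodes.items():
        if isinstance(node, TerminalNode):
            doc["nodes"][nid] = {"kind": "terminal", "location": node.location}
        else:
            doc["nodes"][nid] = {"kind": "chance", "branches": [
                {"to": b.child, "p": b.probability, "costs": list(b.costs)}
                for b in node.branches
            ]}
    for pid, param in model.params.items():
        spec: dict[str, Any] = {"base": param.base}
        if param.range is not None:
            spec["range"] = list(param.range)
        if param.complement_group is not None:
            spec["complement_group"] = param.complement_group
        if not param.psa_included:
            spec["psa"] = False
        if param.source:
            spec["source"] = param.source
        doc["parameters"][pid] = spec
    for cid, comp in model.costbook.components.items():
        cspec: dict[str, Any] = {
            "location": comp.location, "bearer": comp.bearer,
            "quantity": comp.quantity, "unit_price": comp.unit_price,
        }
        if comp.applies_to != "both":
            cspec["applies_to"] = comp.applies_to
        if comp.range is not None:
            cspec["range"] = list(comp.range)
        if comp.group is not None:
            cspec["group"] = comp.group
        if not comp.psa_included:
            cspec["psa"] = False
        if comp.source:
            cspec["source"] = comp.source
        doc["costs"][cid] = cspec
    if model.costbook.groups:
        doc["cost_groups"] = {
            gid: ({"members": list(g.members), "range": list(g.range)}
                  if g.range is not None else {"members": list(g.members)})
            for gid, g in model.costbook.groups.items()
        }
    return doc


def write_config(model: CmaModel, path: str | FsPath, **run: Any) -> None:
    FsPath(path).write_text(
        yaml.safe_dump(emit_config(model, **run), sort_keys=False, allow_unicode=True)
    )


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _write_csv(path: FsPath, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def write_report(
    results: Mapping[str, Any],
    out_dir: str | FsPath,
) -> list[FsPath]:
    """Write whatever results are present to ``out_dir``; return the files.

    Recognised keys: ``evaluation`` (:class:`EvaluationResult`), ``tornado``
    (list of :class:`TornadoEntry`, already ranked), ``psa``
    (:class:`PsaResult`), ``remuneration`` (:class:`Remuneration`).  CSV
    carries two-decimal €, JSON full precision, the human summary whole €.
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[FsPath] = []

    evaluation = results.get("evaluation")
    if evaluation is not None:
        assert isinstance(evaluation, EvaluationResult)
        rounded = {
            name: round(cost)
            for name, cost in evaluation.expected_cost_by_alternative.items()
        }
        rounded_values = list(rounded.values())
        # headline incremental as the difference of the rounded averages
        # (the convention of the underlying study: 235 − 125 → 110)
        inc_from_rounded = (
            rounded_values[-1] - rounded_values[0] if len(rounded_values) >= 2 else 0
        )
        payload = {
            "perspective": evaluation.perspective,
            "expected_cost_eur": dict(evaluation.expected_cost_by_alternative),
            "incremental_eur": evaluation.incremental,
            "expected_cost_rounded_eur": rounded,
            "incremental_rounded_eur": round(evaluation.incremental),
            "incremental_from_rounded_eur": inc_from_rounded,
        }
        jpath = out / "evaluation.json"
        jpath.write_text(json.dumps(payload, indent=2) + "\n")
        written.append(jpath)
        lines = [f"Perspective: {evaluation.perspective}"]
        for name, cost in evaluation.expected_cost_by_alternative.items():
            lines.append(f"  {name}: EUR {round(cost)} per patient ({cost:.2f})")
        inc = evaluation.incremental
        lines.append(f"  incremental (full precision): EUR {inc:.2f}")
        lines.append(
            f"  cost-saving of the intervention: EUR {-inc_from_rounded} per "
            "patient (difference of rounded averages)"
        )
        tpath = out / "evaluation.txt"
        tpath.write_text("\n".join(lines) + "\n")
        written.append(tpath)

    tornado_entries = results.get("tornado")
    if tornado_entries is not None:
        rows = [
            [e.parameter_id, f"{e.low:.4f}", f"{e.high:.4f}",
             f"{e.incremental_at_low:.2f}", f"{e.incremental_at_high:.2f}",
             f"{e.swing:.2f}"]
            for e in tornado_entries
        ]
        path = out / "tornado.csv"
        _write_csv(path, ["parameter", "low", "high",
                          "incremental_low", "incremental_high", "swing"], rows)
        written.append(path)

    psa = results.get("psa")
    if psa is not None:
        assert isinstance(psa, PsaResult)
        dpath = out / "psa_draws.csv"
        _write_csv(dpath, ["draw", "incremental_eur"],
                   [[str(i), f"{x:.2f}"] for i, x in enumerate(psa.draws)])
        written.append(dpath)
        spath = out / "psa_summary.json"
        spath.write_text(json.dumps({
            "mean": psa.mean, "sd": psa.sd,
            "p2.5": psa.p2_5, "p97.5": psa.p97_5,
            "fraction_cost_saving": psa.fraction_cost_saving,
            "n": psa.n_draws, "seed": psa.seed,
        }, indent=2) + "\n")
        written.append(spath)

    remun = results.get("remuneration")
    if remun is not None:
        assert isinstance(remun, Remuneration)
        rows = [[label, f"{cost:.2f}"] for label, cost in remun.components]
        rows.append(["total", f"{remun.total:.2f}"])
        path = out / "remuneration.csv"
        _write_csv(path, ["label", "EUR"], rows)
        written.append(path)

    return written
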