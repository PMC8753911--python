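"""Built-in case study and synthetic-input generators.

``build_paper_model`` encodes the package's reference model: a Danish
general-practice pathway for women with vaginal bleeding in early pregnancy,
comparing usual practice (GP refers every patient to a private
gynaecologist or a hospital gynaecology department) against an intervention
where the GP performs point-of-care ultrasound and completes management for
most patients.  All probabilities, resource use and 2019 € unit prices are
the published base-case inputs.

The referral probabilities in that model came from a questionnaire of 21
ultrasound-using GPs, aggregated as arithmetic means with min/max ranges.
``simulate_gp_responses`` generates a synthetic stand-in panel of per-GP
probability estimates (the raw responses are not public) and
``aggregate_questionnaire`` performs the same aggregation.
``random_model`` builds arbitrary valid decision trees for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .costing import (
    BEARER_HEALTHCARE,
    BEARER_PATIENT,
    GP,
    HOSPITAL,
    LOCATIONS,
    PRIVATE_GYNAECOLOGIST,
    Costbook,
    CostComponent,
    CostGroup,
)
from .model import (
    Branch,
    ChanceNode,
    CmaModel,
    DecisionTree,
    ProbabilityParameter,
    TerminalNode,
)
from .sensitivity import beta_from_mean_sd

__all__ = [
    "USUAL_PRACTICE",
    "INTERVENTION",
    "QuestionnairePanel",
    "build_paper_model",
    "aggregate_questionnaire",
    "simulate_gp_responses",
    "random_model",
]

USUAL_PRACTICE = "usual_practice"
INTERVENTION = "intervention"

# Patient-borne unit prices (2019 €): lost earnings per minute and mileage
# compensation per km.  Fixed in the probabilistic analysis.
PATIENT_TIME_EUR_PER_MIN = 0.408
MILEAGE_EUR_PER_KM = 0.473
GP_SCAN_TIME_EUR_PER_MIN = 1.807

_MIN = PATIENT_TIME_EUR_PER_MIN
_KM = MILEAGE_EUR_PER_KM


def _components() -> dict[str, CostComponent]:
    """Base-case cost components; ranges are per-visit € (resource-use
    ranges stated in minutes or km are converted at the fixed unit price)."""
    comps = [
        # --- general practice, healthcare-borne ---
        CostComponent("gp_consult_tariff", GP, BEARER_HEALTHCARE, 1, 19.02,
                      applies_to="both", range=(19.02, 19.25), source="national tariff"),
        # 10 min of GP time per scan; no published range, held at base.
        CostComponent("gp_scan_time", GP, BEARER_HEALTHCARE, 10, GP_SCAN_TIME_EUR_PER_MIN,
                      applies_to=INTERVENTION, source="tariff"),
        # Scanner and training are stored as their published per-scan
        # annuitised costs; the range is on the per-scan cost.
        CostComponent("scanner", GP, BEARER_HEALTHCARE, 1, 7.54,
                      applies_to=INTERVENTION, range=(1.30, 13.77),
                      source="annuitised €15,508.70 scanner, indication share"),
        CostComponent("ceclus_training", GP, BEARER_HEALTHCARE, 1, 5.81,
                      applies_to=INTERVENTION, range=(3.35, 5.81),
                      source="annuitised CECLUS heartbeat module"),
        # Consumables per scan, varied jointly as the 'utensils' bundle.
        CostComponent("wet_wipes", GP, BEARER_HEALTHCARE, 2, 0.054,
                      applies_to=INTERVENTION, group="utensils"),
        CostComponent("transducer_cover", GP, BEARER_HEALTHCARE, 1, 0.24,
                      applies_to=INTERVENTION, group="utensils"),
        CostComponent("gel", GP, BEARER_HEALTHCARE, 10, 0.021,
                      applies_to=INTERVENTION, group="utensils"),
        # --- specialist tariffs, healthcare-borne ---
        CostComponent("gyn_consult_tariff", PRIVATE_GYNAECOLOGIST, BEARER_HEALTHCARE,
                      1, 96.78, applies_to="both", range=(96.78, 97.99),
                      source="national tariff incl. ultrasound"),
        CostComponent("hospital_drg_tariff", HOSPITAL, BEARER_HEALTHCARE,
                      1, 164.26, applies_to="both", range=(164.26, 164.79),
                      source="DRG tariff DO209/UXUD82"),
        # --- patient time (lost earnings), minutes × €0.408 ---
        CostComponent("patient_time_gp_usual", GP, BEARER_PATIENT, 15, _MIN,
                      applies_to=USUAL_PRACTICE, range=(5 * _MIN, 15 * _MIN)),
        CostComponent("patient_time_gp_pocus", GP, BEARER_PATIENT, 25, _MIN,
                      applies_to=INTERVENTION, range=(13 * _MIN, 26 * _MIN)),
        CostComponent("patient_time_gyn", PRIVATE_GYNAECOLOGIST, BEARER_PATIENT, 25, _MIN,
                      applies_to="both", range=(13 * _MIN, 26 * _MIN)),
        CostComponent("patient_time_hospital", HOSPITAL, BEARER_PATIENT, 25, _MIN,
                      applies_to="both", range=(13 * _MIN, 26 * _MIN)),
        # --- transport distance, round-trip km × €0.473 ---
        CostComponent("transport_km_gp", GP, BEARER_PATIENT, 9.5, _KM,
                      applies_to="both", range=(0.2 * _KM, 42 * _KM)),
        CostComponent("transport_km_gyn", PRIVATE_GYNAECOLOGIST, BEARER_PATIENT, 39.2, _KM,
                      applies_to="both", range=(0.2 * _KM, 100 * _KM)),
        CostComponent("transport_km_hospital", HOSPITAL, BEARER_PATIENT, 39.2, _KM,
                      applies_to="both", range=(0.2 * _KM, 100 * _KM)),
        # --- transport time, published minutes × €0.408 (11 min stored as
        # printed, not the 11.4 the 50 km/h rule implies) ---
        CostComponent("transport_min_gp", GP, BEARER_PATIENT, 11, _MIN,
                      applies_to="both", range=(0.24 * _MIN, 50.40 * _MIN)),
        CostComponent("transport_min_gyn", PRIVATE_GYNAECOLOGIST, BEARER_PATIENT, 47, _MIN,
                      applies_to="both", range=(0.24 * _MIN, 120 * _MIN)),
        CostComponent("transport_min_hospital", HOSPITAL, BEARER_PATIENT, 47, _MIN,
                      applies_to="both", range=(0.24 * _MIN, 120 * _MIN)),
    ]
    return {c.id: c for c in comps}


def _parameters() -> dict[str, ProbabilityParameter]:
    """Referral probabilities with questionnaire min/max ranges.

    Within each complement pair the first-declared member is the sampled /
    tornado-primary one; completion-at-GP is declared before its referral
    complement so it carries its group's bar.
    """
    params = [
        ProbabilityParameter("p_up_refer_gyn", 0.23, range=(0.00, 1.00),
                             complement_group="up_referral", source="questionnaire"),
        ProbabilityParameter("p_up_refer_hospital", 0.77, range=(0.00, 1.00),
                             complement_group="up_referral", source="questionnaire"),
        ProbabilityParameter("p_gyn_complete", 0.92, range=(0.92, 1.00),
                             complement_group="gyn_outcome", source="specialist report"),
        ProbabilityParameter("p_gyn_refer_hospital", 0.08, range=(0.00, 0.08),
                             complement_group="gyn_outcome", source="specialist report"),
        ProbabilityParameter("p_pocus_complete_gp", 0.73, range=(0.40, 0.98),
                             complement_group="pocus_completion", source="questionnaire"),
        ProbabilityParameter("p_pocus_refer", 0.27, range=(0.02, 0.60),
                             complement_group="pocus_completion", source="questionnaire"),
        ProbabilityParameter("p_pocus_refer_gyn", 0.16, range=(0.00, 1.00),
                             complement_group="pocus_referral", source="questionnaire"),
        ProbabilityParameter("p_pocus_refer_hospital", 0.84, range=(0.00, 1.00),
                             complement_group="pocus_referral", source="questionnaire"),
    ]
    return {p.id: p for p in params}


# Per-visit cost bundles accrued on entering each location.
_GP_USUAL_COSTS = ("gp_consult_tariff", "patient_time_gp_usual",
                   "transport_km_gp", "transport_min_gp")
_GP_POCUS_COSTS = ("gp_consult_tariff", "gp_scan_time", "scanner", "ceclus_training",
                   "wet_wipes", "transducer_cover", "gel",
                   "patient_time_gp_pocus", "transport_km_gp", "transport_min_gp")
_GYN_COSTS = ("gyn_consult_tariff", "patient_time_gyn",
              "transport_km_gyn", "transport_min_gyn")
_HOSPITAL_COSTS = ("hospital_drg_tariff", "patient_time_hospital",
                   "transport_km_hospital", "transport_min_hospital")


def build_paper_model() -> CmaModel:
    """The full built-in case study: tree, probabilities, costbook.

    Deterministic and side-effect-free; the result passes validation with
    no violations and reproduces the published per-patient expected costs.
    """
    nodes = {
        # usual practice: GP refers everyone
        "up_referral": ChanceNode("up_referral", (
            Branch("up_gyn", "p_up_refer_gyn", _GYN_COSTS),
            Branch("up_complete_hospital_direct", "p_up_refer_hospital", _HOSPITAL_COSTS),
        )),
        "up_gyn": ChanceNode("up_gyn", (
            Branch("up_complete_gyn", "p_gyn_complete"),
            Branch("up_complete_hospital_referred", "p_gyn_refer_hospital", _HOSPITAL_COSTS),
        )),
        "up_complete_gyn": TerminalNode("up_complete_gyn", PRIVATE_GYNAECOLOGIST),
        "up_complete_hospital_referred": TerminalNode("up_complete_hospital_referred", HOSPITAL),
        "up_complete_hospital_direct": TerminalNode("up_complete_hospital_direct", HOSPITAL),
        # intervention: GP scans, completes most patients
        "iv_completion": ChanceNode("iv_completion", (
            Branch("iv_complete_gp", "p_pocus_complete_gp"),
            Branch("iv_referral", "p_pocus_refer"),
        )),
        "iv_referral": ChanceNode("iv_referral", (
            Branch("iv_gyn", "p_pocus_refer_gyn", _GYN_COSTS),
            Branch("iv_complete_hospital_direct", "p_pocus_refer_hospital", _HOSPITAL_COSTS),
        )),
        "iv_gyn": ChanceNode("iv_gyn", (
            Branch("iv_complete_gyn", "p_gyn_complete"),
            Branch("iv_complete_hospital_referred", "p_gyn_refer_hospital", _HOSPITAL_COSTS),
        )),
        "iv_complete_gp": TerminalNode("iv_complete_gp", GP),
        "iv_complete_gyn": TerminalNode("iv_complete_gyn", PRIVATE_GYNAECOLOGIST),
        "iv_complete_hospital_referred": TerminalNode("iv_complete_hospital_referred", HOSPITAL),
        "iv_complete_hospital_direct": TerminalNode("iv_complete_hospital_direct", HOSPITAL),
    }
    tree = DecisionTree(
        alternatives=(
            (USUAL_PRACTICE, Branch("up_referral", costs=_GP_USUAL_COSTS)),
            (INTERVENTION, Branch("iv_completion", costs=_GP_POCUS_COSTS)),
        ),
        nodes=nodes,
    )
    costbook = Costbook(
        components=_components(),
        groups={"utensils": CostGroup("utensils",
                                      ("wet_wipes", "transducer_cover", "gel"),
                                      range=(0.34, 0.56))},
    )
    return CmaModel(tree=tree, params=_parameters(), costbook=costbook)


# ---------------------------------------------------------------------------
# Questionnaire panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuestionnairePanel:
    """Per-GP probability estimates for each referral question."""

    responses: Mapping[str, tuple[float, ...]]
    n_gps: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "responses",
            {q: tuple(float(r) for r in rs) for q, rs in dict(self.responses).items()},
        )
        for q, rs in self.responses.items():
            for r in rs:
                if not (0.0 <= r <= 1.0):
                    raise ValueError(f"question {q!r}: response {r} outside [0, 1]")


def aggregate_questionnaire(
    panel: QuestionnairePanel,
) -> tuple[dict[str, float], dict[str, tuple[float, float]]]:
    """Arithmetic mean per question, and [min, max] response as the range."""
    if panel.n_gps < 1 or not panel.responses:
        raise ValueError("cannot aggregate an empty questionnaire panel")
    means: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for question, responses in panel.responses.items():
        if not responses:
            raise ValueError(f"question {question!r} has no responses")
        means[question] = float(np.mean(responses))
        ranges[question] = (min(responses), max(responses))
    return means, ranges


def simulate_gp_responses(
    n_gps: int,
    true_mean: float,
    dispersion: float,
    seed: int,
    question: str = "completion_at_gp",
) -> QuestionnairePanel:
    """Synthetic panel of beta-distributed per-GP probability estimates.

    ``dispersion`` is the standard deviation of the response distribution;
    zero dispersion yields identical responses at ``true_mean``.
    """
    if n_gps < 1:
        raise ValueError("n_gps must be >= 1")
    dist = beta_from_mean_sd(true_mean, dispersion)  # raises on invalid moments
    rng = np.random.default_rng(seed)
    responses = tuple(float(x) for x in dist.sample(rng, n_gps))
    return QuestionnairePanel(responses={question: responses}, n_gps=n_gps)


# ---------------------------------------------------------------------------
# Random model generator for property tests
# ---------------------------------------------------------------------------

def random_model(seed: int, max_depth: int = 3, max_branching: int = 3) -> CmaModel:
    """A random valid decision model with two alternatives.

    Chance-node probabilities are Dirichlet-normalised; component costs are
    non-negative with random location/bearer tags.  Binary chance nodes get
    complement groups.  Always passes validation; seeded and reproducible.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: dict[str, object] = {}
    params: dict[str, ProbabilityParameter] = {}
    components: dict[str, CostComponent] = {}
    counter = {"node": 0, "param": 0, "comp": 0}

    def new_components(max_n: int = 2) -> tuple[str, ...]:
        ids = []
        for _ in range(int(rng.integers(0, max_n + 1))):
            counter["comp"] += 1
            cid = f"c{counter['comp']}"
            components[cid] = CostComponent(
                id=cid,
                location=LOCATIONS[int(rng.integers(0, len(LOCATIONS)))],
                bearer=(BEARER_HEALTHCARE, BEARER_PATIENT)[int(rng.integers(0, 2))],
                quantity=float(rng.uniform(0, 10)),
                unit_price=float(rng.uniform(0, 50)),
            )
            ids.append(cid)
        return tuple(ids)

    def grow(depth: int) -> str:
        counter["node"] += 1
        nid = f"n{counter['node']}"
        if depth >= max_depth or rng.uniform() < 0.3:
            nodes[nid] = TerminalNode(nid, LOCATIONS[int(rng.integers(0, len(LOCATIONS)))])
            return nid
        k = int(rng.integers(2, max_branching + 1))
        probs = rng.dirichlet(np.ones(k))
        probs = probs / probs.sum()  # exact renormalisation
        group = f"g{nid}" if k == 2 else None
        branches = []
        for p in probs:
            counter["param"] += 1
            pid = f"p{counter['param']}"
            params[pid] = ProbabilityParameter(pid, float(p), complement_group=group)
            branches.append(Branch(grow(depth + 1), pid, new_components()))
        nodes[nid] = ChanceNode(nid, tuple(branches))
        return nid

    alternatives = tuple(
        (name, Branch(grow(1), costs=new_components()))
        for name in (USUAL_PRACTICE, INTERVENTION)
    )
    # binary-group bases can drift off 1 by float error; repair exactly
    for gid, members in _group_members(params).items():
        if len(members) == 2:
            first = params[members[0]]
            params[members[1]] = ProbabilityParameter(
                members[1], 1.0 - first.base, complement_group=gid
            )
    tree = DecisionTree(alternatives=alternatives, nodes=nodes)
    return CmaModel(tree=tree, params=params, costbook=Costbook(components=components))


def _group_members(params: Mapping[str, ProbabilityParameter]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for pid, p in params.items():
        if p.complement_group is not None:
            groups.setdefault(p.complement_group, []).append(pid)
    return groups
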