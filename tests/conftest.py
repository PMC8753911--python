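"""Shared fixtures and an independent hand-arithmetic oracle.

The ``hand`` fixture re-derives every headline quantity of the built-in
case study from raw resource use × unit price and explicit path
enumeration, without touching the package's roll-back code, so tests can
compare the implementation against an independent calculation.
"""

from types import SimpleNamespace

import pytest

from cmatree import build_paper_model


def _hand_values() -> SimpleNamespace:
    # per-visit costs from raw quantities and unit prices
    gp_usual = 19.02 + 15 * 0.408 + 9.5 * 0.473 + 11 * 0.408
    gp_addon = 10 * 1.807 + 7.54 + 5.81 + 2 * 0.054 + 1 * 0.24 + 10 * 0.021
    gp_pocus = 19.02 + gp_addon + 25 * 0.408 + 9.5 * 0.473 + 11 * 0.408
    gyn = 96.78 + 25 * 0.408 + 39.2 * 0.473 + 47 * 0.408
    hosp = 164.26 + 25 * 0.408 + 39.2 * 0.473 + 47 * 0.408

    # explicit path enumeration, societal perspective
    usual = gp_usual + 0.23 * (gyn + 0.08 * hosp) + 0.77 * hosp
    iv = gp_pocus + 0.27 * (0.16 * (gyn + 0.08 * hosp) + 0.84 * hosp)

    # healthcare perspective: tariffs and GP add-on only
    usual_hc = 19.02 + 0.23 * (96.78 + 0.08 * 164.26) + 0.77 * 164.26
    iv_hc = 19.02 + gp_addon + 0.27 * (0.16 * (96.78 + 0.08 * 164.26) + 0.84 * 164.26)

    # referred-branch continuation value after the GP visit in the intervention
    referral_value = 0.16 * (gyn + 0.08 * hosp) + 0.84 * hosp
    return SimpleNamespace(
        gp_usual=gp_usual,
        gp_addon=gp_addon,
        gp_pocus=gp_pocus,
        gyn_visit=gyn,
        hospital_visit=hosp,
        usual_societal=usual,
        intervention_societal=iv,
        incremental_societal=iv - usual,
        usual_healthcare=usual_hc,
        intervention_healthcare=iv_hc,
        incremental_healthcare=iv_hc - usual_hc,
        referral_value=referral_value,
        one_way_completion_low=(gp_pocus + 0.60 * referral_value) - usual,
        one_way_completion_high=(gp_pocus + 0.02 * referral_value) - usual,
    )


@pytest.fixture(scope="session")
def hand() -> SimpleNamespace:
    return _hand_values()


@pytest.fixture(scope="session")
def paper_model():
    return build_paper_model()
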