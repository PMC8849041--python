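"""Registry of simulation parameterizations for the nonadherence study.

Each simulation *setting* corresponds to one causal structure:

``S1``
    Logistic treatment and outcome models; measured confounders ``L1``
    (continuous) and ``L2`` (binary) block every backdoor path, so the
    exclusion restriction holds and there is no residual unmeasured
    confounding after adjustment.  Null treatment effect throughout.
``S2``
    Linear-probability treatment and outcome models; the unmeasured
    confounder ``U`` opens a backdoor path that ``L`` cannot close.
``S3``
    Linear-probability models with a direct effect of randomization on
    the outcome (exclusion-restriction violation of severity ``theta5``).
``A1`` / ``A2``
    Simplified designs without measured confounders (one unmeasured
    confounder only), mirroring the shape of a trial where no baseline
    covariates were collected.  ``A1`` satisfies the exclusion
    restriction; ``A2`` violates it.

Scenario parameter rows are shipped as TSV data files (one per setting,
one row per scenario-arm) so that the registry can be diffed and audited
as plain data rather than buried in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Literal

import pandas as pd

__all__ = ["Setting", "ScenarioConfig", "get_scenario", "list_scenarios", "SETTINGS"]

Setting = Literal["S1", "S2", "S3", "A1", "A2"]

SETTINGS: tuple[str, ...] = ("S1", "S2", "S3", "A1", "A2")

#: registry size per setting
_SIZES = {"S1": 12, "S2": 60, "S3": 24, "A1": 60, "A2": 24}

#: setting-level constants: covariate distributions and link functions.
#: u_dist is ("uniform01", None) or ("bernoulli", p); l2_spec is the
#: (intercept, U, L1) coefficient triple of the logistic model for L2.
_SETTING_CONSTANTS = {
    "S1": dict(u_dist=("uniform01", None), lambda0=0.0, lambda1=6.0, sigma=2.0,
               l2_spec=(-5.0, 3.0, 1.25), link_treat="inverse_logit",
               link_outcome="inverse_logit", has_covariates=True),
    "S2": dict(u_dist=("bernoulli", 0.5), lambda0=3.0, lambda1=0.0, sigma=0.5,
               l2_spec=(-3.5, 0.0, 0.6), link_treat="linear",
               link_outcome="linear", has_covariates=True),
    "S3": dict(u_dist=("bernoulli", 0.5), lambda0=3.0, lambda1=0.05, sigma=0.5,
               l2_spec=(-3.5, 0.1, 0.6), link_treat="linear",
               link_outcome="linear", has_covariates=True),
    "A1": dict(u_dist=("bernoulli", 0.5), lambda0=None, lambda1=None, sigma=None,
               l2_spec=None, link_treat="linear", link_outcome="linear",
               has_covariates=False),
    "A2": dict(u_dist=("bernoulli", 0.5), lambda0=None, lambda1=None, sigma=None,
               l2_spec=None, link_treat="linear", link_outcome="linear",
               has_covariates=False),
}

_DATA_FILES = {s: f"setting_{s.lower()}.tsv" for s in SETTINGS}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: treatment/outcome model coefficients,
    covariate-distribution parameters, and the evaluation truth.

    The treatment model linear predictor is
    ``alpha0(arm) + alpha1*Z + alpha2*L1 + alpha3*L2 + alpha4*U`` and the
    outcome model linear predictor is
    ``theta0 + theta1*A + theta2*L1 + theta3*L2 + theta4*U + theta5*Z``,
    each pushed through ``link_treat`` / ``link_outcome`` (``inverse_logit``
    or ``linear``, i.e. the predictor is already a probability).

    ``true_rd`` is the target risk difference used in bias/coverage
    evaluation: 0 for S1 (null effect on the logit scale) and ``theta1``
    for the linear-link settings, where the marginal RD equals the
    ``A``-coefficient because the outcome model is linear in ``A``.
    """

    setting: str
    scenario_id: int
    alpha0_treat: float
    alpha0_control: float
    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float
    nonadherence_treat: int
    nonadherence_control: int
    u_dist: tuple = field(repr=False)
    lambda0: float | None = field(repr=False, default=None)
    lambda1: float | None = field(repr=False, default=None)
    sigma: float | None = field(repr=False, default=None)
    l2_spec: tuple | None = field(repr=False, default=None)
    link_treat: str = "inverse_logit"
    link_outcome: str = "inverse_logit"
    has_covariates: bool = True

    @property
    def true_rd(self) -> float:
        if self.setting == "S1":
            return 0.0
        return self.theta1

    def to_dict(self) -> dict:
        return asdict(self)


def _load_table(setting: str) -> pd.DataFrame:
    fname = _DATA_FILES[setting]
    with resources.files("adheresim.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _build_registry() -> dict[str, list[ScenarioConfig]]:
    registry: dict[str, list[ScenarioConfig]] = {}
    for setting in SETTINGS:
        tab = _load_table(setting)
        consts = _SETTING_CONSTANTS[setting]
        configs = []
        for sc_id, grp in tab.groupby("scenario", sort=True):
            treat = grp[grp.arm == "Z=1"].iloc[0]
            ctrl = grp[grp.arm == "Z=0"].iloc[0]
            shared = ["alpha1", "alpha2", "alpha3", "alpha4",
                      "theta0", "theta1", "theta2", "theta3", "theta4", "theta5"]
            for col in shared:
                if treat[col] != ctrl[col]:
                    raise ValueError(
                        f"{setting} scenario {sc_id}: arm rows disagree on {col}")
            configs.append(ScenarioConfig(
                setting=setting,
                scenario_id=int(sc_id),
                alpha0_treat=float(treat.alpha0),
                alpha0_control=float(ctrl.alpha0),
                alpha1=float(treat.alpha1), alpha2=float(treat.alpha2),
                alpha3=float(treat.alpha3), alpha4=float(treat.alpha4),
                theta0=float(treat.theta0), theta1=float(treat.theta1),
                theta2=float(treat.theta2), theta3=float(treat.theta3),
                theta4=float(treat.theta4), theta5=float(treat.theta5),
                nonadherence_treat=int(treat.nonadherence),
                nonadherence_control=int(ctrl.nonadherence),
                **consts,
            ))
        if len(configs) != _SIZES[setting]:
            raise ValueError(
                f"{setting}: expected {_SIZES[setting]} scenarios, "
                f"found {len(configs)}")
        registry[setting] = configs
    return registry


_REGISTRY: dict[str, list[ScenarioConfig]] | None = None


def _registry() -> dict[str, list[ScenarioConfig]]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _build_registry()
    return _REGISTRY


def get_scenario(setting: str, scenario_id: int) -> ScenarioConfig:
    """Return the registry entry for ``(setting, scenario_id)``.

    Raises
    ------
    KeyError
        If the setting is unknown or the scenario id is outside the
        setting's table range; the message names the valid values.
    """
    if setting not in SETTINGS:
        raise KeyError(f"unknown setting {setting!r}; valid settings: {SETTINGS}")
    configs = _registry()[setting]
    if not 1 <= scenario_id <= len(configs):
        raise KeyError(
            f"scenario_id {scenario_id} out of range for setting {setting}; "
            f"valid range: 1..{len(configs)}")
    return configs[scenario_id - 1]


def list_scenarios(setting: str) -> list[ScenarioConfig]:
    """All scenarios of one setting, ordered by ``scenario_id``."""
    if setting not in SETTINGS:
        raise KeyError(f"unknown setting {setting!r}; valid settings: {SETTINGS}")
    return list(_registry()[setting])
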