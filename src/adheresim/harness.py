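"""Monte-Carlo orchestration: scenarios x methods x replicates.

`run_scenario` simulates ``n_sim`` independent trials from one scenario,
applies every requested estimator to each, and reduces to per-method
performance summaries against the scenario's true risk difference.
Replicate RNG streams are keyed on (master seed, setting, scenario,
replicate), so results are identical whether replicates run serially or
in parallel and any single replicate can be regenerated in isolation.

`analyze_trial_file` applies the same estimator battery to an imported
subject-level trial file (columns ``z, a, y`` and optionally
``l1, l2``), producing a method-by-row table of risk differences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .estimators import (Method, COVARIATE_METHODS, BoundResult, EstimateResult,
                         estimate, estimate_pyaz, npcb_bounds)
from .metrics import MCSummary, summarize, summarize_bounds, summaries_to_frame
from .scenarios import SETTINGS, ScenarioConfig, get_scenario, list_scenarios
from .simulate import ClampWarning, TrialData, read_trial, replicate_rng, simulate_trial

__all__ = ["RunSpec", "run_scenario", "run_setting", "analyze_trial_file",
           "write_results", "DEFAULT_METHODS"]

#: the full estimator battery plus the nonparametric bound
DEFAULT_METHODS: tuple[str, ...] = tuple(m.value for m in Method) + ("NPCB",)

_SETTING_STREAM = {s: i + 1 for i, s in enumerate(SETTINGS)}


@dataclass
class RunSpec:
    """Configuration of one Monte-Carlo sweep."""

    setting: str
    scenarios: Optional[Sequence[int]] = None   # None = all in the setting
    methods: Sequence[str] = field(default_factory=lambda: DEFAULT_METHODS)
    n: int = 2000
    n_sim: int = 1000
    seed: int = 20220216
    cov_type: str = "HC0"
    n_jobs: int = 1
    clamp_warn_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        methods = [str(m) for m in self.methods]
        if not methods:
            raise ValueError("method list must be non-empty")
        valid = set(DEFAULT_METHODS)
        unknown = [m for m in methods if m not in valid]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; valid: {sorted(valid)}")
        self.methods = tuple(methods)


def _one_replicate(config: ScenarioConfig, spec: RunSpec, rep: int):
    """Simulate one trial and apply every requested method.

    Estimator failures are captured as non-convergence, never raised, so
    a sweep always completes.
    """
    rng = replicate_rng(spec.seed, _SETTING_STREAM[config.setting],
                        config.scenario_id, rep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampWarning)
        data = simulate_trial(config, spec.n, rng)
    out: dict[str, object] = {}
    for name in spec.methods:
        if name == "NPCB":
            try:
                out[name] = npcb_bounds(estimate_pyaz(data))
            except ValueError as err:
                out[name] = None
        else:
            method = Method(name)
            try:
                out[name] = estimate(data, method, cov_type=spec.cov_type)
            except Exception as err:  # capture, don't abort the sweep
                out[name] = EstimateResult.failed(method, data.n, str(err))
    clamp = data.clamp_count_treat + data.clamp_count_outcome
    return out, clamp


def run_scenario(spec: RunSpec, config: ScenarioConfig) -> list[MCSummary]:
    """Run one scenario's Monte-Carlo sweep and summarize per method."""
    if spec.n_jobs == 1:
        results = [_one_replicate(config, spec, rep) for rep in range(spec.n_sim)]
    else:
        results = Parallel(n_jobs=spec.n_jobs)(
            delayed(_one_replicate)(config, spec, rep) for rep in range(spec.n_sim))
    per_rep = [r for r, _ in results]
    clamp_total = sum(c for _, c in results)
    if clamp_total > spec.clamp_warn_fraction * spec.n * spec.n_sim:
        warnings.warn(
            f"{config.setting} scenario {config.scenario_id}: "
            f"{clamp_total} clamped probabilities across {spec.n_sim} replicates",
            ClampWarning, stacklevel=2)

    truth = config.true_rd
    summaries = []
    for name in spec.methods:
        if name == "NPCB":
            bounds = [r[name] for r in per_rep if r[name] is not None]
            if bounds:
                s = summarize_bounds(bounds, truth, setting=config.setting,
                                     scenario_id=config.scenario_id)
                s.n_sim = spec.n_sim
            else:
                s = MCSummary(setting=config.setting, scenario_id=config.scenario_id,
                              method="NPCB", n_sim=spec.n_sim, n_converged=0)
        else:
            s = summarize([r[name] for r in per_rep], truth,
                          setting=config.setting, scenario_id=config.scenario_id,
                          method=name)
        summaries.append(s)
    return summaries


def run_setting(spec: RunSpec, progress: bool = False) -> pd.DataFrame:
    """Sweep the requested scenarios of one setting; tidy results table."""
    ids = spec.scenarios or [c.scenario_id for c in list_scenarios(spec.setting)]
    summaries: list[MCSummary] = []
    for sc_id in ids:
        config = get_scenario(spec.setting, int(sc_id))
        summaries.extend(run_scenario(spec, config))
        if progress:
            print(f"  {spec.setting} scenario {sc_id}: done")
    return summaries_to_frame(summaries)


def analyze_trial_file(path, methods: Optional[Sequence[str]] = None,
                       per_1000: bool = False,
                       cov_type: str = "HC0") -> pd.DataFrame:
    """Estimate the risk difference of an imported trial by every method.

    Returns a table with one row per method (``method, rd, se, ci_lower,
    ci_upper, converged, n_used``) plus a row for the nonparametric
    causal bound, whose lower/upper bound fills the CI columns.
    Covariate-adjusted methods are reported as unsupported when the file
    has no ``l1``/``l2`` columns.  ``per_1000`` rescales the risk
    difference columns to events per 1,000 subjects.
    """
    data = read_trial(path) if not isinstance(path, TrialData) else path
    if (data.Z == 1).sum() == 0 or (data.Z == 0).sum() == 0:
        raise ValueError("both randomization arms must be non-empty")
    if methods is None:
        methods = DEFAULT_METHODS
    rows = []
    for name in methods:
        if name == "NPCB":
            b = npcb_bounds(estimate_pyaz(data))
            rows.append(dict(method="NPCB", rd=np.nan, se=np.nan,
                             ci_lower=b.lower, ci_upper=b.upper,
                             converged=True, n_used=data.n, note="causal bound"))
            continue
        method = Method(name)
        if method in COVARIATE_METHODS and not data.has_covariates:
            rows.append(dict(method=name, rd=np.nan, se=np.nan, ci_lower=np.nan,
                             ci_upper=np.nan, converged=False, n_used=0,
                             note="unsupported: no measured covariates"))
            continue
        r = estimate(data, method, cov_type=cov_type)
        rows.append(dict(method=name, rd=r.rd, se=r.se, ci_lower=r.ci_lower,
                         ci_upper=r.ci_upper, converged=r.converged,
                         n_used=r.n_used, note=r.message))
    out = pd.DataFrame(rows)
    if per_1000:
        for col in ("rd", "se", "ci_lower", "ci_upper"):
            out[col] = out[col] * 1000
    return out


def write_results(table: pd.DataFrame, path, spec: Optional[RunSpec] = None) -> None:
    """Write a results table plus a JSON run-manifest beside it."""
    path = str(path)
    table.to_csv(path, sep="\t", index=False)
    manifest = {"package": "adheresim", "version": __version__}
    if spec is not None:
        manifest["run_spec"] = asdict(spec)
        manifest["run_spec"]["methods"] = list(spec.methods)
        if spec.scenarios is not None:
            manifest["run_spec"]["scenarios"] = list(spec.scenarios)
    if {"n_sim", "n_converged"} <= set(table.columns):
        manifest["replicates_attempted"] = int(table["n_sim"].sum())
        manifest["replicates_converged"] = int(table["n_converged"].sum())
    with open(path + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
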