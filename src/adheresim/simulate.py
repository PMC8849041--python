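"""Subject-level trial simulation for the nonadherence study.

Each simulated trial draws, in causal order, randomization ``Z``,
unmeasured confounder ``U``, measured confounders ``L1`` (continuous)
and ``L2`` (binary), received treatment ``A`` and binary outcome ``Y``:

    Z  ~ Bernoulli(0.5)
    U  ~ Uniform(0,1)  or  Bernoulli(p)
    L1 ~ Normal(lambda0 + lambda1*U, sigma)
    L2 ~ Bernoulli(expit(l2_spec . (1, U, L1)))
    A  ~ Bernoulli(g(alpha0(arm) + alpha1*Z + alpha2*L1 + alpha3*L2 + alpha4*U))
    Y  ~ Bernoulli(g(theta0 + theta1*A + theta2*L1 + theta3*L2 + theta4*U + theta5*Z))

where ``g`` is the inverse logit or the identity depending on the
scenario's link.  For identity ("linear") links the predictor is clamped
to [0, 1] before the Bernoulli draw; clamp events are counted on the
returned :class:`TrialData` and a :class:`ClampWarning` is emitted when
more than 5% of subjects were clamped in either model.

Settings without measured confounders (A1/A2) omit ``L1``/``L2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .scenarios import ScenarioConfig

__all__ = ["TrialData", "ClampWarning", "simulate_trial", "nonadherence_rates",
           "write_trial", "read_trial", "replicate_rng"]

#: clamp fraction above which a validity warning is raised
CLAMP_WARN_FRACTION = 0.05


class ClampWarning(UserWarning):
    """Linear-link probability clamped to [0, 1] for many subjects."""


@dataclass
class TrialData:
    """Subject-level records of one (simulated or imported) trial."""

    Z: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    U: Optional[np.ndarray] = None
    L1: Optional[np.ndarray] = None
    L2: Optional[np.ndarray] = None
    clamp_count_treat: int = 0
    clamp_count_outcome: int = 0

    @property
    def n(self) -> int:
        return len(self.Z)

    @property
    def has_covariates(self) -> bool:
        return self.L1 is not None and self.L2 is not None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"z": self.Z.astype(int)}
        if self.U is not None:
            cols["u"] = self.U
        if self.L1 is not None:
            cols["l1"] = self.L1
        if self.L2 is not None:
            cols["l2"] = self.L2.astype(int)
        cols["a"] = self.A.astype(int)
        cols["y"] = self.Y.astype(int)
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialData":
        cols = {c.lower(): c for c in df.columns}
        missing = {"z", "a", "y"} - set(cols)
        if missing:
            raise ValueError(f"trial table is missing required columns: {sorted(missing)}")
        def binary(name):
            v = df[cols[name]].to_numpy()
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"column {name!r} must contain only 0/1 values")
            return v.astype(np.int8)
        return cls(
            Z=binary("z"), A=binary("a"), Y=binary("y"),
            U=df[cols["u"]].to_numpy(float) if "u" in cols else None,
            L1=df[cols["l1"]].to_numpy(float) if "l1" in cols else None,
            L2=binary("l2") if "l2" in cols else None,
        )


def replicate_rng(master_seed: int, *stream: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one replicate.

    The stream is keyed on ``(master_seed, *stream)`` (typically the
    replicate index plus scenario identifiers), so replicates can be
    generated in any order or in parallel with identical results.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, stream)]))


def _probability(pred: np.ndarray, link: str) -> tuple[np.ndarray, int]:
    """Map a linear predictor to a probability; returns (p, n_clamped)."""
    if link == "inverse_logit":
        return expit(pred), 0
    clamped = int(np.count_nonzero((pred < 0) | (pred > 1)))
    return np.clip(pred, 0.0, 1.0), clamped


def simulate_trial(config: ScenarioConfig, n: int, seed) -> TrialData:
    """Generate one trial of ``n`` subjects from a scenario configuration.

    ``seed`` may be an integer or anything accepted by
    ``numpy.random.default_rng`` (e.g. a ``SeedSequence``); identical
    ``(config, n, seed)`` always yields identical data.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Z = rng.binomial(1, 0.5, n).astype(np.int8)
    kind, par = config.u_dist
    if kind == "uniform01":
        U = rng.uniform(0.0, 1.0, n)
    elif kind == "bernoulli":
        U = rng.binomial(1, par, n).astype(float)
    else:  # pragma: no cover - registry only uses the two tags above
        raise ValueError(f"unknown U distribution {kind!r}")

    if config.has_covariates:
        L1 = rng.normal(config.lambda0 + config.lambda1 * U, config.sigma, n)
        b0, bU, bL1 = config.l2_spec
        L2 = rng.binomial(1, expit(b0 + bU * U + bL1 * L1)).astype(np.int8)
        cov_treat = config.alpha2 * L1 + config.alpha3 * L2
        cov_out = config.theta2 * L1 + config.theta3 * L2
    else:
        L1 = L2 = None
        cov_treat = cov_out = 0.0

    alpha0 = np.where(Z == 1, config.alpha0_treat, config.alpha0_control)
    pred_a = alpha0 + config.alpha1 * Z + cov_treat + config.alpha4 * U
    p_a, clamp_a = _probability(pred_a, config.link_treat)
    A = rng.binomial(1, p_a).astype(np.int8)

    pred_y = (config.theta0 + config.theta1 * A + cov_out
              + config.theta4 * U + config.theta5 * Z)
    p_y, clamp_y = _probability(pred_y, config.link_outcome)
    Y = rng.binomial(1, p_y).astype(np.int8)

    for label, count in (("treatment", clamp_a), ("outcome", clamp_y)):
        if count > CLAMP_WARN_FRACTION * n:
            warnings.warn(
                f"{config.setting} scenario {config.scenario_id}: {count}/{n} "
                f"{label}-model probabilities clamped to [0, 1]", ClampWarning,
                stacklevel=2)

    return TrialData(Z=Z, A=A, Y=Y, U=U, L1=L1, L2=L2,
                     clamp_count_treat=clamp_a, clamp_count_outcome=clamp_y)


def nonadherence_rates(data: TrialData) -> tuple[float, float]:
    """Proportion of subjects with ``A != Z`` in the (treat, control) arms."""
    treat = data.Z == 1
    if not treat.any() or treat.all():
        raise ValueError("both randomization arms must be non-empty")
    dev = data.A != data.Z
    return float(dev[treat].mean()), float(dev[~treat].mean())


def write_trial(data: TrialData, path, include_u: bool = False) -> None:
    """Write subject-level records as tab-delimited text (z,[u],[l1],[l2],a,y)."""
    df = data.to_dataframe()
    if not include_u and "u" in df.columns:
        df = df.drop(columns="u")
    df.to_csv(path, sep="\t", index=False)


def read_trial(path) -> TrialData:
    """Read a subject-level delimited file (tab or comma separated)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
        return TrialData.from_dataframe(df)
    except ValueError as err:
        raise ValueError(f"malformed trial file {path}: {err}") from err
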