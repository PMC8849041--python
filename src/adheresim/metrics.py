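"""Monte-Carlo performance summaries: bias, empirical SE, MSE, coverage.

With truth ``beta`` and converged replicate estimates ``b_1..b_m``:

    bias     = mean(b_i) - beta
    se       = sqrt( sum (b_i - mean(b))^2 / (m - 1) )
    mse      = mean( (b_i - beta)^2 )
    coverage = fraction of replicates with ci_lower <= beta <= ci_upper

Note the divisor asymmetry (``m - 1`` for SE, ``m`` for MSE), so the
decomposition carries a finite-sample factor:
``mse = bias^2 + se^2 * (m - 1) / m`` exactly.

Non-converged replicates are excluded from all four measures but their
count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import BoundResult, EstimateResult

__all__ = ["MCSummary", "summarize", "summarize_bounds", "summaries_to_frame"]


@dataclass
class MCSummary:
    setting: str
    scenario_id: int
    method: str
    n_sim: int
    n_converged: int
    bias: float = np.nan
    se: float = np.nan
    mse: float = np.nan
    coverage: float = np.nan
    bound_lower_mean: float = np.nan
    bound_upper_mean: float = np.nan
    bound_contains_truth: float = np.nan

    @property
    def defined(self) -> bool:
        """Whether the replicate metrics are defined (>= 2 converged)."""
        return self.n_converged >= 2


def summarize(estimates: Sequence[EstimateResult], truth: float,
              setting: str = "", scenario_id: int = 0,
              method: Optional[str] = None) -> MCSummary:
    """Reduce replicate-level estimates to the four performance measures.

    With fewer than 2 converged replicates the metrics are left NaN
    (flagged via :attr:`MCSummary.defined`) but counts are still
    reported.
    """
    estimates = list(estimates)
    if method is None:
        method = estimates[0].method.value if estimates else ""
    conv = [e for e in estimates if e.converged]
    out = MCSummary(setting=setting, scenario_id=scenario_id, method=method,
                    n_sim=len(estimates), n_converged=len(conv))
    if len(conv) < 2:
        return out
    b = np.array([e.rd for e in conv])
    lo = np.array([e.ci_lower for e in conv])
    hi = np.array([e.ci_upper for e in conv])
    out.bias = float(b.mean() - truth)
    out.se = float(b.std(ddof=1))
    out.mse = float(np.mean((b - truth) ** 2))
    out.coverage = float(np.mean((lo <= truth) & (truth <= hi)))
    return out


def summarize_bounds(bounds: Sequence[BoundResult], truth: float,
                     setting: str = "", scenario_id: int = 0) -> MCSummary:
    """Mean lower/upper causal bound and the truth-containment fraction."""
    bounds = list(bounds)
    if not bounds:
        raise ValueError("no bound replicates to summarize")
    lo = np.array([b.lower for b in bounds])
    hi = np.array([b.upper for b in bounds])
    return MCSummary(
        setting=setting, scenario_id=scenario_id, method="NPCB",
        n_sim=len(bounds), n_converged=len(bounds),
        bound_lower_mean=float(lo.mean()), bound_upper_mean=float(hi.mean()),
        bound_contains_truth=float(np.mean((lo <= truth) & (truth <= hi))))


def summaries_to_frame(summaries: Sequence[MCSummary]) -> pd.DataFrame:
    """Tidy table with one row per (setting, scenario, method)."""
    return pd.DataFrame([asdict(s) for s in summaries])
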