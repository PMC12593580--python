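"""Container for calibrated (beta, gamma) parameter draws.

Both calibration routes — the Nelder-Mead residual bootstrap and the HMC
posterior — produce a :class:`CalibrationSamples` for each ground-truth
trace: an array of draws with per-draw convergence/divergence flags, the
per-draw MASE against the original ground truth, and derived quantities
(infectious period 1/gamma and the control reproduction number R_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import QuantileSummary, quantiles
from .reproduction import control_reproduction_number

__all__ = ["CalibrationSamples"]


@dataclass
class CalibrationSamples:
    gt_id: str
    method: str  # "NM" or "HMC"
    beta: np.ndarray
    gamma: np.ndarray
    divergent: np.ndarray  # per-draw flag (failed refit / divergent transition)
    mase: np.ndarray  # per-draw MASE against the original ground truth
    vr: float
    ve: float
    chain: np.ndarray | None = None  # HMC only
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.beta)
        for arr in (self.gamma, self.divergent, self.mase):
            if len(arr) != n:
                raise ValueError("per-draw arrays must have equal length")

    @property
    def n_draws(self) -> int:
        return len(self.beta)

    @property
    def infectious_period(self) -> np.ndarray:
        return 1.0 / self.gamma

    @property
    def rc(self) -> np.ndarray:
        return np.array(
            [
                control_reproduction_number(b, g, self.vr, self.ve).rc
                for b, g in zip(self.beta, self.gamma)
            ]
        )

    @property
    def rc_literal(self) -> np.ndarray:
        """R_c under the alternative convention Rv = ve * Ru, i.e. nearly
        the overall reproduction ratio beta/gamma; the cross-scenario
        stability of this quantity is what the "parameters change in
        tandem" finding is about."""
        return np.array(
            [
                control_reproduction_number(
                    b, g, self.vr, self.ve, rv_formula="as_printed"
                ).rc
                for b, g in zip(self.beta, self.gamma)
            ]
        )

    @property
    def mean_mase(self) -> float:
        ok = np.isfinite(self.mase)
        return float(np.mean(self.mase[ok]))

    @property
    def divergence_fraction(self) -> float:
        return float(np.mean(self.divergent))

    def quantile_summary(self, parameter: str) -> QuantileSummary:
        values = {
            "beta": self.beta,
            "gamma": self.gamma,
            "infectious_period": self.infectious_period,
            "rc": self.rc,
            "rc_literal": self.rc_literal,
        }[parameter]
        return quantiles(values, parameter=parameter)

    def to_frame(self) -> pd.DataFrame:
        """Samples CSV schema: run,sample,beta,gamma,infectious_period,rc,
        mase,converged (plus chain/divergent for HMC)."""
        df = pd.DataFrame(
            {
                "run": self.gt_id,
                "sample": np.arange(self.n_draws),
                "beta": self.beta,
                "gamma": self.gamma,
                "infectious_period": self.infectious_period,
                "rc": self.rc,
                "mase": self.mase,
                "converged": (~self.divergent).astype(int),
            }
        )
        if self.chain is not None:
            df["chain"] = self.chain
            df["divergent"] = self.divergent.astype(int)
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, method: str, vr: float, ve: float
    ) -> "CalibrationSamples":
        return cls(
            gt_id=str(df["run"].iloc[0]),
            method=method,
            beta=df["beta"].to_numpy(float),
            gamma=df["gamma"].to_numpy(float),
            divergent=df["converged"].to_numpy(int) == 0,
            mase=df["mase"].to_numpy(float),
            vr=vr,
            ve=ve,
            chain=df["chain"].to_numpy(int) if "chain" in df else None,
        )
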