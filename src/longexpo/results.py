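"""Uniform result contract shared by all nine methods."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MethodResult"]


@dataclass
class MethodResult:
    """One method's exposure inference in a uniform layout.

    ``estimates`` rows carry (coef, se, or, ci_low, ci_high, p) per reported
    term; ``global_tests`` rows carry (statistic, df, p) for joint tests such
    as a GEE coefficient-equality test, a chi-square cluster-outcome test or a
    likelihood-ratio test on FPC scores.
    """

    method: str
    estimates: pd.DataFrame
    global_tests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["statistic", "df", "p"])
    )
    n_used: int = 0
    notes: list = field(default_factory=list)

    def __post_init__(self):
        est = self.estimates
        if len(est):
            bad = (est["ci_low"] > est["or"] + 1e-12) | (est["or"] > est["ci_high"] + 1e-12)
            if bad.any():
                raise ValueError("confidence interval does not bracket the odds ratio")
            if ((est["p"] < -1e-12) | (est["p"] > 1 + 1e-12)).any():
                raise ValueError("p-values must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimates": json.loads(self.estimates.to_json(orient="index", double_precision=10)),
            "global_tests": json.loads(
                self.global_tests.to_json(orient="index", double_precision=10)
            ),
            "n_used": int(self.n_used),
            "notes": list(self.notes),
        }

    @staticmethod
    def estimate_rows(summary: pd.DataFrame, terms) -> pd.DataFrame:
        """Select named rows of a GlmFit coefficient summary."""
        return summary.loc[[t for t in terms if t in summary.index]]
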