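"""Small design-matrix helpers shared by the model modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "add_intercept"]


def add_intercept(X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    out.insert(0, "intercept", 1.0)
    return out


def build_design(frame: pd.DataFrame, columns, intercept: bool = True) -> pd.DataFrame:
    """Numeric design matrix from named columns.

    Categorical / object columns are dummy-encoded dropping the first level;
    numeric columns pass through as float.
    """
    parts = []
    for name in columns:
        col = frame[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(name))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=frame.index)
    if intercept:
        X = add_intercept(X)
    return X
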