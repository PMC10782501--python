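"""Quintile splits of continuous exposures.

Mortality models treat the sleep exposures as quintile factors (Q1–Q5)
rather than continuous predictors, allowing unspecified non-linearity;
Q1 (least regular sleep / shortest duration) is the reference and is
hypothesised to carry the highest risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QUINTILE_LABELS = ["Q1", "Q2", "Q3", "Q4", "Q5"]


@dataclass
class QuintileAssignment:
    variable: str
    cut_points: np.ndarray  # the 20/40/60/80 empirical percentiles
    labels: pd.Series  # categorical Q1..Q5; NaN where the value is missing

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(QUINTILE_LABELS, fill_value=0)


def assign_quintiles(values: pd.Series | np.ndarray, variable: str = "") -> QuintileAssignment:
    """Split a numeric variable at its 20/40/60/80 empirical percentiles.

    Percentiles use the linear-interpolation definition (numpy default).
    A value equal to a cut point goes to the *lower* quintile; missing
    values stay unassigned.  Constant input is rejected: quintiles are
    undefined.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if isinstance(values, pd.Series):
        s.index = values.index
        variable = variable or str(values.name or "")
    obs = s.dropna()
    if len(obs) < 5:
        raise ValueError(
            f"need at least 5 non-missing values to form quintiles for "
            f"{variable!r}, got {len(obs)}"
        )
    if obs.min() == obs.max():
        raise ValueError(f"variable {variable!r} is constant; quintiles undefined")

    cuts = np.quantile(obs.to_numpy(), [0.2, 0.4, 0.6, 0.8])
    # count of cut points strictly below the value -> ties land in the lower group
    idx = np.searchsorted(cuts, s.to_numpy(), side="left")
    labels = pd.Series(
        pd.Categorical.from_codes(
            np.where(s.notna(), idx, -1), categories=QUINTILE_LABELS
        ),
        index=s.index,
        name=f"{variable}_quintile" if variable else "quintile",
    )
    return QuintileAssignment(variable=variable, cut_points=cuts, labels=labels)
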