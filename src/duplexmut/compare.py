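"""Cross-assay comparison: least-squares regression of paired frequencies.

Used to relate duplex-sequencing mutation frequencies to transgenic-reporter
(lacZ) mutant frequencies measured in the same animals, or to compare
interlaboratory replicates.  Pairing is by sample; the per-dose mode averages
within dose groups before regressing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    scope: str = "per-animal"


def regress(x, y, scope: str = "per-animal") -> RegressionResult:
    """Ordinary least squares of y on x with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x is constant: slope undefined")
    fit = linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(x),
        scope=scope,
    )


def regress_paired(
    a: pd.DataFrame,
    b: pd.DataFrame,
    by: str = "animal",
    metadata: pd.DataFrame | None = None,
) -> RegressionResult:
    """Regress two per-sample frequency tables against each other.

    ``a`` and ``b`` have columns (sample_id, frequency).  ``by='animal'``
    pairs samples directly; ``by='dose'`` first averages frequencies within
    dose groups (requires ``metadata`` with sample_id and dose columns).
    """
    merged = a.merge(b, on="sample_id", suffixes=("_x", "_y"))
    if by == "dose":
        if metadata is None:
            raise ValueError("per-dose pairing requires metadata with doses")
        merged = merged.merge(metadata[["sample_id", "dose"]], on="sample_id")
        merged = merged.groupby("dose", as_index=False)[["frequency_x", "frequency_y"]].mean()
        scope = "per-dose"
    elif by == "animal":
        scope = "per-animal"
    else:
        raise ValueError(f"unknown pairing {by!r}")
    return regress(merged["frequency_x"], merged["frequency_y"], scope=scope)
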