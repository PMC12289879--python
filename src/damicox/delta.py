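"""Delta adjustment: turn MAR imputations into MNAR scenarios by offsetting
the imputed values only.

The default mode adds delta on the transformed (log) scale, i.e. multiplies
the original-scale imputed value by e^delta — an additive shift in the
pattern-mixture sense that is multiplicative on the raw biomarker. delta = 0
is the MAR anchor. Observed values are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .impute import ImputedStack
from .panel import PanelDataset

MODES = ("additive_on_transformed", "additive_on_original",
         "multiplicative_on_original")

DEFAULT_GRID = (-2.0, -1.0, 0.0, 1.0, 2.0)


@dataclass(frozen=True)
class DeltaSpec:
    mode: str = "additive_on_transformed"
    grid: tuple[float, ...] = DEFAULT_GRID
    # optional hook: called with the imputed rows (DataFrame), returns a
    # per-record delta array; overrides the scalar delta when set
    per_record_delta: Callable[[pd.DataFrame], np.ndarray] | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if len(self.grid) == 0:
            raise ValueError("delta grid must be non-empty")


def suggest_grid(values) -> tuple[float, ...]:
    """{-2s, -s, 0, s, 2s} from the SD of the observed log values."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if (v <= 0).any():
        raise ValueError("grid suggestion expects positive observed values")
    s = float(np.std(np.log(v), ddof=1))
    return (-2 * s, -s, 0.0, s, 2 * s)


def _shift(values: np.ndarray, delta, mode: str) -> np.ndarray:
    if mode == "additive_on_transformed":
        return values * np.exp(delta)
    if mode == "additive_on_original":
        return values + delta
    return values * delta  # multiplicative_on_original


def apply_delta(stack: ImputedStack, delta: float,
                spec: DeltaSpec | None = None) -> ImputedStack:
    """Return a new stack whose imputed entries are shifted by delta.

    Entries observed in the source data (r=1) are identical before and
    after; the input stack is untouched.
    """
    spec = spec or DeltaSpec()
    idx = stack.missing_index
    new_datasets = []
    for ds in stack.datasets:
        frame = ds.frame.copy()
        vals = frame[stack.target].to_numpy(float)
        if spec.per_record_delta is not None:
            d = np.asarray(spec.per_record_delta(frame.iloc[idx]), float)
            if d.shape != (len(idx),):
                raise ValueError("per_record_delta must return one delta per "
                                 "imputed record")
        else:
            d = delta
        shifted = _shift(vals[idx], d, spec.mode)
        if spec.mode != "additive_on_transformed" and (shifted <= 0).any():
            raise ValueError(
                f"delta adjustment ({spec.mode}, delta={delta}) produces "
                "non-positive biomarker values")
        vals = vals.copy()
        vals[idx] = shifted
        frame[stack.target] = vals
        new_datasets.append(PanelDataset(frame, ds.schema, validate=False))
    return ImputedStack(new_datasets, stack.trace, stack.spec, stack.seed,
                        stack.target, stack.missing_index)


def sweep_deltas(stack: ImputedStack,
                 spec: DeltaSpec | None = None) -> dict[float, ImputedStack]:
    """One adjusted stack per grid value; deterministic given the input."""
    spec = spec or DeltaSpec()
    return {float(d): apply_delta(stack, float(d), spec) for d in spec.grid}
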