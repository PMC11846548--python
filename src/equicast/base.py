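"""Shared lightweight result containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ForecastSeries:
    """Point forecasts over a horizon, optionally with interval bounds.

    Attributes
    ----------
    steps : ndarray of int
        Forecast index (calendar years when known, otherwise 1-based
        steps past the end of the training series).
    values : ndarray of float
        Point forecasts, one per step.
    lower, upper : ndarray of float, optional
        95% interval bounds where the method provides them.
    label : str
        Human-readable tag for the forecasting method.
    meta : dict
        Method-specific diagnostics (orders, coefficients, gate status).
    """

    steps: np.ndarray
    values: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.steps.shape != self.values.shape:
            raise ValueError("steps and values must have the same shape")
        for name in ("lower", "upper"):
            bound = getattr(self, name)
            if bound is not None:
                setattr(self, name, np.asarray(bound, dtype=float))

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self):
        import pandas as pd

        data = {"step": self.steps, "forecast": self.values}
        if self.lower is not None:
            data["lower95"] = self.lower
        if self.upper is not None:
            data["upper95"] = self.upper
        return pd.DataFrame(data)
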