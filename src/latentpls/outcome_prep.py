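"""Turn each supported outcome type into a continuous working response.

The causal regression downstream is an ordinary least-squares fit, so every
outcome kind is mapped to a single continuous vector first: continuous
outcomes pass through, binary outcomes become 0/1 (a linear-probability
working response, so effects read as risk differences), and right-censored
survival outcomes become martingale residuals from a null (covariate-free)
proportional-hazards model,

    M_i = delta_i - Lambda_hat(t_i),

with Lambda_hat the Nelson-Aalen cumulative hazard. Null-model martingale
residuals sum to zero by construction and live in (-inf, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OutcomeSpec:
    """Declares which clinical columns hold the outcome and how to read them.

    kind: one of 'continuous', 'binary', 'survival'. Continuous/binary use
    ``value_column`` (binary additionally ``positive_label``); survival uses
    ``time_column`` + ``event_column`` (event 1 = observed failure).
    """

    kind: str
    value_column: str | None = None
    time_column: str | None = None
    event_column: str | None = None
    positive_label: str | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "survival"):
            raise ValueError(f"unknown outcome kind '{self.kind}'")
        if self.kind == "survival":
            if not (self.time_column and self.event_column):
                raise ValueError("survival outcome needs time_column and event_column")
        else:
            if not self.value_column:
                raise ValueError(f"{self.kind} outcome needs value_column")
        if self.kind == "binary" and self.positive_label is None:
            raise ValueError("binary outcome needs positive_label")

    @property
    def columns(self) -> list[str]:
        if self.kind == "survival":
            return [self.time_column, self.event_column]
        return [self.value_column]


@dataclass
class SurvivalOutcome:
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have the same length")
        if np.any(self.times <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.events, (0.0, 1.0))):
            raise ValueError("event indicators must be 0/1")


@dataclass
class CumulativeHazard:
    """Nelson-Aalen estimate: step function, 0 before the first event time."""

    event_times: np.ndarray
    values: np.ndarray

    def evaluate(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times, times, side="right")
        padded = np.concatenate([[0.0], self.values])
        return padded[idx]


@dataclass
class WorkingResponse:
    y: np.ndarray
    kind: str
    provenance: str


def nelson_aalen(surv: SurvivalOutcome) -> CumulativeHazard:
    """Nelson-Aalen cumulative hazard: Lambda(t) = sum_{t_j <= t} d_j / n_j.

    d_j counts events at the distinct event time t_j and n_j the subjects
    still at risk (t_i >= t_j). Censored observations tied with an event
    time remain in the risk set at that time.
    """
    if surv.times.size < 2:
        raise ValueError("need at least 2 observations")
    event_times = np.unique(surv.times[surv.events == 1.0])
    if event_times.size == 0:
        return CumulativeHazard(event_times=np.empty(0), values=np.empty(0))
    d = np.array([np.sum((surv.times == t) & (surv.events == 1.0))
                  for t in event_times], dtype=float)
    n_risk = np.array([np.sum(surv.times >= t) for t in event_times], dtype=float)
    return CumulativeHazard(event_times=event_times, values=np.cumsum(d / n_risk))


def martingale_residuals(surv: SurvivalOutcome) -> WorkingResponse:
    """Null-model martingale residuals M_i = delta_i - Lambda_hat(t_i)."""
    haz = nelson_aalen(surv)
    resid = surv.events - haz.evaluate(surv.times)
    return WorkingResponse(y=resid, kind="survival",
                           provenance="null-model martingale residual "
                                      "(Nelson-Aalen cumulative hazard)")


def prepare_outcome(table: pd.DataFrame, spec: OutcomeSpec) -> WorkingResponse:
    """Dispatch the clinical outcome columns to the working-response builder."""
    for col in spec.columns:
        if col not in table.columns:
            raise KeyError(f"outcome column '{col}' not found")
        if table[col].isna().any():
            raise ValueError(f"outcome column '{col}' has missing values; "
                             "run complete_cases first")
    if spec.kind == "continuous":
        y = pd.to_numeric(table[spec.value_column], errors="raise").to_numpy(float)
        return WorkingResponse(y=y, kind="continuous", provenance="continuous value")
    if spec.kind == "binary":
        labels = table[spec.value_column].astype(str)
        observed = sorted(labels.unique())
        if len(observed) > 2:
            raise ValueError(
                f"binary outcome '{spec.value_column}' has {len(observed)} "
                f"observed values: {observed}"
            )
        if str(spec.positive_label) not in observed:
            raise ValueError(
                f"positive_label '{spec.positive_label}' not among observed "
                f"values {observed}"
            )
        y = (labels == str(spec.positive_label)).to_numpy(float)
        return WorkingResponse(
            y=y, kind="binary",
            provenance=f"0/1 indicator of '{spec.positive_label}' "
                       "(linear-probability working response)")
    surv = SurvivalOutcome(
        times=pd.to_numeric(table[spec.time_column], errors="raise").to_numpy(float),
        events=pd.to_numeric(table[spec.event_column], errors="raise").to_numpy(float),
    )
    return martingale_residuals(surv)
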