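"""Tool-versus-observer agreement metrics and a simulated-observer harness.

For each case and parameter, four human observers provide manual
measurements alongside the automated tool's value.  Agreement is summarized
by two per-parameter rates: the fraction of cases in which the tool value
falls inside the observers' range (inclusive bounds), and the fraction with
an absolute error above 5 units against the observer mean (strict).

For exchangeable tool/observer errors the within-range rate has a known
limit: a value is inside the range of n i.i.d. companions with probability
(n − 1)/(n + 1), i.e. 3/5 for four observers — the harness's calibration
law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObserverSet",
    "AgreementReport",
    "within_range",
    "error_gt5",
    "agreement_report",
    "simulate_observers",
]

ERROR_THRESHOLD = 5.0


@dataclass(frozen=True)
class ObserverSet:
    """Multi-observer manual measurements + the tool value for one case."""

    case_id: str
    parameter: str
    observer_values: tuple
    tool_value: float
    set_label: str = ""

    def __post_init__(self) -> None:
        if len(self.observer_values) < 2:
            raise ValueError("need at least 2 observers")
        vals = np.asarray(self.observer_values + (self.tool_value,), float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite measurement")


@dataclass(frozen=True)
class AgreementReport:
    parameter: str
    set_label: str
    within_range_rate: float
    gt5_rate: float
    n_cases: int


def within_range(obs: ObserverSet) -> bool:
    """True iff the tool value lies inside the observers' range (inclusive)."""
    v = np.asarray(obs.observer_values, float)
    return bool(v.min() <= obs.tool_value <= v.max())


def error_gt5(obs: ObserverSet, threshold: float = ERROR_THRESHOLD) -> bool:
    """True iff |tool − observer mean| strictly exceeds the threshold."""
    return bool(abs(obs.tool_value - float(np.mean(obs.observer_values)))
                > threshold)


def agreement_report(
    sets: Sequence[ObserverSet], grouping: str = "set"
) -> list[AgreementReport]:
    """Per parameter × set agreement rates, plus a grand-mean row.

    ``grouping="set"`` groups by the validation-set label, ``"none"`` pools
    all cases per parameter.  Empty groups are omitted with a warning.  The
    grand mean (set label ``"overall"`` / parameter ``"all"``) averages the
    per-parameter rates.
    """
    if not sets:
        warnings.warn("no observer sets; empty report")
        return []
    rows = []
    df = pd.DataFrame(
        {
            "parameter": [o.parameter for o in sets],
            "set": [o.set_label if grouping == "set" else "" for o in sets],
            "within": [within_range(o) for o in sets],
            "gt5": [error_gt5(o) for o in sets],
        }
    )
    for (param, label), g in df.groupby(["parameter", "set"]):
        rows.append(
            AgreementReport(
                parameter=param,
                set_label=label,
                within_range_rate=float(g["within"].mean()),
                gt5_rate=float(g["gt5"].mean()),
                n_cases=len(g),
            )
        )
    rows.append(
        AgreementReport(
            parameter="all",
            set_label="overall",
            within_range_rate=float(np.mean([r.within_range_rate for r in rows])),
            gt5_rate=float(np.mean([r.gt5_rate for r in rows])),
            n_cases=len(df),
        )
    )
    return rows


def simulate_observers(
    truth: pd.DataFrame,
    observer_noise_sd: float,
    tool_noise_sd: float,
    parameters: Sequence[str] = ("pi", "pt", "ss", "ll", "tk", "cobb"),
    n_observers: int = 4,
    seed: int = 0,
    set_label: str = "simulated",
) -> list[ObserverSet]:
    """Emulate the manual-validation protocol on ground-truth parameters.

    Observers measure truth + i.i.d. Gaussian noise; the tool measures
    truth + independent noise.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sets = []
    for _, row in truth.iterrows():
        for p in parameters:
            base = float(row[p])
            obs = base + rng.normal(0.0, observer_noise_sd, n_observers)
            tool = base + rng.normal(0.0, tool_noise_sd)
            sets.append(
                ObserverSet(
                    case_id=str(row.get("subject_id", "")),
                    parameter=p,
                    observer_values=tuple(float(v) for v in obs),
                    tool_value=float(tool),
                    set_label=set_label,
                )
            )
    return sets
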