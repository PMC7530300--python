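"""The p_zero biomarker and hERG-vs-multichannel classification.

p_zero is the largest trajectory-length percentage at which the effect
profile transitions from negative (accelerated repolarization) to
non-negative (delayed).  All-negative profiles map to 100, all-non-negative
profiles to 1.  Drugs whose bootstrap p_zero samples fall below the decision
threshold are predicted to be predominant hERG blockers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RISK_HERG = "hERG_predominant"
RISK_MULTI = "multichannel_low_risk"
RISK_EXCLUDED = "excluded"

#: reference risk-class grouping of the studied drug conditions
REFERENCE_CLASSES = {
    "moxifloxacin": RISK_HERG,
    "dofetilide": RISK_HERG,
    "chloroquine": RISK_HERG,
    "quinidine": RISK_HERG,
    "ranolazine": RISK_MULTI,
    "verapamil": RISK_MULTI,
    "lopinavir+ritonavir": RISK_MULTI,
    "mexiletine": RISK_EXCLUDED,
    "lidocaine": RISK_EXCLUDED,
    "diltiazem": RISK_EXCLUDED,
}

DEFAULT_THRESHOLD = 43


def compute_pzero(profile: np.ndarray) -> int:
    """Largest p with profile[p] < 0 and profile[p+1] >= 0 (zero counts as
    non-negative); 100 if the profile stays/ends negative, 1 if it never
    goes negative."""
    dd = np.asarray(profile, dtype=float)
    if dd.shape != (100,):
        raise ValueError("profile must be defined on the full p = 1..100 grid")
    if not np.isfinite(dd).all():
        raise ValueError("NaN in effect profile")
    neg = dd < 0
    if neg.all():
        return 100
    if not neg.any():
        return 1
    trans = np.flatnonzero(neg[:-1] & ~neg[1:])  # index i -> p = i + 1
    if trans.size:
        return int(trans[-1] + 1)
    # mixed signs without an upward crossing: the profile ends negative
    return 100 if neg[-1] else 1


@dataclass
class DrugCondition:
    drug: str
    study: str = ""
    concentration: dict[str, float] = field(default_factory=dict)
    risk_class: str = RISK_EXCLUDED
    pzero_samples: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.pzero_samples = np.asarray(self.pzero_samples, dtype=float)
        if not self.risk_class:
            self.risk_class = REFERENCE_CLASSES.get(self.drug, RISK_EXCLUDED)


@dataclass
class ClassificationReport:
    threshold: int
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int
    sweep: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json_dict(self) -> dict:
        return {"threshold": self.threshold, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "n_positive_samples": self.n_positive,
                "n_negative_samples": self.n_negative}


def classify(conditions: list[DrugCondition],
             threshold: int = DEFAULT_THRESHOLD,
             sweep_thresholds: np.ndarray | None = None
             ) -> ClassificationReport:
    """Pooled bootstrap-sample classification: predicted hERG-predominant iff
    p_zero < threshold.  Conditions labeled ``excluded`` are ignored."""
    pos = np.concatenate([c.pzero_samples for c in conditions
                          if c.risk_class == RISK_HERG] or [np.array([])])
    negs = np.concatenate([c.pzero_samples for c in conditions
                           if c.risk_class == RISK_MULTI] or [np.array([])])
    if pos.size == 0 or negs.size == 0:
        raise ValueError("both risk classes must be represented with samples")
    if sweep_thresholds is None:
        sweep_thresholds = np.arange(1, 101)
    rows = [{"threshold": int(t),
             "sensitivity": float(np.mean(pos < t)),
             "specificity": float(np.mean(negs >= t))}
            for t in sweep_thresholds]
    sweep = pd.DataFrame(rows)
    return ClassificationReport(
        threshold=int(threshold),
        sensitivity=float(np.mean(pos < threshold)),
        specificity=float(np.mean(negs >= threshold)),
        n_positive=int(pos.size), n_negative=int(negs.size), sweep=sweep)
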