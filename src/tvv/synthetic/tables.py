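"""Quantile-level synthetic study generators with analytic ground truth.

These generators emit replicate-level quantile tables directly (bypassing
signal synthesis), which makes parameter-recovery, coverage and
classification experiments cheap.  The drug effect enters additively on the
corrected quantile scale, so the generating placebo-corrected change from
baseline equals ``g(p) * C / C_ref`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from tvv.vcg import P_GRID, TR_COLS, TRC_COLS

PF = P_GRID.astype(float)


def alpha_true(p: np.ndarray) -> np.ndarray:
    """Reference heart-rate correction exponent profile: flat 1.06 through
    p = 6, declining linearly to 0.44 at p = 100."""
    p = np.asarray(p, dtype=float)
    return np.where(p <= 6.0, 1.06, 1.06 + (0.44 - 1.06) * (p - 6.0) / 94.0)


def tr_base(p: np.ndarray, t100: float = 300.0, shape: float = 0.6
            ) -> np.ndarray:
    """Baseline duration curve at RR = 1 s (concave: ~200 ms at p = 50)."""
    return t100 * (np.asarray(p, dtype=float) / 100.0) ** shape


def g_tanh(p0: float, amp: float, width: float = 15.0
           ) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth effect profile crossing zero at ``p0`` (ms per C_ref)."""
    return lambda p: amp * np.tanh((np.asarray(p, float) - p0) / width)


def g_delay(amp: float, shape: float = 1.5) -> Callable[[np.ndarray], np.ndarray]:
    """Pure-delay profile (positive everywhere): amp * (p/100)^shape."""
    return lambda p: amp * (np.asarray(p, float) / 100.0) ** shape


def pk_shape(t: np.ndarray, ka: float = 1.5, ke: float = 0.3) -> np.ndarray:
    """One-compartment absorption curve normalized to peak 1."""
    t = np.asarray(t, dtype=float)
    tmax = np.log(ka / ke) / (ka - ke)
    peak = np.exp(-ke * tmax) - np.exp(-ka * tmax)
    c = (np.exp(-ke * np.clip(t, 0, None)) - np.exp(-ka * np.clip(t, 0, None)))
    return np.where(t <= 0, 0.0, c / peak)


def drug_free_corpus(n_subjects: int = 30, n_ecgs: int = 40,
                     sd_intercept: float = 0.05, sd_slope: float = 0.10,
                     sd_resid: float = 0.02, rr_log_sd: float = 0.12,
                     seed: int = 0) -> pd.DataFrame:
    """Drug-free quantile table following log Tr(p) = log beta_p +
    (alpha(p) + b1_i) log RR + b0_i + eps."""
    rng = np.random.default_rng(seed)
    log_base = np.log(tr_base(PF))
    alpha = alpha_true(PF)
    rows = []
    for i in range(n_subjects):
        b0 = rng.normal(0.0, sd_intercept)
        b1 = rng.normal(0.0, sd_slope)
        log_rr = rng.normal(0.0, rr_log_sd, size=n_ecgs)
        eps = rng.normal(0.0, sd_resid, size=(n_ecgs, len(PF)))
        log_tr = (log_base[None, :] + b0
                  + (alpha + b1)[None, :] * log_rr[:, None] + eps)
        df = pd.DataFrame(np.exp(log_tr), columns=TR_COLS)
        df.insert(0, "subject", f"S{i:03d}")
        df.insert(1, "treatment", "placebo")
        df.insert(2, "timepoint", np.arange(n_ecgs, dtype=float))
        df.insert(3, "replicate", 0)
        df.insert(4, "RR_s", np.exp(log_rr))
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


@dataclass
class TableTruth:
    """Generating quantities of a quantile-level synthetic study."""

    g: Callable[[np.ndarray], np.ndarray]
    cref: float
    cmax_gm: float
    effect_at_cmax: np.ndarray = field(default=None)
    subject_effects: pd.DataFrame | None = None

    def dd_true(self, conc: float) -> np.ndarray:
        return self.g(PF) * conc / self.cref


def _diurnal(t: np.ndarray, amp: float = 3.0) -> np.ndarray:
    return amp * np.sin(2.0 * np.pi * np.asarray(t, float) / 24.0)


def study_a_table(n_subjects: int = 12,
                  timepoints: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0,
                                       8.0),
                  n_replicates: int = 3,
                  g: Callable = None, cref: float = 1000.0,
                  cmax_gm: float = 1000.0, cmax_log_sd: float = 0.25,
                  drug: str = "drugA",
                  noise_sd: float = 1.5, subj_sd: float = 5.0,
                  slope_sd: float = 0.10, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame, TableTruth]:
    """Crossover exposure-response study: placebo plus one active arm.

    Returns (replicate-level corrected quantile table, PK table, truth).
    The generating placebo-corrected change from baseline at concentration C
    is ``g(p) * C / cref`` for the population (subjects carry a lognormal
    Cmax and a relative random slope).
    """
    if g is None:
        g = g_tanh(40.0, 25.0)
    rng = np.random.default_rng(seed)
    base = tr_base(PF)
    gp = g(PF)
    tps = np.asarray(timepoints, dtype=float)
    rows, pk_rows = [], []
    subj_eff = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        b0 = rng.normal(0.0, subj_sd)
        s_i = rng.normal(0.0, slope_sd)
        cmax_i = cmax_gm * np.exp(rng.normal(0.0, cmax_log_sd))
        subj_eff.append({"subject": sid, "b0": b0, "slope_frac": s_i,
                         "cmax": cmax_i})
        for trt in ("placebo", drug):
            for t in tps:
                conc = cmax_i * pk_shape(t) if trt != "placebo" else 0.0
                if trt != "placebo":
                    pk_rows.append({"subject": sid, "treatment": trt,
                                    "timepoint": t, "drug": drug,
                                    "conc_ng_ml": conc})
                eff = gp * conc / cref * (1.0 + s_i)
                for rep in range(n_replicates):
                    vals = (base + b0 + _diurnal(t) + eff
                            + rng.normal(0.0, noise_sd, size=len(PF)))
                    row = {"subject": sid, "treatment": trt, "timepoint": t,
                           "replicate": rep, "RR_s": 1.0}
                    row.update(dict(zip(TRC_COLS, vals)))
                    rows.append(row)
    table = pd.DataFrame(rows)
    pk = pd.DataFrame(pk_rows)
    truth = TableTruth(g=g, cref=cref, cmax_gm=cmax_gm,
                       effect_at_cmax=gp * cmax_gm / cref,
                       subject_effects=pd.DataFrame(subj_eff))
    return table, pk, truth


def study_b_table(n_subjects: int = 12,
                  phase_timepoints: dict | None = None,
                  n_replicates: int = 3,
                  phase_effects: dict | None = None,
                  noise_sd: float = 1.5, subj_sd: float = 5.0,
                  eff_subj_sd: float = 2.0, seed: int = 0
                  ) -> tuple[pd.DataFrame, dict]:
    """Phase-dosing crossover study: placebo plus one combination arm.

    ``phase_effects`` maps phase -> effect profile (ms) added to every
    post-dose record of the phase; it is the design-B estimand itself.
    """
    if phase_timepoints is None:
        phase_timepoints = {"morning": (0.5, 1.0, 1.5, 2.0),
                            "afternoon": (4.5, 5.0, 5.5, 6.0),
                            "evening": (10.0, 10.5, 11.0, 11.5)}
    if phase_effects is None:
        phase_effects = {"morning": np.full(len(PF), -8.0),
                         "afternoon": g_tanh(40, 15.0)(PF),
                         "evening": g_tanh(30, 20.0)(PF)}
    rng = np.random.default_rng(seed)
    base = tr_base(PF)
    rows = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        b0 = rng.normal(0.0, subj_sd)
        e_i = rng.normal(0.0, eff_subj_sd)
        for trt in ("placebo", "combo"):
            for t0 in (0.0,):
                for rep in range(n_replicates):
                    vals = base + b0 + rng.normal(0.0, noise_sd, len(PF))
                    row = {"subject": sid, "treatment": trt, "timepoint": t0,
                           "replicate": rep, "RR_s": 1.0}
                    row.update(dict(zip(TRC_COLS, vals)))
                    rows.append(row)
            for phase, tps in phase_timepoints.items():
                eff = phase_effects[phase] if trt == "combo" else 0.0
                for t in tps:
                    for rep in range(n_replicates):
                        vals = (base + b0 + _diurnal(t)
                                + eff + (e_i if trt == "combo" else 0.0)
                                + rng.normal(0.0, noise_sd, len(PF)))
                        row = {"subject": sid, "treatment": trt,
                               "timepoint": t, "replicate": rep, "RR_s": 1.0}
                        row.update(dict(zip(TRC_COLS, vals)))
                        rows.append(row)
    return pd.DataFrame(rows), {"phase_effects": phase_effects}


def study_c_table(n_per_arm: int = 12,
                  timepoints: tuple = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0),
                  n_replicates: int = 3,
                  g: Callable = None, theta1: float = 0.0,
                  cref: float = 1000.0, cmax_gm: float = 1000.0,
                  cmax_log_sd: float = 0.25, drug: str = "drugC",
                  noise_sd: float = 1.5, subj_sd: float = 5.0,
                  slope_sd: float = 0.10, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame, TableTruth]:
    """Parallel-design study: a placebo arm and one active arm (distinct
    subjects).  Generating ddTrc at concentration C: theta1 + g(p)*C/cref."""
    if g is None:
        g = g_tanh(55.0, 20.0)
    rng = np.random.default_rng(seed)
    base = tr_base(PF)
    gp = g(PF)
    tps = np.asarray(timepoints, dtype=float)
    rows, pk_rows = [], []
    for arm, trt in ((0, "placebo"), (1, drug)):
        for i in range(n_per_arm):
            sid = f"C{arm}{i:03d}"
            b0 = rng.normal(0.0, subj_sd)
            s_i = rng.normal(0.0, slope_sd)
            cmax_i = cmax_gm * np.exp(rng.normal(0.0, cmax_log_sd))
            for t in tps:
                conc = cmax_i * pk_shape(t) if arm else 0.0
                if arm and t > 0:
                    pk_rows.append({"subject": sid, "treatment": trt,
                                    "timepoint": t, "drug": drug,
                                    "conc_ng_ml": conc})
                eff = (theta1 + gp * conc / cref * (1.0 + s_i)) if (
                    arm and t > 0) else 0.0
                for rep in range(n_replicates):
                    vals = (base + b0 + _diurnal(t) + eff
                            + rng.normal(0.0, noise_sd, len(PF)))
                    row = {"subject": sid, "treatment": trt, "timepoint": t,
                           "replicate": rep, "RR_s": 1.0}
                    row.update(dict(zip(TRC_COLS, vals)))
                    rows.append(row)
    truth = TableTruth(g=g, cref=cref, cmax_gm=cmax_gm,
                       effect_at_cmax=theta1 + gp * cmax_gm / cref)
    return pd.DataFrame(rows), pd.DataFrame(pk_rows), truth


#: transition points and amplitudes of the six-drug demonstration library
SIX_DRUG_LIBRARY = {
    "herg1": (20.0, 25.0, "hERG_predominant"),
    "herg2": (18.0, 30.0, "hERG_predominant"),
    "herg3": (22.0, 20.0, "hERG_predominant"),
    "multi1": (55.0, 18.0, "multichannel_low_risk"),
    "multi2": (57.0, 22.0, "multichannel_low_risk"),
    "multi3": (53.0, 15.0, "multichannel_low_risk"),
}


def six_drug_library(n_subjects: int = 10, seed: int = 0,
                     noise_sd: float = 1.5, **kwargs):
    """Study-A-style datasets for six drugs with known p_zero ground truth."""
    out = {}
    for k, (name, (p0, amp, cls)) in enumerate(SIX_DRUG_LIBRARY.items()):
        table, pk, truth = study_a_table(
            n_subjects=n_subjects, g=g_tanh(p0, amp), drug=name,
            noise_sd=noise_sd, seed=seed + 1000 * k, **kwargs)
        out[name] = {"table": table, "pk": pk, "truth": truth,
                     "risk_class": cls, "p0": p0}
    return out
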