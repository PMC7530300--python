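"""Analysis datasets and per-p pointwise mixed models for the study designs.

Designs:

* ``A`` — crossover, exposure-response: placebo-corrected change from
  baseline regressed on drug concentration with per-subject random
  intercept and slope.
* ``B`` — crossover, dosing phases: intercept-only model of the
  placebo-corrected change from baseline per phase (morning / afternoon /
  evening).
* ``C`` — parallel(+crossover) design: change from baseline with treatment
  indicator, per-drug concentration slopes (fixed + random), categorical
  nominal-timepoint effect (sum-to-zero) and a centered baseline covariate;
  the drug effect is theta1 + sum_l theta2_l * C_l.

Replicate ECGs are averaged per subject x treatment x timepoint before any
differencing; the baseline is the mean of a subject's pre-dose
(timepoint <= 0) records within the treatment period.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from tvv.vcg import P_GRID, TRC_COLS

log = logging.getLogger(__name__)

DD_COLS = [f"dd_{p}" for p in P_GRID]
D_COLS = [f"d_{p}" for p in P_GRID]
BL_COLS = [f"bl_{p}" for p in P_GRID]

#: study-B dosing phase boundaries in hours post first dose
PHASE_BOUNDS = (4.0, 9.5)


class DesignError(ValueError):
    pass


def phase_of(timepoint: float, bounds: tuple[float, float] = PHASE_BOUNDS) -> str:
    if timepoint < bounds[0]:
        return "morning"
    if timepoint < bounds[1]:
        return "afternoon"
    return "evening"


def merge_concentrations(records: pd.DataFrame, pk: pd.DataFrame | None
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Attach wide ``conc_<drug>`` columns (ng/mL, 0 where not dosed)."""
    if pk is None or len(pk) == 0:
        return records, []
    wide = pk.pivot_table(index=["subject", "treatment", "timepoint"],
                          columns="drug", values="conc_ng_ml",
                          aggfunc="mean").reset_index()
    drugs = [c for c in wide.columns
             if c not in ("subject", "treatment", "timepoint")]
    wide = wide.rename(columns={d: f"conc_{d}" for d in drugs})
    out = records.merge(wide, on=["subject", "treatment", "timepoint"],
                        how="left")
    conc_cols = [f"conc_{d}" for d in drugs]
    out[conc_cols] = out[conc_cols].fillna(0.0)
    return out, conc_cols


def build_analysis_dataset(table: pd.DataFrame, design: str,
                           pk: pd.DataFrame | None = None,
                           placebo_label: str = "placebo") -> pd.DataFrame:
    """Replicate-averaged, baseline-differenced analysis records.

    ``table`` holds replicate-level heart-rate-corrected quantile rows
    (``Trc_*`` columns).  For designs A and B the result carries
    placebo-corrected ``dd_*`` columns (active treatments only); for design C
    it carries ``d_*`` change-from-baseline columns for all arms together
    with ``trt`` indicators and per-p baseline covariates ``bl_*``.
    """
    design = design.upper()
    if design not in ("A", "B", "C"):
        raise DesignError(f"unknown design {design!r}")
    if TRC_COLS[0] not in table.columns:
        raise DesignError("table lacks corrected Trc columns; run HR correction")

    # concentrations are attached at replicate level (before any averaging or
    # resampling) so they survive the bootstrap's subject relabeling
    if pk is not None:
        table, _ = merge_concentrations(table, pk)
    conc_cols = [c for c in table.columns if c.startswith("conc_")]
    avg = (table.groupby(["subject", "treatment", "timepoint"], as_index=False)
           [TRC_COLS + conc_cols].mean())
    base = avg[avg["timepoint"] <= 0]
    post = avg[avg["timepoint"] > 0]
    bl = (base.groupby(["subject", "treatment"])[TRC_COLS].mean()
          .rename(columns=dict(zip(TRC_COLS, BL_COLS))))
    merged = post.join(bl, on=["subject", "treatment"])
    missing_bl = merged[BL_COLS[0]].isna()
    for _, r in merged[missing_bl].iterrows():
        log.warning("dropping subject %s treatment %s: no baseline records",
                    r["subject"], r["treatment"])
    merged = merged[~missing_bl].copy()
    delta = merged[TRC_COLS].to_numpy() - merged[BL_COLS].to_numpy()
    merged = pd.concat([merged, pd.DataFrame(delta, columns=D_COLS,
                                             index=merged.index)], axis=1)

    if design == "C":
        merged["trt"] = (merged["treatment"] != placebo_label).astype(int)
        keep = (["subject", "treatment", "trt", "timepoint"] + conc_cols
                + D_COLS + BL_COLS)
        return merged[keep].reset_index(drop=True)

    # crossover designs: placebo-correct within subject by nominal timepoint
    pla = merged[merged["treatment"] == placebo_label]
    act = merged[merged["treatment"] != placebo_label]
    if len(pla) == 0:
        raise DesignError("no placebo records to correct against")
    pla_d = pla.set_index(["subject", "timepoint"])[D_COLS]
    act = act.set_index(["subject", "timepoint"])
    aligned = pla_d.reindex(act.index)
    unmatched = aligned[D_COLS[0]].isna()
    for subj, tp in act.index[unmatched]:
        log.warning("dropping subject %s timepoint %s: no matching placebo "
                    "record", subj, tp)
    act = act[~unmatched.to_numpy()]
    aligned = aligned[~unmatched.to_numpy()]
    dd = act[D_COLS].to_numpy() - aligned.to_numpy()
    out = act.reset_index()[["subject", "treatment", "timepoint"]
                            + conc_cols].copy()
    out = pd.concat([out, pd.DataFrame(dd, columns=DD_COLS, index=out.index)],
                    axis=1)
    if conc_cols:
        out["conc"] = out[conc_cols].sum(axis=1)
    if design == "B":
        out["phase"] = out["timepoint"].map(phase_of)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pointwise fits
# ---------------------------------------------------------------------------


@dataclass
class PointwiseFit:
    design: str
    p: int
    names: list[str]
    theta: np.ndarray
    se: np.ndarray
    re_var: dict[str, float] = field(default_factory=dict)
    condition: str = ""

    def coef(self, name: str) -> float:
        return float(self.theta[self.names.index(name)])

    def predict_dd(self, conc: float | dict[str, float] = 0.0) -> float:
        """Placebo-corrected drug effect at the given concentration(s)."""
        if self.design == "A":
            return self.coef("intercept") + self.coef("slope") * float(conc)
        if self.design == "B":
            return self.coef("intercept")
        eff = self.coef("trt")
        conc = conc if isinstance(conc, dict) else {}
        for name in self.names:
            if name.startswith("conc_"):
                eff += self.coef(name) * conc.get(name.removeprefix("conc_"), 0.0)
        return eff


def _mixedlm(y, X, groups, exog_re):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        try:
            return model.fit(reml=True)
        except Exception:
            return model.fit(reml=True, method="cg")


def fit_pointwise_A(records: pd.DataFrame, p: int,
                    conc_col: str = "conc") -> PointwiseFit:
    if records["subject"].nunique() < 2:
        raise DesignError("need >= 2 subjects")
    conc = records[conc_col].to_numpy(float)
    if np.allclose(conc, 0.0):
        raise DesignError("slope unidentifiable: all concentrations are zero")
    y = records[f"dd_{p}"].to_numpy(float)
    X = np.column_stack([np.ones_like(conc), conc])
    res = _mixedlm(y, X, records["subject"].to_numpy(), X)
    return PointwiseFit("A", p, ["intercept", "slope"],
                        np.asarray(res.fe_params), np.asarray(res.bse_fe),
                        {"cov_re": float(np.asarray(res.cov_re)[0, 0])})


def fit_pointwise_B(records: pd.DataFrame, p: int, phase: str) -> PointwiseFit:
    sub = records[records["phase"] == phase]
    if len(sub) == 0:
        raise DesignError(f"no records in phase {phase!r}")
    if sub["subject"].nunique() < 2:
        raise DesignError("need >= 2 subjects in phase")
    y = sub[f"dd_{p}"].to_numpy(float)
    X = np.ones((len(sub), 1))
    res = _mixedlm(y, X, sub["subject"].to_numpy(), X)
    return PointwiseFit("B", p, ["intercept"], np.asarray(res.fe_params),
                        np.asarray(res.bse_fe), condition=phase)


def sum_contrasts(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero coding of a categorical variable (last level as -1)."""
    levels = sorted(values.unique())
    if len(levels) < 2:
        return np.zeros((len(values), 0)), []
    cols = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(arr == lev, 1.0, 0.0)
    cols[arr == levels[-1], :] = -1.0
    return cols, [f"nt_{lev}" for lev in levels[:-1]]


def fit_pointwise_C(records: pd.DataFrame, p: int,
                    drugs: list[str] | None = None) -> PointwiseFit:
    if records["trt"].nunique() < 2:
        raise DesignError("no placebo arm present in design-C records")
    if drugs is None:
        drugs = [c.removeprefix("conc_") for c in records.columns
                 if c.startswith("conc_")]
    y = records[f"d_{p}"].to_numpy(float)
    n = len(records)
    trt = records["trt"].to_numpy(float)
    conc = np.column_stack([records[f"conc_{d}"].to_numpy(float)
                            for d in drugs]) if drugs else np.zeros((n, 0))
    nt, nt_names = sum_contrasts(records["timepoint"])
    bl = records[f"bl_{p}"].to_numpy(float)
    blc = bl - bl.mean()
    X = np.column_stack([np.ones(n), trt, conc, nt, blc])
    names = (["intercept", "trt"] + [f"conc_{d}" for d in drugs] + nt_names
             + ["baseline"])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("collinear design-C coding (treatment vs nominal "
                          "timepoint); check the treatment/timepoint layout")
    Z = np.column_stack([np.ones(n), conc])
    res = _mixedlm(y, X, records["subject"].to_numpy(), Z)
    return PointwiseFit("C", p, names, np.asarray(res.fe_params),
                        np.asarray(res.bse_fe))
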