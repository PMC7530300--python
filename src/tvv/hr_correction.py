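"""Per-quantile heart-rate correction: Tr(p)c = Tr(p) / RR^alpha_p.

The exponents alpha_p are estimated from drug-free data, one linear mixed
model per p:

    log(Tr(p)) = log(beta_p) + alpha_p * log(RR) + eps

with correlated per-subject random intercept and slope (REML).  Singular or
non-converging fits fall back to a random-intercept-only model, then to OLS;
every fallback is recorded on the profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from tvv.vcg import P_GRID, TR_COLS, TRC_COLS

log = logging.getLogger(__name__)


class AlphaFitError(ValueError):
    pass


@dataclass
class AlphaProfile:
    p: np.ndarray
    alpha: np.ndarray
    se_alpha: np.ndarray
    log_beta: np.ndarray
    n_obs: int = 0
    fingerprint: str = ""
    fallbacks: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=int)
        for name in ("alpha", "se_alpha", "log_beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.log_beta).all()):
            raise AlphaFitError("non-finite alpha/log_beta in AlphaProfile")

    def alpha_at(self, p: int) -> float:
        idx = np.searchsorted(self.p, p)
        if idx >= len(self.p) or self.p[idx] != p:
            raise KeyError(f"no alpha for p={p}")
        return float(self.alpha[idx])

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame({"p": self.p, "alpha": self.alpha,
                           "se": self.se_alpha, "log_beta": self.log_beta})
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlphaProfile":
        df = pd.read_csv(path)
        return cls(df["p"].to_numpy(int), df["alpha"].to_numpy(),
                   df["se"].to_numpy(), df["log_beta"].to_numpy())


def drug_free_mask(table: pd.DataFrame, placebo_label: str = "placebo"
                   ) -> pd.Series:
    """Placebo-period ECGs plus pre-dose (timepoint <= 0) ECGs of active
    periods — the pooled drug-free subset used for the alpha fit."""
    return (table["treatment"] == placebo_label) | (table["timepoint"] <= 0)


def fit_alpha_profile(drug_free: pd.DataFrame,
                      p_grid: np.ndarray = P_GRID) -> AlphaProfile:
    """Fit the per-p log-log mixed models to drug-free quantile-table rows."""
    if drug_free["subject"].nunique() < 2:
        raise AlphaFitError("need at least 2 subjects to fit alpha")
    log_rr = np.log(drug_free["RR_s"].to_numpy(float))
    if not np.isfinite(log_rr).all():
        raise AlphaFitError("non-finite RR in drug-free data")
    if np.var(log_rr) <= 1e-12:
        raise AlphaFitError("alpha unidentifiable: RR constant in drug-free data")
    groups = drug_free["subject"].to_numpy()
    X = np.column_stack([np.ones_like(log_rr), log_rr])
    alphas = np.empty(len(p_grid))
    ses = np.empty(len(p_grid))
    intercepts = np.empty(len(p_grid))
    fallbacks: dict[int, str] = {}
    for i, p in enumerate(p_grid):
        y = np.log(drug_free[f"Tr_{p}"].to_numpy(float))
        icpt, slope, se, fb = _fit_one_p(y, X, groups)
        alphas[i], ses[i], intercepts[i] = slope, se, icpt
        if fb:
            fallbacks[int(p)] = fb
            log.info("alpha fit p=%d used fallback %s", p, fb)
    return AlphaProfile(np.asarray(p_grid), alphas, ses, intercepts,
                        n_obs=len(drug_free), fallbacks=fallbacks)


def _fit_one_p(y, X, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups, exog_re=X).fit(reml=True)
            if res.converged and np.isfinite(res.bse_fe).all():
                return res.fe_params[0], res.fe_params[1], res.bse_fe[1], ""
        except Exception:
            pass
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
            if res.converged and np.isfinite(res.bse_fe).all():
                return (res.fe_params[0], res.fe_params[1], res.bse_fe[1],
                        "random-intercept-only")
        except Exception:
            pass
        res = sm.OLS(y, X).fit()
        return res.params[0], res.params[1], res.bse[1], "ols"


def apply_hr_correction(table: pd.DataFrame, alphas: AlphaProfile
                        ) -> pd.DataFrame:
    """Add Trc_p = Tr_p / RR^alpha_p columns; original Tr columns retained."""
    rr = table["RR_s"].to_numpy(float)
    if np.any(~np.isfinite(rr)) or np.any(rr <= 0):
        raise ValueError("RR must be positive and finite for HR correction")
    if len(alphas.p) != len(P_GRID) or not np.array_equal(alphas.p, P_GRID):
        missing = sorted(set(P_GRID) - set(alphas.p))
        raise ValueError(f"alpha profile incomplete, missing p={missing[:5]}...")
    tr = table[TR_COLS].to_numpy(float)
    trc = tr / np.power.outer(rr, alphas.alpha)
    out = table.drop(columns=TRC_COLS, errors="ignore")
    return pd.concat([out, pd.DataFrame(trc, columns=TRC_COLS,
                                        index=out.index)], axis=1)


_DEFAULT_ALPHA_PATH = Path(__file__).parent / "data" / "default_alpha.csv"


def default_alpha_profile() -> AlphaProfile:
    """Packaged reference profile, fit on the synthetic drug-free corpus."""
    return AlphaProfile.from_csv(_DEFAULT_ALPHA_PATH)
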