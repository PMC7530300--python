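"""Continuous drug-effect profiles via a spline-parametrized functional model.

The per-p pointwise mixed models of :mod:`tvv.effect_models` are joined into
one linear mixed model over all p = 1..100 by expanding every p-dependent
coefficient in a cubic B-spline basis with equidistant breakpoints on
[1, 100].  Each scalar covariate of the pointwise model contributes m
columns (covariate times the basis evaluated at the row's p); per-subject
random effects are spline-expanded the same way with a diagonal covariance.

Inference on the fitted profiles comes from the hierarchical bootstrap
(:mod:`tvv.bootstrap`), not from the single-fit standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from tvv import _lmm
from tvv.effect_models import BL_COLS, D_COLS, DD_COLS, DesignError, sum_contrasts
from tvv.vcg import P_GRID

DEFAULT_KNOTS = {"A": 8, "B": 16, "C": 12}


@dataclass
class SplineBasis:
    """Cubic B-spline basis on the integer p grid 1..100."""

    n_knots: int
    breakpoints: np.ndarray
    t: np.ndarray
    B: np.ndarray  # (len(p_grid), m)
    degree: int = 3

    @property
    def m(self) -> int:
        return self.B.shape[1]


def build_spline_basis(n_knots: int, p_grid: np.ndarray = P_GRID,
                       degree: int = 3) -> SplineBasis:
    """``n_knots`` equidistant breakpoints spanning [1, 100], boundaries
    included; the basis dimension is ``n_knots - 2 + degree + 1``."""
    if n_knots < 2:
        raise ValueError("need at least the two boundary knots")
    bp = np.linspace(1.0, 100.0, n_knots)
    t = np.concatenate([[bp[0]] * degree, bp, [bp[-1]] * degree])
    m = len(t) - degree - 1
    x = np.asarray(p_grid, dtype=float)
    spl = BSpline(t, np.eye(m), degree, extrapolate=False)
    B = spl(np.clip(x, bp[0], bp[-1]))
    # right boundary: the conventional half-open support leaves the last
    # point empty; assign it to the terminal basis function
    B = np.where(np.isfinite(B), B, np.nan)
    edge = (~np.isfinite(B).all(axis=1)) | (B.sum(axis=1) < 0.5)
    B[edge] = 0.0
    B[edge, -1] = 1.0
    return SplineBasis(n_knots=n_knots, breakpoints=bp, t=t, B=B, degree=degree)


@dataclass
class EffectProfile:
    """ddTrc(p) on p = 1..100 with optional 90% band and derived p_zero."""

    ddTrc: np.ndarray
    lower90: np.ndarray | None = None
    upper90: np.ndarray | None = None
    concentrations: dict[str, float] = field(default_factory=dict)
    p_zero: int | None = None

    def __post_init__(self) -> None:
        self.ddTrc = np.asarray(self.ddTrc, dtype=float)
        if self.ddTrc.shape != (len(P_GRID),):
            raise ValueError("profile must cover p = 1..100")
        if self.p_zero is None and np.isfinite(self.ddTrc).all():
            from tvv.pzero import compute_pzero
            self.p_zero = compute_pzero(self.ddTrc)

    def at(self, p: int) -> float:
        return float(self.ddTrc[int(p) - 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"p": P_GRID, "ddTrc": self.ddTrc})
        if self.lower90 is not None:
            df["lower90"] = self.lower90
            df["upper90"] = self.upper90
        return df


@dataclass
class FunctionalModelFit:
    design: str
    basis: SplineBasis
    coefs: dict[str, np.ndarray]      # block name -> m spline coefficients
    lmm: _lmm.LMMResult
    drugs: list[str] = field(default_factory=list)
    condition: str = ""
    n_records: int = 0

    @property
    def converged(self) -> bool:
        return self.lmm.converged

    @property
    def n_params(self) -> int:
        return self.lmm.n_params

    def coef_profile(self, name: str) -> np.ndarray:
        """The fitted coefficient function evaluated on the p grid."""
        return self.basis.B @ self.coefs[name]

    def to_json_dict(self) -> dict:
        """Serializable container: basis spec + coefficient arrays + fit log."""
        return {
            "design": self.design,
            "basis": {"n_knots": self.basis.n_knots,
                      "degree": self.basis.degree,
                      "breakpoints": self.basis.breakpoints.tolist()},
            "coefs": {k: v.tolist() for k, v in self.coefs.items()},
            "drugs": self.drugs,
            "condition": self.condition,
            "n_records": self.n_records,
            "n_params": self.n_params,
            "sigma2": self.lmm.sigma2,
            "re_sd_ratios": self.lmm.lambdas.tolist(),
            "converged": self.converged,
            "reml_deviance": self.lmm.reml_deviance,
        }


def _stack_design(design: str, records: pd.DataFrame, basis: SplineBasis,
                  drugs: list[str] | None):
    """Expand the pointwise design to the stacked (n_records x 100) layout."""
    B = basis.B
    n_rec, m = len(records), basis.m
    if n_rec == 0:
        raise DesignError("no analysis records")
    Bt = np.tile(B, (n_rec, 1))
    groups = np.repeat(records["subject"].to_numpy(), len(P_GRID))

    if design == "A":
        conc = np.repeat(records["conc"].to_numpy(float), len(P_GRID))
        if np.allclose(conc, 0.0):
            raise DesignError("slope unidentifiable: all concentrations zero")
        X = np.hstack([Bt, conc[:, None] * Bt])
        blocks = {"intercept": slice(0, m), "slope": slice(m, 2 * m)}
        return records[DD_COLS].to_numpy(float).ravel(), X, X, groups, blocks, []

    if design == "B":
        X = Bt
        return (records[DD_COLS].to_numpy(float).ravel(), X, X, groups,
                {"intercept": slice(0, m)}, [])

    if drugs is None:
        drugs = [c.removeprefix("conc_") for c in records.columns
                 if c.startswith("conc_")]
    if records["trt"].nunique() < 2:
        raise DesignError("no placebo arm present in design-C records")
    trt = np.repeat(records["trt"].to_numpy(float), len(P_GRID))
    cols = [Bt, trt[:, None] * Bt]
    blocks = {"intercept": slice(0, m), "trt": slice(m, 2 * m)}
    pos = 2 * m
    for d in drugs:
        cd = np.repeat(records[f"conc_{d}"].to_numpy(float), len(P_GRID))
        cols.append(cd[:, None] * Bt)
        blocks[f"conc_{d}"] = slice(pos, pos + m)
        pos += m
    nt, nt_names = sum_contrasts(records["timepoint"])
    for j, name in enumerate(nt_names):
        cj = np.repeat(nt[:, j], len(P_GRID))
        cols.append(cj[:, None] * Bt)
        blocks[name] = slice(pos, pos + m)
        pos += m
    bl = records[BL_COLS].to_numpy(float)
    blc = (bl - bl.mean(axis=0)).ravel()
    cols.append(blc[:, None] * Bt)
    blocks["baseline"] = slice(pos, pos + m)
    X = np.hstack(cols)
    Z = np.hstack([Bt] + [np.repeat(records[f"conc_{d}"].to_numpy(float),
                                    len(P_GRID))[:, None] * Bt for d in drugs])
    return records[D_COLS].to_numpy(float).ravel(), X, Z, groups, blocks, drugs


def fit_functional(design: str, records: pd.DataFrame,
                   basis: SplineBasis | None = None,
                   drugs: list[str] | None = None,
                   phase: str | None = None,
                   start: np.ndarray | None = None) -> FunctionalModelFit:
    """Fit the functional mixed model for one design / treatment condition."""
    design = design.upper()
    if design not in DEFAULT_KNOTS:
        raise DesignError(f"unknown design {design!r}")
    if basis is None:
        basis = build_spline_basis(DEFAULT_KNOTS[design])
    if phase is not None:
        records = records[records["phase"] == phase]
    y, X, Z, groups, blocks, fit_drugs = _stack_design(design, records, basis,
                                                       drugs)
    res = _lmm.reml_fit(y, X, Z, groups, start=start)
    if not np.isfinite(res.beta).all():
        raise _lmm.LMMError("functional fit produced non-finite coefficients")
    coefs = {name: res.beta[sl] for name, sl in blocks.items()}
    return FunctionalModelFit(design=design, basis=basis, coefs=coefs,
                              lmm=res, drugs=fit_drugs,
                              condition=phase or "", n_records=len(records))


def predict_effect_profile(fit: FunctionalModelFit,
                           concentrations: float | dict[str, float] = 0.0
                           ) -> EffectProfile:
    """Evaluate the fitted drug-effect profile at the given concentration(s).

    The zero-concentration prediction (the intercept profile) is obtained by
    passing 0 (designs A, C) — for design A this is the model intercept, for
    design C the treatment main effect at C = 0.
    """
    if not fit.converged:
        raise _lmm.LMMError("functional model did not converge")
    if isinstance(concentrations, dict):
        conc_map = dict(concentrations)
    else:
        conc_map = {"drug": float(concentrations)}
    if any(v < 0 for v in conc_map.values()):
        raise ValueError("negative concentration")

    if fit.design == "A":
        c = sum(conc_map.values())
        dd = fit.coef_profile("intercept") + c * fit.coef_profile("slope")
    elif fit.design == "B":
        dd = fit.coef_profile("intercept")
    else:
        dd = fit.coef_profile("trt").copy()
        for d in fit.drugs:
            dd = dd + conc_map.get(d, 0.0) * fit.coef_profile(f"conc_{d}")
    return EffectProfile(ddTrc=dd, concentrations=conc_map)


def intercept_profile(fit: FunctionalModelFit) -> EffectProfile:
    """Model prediction at zero drug concentration."""
    if fit.design == "B":
        return predict_effect_profile(fit)
    zeros = {d: 0.0 for d in fit.drugs} if fit.design == "C" else 0.0
    return predict_effect_profile(fit, zeros)
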