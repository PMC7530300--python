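"""Two-step nonparametric bootstrap for continuous effect profiles.

Subjects are the primary resampling unit (drawn with replacement and given
fresh identities so the mixed model treats duplicates as distinct); within
every drawn subject the replicate 10-s ECGs of each treatment x timepoint
cell are resampled with replacement before replicate-averaging.  Each
bootstrap replicate re-runs dataset construction, the functional fit and the
profile prediction; the summary profile is the elementwise median with the
5% / 95% empirical quantiles as the two-sided 90% band.

Replicates draw from pre-assigned independent substreams of the master seed,
so results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tvv import _lmm
from tvv.effect_models import DesignError, build_analysis_dataset
from tvv.functional_model import (EffectProfile, FunctionalModelFit,
                                  SplineBasis, fit_functional,
                                  predict_effect_profile)
from tvv.pzero import compute_pzero

log = logging.getLogger(__name__)


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapResult:
    profiles: np.ndarray          # (n_ok, 100)
    N: int
    seed: int
    summary: EffectProfile
    pzero_samples: np.ndarray
    n_failed: int = 0
    base_fit: FunctionalModelFit | None = None

    def band_width(self, p: int) -> float:
        i = int(p) - 1
        return float(self.summary.upper90[i] - self.summary.lower90[i])


class _ResamplePlan:
    """Pre-indexed row structure of a replicate-level quantile table."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)
        subj = self.table["subject"].to_numpy()
        self.subjects = list(dict.fromkeys(subj))
        if len(self.subjects) < 1:
            raise BootstrapError("empty table")
        self.cells: dict = {}
        key = (self.table["subject"].astype(str) + "\x00"
               + self.table["treatment"].astype(str) + "\x00"
               + self.table["timepoint"].astype(str))
        for s in self.subjects:
            self.cells[s] = []
        for _, idx in pd.Series(np.arange(len(self.table))).groupby(
                key.to_numpy()):
            rows = idx.to_numpy()
            self.cells[subj[rows[0]]].append(rows)

    def resample(self, rng: np.random.Generator) -> pd.DataFrame:
        n = len(self.subjects)
        draw = rng.integers(0, n, size=n)
        parts: list[np.ndarray] = []
        new_ids: list[str] = []
        for slot, si in enumerate(draw):
            sid = f"bs{slot:04d}"
            for rows in self.cells[self.subjects[si]]:
                take = rows[rng.integers(0, len(rows), size=len(rows))]
                parts.append(take)
                new_ids.extend([sid] * len(take))
        idx = np.concatenate(parts)
        out = self.table.iloc[idx].copy()
        out["subject"] = new_ids
        return out.reset_index(drop=True)


def two_step_resample(table: pd.DataFrame,
                      rng_state: int | np.random.Generator) -> pd.DataFrame:
    """One draw of the two-step resampling scheme; deterministic given
    ``rng_state``."""
    if table["subject"].nunique() < 1:
        raise BootstrapError("need at least one subject")
    rng = (rng_state if isinstance(rng_state, np.random.Generator)
           else np.random.default_rng(rng_state))
    return _ResamplePlan(table).resample(rng)


def bootstrap_profiles(design: str, table: pd.DataFrame,
                       basis: SplineBasis | None = None,
                       concentrations: float | dict[str, float] = 0.0,
                       N: int = 200, seed: int = 0,
                       pk: pd.DataFrame | None = None,
                       phase: str | None = None,
                       drugs: list[str] | None = None,
                       placebo_label: str = "placebo",
                       max_fail_frac: float = 0.2) -> BootstrapResult:
    """Bootstrap distribution of the effect profile for one drug condition.

    ``table`` is the replicate-level corrected quantile table (the state
    *before* replicate averaging, so the secondary resampling step has
    replicates to draw from).
    """
    if N < 1:
        raise BootstrapError("N must be >= 1")
    if table["subject"].nunique() < 2:
        raise BootstrapError("need at least 2 subjects to bootstrap")
    if pk is not None:
        # attach concentrations up front: resampled subjects get fresh IDs,
        # so a post-hoc merge by subject would lose them
        from tvv.effect_models import merge_concentrations
        table, _ = merge_concentrations(table, pk)
        pk = None

    def run(tab, start=None):
        records = build_analysis_dataset(tab, design, pk=pk,
                                         placebo_label=placebo_label)
        fit = fit_functional(design, records, basis=basis, drugs=drugs,
                             phase=phase, start=start)
        return fit, predict_effect_profile(fit, concentrations)

    base_fit, _ = run(table)
    start = base_fit.lmm.theta

    plan = _ResamplePlan(table)
    streams = np.random.SeedSequence(seed).spawn(N)
    profiles = np.empty((N, 100))
    ok = np.zeros(N, dtype=bool)
    for i in range(N):
        rng = np.random.default_rng(streams[i])
        try:
            _, prof = run(plan.resample(rng), start=start)
            profiles[i] = prof.ddTrc
            ok[i] = np.isfinite(prof.ddTrc).all()
        except (DesignError, _lmm.LMMError, ValueError) as exc:
            log.warning("bootstrap replicate %d failed: %s", i, exc)
    n_failed = int(N - ok.sum())
    if n_failed > max_fail_frac * N:
        raise BootstrapError(
            f"unstable model under resampling: {n_failed}/{N} replicates failed")
    profiles = profiles[ok]
    med = np.quantile(profiles, 0.5, axis=0)
    lo = np.quantile(profiles, 0.05, axis=0)
    hi = np.quantile(profiles, 0.95, axis=0)
    conc_map = (dict(concentrations) if isinstance(concentrations, dict)
                else {"drug": float(concentrations)})
    summary = EffectProfile(ddTrc=med, lower90=lo, upper90=hi,
                            concentrations=conc_map)
    pz = np.array([compute_pzero(row) for row in profiles])
    return BootstrapResult(profiles=profiles, N=N, seed=seed, summary=summary,
                           pzero_samples=pz, n_failed=n_failed,
                           base_fit=base_fit)
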