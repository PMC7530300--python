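"""Signal-level synthesis of annotated 12-lead ECG studies.

Each beat is built from an XYZ dipole: Gaussian wavelets for the P wave and
QRS complex, and a T loop traced by rotating Gaussian components.  The T-loop
curve is re-parametrized by arc length, so the repolarization time course can
be *prescribed*: the dipole at time t after the trajectory start sits at the
arc-length fraction F(t) given by inverting the designed quantile curve
Tr(p).  Heart-rate dependence (RR^alpha(p)) and concentration-proportional
drug warps therefore hold exactly by construction, and the designed Tr(p) is
the ground truth the extraction pipeline must recover (up to sampling
discretization).

Beats are projected to the eight independent leads with the forward Dower
matrix; annotations are emitted from the construction itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from tvv.ecg_io import AnnotatedEcg, BeatAnnotation, StudyKey, write_aecg, \
    write_csv, write_wfdb
from tvv.synthetic.tables import alpha_true, g_tanh, pk_shape, tr_base
from tvv.vcg import DOWER_FORWARD, P_GRID

PF = P_GRID.astype(float)


@dataclass
class BeatMorphology:
    """Subject-specific T-loop / QRS shape parameters."""

    t100_ms: float = 300.0    # Tr(100) at RR = 1 s
    shape: float = 0.6        # concavity of the base duration curve
    amp_mv: float = 0.55      # T-loop amplitude scale
    theta0: float = 0.3       # initial loop direction (rad)
    dtheta: float = 2.6       # total loop rotation (rad)
    tilt: float = 0.9         # phase offset of the Z component
    qrs_amp: float = 1.1

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "BeatMorphology":
        return cls(t100_ms=rng.normal(300.0, 12.0),
                   shape=rng.normal(0.6, 0.03),
                   amp_mv=0.55 * np.exp(rng.normal(0.0, 0.15)),
                   theta0=rng.normal(0.3, 0.2),
                   dtheta=rng.normal(2.6, 0.25),
                   tilt=rng.normal(0.9, 0.15),
                   qrs_amp=1.1 * np.exp(rng.normal(0.0, 0.1)))


def _t_loop_table(morph: BeatMorphology, n_dense: int = 4000):
    """Dense T-loop curve re-parametrized by arc-length fraction."""
    s = np.linspace(0.0, 1.0, n_dense)
    # taper to exactly zero at both ends so the trajectory joins the
    # isoelectric line without steps (steps would ring under filtering)
    taper = np.clip(s / 0.04, 0.0, 1.0) * np.clip((1.0 - s) / 0.04, 0.0, 1.0)
    env1 = np.exp(-0.5 * ((s - 0.45) / 0.22) ** 2) * taper
    env2 = 0.35 * np.exp(-0.5 * ((s - 0.78) / 0.17) ** 2) * taper
    th = morph.theta0 + morph.dtheta * s
    x = morph.amp_mv * (env1 * np.cos(th) + env2 * np.cos(th + 1.2))
    y = 0.6 * morph.amp_mv * (env1 * np.sin(th) + env2 * np.sin(th + 1.2))
    z = 0.4 * morph.amp_mv * env1 * np.sin(th + morph.tilt)
    pts = np.column_stack([x, y, z])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    u = cum / cum[-1]
    keep = np.concatenate([[True], np.diff(u) > 0])
    return u[keep], pts[keep]


def loop_at_fraction(u_table, pts_table, u: np.ndarray) -> np.ndarray:
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return np.column_stack([np.interp(u, u_table, pts_table[:, j])
                            for j in range(3)])


def designed_quantiles(morph: BeatMorphology, rr_s: float,
                       conc: float = 0.0, cref: float = 1000.0,
                       g: Callable | None = None,
                       alpha: Callable = alpha_true) -> np.ndarray:
    """The Tr(p) curve a beat is constructed to realize (ms, p = 1..100)."""
    tr = tr_base(PF, t100=morph.t100_ms, shape=morph.shape) * rr_s ** alpha(PF)
    if g is not None and conc != 0.0:
        tr = tr + g(PF) * conc / cref
    if np.any(np.diff(np.concatenate([[0.0], tr])) <= 0.0):
        raise ValueError("invalid effect profile: non-monotone time warp")
    return tr


def simulate_beat(morph: BeatMorphology, rr_s: float, conc: float = 0.0,
                  cref: float = 1000.0, g: Callable | None = None,
                  alpha: Callable = alpha_true, fs: float = 500.0,
                  rng: np.random.Generator | None = None,
                  jitter_sd_ms: float = 0.0):
    """One beat: (segment (n, 8) in mV, BeatAnnotation, designed Tr(p)).

    Annotation indices are relative to the beat segment start.
    """
    if not 0.4 <= rr_s <= 2.0:
        raise ValueError("rr_s outside [0.4, 2.0] s")
    tr = designed_quantiles(morph, rr_s, conc, cref, g, alpha)
    p_on, q_on, j_ms = 2.0, 60.0, 150.0
    ts = j_ms + 20.0
    t_end_ms = ts + tr[-1]
    n = int(round(rr_s * fs))
    t_ms = np.arange(n) * 1000.0 / fs

    # repolarization: dipole follows the arc-length fraction schedule F(t)
    u_tab, pts_tab = _t_loop_table(morph)
    frac = np.interp(t_ms - ts, np.concatenate([[0.0], tr]),
                     np.concatenate([[0.0], PF / 100.0]))
    xyz = loop_at_fraction(u_tab, pts_tab, frac)
    xyz[(t_ms < ts) | (t_ms > t_end_ms)] = 0.0

    # depolarization wavelets (outside the analyzed trajectory span)
    def bump(center, width, amps):
        w = np.exp(-0.5 * ((t_ms - center) / width) ** 2)
        return w[:, None] * np.asarray(amps)

    xyz = xyz + bump(10.0, 5.0, [0.05, 0.04, 0.01])             # P wave
    xyz = xyz + bump(q_on + 25.0, 8.0,
                     np.array([1.2, -0.45, 0.5]) * morph.qrs_amp)  # QRS

    seg8 = xyz @ DOWER_FORWARD.T

    j_idx = int(round(j_ms * fs / 1000.0))
    t_end_idx = int(round(t_end_ms * fs / 1000.0))
    if rng is not None and jitter_sd_ms > 0.0:
        j_jit = int(round(rng.normal(0.0, jitter_sd_ms) * fs / 1000.0))
        t_jit = int(round(rng.normal(0.0, jitter_sd_ms) * fs / 1000.0))
        lo = int(round(q_on * fs / 1000.0)) + 1
        hi = t_end_idx - int(round(0.020 * fs)) - 2
        j_idx = int(np.clip(j_idx + j_jit, lo, hi))
        t_end_idx = int(np.clip(t_end_idx + t_jit,
                                j_idx + int(round(0.020 * fs)) + 2, n - 1))
    ann = BeatAnnotation(p_on=int(round(p_on * fs / 1000.0)),
                         q_on=int(round(q_on * fs / 1000.0)),
                         j_point=j_idx, t_end=min(t_end_idx, n - 1))
    return seg8, ann, tr


def simulate_ecg(morph: BeatMorphology, rr_s: float = 1.0,
                 duration_s: float = 10.0, conc: float = 0.0,
                 cref: float = 1000.0, g: Callable | None = None,
                 alpha: Callable = alpha_true, fs: float = 500.0,
                 noise_mv: float = 0.0, jitter_sd_ms: float = 0.0,
                 rng: np.random.Generator | None = None,
                 meta: StudyKey | None = None
                 ) -> tuple[AnnotatedEcg, np.ndarray]:
    """A 10-s record of identical beats; returns (ecg, designed Tr(p))."""
    rng = rng or np.random.default_rng(0)
    n_total = int(round(duration_s * fs))
    n_beat = int(round(rr_s * fs))
    sig = np.zeros((n_total, 8))
    beats = []
    tr = None
    offset = 0
    while offset + n_beat <= n_total:
        seg, ann, tr = simulate_beat(morph, rr_s, conc, cref, g, alpha, fs,
                                     rng=rng, jitter_sd_ms=jitter_sd_ms)
        sig[offset:offset + n_beat] += seg
        beats.append(BeatAnnotation(ann.p_on + offset, ann.q_on + offset,
                                    ann.j_point + offset,
                                    ann.t_end + offset))
        offset += n_beat
    if noise_mv > 0.0:
        sig = sig + rng.normal(0.0, noise_mv, size=sig.shape)
    ecg = AnnotatedEcg(sig, fs, beats, meta=meta or StudyKey())
    return ecg, tr


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

STUDY_A_TIMEPOINTS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0,
                      7.0, 8.0, 12.0, 14.0, 24.0)


@dataclass
class DrugSpec:
    name: str
    cmax_gm: float = 1000.0
    cmax_log_sd: float = 0.25
    cref: float = 1000.0
    p0: float = 40.0
    amp: float = 25.0

    def g(self) -> Callable:
        """Effect profile tapered toward p = 0 so the time warp stays
        monotone (the base quantile curve is short at small p)."""
        core = g_tanh(self.p0, self.amp)
        return lambda p: core(p) * np.sqrt(np.asarray(p, float) / 100.0)


@dataclass
class SyntheticDesign:
    design: str = "A"
    n_subjects: int = 22
    timepoints: tuple = STUDY_A_TIMEPOINTS
    n_replicates: int = 3
    drugs: tuple[DrugSpec, ...] = (
        DrugSpec("dofetilide_like", p0=20.0, amp=18.0),
        DrugSpec("quinidine_like", p0=40.0, amp=40.0),
        DrugSpec("ranolazine_like", p0=50.0, amp=10.0),
        DrugSpec("verapamil_like", p0=55.0, amp=4.0),
    )
    rr_log_sd: float = 0.08
    noise_mv: float = 0.0
    jitter_sd_ms: float = 2.0
    duration_s: float = 10.0
    seed: int = 0

    def treatments(self) -> list[str]:
        return ["placebo"] + [d.name for d in self.drugs]


@dataclass
class StudyDataset:
    """Lazy study container: the plan row-set plus per-record generation."""

    design: SyntheticDesign
    plan: pd.DataFrame
    pk: pd.DataFrame
    truth: dict
    _morphs: dict = field(default_factory=dict, repr=False)

    def ecg(self, row: pd.Series) -> AnnotatedEcg:
        d = self.design
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([d.seed, int(row["record"])]))
        morph = self._morphs[row["subject"]]
        spec = next((s for s in d.drugs if s.name == row["treatment"]), None)
        ecg, _ = simulate_ecg(
            morph, rr_s=float(row["RR_s"]), duration_s=d.duration_s,
            conc=float(row["conc"]), cref=spec.cref if spec else 1000.0,
            g=spec.g() if spec else None, noise_mv=d.noise_mv,
            jitter_sd_ms=d.jitter_sd_ms, rng=sub_rng,
            meta=StudyKey(row["subject"], row["treatment"],
                          float(row["timepoint"]), int(row["replicate"])))
        return ecg

    def write(self, out_dir: str | Path, format: str = "wfdb",
              max_records: int | None = None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        writers = {"wfdb": write_wfdb, "aecg": write_aecg, "csv": write_csv}
        suffix = {"wfdb": "", "aecg": ".xml", "csv": ".csv"}[format]
        writer = writers[format]
        rows = self.plan if max_records is None else self.plan.head(max_records)
        for _, row in rows.iterrows():
            name = (f"{row['subject']}_{row['treatment']}"
                    f"_t{row['timepoint']:g}_r{row['replicate']}")
            writer(self.ecg(row), out / (name + suffix))
        self.pk.to_csv(out / "pk.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)
        self.plan.to_csv(out / "plan.csv", index=False)
        return out


def simulate_study(design: SyntheticDesign) -> StudyDataset:
    """Build the record plan, PK curves and ground truth for one study.

    Signals are generated lazily per plan row (see
    :meth:`StudyDataset.ecg` / :meth:`StudyDataset.write`), so large default
    designs stay cheap until records are actually materialized.
    """
    d = design
    rng = np.random.default_rng(np.random.SeedSequence([d.seed, 0xC0FFEE]))
    morphs = {}
    cmax: dict[tuple[str, str], float] = {}
    subjects = [f"S{i:03d}" for i in range(d.n_subjects)]
    for s in subjects:
        morphs[s] = BeatMorphology.sample(rng)
        for spec in d.drugs:
            cmax[(s, spec.name)] = spec.cmax_gm * np.exp(
                rng.normal(0.0, spec.cmax_log_sd))
    arms = ({s: d.treatments()[i % len(d.treatments())]
             for i, s in enumerate(subjects)} if d.design == "C" else {})
    plan_rows, pk_rows = [], []
    rec = 0
    for s in subjects:
        trts = [arms[s]] if d.design == "C" else d.treatments()
        for trt in trts:
            spec = next((x for x in d.drugs if x.name == trt), None)
            for t in d.timepoints:
                conc = (cmax[(s, trt)] * pk_shape(t)
                        if spec is not None and t > 0 else 0.0)
                if spec is not None:
                    pk_rows.append({"subject": s, "treatment": trt,
                                    "timepoint": t, "drug": trt,
                                    "conc_ng_ml": conc})
                for rep in range(d.n_replicates):
                    rr = float(np.exp(rng.normal(0.0, d.rr_log_sd)))
                    plan_rows.append({"record": rec, "subject": s,
                                      "treatment": trt, "timepoint": t,
                                      "replicate": rep, "RR_s": rr,
                                      "conc": conc})
                    rec += 1
    plan = pd.DataFrame(plan_rows)
    pk = pd.DataFrame(pk_rows)
    truth = {
        "design": d.design,
        "seed": d.seed,
        "drugs": [asdict(spec) for spec in d.drugs],
        "alpha_true": list(alpha_true(PF)),
        "geometric_mean_cmax": {
            spec.name: float(np.exp(np.mean([np.log(cmax[(s, spec.name)])
                                             for s in subjects])))
            for spec in d.drugs},
        "subject_cmax": {f"{s}:{n}": v for (s, n), v in cmax.items()},
    }
    ds = StudyDataset(design=d, plan=plan, pk=pk, truth=truth)
    ds._morphs = morphs
    return ds
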