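"""Annotated 12-lead ECG records: formats, baseline correction, filtering.

Records carry the eight independent leads (I, II, V1–V6) in millivolts at a
common sampling frequency (resampled to 500 Hz on load when necessary),
together with per-beat P-onset / Q-onset / J-point / T-end annotations as
0-based sample indices.

Three on-disk representations are supported:

* a minimal WFDB dialect (``.hea`` header + format-16 ``.dat`` + a plain-text
  ``.beats.csv`` annotation sidecar with sample indices),
* a pragmatic subset of HL7 annotated-ECG XML (``.xml``; annotations in ms),
* a long-format CSV dialect (``sample,lead,amplitude_mV`` plus a
  ``.ann.csv`` sidecar with annotation times in ms).
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, make_interp_spline

LEADS8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: minimum trajectory span (samples) beyond J+20 ms for a beat to be usable
_MIN_TRAJ_SAMPLES = 2

TARGET_FS = 500.0


class EcgIoError(Exception):
    """Fatal problem reading or validating an ECG record."""


class MissingLeadError(EcgIoError):
    pass


class InsufficientBeatsError(EcgIoError):
    pass


@dataclass(frozen=True)
class StudyKey:
    """Identifies one 10-s ECG within a study (subject/treatment/time/replicate)."""

    subject: str = ""
    treatment: str = ""
    timepoint: float = 0.0
    replicate: int = 0
    period: str = ""


@dataclass
class BeatAnnotation:
    """Per-beat fiducials as 0-based sample indices."""

    p_on: int
    q_on: int
    j_point: int
    t_end: int
    is_usable: bool = True

    def ordered(self) -> bool:
        return self.p_on < self.q_on < self.j_point < self.t_end


@dataclass
class AnnotatedEcg:
    signal: np.ndarray  # (n_samples, 8) mV, lead order LEADS8
    fs: float
    beats: list[BeatAnnotation] = field(default_factory=list)
    lead_names: tuple[str, ...] = LEADS8
    meta: StudyKey = field(default_factory=StudyKey)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise EcgIoError("signal must be 2-D (n_samples, n_leads)")
        if self.fs <= 0:
            raise EcgIoError("sampling frequency must be positive")
        missing = [ld for ld in LEADS8 if ld not in self.lead_names]
        if missing:
            raise MissingLeadError(f"missing required lead(s): {', '.join(missing)}")
        if tuple(self.lead_names) != LEADS8:
            order = [self.lead_names.index(ld) for ld in LEADS8]
            self.signal = self.signal[:, order]
            self.lead_names = LEADS8
        if self.signal.shape[1] != 8:
            raise EcgIoError("expected 8 independent leads after reordering")
        self._validate_beats()

    def _validate_beats(self) -> None:
        n = self.n_samples
        min_span = int(round(0.020 * self.fs)) + _MIN_TRAJ_SAMPLES
        for b in self.beats:
            inside = 0 <= b.p_on and b.t_end < n
            if not (inside and b.ordered() and b.t_end - b.j_point >= min_span):
                b.is_usable = False
        self.beats.sort(key=lambda b: b.q_on)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def usable_beats(self) -> list[BeatAnnotation]:
        return [b for b in self.beats if b.is_usable]

    def lead(self, name: str) -> np.ndarray:
        """One lead by name; III and the augmented leads are derived on demand."""
        if name in LEADS8:
            return self.signal[:, LEADS8.index(name)]
        i, ii = self.signal[:, 0], self.signal[:, 1]
        if name == "III":
            return ii - i
        if name == "aVR":
            return -(i + ii) / 2.0
        if name == "aVL":
            return i - ii / 2.0
        if name == "aVF":
            return ii - i / 2.0
        raise MissingLeadError(f"unknown lead {name!r}")


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------


def load_annotated_ecg(path: str | Path, format: str | None = None,
                       meta: StudyKey | None = None) -> AnnotatedEcg:
    """Load an annotated ECG from ``path`` and normalize it to 500 Hz.

    ``format`` is one of ``"wfdb"``, ``"aecg"``, ``"csv"``; when omitted it is
    inferred from the file suffix (``.hea``/``.dat`` → wfdb, ``.xml`` → aecg,
    ``.csv`` → csv).
    """
    path = Path(path)
    if format is None:
        format = {".hea": "wfdb", ".dat": "wfdb", ".xml": "aecg", ".csv": "csv"}.get(
            path.suffix.lower())
        if format is None:
            raise EcgIoError(f"cannot infer format of {path}")
    if format == "wfdb":
        ecg = _read_wfdb(path)
    elif format == "aecg":
        ecg = _read_aecg(path)
    elif format == "csv":
        ecg = _read_csv(path)
    else:
        raise EcgIoError(f"unknown format {format!r}")
    if meta is not None:
        ecg.meta = meta
    if abs(ecg.fs - TARGET_FS) > 1e-9:
        ecg = resample_to(ecg, TARGET_FS)
    return ecg


def resample_to(ecg: AnnotatedEcg, fs_new: float) -> AnnotatedEcg:
    """Polyphase resampling with annotation indices rescaled accordingly."""
    ratio = Fraction(fs_new / ecg.fs).limit_denominator(10000)
    sig = sps.resample_poly(ecg.signal, ratio.numerator, ratio.denominator, axis=0)
    scale = fs_new / ecg.fs
    beats = [BeatAnnotation(*(int(round(v * scale)) for v in
                              (b.p_on, b.q_on, b.j_point, b.t_end)), b.is_usable)
             for b in ecg.beats]
    return AnnotatedEcg(sig, fs_new, beats, meta=ecg.meta)


# -- WFDB (minimal dialect: single format-16 .dat, text beat sidecar) --------


def write_wfdb(ecg: AnnotatedEcg, record: str | Path, adc_gain: float = 1000.0) -> Path:
    record = Path(record)
    record.parent.mkdir(parents=True, exist_ok=True)
    name = record.name
    adc = np.round(ecg.signal * adc_gain)
    if np.max(np.abs(adc)) > 32767:
        raise EcgIoError("signal exceeds 16-bit range at this gain")
    adc = adc.astype("<i2")
    with open(record.with_suffix(".hea"), "w") as fh:
        fh.write(f"{name} {len(LEADS8)} {ecg.fs:g} {ecg.n_samples}\n")
        for ld in LEADS8:
            fh.write(f"{name}.dat 16 {adc_gain:g}(0)/mV 16 0 0 0 0 {ld}\n")
    adc.tofile(record.with_suffix(".dat"))
    with open(record.parent / f"{name}.beats.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["beat", "p_on", "q_on", "j_point", "t_end", "is_usable"])
        for i, b in enumerate(ecg.beats):
            w.writerow([i, b.p_on, b.q_on, b.j_point, b.t_end, int(b.is_usable)])
    return record.with_suffix(".hea")


def _read_wfdb(path: Path) -> AnnotatedEcg:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise EcgIoError(f"no such record: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_name, n_sig, fs, n_samp = lines[0].split()[:4]
    n_sig, fs, n_samp = int(n_sig), float(fs), int(n_samp)
    leads, gains = [], []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        fmt = parts[1]
        if fmt != "16":
            raise EcgIoError(f"unsupported WFDB sample format {fmt}")
        gain_spec = parts[2]
        gains.append(float(gain_spec.split("(")[0].split("/")[0]))
        leads.append(parts[-1])
    for ld in LEADS8:
        if ld not in leads:
            raise MissingLeadError(f"missing required lead(s): {ld}")
    dat = hea.with_suffix(".dat")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_samp * n_sig:
        raise EcgIoError(f"{dat}: expected {n_samp * n_sig} samples, got {raw.size}")
    sig = raw.reshape(n_samp, n_sig).astype(float) / np.asarray(gains)
    beats = _read_beat_sidecar(hea.parent / f"{hea.stem}.beats.csv", unit="samples",
                               fs=fs)
    return AnnotatedEcg(sig, fs, beats, lead_names=tuple(leads))


def _read_beat_sidecar(path: Path, unit: str, fs: float) -> list[BeatAnnotation]:
    if not path.exists():
        return []
    beats = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if (row.get("beat") or "").lstrip().startswith("#"):
                continue
            try:
                vals = [row["p_on"], row["q_on"], row["j_point"], row["t_end"]]
                if any(v in ("", None) for v in vals):
                    raise KeyError("empty annotation")
                nums = [float(v) for v in vals]
            except (KeyError, ValueError):
                beats.append(BeatAnnotation(0, 1, 2, 3, is_usable=False))
                continue
            if unit == "ms":
                idx = [int(round(v * fs / 1000.0)) for v in nums]
            else:
                idx = [int(round(v)) for v in nums]
            usable = row.get("is_usable", "1") not in ("0", "false", "False")
            beats.append(BeatAnnotation(*idx, is_usable=usable))
    return beats


# -- HL7 aECG subset ---------------------------------------------------------

_AECG_NS = "urn:hl7-org:v3"
_ANN_CODES = {"p_on": "PONSET", "q_on": "QONSET", "j_point": "JPOINT",
              "t_end": "TOFFSET"}


def write_aecg(ecg: AnnotatedEcg, path: str | Path) -> Path:
    """Write the aECG subset this package reads back (amplitudes scaled to µV)."""
    path = Path(path)
    root = ET.Element("AnnotatedECG", {
        "xmlns": _AECG_NS,
        "xmlns:xsi": "http://www.w3.org/2001/XMLSchema-instance"})
    series = ET.SubElement(ET.SubElement(root, "component"), "series")
    seqset = ET.SubElement(ET.SubElement(series, "component"), "sequenceSet")
    tseq = ET.SubElement(ET.SubElement(seqset, "component"), "sequence")
    ET.SubElement(tseq, "code", code="TIME_ABSOLUTE")
    tval = ET.SubElement(tseq, "value", {"xsi:type": "GLIST_TS"})
    ET.SubElement(tval, "head", value="0")
    ET.SubElement(tval, "increment", value=f"{1.0 / ecg.fs:.9g}", unit="s")
    scale_uv = 1.0  # digits are integers in µV
    for j, ld in enumerate(LEADS8):
        seq = ET.SubElement(ET.SubElement(seqset, "component"), "sequence")
        ET.SubElement(seq, "code", code=f"MDC_ECG_LEAD_{ld}")
        val = ET.SubElement(seq, "value", {"xsi:type": "SLIST_PQ"})
        ET.SubElement(val, "origin", value="0", unit="uV")
        ET.SubElement(val, "scale", value=f"{scale_uv:g}", unit="uV")
        digits = np.round(ecg.signal[:, j] * 1000.0).astype(int)
        ET.SubElement(val, "digits").text = " ".join(str(d) for d in digits)
    annset = ET.SubElement(ET.SubElement(series, "subjectOf"), "annotationSet")
    for i, b in enumerate(ecg.beats):
        for fieldname, code in _ANN_CODES.items():
            ms = getattr(b, fieldname) * 1000.0 / ecg.fs
            ann = ET.SubElement(ET.SubElement(annset, "component"), "annotation")
            ET.SubElement(ann, "code", code=code)
            ET.SubElement(ann, "value", value=f"{ms:.6g}", unit="ms")
            ET.SubElement(ann, "support", beat=str(i))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    return path


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_aecg(path: Path) -> AnnotatedEcg:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise EcgIoError(f"unparseable aECG file {path}: {exc}") from exc
    root = tree.getroot()
    fs = None
    lead_digits: dict[str, np.ndarray] = {}
    for seq in root.iter():
        if _strip_ns(seq.tag) != "sequence":
            continue
        code_el = next((c for c in seq if _strip_ns(c.tag) == "code"), None)
        val_el = next((c for c in seq if _strip_ns(c.tag) == "value"), None)
        if code_el is None or val_el is None:
            continue
        code = code_el.get("code", "")
        if code == "TIME_ABSOLUTE":
            inc = next((c for c in val_el if _strip_ns(c.tag) == "increment"), None)
            if inc is not None:
                fs = 1.0 / float(inc.get("value"))
        elif code.startswith("MDC_ECG_LEAD_"):
            lead = code.removeprefix("MDC_ECG_LEAD_")
            origin = scale = None
            digits = None
            for c in val_el:
                t = _strip_ns(c.tag)
                if t == "origin":
                    origin = float(c.get("value", 0.0)), c.get("unit", "uV")
                elif t == "scale":
                    scale = float(c.get("value", 1.0)), c.get("unit", "uV")
                elif t == "digits":
                    digits = np.array((c.text or "").split(), dtype=float)
            if digits is None:
                continue
            sc, unit = scale if scale else (1.0, "uV")
            org = origin[0] if origin else 0.0
            mv = (org + digits * sc) * (0.001 if unit in ("uV", "µV") else 1.0)
            lead_digits[lead] = mv
    if fs is None:
        raise EcgIoError(f"{path}: no TIME_ABSOLUTE sequence (sampling rate unknown)")
    missing = [ld for ld in LEADS8 if ld not in lead_digits]
    if missing:
        raise MissingLeadError(f"missing required lead(s): {', '.join(missing)}")
    sig = np.column_stack([lead_digits[ld] for ld in LEADS8])
    beats = _collect_aecg_annotations(root, fs)
    return AnnotatedEcg(sig, fs, beats)


def _collect_aecg_annotations(root, fs: float) -> list[BeatAnnotation]:
    per_beat: dict[int, dict[str, int]] = {}
    code_to_field = {v: k for k, v in _ANN_CODES.items()}
    for ann in root.iter():
        if _strip_ns(ann.tag) != "annotation":
            continue
        code = val = beat = None
        for c in ann:
            t = _strip_ns(c.tag)
            if t == "code":
                code = c.get("code")
            elif t == "value":
                val = float(c.get("value"))
            elif t == "support":
                beat = int(c.get("beat", 0))
        if code in code_to_field and val is not None:
            per_beat.setdefault(beat or 0, {})[code_to_field[code]] = int(
                round(val * fs / 1000.0))
    beats = []
    for i in sorted(per_beat):
        d = per_beat[i]
        if set(d) == set(_ANN_CODES):
            beats.append(BeatAnnotation(d["p_on"], d["q_on"], d["j_point"],
                                        d["t_end"]))
        else:
            beats.append(BeatAnnotation(0, 1, 2, 3, is_usable=False))
    return beats


# -- CSV dialect -------------------------------------------------------------


def write_csv(ecg: AnnotatedEcg, path: str | Path) -> Path:
    """Long-format ``sample,lead,amplitude_mV`` plus ``<stem>.ann.csv`` (ms)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "lead", "amplitude_mV"])
        for j, ld in enumerate(LEADS8):
            for i, v in enumerate(ecg.signal[:, j]):
                w.writerow([i, ld, f"{v:.9g}"])
    ann = path.with_suffix(".ann.csv")
    with open(ann, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["beat", "p_on", "q_on", "j_point", "t_end"])
        for i, b in enumerate(ecg.beats):
            w.writerow([i] + [f"{v * 1000.0 / ecg.fs:.6g}"
                              for v in (b.p_on, b.q_on, b.j_point, b.t_end)])
    # sampling rate travels in a one-line sidecar comment of the annotation file
    with open(ann, "a") as fh:
        fh.write(f"# fs={ecg.fs:g}\n")
    return path


def _read_csv(path: Path) -> AnnotatedEcg:
    cols: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cols.setdefault(row["lead"], {})[int(row["sample"])] = float(
                row["amplitude_mV"])
    missing = [ld for ld in LEADS8 if ld not in cols]
    if missing:
        raise MissingLeadError(f"missing required lead(s): {', '.join(missing)}")
    n = max(max(d) for d in cols.values()) + 1
    sig = np.zeros((n, 8))
    for j, ld in enumerate(LEADS8):
        for i, v in cols[ld].items():
            sig[i, j] = v
    ann_path = path.with_suffix(".ann.csv")
    fs = TARGET_FS
    if ann_path.exists():
        for ln in ann_path.read_text().splitlines():
            if ln.startswith("# fs="):
                fs = float(ln.split("=", 1)[1])
    beats = _read_beat_sidecar(ann_path, unit="ms", fs=fs)
    return AnnotatedEcg(sig, fs, beats)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def baseline_correct(ecg: AnnotatedEcg,
                     window_ms: tuple[float, float] = (40.0, 10.0)) -> AnnotatedEcg:
    """Subtract the isoelectric baseline estimated from per-beat PQ medians.

    One node per usable beat: the median amplitude over the PQ window
    ``[q_on - window_ms[0], q_on - window_ms[1]]``, interpolated through the
    record by a natural cubic spline (lower order below 4 beats) and held
    constant beyond the first/last node.
    """
    usable = ecg.usable_beats()
    if len(usable) < 2:
        raise InsufficientBeatsError("insufficient beats for baseline")
    fs = ecg.fs
    w0 = int(round(window_ms[0] * fs / 1000.0))
    w1 = int(round(window_ms[1] * fs / 1000.0))
    node_t, node_v = [], []
    for b in usable:
        lo, hi = max(0, b.q_on - w0), max(1, b.q_on - w1)
        if hi <= lo:
            lo, hi = max(0, b.q_on - 2), b.q_on
        node_t.append(0.5 * (lo + hi - 1))
        node_v.append(np.median(ecg.signal[lo:hi, :], axis=0))
    node_t = np.asarray(node_t)
    node_v = np.asarray(node_v)  # (n_beats, 8)
    t = np.clip(np.arange(ecg.n_samples, dtype=float), node_t[0], node_t[-1])
    if len(usable) >= 4:
        spline = CubicSpline(node_t, node_v, axis=0, bc_type="natural")
        base = spline(t)
    else:
        k = len(usable) - 1
        spline = make_interp_spline(node_t, node_v, k=k, axis=0)
        base = spline(t)
    out = replace(ecg, signal=ecg.signal - base,
                  beats=[replace(b) for b in ecg.beats])
    return out


def bessel_lowpass(ecg: AnnotatedEcg, cutoff_hz: float = 36.0,
                   order: int = 4) -> AnnotatedEcg:
    """Zero-phase low-pass: 4-pole Bessel applied forward then backward."""
    if cutoff_hz >= ecg.fs / 2.0:
        raise EcgIoError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {ecg.fs / 2.0} Hz")
    b, a = sps.bessel(order, cutoff_hz, btype="low", fs=ecg.fs, norm="mag")
    filtered = sps.filtfilt(b, a, ecg.signal, axis=0)
    return replace(ecg, signal=filtered, beats=[replace(bb) for bb in ecg.beats])


def preprocess(ecg: AnnotatedEcg, cutoff_hz: float = 36.0) -> AnnotatedEcg:
    """Baseline correction followed by bidirectional Bessel filtering."""
    return bessel_lowpass(baseline_correct(ecg), cutoff_hz=cutoff_hz)
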