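"""TEP component peak extraction, outlier screening and normality transforms.

The six classic M1-TEP components (N15, P30, N45, P60, N100, P180) are
measured as the signed extremum of the mean trace over a small sensor
ROI within a closed component time window.  The windows are defined so
that neighbouring components do not overlap; because individual subjects
may lack a component or show inverted polarity, the measure is the
windowed extremum (boundary samples eligible), not a local-peak search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ComponentDef, DatasetError, EvokedDataset, SubjectEvoked

__all__ = [
    "M1_COMPONENTS",
    "PeakMeasure",
    "extract_peak",
    "extract_peaks",
    "screen_outliers",
    "TransformChoice",
    "choose_transform",
]

#: Built-in component table: closed time windows (ms) and 4-channel ROIs
#: for M1 stimulation.  User-overridable wherever a component list is
#: accepted.
M1_COMPONENTS: tuple[ComponentDef, ...] = (
    ComponentDef("N15", "negative", (7.0, 24.9), ("C3", "CP3", "CP1", "CP5")),
    ComponentDef("P30", "positive", (25.0, 37.9), ("Cz", "FCz", "C1", "FC1")),
    ComponentDef("N45", "negative", (38.0, 54.9), ("F4", "FC4", "FC2", "F2")),
    ComponentDef("P60", "positive", (55.0, 74.9), ("C3", "CP3", "CP1", "CP5")),
    ComponentDef("N100", "negative", (90.0, 129.9), ("FCz", "C1", "FC1", "FC3")),
    ComponentDef("P180", "positive", (170.0, 219.9), ("F2", "FCz", "FC2", "C2")),
)


@dataclass(frozen=True)
class PeakMeasure:
    subject_id: str
    waveform: str
    direction: str
    component: str
    amplitude: float  # uV, signed
    latency: float  # ms
    roi_waveform: np.ndarray  # the averaged ROI trace inside the TOI


def extract_peak(
    ev: SubjectEvoked, comp: ComponentDef, montage=None
) -> PeakMeasure:
    """Measure one component on one record.

    The ROI trace is the unweighted mean of the ROI channels; the
    amplitude is the minimum (negative components) or maximum (positive
    components) of that trace within the closed TOI, and the latency is
    the time of that extremum.  Equal extrema break to the earliest
    timepoint.  A TOI outside the epoch is an error.
    """
    from .core_io import standard_montage_1010

    if montage is None:
        raise DatasetError("extract_peak needs the montage for ROI lookup")
    idx = montage.index(comp.roi)
    t = ev.times
    lo, hi = comp.toi
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise DatasetError(
            f"component {comp.name}: TOI {comp.toi} outside epoch "
            f"[{t[0]:.1f}, {t[-1]:.1f}]"
        )
    trace = ev.data[idx].mean(axis=0)
    if np.isnan(trace[mask]).all():
        raise DatasetError(f"component {comp.name}: all-NaN ROI trace")
    seg = trace[mask]
    seg_t = t[mask]
    pick = int(np.argmin(seg) if comp.polarity == "negative" else np.argmax(seg))
    return PeakMeasure(
        subject_id=ev.subject_id,
        waveform=ev.waveform,
        direction=ev.direction,
        component=comp.name,
        amplitude=float(seg[pick]),
        latency=float(seg_t[pick]),
        roi_waveform=seg,
    )


def extract_peaks(
    dataset: EvokedDataset,
    components: tuple[ComponentDef, ...] = M1_COMPONENTS,
) -> pd.DataFrame:
    """Long peak table over all records and components."""
    rows = []
    for rec in dataset.records:
        for comp in components:
            m = extract_peak(rec, comp, montage=dataset.montage)
            rows.append(
                {
                    "subject": m.subject_id,
                    "waveform": m.waveform,
                    "direction": m.direction,
                    "component": m.component,
                    "amplitude": m.amplitude,
                    "latency": m.latency,
                }
            )
    return pd.DataFrame(rows)


def screen_outliers(peaks: pd.DataFrame, z: float = 2.5) -> pd.DataFrame:
    """Flag subjects beyond ``z`` group SDs, per component across conditions.

    A subject is flagged for a component when, in any single condition,
    their amplitude or latency deviates from that condition's group mean
    by strictly more than ``z`` SDs (single pass on the full group's
    statistics; a value exactly at the threshold is kept).  The returned
    table adds an ``excluded`` flag applied to every condition of the
    offending component, mirroring component-wise exclusion.
    """
    out = peaks.copy()
    if out.groupby(["waveform", "direction", "component"]).size().min() < 3:
        raise DatasetError("outlier screening needs at least 3 subjects per cell")
    flagged: set[tuple[str, str]] = set()
    for (w, d, comp), grp in out.groupby(["waveform", "direction", "component"]):
        for measure in ("amplitude", "latency"):
            vals = grp[measure].to_numpy(dtype=float)
            sd = vals.std(ddof=1)
            if sd == 0:
                continue
            zs = np.abs(vals - vals.mean()) / sd
            for subj in grp.loc[zs > z, "subject"]:
                flagged.add((subj, comp))
    out["excluded"] = [
        (s, c) in flagged for s, c in zip(out["subject"], out["component"])
    ]
    return out


@dataclass(frozen=True)
class TransformChoice:
    """Outcome of the normality-transform search for one variable."""

    variable: str
    transform: str  # none | sqrt | log10 | inverse
    shift: float  # added before sqrt/log/inverse to ensure valid domain
    w_by_transform: dict[str, float]
    p_by_transform: dict[str, float]
    no_transform_normalizes: bool

    @property
    def w(self) -> float:
        return self.w_by_transform[self.transform]

    @property
    def p(self) -> float:
        return self.p_by_transform[self.transform]


def _shifted(values: np.ndarray, need: str) -> tuple[np.ndarray, float]:
    """Shift to the domain a transform needs; shift amount is recorded."""
    lo = values.min()
    if need == "nonneg":
        shift = -lo if lo < 0 else 0.0
    else:  # strictly positive
        span = values.max() - lo
        shift = (-lo + (span / 100.0 if span > 0 else 1.0)) if lo <= 0 else 0.0
    return values + shift, shift


def choose_transform(
    values, variable: str = "value", alpha: float = 0.05
) -> TransformChoice:
    """Pick the transform that brings a sample closest to normality.

    Candidates are the identity, square root, base-10 logarithm and
    inverse, each shifted into its valid domain when needed.  Normality
    is scored by the Shapiro-Wilk W; the candidate with the highest W is
    selected.  When no candidate reaches p > alpha the result carries
    ``no_transform_normalizes=True``, signalling the robust-statistics
    path downstream.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise DatasetError("transform selection needs n >= 8")
    if np.ptp(x) == 0:
        raise DatasetError("constant sample: no transform applicable")

    ws: dict[str, float] = {}
    ps: dict[str, float] = {}
    shifts: dict[str, float] = {}
    for name in ("none", "sqrt", "log10", "inverse"):
        if name == "none":
            y, shift = x, 0.0
        elif name == "sqrt":
            y, shift = _shifted(x, "nonneg")
            y = np.sqrt(y)
        elif name == "log10":
            y, shift = _shifted(x, "pos")
            y = np.log10(y)
        else:
            y, shift = _shifted(x, "pos")
            y = 1.0 / y
        if np.ptp(y) == 0:
            continue
        w, p = sps.shapiro(y)
        ws[name] = float(w)
        ps[name] = float(p)
        shifts[name] = shift
    chosen = max(ws, key=ws.get)
    return TransformChoice(
        variable=variable,
        transform=chosen,
        shift=shifts[chosen],
        w_by_transform=ws,
        p_by_transform=ps,
        no_transform_normalizes=all(p <= alpha for p in ps.values()),
    )
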