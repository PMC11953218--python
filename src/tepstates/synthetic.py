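"""Synthetic TEP generator with known microstate ground truth.

Each simulated record is a sum of scalp topographies gated in time:

    data[:, t] = g(t - jitter_s) * a_s * sqrt(n_ch) * u_{class(t), s}  + noise

where ``g`` is a non-negative GFP envelope (Gaussian bumps at the classic
M1-TEP component latencies), ``a_s`` a per-subject amplitude scale,
``u_k`` a zero-mean unit-norm template map and ``class(t)`` follows a
per-condition segment plan (an ordered tiling of the analysis window).
The ``sqrt(n_ch)`` factor makes the noise-free GFP equal ``g(t) * a_s``
exactly, so the envelope is specified directly in microvolts of GFP.

Between-subject variation mimics real group data: lognormal amplitude
scales, Gaussian latency jitter applied to the whole response, and a
per-subject spatial perturbation mixing a small amount of a random map
into every template.  Sensor noise is iid Gaussian per channel/timepoint.

The generator's defaults are the study conditions used throughout the
test-suite: 27 subjects, six templates, epochs from -200 to 400 ms, and
component bumps near 15/30/45/60/100/180 ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    CONDITIONS,
    DatasetError,
    EvokedDataset,
    Montage,
    SubjectEvoked,
    standard_montage_1010,
)

__all__ = [
    "Segment",
    "GroundTruth",
    "GfpEnvelope",
    "default_envelope",
    "default_segment_plan",
    "swapped_segment_plan",
    "make_template_maps",
    "simulate_dataset",
    "make_deviant_subject",
    "make_fixture_dataset",
    "FIXTURE_NAMES",
]


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One microstate occupancy: class ``cls`` active on [onset, onset+duration)."""

    cls: int  # 1-based class index
    onset_ms: float
    duration_ms: float

    @property
    def end_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    templates: np.ndarray  # (K, n_channels), zero-mean unit-norm rows
    plans: dict[tuple[str, str], tuple[Segment, ...]]
    noise_sd: float
    seed: int
    amp_sigma: float = 0.2
    jitter_sd_ms: float = 3.0
    #: latency variability between condition blocks within a subject
    #: (conditions are acquired in separate TMS blocks), expressed as a
    #: lognormal time-dilation factor: later events are proportionally
    #: more variable, matching how evoked-latency variability scales
    latency_scale_sd: float = 0.05
    spatial_noise: float = 0.1
    #: filled by :func:`simulate_dataset`
    subject_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2 or self.templates.shape[0] < 1:
            raise DatasetError("templates must be a (K, n_channels) matrix")
        k = self.templates.shape[0]
        for cond, plan in self.plans.items():
            plan = tuple(plan)
            self.plans[cond] = plan
            prev_end = -np.inf
            for seg in plan:
                if not 1 <= seg.cls <= k:
                    raise DatasetError(f"{cond}: segment class {seg.cls} out of range")
                if not seg.duration_ms > 0:
                    raise DatasetError(f"{cond}: non-positive segment duration")
                if seg.onset_ms < prev_end - 1e-9:
                    raise DatasetError(f"{cond}: overlapping segments")
                prev_end = seg.end_ms

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]

    def true_onsets(self) -> dict[tuple[str, str], dict[int, float]]:
        """First appearance of each class per condition, in ms."""
        out: dict[tuple[str, str], dict[int, float]] = {}
        for cond, plan in self.plans.items():
            first: dict[int, float] = {}
            for seg in plan:
                first.setdefault(seg.cls, seg.onset_ms)
            out[cond] = first
        return out

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "templates": self.templates.tolist(),
            "plans": {
                f"{w}/{d}": [asdict(s) for s in plan]
                for (w, d), plan in self.plans.items()
            },
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "amp_sigma": self.amp_sigma,
            "jitter_sd_ms": self.jitter_sd_ms,
            "latency_scale_sd": self.latency_scale_sd,
            "spatial_noise": self.spatial_noise,
            "subject_effects": self.subject_effects,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        plans = {}
        for key, segs in payload["plans"].items():
            w, d = key.split("/")
            plans[(w, d)] = tuple(Segment(**s) for s in segs)
        gt = cls(
            templates=np.array(payload["templates"]),
            plans=plans,
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
            amp_sigma=payload["amp_sigma"],
            jitter_sd_ms=payload["jitter_sd_ms"],
            latency_scale_sd=payload.get("latency_scale_sd", 0.0),
            spatial_noise=payload["spatial_noise"],
        )
        gt.subject_effects = payload["subject_effects"]
        return gt


@dataclass(frozen=True)
class GfpEnvelope:
    """Sum of Gaussian bumps; value is the target GFP in microvolts."""

    components: tuple[tuple[float, float, float], ...]  # (center, width, peak)

    def __post_init__(self) -> None:
        for c, w, p in self.components:
            if not w > 0:
                raise DatasetError("envelope widths must be positive")
            if p < 0:
                raise DatasetError("envelope peaks must be non-negative")

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        for center, width, peak in self.components:
            out += peak * np.exp(-0.5 * ((t - center) / width) ** 2)
        return out

    def scaled(self, factor: float) -> "GfpEnvelope":
        return GfpEnvelope(
            tuple((c, w, p * factor) for c, w, p in self.components)
        )


def default_envelope() -> GfpEnvelope:
    """Bumps at the six classic M1-TEP component latencies.

    Peak GFP values (2-4 uV) and widths grow with latency the way real
    TEP components do (early components are sharp, late ones broad).
    """
    return GfpEnvelope(
        (
            (15.0, 5.0, 2.5),
            (30.0, 6.0, 3.5),
            (45.0, 7.0, 3.0),
            (60.0, 9.0, 3.0),
            (100.0, 18.0, 4.0),
            (180.0, 35.0, 3.0),
        )
    )


def default_segment_plan() -> tuple[Segment, ...]:
    """Six classes tiling [5, 400) ms around the component latencies."""
    bounds = (5.0, 22.5, 37.5, 52.5, 80.0, 140.0, 400.0)
    return tuple(
        Segment(cls=k + 1, onset_ms=bounds[k], duration_ms=bounds[k + 1] - bounds[k])
        for k in range(6)
    )


def swapped_segment_plan(delta_ms: float = 60.0) -> tuple[Segment, ...]:
    """Plan with classes 1 and 2 order-swapped relative to the unswapped plan.

    Classes 1 and 2 occupy two consecutive ``delta_ms``-long slots
    starting at 20 ms, in reversed order; classes 3-6 tile the rest of
    the epoch.  The first 15 ms of the analysis window carry no
    topographic signal (the physiological response has not built up
    yet), so no class has its onset pinned to the window edge -- a
    deliberate property: onset statistics stay on strictly positive,
    boundary-free support.
    """
    start = 20.0
    segs = [
        Segment(cls=2, onset_ms=start, duration_ms=delta_ms),
        Segment(cls=1, onset_ms=start + delta_ms, duration_ms=delta_ms),
    ]
    bounds = (start + 2 * delta_ms, 200.0, 260.0, 320.0, 400.0)
    for k in range(4):
        segs.append(
            Segment(cls=k + 3, onset_ms=bounds[k], duration_ms=bounds[k + 1] - bounds[k])
        )
    return tuple(segs)


def unswapped_segment_plan(delta_ms: float = 60.0) -> tuple[Segment, ...]:
    """Counterpart of :func:`swapped_segment_plan` with classes 1, 2 in order."""
    segs = list(swapped_segment_plan(delta_ms))
    segs[0] = Segment(cls=1, onset_ms=segs[0].onset_ms, duration_ms=segs[0].duration_ms)
    segs[1] = Segment(cls=2, onset_ms=segs[1].onset_ms, duration_ms=segs[1].duration_ms)
    return tuple(segs)


# ---------------------------------------------------------------------------
# Template maps
# ---------------------------------------------------------------------------


def _smooth_random_map(rng: np.random.Generator, positions: np.ndarray,
                       length_scale: float) -> np.ndarray:
    """Spatially low-passed Gaussian field over the electrode positions."""
    z = rng.standard_normal(len(positions))
    d2 = np.sum(
        (positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1
    )
    kern = np.exp(-0.5 * d2 / length_scale**2)
    m = kern @ z
    m = m - m.mean()
    nrm = np.linalg.norm(m)
    if nrm == 0:  # pragma: no cover - probability zero
        raise DatasetError("degenerate random map")
    return m / nrm


def make_template_maps(
    montage: Montage,
    k: int,
    seed: int,
    min_separation: float = 0.5,
    length_scale: float = 0.6,
    max_tries: int = 500,
) -> np.ndarray:
    """Draw ``k`` smooth, mutually distinct unit-norm template maps.

    Pairwise absolute spatial correlation is at most ``1 - min_separation``;
    maps are rejection-sampled until the constraint holds.  Deterministic
    in ``seed``.
    """
    if k > montage.n_channels:
        raise DatasetError("more templates than channels")
    if not 0 <= min_separation < 1:
        raise DatasetError("min_separation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < k:
        if tries >= max_tries:
            raise DatasetError(
                f"could not draw {k} maps with separation {min_separation} "
                f"after {max_tries} tries"
            )
        tries += 1
        cand = _smooth_random_map(rng, montage.positions, length_scale)
        # zero-mean unit-norm rows: correlation reduces to the dot product
        if all(abs(cand @ m) <= 1 - min_separation for m in maps):
            maps.append(cand)
    return np.array(maps)


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------


def _perturb_templates(
    templates: np.ndarray, level: float, rng: np.random.Generator,
    positions: np.ndarray, length_scale: float = 0.6,
) -> np.ndarray:
    """Mix ``level`` of an independent smooth random map into each template."""
    if level == 0:
        return templates
    out = []
    for u in templates:
        v = _smooth_random_map(rng, positions, length_scale)
        m = (1 - level) * u + level * v
        m = m - m.mean()
        out.append(m / np.linalg.norm(m))
    return np.array(out)


def simulate_dataset(
    truth: GroundTruth,
    envelope: GfpEnvelope,
    n_subjects: int,
    montage: Montage,
    srate: float = 960.0,
    epoch_ms: tuple[float, float] = (-200.0, 400.0),
) -> tuple[EvokedDataset, GroundTruth]:
    """Simulate a full 2 x 3 dataset; returns data plus the realised truth.

    The returned ``GroundTruth`` is ``truth`` with ``subject_effects``
    filled in (amplitude scale, latency jitter, spatial-noise level per
    subject).  Bit-reproducible from ``truth.seed``.
    """
    if n_subjects < 1:
        raise DatasetError("need at least one subject")
    rng = np.random.default_rng(truth.seed)
    n_ch = montage.n_channels
    n_t = int(round((epoch_ms[1] - epoch_ms[0]) * srate / 1000.0))
    times = epoch_ms[0] + np.arange(n_t) * (1000.0 / srate)
    root = np.sqrt(n_ch)

    records = []
    truth.subject_effects = {}
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        amp = float(np.exp(rng.normal(0.0, truth.amp_sigma))) if truth.amp_sigma else 1.0
        jit = float(rng.normal(0.0, truth.jitter_sd_ms)) if truth.jitter_sd_ms else 0.0
        subj_templates = _perturb_templates(
            truth.templates, truth.spatial_noise, rng, montage.positions
        )
        truth.subject_effects[sid] = {
            "amp_scale": amp,
            "latency_jitter_ms": jit,
            "spatial_noise": truth.spatial_noise,
        }
        for cond in CONDITIONS:
            plan = truth.plans[cond]
            data = np.zeros((n_ch, n_t))
            # each segment boundary gets its own multiplicative latency
            # perturbation (independent across segments and records):
            # later transitions are proportionally more variable, and the
            # perturbations of different classes stay independent
            if truth.latency_scale_sd and plan:
                v = np.exp(rng.normal(0.0, truth.latency_scale_sd,
                                      size=len(plan) + 1))
            else:
                v = np.ones(len(plan) + 1)
            onsets = [seg.onset_ms * v[i] for i, seg in enumerate(plan)]
            ends = []
            for i, seg in enumerate(plan):
                contiguous = (
                    i + 1 < len(plan)
                    and abs(seg.end_ms - plan[i + 1].onset_ms) < 1e-9
                )
                ends.append(onsets[i + 1] if contiguous else seg.end_ms * v[i + 1])
            g = envelope(times - jit) * amp * root
            for seg, on, end in zip(plan, onsets, ends):
                mask = (times >= on + jit) & (times < end + jit)
                data[:, mask] = np.outer(subj_templates[seg.cls - 1], g[mask])
            if truth.noise_sd > 0:
                data = data + rng.normal(0.0, truth.noise_sd, size=data.shape)
            records.append(
                SubjectEvoked(
                    subject_id=sid,
                    waveform=cond[0],
                    direction=cond[1],
                    data=data,
                    srate=float(srate),
                    t0_offset=float(epoch_ms[0]),
                )
            )
    return EvokedDataset(montage, records), truth


def simulate_from_config(path: str | Path) -> tuple[EvokedDataset, GroundTruth]:
    """Run the generator from a declarative YAML config.

    Expected keys: ``seed``, ``n_subjects``, ``n_classes``, optional
    ``srate``, ``noise_sd``, ``amp_sigma``, ``jitter_sd_ms``,
    ``latency_scale_sd``, ``spatial_noise``, ``min_separation``,
    ``envelope`` (list of ``[center_ms, width_ms, peak_uv]``), and
    ``plans`` mapping ``"waveform/direction"`` to lists of
    ``[class, onset_ms, duration_ms]``; a single ``plan`` entry applies
    to every condition.
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    montage = standard_montage_1010()
    seed = int(cfg["seed"])
    k = int(cfg["n_classes"])
    templates = make_template_maps(
        montage, k, seed=seed,
        min_separation=float(cfg.get("min_separation", 0.5)),
    )
    envelope = (
        GfpEnvelope(tuple(tuple(map(float, c)) for c in cfg["envelope"]))
        if "envelope" in cfg else default_envelope()
    )

    def parse_plan(items):
        return tuple(Segment(int(c), float(o), float(d)) for c, o, d in items)

    if "plans" in cfg:
        plans = {}
        for key, items in cfg["plans"].items():
            w, d = key.split("/")
            plans[(w, d)] = parse_plan(items)
    else:
        plan = parse_plan(cfg.get("plan", [[s.cls, s.onset_ms, s.duration_ms]
                                           for s in default_segment_plan()]))
        plans = {cond: plan for cond in CONDITIONS}

    truth = GroundTruth(
        templates=templates,
        plans=plans,
        noise_sd=float(cfg.get("noise_sd", _CLEAN6_NOISE_SD)),
        seed=seed,
        amp_sigma=float(cfg.get("amp_sigma", 0.2)),
        jitter_sd_ms=float(cfg.get("jitter_sd_ms", 3.0)),
        latency_scale_sd=float(cfg.get("latency_scale_sd", 0.05)),
        spatial_noise=float(cfg.get("spatial_noise", 0.1)),
    )
    return simulate_dataset(truth, envelope, int(cfg["n_subjects"]), montage,
                            srate=float(cfg.get("srate", 960.0)))


DEVIANT_MODES = ("scramble_channels", "flip_polarity", "pure_noise")


def make_deviant_subject(
    dataset: EvokedDataset, subject_id: str, mode: str, seed: int
) -> EvokedDataset:
    """Replace one subject's records with a pathological variant.

    ``scramble_channels`` permutes channels (destroys topography, keeps
    amplitude), ``flip_polarity`` negates the data, ``pure_noise``
    replaces the records with Gaussian noise of matched overall RMS.
    """
    if mode not in DEVIANT_MODES:
        raise DatasetError(f"unknown deviant mode {mode!r}")
    if subject_id not in dataset.subjects:
        raise DatasetError(f"unknown subject {subject_id!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.montage.n_channels)

    def tweak(rec: SubjectEvoked) -> SubjectEvoked:
        if rec.subject_id != subject_id:
            return rec
        if mode == "scramble_channels":
            data = rec.data[perm]
        elif mode == "flip_polarity":
            data = -rec.data
        else:
            rms = float(np.sqrt(np.mean(rec.data**2)))
            data = rng.normal(0.0, rms if rms > 0 else 1.0, size=rec.data.shape)
        from dataclasses import replace

        return replace(rec, data=data)

    return dataset.map_records(tweak)


# ---------------------------------------------------------------------------
# Fixture catalog
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("clean6", "swapAB", "swapAB_null", "deviant1", "nullflat")

#: sensor noise giving GFP signal-to-noise near 5 at the default envelope
#: (mean in-segment envelope GFP is ~2.4 uV; iid sensor noise of sd sigma
#: contributes GFP ~ sigma).
_CLEAN6_NOISE_SD = 0.5


def make_fixture_dataset(
    name: str,
    seed: int,
    n_subjects: int = 27,
    srate: float = 960.0,
    noise_sd: float | None = None,
    jitter_sd_ms: float | None = None,
    spatial_noise: float | None = None,
    amp_sigma: float | None = None,
    latency_scale_sd: float | None = None,
) -> tuple[EvokedDataset, GroundTruth]:
    """Build one of the bundled validation scenarios.

    * ``clean6`` -- 27 subjects, six templates tiling [5, 400) ms, the
      default component envelope, sensor SNR ~ 5.
    * ``swapAB`` -- same, but classes 1 and 2 swap their order between
      the monophasic and biphasic conditions (onset difference 60 ms),
      latency jitter 10 ms.
    * ``swapAB_null`` -- the swapAB timing without the swap (identical
      plans in every condition); for type-I-error calibration.
    * ``deviant1`` -- clean6 with subject S01's channels scrambled.
    * ``nullflat`` -- pure sensor noise, no topographic structure.
    """
    if name not in FIXTURE_NAMES:
        raise DatasetError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    montage = standard_montage_1010()
    envelope = default_envelope()

    if name in ("swapAB", "swapAB_null"):
        # topographic signal throughout the covered epoch so every
        # segment boundary is well supported
        envelope = GfpEnvelope(envelope.components + ((0.0, 1e6, 1.5),))

    if name == "nullflat":
        truth = GroundTruth(
            templates=np.zeros((2, montage.n_channels)),
            plans={cond: () for cond in CONDITIONS},
            noise_sd=1.0 if noise_sd is None else noise_sd,
            seed=seed,
            amp_sigma=0.0,
            jitter_sd_ms=0.0,
            latency_scale_sd=0.0,
            spatial_noise=0.0,
        )
        # zero templates never enter the data: empty plans
        ds, truth = simulate_dataset(truth, envelope, n_subjects, montage, srate)
        return ds, truth

    templates = make_template_maps(montage, 6, seed=seed, min_separation=0.5)
    if name == "clean6" or name == "deviant1":
        plans = {cond: default_segment_plan() for cond in CONDITIONS}
        jit = 3.0
    elif name == "swapAB":
        plans = {
            cond: (
                unswapped_segment_plan() if cond[0] == "monophasic"
                else swapped_segment_plan()
            )
            for cond in CONDITIONS
        }
        jit = 3.0
    else:  # swapAB_null
        plans = {cond: unswapped_segment_plan() for cond in CONDITIONS}
        jit = 3.0

    truth = GroundTruth(
        templates=templates,
        plans=plans,
        noise_sd=_CLEAN6_NOISE_SD if noise_sd is None else noise_sd,
        seed=seed,
        jitter_sd_ms=jit if jitter_sd_ms is None else jitter_sd_ms,
        latency_scale_sd=(
            (0.10 if name in ("swapAB", "swapAB_null") else 0.05)
            if latency_scale_sd is None else latency_scale_sd
        ),
        spatial_noise=0.1 if spatial_noise is None else spatial_noise,
        amp_sigma=0.2 if amp_sigma is None else amp_sigma,
    )
    ds, truth = simulate_dataset(truth, envelope, n_subjects, montage, srate)
    if name == "deviant1":
        ds = make_deviant_subject(ds, "S01", "scramble_channels", seed=seed + 1)
    return ds, truth
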