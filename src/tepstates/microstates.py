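"""Topographic microstate analysis of evoked potentials.

Pipeline order, matching how the analysis is run in practice:

1. :func:`compute_gfp` / :func:`normalize_by_gfp` -- global field power
   and per-subject GFP normalisation, so clustering sees spatial pattern
   rather than amplitude.
2. :func:`tct` -- randomization test for topographic consistency across
   subjects (channel-shuffled surrogates as the null).
3. :func:`mahalanobis_outliers` -- multivariate subject screening on the
   concatenated condition-average topographies.
4. :func:`cross_validate_k` -- split-half cross-validation over the
   number of microstate classes.
5. :func:`segment` -- modified (polarity-sensitive) k-means clustering of
   the concatenated condition grand-averages; the restart with the
   highest global explained variance (GEV) is retained.
6. :func:`backfit` / :func:`features` -- label individual records with
   the group templates and reduce the labels to AUC, duration and onset
   per class.

All spatial correlations are Pearson correlations across channels; maps
are average-referenced, so after unit-normalisation the correlation is a
plain dot product.  GEV weights squared correlations by squared GFP:

    GEV = sum_t GFP(t)^2 r_t^2 / sum_t GFP(t)^2 .
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    CONDITIONS,
    DatasetError,
    EvokedDataset,
    SubjectEvoked,
    crop,
)

__all__ = [
    "compute_gfp",
    "normalize_by_gfp",
    "normalize_dataset",
    "TctResult",
    "tct",
    "CvCurve",
    "cross_validate_k",
    "TemplateSet",
    "LabelSequence",
    "kmeans_microstates",
    "segment",
    "backfit",
    "features",
    "match_templates",
    "mahalanobis_outliers",
]


# ---------------------------------------------------------------------------
# GFP and normalisation
# ---------------------------------------------------------------------------


def compute_gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: spatial SD of the map at each timepoint.

    ``data`` is channels x timepoints (or a single map); the GFP is
    ``sqrt(mean_ch((v - mean_ch v)^2))`` per column, a reference-free
    measure of momentary response strength.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise DatasetError("GFP needs at least 2 channels")
    return data.std(axis=0, ddof=0)


def normalize_by_gfp(
    ev: SubjectEvoked, window: tuple[float, float] | None = None
) -> SubjectEvoked:
    """Divide a record by its mean GFP over the analysis window.

    After normalisation the mean GFP over the window is exactly 1, which
    removes between-subject amplitude differences while preserving the
    relative GFP time-course within the subject.
    """
    from dataclasses import replace

    target = ev if window is None else crop(ev, window)
    mean_gfp = float(compute_gfp(target.data).mean())
    if mean_gfp <= 0:
        raise DatasetError(
            f"record {ev.subject_id}/{ev.waveform}/{ev.direction}: zero mean GFP"
        )
    return replace(ev, data=ev.data / mean_gfp)


def normalize_dataset(
    dataset: EvokedDataset, window: tuple[float, float] | None = None
) -> EvokedDataset:
    """GFP-normalise every record (window defaults to the analysis window)."""
    win = dataset.analysis_window if window is None else window
    return dataset.map_records(lambda rec: normalize_by_gfp(rec, win))


def _unit_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference and L2-normalise maps (rows); returns (unit, norms).

    Zero maps get a zero row and zero norm; callers treat their
    correlation with anything as 0.
    """
    maps = np.asarray(maps, dtype=float)
    centred = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    # constant-up-to-rounding maps have no topography: a residual of
    # pure float error must not be amplified into a fake unit map
    degenerate = norms <= 1e-12 * np.linalg.norm(maps, axis=1)
    norms = np.where(degenerate, 0.0, norms)
    centred[degenerate] = 0.0
    safe = np.where(norms > 0, norms, 1.0)
    return centred / safe[:, None], norms


# ---------------------------------------------------------------------------
# Topographic consistency test
# ---------------------------------------------------------------------------


@dataclass
class TctResult:
    """Per-timepoint topographic-consistency randomization test."""

    times: np.ndarray
    observed: np.ndarray  # GFP of the across-subject mean map
    p: np.ndarray  # add-one permutation p-values
    null_mean: np.ndarray
    null_q95: np.ndarray
    n_permutations: int
    seed: int
    low_permutation_warning: bool = False

    @property
    def significant_fraction(self) -> float:
        return float(np.mean(self.p < 0.05))


def _tct_one(
    stack: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """TCT for one condition. ``stack`` is subjects x channels x times."""
    n_sub, n_ch, n_t = stack.shape
    observed = compute_gfp(stack.mean(axis=0))
    exceed = np.zeros(n_t)
    null_sum = np.zeros(n_t)
    null_all = np.empty((n_perm, n_t)) if n_perm <= 20000 else None
    for i in range(n_perm):
        acc = np.zeros((n_ch, n_t))
        for s in range(n_sub):
            acc += stack[s, rng.permutation(n_ch), :]
        null = compute_gfp(acc / n_sub)
        exceed += null >= observed
        null_sum += null
        if null_all is not None:
            null_all[i] = null
    p = (1.0 + exceed) / (1.0 + n_perm)
    q95 = (
        np.quantile(null_all, 0.95, axis=0)
        if null_all is not None
        else np.full(n_t, np.nan)
    )
    return observed, p, null_sum / n_perm, q95


def tct(
    dataset: EvokedDataset,
    window: tuple[float, float] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict[tuple[str, str], TctResult]:
    """Test for topographic consistency, run separately per condition.

    The observed statistic at each timepoint is the GFP of the
    across-subject mean map; the null redistributes each subject's
    channel values by an independent random permutation of the channel
    order (destroying shared topography, preserving per-subject GFP),
    re-averages and recomputes the GFP.  p-values use the add-one rule
    ``(1 + #{null >= obs}) / (1 + n_perm)``.
    """
    if len(dataset.subjects) < 2:
        raise DatasetError("TCT needs at least 2 subjects")
    win = dataset.analysis_window if window is None else window
    ds = dataset.map_records(lambda r: crop(r, win))
    times = ds.times
    out: dict[tuple[str, str], TctResult] = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(CONDITIONS))
    for cond, ss in zip(CONDITIONS, child_seeds):
        rng = np.random.default_rng(ss)
        stack = ds.stack(*cond)
        observed, p, null_mean, q95 = _tct_one(stack, n_perm, rng)
        out[cond] = TctResult(
            times=times,
            observed=observed,
            p=p,
            null_mean=null_mean,
            null_q95=q95,
            n_permutations=n_perm,
            seed=seed,
            low_permutation_warning=n_perm < 100,
        )
    return out


# ---------------------------------------------------------------------------
# Modified k-means segmentation
# ---------------------------------------------------------------------------


@dataclass
class TemplateSet:
    """K microstate template maps plus fit provenance."""

    maps: np.ndarray  # (K, n_channels), zero-mean unit-norm rows
    gev: float
    seed: int | None = None
    restarts: int = 0
    n_iter: int = 0  # iterations of the winning restart
    restart_gevs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        unit, norms = _unit_maps(self.maps)
        if np.any(norms == 0):
            raise DatasetError("template maps must be non-degenerate")
        if not np.allclose(np.linalg.norm(unit, axis=1), 1.0, atol=1e-12):
            raise DatasetError("template normalisation failed")
        self.maps = unit

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class LabelSequence:
    """Per-timepoint class assignment with the aligned GFP series."""

    labels: np.ndarray  # int, 1..K
    gfp: np.ndarray
    times: np.ndarray
    srate: float
    corr: np.ndarray | None = None  # correlation with the assigned template
    low_confidence_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.gfp) or len(self.labels) != len(self.times):
            raise DatasetError("labels/gfp/times length mismatch")


def _assign(unit_data: np.ndarray, templates: np.ndarray,
            polarity: str) -> tuple[np.ndarray, np.ndarray]:
    """Label unit maps by best spatial correlation with the templates.

    ``polarity='signed'`` keeps evoked-potential polarity (argmax of the
    signed correlation); ``'ignore'`` uses |r| as in resting-state work.
    Ties break to the lowest class index via argmax.
    """
    corr = unit_data @ templates.T  # (T, K)
    score = corr if polarity == "signed" else np.abs(corr)
    labels = score.argmax(axis=1)
    return labels, corr[np.arange(len(labels)), labels]


def _gev(weights: np.ndarray, corr: np.ndarray) -> float:
    tot = weights.sum()
    if tot == 0:
        return 0.0
    return float((weights * corr**2).sum() / tot)


def kmeans_microstates(
    maps: np.ndarray,
    k: int,
    restarts: int = 250,
    seed: int = 0,
    max_iter: int = 200,
    polarity: str = "signed",
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Modified k-means on a (timepoints x channels) matrix of maps.

    Per restart: seed templates from ``k`` distinct data timepoints,
    then alternate labelling (best spatial correlation) and template
    update until the labels stabilise.  An emptied class is reseeded
    from the worst-fit datapoint.  The restart with the highest GEV
    wins.

    The update rule follows the polarity mode.  ``signed`` (the evoked-
    potential convention) labels by signed correlation and refines each
    template as the normalised mean of the raw maps assigned to it.
    ``ignore`` labels by |r| and refines each template as the first
    principal component of the class's GFP^2-weighted map scatter -- the
    template that maximises the class's explained variance, making the
    alternation a monotone ascent on GEV.

    Seeding is k-means++-style in correlation distance: the first seed
    is a uniform draw from the data timepoints, later seeds are drawn
    with probability proportional to ``(1 - max |r|)^2`` against the
    seeds already chosen.  Evoked data spends most of its samples inside
    the longest-lived topography, so uniform seeding rarely covers every
    class; dissimilarity-weighted seeding fixes that while remaining a
    random draw from the data.

    Returns ``(templates, labels, gev, info)`` with 0-based labels.
    """
    maps = np.asarray(maps, dtype=float)
    n_t, n_ch = maps.shape
    if k < 1 or k > n_t:
        raise DatasetError(f"k={k} out of range for {n_t} timepoints")
    if k > n_ch:
        raise DatasetError(f"k={k} exceeds {n_ch} channels")
    unit, norms = _unit_maps(maps)
    weights = compute_gfp(maps.T) ** 2
    rng = np.random.default_rng(seed)
    nonzero = np.flatnonzero(norms > 0)
    if len(nonzero) < k:
        raise DatasetError("fewer non-degenerate maps than classes")

    gfp_w = weights[nonzero] / weights[nonzero].sum()

    def _seed_templates() -> np.ndarray:
        first = int(rng.choice(nonzero, p=gfp_w))
        chosen = [first]
        best_r = np.abs(unit[nonzero] @ unit[first])
        while len(chosen) < k:
            w = gfp_w * np.maximum(0.0, 1.0 - best_r) ** 2
            tot = w.sum()
            if tot <= 0:
                cand = int(rng.choice(nonzero))
            else:
                cand = int(nonzero[rng.choice(len(nonzero), p=w / tot)])
            chosen.append(cand)
            best_r = np.maximum(best_r, np.abs(unit[nonzero] @ unit[cand]))
        return unit[chosen].copy()

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    restart_gevs = np.empty(restarts)
    for r in range(restarts):
        templates = _seed_templates()
        labels = np.full(n_t, -1)
        n_it = 0
        eye = np.eye(k)
        for n_it in range(1, max_iter + 1):
            new_labels, corr = _assign(unit, templates, polarity)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            onehot = eye[labels]  # (T, k)
            counts = onehot.sum(axis=0)
            if polarity == "ignore":
                # optimal template for a fixed labelling: first principal
                # component of the GFP^2-weighted scatter of the class's
                # unit maps (mean updates cancel under sign indifference)
                new_t = templates.copy()
                nrm = np.ones(k)
                wu = unit * weights[:, None]
                for j in range(k):
                    sel = labels == j
                    if not sel.any():
                        continue
                    scatter = unit[sel].T @ wu[sel]
                    vals, vecs = np.linalg.eigh(scatter + scatter.T)
                    u = vecs[:, -1]
                    u = u - u.mean()
                    n = np.linalg.norm(u)
                    nrm[j] = n
                    if n > 0:
                        new_t[j] = u / n
            else:
                sums = onehot.T @ maps  # class-wise sums of raw maps
                new_t, nrm = _unit_maps(sums)
            for j in range(k):
                if counts[j] == 0:
                    # reseed an emptied class from the worst-fit datapoint
                    worst = nonzero[np.argmin(np.abs(corr)[nonzero])]
                    templates[j] = unit[worst]
                elif nrm[j] > 0:
                    templates[j] = new_t[j]
        _, corr = _assign(unit, templates, polarity)
        gev = _gev(weights, corr)
        restart_gevs[r] = gev
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), labels.copy(), n_it)

    assert best is not None
    gev, templates, labels, n_it = best
    info = {
        "seed": seed,
        "restarts": restarts,
        "n_iter": n_it,
        "restart_gevs": restart_gevs,
    }
    return templates, labels, gev, info


def _concat_grand_averages(
    dataset: EvokedDataset, window: tuple[float, float]
) -> tuple[np.ndarray, list[tuple[str, str]], int]:
    """Stack per-condition grand-average maps (times x channels)."""
    ds = dataset.map_records(lambda r: crop(r, window))
    blocks = [ds.grand_average(*cond).T for cond in CONDITIONS]
    return np.vstack(blocks), list(CONDITIONS), blocks[0].shape[0]


def segment(
    dataset: EvokedDataset,
    k: int = 6,
    restarts: int = 250,
    seed: int = 0,
    max_iter: int = 200,
    window: tuple[float, float] | None = None,
    polarity: str = "signed",
    normalize: bool = True,
) -> tuple[TemplateSet, dict[tuple[str, str], LabelSequence]]:
    """Group-level segmentation of the concatenated condition grand-averages.

    Subject records are GFP-normalised (unless ``normalize=False``),
    grand-averaged per condition over the analysis window, concatenated
    in canonical condition order, and clustered.  Returns the winning
    template set and the per-condition group label sequences.
    """
    win = dataset.analysis_window if window is None else window
    ds = normalize_dataset(dataset, win) if normalize else dataset
    maps, conds, n_t = _concat_grand_averages(ds, win)
    templates, labels0, gev, info = kmeans_microstates(
        maps, k, restarts=restarts, seed=seed, max_iter=max_iter, polarity=polarity
    )
    tset = TemplateSet(
        maps=templates,
        gev=gev,
        seed=seed,
        restarts=restarts,
        n_iter=info["n_iter"],
        restart_gevs=info["restart_gevs"],
    )
    times = crop(ds.records[0], win).times
    gfp_all = compute_gfp(maps.T)
    seqs: dict[tuple[str, str], LabelSequence] = {}
    for i, cond in enumerate(conds):
        sl = slice(i * n_t, (i + 1) * n_t)
        seqs[cond] = LabelSequence(
            labels=labels0[sl] + 1,
            gfp=gfp_all[sl],
            times=times,
            srate=ds.srate,
        )
    return tset, seqs


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, stop_exclusive, label)."""
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [len(labels)]))
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def min_duration_filter(
    labels0: np.ndarray, scores: np.ndarray, min_samples: int
) -> np.ndarray:
    """Reassign label runs shorter than ``min_samples`` to a neighbour class.

    Isolated one- or two-sample labels in a backfit are almost always
    driven by sensor noise rather than a genuine microstate visit; this
    post-hoc filter merges each too-short run into the adjacent run
    whose template fits the run's maps better (summed assignment score),
    shortest runs first, deterministically.  ``scores`` is the full
    (timepoints x classes) assignment-score matrix.
    """
    labels = labels0.copy()
    if min_samples <= 1:
        return labels
    while True:
        runs = _runs(labels)
        if len(runs) == 1:
            return labels
        short = [r for r in runs if r[1] - r[0] < min_samples]
        if not short:
            return labels
        short.sort(key=lambda r: (r[1] - r[0], r[0]))
        a, b, _ = short[0]
        i = runs.index(short[0])
        candidates = []
        if i > 0:
            candidates.append(runs[i - 1][2])
        if i < len(runs) - 1:
            candidates.append(runs[i + 1][2])
        gain = [scores[a:b, c].sum() for c in candidates]
        labels[a:b] = candidates[int(np.argmax(gain))]


def backfit(
    templates: TemplateSet | np.ndarray,
    ev: SubjectEvoked,
    window: tuple[float, float] | None = None,
    polarity: str = "signed",
    low_conf_r: float = 0.5,
    min_duration_ms: float = 0.0,
    unassign_low_r: bool = False,
) -> LabelSequence:
    """Label each timepoint of a record with its best-correlated template.

    Deterministic; ties resolve to the lowest class index.  The fraction
    of timepoints whose best |r| falls below ``low_conf_r`` is reported
    as a labelling-confidence diagnostic.  ``min_duration_ms`` > 0
    applies the post-hoc :func:`min_duration_filter` (off by default; no
    temporal constraint is part of the core labelling rule).  With
    ``unassign_low_r`` timepoints whose best correlation stays below
    ``low_conf_r`` after filtering are marked unassigned (label 0): maps
    dominated by sensor noise then contribute to no class's occupancy or
    onset.
    """
    maps = templates.maps if isinstance(templates, TemplateSet) else np.asarray(templates)
    if window is not None:
        ev = crop(ev, window)
    if maps.shape[1] != ev.n_channels:
        raise DatasetError("templates and record have different channel counts")
    unit, _ = _unit_maps(ev.data.T)
    labels0, corr = _assign(unit, maps, polarity)
    if min_duration_ms > 0:
        score = unit @ maps.T
        if polarity == "ignore":
            score = np.abs(score)
        min_samples = int(np.ceil(min_duration_ms * ev.srate / 1000.0))
        labels0 = min_duration_filter(labels0, score, min_samples)
        corr = (unit @ maps.T)[np.arange(len(labels0)), labels0]
    low = float(np.mean(np.abs(corr) < low_conf_r))
    labels1 = labels0 + 1
    if unassign_low_r:
        labels1 = np.where(np.abs(corr) < low_conf_r, 0, labels1)
    return LabelSequence(
        labels=labels1,
        gfp=compute_gfp(ev.data),
        times=ev.times,
        srate=ev.srate,
        corr=corr,
        low_confidence_fraction=low,
    )


def features(labels: LabelSequence, n_classes: int | None = None) -> pd.DataFrame:
    """Reduce a label sequence to per-class AUC, duration and onset.

    * duration_k = (# samples labelled k) * dt, in ms;
    * auc_k = sum of GFP over samples labelled k, times dt (ms * uV);
    * onset_k = time of the first sample labelled k (NaN if absent).

    Durations sum to the labelled span and AUCs to the total GFP area,
    exactly.
    """
    k = int(n_classes if n_classes is not None else labels.labels.max())
    dt = 1000.0 / labels.srate
    rows = []
    for cls in range(1, k + 1):
        sel = labels.labels == cls
        rows.append(
            {
                "class": cls,
                "duration_ms": float(sel.sum() * dt),
                "auc": float(labels.gfp[sel].sum() * dt),
                "onset_ms": float(labels.times[sel][0]) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def subject_features(
    dataset: EvokedDataset,
    templates: TemplateSet,
    window: tuple[float, float] | None = None,
    polarity: str = "signed",
    normalize: bool = True,
    min_duration_ms: float = 0.0,
    unassign_low_r: bool = False,
) -> pd.DataFrame:
    """Backfit group templates to every record; long feature table.

    Columns: subject, waveform, direction, class, duration_ms, auc,
    onset_ms, low_confidence_fraction.
    """
    win = dataset.analysis_window if window is None else window
    ds = normalize_dataset(dataset, win) if normalize else dataset
    frames = []
    for rec in ds.records:
        seq = backfit(templates, rec, window=win, polarity=polarity,
                      min_duration_ms=min_duration_ms,
                      unassign_low_r=unassign_low_r)
        f = features(seq, n_classes=templates.k)
        f.insert(0, "subject", rec.subject_id)
        f.insert(1, "waveform", rec.waveform)
        f.insert(2, "direction", rec.direction)
        f["low_confidence_fraction"] = seq.low_confidence_fraction
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def match_templates(
    estimated: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of template sets by |correlation|.

    Returns ``(permutation, correlations)`` such that ``estimated[perm[i]]``
    corresponds to ``truth[i]``; Hungarian assignment on -|r|.
    """
    from scipy.optimize import linear_sum_assignment

    est_u, _ = _unit_maps(estimated)
    tru_u, _ = _unit_maps(truth)
    r = tru_u @ est_u.T
    rows, cols = linear_sum_assignment(-np.abs(r))
    return cols, r[rows, cols]


# ---------------------------------------------------------------------------
# Cross-validation over the number of classes
# ---------------------------------------------------------------------------


@dataclass
class CvCurve:
    """Split-half cross-validation curve over candidate map counts."""

    ks: np.ndarray
    curve: np.ndarray  # mean test-set GEV per K
    per_iteration: np.ndarray  # (n_iter, n_K)
    selected_k: int
    n_iterations: int
    seed: int
    plateau_tol: float
    unreliable: bool  # no K explains even half the topographic variance


def cross_validate_k(
    dataset: EvokedDataset,
    k_range: tuple[int, int] = (3, 12),
    n_iter: int = 50,
    seed: int = 0,
    restarts: int = 6,
    max_iter: int = 25,
    window: tuple[float, float] | None = None,
    polarity: str = "signed",
    plateau_tol: float = 0.01,
) -> CvCurve:
    """Choose the number of microstate classes by split-half validation.

    Each iteration randomly splits the subjects into halves; templates
    are fit on the learning half's condition grand-averages for each K
    and scored by the GEV they attain when backfit to the test half's
    grand-averages.  The selected K is the smallest whose mean curve
    value reaches within ``plateau_tol`` of the curve maximum ("first K
    on the plateau").
    """
    subjects = dataset.subjects
    if len(subjects) < 4:
        raise DatasetError("cross-validation needs at least 4 subjects")
    win = dataset.analysis_window if window is None else window
    ds = normalize_dataset(dataset, win)
    k_min, k_max = k_range
    n_t_win = crop(ds.records[0], win).n_times
    if k_max >= min(ds.montage.n_channels, n_t_win):
        raise DatasetError("k_max must be below channel and timepoint counts")

    # pre-crop per subject x condition to avoid repeated work
    per_subj = {
        s: {cond: crop(ds.get(s, *cond), win).data for cond in CONDITIONS}
        for s in subjects
    }

    ks = np.arange(k_min, k_max + 1)
    scores = np.empty((n_iter, len(ks)))
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = rng.integers(0, 2**31 - 1, size=(n_iter, len(ks)))
    for it in range(n_iter):
        perm = rng.permutation(len(subjects))
        half = len(subjects) // 2
        learn = [subjects[i] for i in perm[:half]]
        test = [subjects[i] for i in perm[half:]]

        def ga(group: list[str]) -> np.ndarray:
            blocks = []
            for cond in CONDITIONS:
                blocks.append(
                    np.mean([per_subj[s][cond] for s in group], axis=0).T
                )
            return np.vstack(blocks)

        learn_maps = ga(learn)
        test_maps = ga(test)
        test_unit, _ = _unit_maps(test_maps)
        test_w = compute_gfp(test_maps.T) ** 2
        for j, k in enumerate(ks):
            templates, _, _, _ = kmeans_microstates(
                learn_maps,
                int(k),
                restarts=restarts,
                seed=int(fit_seeds[it, j]),
                max_iter=max_iter,
                polarity=polarity,
            )
            _, corr = _assign(test_unit, templates, polarity)
            scores[it, j] = _gev(test_w, corr)

    curve = scores.mean(axis=0)
    thresh = (1.0 - plateau_tol) * curve.max()
    selected_k = int(ks[np.argmax(curve >= thresh)])
    return CvCurve(
        ks=ks,
        curve=curve,
        per_iteration=scores,
        selected_k=selected_k,
        n_iterations=n_iter,
        seed=seed,
        plateau_tol=plateau_tol,
        unreliable=bool(curve.max() < 0.5),
    )


# ---------------------------------------------------------------------------
# Mahalanobis subject screening
# ---------------------------------------------------------------------------


def mahalanobis_outliers(
    dataset: EvokedDataset,
    window: tuple[float, float] | None = None,
    var_keep: float = 0.90,
    quantile: float = 0.99,
    normalize: bool = True,
) -> pd.DataFrame:
    """Screen subjects by Mahalanobis distance in topography space.

    Each subject is represented by the concatenation of their six
    condition-average maps over the window (GFP-normalised).  The
    subject's squared Mahalanobis distance is computed leave-one-out:
    against the mean and covariance of the *other* subjects, in the PCA
    subspace of those subjects retaining at least ``var_keep`` of the
    variance (at most ``n_subjects - 2`` dimensions).  Scoring each
    subject as a new observation keeps the distance unbounded (the
    all-in sample distance saturates at ``(n-1)^2/n`` with a few dozen
    subjects) and makes the exact threshold available: for a new
    observation from the same population the distance follows a scaled
    F distribution, so the ``quantile`` cut uses

        d^2 > ((m+1)/m) * p (m-1)/(m-p) * F_{quantile}(p, m-p),  m = n-1.

    Returns a DataFrame sorted by decreasing distance with columns
    ``subject, distance2, threshold, flag`` and attrs ``n_dims``
    (median retained dimension).
    """
    subjects = dataset.subjects
    n = len(subjects)
    if n < 5:
        raise DatasetError("Mahalanobis screening needs at least 5 subjects")
    win = dataset.analysis_window if window is None else window
    ds = normalize_dataset(dataset, win) if normalize else dataset
    vecs = []
    for s in subjects:
        parts = [crop(ds.get(s, *cond), win).data.ravel() for cond in CONDITIONS]
        vecs.append(np.concatenate(parts))
    x = np.array(vecs)

    # all leave-one-out quantities derive from the full Gram matrix
    g0 = x @ x.T
    m = n - 1
    d2 = np.empty(n)
    thresholds = np.empty(n)
    dims = np.empty(n, dtype=int)
    for i in range(n):
        j = np.delete(np.arange(n), i)
        sub = g0[np.ix_(j, j)]
        s_j = sub.sum(axis=1)
        s_tot = s_j.sum()
        # Gram of the others, centred on their own mean
        h = sub - s_j[:, None] / m - s_j[None, :] / m + s_tot / m**2
        # w_j = (x_j - mean) . (x_i - mean)
        t_j = g0[j, i]
        w = t_j - t_j.sum() / m - s_j / m + s_tot / m**2
        evals, evecs_ = np.linalg.eigh(h)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs_ = evecs_[:, order]
        total = evals.sum()
        if total <= 0:
            raise DatasetError("degenerate data: zero variance across subjects")
        cum = np.cumsum(evals) / total
        p_i = int(np.searchsorted(cum, var_keep) + 1)
        p_i = min(p_i, n - 2)
        lam = evals[:p_i] / (m - 1)  # PC variances of the others
        if np.any(lam <= 0):
            raise DatasetError(
                "singular covariance after reduction; lower var_keep to "
                "retain fewer dimensions"
            )
        proj = (evecs_[:, :p_i].T @ w) / np.sqrt(evals[:p_i])
        d2[i] = float(np.sum(proj**2 / lam))
        dims[i] = p_i
        thresholds[i] = float(
            ((m + 1) / m) * p_i * (m - 1) / (m - p_i)
            * sps.f.ppf(quantile, p_i, m - p_i)
        )
    out = pd.DataFrame(
        {
            "subject": subjects,
            "distance2": d2,
            "threshold": thresholds,
            "flag": d2 > thresholds,
        }
    ).sort_values("distance2", ascending=False, ignore_index=True)
    out.attrs["n_dims"] = int(np.median(dims))
    out.attrs["quantile"] = quantile
    return out
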