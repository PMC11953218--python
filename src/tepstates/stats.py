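"""Inferential layer for TEP peak measures and microstate features.

Implements the study's statistical toolkit for a 2 (pulse waveform) x 3
(current direction) within-subject design:

* two-factor repeated-measures ANOVA with Mauchly sphericity tests,
  Greenhouse-Geisser correction and partial eta-squared;
* Tukey-corrected pairwise post-hoc contrasts with paired Cohen's d;
* a robust one-way repeated-measures ANOVA on trimmed means (20 %
  trimming, Winsorized covariances), used when no normality transform
  works;
* ANCOVA of the direction effect controlling for TMS intensity;
* a gamma / identity-link model for microstate onsets with subject
  intercepts, Wald chi-square tests and Benjamini-Hochberg-corrected
  within-condition class contrasts (the declared 90-contrast family),
  including detection of class-pair order swaps across conditions.

The repeated-measures machinery is written directly from the
sums-of-squares definitions so each quantity (F, epsilon, eta_p^2) is
auditable; test code checks it against independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import CONDITIONS, DIRECTIONS, WAVEFORMS, DatasetError

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "rm_anova_2x3",
    "PosthocContrast",
    "tukey_posthoc",
    "RobustAnovaResult",
    "robust_trimmed_rm_anova",
    "ancova_direction",
    "OnsetModelResult",
    "onset_mixed_model",
    "bh_adjust",
    "pivot_conditions",
]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def pivot_conditions(
    df: pd.DataFrame, value: str, on_incomplete: str = "raise"
) -> tuple[np.ndarray, list[str]]:
    """Long (subject, waveform, direction, value) table -> (n, 2, 3) array.

    Subjects with a missing cell raise a :class:`DatasetError` naming
    them (``on_incomplete="raise"``, the default) or are dropped for a
    complete-case analysis (``on_incomplete="drop"``).  The returned
    subject list preserves first-appearance order.
    """
    wide = df.pivot_table(
        index="subject", columns=["waveform", "direction"], values=value,
        aggfunc="first", sort=False,
    )
    cols = [(w, d) for w in WAVEFORMS for d in DIRECTIONS]
    missing_cols = [c for c in cols if c not in wide.columns]
    if missing_cols:
        raise DatasetError(f"conditions absent from the table: {missing_cols}")
    wide = wide[cols]
    incomplete = list(wide.index[wide.isna().any(axis=1)])
    if incomplete and on_incomplete == "raise":
        raise DatasetError(f"incomplete design for subjects: {incomplete}")
    complete = wide.dropna()
    subjects = list(complete.index)
    y = complete.to_numpy(dtype=float).reshape(len(subjects), 2, 3)
    return y, subjects


def _box_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a levels x levels covariance matrix."""
    j = cov.shape[0]
    dbar = np.diag(cov).mean()
    mbar = cov.mean()
    rbar = cov.mean(axis=1)
    num = (j * (dbar - mbar)) ** 2
    den = (j - 1) * (
        np.sum(cov**2) - 2 * j * np.sum(rbar**2) + j**2 * mbar**2
    )
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def _mauchly(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on subject x levels scores.

    Returns (W, p).  Uses the orthonormal-contrast formulation with the
    standard chi-square approximation.
    """
    n, j = scores.shape
    p = j - 1
    # orthonormal contrast basis (Helmert, normalised)
    c = np.linalg.qr(np.eye(j) - 1.0 / j)[0][:, :p]
    s = c.T @ np.cov(scores, rowvar=False, ddof=1) @ c
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 1e-300, None)
    w = float(np.prod(eig) / (eig.mean() ** p))
    df = p * (p + 1) // 2 - 1
    f = n - 1
    chi2 = -(f - (2 * p**2 + p + 2) / (6.0 * p)) * np.log(w)
    pval = float(sps.chi2.sf(chi2, df))
    return w, pval


# ---------------------------------------------------------------------------
# Two-factor repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaEffect:
    name: str
    f: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    gg_df1: float | None = None
    gg_df2: float | None = None
    gg_p: float | None = None
    sphericity_violated: bool = False

    @property
    def p_reported(self) -> float:
        """Greenhouse-Geisser-corrected p where sphericity was rejected."""
        return self.gg_p if self.sphericity_violated else self.p


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eff in self.effects.values():
            rows.append(
                {
                    "effect": eff.name,
                    "F": eff.f,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "eta_p2": eff.eta_p2,
                    "mauchly_W": eff.mauchly_w,
                    "mauchly_p": eff.mauchly_p,
                    "gg_epsilon": eff.gg_epsilon,
                    "p_reported": eff.p_reported,
                }
            )
        return pd.DataFrame(rows)


def rm_anova_2x3(y: np.ndarray | pd.DataFrame, value: str | None = None,
                 sphericity_alpha: float = 0.05) -> AnovaResult:
    """Two-factor (2 x 3) within-subject ANOVA.

    ``y`` is an (n, 2, 3) array ordered (waveform, direction), or a long
    DataFrame (with ``value`` naming the response column).  Sphericity
    is assessed with Mauchly's test for the direction main effect and
    the interaction (the two-level waveform factor is spherical by
    construction); Greenhouse-Geisser correction is applied when Mauchly
    rejects at ``sphericity_alpha``.  eta_p^2 = SS_effect /
    (SS_effect + SS_error).
    """
    if isinstance(y, pd.DataFrame):
        y, _ = pivot_conditions(y, value or "value")
    y = np.asarray(y, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 3):
        raise DatasetError("expected an (n, 2, 3) array of complete cases")
    n = y.shape[0]
    if n < 5:
        raise DatasetError("rmANOVA needs at least 5 complete subjects")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))  # (n,)
    a_mean = y.mean(axis=(0, 2))  # (2,)
    b_mean = y.mean(axis=(0, 1))  # (3,)
    ab_mean = y.mean(axis=0)  # (2, 3)
    ia_mean = y.mean(axis=2)  # (n, 2) subject x waveform
    ib_mean = y.mean(axis=1)  # (n, 3) subject x direction

    ss_a = 3 * n * np.sum((a_mean - grand) ** 2)
    ss_b = 2 * n * np.sum((b_mean - grand) ** 2)
    ss_ab = n * np.sum(
        (ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2
    )
    ss_err_a = 3 * np.sum(
        (ia_mean - subj[:, None] - a_mean[None, :] + grand) ** 2
    )
    ss_err_b = 2 * np.sum(
        (ib_mean - subj[:, None] - b_mean[None, :] + grand) ** 2
    )
    resid = (
        y
        - ia_mean[:, :, None]
        - ib_mean[:, None, :]
        - ab_mean[None, :, :]
        + subj[:, None, None]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        - grand
    )
    ss_err_ab = np.sum(resid**2)

    specs = [
        ("waveform", ss_a, 1, ss_err_a, n - 1, None),
        ("direction", ss_b, 2, ss_err_b, 2 * (n - 1), ib_mean),
        ("interaction", ss_ab, 2, ss_err_ab, 2 * (n - 1),
         y[:, 0, :] - y[:, 1, :]),
    ]
    effects: dict[str, AnovaEffect] = {}
    for name, ss_eff, df1, ss_err, df2, scores in specs:
        f = (ss_eff / df1) / (ss_err / df2)
        p = float(sps.f.sf(f, df1, df2))
        eff = AnovaEffect(
            name=name,
            f=float(f),
            df1=float(df1),
            df2=float(df2),
            p=p,
            eta_p2=float(ss_eff / (ss_eff + ss_err)),
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )
        if scores is not None:
            w, wp = _mauchly(scores)
            eps = _box_epsilon(np.cov(scores, rowvar=False, ddof=1))
            eff.mauchly_w = w
            eff.mauchly_p = wp
            eff.gg_epsilon = eps
            eff.gg_df1 = df1 * eps
            eff.gg_df2 = df2 * eps
            eff.gg_p = float(sps.f.sf(f, df1 * eps, df2 * eps))
            eff.sphericity_violated = wp < sphericity_alpha
        effects[name] = eff
    return AnovaResult(effects=effects, n_subjects=n)


# ---------------------------------------------------------------------------
# Tukey post-hoc contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosthocContrast:
    cell_a: str
    cell_b: str
    t: float
    df: float
    p_raw: float
    p_tukey: float
    cohen_d: float


def tukey_posthoc(
    y: np.ndarray, cell_names: list[str] | None = None
) -> list[PosthocContrast]:
    """All pairwise paired contrasts with Tukey (studentized-range) correction.

    ``y`` is subjects x cells.  For each pair the paired t statistic is
    referred to the studentized-range distribution with ``k`` groups and
    ``n - 1`` degrees of freedom (``q = |t| * sqrt(2)``); Cohen's d for
    paired data is the mean difference over the SD of the differences.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    if cell_names is None:
        cell_names = [f"cell{j + 1}" for j in range(k)]
    df = n - 1
    out = []
    for i, j in combinations(range(k), 2):
        d = y[:, i] - y[:, j]
        sd = d.std(ddof=1)
        if sd == 0:
            t = 0.0
            p_raw = 1.0
            p_tuk = 1.0
            cd = 0.0
        else:
            t = float(d.mean() / (sd / np.sqrt(n)))
            p_raw = float(2 * sps.t.sf(abs(t), df))
            p_tuk = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            p_tuk = max(p_tuk, p_raw)  # numerical guard; q-test dominates t-test
            cd = float(d.mean() / sd)
        out.append(
            PosthocContrast(
                cell_a=cell_names[i],
                cell_b=cell_names[j],
                t=t,
                df=float(df),
                p_raw=p_raw,
                p_tukey=min(p_tuk, 1.0),
                cohen_d=cd,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Robust trimmed-means repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _winsorize_columns(y: np.ndarray, trim: float) -> np.ndarray:
    n = y.shape[0]
    g = int(np.floor(trim * n))
    if g == 0:
        return y.copy()
    srt = np.sort(y, axis=0)
    lo = srt[g]
    hi = srt[n - g - 1]
    return np.clip(y, lo, hi)


@dataclass
class RobustAnovaResult:
    f: float
    df1: float
    df2: float
    p: float
    trim: float
    trimmed_means: np.ndarray
    epsilon: float
    contrasts: pd.DataFrame  # pairwise psi estimates with p-values


def robust_trimmed_rm_anova(
    y: np.ndarray | pd.DataFrame,
    trim: float = 0.2,
    value: str | None = None,
    levels: list[str] | None = None,
) -> RobustAnovaResult:
    """One-way repeated-measures ANOVA on trimmed means.

    ``y`` is subjects x levels (e.g. the three current directions within
    one pulse waveform).  Group location is the ``trim``-trimmed mean;
    the error term is built from the Winsorized covariance matrix with
    Yuen scaling, and the degrees of freedom carry a Huynh-Feldt-type
    sphericity adjustment estimated from the Winsorized covariances.
    At ``trim = 0`` the statistic reduces exactly to the classical
    repeated-measures F.

    Pairwise linear contrasts psi (differences of trimmed means) are
    tested with Yuen-style paired standard errors on ``h - 1`` df.
    """
    if isinstance(y, pd.DataFrame):
        if levels is None or value is None:
            raise DatasetError("DataFrame input needs `value` and `levels`")
        y = y.pivot_table(index="subject", columns="level", values=value)[
            levels
        ].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, j = y.shape
    if not 0 <= trim <= 0.25:
        raise DatasetError("trim must be in [0, 0.25]")
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 2 or (trim > 0 and n - 2 * g < 8):
        # with trimming, fewer than 8 effective subjects makes the
        # Winsorized-variance df approximation meaningless
        if h < 2:
            raise DatasetError("trimming leaves fewer than 2 subjects")
    tmeans = sps.trim_mean(y, trim, axis=0) if trim > 0 else y.mean(axis=0)
    w = _winsorize_columns(y, trim)
    v = np.cov(w, rowvar=False, ddof=1)
    vbar_d = np.diag(v).mean()
    vbar = v.mean()
    if vbar_d - vbar <= 0:
        raise DatasetError("degenerate Winsorized covariance")

    # Yuen scaling: SE^2 of a trimmed mean is s_w^2 (n-1) / (h (h-1))
    scale = h * (h - 1) / (n - 1)
    f_stat = scale * np.sum((tmeans - tmeans.mean()) ** 2) / (j * (vbar_d - vbar))

    eps_hat = _box_epsilon(v)
    # Huynh-Feldt-type adjustment with the effective sample size
    num = h * (j - 1) * eps_hat - 2
    den = (j - 1) * (h - 1 - (j - 1) * eps_hat)
    eps = float(min(1.0, num / den)) if den > 0 else 1.0
    eps = max(eps, 1.0 / (j - 1))
    df1 = (j - 1) * eps
    df2 = (j - 1) * eps * (h - 1)
    p = float(sps.f.sf(f_stat, df1, df2))

    # pairwise psi contrasts with Yuen paired SEs
    names = levels if levels is not None else [f"L{i + 1}" for i in range(j)]
    dscale = (n - 1) / (h * (h - 1))
    rows = []
    for a, b in combinations(range(j), 2):
        psi = tmeans[a] - tmeans[b]
        se = np.sqrt(dscale * (v[a, a] + v[b, b] - 2 * v[a, b]))
        tval = psi / se if se > 0 else 0.0
        rows.append(
            {
                "contrast": f"{names[a]} - {names[b]}",
                "psi": float(psi),
                "se": float(se),
                "t": float(tval),
                "df": h - 1,
                "p": float(2 * sps.t.sf(abs(tval), h - 1)) if se > 0 else 1.0,
            }
        )
    return RobustAnovaResult(
        f=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        p=p,
        trim=trim,
        trimmed_means=tmeans,
        epsilon=eps,
        contrasts=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# ANCOVA: direction effect controlling for TMS intensity
# ---------------------------------------------------------------------------


def ancova_direction(df: pd.DataFrame, value: str = "value",
                     covariate: str = "intensity") -> pd.DataFrame:
    """Direction effect adjusted for a linear covariate (TMS intensity).

    Expects a long table with columns ``subject, direction`` plus the
    response and covariate (one row per subject x direction, i.e. within
    one pulse waveform).  Subject effects are partialled out with
    subject intercepts, so with an uninformative covariate the direction
    F approaches its repeated-measures value.  Returns a type-II ANOVA
    table with F, p and partial eta-squared per term.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if df[covariate].nunique() <= 1:
        raise DatasetError("covariate is constant; ANCOVA is undefined")
    model = smf.ols(
        f"{value} ~ C(subject) + {covariate} + C(direction)", data=df
    ).fit()
    tab = anova_lm(model, typ=2)
    ss_res = tab.loc["Residual", "sum_sq"]
    out = tab.rename(
        columns={"sum_sq": "SS", "df": "df", "F": "F", "PR(>F)": "p"}
    )
    out["eta_p2"] = out["SS"] / (out["SS"] + ss_res)
    out.loc["Residual", "eta_p2"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Gamma / identity onset model
# ---------------------------------------------------------------------------


@dataclass
class OnsetModelResult:
    fixed_effects: pd.DataFrame  # term, wald chi2, df, p
    contrasts: pd.DataFrame  # within-condition class-pair contrasts
    swaps: pd.DataFrame  # class pairs whose significant contrast flips sign
    family_size: int
    n_observations: int
    n_dropped: int
    converged: bool
    link: str  # "identity" or the "log" fallback


_COND_ORDER = [f"{w}/{d}" for w, d in CONDITIONS]


def onset_mixed_model(
    onsets: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> OnsetModelResult:
    """Gamma, identity-link model for microstate onsets with subject effects.

    ``onsets`` is a long table with columns ``subject, waveform,
    direction, class, onset_ms`` (missing onsets NaN).  Fixed effects
    are microstate class, stimulation condition (the six waveform x
    direction cells) and their interaction, with sum-coded subject
    intercepts absorbing between-subject level differences; inference is
    by Wald chi-square on the sum-coded term blocks (type-III style).

    Post-hoc contrasts compare every pair of classes within each
    condition (15 pairs x 6 conditions = the 90-contrast family) and are
    Benjamini-Hochberg corrected over that family.  The swap report
    lists class pairs whose significant contrast changes sign across
    conditions -- the signature of an onset-order swap.

    Rows with missing onsets are dropped listwise (gamma support is
    strictly positive); their count is reported.  If the identity-link
    fit fails or leaves invalid fitted values, the model is refit with a
    log link and flagged -- never silently.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = onsets.copy()
    d["condition"] = d["waveform"].astype(str) + "/" + d["direction"].astype(str)
    n_total = len(d)
    d = d.dropna(subset=["onset_ms"])
    d = d[d["onset_ms"] > 0]
    n_dropped = n_total - len(d)
    d["cls"] = d["class"].astype(str)

    classes = sorted(d["cls"].unique(), key=lambda s: (len(s), s))
    conds = [c for c in _COND_ORDER if c in set(d["condition"])]
    if len(conds) < 2:
        formula = "onset_ms ~ C(cls, Sum) + C(subject, Sum)"
    else:
        formula = "onset_ms ~ C(cls, Sum) * C(condition, Sum) + C(subject, Sum)"

    def _fit(link):
        import warnings

        with warnings.catch_warnings():
            # identity link is the study's deliberate choice for gamma onsets
            warnings.simplefilter("ignore")
            fam = sm.families.Gamma(link=link)
            model = smf.glm(formula, data=d, family=fam)
            start = None
            if isinstance(link, sm.families.links.Identity):
                # IRLS for identity-link gamma is touchy; start from OLS
                ols = smf.ols(formula, data=d).fit()
                start = ols.params.to_numpy()
            return model.fit(start_params=start, maxiter=200)

    link_used = "identity"
    try:
        res = _fit(sm.families.links.Identity())
        bad = (not np.all(np.isfinite(res.params))) or np.any(
            res.fittedvalues <= 0
        )
    except Exception:
        res, bad = None, True
    if bad:
        link_used = "log"
        res = _fit(sm.families.links.Log())

    converged = bool(getattr(res, "converged", True))

    # Wald chi-square per term block (sum coding -> type-III style tests);
    # p-values refer the statistic to F(df, df_resid), the finite-sample
    # correction without which the chi-square reference is liberal at
    # this ratio of parameters to observations
    wt = res.wald_test_terms(scalar=True)
    ft = wt.table.copy()
    dfr = float(res.df_resid)
    ft["pvalue"] = sps.f.sf(
        ft["statistic"] / ft["df_constraint"], ft["df_constraint"], dfr
    )
    rename = {}
    for idx in ft.index:
        if "cls" in idx and ":" in idx:
            rename[idx] = "class:condition"
        elif "cls" in idx:
            rename[idx] = "class"
        elif "condition" in idx:
            rename[idx] = "condition"
        elif "subject" in idx:
            rename[idx] = "subject"
    fixed = (
        ft.rename(index=rename)
        .loc[lambda t: t.index.isin(["class", "condition", "class:condition"])]
        .rename(columns={"statistic": "wald_chi2", "pvalue": "p",
                         "df_constraint": "df"})
    )
    fixed = fixed.reset_index().rename(columns={"index": "term"})

    # cell means at the average subject: sum-coded subject columns at 0
    design_info = res.model.data.design_info
    from patsy import dmatrix

    cells = pd.DataFrame(
        [(c, cond) for cond in conds for c in classes],
        columns=["cls", "condition"],
    )
    cells["subject"] = d["subject"].iloc[0]  # placeholder, zeroed below
    x_cells = np.asarray(dmatrix(design_info, cells))
    subj_cols = [
        i for i, name in enumerate(design_info.column_names) if "subject" in name
    ]
    x_cells[:, subj_cols] = 0.0

    cov = np.asarray(res.cov_params())
    beta = np.asarray(res.params)
    rows = []
    for ci, cond in enumerate(conds):
        for a_i, b_i in combinations(range(len(classes)), 2):
            ra = x_cells[ci * len(classes) + a_i]
            rb = x_cells[ci * len(classes) + b_i]
            lvec = ra - rb
            est = float(lvec @ beta)
            se = float(np.sqrt(lvec @ cov @ lvec))
            z = est / se if se > 0 else 0.0
            rows.append(
                {
                    "condition": cond,
                    "class_a": classes[a_i],
                    "class_b": classes[b_i],
                    "estimate": est,
                    "se": se,
                    "z": z,
                    # t reference with the model's residual df; clipped
                    # against float underflow of the tail
                    "p_raw": float(
                        max(2 * sps.t.sf(abs(z), res.df_resid), 1e-300)
                    ),
                }
            )
    contrasts = pd.DataFrame(rows)
    m = family_size if family_size is not None else max(90, len(contrasts))
    contrasts["p_bh"] = bh_adjust(contrasts["p_raw"].to_numpy(), family_size=m)
    contrasts["significant"] = contrasts["p_bh"] < alpha

    swap_rows = []
    for (a, b), grp in contrasts.groupby(["class_a", "class_b"]):
        sig = grp[grp["significant"]]
        if len(sig) >= 2 and sig["estimate"].min() < 0 < sig["estimate"].max():
            swap_rows.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "conditions_a_first": ", ".join(
                        sig.loc[sig["estimate"] < 0, "condition"]
                    ),
                    "conditions_b_first": ", ".join(
                        sig.loc[sig["estimate"] > 0, "condition"]
                    ),
                }
            )
    swaps = pd.DataFrame(
        swap_rows, columns=["class_a", "class_b", "conditions_a_first",
                            "conditions_b_first"]
    )
    return OnsetModelResult(
        fixed_effects=fixed,
        contrasts=contrasts,
        swaps=swaps,
        family_size=m,
        n_observations=len(d),
        n_dropped=n_dropped,
        converged=converged,
        link=link_used,
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    ``family_size`` may exceed the number of supplied p-values; the
    unsupplied members of the family are treated as p = 1 (they occupy
    the top ranks and never constrain the step-up minimum).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DatasetError("p-values must lie in (0, 1]")
    k = len(p)
    m = family_size if family_size is not None else k
    if m < k:
        raise DatasetError("family_size smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out
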