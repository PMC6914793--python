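"""Cohort-level statistics on per-patient BPE metric tables.

Covers the statistics battery applied to the per-patient quantitative and
visual measures: diagnostic accuracy of radiological complete response for
pathological complete response (pCR), inter-/intra-rater agreement (kappa),
Pearson correlation between visual and quantitative measures, Student t
group comparisons, and multivariate Cox proportional-hazards modelling of
recurrence-free survival (RFS: time from surgery to recurrence or last
follow-up; patients lost to follow-up are excluded).  No multiple-testing
correction is applied; the working significance level is 0.05.

The cohort table is a pandas DataFrame.  Expected columns (per patient):

    id, age, menopausal_status, tumor_subtype,
    bpe20_pre, bpe20_post, fgt_pct_pre, fgt_pct_post, delta_bpe20,
    visual_fgt_r1, visual_fgt_r2, visual_bpe_pre_r1, visual_bpe_pre_r2,
    visual_bpe_post_r1, visual_bpe_post_r2,
    radiological_complete_response, pcr, recurrence, rfs_months,
    lost_to_followup

Analyses use listwise deletion of rows with missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

__all__ = [
    "DiagnosticAccuracy",
    "KappaResult",
    "CoxResult",
    "diagnostic_accuracy",
    "cohen_kappa",
    "fleiss_kappa",
    "pearson_r",
    "two_sample_t",
    "fit_recurrence_model",
    "simulate_cohort",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class DiagnosticAccuracy:
    """Sensitivity/specificity of a binary test with 95% confidence intervals."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float  # percent
    specificity: float  # percent
    ci_sensitivity: tuple[float, float]  # percent, clipped to [0, 100]
    ci_specificity: tuple[float, float]


def _proportion_ci(k: int, n: int, method: str) -> tuple[float, float]:
    p = k / n
    if method == "wald":
        half = Z95 * np.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    elif method == "clopper-pearson":
        lo = sps.beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi = sps.beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return (max(0.0, 100.0 * lo), min(100.0, 100.0 * hi))


def diagnostic_accuracy(tp: int, fn: int, fp: int, tn: int, ci_method: str = "wald") -> DiagnosticAccuracy:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp), as percent.

    Confidence intervals are 95% Wald normal-approximation intervals
    ``p ± 1.96 sqrt(p(1-p)/n)`` clipped to [0, 100] (exact Clopper–Pearson via
    ``ci_method="clopper-pearson"``).  Rounding to integer percent is left to
    the display layer.
    """
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0:
        raise ValueError("no positive cases (tp + fn = 0); sensitivity undefined")
    if fp + tn == 0:
        raise ValueError("no negative cases (fp + tn = 0); specificity undefined")
    return DiagnosticAccuracy(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        ci_sensitivity=_proportion_ci(tp, tp + fn, ci_method),
        ci_specificity=_proportion_ci(tn, tn + fp, ci_method),
    )


@dataclass
class KappaResult:
    kappa: float
    p_value: float
    n: int
    method: str


def cohen_kappa(ratings_a, ratings_b) -> KappaResult:
    """Cohen's kappa between two raters' categorical ratings, with a z-test p-value.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with chance agreement ``p_e`` from the
    marginal products.  The p-value tests kappa = 0 with the large-sample
    null-variance formula.  Two constant, identical rating vectors give
    ``p_e = 1`` and kappa is undefined (raised as an error).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length rating vectors with n >= 2")
    n = len(a)
    cats = np.union1d(np.unique(a), np.unique(b))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    k = len(cats)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1)
    table /= n
    p_o = np.trace(table)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("both raters are constant (p_e = 1); kappa is undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    # large-sample variance of kappa under the null of chance agreement
    var0 = (p_e + p_e**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - p_e) ** 2)
    if var0 <= 0:
        p_value = float("nan")
    else:
        z = kappa / np.sqrt(var0)
        p_value = float(2 * sps.norm.sf(abs(z)))
    return KappaResult(kappa=float(kappa), p_value=p_value, n=n, method="cohen")


def fleiss_kappa(ratings: np.ndarray) -> KappaResult:
    """Fleiss' kappa for >= 2 raters (subjects x raters categorical matrix).

    Note: for exactly two raters Fleiss' form differs from Cohen's kappa (it
    uses pooled rather than per-rater marginals); both are exposed.
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix with >= 2 raters")
    counts, _ = aggregate_raters(ratings)
    kappa = float(_sm_fleiss_kappa(counts))
    return KappaResult(kappa=kappa, p_value=float("nan"), n=ratings.shape[0], method="fleiss")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with its t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), n=len(x))


def two_sample_t(x, y, equal_var: bool = True) -> TestResult:
    """Two-sided Student t test (pooled variance; Welch via ``equal_var=False``)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(statistic=float(t), p_value=float(p), n=len(x) + len(y))


@dataclass
class CoxResult:
    """Multivariate Cox proportional-hazards fit for recurrence-free survival.

    ``summary`` has one row per covariate with both scales (log-hazard ``coef``
    and ``hazard_ratio``), 95% CIs on each, and per-covariate Wald p-values;
    ``lrt_p_value`` is the model-level likelihood-ratio test p-value.
    """

    summary: pd.DataFrame
    n: int
    n_events: int
    lrt_p_value: float


def fit_recurrence_model(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "rfs_months",
    event_col: str = "recurrence",
) -> CoxResult:
    """Fit a multivariate Cox model of recurrence on the cohort table.

    Rows flagged ``lost_to_followup`` and rows with missing covariates are
    dropped (listwise deletion).  Zero events or a non-converging fit
    (e.g. complete separation) raise explicit errors.
    """
    df = cohort.copy()
    if "lost_to_followup" in df.columns:
        df = df[~df["lost_to_followup"].astype(bool)]
    cols = [duration_col, event_col] + list(covariates)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    df = df[cols].dropna()
    n_events = int(df[event_col].astype(bool).sum())
    if n_events == 0:
        raise ValueError("no recurrence events after exclusions; Cox model cannot be fit")
    if (df[duration_col] < 0).any():
        raise ValueError("negative follow-up times")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox fit failed to converge (possible complete separation): {exc}"
        ) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "coef_ci_lower": s["coef lower 95%"],
            "coef_ci_upper": s["coef upper 95%"],
            "hazard_ratio": s["exp(coef)"],
            "hr_ci_lower": s["exp(coef) lower 95%"],
            "hr_ci_upper": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )
    lrt = cph.log_likelihood_ratio_test()
    return CoxResult(summary=summary, n=len(df), n_events=n_events, lrt_p_value=float(lrt.p_value))


def simulate_cohort(
    n: int = 100,
    seed: int = 0,
    log_hr_bpe_post: float = 1.0,
    baseline_hazard: float = 0.0022,
    followup_months: float = 48.0,
    bpe_pre_mean: float = 8.0,
    bpe_pre_sd: float = 1.8,
    bpe_post_mean: float = 5.0,
    bpe_post_sd: float = 2.2,
    lost_rate: float = 0.01,
) -> pd.DataFrame:
    """Synthetic per-patient cohort table with a known BPE–hazard association.

    Post-treatment BPE20% is drawn per patient; recurrence times are
    exponential with hazard ``baseline * exp(log_hr_bpe_post * z(bpe20_post))``
    (the covariate standardised), censored administratively at
    ``followup_months``.  Default rates give roughly 15 events per 100
    patients.  Visual ratings are noisy ordinal views of the quantitative
    measures, and pCR / radiological response flags are correlated the way a
    neoadjuvant cohort's would be.  Purely a structural analogue generator —
    no real-cohort parameters are reproduced.
    """
    rng = np.random.default_rng(seed)
    bpe_pre = np.clip(rng.normal(bpe_pre_mean, bpe_pre_sd, n), 0.3, None)
    bpe_post = np.clip(rng.normal(bpe_post_mean, bpe_post_sd, n), 0.1, None)
    fgt_pre = np.clip(rng.normal(10, 9, n), 1, 60)
    fgt_post = np.clip(fgt_pre * rng.normal(1.0, 0.08, n), 1, 60)

    z = (bpe_post - bpe_post.mean()) / bpe_post.std()
    hazard = baseline_hazard * np.exp(log_hr_bpe_post * z)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.full(n, followup_months)
    rfs = np.minimum(event_time, censor_time)
    recurrence = event_time <= censor_time

    pcr = rng.random(n) < 0.26
    rcr = np.where(pcr, rng.random(n) < 0.93, rng.random(n) < 0.16)

    def ordinal(x, k):
        edges = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
        return np.digitize(x, edges) + 1

    def noisy(v, k):
        return np.clip(v + rng.integers(-1, 2, n) * (rng.random(n) < 0.3), 1, k).astype(int)

    vfgt = ordinal(fgt_pre, 4)
    vbpe_pre = ordinal(bpe_pre, 4)
    vbpe_post = ordinal(bpe_post, 4)

    return pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(n)],
            "age": rng.normal(50, 10, n).round(1),
            "menopausal_status": rng.random(n) < 0.46,
            "tumor_subtype": rng.choice(["luminal", "her2", "basal"], n, p=[0.45, 0.28, 0.27]),
            "bpe20_pre": bpe_pre,
            "bpe20_post": bpe_post,
            "fgt_pct_pre": fgt_pre,
            "fgt_pct_post": fgt_post,
            "delta_bpe20": 100.0 * (bpe_post - bpe_pre) / bpe_pre,
            "visual_fgt_r1": vfgt,
            "visual_fgt_r2": noisy(vfgt, 4),
            "visual_bpe_pre_r1": vbpe_pre,
            "visual_bpe_pre_r2": noisy(vbpe_pre, 4),
            "visual_bpe_post_r1": vbpe_post,
            "visual_bpe_post_r2": noisy(vbpe_post, 4),
            "radiological_complete_response": rcr,
            "pcr": pcr,
            "recurrence": recurrence,
            "rfs_months": rfs,
            "lost_to_followup": rng.random(n) < lost_rate,
        }
    )
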