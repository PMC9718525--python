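"""Statistical battery for trafficking comparisons.

Distribution comparisons use the two-sided Kolmogorov–Smirnov test and the
Wilcoxon signed-rank test for paired per-axon means.  Condition effects on
segment-level speeds (synapse vs shaft, active vs rest, stimulation epochs)
are tested with a hierarchical linear model: speed ~ condition with nested
random intercepts (mouse ⊃ dataset ⊃ track), fitted by maximum likelihood and
compared by likelihood-ratio test against the model without the fixed effect.

With few top-level clusters (typical experiments have 2–5 mice) the
asymptotic LRT is anti-conservative, so a within-track permutation oracle
(:func:`permutation_lrt_check`) is provided and reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "LmmResult",
    "ks_two_sample",
    "wilcoxon_paired",
    "hierarchical_lrt",
    "permutation_lrt_check",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Figure-legend star convention."""
    if not np.isfinite(p):
        return ""
    for thr, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return s
    return "ns"


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    alternative: str = "two-sided"

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def ks_two_sample(a, b) -> TestResult:
    """Two-sided Kolmogorov–Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult("ks_two_sample", float(res.statistic),
                      float(min(res.pvalue, 1.0)), len(a), len(b))


def wilcoxon_paired(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n ≥ 2")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, len(a), len(b))
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), len(a), len(b))


@dataclass
class LmmResult:
    """Hierarchical model comparison for one condition effect."""

    condition: str
    effect: float            # fixed-effect estimate (second level vs first), µm/s
    levels: tuple[str, ...]  # condition levels in model order
    lr_statistic: float
    df: int
    p_value: float
    converged: bool
    n_obs: int
    group_counts: dict[str, int]
    llf_full: float
    llf_null: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if np.isfinite(self.p_value) else ""


def _prepare(samples: pd.DataFrame, condition: str, response: str):
    df = samples.copy()
    for col in (response, condition, "track"):
        if col not in df.columns:
            raise ValueError(f"samples lack a {col!r} column")
    for col in ("mouse", "dataset"):
        if col not in df.columns:
            df[col] = "0"
    df = df.dropna(subset=[response, condition])
    if df[condition].nunique() < 2:
        raise ValueError(f"condition {condition!r} needs ≥2 levels")
    # globally unique nested codes
    df["_mouse"] = df["mouse"].astype(str)
    df["_dataset"] = df["_mouse"] + "/" + df["dataset"].astype(str)
    df["_track"] = df["_dataset"] + "/" + df["track"].astype(str)
    return df


def _fit_lmm(df: pd.DataFrame, formula: str):
    """ML fit with nested random intercepts; levels with a single group are
    dropped (with a warning) rather than fitted degenerately."""
    n_mouse = df["_mouse"].nunique()
    n_dataset = df["_dataset"].nunique()
    n_track = df["_track"].nunique()
    vcf = {}
    if n_mouse > 1:
        groups = df["_mouse"]
        if n_dataset > n_mouse:
            vcf["dataset"] = "0 + C(_dataset)"
        if n_track > n_dataset:
            vcf["track"] = "0 + C(_track)"
        re_formula = "1"
    else:
        warnings.warn("single mouse; mouse level dropped from random effects")
        if n_dataset > 1:
            groups = df["_dataset"]
            if n_track > n_dataset:
                vcf["track"] = "0 + C(_track)"
        else:
            groups = df["_track"]
        re_formula = "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(formula, data=df, groups=groups,
                                        re_formula=re_formula,
                                        vc_formula=vcf or None)
        fit = model.fit(reml=False, maxiter=1000, disp=False)
        # the gradient optimizer routinely stops short of the ML optimum
        # (even while reporting success), especially near variance-component
        # boundaries; a derivative-free Powell polish from the current
        # solution is cheap and reliable, so polish repeatedly until the
        # likelihood is stationary
        converged = False
        for _ in range(10):
            if not np.isfinite(fit.llf):
                break
            try:
                polish = model.fit(reml=False, method="powell", maxiter=2000,
                                   disp=False, start_params=fit.params_object)
            except (np.linalg.LinAlgError, ValueError):
                break
            if not np.isfinite(polish.llf):
                break
            if polish.llf <= fit.llf + 1e-6:
                converged = True
                if polish.llf >= fit.llf:
                    fit = polish
                break
            fit = polish
    fit._axotrack_converged = converged and bool(np.isfinite(fit.llf))
    return fit


def hierarchical_lrt(samples: pd.DataFrame, condition: str,
                     response: str = "speed") -> LmmResult:
    """Likelihood-ratio test for a condition effect on speed.

    Fits ``response ~ C(condition)`` with nested random intercepts
    (mouse ⊃ dataset ⊃ track) by maximum likelihood, and the same model
    without the fixed effect; the LRT statistic 2·Δll is referred to a χ²
    with (levels − 1) degrees of freedom.  The reported effect is the
    coefficient of the second condition level versus the first (alphabetical
    order).  If either fit fails to converge the p-value is withheld (NaN)
    and the convergence flag cleared.
    """
    df = _prepare(samples, condition, response)
    levels = tuple(sorted(df[condition].astype(str).unique()))
    full = _fit_lmm(df, f"{response} ~ C({condition})")
    null = _fit_lmm(df, f"{response} ~ 1")
    lr = max(2.0 * (full.llf - null.llf), 0.0)
    dof = len(levels) - 1
    converged = bool(full._axotrack_converged and null._axotrack_converged
                     and np.isfinite(full.llf) and np.isfinite(null.llf))
    p = float(sps.chi2.sf(lr, dof)) if converged else np.nan
    effect = float(full.fe_params.iloc[1]) if len(full.fe_params) > 1 else np.nan
    return LmmResult(
        condition=condition, effect=effect, levels=levels,
        lr_statistic=float(lr), df=dof, p_value=p, converged=converged,
        n_obs=len(df),
        group_counts={"mouse": df["_mouse"].nunique(),
                      "dataset": df["_dataset"].nunique(),
                      "track": df["_track"].nunique()},
        llf_full=float(full.llf), llf_null=float(null.llf))


def permutation_lrt_check(samples: pd.DataFrame, condition: str,
                          n_permutations: int = 200,
                          response: str = "speed",
                          seed: int | np.random.Generator = 0) -> float:
    """Permutation oracle for :func:`hierarchical_lrt`.

    Condition labels are permuted within each track (respecting the
    hierarchy); the empirical p-value is the fraction of permuted LR
    statistics at least as large as the observed one, with the usual
    add-one correction.  Only the full model is refitted per permutation:
    the null model does not involve the condition, so its likelihood is
    permutation-invariant.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations; empirical p is coarse")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if samples[condition].dropna().nunique() < 2:
        # constant labels: every permutation reproduces the observed fit
        return 1.0
    df = _prepare(samples, condition, response)
    null = _fit_lmm(df, f"{response} ~ 1")
    full = _fit_lmm(df, f"{response} ~ C({condition})")
    lr_obs = max(2.0 * (full.llf - null.llf), 0.0)

    groups = df.groupby("_track").indices
    cond = df[condition].to_numpy()
    count = 0
    work = df.copy()
    for _ in range(n_permutations):
        perm = cond.copy()
        for idx in groups.values():
            perm[idx] = cond[rng.permutation(idx)]
        work[condition] = perm
        try:
            f = _fit_lmm(work, f"{response} ~ C({condition})")
            lr = max(2.0 * (f.llf - null.llf), 0.0)
        except Exception:
            continue
        if lr >= lr_obs - 1e-9:
            count += 1
    return (count + 1) / (n_permutations + 1)
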