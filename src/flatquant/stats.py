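"""Group comparisons for flatmount expression: LME, Tukey, normality.

Percent-expression values are correlated within mouse (two eyes per mouse)
and within eye (regional repeated measures), and eyes are missing whenever
an image fails the signal-to-noise gate. The inference layer therefore
fits a linear mixed-effects model — fixed treatment-group effects with
random intercepts for mouse and, when the table carries several rows per
eye, for eye nested in mouse — by REML, and controls the family-wise error
of all pairwise group contrasts with a single-step (max-|z|) simultaneous
adjustment under the estimated contrast correlation, the mixed-model
analogue of Tukey's post-test. Significance is declared at alpha = 0.05;
stars follow the usual <=0.05 / <=0.01 / <=0.001 convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

logger = logging.getLogger("flatquant")

ALPHA = 0.05

REQUIRED_COLUMNS = ("mouse_id", "eye_id", "group", "region_label", "percent")


@dataclass
class ComparisonResult:
    """One pairwise group contrast with its family-wise-adjusted p."""

    contrast: str
    estimate: float
    se: float
    statistic: float
    unadjusted_p: float
    adjusted_p: float
    significant: bool
    stars: str


@dataclass
class LMEFit:
    """A fitted mixed model plus the metadata the post-test needs."""

    result: object  # statsmodels MixedLMResults
    fixed_factor: str
    levels: tuple[str, ...]
    n_obs: int
    converged: bool
    #: between-mouse degrees of freedom (mice - groups); the reference for
    #: contrasts of a between-mouse factor
    df_between: int = 0

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    def variance_components(self) -> dict[str, float]:
        res = self.result
        out = {"mouse": float(np.squeeze(res.cov_re))}
        if res.model.exog_vc.names:
            for name, vc in zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)):
                out[name] = float(vc)
        out["residual"] = float(res.scale)
        return out


def validate_study_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns {missing}")
    eye_mouse = table.groupby("eye_id")["mouse_id"].nunique()
    if (eye_mouse > 1).any():
        raise ValueError("an eye_id is assigned to more than one mouse")
    eyes_per_mouse = table.groupby("mouse_id")["eye_id"].nunique()
    if (eyes_per_mouse > 2).any():
        raise ValueError("a mouse has more than 2 eyes")


def fit_lme(
    table: pd.DataFrame,
    fixed: str = "group",
    *,
    region: str | None = "total",
) -> LMEFit:
    """Fit percent ~ fixed factor with mouse (and eye-in-mouse) intercepts.

    ``region`` selects which rows enter the model (``None`` keeps all rows).
    The eye-within-mouse variance component is included only when the
    selected rows contain repeated measures per eye; with a single row per
    eye that component is confounded with the residual and unidentifiable.
    Fitting is by REML. Missing eyes and regions are simply absent rows —
    the model accepts unbalanced data by construction.
    """
    validate_study_table(table)
    data = table if region is None else table[table["region_label"] == region]
    data = data.dropna(subset=["percent"]).copy()
    if data.empty:
        raise ValueError("no rows to fit")

    levels = tuple(sorted(data[fixed].unique()))
    if len(levels) < 2:
        raise ValueError(f"need at least 2 levels of {fixed!r}, found {levels}")
    mice_per_level = data.groupby(fixed)["mouse_id"].nunique()
    thin = mice_per_level[mice_per_level < 2]
    if not thin.empty:
        raise ValueError(
            f"singular design: groups with <2 mice with data: {list(thin.index)}"
        )

    repeated = (data.groupby("eye_id").size() > 1).any()
    vc = {"eye": "0 + C(eye_id)"} if repeated else None
    model = smf.mixedlm(
        f"percent ~ C({fixed})",
        data=data,
        groups=data["mouse_id"],
        re_formula="1",
        vc_formula=vc,
    )
    # variance components at the zero boundary can defeat BFGS; fall back to
    # gradient-free optimizers before declaring non-convergence
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            try:
                candidate = model.fit(reml=True, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if candidate.converged:
                result = candidate
                break
    if result is None or not result.converged:
        raise RuntimeError(
            "mixed model did not converge; "
            f"n={len(data)}, groups={len(levels)}, vc={'eye' if repeated else 'none'}"
        )
    logger.info(
        "LME fit: %d rows, levels %s, variance components %s",
        len(data), levels,
        {k: round(v, 4) for k, v in LMEFit(result, fixed, levels, len(data), True).variance_components().items()},
    )
    return LMEFit(
        result=result,
        fixed_factor=fixed,
        levels=levels,
        n_obs=len(data),
        converged=bool(result.converged),
        df_between=int(data["mouse_id"].nunique() - len(levels)),
    )


def _max_abs_survival(
    corr: np.ndarray, ts: np.ndarray, df: int | None, n_points: int = 2**14
) -> np.ndarray:
    """P(max_j |T_j| >= t) for T multivariate t(corr, df), at each t.

    ``df`` None means the multivariate normal (asymptotic z) reference. The
    contrast correlation matrix of all pairwise comparisons is rank
    deficient (k groups give k-1 free contrasts), so the distribution is
    evaluated on its reduced-rank square root with a deterministic
    scrambled-Sobol quasi-Monte-Carlo sample; one extra QMC dimension
    carries the shared chi-square mixing variable of the multivariate t.
    Resolution ~1/n_points; ample for 0.05-level family-wise decisions.
    """
    w, V = np.linalg.eigh(corr)
    keep = w > 1e-10
    rank = int(keep.sum())
    A = V[:, keep] * np.sqrt(w[keep])  # k x r factor, corr = A A'
    eng = sps.qmc.Sobol(d=rank + (df is not None), scramble=True, seed=12345)
    u = eng.random(n_points)
    y = sps.norm.ppf(np.clip(u[:, :rank], 1e-12, 1.0 - 1e-12))
    max_abs = np.abs(y @ A.T).max(axis=1)
    if df is not None:
        chi2 = sps.chi2.ppf(np.clip(u[:, rank], 1e-12, 1.0 - 1e-12), df)
        max_abs = max_abs / np.sqrt(chi2 / df)
    return np.array([float((max_abs >= t).mean()) for t in np.atleast_1d(ts)])


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def tukey_posttest(fit: LMEFit, *, reference: str = "t") -> list[ComparisonResult]:
    """All pairwise group contrasts with single-step family-wise adjustment.

    Each contrast's adjusted p is P(max_j |T_j| >= |t_i|) where T follows a
    multivariate t with the estimated correlation of the contrast
    statistics — the single-step simultaneous inference behind Tukey-style
    post-tests on fitted (mixed) models. The default reference uses
    between-mouse degrees of freedom (mice - groups), because treatment
    group varies between mice; ``reference="z"`` selects the asymptotic
    normal reference instead (slightly liberal in small samples). With two
    groups (one contrast) the family-wise adjustment is an exact no-op.
    """
    if reference not in ("t", "z"):
        raise ValueError(f"reference must be 't' or 'z', got {reference!r}")
    df = fit.df_between if reference == "t" else None
    if df is not None and df < 1:
        raise ValueError(f"non-positive between-mouse df ({df})")
    levels = fit.levels
    if len(levels) < 2:
        raise ValueError("post-test needs a fixed factor with >= 2 levels")
    res = fit.result
    fe = res.fe_params
    k_fe = len(fe)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]

    # treatment coding relative to levels[0]: mean(level_i) = intercept + beta_i
    names = list(fe.index)

    def level_vector(level: str) -> np.ndarray:
        v = np.zeros(k_fe)
        v[0] = 1.0
        if level != levels[0]:
            v[names.index(f"C({fit.fixed_factor})[T.{level}]")] = 1.0
        return v

    pairs = list(combinations(levels, 2))
    C = np.array([level_vector(b) - level_vector(a) for a, b in pairs])
    est = C @ np.asarray(fe)
    V = C @ cov @ C.T
    se = np.sqrt(np.diag(V))
    z = est / se
    corr = V / np.outer(se, se)

    out: list[ComparisonResult] = []
    if len(pairs) > 1:
        p_adj_all = _max_abs_survival(corr, np.abs(z), df)
    for i, (a, b) in enumerate(pairs):
        zi = abs(z[i])
        p_raw = 2.0 * (sps.norm.sf(zi) if df is None else sps.t.sf(zi, df))
        if len(pairs) == 1:
            p_adj = p_raw
        else:
            p_adj = min(1.0, max(float(p_adj_all[i]), p_raw))
        out.append(
            ComparisonResult(
                contrast=f"{b} - {a}",
                estimate=float(est[i]),
                se=float(se[i]),
                statistic=float(z[i]),
                unadjusted_p=float(p_raw),
                adjusted_p=float(p_adj),
                significant=p_adj < ALPHA,
                stars=_stars(p_adj),
            )
        )
    return out


@dataclass
class KSResult:
    """One-sample KS test of residual normality with estimated parameters."""

    statistic: float
    pvalue: float
    n: int
    params_estimated: bool = True  # caveat: mean/SD estimated from the sample


def ks_normality(residuals: np.ndarray) -> KSResult:
    """KS test of the residuals against a normal with the sample mean and SD.

    The p-value is computed as if the normal parameters were known; because
    they are estimated from the same sample it is conservative, which the
    ``params_estimated`` flag records.
    """
    resid = np.asarray(residuals, dtype=float)
    if len(resid) < 5:
        raise ValueError("need at least 5 residuals")
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance residuals")
    stat, p = sps.kstest(resid, "norm", args=(resid.mean(), sd))
    return KSResult(statistic=float(stat), pvalue=float(p), n=len(resid))


@dataclass
class GroupSummary:
    """Per-(group, region) descriptives plus the central-peripheral gap."""

    table: pd.DataFrame  # columns: group, region_label, mean, sd, n, sd_undefined
    central_minus_peripheral: float | None


def group_summary(table: pd.DataFrame) -> GroupSummary:
    """Per-group/region means, SDs, ns, and the central-peripheral difference.

    The central-minus-peripheral difference is the difference of the two
    regional means pooled across all groups (the headline regional gap);
    None when either region is absent. SD is flagged undefined at n = 1.
    """
    if table.empty:
        raise ValueError("empty study table")
    g = (
        table.dropna(subset=["percent"])
        .groupby(["group", "region_label"])["percent"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    g["sd_undefined"] = g["n"] < 2
    diff = region_mean_difference(table, "central", "peripheral")
    return GroupSummary(table=g, central_minus_peripheral=diff)


def region_mean_difference(
    table: pd.DataFrame, region_a: str, region_b: str
) -> float | None:
    """Mean(region_a) - mean(region_b) across all groups, or None if absent."""
    sel = table.dropna(subset=["percent"])
    a = sel.loc[sel["region_label"] == region_a, "percent"]
    b = sel.loc[sel["region_label"] == region_b, "percent"]
    if a.empty or b.empty:
        return None
    return float(a.mean() - b.mean())
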