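"""Dose-response differential expression with empirical-Bayes moderated
t-statistics, pairwise group comparisons, comparative-Ct RT-qPCR
processing and a leave-one-out Spearman comparison.

The variance moderation follows the standard empirical-Bayes shrinkage of
per-feature residual variances toward a common prior, with the prior
degrees of freedom and scale estimated by the method of moments on the log
residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .io_formats import ExperimentDesign, ProbeSetData


# ---------------------------------------------------------------------------
# variance moderation
# ---------------------------------------------------------------------------


def _trigamma(x: np.ndarray) -> np.ndarray:
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class VariancePrior:
    df_prior: float  # d0; inf means complete shrinkage
    var_prior: float  # s0^2


def estimate_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Uses the fact that log(s2) for a scaled chi-square variance has mean
    log(sigma2) + digamma(df/2) - log(df/2) and variance trigamma(df/2).
    """
    s2 = np.asarray(s2, dtype=float)
    usable = np.isfinite(s2) & (s2 > 0)
    if usable.sum() < 2:
        raise ConfigurationError("too few positive residual variances")
    z = np.log(s2[usable])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(_trigamma(df / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0 = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
    return VariancePrior(df_prior=d0, var_prior=s0)


def moderate_variances(
    s2: np.ndarray, df: float, prior: VariancePrior
) -> np.ndarray:
    """Posterior (shrunken) variances s2_post = (d0 s0 + df s2)/(d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(prior.df_prior):
        return np.full_like(s2, prior.var_prior)
    if prior.df_prior == 0:
        return s2.copy()
    return (prior.df_prior * prior.var_prior + df * s2) / (prior.df_prior + df)


# ---------------------------------------------------------------------------
# dose-response fit
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseResult:
    table: pd.DataFrame  # per probe set: slope, intercept, s2, t, p, fdr...
    prior: VariancePrior
    dose: pd.Series  # normalized dose per array


def fit_dose_response(
    psd: ProbeSetData,
    design: ExperimentDesign,
    dose_scaling: str = "max",
    df_prior: float | None = None,
) -> DoseResponseResult:
    """Per-probe-set OLS of intensity on normalized dose with moderated t.

    ``dose_scaling`` is ``"max"`` (doses divided by the maximum dose,
    default) or ``"ordinal"`` (dose levels replaced by their rank starting
    at 0).  ``df_prior`` overrides the estimated prior degrees of freedom
    (0 gives ordinary t-statistics).
    """
    arrays = psd.array_labels
    doses = design.dose_vector(arrays).astype(float)
    if np.unique(doses).size < 2:
        raise ConfigurationError("all doses equal: dose response unidentifiable")
    if len(arrays) < 3:
        raise ConfigurationError("dose-response fit needs >= 3 arrays")
    if dose_scaling == "max":
        d = doses / doses.max()
    elif dose_scaling == "ordinal":
        levels = {v: i for i, v in enumerate(sorted(np.unique(doses)))}
        d = np.array([levels[v] for v in doses], dtype=float)
        d = d / d.max()
    else:
        raise ConfigurationError(f"unknown dose scaling {dose_scaling!r}")

    y = psd.intensities.to_numpy(dtype=float)  # sets x arrays
    n = len(arrays)
    X = np.column_stack([np.ones(n), d])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv.T  # sets x 2 (intercept, slope)
    fitted = beta @ X.T
    resid = y - fitted
    df_resid = n - 2
    s2 = (resid**2).sum(axis=1) / df_resid
    c_slope = xtx_inv[1, 1]

    positive = s2 > 0
    if df_prior is None:
        prior = estimate_variance_prior(s2[positive], df_resid)
    else:
        prior = VariancePrior(df_prior=df_prior, var_prior=float(np.nan))
        if df_prior > 0:
            est = estimate_variance_prior(s2[positive], df_resid)
            prior = VariancePrior(df_prior=df_prior, var_prior=est.var_prior)
    s2_post = moderate_variances(s2, df_resid, prior)
    if prior.df_prior == 0:
        s2_post = s2.copy()

    se = np.sqrt(s2_post * c_slope)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
    df_total = df_resid + prior.df_prior
    if np.isinf(df_total):
        p = 2.0 * sp_stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * sp_stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "intercept": beta[:, 0],
            "slope": beta[:, 1],
            "s2": s2,
            "df_resid": float(df_resid),
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "fdr": fdr,
        },
        index=psd.probe_set_ids,
    )
    return DoseResponseResult(
        table=table, prior=prior, dose=pd.Series(d, index=arrays)
    )


# ---------------------------------------------------------------------------
# pairwise comparison
# ---------------------------------------------------------------------------


def pairwise_log2fc(
    psd: ProbeSetData,
    design: ExperimentDesign,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-probe-set log2 difference of group means (a minus b) with the
    95% CI half-width ``t_{0.975,df} * difference / t`` of the pooled
    two-sample comparison (df = N_a + N_b - 2)."""
    for g in (group_a, group_b):
        if g not in design.groups:
            raise ConfigurationError(f"group {g!r} absent from design")
    arrays_a = [a for a in psd.array_labels if design.group_of[a] == group_a]
    arrays_b = [a for a in psd.array_labels if design.group_of[a] == group_b]
    if len(arrays_a) < 2 or len(arrays_b) < 2:
        raise ConfigurationError("both groups need >= 2 arrays")
    ya = psd.intensities[arrays_a].to_numpy(dtype=float)
    yb = psd.intensities[arrays_b].to_numpy(dtype=float)
    na, nb = ya.shape[1], yb.shape[1]
    diff = ya.mean(axis=1) - yb.mean(axis=1)
    df = na + nb - 2
    sp2 = (
        (na - 1) * ya.var(axis=1, ddof=1) + (nb - 1) * yb.var(axis=1, ddof=1)
    ) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.inf * np.sign(diff))
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    tq = sp_stats.t.ppf(0.975, df)
    halfwidth = tq * se  # equals tq * diff / t wherever t != 0
    p = 2.0 * sp_stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "df": float(df),
            "ci_halfwidth": halfwidth,
            "p": p,
        },
        index=psd.probe_set_ids,
    )


# ---------------------------------------------------------------------------
# comparative Ct (RT-qPCR)
# ---------------------------------------------------------------------------


def comparative_ct(
    qpcr: pd.DataFrame,
    design: ExperimentDesign,
    comparison: tuple[str, str],
    endogenous_control: str = "sno135",
    sign_convention: str = "down_negative",
) -> pd.DataFrame:
    """Comparative-Ct processing of a long-format qPCR table.

    ``qpcr`` needs columns ``mirna``, ``sample``, ``ct`` (and optionally
    ``replicate``).  Triplicate Cts are averaged per (miRNA, sample), the
    endogenous control Ct is subtracted per sample, and the between-group
    difference of delta-Ct is reported per miRNA together with a
    two-sample t-test p-value.

    With ``sign_convention="down_negative"`` (default) the value is
    deltaCt(control) - deltaCt(treated), so lower expression in the treated
    group gives a negative value (a log2 fold change).  The literal printed
    convention deltaCt(treated) - deltaCt(control) is available as
    ``"as_printed"``.
    """
    treated, control = comparison
    for col in ("mirna", "sample", "ct"):
        if col not in qpcr.columns:
            raise ConfigurationError(f"qPCR table missing column {col!r}")
    if sign_convention not in ("down_negative", "as_printed"):
        raise ConfigurationError(f"unknown sign convention {sign_convention!r}")

    mean_ct = qpcr.groupby(["mirna", "sample"])["ct"].mean().unstack("sample")
    if endogenous_control not in mean_ct.index:
        raise ConfigurationError(
            f"endogenous control {endogenous_control!r} absent from qPCR table"
        )
    control_ct = mean_ct.loc[endogenous_control]
    missing = control_ct.index[control_ct.isna()]
    if len(missing):
        raise ConfigurationError(
            f"endogenous control Ct missing for sample(s): {list(missing)[:10]}"
        )
    delta_ct = mean_ct.sub(control_ct, axis=1)
    delta_ct = delta_ct.drop(index=endogenous_control)

    samples_by_group: dict[str, list[str]] = {treated: [], control: []}
    for sample in delta_ct.columns:
        if sample not in design.group_of:
            raise ConfigurationError(f"sample {sample!r} absent from design")
        group = design.group_of[sample]
        if group in samples_by_group:
            samples_by_group[group].append(sample)
    for g, samples in samples_by_group.items():
        if len(samples) < 2:
            raise ConfigurationError(f"group {g!r} needs >= 2 qPCR samples")

    rows = []
    for mirna, row in delta_ct.iterrows():
        dt = row[samples_by_group[treated]].dropna().to_numpy(dtype=float)
        dc = row[samples_by_group[control]].dropna().to_numpy(dtype=float)
        if sign_convention == "down_negative":
            value = dc.mean() - dt.mean()
        else:
            value = dt.mean() - dc.mean()
        if dt.size >= 2 and dc.size >= 2 and (dt.std() > 0 or dc.std() > 0):
            p = float(sp_stats.ttest_ind(dt, dc, equal_var=True).pvalue)
        else:
            p = np.nan if dt.size < 2 or dc.size < 2 else 1.0
        rows.append({"mirna": mirna, "minus_ddct": float(value), "p": p})
    return pd.DataFrame(rows).set_index("mirna")


# ---------------------------------------------------------------------------
# leave-one-out Spearman CI
# ---------------------------------------------------------------------------


def spearman_loo_ci(x, y) -> tuple[float, float, float]:
    """Spearman correlation with a leave-one-out 2.5th-97.5th percentile
    interval over the n drop-one correlations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 4:
        raise ConfigurationError("need at least 4 paired values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ConfigurationError("constant input: correlation undefined")
    r = float(sp_stats.spearmanr(x, y).statistic)
    loo = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        loo[i] = sp_stats.spearmanr(x[keep], y[keep]).statistic
    lo, hi = np.percentile(loo, [2.5, 97.5])
    return r, float(lo), float(hi)
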