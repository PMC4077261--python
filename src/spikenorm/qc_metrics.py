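"""Detection calls and coefficient-of-variation quality metrics.

All CVs use the sample standard deviation (n-1 denominator) on log2-scale
intensities.  Quartiles use linear interpolation (numpy's default,
"type 7"), which matters for the whisker-fence endpoints of the
``relativeCVspike`` rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import ConfigurationError
from .io_formats import ExperimentDesign, ProbeLevelData, ProbeSetData


# ---------------------------------------------------------------------------
# detection calls
# ---------------------------------------------------------------------------


def detection_call_exiqon(
    pld: ProbeLevelData,
    threshold_factor: float = 1.5,
    min_passing_probes: int = 2,
) -> pd.DataFrame:
    """Present/absent calls by the array-median rule.

    A probe passes on an array iff it is not flagged and its linear-scale
    intensity exceeds ``threshold_factor`` times the median of all linear
    probe intensities on that array; a probe set is present iff at least
    ``min_passing_probes`` of its probes pass.
    """
    linear = np.power(2.0, pld.intensities.to_numpy(dtype=float))
    flags = pld.flags.to_numpy(dtype=bool)
    medians = np.median(linear, axis=0)
    passing = (~flags) & (linear > threshold_factor * medians[None, :])
    passing_frame = pd.DataFrame(
        passing, index=pld.probe_ids, columns=pld.array_labels
    )
    counts = passing_frame.groupby(pld.probe_set_of().to_numpy(), sort=True).sum()
    present = counts >= min_passing_probes
    present.index.name = "probe_set"
    return present


def detection_call_wilcoxon(
    pld: ProbeLevelData,
    background_groups: dict[str, list[str]],
    alpha: float = 0.06,
) -> pd.DataFrame:
    """Present/absent calls by a one-sided rank-sum test against matched
    background probes; present iff p < ``alpha``."""
    probe_set_of = pld.probe_set_of()
    sets = sorted(probe_set_of.unique())
    missing = [s for s in sets if s not in background_groups]
    if missing:
        raise ConfigurationError(
            f"probe sets without background group: {missing[:10]}"
        )
    result = {}
    for array in pld.array_labels:
        column = pld.intensities[array]
        calls = []
        for set_id in sets:
            fg = column[probe_set_of.index[(probe_set_of == set_id).to_numpy()]]
            bg_ids = background_groups[set_id]
            if len(bg_ids) == 0:
                raise ConfigurationError(f"empty background group for {set_id!r}")
            bg = column.loc[bg_ids]
            p = rank_sum_pvalue(fg.to_numpy(dtype=float), bg.to_numpy(dtype=float))
            calls.append(p < alpha)
        result[array] = calls
    out = pd.DataFrame(result, index=pd.Index(sets, name="probe_set"))
    return out


def rank_sum_pvalue(foreground: np.ndarray, background: np.ndarray) -> float:
    """One-sided (foreground > background) Wilcoxon rank-sum p-value; exact
    null enumeration for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's ``mannwhitneyu``)."""
    res = sp_stats.mannwhitneyu(
        foreground, background, alternative="greater", method="auto"
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# coefficient-of-variation metrics
# ---------------------------------------------------------------------------


def _cv(values: np.ndarray) -> float:
    """Sample SD over mean; nan when undefined (n < 2 or zero mean)."""
    values = values[np.isfinite(values)]
    if values.size < 2:
        return np.nan
    mean = values.mean()
    if mean == 0:
        warnings.warn("zero mean in CV computation; value excluded")
        return np.nan
    return float(values.std(ddof=1) / mean)


def cv_within(
    pld: ProbeLevelData, detection: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Within-array CV over the replicate probes of each probe set, per
    (probe set, array); entries with absent detection calls are masked."""
    probe_set_of = pld.probe_set_of()
    grouped = pld.intensities.groupby(probe_set_of.to_numpy(), sort=True)
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    n = grouped.size()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    cv.loc[n < 2] = np.nan
    cv.index.name = "probe_set"
    if detection is not None:
        cv = cv.where(detection.reindex(index=cv.index, columns=cv.columns))
    return cv


def cv_between(
    psd: ProbeSetData,
    design: ExperimentDesign,
    detection: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Between-array CV over the biological replicates of each group, per
    (probe set, group)."""
    design.check_covers(psd.array_labels)
    out = {}
    for group in design.groups:
        arrays = [a for a in psd.array_labels if design.group_of[a] == group]
        block = psd.intensities[arrays]
        if detection is not None:
            block = block.where(
                detection.reindex(index=block.index, columns=arrays)
            )
        out[group] = block.apply(
            lambda row: _cv(row.to_numpy(dtype=float)), axis=1
        )
    frame = pd.DataFrame(out)
    frame.index.name = "probe_set"
    return frame


def cv_treat(
    psd: ProbeSetData,
    design: ExperimentDesign,
    detection: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment-induced CV per (probe set, treated group).

    For arrays k in the treated group or the control group, the residual is
    the deviation from k's own group mean; the metric is
    ``sqrt(sum residual^2) / (N_l + N_control)`` divided by the absolute
    difference of the treated and control group means.  A zero mean
    difference yields +inf.  Returns (cv_treat frame, residual frame).
    """
    design.check_covers(psd.array_labels)
    control = design.control_group
    control_arrays = [
        a for a in psd.array_labels if design.group_of[a] == control
    ]
    if len(control_arrays) < 2:
        raise ConfigurationError("control group needs >= 2 arrays")

    values = psd.intensities
    if detection is not None:
        values = values.where(
            detection.reindex(index=values.index, columns=values.columns)
        )

    # residuals vs own-group mean, all arrays
    residuals = pd.DataFrame(
        np.nan, index=values.index, columns=values.columns
    )
    group_means = {}
    for group in design.groups:
        arrays = [a for a in psd.array_labels if design.group_of[a] == group]
        block = values[arrays]
        gmean = block.mean(axis=1)
        group_means[group] = gmean
        residuals[arrays] = block.sub(gmean, axis=0).to_numpy()

    out = {}
    for group in design.treated_groups:
        arrays = [a for a in psd.array_labels if design.group_of[a] == group]
        if len(arrays) < 2:
            raise ConfigurationError(f"group {group!r} needs >= 2 arrays")
        pooled = residuals[arrays + control_arrays]
        rss = (pooled**2).sum(axis=1, min_count=1)
        n_total = len(arrays) + len(control_arrays)
        diff = (group_means[group] - group_means[control]).abs()
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.sqrt(rss) / n_total / diff
        cv[diff == 0] = np.inf
        out[group] = cv
    frame = pd.DataFrame(out)
    frame.index.name = "probe_set"
    return frame, residuals


def whisker_range(values: np.ndarray) -> dict:
    """Tukey whisker endpoints: the two extreme observed values inside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (type-7 quartiles)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ConfigurationError("no finite values for whisker computation")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1),
        "q3": float(q3),
        "lo": float(inside.min()),
        "hi": float(inside.max()),
    }


def cv_spike_relative(
    psd_spike: ProbeSetData | pd.DataFrame,
    cv_between_values: pd.DataFrame | np.ndarray,
) -> tuple[pd.Series, pd.Series, dict]:
    """Spike-set technical CV over all arrays and its rescaling into the
    whisker range of the CVbetween distribution.

    Returns (cv_spike, relative_cv_spike, whiskers).  Relative values may
    fall outside [0, 1].
    """
    frame = (
        psd_spike.intensities
        if isinstance(psd_spike, ProbeSetData)
        else psd_spike
    )
    cv_spike = frame.apply(lambda row: _cv(row.to_numpy(dtype=float)), axis=1)
    pooled = (
        cv_between_values.to_numpy(dtype=float).ravel()
        if isinstance(cv_between_values, pd.DataFrame)
        else np.asarray(cv_between_values, dtype=float).ravel()
    )
    whiskers = whisker_range(pooled)
    lo, hi = whiskers["lo"], whiskers["hi"]
    if hi <= lo:
        raise ConfigurationError("degenerate CVbetween distribution (hi == lo)")
    relative = (cv_spike - lo) / (hi - lo)
    return cv_spike, relative, whiskers


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """All CV metrics for one normalized dataset."""

    cv_within: pd.DataFrame
    cv_between: pd.DataFrame
    cv_treat: pd.DataFrame
    residuals: pd.DataFrame
    cv_spike: pd.Series
    relative_cv_spike: pd.Series
    whiskers: dict
    detection: pd.DataFrame | None = None

    def summary(self) -> dict:
        def _summarize(values: np.ndarray) -> dict:
            values = np.asarray(values, dtype=float).ravel()
            values = values[np.isfinite(values)]
            if values.size == 0:
                return {"n": 0}
            q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
            return {
                "n": int(values.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
            }

        return {
            "cv_within": _summarize(self.cv_within.to_numpy()),
            "cv_between": _summarize(self.cv_between.to_numpy()),
            "cv_treat": _summarize(self.cv_treat.to_numpy()),
            "cv_spike": _summarize(self.cv_spike.to_numpy()),
            "relative_cv_spike": _summarize(self.relative_cv_spike.to_numpy()),
            "whiskers": self.whiskers,
        }


def compute_cv_report(
    raw_pld: ProbeLevelData,
    normalized_psd: ProbeSetData,
    design: ExperimentDesign,
    detection: pd.DataFrame | None = None,
) -> CVReport:
    """Assemble all CV metrics: CVwithin on raw probe data, CVbetween /
    CVtreat on normalized miRNA probe sets, CVspike on normalized spike-in
    sets rescaled to the CVbetween whiskers."""
    mirna_sets = normalized_psd.sets_of_class("mirna")
    spike_sets = normalized_psd.sets_of_class("spikein")
    mirna_psd = normalized_psd.subset(mirna_sets)
    within = cv_within(raw_pld, detection=detection)
    between = cv_between(mirna_psd, design, detection=detection)
    treat, residuals = cv_treat(mirna_psd, design, detection=detection)
    spike_frame = normalized_psd.intensities.loc[spike_sets]
    cv_spike, relative, whiskers = cv_spike_relative(spike_frame, between)
    return CVReport(
        cv_within=within,
        cv_between=between,
        cv_treat=treat,
        residuals=residuals,
        cv_spike=cv_spike,
        relative_cv_spike=relative,
        whiskers=whiskers,
        detection=detection,
    )
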