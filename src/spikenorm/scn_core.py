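"""Spike-in control based normalization (SCN).

The method assumes every spike-in RNA is present at the same concentration
in every sample, so systematic deviations of spike-in probe-set
intensities across arrays measure array-specific bias.  A rank-1
("shared variance") decomposition of those deviations yields per-array,
intensity-dependent correction values, which are extended to the full
intensity range by stabilization, linear extrapolation, LOWESS smoothing
and piecewise-linear interpolation.  If the applicability checks fail,
MEDIAN normalization is used instead.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .baseline_norm import median_normalize
from .exceptions import ConfigurationError, FallbackRequired
from .io_formats import (
    ExperimentDesign,
    ProbeLevelData,
    ProbeSetData,
    summarize_probesets,
)

DEGENERATE_NORM = 1e-12


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class SpikeInMatrix:
    """Spike-in probe-set log2 intensities with row means and the
    underlying probe-level submatrix."""

    values: pd.DataFrame  # spike set x array, summarized
    row_means: pd.Series  # per-set mean over arrays
    probe_level: pd.DataFrame  # spike probe x array
    probe_set_of: pd.Series  # spike probe -> set

    @property
    def set_ids(self) -> pd.Index:
        return self.values.index

    @property
    def array_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SpikeInCorrections:
    """First-step output: centered/normed deviations and the rank-1
    reconstruction of the spike-set corrections."""

    U: pd.DataFrame
    U_mean: pd.Series
    row_norms: pd.Series
    delta_S: pd.DataFrame
    residuals: pd.DataFrame
    corr: pd.DataFrame


@dataclass
class AssumptionCheck:
    passed: bool
    stats: dict

    def to_dict(self) -> dict:
        return {"passed": bool(self.passed), **_jsonable(self.stats)}


@dataclass
class AssumptionReport:
    a1: AssumptionCheck | None
    a2: AssumptionCheck | None
    a3: AssumptionCheck | None
    fallback_used: bool
    reason: str | None = None

    def all_passed(self) -> bool:
        checks = (self.a1, self.a2, self.a3)
        return all(c is not None and c.passed for c in checks)

    def to_dict(self) -> dict:
        return {
            "a1": None if self.a1 is None else self.a1.to_dict(),
            "a2": None if self.a2 is None else self.a2.to_dict(),
            "a3": None if self.a3 is None else self.a3.to_dict(),
            "fallback_used": bool(self.fallback_used),
            "reason": self.reason,
        }


@dataclass
class CorrectionFunction:
    """Per-array piecewise-linear intensity -> correction mapping.

    ``knots[k]`` is a frame with columns ``x`` (strictly increasing),
    ``delta`` (smoothed correction), ``delta_raw`` (pre-smoothing value)
    and ``provenance`` (``spike`` / ``stabilization`` / ``extrapolation``).
    Evaluation clamps to the end-knot values outside the knot range.
    """

    knots: dict[str, pd.DataFrame]

    def evaluate(self, x, array: str) -> np.ndarray:
        if array not in self.knots:
            raise ConfigurationError(
                f"array {array!r} absent from correction function"
            )
        table = self.knots[array]
        return np.interp(
            np.asarray(x, dtype=float),
            table["x"].to_numpy(),
            table["delta"].to_numpy(),
        )

    @property
    def array_labels(self) -> list[str]:
        return list(self.knots)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for array, table in self.knots.items():
            part = table.copy()
            part.insert(0, "array", array)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ScnResult:
    data: ProbeSetData
    report: AssumptionReport
    correction: CorrectionFunction | None
    probe_level: ProbeLevelData | None = None


# ---------------------------------------------------------------------------
# extraction and assumption checks
# ---------------------------------------------------------------------------


def extract_spikein(psd: ProbeSetData, pld: ProbeLevelData) -> SpikeInMatrix:
    """Pull the spike-in probe-set submatrix (and probe submatrix) out of
    summarized and probe-level data."""
    spike_sets = psd.sets_of_class("spikein")
    if len(spike_sets) < 2:
        raise ConfigurationError(
            f"SCN requires >= 2 spike-in probe sets, found {len(spike_sets)}"
        )
    values = psd.intensities.loc[spike_sets]
    probe_ids = pld.probes_of_class("spikein")
    probe_level = pld.intensities.loc[probe_ids]
    return SpikeInMatrix(
        values=values,
        row_means=values.mean(axis=1),
        probe_level=probe_level,
        probe_set_of=pld.probe_set_of().loc[probe_ids],
    )


def _row_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows; zero-variance rows yield 0."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms < DEGENERATE_NORM
    if degenerate.any():
        warnings.warn(
            "constant spike-in rows: correlations set to 0", stacklevel=2
        )
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def check_assumption_a1(sm: SpikeInMatrix, threshold: float = 0.5) -> AssumptionCheck:
    """A1: deviations are shared across spike-in sets — the median
    off-diagonal Pearson correlation between set rows must reach
    ``threshold``."""
    if sm.values.shape[0] < 2:
        raise ConfigurationError("A1 needs >= 2 spike-in probe sets")
    if sm.values.shape[1] < 3:
        raise ConfigurationError("A1 needs >= 3 arrays for correlations")
    corr = _row_correlations(sm.values.to_numpy(dtype=float))
    off = corr[np.triu_indices_from(corr, k=1)]
    median = float(np.median(off))
    return AssumptionCheck(
        passed=median >= threshold,
        stats={
            "median_offdiagonal": median,
            "mean_offdiagonal": float(np.mean(off)),
            "min_offdiagonal": float(np.min(off)),
            "threshold": float(threshold),
            "n_pairs": int(off.size),
        },
    )


def check_assumption_a2(sm: SpikeInMatrix) -> AssumptionCheck:
    """A2: each spike-in set maps to a well-defined intensity — every
    within-set probe SD (pooled over arrays) is smaller than the minimum
    gap between consecutive sorted set mean intensities."""
    sds = {}
    for set_id in sm.set_ids:
        probes = sm.probe_set_of.index[(sm.probe_set_of == set_id).to_numpy()]
        block = sm.probe_level.loc[probes].to_numpy(dtype=float)
        if block.shape[0] < 2:
            sds[set_id] = 0.0
            continue
        within = block.var(axis=0, ddof=1)  # per-array variance over probes
        sds[set_id] = float(np.sqrt(within.mean()))
    means = np.sort(sm.row_means.to_numpy(dtype=float))
    gaps = np.diff(means)
    min_gap = float(gaps.min()) if gaps.size else 0.0
    passed = all(sd < min_gap for sd in sds.values())
    return AssumptionCheck(
        passed=passed,
        stats={
            "within_set_sd": {str(k): v for k, v in sds.items()},
            "min_between_set_gap": min_gap,
            "max_within_set_sd": float(max(sds.values())) if sds else 0.0,
        },
    )


def check_assumption_a3(
    sm: SpikeInMatrix,
    full: ProbeSetData,
    max_extrapolation: float = 2.0,
    band: tuple[float, float] = (5.0, 95.0),
) -> AssumptionCheck:
    """A3: spike-in intensities cover the miRNA intensity range — the
    central percentile band of miRNA probe-set intensities must lie within
    the spike-in mean range extended by ``max_extrapolation`` log2 units
    on each side."""
    mirna_sets = full.sets_of_class("mirna")
    mirna_values = full.intensities.loc[mirna_sets].to_numpy(dtype=float).ravel()
    lo_band, hi_band = np.percentile(mirna_values, band)
    spike_lo = float(sm.row_means.min())
    spike_hi = float(sm.row_means.max())
    passed = (lo_band >= spike_lo - max_extrapolation) and (
        hi_band <= spike_hi + max_extrapolation
    )
    overlap = max(0.0, min(spike_hi, hi_band) - max(spike_lo, lo_band))
    width = hi_band - lo_band
    covered = overlap / width if width > 0 else 1.0
    return AssumptionCheck(
        passed=passed,
        stats={
            "spike_range": [spike_lo, spike_hi],
            "mirna_band": [float(lo_band), float(hi_band)],
            "band_percentiles": [float(band[0]), float(band[1])],
            "covered_fraction": float(covered),
            "max_extrapolation": float(max_extrapolation),
        },
    )


# ---------------------------------------------------------------------------
# first step: rank-1 spike-set corrections
# ---------------------------------------------------------------------------


def compute_spikein_corrections(sm: SpikeInMatrix) -> SpikeInCorrections:
    """Decompose spike-set deviations into a shared rank-1 correction.

    Every set row is centered on its across-array mean and scaled to unit
    Euclidean norm; the per-array mean of these unit rows defines the
    shared deviation pattern, which is scaled back per set by its row norm.
    """
    values = sm.values.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ConfigurationError("need >= 2 spike sets and >= 2 arrays")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms < DEGENERATE_NORM
    safe = np.where(degenerate, 1.0, norms)
    U = centered / safe[:, None]
    U[degenerate, :] = 0.0
    u_mean = U.mean(axis=0)
    delta = np.outer(norms, u_mean)
    residuals = centered - delta
    corr = _row_correlations(values)
    idx, cols = sm.values.index, sm.values.columns
    return SpikeInCorrections(
        U=pd.DataFrame(U, index=idx, columns=cols),
        U_mean=pd.Series(u_mean, index=cols),
        row_norms=pd.Series(norms, index=idx),
        delta_S=pd.DataFrame(delta, index=idx, columns=cols),
        residuals=pd.DataFrame(residuals, index=idx, columns=cols),
        corr=pd.DataFrame(corr, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# second step: correction function
# ---------------------------------------------------------------------------


def _merge_duplicate_x(x: np.ndarray, y: np.ndarray, prov: list[str]):
    """Average delta values at coincident knot positions."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    prov = [prov[i] for i in order]
    out_x, out_y, out_p = [], [], []
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[j + 1] - x[i] < 1e-12:
            j += 1
        out_x.append(x[i])
        out_y.append(float(np.mean(y[i : j + 1])))
        out_p.append(prov[i])
        i = j + 1
    return np.array(out_x), np.array(out_y), out_p


def build_correction_function(
    sc: SpikeInCorrections,
    sm: SpikeInMatrix,
    full: ProbeLevelData | ProbeSetData,
    lowess_frac: float = 0.4,
    lowess_iterations: int = 3,
) -> CorrectionFunction:
    """Extend the spike-set corrections to the full intensity range.

    Per array: knots at (set mean intensity, set correction); the dataset
    minimum is prepended carrying the correction of the lowest spike set;
    the high-intensity side is completed at every integer up to the dataset
    maximum using the straight line through the two highest-intensity spike
    sets; the knot set is LOWESS-smoothed (tricube local linear, fraction
    ``lowess_frac``) and evaluated by clamped piecewise-linear
    interpolation.
    """
    if sm.values.shape[0] < 2:
        raise FallbackRequired(
            "fewer than 2 spike-in sets: use MEDIAN normalization instead"
        )
    order = np.argsort(sm.row_means.to_numpy(), kind="stable")
    base_x = sm.row_means.to_numpy(dtype=float)[order]
    all_values = full.intensities.to_numpy(dtype=float)
    data_lo = float(all_values.min())
    data_hi = float(all_values.max())

    knots: dict[str, pd.DataFrame] = {}
    for array in sm.array_labels:
        delta_col = sc.delta_S[array].to_numpy(dtype=float)[order]
        x = base_x.copy()
        y = delta_col.copy()
        prov = ["spike"] * len(x)

        # stabilization at low intensities
        if data_lo < x[0]:
            x = np.concatenate([[data_lo], x])
            y = np.concatenate([[y[0]], y])
            prov = ["stabilization"] + prov

        # linear extrapolation at high intensities from the two
        # highest-intensity spike sets
        spike_hi_x = base_x[-1]
        if data_hi > spike_hi_x:
            x1, x2 = base_x[-2], base_x[-1]
            y1, y2 = delta_col[-2], delta_col[-1]
            slope = (y2 - y1) / (x2 - x1) if x2 != x1 else 0.0
            new_x = [
                float(v)
                for v in np.arange(np.floor(spike_hi_x) + 1, np.floor(data_hi) + 1)
                if v > spike_hi_x and v <= data_hi
            ]
            if not new_x or new_x[-1] < data_hi:
                new_x.append(data_hi)
            new_y = [y2 + slope * (v - x2) for v in new_x]
            x = np.concatenate([x, new_x])
            y = np.concatenate([y, new_y])
            prov = prov + ["extrapolation"] * len(new_x)

        x, y, prov = _merge_duplicate_x(x, y, prov)

        smoothed = _lowess_at_knots(x, y, lowess_frac, lowess_iterations)
        knots[array] = pd.DataFrame(
            {"x": x, "delta": smoothed, "delta_raw": y, "provenance": prov}
        )
    return CorrectionFunction(knots=knots)


def _lowess_at_knots(
    x: np.ndarray, y: np.ndarray, frac: float, iterations: int
) -> np.ndarray:
    if len(x) < 4 or frac * len(x) < 2:
        return y.copy()
    fitted = _sm_lowess(y, x, frac=frac, it=iterations, return_sorted=True)
    return np.interp(x, fitted[:, 0], fitted[:, 1])


def apply_correction(
    data: ProbeLevelData | ProbeSetData, cf: CorrectionFunction
) -> ProbeLevelData | ProbeSetData:
    """Subtract the per-array correction, evaluated at each entry's own
    intensity (clamped outside the knot range)."""
    frame = data.intensities
    corrected = {}
    for array in frame.columns:
        col = frame[array].to_numpy(dtype=float)
        corrected[array] = col - cf.evaluate(col, array)
    out = pd.DataFrame(corrected, index=frame.index, columns=frame.columns)
    return data.with_intensities(out)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def scn_normalize(
    pld: ProbeLevelData,
    design: ExperimentDesign | None = None,
    a1_threshold: float = 0.5,
    a3_max_extrapolation: float = 2.0,
    lowess_frac: float = 0.4,
) -> ScnResult:
    """Run the full SCN pipeline with MEDIAN fallback.

    Summarizes probe sets, checks assumptions A1-A3 on the spike-in
    submatrix, and either applies the SCN correction (probe-set and
    probe level) or falls back to MEDIAN normalization.
    """
    if design is not None:
        design.check_covers(pld.array_labels)
    psd = summarize_probesets(pld)

    try:
        sm = extract_spikein(psd, pld)
    except ConfigurationError as exc:
        warnings.warn(f"SCN unavailable ({exc}); falling back to MEDIAN")
        report = AssumptionReport(
            a1=None, a2=None, a3=None, fallback_used=True, reason=str(exc)
        )
        return ScnResult(
            data=median_normalize(psd),
            report=report,
            correction=None,
            probe_level=median_normalize(pld),
        )

    try:
        a1 = check_assumption_a1(sm, threshold=a1_threshold)
    except ConfigurationError as exc:
        a1 = AssumptionCheck(passed=False, stats={"error": str(exc)})
    a2 = check_assumption_a2(sm)
    a3 = check_assumption_a3(sm, psd, max_extrapolation=a3_max_extrapolation)

    if not (a1.passed and a2.passed and a3.passed):
        failed = [
            name
            for name, check in (("A1", a1), ("A2", a2), ("A3", a3))
            if not check.passed
        ]
        report = AssumptionReport(
            a1=a1,
            a2=a2,
            a3=a3,
            fallback_used=True,
            reason=f"assumption(s) {', '.join(failed)} failed",
        )
        return ScnResult(
            data=median_normalize(psd),
            report=report,
            correction=None,
            probe_level=median_normalize(pld),
        )

    sc = compute_spikein_corrections(sm)
    cf = build_correction_function(sc, sm, pld, lowess_frac=lowess_frac)
    report = AssumptionReport(a1=a1, a2=a2, a3=a3, fallback_used=False)
    return ScnResult(
        data=apply_correction(psd, cf),
        report=report,
        correction=cf,
        probe_level=apply_correction(pld, cf),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
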