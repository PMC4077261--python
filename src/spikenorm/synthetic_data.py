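"""Synthetic miRNA array experiments with known ground truth.

Generates probe-level data with the structure the spike-in normalization
assumes: miRNA probe sets of a few replicate probes with baseline, optional
dose response and biological noise; spike-in probe sets of many replicate
probes at fixed log2 levels spanning the intensity range; smooth per-array
intensity-dependent biases applied to all probes; probe-level noise and
random quality flags.

Bias functions are generated in antithetic pairs (array 2m+1 gets the
negated bias of array 2m), which makes the biases sum to zero across
arrays at every intensity and keeps both the mean and the median of
intensity-independent offsets at zero, so the "true" normalized data is
identifiable.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_formats import (
    ExperimentDesign,
    ProbeLevelData,
    write_annotation_tsv,
    write_design_tsv,
    write_imagene,
)

BIAS_MODELS = ("separable", "constant", "none")


@dataclass
class GroupSpec:
    name: str
    dose: float
    n_replicates: int


DEFAULT_GROUPS = (
    GroupSpec("sham", 0.0, 4),
    GroupSpec("low", 75.0, 4),
    GroupSpec("medium", 150.0, 4),
    GroupSpec("high", 300.0, 4),
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment (defaults mirror a 16-array,
    4-group dose-response design with 10 spike-in levels)."""

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    n_mirna_sets: int = 600
    probes_per_set: int = 4
    n_spike_sets: int = 10
    probes_per_spike_set: int = 48
    spike_level_range: tuple[float, float] = (4.0, 14.0)
    baseline_range: tuple[float, float] = (5.0, 13.0)
    bias_model: str = "separable"  # separable | constant | none
    bias_amplitude: float = 0.3
    bias_degree: int = 3
    probe_noise_sd: float = 0.05
    probe_offset_sd: float = 0.0  # fixed per-probe offset within a set
    biological_sd: float = 0.0
    de_fraction: float = 0.0
    de_slope_sd: float = 1.0
    global_decrease: bool = False
    global_decrease_magnitude: float = 0.3
    spike_bias_free: bool = False  # if True, spikes receive no array bias
    flag_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirna_sets < 1 or self.n_spike_sets < 1:
            raise ConfigurationError("set counts must be >= 1")
        if self.probes_per_set < 1 or self.probes_per_spike_set < 1:
            raise ConfigurationError("probe counts must be >= 1")
        if min(
            self.probe_noise_sd,
            self.biological_sd,
            self.probe_offset_sd,
            self.flag_rate,
        ) < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if self.spike_level_range[0] >= self.spike_level_range[1]:
            raise ConfigurationError("spike levels must be strictly increasing")
        if self.bias_model not in BIAS_MODELS:
            raise ConfigurationError(f"unknown bias model {self.bias_model!r}")
        if self.bias_degree < 0 or self.bias_degree > 3:
            raise ConfigurationError("bias_degree must be in 0..3")

    @property
    def n_arrays(self) -> int:
        return sum(g.n_replicates for g in self.groups)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    bias_coefficients: dict[str, list[float]]  # per-array polynomial coeffs
    bias_domain: tuple[float, float]  # x interval the polynomials live on
    bias_grid: dict[str, list[list[float]]]  # per-array sampled (x, b(x))
    spike_levels: dict[str, float]
    mirna_baselines: dict[str, float]
    mirna_slopes: dict[str, float]
    de_sets: list[str]
    seed: int

    def bias_value(self, array: str, x) -> np.ndarray:
        """Evaluate the injected bias polynomial of one array (the
        polynomial is defined in coordinates scaled to [-1, 1] over the
        bias domain)."""
        lo, hi = self.bias_domain
        scaled = (2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)) - 1.0
        return np.polyval(self.bias_coefficients[array], scaled)

    def to_json(self) -> str:
        payload = {
            "bias_coefficients": self.bias_coefficients,
            "bias_domain": list(self.bias_domain),
            "bias_grid": self.bias_grid,
            "spike_levels": self.spike_levels,
            "mirna_baselines": self.mirna_baselines,
            "mirna_slopes": self.mirna_slopes,
            "de_sets": self.de_sets,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        payload = json.loads(text)
        return cls(
            bias_coefficients=payload["bias_coefficients"],
            bias_domain=tuple(payload["bias_domain"]),
            bias_grid=payload["bias_grid"],
            spike_levels=payload["spike_levels"],
            mirna_baselines=payload["mirna_baselines"],
            mirna_slopes=payload["mirna_slopes"],
            de_sets=payload["de_sets"],
            seed=payload["seed"],
        )


def _spike_labels(n: int) -> list[str]:
    letters = string.ascii_lowercase
    labels = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(f"spike_{label}")
    return labels


def _make_bias_functions(
    cfg: SimulationConfig, rng: np.random.Generator, array_labels: list[str]
) -> tuple[dict[str, np.ndarray], tuple[float, float]]:
    """Per-array bias polynomial coefficients (in scaled coordinates).

    ``separable`` draws one smooth single-signed profile g(x) shared by all
    arrays and per-array coefficients u_k in antithetic pairs, giving the
    rank-1 deviation structure the normalization assumes.  ``constant``
    yields intensity-independent offsets (again antithetic).  ``none``
    yields all-zero biases.
    """
    lo, hi = cfg.spike_level_range
    domain = (lo - 1.0, hi + 1.0)
    n = len(array_labels)
    coeffs: dict[str, np.ndarray] = {}
    if cfg.bias_model == "none" or cfg.bias_amplitude == 0:
        for label in array_labels:
            coeffs[label] = np.zeros(1)
        return coeffs, domain

    # antithetic array coefficients with unit max magnitude
    raw = rng.uniform(0.3, 1.0, size=(n + 1) // 2) * rng.choice(
        [-1.0, 1.0], size=(n + 1) // 2
    )
    u = np.empty(n)
    u[0::2] = raw[: len(u[0::2])]
    u[1::2] = -raw[: len(u[1::2])]
    if n % 2 == 1:
        u[-1] = 0.0
    u = u / np.max(np.abs(u))

    if cfg.bias_model == "constant":
        for label, uk in zip(array_labels, u):
            coeffs[label] = np.array([cfg.bias_amplitude * uk])
        return coeffs, domain

    # separable: shared profile = gentle polynomial, shifted single-signed
    profile = rng.normal(size=cfg.bias_degree + 1)
    profile *= 0.5 ** np.arange(cfg.bias_degree, -1, -1)  # damp high orders
    grid = np.linspace(-1.0, 1.0, 101)
    sampled = np.polyval(profile, grid)
    # shift so min(g) >= 0.3 * max(g): keeps every spike level informative
    span = sampled.max() - sampled.min()
    if span < 1e-9:
        shifted = np.array([*np.zeros(cfg.bias_degree), 1.0])
    else:
        shift = 0.45 * span - sampled.min()
        shifted = profile.copy()
        shifted[-1] += shift
    g_max = np.abs(np.polyval(shifted, grid)).max()
    shifted = shifted / g_max  # max |g| = 1
    for label, uk in zip(array_labels, u):
        coeffs[label] = cfg.bias_amplitude * uk * shifted
    return coeffs, domain


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[ProbeLevelData, ExperimentDesign, SimulationTruth]:
    """Generate one synthetic experiment; deterministic under ``cfg.seed``."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_bias, rng_mirna, rng_noise, rng_flags = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    array_labels = []
    group_of = {}
    dose_of = {}
    control = None
    for spec in cfg.groups:
        dose_of[spec.name] = spec.dose
        if spec.dose == 0:
            control = spec.name
        for r in range(spec.n_replicates):
            label = f"{spec.name}_{r + 1:02d}"
            array_labels.append(label)
            group_of[label] = spec.name
    if control is None:
        raise ConfigurationError("one group must have dose 0 (control)")
    design = ExperimentDesign(
        group_of=group_of, dose_of=dose_of, control_group=control
    )
    doses = design.dose_vector(array_labels)
    max_dose = doses.max()
    d_norm = doses / max_dose if max_dose > 0 else doses

    coeffs, domain = _make_bias_functions(cfg, rng_bias, array_labels)

    def bias(array: str, x: np.ndarray) -> np.ndarray:
        lo, hi = domain
        scaled = (2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)) - 1.0
        return np.polyval(coeffs[array], scaled)

    # ground-truth miRNA parameters
    mirna_ids = [f"mir{i + 1:04d}" for i in range(cfg.n_mirna_sets)]
    baselines = rng_mirna.uniform(*cfg.baseline_range, size=cfg.n_mirna_sets)
    slopes = np.zeros(cfg.n_mirna_sets)
    n_de = int(round(cfg.de_fraction * cfg.n_mirna_sets))
    de_idx = (
        rng_mirna.choice(cfg.n_mirna_sets, size=n_de, replace=False)
        if n_de
        else np.array([], dtype=int)
    )
    slopes[de_idx] = rng_mirna.normal(0.0, cfg.de_slope_sd, size=n_de)
    if cfg.global_decrease:
        slopes = slopes - cfg.global_decrease_magnitude

    spike_ids = _spike_labels(cfg.n_spike_sets)
    spike_levels = np.linspace(*cfg.spike_level_range, cfg.n_spike_sets)

    # per-probe fixed offsets (replicate probes are not perfectly identical)
    mirna_offsets = rng_mirna.normal(
        0.0, cfg.probe_offset_sd, size=(cfg.n_mirna_sets, cfg.probes_per_set)
    )
    spike_offsets = rng_mirna.normal(
        0.0,
        cfg.probe_offset_sd,
        size=(cfg.n_spike_sets, cfg.probes_per_spike_set),
    )

    n_arrays = len(array_labels)
    n_mirna_probes = cfg.n_mirna_sets * cfg.probes_per_set
    n_spike_probes = cfg.n_spike_sets * cfg.probes_per_spike_set

    bio = rng_noise.normal(
        0.0, cfg.biological_sd, size=(cfg.n_mirna_sets, n_arrays)
    )
    mirna_noise = rng_noise.normal(
        0.0, cfg.probe_noise_sd, size=(n_mirna_probes, n_arrays)
    )
    spike_noise = rng_noise.normal(
        0.0, cfg.probe_noise_sd, size=(n_spike_probes, n_arrays)
    )

    # expected set-level intensity per (set, array), noise-free: this is
    # the argument of the bias function so the injected truth stays exact
    mirna_expected = baselines[:, None] + slopes[:, None] * d_norm[None, :]
    spike_expected = np.repeat(spike_levels[:, None], n_arrays, axis=1)

    mirna_bias = np.zeros_like(mirna_expected)
    spike_bias = np.zeros_like(spike_expected)
    for a, label in enumerate(array_labels):
        mirna_bias[:, a] = bias(label, mirna_expected[:, a])
        if not cfg.spike_bias_free:
            spike_bias[:, a] = bias(label, spike_expected[:, a])

    mirna_values = (
        np.repeat(mirna_expected + mirna_bias + bio, cfg.probes_per_set, axis=0)
        + np.repeat(mirna_offsets.reshape(-1), n_arrays).reshape(
            n_mirna_probes, n_arrays
        )
        + mirna_noise
    )
    spike_values = (
        np.repeat(spike_expected + spike_bias, cfg.probes_per_spike_set, axis=0)
        + np.repeat(spike_offsets.reshape(-1), n_arrays).reshape(
            n_spike_probes, n_arrays
        )
        + spike_noise
    )

    probe_ids = []
    ann_rows = []
    for set_id in mirna_ids:
        for p in range(cfg.probes_per_set):
            probe_ids.append(f"{set_id}_p{p + 1}")
            ann_rows.append((set_id, "mirna", "mmu"))
    for set_id in spike_ids:
        for p in range(cfg.probes_per_spike_set):
            probe_ids.append(f"{set_id}_p{p + 1:02d}")
            ann_rows.append((set_id, "spikein", "synthetic"))

    values = np.vstack([mirna_values, spike_values])
    flags = rng_flags.random(values.shape) < cfg.flag_rate

    index = pd.Index(probe_ids, name="probe")
    intensities = pd.DataFrame(values, index=index, columns=array_labels)
    flag_frame = pd.DataFrame(flags, index=index, columns=array_labels)
    annotation = pd.DataFrame(
        ann_rows, index=index, columns=["probe_set", "probe_class", "species"]
    )
    pld = ProbeLevelData(
        intensities=intensities,
        flags=flag_frame,
        annotation=annotation,
        channel="Hy3",
    )

    grid_x = np.linspace(domain[0], domain[1], 41)
    truth = SimulationTruth(
        bias_coefficients={k: list(map(float, v)) for k, v in coeffs.items()},
        bias_domain=domain,
        bias_grid={
            k: [list(map(float, grid_x)), list(map(float, bias(k, grid_x)))]
            for k in array_labels
        },
        spike_levels=dict(zip(spike_ids, map(float, spike_levels))),
        mirna_baselines=dict(zip(mirna_ids, map(float, baselines))),
        mirna_slopes=dict(zip(mirna_ids, map(float, slopes))),
        de_sets=[mirna_ids[i] for i in sorted(de_idx)],
        seed=cfg.seed,
    )
    return pld, design, truth


def write_fixture(
    directory: str | Path,
    pld: ProbeLevelData,
    design: ExperimentDesign,
    truth: SimulationTruth,
) -> dict[str, object]:
    """Write a simulated experiment as ImaGene-dialect files plus design,
    annotation and truth JSON; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    array_paths = write_imagene(pld, directory / "arrays")
    design_path = directory / "design.tsv"
    write_design_tsv(design, design_path)
    annotation_path = directory / "annotation.tsv"
    write_annotation_tsv(pld.annotation, annotation_path)
    truth_path = directory / "truth.json"
    truth_path.write_text(truth.to_json())
    return {
        "arrays": array_paths,
        "design": design_path,
        "annotation": annotation_path,
        "truth": truth_path,
    }
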