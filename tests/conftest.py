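import numpy as np
import pandas as pd
import pytest

from spikenorm.io_formats import (
    ExperimentDesign,
    ProbeLevelData,
    ProbeSetData,
)
from spikenorm.synthetic_data import SimulationConfig, simulate_experiment


def make_pld(values, annotation=None, flags=None, columns=None, channel="single"):
    """Build a ProbeLevelData from a dict probe -> row or an array."""
    if isinstance(values, dict):
        frame = pd.DataFrame.from_dict(values, orient="index", dtype=float)
        if columns is not None:
            frame.columns = columns
        else:
            frame.columns = [f"a{i + 1}" for i in range(frame.shape[1])]
    else:
        values = np.asarray(values, dtype=float)
        index = [f"p{i + 1}" for i in range(values.shape[0])]
        cols = columns or [f"a{i + 1}" for i in range(values.shape[1])]
        frame = pd.DataFrame(values, index=index, columns=cols)
    frame.index.name = "probe"
    if flags is None:
        flag_frame = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    else:
        flag_frame = pd.DataFrame(
            np.asarray(flags, dtype=bool), index=frame.index, columns=frame.columns
        )
    if annotation is None:
        ann = pd.DataFrame(
            {
                "probe_set": list(frame.index),
                "probe_class": "mirna",
                "species": "",
            },
            index=frame.index,
        )
    elif isinstance(annotation, dict):
        ann = pd.DataFrame.from_dict(annotation, orient="index")
        ann.columns = ["probe_set", "probe_class", "species"][: ann.shape[1]]
        for col, default in (("probe_class", "mirna"), ("species", "")):
            if col not in ann.columns:
                ann[col] = default
    else:
        ann = annotation
    return ProbeLevelData(
        intensities=frame, flags=flag_frame, annotation=ann, channel=channel
    )


def make_psd(values, columns=None, set_classes=None, index=None):
    values = np.asarray(values, dtype=float)
    idx = pd.Index(index or [f"s{i + 1}" for i in range(values.shape[0])])
    cols = columns or [f"a{i + 1}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=idx, columns=cols)
    classes = pd.Series(set_classes or "mirna", index=idx)
    return ProbeSetData(
        intensities=frame,
        n_probes=pd.Series(1, index=idx),
        set_classes=classes,
    )


def make_design(groups):
    """groups: list of (group, dose, [array labels]); first dose-0 group is
    the control."""
    group_of, dose_of = {}, {}
    control = None
    for name, dose, arrays in groups:
        dose_of[name] = dose
        if dose == 0 and control is None:
            control = name
        for a in arrays:
            group_of[a] = name
    return ExperimentDesign(
        group_of=group_of, dose_of=dose_of, control_group=control
    )


@pytest.fixture(scope="session")
def default_design():
    return make_design(
        [
            ("sham", 0.0, [f"sham_{i:02d}" for i in range(1, 5)]),
            ("low", 75.0, [f"low_{i:02d}" for i in range(1, 5)]),
            ("medium", 150.0, [f"medium_{i:02d}" for i in range(1, 5)]),
            ("high", 300.0, [f"high_{i:02d}" for i in range(1, 5)]),
        ]
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated experiment with a separable bias, shared across
    tests that only read it."""
    cfg = SimulationConfig(
        seed=101,
        n_mirna_sets=80,
        bias_amplitude=0.4,
        probe_noise_sd=0.05,
    )
    return simulate_experiment(cfg)
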