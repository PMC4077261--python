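"""MEDIAN and quantile normalization of intensity matrices.

Both operate on either :class:`~spikenorm.io_formats.ProbeLevelData` or
:class:`~spikenorm.io_formats.ProbeSetData` and return the same type with
the intensity matrix replaced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_formats import ProbeLevelData, ProbeSetData

Data = ProbeLevelData | ProbeSetData


def median_normalize(data: Data) -> Data:
    """Equalize per-array medians.

    Each array's median is subtracted and the grand median of all per-array
    medians is added back, so the overall log2 location of the data is
    preserved while per-array medians become identical.
    """
    frame = data.intensities
    medians = frame.median(axis=0)
    grand = float(np.median(medians.to_numpy()))
    corrected = frame.sub(medians, axis=1) + grand
    return data.with_intensities(corrected)


def quantile_normalize(data: Data) -> Data:
    """Classic quantile normalization.

    Every array's sorted values are replaced by the row-wise mean of the
    sorted columns; tied values receive the mean of the quantile targets
    they jointly occupy (average-rank convention).
    """
    frame = data.intensities
    if frame.shape[1] < 2:
        raise ConfigurationError("quantile normalization needs >= 2 arrays")
    values = frame.to_numpy(dtype=float)
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(n, dtype=float)
    for k in range(values.shape[1]):
        # average rank (0-based, fractional at ties) interpolated into the
        # mean-sorted reference distribution
        ranks = pd.Series(values[:, k]).rank(method="average").to_numpy() - 1.0
        out[:, k] = np.interp(ranks, positions, mean_sorted)
    corrected = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return data.with_intensities(corrected)


NORMALIZERS = {
    "median": median_normalize,
    "quantile": quantile_normalize,
}
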