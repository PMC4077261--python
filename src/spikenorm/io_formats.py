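"""Core data model and text I/O for probe-level microarray data.

Two on-disk dialects are supported:

* a minimal ImaGene-style export: free-form header, then a tab-delimited
  table between ``Begin Raw Data`` / ``End Raw Data`` lines with columns
  ``Gene ID``, ``Signal Median``, ``Background Median`` and ``Flag``
  (one file per array/channel, linear-scale intensities);
* a generic TSV matrix (probe ids in the first column, array labels in the
  header, log2 scale unless a ``# scale: linear`` directive is present).

All downstream modules operate on the in-memory types defined here, which
hold log2-scale intensities throughout.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    AnnotationError,
    ConfigurationError,
    FormatError,
    ParseError,
)

PROBE_CLASSES = ("mirna", "spikein", "other")

RAW_DATA_BEGIN = "Begin Raw Data"
RAW_DATA_END = "End Raw Data"
REQUIRED_IMAGENE_COLUMNS = ("Gene ID", "Signal Median", "Background Median", "Flag")

SCALE_DIRECTIVE = "# scale:"


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class ProbeLevelData:
    """Log2 probe x array intensity matrix with annotation and quality flags.

    Parameters
    ----------
    intensities
        ``DataFrame`` indexed by probe id with one column per array label,
        log2 scale, all finite.
    flags
        Boolean ``DataFrame`` of the same shape; ``True`` marks a probe
        measurement flagged as bad quality by the scanner.
    annotation
        ``DataFrame`` indexed by probe id with columns ``probe_set``,
        ``probe_class`` (one of ``mirna``/``spikein``/``other``) and
        ``species``.
    channel
        Which channel the intensities come from (``Hy3``, ``Hy5`` or
        ``single``).
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    annotation: pd.DataFrame
    channel: str = "single"

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------

    def validate(self, require_spikeins: bool = False) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise FormatError("probe-level intensities contain non-finite values")
        if self.intensities.shape[1] < 2:
            raise ConfigurationError(
                "at least 2 arrays are required (multi-array method)"
            )
        if self.flags.shape != self.intensities.shape:
            raise FormatError("flags matrix shape differs from intensities")
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise FormatError(f"duplicate probe ids: {sorted(set(dups))[:10]}")
        missing = self.intensities.index.difference(self.annotation.index)
        if len(missing):
            raise AnnotationError(
                f"probes absent from annotation: {sorted(missing)[:10]}"
            )
        bad_class = set(self.annotation["probe_class"]) - set(PROBE_CLASSES)
        if bad_class:
            raise AnnotationError(f"unknown probe classes: {sorted(bad_class)}")
        if require_spikeins and len(self.probe_sets_of_class("spikein")) == 0:
            raise ConfigurationError("no spike-in probe sets in annotation")

    # -- convenience -------------------------------------------------------

    @property
    def array_labels(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    def probe_class_of(self) -> pd.Series:
        """Per-probe class, aligned to the intensity matrix rows."""
        return self.annotation.loc[self.probe_ids, "probe_class"]

    def probe_set_of(self) -> pd.Series:
        return self.annotation.loc[self.probe_ids, "probe_set"]

    def probes_of_class(self, probe_class: str) -> pd.Index:
        keep = self.probe_class_of() == probe_class
        return self.probe_ids[keep.to_numpy()]

    def probe_sets_of_class(self, probe_class: str) -> list[str]:
        ann = self.annotation.loc[self.probe_ids]
        keep = ann["probe_class"] == probe_class
        return sorted(ann.loc[keep, "probe_set"].unique())

    def with_intensities(self, intensities: pd.DataFrame) -> "ProbeLevelData":
        return dataclasses.replace(self, intensities=intensities)


@dataclass
class ProbeSetData:
    """Probe-set x array summarized log2 intensity matrix."""

    intensities: pd.DataFrame
    n_probes: pd.Series
    set_classes: pd.Series
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.n_probes < 1).any():
            raise FormatError("probe sets must contain at least one probe")
        if not self.n_probes.index.equals(self.intensities.index):
            self.n_probes = self.n_probes.reindex(self.intensities.index)
        if not self.set_classes.index.equals(self.intensities.index):
            self.set_classes = self.set_classes.reindex(self.intensities.index)

    @property
    def array_labels(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def probe_set_ids(self) -> pd.Index:
        return self.intensities.index

    def sets_of_class(self, probe_class: str) -> pd.Index:
        keep = (self.set_classes == probe_class).to_numpy()
        return self.intensities.index[keep]

    def subset(self, probe_sets: Sequence[str]) -> "ProbeSetData":
        idx = pd.Index(probe_sets)
        return ProbeSetData(
            intensities=self.intensities.loc[idx],
            n_probes=self.n_probes.loc[idx],
            set_classes=self.set_classes.loc[idx],
            detection=None if self.detection is None else self.detection.loc[idx],
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "ProbeSetData":
        return dataclasses.replace(self, intensities=intensities)


@dataclass
class ExperimentDesign:
    """Array -> group and group -> dose mapping with a control group."""

    group_of: dict[str, str]
    dose_of: dict[str, float]
    control_group: str

    def __post_init__(self) -> None:
        if self.control_group not in self.dose_of:
            raise ConfigurationError(
                f"control group {self.control_group!r} has no dose entry"
            )
        missing = set(self.group_of.values()) - set(self.dose_of)
        if missing:
            raise ConfigurationError(f"groups without dose: {sorted(missing)}")
        if any(d < 0 for d in self.dose_of.values()):
            raise ConfigurationError("doses must be non-negative")
        if self.dose_of[self.control_group] != 0:
            raise ConfigurationError("control group must have dose 0")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g, None)
        return list(seen)

    @property
    def treated_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control_group]

    def arrays_in_group(self, group: str) -> list[str]:
        return [a for a, g in self.group_of.items() if g == group]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.group_of.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def dose_vector(self, array_labels: Sequence[str]) -> np.ndarray:
        missing = [a for a in array_labels if a not in self.group_of]
        if missing:
            raise ConfigurationError(f"arrays absent from design: {missing[:10]}")
        return np.array([self.dose_of[self.group_of[a]] for a in array_labels])

    def check_covers(self, array_labels: Sequence[str]) -> None:
        self.dose_vector(array_labels)


# ---------------------------------------------------------------------------
# ImaGene dialect
# ---------------------------------------------------------------------------


def _floor_log2(values: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(values, 1.0))


def _parse_imagene_file(path: str | Path) -> pd.DataFrame:
    """Parse one ImaGene-dialect file into a raw (linear-scale) table."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(
            i for i, ln in enumerate(lines) if ln.strip() == RAW_DATA_BEGIN
        )
    except StopIteration:
        raise FormatError(f"{path}: no '{RAW_DATA_BEGIN}' section") from None
    header_idx = begin + 1
    if header_idx >= len(lines):
        raise FormatError(f"{path}: truncated raw-data section")
    header = lines[header_idx].rstrip("\n").split("\t")
    for col in REQUIRED_IMAGENE_COLUMNS:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    col_idx = {c: header.index(c) for c in header}
    records: list[tuple] = []
    for offset, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if line.strip() == RAW_DATA_END:
            break
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < len(header):
            raise ParseError(f"{path}: expected {len(header)} fields", offset)
        gene = parts[col_idx["Gene ID"]]
        try:
            signal = float(parts[col_idx["Signal Median"]])
            background = float(parts[col_idx["Background Median"]])
        except ValueError:
            raise ParseError(f"{path}: non-numeric signal value", offset) from None
        try:
            flag = int(float(parts[col_idx["Flag"]]))
        except ValueError:
            raise ParseError(f"{path}: non-numeric flag value", offset) from None
        records.append((gene, signal, background, flag))
    else:
        raise FormatError(f"{path}: missing '{RAW_DATA_END}' line")
    frame = pd.DataFrame(
        records, columns=["probe", "signal", "background", "flag"]
    ).set_index("probe")
    if frame.index.has_duplicates:
        dups = sorted(set(frame.index[frame.index.duplicated()]))
        raise FormatError(f"{path}: duplicate probe ids {dups[:10]}")
    return frame


def _default_annotation(probe_ids: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_set": list(probe_ids),
            "probe_class": "mirna",
            "species": "",
        },
        index=probe_ids,
    )


def read_imagene(
    paths: Sequence[str | Path],
    channel: str = "Hy3",
    background: str = "none",
    annotation: pd.DataFrame | str | Path | None = None,
    labels: Sequence[str] | None = None,
) -> ProbeLevelData:
    """Read one ImaGene-dialect file per array into a :class:`ProbeLevelData`.

    ``background`` is either ``"none"`` (log2 of the Signal Median, floored
    at 1) or ``"subtract"`` (linear-scale Background Median subtracted from
    the linear-scale Signal Median, floored at 1, then log2).  Any nonzero
    scanner flag marks the probe as bad quality.
    """
    if background not in ("none", "subtract"):
        raise ConfigurationError(f"unknown background policy {background!r}")
    if not paths:
        raise ConfigurationError("no input files given")
    if labels is None:
        labels = [Path(p).stem for p in paths]
    if len(labels) != len(paths):
        raise ConfigurationError("labels/paths length mismatch")

    tables = [_parse_imagene_file(p) for p in paths]
    roster = tables[0].index
    for p, table in zip(list(paths)[1:], tables[1:]):
        if not table.index.sort_values().equals(roster.sort_values()):
            offending = sorted(
                set(roster).symmetric_difference(table.index)
            )
            raise AlignmentError(
                f"{p}: probe roster differs from {paths[0]}: {offending[:20]}",
                probes=offending,
            )

    signal = {}
    flags = {}
    for label, table in zip(labels, tables):
        table = table.reindex(roster)
        linear = table["signal"].to_numpy(dtype=float)
        if background == "subtract":
            linear = linear - table["background"].to_numpy(dtype=float)
        signal[label] = _floor_log2(linear)
        flags[label] = table["flag"].to_numpy() != 0

    intensities = pd.DataFrame(signal, index=roster)
    flag_frame = pd.DataFrame(flags, index=roster)

    if annotation is None:
        ann = _default_annotation(roster)
    elif isinstance(annotation, (str, Path)):
        ann = read_annotation_tsv(annotation)
    else:
        ann = annotation
    return ProbeLevelData(
        intensities=intensities, flags=flag_frame, annotation=ann, channel=channel
    )


def write_imagene(
    pld: ProbeLevelData,
    directory: str | Path,
    background: pd.DataFrame | None = None,
) -> list[Path]:
    """Write one ImaGene-dialect file per array (linear scale), for fixtures.

    Returns the written paths, named ``<label>.txt``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for label in pld.array_labels:
        path = directory / f"{label}.txt"
        linear = np.power(2.0, pld.intensities[label].to_numpy(dtype=float))
        flags = pld.flags[label].to_numpy().astype(int)
        bg = (
            np.zeros_like(linear)
            if background is None
            else background[label].to_numpy(dtype=float)
        )
        with path.open("w") as fh:
            fh.write("Begin Header\n")
            fh.write(f"\tchannel\t{pld.channel}\n")
            fh.write(f"\tarray\t{label}\n")
            fh.write("End Header\n")
            fh.write(f"{RAW_DATA_BEGIN}\n")
            fh.write("Gene ID\tSignal Median\tBackground Median\tFlag\n")
            for probe, value, b, f in zip(pld.probe_ids, linear, bg, flags):
                fh.write(f"{probe}\t{float(value)!r}\t{float(b)!r}\t{f}\n")
            fh.write(f"{RAW_DATA_END}\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# generic TSV matrix + annotation + design
# ---------------------------------------------------------------------------


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe", "probe_set", "probe_class"):
        if col not in ann.columns:
            raise FormatError(f"annotation file missing column {col!r}")
    if "species" not in ann.columns:
        ann["species"] = ""
    if ann["probe"].duplicated().any():
        raise FormatError("annotation contains duplicate probe ids")
    return ann.set_index("probe")[["probe_set", "probe_class", "species"]]


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()
    out.columns = ["probe", *annotation.columns]
    out.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(
    path: str | Path,
    annotation: pd.DataFrame | str | Path | None = None,
    missing: str = "error",
) -> ProbeLevelData:
    """Read a probe x array TSV matrix (log2 scale unless directed linear).

    A first line ``# scale: linear`` triggers a floored log2 transform at
    import.  ``missing`` is ``"error"`` (default) or ``"impute"`` (missing
    entries replaced by the array median).
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    scale = "log2"
    skip = 0
    if first.startswith(SCALE_DIRECTIVE):
        scale = first[len(SCALE_DIRECTIVE) :].strip()
        skip = 1
    if scale not in ("log2", "linear"):
        raise FormatError(f"unknown scale directive {scale!r}")
    frame = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dups = sorted(set(frame.index[frame.index.duplicated()]))
        raise FormatError(f"duplicate probe ids: {dups[:10]}")
    if frame.isna().any().any():
        if missing == "error":
            raise FormatError(f"{path}: matrix contains missing values")
        frame = frame.apply(lambda col: col.fillna(col.median()))
    values = frame.to_numpy(dtype=float)
    if scale == "linear":
        values = _floor_log2(values)
        frame = pd.DataFrame(values, index=frame.index, columns=frame.columns)
    if annotation is None:
        ann = _default_annotation(frame.index)
    elif isinstance(annotation, (str, Path)):
        ann = read_annotation_tsv(annotation)
    else:
        ann = annotation
    missing_probes = frame.index.difference(ann.index)
    if len(missing_probes):
        raise AnnotationError(
            f"probes absent from annotation: {sorted(missing_probes)[:10]}"
        )
    flags = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    return ProbeLevelData(
        intensities=frame, flags=flags, annotation=ann, channel="single"
    )


def write_matrix_tsv(data: ProbeLevelData | ProbeSetData, path: str | Path) -> None:
    """Write the intensity matrix as a round-trip-safe TSV (full precision)."""
    frame = data.intensities
    label = "probe_set" if isinstance(data, ProbeSetData) else "probe"
    with Path(path).open("w") as fh:
        fh.write(label + "\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for idx, row in zip(frame.index, frame.to_numpy(dtype=float)):
            fh.write(
                str(idx) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )


def read_design_tsv(path: str | Path) -> ExperimentDesign:
    frame = pd.read_csv(path, sep="\t", dtype={"array": str, "group": str})
    for col in ("array", "group", "dose", "is_control"):
        if col not in frame.columns:
            raise FormatError(f"design file missing column {col!r}")
    group_of = dict(zip(frame["array"], frame["group"]))
    dose_of: dict[str, float] = {}
    control = None
    for _, row in frame.iterrows():
        dose_of[row["group"]] = float(row["dose"])
        if bool(int(row["is_control"])):
            control = row["group"]
    if control is None:
        raise FormatError("design file declares no control group")
    return ExperimentDesign(group_of=group_of, dose_of=dose_of, control_group=control)


def write_design_tsv(design: ExperimentDesign, path: str | Path) -> None:
    rows = []
    for array, group in design.group_of.items():
        rows.append(
            {
                "array": array,
                "group": group,
                "dose": design.dose_of[group],
                "is_control": int(group == design.control_group),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------


def summarize_probesets(pld: ProbeLevelData) -> ProbeSetData:
    """Median-summarize probes into probe sets (flags are ignored here;
    they only feed detection calls)."""
    probe_sets = pld.probe_set_of()
    grouped = pld.intensities.groupby(probe_sets.to_numpy(), sort=True)
    intensities = grouped.median()
    intensities.index.name = "probe_set"
    n_probes = grouped.size()
    classes = pld.probe_class_of().groupby(probe_sets.to_numpy()).agg(
        lambda s: _unique_class(s)
    )
    return ProbeSetData(
        intensities=intensities,
        n_probes=n_probes.reindex(intensities.index),
        set_classes=classes.reindex(intensities.index),
    )


def _unique_class(series: pd.Series) -> str:
    classes = set(series)
    if len(classes) != 1:
        raise AnnotationError(
            f"probe set mixes probe classes: {sorted(classes)}"
        )
    return classes.pop()
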