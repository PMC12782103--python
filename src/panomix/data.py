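"""Core data containers: metadata table, omics matrices, and the aligned Study.

All inputs follow the n x p orientation (samples are rows, variables are
columns) and every omics matrix must share the metadata's sample count and
ordering.  Alignment is positional; when both files carry a sample-id column
(detected as a first column that is non-numeric and unique) the ids are used
as a cross-check only.

Missing values are a hard error at load time: no imputation is performed
anywhere in the pipeline, because silent imputation would leak information
into cross-validation downstream.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResponseSpec",
    "MetadataTable",
    "OmicsMatrix",
    "Study",
    "load_metadata",
    "load_omics",
    "assemble_study",
    "classify_variables",
    "sniff_delimiter",
]

#: a numeric metadata column with at most this many distinct values is
#: treated as categorical (captures 0/1-coded clinical flags)
DEFAULT_MAX_CATEGORICAL_LEVELS = 5


class DataError(ValueError):
    """Raised for malformed or misaligned input data."""


@dataclass(frozen=True)
class ResponseSpec:
    """The categorical response variable and its reference level."""

    name: str
    reference_level: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise DataError(
                f"response {self.name!r} needs >= 2 levels, got {list(self.levels)}"
            )
        if self.reference_level not in self.levels:
            raise DataError(
                f"reference level {self.reference_level!r} not among observed "
                f"levels {list(self.levels)} of response {self.name!r}"
            )

    @property
    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass
class MetadataTable:
    """Samples x clinical/demographic variables with a kind per column."""

    frame: pd.DataFrame
    var_kind: dict[str, str]  # column -> "numerical" | "categorical"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        missing = set(self.frame.columns) - set(self.var_kind)
        if missing:
            raise DataError(f"var_kind missing for columns: {sorted(missing)}")

    @property
    def n(self) -> int:
        return len(self.frame)

    def variables(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class OmicsMatrix:
    """One omics dataset: n samples x p_j features, fully numeric, no NAs."""

    name: str
    frame: pd.DataFrame  # float values, columns = feature ids
    is_count: bool
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


@dataclass
class Study:
    """Aligned bundle of metadata, J omics datasets and the response spec."""

    metadata: MetadataTable
    datasets: list[OmicsMatrix]
    response: ResponseSpec

    @property
    def n(self) -> int:
        return self.metadata.n

    @property
    def response_labels(self) -> np.ndarray:
        return self.metadata.frame[self.response.name].astype(str).to_numpy()

    def dataset(self, name: str) -> OmicsMatrix:
        for d in self.datasets:
            if d.name == name:
                return d
        raise KeyError(f"no dataset named {name!r}")

    def content_hash(self) -> str:
        """SHA-256 over canonical CSV serializations (order-sensitive)."""
        h = hashlib.sha256()
        h.update(self.metadata.frame.to_csv(index=False).encode())
        for d in self.datasets:
            h.update(d.name.encode())
            h.update(d.frame.to_csv(index=False).encode())
        h.update(repr(self.response).encode())
        return h.hexdigest()

    # -- serialization ----------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = self.metadata.frame.copy()
        if self.metadata.sample_ids is not None:
            meta.insert(0, "sample_id", self.metadata.sample_ids)
        meta.to_csv(directory / "metadata.csv", index=False)
        for d in self.datasets:
            d.frame.to_csv(directory / f"{d.name}.csv", index=False)
        manifest = {
            "n": self.n,
            "datasets": [
                {"name": d.name, "p": d.p, "is_count": d.is_count}
                for d in self.datasets
            ],
            "response": {
                "name": self.response.name,
                "reference_level": self.response.reference_level,
                "levels": list(self.response.levels),
            },
            "var_kind": self.metadata.var_kind,
            "has_sample_ids": self.metadata.sample_ids is not None,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "Study":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        meta, resp = load_metadata(
            directory / "metadata.csv",
            manifest["response"]["name"],
            manifest["response"]["reference_level"],
        )
        datasets = [
            load_omics(directory / f"{d['name']}.csv", d["name"])
            for d in manifest["datasets"]
        ]
        return assemble_study(meta, resp, datasets)


# ---------------------------------------------------------------------------


def sniff_delimiter(path: str | Path) -> str:
    """Detect the delimiter of a text table from {comma, tab, semicolon}."""
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    if not sample.strip():
        raise DataError(f"{path}: empty file")
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _read_table(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read as strings; also return the raw header (pandas mangles duplicates)."""
    sep = sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] == 0:
        raise DataError(f"{path}: empty table")
    return df, header


_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in _NA_TOKENS


def _detect_id_column(df: pd.DataFrame) -> bool:
    """First column treated as sample ids if non-numeric and unique.

    Missing-value tokens do not count as "non-numeric": a numeric column
    with NAs must be reported as missing data, not mistaken for ids.
    """
    first = df.iloc[:, 0]
    present = first[~first.map(_is_missing)]
    if present.empty:
        return False
    numeric = pd.to_numeric(present, errors="coerce").notna().all()
    return (not numeric) and first.is_unique


def classify_variables(
    df: pd.DataFrame, max_levels: int = DEFAULT_MAX_CATEGORICAL_LEVELS
) -> dict[str, str]:
    """Assign each column a kind: numerical, or categorical.

    A column is categorical if any value fails numeric parsing, or if it is
    numeric with at most ``max_levels`` distinct values (0/1 flags etc.).
    """
    kinds: dict[str, str] = {}
    for col in df.columns:
        as_num = pd.to_numeric(df[col], errors="coerce")
        if as_num.isna().any() or df[col].nunique() <= max_levels:
            kinds[col] = "categorical"
        else:
            kinds[col] = "numerical"
    return kinds


def load_metadata(
    path: str | Path,
    response_name: str,
    reference_level: str,
    max_levels: int = DEFAULT_MAX_CATEGORICAL_LEVELS,
) -> tuple[MetadataTable, ResponseSpec]:
    """Read the metadata CSV and build the response specification.

    The response column is always treated as categorical with the reference
    level ordered first; it must have no missing values and >= 2 levels.
    """
    raw, _ = _read_table(path)
    sample_ids = None
    if _detect_id_column(raw) and raw.columns[0] != response_name:
        sample_ids = raw.iloc[:, 0].tolist()
        raw = raw.iloc[:, 1:]
    if response_name not in raw.columns:
        raise DataError(
            f"{path}: response column {response_name!r} not found "
            f"(columns: {list(raw.columns)})"
        )
    for col in raw.columns:
        bad = raw.index[raw[col].map(_is_missing)]
        if len(bad):
            raise DataError(
                f"{path}: missing value in column {col!r}, row {int(bad[0]) + 2}"
            )
    levels = list(dict.fromkeys(raw[response_name]))
    if reference_level not in levels:
        raise DataError(
            f"{path}: reference level {reference_level!r} not among observed "
            f"values {levels} of {response_name!r}"
        )
    ordered = [reference_level] + [l for l in levels if l != reference_level]
    response = ResponseSpec(response_name, reference_level, tuple(ordered))

    frame = pd.DataFrame(index=raw.index)
    kinds = classify_variables(raw, max_levels=max_levels)
    kinds[response_name] = "categorical"
    for col in raw.columns:
        if kinds[col] == "numerical":
            frame[col] = raw[col].astype(float)  # exact strtod round-trip
        else:
            frame[col] = raw[col].astype(str)
    return MetadataTable(frame, kinds, sample_ids), response


def load_omics(path: str | Path, name: str) -> OmicsMatrix:
    """Read one omics matrix; all non-header cells must parse as numbers."""
    raw, header = _read_table(path)
    sample_ids = None
    if _detect_id_column(raw):
        sample_ids = raw.iloc[:, 0].tolist()
        raw = raw.iloc[:, 1:]
        header = header[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise DataError(f"{path}: duplicate feature names: {dupes}")
    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        as_num = pd.to_numeric(raw[col], errors="coerce")
        if as_num.isna().any():
            row = int(as_num.index[as_num.isna()][0])
            raise DataError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} at "
                f"row {row + 2}, column {col!r}"
            )
        values[col] = raw[col].astype(float)  # exact strtod round-trip
    arr = values.to_numpy()
    is_count = bool(np.all(arr >= 0) and np.all(arr == np.round(arr)))
    return OmicsMatrix(name, values, is_count, sample_ids)


def assemble_study(
    metadata: MetadataTable,
    response: ResponseSpec,
    datasets: list[OmicsMatrix],
) -> Study:
    """Validate row counts and (when available) positional sample-id agreement."""
    if not datasets:
        raise DataError("a Study needs at least one omics dataset")
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise DataError(f"duplicate dataset names: {names}")
    for j, d in enumerate(datasets, start=1):
        if d.n != metadata.n:
            raise DataError(
                f"dataset {j} ({d.name!r}) has {d.n} rows but metadata has "
                f"{metadata.n}; sample ordering must be shared"
            )
        if metadata.sample_ids is not None and d.sample_ids is not None:
            for pos, (a, b) in enumerate(zip(metadata.sample_ids, d.sample_ids)):
                if a != b:
                    raise DataError(
                        f"dataset {j} ({d.name!r}): sample id mismatch at "
                        f"position {pos}: metadata {a!r} vs dataset {b!r}"
                    )
    return Study(metadata, datasets, response)
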