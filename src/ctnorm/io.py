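"""Reading and writing Ct matrices and sample annotations.

The on-disk dialect is the wide table exported by real-time PCR instrument
software: first column gene (assay) identifiers, header row sample
identifiers, one Ct value per cell. Reactions that never crossed the
fluorescence threshold within the run appear as a token such as
``Undetermined``; they are right-censored observations, not zeros.

Internally a :class:`CtMatrix` stores values as a float DataFrame in which
``NaN`` is the explicit non-determined (ND) marker. ND is never silently
replaced by the censoring bound ``ct_max``; methods that need that
substitution (e.g. mean-centering over all genes) perform it locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateLabelError, ParseError, SchemaError

DEFAULT_ND_TOKENS = frozenset({"Undetermined", "ND", ""})
DEFAULT_CT_MAX = 40.0


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class CtMatrix:
    """A genes x samples matrix of PCR cycle-threshold values.

    Parameters
    ----------
    data
        Float DataFrame, rows = gene assays, columns = samples. ``NaN``
        encodes a non-determined (censored) reaction. Every numeric value v
        must satisfy ``0 < v <= ct_max``.
    ct_max
        The censoring bound of the run (cycles). Reactions with Ct above
        this bound are non-determined.
    """

    data: pd.DataFrame
    ct_max: float = DEFAULT_CT_MAX

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("CtMatrix must have at least one gene and one sample")
        if self.ct_max <= 0:
            raise ValueError("ct_max must be positive")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateLabelError(f"duplicate gene id(s): {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateLabelError(f"duplicate sample id(s): {dupes}")
        values = self.data.to_numpy(dtype=float)
        finite = np.isfinite(values)
        if np.any(values[finite] <= 0) or np.any(values[finite] > self.ct_max):
            raise ValueError(
                f"numeric Ct values must lie in (0, {self.ct_max}]; "
                "values beyond the bound must be stored as non-determined"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def nd_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the reaction is non-determined."""
        return self.data.isna()

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.data.copy(), ct_max=self.ct_max)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: origin group and optional titration input level."""

    sample_id: str
    origin: str
    input_level: float | None = None


def read_ct_table(
    path: str | Path,
    nd_tokens: Iterable[str] = DEFAULT_ND_TOKENS,
    ct_max: float = DEFAULT_CT_MAX,
    delimiter: str | None = None,
) -> CtMatrix:
    """Read a wide Ct table; cells above ``ct_max`` or in ``nd_tokens`` become ND.

    The detection chemistry reports Ct > ``ct_max`` (default 40 cycles) as
    non-determined, so numeric cells beyond the bound are converted to the ND
    marker rather than kept as numbers. Parsing is locale-independent:
    decimal commas are rejected.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    nd_tokens = {str(t).strip() for t in nd_tokens}
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{path}: empty Ct table")
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise DuplicateLabelError(f"{path}: duplicate gene id(s): {dupes}")
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DuplicateLabelError(f"{path}: duplicate sample id(s): {dupes}")

    out = np.empty(raw.shape, dtype=float)
    for i, gene in enumerate(raw.index):
        for j, sample in enumerate(raw.columns):
            cell = raw.iat[i, j].strip()
            if cell in nd_tokens:
                out[i, j] = np.nan
                continue
            try:
                value = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: cannot parse cell at gene {gene!r}, sample "
                    f"{sample!r}: {cell!r}"
                ) from None
            if not math.isfinite(value) or value <= 0:
                raise ParseError(
                    f"{path}: invalid Ct value {cell!r} at gene {gene!r}, "
                    f"sample {sample!r} (must be finite and positive)"
                )
            out[i, j] = np.nan if value > ct_max else value
    frame = pd.DataFrame(out, index=raw.index.astype(str), columns=raw.columns.astype(str))
    return CtMatrix(frame, ct_max=ct_max)


def write_ct_table(
    matrix: CtMatrix,
    path: str | Path,
    nd_token: str = "Undetermined",
    delimiter: str | None = None,
) -> None:
    """Write a CtMatrix in the same wide dialect; ND cells become ``nd_token``.

    Values are printed with 10 significant digits so a read/write round trip
    reproduces both the numeric values and the ND pattern.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    printable = matrix.data.map(lambda v: nd_token if pd.isna(v) else format(v, ".10g"))
    printable.index.name = printable.index.name or "gene_id"
    printable.to_csv(path, sep=sep)


def read_annotation(path: str | Path, delimiter: str | None = None) -> list[SampleAnnotation]:
    """Read a sample annotation table with columns sample_id, origin[, input_level]."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "origin": str})
    for col in ("sample_id", "origin"):
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateLabelError(f"{path}: duplicate sample_id(s): {dupes}")
    records = []
    for _, row in table.iterrows():
        level = None
        if "input_level" in table.columns and pd.notna(row["input_level"]):
            level = float(row["input_level"])
        records.append(
            SampleAnnotation(sample_id=str(row["sample_id"]), origin=str(row["origin"]), input_level=level)
        )
    return records


def write_annotation(
    annotations: Sequence[SampleAnnotation], path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    frame = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "origin": [a.origin for a in annotations],
            "input_level": [a.input_level for a in annotations],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


def origin_series(
    annotations: Sequence[SampleAnnotation], sample_ids: Sequence[str]
) -> pd.Series:
    """Map the sample ids of a matrix to origin labels, validating coverage."""
    by_id = {}
    for a in annotations:
        if a.sample_id in by_id:
            raise DuplicateLabelError(f"duplicate annotation for sample {a.sample_id!r}")
        if not a.origin:
            raise SchemaError(f"sample {a.sample_id!r} has an empty origin label")
        by_id[a.sample_id] = a.origin
    missing = [s for s in sample_ids if s not in by_id]
    if missing:
        raise SchemaError(f"samples without annotation: {missing}")
    return pd.Series({s: by_id[s] for s in sample_ids}, name="origin").loc[list(sample_ids)]
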