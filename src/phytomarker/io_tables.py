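"""Tabular containers and CSV I/O for the screening pipeline.

Two in-memory containers travel through every stage:

* :class:`PeakTable` — the predictor block X: one chromatographic peak area
  per sample and compound (non-negative, arbitrary units), plus optional
  per-compound annotations (name, chemical class, SMILES).
* :class:`ActivityTable` — the response block Y: one bioassay readout per
  sample and assay (units are assay-specific: %, µmol Fe(II)/g, %).

Sample and compound identifiers are opaque strings; numeric peak ids are
stored as strings ("1".."22") to avoid type drift between CSV round trips.
Missing cells are never imputed — they are a hard validation error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AlignmentError, LookupError_, TableFormatError, TableValidationError

logger = logging.getLogger(__name__)

_FIXTURES = {
    "table2_grd": "table2_grd.csv",
    "table3_antioxidant": "table3_antioxidant.csv",
    "table4_antiinflammatory": "table4_antiinflammatory.csv",
}


def _check_ids(ids: Iterable[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if any(i == "" or i.lower() == "nan" for i in ids):
        raise TableFormatError(f"missing {kind} identifier")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableFormatError(f"duplicated {kind} identifiers: {dupes}")
    return ids


def _validate_numeric(df: pd.DataFrame, allow_negative: bool) -> None:
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise TableValidationError(
                f"non-numeric or missing value at row {row!r}, column {col!r}"
            )
        if not allow_negative and (numeric < 0).any():
            row = df.index[(numeric < 0).argmax()]
            raise TableValidationError(
                f"negative value at row {row!r}, column {col!r}"
            )


@dataclass
class PeakTable:
    """Sample × compound peak-area matrix with compound annotations."""

    data: pd.DataFrame                       # rows = samples, cols = compounds
    compound_meta: pd.DataFrame | None = None  # index = compound ids

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = _check_ids(self.data.index, "sample")
        self.data.columns = _check_ids(self.data.columns, "compound")
        _validate_numeric(self.data, allow_negative=False)
        self.data = self.data.astype(float)
        if self.compound_meta is not None:
            meta = self.compound_meta.copy()
            meta.index = [str(i) for i in meta.index]
            missing = set(self.data.columns) - set(meta.index)
            if missing:
                raise TableFormatError(
                    f"compound_meta lacks entries for {sorted(missing)}"
                )
            self.compound_meta = meta.loc[list(self.data.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.data.shape[1]

    def write_csv(self, path: str | Path) -> None:
        # repr-precision printing so write→read round trips bit-exactly
        self.data.to_csv(path, float_format="%.17g", index_label="sample")


@dataclass
class ActivityTable:
    """Sample × assay bioactivity matrix (assay-specific units)."""

    data: pd.DataFrame  # rows = samples, cols = assays

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = _check_ids(self.data.index, "sample")
        self.data.columns = _check_ids(self.data.columns, "assay")
        _validate_numeric(self.data, allow_negative=True)
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, float_format="%.17g", index_label="sample")


def _read_matrix_csv(path: str | Path) -> pd.DataFrame:
    import csv

    with open(path, newline="") as fh:  # pandas dedupes headers silently
        header = next(csv.reader(fh), [])
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise TableFormatError(f"{path}: duplicated compound header {dupes}")
    try:
        raw = pd.read_csv(path, index_col=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise TableFormatError(f"{path}: no data columns found")
    return raw


def read_peak_table(
    path: str | Path, meta_path: str | Path | None = None
) -> PeakTable:
    """Read a sample × compound CSV (first column = sample ids, header = compound ids)."""
    raw = _read_matrix_csv(path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0, dtype=str)
    return PeakTable(raw, compound_meta=meta)


def read_activity_table(path: str | Path) -> ActivityTable:
    """Read a sample × assay CSV with the same layout as the peak table."""
    return ActivityTable(_read_matrix_csv(path))


def align_tables(
    peaks: PeakTable, acts: ActivityTable
) -> tuple[PeakTable, ActivityTable]:
    """Restrict both tables to their shared samples, in the peak table's order.

    Matching is by identifier, never by row position. Dropped samples are
    logged. Idempotent: aligning an aligned pair is the identity.
    """
    shared = [s for s in peaks.sample_ids if s in set(acts.sample_ids)]
    if not shared:
        raise AlignmentError(
            "no shared sample ids between peak and activity tables"
        )
    dropped = (set(peaks.sample_ids) | set(acts.sample_ids)) - set(shared)
    if dropped:
        logger.info("align_tables dropped %d sample(s): %s",
                    len(dropped), sorted(dropped))
    return (
        PeakTable(peaks.data.loc[shared], compound_meta=peaks.compound_meta),
        ActivityTable(acts.data.loc[shared]),
    )


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the bundled worked-example tables.

    ``table2_grd`` — grey relational degree of the 22 study peaks against the
    DPPH, FRAP and anti-inflammatory assays. ``table3_antioxidant`` /
    ``table4_antiinflammatory`` — printed VIP and standardized-coefficient
    values for the peaks the antioxidant and anti-inflammatory models listed.
    Peak ids come back as the index (strings).
    """
    if name not in _FIXTURES:
        raise LookupError_(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        )
    ref = resources.files("phytomarker.data") / _FIXTURES[name]
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, index_col=0)
    df.index = [str(i) for i in df.index]
    return df
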