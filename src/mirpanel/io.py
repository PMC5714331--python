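"""Tabular I/O for RT-qPCR miRNA panel data.

The panel format mirrors vendor exports of serum/plasma focus panels: a
rectangular tab- (or comma-) delimited table with one header row of sample
ids and a first column of assay ids (rows = assays, columns = samples).
Undetected reactions are encoded by configurable tokens; in memory they are
an explicit missing state (NaN), never a sentinel cycle number.
"""

from __future__ import annotations

import csv
import io as _io
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

#: Diagnostic group labels: normal glucose tolerance, impaired glucose
#: tolerance split into non-progressors and progressors (by diabetes
#: diagnosis during follow-up), and newly diagnosed type 2 diabetes.
GROUPS = ("NGT", "NP_IGT", "P_IGT", "T2D")

#: Three-level grouping with the IGT umbrella pooling NP_IGT and P_IGT.
GROUPS3 = ("NGT", "IGT", "T2D")

DEFAULT_UNDETECTED_TOKENS = frozenset({"", "NA", "Undetermined"})

CT_MAX = 50.0


class FormatError(ValueError):
    """Malformed input table (ragged rows, unparseable cells)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


def group3(group: str) -> str:
    """Collapse the four-level group label onto the NGT/IGT/T2D axis."""
    if group in ("NP_IGT", "P_IGT", "IGT"):
        return "IGT"
    if group in GROUPS3:
        return group
    raise ValidationError(f"unknown group label: {group!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CtMatrix:
    """Assay x sample grid of quantification-cycle (Ct/Cq) values.

    ``ct`` is a float array of shape (n_assays, n_samples); undetected
    reactions are ``NaN``. Detected values must be finite and in (0, 50].
    """

    assay_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise ValidationError(
                f"ct grid shape {self.ct.shape} does not match "
                f"{len(self.assay_ids)} assays x {len(self.sample_ids)} samples"
            )
        _check_unique(self.assay_ids, "assay")
        _check_unique(self.sample_ids, "sample")
        detected = self.ct[~np.isnan(self.ct)]
        if detected.size and (
            not np.all(np.isfinite(detected))
            or np.any(detected <= 0.0)
            or np.any(detected > CT_MAX)
        ):
            raise ValidationError(
                f"detected Ct values must be finite and in (0, {CT_MAX}]"
            )

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of detected cells."""
        return ~np.isnan(self.ct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.assay_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CtMatrix":
        return cls(
            assay_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            ct=frame.to_numpy(dtype=float),
        )

    def assay_index(self, assay_id: str) -> int:
        try:
            return self.assay_ids.index(assay_id)
        except ValueError:
            raise ValidationError(f"assay {assay_id!r} not in panel") from None

    def row(self, assay_id: str) -> np.ndarray:
        return self.ct[self.assay_index(assay_id)]

    def copy(self) -> "CtMatrix":
        return CtMatrix(list(self.assay_ids), list(self.sample_ids), self.ct.copy())


@dataclass
class SampleAnnotation:
    """Per-sample metadata: progression group, sex, clinical covariates.

    ``clinical`` maps a covariate name (e.g. ``"OGTT glucose (mg/dL)"``) to a
    non-negative value; missing covariates are simply absent (or NaN).
    """

    sample_id: str
    group: str
    sex: str | None = None
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group {self.group!r} not one of {GROUPS}"
            )
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        for name, value in self.clinical.items():
            if value is not None and not math.isnan(value) and value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: clinical {name!r} negative ({value})"
                )

    @property
    def group3(self) -> str:
        return group3(self.group)


@dataclass
class AssayQCMetadata:
    """Per-assay amplification QC: efficiency, melt flag, negative control."""

    assay_id: str
    efficiency: float
    melt_ok: bool
    negctrl_ct: float = float("nan")  # NaN = negative control undetected

    def __post_init__(self) -> None:
        if not (self.efficiency > 0):
            raise ValidationError(
                f"assay {self.assay_id!r}: efficiency must be > 0"
            )
        if not math.isnan(self.negctrl_ct) and not (0 < self.negctrl_ct <= CT_MAX):
            raise ValidationError(
                f"assay {self.assay_id!r}: negctrl_ct out of (0, {CT_MAX}]"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def _open(source: str | os.PathLike | TextIO) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "r", encoding="utf-8", newline=""), True


def read_ct_table(
    source: str | os.PathLike | TextIO,
    dialect: str = "tab",
    undetected_tokens: Iterable[str] = DEFAULT_UNDETECTED_TOKENS,
    ct_ceiling: float | None = None,
    transpose: bool = False,
) -> CtMatrix:
    """Parse a rectangular Ct table into a :class:`CtMatrix`.

    Parameters
    ----------
    source
        Path or open text stream. First row: sample ids (first cell is a
        corner label and is ignored); first column: assay ids.
    dialect
        ``"tab"`` or ``"csv"``.
    undetected_tokens
        Cell strings mapped to the undetected state (case-sensitive after
        stripping whitespace).
    ct_ceiling
        Optional threshold: detected values >= this are mapped to
        undetected (some instruments export a ceiling cycle instead of a
        blank). Default: no ceiling.
    transpose
        Set when the file is samples x assays instead of assays x samples.
    """
    if dialect not in ("tab", "csv"):
        raise ValueError(f"dialect must be 'tab' or 'csv', got {dialect!r}")
    delim = "\t" if dialect == "tab" else ","
    tokens = {t.strip() for t in undetected_tokens}

    handle, close = _open(source)
    try:
        reader = csv.reader(handle, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty table") from None
        ncol = len(header)
        if ncol < 2:
            raise FormatError("header row has no sample columns")
        col_ids = [c.strip() for c in header[1:]]
        row_ids: list[str] = []
        values: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise FormatError(
                    f"row {lineno}: expected {ncol} columns, found {len(row)}"
                )
            row_ids.append(row[0].strip())
            parsed: list[float] = []
            for j, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell in tokens:
                    parsed.append(float("nan"))
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"row {lineno}, column {j}: unparseable Ct {cell!r}"
                    ) from None
                if ct_ceiling is not None and v >= ct_ceiling:
                    v = float("nan")
                parsed.append(v)
            values.append(parsed)
    finally:
        if close:
            handle.close()

    grid = np.array(values, dtype=float) if values else np.empty((0, len(col_ids)))
    if transpose:
        grid = grid.T
        row_ids, col_ids = col_ids, row_ids
    return CtMatrix(assay_ids=row_ids, sample_ids=col_ids, ct=grid)


def write_ct_table(
    ct: CtMatrix,
    dest: str | os.PathLike | TextIO,
    dialect: str = "tab",
    undetected_token: str = "NA",
    precision: int = 4,
) -> None:
    """Write a Ct table in the same layout :func:`read_ct_table` expects."""
    delim = "\t" if dialect == "tab" else ","
    if hasattr(dest, "write"):
        handle, close = dest, False
    else:
        handle, close = open(dest, "w", encoding="utf-8", newline=""), True
    try:
        writer = csv.writer(handle, delimiter=delim, lineterminator="\n")
        writer.writerow(["assay_id", *ct.sample_ids])
        for i, assay in enumerate(ct.assay_ids):
            cells = [
                undetected_token if np.isnan(v) else f"{v:.{precision}f}"
                for v in ct.ct[i]
            ]
            writer.writerow([assay, *cells])
    finally:
        if close:
            handle.close()


#: Column names accepted for the annotation TSV, in canonical order.
ANNOTATION_REQUIRED = ("sample_id", "group")


def read_annotations(
    source: str | os.PathLike | TextIO,
    ct: CtMatrix | None = None,
) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (one row per sample).

    Required columns: ``sample_id``, ``group``; optional ``sex``; every
    other column is treated as a numeric clinical covariate (empty cells
    become missing, never zero). If ``ct`` is given, sample ids absent from
    the Ct matrix are reported via a logger warning, not an error.
    """
    import logging

    handle, close = _open(source)
    try:
        frame = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    for col in ANNOTATION_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"annotation file missing required column {col!r}")
    clinical_cols = [
        c for c in frame.columns if c not in ("sample_id", "group", "sex")
    ]
    annotations: list[SampleAnnotation] = []
    for rowno, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        clinical: dict[str, float] = {}
        for col in clinical_cols:
            cell = record[col].strip()
            if cell == "" or cell in ("NA", "nan"):
                continue  # missing, not zero
            try:
                clinical[col] = float(cell)
            except ValueError:
                raise FormatError(
                    f"annotation row {rowno}, column {col!r}: "
                    f"unparseable numeric {cell!r}"
                ) from None
        sex = record.get("sex", "").strip() or None
        annotations.append(
            SampleAnnotation(
                sample_id=record["sample_id"].strip(),
                group=record["group"].strip(),
                sex=sex,
                clinical=clinical,
            )
        )
    _check_unique([a.sample_id for a in annotations], "sample")
    if ct is not None:
        known = set(ct.sample_ids)
        orphans = [a.sample_id for a in annotations if a.sample_id not in known]
        if orphans:
            logging.getLogger(__name__).warning(
                "annotation samples absent from Ct matrix: %s", ", ".join(orphans)
            )
    return annotations


def read_qc_metadata(source: str | os.PathLike | TextIO) -> list[AssayQCMetadata]:
    """Read per-assay QC metadata TSV.

    Columns: ``assay_id``, ``efficiency``, ``melt_ok`` (true/false/1/0),
    ``negctrl_ct`` (may be an undetected token).
    """
    handle, close = _open(source)
    try:
        frame = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    for col in ("assay_id", "efficiency", "melt_ok"):
        if col not in frame.columns:
            raise FormatError(f"QC metadata missing required column {col!r}")
    out: list[AssayQCMetadata] = []
    for row in frame.itertuples(index=False):
        record = dict(zip(frame.columns, row))
        melt = record["melt_ok"].strip().lower()
        if melt not in ("true", "false", "1", "0"):
            raise FormatError(
                f"assay {record['assay_id']!r}: melt_ok must be boolean, "
                f"got {record['melt_ok']!r}"
            )
        neg = record.get("negctrl_ct", "").strip()
        neg_ct = float("nan") if neg in ("", "NA", "Undetermined") else float(neg)
        out.append(
            AssayQCMetadata(
                assay_id=record["assay_id"].strip(),
                efficiency=float(record["efficiency"]),
                melt_ok=melt in ("true", "1"),
                negctrl_ct=neg_ct,
            )
        )
    _check_unique([m.assay_id for m in out], "assay")
    return out


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
) -> list[Path]:
    """Write result tables as tab-delimited UTF-8 files with one header row.

    Returns the list of written paths (one per requested table, in input
    order); output is deterministic for identical inputs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    manifest: list[Path] = []
    for name, frame in tables.items():
        path = out / f"{name}.tsv"
        buffer = _io.StringIO()
        frame.to_csv(buffer, sep="\t", na_rep="NA", index=False, lineterminator="\n")
        path.write_text(buffer.getvalue(), encoding="utf-8")
        manifest.append(path)
    return manifest
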