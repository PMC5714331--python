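"""Assay-level quality control for miRNA qPCR panels.

Filters follow standard vendor-panel practice: an assay (or cell) is
discarded when the melting curve is out of specification, when the
amplification efficiency is below 1.6, or when the measured Ct comes within
a safety margin (default 5 cycles) of the assay's negative control.
Detection summaries, the miR-23a/miR-451a hemolysis indicator and RNA
spike-in ladder checks complete the pre-normalization battery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssayQCMetadata, CtMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Removal reasons, in precedence order (an assay gets exactly one).
REASON_MULTI_MELT = "multi_melt"
REASON_LOW_EFFICIENCY = "low_efficiency"
REASON_NEAR_NEGCTRL = "near_negative_control"

#: 100-fold dilution spacing of the extraction spike-in ladder, in cycles,
#: at amplification efficiency 2: log2(100).
LADDER_SPACING = math.log2(100.0)

HEMOLYSIS_TARGET = "hsa-miR-23a-3p"
HEMOLYSIS_MARKER = "hsa-miR-451a"
EXTRACTION_SPIKEINS = ("UniSp2", "UniSp4", "UniSp5")
RT_SPIKEIN = "UniSp6"


@dataclass
class QCReport:
    """Outcome of the QC battery.

    ``removed`` rows are ``(assay_id, sample_id or None, reason)`` — a
    ``None`` sample means the whole assay row was removed.
    """

    removed: list[tuple[str, str | None, str]] = field(default_factory=list)
    detected_per_sample: dict[str, int] = field(default_factory=dict)
    coexpressed_set: list[str] = field(default_factory=list)
    hemolysis: dict[str, float] = field(default_factory=dict)
    spikein_flags: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"assay_id": a, "sample_id": s if s is not None else "ALL",
                 "action": "removed", "reason": r}
                for a, s, r in self.removed
            ],
            columns=["assay_id", "sample_id", "action", "reason"],
        )


def apply_assay_qc(
    ct: CtMatrix,
    meta: list[AssayQCMetadata],
    margin: float = 5.0,
    min_efficiency: float = 1.6,
    scope: str = "cell",
) -> tuple[CtMatrix, QCReport]:
    """Apply melt / efficiency / negative-control filters.

    Melt failure and low efficiency are assay-level properties and always
    remove the whole assay row. The negative-control rule (detected Ct
    within ``margin`` cycles of the assay's negative control, i.e.
    ``Ct >= negctrl_ct - margin``) is applied per cell when
    ``scope="cell"`` (default) or removes the whole assay on any violation
    when ``scope="assay"``. Assays whose negative control is undetected
    pass the margin rule. Efficiency removal is strict: ``< min_efficiency``
    fails, equality passes.
    """
    if scope not in ("cell", "assay"):
        raise ValueError(f"scope must be 'cell' or 'assay', got {scope!r}")
    by_assay = {m.assay_id: m for m in meta}
    missing = [a for a in ct.assay_ids if a not in by_assay]
    if missing:
        raise ValidationError(
            "QC metadata missing for assays: " + ", ".join(missing)
        )

    out = ct.copy()
    report = QCReport()
    for i, assay in enumerate(ct.assay_ids):
        m = by_assay[assay]
        if not m.melt_ok:
            out.ct[i, :] = np.nan
            report.removed.append((assay, None, REASON_MULTI_MELT))
            continue
        if m.efficiency < min_efficiency:
            out.ct[i, :] = np.nan
            report.removed.append((assay, None, REASON_LOW_EFFICIENCY))
            continue
        if math.isnan(m.negctrl_ct):
            continue
        near = ct.detected[i] & (ct.ct[i] >= m.negctrl_ct - margin)
        if not near.any():
            continue
        if scope == "assay":
            out.ct[i, :] = np.nan
            report.removed.append((assay, None, REASON_NEAR_NEGCTRL))
        else:
            for j in np.flatnonzero(near):
                out.ct[i, j] = np.nan
                report.removed.append(
                    (assay, ct.sample_ids[j], REASON_NEAR_NEGCTRL)
                )
    counts, coexpressed = detection_summary(out)
    report.detected_per_sample = counts
    report.coexpressed_set = coexpressed
    return out, report


def detection_summary(ct: CtMatrix) -> tuple[dict[str, int], list[str]]:
    """Per-sample detected-assay counts and the co-expressed set.

    The co-expressed set is the list of assays detected in every sample;
    it is the candidate pool for global-mean normalization.
    """
    mask = ct.detected
    counts = {s: int(mask[:, j].sum()) for j, s in enumerate(ct.sample_ids)}
    coexpressed = [a for i, a in enumerate(ct.assay_ids) if mask[i].all()]
    return counts, coexpressed


@dataclass
class HemolysisResult:
    delta_ct: dict[str, float]          # sample -> Ct(target) - Ct(marker)
    flagged: list[str]                  # samples with delta_ct > threshold
    kruskal_h: float | None = None      # across-group test (3-level axis)
    kruskal_p: float | None = None


def hemolysis_delta_ct(
    ct: CtMatrix,
    target: str = HEMOLYSIS_TARGET,
    marker: str = HEMOLYSIS_MARKER,
    warn_threshold: float = 7.0,
    annotations=None,
) -> HemolysisResult:
    """Hemolysis indicator: ΔCt = Ct(miR-23a-3p) − Ct(miR-451a).

    miR-451a is highly abundant in erythrocytes, so red-cell lysis lowers
    its Ct and inflates ΔCt; ΔCt above ``warn_threshold`` (7 cycles by
    common convention) flags the sample. When ``annotations`` are given,
    ΔCt is compared across the NGT/IGT/T2D axis by Kruskal–Wallis.
    """
    t_row = ct.row(target)
    m_row = ct.row(marker)
    delta: dict[str, float] = {}
    for j, sample in enumerate(ct.sample_ids):
        if np.isnan(t_row[j]) or np.isnan(m_row[j]):
            delta[sample] = float("nan")
        else:
            delta[sample] = float(t_row[j] - m_row[j])
    flagged = [
        s for s, d in delta.items() if not math.isnan(d) and d > warn_threshold
    ]
    result = HemolysisResult(delta_ct=delta, flagged=flagged)
    if annotations is not None:
        from .coregulation import kruskal_wallis

        by_sample = {a.sample_id: a.group3 for a in annotations}
        values, groups = [], []
        for s, d in delta.items():
            if not math.isnan(d) and s in by_sample:
                values.append(d)
                groups.append(by_sample[s])
        if len(set(groups)) >= 2:
            h, p = kruskal_wallis(np.asarray(values), groups)
            result.kruskal_h, result.kruskal_p = h, p
    return result


def spikein_check(
    spikein_cts: pd.DataFrame,
    spacing_tol: float = 1.0,
    rt_band: float = 2.0,
) -> dict[str, list[str]]:
    """Check extraction and reverse-transcription spike-ins.

    ``spikein_cts``: rows indexed by spike-in name (UniSp2/4/5 at 100-fold
    concentration steps, UniSp6 added at reverse transcription), columns =
    samples. Extraction check: each consecutive ladder step should be
    ≈ log2(100) ≈ 6.64 cycles; deviations beyond ``spacing_tol`` warn.
    RT check: UniSp6 within ``rt_band`` cycles of the cohort median.
    Absent spike-ins skip their check with a log notice.
    """
    warnings: dict[str, list[str]] = {s: [] for s in spikein_cts.columns}
    ladder = [s for s in EXTRACTION_SPIKEINS if s in spikein_cts.index]
    if len(ladder) < 2:
        logger.info("extraction spike-in ladder absent; check skipped")
    else:
        for sample in spikein_cts.columns:
            cts = spikein_cts.loc[ladder, sample].to_numpy(dtype=float)
            for k in range(len(ladder) - 1):
                spacing = cts[k + 1] - cts[k]
                if math.isnan(spacing):
                    continue
                if abs(spacing - LADDER_SPACING) > spacing_tol:
                    warnings[sample].append(
                        f"extraction ladder {ladder[k]}->{ladder[k+1]} spacing "
                        f"{spacing:.2f} deviates from {LADDER_SPACING:.2f} "
                        f"by more than {spacing_tol}"
                    )
    if RT_SPIKEIN not in spikein_cts.index:
        logger.info("RT spike-in %s absent; check skipped", RT_SPIKEIN)
    else:
        row = spikein_cts.loc[RT_SPIKEIN].to_numpy(dtype=float)
        median = float(np.nanmedian(row))
        for sample, v in zip(spikein_cts.columns, row):
            if not math.isnan(v) and abs(v - median) > rt_band:
                warnings[sample].append(
                    f"{RT_SPIKEIN} Ct {v:.2f} outside ±{rt_band} of cohort "
                    f"median {median:.2f}"
                )
    return warnings
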