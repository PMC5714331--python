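"""Clinical-statistics utilities for the cohort table and miRNA links.

Covers the group-comparison battery used for baseline clinical tables:
one-way ANOVA reconstructed exactly from printed group means/SDs/sizes,
Fisher's exact test for r x c contingency tables (complete enumeration of
tables with fixed margins), the HOMA-IR insulin-resistance index in both
the mg/dL-with-22.5 convention (as sometimes printed) and the conventional
definition, a skewness-routed per-variable summary table, and the Spearman
correlation map between signature miRNAs and clinical covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleAnnotation, ValidationError
from .normalization import NrqMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# One-way ANOVA from summary statistics
# ---------------------------------------------------------------------------

def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, int, int, float]:
    """One-way ANOVA (F, df1, df2, p) from group means, SDs and sizes.

    SS_between = sum n_i (mean_i − grand_mean)^2 with the size-weighted
    grand mean; SS_within = sum (n_i − 1) sd_i^2. Exactly equivalent to the
    classical ANOVA on raw data when the summaries are exact. A degenerate
    zero within-group variance with non-zero between-group spread reports
    p = 0.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if means.size < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if np.any(ns < 2):
        raise ValidationError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ValidationError("standard deviations must be >= 0")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1 = means.size - 1
    df2 = n_total - means.size
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        logger.warning("ANOVA degenerate: zero within-group variance")
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables
# ---------------------------------------------------------------------------

_MAX_TABLES = 5_000_000


def fisher_exact_rxc(counts: Sequence[Sequence[int]]) -> float:
    """Exact conditional p for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one (the standard two-sided conditional exact test;
    no mid-p). All-zero rows/columns are dropped before enumeration. Raises
    if the enumeration would exceed an internal size cap.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValidationError("contingency table must be 2-d")
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValidationError("counts must be non-negative integers")
    table = table.astype(np.int64)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 2:
        return 1.0  # degenerate after margin reduction: nothing to test
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())

    # crude enumeration-size bound
    bound = 1.0
    for r in row_sums[:-1]:
        for c in col_sums[:-1]:
            bound *= min(r, c) + 1
    if bound > _MAX_TABLES:
        raise ValidationError(
            f"table too large for exact enumeration (~{bound:.2g} candidate "
            "tables); use a Monte-Carlo approximation instead"
        )

    lgam = math.lgamma
    log_const = (
        sum(lgam(r + 1) for r in row_sums)
        + sum(lgam(c + 1) for c in col_sums)
        - lgam(n + 1)
    )

    def log_prob(cells: np.ndarray) -> float:
        return log_const - sum(lgam(v + 1) for v in cells.ravel())

    obs_lp = log_prob(table)
    tol = 1e-10  # ties at the observed probability count as "as extreme"

    r_rows, r_cols = table.shape
    total_p = 0.0

    # depth-first over cells in row-major order with remaining margins
    cells = np.zeros((r_rows, r_cols), dtype=np.int64)

    def rec(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray) -> None:
        nonlocal total_p
        if i == r_rows - 1:
            # last row fully determined by the remaining column margins
            cells[i, :] = col_left
            lp = log_prob(cells)
            if lp <= obs_lp + tol:
                total_p += math.exp(lp)
            return
        if j == r_cols - 1:
            # last column of a row determined by the row margin
            v = row_left[i]
            if v <= col_left[j]:
                cells[i, j] = v
                col_left[j] -= v
                rec(i + 1, 0, row_left, col_left)
                col_left[j] += v
            return
        upper = min(row_left[i], col_left[j])
        for v in range(upper + 1):
            cells[i, j] = v
            row_left[i] -= v
            col_left[j] -= v
            rec(i, j + 1, row_left, col_left)
            row_left[i] += v
            col_left[j] += v

    rec(0, 0, row_sums.copy(), col_sums.copy())
    return float(min(1.0, total_p))


# ---------------------------------------------------------------------------
# HOMA-IR
# ---------------------------------------------------------------------------

def homa_ir(
    fasting_glucose: float, insulin: float, convention: str = "conventional"
) -> float:
    """Homeostasis-model insulin-resistance index.

    ``conventional``: glucose (mg/dL) x insulin (mU/L) / 405, i.e. the
    usual mmol/L x mU/L / 22.5 definition. ``paper``: glucose (mg/dL) x
    insulin / 22.5 as occasionally printed in clinical methods sections;
    the two differ by exactly the mg/dL-to-mmol/L factor 18.
    """
    if fasting_glucose <= 0 or insulin <= 0:
        raise ValidationError("glucose and insulin must be positive")
    if convention == "paper":
        return fasting_glucose * insulin / 22.5
    if convention == "conventional":
        return fasting_glucose * insulin / 405.0
    raise ValueError(f"unknown HOMA convention {convention!r}")


# ---------------------------------------------------------------------------
# Per-variable clinical summary table
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatRow:
    variable: str
    per_group: dict[str, tuple[float, float, int]]  # group -> (mean, sd, n)
    test: str                                       # anova | kruskal_wallis
    p: float


def clinical_table(
    annotations: Sequence[SampleAnnotation],
    variables: Sequence[str] | None = None,
    levels: str = "three",
    skew_threshold: float = 1.0,
    max_missing_frac: float = 0.5,
) -> list[SummaryStatRow]:
    """Group means/SDs and a between-group test per clinical variable.

    Test routing: Kruskal–Wallis when any group's sample skewness exceeds
    ``skew_threshold`` in absolute value (a pragmatic stand-in for the
    usual "skewed distribution" criterion), ANOVA otherwise. Variables
    missing in more than ``max_missing_frac`` of samples are excluded with
    a warning. p is computed on the raw per-sample values.
    """
    from .coregulation import kruskal_wallis

    if variables is None:
        seen: list[str] = []
        for a in annotations:
            for v in a.clinical:
                if v not in seen:
                    seen.append(v)
        variables = seen
    group_key = (lambda a: a.group3) if levels == "three" else (lambda a: a.group)
    rows: list[SummaryStatRow] = []
    n_samples = len(annotations)
    for var in variables:
        values, labels = [], []
        for a in annotations:
            v = a.clinical.get(var)
            if v is None or np.isnan(v):
                continue
            values.append(float(v))
            labels.append(group_key(a))
        if len(values) < (1.0 - max_missing_frac) * n_samples:
            logger.warning("variable %r missing in >50%% of samples; excluded", var)
            continue
        values_arr = np.asarray(values)
        uniq = sorted(set(labels))
        per_group: dict[str, tuple[float, float, int]] = {}
        skewed = False
        group_arrays = []
        for g in uniq:
            gv = values_arr[np.asarray(labels) == g]
            group_arrays.append(gv)
            per_group[g] = (
                float(gv.mean()),
                float(gv.std(ddof=1)) if gv.size > 1 else 0.0,
                int(gv.size),
            )
            if gv.size >= 3 and gv.std(ddof=1) > 0:
                if abs(float(stats.skew(gv, bias=False))) > skew_threshold:
                    skewed = True
        if np.ptp(values_arr) == 0:
            test, p = ("kruskal_wallis" if skewed else "anova"), 1.0
        elif skewed:
            test = "kruskal_wallis"
            _, p = kruskal_wallis(values_arr, labels)
        else:
            test = "anova"
            if any(gv.size < 2 for gv in group_arrays):
                _, p = kruskal_wallis(values_arr, labels)
                test = "kruskal_wallis"
            else:
                _, _, _, p = anova_from_summary(
                    [gv.mean() for gv in group_arrays],
                    [gv.std(ddof=1) for gv in group_arrays],
                    [gv.size for gv in group_arrays],
                )
        rows.append(SummaryStatRow(variable=var, per_group=per_group, test=test, p=p))
    return rows


def clinical_table_frame(rows: Sequence[SummaryStatRow]) -> pd.DataFrame:
    groups = sorted({g for r in rows for g in r.per_group})
    records = []
    for r in rows:
        rec: dict[str, object] = {"variable": r.variable}
        for g in groups:
            mean, sd, n = r.per_group.get(g, (np.nan, np.nan, 0))
            rec[f"{g}_mean"] = mean
            rec[f"{g}_sd"] = sd
            rec[f"{g}_n"] = n
        rec["test"] = r.test
        rec["p"] = r.p
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# miRNA vs clinical-covariate correlation map
# ---------------------------------------------------------------------------

@dataclass
class ClinicalCorrelationMap:
    rows: list[str]
    cols: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at p <= alpha

    def filtered(self, min_significant: int = 2) -> "ClinicalCorrelationMap":
        keep = self.significant.sum(axis=1) >= min_significant
        kept = [a for a in self.rows if keep[a]]
        return ClinicalCorrelationMap(
            rows=kept,
            cols=list(self.cols),
            r=self.r.loc[kept],
            p=self.p.loc[kept],
            significant=self.significant.loc[kept],
        )


def clinical_correlation_map(
    lognrq: NrqMatrix,
    annotations: Sequence[SampleAnnotation],
    signature: Sequence[str],
    variables: Sequence[str],
    alpha: float = 0.05,
    min_significant: int | None = 2,
) -> ClinicalCorrelationMap:
    """Spearman r and p per (signature miRNA, clinical covariate).

    Each pair uses every sample with both values defined. By default only
    miRNAs significantly correlated (p <= alpha) with at least two
    covariates are retained; pass ``min_significant=None`` to keep all.
    """
    from .coregulation import ConstantInputWarning, spearman
    import warnings as _warnings

    signature = sorted(signature)
    if not signature or not variables:
        raise ValidationError("signature and variables must be non-empty")
    by_sample = {a.sample_id: a for a in annotations}
    available = {
        v for a in annotations for v in a.clinical
    }
    missing_vars = [v for v in variables if v not in available]
    if missing_vars:
        raise ValidationError(
            "clinical variables absent from annotations: " + ", ".join(missing_vars)
        )
    r = pd.DataFrame(np.nan, index=signature, columns=list(variables))
    p = pd.DataFrame(np.nan, index=signature, columns=list(variables))
    frame = lognrq.to_frame()
    for assay in signature:
        row = frame.loc[assay]
        for var in variables:
            xs, ys = [], []
            for s in lognrq.sample_ids:
                ann = by_sample.get(s)
                v = None if ann is None else ann.clinical.get(var)
                q = row[s]
                if v is None or np.isnan(v) or np.isnan(q):
                    continue
                xs.append(q)
                ys.append(v)
            if len(xs) < 3:
                continue
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", ConstantInputWarning)
                r.loc[assay, var], p.loc[assay, var] = spearman(xs, ys)
    sig = (p <= alpha).fillna(False)
    cmap = ClinicalCorrelationMap(
        rows=signature, cols=list(variables), r=r, p=p, significant=sig
    )
    if min_significant is not None:
        cmap = cmap.filtered(min_significant)
    return cmap
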