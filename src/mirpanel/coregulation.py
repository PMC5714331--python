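"""Co-regulation structure diagnostics and the shared rank-statistics kernel.

Circulating miRNAs measured on one plasma sample share a strong common
component (total miRNA concentration). These diagnostics quantify that
coupling per diagnostic group: each miRNA's Spearman correlation with the
per-sample global mean, the full pairwise Spearman map, the trend of the
global quantity against clinical covariates, and per-group OLS slopes of a
single assay's Ct against the global mean ("local vs global" coupling).

Rank statistics use average ranks for ties throughout; Kruskal–Wallis uses
the tie-corrected H, and Dunn's post hoc test uses the pooled-rank z with
tie correction and a configurable multiplicity adjustment over the
requested comparison family.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtMatrix, SampleAnnotation, ValidationError
from .normalization import global_mean

logger = logging.getLogger(__name__)


class ConstantInputWarning(UserWarning):
    """A correlation input was constant; the coefficient is undefined."""


# ---------------------------------------------------------------------------
# Rank-statistics kernel
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (average ranks for ties).

    A constant input leaves r undefined: returns (nan, nan) and emits
    :class:`ConstantInputWarning` rather than silently reporting 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two 1-d arrays of equal length")
    if x.size < 3:
        raise ValidationError("spearman needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("spearman inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        _warnings.warn(
            "constant input: Spearman r undefined", ConstantInputWarning,
            stacklevel=2,
        )
        return float("nan"), float("nan")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-squared p on k−1 df.

    All observations identical is a degenerate, not an error: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValidationError("values and groups must have equal length")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise ValidationError("kruskal_wallis needs >= 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) < 1 for s in samples):
        raise ValidationError("every group needs >= 1 observation")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    comparisons: Sequence[tuple[str, str]],
    adjust: str = "bonferroni",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's multiple-comparison test on pooled ranks.

    For each requested ``(group, reference)`` pair:

        z = (R̄_g − R̄_ref) / sqrt( (N(N+1)/12 − T) (1/n_g + 1/n_ref) )

    with tie correction ``T = Σ(t³−t) / (12(N−1))`` over tied values in the
    pooled sample; two-sided normal p, adjusted over the requested family
    (``bonferroni`` default, ``holm`` or ``sidak``).
    """
    if adjust not in ("bonferroni", "holm", "sidak"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = set(labels.tolist())
    for a, b in comparisons:
        if a not in uniq or b not in uniq:
            raise ValidationError(f"unknown group in comparison ({a!r}, {b!r})")
    n_total = values.size
    ranks = stats.rankdata(values)  # average ranks
    # tie correction over pooled values
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1))) \
        if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    raw: list[float] = []
    zs: list[float] = []
    for a, b in comparisons:
        ia = labels == a
        ib = labels == b
        na, nb = int(ia.sum()), int(ib.sum())
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        diff = ranks[ia].mean() - ranks[ib].mean()
        z = 0.0 if se == 0 else diff / se
        p = 2.0 * stats.norm.sf(abs(z))
        zs.append(float(z))
        raw.append(float(min(1.0, p)))

    m = len(comparisons)
    if adjust == "bonferroni":
        adj = [min(1.0, p * m) for p in raw]
    elif adjust == "sidak":
        adj = [min(1.0, 1.0 - (1.0 - p) ** m) for p in raw]
    else:  # holm step-down
        order = np.argsort(raw)
        adj_arr = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * raw[idx])
            adj_arr[idx] = min(1.0, running)
        adj = adj_arr.tolist()
    return {
        comp: (z, p_adj) for comp, z, p_adj in zip(comparisons, zs, adj)
    }


# ---------------------------------------------------------------------------
# Structure diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CorrelationProfile:
    group: str
    per_miRNA_r: dict[str, float]
    mean_r: float
    pairwise_r: pd.DataFrame


@dataclass
class SlopeFit:
    assay_id: str
    group: str
    slope: float
    intercept: float
    n: int


def _groups_of(
    annotations: Sequence[SampleAnnotation], levels: str = "three"
) -> dict[str, str]:
    if levels == "three":
        return {a.sample_id: a.group3 for a in annotations}
    return {a.sample_id: a.group for a in annotations}


def group_quantity_trend(
    ct: CtMatrix,
    annotations: Sequence[SampleAnnotation],
    coexpressed_set: Sequence[str],
    clinical_vars: Sequence[str] = ("ogtt_glucose_mg_dl", "hba1c_mmol_mol"),
) -> dict[str, tuple[float, float]]:
    """Spearman of the reversed-Ct global mean against clinical covariates.

    The global mean is negated so that higher values mean more circulating
    miRNA; samples missing a covariate are dropped with a log notice.
    """
    gm = global_mean(ct, coexpressed_set)
    by_sample = {a.sample_id: a for a in annotations}
    out: dict[str, tuple[float, float]] = {}
    for var in clinical_vars:
        xs, ys = [], []
        dropped = []
        for s in ct.sample_ids:
            ann = by_sample.get(s)
            v = None if ann is None else ann.clinical.get(var)
            if v is None or np.isnan(v):
                dropped.append(s)
                continue
            xs.append(-gm[s])
            ys.append(v)
        if dropped:
            logger.info(
                "trend vs %s: dropped samples without value: %s",
                var, ", ".join(dropped),
            )
        out[var] = spearman(xs, ys)
    return out


def correlation_profiles(
    ct: CtMatrix,
    annotations: Sequence[SampleAnnotation],
    coexpressed_set: Sequence[str],
    levels: str = "three",
    reference: str = "IGT",
    min_samples: int = 3,
    dunn_adjust: str = "bonferroni",
) -> tuple[dict[str, CorrelationProfile], dict]:
    """Per-group co-regulation profiles and a cross-group comparison.

    For each group separately: Spearman of each co-expressed miRNA's Ct
    against the per-sample global-mean Ct over that group's samples, and
    the full pairwise Spearman map. The per-miRNA r distributions are then
    compared across groups by Kruskal–Wallis with Dunn's test against
    ``reference``. Groups below ``min_samples`` are skipped with a warning.
    """
    gm = global_mean(ct, coexpressed_set)
    membership = _groups_of(annotations, levels)
    sample_pos = {s: j for j, s in enumerate(ct.sample_ids)}
    idx = [ct.assay_index(a) for a in coexpressed_set]

    profiles: dict[str, CorrelationProfile] = {}
    for group in sorted(set(membership.values())):
        cols = [
            sample_pos[s]
            for s in ct.sample_ids
            if membership.get(s) == group
        ]
        if len(cols) < min_samples:
            logger.warning(
                "group %s has %d samples (< %d); skipped", group, len(cols),
                min_samples,
            )
            continue
        block = ct.ct[np.ix_(idx, cols)]
        gm_vec = gm.to_numpy()[cols]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConstantInputWarning)
            per_r = {
                a: spearman(block[i], gm_vec)[0]
                for i, a in enumerate(coexpressed_set)
            }
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rho = stats.spearmanr(block, axis=1).statistic
        rho = np.atleast_2d(rho)
        np.fill_diagonal(rho, 1.0)
        pairwise = pd.DataFrame(
            rho, index=list(coexpressed_set), columns=list(coexpressed_set)
        )
        rs = np.array([v for v in per_r.values() if not np.isnan(v)])
        profiles[group] = CorrelationProfile(
            group=group,
            per_miRNA_r=per_r,
            mean_r=float(rs.mean()) if rs.size else float("nan"),
            pairwise_r=pairwise,
        )

    cross: dict = {}
    if len(profiles) >= 2:
        values, labels = [], []
        for g, prof in profiles.items():
            for r in prof.per_miRNA_r.values():
                if not np.isnan(r):
                    values.append(r)
                    labels.append(g)
        h, p = kruskal_wallis(values, labels)
        cross["kruskal"] = (h, p)
        if reference in profiles:
            comps = [(g, reference) for g in profiles if g != reference]
            cross["dunn_vs_reference"] = dunn_posthoc(
                values, labels, comps, adjust=dunn_adjust
            )
    return profiles, cross


def local_vs_global_slope(
    ct: CtMatrix,
    assay_id: str,
    annotations: Sequence[SampleAnnotation],
    coexpressed_set: Sequence[str],
    levels: str = "three",
    min_samples: int = 3,
) -> dict[str, SlopeFit]:
    """Per-group OLS of one assay's Ct on the per-sample global-mean Ct.

    A slope near 1 means the assay tracks the global miRNA quantity
    one-to-one; attenuation (slope < 1) means its level decouples from the
    global pool. A constant global mean within a group leaves the slope
    undefined (NaN, flagged via log).
    """
    gm = global_mean(ct, coexpressed_set)
    row = ct.row(assay_id)
    membership = _groups_of(annotations, levels)
    sample_pos = {s: j for j, s in enumerate(ct.sample_ids)}
    fits: dict[str, SlopeFit] = {}
    for group in sorted(set(membership.values())):
        cols = [
            sample_pos[s] for s in ct.sample_ids if membership.get(s) == group
        ]
        y = row[cols]
        x = gm.to_numpy()[cols]
        ok = ~np.isnan(y)
        x, y = x[ok], y[ok]
        if x.size < min_samples:
            logger.warning(
                "slope for %s in %s: only %d detected samples (< %d); skipped",
                assay_id, group, x.size, min_samples,
            )
            continue
        if np.ptp(x) == 0:
            logger.warning(
                "slope for %s in %s: constant global mean, slope undefined",
                assay_id, group,
            )
            fits[group] = SlopeFit(assay_id, group, float("nan"), float("nan"),
                                   int(x.size))
            continue
        res = stats.linregress(x, y)
        fits[group] = SlopeFit(
            assay_id=assay_id,
            group=group,
            slope=float(res.slope),
            intercept=float(res.intercept),
            n=int(x.size),
        )
    return fits


def slope_table(fits: Mapping[str, SlopeFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"assay_id": f.assay_id, "group": g, "slope": f.slope,
             "intercept": f.intercept, "n": f.n}
            for g, f in fits.items()
        ],
        columns=["assay_id", "group", "slope", "intercept", "n"],
    )
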