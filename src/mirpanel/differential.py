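"""Differential expression of normalized miRNA quantities across groups.

Per-miRNA two-sided unpaired t tests on log-NRQ values over a lattice of
group contrasts (IGT vs NGT, its NP/P sub-splits, T2D vs NGT, and NP vs P
within IGT), with the conventional star categories (n.s. / * / ** / ***
at p thresholds 0.05 / 0.01 / 0.001). No multiple-testing correction is
applied across miRNAs by default (raw p < 0.05 defines significance); an
optional Benjamini–Hochberg flag is provided for modern use. The union of
significant assays forms the signature used for group-profile clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import SampleAnnotation, ValidationError
from .normalization import NrqMatrix

logger = logging.getLogger(__name__)

#: Contrast name -> (test group selector, reference group selector).
#: Selectors are sets of four-level group labels; the first-named side's
#: mean minus the reference mean gives the reported direction.
CONTRASTS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "IGT_vs_NGT": (frozenset({"NP_IGT", "P_IGT"}), frozenset({"NGT"})),
    "NP_IGT_vs_NGT": (frozenset({"NP_IGT"}), frozenset({"NGT"})),
    "P_IGT_vs_NGT": (frozenset({"P_IGT"}), frozenset({"NGT"})),
    "T2D_vs_NGT": (frozenset({"T2D"}), frozenset({"NGT"})),
    "NP_vs_P_IGT": (frozenset({"NP_IGT"}), frozenset({"P_IGT"})),
}

CATEGORY_NS = "n.s."


def categorize(p: float) -> str:
    """Star category from a two-sided p: ≥0.05 n.s.; <0.05 *; <0.01 **; <0.001 ***."""
    if np.isnan(p):
        return CATEGORY_NS
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return CATEGORY_NS


@dataclass
class ContrastResult:
    assay_id: str
    contrast: str
    t: float
    p: float
    category: str
    direction: int  # sign of (test-group mean − reference mean)


def run_contrasts(
    lognrq: NrqMatrix,
    annotations: Sequence[SampleAnnotation],
    contrasts: Sequence[str] | None = None,
    equal_var: bool = True,
    fdr: bool = False,
) -> list[ContrastResult]:
    """Two-sided unpaired t test per (assay, contrast) on log-NRQ values.

    ``equal_var=True`` gives the classic pooled-variance Student t;
    ``False`` switches to Welch. Assays with fewer than two defined values
    on either side of a contrast are skipped with a log notice. With
    ``fdr=True`` the p-values are Benjamini–Hochberg adjusted within each
    contrast before categorization.
    """
    names = list(contrasts) if contrasts is not None else list(CONTRASTS)
    for name in names:
        if name not in CONTRASTS:
            raise ValidationError(f"unknown contrast label {name!r}")
    group_of = {a.sample_id: a.group for a in annotations}
    cols = np.array([group_of.get(s, "") for s in lognrq.sample_ids])

    results: list[ContrastResult] = []
    for name in names:
        test_sel, ref_sel = CONTRASTS[name]
        test_cols = np.isin(cols, list(test_sel))
        ref_cols = np.isin(cols, list(ref_sel))
        per_contrast: list[ContrastResult] = []
        for i, assay in enumerate(lognrq.assay_ids):
            row = lognrq.lognrq[i]
            a = row[test_cols]
            b = row[ref_cols]
            a = a[~np.isnan(a)]
            b = b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                logger.info(
                    "contrast %s, assay %s: insufficient data (%d vs %d); skipped",
                    name, assay, a.size, b.size,
                )
                continue
            if np.ptp(np.concatenate([a, b])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                t, p = float(t), float(p)
                if np.isnan(t):
                    t, p = 0.0, 1.0
            per_contrast.append(
                ContrastResult(
                    assay_id=assay,
                    contrast=name,
                    t=t,
                    p=p,
                    category=categorize(p),
                    direction=int(np.sign(a.mean() - b.mean())),
                )
            )
        if fdr and per_contrast:
            ps = np.array([r.p for r in per_contrast])
            order = np.argsort(ps)
            m = ps.size
            adj = np.empty(m)
            running = 1.0
            for rank_i in range(m - 1, -1, -1):
                idx = order[rank_i]
                running = min(running, ps[idx] * m / (rank_i + 1))
                adj[idx] = running
            for r, q in zip(per_contrast, adj):
                r.p = float(q)
                r.category = categorize(r.p)
        results.extend(per_contrast)
    return results


def select_signature(results: Sequence[ContrastResult]) -> set[str]:
    """Assays significant (category != n.s.) in at least one contrast."""
    if not results:
        raise ValidationError("no contrast results to select from")
    return {r.assay_id for r in results if r.category != CATEGORY_NS}


def contrast_table(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Wide table mirroring the usual publication layout: rows = miRNAs,
    one category column and one p column per contrast."""
    order = list(CONTRASTS)
    names = sorted(
        {r.contrast for r in results},
        key=lambda c: (order.index(c), "") if c in order else (len(order), c),
    )
    assays = sorted({r.assay_id for r in results})
    by_key = {(r.assay_id, r.contrast): r for r in results}
    rows = []
    for a in assays:
        row: dict[str, object] = {"assay_id": a}
        for c in names:
            r = by_key.get((a, c))
            row[c] = r.category if r else "NA"
            row[f"{c}_p"] = r.p if r else np.nan
        rows.append(row)
    cols = ["assay_id"] + names + [f"{c}_p" for c in names]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class GroupDendrogram:
    leaves: list[str]
    merge_order: list[tuple[frozenset[str], frozenset[str], float]]
    distance_metric: str
    linkage_method: str
    linkage_matrix: np.ndarray

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.leaves[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(tree) + ";"

    def merge_partners(self) -> frozenset[str]:
        """Leaves joined by the first (lowest) merge."""
        first = self.merge_order[0]
        return first[0] | first[1]


def cluster_groups(
    lognrq: NrqMatrix,
    annotations: Sequence[SampleAnnotation],
    signature: Sequence[str],
    linkage: str = "average",
    metric: str = "euclidean",
) -> GroupDendrogram:
    """Agglomerative clustering of the four group-mean log-NRQ profiles.

    Profiles are restricted to signature miRNAs with a defined value in
    every clustered sample. Assays undetected in some samples are dropped
    with a log notice: their detected-subset group means are biased by the
    censoring (undetected means low abundance), so they do not yield
    comparable group profiles.
    """
    signature = sorted(signature)
    if not signature:
        raise ValidationError("signature is empty")
    group_of = {a.sample_id: a.group for a in annotations}
    groups = sorted({a.group for a in annotations})
    if len(groups) < 2:
        raise ValidationError("clustering needs >= 2 groups")
    clustered_samples = [s for s in lognrq.sample_ids if s in group_of]
    frame = lognrq.to_frame().loc[signature, clustered_samples]
    complete = ~frame.isna().any(axis=1)
    if not complete.all():
        dropped = [a for a, keep in zip(signature, complete) if not keep]
        logger.info(
            "clustering: dropped %d signature assays with undetected cells "
            "(censoring-biased group means): %s",
            len(dropped), ", ".join(dropped[:5]),
        )
        signature = [a for a, keep in zip(signature, complete) if keep]
        frame = frame.loc[signature]
    if not signature:
        raise ValidationError(
            "no signature assay is detected in every clustered sample"
        )
    profiles = np.empty((len(groups), len(signature)))
    for gi, g in enumerate(groups):
        members = [s for s in clustered_samples if group_of.get(s) == g]
        profiles[gi] = frame[members].to_numpy().mean(axis=1)
    dist = pdist(profiles, metric=metric)
    z = hierarchy.linkage(dist, method=linkage)

    clusters: dict[int, frozenset[str]] = {
        i: frozenset({g}) for i, g in enumerate(groups)
    }
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    for step, (a, b, height, _) in enumerate(z):
        left, right = clusters[int(a)], clusters[int(b)]
        merges.append((left, right, float(height)))
        clusters[len(groups) + step] = left | right
    return GroupDendrogram(
        leaves=groups,
        merge_order=merges,
        distance_metric=metric,
        linkage_method=linkage,
        linkage_matrix=z,
    )


def stratify_check(
    lognrq: NrqMatrix,
    annotations: Sequence[SampleAnnotation],
    variable: str = "bmi_kg_m2",
    cutpoints: Sequence[float] = (25.0,),
    equal_var: bool = True,
    min_stratum: int = 2,
) -> list[ContrastResult]:
    """Re-run the t-test battery with strata of a clinical covariate as groups.

    Samples are binned by ``cutpoints`` (right-open intervals); all
    pairwise stratum contrasts are tested. Used to show that group effects
    do not simply track e.g. body-mass index.
    """
    edges = [-np.inf, *sorted(cutpoints), np.inf]
    strata: dict[str, list[str]] = {}
    for ann in annotations:
        v = ann.clinical.get(variable)
        if v is None or np.isnan(v):
            logger.info("stratify: %s missing %s; dropped", ann.sample_id, variable)
            continue
        for k in range(len(edges) - 1):
            if edges[k] <= v < edges[k + 1]:
                strata.setdefault(f"stratum_{k}", []).append(ann.sample_id)
                break
    strata = {k: v for k, v in strata.items() if len(v) >= min_stratum}
    if len(strata) < 2:
        raise ValidationError(
            f"stratification by {variable!r} leaves fewer than two usable strata"
        )
    names = sorted(strata)
    frame = lognrq.to_frame()
    results: list[ContrastResult] = []
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            ga, gb = names[ai], names[bi]
            contrast = f"{gb}_vs_{ga}"
            a_block = frame[strata[gb]]
            b_block = frame[strata[ga]]
            for assay in lognrq.assay_ids:
                a = a_block.loc[assay].dropna().to_numpy()
                b = b_block.loc[assay].dropna().to_numpy()
                if a.size < 2 or b.size < 2:
                    continue
                if np.ptp(np.concatenate([a, b])) == 0:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                    t, p = float(t), float(p)
                    if np.isnan(t):
                        t, p = 0.0, 1.0
                results.append(
                    ContrastResult(
                        assay_id=assay,
                        contrast=contrast,
                        t=t,
                        p=p,
                        category=categorize(p),
                        direction=int(np.sign(a.mean() - b.mean())),
                    )
                )
    return results
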