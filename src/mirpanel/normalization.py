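"""Global-mean normalization of qPCR panels and normalizer stability.

Normalized relative quantities are computed against the per-sample mean Ct
of the co-expressed assay set (the assays detected in every sample):

    NRQ(a, s) = 2 ** (GM_s - Ct_{a,s})

and reported on a log scale (log10 by default). Because the exponent is a
difference against the per-sample mean, the sum of log2 NRQ over the
co-expressed set is identically zero in every sample.

The suitability of the global mean as a normalizer is scored with a
model-based variance-decomposition stability value in the style of the
NormFinder algorithm: a candidate's score combines its intragroup
(technical + biological) variance with its systematic intergroup bias,
both estimated relative to the candidate-set average; lower is more
stable. The per-sample mean over the co-expressed set can be entered as a
pseudo-candidate ("global_mean") and scored alongside single assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CtMatrix, ValidationError

GLOBAL_MEAN_ID = "global_mean"


# ---------------------------------------------------------------------------
# Global mean & NRQ
# ---------------------------------------------------------------------------

def global_mean(ct: CtMatrix, coexpressed_set: Sequence[str]) -> pd.Series:
    """Per-sample arithmetic mean Ct over the co-expressed set (cycles).

    Every assay in the set must be detected in every sample — an
    undetected cell violates the set's definition and raises.
    """
    if not coexpressed_set:
        raise ValidationError("coexpressed_set is empty")
    idx = [ct.assay_index(a) for a in coexpressed_set]
    block = ct.ct[idx, :]
    if np.isnan(block).any():
        bad = [
            coexpressed_set[i]
            for i in range(len(idx))
            if np.isnan(block[i]).any()
        ]
        raise ValidationError(
            "undetected cells inside co-expressed set for assays: "
            + ", ".join(bad)
        )
    return pd.Series(block.mean(axis=0), index=ct.sample_ids, name="global_mean")


@dataclass
class NrqMatrix:
    """Log-scale normalized relative quantities, assays x samples."""

    assay_ids: list[str]
    sample_ids: list[str]
    lognrq: np.ndarray           # NaN where Ct undetected
    base: float                  # logarithm base of the stored values
    global_mean: pd.Series       # per-sample mean Ct of the co-expressed set
    coexpressed_set: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.lognrq, index=self.assay_ids, columns=self.sample_ids
        )

    def row(self, assay_id: str) -> np.ndarray:
        try:
            return self.lognrq[self.assay_ids.index(assay_id)]
        except ValueError:
            raise ValidationError(f"assay {assay_id!r} not in NRQ matrix") from None

    def log2(self) -> np.ndarray:
        """Values rebased to log2 regardless of the stored base."""
        return self.lognrq * np.log2(self.base)


def nrq(
    ct: CtMatrix,
    gm: pd.Series,
    log_base: float = 10.0,
    coexpressed_set: Sequence[str] | None = None,
) -> NrqMatrix:
    """NRQ(a, s) = 2^(GM_s − Ct_{a,s}), stored as a ``log_base`` logarithm.

    Undetected cells stay undefined (NaN). Because log_b(2^x) = x·log_b(2)
    the stored value is (GM_s − Ct) · log_b(2).
    """
    missing = [s for s in ct.sample_ids if s not in gm.index]
    if missing:
        raise ValidationError(
            "global mean missing for samples: " + ", ".join(missing)
        )
    gm_vec = gm.reindex(ct.sample_ids).to_numpy(dtype=float)
    log2nrq = gm_vec[np.newaxis, :] - ct.ct
    lognrq = log2nrq * np.log(2.0) / np.log(log_base)
    return NrqMatrix(
        assay_ids=list(ct.assay_ids),
        sample_ids=list(ct.sample_ids),
        lognrq=lognrq,
        base=float(log_base),
        global_mean=gm.reindex(ct.sample_ids),
        coexpressed_set=list(coexpressed_set or []),
    )


# ---------------------------------------------------------------------------
# Model-based stability (NormFinder-style)
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    candidate_id: str
    intragroup_variances: dict[str, float]
    intergroup_bias: dict[str, float]
    stability_value: float


def _variance_components(
    z: np.ndarray, group_slices: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Intragroup variance and group means of sample-centered values.

    ``z``: genes x samples, already centered by the per-sample candidate-set
    average. Returns per-gene-per-group residual mean squares ``s`` (before
    bias correction), group means ``zbar`` (genes x groups) and group sizes.
    """
    k, _ = z.shape
    n_groups = len(group_slices)
    s = np.empty((k, n_groups))
    zbar = np.empty((k, n_groups))
    sizes: list[float] = []
    for g, cols in enumerate(group_slices):
        block = z[:, cols]
        n = block.shape[1]
        sizes.append(float(n))
        zbar[:, g] = block.mean(axis=1)
        s[:, g] = block.var(axis=1, ddof=1) if n > 1 else 0.0
    return s, zbar, sizes


def _corrected_sigma2(s: np.ndarray, k: int) -> np.ndarray:
    """Unbias the naive residual variances for the shared sample effect.

    With k genes entering the per-sample average, the naive per-gene
    residual mean square s_ig has expectation
    (1 − 2/k)·σ²_ig + (1/k²)·Σ_l σ²_lg, so the ensemble sum is recovered as
    Σσ² = (k/(k−1))·Σ_i s_ig and each gene as
    σ̂²_ig = (s_ig − Σ̂σ²_g/k²) · k/(k−2); negative estimates truncate at 0.
    """
    if k < 3:
        raise ValidationError("stability model needs >= 3 candidate genes")
    total = s.sum(axis=0) * k / (k - 1)            # per group
    sigma2 = (s - total[np.newaxis, :] / k**2) * k / (k - 2)
    return np.clip(sigma2, 0.0, None)


def stability_scores(
    values: pd.DataFrame,
    groups: Sequence[str] | None = None,
    include_global_mean: bool = True,
    grouped: bool = True,
) -> list[StabilityResult]:
    """Rank candidate normalizers by a model-based stability value.

    Parameters
    ----------
    values
        Candidate genes x samples, on a log2 expression-like scale (e.g.
        negated Ct or log2 NRQ — any per-sample affine shift cancels in the
        model). Must be complete (no NaN).
    groups
        Per-sample group labels (aligned with columns). Required when
        ``grouped=True``; with ``grouped=False`` all samples form one group
        and the score reduces to the corrected intragroup standard
        deviation.
    include_global_mean
        Add the per-sample mean over the candidate rows as the
        pseudo-candidate ``"global_mean"``. The candidate-set average used
        by the model always excludes the pseudo-candidate, so single-gene
        scores are unchanged by its presence.

    Returns
    -------
    list of :class:`StabilityResult`, ascending stability value (more
    stable first).

    Notes
    -----
    Grouped mode follows the model-based decomposition of the NormFinder
    algorithm: per gene i and group g the intragroup variance σ²_ig and the
    intergroup deviation d_ig (gene-group mean relative to the candidate
    ensemble, centered across groups) are estimated; d is shrunk by an
    empirical-Bayes factor γ²/(γ² + σ²_ig/n_g) where γ² is the
    method-of-moments variance of the true group differences, and the
    stability value is the mean over groups of |d̃_ig| + sqrt(σ̂²_ig/n_g).
    A candidate that is constant across all samples scores exactly 0.
    """
    if values.isna().any().any():
        raise ValidationError("stability input must have no missing values")
    k, n = values.shape
    if k < 3:
        raise ValidationError("stability model needs >= 3 candidate genes")
    y = values.to_numpy(dtype=float)

    if grouped:
        if groups is None:
            raise ValidationError("grouped stability requires group labels")
        labels = list(groups)
        if len(labels) != n:
            raise ValidationError("groups length must match sample count")
        uniq = sorted(set(labels))
        if len(uniq) < 2:
            raise ValidationError("grouped stability needs >= 2 groups")
        group_slices = [
            np.flatnonzero(np.array(labels) == g) for g in uniq
        ]
        if any(len(c) < 2 for c in group_slices):
            raise ValidationError("each group needs >= 2 samples")
    else:
        uniq = ["all"]
        group_slices = [np.arange(n)]
        if n < 2:
            raise ValidationError("stability needs >= 2 samples")

    # Sample effect: per-sample average over the real candidate rows.
    beta = y.mean(axis=0)
    z = y - beta[np.newaxis, :]

    s, zbar, sizes = _variance_components(z, group_slices)
    sigma2 = _corrected_sigma2(s, k)

    ids = list(values.index)
    if include_global_mean:
        pseudo = y.mean(axis=0)
        zp = (pseudo - beta)[np.newaxis, :]
        sp, zbarp, _ = _variance_components(zp, group_slices)
        total = s.sum(axis=0) * k / (k - 1)
        sig2p = np.clip((sp - total[np.newaxis, :] / k**2) * k / (k - 2), 0.0, None)
        sigma2 = np.vstack([sigma2, sig2p])
        zbar = np.vstack([zbar, zbarp])
        ids = ids + [GLOBAL_MEAN_ID]

    n_g = np.asarray(sizes)
    results: list[StabilityResult] = []
    if grouped and len(uniq) >= 2:
        d = zbar - zbar.mean(axis=1, keepdims=True)
        v = sigma2 / n_g[np.newaxis, :]
        # gamma^2 from the real candidates only (method of moments)
        n_real = k
        gamma2 = max(
            0.0,
            float(
                (d[:n_real] ** 2).sum() / ((len(uniq) - 1) * (n_real - 1))
                - v[:n_real].mean()
            ),
        )
        denom = gamma2 + v
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
        d_shrunk = d * shrink
        # |shrunk bias| plus the sampling SE of the group difference: the
        # SE term keeps intragroup variance in play even when the
        # between-group variance estimate truncates to zero
        rho = np.abs(d_shrunk) + np.sqrt(v)
        stability = rho.mean(axis=1)
    else:
        d = np.zeros_like(zbar)
        stability = np.sqrt(sigma2[:, 0])

    for i, cid in enumerate(ids):
        results.append(
            StabilityResult(
                candidate_id=cid,
                intragroup_variances={g: float(sigma2[i, j]) for j, g in enumerate(uniq)},
                intergroup_bias={g: float(d[i, j]) for j, g in enumerate(uniq)},
                stability_value=float(stability[i]),
            )
        )
    results.sort(key=lambda r: (r.stability_value, r.candidate_id))
    return results


def stability_table(results: list[StabilityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate_id": [r.candidate_id for r in results],
            "stability_value": [r.stability_value for r in results],
            "rank": np.arange(1, len(results) + 1),
        }
    )
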