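"""Synthetic plasma-miRNA qPCR cohorts with known ground truth.

The generator emulates the structure of a small progression cohort
profiled on a ~179-assay serum/plasma panel:

* a per-group global concentration shift (lower Ct = more miRNA in the
  impaired groups),
* a single latent per-sample factor ``f_s`` (inter-individual global
  miRNA concentration) to which every assay couples through a loading
  drawn around 1 — the loading dispersion is group-dependent, so
  co-regulation can be weakened selectively (the pre-diabetes pattern),
* per-(assay, group) differential-expression shifts in cycles,
* detection-limit censoring at a Ct ceiling, producing a realistic split
  into a clean co-expressed core and borderline assays that drop out in
  some samples,
* hemolysis contamination (an erythrocyte-marker Ct drop in chosen
  samples), extraction/RT spike-in ladders, per-assay QC metadata with a
  configurable handful of failing assays, and Table-1-like clinical
  covariates linked to the latent factor.

The cell model is

    Ct[a, s] = mu_a + shift[grp(s)] + lambda[a, grp(s)] * f_s
               + delta[a, grp(s)] + eps[a, s],

with ``f_s ~ N(0, 1)``, ``lambda ~ N(1, loading_sd[grp]^2)`` (coupling
assays get their loading fixed to the configured per-group slope),
``eps ~ N(0, noise_sd^2)``; cells with Ct above ``lod_ct`` are undetected.
All randomness flows from one seeded generator: identical seed and config
give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    GROUPS,
    AssayQCMetadata,
    CtMatrix,
    SampleAnnotation,
    ValidationError,
    group3,
    write_ct_table,
)
from .qc import EXTRACTION_SPIKEINS, HEMOLYSIS_MARKER, HEMOLYSIS_TARGET, RT_SPIKEIN

COUPLING_ASSAY = "sim-miR-27a-3p"

#: Group-level clinical model (mean, sd) per NGT/IGT/T2D axis, on the
#: scales of a typical progression-cohort baseline table. Values linked to
#: the latent factor are adjusted per sample on top of the group mean.
CLINICAL_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "age_years": {"NGT": (57.9, 8.9), "IGT": (62.9, 7.3), "T2D": (60.2, 8.0)},
    "weight_kg": {"NGT": (67.2, 12.7), "IGT": (71.7, 13.0), "T2D": (78.3, 17.0)},
    "height_cm": {"NGT": (167.9, 10.5), "IGT": (166.9, 9.7), "T2D": (163.3, 11.9)},
    "bmi_kg_m2": {"NGT": (23.7, 3.3), "IGT": (25.6, 3.3), "T2D": (29.6, 7.8)},
    "waist_cm": {"NGT": (88.2, 13.0), "IGT": (96.6, 7.5), "T2D": (101.0, 11.3)},
    "fasting_glucose_mg_dl": {"NGT": (81.8, 9.1), "IGT": (99.6, 8.4), "T2D": (106.8, 17.9)},
    "ogtt_glucose_mg_dl": {"NGT": (94.7, 26.2), "IGT": (162.8, 21.0), "T2D": (231.2, 32.6)},
    "hba1c_mmol_mol": {"NGT": (36.8, 2.2), "IGT": (44.6, 3.4), "T2D": (46.4, 6.3)},
    "insulin_mu_l": {"NGT": (11.6, 6.0), "IGT": (18.0, 9.0), "T2D": (18.8, 9.0)},
    "triglycerides_mg_dl": {"NGT": (103.3, 58.0), "IGT": (158.7, 69.9), "T2D": (116.1, 61.7)},
    "total_cholesterol_mg_dl": {"NGT": (196.4, 26.0), "IGT": (218.7, 23.2), "T2D": (199.0, 30.5)},
    "ldl_cholesterol_mg_dl": {"NGT": (116.2, 18.5), "IGT": (132.7, 28.0), "T2D": (121.9, 30.3)},
    "hdl_cholesterol_mg_dl": {"NGT": (59.6, 14.2), "IGT": (54.2, 17.9), "T2D": (53.9, 16.5)},
    "endothelial_index": {"NGT": (2.2, 0.5), "IGT": (2.4, 0.9), "T2D": (2.5, 0.7)},
}

#: Log-scale model for the heavily skewed covariate (exercises the
#: Kruskal–Wallis routing of the summary table): (log-median, log-sd).
MICROALBUMINURIA_LOG = {"NGT": (2.0, 0.8), "IGT": (2.6, 1.4), "T2D": (2.0, 0.7)}

MALE_FRACTION = {"NGT": 0.44, "NP_IGT": 0.56, "P_IGT": 0.56, "T2D": 0.22}


def _default_de_effects() -> dict[tuple[str, str], float]:
    """Differential block echoing the pre-diabetes pattern: a handful of
    assays shifted mostly in the non-progressor IGT group (negative delta
    = lower Ct = up-regulated), two shared IGT effects, two T2D effects."""
    effects: dict[tuple[str, str], float] = {}
    np_only = [-1.5, -1.2, 0.5, 0.7, 0.9, 1.1, 1.3, 1.5, 1.0]
    for i, d in enumerate(np_only):
        effects[(f"sim-mir-de-{i:02d}", "NP_IGT")] = d
    for i, d in enumerate([-1.3, 1.2]):
        a = f"sim-mir-de-{len(np_only) + i:02d}"
        effects[(a, "NP_IGT")] = d
        effects[(a, "P_IGT")] = d
    for i, d in enumerate([-1.0, 1.0]):
        effects[(f"sim-mir-de-{len(np_only) + 2 + i:02d}", "T2D")] = d
    return effects


@dataclass
class SyntheticConfig:
    """Full generative parameterization of a simulated cohort."""

    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NGT": 9, "NP_IGT": 4, "P_IGT": 5, "T2D": 9}
    )
    n_assays: int = 179
    #: abundance profile: a clean core well inside the detectable range
    #: plus a borderline tail near the LOD (drives realistic censoring)
    baseline_core_range: tuple[float, float] = (20.0, 34.0)
    baseline_borderline_range: tuple[float, float] = (34.5, 37.5)
    n_borderline: int = 89
    #: additive per-group Ct shift (negative = more circulating miRNA)
    global_shift: dict[str, float] = field(
        default_factory=lambda: {"NGT": 0.0, "NP_IGT": -0.7, "P_IGT": -0.7, "T2D": -0.9}
    )
    #: per-group SD of latent-factor loadings (higher = weaker co-regulation)
    factor_loading_sd: dict[str, float] = field(
        default_factory=lambda: {"NGT": 0.2, "NP_IGT": 0.6, "P_IGT": 0.6, "T2D": 0.3}
    )
    de_effects: dict[tuple[str, str], float] = field(default_factory=_default_de_effects)
    noise_sd: float = 0.4
    lod_ct: float = 37.0
    hemolysis_samples: tuple[str, ...] = ()
    hemolysis_shift: float = -4.0
    #: per-group latent-factor coupling of designated assays (true slope of
    #: assay Ct on the global-mean Ct); keyed on the three-level axis
    coupling: dict[str, dict[str, float]] = field(
        default_factory=lambda: {COUPLING_ASSAY: {"NGT": 1.0, "IGT": 0.6, "T2D": 0.3}}
    )
    #: cycles-to-covariate link: covariate -= link * f_s (more global miRNA
    #: -> higher glycemic burden, matching the observed positive trend)
    clinical_links: dict[str, float] = field(
        default_factory=lambda: {"ogtt_glucose_mg_dl": 12.0, "hba1c_mmol_mol": 1.8}
    )
    spikein_noise_sd: float = 0.05
    n_low_efficiency: int = 3
    n_multi_melt: int = 2
    n_near_negctrl: int = 2
    negctrl_margin_above_lod: float = 6.0

    def __post_init__(self) -> None:
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ValidationError(f"unknown group key {g!r}")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValidationError("group sizes must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not (0 < self.lod_ct <= 50):
            raise ValidationError("lod_ct must lie in the valid Ct range")

    # -- config file round-trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["de_effects"] = [
            {"assay": a, "group": g, "delta_ct": d}
            for (a, g), d in self.de_effects.items()
        ]
        data["hemolysis_samples"] = list(self.hemolysis_samples)
        data["baseline_core_range"] = list(self.baseline_core_range)
        data["baseline_borderline_range"] = list(self.baseline_borderline_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "de_effects" in data:
            data["de_effects"] = {
                (e["assay"], e["group"]): float(e["delta_ct"])
                for e in data["de_effects"]
            }
        for key in ("baseline_core_range", "baseline_borderline_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "hemolysis_samples" in data:
            data["hemolysis_samples"] = tuple(data["hemolysis_samples"])
        return cls(**data)


@dataclass
class SyntheticCohort:
    ct: CtMatrix
    qc_metadata: list[AssayQCMetadata]
    spikeins: pd.DataFrame
    annotations: list[SampleAnnotation]
    latent_factor: pd.Series          # f_s, for diagnostics only


def _assay_names(config: SyntheticConfig) -> list[str]:
    special = [HEMOLYSIS_TARGET, HEMOLYSIS_MARKER, COUPLING_ASSAY]
    de_assays = sorted({a for (a, _g) in config.de_effects})
    names = special + [a for a in de_assays if a not in special]
    i = 0
    while len(names) < config.n_assays:
        cand = f"sim-mir-{i:03d}"
        if cand not in names:
            names.append(cand)
        i += 1
    if len(names) > config.n_assays:
        raise ValidationError(
            "n_assays too small for the special + differential assays"
        )
    return names


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort under ``config`` (deterministic given seed+config)."""
    rng = np.random.default_rng(config.seed)
    assays = _assay_names(config)
    n_assays = len(assays)

    samples: list[str] = []
    groups: list[str] = []
    for g in GROUPS:
        for i in range(config.n_per_group.get(g, 0)):
            samples.append(f"{g}-{i + 1:02d}")
            groups.append(g)
    n_samples = len(samples)

    # abundance profile: clean core + borderline tail near the LOD; the
    # special assays stay in the core so hemolysis/coupling are computable
    mu = np.empty(n_assays)
    n_border = min(config.n_borderline, n_assays - 3)
    core = n_assays - n_border
    mu[:core] = rng.uniform(*config.baseline_core_range, size=core)
    mu[core:] = rng.uniform(*config.baseline_borderline_range, size=n_border)
    fixed_baselines = {HEMOLYSIS_TARGET: 25.0, HEMOLYSIS_MARKER: 19.5,
                       COUPLING_ASSAY: 26.0}
    for a, b in fixed_baselines.items():
        mu[assays.index(a)] = b

    # per-(assay, group) loadings
    uniq_groups = [g for g in GROUPS if config.n_per_group.get(g, 0) > 0]
    loadings = {
        g: rng.normal(1.0, config.factor_loading_sd.get(g, 0.0), size=n_assays)
        for g in uniq_groups
    }
    for a, per_group in config.coupling.items():
        ai = assays.index(a)
        for g in uniq_groups:
            axis = per_group.get(g, per_group.get(group3(g)))
            if axis is not None:
                loadings[g][ai] = axis

    f = rng.normal(0.0, 1.0, size=n_samples)
    eps = rng.normal(0.0, config.noise_sd, size=(n_assays, n_samples))

    delta = np.zeros((n_assays, n_samples))
    for (a, g), d in config.de_effects.items():
        if a not in assays:
            raise ValidationError(f"de_effects names unknown assay {a!r}")
        if g not in GROUPS:
            raise ValidationError(f"de_effects names unknown group {g!r}")
        ai = assays.index(a)
        for j, grp in enumerate(groups):
            if grp == g:
                delta[ai, j] += d

    ct = np.empty((n_assays, n_samples))
    for j, grp in enumerate(groups):
        ct[:, j] = (
            mu
            + config.global_shift.get(grp, 0.0)
            + loadings[grp] * f[j]
            + delta[:, j]
            + eps[:, j]
        )

    # hemolysis: erythrocyte marker released into plasma -> marker Ct drops
    marker_idx = assays.index(HEMOLYSIS_MARKER)
    for s in config.hemolysis_samples:
        if s not in samples:
            raise ValidationError(f"hemolysis sample {s!r} not in cohort")
        ct[marker_idx, samples.index(s)] += config.hemolysis_shift

    ct = np.clip(ct, 1.0, None)
    ct[ct > config.lod_ct] = np.nan
    ct_matrix = CtMatrix(assay_ids=assays, sample_ids=samples, ct=ct)

    # QC metadata: a few failing assays drawn from the clean core, never
    # the special assays
    candidates = [
        a for a in assays[:core]
        if a not in fixed_baselines and not a.startswith("sim-mir-de-")
    ]
    n_bad = config.n_low_efficiency + config.n_multi_melt + config.n_near_negctrl
    bad = list(rng.choice(candidates, size=min(n_bad, len(candidates)), replace=False))
    low_eff = set(bad[: config.n_low_efficiency])
    multi_melt = set(bad[config.n_low_efficiency:
                         config.n_low_efficiency + config.n_multi_melt])
    near_neg = set(bad[config.n_low_efficiency + config.n_multi_melt:])
    qc_meta: list[AssayQCMetadata] = []
    for i, a in enumerate(assays):
        eff = float(np.clip(rng.normal(1.9, 0.08), 1.62, 2.0))
        melt = True
        neg = float("nan")
        if a in low_eff:
            eff = float(rng.uniform(1.30, 1.59))
        elif a in multi_melt:
            melt = False
        elif a in near_neg:
            neg = float(np.nanmean(ct[i]) + 3.0) if np.isfinite(np.nanmean(ct[i])) \
                else config.lod_ct
        else:
            # passing assays: negative control undetected or safely late
            if rng.random() < 0.5:
                neg = min(50.0, config.lod_ct + config.negctrl_margin_above_lod)
        qc_meta.append(AssayQCMetadata(a, efficiency=eff, melt_ok=melt, negctrl_ct=neg))

    # spike-ins: extraction ladder at exact 100-fold spacing + tiny noise,
    # RT spike-in around one shared cycle
    ladder_base = 18.0
    spacing = np.log2(100.0)
    spike_rows = {}
    for k, name in enumerate(EXTRACTION_SPIKEINS):
        spike_rows[name] = (
            ladder_base + k * spacing
            + rng.normal(0.0, config.spikein_noise_sd, size=n_samples)
        )
    spike_rows[RT_SPIKEIN] = 19.0 + rng.normal(
        0.0, config.spikein_noise_sd, size=n_samples
    )
    spikeins = pd.DataFrame(spike_rows, index=samples).T

    # clinical covariates
    annotations: list[SampleAnnotation] = []
    for j, (s, grp) in enumerate(zip(samples, groups)):
        axis = group3(grp)
        clinical: dict[str, float] = {}
        for var, per_group in CLINICAL_MODEL.items():
            mean, sd = per_group[axis]
            value = rng.normal(mean, sd)
            value -= config.clinical_links.get(var, 0.0) * f[j]
            clinical[var] = float(max(value, 0.1))
        log_m, log_s = MICROALBUMINURIA_LOG[axis]
        clinical["microalbuminuria_mg_l"] = float(rng.lognormal(log_m, log_s))
        clinical["homa_ir"] = (
            clinical["fasting_glucose_mg_dl"] * clinical["insulin_mu_l"] / 405.0
        )
        sex = "M" if rng.random() < MALE_FRACTION[grp] else "F"
        annotations.append(
            SampleAnnotation(sample_id=s, group=grp, sex=sex, clinical=clinical)
        )

    return SyntheticCohort(
        ct=ct_matrix,
        qc_metadata=qc_meta,
        spikeins=spikeins,
        annotations=annotations,
        latent_factor=pd.Series(f, index=samples, name="latent_factor"),
    )


def truth_table(config: SyntheticConfig) -> dict:
    """Machine-readable ground truth for parameter-recovery tests."""
    return {
        "de": [
            {"assay_id": a, "group": g, "delta_ct": d}
            for (a, g), d in sorted(config.de_effects.items())
        ],
        "coupling": {a: dict(v) for a, v in config.coupling.items()},
        "global_shift": dict(config.global_shift),
        "factor_loading_sd": dict(config.factor_loading_sd),
        "lod_ct": config.lod_ct,
        "noise_sd": config.noise_sd,
    }


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the same text formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": out / "ct.tsv",
        "annotations": out / "annotations.tsv",
        "qc_metadata": out / "qc_metadata.tsv",
        "spikeins": out / "spikeins.tsv",
    }
    write_ct_table(cohort.ct, paths["ct"])

    clin_vars: list[str] = []
    for a in cohort.annotations:
        for v in a.clinical:
            if v not in clin_vars:
                clin_vars.append(v)
    rows = []
    for a in cohort.annotations:
        row = {"sample_id": a.sample_id, "group": a.group, "sex": a.sex or ""}
        for v in clin_vars:
            val = a.clinical.get(v)
            row[v] = "" if val is None else f"{val:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["annotations"], sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "assay_id": m.assay_id,
                "efficiency": f"{m.efficiency:.4f}",
                "melt_ok": str(m.melt_ok).lower(),
                "negctrl_ct": "NA" if np.isnan(m.negctrl_ct) else f"{m.negctrl_ct:.2f}",
            }
            for m in cohort.qc_metadata
        ]
    ).to_csv(paths["qc_metadata"], sep="\t", index=False)

    cohort.spikeins.round(4).rename_axis("spikein").reset_index().to_csv(
        paths["spikeins"], sep="\t", index=False
    )
    return paths
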