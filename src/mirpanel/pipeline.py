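"""End-to-end orchestration: read -> QC -> normalize -> analyze -> write.

Stage order follows the analysis a panel study runs: assay QC and
detection summaries, hemolysis and spike-in checks, global-mean NRQ
normalization with a stability ranking, co-regulation diagnostics, the
group-contrast battery with signature selection and group clustering, and
the clinical-statistics tables. Every stage logs its inputs and row
counts; all outputs are tab-delimited and a JSON manifest records the
resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import clinical_correlation_map, clinical_table, clinical_table_frame
from .coregulation import (
    correlation_profiles,
    group_quantity_trend,
    local_vs_global_slope,
    slope_table,
)
from .differential import (
    cluster_groups,
    contrast_table,
    run_contrasts,
    select_signature,
)
from .io import (
    CtMatrix,
    ValidationError,
    read_annotations,
    read_ct_table,
    read_qc_metadata,
    write_results,
)
from .normalization import global_mean, nrq, stability_scores, stability_table
from .qc import apply_assay_qc, hemolysis_delta_ct, spikein_check
from .simulate import COUPLING_ASSAY, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Exactly one of (``ct_path`` + ``annotations_path`` + ``qc_path``) or
    ``synthetic`` must be supplied.
    """

    out_dir: str = "results"
    ct_path: str | None = None
    annotations_path: str | None = None
    qc_path: str | None = None
    spikeins_path: str | None = None
    synthetic: SyntheticConfig | None = None
    seed: int = 0
    # QC
    qc_margin: float = 5.0
    qc_min_efficiency: float = 1.6
    qc_scope: str = "cell"
    hemolysis_warn_threshold: float = 7.0
    spikein_spacing_tol: float = 1.0
    # normalization
    log_base: float = 10.0
    stability_grouped: bool = True
    # analysis
    contrasts: Sequence[str] | None = None
    equal_var: bool = True
    fdr: bool = False
    linkage: str = "average"
    metric: str = "euclidean"
    dunn_adjust: str = "bonferroni"
    slope_assay: str | None = None
    clinical_vars: Sequence[str] = (
        "bmi_kg_m2",
        "waist_cm",
        "fasting_glucose_mg_dl",
        "ogtt_glucose_mg_dl",
        "hba1c_mmol_mol",
        "homa_ir",
        "triglycerides_mg_dl",
        "total_cholesterol_mg_dl",
        "ldl_cholesterol_mg_dl",
        "hdl_cholesterol_mg_dl",
    )
    verbosity: str = "INFO"

    def validate(self) -> None:
        real = all(p is not None for p in (self.ct_path, self.annotations_path, self.qc_path))
        some_real = any(p is not None for p in (self.ct_path, self.annotations_path, self.qc_path))
        if self.synthetic is not None and some_real:
            raise ValidationError(
                "supply either real input paths or a synthetic config, not both"
            )
        if self.synthetic is None and not real:
            raise ValidationError(
                "incomplete input: need ct, annotations and qc paths, "
                "or a synthetic config"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "synthetic" in data and data["synthetic"] is not None:
            data["synthetic"] = SyntheticConfig(**data["synthetic"])
        return cls(**data)

    def resolved(self) -> dict:
        data = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = dataclasses.asdict(self.synthetic)
            syn["de_effects"] = [
                {"assay": a, "group": g, "delta_ct": d}
                for (a, g), d in self.synthetic.de_effects.items()
            ]
            data["synthetic"] = syn
        data["contrasts"] = list(self.contrasts) if self.contrasts else None
        data["clinical_vars"] = list(self.clinical_vars)
        return data


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (paths + summaries)."""
    config.validate()
    out_dir = Path(config.out_dir)

    # ---- stage: inputs ---------------------------------------------------
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        logger.info("stage input: generating synthetic cohort (seed=%d)", config.seed)
        cohort = generate_cohort(syn)
        ct, annotations, qc_meta, spikeins = (
            cohort.ct, cohort.annotations, cohort.qc_metadata, cohort.spikeins,
        )
    else:
        logger.info("stage input: reading %s", config.ct_path)
        ct = read_ct_table(config.ct_path)
        annotations = read_annotations(config.annotations_path, ct=ct)
        qc_meta = read_qc_metadata(config.qc_path)
        spikeins = None
        if config.spikeins_path:
            spikeins = pd.read_csv(
                config.spikeins_path, sep="\t", index_col="spikein"
            )
    logger.info(
        "input: %d assays x %d samples, %d annotations",
        len(ct.assay_ids), len(ct.sample_ids), len(annotations),
    )

    # ---- stage: QC -------------------------------------------------------
    filtered, qc_report = apply_assay_qc(
        ct, qc_meta, margin=config.qc_margin,
        min_efficiency=config.qc_min_efficiency, scope=config.qc_scope,
    )
    logger.info(
        "QC: %d removals, mean detected/sample %.1f, %d co-expressed",
        len(qc_report.removed),
        float(np.mean(list(qc_report.detected_per_sample.values()))),
        len(qc_report.coexpressed_set),
    )
    hemolysis = hemolysis_delta_ct(
        filtered, warn_threshold=config.hemolysis_warn_threshold,
        annotations=annotations,
    )
    spike_warnings = (
        spikein_check(spikeins, spacing_tol=config.spikein_spacing_tol)
        if spikeins is not None else {}
    )

    # ---- stage: normalization -------------------------------------------
    coexpressed = qc_report.coexpressed_set
    if not coexpressed:
        raise ValidationError("no co-expressed assays after QC")
    gm = global_mean(filtered, coexpressed)
    nrq_matrix = nrq(filtered, gm, log_base=config.log_base,
                     coexpressed_set=coexpressed)
    group3_of = {a.sample_id: a.group3 for a in annotations}
    stab_values = pd.DataFrame(
        -filtered.ct[[filtered.assay_index(a) for a in coexpressed], :],
        index=coexpressed, columns=filtered.sample_ids,
    )
    stability = stability_scores(
        stab_values,
        groups=[group3_of[s] for s in filtered.sample_ids]
        if config.stability_grouped else None,
        include_global_mean=True,
        grouped=config.stability_grouped,
    )
    logger.info(
        "normalization: most stable candidate %s (value %.4g)",
        stability[0].candidate_id, stability[0].stability_value,
    )

    # ---- stage: co-regulation diagnostics -------------------------------
    trend = group_quantity_trend(filtered, annotations, coexpressed)
    profiles, cross = correlation_profiles(filtered, annotations, coexpressed)
    slope_assay = config.slope_assay or (
        COUPLING_ASSAY if COUPLING_ASSAY in filtered.assay_ids
        else filtered.assay_ids[0]
    )
    slopes = (
        local_vs_global_slope(filtered, slope_assay, annotations, coexpressed)
        if slope_assay in coexpressed or slope_assay in filtered.assay_ids else {}
    )

    # ---- stage: differential expression ---------------------------------
    results = run_contrasts(
        nrq_matrix, annotations, contrasts=config.contrasts,
        equal_var=config.equal_var, fdr=config.fdr,
    )
    signature = select_signature(results)
    logger.info("differential: %d assays in signature", len(signature))
    dendrogram = (
        cluster_groups(nrq_matrix, annotations, sorted(signature),
                       linkage=config.linkage, metric=config.metric)
        if signature and len({a.group for a in annotations}) >= 2 else None
    )

    # ---- stage: clinical statistics -------------------------------------
    table1 = clinical_table(annotations)
    corr_map = None
    if signature:
        available = {v for a in annotations for v in a.clinical}
        variables = [v for v in config.clinical_vars if v in available]
        if variables:
            corr_map = clinical_correlation_map(
                nrq_matrix, annotations, sorted(signature), variables,
                min_significant=None,
            )

    # ---- stage: output ---------------------------------------------------
    tables: dict[str, pd.DataFrame] = {
        "qc_report": qc_report.to_frame(),
        "detection": pd.DataFrame(
            {
                "sample_id": list(qc_report.detected_per_sample),
                "n_detected": list(qc_report.detected_per_sample.values()),
            }
        ),
        "hemolysis": pd.DataFrame(
            {
                "sample_id": list(hemolysis.delta_ct),
                "delta_ct": list(hemolysis.delta_ct.values()),
                "flag": [
                    s in hemolysis.flagged for s in hemolysis.delta_ct
                ],
            }
        ),
        "nrq": nrq_matrix.to_frame().rename_axis("assay_id").reset_index(),
        "stability": stability_table(stability),
        "global_mean": pd.DataFrame(
            {"sample_id": gm.index, "global_mean_ct": gm.to_numpy()}
        ),
        "contrasts": contrast_table(results),
        "clinical_table": clinical_table_frame(table1),
    }
    for g, prof in profiles.items():
        tables[f"correlation_{g}"] = pd.DataFrame(
            {
                "assay_id": list(prof.per_miRNA_r),
                "r_vs_global_mean": list(prof.per_miRNA_r.values()),
            }
        )
        tables[f"pairwise_r_{g}"] = (
            prof.pairwise_r.rename_axis("assay_id").reset_index()
        )
    if slopes:
        tables["slopes"] = slope_table(slopes)
    if corr_map is not None:
        tables["clinical_correlation_r"] = (
            corr_map.r.rename_axis("assay_id").reset_index()
        )
        tables["clinical_correlation_p"] = (
            corr_map.p.rename_axis("assay_id").reset_index()
        )
    paths = write_results(tables, out_dir)
    if dendrogram is not None:
        newick_path = out_dir / "group_dendrogram.nwk"
        newick_path.write_text(dendrogram.newick() + "\n", encoding="utf-8")
        paths.append(newick_path)

    manifest = {
        "version": __version__,
        "config": config.resolved(),
        "outputs": [str(p) for p in paths],
        "summary": {
            "n_assays": len(ct.assay_ids),
            "n_samples": len(ct.sample_ids),
            "n_removed": len(qc_report.removed),
            "mean_detected_per_sample": float(
                np.mean(list(qc_report.detected_per_sample.values()))
            ),
            "n_coexpressed": len(coexpressed),
            "hemolysis_kruskal_p": hemolysis.kruskal_p,
            "spikein_warnings": sum(len(w) for w in spike_warnings.values()),
            "most_stable_candidate": stability[0].candidate_id,
            "trend": {k: list(v) for k, v in trend.items()},
            "mean_r_per_group": {
                g: prof.mean_r for g, prof in profiles.items()
            },
            "n_signature": len(signature),
            "first_merge": sorted(dendrogram.merge_partners())
            if dendrogram else None,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
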