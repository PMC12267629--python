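"""End-to-end orchestration: cohort -> embeddings -> displacement maps ->
group ROIs -> discriminant nodes -> leave-one-out outcome prediction.

A run is fully described by a :class:`RunConfig` (serializable to JSON) and
is reproducible bit-for-bit from its master seed.  Outputs are plain-text
CSV/JSON files in the run directory:

    manifest.json                 config echo, seeds, reference ids
    embeddings/<sid>_{pre,post}.csv
    scores/<sid>.csv              per-node displacement scores
    rasters/<sid>.csv             interpolated disk maps
    roi_<side>.csv                pixelwise test + ROI mask per stratum
    discriminant_nodes_<side>.csv
    resected_nodes.csv            per-patient degree-drop report
    prediction.json               per-patient probabilities and metrics
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .embedding import EmbeddingParams, embed
from .io import read_cohort, read_connectome, read_node_table, check_same_nodes
from .predict import (
    PatientData,
    displacement_maps,
    lopo_predict,
    replicate_over_references,
)
from .raster import RasterParams
from .roi import RoiParams, discriminant_nodes, pixelwise_ttest, resected_node_report
from .synth import SyntheticConfig, generate_cohort


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    cohort_dir: str | None = None  # existing cohort; None -> generate synthetic
    synthetic: SyntheticConfig | None = None
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    raster: RasterParams = field(default_factory=RasterParams)
    roi: RoiParams = field(default_factory=RoiParams)
    n_refs: int = 3
    stratify_by_side: bool = True
    seed: int = 0
    out_dir: str = "hypdisp_run"

    def to_json(self) -> dict:
        d = asdict(self)
        return d

    @staticmethod
    def from_json(d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        for key, cls in (
            ("embedding", EmbeddingParams),
            ("raster", RasterParams),
            ("roi", RoiParams),
        ):
            if d.get(key):
                d[key] = cls(**d[key])
        return RunConfig(**d)


def load_patients(cohort_dir: str):
    """Load a cohort directory into patient and control objects.

    Expects ``cohort.csv`` and ``nodes.csv`` in the directory; every network
    must share the node table's node order.  Returns
    ``(patients, controls)`` with controls as an id -> Connectome dict.
    """
    table = read_cohort(os.path.join(cohort_dir, "cohort.csv"))
    node_table = read_node_table(os.path.join(cohort_dir, "nodes.csv"))
    patients, controls, nets = [], {}, []
    for rec in table.records:
        pre = read_connectome(rec.pre_path, node_table)
        nets.append(pre)
        if rec.role == "patient":
            post = read_connectome(rec.post_path, node_table)
            nets.append(post)
            patients.append(
                PatientData(rec.subject_id, rec.side, rec.outcome, pre, post)
            )
        else:
            controls[rec.subject_id] = pre
    check_same_nodes(nets)
    return patients, controls


def _load_truths(cohort_dir: str):
    path = os.path.join(cohort_dir, "ground_truth.json")
    if not os.path.exists(path):
        return None
    from .synth import GroundTruth

    with open(path) as fh:
        raw = json.load(fh)
    return {
        sid: GroundTruth(
            true_radius=np.asarray(s["true_radius"]),
            true_angle=np.asarray(s["true_angle"]),
            resected_nodes=tuple(s["resected_nodes"]),
            contralateral_sector=tuple(s["contralateral_sector"]),
            side=s["side"],
            subject_seed=s["subject_seed"],
        )
        for sid, s in raw["subjects"].items()
    }


def run_pipeline(config: RunConfig) -> str:
    """Execute the full analysis; returns the run directory path."""
    out = config.out_dir
    for sub in ("embeddings", "scores", "rasters"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)

    if config.cohort_dir is None:
        syn = config.synthetic or SyntheticConfig(seed=config.seed)
        cohort_dir = os.path.join(out, "cohort")
        generate_cohort(syn, cohort_dir)
    else:
        cohort_dir = config.cohort_dir
    patients, controls = load_patients(cohort_dir)
    if not controls:
        raise ValueError("pipeline needs at least one healthy control as reference")

    # reference for serialized maps = first sampled reference
    rng = np.random.default_rng(int(config.seed))
    ids = sorted(controls)
    primary_ref = ids[int(rng.integers(len(ids)))]
    maps = displacement_maps(
        patients, controls[primary_ref], config.embedding, config.raster
    )

    alignment_log = {
        m.patient.subject_id: {
            stage: {
                "rotation": t.rotation,
                "reflected": t.reflected,
                "loss": t.loss,
            }
            for stage, t in (("pre", m.alignment_pre), ("post", m.alignment_post))
        }
        for m in maps
    }
    with open(os.path.join(out, "alignment_log.json"), "w") as fh:
        json.dump({"reference_id": primary_ref, "subjects": alignment_log}, fh, indent=1)

    hemisphere = patients[0].pre.hemisphere if patients else ()
    for m in maps:
        sid = m.patient.subject_id
        m.pre_embedding.to_csv(os.path.join(out, "embeddings", f"{sid}_pre.csv"))
        m.post_embedding.to_csv(os.path.join(out, "embeddings", f"{sid}_post.csv"))
        pd.DataFrame(
            {"node_id": m.pre_embedding.node_ids, "hypdisp": m.scores}
        ).to_csv(os.path.join(out, "scores", f"{sid}.csv"), index=False)
        m.raster.to_csv(os.path.join(out, "rasters", f"{sid}.csv"))

    # group-level ROIs and discriminant nodes, per surgery-side stratum
    roi_summary = {}
    for side in ("left", "right"):
        stratum = [m for m in maps if m.patient.side == side]
        fav = [m.raster for m in stratum if m.patient.outcome == "favorable"]
        poor = [m.raster for m in stratum if m.patient.outcome == "poor"]
        if len(fav) < 2 or len(poor) < 2:
            continue
        roi = pixelwise_ttest(fav, poor, config.roi)
        roi.to_csv(os.path.join(out, f"roi_{side}.csv"))
        disc = discriminant_nodes(
            [m.pre_embedding for m in stratum],
            roi,
            config.roi,
            hemisphere=hemisphere,
        )
        disc.to_csv(os.path.join(out, f"discriminant_nodes_{side}.csv"), index=False)
        roi_summary[side] = {
            "n_pixels": roi.n_pixels,
            "n_components": roi.n_components,
            "n_discriminant_nodes": int(disc["discriminant"].sum()),
        }

    reports = []
    for p in patients:
        rep = resected_node_report(p.pre, p.post, config.roi)
        rep.insert(0, "subject_id", p.subject_id)
        reports.append(rep)
    if reports:
        pd.concat(reports).to_csv(os.path.join(out, "resected_nodes.csv"), index=False)

    summary, results = replicate_over_references(
        patients,
        controls,
        n_refs=min(config.n_refs, len(controls)),
        seed=config.seed,
        emb_params=config.embedding,
        raster_params=config.raster,
        roi_params=config.roi,
        stratify_by_side=config.stratify_by_side,
    )
    prediction = {
        "summary": summary,
        "replicates": [
            {
                "reference_id": r.reference_id,
                "auc": r.auc,
                "balanced_accuracy": r.balanced_accuracy,
                "accuracy": r.accuracy,
                "by_side": r.by_side,
                "folds": [
                    {
                        "subject_id": f.subject_id,
                        "side": f.side,
                        "outcome": f.outcome,
                        "probability": f.probability,
                        "feature": None if np.isnan(f.feature) else f.feature,
                        "roi_n_pixels": f.roi_n_pixels,
                        "empty_roi": f.empty_roi,
                    }
                    for f in r.folds
                ],
            }
            for r in results
        ],
    }
    with open(os.path.join(out, "prediction.json"), "w") as fh:
        json.dump(prediction, fh, indent=1)

    manifest = {
        "config": config.to_json(),
        "cohort_dir": cohort_dir,
        "primary_reference": primary_ref,
        "reference_ids": summary["reference_ids"],
        "n_patients": len(patients),
        "n_controls": len(controls),
        "roi_summary": roi_summary,
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
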