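"""Readers, writers, and the end-to-end pipeline runner.

Primary interchange format is plain CSV (trials x voxels pattern tables plus
a trial-metadata table) with JSON sidecars for vector index maps, ground
truth, and provenance.  4-D NIfTI + ROI-mask ingestion is supported through
nibabel when available; masks must be voxel-aligned to the data (no
resampling is attempted).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign, TrialEvent, default_design
from .pois import POILibrary, standard_library
from .rsa import ConditionSimilarity, TrialPatternMatrix, vector_index_map
from .search import SearchConfig, search_trace
from .validate import MCCVConfig, mccv, summarize_mccv

__all__ = [
    "SchemaError",
    "RunConfig",
    "ResultBundle",
    "load_patterns",
    "load_similarity",
    "load_nifti_patterns",
    "write_index_map",
    "run_pipeline",
]


class SchemaError(ValueError):
    """Input tables do not match the declared design."""


def _read_metadata(meta_path: str | Path, design: ExperimentDesign) -> tuple[TrialEvent, ...]:
    meta = pd.read_csv(meta_path)
    required = {"trial_id", "condition_id", "block_id", "task"}
    missing = required - set(meta.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    if len(meta) != design.n_trials:
        have = set(meta["trial_id"])
        expected = {t.trial_id for t in design.trials}
        lost = sorted(expected - have)
        raise SchemaError(
            f"metadata has {len(meta)} trials, design expects {design.n_trials}"
            + (f"; missing trial ids {lost}" if lost else "")
        )
    return tuple(
        TrialEvent(int(r.trial_id), int(r.condition_id), int(r.block_id), str(r.task))
        for r in meta.itertuples()
    )


def load_patterns(pattern_paths, meta_path, design: ExperimentDesign | None = None,
                  roi_id: str = "roi") -> list[TrialPatternMatrix]:
    """Load per-participant trials x voxels CSV tables with shared metadata.

    Raises :class:`SchemaError` on trial-count mismatches and surfaces
    non-finite values as validation errors.
    """
    design = design if design is not None else default_design()
    meta = _read_metadata(meta_path, design)
    out = []
    for p in pattern_paths:
        p = Path(p)
        values = pd.read_csv(p).to_numpy(dtype=float)
        if values.shape[0] != len(meta):
            raise SchemaError(
                f"{p.name}: {values.shape[0]} pattern rows != {len(meta)} metadata rows"
            )
        out.append(TrialPatternMatrix(values=values, trial_meta=meta,
                                      roi_id=roi_id, participant_id=p.stem))
    return out


def load_similarity(path: str | Path) -> np.ndarray:
    """Participants x cells similarity table (first column = participant id)."""
    df = pd.read_csv(path, index_col=0)
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise SchemaError(f"{path}: non-finite similarity values")
    return data


def load_nifti_patterns(image_path, mask_path, meta_path,
                        design: ExperimentDesign | None = None,
                        roi_id: str = "roi",
                        participant_id: str = "sub") -> TrialPatternMatrix:
    """Extract a trials x voxels matrix from a 4-D NIfTI and a binary mask.

    One volume per trial; voxels are the nonzero mask entries.  The mask must
    be voxel-aligned to the image (same grid; no resampling).
    """
    import nibabel as nib

    design = design if design is not None else default_design()
    meta = _read_metadata(meta_path, design)
    img = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if img.ndim != 4:
        raise SchemaError("expected a 4-D image (x, y, z, trials)")
    if img.shape[:3] != mask.shape:
        raise SchemaError("mask grid does not match image grid")
    if img.shape[3] != len(meta):
        raise SchemaError(f"{img.shape[3]} volumes != {len(meta)} metadata trials")
    values = img[mask].T  # trials x voxels
    return TrialPatternMatrix(values=values, trial_meta=meta,
                              roi_id=roi_id, participant_id=participant_id)


def write_index_map(path: str | Path, m: int = 6) -> Path:
    """Write the vectorization cell-order convention as JSON."""
    path = Path(path)
    cells = [{"index": k, "row": i, "col": j}
             for k, (i, j) in enumerate(vector_index_map(m))]
    path.write_text(json.dumps({"order": "row-major upper triangle with diagonal",
                                "cells": cells}, indent=2))
    return path


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    similarity_path: str | None = None
    pattern_paths: list[str] = field(default_factory=list)
    meta_path: str | None = None
    library: str = "base"  # base | lateralized
    delta_accept: float = 2.0
    delta_equiv: float = 2.0
    mccv_iters: int = 0  # 0 = skip cross-validation
    n_rs: int = 60
    n_ho: int = 7
    seed: int = 0
    out_dir: str = "poipcm_out"


@dataclass
class ResultBundle:
    final_set: tuple[str, ...]
    betas: dict[str, float]
    intercept: float
    bic: float
    r2: float
    n_path: int
    trace: pd.DataFrame
    mccv_summary: dict | None
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(vars(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute similarity ingestion (or RSA), search, weighting, and MCCV.

    Similarity-level input skips the RSA stage; voxel-level input is condensed
    first.  All outputs are written under ``config.out_dir`` and the bundle
    carries a provenance block (config hash, seed).
    """
    from .search import PatternComponentModel

    design = default_design()
    library = standard_library(design, lateralized=(config.library == "lateralized"))
    if config.similarity_path:
        data = load_similarity(config.similarity_path)
    elif config.pattern_paths and config.meta_path:
        patterns = load_patterns(config.pattern_paths, config.meta_path, design)
        data = ConditionSimilarity(design).fit_transform(patterns)
    else:
        raise SchemaError("config must provide similarity_path or pattern+meta paths")

    model = PatternComponentModel(library=library,
                                  delta_accept=config.delta_accept,
                                  delta_equiv=config.delta_equiv)
    model.fit(data)
    trace = search_trace(model.result_, library)

    mccv_summary = None
    if config.mccv_iters > 0:
        cfg = MCCVConfig(n_iter=config.mccv_iters, n_rs=config.n_rs,
                         n_ho=config.n_ho, seed=config.seed,
                         search=SearchConfig(config.delta_accept, config.delta_equiv))
        summary = summarize_mccv(mccv(data, library, cfg))
        mccv_summary = {
            "identification": summary.identification,
            "chance_threshold": summary.chance_threshold,
            "mean_beta": summary.mean_beta,
            "mean_n_path": summary.mean_n_path,
            "mean_r2": summary.mean_r2,
            "mean_p": summary.mean_p,
            "mean_recon_beta": summary.mean_recon_beta,
        }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": _config_hash(config), "seed": config.seed,
                  "library": config.library, "n_participants": int(data.shape[0])}
    bundle = ResultBundle(
        final_set=model.selected_,
        betas={n: float(b) for n, b in zip(model.selected_, model.betas_)},
        intercept=float(model.intercept_),
        bic=float(model.bic_),
        r2=float(model.r2_),
        n_path=model.n_path_,
        trace=trace,
        mccv_summary=mccv_summary,
        provenance=provenance,
    )
    (out / "final_model.json").write_text(json.dumps({
        "final_set": list(bundle.final_set),
        "betas": bundle.betas,
        "intercept": bundle.intercept,
        "bic": bundle.bic,
        "r2": bundle.r2,
        "n_path": bundle.n_path,
        "mccv": bundle.mccv_summary,
        "provenance": bundle.provenance,
    }, indent=2))
    trace.to_csv(out / "search_trace.csv", index=False)
    write_index_map(out / "vector_index_map.json", design.n_conditions)
    return bundle
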