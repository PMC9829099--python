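"""Synthetic datasets with known POI mixture for end-to-end testing.

Two generation modes mirror the two entry points of the pipeline:

* ``similarity`` — each participant's 21-cell condition-similarity vector is
  the linear POI mixture ``intercept + sum(w_k * poi_k)`` plus iid Gaussian
  noise, i.e. exactly the representational model the decomposition fits.
* ``voxel`` — per-participant trials x voxels coefficient matrices whose
  across-voxel trial covariance targets the POI mixture expanded to trial
  level, so running the RSA stage on the output approximately recovers the
  mixture.  The expanded target is repaired to the nearest positive
  semidefinite matrix by clipping negative eigenvalues at zero; voxel
  profiles are mean-zero draws from ``shared_var * PSD(target) +
  noise_var * I``.

Defaults emulate the study conditions: 67 participants, a two-component
mixture (nonspecific touch 0.12, experimental task 0.06) over intercept 0.05
with similarity-level noise SD 0.02 — weights of the magnitude observed for
the dominant somatosensory components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .design import ExperimentDesign, default_design
from .pois import POILibrary
from .rsa import TrialPatternMatrix, devectorize

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "gen_similarity",
    "gen_voxel_patterns",
    "export_fixtures",
    "load_fixtures",
]


def _default_weights() -> dict[str, float]:
    return {"nST": 0.12, "ET": 0.06}


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth mixture and noise for synthetic data.

    ``noise_sd`` is the similarity-level cell noise (Fisher-z units);
    ``shared_var``/``noise_var`` are the structured and white variance
    components of the voxel-level trial covariance.
    """

    n_participants: int = 67
    weights: dict[str, float] = field(default_factory=_default_weights)
    intercept: float = 0.05
    noise_sd: float = 0.02
    n_voxels: int = 500
    shared_var: float = 1.0
    noise_var: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class SyntheticDataset:
    mode: str  # {"similarity", "voxel"}
    similarity: np.ndarray | None  # (n_participants, 21)
    patterns: list[TrialPatternMatrix] | None
    config: GeneratorConfig
    target_vector: np.ndarray
    psd_deviation: float = 0.0  # max |target - PSD repair| at trial level


def _target_vector(config: GeneratorConfig, library: POILibrary) -> np.ndarray:
    n_cells = library.pois[0].vector.size
    target = np.full(n_cells, config.intercept)
    for name, w in config.weights.items():
        target = target + w * library[name].vector  # KeyError on unknown POI
    return target


def gen_similarity(config: GeneratorConfig, library: POILibrary) -> SyntheticDataset:
    """Similarity-level dataset: POI mixture plus iid cell noise, seeded."""
    target = _target_vector(config, library)
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd,
                       size=(config.n_participants, target.size))
    data = target[None, :] + noise
    return SyntheticDataset(mode="similarity", similarity=data, patterns=None,
                            config=config, target_vector=target)


def _psd_clip(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-PSD repair by clipping negative eigenvalues at zero."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    clipped = np.clip(vals, 0.0, None)
    if clipped.max() <= 1e-10 * max(1.0, float(np.abs(vals).max())):
        raise ValueError("target similarity has an all-zero clipped spectrum")
    repaired = (vecs * clipped) @ vecs.T
    repaired = (repaired + repaired.T) / 2.0
    return repaired, float(np.abs(repaired - mat).max())


def gen_voxel_patterns(config: GeneratorConfig,
                       design: ExperimentDesign | None = None,
                       library: POILibrary | None = None) -> SyntheticDataset:
    """Voxel-level dataset whose expected trial similarity matches the mixture.

    The condition-level target (intercept + weighted POIs) is expanded to a
    trials x trials matrix via the trial-to-condition map, PSD-repaired, and
    used as the structured part of the voxel sampling covariance.  Each
    voxel's trial profile is an independent zero-mean Gaussian draw.
    """
    from .pois import standard_library

    design = design if design is not None else default_design()
    library = library if library is not None else standard_library(design)
    target = _target_vector(config, library)
    cond_target = devectorize(target)
    cond = np.array([t.condition_id for t in design.trials])
    trial_target = cond_target[np.ix_(cond, cond)]
    psd, deviation = _psd_clip(trial_target)
    cov = config.shared_var * psd + config.noise_var * np.eye(len(cond))
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cond)))
    rng = np.random.default_rng(config.seed)
    patterns = []
    for p in range(config.n_participants):
        draws = rng.standard_normal((len(cond), config.n_voxels))
        values = chol @ draws  # trials x voxels, each voxel ~ N(0, cov)
        patterns.append(
            TrialPatternMatrix(values=values, trial_meta=design.trials,
                               roi_id="synthetic", participant_id=f"sub{p:03d}")
        )
    return SyntheticDataset(mode="voxel", similarity=None, patterns=patterns,
                            config=config, target_vector=target,
                            psd_deviation=deviation)


def export_fixtures(ds: SyntheticDataset, path: str | Path) -> dict[str, Path]:
    """Write a dataset plus ground truth to ``path``; returns written files.

    Similarity mode: one CSV (participants x cells).  Voxel mode: one CSV per
    participant plus a shared trial-metadata CSV.  Both write a ground-truth
    JSON echoing weights, intercept, noise and seed.
    """
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    truth = {
        "mode": ds.mode,
        "weights": ds.config.weights,
        "intercept": ds.config.intercept,
        "noise_sd": ds.config.noise_sd,
        "seed": ds.config.seed,
        "n_participants": ds.config.n_participants,
        "target_vector": ds.target_vector.tolist(),
    }
    if ds.mode == "similarity":
        f = path / "similarity.csv"
        pd.DataFrame(
            ds.similarity,
            index=[f"sub{i:03d}" for i in range(ds.similarity.shape[0])],
            columns=[f"cell{j:02d}" for j in range(ds.similarity.shape[1])],
        ).to_csv(f, index_label="participant_id")
        written["similarity"] = f
    else:
        meta = ds.patterns[0].trial_meta
        mf = path / "trial_metadata.csv"
        pd.DataFrame(
            [{"trial_id": t.trial_id, "condition_id": t.condition_id,
              "block_id": t.block_id, "task": t.task} for t in meta]
        ).to_csv(mf, index=False)
        written["metadata"] = mf
        for p in ds.patterns:
            f = path / f"patterns_{p.participant_id}.csv"
            pd.DataFrame(p.values).to_csv(f, index=False)
            written[p.participant_id] = f
    tf = path / "ground_truth.json"
    tf.write_text(json.dumps(truth, indent=2))
    written["ground_truth"] = tf
    return written


def load_fixtures(path: str | Path) -> SyntheticDataset:
    """Round-trip reader for :func:`export_fixtures` output."""
    import pandas as pd

    from .design import default_design
    from .io import load_patterns

    path = Path(path)
    truth = json.loads((path / "ground_truth.json").read_text())
    config = GeneratorConfig(
        n_participants=truth["n_participants"],
        weights=truth["weights"],
        intercept=truth["intercept"],
        noise_sd=truth["noise_sd"],
        seed=truth["seed"],
    )
    target = np.asarray(truth["target_vector"])
    if truth["mode"] == "similarity":
        df = pd.read_csv(path / "similarity.csv", index_col=0)
        return SyntheticDataset(mode="similarity", similarity=df.to_numpy(),
                                patterns=None, config=config, target_vector=target)
    patterns = load_patterns(sorted(path.glob("patterns_*.csv")),
                             path / "trial_metadata.csv",
                             design=default_design())
    return SyntheticDataset(mode="voxel", similarity=None, patterns=patterns,
                            config=config, target_vector=target)
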