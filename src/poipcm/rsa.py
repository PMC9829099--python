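"""Trial-level representational similarity and condition-level condensation.

Trial activation patterns (trials x voxels regression coefficients) are
correlated pairwise (Pearson, across voxels), Fisher z-transformed, and then
down-sampled to a condition-by-condition similarity matrix.  Within-condition
cells average the 30 ordered same-condition trial pairs (auto-correlations on
the diagonal removed); between-condition cells average the full 36-pair cross
block at the default 6 repetitions per condition.  Values stay on the Fisher-z
scale throughout; no back-transform to r is applied before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ExperimentDesign, TrialEvent

__all__ = [
    "RSAError",
    "Z_CAP_EPS",
    "TrialPatternMatrix",
    "fisher_z",
    "trial_similarity",
    "condense",
    "vectorize",
    "devectorize",
    "vector_index_map",
    "similarity_vector",
    "ConditionSimilarity",
]

#: |r| at which the Fisher transform is clamped; atanh(1 - 1e-7) ~ 8.4.
Z_CAP_EPS = 1e-7


class RSAError(ValueError):
    """Raised for degenerate patterns or malformed similarity inputs."""


@dataclass
class TrialPatternMatrix:
    """Trials x voxels regression coefficients with trial metadata."""

    values: np.ndarray
    trial_meta: tuple[TrialEvent, ...]
    roi_id: str = "roi"
    participant_id: str = "sub"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RSAError("pattern matrix must be 2-D (trials x voxels)")
        if self.values.shape[1] < 2:
            raise RSAError("pattern matrix needs at least 2 voxels")
        if len(self.trial_meta) != self.values.shape[0]:
            raise RSAError(
                f"metadata rows ({len(self.trial_meta)}) != pattern rows "
                f"({self.values.shape[0]})"
            )
        if not np.all(np.isfinite(self.values)):
            raise RSAError("pattern matrix contains non-finite values")


def fisher_z(r, eps: float = Z_CAP_EPS):
    """Fisher z-transform atanh(r), clamped near |r| = 1.

    Correlations with ``|r| >= 1 - eps`` map to ``+/- atanh(1 - eps)`` so the
    transform stays finite; ``|r| > 1`` (beyond float tolerance) is a domain
    error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise RSAError("correlation outside [-1, 1]")
    clipped = np.clip(r, -(1 - eps), 1 - eps)
    out = np.arctanh(clipped)
    return out if out.ndim else float(out)


def trial_similarity(patterns: TrialPatternMatrix) -> np.ndarray:
    """Fisher-z trial-by-trial similarity matrix of a pattern matrix.

    Pearson correlation is computed across voxels for every trial pair.  Rows
    with zero variance cannot be correlated and raise :class:`RSAError`
    naming the offending trial.
    """
    x = patterns.values
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise RSAError(f"zero-variance pattern for trial(s) {dead.tolist()}")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)  # guard float overshoot
    z = fisher_z(r)
    return np.asarray((z + z.T) / 2.0)


def condense(tsm: np.ndarray, design: ExperimentDesign,
             trial_meta: tuple[TrialEvent, ...] | None = None) -> np.ndarray:
    """Down-sample a trial similarity matrix to condition-by-condition means.

    Parameters
    ----------
    tsm : ndarray
        Trials x trials Fisher-z similarity (symmetric).
    design : ExperimentDesign
        Supplies the condition count and, when ``trial_meta`` is omitted, the
        trial-to-condition mapping.
    trial_meta : tuple of TrialEvent, optional
        Per-row metadata when the rows of ``tsm`` are not in design order.

    Returns
    -------
    ndarray
        m x m matrix; diagonal cells are means over ordered same-condition
        pairs excluding self-pairs, off-diagonal cells means over the full
        cross block.
    """
    tsm = np.asarray(tsm, dtype=float)
    meta = trial_meta if trial_meta is not None else design.trials
    if tsm.shape[0] != tsm.shape[1] or tsm.shape[0] != len(meta):
        raise RSAError("trial similarity shape does not match trial metadata")
    m = design.n_conditions
    cond = np.array([t.condition_id for t in meta])
    idx = [np.flatnonzero(cond == c) for c in range(m)]
    for c, rows in enumerate(idx):
        if rows.size < 2:
            raise RSAError(f"condition {c} has fewer than 2 repetitions")
    out = np.empty((m, m))
    for c in range(m):
        block = tsm[np.ix_(idx[c], idx[c])]
        n = block.shape[0]
        out[c, c] = (block.sum() - np.trace(block)) / (n * (n - 1))
        for d in range(c + 1, m):
            cross = tsm[np.ix_(idx[c], idx[d])]
            out[c, d] = out[d, c] = cross.mean()
    return out


def condensation_counts(design: ExperimentDesign) -> tuple[int, int]:
    """Number of trial pairs averaged into a within- and a between-condition
    cell (30 and 36 at the default 6 repetitions)."""
    n = design.reps_per_condition
    return n * (n - 1), n * n


def vector_index_map(m: int = 6) -> list[tuple[int, int]]:
    """Row-major upper-triangle (with diagonal) cell order used throughout."""
    return [(i, j) for i in range(m) for j in range(i, m)]


def vectorize(csm: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Vectorize a symmetric m x m matrix to its m(m+1)/2 upper-triangle cells."""
    csm = np.asarray(csm, dtype=float)
    if csm.ndim != 2 or csm.shape[0] != csm.shape[1]:
        raise RSAError("expected a square matrix")
    if not np.allclose(csm, csm.T, atol=atol):
        raise RSAError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(csm.shape[0])
    return csm[iu]


def devectorize(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    vec = np.asarray(vec, dtype=float)
    m = int(round((np.sqrt(8 * vec.size + 1) - 1) / 2))
    if m * (m + 1) // 2 != vec.size:
        raise RSAError(f"vector length {vec.size} is not triangular")
    out = np.zeros((m, m))
    iu = np.triu_indices(m)
    out[iu] = vec
    return out + np.triu(out, 1).T


def similarity_vector(patterns: TrialPatternMatrix,
                      design: ExperimentDesign) -> np.ndarray:
    """Full per-participant pipeline: patterns -> 21-cell similarity vector."""
    tsm = trial_similarity(patterns)
    csm = condense(tsm, design, patterns.trial_meta)
    return vectorize(csm)


class ConditionSimilarity:
    """Transformer mapping trial pattern matrices to condition similarity.

    Follows the scikit-learn transformer protocol: ``fit`` records the design,
    ``transform`` maps a sequence of :class:`TrialPatternMatrix` to a
    participants x 21 array of condensed Fisher-z similarity vectors.
    """

    def __init__(self, design: ExperimentDesign | None = None):
        self.design = design

    def get_params(self, deep: bool = True) -> dict:
        return {"design": self.design}

    def set_params(self, **params) -> "ConditionSimilarity":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "ConditionSimilarity":
        from .design import default_design

        self.design_ = self.design if self.design is not None else default_design()
        self.n_cells_ = self.design_.n_conditions * (self.design_.n_conditions + 1) // 2
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "design_"):
            self.fit()
        return np.vstack([similarity_vector(p, self.design_) for p in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
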