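"""POI-combination regression, BIC scoring, and greedy best-first search.

The observed data are participants' 21-cell condition-similarity vectors
stacked into one response vector.  Candidate models are ordinary least squares
fits of that response on an intercept plus the vectorized POIs (tiled per
participant).  Model comparison uses the Gaussian-likelihood BIC

    BIC = n ln(RSS / n) + p ln(n),      p = regressors + intercept + variance,

and the greedy best-first search accepts, per path, the best candidate POI
whose BIC improves on the path's current BIC by more than ``delta_accept``
(default 2); candidates within ``delta_equiv`` of the level's best that also
pass the acceptance rule spawn additional paths, each extended to completion.
Only BIC differences matter for selection, so any affine-consistent BIC
variant yields identical decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .pois import POILibrary

__all__ = [
    "SearchError",
    "CollinearityError",
    "ModelFit",
    "SearchConfig",
    "SearchPath",
    "SearchResult",
    "bic",
    "fit_model",
    "gbfs_search",
    "best_subset_search",
    "search_trace",
    "PatternComponentModel",
]

_RSS_FLOOR = 1e-12


class SearchError(ValueError):
    pass


class CollinearityError(SearchError):
    """Design matrix is rank deficient for the requested POI set."""


@dataclass(frozen=True)
class ModelFit:
    """OLS fit of stacked similarity on an intercept plus POI vectors."""

    poi_set: tuple[str, ...]
    betas: tuple[float, ...]
    intercept: float
    rss: float
    n_obs: int
    k_params: int
    bic: float
    r2: float

    @property
    def coef_map(self) -> dict[str, float]:
        return dict(zip(self.poi_set, self.betas))


@dataclass(frozen=True)
class SearchConfig:
    delta_accept: float = 2.0
    delta_equiv: float = 2.0
    max_levels: int | None = None
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.delta_accept <= 0 or self.delta_equiv <= 0:
            raise SearchError("BIC thresholds must be positive")


@dataclass
class SearchPath:
    """One completed greedy path: accepted POIs and the per-level BIC tables."""

    accepted: tuple[str, ...]
    terminal_fit: ModelFit
    levels: list[dict[str, float]] = field(default_factory=list)


@dataclass
class SearchResult:
    final_set: tuple[str, ...]
    final_fit: ModelFit
    paths: list[SearchPath]
    baseline_none: ModelFit
    baseline_all: ModelFit | None

    @property
    def n_path(self) -> int:
        return len(self.paths)


def bic(rss: float, n_obs: int, k_params: int) -> float:
    """Gaussian BIC from a residual sum of squares.

    ``k_params`` counts the mean-model parameters (regressors + intercept);
    the error variance is counted as one further parameter.
    """
    if n_obs <= k_params:
        raise SearchError(f"n_obs ({n_obs}) must exceed k_params ({k_params})")
    rss = max(float(rss), _RSS_FLOOR)
    return n_obs * np.log(rss / n_obs) + (k_params + 1) * np.log(n_obs)


def _stack(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if not np.all(np.isfinite(data)):
        raise SearchError("similarity data contain non-finite values")
    return data


def fit_model(data: np.ndarray, library: POILibrary,
              poi_names=()) -> ModelFit:
    """OLS of stacked similarity vectors on intercept + selected POIs.

    Parameters
    ----------
    data : ndarray, shape (n_participants, n_cells)
        Per-participant condition-similarity vectors.
    library : POILibrary
        Source of POI vectors.
    poi_names : sequence of str
        POIs to include; empty gives the intercept-only ("None") baseline.
    """
    data = _stack(data)
    n_sub, n_cells = data.shape
    y = data.ravel()
    names = tuple(poi_names)
    cols = [np.ones(n_cells)]
    for name in names:
        v = library[name].vector
        if v.size != n_cells:
            raise SearchError(f"POI {name!r} has {v.size} cells, data has {n_cells}")
        cols.append(v)
    X_cell = np.column_stack(cols)
    X = np.tile(X_cell, (n_sub, 1))
    k = X.shape[1]
    n = y.size
    if n <= k:
        raise SearchError("more parameters than observations")
    rank = np.linalg.matrix_rank(X_cell)
    if rank < k:
        raise CollinearityError(
            f"POI set {list(names)} is collinear (rank {rank} < {k})"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    return ModelFit(
        poi_set=names,
        betas=tuple(float(b) for b in coef[1:]),
        intercept=float(coef[0]),
        rss=rss,
        n_obs=n,
        k_params=k,
        bic=bic(rss, n, k),
        r2=r2,
    )


def _extend_path(data, library, config, parent_set, parent_fit, levels,
                 completed, seen_terminal, tie_tol=1e-9):
    """Depth-first path extension with equivalency branching."""
    remaining = [n for n in library.names if n not in parent_set]
    if not remaining or (config.max_levels is not None
                        and len(parent_set) >= config.max_levels):
        _finish(parent_set, parent_fit, levels, completed, seen_terminal, config)
        return
    fits = {}
    for name in remaining:
        try:
            fits[name] = fit_model(data, library, parent_set + (name,))
        except CollinearityError:
            continue
    accepted = {n: f for n, f in fits.items()
                if parent_fit.bic - f.bic > config.delta_accept}
    level_table = {n: f.bic for n, f in fits.items()}
    if not accepted:
        _finish(parent_set, parent_fit, levels + [level_table],
                completed, seen_terminal, config)
        return
    best_bic = min(f.bic for f in accepted.values())
    # Best candidate first (ties broken by library order), then equivalents.
    branch_names = [n for n in library.names
                    if n in accepted and accepted[n].bic <= best_bic + config.delta_equiv]
    exact_best = [n for n in branch_names
                  if abs(accepted[n].bic - best_bic) <= tie_tol]
    ordered = exact_best[:1] + [n for n in branch_names if n not in exact_best[:1]]
    for name in ordered:
        _extend_path(data, library, config, parent_set + (name,), accepted[name],
                     levels + [level_table], completed, seen_terminal, tie_tol)


def _finish(poi_set, fit, levels, completed, seen_terminal, config):
    key = frozenset(poi_set)
    if config.dedupe and key in seen_terminal:
        return
    seen_terminal.add(key)
    completed.append(SearchPath(accepted=poi_set, terminal_fit=fit, levels=levels))


def gbfs_search(data: np.ndarray, library: POILibrary,
                config: SearchConfig | None = None) -> SearchResult:
    """Greedy best-first search over POI combinations with BIC scoring.

    Starts from the intercept-only baseline; a first POI is accepted only if
    it beats that baseline by more than ``delta_accept``, so on null data the
    final set is empty.  Returns the terminal set with minimal BIC across all
    completed paths, along with every path's trace.
    """
    if len(library) == 0:
        raise SearchError("empty POI library")
    config = config if config is not None else SearchConfig()
    data = _stack(data)
    baseline = fit_model(data, library, ())
    try:
        baseline_all = fit_model(data, library, tuple(library.names))
    except (CollinearityError, SearchError):
        baseline_all = None
    completed: list[SearchPath] = []
    seen: set[frozenset] = set()
    _extend_path(data, library, config, (), baseline, [], completed, seen)
    best = min(completed, key=lambda p: p.terminal_fit.bic)
    return SearchResult(
        final_set=best.accepted,
        final_fit=best.terminal_fit,
        paths=completed,
        baseline_none=baseline,
        baseline_all=baseline_all,
    )


def best_subset_search(data: np.ndarray, library: POILibrary,
                       max_size: int | None = None) -> ModelFit:
    """Exhaustive best-subset BIC minimization (test oracle, not the default).

    Enumerates every POI subset (2^k fits); intended for small libraries and
    for validating the greedy search on constructed data.
    """
    data = _stack(data)
    names = library.names
    max_size = len(names) if max_size is None else max_size
    best = fit_model(data, library, ())
    for size in range(1, max_size + 1):
        for subset in combinations(names, size):
            try:
                fit = fit_model(data, library, subset)
            except CollinearityError:
                continue
            if fit.bic < best.bic:
                best = fit
    return best


def search_trace(result: SearchResult, library: POILibrary):
    """Flatten a search result into a per-path, per-level candidate BIC table.

    Returns a pandas DataFrame with one row per (path, level): the POIs held
    going into the level, each candidate's BIC, and reference columns for the
    intercept-only ("None") and all-POI ("All") fits.
    """
    import pandas as pd

    rows = []
    all_bic = result.baseline_all.bic if result.baseline_all is not None else np.nan
    for p_idx, path in enumerate(result.paths):
        for lvl, table in enumerate(path.levels):
            row = {
                "path": p_idx,
                "level": lvl + 1,
                "included": "+".join(path.accepted[:lvl]) or "-",
                "None": result.baseline_none.bic,
                "All": all_bic,
            }
            for name in library.names:
                row[name] = table.get(name, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


class PatternComponentModel:
    """Greedy BIC decomposition of condition similarity into weighted POIs.

    A scikit-learn-style estimator.  ``fit`` takes a participants x cells
    array of Fisher-z condition-similarity vectors, runs the greedy best-first
    BIC search over the configured POI library, and refits the selected POIs
    for their weights.  ``predict`` returns the reconstructed similarity
    vector (intercept + weighted POI sum) tiled per requested participant
    count; ``score`` is the R^2 of that reconstruction against held-out data.

    Parameters
    ----------
    library : POILibrary, optional
        POI library to search; defaults to the 13-POI standard library.
    delta_accept, delta_equiv : float
        BIC improvement and equivalency-branching thresholds (default 2).
    max_levels : int, optional
        Cap on the number of accepted POIs per path.

    Attributes
    ----------
    selected_ : tuple of str
        Names of POIs in the winning combination.
    betas_ : ndarray
        Weight per selected POI (Fisher-z units).
    intercept_ : float
    bic_ : float
    r2_ : float
    n_path_ : int
        Number of completed search paths.
    result_ : SearchResult
        Full search record including baselines and per-level BIC tables.
    """

    def __init__(self, library: POILibrary | None = None,
                 delta_accept: float = 2.0, delta_equiv: float = 2.0,
                 max_levels: int | None = None, dedupe: bool = True):
        self.library = library
        self.delta_accept = delta_accept
        self.delta_equiv = delta_equiv
        self.max_levels = max_levels
        self.dedupe = dedupe

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "library": self.library,
            "delta_accept": self.delta_accept,
            "delta_equiv": self.delta_equiv,
            "max_levels": self.max_levels,
            "dedupe": self.dedupe,
        }

    def set_params(self, **params) -> "PatternComponentModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _library(self) -> POILibrary:
        if self.library is not None:
            return self.library
        from .pois import standard_library

        return standard_library()

    # -- estimator API -----------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "PatternComponentModel":
        X = _stack(X)
        lib = self._library()
        config = SearchConfig(self.delta_accept, self.delta_equiv,
                              self.max_levels, self.dedupe)
        result = gbfs_search(X, lib, config)
        self.result_ = result
        self.selected_ = result.final_set
        fit = result.final_fit
        self.betas_ = np.asarray(fit.betas)
        self.intercept_ = fit.intercept
        self.bic_ = fit.bic
        self.r2_ = fit.r2
        self.n_path_ = result.n_path
        self.n_cells_ = X.shape[1]
        return self

    def reconstruction_(self) -> np.ndarray:
        """Predicted 21-cell similarity vector from the fitted weights."""
        self._check_fitted()
        lib = self._library()
        out = np.full(self.n_cells_, self.intercept_)
        for name, beta in zip(self.selected_, self.betas_):
            out = out + beta * lib[name].vector
        return out

    def predict(self, X=None, n_participants: int | None = None) -> np.ndarray:
        """Reconstructed similarity vectors, one row per participant.

        ``X`` (if given) only sets the output row count, matching the
        transformer convention that predictions align with inputs.
        """
        recon = self.reconstruction_()
        if n_participants is None:
            n_participants = 1 if X is None else _stack(X).shape[0]
        return np.tile(recon, (n_participants, 1))

    def score(self, X: np.ndarray, y=None) -> float:
        """R^2 of the tiled reconstruction against ``X`` (stacked cells)."""
        X = _stack(X)
        pred = self.predict(X).ravel()
        obs = X.ravel()
        ss_res = float(((obs - pred) ** 2).sum())
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot if ss_tot else 0.0

    def _check_fitted(self) -> None:
        if not hasattr(self, "selected_"):
            raise SearchError("PatternComponentModel is not fitted")
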