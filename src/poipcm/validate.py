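"""Monte Carlo cross-validation of POI decompositions and n-path comparison.

Each MCCV iteration draws a random sample (RS, default 60 participants) and a
hold-out (HO, default 7), runs the greedy BIC search on the stacked RS
similarity vectors, refits the selected POIs for their weights, reconstructs
the predicted 21-cell similarity vector, and fits that single reconstructed
predictor (plus intercept) to the stacked hold-out cells.  With 7 hold-out
participants the hold-out regression has 7 x 21 = 147 observations and
denominator degrees of freedom 145.

Summaries follow the convention that a POI's mean contributing weight is
reported only when its identification proportion exceeds the chance level
mean(|selected set|) / |library|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .pois import POILibrary
from .search import (ModelFit, PatternComponentModel, SearchConfig, SearchError,
                     fit_model, gbfs_search)

__all__ = [
    "ValidationError",
    "HoldoutFit",
    "MCCVConfig",
    "MCCVIterationRecord",
    "MCCVResult",
    "MCCVSummary",
    "NPathComparison",
    "reconstruct",
    "holdout_fit",
    "mccv",
    "summarize_mccv",
    "npath_compare",
]


class ValidationError(ValueError):
    pass


def reconstruct(poi_weights: dict[str, float], intercept: float,
                library: POILibrary) -> np.ndarray:
    """Predicted similarity vector: intercept + sum of beta-weighted POIs."""
    n_cells = library.pois[0].vector.size if len(library) else 21
    out = np.full(n_cells, float(intercept))
    for name, beta in poi_weights.items():
        out = out + float(beta) * library[name].vector  # KeyError on unknown name
    return out


@dataclass(frozen=True)
class HoldoutFit:
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    recon_beta: float
    intercept: float


def holdout_fit(recon: np.ndarray, holdout: np.ndarray) -> HoldoutFit:
    """Regress stacked hold-out similarity cells on the reconstructed vector.

    The single group-level reconstruction is tiled per hold-out participant
    and fitted with an intercept; reports R^2, the model F statistic with
    df (1, n_holdout * n_cells - 2), its p value, and the slope.
    """
    recon = np.asarray(recon, dtype=float).ravel()
    holdout = np.asarray(holdout, dtype=float)
    if holdout.ndim == 1:
        holdout = holdout[None, :]
    if holdout.shape[1] != recon.size:
        raise ValidationError("hold-out cell count does not match reconstruction")
    if np.ptp(recon) == 0:
        raise ValidationError("reconstructed predictor is constant")
    n_sub = holdout.shape[0]
    x = np.tile(recon, n_sub)
    y = holdout.ravel()
    n = y.size
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    df = (1, n - 2)
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = df[1] * r2 / (1.0 - r2)
        p = float(stats.f.sf(f, *df))
    return HoldoutFit(r2=r2, f_stat=float(f), df=df, p_value=p,
                      recon_beta=float(res.slope), intercept=float(res.intercept))


@dataclass(frozen=True)
class MCCVConfig:
    """Monte Carlo cross-validation parameters (defaults mirror RS=60/HO=7,
    1000 iterations)."""

    n_iter: int = 1000
    n_rs: int = 60
    n_ho: int = 7
    seed: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if self.n_rs < 1 or self.n_ho < 1:
            raise ValidationError("n_rs and n_ho must be >= 1")


@dataclass(frozen=True)
class MCCVIterationRecord:
    iteration: int
    rs_ids: tuple[int, ...]
    ho_ids: tuple[int, ...]
    poi_set: tuple[str, ...]
    betas: tuple[float, ...]
    intercept: float
    n_path: int
    holdout: HoldoutFit | None


@dataclass
class MCCVResult:
    records: list[MCCVIterationRecord]
    library_names: tuple[str, ...]
    config: MCCVConfig


@dataclass
class MCCVSummary:
    identification: dict[str, float]
    chance_threshold: float
    mean_beta: dict[str, float]
    mean_set_size: float
    mean_n_path: float
    mean_r2: float
    mean_p: float
    mean_recon_beta: float
    n_iter: int


def mccv(dataset: np.ndarray, library: POILibrary,
         config: MCCVConfig | None = None) -> MCCVResult:
    """Monte Carlo cross-validation over participants.

    Parameters
    ----------
    dataset : ndarray, shape (n_participants, n_cells)
        Per-participant condition-similarity vectors.
    library : POILibrary
    config : MCCVConfig
        Iteration count, RS/HO sizes, seed, and search thresholds.

    Each iteration samples ``n_rs`` participants uniformly without
    replacement; the first ``n_ho`` of the remainder form the hold-out.  The
    whole procedure is a pure function of (dataset, library, config.seed).
    """
    config = config if config is not None else MCCVConfig()
    data = np.asarray(dataset, dtype=float)
    n_sub = data.shape[0]
    if n_sub < config.n_rs + config.n_ho:
        raise ValidationError(
            f"need >= {config.n_rs + config.n_ho} participants, have {n_sub}"
        )
    rng = np.random.default_rng(config.seed)
    records: list[MCCVIterationRecord] = []
    for it in range(config.n_iter):
        perm = rng.permutation(n_sub)
        rs_ids = np.sort(perm[: config.n_rs])
        ho_ids = np.sort(perm[config.n_rs: config.n_rs + config.n_ho])
        result = gbfs_search(data[rs_ids], library, config.search)
        fit = result.final_fit
        ho: HoldoutFit | None = None
        if fit.poi_set:
            recon = reconstruct(fit.coef_map, fit.intercept, library)
            ho = holdout_fit(recon, data[ho_ids])
        records.append(
            MCCVIterationRecord(
                iteration=it,
                rs_ids=tuple(int(i) for i in rs_ids),
                ho_ids=tuple(int(i) for i in ho_ids),
                poi_set=fit.poi_set,
                betas=fit.betas,
                intercept=fit.intercept,
                n_path=result.n_path,
                holdout=ho,
            )
        )
    return MCCVResult(records=records, library_names=tuple(library.names),
                      config=config)


def summarize_mccv(result: MCCVResult) -> MCCVSummary:
    """Collapse MCCV iterations into per-POI identification proportions,
    above-chance mean weights, and mean hold-out statistics."""
    if not result.records:
        raise ValidationError("empty MCCV result")
    n = len(result.records)
    names = result.library_names
    counts = {name: 0 for name in names}
    beta_sums = {name: 0.0 for name in names}
    for rec in result.records:
        for name, beta in zip(rec.poi_set, rec.betas):
            counts[name] += 1
            beta_sums[name] += beta
    identification = {name: counts[name] / n for name in names}
    mean_set_size = float(np.mean([len(r.poi_set) for r in result.records]))
    chance = mean_set_size / len(names)
    mean_beta = {
        name: beta_sums[name] / counts[name]
        for name in names
        if counts[name] and identification[name] > chance
    }
    ho = [r.holdout for r in result.records if r.holdout is not None]
    return MCCVSummary(
        identification=identification,
        chance_threshold=chance,
        mean_beta=mean_beta,
        mean_set_size=mean_set_size,
        mean_n_path=float(np.mean([r.n_path for r in result.records])),
        mean_r2=float(np.mean([h.r2 for h in ho])) if ho else np.nan,
        mean_p=float(np.mean([h.p_value for h in ho])) if ho else np.nan,
        mean_recon_beta=float(np.mean([h.recon_beta for h in ho])) if ho else np.nan,
        n_iter=n,
    )


@dataclass
class NPathComparison:
    f_stat: float
    df: tuple[int, int]
    p_value: float
    pairwise: dict[tuple[str, str], dict[str, float]]
    n_comparisons: int


def npath_compare(samples: dict[str, "np.ndarray | list"]) -> NPathComparison:
    """One-way ANOVA plus Bonferroni-corrected pairwise t tests on per-ROI
    n-path samples.

    ``samples`` maps ROI name to its per-iteration n-path values.  Adjusted
    pairwise p values are ``min(1, raw p x number of pairs)``.  If every group
    is an identical constant the omnibus F is reported as 0 with p = 1.
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} has fewer than 2 samples")
    arrays = list(groups.values())
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df = (k - 1, n_total - k)
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
    pairs = list(combinations(groups.keys(), 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            t, raw = 0.0, 1.0
        else:
            t, raw = stats.ttest_ind(xa, xb)
            t, raw = float(t), float(raw)
        pairwise[(a, b)] = {
            "t": t,
            "p_raw": raw,
            "p_adj": min(1.0, raw * m),
        }
    return NPathComparison(f_stat=f_stat, df=df, p_value=p,
                           pairwise=pairwise, n_comparisons=m)
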