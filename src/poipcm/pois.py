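"""Patterns of interest: idealized condition-level similarity matrices.

A POI is the 6 x 6 condition similarity matrix that would be observed if a
region represented exactly one type of task information perfectly: cells are
+1 (identical representation), -1 (opposite poles of one representational
axis) or 0 (unrelated).  The standard library holds the 13 base patterns
(task, touch, valence, salience, face identity, expectation, temporal
adjacency) plus two lateralized specific-touch variants for unilateral S1
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ExperimentDesign, default_design
from .rsa import vectorize

__all__ = [
    "POIError",
    "POISpec",
    "POI",
    "POILibrary",
    "build_poi",
    "standard_library",
    "BASE_POI_NAMES",
    "LATERALIZED_POI_NAMES",
]


class POIError(ValueError):
    """Raised for conflicting or malformed POI specifications."""


@dataclass(frozen=True)
class POISpec:
    """Declarative POI recipe.

    ``positive_groups`` are condition-id sets whose within-group pairs get +1
    (diagonal included unless ``include_diagonal`` is False);
    ``negative_group_pairs`` are pairs of sets whose cross pairs get -1.
    """

    name: str
    positive_groups: tuple[frozenset[int], ...] = ()
    negative_group_pairs: tuple[tuple[frozenset[int], frozenset[int]], ...] = ()
    include_diagonal: bool = True
    abbreviation: str = ""


@dataclass(frozen=True)
class POI:
    name: str
    abbreviation: str
    m: np.ndarray
    vector: np.ndarray

    def __eq__(self, other) -> bool:  # identity by matrix content
        return isinstance(other, POI) and self.name == other.name and np.array_equal(self.m, other.m)

    def __hash__(self) -> int:
        return hash((self.name, self.m.tobytes()))


@dataclass
class POILibrary:
    """Ordered collection of distinct POIs."""

    pois: tuple[POI, ...]
    lateralized: bool = False

    def __post_init__(self) -> None:
        seen: dict[bytes, str] = {}
        for p in self.pois:
            key = p.m.tobytes()
            if key in seen:
                raise POIError(f"POIs {seen[key]!r} and {p.name!r} have identical matrices")
            seen[key] = p.name

    def __len__(self) -> int:
        return len(self.pois)

    def __iter__(self):
        return iter(self.pois)

    def __getitem__(self, name: str) -> POI:
        for p in self.pois:
            if name in (p.name, p.abbreviation):
                return p
        raise KeyError(f"no POI named {name!r}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pois]

    def design_matrix(self) -> np.ndarray:
        """Cells x POIs matrix of stacked POI vectors (no intercept column)."""
        return np.column_stack([p.vector for p in self.pois])

    def subset(self, names) -> "POILibrary":
        return POILibrary(tuple(self[n] for n in names), lateralized=self.lateralized)


def build_poi(spec: POISpec, design: ExperimentDesign | None = None) -> POI:
    """Materialize a :class:`POISpec` into a symmetric {-1, 0, +1} matrix.

    Raises :class:`POIError` if any cell would receive both +1 and -1.
    """
    design = design if design is not None else default_design()
    m = design.n_conditions
    pos = np.zeros((m, m), dtype=bool)
    neg = np.zeros((m, m), dtype=bool)
    valid = range(m)
    for group in spec.positive_groups:
        g = sorted(group)
        if any(c not in valid for c in g):
            raise POIError(f"{spec.name}: condition id outside design in {g}")
        for i in g:
            for j in g:
                if i == j and not spec.include_diagonal:
                    continue
                pos[i, j] = True
    for a, b in spec.negative_group_pairs:
        for i in sorted(a):
            for j in sorted(b):
                if i not in valid or j not in valid:
                    raise POIError(f"{spec.name}: condition id outside design")
                neg[i, j] = neg[j, i] = True
    if np.any(pos & neg):
        cells = np.argwhere(pos & neg)
        raise POIError(f"{spec.name}: cells assigned both +1 and -1: {cells.tolist()}")
    mat = pos.astype(int) - neg.astype(int)
    mat = np.asarray(mat, dtype=float)
    return POI(name=spec.name, abbreviation=spec.abbreviation or spec.name,
               m=mat, vector=vectorize(mat))


#: Condition-id groups of the canonical order [P+1, P+2, P-, B+1, B+2, B-].
_P_PLUS = frozenset({0, 1})
_B_PLUS = frozenset({3, 4})
_PT = frozenset({2, 3, 4})      # brush CS+ and pressure-task CS- (safety)
_NT = frozenset({0, 1, 5})      # pressure CS+ and brush-task CS- (omission)
_HI = _P_PLUS | _B_PLUS         # touch-stimulated, high salience
_LO = frozenset({2, 5})         # unstimulated CS-, low salience
_PRESSURE_TASK = frozenset({0, 1, 2})
_BRUSH_TASK = frozenset({3, 4, 5})

BASE_POI_NAMES = ("ET", "nST", "ST", "AB", "AP", "TV", "PE", "NE", "AV",
                  "Sa", "FS", "VE", "TA")
LATERALIZED_POI_NAMES = ("rST", "lST")


def _base_specs() -> list[POISpec]:
    singletons = tuple(frozenset({i}) for i in range(6))
    return [
        POISpec("ET", (_PRESSURE_TASK, _BRUSH_TASK)),
        POISpec("nST", (_HI,)),
        POISpec("ST", (_P_PLUS, _B_PLUS, _LO)),
        POISpec("AB", (_B_PLUS,), abbreviation="AC"),
        POISpec("AP", (_P_PLUS,)),
        POISpec("TV", (_P_PLUS, _B_PLUS), ((_P_PLUS, _B_PLUS),)),
        POISpec("PE", (_PT,)),
        POISpec("NE", (_NT,)),
        POISpec("AV", (_PT, _NT), ((_PT, _NT),)),
        POISpec("Sa", (_HI, _LO), ((_HI, _LO),)),
        POISpec("FS", singletons),
        POISpec("VE", (_LO,)),
        # Same-block (temporally adjacent) pairs are the same-task
        # cross-condition cells; the diagonal is excluded because
        # within-condition averaging removes temporally adjacent pairs.
        POISpec("TA", (_PRESSURE_TASK, _BRUSH_TASK), include_diagonal=False),
    ]


def standard_library(design: ExperimentDesign | None = None,
                     lateralized: bool = False) -> POILibrary:
    """The 13 base POIs, optionally extended with the rST/lST lateralized pair.

    Only the default 6-condition design is supported; other designs must use
    :func:`build_poi` with explicit specs.
    """
    design = design if design is not None else default_design()
    if design.n_conditions != 6:
        raise POIError("standard library requires the default 6-condition design")
    specs = _base_specs()
    if lateralized:
        specs += [
            # Right-body touch: aversive pressure (right thumb) distinct from
            # generic scanner touch felt on the right during all other trials.
            POISpec("rST", (_P_PLUS, frozenset({2, 3, 4, 5}))),
            # Left-body touch: appetitive brush (left forearm) distinct from
            # generic left-side scanner touch.
            POISpec("lST", (_B_PLUS, frozenset({0, 1, 2, 5}))),
        ]
    pois = tuple(build_poi(s, design) for s in specs)
    return POILibrary(pois, lateralized=lateralized)
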