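"""Assignment of bins or genes to chromatin regulatory complexes.

A complex is declared by its member tracks and the minimum number of members
whose occupancy is required: here PEAT needs any two of UBP5/EPCR1/PWWP1,
NuA4 needs both HAM1 and EPL1B, PRC2 needs both CLF and SWN, and JMJ14 is a
single-protein rule.  Presence is decided on occupancy alone (decile > 0);
decile magnitude is kept only for display ordering.  The assigned complex
subsets are turned into mutually exclusive category labels (canonical sorted
join, "Unassigned" for the empty subset, optionally collapsing subsets of
three or more complexes into one "Multi(3+)" label), and each row also gets
the combination of TRB paralogs occupying it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "ComplexRule",
    "ComplexScheme",
    "DEFAULT_SCHEME",
    "DEFAULT_TRB_TRACKS",
    "assign_complexes",
    "categorize",
    "trb_combination",
    "correlation_matrix",
]

MULTI_LABEL = "Multi(3+)"
UNASSIGNED_LABEL = "Unassigned"
DEFAULT_TRB_TRACKS = ("TRB1", "TRB2", "TRB3")


@dataclass(frozen=True)
class ComplexRule:
    name: str
    members: tuple[str, ...]
    min_members: int

    def __post_init__(self) -> None:
        if not 1 <= self.min_members <= len(self.members):
            raise ValueError(
                f"complex {self.name!r}: min_members must be in 1..{len(self.members)}"
            )


@dataclass(frozen=True)
class ComplexScheme:
    complexes: tuple[ComplexRule, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.complexes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate complex names in scheme")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.complexes]

    @classmethod
    def from_dict(cls, spec: dict) -> "ComplexScheme":
        rules = tuple(
            ComplexRule(c["name"], tuple(c["members"]), int(c["min_members"]))
            for c in spec["complexes"]
        )
        return cls(rules)

    @classmethod
    def from_yaml(cls, path) -> "ComplexScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "complexes": [
                {"name": c.name, "members": list(c.members), "min_members": c.min_members}
                for c in self.complexes
            ]
        }


DEFAULT_SCHEME = ComplexScheme(
    (
        ComplexRule("PEAT", ("UBP5", "EPCR1", "PWWP1"), 2),
        ComplexRule("NuA4", ("HAM1", "EPL1B"), 2),
        ComplexRule("PRC2", ("CLF", "SWN"), 2),
        ComplexRule("JMJ14", ("JMJ14",), 1),
    )
)


def assign_complexes(matrix: pd.DataFrame, scheme: ComplexScheme) -> pd.Series:
    """Per row, the subset of complexes whose membership rule is satisfied.

    A complex is assigned iff at least ``min_members`` of its member tracks
    are occupied (decile > 0) in the row.
    """
    for rule in scheme.complexes:
        unknown = set(rule.members) - set(matrix.columns)
        if unknown:
            raise ValueError(
                f"complex {rule.name!r} references unknown track(s) {sorted(unknown)}"
            )
    hit = {}
    for rule in scheme.complexes:
        occupied = (matrix[list(rule.members)] > 0).sum(axis=1)
        hit[rule.name] = occupied >= rule.min_members
    hits = pd.DataFrame(hit)
    names = np.array(scheme.names, dtype=object)
    values = hits.to_numpy(dtype=bool)
    return pd.Series(
        [frozenset(names[row]) for row in values], index=matrix.index, name="complexes"
    )


def categorize(assignments: pd.Series, collapse_multi: bool = False) -> pd.DataFrame:
    """Mutually exclusive category label per row from its complex subset.

    Full mode: the label is the canonical sorted '+'-join of the subset
    ("Unassigned" when empty).  Collapsed mode merges all subsets of three
    or more complexes into a single "Multi(3+)" label.
    """

    def label(subset: frozenset) -> str:
        if not subset:
            return UNASSIGNED_LABEL
        if collapse_multi and len(subset) >= 3:
            return MULTI_LABEL
        return "+".join(sorted(subset))

    return pd.DataFrame(
        {"complexes": assignments, "category": assignments.map(label)}
    )


def trb_combination(
    matrix: pd.DataFrame, trb_tracks: tuple[str, ...] = DEFAULT_TRB_TRACKS
) -> pd.Series:
    """Per row, the '+'-joined subset of occupied TRB tracks ('none' if unbound)."""
    missing = set(trb_tracks) - set(matrix.columns)
    if missing:
        raise ValueError(f"TRB track(s) {sorted(missing)} absent from matrix")
    occ = (matrix[list(trb_tracks)] > 0).to_numpy(dtype=bool)
    order = sorted(range(len(trb_tracks)), key=lambda i: trb_tracks[i])
    labels = [
        "+".join(trb_tracks[i] for i in order if row[i]) or "none" for row in occ
    ]
    return pd.Series(labels, index=matrix.index, name="trb_combo")


def correlation_matrix(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of track columns, with p-values.

    r is computed on the decile values over all retained rows; the p-value
    comes from the t-transform ``t = r·sqrt((n-2)/(1-r²))`` with n−2 degrees
    of freedom.  Zero-variance columns give undefined (NaN) correlations
    with a warning.  The diagonal is exactly 1 (p = 0).
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 rows for correlation")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 track columns")
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance track(s) {list(matrix.columns[degenerate])}: "
            "correlations undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rc * np.sqrt((n - 2) / (1.0 - rc**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rc) == 1.0] = 0.0
    p[np.isnan(rc)] = np.nan
    cols = matrix.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
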