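"""Peak-to-gene annotation and gene-level complex assignment.

Peaks from chromatin complexes are broad, so a peak is annotated to every
gene whose body it overlaps by at least one base — multi-gene spanning
peaks map to all spanned genes — plus every gene whose TSS lies within a
configurable window (default ±2000 bp) of the peak.  Gene-level occupancy
flags (gene has ≥1 annotated peak of a track) are then fed through the same
complex-membership rules used for genomic bins, and any gene→term map can
be tested for over-representation with a one-sided hypergeometric test.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .binning import PeakSet
from .complexes import (
    ComplexScheme,
    DEFAULT_SCHEME,
    DEFAULT_TRB_TRACKS,
    assign_complexes,
    categorize,
    trb_combination,
)
from .stats import bh_adjust

__all__ = [
    "GeneModel",
    "TermMap",
    "read_gene_models",
    "annotate_peaks_to_genes",
    "build_gene_database",
    "overrepresentation",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end−1 on '−'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TermMap:
    """term id → gene set, with optional human-readable labels."""

    terms: dict[str, frozenset]
    labels: dict[str, str] | None = None

    @classmethod
    def from_tsv(cls, path, labels_path=None) -> "TermMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
        terms = {
            t: frozenset(g) for t, g in df.groupby("term")["gene"]
        }
        labels = None
        if labels_path is not None:
            ldf = pd.read_csv(labels_path, sep="\t", header=None, names=["term", "label"])
            labels = dict(zip(ldf["term"], ldf["label"]))
        return cls(terms, labels)


def read_gene_models(path, feature_types: Iterable[str] = ("gene",)) -> list[GeneModel]:
    """Read gene models from GFF3, converting to 0-based half-open coordinates.

    Only features of the requested types are kept; every kept feature must
    carry an ``ID`` attribute.
    """
    feature_types = tuple(feature_types)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            if feat.id.startswith("autoincrement") or not feat.attributes.get("ID"):
                raise ValueError(
                    f"{ftype} feature at {feat.seqid}:{feat.start}-{feat.end} "
                    "lacks an ID attribute"
                )
            genes.append(
                GeneModel(
                    gene_id=feat.attributes["ID"][0],
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GFF is 1-based closed
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    feature_type=ftype,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def annotate_peaks_to_genes(
    peaks: PeakSet, genes: list[GeneModel], tss_window: int = 2000
) -> dict[int, frozenset]:
    """Map each peak (by positional index in the PeakSet) to its gene set.

    A peak is annotated to every gene whose body it overlaps by ≥1 bp and to
    every gene whose TSS lies within ``tss_window`` bp of the peak interval
    (distance 0 if the TSS falls inside the peak).  With ``tss_window=0``
    this reduces to pure body overlap.  A peak may map to many genes and a
    gene to many peaks; the result is independent of input order.
    """
    if tss_window < 0:
        raise ValueError("tss_window must be non-negative")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    tss_pos: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for g in genes:
        trees[g.chrom].addi(g.start, g.end, g.gene_id)
        tss_pos[g.chrom].append((g.tss, g.gene_id))
    tss_sorted = {
        c: (np.array([p for p, _ in sorted(v)]), [g for _, g in sorted(v)])
        for c, v in tss_pos.items()
    }
    out: dict[int, frozenset] = {}
    for i, row in enumerate(peaks.peaks.itertuples(index=False)):
        hits: set[str] = set()
        if row.chrom in trees:
            hits.update(iv.data for iv in trees[row.chrom].overlap(row.start, row.end))
        if row.chrom in tss_sorted:
            pos, ids = tss_sorted[row.chrom]
            lo = np.searchsorted(pos, row.start - tss_window, side="left")
            hi = np.searchsorted(pos, (row.end - 1) + tss_window, side="right")
            hits.update(ids[j] for j in range(lo, hi))
        out[i] = frozenset(hits)
    return out


def build_gene_database(
    annotations: Mapping[str, Iterable[str]],
    genes: list[GeneModel],
    scheme: ComplexScheme = DEFAULT_SCHEME,
    trb_tracks: tuple[str, ...] = DEFAULT_TRB_TRACKS,
    collapse_multi: bool = False,
    clusters: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Gene-level occupancy flags, complex subsets and TRB combinations.

    ``annotations`` maps track name → the gene ids bound by that track
    (genes having ≥1 annotated peak).  Complex subsets and TRB combinations
    follow the same rules as for genomic bins, applied to the 0/1 flags.
    """
    universe = pd.Index([g.gene_id for g in genes], name="gene")
    if universe.has_duplicates:
        raise ValueError("duplicate gene ids in gene models")
    flags = pd.DataFrame(0, index=universe, columns=list(annotations), dtype=np.int8)
    for track, bound in annotations.items():
        bound = pd.Index(set(bound))
        stray = bound.difference(universe)
        if len(stray):
            raise ValueError(
                f"track {track!r} annotated to gene(s) outside the gene models, "
                f"e.g. {stray[0]!r}"
            )
        flags.loc[bound, track] = 1
    assignments = assign_complexes(flags, scheme)
    cat = categorize(assignments, collapse_multi=collapse_multi)
    db = flags.copy()
    db["complexes"] = cat["complexes"]
    db["category"] = cat["category"]
    db["trb_combo"] = trb_combination(flags, trb_tracks)
    if clusters is not None:
        db["cluster"] = pd.Series(dict(clusters)).reindex(universe)
    return db


def overrepresentation(
    query: Iterable[str], terms: TermMap, background: Iterable[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each term in a query set.

    BH adjustment is applied within the term family; fold enrichment is
    observed / expected with expected = |term ∩ background|·|query|/N.
    """
    bg = frozenset(background)
    q = frozenset(query)
    if not q:
        raise ValueError("empty query set")
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    N, nq = len(bg), len(q)
    rows = []
    for term, members in sorted(terms.terms.items()):
        members = members & bg
        k = len(members & q)
        expected = len(members) * nq / N
        p = float(hypergeom.sf(k - 1, N, len(members), nq)) if members else 1.0
        rows.append(
            {
                "term": term,
                "label": (terms.labels or {}).get(term, term),
                "term_size": len(members),
                "observed": k,
                "expected": expected,
                "fold_enrichment": k / expected if expected > 0 else np.nan,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
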