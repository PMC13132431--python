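"""Genome tiling, peak ingestion, and decile-normalized occupancy matrices.

A genome is tiled into fixed-width half-open bins (default 300 bp; the last
bin of each chromosome may be shorter).  Peaks from heterogeneous ChIP-seq
pipelines are mapped onto this lattice — a bin counts as bound by a track if
any base of any peak of that track overlaps it — and each track's
significance scores are rank-normalized into deciles 1–10 so that tracks
processed by different pipelines become comparable.  Unbound bins carry 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation, rankdata

__all__ = [
    "GenomeLayout",
    "BinIndex",
    "PeakSet",
    "Blacklist",
    "tile_genome",
    "read_peaks",
    "read_chrom_sizes",
    "assign_peaks_to_bins",
    "decile_normalize",
    "build_occupancy_matrix",
    "blacklist_windows",
]

_NARROWPEAK_COLS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome layout has no chromosomes")
        for name, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    if df["chrom"].duplicated().any():
        dup = df["chrom"][df["chrom"].duplicated()].iloc[0]
        raise ValueError(f"duplicate chromosome {dup!r} in sizes file")
    return GenomeLayout(dict(zip(df["chrom"], df["length"].astype(int))))


class BinIndex:
    """Fixed-width half-open bins covering a genome, with stable integer ids.

    Bin ids run 0..n_bins-1 in chromosome declaration order; within a
    chromosome bins are contiguous and cover [0, length), with only the last
    bin possibly shorter than ``bin_size``.
    """

    def __init__(self, layout: GenomeLayout, bin_size: int):
        if bin_size < 1:
            raise ValueError("bin_size must be a positive number of base pairs")
        self.layout = layout
        self.bin_size = int(bin_size)
        counts = {
            c: -(-length // bin_size) for c, length in layout.lengths.items()
        }
        self._counts = counts
        offsets = {}
        total = 0
        for c in layout.names:
            offsets[c] = total
            total += counts[c]
        self._offsets = offsets
        self.n_bins = total

    def bins_overlapping(self, chrom: str, start: int, end: int) -> range:
        """Ids of all bins overlapped by the half-open interval [start, end)."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end})")
        length = self.layout.lengths[chrom]
        first = max(0, start) // self.bin_size
        last = (min(end, length) - 1) // self.bin_size
        off = self._offsets[chrom]
        return range(off + first, off + last + 1)

    def to_frame(self) -> pd.DataFrame:
        """Bin table: bin_id, chrom, start, end."""
        chroms, starts, ends = [], [], []
        for c in self.layout.names:
            n = self._counts[c]
            length = self.layout.lengths[c]
            s = np.arange(n, dtype=np.int64) * self.bin_size
            e = np.minimum(s + self.bin_size, length)
            chroms.extend([c] * n)
            starts.append(s)
            ends.append(e)
        return pd.DataFrame(
            {
                "bin_id": np.arange(self.n_bins, dtype=np.int64),
                "chrom": chroms,
                "start": np.concatenate(starts),
                "end": np.concatenate(ends),
            }
        ).set_index("bin_id")


def tile_genome(layout: GenomeLayout, bin_size: int) -> BinIndex:
    """Tile every chromosome into ``ceil(length / bin_size)`` half-open bins."""
    return BinIndex(layout, bin_size)


@dataclass
class PeakSet:
    """One track's peaks: 0-based half-open intervals with a score."""

    name: str
    peaks: pd.DataFrame  # columns chrom, start, end, score[, name]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "score"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table missing columns {sorted(missing)}")
        if len(self.peaks) and (self.peaks["start"] >= self.peaks["end"]).any():
            bad = self.peaks[self.peaks["start"] >= self.peaks["end"]].index[0]
            raise ValueError(f"peak {bad} has start >= end")

    def __len__(self) -> int:
        return len(self.peaks)


def read_peaks(
    path,
    format: str = "narrowPeak",
    score_column: str | None = None,
    name: str | None = None,
) -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    Formats: ``bed`` (BED3/BED6, score from column 5), ``narrowPeak``
    (ENCODE 10-column; ``score_column`` selects score/signalValue/pValue/
    qValue, default signalValue), ``tsv`` (headered table; ``score_column``
    required).  BED-family coordinates are already 0-based half-open and are
    stored as-is.
    """
    path = Path(path)
    track = name if name is not None else path.stem
    if format == "narrowPeak":
        df = _read_table(path, names=_NARROWPEAK_COLS)
        col = score_column or "signalValue"
        if col not in _NARROWPEAK_COLS:
            raise ValueError(f"{col!r} is not a narrowPeak column")
    elif format == "bed":
        df = _read_table(path, names=["chrom", "start", "end", "name", "score", "strand"])
        col = score_column or "score"
    elif format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", comment="#")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        if score_column is None:
            raise ValueError("tsv format requires an explicit score_column")
        col = score_column
        for c in ("chrom", "start", "end"):
            if c not in df.columns and len(df):
                raise ValueError(f"tsv peak file lacks required column {c!r}")
    else:
        raise ValueError(f"unknown peak format {format!r}")
    if len(df) == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "score", "name"])
        return PeakSet(track, empty)
    if col not in df.columns or df[col].isna().all():
        raise ValueError(f"score column {col!r} absent from {path}")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": _int_col(df["start"], path, "start"),
            "end": _int_col(df["end"], path, "end"),
            "score": pd.to_numeric(df[col], errors="raise").astype(float),
        }
    )
    if "name" in df.columns:
        out["name"] = df["name"]
    return PeakSet(track, out)


def _read_table(path, names):
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=names,
            usecols=range(len(names)), dtype=str, engine="python",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed peak file {path}: {err}") from None
    return df


def _int_col(series, path, label):
    try:
        return pd.to_numeric(series, errors="raise").astype(np.int64)
    except (ValueError, TypeError) as err:
        bad = int(series.index[pd.to_numeric(series, errors="coerce").isna()][0]) + 1
        raise ValueError(
            f"malformed {label} field at data line {bad} of {path}: {err}"
        ) from None


def assign_peaks_to_bins(peaks: PeakSet, index: BinIndex) -> dict[int, float]:
    """Map each bin overlapped (≥1 bp) by any peak of the track to a score.

    When several peaks of the track hit the same bin, the maximum score is
    kept: occupancy marks bound/strength, not peak counts.
    """
    scores: dict[int, float] = {}
    known = set(index.layout.names)
    for row in peaks.peaks.itertuples(index=False):
        if row.chrom not in known:
            raise KeyError(
                f"peak on unknown chromosome {row.chrom!r} (track {peaks.name})"
            )
        for b in index.bins_overlapping(row.chrom, row.start, row.end):
            prev = scores.get(b)
            if prev is None or row.score > prev:
                scores[b] = float(row.score)
    return scores


def decile_normalize(scores: Mapping[int, float]) -> dict[int, int]:
    """Rank-normalize occupied-bin scores into deciles 1..10.

    decile(b) = ceil(10·r(b)/n) with r the average (midrank) ascending rank
    among the n occupied bins, so tied scores always share a decile.
    Unoccupied bins are simply absent (occupancy value 0 downstream).
    """
    if not scores:
        return {}
    ids = np.fromiter(scores.keys(), dtype=np.int64, count=len(scores))
    vals = np.fromiter(scores.values(), dtype=float, count=len(scores))
    r2 = (2.0 * rankdata(vals, method="average")).astype(np.int64)  # midranks are halves
    n = len(vals)
    deciles = -((-10 * r2) // (2 * n))  # exact integer ceil(10*r/n)
    return {int(i): int(d) for i, d in zip(ids, deciles)}


@dataclass
class Blacklist:
    """Half-open windows flagged as over- or under-sampled."""

    windows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        if len(self.windows) and (self.windows["start"] >= self.windows["end"]).any():
            raise ValueError("blacklist contains an empty or inverted window")

    def __len__(self) -> int:
        return len(self.windows)


def blacklist_windows(
    coverage: pd.DataFrame, k: float = 5.0, eps: float = 1e-8
) -> Blacklist:
    """Flag coverage outlier windows, two-sided.

    ``coverage`` has columns chrom, start, end, count (read counts of
    control samples over a genome tiling, conventionally 200-bp windows).
    A window is flagged when log10(count+1) falls outside
    median ± k·MAD (MAD with the normal-consistency factor; an ε floor
    handles the degenerate all-equal case, which yields an empty blacklist).
    """
    required = {"chrom", "start", "end", "count"}
    if missing := required - set(coverage.columns):
        raise ValueError(f"coverage table missing columns {sorted(missing)}")
    counts = coverage["count"].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative read counts")
    if counts.sum() == 0:
        warnings.warn("all-zero coverage: empty blacklist", stacklevel=2)
        return Blacklist()
    x = np.log10(counts + 1.0)
    med = np.median(x)
    mad = max(median_abs_deviation(x, scale="normal"), eps)
    flagged = np.abs(x - med) > k * mad
    return Blacklist(
        coverage.loc[flagged, ["chrom", "start", "end"]].reset_index(drop=True)
    )


def build_occupancy_matrix(
    tracks: Mapping[str, Mapping[int, int]],
    index: BinIndex,
    blacklist: Blacklist | None = None,
) -> pd.DataFrame:
    """Assemble the bins × tracks decile matrix (0 = unbound).

    Rows are all bins of the index except those overlapping any blacklist
    window.  ``tracks`` maps track name → {bin id → decile}.
    """
    names = list(tracks)
    if len(set(names)) != len(names):
        raise ValueError("duplicate track names")
    mat = np.zeros((index.n_bins, len(names)), dtype=np.int8)
    for j, name in enumerate(names):
        col = tracks[name]
        if col:
            ids = np.fromiter(col.keys(), dtype=np.int64, count=len(col))
            vals = np.fromiter(col.values(), dtype=np.int8, count=len(col))
            mat[ids, j] = vals
    df = pd.DataFrame(mat, columns=names)
    df.index.name = "bin_id"
    if blacklist is not None and len(blacklist):
        drop: set[int] = set()
        for w in blacklist.windows.itertuples(index=False):
            if w.chrom in index.layout.lengths:
                start = max(0, int(w.start))
                end = min(int(w.end), index.layout.lengths[w.chrom])
                if start < end:
                    drop.update(index.bins_overlapping(w.chrom, start, end))
        df = df.drop(index=sorted(drop))
    return df
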