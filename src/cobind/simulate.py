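"""Synthetic study generator: peak tracks, genes, counts and term maps.

Emulates the statistical structure of a multi-track ChIP-seq co-occupancy
study on a toy genome: for each regulatory complex a set of target bins is
planted and every member track drops a peak into a target bin with
probability ``q_on`` (and into background bins with ``q_off``); the three
TRB paralog tracks bind complex-``c`` target bins with preference
``pi[trb][c]`` and elsewhere at a background rate ``pi0``.  Peak scores are
Gamma-distributed with a mean shift at planted sites so decile
normalization has real structure.  Gene models are tiled with random gaps,
expression counts are negative-binomial with planted cluster-specific
genotype effects (the five archetype response patterns across a wild type,
three single and three double mutants), and term maps mix random terms with
terms planted on the true complex gene sets.

Everything derives from one seed; identical seeds give identical output.
The emitted ``Truth`` records, by direct coordinate arithmetic at
generation time, which bins each planted peak covers and hence the true
complex category and TRB combination per bin — an independent path from the
pipeline's own peak-to-bin machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinIndex, GenomeLayout, PeakSet, tile_genome
from .complexes import ComplexScheme, DEFAULT_SCHEME, DEFAULT_TRB_TRACKS, UNASSIGNED_LABEL
from .genes import GeneModel

__all__ = [
    "Scenario",
    "Truth",
    "SimulatedData",
    "default_scenario",
    "generate_tracks",
    "generate_genes_and_counts",
    "generate_term_map",
    "simulate",
]

GENOTYPES = ("Col0", "trb1", "trb2", "trb3", "trb1trb2", "trb1trb3", "trb2trb3")

# Five archetype genotype responses (log2 units), one per planted cluster,
# mirroring the qualitative patterns of DEG clusters in trb mutants: e.g.
# cluster 1 flips sign between the single and double mutant, cluster 5
# responds only in double mutants.
DEFAULT_EFFECTS = (
    (0.0, -2.0, 0.0, 0.0, 2.0, 2.0, 0.0),
    (0.0, 2.0, 0.0, 0.0, 2.0, 2.0, 0.0),
    (0.0, -2.0, 0.0, 0.0, -2.0, -2.0, 0.0),
    (0.0, 0.0, 0.0, 0.0, -2.0, -2.0, -2.0),
    (0.0, 0.0, 0.0, 0.0, 2.0, 2.0, 2.0),
)

DEFAULT_TRB_PREF = {
    "TRB1": {"PEAT": 0.6, "NuA4": 0.5, "PRC2": 0.05, "JMJ14": 0.3},
    "TRB2": {"PEAT": 0.3, "NuA4": 0.3, "PRC2": 0.3, "JMJ14": 0.5},
    "TRB3": {"PEAT": 0.1, "NuA4": 0.1, "PRC2": 0.6, "JMJ14": 0.3},
}


@dataclass
class Scenario:
    """All knobs of one synthetic study; every random draw flows from ``seed``."""

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    bin_size: int = 300
    scheme: ComplexScheme = DEFAULT_SCHEME
    n_target_bins: dict = field(
        default_factory=lambda: {"PEAT": 400, "NuA4": 300, "PRC2": 350, "JMJ14": 300}
    )
    shared_target_frac: float = 0.05
    q_on: float = 0.9
    q_off: float = 0.01
    trb_pref: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_TRB_PREF.items()
    })
    pi0: float = 0.01
    peak_width_frac: tuple[float, float] = (0.3, 1.2)
    score_shape: float = 2.0
    score_scale_background: float = 1.0
    score_scale_target: float = 3.0
    n_genes: int = 2000
    gene_length: tuple[int, int] = (300, 600)
    gene_gap: tuple[int, int] = (100, 400)
    genotypes: tuple[str, ...] = GENOTYPES
    replicates: int = 3
    n_deg: int = 500
    k_clusters: int = 5
    effects: tuple = DEFAULT_EFFECTS
    baseline_mean: float = 100.0
    baseline_log_sd: float = 0.5
    nb_dispersion: float = 0.05
    n_terms: int = 200
    term_size: tuple[int, int] = (10, 100)
    n_planted_terms: int = 0

    def __post_init__(self) -> None:
        probs = [self.q_on, self.q_off, self.pi0, self.shared_target_frac]
        probs += [p for t in self.trb_pref.values() for p in t.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.effects) != self.k_clusters:
            raise ValueError("one effect vector per planted cluster required")
        if any(len(e) != len(self.genotypes) for e in self.effects):
            raise ValueError("effect vectors must cover all genotypes")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.chrom_lengths))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = self.scheme.to_dict()
        d["effects"] = [list(e) for e in self.effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if "scheme" in d and isinstance(d["scheme"], dict):
            d["scheme"] = ComplexScheme.from_dict(d["scheme"])
        for key in ("peak_width_frac", "gene_length", "gene_gap", "term_size"):
            if key in d:
                d[key] = tuple(d[key])
        if "effects" in d:
            d["effects"] = tuple(tuple(e) for e in d["effects"])
        if "genotypes" in d:
            d["genotypes"] = tuple(d["genotypes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_scenario(seed: int = 0, **overrides) -> Scenario:
    return Scenario(seed=seed, **overrides)


@dataclass
class Truth:
    """Planted ground truth, consistent with the emitted files."""

    target_bins: dict  # complex -> ndarray of planted target bin ids
    bin_category: pd.Series | None = None  # bin id -> true category label
    bin_trb_combo: pd.Series | None = None  # bin id -> true TRB combination
    gene_clusters: pd.Series | None = None  # DEG gene -> planted cluster id
    deg_genes: list | None = None
    gene_complexes: pd.Series | None = None  # gene -> true complex subset
    planted_terms: list | None = None


def _covered_bins(index: BinIndex, chrom: str, start: int, end: int) -> np.ndarray:
    """Bins covered by [start, end) via direct floor arithmetic."""
    off = index._offsets[chrom]
    length = index.layout.lengths[chrom]
    first = max(0, start) // index.bin_size
    last = (min(end, length) - 1) // index.bin_size
    return np.arange(off + first, off + last + 1)


def generate_tracks(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> tuple[dict[str, PeakSet], Truth]:
    """Generate the 11 peak tracks with planted complex and TRB structure."""
    rng = rng or np.random.default_rng(scenario.seed)
    index = tile_genome(scenario.layout, scenario.bin_size)
    n_bins = index.n_bins
    bin_frame = index.to_frame()

    # Plant target bins per complex; a configurable fraction is shared with
    # already-drawn complexes so multi-complex categories occur.
    target_bins: dict[str, np.ndarray] = {}
    pool: list[int] = []
    for rule in scenario.scheme.complexes:
        want = scenario.n_target_bins.get(rule.name, 0)
        if want > n_bins:
            raise ValueError(
                f"complex {rule.name!r} demands {want} target bins, genome has {n_bins}"
            )
        n_shared = min(int(round(want * scenario.shared_target_frac)), len(pool))
        shared = (
            rng.choice(np.array(sorted(set(pool))), size=n_shared, replace=False)
            if n_shared
            else np.empty(0, dtype=np.int64)
        )
        fresh = rng.choice(n_bins, size=want, replace=False)
        chosen = np.unique(np.concatenate([shared, fresh]))[:want]
        target_bins[rule.name] = np.sort(chosen)
        pool.extend(chosen.tolist())

    track_targets: dict[str, set] = {}
    for rule in scenario.scheme.complexes:
        for member in rule.members:
            track_targets.setdefault(member, set()).update(target_bins[rule.name])

    peaksets: dict[str, PeakSet] = {}
    occupancy: dict[str, np.ndarray] = {}

    def emit(track: str, occupied: np.ndarray, is_target: np.ndarray) -> None:
        starts = bin_frame["start"].to_numpy()[occupied]
        chroms = bin_frame["chrom"].to_numpy()[occupied]
        lengths = np.array([scenario.layout.lengths[c] for c in chroms])
        widths = (
            rng.uniform(*scenario.peak_width_frac, size=len(occupied))
            * scenario.bin_size
        ).astype(np.int64)
        widths = np.maximum(widths, 1)
        centers = starts + rng.uniform(0, 1, size=len(occupied)) * scenario.bin_size
        centers = np.minimum(centers, lengths - 1)
        p_start = np.clip((centers - widths / 2).astype(np.int64), 0, lengths - 1)
        p_end = np.clip(p_start + widths, p_start + 1, lengths)
        scale = np.where(
            is_target, scenario.score_scale_target, scenario.score_scale_background
        )
        scores = rng.gamma(scenario.score_shape, scale)
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "start": p_start,
                "end": p_end,
                "score": scores,
                "name": [f"{track}_p{i}" for i in range(len(occupied))],
            }
        )
        peaksets[track] = PeakSet(track, df)
        occ = np.zeros(n_bins, dtype=bool)
        for c, s, e in zip(chroms, p_start, p_end):
            occ[_covered_bins(index, c, int(s), int(e))] = True
        occupancy[track] = occ

    for track in sorted(track_targets):
        targets = np.array(sorted(track_targets[track]), dtype=np.int64)
        is_target = np.zeros(n_bins, dtype=bool)
        is_target[targets] = True
        u = rng.uniform(size=n_bins)
        bound = np.where(is_target, u < scenario.q_on, u < scenario.q_off)
        occupied = np.flatnonzero(bound)
        emit(track, occupied, is_target[occupied])

    for trb in DEFAULT_TRB_TRACKS:
        prefs = scenario.trb_pref.get(trb, {})
        p = np.full(n_bins, scenario.pi0)
        for cname, bins in target_bins.items():
            p[bins] = np.maximum(p[bins], prefs.get(cname, scenario.pi0))
        bound = rng.uniform(size=n_bins) < p
        occupied = np.flatnonzero(bound)
        emit(trb, occupied, p[occupied] > scenario.pi0)

    # True per-bin labels from the planted occupancy, by the same membership
    # rules but computed directly on the generator's boolean coverage.
    categories = []
    for b in range(n_bins):
        subset = [
            rule.name
            for rule in scenario.scheme.complexes
            if sum(occupancy.get(m, np.zeros(1, bool))[b] for m in rule.members)
            >= rule.min_members
        ]
        categories.append("+".join(sorted(subset)) if subset else UNASSIGNED_LABEL)
    trb_labels = []
    for b in range(n_bins):
        present = sorted(t for t in DEFAULT_TRB_TRACKS if occupancy[t][b])
        trb_labels.append("+".join(present) if present else "none")

    truth = Truth(
        target_bins=target_bins,
        bin_category=pd.Series(categories, index=bin_frame.index, name="category"),
        bin_trb_combo=pd.Series(trb_labels, index=bin_frame.index, name="trb_combo"),
    )
    return peaksets, truth


def generate_genes_and_counts(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame, Truth]:
    """Tile gene models and draw negative-binomial counts with planted clusters."""
    rng = rng or np.random.default_rng(scenario.seed)
    genes: list[GeneModel] = []
    chroms = list(scenario.chrom_lengths)
    ci, pos = 0, 0
    while len(genes) < scenario.n_genes:
        if ci >= len(chroms):
            raise ValueError(
                f"only {len(genes)} of {scenario.n_genes} genes fit the genome"
            )
        gap = int(rng.integers(*scenario.gene_gap, endpoint=True))
        length = int(rng.integers(*scenario.gene_length, endpoint=True))
        start = pos + gap
        end = start + length
        if end > scenario.chrom_lengths[chroms[ci]]:
            ci, pos = ci + 1, 0
            continue
        strand = "+" if rng.uniform() < 0.5 else "-"
        genes.append(
            GeneModel(f"g{len(genes) + 1:05d}", chroms[ci], start, end, strand)
        )
        pos = end

    gene_ids = [g.gene_id for g in genes]
    deg_idx = np.sort(rng.choice(len(genes), size=scenario.n_deg, replace=False))
    deg_genes = [gene_ids[i] for i in deg_idx]
    cluster_of = rng.integers(1, scenario.k_clusters + 1, size=scenario.n_deg)

    samples = [
        (f"{g}_r{r + 1}", g, r + 1)
        for g in scenario.genotypes
        for r in range(scenario.replicates)
    ]
    sheet = pd.DataFrame(samples, columns=["sample", "genotype", "replicate"])

    base = scenario.baseline_mean * rng.lognormal(
        0.0, scenario.baseline_log_sd, size=len(genes)
    )
    effects = np.asarray(scenario.effects)
    log2fc = np.zeros((len(genes), len(scenario.genotypes)))
    log2fc[deg_idx] = effects[cluster_of - 1]
    mu_geno = base[:, None] * np.power(2.0, log2fc)

    alpha = scenario.nb_dispersion
    nb_n = 1.0 / alpha
    cols = {}
    for j, (sample, genotype, _) in enumerate(samples):
        mu = mu_geno[:, scenario.genotypes.index(genotype)]
        cols[sample] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))

    truth = Truth(
        target_bins={},
        gene_clusters=pd.Series(cluster_of, index=pd.Index(deg_genes, name="gene")),
        deg_genes=deg_genes,
    )
    return genes, counts, sheet, truth


def gene_complex_truth(
    scenario: Scenario, genes: list[GeneModel], target_bins: dict
) -> pd.Series:
    """True complex membership per gene: body overlaps ≥1 planted target bin."""
    index = tile_genome(scenario.layout, scenario.bin_size)
    sets = {c: set(map(int, bins)) for c, bins in target_bins.items()}
    out = {}
    for g in genes:
        covered = set(map(int, _covered_bins(index, g.chrom, g.start, g.end)))
        out[g.gene_id] = frozenset(c for c, bins in sets.items() if covered & bins)
    return pd.Series(out, name="complexes")


def generate_term_map(
    scenario: Scenario,
    genes: list[GeneModel],
    truth: Truth | None = None,
    rng: np.random.Generator | None = None,
):
    """Random gene→term map, optionally with terms planted on complex gene sets."""
    from .genes import TermMap

    rng = rng or np.random.default_rng(scenario.seed)
    gene_ids = np.array([g.gene_id for g in genes])
    terms: dict[str, frozenset] = {}
    for i in range(scenario.n_terms):
        size = int(rng.integers(*scenario.term_size, endpoint=True))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        terms[f"T{i + 1:04d}"] = frozenset(members)
    planted = []
    if scenario.n_planted_terms:
        if truth is None or truth.gene_complexes is None:
            raise ValueError("planted terms require gene-level complex truth")
        by_complex = {
            c: frozenset(
                g for g, s in truth.gene_complexes.items() if c in s
            )
            for c in [r.name for r in scenario.scheme.complexes]
        }
        for c, members in list(by_complex.items())[: scenario.n_planted_terms]:
            if members:
                name = f"PLANTED_{c}"
                terms[name] = members
                planted.append(name)
    return TermMap(terms), planted


@dataclass
class SimulatedData:
    """Everything one synthetic study emits, plus its ground truth."""

    scenario: Scenario
    peaksets: dict
    genes: list
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    term_map: object
    truth: Truth

    def write(self, outdir) -> Path:
        """Emit all files (plain text) and the resolved scenario; returns outdir."""
        out = Path(outdir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        sizes = pd.DataFrame(
            list(self.scenario.chrom_lengths.items()), columns=["chrom", "length"]
        )
        sizes.to_csv(out / "sizes.tsv", sep="\t", header=False, index=False)
        for name, ps in self.peaksets.items():
            df = ps.peaks
            np_df = pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"],
                    "end": df["end"],
                    "name": df.get("name", "."),
                    "score": 0,
                    "strand": ".",
                    "signalValue": df["score"],
                    "pValue": -1,
                    "qValue": -1,
                    "peak": -1,
                }
            )
            np_df.to_csv(
                out / "peaks" / f"{name}.narrowPeak", sep="\t", header=False, index=False
            )
        with open(out / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tcobind_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        self.counts.to_csv(out / "counts.tsv", sep="\t")
        self.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
        with open(out / "degs.txt", "w") as fh:
            fh.write("\n".join(self.truth.deg_genes) + "\n")
        rows = [
            (g, t) for t, members in sorted(self.term_map.terms.items())
            for g in sorted(members)
        ]
        pd.DataFrame(rows).to_csv(out / "terms.tsv", sep="\t", header=False, index=False)
        truth_bins = pd.DataFrame(
            {
                "category": self.truth.bin_category,
                "trb_combo": self.truth.bin_trb_combo,
            }
        )
        truth_bins.to_csv(out / "truth_bins.tsv", sep="\t")
        self.truth.gene_clusters.rename("cluster").to_csv(
            out / "truth_clusters.tsv", sep="\t"
        )
        with open(out / "scenario.yaml", "w") as fh:
            yaml.safe_dump(self.scenario.to_dict(), fh, sort_keys=False)
        return out


def simulate(scenario: Scenario) -> SimulatedData:
    """Run the full generator; all stages draw from seeds spawned off one seed."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_tracks, rng_genes, rng_terms = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    peaksets, truth_tracks = generate_tracks(scenario, rng_tracks)
    genes, counts, sheet, truth_expr = generate_genes_and_counts(scenario, rng_genes)
    truth = Truth(
        target_bins=truth_tracks.target_bins,
        bin_category=truth_tracks.bin_category,
        bin_trb_combo=truth_tracks.bin_trb_combo,
        gene_clusters=truth_expr.gene_clusters,
        deg_genes=truth_expr.deg_genes,
        gene_complexes=gene_complex_truth(scenario, genes, truth_tracks.target_bins),
    )
    term_map, planted = generate_term_map(scenario, genes, truth, rng_terms)
    truth.planted_terms = planted
    return SimulatedData(scenario, peaksets, genes, counts, sheet, term_map, truth)
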