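"""Config-driven orchestration of the full co-occupancy analysis.

Stages run in dependency order: genome tiling → peak ingestion → decile
occupancy matrix → complex categories and TRB combinations → pairwise exact
enrichment grid → (optional) gene annotation and gene-level database →
(optional) expression normalization, PAM clustering and cluster × category
enrichment.  Every stage logs its row counts, all tables are written as TSV
into the run directory, and a manifest records the resolved configuration,
input checksums and package version so a rerun is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binning import (
    Blacklist,
    assign_peaks_to_bins,
    build_occupancy_matrix,
    decile_normalize,
    read_chrom_sizes,
    read_peaks,
    tile_genome,
)
from .complexes import (
    ComplexScheme,
    DEFAULT_SCHEME,
    DEFAULT_TRB_TRACKS,
    assign_complexes,
    categorize,
    correlation_matrix,
    trb_combination,
)
from .expression import (
    Clustering,
    cluster_category_enrichment,
    cluster_profiles,
    deg_target_association,
    normalize_counts,
    pam_cluster,
)
from .genes import annotate_peaks_to_genes, build_gene_database, read_gene_models
from .stats import pairwise_grid_tests

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_reports"]

log = logging.getLogger("cobind")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    sizes: str
    peaks: dict  # track name -> {path, format, score_column}
    outdir: str
    bin_size: int = 300
    blacklist: str | None = None
    scheme: str | None = None  # YAML path; default scheme if absent
    collapse_multi: bool = False
    trb_tracks: tuple[str, ...] = DEFAULT_TRB_TRACKS
    grid_tiers: tuple[float, float, float] = (0.0001, 0.001, 0.01)
    gff: str | None = None
    feature_types: tuple[str, ...] = ("gene",)
    tss_window: int = 2000
    counts: str | None = None
    samples: str | None = None
    degs: str | None = None
    k: int | str = 5
    k_range: tuple[int, int] = (2, 10)
    cluster_tiers: tuple[float, float, float] = (0.0005, 0.005, 0.05)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("trb_tracks", "grid_tiers", "feature_types", "k_range", "cluster_tiers"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate(self) -> None:
        """Check all referenced inputs before any compute."""
        missing = []
        paths = [self.sizes] + [spec["path"] for spec in self.peaks.values()]
        for opt in (self.blacklist, self.scheme, self.gff, self.counts, self.samples, self.degs):
            if opt is not None:
                paths.append(opt)
        for p in paths:
            if not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if self.counts is not None and (self.samples is None or self.degs is None):
            raise ValueError("expression stage needs counts, samples and degs together")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
    }
    stage = "binning"
    try:
        layout = read_chrom_sizes(config.sizes)
        manifest["inputs"][str(config.sizes)] = _sha256(config.sizes)
        index = tile_genome(layout, config.bin_size)
        log.info("tiled %d chromosomes into %d bins", len(layout.names), index.n_bins)
        manifest["counts"]["bins"] = index.n_bins

        deciles = {}
        for track, spec in config.peaks.items():
            ps = read_peaks(
                spec["path"],
                format=spec.get("format", "narrowPeak"),
                score_column=spec.get("score_column"),
                name=track,
            )
            manifest["inputs"][str(spec["path"])] = _sha256(spec["path"])
            scores = assign_peaks_to_bins(ps, index)
            deciles[track] = decile_normalize(scores)
            log.info("track %s: %d peaks -> %d bound bins", track, len(ps), len(scores))
            manifest["counts"][f"peaks_{track}"] = len(ps)

        blacklist = None
        if config.blacklist is not None:
            bl = pd.read_csv(
                config.blacklist, sep="\t", header=None,
                names=["chrom", "start", "end"], usecols=[0, 1, 2],
            )
            blacklist = Blacklist(bl)
            manifest["inputs"][str(config.blacklist)] = _sha256(config.blacklist)
        matrix = build_occupancy_matrix(deciles, index, blacklist)
        manifest["counts"]["retained_bins"] = len(matrix)
        bin_frame = index.to_frame().loc[matrix.index]
        pd.concat([bin_frame, matrix], axis=1).to_csv(out / "occupancy_matrix.tsv", sep="\t")

        stage = "complexes"
        scheme = (
            ComplexScheme.from_yaml(config.scheme) if config.scheme else DEFAULT_SCHEME
        )
        assignments = assign_complexes(matrix, scheme)
        cats = categorize(assignments, collapse_multi=config.collapse_multi)
        trb = trb_combination(matrix, config.trb_tracks)
        table = pd.DataFrame({"category": cats["category"], "trb_combo": trb})
        table.to_csv(out / "categories.tsv", sep="\t")
        manifest["counts"]["categories"] = int(table["category"].nunique())
        r, p = correlation_matrix(matrix)
        r.to_csv(out / "correlation_r.tsv", sep="\t")
        p.to_csv(out / "correlation_p.tsv", sep="\t")

        stage = "enrichment"
        grid = pairwise_grid_tests(
            table["category"], table["trb_combo"], tiers=config.grid_tiers
        )
        grid.to_csv(out / "grid_category_trb.tsv", sep="\t", index=False)

        genedb = None
        if config.gff is not None:
            stage = "genes"
            genes = read_gene_models(config.gff, config.feature_types)
            manifest["inputs"][str(config.gff)] = _sha256(config.gff)
            manifest["counts"]["genes"] = len(genes)
            annotations = {}
            for track, spec in config.peaks.items():
                ps = read_peaks(
                    spec["path"],
                    format=spec.get("format", "narrowPeak"),
                    score_column=spec.get("score_column"),
                    name=track,
                )
                peak2genes = annotate_peaks_to_genes(ps, genes, config.tss_window)
                annotations[track] = set().union(*peak2genes.values()) if peak2genes else set()
            genedb = build_gene_database(
                annotations, genes, scheme, config.trb_tracks,
                collapse_multi=config.collapse_multi,
            )
            genedb.drop(columns=["complexes"]).to_csv(out / "gene_database.tsv", sep="\t")

        if config.counts is not None:
            stage = "expression"
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            sheet = pd.read_csv(config.samples, sep="\t")
            degs = [
                line.strip()
                for line in Path(config.degs).read_text().splitlines()
                if line.strip()
            ]
            for p_ in (config.counts, config.samples, config.degs):
                manifest["inputs"][str(p_)] = _sha256(p_)
            norm = normalize_counts(counts)
            deg_present = [g for g in degs if g in norm.index]
            clustering = pam_cluster(norm.loc[deg_present], k=config.k, k_range=config.k_range)
            clustering.labels.to_csv(out / "clusters.tsv", sep="\t")
            manifest["counts"]["clustered_genes"] = len(clustering.labels)
            manifest["counts"]["k"] = clustering.k
            genotype_map = dict(zip(sheet["sample"], sheet["genotype"]))
            profiles = cluster_profiles(norm, clustering, genotype_map)
            profiles.to_csv(out / "cluster_profiles.tsv", sep="\t")
            if genedb is not None:
                bg = genedb.index.intersection(norm.index)
                grid6 = cluster_category_enrichment(
                    clustering, genedb, background=bg, tiers=config.cluster_tiers
                )
                grid6.to_csv(out / "grid_cluster_category.tsv", sep="\t", index=False)
                targets = genedb.index[genedb["trb_combo"] != "none"]
                assoc = deg_target_association(deg_present, targets, bg)
                pd.DataFrame(
                    {
                        "odds_ratio": [assoc.odds_ratio],
                        "p_value": [assoc.p_value],
                        "deg_and_target": [assoc.table[0, 0]],
                        "deg_only": [assoc.table[0, 1]],
                        "target_only": [assoc.table[1, 0]],
                        "neither": [assoc.table[1, 1]],
                    }
                ).to_csv(out / "deg_target_association.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def write_reports(run_dir, plots: bool = True) -> Path:
    """Summary tables (and simple plots) from a completed run directory."""
    run_dir = Path(run_dir)
    needed = ["categories.tsv", "correlation_r.tsv", "grid_category_trb.tsv"]
    missing = [f for f in needed if not (run_dir / f).exists()]
    if missing:
        raise PipelineError("reports", f"incomplete run, missing {missing}")
    table = pd.read_csv(run_dir / "categories.tsv", sep="\t", index_col=0)
    counts = table["category"].value_counts().rename_axis("category").rename("n_bins")
    counts.to_csv(run_dir / "category_counts.tsv", sep="\t")
    dist = (
        table.groupby("category")["trb_combo"].value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    dist.to_csv(run_dir / "trb_distribution.tsv", sep="\t")
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        r = pd.read_csv(run_dir / "correlation_r.tsv", sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(r)), r.columns, rotation=90)
        ax.set_yticks(range(len(r)), r.index)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(run_dir / "correlation_matrix.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(7, 4))
        counts.plot.bar(ax=ax)
        ax.set_ylabel("bins")
        fig.tight_layout()
        fig.savefig(run_dir / "category_counts.png", dpi=120)
        plt.close(fig)
    return run_dir
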