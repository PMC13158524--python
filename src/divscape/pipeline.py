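"""End-to-end orchestration: filter -> stats -> islands -> select.

Every run is driven by a :class:`RunConfig` (YAML-serialisable), executes
its stages in a fixed order into a run directory, and records a manifest
(input checksums, resolved parameters, per-stage child seeds, package
versions) sufficient to reproduce the run byte-identically.  The single
top-level seed fans out to per-stage child seeds by stable hashing of the
stage name, so any stage can be re-run independently with identical
results.  A failing stage leaves its partial outputs behind with a
``.partial`` suffix and raises.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (
    FilterParams, apply_filters, load_gff, load_popmap, load_vcf,
    write_bed, write_tsv,
)
from .island_scan import island_background_contrast, scan_islands
from .selection_scan import (
    call_psgs, gene_selection_table, psg_sets, sharing_analysis,
    term_enrichment,
)
from .window_stats import make_windows, windowed_statistics

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, window sizes, thresholds and the top-level seed for one run."""

    vcf: str
    popmap: str
    gff: str
    rho_track: str | None = None
    gene2term: str | None = None
    stats_window: int = 20_000
    island_window: int = 50_000
    top_fraction: float = 0.05
    q_threshold: float = 0.01
    hka_q_max: float = 0.01
    pbs_top_frac: float = 0.05
    permutations: int = 1000
    seed: int = 0
    excluded_samples: list[str] = field(default_factory=list)
    estimator: str = "hudson"
    fixed_mode: str = "pooled"
    max_gap_windows: int = 0
    filter_params: FilterParams = field(default_factory=FilterParams)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fp = FilterParams(**raw.pop("filter_params", {}))
        return cls(filter_params=fp, **raw)

    def validate(self) -> None:
        for name in ("vcf", "popmap", "gff", "rho_track", "gene2term"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) from the run seed."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Write-then-rename helper: outputs appear atomically per stage."""

    def __init__(self, outdir: str):
        self.outdir = outdir
        self.pending: list[tuple[str, str]] = []

    def path(self, name: str) -> str:
        tmp = os.path.join(self.outdir, name + ".partial")
        self.pending.append((tmp, os.path.join(self.outdir, name)))
        return tmp

    def commit(self) -> None:
        for tmp, final in self.pending:
            if os.path.exists(tmp):
                os.replace(tmp, final)
        self.pending.clear()


def run_pipeline(cfg: RunConfig, outdir: str) -> dict:
    """Execute all stages into ``outdir``; returns the manifest dict."""
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "inputs": {k: {"path": getattr(cfg, k), "sha256": _sha256(getattr(cfg, k))}
                   for k in ("vcf", "popmap", "gff", "rho_track", "gene2term")
                   if getattr(cfg, k)},
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("filter", "stats", "islands", "select")},
        "versions": {"divscape": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }

    # ---- filter ----------------------------------------------------------
    st = _Stage(outdir)
    gm = load_vcf(cfg.vcf)
    pm = load_popmap(cfg.popmap)
    pm.excluded_samples = sorted(set(pm.excluded_samples)
                                 | set(cfg.excluded_samples))
    pm.check_against(gm)
    genes = load_gff(cfg.gff)
    gm, report = apply_filters(gm, pm, cfg.filter_params)
    with open(st.path("filter_report.json"), "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    st.commit()
    manifest["stages"]["filter"] = report.as_dict()
    logger.info("filter stage: %d sites retained", gm.n_sites)

    contig_lengths = gm.contig_lengths()

    # ---- stats -----------------------------------------------------------
    st = _Stage(outdir)
    stats_windows = make_windows(contig_lengths, cfg.stats_window)
    stats = windowed_statistics(gm, pm, stats_windows,
                                estimator=cfg.estimator)
    write_tsv(stats, st.path("window_stats.tsv"))
    st.commit()
    manifest["stages"]["stats"] = {"n_windows": len(stats),
                                   "window": cfg.stats_window}

    # ---- islands ---------------------------------------------------------
    st = _Stage(outdir)
    island_windows = make_windows(contig_lengths, cfg.island_window)
    island_stats = windowed_statistics(gm, pm, island_windows,
                                       estimator=cfg.estimator)
    species = pm.species
    pairs = [(species[i], species[j])
             for i in range(len(species)) for j in range(i + 1, len(species))]
    all_islands = []
    contrast_rows = []
    rho = pd.read_csv(cfg.rho_track, sep="\t") if cfg.rho_track else None
    for pair in pairs:
        a, b = pair
        table, islands = scan_islands(
            gm, pm, pair, island_windows,
            B=cfg.permutations, seed=stage_seed(cfg.seed, f"islands:{a}_{b}"),
            top_fraction=cfg.top_fraction, q_threshold=cfg.q_threshold,
            max_gap_windows=cfg.max_gap_windows, estimator=cfg.estimator)
        write_tsv(table, st.path(f"windows_fst_{a}_{b}.tsv"))
        all_islands.extend(islands)
        is_isl = table["is_outlier"].to_numpy()
        tracks = {f"pi_{a}": island_stats[f"pi_{a}"],
                  f"pi_{b}": island_stats[f"pi_{b}"],
                  f"tajd_{a}": island_stats[f"tajd_{a}"],
                  f"tajd_{b}": island_stats[f"tajd_{b}"],
                  "dxy": island_stats[f"dxy_{a}_{b}"]
                  if f"dxy_{a}_{b}" in island_stats
                  else island_stats[f"dxy_{b}_{a}"]}
        if rho is not None:
            merged = island_stats.merge(rho, on=["chrom", "start"],
                                        how="left", suffixes=("", "_rho"))
            tracks["rho"] = merged["rho"]
        for stat_name, values in tracks.items():
            vals = values.to_numpy(dtype=float)
            u, p, direction = island_background_contrast(
                vals[is_isl], vals[~is_isl])
            contrast_rows.append({"pair": f"{a}_{b}", "statistic": stat_name,
                                  "U": u, "p": p, "direction": direction})
    write_bed([(i.chrom, i.start, i.end, f"{i.pair};q={i.min_q:.3g}")
               for i in all_islands], st.path("islands.bed"))
    write_tsv(pd.DataFrame(
        [{"chrom": i.chrom, "start": i.start, "end": i.end, "pair": i.pair,
          "n_windows": len(i.member_windows), "min_q": i.min_q,
          "max_fst": i.max_fst} for i in all_islands]),
        st.path("islands.tsv"))
    write_tsv(pd.DataFrame(contrast_rows), st.path("island_contrasts.tsv"))
    st.commit()
    manifest["stages"]["islands"] = {
        "n_islands": len(all_islands),
        "pairs": [f"{a}_{b}" for a, b in pairs],
        "B": cfg.permutations,
    }

    # ---- select ----------------------------------------------------------
    st = _Stage(outdir)
    records = gene_selection_table(gm, pm, genes, mode=cfg.fixed_mode,
                                   estimator=cfg.estimator)
    records = call_psgs(records, hka_q_max=cfg.hka_q_max,
                        pbs_top_frac=cfg.pbs_top_frac)
    write_tsv(records, st.path("gene_selection.tsv"))
    sets = psg_sets(records)
    summary = sharing_analysis(sets, n_genes_universe=len(genes))
    write_tsv(pd.DataFrame([{
        **{f"n_psg_{sp}": n for sp, n in summary.per_species.items()},
        "n_unique": summary.n_unique, "n_shared_ge2": summary.n_shared_ge2,
        "pct_shared": summary.pct_shared,
        "expected_shared": summary.expected_shared,
        "chi2": summary.chi2, "p": summary.p,
    }]), st.path("psg_sharing.tsv"))
    for sp, genes_sp in sorted(sets.items()):
        with open(st.path(f"psg_{sp}.txt"), "w") as fh:
            fh.write("\n".join(sorted(genes_sp)) + ("\n" if genes_sp else ""))
    if cfg.gene2term:
        g2t_df = pd.read_csv(cfg.gene2term, sep="\t",
                             names=["gene_id", "term"], header=None)
        g2t: dict[str, list[str]] = {}
        for row in g2t_df.itertuples(index=False):
            g2t.setdefault(str(row.gene_id), []).append(str(row.term))
        universe = {g.gene_id for g in genes}
        for sp, genes_sp in sorted(sets.items()):
            enr = term_enrichment(genes_sp, g2t, universe)
            write_tsv(enr, st.path(f"enrichment_{sp}.tsv"))
    st.commit()
    manifest["stages"]["select"] = {
        "n_genes": len(genes),
        "psg_counts": {sp: len(s) for sp, s in sorted(sets.items())},
        "n_unique": summary.n_unique, "n_shared_ge2": summary.n_shared_ge2,
    }

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
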