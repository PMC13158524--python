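"""Three-species genotype simulator with known truth.

Generates diploid genotype datasets for a three-species radiation on the
fixed topology ((OK, OI), OT) using hierarchical Balding-Nichols allele-
frequency drift: each SNP's ancestral frequency is drawn uniformly, drifts
along the internal (OK, OI) ancestor branch and then along each terminal
branch as Beta(p(1-F)/F, (1-p)(1-F)/F) draws, receives one-shot asymmetric
migration mixing, and is realised as per-individual Binomial(2, p)
genotypes with missingness.  Planted structure with recorded truth:

* high-divergence islands — intervals where branch drift is amplified by a
  multiplier lambda, producing elevated F_ST;
* sweep-like genes — the focal species' frequency is pushed toward the
  nearer boundary and its residual polymorphism thinned, producing the
  segregating-site deficit and divergence excess that HKA and PBS target.

The default parameters emulate a strongly differentiated radiation
(genome-wide pairwise Hudson F_ST roughly 0.38-0.50, deepest for the OT
pairs) with sample sizes in the 54:45:27 OT:OK:OI ratio at one-third scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotype_io import (
    MISSING,
    GeneInterval,
    GenotypeMatrix,
    PopulationMap,
    write_bed,
    write_gff,
    write_popmap,
)

logger = logging.getLogger(__name__)

SPECIES = ("OT", "OK", "OI")


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IslandSpec:
    """A planted high-divergence interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    lam: float = 5.0
    #: branches whose drift is amplified inside the interval
    branches: tuple[str, ...] = SPECIES
    #: when set, overrides the lineage-sorting site rate inside the island,
    #: planting ancestral (fixed-difference) divergence that elevates D_xy
    div_rate: float | None = None


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep-like gene for one focal species."""

    gene_id: str
    chrom: str
    start: int
    end: int
    focal: str
    strength: float = 0.9
    #: fraction of the gene's focal-species polymorphism fixed outright
    thin: float = 0.7
    #: probability that a gene site becomes a focal-branch sorting site,
    #: i.e. a fixed difference dragged along by the sweep
    div_boost: float = 0.3


@dataclass
class SimConfig:
    """Generative parameters of the three-species simulator.

    Branch drift intensities F in (0, 1) follow the Balding-Nichols
    parameterisation (larger F = more drift).  ``migration`` maps directed
    (source, recipient) pairs to admixture fractions m in [0, 0.5): after
    drift, p_recipient <- (1 - m) p_recipient + m p_source.  The expected
    Hudson F_ST of a pair is half the sum of the two tips' compound drift
    variance factors (1 - prod(1 - F) from root to tip; the shared
    ancestral branch cancels), slightly shrunk by migration; the defaults
    put the three pairs near 0.49 (OT-OK), 0.45 (OT-OI) and 0.38 (OK-OI),
    with gene flow strongest between OT and the OK/OI lineages.
    """

    contigs: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000)])
    snp_density: float = 1 / 200.0  # SNPs per bp
    n_snps: int | None = None  # overrides density when set
    samples: dict[str, int] = field(
        default_factory=lambda: {"OT": 18, "OK": 15, "OI": 9})
    f_ot: float = 0.50
    f_anc: float = 0.20
    f_ok: float = 0.46
    f_oi: float = 0.36
    migration: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("OT", "OK"): 0.02, ("OK", "OT"): 0.02,
            ("OT", "OI"): 0.02, ("OI", "OT"): 0.02,
            ("OK", "OI"): 0.005, ("OI", "OK"): 0.005,
        })
    #: fraction of sites where lineage sorting has fixed one tip branch for
    #: the alternative allele — the fixed-difference class that deep
    #: divergence produces and pure desk-scale drift underproduces
    divergent_site_rate: float = 0.02
    islands: list[IslandSpec] = field(default_factory=list)
    sweeps: list[SweepSpec] = field(default_factory=list)
    n_background_genes: int = 40  # evenly spaced neutral genes per contig
    gene_length: int = 5_000
    #: intervals whose sites copy the block's first dosage column with
    #: per-genotype noise, planting local linkage disequilibrium (the
    #: frequency model itself carries no linkage)
    ld_blocks: list[tuple[str, int, int]] = field(default_factory=list)
    ld_copy_noise: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_ot", "f_anc", "f_ok", "f_oi"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for pair, m in self.migration.items():
            if not 0.0 <= m < 0.5:
                raise ValueError(f"migration rate {pair} must be in [0, 0.5)")
        lengths = dict(self.contigs)
        for isl in self.islands:
            if not (0 <= isl.start < isl.end <= lengths.get(isl.chrom, -1)):
                raise ValueError(f"island {isl} outside contig bounds")


@dataclass
class SimTruth:
    """Planted structure and realised parameters for recovery tests."""

    islands: list[IslandSpec]
    sweep_genes: list[SweepSpec]
    branch_f: dict[str, float]
    seed: int
    config: SimConfig


@dataclass
class SimResult:
    gm: GenotypeMatrix
    popmap: PopulationMap
    genes: list[GeneInterval]
    truth: SimTruth


# ---------------------------------------------------------------------------
# Drift kernel
# ---------------------------------------------------------------------------


def drift_freq(p, f: float, rng: np.random.Generator):
    """Balding-Nichols drift: p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F).

    ``f`` may be a scalar or an array broadcastable against ``p``.
    Boundary frequencies (0 and 1) are absorbing and returned unchanged.
    """
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("drift parameter F must be in (0, 1)")
    scale = (1.0 - f) / f
    interior = (p > 0.0) & (p < 1.0)
    out = p.copy()
    if np.any(interior):
        a = np.broadcast_to(p * scale, p.shape)[interior]
        b = np.broadcast_to((1.0 - p) * scale, p.shape)[interior]
        out[interior] = rng.beta(a, b)
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _site_positions(cfg: SimConfig, rng: np.random.Generator):
    chroms, poss = [], []
    total_len = sum(length for _, length in cfg.contigs)
    for name, length in cfg.contigs:
        if cfg.n_snps is not None:
            n = int(round(cfg.n_snps * length / total_len))
        else:
            n = int(round(cfg.snp_density * length))
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1  # 1-based
        chroms.append(np.full(n, name, dtype=object))
        poss.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(poss)


def _interval_mask(chrom, pos, spec_chrom, start, end):
    # pos is 1-based; interval 0-based half-open
    return (chrom == spec_chrom) & (pos - 1 >= start) & (pos - 1 < end)


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Generate genotypes, population map, gene annotation, and truth."""
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _site_positions(cfg, rng)
    n_sites = pos.size

    p0 = rng.uniform(0.05, 0.95, size=n_sites)

    # lineage-sorting sites: one tip branch starts near one boundary, the
    # rest of the tree near the other, yielding reciprocally fixed
    # differences for that branch.  Sweep genes boost the rate on the
    # focal branch (hitchhiking fixed differences).
    sort_branch = np.full(n_sites, -1, dtype=np.int8)
    if cfg.divergent_site_rate > 0:
        hit = rng.random(n_sites) < cfg.divergent_site_rate
        sort_branch[hit] = rng.integers(0, len(SPECIES), size=int(hit.sum()))
    for isl in cfg.islands:
        if isl.div_rate is None:
            continue
        m = _interval_mask(chrom, pos, isl.chrom, isl.start, isl.end)
        hit = m & (rng.random(n_sites) < isl.div_rate)
        sort_branch[hit] = rng.integers(0, len(SPECIES), size=n_sites)[hit]
    for sw in cfg.sweeps:
        m = _interval_mask(chrom, pos, sw.chrom, sw.start, sw.end)
        boost = m & (rng.random(n_sites) < sw.div_boost)
        sort_branch[boost] = SPECIES.index(sw.focal)
    sorted_sites = sort_branch >= 0
    p_lo = rng.uniform(0.01, 0.05, size=n_sites)
    p_hi = rng.uniform(0.95, 0.99, size=n_sites)
    flip = rng.random(n_sites) < 0.5  # allele polarity of the sorted branch
    p_lo2, p_hi2 = (np.where(flip, p_hi, p_lo), np.where(flip, p_lo, p_hi))
    p0 = np.where(sorted_sites, p_lo2, p0)

    # per-site branch drift intensities, amplified inside planted islands
    branch_f = {"OT": cfg.f_ot, "OK": cfg.f_ok, "OI": cfg.f_oi}
    f_site = {sp: np.full(n_sites, branch_f[sp]) for sp in SPECIES}
    for isl in cfg.islands:
        m = _interval_mask(chrom, pos, isl.chrom, isl.start, isl.end)
        for sp in isl.branches:
            f_site[sp][m] = np.minimum(branch_f[sp] * isl.lam, 1.0 - 1e-3)

    p_anc = drift_freq(p0, cfg.f_anc, rng)  # OK/OI common ancestor
    tip_input = {
        "OT": np.where(sort_branch == 0, p_hi2, p0),
        "OK": np.where(sort_branch == 1, p_hi2, p_anc),
        "OI": np.where(sort_branch == 2, p_hi2, p_anc),
    }
    freq = {sp: drift_freq(tip_input[sp], f_site[sp], rng)
            for sp in SPECIES}

    # one-shot migration admixture on post-drift frequencies
    pre = {sp: freq[sp].copy() for sp in SPECIES}
    for sp in SPECIES:
        m_in = {src: m for (src, dst), m in cfg.migration.items()
                if dst == sp and m > 0}
        if m_in:
            total = sum(m_in.values())
            freq[sp] = (1.0 - total) * pre[sp] + sum(
                m * pre[src] for src, m in m_in.items())

    # sweep-like genes: push focal frequency to the nearer boundary and
    # thin residual focal polymorphism
    for sw in cfg.sweeps:
        m = _interval_mask(chrom, pos, sw.chrom, sw.start, sw.end)
        if not m.any():
            continue
        pf = freq[sw.focal][m]
        target = (pf >= 0.5).astype(float)
        pushed = (1.0 - sw.strength) * pf + sw.strength * target
        fix = rng.random(pf.size) < sw.thin
        pushed[fix] = target[fix]
        freq[sw.focal][m] = pushed

    # genotypes: Binomial(2, p) per individual, missing at rate epsilon
    sample_ids: list[str] = []
    species_of: dict[str, str] = {}
    blocks = []
    for sp in SPECIES:
        n_ind = cfg.samples.get(sp, 0)
        ids = [f"{sp}{i + 1:02d}" for i in range(n_ind)]
        sample_ids.extend(ids)
        species_of.update({s: sp for s in ids})
        g = rng.binomial(2, freq[sp][:, None],
                         size=(n_sites, n_ind)).astype(np.int8)
        blocks.append(g)
    dosage = np.concatenate(blocks, axis=1)
    sp_slices = {}
    off = 0
    for sp in SPECIES:
        sp_slices[sp] = slice(off, off + cfg.samples.get(sp, 0))
        off += cfg.samples.get(sp, 0)
    for bchrom, bstart, bend in cfg.ld_blocks:
        rows = np.flatnonzero(_interval_mask(chrom, pos, bchrom, bstart, bend))
        if rows.size < 2:
            continue
        # template: block site most polymorphic within every species, so
        # the planted correlation is visible inside each population
        within_var = np.stack(
            [dosage[rows][:, sl].var(axis=1) for sl in sp_slices.values()
             if sl.stop > sl.start])
        t = rows[int(np.argmax(within_var.min(axis=0)))]
        template = dosage[t]
        for r in rows:
            if r == t:
                continue
            noise = rng.random(dosage.shape[1]) < cfg.ld_copy_noise
            dosage[r] = np.where(noise, dosage[r], template)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    refs = np.full(n_sites, "A", dtype=object)
    alts = np.full(n_sites, "T", dtype=object)
    gm = GenotypeMatrix(chrom=chrom, pos=pos, ref_allele=refs,
                        alt_allele=alts, dosage=dosage,
                        sample_ids=sample_ids)
    pm = PopulationMap(mapping=species_of)
    genes = _make_genes(cfg)
    truth = SimTruth(islands=list(cfg.islands), sweep_genes=list(cfg.sweeps),
                     branch_f=branch_f, seed=cfg.seed, config=cfg)
    logger.info("simulated %d sites x %d samples on %d contig(s)",
                n_sites, len(sample_ids), len(cfg.contigs))
    return SimResult(gm=gm, popmap=pm, genes=genes, truth=truth)


def _make_genes(cfg: SimConfig) -> list[GeneInterval]:
    """Sweep genes plus evenly spaced neutral background genes."""
    genes = [GeneInterval(sw.gene_id, sw.chrom, sw.start, sw.end)
             for sw in cfg.sweeps]
    taken = [(g.chrom, g.start, g.end) for g in genes]
    k = 0
    for name, length in cfg.contigs:
        if cfg.n_background_genes <= 0:
            continue
        spacing = length // (cfg.n_background_genes + 1)
        for i in range(cfg.n_background_genes):
            start = (i + 1) * spacing
            end = min(start + cfg.gene_length, length)
            if end <= start:
                continue
            if any(c == name and start < e and s < end
                   for c, s, e in taken):
                continue  # background genes never overlap planted sweeps
            k += 1
            genes.append(GeneInterval(f"bg{k:04d}", name, start, end))
    return sorted(genes, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------


def write_vcf(gm: GenotypeMatrix, path: str,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT genotypes, deterministically."""
    geno_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(geno_str[int(d)] for d in gm.dosage[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref_allele[i]}\t"
                     f"{gm.alt_allele[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def write_dataset(sim: SimResult, outdir: str) -> dict[str, str]:
    """Emit VCF, popmap TSV, GFF3, and truth BED/TSV files; return paths."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "islands_bed": os.path.join(outdir, "truth_islands.bed"),
        "sweeps_tsv": os.path.join(outdir, "truth_sweeps.tsv"),
        "config": os.path.join(outdir, "sim_config.json"),
    }
    write_vcf(sim.gm, paths["vcf"],
              contig_lengths=dict(sim.truth.config.contigs))
    write_popmap(sim.popmap, paths["popmap"])
    write_gff(sim.genes, paths["gff"])
    write_bed([(i.chrom, i.start, i.end,
                f"lam={i.lam};branches={','.join(i.branches)}")
               for i in sim.truth.islands], paths["islands_bed"])
    with open(paths["sweeps_tsv"], "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tfocal\tstrength\tthin\n")
        for sw in sim.truth.sweep_genes:
            fh.write(f"{sw.gene_id}\t{sw.chrom}\t{sw.start}\t{sw.end}\t"
                     f"{sw.focal}\t{sw.strength}\t{sw.thin}\n")
    cfg = asdict(sim.truth.config)
    cfg["migration"] = {f"{a}->{b}": m
                        for (a, b), m in cfg["migration"].items()}
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    return paths


# ---------------------------------------------------------------------------
# Truth recovery metrics
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_bp(a: dict[str, list], b: dict[str, list]) -> int:
    total = 0
    for c, ivs in a.items():
        if c not in b:
            continue
        for s1, e1 in ivs:
            for s2, e2 in b[c]:
                total += max(0, min(e1, e2) - max(s1, s2))
    return total


def truth_overlap(calls, truth_intervals) -> tuple[float, float]:
    """bp-level (sensitivity, false-call fraction) of interval calls.

    ``calls`` and ``truth_intervals`` are iterables of objects with chrom /
    start / end.  Sensitivity is the fraction of truth bp covered by calls;
    the false-call fraction is the fraction of called bp outside truth.
    Empty calls return (0.0, 0.0).
    """

    def as_dict(items):
        d: dict[str, list] = {}
        for it in items:
            d.setdefault(it.chrom, []).append((it.start, it.end))
        return {c: _merge_intervals(v) for c, v in d.items()}

    cd, td = as_dict(calls), as_dict(truth_intervals)
    called_bp = sum(e - s for ivs in cd.values() for s, e in ivs)
    truth_bp = sum(e - s for ivs in td.values() for s, e in ivs)
    if called_bp == 0:
        return 0.0, 0.0
    inter = _overlap_bp(cd, td)
    sens = inter / truth_bp if truth_bp else 0.0
    false_frac = (called_bp - inter) / called_bp
    return float(sens), float(false_frac)


def sweep_recovery(psg_or_rank_sets: dict[str, set[str]],
                   truth: SimTruth) -> tuple[float, float]:
    """Set-level (recall, precision) of per-species sweep-gene calls."""
    true_by_sp: dict[str, set[str]] = {}
    for sw in truth.sweep_genes:
        true_by_sp.setdefault(sw.focal, set()).add(sw.gene_id)
    tp = fp = fn = 0
    for sp, called in psg_or_rank_sets.items():
        truth_sp = true_by_sp.get(sp, set())
        tp += len(called & truth_sp)
        fp += len(called - truth_sp)
        fn += len(truth_sp - called)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return float(recall), float(precision)
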