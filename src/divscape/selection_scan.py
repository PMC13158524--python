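"""Gene-wise selection tests: HKA, PBS, PSG calling, sharing, enrichment.

For each gene and focal species the scan counts segregating sites within
the focal lineage (S) and fixed differences against the other two species
(D, sites reciprocally fixed for alternative alleles), tests the gene's
polymorphism-to-divergence ratio against the genome-wide expectation with
a 2x2 contingency HKA test, and converts gene-level pairwise F_ST into the
population branch statistic PBS = (T_f,o1 + T_f,o2 - T_o1,o2)/2 with
T = -ln(1 - F_ST).  Candidate positively selected genes (PSGs) must pass a
dual criterion: FDR-adjusted HKA q below threshold AND PBS in the top
fraction of the focal species' empirical distribution.  Cross-species PSG
sharing is summarised against an independence expectation, and term
enrichment uses one-sided Fisher tests with BH correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GeneInterval, GenotypeMatrix, PopulationMap
from .island_scan import bh_fdr
from .window_stats import Window, allele_counts, fst_components

logger = logging.getLogger(__name__)

#: F_ST is clamped to [0, 1 - PBS_CLAMP_EPS] before the log transform.
PBS_CLAMP_EPS = 1e-6


# ---------------------------------------------------------------------------
# Site counts
# ---------------------------------------------------------------------------


def gene_site_counts(
    gm: GenotypeMatrix,
    gene: GeneInterval,
    focal: str,
    others: tuple[str, str],
    pm: PopulationMap,
    mode: str = "pooled",
    fixed_call_rate_min: float = 0.8,
) -> tuple[int, int]:
    """(S_focal, D_fixed) for one gene.

    S counts sites polymorphic within the focal species (0 < p < 1 among
    called alleles).  D counts reciprocal fixation: under ``mode="pooled"``
    the focal species fixed for one allele with BOTH others fixed for the
    alternative; ``mode="pairwise-sum"`` sums reciprocally fixed sites over
    the two focal-vs-other comparisons.  A site contributes only where the
    species involved each reach ``fixed_call_rate_min``.
    """
    counts = _species_site_counts(gm, pm, (focal, *others))
    idx = _gene_site_index(gm, gene)
    return _classify_gene_sites(counts, idx, focal, others, mode,
                                fixed_call_rate_min, pm)


def _gene_site_index(gm: GenotypeMatrix, gene: GeneInterval) -> np.ndarray:
    from .window_stats import window_site_index
    return window_site_index(gm, Window(gene.chrom, gene.start, gene.end))


def _species_site_counts(gm, pm, species) -> dict[str, tuple]:
    out = {}
    for sp in species:
        cols = pm.indices_of(sp, gm)
        an, ac = allele_counts(gm, cols)
        out[sp] = (an, ac, 2 * cols.size)
    return out


def _classify_gene_sites(counts, idx, focal, others, mode,
                         fixed_call_rate_min, pm) -> tuple[int, int]:
    if idx.size == 0:
        return 0, 0
    an_f, ac_f, tot_f = (a[idx] if isinstance(a, np.ndarray) else a
                         for a in counts[focal])
    ok_f = an_f >= fixed_call_rate_min * tot_f
    seg = ok_f & (ac_f > 0) & (ac_f < an_f)
    s_focal = int(seg.sum())

    def fixed_state(sp):
        an, ac, tot = (a[idx] if isinstance(a, np.ndarray) else a
                       for a in counts[sp])
        ok = an >= fixed_call_rate_min * tot
        # +1 fixed alt, 0 fixed ref, -1 not fixed / insufficient calls
        state = np.full(idx.size, -1, dtype=np.int8)
        state[ok & (ac == an) & (an > 0)] = 1
        state[ok & (ac == 0) & (an > 0)] = 0
        return state

    st_f = fixed_state(focal)
    st_o = [fixed_state(sp) for sp in others]
    if mode == "pooled":
        recip = ((st_f >= 0) & (st_o[0] >= 0) & (st_o[1] >= 0)
                 & (st_o[0] == st_o[1]) & (st_f != st_o[0]))
        d_fixed = int(recip.sum())
    elif mode == "pairwise-sum":
        d_fixed = 0
        for st in st_o:
            d_fixed += int(((st_f >= 0) & (st >= 0) & (st_f != st)).sum())
    else:
        raise ValueError("mode must be 'pooled' or 'pairwise-sum'")
    return s_focal, d_fixed


# ---------------------------------------------------------------------------
# HKA and PBS
# ---------------------------------------------------------------------------


def hka_gene(s_g: int, d_g: int, s_genome: int, d_genome: int
             ) -> tuple[float, float]:
    """HKA as a 2x2 test of gene vs rest-of-genome polymorphism/divergence.

    Table [[S_g, D_g], [S_genome - S_g, D_genome - D_g]]; Pearson
    chi-square (df=1, no continuity correction), with Fisher's exact test
    substituted when any expected cell is below 5.  A zero marginal gives
    (0, 1).
    """
    if s_genome < s_g or d_genome < d_g:
        raise ValueError("genome totals must include the gene's counts")
    table = np.array([[s_g, d_g],
                      [s_genome - s_g, d_genome - d_g]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 0.0, 1.0
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if expected.min() < 5:
        _, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
        chi2 = float(sps.chi2_contingency(table, correction=False)[0])
        return chi2, float(p)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def branch_length(fst: float) -> float:
    """Divergence-scale branch transform T = -ln(1 - F_ST), F clamped."""
    f = min(max(fst, 0.0), 1.0 - PBS_CLAMP_EPS)
    return float(-np.log(1.0 - f))


def gene_pbs(fst_f_o1: float, fst_f_o2: float, fst_o1_o2: float) -> float:
    """Population branch statistic of the focal lineage.

    PBS = (T_f,o1 + T_f,o2 - T_o1,o2) / 2 with T = -ln(1 - F_ST); inputs
    are clamped to [0, 1 - 1e-6] before the log.  NaN when any input F_ST
    is undefined.
    """
    if any(np.isnan(f) for f in (fst_f_o1, fst_f_o2, fst_o1_o2)):
        return float("nan")
    t1 = branch_length(fst_f_o1)
    t2 = branch_length(fst_f_o2)
    t3 = branch_length(fst_o1_o2)
    return (t1 + t2 - t3) / 2.0


# ---------------------------------------------------------------------------
# Gene table and PSG calling
# ---------------------------------------------------------------------------


def gene_selection_table(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    genes: list[GeneInterval],
    mode: str = "pooled",
    fixed_call_rate_min: float = 0.8,
    estimator: str = "hudson",
    low_info_min_sites: int = 3,
) -> pd.DataFrame:
    """One row per gene x focal species with S, D, HKA, F_ST triple, PBS.

    HKA genome-wide totals are the sums of S and D over all genes for the
    focal species.  Gene F_ST is the ratio of summed per-SNP components
    over the gene's sites.  Genes with fewer than ``low_info_min_sites``
    sites in the matrix are flagged ``low_information``.
    """
    species = pm.species
    if len(species) != 3:
        raise ValueError("selection scan expects exactly 3 species")
    counts = _species_site_counts(gm, pm, species)
    cols = {sp: pm.indices_of(sp, gm) for sp in species}
    pairs = list(itertools.combinations(species, 2))
    comp = {p: fst_components(gm, cols[p[0]], cols[p[1]], p, estimator)
            for p in pairs}

    gene_idx = {g.gene_id: _gene_site_index(gm, g) for g in genes}
    rows = []
    for focal in species:
        others = tuple(sp for sp in species if sp != focal)
        sd = {}
        for g in genes:
            sd[g.gene_id] = _classify_gene_sites(
                counts, gene_idx[g.gene_id], focal, others, mode,
                fixed_call_rate_min, pm)
        s_genome = sum(v[0] for v in sd.values())
        d_genome = sum(v[1] for v in sd.values())
        for g in genes:
            s_g, d_g = sd[g.gene_id]
            chi2, p = hka_gene(s_g, d_g, s_genome, d_genome)
            idx = gene_idx[g.gene_id]
            fst = {}
            for pr in pairs:
                fst[pr] = comp[pr].ratio(idx) if idx.size else float("nan")
            f_o1 = fst[_pair_key(focal, others[0], pairs)]
            f_o2 = fst[_pair_key(focal, others[1], pairs)]
            f_oo = fst[_pair_key(others[0], others[1], pairs)]
            rows.append({
                "gene_id": g.gene_id, "focal_species": focal,
                "chrom": g.chrom, "start": g.start, "end": g.end,
                "n_sites": int(idx.size),
                "S_focal": s_g, "D_fixed": d_g,
                "hka_chi2": chi2, "hka_p": p,
                f"fst_{focal}_{others[0]}": f_o1,
                f"fst_{focal}_{others[1]}": f_o2,
                f"fst_{others[0]}_{others[1]}": f_oo,
                "pbs": gene_pbs(f_o1, f_o2, f_oo),
                "low_information": idx.size < low_info_min_sites,
            })
    return pd.DataFrame(rows)


def _pair_key(a: str, b: str, pairs) -> tuple[str, str]:
    return (a, b) if (a, b) in pairs else (b, a)


def call_psgs(
    records: pd.DataFrame,
    hka_q_max: float = 0.01,
    pbs_top_frac: float = 0.05,
) -> pd.DataFrame:
    """Flag PSGs per focal species with the dual HKA-FDR + PBS criterion.

    BH correction is applied within each focal species' gene list; the PBS
    cutoff is the per-species (1 - pbs_top_frac) quantile over genes with
    defined PBS.  Adds hka_q, pbs_cutoff and is_psg columns.
    """
    out = records.copy()
    out["hka_q"] = np.nan
    out["is_psg"] = False
    out["pbs_cutoff"] = np.nan
    for focal, grp in out.groupby("focal_species"):
        if len(grp) < 20:
            warnings.warn(
                f"{focal}: only {len(grp)} genes; PBS percentile cutoff is "
                "unstable", stacklevel=2)
        q = bh_fdr(grp["hka_p"].to_numpy())
        out.loc[grp.index, "hka_q"] = q
        pbs = grp["pbs"].to_numpy()
        defined = ~np.isnan(pbs)
        cutoff = (np.quantile(pbs[defined], 1.0 - pbs_top_frac)
                  if defined.any() else np.inf)
        out.loc[grp.index, "pbs_cutoff"] = cutoff
        out.loc[grp.index, "is_psg"] = (q < hka_q_max) & (pbs >= cutoff)
    return out


def psg_sets(records: pd.DataFrame) -> dict[str, set[str]]:
    return {
        focal: set(grp.loc[grp["is_psg"], "gene_id"])
        for focal, grp in records.groupby("focal_species")
    }


# ---------------------------------------------------------------------------
# Sharing and enrichment
# ---------------------------------------------------------------------------


@dataclass
class SharingSummary:
    """Cross-species PSG overlap vs an independence expectation."""

    per_species: dict[str, int]
    n_unique: int
    n_shared_ge2: int
    pct_shared: float
    expected_shared: float
    expected_unique: float
    chi2: float
    p: float


def sharing_analysis(psg_sets: dict[str, set[str]],
                     n_genes_universe: int) -> SharingSummary:
    """Summarise how many PSGs are shared by >= 2 species.

    The expectation treats each species' PSG set as an independent uniform
    draw of its observed size from the gene universe (per-gene inclusion
    probabilities k_i/N; shared-by->=2 probability by inclusion-exclusion).
    The chi-square compares observed counts of genes called in >= 2, exactly
    1, and 0 species against those expectations.
    """
    sets = {sp: set(s) for sp, s in psg_sets.items()}
    ks = {sp: len(s) for sp, s in sets.items()}
    if n_genes_universe <= 0 or sum(ks.values()) == 0:
        return SharingSummary(ks, 0, 0, 0.0, 0.0, 0.0, 0.0, 1.0)
    n = float(n_genes_universe)
    union: set[str] = set().union(*sets.values())
    calls = {g: sum(g in s for s in sets.values()) for g in union}
    n_unique = len(union)
    n_shared = sum(1 for v in calls.values() if v >= 2)

    probs = [k / n for k in ks.values()]
    p_ge2 = (sum(pi * pj for pi, pj in itertools.combinations(probs, 2))
             - 2.0 * np.prod(probs))
    p_ge1 = 1.0 - np.prod([1.0 - pi for pi in probs])
    exp_shared = n * p_ge2
    exp_unique = n * p_ge1
    exp_exactly1 = exp_unique - exp_shared
    exp_none = n - exp_unique

    obs = np.array([n_shared, n_unique - n_shared,
                    n_genes_universe - n_unique], dtype=float)
    exp = np.array([exp_shared, exp_exactly1, exp_none], dtype=float)
    if np.all(exp > 0):
        chi2, p = sps.chisquare(obs, exp)
    else:
        chi2, p = 0.0, 1.0
    pct = 100.0 * n_shared / n_unique if n_unique else 0.0
    return SharingSummary(
        per_species=ks, n_unique=n_unique, n_shared_ge2=n_shared,
        pct_shared=pct, expected_shared=float(exp_shared),
        expected_unique=float(exp_unique), chi2=float(chi2), p=float(p))


def term_enrichment(
    psg_set: set[str],
    gene2term: dict[str, list[str]],
    universe: set[str],
    q_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of annotation terms in a PSG set.

    Terms with no member in the universe are skipped.  Returns the full
    per-term table (term, n_psg, n_term, odds, p, q, significant) sorted by
    q; ``significant`` marks q < ``q_max``.
    """
    psg = set(psg_set) & set(universe)
    terms: dict[str, set[str]] = {}
    for g, tlist in gene2term.items():
        if g not in universe:
            continue
        for t in tlist:
            terms.setdefault(t, set()).add(g)
    rows = []
    n_univ = len(universe)
    for term, members in sorted(terms.items()):
        a = len(psg & members)
        b = len(psg) - a
        c = len(members) - a
        d = n_univ - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "n_psg_in_term": a, "n_term": len(members),
                     "odds": float(odds), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] < q_max
        df = df.sort_values("q", kind="stable").reset_index(drop=True)
    return df
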