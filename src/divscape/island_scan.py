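"""Permutation-calibrated detection of genomic islands of divergence.

A window's F_ST is compared against a null distribution built by
resampling per-SNP estimator components from the genome-wide pool while
preserving the window's number of informative SNPs: windows are grouped
into SNP-count categories, and for each category B pseudo-windows are drawn
(components sampled jointly, without replacement within a draw) so every
null value is itself a valid ratio-of-sums estimate.  Conditioning the null
on SNP content absorbs the extra variance of sparse windows.

Outlier windows must satisfy a dual criterion — top fraction of the
empirical F_ST distribution AND Benjamini-Hochberg q below threshold —
and adjacent outliers are merged into contiguous island calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeMatrix, PopulationMap
from .window_stats import SnpFstComponents, Window, fst_components

logger = logging.getLogger(__name__)

#: SNP-count categories are exact up to this count, logarithmic above it.
EXACT_CATEGORY_MAX = 50


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Sorted permutation draws of window F_ST for one SNP-count category."""

    snp_count_category: str
    s_drawn: int
    values: np.ndarray
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size != self.B:
            raise ValueError("null distribution must hold exactly B values")


@dataclass
class IslandCall:
    """A maximal run of merged adjacent outlier windows."""

    chrom: str
    start: int
    end: int
    pair: str
    member_windows: list[tuple[int, int]] = field(default_factory=list)
    min_q: float = float("nan")
    max_fst: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


def snp_count_category(s: int) -> str:
    """Exact count up to EXACT_CATEGORY_MAX, then power-of-two bins."""
    if s <= EXACT_CATEGORY_MAX:
        return str(int(s))
    k = int(np.floor(np.log2(s / EXACT_CATEGORY_MAX)))
    if s <= EXACT_CATEGORY_MAX * 2 ** k:  # boundary falls in the lower bin
        k -= 1
    return f"log{k}"


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def _draw_index_matrix(rng: np.random.Generator, pool: int, s: int,
                       B: int) -> np.ndarray:
    """B rows of s indices drawn uniformly without replacement per row."""
    if s > pool:
        raise ValueError(f"category SNP count {s} exceeds pool size {pool}")
    if s > 0.25 * pool:
        return np.stack([rng.choice(pool, size=s, replace=False)
                         for _ in range(B)])
    out = rng.integers(0, pool, size=(B, s))
    for _ in range(1000):  # reject rows containing duplicates
        srt = np.sort(out, axis=1)
        bad = np.any(srt[:, 1:] == srt[:, :-1], axis=1) if s > 1 else \
            np.zeros(B, dtype=bool)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, pool, size=(int(bad.sum()), s))
    raise RuntimeError("rejection sampling failed to converge")


def permutation_null(
    components: SnpFstComponents,
    windows: list[Window],
    B: int = 1000,
    seed: int = 0,
) -> dict[str, NullDistribution]:
    """Build per-category null F_ST distributions by SNP resampling.

    The genome-wide pool holds every SNP's (num, den) component pair; a
    null window of category s is the ratio of sums over s pairs sampled
    jointly without replacement.  Windows are assigned categories by their
    count of valid SNPs; one null distribution is built per observed
    category, with the draw size set to the (rounded) median SNP count of
    the category's windows.
    """
    if B < 100:
        warnings.warn(f"B={B} permutation draws is low; p-value resolution "
                      f"is 1/{B + 1}", stacklevel=2)
    ok = components.valid
    num = components.num[ok]
    den = components.den[ok]
    pool = num.size
    if pool == 0:
        raise ValueError("no valid SNP components to permute")

    counts = _window_snp_counts(components, windows)
    cats: dict[str, list[int]] = {}
    for s in counts:
        if s > 0:
            cats.setdefault(snp_count_category(s), []).append(int(s))

    rng = np.random.default_rng(seed)
    nulls: dict[str, NullDistribution] = {}
    for cat in sorted(cats):
        s_drawn = int(round(float(np.median(cats[cat]))))
        idx = _draw_index_matrix(rng, pool, s_drawn, B)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num[idx].sum(axis=1) / den[idx].sum(axis=1)
        nulls[cat] = NullDistribution(
            snp_count_category=cat, s_drawn=s_drawn,
            values=vals, B=B, seed=seed)
    logger.info("permutation null: %d categories, pool %d SNPs, B=%d",
                len(nulls), pool, B)
    return nulls


def _window_snp_counts(components: SnpFstComponents,
                       windows: list[Window]) -> np.ndarray:
    ok = components.valid
    counts = np.zeros(len(windows), dtype=np.int64)
    chrom = components.chrom[ok]
    pos0 = components.pos[ok] - 1
    for c in pd.unique(chrom):
        sel = chrom == c
        p = pos0[sel]  # sorted: matrix order is position-sorted per contig
        for i, w in enumerate(windows):
            if w.chrom == c:
                lo, hi = np.searchsorted(p, [w.start, w.end])
                counts[i] = hi - lo
    return counts


def empirical_p(fst_obs: float, null: NullDistribution) -> float:
    """Add-one empirical p: (1 + #{null >= obs}) / (1 + B); never zero."""
    n_ge = null.B - int(np.searchsorted(null.values, fst_obs, side="left"))
    return (1.0 + n_ge) / (1.0 + null.B)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Outlier calling and merging
# ---------------------------------------------------------------------------


def window_fst_table(components: SnpFstComponents,
                     windows: list[Window]) -> pd.DataFrame:
    """Per-window F_ST (ratio of sums) with valid-SNP counts."""
    ok = components.valid
    chrom = components.chrom[ok]
    pos0 = components.pos[ok] - 1
    num, den = components.num[ok], components.den[ok]
    cum_n = {}
    for c in pd.unique(chrom):
        sel = chrom == c
        cum_n[c] = (pos0[sel], np.cumsum(num[sel]), np.cumsum(den[sel]))
    rows = []
    for w in windows:
        if w.chrom in cum_n:
            p, cn, cd = cum_n[w.chrom]
            lo, hi = np.searchsorted(p, [w.start, w.end])
            s = hi - lo
            nsum = cn[hi - 1] - (cn[lo - 1] if lo else 0.0) if s else 0.0
            dsum = cd[hi - 1] - (cd[lo - 1] if lo else 0.0) if s else 0.0
        else:
            s, nsum, dsum = 0, 0.0, 0.0
        fst = nsum / dsum if dsum > 0 else np.nan
        rows.append({"chrom": w.chrom, "start": w.start, "end": w.end,
                     "n_snps": int(s), "fst": fst})
    return pd.DataFrame(rows)


def call_outliers(
    fst_table: pd.DataFrame,
    nulls: dict[str, NullDistribution],
    top_fraction: float = 0.05,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Apply the dual outlier criterion to a per-window F_ST table.

    Adds empirical_p, q_value, is_top_fraction and is_outlier columns.
    Windows with undefined F_ST (no informative SNPs) are excluded from
    the empirical distribution and flagged non-outliers; their count is
    stored in ``result.attrs['n_undefined']``.
    """
    out = fst_table.copy()
    defined = out["fst"].notna() & (out["n_snps"] > 0)
    n_undef = int((~defined).sum())

    fst_def = out.loc[defined, "fst"].to_numpy()
    cutoff = (np.quantile(fst_def, 1.0 - top_fraction)
              if fst_def.size else np.inf)
    out["empirical_p"] = np.nan
    for i in out.index[defined]:
        cat = snp_count_category(int(out.at[i, "n_snps"]))
        if cat not in nulls:
            raise KeyError(f"window SNP-count category {cat} has no null")
        out.at[i, "empirical_p"] = empirical_p(out.at[i, "fst"], nulls[cat])
    out["q_value"] = np.nan
    if defined.any():
        out.loc[defined, "q_value"] = bh_fdr(
            out.loc[defined, "empirical_p"].to_numpy())
    out["is_top_fraction"] = defined & (out["fst"] >= cutoff)
    out["is_outlier"] = out["is_top_fraction"] & (out["q_value"] < q_threshold)
    out.attrs["n_undefined"] = n_undef
    out.attrs["top_fraction_cutoff"] = float(cutoff)
    return out


def merge_adjacent(
    outlier_table: pd.DataFrame,
    pair: str = "",
    max_gap_windows: int = 0,
) -> list[IslandCall]:
    """Merge runs of adjacent (or overlapping) outlier windows into islands.

    Windows are adjacent when the next start is at or before the current
    island end plus ``max_gap_windows`` window-lengths; overlapping windows
    from sliding tilings merge by interval union.
    """
    sel = outlier_table[outlier_table["is_outlier"]].sort_values(
        ["chrom", "start"])
    islands: list[IslandCall] = []
    cur: IslandCall | None = None
    for row in sel.itertuples(index=False):
        wsize = row.end - row.start
        if (cur is not None and row.chrom == cur.chrom
                and row.start <= cur.end + max_gap_windows * wsize):
            cur.end = max(cur.end, row.end)
            cur.member_windows.append((row.start, row.end))
            cur.min_q = np.nanmin([cur.min_q, row.q_value])
            cur.max_fst = np.nanmax([cur.max_fst, row.fst])
        else:
            cur = IslandCall(chrom=row.chrom, start=row.start, end=row.end,
                             pair=pair, member_windows=[(row.start, row.end)],
                             min_q=row.q_value, max_fst=row.fst)
            islands.append(cur)
    return islands


def island_background_contrast(
    island_values, background_values
) -> tuple[float, float, int]:
    """Two-sided Mann-Whitney U of island vs background window values.

    Returns (U, p, direction) where direction is the sign of the island
    median minus the background median.  Undefined (NaN, NaN, 0) with a
    warning when either group has fewer than 3 defined values.
    """
    isl = np.asarray(island_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    isl = isl[~np.isnan(isl)]
    bg = bg[~np.isnan(bg)]
    if isl.size < 3 or bg.size < 3:
        warnings.warn("island/background contrast needs >= 3 windows per "
                      "group", stacklevel=2)
        return float("nan"), float("nan"), 0
    res = sps.mannwhitneyu(isl, bg, alternative="two-sided")
    direction = int(np.sign(np.median(isl) - np.median(bg)))
    return float(res.statistic), float(res.pvalue), direction


# ---------------------------------------------------------------------------
# High-level per-pair scan
# ---------------------------------------------------------------------------


def scan_islands(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pair: tuple[str, str],
    windows: list[Window],
    B: int = 1000,
    seed: int = 0,
    top_fraction: float = 0.05,
    q_threshold: float = 0.01,
    max_gap_windows: int = 0,
    estimator: str = "hudson",
) -> tuple[pd.DataFrame, list[IslandCall]]:
    """Window F_ST table with p/q/outlier flags, plus merged island calls."""
    a, b = pair
    comp = fst_components(gm, pm.indices_of(a, gm), pm.indices_of(b, gm),
                          pair, estimator)
    table = window_fst_table(comp, windows)
    nulls = permutation_null(comp, windows, B=B, seed=seed)
    table = call_outliers(table, nulls, top_fraction, q_threshold)
    islands = merge_adjacent(table, pair=f"{a}_{b}",
                             max_gap_windows=max_gap_windows)
    logger.info("pair %s-%s: %d outlier windows -> %d islands",
                a, b, int(table['is_outlier'].sum()), len(islands))
    return table, islands
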