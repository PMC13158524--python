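"""Windowed population-genetic statistics: pi, D_xy, F_ST, Tajima's D, LD.

All estimators operate on allele dosages and per-site called-allele counts;
no imputation is performed.  Within-population diversity (pi) uses the
unbiased per-site estimator ``n/(n-1) * 2p(1-p)``; absolute divergence
(D_xy) is the expected between-population allele difference
``p_A(1-p_B) + p_B(1-p_A)``; differentiation defaults to Hudson's
estimator accumulated as per-SNP numerator/denominator components so that
window values are ratios of sums and the permutation null can resample the
same components.  Weir-Cockerham components are available as an alternative.

Per-bp statistics divide by the full window length by default (sites absent
from the matrix are assumed invariant); an accessible-sites denominator can
be selected where that assumption is unsafe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """Genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(
    contig_lengths: dict[str, int], size: int, step: int | None = None
) -> list[Window]:
    """Tile every contig with windows of ``size`` bp.

    ``step`` defaults to ``size`` (non-overlapping tiling that covers every
    contig, last window truncated at the contig end).  ``step < size``
    yields sliding windows: ceil((L - size)/step) + 1 per contig of length
    L > size.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    step = size if step is None else step
    if step <= 0:
        raise ValueError("window step must be positive")
    windows: list[Window] = []
    for chrom, length in contig_lengths.items():
        length = int(length)
        if step == size:
            starts = range(0, length, size)
        else:
            n = (int(np.ceil((length - size) / step)) + 1
                 if length > size else 1)
            starts = (i * step for i in range(n))
        for s in starts:
            windows.append(Window(str(chrom), s, min(s + size, length)))
    return windows


def _pos0_by_chrom(gm: GenotypeMatrix) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contig (site indices, 0-based positions), in matrix order."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        out[str(c)] = (idx, gm.pos[idx] - 1)
    return out


def window_site_index(gm: GenotypeMatrix, window: Window) -> np.ndarray:
    """Indices of matrix sites falling in a window (0-based half-open)."""
    on_c = np.flatnonzero(gm.chrom == window.chrom)
    pos0 = gm.pos[on_c] - 1
    lo, hi = np.searchsorted(pos0, [window.start, window.end])
    return on_c[lo:hi]


# ---------------------------------------------------------------------------
# Per-site frequency machinery
# ---------------------------------------------------------------------------


def allele_counts(gm: GenotypeMatrix, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(called allele count, alt allele count) per site for given columns."""
    d = gm.dosage[:, cols]
    called = d != MISSING
    an = 2 * called.sum(axis=1)
    ac = np.where(called, d, 0).sum(axis=1)
    return an.astype(np.int64), ac.astype(np.int64)


def _freqs(an: np.ndarray, ac: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(an > 0, ac / np.maximum(an, 1), np.nan)


def pi_per_site(an: np.ndarray, ac: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity; NaN where fewer than 2 alleles."""
    p = _freqs(an, ac)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (an / np.maximum(an - 1, 1)) * 2.0 * p * (1.0 - p)
    pi[an < 2] = np.nan
    return pi


def dxy_per_site(an_a, ac_a, an_b, ac_b) -> np.ndarray:
    """Expected between-population difference; NaN where a side is uncalled."""
    pa, pb = _freqs(an_a, ac_a), _freqs(an_b, ac_b)
    d = pa * (1.0 - pb) + pb * (1.0 - pa)
    d[(an_a < 1) | (an_b < 1)] = np.nan
    return d


# ---------------------------------------------------------------------------
# F_ST components
# ---------------------------------------------------------------------------


@dataclass
class SnpFstComponents:
    """Per-SNP numerator/denominator decomposition of a pairwise estimator.

    The window (or gene) statistic is sum(num)/sum(den) over the valid sites
    it contains — a ratio of sums, never a mean of per-site ratios.  Sites
    where either population has fewer than two called alleles carry NaN.
    """

    pair: tuple[str, str]
    chrom: np.ndarray
    pos: np.ndarray  # 1-based, matching the source matrix
    num: np.ndarray
    den: np.ndarray
    estimator: str = "hudson"

    @property
    def valid(self) -> np.ndarray:
        return ~(np.isnan(self.num) | np.isnan(self.den))

    def ratio(self, index: np.ndarray | None = None) -> float:
        """sum(num)/sum(den) over ``index`` (all sites when None)."""
        num = self.num if index is None else self.num[index]
        den = self.den if index is None else self.den[index]
        ok = ~(np.isnan(num) | np.isnan(den))
        d = den[ok].sum()
        return float(num[ok].sum() / d) if d > 0 else float("nan")


def hudson_components(
    gm: GenotypeMatrix, cols_a: np.ndarray, cols_b: np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
) -> SnpFstComponents:
    """Hudson per-SNP components.

    num = (p_A - p_B)^2 - p_A(1-p_A)/(n_A-1) - p_B(1-p_B)/(n_B-1);
    den = p_A(1-p_B) + p_B(1-p_A), with n the called allele counts.
    Sites with n < 2 in either population are NaN (skipped downstream).
    """
    an_a, ac_a = allele_counts(gm, cols_a)
    an_b, ac_b = allele_counts(gm, cols_b)
    pa, pb = _freqs(an_a, ac_a), _freqs(an_b, ac_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / np.maximum(an_a - 1, 1)
               - pb * (1 - pb) / np.maximum(an_b - 1, 1))
    den = pa * (1 - pb) + pb * (1 - pa)
    bad = (an_a < 2) | (an_b < 2)
    num[bad] = np.nan
    den[bad] = np.nan
    return SnpFstComponents(pair=pair, chrom=gm.chrom, pos=gm.pos,
                            num=num, den=den, estimator="hudson")


def weir_cockerham_components(
    gm: GenotypeMatrix, cols_a: np.ndarray, cols_b: np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
) -> SnpFstComponents:
    """Weir-Cockerham (1984) two-population a / (a+b+c) components."""
    comps = []
    for cols in (cols_a, cols_b):
        d = gm.dosage[:, cols]
        called = d != MISSING
        n = called.sum(axis=1).astype(float)  # diploids called
        ac = np.where(called, d, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, ac / (2 * n), np.nan)
            h = np.where(n > 0, (d == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num, den = a, a + b + c
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return SnpFstComponents(pair=pair, chrom=gm.chrom, pos=gm.pos,
                            num=num, den=den, estimator="wc")


def fst_components(gm, cols_a, cols_b, pair=("A", "B"), estimator="hudson"):
    if estimator == "hudson":
        return hudson_components(gm, cols_a, cols_b, pair)
    if estimator == "wc":
        return weir_cockerham_components(gm, cols_a, cols_b, pair)
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


# ---------------------------------------------------------------------------
# Per-window operations
# ---------------------------------------------------------------------------


def _denominator(gm: GenotypeMatrix, window: Window, idx: np.ndarray,
                 denom_mode: str) -> float:
    if denom_mode == "window":
        return float(window.length)
    if denom_mode == "accessible":
        return float(idx.size)
    raise ValueError("denom_mode must be 'window' or 'accessible'")


def pi_window(gm: GenotypeMatrix, samples, window: Window,
              denom_mode: str = "window") -> float:
    """Per-bp nucleotide diversity of one population in one window."""
    cols = gm.sample_indices(samples)
    idx = window_site_index(gm, window)
    denom = _denominator(gm, window, idx, denom_mode)
    if denom <= 0:
        return float("nan")
    an, ac = allele_counts(gm, cols)
    pi = pi_per_site(an, ac)[idx]
    return float(np.nansum(pi) / denom)


def dxy_window(gm: GenotypeMatrix, samples_a, samples_b, window: Window,
               denom_mode: str = "window") -> float:
    """Per-bp absolute divergence between two populations in one window."""
    ca, cb = gm.sample_indices(samples_a), gm.sample_indices(samples_b)
    idx = window_site_index(gm, window)
    denom = _denominator(gm, window, idx, denom_mode)
    if denom <= 0:
        return float("nan")
    an_a, ac_a = allele_counts(gm, ca)
    an_b, ac_b = allele_counts(gm, cb)
    d = dxy_per_site(an_a, ac_a, an_b, ac_b)[idx]
    return float(np.nansum(d) / denom)


def hudson_fst_window(components: SnpFstComponents, gm: GenotypeMatrix,
                      window: Window) -> float:
    """Window F_ST as the ratio of summed per-SNP components."""
    idx = window_site_index(gm, window)
    return components.ratio(idx)


def tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima (1989) normalisation constants for n sampled alleles."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _tajd_from_counts(an_w: np.ndarray, ac_w: np.ndarray) -> float:
    if an_w.size == 0:
        return float("nan")
    called = an_w >= 2
    if not called.any():
        return float("nan")
    counts = np.bincount(an_w[called])
    n_modal = int(counts.argmax())
    if n_modal < 4:
        return float("nan")
    use = called & (np.abs(an_w - n_modal) <= 0.2 * n_modal)
    an_u, ac_u = an_w[use], ac_w[use]
    p = _freqs(an_u, ac_u)
    seg = (ac_u > 0) & (ac_u < an_u)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    k = tajima_constants(n_modal)
    pi_sum = float(np.sum((an_u[seg] / (an_u[seg] - 1))
                          * 2.0 * p[seg] * (1.0 - p[seg])))
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - theta_w) / np.sqrt(var))


def tajimas_d_window(gm: GenotypeMatrix, samples, window: Window) -> float:
    """Tajima's D for one population in one window; NaN when undefined.

    Sample size is taken as the modal called-allele count across the
    window's sites; sites whose call count deviates from it by more than
    20% are excluded (no imputation).  Undefined for S = 0 or n < 4.
    """
    cols = gm.sample_indices(samples)
    idx = window_site_index(gm, window)
    an, ac = allele_counts(gm, cols)
    return _tajd_from_counts(an[idx], ac[idx])


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def ld_decay(
    gm: GenotypeMatrix,
    samples,
    max_dist: int = 100_000,
    bin_width: int = 1_000,
    subsample_n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean squared dosage correlation (r^2) by pairwise distance bin.

    r^2 is the squared Pearson correlation of unphased dosage vectors over
    co-called samples.  Pairs involving a site monomorphic among co-called
    samples are skipped.  ``subsample_n`` draws an equal-size random subset
    of samples (seeded) so species with different sample sizes are
    comparable.
    """
    cols = gm.sample_indices(samples)
    if subsample_n is not None and subsample_n < cols.size:
        rng = np.random.default_rng(seed)
        cols = rng.choice(cols, size=subsample_n, replace=False)
    nbins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    dosage = gm.dosage[:, cols].astype(float)
    dosage[gm.dosage[:, cols] == MISSING] = np.nan
    for c in pd.unique(gm.chrom):
        on_c = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[on_c]
        d = dosage[on_c]
        for i in range(on_c.size - 1):
            hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            if hi <= i + 1:
                continue
            x = d[i]
            y = d[i + 1:hi]
            m = ~np.isnan(x) & ~np.isnan(y)
            n = m.sum(axis=1).astype(float)
            x0 = np.where(m, x, 0.0)
            y0 = np.where(m, y, 0.0)
            sx, sy = x0.sum(1), y0.sum(1)
            sxx, syy = (x0 * x0).sum(1), (y0 * y0).sum(1)
            sxy = (x0 * y0).sum(1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = sxy - sx * sy / n
                vx = sxx - sx ** 2 / n
                vy = syy - sy ** 2 / n
                r2 = cov ** 2 / (vx * vy)
            ok = (n >= 2) & (vx > 0) & (vy > 0)
            if not ok.any():
                continue
            dist = pos[i + 1:hi] - pos[i]
            bins = np.minimum((dist - 1) // bin_width, nbins - 1)
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)
    lo = np.arange(nbins) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "dist_lo": lo, "dist_hi": lo + bin_width,
        "mean_r2": mean_r2, "n_pairs": counts,
    })


# ---------------------------------------------------------------------------
# Bulk per-window table
# ---------------------------------------------------------------------------


def windowed_statistics(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    windows: list[Window],
    denom_mode: str = "window",
    estimator: str = "hudson",
    with_tajd: bool = True,
) -> pd.DataFrame:
    """One row per window: n_snps, pi per species, D_xy/F_ST per pair.

    Vectorised across windows; per-site quantities are computed once and
    aggregated with prefix sums over the (sorted) site positions.
    """
    species = pm.species
    cols = {sp: pm.indices_of(sp, gm) for sp in species}
    counts = {sp: allele_counts(gm, cols[sp]) for sp in species}

    per_site: dict[str, np.ndarray] = {}
    for sp in species:
        per_site[f"pi_{sp}"] = pi_per_site(*counts[sp])
    pairs = [(species[i], species[j])
             for i in range(len(species)) for j in range(i + 1, len(species))]
    comp: dict[tuple[str, str], SnpFstComponents] = {}
    for a, b in pairs:
        per_site[f"dxy_{a}_{b}"] = dxy_per_site(*counts[a], *counts[b])
        comp[(a, b)] = fst_components(gm, cols[a], cols[b], (a, b), estimator)

    by_chrom = _pos0_by_chrom(gm)
    rows = []
    for w in windows:
        idx_all, pos0 = by_chrom.get(w.chrom, (np.array([], dtype=int),
                                               np.array([], dtype=int)))
        lo, hi = np.searchsorted(pos0, [w.start, w.end])
        idx = idx_all[lo:hi]
        denom = _denominator(gm, w, idx, denom_mode)
        row: dict = {"chrom": w.chrom, "start": w.start, "end": w.end,
                     "n_snps": int(idx.size)}
        for sp in species:
            vals = per_site[f"pi_{sp}"][idx]
            row[f"pi_{sp}"] = (np.nansum(vals) / denom if denom > 0
                               else np.nan)
        for a, b in pairs:
            vals = per_site[f"dxy_{a}_{b}"][idx]
            row[f"dxy_{a}_{b}"] = (np.nansum(vals) / denom if denom > 0
                                   else np.nan)
            row[f"fst_{a}_{b}"] = comp[(a, b)].ratio(idx)
        if with_tajd:
            for sp in species:
                an, ac = counts[sp]
                row[f"tajd_{sp}"] = _tajd_from_counts(an[idx], ac[idx])
        rows.append(row)
    return pd.DataFrame(rows)
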