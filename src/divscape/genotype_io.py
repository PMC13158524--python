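"""Genotype data model, standard-format I/O, and the SNP filtering cascade.

The central container is :class:`GenotypeMatrix`, a sites x samples matrix of
diploid allele dosages (0, 1, 2, or missing) with 1-based VCF coordinates and
optional site-level (QD, FS, MQ, MQRankSum, ReadPosRankSum) and genotype-level
(GQ, DP) annotations.  Internally all interval arithmetic is 0-based
half-open; VCF positions are converted on the way in and out.

Filtering follows a fixed cascade: site-level hard filters on INFO
annotations, indel proximity, genotype-level masking (GQ and a percentile
band on depth), biallelic restriction, call rate, and minor allele
frequency — in that order, so that MAF and call rate are evaluated on
post-masking genotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid dosage.
MISSING: int = -1

#: INFO annotations consumed by the hard filters, in VCF spelling.
INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a :class:`GenotypeMatrix`."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Sites x samples allele-dosage matrix with per-site metadata.

    Attributes
    ----------
    chrom : object ndarray of contig names, one per site.
    pos : int64 ndarray of 1-based positions, strictly increasing per contig.
    ref_allele, alt_allele : object ndarrays of allele strings.
    dosage : int8 ndarray, sites x samples, values in {0, 1, 2, MISSING}.
    sample_ids : list of unique sample identifiers (column order).
    is_biallelic : bool ndarray; False flags multiallelic records retained
        at parse time and removed later by the filter cascade.
    info : optional DataFrame of float INFO annotations (NaN when absent).
    gq, dp : optional int32 ndarrays, sites x samples; negative = absent.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]
    is_biallelic: np.ndarray = None  # type: ignore[assignment]
    info: pd.DataFrame | None = None
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D sites x samples matrix")
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(self.n_sites, dtype=bool)
        self.is_biallelic = np.asarray(self.is_biallelic, dtype=bool)
        self.validate()

    # -- basic geometry ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def validate(self) -> None:
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length does not match dosage columns")
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValueError("sample_ids must be unique")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref_allele, "ref_allele"),
                          (self.alt_allele, "alt_allele"),
                          (self.is_biallelic, "is_biallelic")):
            if len(arr) != self.n_sites:
                raise ValueError(f"{name} length does not match dosage rows")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")
        if self.n_sites and np.any(
            (self.ref_allele == self.alt_allele) & self.is_biallelic
        ):
            raise ValueError("ref_allele must differ from alt_allele")
        # positions strictly increasing within each contig (file order kept)
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- subsetting --------------------------------------------------------

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return GenotypeMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            dosage=self.dosage[idx],
            sample_ids=list(self.sample_ids),
            is_biallelic=self.is_biallelic[idx],
            info=self.info.loc[idx].reset_index(drop=True)
            if self.info is not None else None,
            gq=self.gq[idx] if self.gq is not None else None,
            dp=self.dp[idx] if self.dp is not None else None,
        )

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc} not present in matrix") from exc

    def contig_lengths(self) -> dict[str, int]:
        """Upper-bound contig lengths implied by the last site per contig."""
        out: dict[str, int] = {}
        for c in pd.unique(self.chrom):
            out[str(c)] = int(self.pos[self.chrom == c].max())
        return out

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and np.array_equal(self.alt_allele, other.alt_allele)
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class PopulationMap:
    """Sample -> species assignment with an explicit exclusion list.

    Downstream scans expect exactly three species, but the map itself admits
    any number.  Excluded samples (e.g. admixed individuals) are dropped from
    every analysis view without being removed from the underlying matrix.
    """

    mapping: dict[str, str]
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(not lbl for lbl in self.mapping.values()):
            raise ValueError("species labels must be non-empty")

    @property
    def species(self) -> list[str]:
        """Species labels in first-appearance order, excluding dropped samples."""
        seen: list[str] = []
        excl = set(self.excluded_samples)
        for s, lbl in self.mapping.items():
            if s not in excl and lbl not in seen:
                seen.append(lbl)
        return seen

    def samples_of(self, species: str) -> list[str]:
        excl = set(self.excluded_samples)
        return [s for s, lbl in self.mapping.items()
                if lbl == species and s not in excl]

    def indices_of(self, species: str, gm: GenotypeMatrix) -> np.ndarray:
        present = [s for s in self.samples_of(species) if s in gm.sample_ids]
        return gm.sample_indices(present)

    def check_against(self, gm: GenotypeMatrix) -> None:
        """Warn on popmap samples missing from the matrix; error on unmapped."""
        matrix = set(gm.sample_ids)
        mapped = set(self.mapping) | set(self.excluded_samples)
        missing = sorted(set(self.mapping) - matrix)
        if missing:
            warnings.warn(
                f"{len(missing)} popmap samples absent from the VCF: "
                f"{missing[:5]}...", stacklevel=2)
        unmapped = sorted(matrix - mapped)
        if unmapped:
            raise ValueError(f"samples without species label: {unmapped[:5]}")


@dataclass
class FilterParams:
    """Thresholds for the SNP filtering cascade.

    Defaults follow standard GATK-style hard filtering plus genotype- and
    sample-level criteria: QD >= 2, FS <= 60, MQ >= 40, MQRankSum >= -12.5,
    ReadPosRankSum >= -8, sites >= 5 bp from an indel, GQ >= 30, per-genotype
    depth inside the genome-wide 2.5-97.5 percentile band, biallelic only,
    call rate >= 80% and MAF >= 5%.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    indel_distance_min: int = 5
    gq_min: int = 30
    depth_lo_pct: float = 2.5
    depth_hi_pct: float = 97.5
    maf_min: float = 0.05
    call_rate_min: float = 0.8
    biallelic_only: bool = True
    #: "pooled" evaluates MAF/call-rate across all analysed samples;
    #: "per-species" requires each species to pass separately.
    freq_scope: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValueError("call_rate_min must be in [0, 1]")
        if self.depth_lo_pct >= self.depth_hi_pct:
            raise ValueError("depth_lo_pct must be below depth_hi_pct")
        if self.freq_scope not in ("pooled", "per-species"):
            raise ValueError("freq_scope must be 'pooled' or 'per-species'")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    n_input: int = 0
    removed_hard_filter: int = 0
    removed_indel_proximity: int = 0
    masked_genotypes_gq: int = 0
    masked_genotypes_dp: int = 0
    removed_not_biallelic: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    n_output: int = 0
    depth_band: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, np.iinfo(np.int64).max
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi)


def load_vcf(path: str, region: str | None = None) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields map to dosages (0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing).  Multiallelic records are retained but flagged
    ``is_biallelic=False``; INFO hard-filter annotations and FORMAT GQ/DP
    are captured when present.  ``region`` restricts to "chrom" or
    "chrom:start-end" (1-based inclusive).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF has no sample columns (GT required)")

    want = _parse_region(region) if region else None
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    bi: list[bool] = []
    dosages: list[np.ndarray] = []
    info_rows: list[list[float]] = []
    gq_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    any_info = False
    any_gq = False
    any_dp = False

    try:
        for v in vcf:
            if want is not None and not (
                v.CHROM == want[0] and want[1] <= v.POS <= want[2]
            ):
                continue
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0] if v.ALT else ".")
            bi.append(len(v.ALT) == 1)
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt = np.asarray(v.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            dosages.append(gt)
            row = []
            for key in INFO_FIELDS:
                val = v.INFO.get(key)
                row.append(float(val) if val is not None else np.nan)
                any_info = any_info or val is not None
            info_rows.append(row)
            fmt_keys = v.FORMAT or []
            fgq = v.format("GQ") if "GQ" in fmt_keys else None
            fdp = v.format("DP") if "DP" in fmt_keys else None
            if fgq is not None:
                any_gq = True
                gq_rows.append(np.asarray(fgq, dtype=np.int32).reshape(-1))
            else:
                gq_rows.append(np.full(len(samples), -1, dtype=np.int32))
            if fdp is not None:
                any_dp = True
                dp_rows.append(np.asarray(fdp, dtype=np.int32).reshape(-1))
            else:
                dp_rows.append(np.full(len(samples), -1, dtype=np.int32))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record in {path} near site {len(poss) + 1}: {exc}"
        ) from exc

    n = len(poss)
    info = (
        pd.DataFrame(info_rows, columns=list(INFO_FIELDS))
        if any_info else None
    )
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=(np.vstack(dosages) if n else
                np.empty((0, len(samples)), dtype=np.int8)),
        sample_ids=samples,
        is_biallelic=np.array(bi, dtype=bool),
        info=info,
        gq=np.vstack(gq_rows) if any_gq and n else None,
        dp=np.vstack(dp_rows) if any_dp and n else None,
    )
    logger.info("loaded %d sites x %d samples from %s", n, len(samples), path)
    return gm


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------


def _allele_stats(dosage: np.ndarray, cols: np.ndarray | None = None):
    """Called allele count and alt allele count per site over given columns."""
    d = dosage if cols is None else dosage[:, cols]
    called = d != MISSING
    an = 2 * called.sum(axis=1)
    ac = np.where(called, d, 0).sum(axis=1)
    return an, ac


def apply_filters(
    gm: GenotypeMatrix,
    pm: PopulationMap | None = None,
    fp: FilterParams | None = None,
    indels: list[tuple[str, int]] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full SNP filtering cascade and report per-rule removals.

    Order: INFO hard filters -> indel proximity -> genotype masking (GQ,
    depth percentile band) -> biallelic -> call rate -> MAF.  Genotype
    masking precedes the site-level frequency criteria so that MAF and call
    rate reflect the retained genotypes.  A missing INFO annotation skips
    that hard filter for the site rather than failing it.  Samples listed in
    ``pm.excluded_samples`` do not contribute to call rate or MAF.

    Returns the filtered matrix (possibly empty — never raises for an empty
    result) and a :class:`FilterReport`.
    """
    fp = fp or FilterParams()
    report = FilterReport(n_input=gm.n_sites)
    keep = np.ones(gm.n_sites, dtype=bool)

    # 1. site-level INFO hard filters (NaN annotation -> criterion skipped)
    if gm.info is not None:
        inf = gm.info
        fail = np.zeros(gm.n_sites, dtype=bool)
        checks = (
            ("QD", inf.get("QD"), lambda x: x < fp.qd_min),
            ("FS", inf.get("FS"), lambda x: x > fp.fs_max),
            ("MQ", inf.get("MQ"), lambda x: x < fp.mq_min),
            ("MQRankSum", inf.get("MQRankSum"), lambda x: x < fp.mqranksum_min),
            ("ReadPosRankSum", inf.get("ReadPosRankSum"),
             lambda x: x < fp.readpos_min),
        )
        for name, col, bad in checks:
            if col is None:
                continue
            vals = col.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                hit = bad(vals) & ~np.isnan(vals)
            n_skip = int(np.isnan(vals).sum())
            if n_skip:
                logger.debug("%s missing at %d sites; filter skipped there",
                             name, n_skip)
            fail |= hit
        report.removed_hard_filter = int((keep & fail).sum())
        keep &= ~fail

    # 2. indel proximity
    if indels:
        near = np.zeros(gm.n_sites, dtype=bool)
        by_chrom: dict[str, list[int]] = {}
        for c, p in indels:
            by_chrom.setdefault(str(c), []).append(int(p))
        for c, plist in by_chrom.items():
            parr = np.sort(np.asarray(plist, dtype=np.int64))
            on_c = np.flatnonzero(gm.chrom == c)
            if on_c.size == 0:
                continue
            site_pos = gm.pos[on_c]
            j = np.searchsorted(parr, site_pos)
            dist = np.full(on_c.size, np.iinfo(np.int64).max)
            has_right = j < parr.size
            dist[has_right] = np.abs(parr[j[has_right]] - site_pos[has_right])
            has_left = j > 0
            dist[has_left] = np.minimum(
                dist[has_left],
                np.abs(site_pos[has_left] - parr[j[has_left] - 1]))
            near[on_c[dist < fp.indel_distance_min]] = True
        report.removed_indel_proximity = int((keep & near).sum())
        keep &= ~near

    # 3. genotype-level masking: GQ then depth percentile band.  Masked
    # genotypes keep their DP so the band does not drift on re-application.
    dosage = gm.dosage.copy()
    if gm.gq is not None:
        mask = (gm.gq >= 0) & (gm.gq < fp.gq_min) & (dosage != MISSING)
        report.masked_genotypes_gq = int(mask.sum())
        dosage[mask] = MISSING
    if gm.dp is not None:
        valid_dp = gm.dp[gm.dp >= 0]
        if valid_dp.size:
            lo, hi = np.percentile(
                valid_dp.astype(float),
                [fp.depth_lo_pct, fp.depth_hi_pct],
                method="linear")
            report.depth_band = (float(lo), float(hi))
            mask = ((gm.dp >= 0) & ((gm.dp < lo) | (gm.dp > hi))
                    & (dosage != MISSING))
            report.masked_genotypes_dp = int(mask.sum())
            dosage[mask] = MISSING

    # 4. biallelic restriction
    if fp.biallelic_only:
        report.removed_not_biallelic = int((keep & ~gm.is_biallelic).sum())
        keep &= gm.is_biallelic

    # 5-6. call rate then MAF, on post-masking genotypes
    excl = set(pm.excluded_samples) if pm is not None else set()
    use_cols = np.array(
        [i for i, s in enumerate(gm.sample_ids) if s not in excl],
        dtype=np.intp)

    def _freq_fail(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        an, ac = _allele_stats(dosage, cols)
        n_ind = cols.size
        call_rate = (an / 2) / n_ind if n_ind else np.zeros(gm.n_sites)
        cr_fail = call_rate < fp.call_rate_min
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        maf = np.minimum(p, 1.0 - p)
        maf_fail = ~(maf >= fp.maf_min)  # NaN (no calls) fails
        return cr_fail, maf_fail

    if fp.freq_scope == "pooled":
        cr_fail, maf_fail = _freq_fail(use_cols)
    else:
        cr_fail = np.zeros(gm.n_sites, dtype=bool)
        maf_fail = np.zeros(gm.n_sites, dtype=bool)
        assert pm is not None, "per-species scope requires a population map"
        for sp in pm.species:
            cols = pm.indices_of(sp, gm)
            cols = cols[np.isin(cols, use_cols)]
            c, m = _freq_fail(cols)
            cr_fail |= c
            maf_fail |= m
    report.removed_call_rate = int((keep & cr_fail).sum())
    keep &= ~cr_fail
    report.removed_maf = int((keep & maf_fail).sum())
    keep &= ~maf_fail

    out = replace(gm, dosage=dosage, info=gm.info,
                  is_biallelic=gm.is_biallelic).take_sites(keep)
    report.n_output = out.n_sites
    logger.info("filter cascade: %d -> %d sites (%s)",
                report.n_input, report.n_output,
                {k: v for k, v in report.as_dict().items()
                 if isinstance(v, int) and v})
    return out, report


# ---------------------------------------------------------------------------
# Tabular / annotation I/O
# ---------------------------------------------------------------------------


def load_popmap(path: str) -> PopulationMap:
    """Read a sample -> species TSV.

    Two columns (sample, species) with optional header; an optional third
    column marks exclusions with the literal value ``excluded``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                     names=["sample", "species", "status"])
    if df["species"].isna().any():
        raise ValueError(f"{path}: popmap needs >= 2 tab-separated columns")
    first = str(df.iloc[0, 0]).lower()
    if first in ("sample", "sample_id", "id"):
        df = df.iloc[1:].reset_index(drop=True)
    mapping: dict[str, str] = {}
    excluded: list[str] = []
    for row in df.itertuples(index=False):
        sample, species = str(row.sample), str(row.species)
        mapping[sample] = species
        if isinstance(row.status, str) and \
                row.status.strip().lower() == "excluded":
            excluded.append(sample)
    return PopulationMap(mapping=mapping, excluded_samples=excluded)


def write_popmap(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        excl = set(pm.excluded_samples)
        for sample, species in pm.mapping.items():
            status = "\texcluded" if sample in excl else ""
            fh.write(f"{sample}\t{species}{status}\n")


def load_gff(path: str) -> list[GeneInterval]:
    """Read gene features from GFF3 into 0-based half-open intervals."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="error")
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = f.attributes.get("ID", [f.id])[0]
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r} in {path}")
        seen.add(gid)
        genes.append(GeneInterval(
            gene_id=gid, chrom=f.seqid,
            start=f.start - 1, end=f.end,  # 1-based closed -> 0-based half-open
            strand=f.strand if f.strand in "+-" else "+"))
    return genes


def write_gff(genes: list[GeneInterval], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.chrom, "divscape", "gene",
                str(g.start + 1), str(g.end), ".", g.strand, ".",
                f"ID={g.gene_id}",
            ]) + "\n")


def write_bed(intervals, path: str) -> None:
    """Write (chrom, start, end[, name]) records as 0-based half-open BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, GeneInterval):
                rec = (iv.chrom, iv.start, iv.end, iv.gene_id)
            else:
                rec = tuple(iv)
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path: str) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            rec = [parts[0], int(parts[1]), int(parts[2])] + parts[3:]
            out.append(tuple(rec))
    return out


def write_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
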