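"""Genotype matrices, VCF I/O, the post-calling filter cascade and LD clumping.

The central container is :class:`GenotypeMatrix`: an ordered sample list over
an ordered list of biallelic variant sites, with genotypes coded as ALT-allele
dosage (0, 1, 2) and ``-1`` for missing.  All downstream statistics
(site classification, LD, diversity) operate on this matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING: int = -1
"""Dosage code for a missing genotype."""


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic variant record (VCF coordinate convention, 1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with ALT-dosage genotype codes.

    Parameters
    ----------
    samples : list of str
        Ordered sample names.
    chrom, pos, ref, alt : arrays, one entry per site
        Site coordinates and alleles.  Sites must be sorted by
        ``(chrom, pos)`` with no duplicate ``(chrom, pos, alt)``.
    dosage : int8 array, shape (n_samples, n_sites)
        ALT-allele counts in {0, 1, 2}, ``-1`` for missing.
    ref_depth, alt_depth : optional int32 arrays, shape (n_samples, n_sites)
        Per-genotype supporting read depth for each allele; ``-1`` when unknown.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    ref_depth: np.ndarray | None = None
    alt_depth: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_sites = len(self.pos)
        if self.dosage.shape != (len(self.samples), n_sites):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {n_sites})"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        # sorted by (chrom, pos); duplicate (chrom, pos, alt) forbidden
        keys = list(zip(self.chrom, self.pos))
        if keys != sorted(keys):
            raise ValueError("sites must be sorted by (chrom, pos)")
        trip = list(zip(self.chrom, self.pos, self.alt))
        if len(set(trip)) != len(trip):
            raise ValueError("duplicate (chrom, pos, alt) site")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def sites(self) -> list[VariantSite]:
        ids = self.ids if self.ids is not None else [None] * self.n_sites
        return [
            VariantSite(c, int(p), r, a, i)
            for c, p, r, a, i in zip(self.chrom, self.pos, self.ref, self.alt, ids)
        ]

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        """Row indices for the given sample names (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        idx = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            ref_depth=None if self.ref_depth is None else self.ref_depth[:, idx],
            alt_depth=None if self.alt_depth is None else self.alt_depth[:, idx],
            ids=None if self.ids is None else self.ids[idx],
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ref, alt) allele counts over non-missing genotypes."""
        d = self.dosage
        called = d >= 0
        alt = np.where(called, d, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return total - alt, alt


@dataclass(frozen=True)
class FilterConfig:
    """Post-calling QC thresholds applied to a genotype matrix.

    Defaults follow the cascade used to derive an analysis-ready variant set
    from raw calls: genotypes whose supporting allele depth is below
    ``min_allele_depth_for_call`` become missing, then sites are dropped when
    the missing rate exceeds ``max_missing_rate``, the minor allele frequency
    falls below ``min_maf``, or more than ``max_het_count`` genotypes are
    heterozygous.
    """

    max_missing_rate: float = 0.05
    min_allele_depth_for_call: int = 5
    min_maf: float = 0.01
    max_het_count: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_rate <= 1:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.max_het_count < 0 or self.min_allele_depth_for_call < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_variation_set2`.

    A site failing several rules is attributed to the first rule in the
    order missing-rate, MAF, heterozygote-count.
    """

    n_input: int
    removed_missing: int
    removed_maf: int
    removed_het: int
    n_retained: int
    genotypes_masked: int = 0


@dataclass
class SampleTable:
    """Sample -> (population, variety) assignments read from a TSV."""

    population: dict[str, str]
    variety: dict[str, str] = field(default_factory=dict)

    @classmethod
    def read(cls, path: str | Path) -> "SampleTable":
        pop: dict[str, str] = {}
        var: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample", "population"]:
                raise ValueError(
                    f"{path}: expected header 'sample\\tpopulation[\\tvariety]', "
                    f"got {header}"
                )
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}: malformed row {parts}")
                pop[parts[0]] = parts[1]
                if len(parts) > 2 and parts[2]:
                    var[parts[0]] = parts[2]
        return cls(population=pop, variety=var)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample\tpopulation\tvariety\n")
            for s, p in self.population.items():
                fh.write(f"{s}\t{p}\t{self.variety.get(s, '-')}\n")

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.population.items() if p == population]


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records are dropped and counted; returns
    ``(matrix, n_multiallelic_dropped)``.  Phased and unphased genotypes are
    treated identically.  If the AD format field is present, per-allele depths
    are stored for later depth-based masking.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own diagnostics
        raise ValueError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt, ids = [], [], [], [], []
    dosages: list[np.ndarray] = []
    rdepth: list[np.ndarray] = []
    adepth: list[np.ndarray] = []
    n_multi = 0
    any_ad = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        ids.append(rec.ID)
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = rec.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dos.astype(np.int8))
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            any_ad = True
            ad = ad.astype(np.int32)
            ad[ad < 0] = -1
            rdepth.append(ad[:, 0])
            adepth.append(ad[:, 1])
        else:
            rdepth.append(np.full(len(samples), -1, dtype=np.int32))
            adepth.append(np.full(len(samples), -1, dtype=np.int32))
    n = len(pos)
    dosage = (
        np.stack(dosages, axis=1) if n else np.zeros((len(samples), 0), np.int8)
    )
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
        ref_depth=np.stack(rdepth, axis=1) if (n and any_ad) else None,
        alt_depth=np.stack(adepth, axis=1) if (n and any_ad) else None,
        ids=np.array(ids, dtype=object) if n else None,
    )
    return gm, n_multi


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a matrix as uncompressed VCF 4.2 (missing genotypes as ``./.``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyorigin\n")
        contigs: dict[str, int] = {}
        for c, p in zip(gm.chrom, gm.pos):
            contigs[c] = max(contigs.get(c, 0), int(p))
        if chrom_lengths:
            contigs.update(chrom_lengths)
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_ad = gm.ref_depth is not None and gm.alt_depth is not None
        if has_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        ids = gm.ids if gm.ids is not None else [None] * gm.n_sites
        fmt = "GT:AD" if has_ad else "GT"
        for j in range(gm.n_sites):
            cols = [
                str(gm.chrom[j]),
                str(int(gm.pos[j])),
                ids[j] or ".",
                str(gm.ref[j]),
                str(gm.alt[j]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(gm.n_samples):
                g = _GT_CODE[int(gm.dosage[i, j])]
                if has_ad:
                    rd = int(gm.ref_depth[i, j])
                    ad = int(gm.alt_depth[i, j])
                    g += f":{rd if rd >= 0 else '.'},{ad if ad >= 0 else '.'}"
                cols.append(g)
            fh.write("\t".join(cols) + "\n")


def mask_low_depth(gm: GenotypeMatrix, min_depth: int) -> tuple[GenotypeMatrix, int]:
    """Set genotypes missing when a carried allele has depth below ``min_depth``.

    A homozygote is masked when its single allele is under-supported; a
    heterozygote when either allele is.  Genotypes without depth information
    (depth coded ``-1``) are left untouched.  Returns the masked matrix and
    the number of genotypes newly set missing.
    """
    if gm.ref_depth is None or gm.alt_depth is None:
        return gm, 0
    d = gm.dosage
    rd, ad = gm.ref_depth, gm.alt_depth
    low_ref = (rd >= 0) & (rd < min_depth)
    low_alt = (ad >= 0) & (ad < min_depth)
    mask = ((d == 0) & low_ref) | ((d == 2) & low_alt) | (
        (d == 1) & (low_ref | low_alt)
    )
    new_d = np.where(mask, MISSING, d).astype(np.int8)
    n_masked = int(mask.sum())
    return replace(gm, dosage=new_d), n_masked


def filter_variation_set2(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the post-calling QC cascade to produce an analysis-ready matrix.

    Depth-based masking runs first (when allele depths are present); then a
    site is removed when its missing rate exceeds ``cfg.max_missing_rate``,
    its minor allele frequency (computed over non-missing allele counts)
    falls below ``cfg.min_maf``, or its heterozygote count exceeds
    ``cfg.max_het_count``.  The report attributes each removed site to the
    first violated rule in that order.
    """
    cfg = cfg or FilterConfig()
    gm, n_masked = mask_low_depth(gm, cfg.min_allele_depth_for_call)
    d = gm.dosage
    n = gm.n_samples
    miss_rate = (d == MISSING).sum(axis=0) / n
    ref_ct, alt_ct = gm.allele_counts()
    total = ref_ct + alt_ct
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt_ct / np.maximum(total, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    het = (d == 1).sum(axis=0)

    fail_miss = miss_rate > cfg.max_missing_rate
    fail_maf = ~fail_miss & (maf < cfg.min_maf)
    fail_het = ~fail_miss & ~fail_maf & (het > cfg.max_het_count)
    keep = ~(fail_miss | fail_maf | fail_het)
    report = FilterReport(
        n_input=gm.n_sites,
        removed_missing=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_het=int(fail_het.sum()),
        n_retained=int(keep.sum()),
        genotypes_masked=n_masked,
    )
    return gm.take_sites(np.nonzero(keep)[0]), report


def ld_clump(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.5,
    window_bp: int = 250_000,
) -> list[int]:
    """Greedy LD pruning in genomic order (PLINK clumping with all p = 1).

    Sweeping each chromosome in coordinate order, a site is retained iff its
    r-squared with every already-retained site within ``window_bp`` is below
    ``r2_threshold``.  Returns the retained site indices.  Pairs whose
    r-squared is undefined (monomorphic site or <4 complete observations)
    never block retention.
    """
    from .ld_decay import pair_r2

    X = gm.dosage.astype(float)
    X[gm.dosage == MISSING] = np.nan
    retained: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j in range(gm.n_sites):
        c = gm.chrom[j]
        prior = kept_by_chrom.setdefault(c, [])
        ok = True
        for k in reversed(prior):
            if gm.pos[j] - gm.pos[k] > window_bp:
                break
            r2 = pair_r2(X[:, j], X[:, k])
            if r2 is not None and r2 >= r2_threshold:
                ok = False
                break
        if ok:
            retained.append(j)
            prior.append(j)
    return retained
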