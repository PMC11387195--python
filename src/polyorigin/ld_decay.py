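"""Linkage-disequilibrium decay: pairwise r², 100-bp binning, half-maximum distance.

r² is the squared Pearson correlation of ALT-dosage vectors (composite LD).
In near-fully homozygous panels this coincides with the haplotype-based
estimator; the divergence on heterozygous data is documented in the methods
note.  The half-maximum decay distance is read off the binned mean-r² curve:
the upper edge of the first separation bin whose mean falls to half the
curve's maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .genotype_io import GenotypeMatrix

from .genotype_io import MISSING


def pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """r² between two dosage vectors over pairwise-complete samples.

    Returns ``None`` when fewer than 4 complete observations remain or either
    site has zero variance among them.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 4:
        return None
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return None
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(c * c / (vx * vy))


def pairwise_r2(
    gm: "GenotypeMatrix",
    sample_ids: Sequence[str] | None = None,
    max_dist: int = 300_000,
    min_maf: float = 0.0,
) -> Iterator[tuple[int, float]]:
    """Yield ``(separation_bp, r2)`` for within-chromosome site pairs.

    Pairs are restricted to 0 < separation <= ``max_dist``.  Sites with minor
    allele frequency below ``min_maf`` are excluded up front; pairs with <4
    pairwise-complete samples or zero variance at either site are skipped.
    """
    rows = (
        slice(None) if sample_ids is None else gm.sample_indices(sample_ids)
    )
    X = gm.dosage[rows].astype(float)
    X[X == MISSING] = np.nan
    n = X.shape[0]
    if n < 2:
        raise ValueError("pairwise_r2 needs at least 2 samples")

    if min_maf > 0:
        called = ~np.isnan(X)
        alt = np.nansum(X, axis=0)
        tot = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
        keep = np.minimum(af, 1 - af) >= min_maf
    else:
        keep = np.ones(X.shape[1], dtype=bool)

    for chrom in dict.fromkeys(gm.chrom):  # preserves order
        cols = np.nonzero((gm.chrom == chrom) & keep)[0]
        if cols.size < 2:
            continue
        pos = gm.pos[cols]
        sub = X[:, cols]
        valid = ~np.isnan(sub)
        filled = np.nan_to_num(sub)
        for a in range(cols.size - 1):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            js = np.arange(a + 1, hi)
            sep = pos[js] - pos[a]
            nz = sep > 0
            js, sep = js[nz], sep[nz]
            if js.size == 0:
                continue
            # pairwise-complete moments, vectorised over the window
            m = valid[:, [a]] & valid[:, js]
            cnt = m.sum(axis=0)
            xa = filled[:, [a]] * m
            yb = filled[:, js] * m
            sx = xa.sum(axis=0)
            sy = yb.sum(axis=0)
            sxx = (xa * xa).sum(axis=0)
            syy = (yb * yb).sum(axis=0)
            sxy = (xa * yb).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                covn = sxy - sx * sy / np.maximum(cnt, 1)
                vxn = sxx - sx * sx / np.maximum(cnt, 1)
                vyn = syy - sy * sy / np.maximum(cnt, 1)
                r2 = covn * covn / (vxn * vyn)
            good = (cnt >= 4) & (vxn > 0) & (vyn > 0)
            for s, v in zip(sep[good], r2[good]):
                yield int(s), float(v)


@dataclass
class LDBinCurve:
    """Mean r² by physical-separation bin.

    Bin ``b`` covers separations in ``(b*bin_bp, (b+1)*bin_bp]`` — i.e.
    1–100 bp, 101–200 bp, ... for the default 100-bp width.  Empty bins have
    ``n_pairs == 0`` and NaN mean.
    """

    bin_bp: int
    max_dist: int
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.mean_r2)

    def bin_edges(self, b: int) -> tuple[int, int]:
        """(lower, upper] physical bounds of bin ``b`` in bp."""
        return b * self.bin_bp, (b + 1) * self.bin_bp

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# bins are (bin_low, bin_high] in bp\n")
            fh.write("bin_low\tbin_high\tmean_r2\tn_pairs\n")
            for b in range(self.n_bins):
                lo, hi = self.bin_edges(b)
                m = self.mean_r2[b]
                fh.write(
                    f"{lo}\t{hi}\t{'' if np.isnan(m) else f'{m:.6g}'}\t"
                    f"{int(self.n_pairs[b])}\n"
                )


NOT_REACHED = None
"""Sentinel half-max distance for curves that never fall to half maximum."""


@dataclass
class HalfMaxResult:
    """Half-maximum LD decay distance read from a binned curve.

    ``half_max_bp`` is the upper edge of the first non-empty bin whose mean
    r² is at most half the curve maximum, or ``None`` (NOT_REACHED).  For
    sample-size-standardized estimates, ``replicate_distances`` holds the
    per-subsample values and ``half_max_bp`` their inverse-empirical-CDF
    median (R quantile type 1, p = 0.5).
    """

    half_max_bp: int | None
    max_mean_r2: float
    replicate_distances: list[int] = field(default_factory=list)
    n_not_reached: int = 0
    median_rule: str = "single"

    @property
    def reached(self) -> bool:
        return self.half_max_bp is not None


def bin_curve(
    pairs: Iterable[tuple[int, float]],
    bin_bp: int = 100,
    max_dist: int = 300_000,
) -> LDBinCurve:
    """Average r² within contiguous separation bins of width ``bin_bp``."""
    n_bins = -(-max_dist // bin_bp)
    seps: list[int] = []
    vals: list[float] = []
    for s, v in pairs:
        seps.append(s)
        vals.append(v)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    if seps:
        sep_arr = np.asarray(seps, dtype=np.int64)
        val_arr = np.asarray(vals)
        inside = (sep_arr >= 1) & (sep_arr <= max_dist)
        idx = (sep_arr[inside] - 1) // bin_bp
        sums = np.bincount(idx, weights=val_arr[inside], minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDBinCurve(bin_bp=bin_bp, max_dist=max_dist, mean_r2=means, n_pairs=counts)


def half_max_distance(curve: LDBinCurve) -> HalfMaxResult:
    """Distance at which binned mean r² first falls to half its maximum.

    The reference level is the maximum binned mean; the reported distance is
    the upper edge of the first (smallest-separation) non-empty bin whose
    mean is <= max/2.
    """
    filled = curve.n_pairs > 0
    if not filled.any():
        raise ValueError("curve has no non-empty bins")
    m = float(np.nanmax(curve.mean_r2[filled]))
    hit = filled & (curve.mean_r2 <= m / 2)
    if not hit.any():
        return HalfMaxResult(half_max_bp=NOT_REACHED, max_mean_r2=m)
    b = int(np.nonzero(hit)[0][0])
    return HalfMaxResult(half_max_bp=curve.bin_edges(b)[1], max_mean_r2=m)


def quantile_type1(values: Sequence[float], p: float = 0.5) -> float:
    """Inverse-empirical-CDF quantile: smallest order statistic x_(k), k >= n*p."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    v = sorted(values)
    if not v:
        raise ValueError("empty value list")
    k = int(np.ceil(p * len(v)))
    return v[k - 1]


def standardized_half_max(
    gm: "GenotypeMatrix",
    sample_ids: Sequence[str],
    n_target: int,
    replicates: int = 100,
    seed: int | None = None,
    bin_bp: int = 100,
    max_dist: int = 300_000,
    min_maf: float = 0.0,
) -> HalfMaxResult:
    """Sample-size-standardized half-max distance by repeated subsampling.

    Each replicate draws ``n_target`` samples without replacement, bins the
    pairwise r² curve and takes its half-max distance; the summary is the
    type-1 (inverse empirical CDF) median over replicates.  Replicates whose
    curve never reaches half maximum are excluded with a warning.
    """
    ids = list(sample_ids)
    if n_target > len(ids):
        raise ValueError(f"n_target {n_target} > available samples {len(ids)}")
    rng = np.random.default_rng(seed)
    dists: list[int] = []
    n_nr = 0
    max_means: list[float] = []
    for _ in range(replicates):
        pick = rng.choice(len(ids), size=n_target, replace=False)
        chosen = [ids[i] for i in sorted(pick)]
        curve = bin_curve(
            pairwise_r2(gm, chosen, max_dist=max_dist, min_maf=min_maf),
            bin_bp=bin_bp,
            max_dist=max_dist,
        )
        res = half_max_distance(curve)
        max_means.append(res.max_mean_r2)
        if res.reached:
            dists.append(res.half_max_bp)
        else:
            n_nr += 1
    if n_nr:
        warnings.warn(
            f"{n_nr}/{replicates} replicates never decayed to half maximum; "
            "excluded from the median",
            stacklevel=2,
        )
    if not dists:
        return HalfMaxResult(
            half_max_bp=NOT_REACHED,
            max_mean_r2=float(np.mean(max_means)),
            n_not_reached=n_nr,
            median_rule="type1-median",
        )
    med = int(quantile_type1(dists, 0.5))
    return HalfMaxResult(
        half_max_bp=med,
        max_mean_r2=float(np.mean(max_means)),
        replicate_distances=dists,
        n_not_reached=n_nr,
        median_rule="type1-median",
    )
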