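"""Windowed nucleotide diversity (pi) per sample group.

Per variant site with non-missing ref/alt allele counts (c_r, c_a) and
n = c_r + c_a >= 2, the unbiased per-site heterozygosity is
2 c_r c_a / (n (n - 1)).  Window pi sums the per-site values over sites
contained in the window and divides by the full window length in bp, so
monomorphic and uncalled positions count as invariant — the convention of
the standard windowed-pi tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class WindowStat:
    """Nucleotide diversity in one window (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    pi: float
    n_sites: int


def site_pi(ref_count: np.ndarray, alt_count: np.ndarray) -> np.ndarray:
    """Unbiased per-site pi from allele counts; 0 where n < 2."""
    n = ref_count + alt_count
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * ref_count * alt_count / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def windowed_pi(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    window_bp: int = 200_000,
    step_bp: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Sliding-window pi for a sample group (default 200 kb window, 100 kb step).

    Windows start at 1-based positions 1, 1+step, 1+2*step, ... while the
    start lies within the chromosome; the final windows may extend past the
    end but the denominator stays the full ``window_bp``.  Overlapping
    windows each count their contained sites.
    """
    if sample_ids is not None:
        rows = gm.sample_indices(sample_ids)
        if len(rows) < 2:
            raise ValueError("windowed_pi needs at least 2 samples")
        d = gm.dosage[rows]
    else:
        if gm.n_samples < 2:
            raise ValueError("windowed_pi needs at least 2 samples")
        d = gm.dosage
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    spi = site_pi(total - alt, alt)

    out: list[WindowStat] = []
    chroms = dict.fromkeys(gm.chrom)
    for chrom in chroms:
        on = gm.chrom == chrom
        pos = gm.pos[on]
        vals = spi[on]
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(pos.max()) if pos.size else window_bp
        )
        start0 = 0
        while start0 < length:
            end0 = start0 + window_bp  # half-open [start0, end0) in 0-based
            inside = (pos > start0) & (pos <= end0)
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=start0 + 1,
                    end=end0,
                    pi=float(vals[inside].sum()) / window_bp,
                    n_sites=int(inside.sum()),
                )
            )
            start0 += step_bp
    return out
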