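"""Classification of sites as between-group fixed differences vs shared polymorphisms.

The central contrast: sampling two small groups of individuals from two
populations, a site is a *between-group polymorphism* (P_B) when each group
is fixed for a different allele (per-site Hudson FST = 1), and a *shared
polymorphism* (P_A) when both alleles segregate within each group.  Descent
of two lineages from distinct founders produces an excess of P_B over P_A;
descent from a single polymorphic founder produces the reverse.  The contrast
is assessed by bootstrap resampling of groups, tallied separately for the two
subgenomes of an allotetraploid (chromosomes 1-10 = subgenome A,
11-20 = subgenome B), and mapped in genomic windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


class SiteClass(IntEnum):
    """Per-site outcome of the two-group comparison."""

    P_B = 0  # both groups fixed, for different alleles
    P_A = 1  # both groups segregating
    NEITHER = 2  # monomorphic overall, or one fixed / one segregating
    UNCLASSIFIABLE = 3  # too few called genotypes in a group


@dataclass(frozen=True)
class BootstrapSpec:
    """Group-resampling design for the P_A/P_B contrast.

    Two disjoint groups of ``group_size`` individuals are drawn per replicate,
    either one from each population (BETWEEN) or both from the same population
    (WITHIN_1 / WITHIN_2).  Sites where either group has fewer than
    ``min_called_per_group`` non-missing genotypes are UNCLASSIFIABLE.
    """

    group_size: int = 5
    replicates: int = 100
    pairing: str = "BETWEEN"  # BETWEEN | WITHIN_1 | WITHIN_2
    min_called_per_group: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.pairing not in ("BETWEEN", "WITHIN_1", "WITHIN_2"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.min_called_per_group > self.group_size:
            raise ValueError("min_called_per_group must be <= group_size")


@dataclass
class PolymorphismSummary:
    """P_A/P_B tallies for one bootstrap replicate, split by subgenome."""

    replicate: int
    group1: list[str]
    group2: list[str]
    pa_total: int
    pb_total: int
    pa_A: int
    pa_B: int
    pb_A: int
    pb_B: int


@dataclass
class WindowDensity:
    """P_A/P_B counts in one genomic window (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    pa: int
    pb: int


def subgenome_of(chrom: str) -> str:
    """Map a chromosome name to subgenome 'A' (1-10) or 'B' (11-20).

    The chromosome index is the last run of digits in the name, so
    'chr03', 'Arahy.03' and '3' all map to subgenome A.
    """
    m = re.search(r"(\d+)(?!.*\d)", chrom)
    if not m:
        raise ValueError(f"cannot parse chromosome index from {chrom!r}")
    idx = int(m.group(1))
    if 1 <= idx <= 10:
        return "A"
    if 11 <= idx <= 20:
        return "B"
    raise ValueError(f"chromosome index {idx} outside 1-20 in {chrom!r}")


def _group_state(
    d: np.ndarray, min_called: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (enough_calls, fixed_ref, fixed_alt, segregating) for one group.

    ``d`` is the (group_size, n_sites) dosage slice.  A group is *fixed* when
    all non-missing calls are the same homozygote, and *segregating* when both
    alleles are observed (a single heterozygote suffices).
    """
    called = d != MISSING
    n_called = called.sum(axis=0)
    has0 = ((d == 0) & called).any(axis=0)
    has1 = (d == 1).any(axis=0)
    has2 = (d == 2).any(axis=0)
    ref_present = has0 | has1
    alt_present = has2 | has1
    fixed_ref = has0 & ~alt_present
    fixed_alt = has2 & ~ref_present
    segregating = ref_present & alt_present
    return n_called >= min_called, fixed_ref, fixed_alt, segregating


def classify_sites(
    gm: GenotypeMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    min_called_per_group: int = 4,
) -> np.ndarray:
    """Classify every site for a pair of disjoint groups.

    Returns an int8 array of :class:`SiteClass` values, one per site:
    P_B iff both groups are fixed for different alleles; P_A iff both groups
    are segregating; UNCLASSIFIABLE iff either group has fewer than
    ``min_called_per_group`` non-missing calls; NEITHER otherwise.
    """
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    i1 = gm.sample_indices(group1)
    i2 = gm.sample_indices(group2)
    ok1, fr1, fa1, seg1 = _group_state(gm.dosage[i1], min_called_per_group)
    ok2, fr2, fa2, seg2 = _group_state(gm.dosage[i2], min_called_per_group)
    pb = (fr1 & fa2) | (fa1 & fr2)
    pa = seg1 & seg2
    out = np.full(gm.n_sites, SiteClass.NEITHER, dtype=np.int8)
    out[pa] = SiteClass.P_A
    out[pb] = SiteClass.P_B
    out[~(ok1 & ok2)] = SiteClass.UNCLASSIFIABLE
    return out


def per_site_fst(
    gm: GenotypeMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
) -> np.ndarray:
    """Hudson's two-population FST per site; NaN where undefined.

    F = 1 - Hw/Hb with within heterozygosity Hw = (h_1 + h_2)/2,
    h_i = 2 p_i (1 - p_i), and between heterozygosity
    Hb = p_1 (1 - p_2) + p_2 (1 - p_1), all from allele frequencies over
    non-missing calls.  Attains exactly 1 at a fixed difference and exactly 0
    at equal frequencies.  Undefined (NaN) when Hb = 0 or either group has
    fewer than 2 allele observations.
    """
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")

    def freqs(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = gm.dosage[idx]
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return p, n.astype(float)

    p1, n1 = freqs(gm.sample_indices(group1))
    p2, n2 = freqs(gm.sample_indices(group2))
    with np.errstate(invalid="ignore", divide="ignore"):
        hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        fst = 1 - hw / hb
    fst[(n1 < 2) | (n2 < 2) | (hb == 0)] = np.nan
    return fst


def _split_counts(
    classes: np.ndarray, sub: np.ndarray
) -> tuple[int, int, int, int, int, int]:
    pa = classes == SiteClass.P_A
    pb = classes == SiteClass.P_B
    in_a = sub == "A"
    return (
        int(pa.sum()),
        int(pb.sum()),
        int((pa & in_a).sum()),
        int((pa & ~in_a).sum()),
        int((pb & in_a).sum()),
        int((pb & ~in_a).sum()),
    )


def bootstrap_pa_pb(
    gm: GenotypeMatrix,
    pop1: Sequence[str],
    pop2: Sequence[str],
    spec: BootstrapSpec | None = None,
) -> list[PolymorphismSummary]:
    """Bootstrap the P_A/P_B contrast by resampling small groups.

    Each replicate draws two disjoint groups of ``spec.group_size``
    individuals uniformly without replacement — one from each population
    (BETWEEN) or both from the same one (WITHIN_1/WITHIN_2) — classifies every
    site, and tallies P_A/P_B totals and their subgenome split.  Replicates
    are independent; the draw sequence is fixed by ``spec.seed``.
    """
    spec = spec or BootstrapSpec()
    g = spec.group_size
    pop1, pop2 = list(pop1), list(pop2)
    if spec.pairing == "BETWEEN":
        if len(pop1) < g or len(pop2) < g:
            raise ValueError(f"each population needs >= {g} members")
    else:
        src = pop1 if spec.pairing == "WITHIN_1" else pop2
        if len(src) < 2 * g:
            raise ValueError(
                f"WITHIN pairing needs >= {2 * g} members, got {len(src)}"
            )
    rng = np.random.default_rng(spec.seed)
    sub = np.array([subgenome_of(c) for c in gm.chrom], dtype=object)
    out: list[PolymorphismSummary] = []
    for r in range(spec.replicates):
        if spec.pairing == "BETWEEN":
            g1 = [pop1[i] for i in rng.choice(len(pop1), g, replace=False)]
            g2 = [pop2[i] for i in rng.choice(len(pop2), g, replace=False)]
        else:
            src = pop1 if spec.pairing == "WITHIN_1" else pop2
            pick = rng.choice(len(src), 2 * g, replace=False)
            g1 = [src[i] for i in pick[:g]]
            g2 = [src[i] for i in pick[g:]]
        classes = classify_sites(gm, g1, g2, spec.min_called_per_group)
        pa, pb, pa_a, pa_b, pb_a, pb_b = _split_counts(classes, sub)
        out.append(
            PolymorphismSummary(
                replicate=r,
                group1=g1,
                group2=g2,
                pa_total=pa,
                pb_total=pb,
                pa_A=pa_a,
                pa_B=pa_b,
                pb_A=pb_a,
                pb_B=pb_b,
            )
        )
    return out


def window_density(
    gm: GenotypeMatrix,
    classes: np.ndarray,
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000_000,
) -> list[WindowDensity]:
    """Count P_A and P_B sites in tiling windows along each chromosome.

    Windows tile each declared chromosome from position 1 in steps of
    ``window_bp``; the last partial window is kept.  Reported coordinates are
    1-based inclusive (position 1,000,000 falls in the first 1-Mb window,
    1,000,001 in the second).
    """
    out: list[WindowDensity] = []
    for chrom, length in chrom_lengths.items():
        on = gm.chrom == chrom
        pos = gm.pos[on]
        if pos.size and pos.max() > length:
            raise ValueError(
                f"site at {chrom}:{pos.max()} beyond declared length {length}"
            )
        cls = classes[on]
        n_win = max(1, -(-length // window_bp))
        widx = (pos - 1) // window_bp
        for w in range(n_win):
            here = widx == w
            out.append(
                WindowDensity(
                    chrom=chrom,
                    start=w * window_bp + 1,
                    end=min((w + 1) * window_bp, length),
                    pa=int((cls[here] == SiteClass.P_A).sum()),
                    pb=int((cls[here] == SiteClass.P_B).sum()),
                )
            )
    return out


@dataclass
class ScenarioReport:
    """Mean/SD of P_A and P_B (total and per subgenome) over replicates."""

    n_replicates: int
    mean: dict[str, float]
    sd: dict[str, float]
    frac_pb_gt_pa: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"statistic": k, "mean": self.mean[k], "sd": self.sd[k]}
            for k in self.mean
        ]
        return pd.DataFrame(rows)


def summarize_scenario(summaries: Sequence[PolymorphismSummary]) -> ScenarioReport:
    """Arithmetic summary of bootstrap replicates: means, SDs and the
    fraction of replicates with P_B > P_A (population SD, ddof=0)."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    cols = ("pa_total", "pb_total", "pa_A", "pa_B", "pb_A", "pb_B")
    arr = {c: np.array([getattr(s, c) for s in summaries], float) for c in cols}
    return ScenarioReport(
        n_replicates=len(summaries),
        mean={c: float(arr[c].mean()) for c in cols},
        sd={c: float(arr[c].std(ddof=0)) for c in cols},
        frac_pb_gt_pa=float(np.mean(arr["pb_total"] > arr["pa_total"])),
    )


def summaries_to_frame(summaries: Sequence[PolymorphismSummary]) -> pd.DataFrame:
    """Per-replicate tally table (one row per bootstrap replicate)."""
    return pd.DataFrame(
        {
            "replicate": [s.replicate for s in summaries],
            "P_A_total": [s.pa_total for s in summaries],
            "P_B_total": [s.pb_total for s in summaries],
            "P_A_subA": [s.pa_A for s in summaries],
            "P_A_subB": [s.pa_B for s in summaries],
            "P_B_subA": [s.pb_A for s in summaries],
            "P_B_subB": [s.pb_B for s in summaries],
            "group1": [",".join(s.group1) for s in summaries],
            "group2": [",".join(s.group2) for s in summaries],
        }
    )
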