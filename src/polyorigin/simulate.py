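"""Synthetic data generators with known ground truth.

Three generators cover the inputs the analysis assumes:

* :func:`simulate_tetraploid_panel` — genotype matrices for two highly inbred
  tetraploid lineages over 20 chromosomes (subgenomes A and B), in which each
  site is a fixed difference between lineages, a polymorphism shared by both,
  private to one, or monomorphic.  Two scenarios differ only in the rate of
  fixed differences: lineages founded by *distinct* tetraploid ancestors
  carry many, lineages splitting from a *common* polymorphic founder almost
  none.
* :func:`simulate_chloroplast_set` — chloroplast-like sequences (AT-rich,
  with seeded mononucleotide-repeat tracts) evolved along a known tree by
  substitutions and short indels, with a full event log.
* :func:`simulate_wf_population` — a forward-in-time Wright-Fisher population
  with partial selfing and recombination, producing the distance-dependent
  linkage disequilibrium the LD module measures.

Every generator takes a mandatory seed and is deterministic given its config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, SampleTable, write_vcf


def default_chrom_layout(
    n_chrom: int = 20, length_bp: int = 10_000_000
) -> list[tuple[str, int]]:
    """20 chromosomes chr01..chr20 (1-10 = subgenome A, 11-20 = B)."""
    return [(f"chr{i:02d}", length_bp) for i in range(1, n_chrom + 1)]


class SiteCategory(IntEnum):
    """Ground-truth category of a simulated panel site."""

    FIXED_DIFF = 0
    SHARED_POLY = 1
    PRIVATE_1 = 2
    PRIVATE_2 = 3
    MONOMORPHIC = 4


@dataclass
class TruthLabels:
    """Per-site ground-truth categories for a simulated panel."""

    categories: np.ndarray  # int8 of SiteCategory

    def counts(self) -> dict[str, int]:
        return {
            cat.name: int((self.categories == cat).sum()) for cat in SiteCategory
        }


@dataclass
class PanelScenarioConfig:
    """Generative settings for a two-lineage inbred tetraploid panel.

    ``scenario`` is "DISTINCT" (lineages from different founders: theta_B
    large) or "COMMON" (lineages from one polymorphic founder: theta_B is a
    small drift-fixation probability).  ``theta_B``/``theta_A`` are the
    per-site probabilities of a fixed difference / shared polymorphism;
    the remainder is split evenly between lineage-private polymorphisms.
    Segregating-site ALT frequencies are drawn from Beta(beta_a, beta_b);
    the default (0.5, 5) emulates the rare-variant-skewed site frequency
    spectrum of resequencing panels, where the ALT (derived) allele is
    usually at low frequency.  Residual heterozygosity and missingness are
    injected per genotype.
    """

    scenario: str = "DISTINCT"
    n_sites: int = 5000
    chrom_layout: list[tuple[str, int]] = field(default_factory=default_chrom_layout)
    n1: int = 30
    n2: int = 30
    theta_B: float = 0.2
    theta_A: float = 0.02
    beta_a: float = 0.5
    beta_b: float = 5.0
    het_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("DISTINCT", "COMMON"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.theta_B + self.theta_A > 1:
            raise ValueError("theta_B + theta_A must be <= 1")
        for name in ("theta_B", "theta_A", "het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("lineage sizes must be >= 1")


def common_scenario_config(**overrides) -> PanelScenarioConfig:
    """COMMON-founder defaults: shared polymorphism dominates, fixed
    differences arise only through rare post-split drift fixation."""
    kw = dict(scenario="COMMON", theta_B=0.001, theta_A=0.2)
    kw.update(overrides)
    return PanelScenarioConfig(**kw)


def _draw_positions(
    rng: np.random.Generator,
    layout: Sequence[tuple[str, int]],
    n_sites: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform site placement across the genome: chromosome weighted by
    length, positions unique within chromosome, sorted."""
    layout = sorted(layout)  # GenotypeMatrix requires lexicographic chrom order
    lengths = np.array([ln for _, ln in layout], dtype=float)
    which = rng.choice(len(layout), size=n_sites, p=lengths / lengths.sum())
    chroms: list[str] = []
    poss: list[int] = []
    for ci, (name, ln) in enumerate(layout):
        k = int((which == ci).sum())
        if k == 0:
            continue
        pos = rng.choice(ln, size=min(k, ln), replace=False) + 1
        pos.sort()
        chroms.extend([name] * len(pos))
        poss.extend(int(p) for p in pos)
    return np.array(chroms, dtype=object), np.array(poss, dtype=np.int64)


def _segregating_dosage(
    rng: np.random.Generator, n: int, beta_a: float, beta_b: float,
    max_tries: int = 1000,
) -> np.ndarray:
    """Inbred-baseline genotypes segregating in the sample: ALT-homozygote
    with Beta-drawn probability p, rejected until both alleles realized."""
    for _ in range(max_tries):
        p = rng.beta(beta_a, beta_b)
        d = np.where(rng.random(n) < p, 2, 0).astype(np.int8)
        if 0 < d.sum() < 2 * n:
            return d
    raise RuntimeError("failed to realize a segregating site")


def simulate_tetraploid_panel(
    cfg: PanelScenarioConfig,
) -> tuple[GenotypeMatrix, TruthLabels]:
    """Simulate the two-lineage inbred panel with per-site truth labels.

    Sites are assigned independent categories (FIXED_DIFF w.p. ``theta_B``,
    SHARED_POLY w.p. ``theta_A``, remainder split between PRIVATE_1/2); a
    private site whose frequency draw happens to fix in the sample is
    relabelled MONOMORPHIC.  Baseline genotypes are fully homozygous
    (ALT-homozygote w.p. p at a segregating site); residual heterozygosity
    then flips genotypes to 1 w.p. ``het_rate`` and missingness masks them
    w.p. ``missing_rate``.  FIXED_DIFF sites are REF-fixed in lineage 1 and
    ALT-fixed in lineage 2 before noise.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _draw_positions(rng, cfg.chrom_layout, cfg.n_sites)
    n_sites = len(pos)
    n1, n2 = cfg.n1, cfg.n2
    n = n1 + n2
    samples = [f"L1_{i:03d}" for i in range(n1)] + [
        f"L2_{i:03d}" for i in range(n2)
    ]

    u = rng.random(n_sites)
    cats = np.empty(n_sites, dtype=np.int8)
    dosage = np.zeros((n, n_sites), dtype=np.int8)
    for j in range(n_sites):
        if u[j] < cfg.theta_B:
            cats[j] = SiteCategory.FIXED_DIFF
            dosage[:n1, j] = 0
            dosage[n1:, j] = 2
        elif u[j] < cfg.theta_B + cfg.theta_A:
            cats[j] = SiteCategory.SHARED_POLY
            dosage[:n1, j] = _segregating_dosage(rng, n1, cfg.beta_a, cfg.beta_b)
            dosage[n1:, j] = _segregating_dosage(rng, n2, cfg.beta_a, cfg.beta_b)
        else:
            lineage = 1 if rng.random() < 0.5 else 2
            nl = n1 if lineage == 1 else n2
            # an all-ALT private draw would be a de-facto fixed difference;
            # redraw so residual monomorphic sites are REF-fixed overall
            for _ in range(1000):
                p = rng.beta(cfg.beta_a, cfg.beta_b)
                d = np.where(rng.random(nl) < p, 2, 0).astype(np.int8)
                if d.sum() < 2 * nl:
                    break
            if lineage == 1:
                dosage[:n1, j] = d
            else:
                dosage[n1:, j] = d
            seg = d.sum() > 0
            if seg:
                cats[j] = (
                    SiteCategory.PRIVATE_1 if lineage == 1 else SiteCategory.PRIVATE_2
                )
            else:
                cats[j] = SiteCategory.MONOMORPHIC

    if cfg.het_rate > 0:
        flip = rng.random(dosage.shape) < cfg.het_rate
        dosage[flip] = 1
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    gm = GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosage=dosage,
    )
    return gm, TruthLabels(categories=cats)


def panel_sample_table(cfg: PanelScenarioConfig) -> SampleTable:
    """Population assignments matching :func:`simulate_tetraploid_panel`."""
    pop = {f"L1_{i:03d}": "lineage1" for i in range(cfg.n1)}
    pop.update({f"L2_{i:03d}": "lineage2" for i in range(cfg.n2)})
    return SampleTable(population=pop)


# ---------------------------------------------------------------------------
# chloroplast-like sequence evolution


@dataclass
class ChloroSimConfig:
    """Settings for evolving chloroplast-like sequences along a known tree.

    ``tree_newick`` is a rooted Newick string with branch lengths in expected
    substitutions per site.  The root sequence is drawn at ``gc_content``
    (chloroplasts are AT-rich, hence the low default) and seeded with
    ``mnr_seed_count`` mononucleotide tracts whose lengths are drawn from
    ``mnr_length_weights`` over 3-20.  Indels occur at ``indel_rate`` times
    the substitution count, with lengths uniform in ``indel_length_range``.
    """

    genome_length: int = 150_000
    tree_newick: str = "((s1:0.01,s2:0.01):0.02,(s3:0.01,s4:0.01):0.02):0;"
    gc_content: float = 0.36
    indel_rate: float = 0.1
    indel_length_range: tuple[int, int] = (1, 6)
    mnr_seed_count: int = 200
    mnr_length_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        lo, hi = self.indel_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid indel_length_range")


@dataclass
class SimEvent:
    """One recorded mutation event on a branch."""

    branch: str  # name of the child node the branch leads to
    kind: str  # "SUB" | "INS" | "DEL"
    position: int  # 0-based coordinate in the parent sequence
    detail: str


def _parse_tree(newick: str):
    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    for i, cl in enumerate(tree.find_clades()):
        if cl.name is None:
            cl.name = f"node{i}"
        if cl.branch_length is None:
            cl.branch_length = 0.0
        if cl.branch_length < 0:
            raise ValueError("branch lengths must be >= 0")
    return tree


def _seed_root(
    rng: np.random.Generator, cfg: ChloroSimConfig
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    seq = rng.choice(bases, size=cfg.genome_length, p=probs)
    weights = cfg.mnr_length_weights
    lens = np.arange(3, 21)
    if weights is None:
        w = np.ones(len(lens)) / len(lens)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    tracts: list[tuple[int, int]] = []
    occupied = np.zeros(cfg.genome_length, dtype=bool)
    for _ in range(cfg.mnr_seed_count):
        L = int(rng.choice(lens, p=w))
        for _try in range(100):
            start = int(rng.integers(0, cfg.genome_length - L))
            # pad by 1 so adjacent tracts cannot merge into longer runs
            lo, hi = max(0, start - 1), min(cfg.genome_length, start + L + 1)
            if not occupied[lo:hi].any():
                break
        else:
            continue
        base = bases[rng.integers(0, 4)]
        seq[start : start + L] = base
        # break accidental run extension at the flanks
        for edge in (start - 1, start + L):
            if 0 <= edge < cfg.genome_length and seq[edge] == base:
                others = [b for b in bases if b != base]
                seq[edge] = others[int(rng.integers(0, 3))]
        occupied[lo:hi] = True
        tracts.append((start, L))
    return seq, tracts


def _evolve_branch(
    rng: np.random.Generator,
    seq: np.ndarray,
    tracts: list[tuple[int, int]],
    branch_length: float,
    cfg: ChloroSimConfig,
    branch_name: str,
    log: list[SimEvent],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    n_sub = rng.poisson(branch_length * len(seq))
    seq = seq.copy()
    tracts = list(tracts)
    for _ in range(n_sub):
        # substitutions avoid seeded tract interiors so tract recovery
        # remains well defined; flanks and background evolve freely
        for _try in range(100):
            p = int(rng.integers(0, len(seq)))
            if not any(s <= p < s + L for s, L in tracts):
                break
        old = seq[p]
        choices = [b for b in bases if b != old]
        new = choices[int(rng.integers(0, 3))]
        seq[p] = new
        log.append(SimEvent(branch_name, "SUB", p, f"{old.decode()}>{new.decode()}"))

    n_indel = rng.poisson(cfg.indel_rate * n_sub)
    lo_len, hi_len = cfg.indel_length_range
    for _ in range(n_indel):
        L = int(rng.integers(lo_len, hi_len + 1))
        is_del = rng.random() < 0.5
        for _try in range(200):
            p = int(rng.integers(0, len(seq) - L if is_del else len(seq) + 1))
            if is_del:
                # never erase (or truncate) a seeded tract
                if not any(
                    p < s + tl and s < p + L for s, tl in tracts
                ):
                    break
            else:
                # never insert inside a seeded tract
                if not any(s < p < s + tl for s, tl in tracts):
                    break
        else:
            continue
        if is_del:
            removed = seq[p : p + L].tobytes().decode()
            seq = np.delete(seq, np.s_[p : p + L])
            tracts = [(s - L if s >= p + L else s, tl) for s, tl in tracts]
            log.append(SimEvent(branch_name, "DEL", p, removed))
        else:
            ins = rng.choice(bases, size=L)
            seq = np.insert(seq, p, ins)
            tracts = [(s + L if s >= p else s, tl) for s, tl in tracts]
            log.append(SimEvent(branch_name, "INS", p, ins.tobytes().decode()))
    return seq, tracts


def simulate_chloroplast_set(
    cfg: ChloroSimConfig,
) -> tuple[dict[str, str], str, list[SimEvent]]:
    """Evolve chloroplast-like sequences along ``cfg.tree_newick``.

    Returns ``(sequences, tree_newick, event_log)`` where ``sequences`` maps
    each leaf name to its (unaligned) sequence and the log records every
    substitution and indel by branch.  Indels never erase a seeded MNR tract
    and substitutions avoid tract interiors, so seeded tracts remain
    recoverable by the MNR scanner in every descendant.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = _parse_tree(cfg.tree_newick)
    root_seq, root_tracts = _seed_root(rng, cfg)
    log: list[SimEvent] = []
    leaves: dict[str, str] = {}

    def walk(clade, seq: np.ndarray, tracts: list[tuple[int, int]]) -> None:
        for child in clade.clades:
            cseq, ctracts = _evolve_branch(
                rng, seq, tracts, child.branch_length, cfg, child.name, log
            )
            if child.clades:
                walk(child, cseq, ctracts)
            else:
                leaves[child.name] = cseq.tobytes().decode()

    root = tree.root
    if not root.clades:  # single-leaf tree
        leaves[root.name] = root_seq.tobytes().decode()
    else:
        walk(root, root_seq, root_tracts)
    return leaves, cfg.tree_newick, log


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation


@dataclass
class WFConfig:
    """Forward Wright-Fisher settings: diploid population of ``pop_size``
    with per-offspring selfing probability ``selfing_rate``, per-bp
    recombination and infinite-sites-style mutation on a discrete grid."""

    pop_size: int = 100
    region_length: int = 100_000
    recomb_per_bp: float = 1e-7
    selfing_rate: float = 0.99
    mutation_per_bp: float = 1e-6
    generations: int = 200
    sample_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recomb_per_bp", "mutation_per_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.selfing_rate <= 1:
            raise ValueError("selfing_rate must be in [0, 1]")
        if self.sample_size > self.pop_size:
            raise ValueError("sample_size must be <= pop_size")
        if self.pop_size < 1 or self.generations < 0:
            raise ValueError("pop_size >= 1 and generations >= 0 required")


def _gamete(
    rng: np.random.Generator,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cfg: WFConfig,
) -> np.ndarray:
    """Meiosis: crossovers at Poisson-placed breakpoints, then new mutations."""
    n_cross = rng.poisson(cfg.recomb_per_bp * cfg.region_length)
    if rng.random() < 0.5:
        hap_a, hap_b = hap_b, hap_a
    if n_cross == 0:
        out = hap_a
    else:
        breaks = np.sort(rng.integers(1, cfg.region_length + 1, size=n_cross))
        pieces = []
        use_a = True
        prev = 0
        for b in list(breaks) + [cfg.region_length + 1]:
            cur = hap_a if use_a else hap_b
            lo = np.searchsorted(cur, prev)
            hi = np.searchsorted(cur, b)
            pieces.append(cur[lo:hi])
            use_a = not use_a
            prev = b
        out = np.concatenate(pieces)
    n_mut = rng.poisson(cfg.mutation_per_bp * cfg.region_length)
    if n_mut:
        muts = rng.integers(1, cfg.region_length + 1, size=n_mut)
        out = np.unique(np.concatenate([out, muts]))
    return out


def simulate_wf_population(
    cfg: WFConfig, chrom_name: str = "chr01"
) -> GenotypeMatrix:
    """Forward-simulate a partially selfing Wright-Fisher population.

    Haplotypes carry sets of derived-allele positions (1-based grid).  Each
    offspring selfs with probability ``selfing_rate``, otherwise outcrosses
    between two random parents; gametes recombine at Poisson breakpoints and
    gain Poisson-many new mutations.  Returns the diploid ALT-dosage matrix
    of ``sample_size`` individuals at sites segregating in the sample.
    """
    rng = np.random.default_rng(cfg.seed)
    empty = np.array([], dtype=np.int64)
    pop = [(empty, empty) for _ in range(cfg.pop_size)]
    for _ in range(cfg.generations):
        new_pop = []
        for _ in range(cfg.pop_size):
            if rng.random() < cfg.selfing_rate:
                p1 = p2 = pop[int(rng.integers(0, cfg.pop_size))]
            else:
                p1 = pop[int(rng.integers(0, cfg.pop_size))]
                p2 = pop[int(rng.integers(0, cfg.pop_size))]
            new_pop.append(
                (_gamete(rng, *p1, cfg), _gamete(rng, *p2, cfg))
            )
        pop = new_pop
    pick = rng.choice(cfg.pop_size, size=cfg.sample_size, replace=False)
    sampled = [pop[i] for i in sorted(pick)]
    all_pos = np.unique(
        np.concatenate([np.concatenate([a, b]) for a, b in sampled])
        if sampled
        else empty
    )
    n = len(sampled)
    dosage = np.zeros((n, len(all_pos)), dtype=np.int8)
    for i, (a, b) in enumerate(sampled):
        dosage[i, np.searchsorted(all_pos, a)] += 1
        dosage[i, np.searchsorted(all_pos, b)] += 1
    seg = (dosage.sum(axis=0) > 0) & (dosage.sum(axis=0) < 2 * n)
    all_pos = all_pos[seg]
    dosage = dosage[:, seg]
    m = len(all_pos)
    return GenotypeMatrix(
        samples=[f"WF_{i:03d}" for i in range(n)],
        chrom=np.array([chrom_name] * m, dtype=object),
        pos=all_pos,
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=dosage,
    )


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(outputs: dict, directory: str | Path) -> dict:
    """Write simulation outputs as plain-text fixtures and a JSON manifest.

    ``outputs`` may contain:

    * ``"panel"``: ``(GenotypeMatrix, TruthLabels, PanelScenarioConfig)`` —
      written as ``panel.vcf``, ``samples.tsv`` and ``truth.tsv``;
    * ``"chloro"``: ``(sequences dict, tree_newick, log, ChloroSimConfig)`` —
      written as ``chloro.fasta`` and ``chloro_tree.nwk``;
    * ``"wf"``: ``(GenotypeMatrix, WFConfig)`` — written as ``wf.vcf``.

    The manifest records configs (with seeds) and written file names; all
    genotype files round-trip losslessly through the VCF reader.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "configs": {}}
    if "panel" in outputs:
        gm, truth, cfg = outputs["panel"]
        write_vcf(gm, directory / "panel.vcf", chrom_lengths=dict(cfg.chrom_layout))
        panel_sample_table(cfg).write(directory / "samples.tsv")
        with open(directory / "truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("chrom\tpos\tcategory\n")
            for c, p, cat in zip(gm.chrom, gm.pos, truth.categories):
                fh.write(f"{c}\t{int(p)}\t{SiteCategory(cat).name}\n")
        manifest["files"]["panel"] = ["panel.vcf", "samples.tsv", "truth.tsv"]
        manifest["configs"]["panel"] = asdict(cfg)
    if "chloro" in outputs:
        seqs, tree_newick, log, cfg = outputs["chloro"]
        with open(directory / "chloro.fasta", "w", encoding="utf-8") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        (directory / "chloro_tree.nwk").write_text(tree_newick + "\n")
        manifest["files"]["chloro"] = ["chloro.fasta", "chloro_tree.nwk"]
        cfg_d = asdict(cfg)
        cfg_d["n_events"] = len(log)
        manifest["configs"]["chloro"] = cfg_d
    if "wf" in outputs:
        gm, cfg = outputs["wf"]
        write_vcf(gm, directory / "wf.vcf", {str(gm.chrom[0]) if gm.n_sites else "chr01": cfg.region_length})
        manifest["files"]["wf"] = ["wf.vcf"]
        manifest["configs"]["wf"] = asdict(cfg)
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
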