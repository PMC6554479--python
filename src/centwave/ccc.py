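"""Allele-specific SNP co-segregation with the Custom Correlation Coefficient.

For allele x at site i and allele y at site j, over the individuals with a
non-missing genotype at both sites,

    CCC(i,x; j,y) = (9/2) * R(i,x; j,y) * (1 - f_ix) * (1 - f_jy)

where R is the relative co-occurrence of the two alleles and f_ix, f_jy are
their frequencies *within that overlap*. The frequency penalty rewards
co-segregation of rare alleles; monomorphic alleles score 0. Edges are kept
at CCC >= 0.7 with a minimum pairwise overlap of 100 individuals, after
site filtering at MAF > 0.01 and call rate > 0.5 (sites at the boundary are
removed).

Two co-occurrence rules are provided for unphased diploid dosages:

- "carrier" (default): R = fraction of overlap individuals carrying at
  least one copy of both alleles. A perfectly co-segregating pair at MAF
  0.3 under Hardy-Weinberg scores 4.5 * 0.51 * 0.49 ~ 1.12, comfortably
  above the 0.7 threshold.
- "min_dosage": R = sum_k min(d_x(k), d_y(k)) / (2 n), the maximal
  within-individual pairing without phase. Note its ceiling under the
  (1 - f) penalty is 4.5 * f * (1-f)^2 <= 2/3, below threshold 0.7 for
  every frequency, so it is useful as a graded LD measure, not with the
  default threshold.

Both the frequency-penalty reading and the pairing rule are recorded in
output metadata. The all-pairs scan can be partitioned into near-equal
contiguous site blocks; within-block plus cross-block jobs cover every site
pair exactly once (20 blocks -> 210 jobs), matching how the metric is
parallelized at population scale. Here the jobs run serially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .signals import DensityProfile, WindowGrid, point_density

logger = logging.getLogger("centwave")

MISSING = -1

DEFAULT_MAF_MIN = 0.01
DEFAULT_CALLRATE_MIN = 0.5
DEFAULT_THRESHOLD = 0.7
DEFAULT_MIN_OVERLAP = 100


@dataclass(frozen=True)
class SNPSite:
    chrom: str
    pos: int  # 0-based bp
    ref: str = "A"
    alt: str = "G"


@dataclass
class SiteStats:
    call_rate: float
    maf: float
    f_ref: float
    f_alt: float
    defined: bool = True


@dataclass
class GenotypeMatrix:
    """Individuals x sites ALT-dosage table; missing calls are -1."""

    individuals: list[str]
    sites: list[SNPSite]
    dosage: np.ndarray  # int8, shape (n_individuals, n_sites)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.individuals)}, {len(self.sites)})"
            )
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def allele_dosage(self, site: int, allele: int) -> np.ndarray:
        """Per-individual dosage of allele 0 (ref) or 1 (alt); missing -> -1."""
        d = self.dosage[:, site].astype(np.int16)
        out = d if allele == 1 else 2 - d
        out[d == MISSING] = MISSING
        return out


@dataclass(frozen=True)
class CCCEdge:
    """One above-threshold allele pair; symmetric under (i,x) <-> (j,y)."""

    site_i: int
    allele_x: int
    site_j: int
    allele_y: int
    R: float
    f_ix: float
    f_jy: float
    n_overlap: int
    ccc: float


@dataclass(frozen=True)
class BlockJob:
    job_id: int
    block_a: int
    block_b: int


@dataclass
class BlockSchedule:
    """Contiguous near-equal site blocks and the job list covering every
    unordered site pair exactly once."""

    blocks: list[tuple[int, int]]  # [start, stop) site-index ranges
    jobs: list[BlockJob]

    def job_pairs(self, job: BlockJob):
        """Unordered site pairs (i < j) evaluated by one job."""
        a0, a1 = self.blocks[job.block_a]
        if job.block_a == job.block_b:
            yield from combinations(range(a0, a1), 2)
        else:
            b0, b1 = self.blocks[job.block_b]
            for i in range(a0, a1):
                for j in range(b0, b1):
                    yield (i, j) if i < j else (j, i)


def site_stats(matrix: GenotypeMatrix, site: int) -> SiteStats:
    """Call rate, allele frequencies and MAF for one site."""
    col = matrix.dosage[:, site]
    obs = col != MISSING
    n_obs = int(obs.sum())
    call_rate = n_obs / matrix.n_individuals
    if n_obs == 0:
        return SiteStats(0.0, float("nan"), float("nan"), float("nan"), defined=False)
    f_alt = float(col[obs].sum()) / (2 * n_obs)
    f_ref = 1.0 - f_alt
    return SiteStats(call_rate, min(f_ref, f_alt), f_ref, f_alt)


def filter_sites(
    matrix: GenotypeMatrix,
    maf_min: float = DEFAULT_MAF_MIN,
    callrate_min: float = DEFAULT_CALLRATE_MIN,
) -> GenotypeMatrix:
    """Remove sites with MAF <= maf_min or call rate <= callrate_min
    (strict: a site exactly at either boundary is removed)."""
    keep = []
    for s in range(matrix.n_sites):
        st = site_stats(matrix, s)
        if st.defined and st.maf > maf_min and st.call_rate > callrate_min:
            keep.append(s)
    if not keep:
        logger.warning("site filter retained no sites")
    return GenotypeMatrix(
        individuals=matrix.individuals,
        sites=[matrix.sites[s] for s in keep],
        dosage=matrix.dosage[:, keep] if keep else
        np.empty((matrix.n_individuals, 0), dtype=np.int8),
    )


def relative_cooccurrence(
    matrix: GenotypeMatrix,
    i: int, x: int, j: int, y: int,
    pairing: str = "carrier",
) -> tuple[float, int]:
    """Relative co-occurrence R of allele x at site i with allele y at site
    j, over individuals non-missing at both; returns (R, n_overlap).
    R is NaN when the overlap is empty."""
    if i == j:
        raise ValueError("co-occurrence requires two distinct sites")
    if x not in (0, 1) or y not in (0, 1):
        raise ValueError("alleles are 0 (ref) or 1 (alt)")
    di = matrix.dosage[:, i].astype(np.int16)
    dj = matrix.dosage[:, j].astype(np.int16)
    ok = (di != MISSING) & (dj != MISSING)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    dx = di[ok] if x == 1 else 2 - di[ok]
    dy = dj[ok] if y == 1 else 2 - dj[ok]
    if pairing == "carrier":
        R = float(np.count_nonzero((dx > 0) & (dy > 0))) / n
    elif pairing == "min_dosage":
        R = float(np.minimum(dx, dy).sum()) / (2 * n)
    else:
        raise ValueError(f"unknown pairing rule {pairing!r}")
    return R, n


def ccc_value(R: float, f_ix: float, f_jy: float, reading: str = "one_minus_f") -> float:
    """CCC = (9/2) * R * penalty(f_ix) * penalty(f_jy).

    ``reading`` picks the frequency penalty: "one_minus_f" (default) uses
    (1 - f); "one_minus_inv_f" uses (1 - 1/f). Frequencies must be in
    (0, 1]; a monomorphic allele (f = 1) scores 0 under the default.
    """
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R must be in [0, 1], got {R}")
    for f in (f_ix, f_jy):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"allele frequency must be in (0, 1], got {f}")
    if reading == "one_minus_f":
        pen = (1.0 - f_ix) * (1.0 - f_jy)
    elif reading == "one_minus_inv_f":
        pen = (1.0 - 1.0 / f_ix) * (1.0 - 1.0 / f_jy)
    else:
        raise ValueError(f"unknown Eq-penalty reading {reading!r}")
    return 4.5 * R * pen


def _overlap_freqs(matrix: GenotypeMatrix, i: int, j: int) -> tuple[np.ndarray, int]:
    """ALT frequencies at sites i and j over their overlap individuals."""
    di = matrix.dosage[:, i].astype(np.int16)
    dj = matrix.dosage[:, j].astype(np.int16)
    ok = (di != MISSING) & (dj != MISSING)
    n = int(ok.sum())
    if n == 0:
        return np.array([np.nan, np.nan]), 0
    return np.array([di[ok].sum(), dj[ok].sum()]) / (2.0 * n), n


def pair_edges(
    matrix: GenotypeMatrix,
    i: int, j: int,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    pairing: str = "carrier",
    reading: str = "one_minus_f",
) -> list[CCCEdge]:
    """All passing allele pairs for one unordered site pair (i < j).

    All four (x, y) allele combinations are evaluated; combinations with a
    monomorphic allele in the overlap are suppressed, as are pairs whose
    overlap is below ``min_overlap``.
    """
    (f_alt_i, f_alt_j), n = _overlap_freqs(matrix, i, j)
    if n < min_overlap:
        return []
    edges = []
    for x in (0, 1):
        f_ix = f_alt_i if x == 1 else 1.0 - f_alt_i
        if f_ix <= 0.0:
            continue
        for y in (0, 1):
            f_jy = f_alt_j if y == 1 else 1.0 - f_alt_j
            if f_jy <= 0.0:
                continue
            R, _ = relative_cooccurrence(matrix, i, x, j, y, pairing=pairing)
            ccc = ccc_value(R, f_ix, f_jy, reading=reading)
            if ccc >= threshold:
                edges.append(CCCEdge(i, x, j, y, R, float(f_ix), float(f_jy), n, ccc))
    return edges


def block_schedule(n_items: int, n_blocks: int) -> BlockSchedule:
    """Partition ``n_items`` sites into contiguous near-equal blocks and
    list one job per within-block and per unordered cross-block comparison
    (n_blocks + n_blocks*(n_blocks-1)/2 jobs; 20 blocks -> 210)."""
    if not 1 <= n_blocks <= n_items:
        raise ValueError(f"need 1 <= n_blocks ({n_blocks}) <= n_items ({n_items})")
    bounds = np.linspace(0, n_items, n_blocks + 1).astype(int)
    blocks = [(int(bounds[k]), int(bounds[k + 1])) for k in range(n_blocks)]
    jobs = []
    for a in range(n_blocks):
        jobs.append(BlockJob(len(jobs), a, a))
    for a in range(n_blocks):
        for b in range(a + 1, n_blocks):
            jobs.append(BlockJob(len(jobs), a, b))
    return BlockSchedule(blocks, jobs)


def ccc_scan(
    matrix: GenotypeMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    pairing: str = "carrier",
    reading: str = "one_minus_f",
    n_blocks: int = 1,
) -> list[CCCEdge]:
    """Serial all-pairs CCC scan; each unordered allele pair reported once.

    ``n_blocks`` > 1 runs the scan job-by-job over the block schedule (same
    result set; the schedule covers every pair exactly once)."""
    schedule = block_schedule(max(matrix.n_sites, 1), min(n_blocks, max(matrix.n_sites, 1)))
    edges: list[CCCEdge] = []
    for job in schedule.jobs:
        for i, j in schedule.job_pairs(job):
            edges.extend(pair_edges(matrix, i, j, threshold=threshold,
                                    min_overlap=min_overlap,
                                    pairing=pairing, reading=reading))
    edges.sort(key=lambda e: (e.site_i, e.site_j, e.allele_x, e.allele_y))
    return edges


def coevolution_profile(
    edges: list[CCCEdge],
    sites: list[SNPSite],
    anchor_chrom: str,
    anchor_start: int,
    anchor_end: int,
    grid: WindowGrid,
) -> DensityProfile:
    """Density of distinct SNPs co-segregating with SNPs inside an anchor
    gene interval [anchor_start, anchor_end) on ``anchor_chrom``.

    A SNP is counted (once, however many anchor partners it has) if it lies
    outside the anchor and appears in at least one edge whose partner lies
    inside it; the profile is restricted to ``grid.chrom``.
    """
    def inside(site: SNPSite) -> bool:
        return (site.chrom == anchor_chrom
                and anchor_start <= site.pos < anchor_end)

    partners: set[tuple[str, int]] = set()
    any_anchor = False
    for e in edges:
        si, sj = sites[e.site_i], sites[e.site_j]
        for a, b in ((si, sj), (sj, si)):
            if inside(a) and not inside(b):
                any_anchor = True
                partners.add((b.chrom, b.pos))
    if not any_anchor:
        logger.warning("anchor %s:%d-%d matched no edge endpoints",
                       anchor_chrom, anchor_start, anchor_end)
    positions = [pos for chrom, pos in partners if chrom == grid.chrom]
    prof = point_density(positions, grid)
    prof.kind = "corr_snp"
    return prof
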