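"""Synthetic chromosomes and genotype matrices with known ground truth.

Signals: the generator emulates the empirical structure of a plant
chromosome around its centromere — a broad pericentromeric methylation peak
(Gaussian of sd sigma_p windows) carrying a narrower central dip (sd
sigma_c), with coincident valleys in SNP and gene density and an otherwise
flat baseline. Realized window counts are Poisson around the closed-form
expectation (all signals are counts), with an optional negative-binomial
overdispersion knob for robustness experiments. Assembly-gap runs force
windows to zero in every signal and are reported as the gap profile.

Genotypes: individuals x SNPs dosage matrices with planted LD blocks. Each
block has one latent biallelic haplotype pair drawn at the block's minor
allele frequency under Hardy-Weinberg; every SNP in the block copies the
latent haplotypes with a per-allele flip probability epsilon, so
within-block pairs co-segregate almost perfectly while cross-block pairs
are independent (blocks can be explicitly linked to share a latent, e.g. to
emulate a gene anchor co-evolving with a distal region). Calls are masked
missing at a fixed rate.

Everything is driven by a single integer seed; identical scenarios and
seeds are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ccc import GenotypeMatrix, SNPSite
from .signals import DensityProfile, make_windows

DEFAULT_WINDOW_SIZE = 10_000


@dataclass
class CentromereScenario:
    """Planted-centromere chromosome, in window units.

    Defaults give a 2000-window (20 Mb at 10 kb windows) chromosome with
    the centromere center at window 800, a pericentromere of sd 150 windows
    and a central dip of sd 25 windows, at count levels typical of 10 kb
    windows (methylation-read and SNP counts in the tens-to-hundreds, gene
    coverage in the thousands of bp).
    """

    n_windows: int = 2000
    center: float = 800.0            # mu, windows
    sigma_p: float = 150.0           # pericentromere sd, windows
    sigma_c: float = 25.0            # centromeric dip sd, windows
    meth_baseline: float = 100.0     # beta_m, counts/window
    peri_amplitude: float = 200.0    # A_p
    dip_amplitude: float = 120.0     # A_d
    snp_baseline: float = 80.0       # beta_s
    snp_valley: float = 60.0         # B
    snp_shoulder: float = 0.0        # optional pericentromeric SNP elevation
    gene_baseline: float = 5000.0    # beta_g, bp covered/window
    gene_valley: float = 4500.0      # C
    gap_runs: list[tuple[int, int]] = field(default_factory=list)  # (start, width) windows
    overdispersion: float | None = None  # NB dispersion; None -> Poisson
    window_size: int = DEFAULT_WINDOW_SIZE
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.center < self.n_windows:
            raise ValueError("center must lie strictly inside the chromosome")
        if self.sigma_c >= self.sigma_p:
            raise ValueError("the dip must be narrower than the pericentromere")
        if self.dip_amplitude > self.peri_amplitude:
            raise ValueError("the dip must be shallower than the pericentromere peak")

    def expected_signals(self) -> dict[str, np.ndarray]:
        """Closed-form per-window expectations (before noise and gap runs)."""
        w = np.arange(self.n_windows, dtype=float)
        g_p = _gauss(w, self.center, self.sigma_p)
        g_c = _gauss(w, self.center, self.sigma_c)
        meth = self.meth_baseline + self.peri_amplitude * g_p - self.dip_amplitude * g_c
        # the SNP signature is a medium-scale valley at the centromere; the
        # optional shoulder term adds the broad pericentromeric elevation of
        # the full SNP tooth-X-ray
        snp = self.snp_baseline - self.snp_valley * g_c + self.snp_shoulder * g_p
        gene = self.gene_baseline - self.gene_valley * g_p
        return {
            "meth": np.clip(meth, 0, None),
            "snp": np.clip(snp, 0, None),
            "gene": np.clip(gene, 0, None),
        }


@dataclass
class LDScenario:
    """Planted-LD genotype matrix.

    Defaults match a small association-panel slice: 200 individuals, three
    8-SNP blocks at latent minor allele frequencies 0.25 / 0.20 / 0.30,
    per-allele flip noise 0.01 and 10% missing calls (pairwise overlap
    ~162 individuals, above the 100-individual scan floor). Block k's SNPs
    sit on ``chrom`` at ``block_span * k + spacing * m`` bp.
    """

    n_individuals: int = 200
    blocks: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(8, 0.25, 0.01), (8, 0.20, 0.01), (8, 0.30, 0.01)]
    )
    anchor_block: int = 0
    missing_rate: float = 0.1
    linked_blocks: list[tuple[int, int]] = field(default_factory=list)  # b copies a's latent
    chrom: str = "chrSim"
    block_span: int = 100_000
    spacing: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        for _, maf, eps in self.blocks:
            if not 0.01 < maf <= 0.5:
                raise ValueError(f"block MAF {maf} outside (0.01, 0.5]")
            if not 0.0 <= eps < 0.5:
                raise ValueError(f"flip noise {eps} outside [0, 0.5)")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError(f"missing rate {self.missing_rate} outside [0, 0.5)")
        for a, b in self.linked_blocks:
            if not (0 <= a < b < len(self.blocks)):
                raise ValueError(f"invalid linked block pair ({a}, {b})")


def _gauss(w: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Unit-height Gaussian."""
    return np.exp(-0.5 * ((w - mu) / sigma) ** 2)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray,
                 overdispersion: float | None) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(lam)
    # NB with mean lam, variance lam * (1 + lam / r)
    r = float(overdispersion)
    lam = np.clip(lam, 1e-12, None)
    return rng.poisson(rng.gamma(shape=r, scale=lam / r))


def simulate_signals(
    scenario: CentromereScenario, seed: int | None = None
) -> tuple[DensityProfile, DensityProfile, DensityProfile, DensityProfile]:
    """Simulate (methylation, snp, gene, gap) profiles for one chromosome.

    ``seed`` overrides ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    grid = make_windows(scenario.n_windows * scenario.window_size,
                        scenario.window_size, chrom="chrSim")
    exp = scenario.expected_signals()

    gap = np.zeros(scenario.n_windows)
    in_gap = np.zeros(scenario.n_windows, dtype=bool)
    for start, width in scenario.gap_runs:
        if not (0 <= start and start + width <= scenario.n_windows and width > 0):
            raise ValueError(f"gap run ({start}, {width}) outside the chromosome")
        in_gap[start:start + width] = True
    gap[in_gap] = scenario.window_size

    profiles = {}
    for kind, key in (("reads", "meth"), ("snp", "snp"), ("coverage", "gene")):
        vals = _draw_counts(rng, exp[key], scenario.overdispersion).astype(float)
        if kind == "coverage":
            vals = np.minimum(vals, grid.lengths)  # coverage cannot exceed window
        vals[in_gap] = 0.0  # assembly gaps carry no features
        profiles[key] = DensityProfile(grid, kind, vals)
    return (profiles["meth"], profiles["snp"], profiles["gene"],
            DensityProfile(grid, "gap", gap))


def simulate_genotypes(scenario: LDScenario, seed: int | None = None) -> GenotypeMatrix:
    """Simulate a genotype matrix with planted LD blocks (see module notes)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_individuals
    latents: dict[int, np.ndarray] = {}
    copy_of = {b: a for a, b in scenario.linked_blocks}

    cols, sites = [], []
    for k, (n_snps, maf, eps) in enumerate(scenario.blocks):
        if k in copy_of:
            hap = latents[copy_of[k]]
        else:
            hap = rng.random((n, 2)) < maf  # HWE: two independent haplotypes
        latents[k] = hap
        for m in range(n_snps):
            flips = rng.random((n, 2)) < eps
            cols.append((hap ^ flips).sum(axis=1).astype(np.int8))
            sites.append(SNPSite(scenario.chrom,
                                 scenario.block_span * k + scenario.spacing * m))
    dosage = np.stack(cols, axis=1)
    if scenario.missing_rate > 0:
        mask = rng.random(dosage.shape) < scenario.missing_rate
        dosage[mask] = -1
    individuals = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(individuals=individuals, sites=sites, dosage=dosage)
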