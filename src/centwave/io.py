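"""File formats, run configuration and output metadata.

Internal coordinates are 0-based half-open everywhere; conversions applied
on ingestion: VCF POS is 1-based (-1), GFF3 start/end are 1-based inclusive
([start-1, end)), BED is already half-open, BLAST outfmt-6 subject
coordinates are 1-based inclusive and reverse-strand hits have sstart >
send (normalized to [min-1, max)).

Every writer emits '#'-prefixed metadata lines (tool version, config hash,
seed, paper-deviation knobs such as the CWT normalization and the CCC
penalty reading) so any output can be traced to the options that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .caller import CentromereCall
from .ccc import MISSING, CCCEdge, GenotypeMatrix, SNPSite
from .signals import DensityProfile, IntervalSet, WindowGrid
from .wavelet import ScaleGrid, WaveletLandscape

logger = logging.getLogger("centwave")


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """All tunables, at the published defaults."""

    window_size: int = 10_000
    voices: int = 8
    norm: str = "l2"            # CWT prefactor: "l2" (1/sqrt(s)) or "l1" (1/s)
    boundary: str = "reflect"   # CWT padding: "reflect" or "zero"
    search: str = "borders"     # caller argmax domain: "borders" or "global"
    maf_min: float = 0.01
    callrate_min: float = 0.5
    min_overlap: int = 100
    threshold: float = 0.7
    blocks: int = 1
    reading: str = "one_minus_f"   # CCC frequency penalty
    pairing: str = "carrier"       # CCC co-occurrence rule
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def metadata_lines(config: RunConfig | None = None, **extra) -> list[str]:
    meta = {"tool": f"centwave {__version__}"}
    if config is not None:
        meta["config_hash"] = config.config_hash()
        meta.update({k: v for k, v in config.to_dict().items() if k != "log_level"})
    meta.update(extra)
    return [f"# {k}={v}" for k, v in meta.items()]


def _read_meta(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k] = v
    return meta


# ---------------------------------------------------------------- readers

def read_vcf_sites(path: str):
    """Biallelic SNPs from a VCF with GT: (GenotypeMatrix, n_skipped).

    Multi-allelic or non-SNP records are skipped with a logged count;
    missing genotypes (./.) are preserved as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    individuals = list(vcf.samples)
    if not individuals:
        raise ValueError(f"{path}: VCF has no sample columns (GT required)")
    sites, cols, skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
        sites.append(SNPSite(rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
    vcf.close()
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, skipped)
    dosage = (np.stack(cols, axis=1) if cols
              else np.empty((len(individuals), 0), dtype=np.int8))
    return GenotypeMatrix(individuals, sites, dosage), skipped


def read_vcf_positions(path: str, chrom: str) -> np.ndarray:
    """0-based positions of biallelic SNPs on one chromosome (sites only)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    pos = [rec.POS - 1 for rec in vcf
           if rec.CHROM == chrom and len(rec.ALT) == 1 and rec.is_snp]
    vcf.close()
    return np.asarray(pos, dtype=np.int64)


def read_gff3_genes(path: str, chrom: str) -> IntervalSet:
    """Gene-body intervals (type == gene) on one chromosome."""
    import gffutils.iterators

    ivs = []
    for feat in gffutils.iterators.DataIterator(path):
        if feat.featuretype == "gene" and feat.seqid == chrom:
            ivs.append((feat.start - 1, feat.end))  # inclusive -> half-open
    return IntervalSet(chrom, np.asarray(ivs, dtype=np.int64).reshape(-1, 2))


def read_bed(path: str, chrom: str) -> IntervalSet:
    """BED3+ intervals on one chromosome (already 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    sub = df[df["chrom"] == chrom]
    return IntervalSet(chrom, sub[["start", "end"]].to_numpy())


def read_blast6(path: str, chrom: str) -> IntervalSet:
    """Subject-side hit intervals from BLAST tabular outfmt 6.

    Uses columns 2 (sseqid), 9 (sstart), 10 (send); sstart > send marks a
    reverse-strand hit and is normalized to [min-1, max).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 10:
        raise ValueError(f"{path}: expected >= 10 outfmt-6 columns, got {df.shape[1]}")
    sub = df[df[1].astype(str) == chrom]
    lo = np.minimum(sub[8], sub[9]).to_numpy(dtype=np.int64) - 1
    hi = np.maximum(sub[8], sub[9]).to_numpy(dtype=np.int64)
    return IntervalSet(chrom, np.stack([lo, hi], axis=1) if len(lo) else
                       np.empty((0, 2), dtype=np.int64))


def read_fasta(path: str, chrom: str) -> str:
    """One chromosome's sequence from a FASTA (indexed access)."""
    from pyfaidx import Fasta

    fa = Fasta(path)
    if chrom not in fa:
        raise KeyError(f"{chrom} not in {path}")
    return str(fa[chrom][:])


# ---------------------------------------------------------------- writers

def write_profile(profile: DensityProfile, path: str,
                  config: RunConfig | None = None, **extra) -> None:
    """BED-like TSV: chrom, start, end, count (0-based half-open)."""
    g = profile.grid
    lines = metadata_lines(config, kind=profile.kind, window_size=g.window_size,
                           chrom_length=g.chrom_length, **extra)
    df = pd.DataFrame({"chrom": g.chrom, "start": g.starts, "end": g.ends,
                       "count": profile.values})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_profile(path: str) -> DensityProfile:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty profile")
    chrom = str(df["chrom"].iloc[0])
    chrom_length = int(meta.get("chrom_length", df["end"].iloc[-1]))
    window_size = int(meta.get("window_size", df["end"].iloc[0] - df["start"].iloc[0]))
    grid = WindowGrid(chrom, chrom_length, window_size)
    kind = meta.get("kind", "snp")
    return DensityProfile(grid, kind, df["count"].to_numpy(dtype=float))


def write_landscape(landscape: WaveletLandscape, grid: WindowGrid, path: str,
                    config: RunConfig | None = None) -> None:
    """TSV: first column `scale`, one column per window start, row per scale."""
    lines = metadata_lines(config, chrom=grid.chrom,
                           chrom_length=grid.chrom_length,
                           window_size=grid.window_size,
                           profile_ref=landscape.profile_ref,
                           **landscape.meta)
    df = pd.DataFrame(landscape.coeffs, columns=grid.starts.astype(str))
    df.insert(0, "scale", landscape.scales.scales)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_landscape(path: str) -> tuple[WaveletLandscape, WindowGrid]:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    scales = ScaleGrid(df["scale"].to_numpy(dtype=float))
    coeffs = df.drop(columns="scale").to_numpy(dtype=float)
    n_windows = coeffs.shape[1]
    window_size = int(meta.get("window_size", 1))
    chrom_length = int(meta.get("chrom_length", n_windows * window_size))
    grid = WindowGrid(meta.get("chrom", "chr"), chrom_length, window_size)
    landscape = WaveletLandscape(
        scales, coeffs, profile_ref=meta.get("profile_ref", ""),
        meta={k: meta[k] for k in ("norm", "boundary") if k in meta})
    return landscape, grid


CALL_COLUMNS = ["chrom", "center_bp", "region_start", "region_end", "b1", "b2",
                "p_scale", "c_scale", "D", "qc_flags"]


def write_calls(calls: list[CentromereCall], path: str,
                config: RunConfig | None = None) -> None:
    rows = []
    for c in calls:
        rows.append({
            "chrom": c.chrom, "center_bp": c.center_bp,
            "region_start": c.region_start_bp, "region_end": c.region_end_bp,
            "b1": c.b1_bp, "b2": c.b2_bp,
            "p_scale": c.p_scale_value, "c_scale": c.c_scale_value,
            "D": c.D, "qc_flags": ";".join(c.qc_flags) or ".",
        })
    with open(path, "w") as fh:
        fh.write("\n".join(metadata_lines(config)) + "\n")
        pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(fh, sep="\t", index=False)


EDGE_COLUMNS = ["chrom_i", "pos_i", "allele_x", "chrom_j", "pos_j", "allele_y",
                "R", "n_overlap", "ccc"]


def write_edges(edges: list[CCCEdge], sites: list[SNPSite], path: str,
                config: RunConfig | None = None) -> None:
    rows = []
    for e in edges:
        si, sj = sites[e.site_i], sites[e.site_j]
        rows.append({
            "chrom_i": si.chrom, "pos_i": si.pos,
            "allele_x": si.alt if e.allele_x == 1 else si.ref,
            "chrom_j": sj.chrom, "pos_j": sj.pos,
            "allele_y": sj.alt if e.allele_y == 1 else sj.ref,
            "R": e.R, "n_overlap": e.n_overlap, "ccc": e.ccc,
        })
    with open(path, "w") as fh:
        fh.write("\n".join(metadata_lines(config)) + "\n")
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_edges(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_schedule(schedule, path: str, config: RunConfig | None = None) -> None:
    rows = [{"job_id": j.job_id, "block_a": j.block_a, "block_b": j.block_b}
            for j in schedule.jobs]
    with open(path, "w") as fh:
        fh.write("\n".join(metadata_lines(config)) + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Minimal single-ALT VCF 4.2 with GT fields (missing as ./.)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=centwave {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({s.chrom for s in matrix.sites})
        for ch in chroms:
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individuals) + "\n")
        for s_idx, site in enumerate(matrix.sites):
            gts = "\t".join(gt_of[int(d)] for d in matrix.dosage[:, s_idx])
            fh.write(f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
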