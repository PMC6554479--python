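"""Centromere localization from methylation and SNP wavelet landscapes.

Plant centromeres sit inside a broad, hypermethylated, SNP- and gene-poor
pericentromere, while the active centromere itself is often *less*
methylated than its flanks. In a wavelet coefficient landscape this prints
as a broad-scale positive peak containing a narrower-scale negative valley
at its center — the "tooth-X-ray" signature. The caller finds it in four
steps, given the methylation landscape M and the SNP landscape S of one
chromosome:

1. pericentromeric scale p: location of the maximum coefficient in the
   upper third of M's scale rows (the broad methylation peak);
2. pericentromere borders b1, b2: the zero crossings of the scale-p
   methylation coefficient vector on either side of that maximum;
3. centromeric scale c: location of the minimum coefficient in the lower
   two-thirds of S's scale rows, restricted to columns [b1, b2] (the narrow
   SNP-density valley inside the pericentromere);
4. center: with M_p and S_c each standardized to mean 0 / sd 1, the window
   x in [b1, b2] maximizing M*_p,x - S*_c,x; the general centromeric region
   runs to the first sign change of that difference on each side of the
   center. The reported statistic D is the difference of the *unscaled*
   coefficients at the called center.

Degenerate chromosomes (no positive methylation peak at the claimed scale)
produce a structured no-call with qc flags instead of an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signals import DensityProfile
from .wavelet import ScaleGrid, WaveletLandscape, cwt, scale_vector

logger = logging.getLogger("centwave")


class DegenerateSignatureError(ValueError):
    """The landscape has no positive peak where the signature requires one."""


@dataclass
class CentromereCall:
    """One chromosome's centromere call (window and bp coordinates).

    ``center_*`` fields are None for a no-call (see ``qc_flags``).
    ``p_scale_value > c_scale_value`` is expected of a true tooth-X-ray
    signature but is only warned about (flag ``scale_order``), not enforced.
    """

    chrom: str
    center_window: int | None
    center_bp: int | None
    region_start_bp: int | None
    region_end_bp: int | None
    p_scale_index: int | None
    p_scale_value: float | None
    c_scale_index: int | None
    c_scale_value: float | None
    b1_bp: int | None
    b2_bp: int | None
    D: float | None
    qc_flags: list[str] = field(default_factory=list)
    # window-resolution counterparts, used by tests and plotting
    region_start_window: int | None = None
    region_end_window: int | None = None
    b1_window: int | None = None
    b2_window: int | None = None

    @property
    def is_call(self) -> bool:
        return self.center_window is not None


def _top_third_start(n_scales: int) -> int:
    # rows are ascending in scale; the "upper third" is the largest-scale
    # third, split at ceil(2 n / 3)
    return -(-2 * n_scales // 3)


def standardize(v) -> np.ndarray:
    """Scale a vector to mean 0 and standard deviation 1 (population sd)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = v.std()  # n denominator
    if sd == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (v - v.mean()) / sd


def find_pericentromeric_scale(M: WaveletLandscape) -> tuple[int, int]:
    """Locate the maximum coefficient in the upper third of the methylation
    landscape; returns (scale row index p, window index of the maximum)."""
    if M.n_scales < 3:
        raise ValueError("need at least 3 scales to take an upper third")
    lo = _top_third_start(M.n_scales)
    top = M.coeffs[lo:]
    # ties broken to smallest scale then smallest window (C-order argmax)
    flat = int(np.argmax(top))
    p = lo + flat // top.shape[1]
    x_peak = flat % top.shape[1]
    return p, x_peak


def find_pericentromere_borders(m_p: np.ndarray, x_peak: int) -> tuple[int, int, list[str]]:
    """Zero crossings of the scale-p methylation vector around its peak.

    Returns (b1, b2, qc_flags): the nearest windows at or below / above
    ``x_peak`` where the coefficient is <= 0 (exact zeros count as
    crossings). A side with no crossing falls back to the chromosome end
    with a qc flag.
    """
    m_p = np.asarray(m_p, dtype=float)
    if not 0 <= x_peak < m_p.size:
        raise IndexError(f"x_peak {x_peak} outside vector of length {m_p.size}")
    if m_p[x_peak] <= 0:
        raise DegenerateSignatureError(
            f"no positive methylation peak at the pericentromeric scale "
            f"(coefficient {m_p[x_peak]:.3g} at window {x_peak})"
        )
    flags: list[str] = []
    nonpos = m_p <= 0
    left = np.flatnonzero(nonpos[:x_peak + 1])
    if left.size:
        b1 = int(left[-1])
    else:
        b1 = 0
        flags.append("b1_at_chrom_start")
    right = np.flatnonzero(nonpos[x_peak:])
    if right.size:
        b2 = x_peak + int(right[0])
    else:
        b2 = m_p.size - 1
        flags.append("b2_at_chrom_end")
    return b1, b2, flags


def find_centromeric_scale(S: WaveletLandscape, b1: int, b2: int) -> tuple[int, int]:
    """Locate the minimum coefficient in the lower two-thirds of the SNP
    landscape, columns restricted to [b1, b2]; returns (row c, window)."""
    if b1 >= b2:
        raise ValueError(f"empty border range [{b1}, {b2}]")
    hi = _top_third_start(S.n_scales)
    sub = S.coeffs[:hi, b1:b2 + 1]
    if sub.size == 0:
        raise ValueError("empty search region for the centromeric scale")
    flat = int(np.argmin(sub))
    c = flat // sub.shape[1]
    x_min = b1 + flat % sub.shape[1]
    return c, x_min


def locate_centromere(
    M: WaveletLandscape,
    S: WaveletLandscape,
    chrom: str = "chr",
    window_size: int = 1,
    chrom_length: int | None = None,
    search: str = "borders",
) -> CentromereCall:
    """Call the centromere from paired methylation / SNP landscapes.

    ``search`` restricts the center argmax to [b1, b2] ("borders", default)
    or searches every window ("global"). bp fields are derived from
    ``window_size`` (center at the called window's midpoint); with the
    default ``window_size=1`` they equal window indices.
    """
    if M.n_windows != S.n_windows:
        raise ValueError("methylation and SNP landscapes must share a window grid")
    n = M.n_windows

    def _bp(w: int | None, end: bool = False) -> int | None:
        if w is None:
            return None
        pos = (w + 1) * window_size if end else w * window_size
        return min(pos, chrom_length) if chrom_length is not None else pos

    try:
        p, x_peak = find_pericentromeric_scale(M)
        m_p = scale_vector(M, p)
        b1, b2, flags = find_pericentromere_borders(m_p, x_peak)
        c, _ = find_centromeric_scale(S, b1, b2)
        s_c = scale_vector(S, c)
    except (DegenerateSignatureError, ValueError) as exc:
        logger.warning("%s: no call (%s)", chrom, exc)
        return CentromereCall(
            chrom=chrom, center_window=None, center_bp=None,
            region_start_bp=None, region_end_bp=None,
            p_scale_index=None, p_scale_value=None,
            c_scale_index=None, c_scale_value=None,
            b1_bp=None, b2_bp=None, D=None,
            qc_flags=["no_call", str(exc)],
        )

    diff = standardize(m_p) - standardize(s_c)
    if search == "borders":
        lo, hi = b1, b2
    elif search == "global":
        lo, hi = 0, n - 1
    else:
        raise ValueError(f"unknown search domain {search!r}")
    center = lo + int(np.argmax(diff[lo:hi + 1]))  # ties -> smallest x

    # general centromeric region: first sign change of the standardized
    # difference walking outward from the center, clipped to [b1, b2]
    flags = list(flags)
    nonpos = diff <= 0
    left = np.flatnonzero(nonpos[b1:center + 1])
    if left.size:
        region_start = b1 + int(left[-1])
    else:
        region_start = b1
        flags.append("region_start_at_b1")
    right = np.flatnonzero(nonpos[center:b2 + 1])
    if right.size:
        region_end = center + int(right[0])
    else:
        region_end = b2
        flags.append("region_end_at_b2")

    p_val = float(M.scales.scales[p])
    c_val = float(S.scales.scales[c])
    if p_val <= c_val:
        flags.append("scale_order")
        logger.warning("%s: pericentromeric scale %.3g <= centromeric scale %.3g",
                       chrom, p_val, c_val)

    D = float(m_p[center] - s_c[center])  # unscaled coefficients
    center_bp = center * window_size + window_size // 2  # window midpoint
    if chrom_length is not None:
        center_bp = min(center_bp, chrom_length - 1)
    return CentromereCall(
        chrom=chrom,
        center_window=center,
        center_bp=center_bp,
        region_start_bp=_bp(region_start),
        region_end_bp=_bp(region_end, end=True),
        p_scale_index=p, p_scale_value=p_val,
        c_scale_index=c, c_scale_value=c_val,
        b1_bp=_bp(b1), b2_bp=_bp(b2, end=True),
        D=D, qc_flags=flags,
        region_start_window=region_start, region_end_window=region_end,
        b1_window=b1, b2_window=b2,
    )


def call_chromosome(
    meth: DensityProfile,
    snp: DensityProfile,
    voices: int = 8,
    norm: str = "l2",
    boundary: str = "reflect",
    search: str = "borders",
    scales: ScaleGrid | None = None,
) -> CentromereCall:
    """End-to-end call: standardize both density profiles, transform each
    with the same scale grid, and locate the tooth-X-ray signature."""
    if meth.grid != snp.grid:
        raise ValueError("methylation and SNP profiles must share a window grid")
    grid = meth.grid
    if scales is None:
        scales = ScaleGrid.dyadic(grid.n_windows, voices=voices)
    try:
        m_std = standardize(meth.values)
        s_std = standardize(snp.values)
    except ValueError as exc:
        return CentromereCall(
            chrom=grid.chrom, center_window=None, center_bp=None,
            region_start_bp=None, region_end_bp=None,
            p_scale_index=None, p_scale_value=None,
            c_scale_index=None, c_scale_value=None,
            b1_bp=None, b2_bp=None, D=None,
            qc_flags=["no_call", f"flat profile: {exc}"],
        )
    M = cwt(m_std, scales, norm=norm, boundary=boundary, profile_ref="methylation")
    S = cwt(s_std, scales, norm=norm, boundary=boundary, profile_ref="snp")
    return locate_centromere(
        M, S, chrom=grid.chrom, window_size=grid.window_size,
        chrom_length=grid.chrom_length, search=search,
    )
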