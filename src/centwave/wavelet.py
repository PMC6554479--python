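"""Continuous wavelet transform of density profiles with the Ricker wavelet.

The transform correlates a chromosome density signal f(t) with scaled,
translated copies of the Ricker (Mexican-hat) mother wavelet

    psi(u) = (1 - u**2) * exp(-u**2 / 2),          u = (t - tau) / s,

giving a coefficient W(s, tau) for every scale s and window position tau.
Because the wavelet is a zero-mean, symmetric bump flanked by negative
lobes, W(s, tau) is positive where the signal has a peak of width ~s at tau
and negative at a valley — the property the centromere caller relies on.

Two normalization conventions are supported: "l2" multiplies by s**-0.5
(unit-energy wavelets, the common CWT convention and the default) and "l1"
multiplies by 1/s. Within a scale the two differ by a positive constant, so
every within-scale decision downstream (argmax, argmin, zero crossings) is
normalization-invariant; cross-scale scale selection is not, which is why
the choice is carried in the landscape metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

logger = logging.getLogger("centwave")

#: wavelet support truncation, in units of scale; beyond this the Ricker
#: amplitude is < 1e-13 of its peak
SUPPORT_RADIUS = 8.0

#: reflection/zero padding width, in units of the largest scale
PAD_RADIUS = 4.0


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing positive scales, in window units."""

    scales: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        s = self.scales
        if s.ndim != 1 or s.size == 0:
            raise ValueError("scales must be a non-empty 1-D array")
        if np.any(s[:-1] >= s[1:]) or s[0] < 1:
            raise ValueError("scales must be strictly increasing and >= 1 window")

    def __len__(self) -> int:
        return self.scales.size

    @classmethod
    def dyadic(cls, n_windows: int, s_min: float = 2.0, s_max: float | None = None,
               voices: int = 8) -> "ScaleGrid":
        """Dyadic grid with ``voices`` scales per octave from ``s_min`` up to
        ``s_max`` (default ``n_windows / 4``, the largest scale the boundary
        rule supports)."""
        if s_max is None:
            s_max = n_windows / 4.0
        if s_max < s_min:
            raise ValueError(f"s_max {s_max} < s_min {s_min}")
        n = int(np.floor(voices * np.log2(s_max / s_min))) + 1
        return cls(s_min * 2.0 ** (np.arange(n) / voices))


@dataclass
class WaveletLandscape:
    """Coefficient matrix W(s, tau): one row per scale (ascending), one
    column per window position."""

    scales: ScaleGrid
    coeffs: np.ndarray
    profile_ref: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[0] != len(self.scales):
            raise ValueError("one coefficient row per scale required")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("landscape coefficients must be finite")

    @property
    def n_scales(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_windows(self) -> int:
        return self.coeffs.shape[1]


def ricker(t, s: float, norm: str = "none"):
    """Ricker wavelet A * (1 - (t/s)**2) * exp(-t**2 / (2 s**2)).

    Maximal at t=0, zero at t = +/-s, negative lobes beyond. ``norm``
    selects the amplitude A: "none" -> 1, "l2" -> s**-0.5, "l1" -> 1/s.
    """
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")
    t = np.asarray(t, dtype=float)
    u = t / s
    out = (1.0 - u**2) * np.exp(-0.5 * u**2)
    return _prefactor(s, norm) * out


def _prefactor(s: float, norm: str) -> float:
    if norm in ("none", None):
        return 1.0
    if norm == "l2":
        return s**-0.5
    if norm == "l1":
        return 1.0 / s
    raise ValueError(f"unknown normalization {norm!r}")


def cwt(values, scales: ScaleGrid, norm: str = "l2",
        boundary: str = "reflect", profile_ref: str = "") -> WaveletLandscape:
    """Transform a signal into its wavelet coefficient landscape.

    Scales larger than a quarter of the signal length lack support and are
    dropped with a warning. The signal is padded on both sides by 4x the
    largest retained scale — mirror-reflected (default) or zero — and the
    coefficients are cropped back to the original length, so a coefficient
    at least 4s from either end is unaffected by the boundary rule.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    n = x.size
    s = scales.scales
    keep = s <= n / 4.0
    if not np.any(keep):
        raise ValueError(f"signal of length {n} too short for smallest scale {s[0]}")
    if not np.all(keep):
        logger.warning("dropping %d scales too large for signal of length %d",
                       int((~keep).sum()), n)
        scales = ScaleGrid(s[keep])
        s = scales.scales

    pad = int(np.ceil(PAD_RADIUS * s.max()))
    if boundary == "reflect":
        padded = np.pad(x, pad, mode="reflect")
    elif boundary == "zero":
        padded = np.pad(x, pad, mode="constant")
    else:
        raise ValueError(f"unknown boundary rule {boundary!r}")

    rows = np.empty((s.size, n))
    for k, sk in enumerate(s):
        half = int(np.ceil(SUPPORT_RADIUS * sk))
        kernel = ricker(np.arange(-half, half + 1), sk)  # symmetric, odd length
        full = fftconvolve(padded, kernel, mode="same")
        rows[k] = _prefactor(sk, norm) * full[pad:pad + n]
    return WaveletLandscape(
        scales=scales, coeffs=rows, profile_ref=profile_ref,
        meta={"norm": norm, "boundary": boundary},
    )


def scale_vector(landscape: WaveletLandscape, s_index: int) -> np.ndarray:
    """Row ``s_index`` of the landscape: W(s, .) at one scale."""
    if not 0 <= s_index < landscape.n_scales:
        raise IndexError(f"scale index {s_index} out of range [0, {landscape.n_scales})")
    return landscape.coeffs[s_index]


def plot_landscape(landscape: WaveletLandscape, path: str, title: str = "") -> None:
    """Heatmap of the landscape: positive coefficients blue, negative red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lim = np.abs(landscape.coeffs).max() or 1.0
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.imshow(landscape.coeffs, aspect="auto", origin="lower",
              cmap="RdBu", vmin=-lim, vmax=lim)
    ax.set_xlabel("window position")
    ax.set_ylabel("scale index (ascending)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
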