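"""Fourier analysis of contact maps.

A zero-mean contact map is decomposed with the unnormalised forward 2-D
discrete Fourier transform over signed integer frequencies
kx, ky in [-floor(N/2), ceil(N/2) - 1].  The power P(kx, ky) = |C_hat|^2
satisfies Parseval's identity Var(C) = sum P / N^4, so the per-mode powers
partition the contact-map variance exactly.  Because the map is symmetric,
modes are aggregated over the wavenumber k = sqrt(kx^2 + ky^2); k = 0 is
the (zeroed) mean mode and is excluded from the unique-wavenumber list.

Derived features:

* partial sums S<=k-dagger and the complementary split sum S>k-dagger, in
  variance units (they add up to Var(C));
* lowpass reconstructions keeping only modes with k <= k-dagger;
* explained-variance curves EV(k) (prefix fractions of total power in
  ascending-wavenumber order) and EV(p) (descending-power order), and the
  variance divergence index, the mean squared gap between the two curves.
  A large index flags maps with unusually strong short-wavelength structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap
from .errors import DegenerateSpectrumError

__all__ = [
    "PowerSpectrum",
    "SplitFeatures",
    "EVCurves",
    "power_spectrum",
    "partial_sum",
    "split_sum",
    "lowpass_reconstruction",
    "ev_curves",
]

#: wavenumbers are compared after rounding to this many decimals; sqrt of
#: small integer sums is exact well beyond this at N <= 64
K_DECIMALS = 9


def _signed_frequencies(n: int) -> np.ndarray:
    return np.rint(np.fft.fftfreq(n) * n).astype(int)


def wavenumber_grid(n: int) -> np.ndarray:
    """k = sqrt(kx^2 + ky^2) over the signed integer frequency grid."""
    f = _signed_frequencies(n).astype(float)
    return np.round(np.sqrt(f[:, None] ** 2 + f[None, :] ** 2), K_DECIMALS)


@dataclass
class PowerSpectrum:
    """Aggregated Fourier power of a zero-mean contact map.

    ``aggregated_power`` sums the per-mode power over all modes (conjugate
    pairs included) sharing the same wavenumber; it sums to the total power
    S = N^4 * Var(C).  ``per_mode`` is the full P(kx, ky) grid when the
    spectrum came from a map (optional for synthetically constructed
    spectra).
    """

    N: int
    unique_wavenumbers: np.ndarray  # sorted, k = 0 excluded
    aggregated_power: np.ndarray
    per_mode: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.unique_wavenumbers = np.asarray(self.unique_wavenumbers, dtype=float)
        self.aggregated_power = np.asarray(self.aggregated_power, dtype=float)
        if len(self.unique_wavenumbers) != len(self.aggregated_power):
            raise ValueError("wavenumber and power arrays must align")
        if np.any(np.diff(self.unique_wavenumbers) <= 0):
            raise ValueError("unique wavenumbers must be sorted and distinct")
        if np.any(self.aggregated_power < 0):
            raise ValueError("power must be non-negative")

    @property
    def total_power(self) -> float:
        """S: total Fourier power (equals N^4 * Var(C))."""
        return float(self.aggregated_power.sum())

    @property
    def Nk(self) -> int:
        """Number of unique (nonzero) wavenumbers."""
        return len(self.unique_wavenumbers)

    @property
    def variance(self) -> float:
        return self.total_power / self.N**4


@dataclass(frozen=True)
class SplitFeatures:
    """Partition of the contact-map variance at threshold wavenumber k_dagger."""

    k_dagger: float
    S_leq: float
    S_gt: float


@dataclass(frozen=True)
class EVCurves:
    """Explained-variance curves and the variance divergence index."""

    ev_by_wavenumber: np.ndarray
    ev_by_power: np.ndarray
    divergence_index: float


def power_spectrum(cmap: ContactMap | np.ndarray) -> PowerSpectrum:
    """Per-mode and per-wavenumber Fourier power of a contact map.

    The map mean is subtracted before the (unnormalised forward) transform,
    so the (0, 0) mode carries exactly zero power.
    """
    c = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    n = c.shape[0]
    f = np.fft.fft2(c - c.mean())
    p = np.abs(f) ** 2
    p[0, 0] = 0.0
    k = wavenumber_grid(n)
    flat_k = k.ravel()
    flat_p = p.ravel()
    uniq, inverse = np.unique(flat_k, return_inverse=True)
    agg = np.bincount(inverse, weights=flat_p, minlength=len(uniq))
    nonzero = uniq > 0
    return PowerSpectrum(
        N=n,
        unique_wavenumbers=uniq[nonzero],
        aggregated_power=agg[nonzero],
        per_mode=p,
    )


def partial_sum(spec: PowerSpectrum, k_dagger: float) -> float:
    """S<=k_dagger in variance units: aggregated power at k <= k_dagger / N^4."""
    if k_dagger < 0:
        raise ValueError("k_dagger must be non-negative")
    mask = spec.unique_wavenumbers <= k_dagger + 10.0**-K_DECIMALS
    return float(spec.aggregated_power[mask].sum()) / spec.N**4


def split_sum(spec: PowerSpectrum, k_dagger: float) -> SplitFeatures:
    """Split the variance into S<=k_dagger and the residual S>k_dagger."""
    s_leq = partial_sum(spec, k_dagger)
    return SplitFeatures(
        k_dagger=float(k_dagger), S_leq=s_leq, S_gt=spec.variance - s_leq
    )


def lowpass_reconstruction(cmap: ContactMap | np.ndarray, k_dagger: float) -> np.ndarray:
    """Inverse transform keeping only modes with k <= k_dagger (mean re-added).

    The result is real and symmetric but is deliberately not clipped to
    [0, 1]; it is a diagnostic, not a contact map.
    """
    c = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    n = c.shape[0]
    mean = c.mean()
    f = np.fft.fft2(c - mean)
    keep = wavenumber_grid(n) <= k_dagger + 10.0**-K_DECIMALS
    recon = np.fft.ifft2(f * keep).real + mean
    return 0.5 * (recon + recon.T)


def ev_curves(spec: PowerSpectrum) -> EVCurves:
    """Explained-variance curves over unique wavenumbers, and their gap.

    EV(k)_l: fraction of total power in the first l unique wavenumbers in
    ascending-k order.  EV(p)_l: same prefix fractions with the wavenumbers
    reordered by descending aggregated power (ties broken by ascending k,
    which minimises the index under ties).  The variance divergence index is
    (1/Nk) * sum_l [EV(k)_l - EV(p)_l]^2.
    """
    s = spec.total_power
    if s <= 0:
        raise DegenerateSpectrumError("spectrum has zero total power")
    p = spec.aggregated_power
    ev_k = np.cumsum(p) / s
    order = np.lexsort((spec.unique_wavenumbers, -p))
    ev_p = np.cumsum(p[order]) / s
    index = float(np.mean((ev_k - ev_p) ** 2))
    return EVCurves(ev_by_wavenumber=ev_k, ev_by_power=ev_p, divergence_index=index)
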