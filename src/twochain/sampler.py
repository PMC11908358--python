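"""Monte Carlo sampling of one- and two-chain systems and PMF estimation.

The two-chain potential of mean force u(r) between chain centres of mass is
estimated from umbrella windows in r.  The default scheme uses hard-bound
windows (moves leaving the window are rejected) of width 1 sigma spaced
0.5 sigma apart, stitched together by matching log-densities in the overlap
regions; harmonic windows combined by WHAM are available behind the same
interface.  The PMF is defined as -ln g(r) with the 4*pi*r^2 shell volume
divided out and is anchored so that it averages to zero over the outermost
(non-interacting) region, which makes the second virial integral directly
applicable and fixes u(inf) = 0.

The attractive well of the PMF is the maximal contiguous interval around the
minimum over which u(r) stays within 1 kBT of the minimum; decorrelated
configurations drawn from it feed the interchain contact map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import SamplingShortfallError, StitchingError
from .model import HPSequence, ModelParameters

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "SampleEnsemble",
    "AutocorrelationTime",
    "mc_sample_single_chain",
    "mc_sample_two_chain_window",
    "default_windows",
    "sample_two_chain_pmf",
    "estimate_pmf",
    "well_bounds_from_profile",
    "integrated_autocorrelation_time",
    "draw_well_configurations",
    "mean_radius_of_gyration",
]

#: bond length used for the initial straight-chain configuration; near the
#: minimum of the FENE + WCA bond potential for the default Kremer-Grest
#: parameters (k = 30 kBT/sigma^2, R0 = 1.5 sigma).
INITIAL_BOND_LENGTH = 0.97


@dataclass
class UmbrellaWindow:
    """One restrained sampling window in the centre-of-mass distance r.

    Hard mode (``kappa == 0``): configurations are confined to
    ``[r_lo, r_hi)``.  Harmonic mode (``kappa > 0``): a spring
    0.5*kappa*(r - r_center)^2 biases sampling around ``r_center`` and the
    bounds are ignored.  After sampling, ``states``/``r_samples``/``energies``
    hold the retained snapshots.
    """

    r_lo: float
    r_hi: float
    kappa: float = 0.0
    r_center: float | None = None
    states: np.ndarray | None = None      # (M, 2, N, 3)
    r_samples: np.ndarray | None = None   # (M,)
    energies: np.ndarray | None = None    # (M,)
    seed: int | None = None
    accepted: int = 0
    attempted: int = 0

    def __post_init__(self) -> None:
        if self.kappa == 0.0 and not (0 <= self.r_lo < self.r_hi):
            raise ValueError("hard window needs 0 <= r_lo < r_hi")
        if self.kappa > 0.0 and self.r_center is None:
            raise ValueError("harmonic window needs r_center")
        if self.r_center is None:
            self.r_center = 0.5 * (self.r_lo + self.r_hi)

    @property
    def n_samples(self) -> int:
        return 0 if self.r_samples is None else len(self.r_samples)


@dataclass
class PMFProfile:
    """Tabulated u(r)/kBT on a regular r grid, tail-anchored to zero.

    Bins never visited by the sampler carry ``u = +inf`` (an effectively
    impenetrable region at the resolution of the run).  ``well_bounds`` is
    the maximal contiguous interval around the minimum with
    u <= u_min + 1 kBT.
    """

    r_grid: np.ndarray
    u_over_kBT: np.ndarray
    statistical_error: np.ndarray
    well_bounds: tuple[float, float]
    u_min: float
    bin_width: float = field(default=0.0)
    #: part of ``statistical_error`` that is correlated across bins (stitch
    #: frame drift and the tail-anchor offset); zero for exact toy profiles
    correlated_error: np.ndarray | None = None
    #: random-walk drift bookkeeping for exact propagation into integrals:
    #: variance introduced by each stitch, and each bin's window index
    stitch_variances: np.ndarray | None = None
    bin_window: np.ndarray | None = None
    #: standard deviation of the common tail-anchor offset
    anchor_error: float = 0.0

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.u_over_kBT = np.asarray(self.u_over_kBT, dtype=float)
        self.statistical_error = np.asarray(self.statistical_error, dtype=float)
        if self.correlated_error is None:
            self.correlated_error = np.zeros_like(self.u_over_kBT)
        else:
            self.correlated_error = np.asarray(self.correlated_error, dtype=float)
        if not np.all(np.diff(self.r_grid) > 0):
            raise ValueError("r grid must be strictly increasing")
        if self.bin_width == 0.0 and len(self.r_grid) > 1:
            self.bin_width = float(np.median(np.diff(self.r_grid)))

    def in_well(self, r: np.ndarray | float) -> np.ndarray | bool:
        lo, hi = self.well_bounds
        return (np.asarray(r) >= lo) & (np.asarray(r) <= hi)


@dataclass
class SampleEnsemble:
    """Snapshots retained at a fixed stride; reproducible from the seed.

    ``states`` has shape (M, 2, N, 3) for two-chain ensembles and
    (M, N, 3) for single-chain ensembles.
    """

    states: np.ndarray
    sequence: HPSequence | None
    stride: int
    seed: int

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def com_distances(self) -> np.ndarray:
        if self.states.ndim != 4:
            raise ValueError("not a two-chain ensemble")
        coms = self.states.mean(axis=2)  # (M, 2, 3)
        return np.linalg.norm(coms[:, 0] - coms[:, 1], axis=1)


@dataclass(frozen=True)
class AutocorrelationTime:
    """Integrated autocorrelation time with degeneracy/truncation flags."""

    tau: float
    degenerate: bool = False
    truncated_at: int | None = None

    def __float__(self) -> float:
        return self.tau


# ---------------------------------------------------------------------------
# Initial configurations and kernel plumbing
# ---------------------------------------------------------------------------


def _straight_chain(n: int, origin: np.ndarray) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = (np.arange(n) - (n - 1) / 2.0) * INITIAL_BOND_LENGTH
    return coords + origin


def initial_two_chain_configuration(n: int, r: float) -> np.ndarray:
    """Two straight parallel chains offset by r perpendicular to their axis."""
    x = np.empty((2, n, 3))
    x[0] = _straight_chain(n, np.zeros(3))
    x[1] = _straight_chain(n, np.array([0.0, 0.0, max(r, 1e-3)]))
    return x


def _kernel_args(seq: HPSequence, params: ModelParameters):
    att, diam = params.resolve(seq)
    return (
        att,
        diam,
        params.epsilon,
        params.lj_cutoff,
        params.lj_shift,
        params.bond_spring_constant,
        params.bond_max_extension,
    )


def mc_sample_single_chain(
    seq: HPSequence,
    params: ModelParameters,
    n_sweeps: int,
    seed: int,
    *,
    burn_in_fraction: float = 0.1,
    stride: int = 1,
    max_displacement: float = 0.3,
    max_rotation: float = math.pi / 2,
) -> SampleEnsemble:
    """Sample one chain with bead-displacement and pivot moves."""
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    x0 = _straight_chain(seq.N, np.zeros(3))
    n_burn = int(burn_in_fraction * n_sweeps)
    states, _, _ = _kernels.run_single_chain(
        x0, *_kernel_args(seq, params), n_sweeps, n_burn, stride,
        max_displacement, max_rotation, int(seed) % 2**31,
    )
    return SampleEnsemble(states=states, sequence=seq, stride=stride, seed=int(seed))


def mean_radius_of_gyration(ensemble: SampleEnsemble) -> float:
    """Ensemble-average radius of gyration of a single-chain ensemble."""
    coords = ensemble.states
    delta = coords - coords.mean(axis=1, keepdims=True)
    rg = np.sqrt((delta**2).sum(axis=2).mean(axis=1))
    return float(rg.mean())


def mc_sample_two_chain_window(
    seq: HPSequence,
    params: ModelParameters,
    window: UmbrellaWindow,
    n_sweeps: int,
    seed: int,
    *,
    burn_in_fraction: float = 0.1,
    stride: int = 1,
    max_displacement: float = 0.3,
    max_rotation: float = math.pi / 2,
) -> UmbrellaWindow:
    """Fill one umbrella window with two-chain Metropolis samples."""
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if window.kappa > 0.0:
        r_init = float(window.r_center)
        r_lo, r_hi = 0.0, np.inf
    else:
        r_lo, r_hi = window.r_lo, window.r_hi
        r_init = 0.5 * (r_lo + min(r_hi, r_lo + 2.0))
    x0 = initial_two_chain_configuration(seq.N, r_init)
    n_burn = int(burn_in_fraction * n_sweeps)
    states, r_s, e_s, acc, att_moves = _kernels.run_two_chain_window(
        x0, *_kernel_args(seq, params),
        r_lo, r_hi, window.kappa, float(window.r_center),
        n_sweeps, n_burn, stride, max_displacement, max_rotation,
        int(seed) % 2**31,
    )
    if acc == 0:
        import warnings

        warnings.warn(
            f"window around r={window.r_center:.2f}: no accepted moves",
            RuntimeWarning,
            stacklevel=2,
        )
    filled = replace(window)
    filled.states = states
    filled.r_samples = r_s
    filled.energies = e_s
    filled.seed = int(seed)
    filled.accepted = int(acc)
    filled.attempted = int(att_moves)
    return filled


def default_windows(
    r_max: float, width: float = 1.0, step: float = 0.5, r_min: float = 0.0
) -> list[UmbrellaWindow]:
    """Overlapping hard-bound windows covering [r_min, ~r_max]."""
    windows = []
    lo = r_min
    while lo < r_max:
        windows.append(UmbrellaWindow(r_lo=lo, r_hi=lo + width))
        lo += step
    return windows


def _window_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed) % 2**31, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % 2**31)


def sample_two_chain_pmf(
    seq: HPSequence,
    params: ModelParameters,
    *,
    n_sweeps: int = 4000,
    seed: int = 0,
    r_max: float | None = None,
    window_width: float = 1.0,
    window_step: float = 0.5,
    bin_width: float = 0.1,
    **mc_kwargs,
) -> tuple[list[UmbrellaWindow], PMFProfile]:
    """Convenience driver: build windows, sample each, estimate the PMF."""
    if r_max is None:
        r_max = max(float(seq.N), params.lj_cutoff + 2.0)
    windows = default_windows(r_max, width=window_width, step=window_step)
    filled = [
        mc_sample_two_chain_window(
            seq, params, w, n_sweeps, _window_seed(seed, i), **mc_kwargs
        )
        for i, w in enumerate(windows)
    ]
    return filled, estimate_pmf(filled, bin_width=bin_width)


# ---------------------------------------------------------------------------
# PMF estimation
# ---------------------------------------------------------------------------


def _window_histogram(window: UmbrellaWindow, edges: np.ndarray):
    counts, _ = np.histogram(window.r_samples, bins=edges)
    tau = integrated_autocorrelation_time(window.r_samples).tau
    return counts.astype(float), max(tau, 1.0)


def estimate_pmf(
    windows: list[UmbrellaWindow],
    *,
    bin_width: float = 0.1,
    anchor_width: float = 1.0,
    well_depth_tolerance: float = 1.0,
) -> PMFProfile:
    """Estimate u(r)/kBT from umbrella windows.

    Per-window histograms of r are divided by the 4*pi*r^2 shell volume and
    converted to -ln(density).  Hard windows are stitched sequentially by
    matching log-densities over overlap bins (inverse-variance weighted);
    harmonic windows are combined by WHAM.  The profile is then anchored so
    its inverse-variance-weighted mean over the outermost ``anchor_width``
    of the grid is zero.  Per-bin errors come from a delta-method estimate
    with effective sample sizes n/tau, plus the anchor offset uncertainty.
    """
    windows = [w for w in windows if w.n_samples > 0]
    if not windows:
        raise ValueError("no non-empty windows")
    harmonic = any(w.kappa > 0 for w in windows)
    r_lo = min((np.min(w.r_samples) for w in windows))
    r_hi = max((np.max(w.r_samples) for w in windows))
    if not harmonic:
        r_lo = min(r_lo, min(w.r_lo for w in windows))
        r_hi = max(r_hi, max(w.r_hi for w in windows))
    n_bins = max(int(np.ceil((r_hi - r_lo) / bin_width)), 1)
    edges = r_lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    jac = 4.0 * np.pi * centers**2

    if harmonic:
        u, var = _combine_wham(windows, edges, centers, jac)
        frame_var = np.zeros_like(var)
        stitch_var = None
        bin_window = None
    else:
        u, var, frame_var, stitch_var, bin_window = _combine_stitch(
            windows, edges, centers, jac
        )

    # tail anchor over the outermost anchor_width
    anchor = centers >= (centers[-1] - anchor_width)
    ok = anchor & np.isfinite(u)
    if not np.any(ok):
        ok = np.isfinite(u)
    if not np.any(ok):
        raise ValueError("PMF has no finite bins; sampling failed everywhere")
    w_anchor = 1.0 / var[ok]
    offset = float(np.sum(w_anchor * u[ok]) / np.sum(w_anchor))
    var_anchor = 1.0 / float(np.sum(w_anchor))
    u = u - offset
    corr_var = frame_var + var_anchor
    se = np.sqrt(var + corr_var)

    well, u_min = well_bounds_from_profile(centers, u, well_depth_tolerance)
    return PMFProfile(
        r_grid=centers,
        u_over_kBT=u,
        statistical_error=se,
        well_bounds=well,
        u_min=u_min,
        bin_width=bin_width,
        correlated_error=np.sqrt(corr_var),
        stitch_variances=stitch_var,
        bin_window=bin_window,
        anchor_error=float(np.sqrt(var_anchor)),
    )


def well_bounds_from_profile(
    r: np.ndarray, u: np.ndarray, depth_tolerance: float = 1.0
) -> tuple[tuple[float, float], float]:
    """Maximal contiguous interval around the minimum with u within
    ``depth_tolerance`` (1 kBT) of the minimum (strictly, so a square well of
    depth exactly 1 kBT ends at its rim).  Returns ((r_L, r_R), u_min)."""
    finite = np.isfinite(u)
    if not np.any(finite):
        raise ValueError("profile has no finite values")
    u_min = float(np.min(u[finite]))
    i_min = int(np.flatnonzero(finite)[np.argmin(u[finite])])
    lo_i = i_min
    while lo_i > 0 and finite[lo_i - 1] and u[lo_i - 1] < u_min + depth_tolerance:
        lo_i -= 1
    hi_i = i_min
    n = len(r)
    while hi_i < n - 1 and finite[hi_i + 1] and u[hi_i + 1] < u_min + depth_tolerance:
        hi_i += 1
    return (float(r[lo_i]), float(r[hi_i])), u_min


def _combine_stitch(windows, edges, centers, jac):
    """Sequential overlap-matched stitching, left to right.

    Consecutive windows are aligned by matching their *pooled* densities
    over the jointly sampled bins (offset = log of the pooled-count ratio),
    which is nearly unbiased, unlike weighting per-bin log-densities by
    their own noisy counts.  Besides the per-bin delta-method variance,
    each stitch contributes a frame-offset variance; a bin's frame variance
    is the sum of the stitch variances separating its window from the tail
    (where the profile is anchored).
    """
    order = np.argsort([w.r_center for w in windows])
    n_w = len(order)
    n_b = len(centers)
    bin_w = edges[1] - edges[0]
    counts_all = np.empty((n_w, n_b))
    tau_all = np.empty(n_w)
    n_all = np.empty(n_w)
    for s, idx in enumerate(order):
        c, tau = _window_histogram(windows[idx], edges)
        counts_all[s] = c
        tau_all[s] = tau
        n_all[s] = windows[idx].n_samples
    # per-window profiles and variances
    with np.errstate(divide="ignore", invalid="ignore"):
        p_all = counts_all / n_all[:, None]
        u_all = -np.log(p_all / (bin_w * jac[None, :]))
    var_all = np.full_like(u_all, np.inf)
    nz_all = counts_all > 0
    # floor (1 - p) at 1/(2c) so a window falling entirely into one bin
    # does not claim infinite precision
    var_all[nz_all] = (
        np.maximum(1.0 - p_all[nz_all], 0.5 / counts_all[nz_all])
        / (counts_all / tau_all[:, None])[nz_all]
    )
    # offsets aligning each window to the frame of window 0
    offsets = np.zeros(n_w)
    stitch_var = np.zeros(n_w)
    for s in range(1, n_w):
        ov = nz_all[s - 1] & nz_all[s]
        if not np.any(ov):
            raise StitchingError(
                f"windows around r={windows[order[s]].r_center:.2f} share no "
                "sampled bins with their left neighbour"
            )
        c_prev = float(counts_all[s - 1, ov].sum())
        c_cur = float(counts_all[s, ov].sum())
        delta = np.log((c_cur / n_all[s]) / (c_prev / n_all[s - 1]))
        offsets[s] = offsets[s - 1] + delta
        stitch_var[s] = tau_all[s - 1] / c_prev + tau_all[s] / c_cur
    u_aligned = u_all + offsets[:, None]
    # inverse-variance merge per bin
    with np.errstate(divide="ignore"):
        wgt = np.where(nz_all, 1.0 / np.where(nz_all, var_all, 1.0), 0.0)
    w_sum = wgt.sum(axis=0)
    with np.errstate(invalid="ignore"):
        u = np.where(
            w_sum > 0,
            np.nansum(np.where(nz_all, wgt * u_aligned, 0.0), axis=0)
            / np.maximum(w_sum, 1e-300),
            np.inf,
        )
    var = np.where(w_sum > 0, 1.0 / np.maximum(w_sum, 1e-300), np.inf)
    # frame variance relative to the tail: suffix sums of stitch variances,
    # attributed per bin via its first contributing window
    first_win = np.full(n_b, -1, dtype=int)
    for s in range(n_w - 1, -1, -1):
        first_win[nz_all[s]] = s
    suffix = np.concatenate([np.cumsum(stitch_var[::-1])[::-1], [0.0]])
    frame_var = np.where(
        first_win >= 0, suffix[np.minimum(first_win + 1, n_w)], 0.0
    )
    return u, var, frame_var, stitch_var, first_win


def _combine_wham(windows, edges, centers, jac, n_iter: int = 2000, tol: float = 1e-10):
    n_b = len(centers)
    n_w = len(windows)
    counts = np.zeros((n_w, n_b))
    n_eff = np.zeros(n_w)
    bias = np.ones((n_w, n_b))
    for wi, w in enumerate(windows):
        c, tau = _window_histogram(w, edges)
        counts[wi] = c / tau
        n_eff[wi] = w.n_samples / tau
        if w.kappa > 0:
            bias[wi] = np.exp(-0.5 * w.kappa * (centers - w.r_center) ** 2)
        else:
            bias[wi] = ((centers >= w.r_lo) & (centers < w.r_hi)).astype(float)
    total = counts.sum(axis=0)
    f = np.zeros(n_w)
    rho = np.full(n_b, 1.0 / n_b)
    for _ in range(n_iter):
        denom = (n_eff[:, None] * bias * np.exp(f)[:, None]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho_new = np.where(denom > 0, total / denom, 0.0)
        z = (bias * rho_new[None, :]).sum(axis=1)
        f_new = -np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            rho = rho_new
            break
        f = f_new
        rho = rho_new
    with np.errstate(divide="ignore", invalid="ignore"):
        u = -np.log(rho / jac)
    var = np.where(total > 0, 1.0 / np.maximum(total, 1e-300), np.inf)
    u = np.where(total > 0, u, np.inf)
    return u, var


# ---------------------------------------------------------------------------
# Decorrelation
# ---------------------------------------------------------------------------


def integrated_autocorrelation_time(series: np.ndarray) -> AutocorrelationTime:
    """Integrated autocorrelation time tau = 1 + 2*sum(rho(t)).

    The sum is truncated at the first non-positive autocorrelation (initial
    positive-sequence truncation).  A constant series is degenerate and
    returns tau = 1 with the flag set.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return AutocorrelationTime(1.0, degenerate=True)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        return AutocorrelationTime(1.0, degenerate=True)
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n].real
    rho = acf / acf[0]
    max_lag = n // 2
    tau = 1.0
    truncated_at = None
    for t in range(1, max_lag):
        if rho[t] <= 0.0:
            truncated_at = t
            break
        tau += 2.0 * rho[t]
    return AutocorrelationTime(max(tau, 1.0), truncated_at=truncated_at)


def draw_well_configurations(
    windows: list[UmbrellaWindow],
    pmf: PMFProfile,
    n_configs: int,
    seed: int,
    *,
    rc: float = 3.0,
) -> SampleEnsemble:
    """Decorrelated two-chain configurations from the attractive PMF well.

    Snapshots with r inside ``pmf.well_bounds`` are pooled across windows,
    thinned at a stride no smaller than the integrated autocorrelation time
    of the interchain contact count (the observable that feeds the contact
    map), and the first ``n_configs`` survivors are returned.  Raises
    :class:`SamplingShortfallError` if too few remain.
    """
    lo, hi = pmf.well_bounds
    pool = []
    taus = [1.0]
    for w in sorted(
        (w for w in windows if w.n_samples > 0), key=lambda w: w.r_center
    ):
        mask = (w.r_samples >= lo) & (w.r_samples <= hi)
        if np.any(mask):
            states = w.states[mask]
            pool.append(states)
            # decorrelation measured per window: windows are independent
            # runs, so a cross-window series would alias the r-dependence
            # of the contact count into a spurious correlation time
            if len(states) >= 50:
                counts = _kernels.interchain_contact_counts(states, rc)
                taus.append(integrated_autocorrelation_time(counts).tau)
    if not pool:
        raise SamplingShortfallError(n_configs, 0)
    stride = max(1, int(np.ceil(max(taus))))
    rng = np.random.default_rng(int(seed))
    thinned = [chunk[int(rng.integers(stride))::stride] for chunk in pool]
    pooled = np.concatenate(thinned, axis=0)
    if len(pooled) < n_configs:
        raise SamplingShortfallError(n_configs, len(pooled))
    return SampleEnsemble(
        states=pooled[:n_configs],
        sequence=None,
        stride=stride,
        seed=int(seed),
    )
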