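"""Second virial coefficient B22 from a PMF, and epsilon-matching.

B22 = 2*pi * integral_0^inf [1 - exp(-u(r)/kBT)] r^2 dr, in units of sigma^3.
Negative B22 means net interchain attraction.  The dataset-construction
protocol tunes the hydrophobic well depth epsilon/kBT independently for each
sequence until its B22 matches a prescribed target, so that sequences with
identical overall two-body attraction can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import BracketError, TailAnchorError
from .model import HPSequence, ModelParameters
from .sampler import PMFProfile, sample_two_chain_pmf

__all__ = ["B22Result", "MatchResult", "compute_b22", "match_b22", "U_CAP"]

#: PMF values above this cap (in kBT) are treated as an impenetrable core:
#: exp(-50) is far below double-precision relevance in the integrand.
U_CAP = 50.0


@dataclass(frozen=True)
class B22Result:
    """B22 in sigma^3 with a linearly propagated statistical error."""

    value: float
    statistical_error: float
    quadrature_grid: np.ndarray
    tail_truncation_radius: float

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class MatchResult:
    epsilon: float
    achieved_b22: B22Result
    target_b22: float
    iterations: int
    converged: bool


def compute_b22(pmf: PMFProfile, *, tail_tolerance: float = 0.05) -> B22Result:
    """Composite-trapezoid quadrature of Eq. B22 = 2*pi*int [1-e^(-u)] r^2 dr.

    The PMF must be tail-anchored: the mean of u over the outermost grid
    region (|mean| <= ``tail_tolerance``) is checked and the integrand is
    treated as exactly zero beyond the last grid point.  Bins with u above
    ``U_CAP`` (including +inf for unvisited core bins) contribute the
    hard-core integrand 1.  Per-bin statistical errors are propagated
    linearly: d(B22)/d(u_i) = 2*pi*e^(-u_i)*r_i^2*w_i with trapezoid
    weights w_i; independent per-bin errors add in quadrature while the
    correlated component (stitch drift + anchor offset, when present)
    adds linearly across bins.
    """
    r = pmf.r_grid
    u = np.asarray(pmf.u_over_kBT, dtype=float)
    se = np.asarray(pmf.statistical_error, dtype=float)
    if not np.all(np.diff(r) > 0):
        raise ValueError("quadrature grid must be strictly increasing")
    corr = (
        np.asarray(pmf.correlated_error, dtype=float)
        if pmf.correlated_error is not None
        else np.zeros_like(se)
    )
    corr = np.where(np.isfinite(corr), corr, 0.0)
    total = np.where(np.isfinite(se), se, 0.0)
    indep = np.sqrt(np.maximum(total**2 - corr**2, 0.0))
    tail = r >= r[-1] - max(pmf.bin_width * 5, 1.0)
    tail_ok = tail & np.isfinite(u)
    if np.any(tail_ok):
        # inverse-variance weighting (independent errors) matches how a
        # sampled profile is anchored; exact profiles reduce to a plain mean
        wts = 1.0 / np.maximum(indep[tail_ok], 1e-12) ** 2
        if not np.all(np.isfinite(wts)):
            wts = np.ones_like(wts)
        tail_mean = float(np.sum(wts * u[tail_ok]) / np.sum(wts))
    else:
        tail_mean = np.inf
    if not np.isfinite(tail_mean) or abs(tail_mean) > tail_tolerance:
        raise TailAnchorError(
            f"PMF tail is not anchored to zero (mean u over the outermost "
            f"region = {tail_mean:.3g}); cannot integrate to infinity"
        )
    capped = ~np.isfinite(u) | (u > U_CAP)
    integrand = np.where(capped, 1.0, -np.expm1(-np.where(capped, 0.0, u)))
    # extend to r = 0 with a hard-core integrand if the grid starts above 0
    if r[0] > 0:
        r_ext = np.concatenate([[0.0], r])
        f_ext = np.concatenate([[integrand[0] if capped[0] else 1.0], integrand])
    else:
        r_ext, f_ext = r, integrand
    value = 2.0 * np.pi * np.trapezoid(f_ext * r_ext**2, r_ext)

    # trapezoid weights for error propagation (original grid only)
    w = np.zeros_like(r)
    if len(r) > 1:
        dr = np.diff(r)
        w[:-1] += 0.5 * dr
        w[1:] += 0.5 * dr
    sens = 2.0 * np.pi * np.exp(-np.clip(u, None, U_CAP)) * r**2 * w
    sens[capped] = 0.0
    err_sq = float(np.sum((sens * indep) ** 2))
    if pmf.stitch_variances is not None and pmf.bin_window is not None:
        # random-walk drift: stitch s shifts every bin whose window lies to
        # its left relative to the tail anchor, so its contribution is
        # var_s * (total sensitivity on that side)^2; the anchor offset is
        # common to all bins
        sv = np.asarray(pmf.stitch_variances, dtype=float)
        bw = np.asarray(pmf.bin_window)
        for s in range(1, len(sv)):
            s_left = float(np.sum(sens[(bw >= 0) & (bw < s)]))
            err_sq += sv[s] * s_left**2
        err_sq += (pmf.anchor_error * float(np.sum(sens))) ** 2
    else:
        err_sq += float(np.sum(sens * corr)) ** 2
    err = float(np.sqrt(err_sq))
    return B22Result(
        value=float(value),
        statistical_error=err,
        quadrature_grid=r,
        tail_truncation_radius=float(r[-1]),
    )


def _default_b22_of_epsilon(
    seq: HPSequence,
    params: ModelParameters,
    n_sweeps: int,
    seed: int,
    **pmf_kwargs,
) -> Callable[[float], B22Result]:
    def evaluate(eps: float) -> B22Result:
        _, pmf = sample_two_chain_pmf(
            seq, params.with_epsilon(eps), n_sweeps=n_sweeps, seed=seed, **pmf_kwargs
        )
        return compute_b22(pmf)

    return evaluate


def match_b22(
    seq: HPSequence,
    target: float,
    *,
    tolerance: float,
    eps_bracket: tuple[float, float] = (0.0, 6.0),
    params: ModelParameters | None = None,
    n_sweeps: int = 4000,
    seed: int = 0,
    max_iterations: int = 40,
    b22_of_epsilon: Callable[[float], B22Result] | None = None,
    **pmf_kwargs,
) -> MatchResult:
    """Tune epsilon/kBT by bisection until B22(epsilon) matches ``target``.

    B22 is monotonically decreasing in epsilon (stronger H-H attraction makes
    the chains stickier), so bisection on a bracket whose endpoint B22 values
    straddle the target is robust to the statistical noise of each estimate.
    Convergence means |B22 - target| <= max(tolerance, 1 SE) of the estimate,
    operationalising "matched to within statistical error".

    ``b22_of_epsilon`` overrides the default sampled evaluator; it must map
    epsilon to a :class:`B22Result` (used, e.g., with closed-form toy models).
    """
    if target >= 0:
        raise ValueError(
            "target B22 must be negative: matching relies on attractive H-H "
            "interactions overcoming the repulsive core"
        )
    if params is None:
        params = ModelParameters()
    if b22_of_epsilon is None:
        b22_of_epsilon = _default_b22_of_epsilon(seq, params, n_sweeps, seed, **pmf_kwargs)

    lo, hi = eps_bracket
    if not lo < hi:
        raise ValueError("eps_bracket must be an increasing interval")
    b_lo = b22_of_epsilon(lo)
    iterations = 1
    if _close(b_lo, target, tolerance):
        return MatchResult(lo, b_lo, target, iterations, True)
    b_hi = b22_of_epsilon(hi)
    iterations += 1
    if _close(b_hi, target, tolerance):
        return MatchResult(hi, b_hi, target, iterations, True)
    # B22 decreases with epsilon: need B22(lo) > target > B22(hi)
    if not (b_lo.value > target > b_hi.value):
        raise BracketError(
            f"bracket does not straddle target: B22({lo})={b_lo.value:.4g}, "
            f"B22({hi})={b_hi.value:.4g}, target={target:.4g}"
        )
    best = (lo, b_lo) if abs(b_lo.value - target) < abs(b_hi.value - target) else (hi, b_hi)
    while iterations < max_iterations:
        mid = 0.5 * (lo + hi)
        b_mid = b22_of_epsilon(mid)
        iterations += 1
        if abs(b_mid.value - target) < abs(best[1].value - target):
            best = (mid, b_mid)
        if _close(b_mid, target, tolerance):
            return MatchResult(mid, b_mid, target, iterations, True)
        if b_mid.value > target:
            lo = mid
        else:
            hi = mid
    return MatchResult(best[0], best[1], target, iterations, False)


def _close(b: B22Result, target: float, tolerance: float) -> bool:
    return abs(b.value - target) <= max(tolerance, b.statistical_error)
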