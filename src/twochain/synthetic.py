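"""Synthetic fixtures: toy PMFs, contact maps with prescribed spectra, and
labelled feature datasets.

These generators exercise the mathematics of the pipeline (the virial
integral, Parseval accounting, split sums, explained-variance curves, and
the classifiers) without any chain sampling.  They emulate the *structure*
of real data — tail-anchored PMFs with closed-form B22, symmetric maps with
chosen power spectra, feature tables whose binary label tracks the
contact-map variance up to controllable label noise — not its physics; the
labelled datasets follow the empirical convention that higher contact-map
variance accompanies aggregation rather than phase separation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap, contact_stats
from .model import HPSequence
from .sampler import PMFProfile, well_bounds_from_profile
from .spectral import (
    K_DECIMALS,
    PowerSpectrum,
    ev_curves,
    power_spectrum,
    split_sum,
    wavenumber_grid,
)

__all__ = [
    "ToyPMFSpec",
    "SyntheticMapSpec",
    "SyntheticDatasetSpec",
    "make_toy_pmf",
    "closed_form_b22",
    "make_synthetic_map",
    "make_labeled_dataset",
    "make_gaussian_feature_table",
    "random_hp_sequence",
]

#: finite stand-in for an impenetrable core in tabulated toy PMFs
HARD_CORE_U = 1.0e6


@dataclass(frozen=True)
class ToyPMFSpec:
    """A closed-form toy PMF: hard sphere, square well, or Gaussian well.

    ``d`` is the hard-core diameter, ``lam`` the square-well range factor
    (> 1), ``depth`` the well depth in kBT, ``r0``/``width`` the Gaussian
    well centre and standard deviation.  ``n_points`` sets the grid
    resolution on [0, r_max].
    """

    kind: str  # hard_sphere | square_well | gaussian_well
    d: float = 1.0
    lam: float = 1.5
    depth: float = 1.0
    r0: float = 2.0
    width: float = 0.3
    r_max: float | None = None
    n_points: int = 10_001

    def __post_init__(self) -> None:
        if self.kind not in ("hard_sphere", "square_well", "gaussian_well"):
            raise ValueError(f"unknown toy PMF kind {self.kind!r}")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.kind == "square_well" and self.lam <= 1:
            raise ValueError("square well needs lam > 1")

    @property
    def effective_r_max(self) -> float:
        if self.r_max is not None:
            return self.r_max
        if self.kind == "hard_sphere":
            return 3.0 * self.d
        if self.kind == "square_well":
            return self.lam * self.d + 1.5
        return self.r0 + 8.0 * self.width


def make_toy_pmf(spec: ToyPMFSpec) -> PMFProfile:
    """Tabulate a toy PMF honouring the profile contract (tail-anchored,
    well bounds per the 1-kBT rule, hard cores as a large finite cap)."""
    r = np.linspace(0.0, spec.effective_r_max, spec.n_points)
    if spec.kind == "hard_sphere":
        u = np.where(r < spec.d, HARD_CORE_U, 0.0)
    elif spec.kind == "square_well":
        u = np.where(
            r < spec.d, HARD_CORE_U, np.where(r < spec.lam * spec.d, -spec.depth, 0.0)
        )
    else:
        u = -spec.depth * np.exp(-((r - spec.r0) ** 2) / (2.0 * spec.width**2))
    # drop r = 0 (the Jacobian vanishes there and the grid must be positive
    # for quadrature weights anyway)
    r, u = r[1:], u[1:]
    well, u_min = well_bounds_from_profile(r, np.where(u >= HARD_CORE_U, np.inf, u))
    return PMFProfile(
        r_grid=r,
        u_over_kBT=u,
        statistical_error=np.zeros_like(u),
        well_bounds=well,
        u_min=u_min,
    )


def closed_form_b22(spec: ToyPMFSpec) -> float:
    """Analytic B22 for the hard-sphere and square-well toys (sigma^3)."""
    hs = 2.0 * np.pi * spec.d**3 / 3.0
    if spec.kind == "hard_sphere":
        return hs
    if spec.kind == "square_well":
        return hs * (1.0 - (spec.lam**3 - 1.0) * math.expm1(spec.depth))
    raise ValueError("no closed form for this kind")


# ---------------------------------------------------------------------------
# Synthetic contact maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMapSpec:
    """A symmetric map with prescribed aggregated power per wavenumber.

    ``target_power`` maps wavenumber k -> contribution to Var(C) (variance
    units; the raw Fourier power is N^4 times larger).  Phases are random;
    per-wavenumber aggregated power is deterministic, so two seeds give
    different maps with identical attained spectra whenever the target fits
    in [0, 1] around ``base_mean``.
    """

    N: int
    target_power: dict[float, float] = field(default_factory=dict)
    base_mean: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0 < self.base_mean < 1:
            raise ValueError("base_mean must be inside (0, 1)")
        if any(v < 0 for v in self.target_power.values()):
            raise ValueError("target power must be non-negative")


def make_synthetic_map(spec: SyntheticMapSpec) -> tuple[ContactMap, PowerSpectrum]:
    """Build the map and return it with its attained aggregated spectrum.

    A random symmetric matrix provides Hermitian- and transpose-symmetric
    phases; mode magnitudes are rescaled so each requested wavenumber group
    carries exactly its target power, all other modes are zeroed, and the
    zero-mean field is shifted to ``base_mean``.  If the field cannot fit in
    [0, 1] it is rescaled to fit (with a warning) and the attained spectrum
    reflects that.
    """
    n = spec.N
    rng = np.random.default_rng(int(spec.seed))
    a = rng.standard_normal((n, n))
    f = np.fft.fft2(a + a.T)
    k = wavenumber_grid(n)
    mask_total = np.zeros((n, n), dtype=bool)
    for k_target, power in spec.target_power.items():
        kt = round(float(k_target), K_DECIMALS)
        if kt <= 0:
            raise ValueError("target wavenumbers must be positive (k=0 is the mean)")
        group = k == kt
        if not np.any(group):
            raise ValueError(f"wavenumber {k_target} does not exist for N={n}")
        raw_target = power * n**4
        group_power = float(np.sum(np.abs(f[group]) ** 2))
        scale = 0.0 if group_power == 0 else np.sqrt(raw_target / group_power)
        f[group] *= scale
        mask_total |= group
    f[~mask_total] = 0.0
    delta = np.fft.ifft2(f).real
    lo, hi = float(delta.min()), float(delta.max())
    margin = 1e-9
    scale = 1.0
    if hi > 0 and spec.base_mean + hi > 1 - margin:
        scale = min(scale, (1 - margin - spec.base_mean) / hi)
    if lo < 0 and spec.base_mean + lo < margin:
        scale = min(scale, (spec.base_mean - margin) / (-lo))
    if scale < 1.0:
        warnings.warn(
            f"target spectrum does not fit in [0, 1] around mean "
            f"{spec.base_mean}; rescaled by {scale:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        delta = delta * scale
    cmap = ContactMap(
        matrix=spec.base_mean + 0.5 * (delta + delta.T),
        n_configs=0,
        rc=float("nan"),
        sequence_id=f"synthetic-{spec.seed}",
    )
    return cmap, power_spectrum(cmap)


# ---------------------------------------------------------------------------
# Labelled datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """A labelled dataset in which the label tracks contact-map variance.

    Per sequence, a variance level is drawn from one of two overlapping
    lognormal distributions, a map with that total power is synthesised with
    a smoothly decaying spectrum, and the label is 1 (phase separating) when
    the *computed* contact-map variance falls below ``variance_threshold``,
    then flipped with probability ``label_flip_q``.
    """

    n_sequences: int = 300
    N: int = 20
    base_mean: float = 0.4
    variance_levels: tuple[float, float] = (0.004, 0.012)
    level_sigma: float = 0.45
    variance_threshold: float = 0.008
    label_flip_q: float = 0.0
    k_dagger: float = 2.0
    spectral_decay: float = 2.0
    seed: int = 0
    class_cap: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.label_flip_q <= 0.5:
            raise ValueError("label_flip_q must be in [0, 0.5]")
        if self.n_sequences < 4:
            raise ValueError("need at least 4 sequences")


def _one_synthetic_entry(
    ds: SyntheticDatasetSpec, rng: np.random.Generator, index: int
) -> tuple[dict, ContactMap]:
    intent = int(rng.integers(2))
    level = ds.variance_levels[intent]
    v_target = float(
        np.exp(np.log(level) + ds.level_sigma * rng.standard_normal())
    )
    uniq = np.unique(wavenumber_grid(ds.N))
    uniq = uniq[uniq > 0]
    weights = np.exp(-uniq / ds.spectral_decay) * rng.uniform(0.5, 1.5, len(uniq))
    weights /= weights.sum()
    target = {float(k): v_target * w for k, w in zip(uniq, weights)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cmap, spec = make_synthetic_map(
            SyntheticMapSpec(
                N=ds.N,
                target_power=target,
                base_mean=ds.base_mean,
                seed=int(rng.integers(2**31)),
            )
        )
    stats = contact_stats(cmap)
    split = split_sum(spec, ds.k_dagger)
    curves = ev_curves(spec)
    label = int(stats.variance < ds.variance_threshold)
    if rng.random() < ds.label_flip_q:
        label = 1 - label
    row = {
        "sequence_id": f"synth-{index:04d}",
        "contact_mean": stats.mean,
        "contact_variance": stats.variance,
        "S_leq": split.S_leq,
        "S_gt": split.S_gt,
        "divergence_index": curves.divergence_index,
        "label": label,
    }
    return row, cmap


def make_labeled_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[pd.DataFrame, list[ContactMap]]:
    """Feature table plus the underlying maps.

    All features are computed through the contact-map and spectral modules
    from the synthesised maps — never shortcut from the generating
    parameters.  Regenerates (bounded) until both classes are present.
    """
    for attempt in range(spec.class_cap):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(spec.seed) % 2**31, spawn_key=(attempt,))
        )
        rows, maps = [], []
        for i in range(spec.n_sequences):
            row, cmap = _one_synthetic_entry(spec, rng, i)
            rows.append(row)
            maps.append(cmap)
        df = pd.DataFrame(rows)
        if df["label"].nunique() == 2:
            return df, maps
    raise RuntimeError(
        f"failed to realise both classes in {spec.class_cap} attempts"
    )


def make_gaussian_feature_table(
    n: int, delta: float = 1.0, sd: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Two-Gaussian benchmark table: class-conditional feature N(+/-delta, sd).

    The population ROC-AUC of ranking by the feature is
    Phi(2*delta / sqrt(2*sd^2)) — the closed form used to sanity-check the
    split-evaluation machinery.
    """
    rng = np.random.default_rng(int(seed))
    y = rng.integers(2, size=n)
    x = rng.normal(loc=np.where(y == 1, delta, -delta), scale=sd)
    return pd.DataFrame(
        {"sequence_id": [f"g-{i:04d}" for i in range(n)], "feature": x, "label": y}
    )


def random_hp_sequence(
    N: int, hydrophobic_fraction: float, seed: int, sequence_id: str | None = None
) -> HPSequence:
    """Random HP sequence with exactly round(fraction * N) H monomers."""
    if not 0 <= hydrophobic_fraction <= 1:
        raise ValueError("hydrophobic_fraction must be in [0, 1]")
    n_h = int(round(hydrophobic_fraction * N))
    rng = np.random.default_rng(int(seed))
    positions = rng.choice(N, size=n_h, replace=False)
    chars = np.full(N, "P")
    chars[positions] = "H"
    if sequence_id is None:
        sequence_id = f"hp-{N}-{n_h}-{seed}"
    return HPSequence(id=sequence_id, monomers="".join(chars))
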