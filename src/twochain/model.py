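"""Minimal hydrophobic-polar (HP) heteropolymer model.

A heteropolymer is a Kremer-Grest bead-spring chain whose beads are either
hydrophobic (H) or polar (P).  H-H pairs attract through a Lennard-Jones
potential of tunable well depth ``epsilon`` (in units of kBT); any pair that
involves a P bead interacts through the purely repulsive
Weeks-Chandler-Andersen (WCA) potential.  All energies are expressed in kBT
and all lengths in units of the bead diameter sigma, so the temperature never
appears explicitly.

The H-H potential is stored in its WCA-decomposed form

    u_HH(r) = u_WCA(r) + epsilon * u_tail(r),

where ``u_tail`` is the attractive branch of the unit-depth Lennard-Jones
potential, truncated and shifted to zero at the cutoff (3 sigma by default).
At ``epsilon = 1`` this is identical to the truncated-and-shifted
Lennard-Jones potential, and at ``epsilon = 0`` it reduces exactly to WCA,
so the attraction strength can be dialled continuously without touching the
repulsive core.

Other pairwise models (e.g. residue-level coarse-grained IDP models) plug in
through :class:`PairPotential`: any callable ``(r, type_i, type_j) -> energy``
with a declared finite ``cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MonomerType",
    "HPSequence",
    "ModelParameters",
    "ChainConfiguration",
    "TwoChainState",
    "PairPotential",
    "pair_energy",
    "bond_energy",
    "total_energy",
    "radius_of_gyration",
    "BondOverstretchError",
    "DEFAULT_MONOMER_TYPES",
]

R_MIN_FACTOR = 2.0 ** (1.0 / 6.0)  # location of the LJ minimum, in sigma


class BondOverstretchError(ValueError):
    """A bonded pair exceeds the maximum FENE extension."""


@dataclass(frozen=True)
class MonomerType:
    """A monomer species: single-character label, size and interaction class.

    ``charge`` is carried for plug-in models; the HP model ignores it.
    """

    label: str
    diameter: float = 1.0
    interaction_class: str = "repulsive"  # "attractive" or "repulsive"
    charge: float = 0.0

    def __post_init__(self) -> None:
        if len(self.label) != 1:
            raise ValueError(f"monomer label must be one character, got {self.label!r}")
        if self.diameter <= 0:
            raise ValueError("monomer diameter must be positive")
        if self.interaction_class not in ("attractive", "repulsive"):
            raise ValueError(f"unknown interaction class {self.interaction_class!r}")

    @property
    def is_attractive(self) -> bool:
        return self.interaction_class == "attractive"


DEFAULT_MONOMER_TYPES: Mapping[str, MonomerType] = {
    "H": MonomerType("H", 1.0, "attractive"),
    "P": MonomerType("P", 1.0, "repulsive"),
}


@dataclass(frozen=True)
class HPSequence:
    """A heteropolymer sequence: an id plus an ordered string of type labels."""

    id: str
    monomers: str

    def __post_init__(self) -> None:
        if len(self.monomers) < 1:
            raise ValueError("a sequence needs at least one monomer")

    @property
    def N(self) -> int:
        return len(self.monomers)

    def hydrophobic_fraction(self) -> float:
        return self.monomers.count("H") / self.N


@dataclass(frozen=True)
class ModelParameters:
    """Reduced-unit parameters of the bead-spring model.

    epsilon
        H-H attraction well depth, in kBT (dimensionless epsilon/kBT).
    lj_cutoff
        Cutoff of the attractive Lennard-Jones branch, in units of the pair
        diameter (3 by default, matching the contact-map cutoff rc = 3 sigma).
    bond_spring_constant, bond_max_extension
        Kremer-Grest FENE parameters k = 30 kBT/sigma^2 and R0 = 1.5 sigma.
    """

    epsilon: float = 1.0
    lj_cutoff: float = 3.0
    bond_spring_constant: float = 30.0
    bond_max_extension: float = 1.5
    temperature: float = 1.0  # energies are in kBT; kept for bookkeeping
    monomer_types: Mapping[str, MonomerType] = field(
        default_factory=lambda: dict(DEFAULT_MONOMER_TYPES)
    )

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        dmax = max((t.diameter for t in self.monomer_types.values()), default=1.0)
        if self.lj_cutoff * dmax <= dmax:
            raise ValueError("lj_cutoff must exceed the pair diameter")
        if self.bond_max_extension <= 1.0:
            raise ValueError("bond_max_extension must exceed the bead diameter")

    @property
    def lj_shift(self) -> float:
        """Unit-depth LJ value at the cutoff; subtracted so u(cutoff) = 0."""
        c6 = self.lj_cutoff ** -6
        return 4.0 * (c6 * c6 - c6)

    def with_epsilon(self, epsilon: float) -> "ModelParameters":
        return replace(self, epsilon=epsilon)

    # --- sequence resolution -------------------------------------------------

    def resolve(self, seq: HPSequence) -> tuple[np.ndarray, np.ndarray]:
        """Per-bead (attractive-mask, diameter) arrays for a sequence."""
        try:
            types = [self.monomer_types[c] for c in seq.monomers]
        except KeyError as exc:
            raise KeyError(
                f"sequence {seq.id!r} uses undefined monomer label {exc.args[0]!r}"
            ) from None
        att = np.array([t.is_attractive for t in types], dtype=bool)
        diam = np.array([t.diameter for t in types], dtype=float)
        return att, diam


@runtime_checkable
class PairPotential(Protocol):
    """Plug-in contract: pairwise energy with a declared finite cutoff."""

    cutoff: float

    def __call__(
        self, r: np.ndarray | float, type_i: MonomerType, type_j: MonomerType
    ) -> np.ndarray | float: ...


@dataclass
class ChainConfiguration:
    """Bead coordinates of one chain, shape (N, 3), in sigma units."""

    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")

    @property
    def N(self) -> int:
        return self.coordinates.shape[0]

    def center_of_mass(self) -> np.ndarray:
        return self.coordinates.mean(axis=0)


@dataclass
class TwoChainState:
    """Two homotypic chains plus their center-of-mass separation r."""

    chain_a: ChainConfiguration
    chain_b: ChainConfiguration
    sequence: HPSequence

    def __post_init__(self) -> None:
        if self.chain_a.N != self.sequence.N or self.chain_b.N != self.sequence.N:
            raise ValueError("chain lengths must match the sequence length")

    @property
    def com_distance(self) -> float:
        delta = self.chain_a.center_of_mass() - self.chain_b.center_of_mass()
        return float(np.linalg.norm(delta))


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------


def _wca(r: np.ndarray, sigma: float) -> np.ndarray:
    """Unit-strength WCA: LJ truncated at 2^(1/6) sigma, shifted so min = 0."""
    r = np.asarray(r, dtype=float)
    u = np.zeros_like(r)
    inside = r < R_MIN_FACTOR * sigma
    if np.any(inside):
        x6 = (sigma / r[inside]) ** 6
        u[inside] = 4.0 * (x6 * x6 - x6) + 1.0
    return u


def _lj_tail(r: np.ndarray, sigma: float, params: ModelParameters) -> np.ndarray:
    """Attractive branch of unit-depth LJ, truncated and shifted at the cutoff."""
    r = np.asarray(r, dtype=float)
    u = np.zeros_like(r)
    shift = params.lj_shift
    rmin = R_MIN_FACTOR * sigma
    rcut = params.lj_cutoff * sigma
    core = r < rmin
    mid = (r >= rmin) & (r < rcut)
    u[core] = -1.0 - shift
    if np.any(mid):
        x6 = (sigma / r[mid]) ** 6
        u[mid] = 4.0 * (x6 * x6 - x6) - shift
    return u


def pair_energy(
    r_ij: np.ndarray | float,
    type_i: MonomerType,
    type_j: MonomerType,
    params: ModelParameters,
) -> np.ndarray | float:
    """Nonbonded pair energy in kBT.

    H-H pairs: WCA core plus ``epsilon`` times the truncated-shifted LJ tail
    (identically the truncated-shifted LJ of depth epsilon when epsilon = 1).
    Any pair involving a P bead: WCA only.  Continuous at every cutoff.
    """
    scalar = np.isscalar(r_ij)
    r = np.atleast_1d(np.asarray(r_ij, dtype=float))
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sigma = 0.5 * (type_i.diameter + type_j.diameter)
    u = _wca(r, sigma)
    if type_i.is_attractive and type_j.is_attractive:
        u = u + params.epsilon * _lj_tail(r, sigma, params)
    return float(u[0]) if scalar else u


def bond_energy(
    r_ij: np.ndarray | float, params: ModelParameters, sigma: float = 1.0
) -> np.ndarray | float:
    """Kremer-Grest bonded energy: FENE spring plus WCA core, in kBT.

    Diverges logarithmically as r -> bond_max_extension; raises
    :class:`BondOverstretchError` at or beyond it.
    """
    scalar = np.isscalar(r_ij)
    r = np.atleast_1d(np.asarray(r_ij, dtype=float))
    if np.any(r <= 0):
        raise ValueError("bond distance must be positive")
    r0 = params.bond_max_extension * sigma
    if np.any(r >= r0):
        raise BondOverstretchError(
            f"bond length {float(np.max(r)):.4f} >= max extension {r0:.4f}"
        )
    k = params.bond_spring_constant
    u = -0.5 * k * r0 * r0 * np.log1p(-((r / r0) ** 2)) + _wca(r, sigma)
    return float(u[0]) if scalar else u


def _chain_energy(
    coords: np.ndarray,
    types: list[MonomerType],
    params: ModelParameters,
    pair_potential: Callable | None,
) -> float:
    """Bonded terms plus intrachain nonbonded terms (|i-j| >= 2)."""
    n = coords.shape[0]
    e = 0.0
    for i in range(n - 1):
        d = float(np.linalg.norm(coords[i + 1] - coords[i]))
        sigma = 0.5 * (types[i].diameter + types[i + 1].diameter)
        e += float(bond_energy(d, params, sigma=sigma))
    for i in range(n):
        for j in range(i + 2, n):
            d = float(np.linalg.norm(coords[j] - coords[i]))
            if pair_potential is None:
                e += float(pair_energy(d, types[i], types[j], params))
            else:
                e += float(pair_potential(d, types[i], types[j]))
    return e


def total_energy(
    state: TwoChainState,
    params: ModelParameters,
    pair_potential: Callable | None = None,
) -> float:
    """Total energy of a two-chain state, in kBT.

    Sum of the bonded terms within each chain, intrachain nonbonded terms for
    pairs separated by two or more bonds (bonded neighbours interact only
    through the bond potential), and all interchain nonbonded terms.
    """
    types = [params.monomer_types[c] for c in state.sequence.monomers]
    xa, xb = state.chain_a.coordinates, state.chain_b.coordinates
    e = _chain_energy(xa, types, params, pair_potential)
    e += _chain_energy(xb, types, params, pair_potential)
    d = cdist(xa, xb)
    for i in range(state.sequence.N):
        for j in range(state.sequence.N):
            if pair_potential is None:
                e += float(pair_energy(d[i, j], types[i], types[j], params))
            else:
                e += float(pair_potential(d[i, j], types[i], types[j]))
    return e


def radius_of_gyration(conf: ChainConfiguration | np.ndarray) -> float:
    """Root-mean-square distance of the beads from their centroid."""
    coords = conf.coordinates if isinstance(conf, ChainConfiguration) else np.asarray(conf, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one bead")
    delta = coords - coords.mean(axis=0)
    return float(np.sqrt((delta**2).sum(axis=1).mean()))
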