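"""Interchain contact maps and their first- and second-moment statistics.

The contact map C is an N x N matrix whose entry C_ij is the fraction of
decorrelated PMF-well configurations in which bead i of one chain lies
within the cutoff rc of bead j of the other chain (strict inequality,
centre-to-centre distance).  Because the two chains carry the same sequence
and are exchangeable, C is symmetrised with its transpose.  The default
cutoff rc = 3 sigma coincides with the cutoff of the hydrophobic
Lennard-Jones attraction; for other models rc is a hyperparameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampler import SampleEnsemble

__all__ = ["ContactMap", "ContactStats", "compute_contact_map", "contact_stats"]


@dataclass
class ContactMap:
    """Symmetric N x N matrix of interchain contact frequencies in [0, 1]."""

    matrix: np.ndarray
    n_configs: int
    rc: float
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        validate_contact_matrix(self.matrix)

    @property
    def N(self) -> int:
        return self.matrix.shape[0]


def validate_contact_matrix(c: np.ndarray, tol: float = 1e-8) -> None:
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("contact map must be a square matrix")
    if np.any(c < -tol) or np.any(c > 1 + tol):
        bad = np.argwhere((c < -tol) | (c > 1 + tol))[0]
        raise ValueError(
            f"contact map entry ({bad[0]}, {bad[1]}) = {c[bad[0], bad[1]]!r} "
            "outside [0, 1]"
        )
    if not np.allclose(c, c.T, atol=tol):
        raise ValueError("contact map is not symmetric")


@dataclass(frozen=True)
class ContactStats:
    """Population mean and variance over the N^2 entries of a contact map."""

    mean: float
    variance: float


def compute_contact_map(
    ensemble: SampleEnsemble, rc: float, sequence_id: str | None = None
) -> ContactMap:
    """Contact frequencies over a two-chain ensemble at cutoff rc.

    C_ij = fraction of configurations with |x_i^A - x_j^B| < rc, then
    symmetrised as (C + C^T)/2 to remove the arbitrary chain labelling.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    states = ensemble.states
    if states.ndim != 4 or states.shape[1] != 2:
        raise ValueError("need a two-chain ensemble with states (M, 2, N, 3)")
    a = states[:, 0]  # (M, N, 3)
    b = states[:, 1]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)  # (M, N, N)
    c = (d < rc).mean(axis=0)
    c = 0.5 * (c + c.T)
    if sequence_id is None:
        sequence_id = ensemble.sequence.id if ensemble.sequence is not None else ""
    return ContactMap(matrix=c, n_configs=ensemble.n, rc=rc, sequence_id=sequence_id)


def contact_stats(cmap: ContactMap | np.ndarray) -> ContactStats:
    """<C> = sum_ij C_ij / N^2 and Var(C) = sum_ij C_ij^2 / N^2 - <C>^2."""
    c = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    mean = float(c.mean())
    variance = float((c**2).mean() - mean**2)
    return ContactStats(mean=mean, variance=max(variance, 0.0))
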