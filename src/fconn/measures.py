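"""Weighted network measures on connectivity matrices.

Three node-level measures characterise the weighted, undirected functional
graph (weight matrix W, diagonal zeroed):

* node strength          Ns_i = sum_j w_ij
* eigenvector centrality theta = unit-norm eigenvector of the largest
                         eigenvalue lambda of W (so theta_i =
                         (1/lambda) sum_j w_ij theta_j)
* weighted clustering    C_i = [sum_{j != i} sum_{k != i, k != j}
                         w_ij w_jk w_ki] / [l_i (l_i - 1)], l_i = Ns_i,
                         with C_i = 0 where l_i <= 1 (denominator <= 0)

and each has a network mean (arithmetic mean over nodes).  Because the
clustering product and the Perron-Frobenius argument behind the centrality
presuppose nonnegative weights, correlations pass through a weight policy
first; the default takes absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix

ABSOLUTE = "absolute"
POSITIVE_ONLY = "positive_only"
RAW = "raw"
WEIGHT_MODES = (ABSOLUTE, POSITIVE_ONLY, RAW)

#: Eigengap below which the leading eigenpair is treated as degenerate.
DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class WeightPolicy:
    """How signed correlations become edge weights. Diagonal is always zeroed."""

    mode: str = ABSOLUTE

    def __post_init__(self):
        if self.mode not in WEIGHT_MODES:
            raise ValueError(f"unknown weight mode {self.mode!r}; expected one of {WEIGHT_MODES}")


@dataclass
class NodeMeasureSet:
    """Per-subject node measure vectors and their network means."""

    subject_id: str
    clustering: np.ndarray = field(repr=False)
    centrality: np.ndarray = field(repr=False)
    strength: np.ndarray = field(repr=False)
    eigenvalue: float = 0.0
    policy: WeightPolicy = WeightPolicy()

    @property
    def mean_clustering(self) -> float:
        return network_mean(self.clustering)

    @property
    def mean_centrality(self) -> float:
        return network_mean(self.centrality)

    @property
    def mean_strength(self) -> float:
        return network_mean(self.strength)


def apply_weight_policy(R, policy: WeightPolicy = WeightPolicy()) -> np.ndarray:
    """Turn a connectivity matrix into a weight matrix with zero diagonal."""
    if isinstance(R, ConnectivityMatrix):
        R = R.R
    W = np.array(R, dtype=float)
    if policy.mode == ABSOLUTE:
        W = np.abs(W)
    elif policy.mode == POSITIVE_ONLY:
        W = np.clip(W, 0.0, None)
    np.fill_diagonal(W, 0.0)
    return W


def _check_square_symmetric(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    return W


def node_strength(W: np.ndarray) -> np.ndarray:
    """Ns_i = sum_j w_ij (diagonal assumed zero)."""
    W = _check_square_symmetric(W)
    return W.sum(axis=1)


def eigenvector_centrality(W: np.ndarray):
    """Leading eigenpair (theta, lambda) of W, theta unit-norm.

    The global sign is fixed so sum(theta) >= 0; under nonnegative W the
    Perron-Frobenius vector is entrywise nonnegative and tiny negative
    round-off is clipped.  A degenerate leading eigenvalue (multiplicity
    > 1 within 1e-10) or an all-zero matrix is an error, never a silent
    tie-break.
    """
    W = _check_square_symmetric(W)
    if not W.any():
        raise ValueError("eigenvector centrality undefined for the zero matrix")
    w, v = np.linalg.eigh(W)
    lam = w[-1]
    if len(w) > 1 and (lam - w[-2]) <= DEGENERACY_TOL * max(1.0, abs(lam)):
        raise ValueError(
            f"degenerate leading eigenvalue (gap {lam - w[-2]:.3e}); centrality is not unique"
        )
    theta = v[:, -1]
    if theta.sum() < 0:
        theta = -theta
    if np.all(W >= 0):
        theta = np.clip(theta, 0.0, None)
        theta = theta / np.linalg.norm(theta)
    return theta, float(lam)


def clustering_coefficient(W: np.ndarray) -> np.ndarray:
    """Weighted clustering per node; see module docstring for the formula.

    Requires nonnegative weights (use an absolute or positive-only policy);
    with the diagonal zero the double sum over ordered pairs equals
    ``diag(W^3)``.
    """
    W = _check_square_symmetric(W)
    if np.any(W < 0):
        raise ValueError(
            "clustering coefficient requires nonnegative weights; "
            "apply an 'absolute' or 'positive_only' weight policy first"
        )
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    numerator = np.einsum("ij,jk,ki->i", W, W, W)
    l = W.sum(axis=1)
    denominator = l * (l - 1.0)
    out = np.zeros_like(l)
    ok = l > 1.0
    out[ok] = numerator[ok] / denominator[ok]
    return out


def network_mean(values) -> float:
    """Arithmetic mean over nodes (the network-level summary of a measure)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("network mean of an empty vector")
    return float(values.mean())


def compute_measures(
    conn: ConnectivityMatrix, policy: WeightPolicy = WeightPolicy()
) -> NodeMeasureSet:
    """All three node measures for one subject under one weight policy."""
    W = apply_weight_policy(conn, policy)
    theta, lam = eigenvector_centrality(W)
    return NodeMeasureSet(
        subject_id=conn.subject_id,
        clustering=clustering_coefficient(W),
        centrality=theta,
        strength=node_strength(W),
        eigenvalue=lam,
        policy=policy,
    )
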