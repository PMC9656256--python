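"""Cluster-based permutation testing of node measures over the atlas ordering.

Per node, a two-sample pooled t compares the measure between groups;
supra-threshold nodes (|t| above the two-sided critical value at the
cluster-forming alpha) are segmented into maximal sign-homogeneous runs of
consecutive atlas indices — the operational reading of "anatomical
neighbourhood", since consecutive AAL indices are anatomically adjacent
regions.  The cluster statistic is the mass (sum of member t values); the
null distribution is the maximum |mass| over seeded group-label
permutations, pooled over both signs, which controls family-wise error
across positive (Control > patients) and negative (patients > Control)
clusters jointly.

An optional adjacency matrix (e.g. from MNI centroid distances) replaces
the 1-D chain for atlases without a meaningful index ordering; clusters are
then connected components of same-sign supra-threshold nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import RegionTable

POSITIVE = "positive"  # Control > MDE
NEGATIVE = "negative"  # MDE > Control


@dataclass
class NodeCluster:
    """A contiguous run of same-sign supra-threshold nodes."""

    members: list  # node indices, contiguous in atlas order
    sign: str
    mass: float  # sum of member t statistics
    p_value: float
    measure: str = ""

    def __len__(self) -> int:
        return len(self.members)


def spatial_adjacency(regions: RegionTable, threshold_mm: float) -> np.ndarray:
    """Boolean adjacency from pairwise MNI centroid distance <= threshold."""
    xyz = regions.coordinates
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    adj = d2 <= threshold_mm**2
    np.fill_diagonal(adj, False)
    return adj


def _group_t(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column of ``values``."""
    a, b = values[mask_a], values[mask_b]
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return np.nan_to_num(t, nan=0.0)


def _perm_t(values: np.ndarray, perms: np.ndarray, na: int) -> np.ndarray:
    """t matrix (n_perm x n_nodes) for permuted group assignments."""
    xa = values[perms[:, :na]]  # (P, na, N)
    xb = values[perms[:, na:]]
    nb = perms.shape[1] - na
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return np.nan_to_num(t, nan=0.0)


def _runs(signed: np.ndarray):
    """Maximal sign-homogeneous runs of nonzero entries -> list of (indices, mass)."""
    out = []
    start = None
    cur_sign = 0
    for i, v in enumerate(signed):
        s = 0 if v == 0 else (1 if v > 0 else -1)
        if s != cur_sign:
            if cur_sign != 0:
                out.append((list(range(start, i)), float(signed[start:i].sum())))
            start = i if s != 0 else None
            cur_sign = s
    if cur_sign != 0:
        out.append((list(range(start, len(signed))), float(signed[start:].sum())))
    return out


def _components(signed: np.ndarray, adjacency: np.ndarray):
    """Connected components of same-sign supra-threshold nodes -> (indices, mass)."""
    out = []
    for sgn in (1, -1):
        nodes = np.flatnonzero(np.sign(signed) == sgn)
        if len(nodes) == 0:
            continue
        sub = csr_matrix(adjacency[np.ix_(nodes, nodes)])
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = nodes[labels == c]
            out.append((sorted(int(i) for i in members), float(signed[members].sum())))
    return out


def _max_run_mass(tmat: np.ndarray, thr: float) -> np.ndarray:
    """Max |run mass| per row of a t matrix, vectorised over permutations."""
    n_perm, n_nodes = tmat.shape
    best = np.zeros(n_perm)
    for sgn in (1.0, -1.0):
        v = np.where(sgn * tmat > thr, sgn * tmat, 0.0)
        v = np.concatenate([np.zeros((n_perm, 1)), v], axis=1)
        cs = np.cumsum(v, axis=1)
        positions = np.arange(n_nodes + 1)[None, :]
        last_zero = np.maximum.accumulate(np.where(v == 0, positions, 0), axis=1)
        run = cs - np.take_along_axis(cs, last_zero, axis=1)
        best = np.maximum(best, run.max(axis=1))
    return best


def _max_component_mass(tmat: np.ndarray, thr: float, adjacency: np.ndarray) -> np.ndarray:
    best = np.zeros(tmat.shape[0])
    for k, row in enumerate(tmat):
        signed = np.where(np.abs(row) > thr, row, 0.0)
        comps = _components(signed, adjacency)
        if comps:
            best[k] = max(abs(mass) for _, mass in comps)
    return best


def cluster_permutation_test(
    values: np.ndarray,
    groups,
    forming_alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    measure: str = "",
    adjacency: np.ndarray | None = None,
) -> list[NodeCluster]:
    """Permutation cluster test of per-node measures between two groups.

    ``values``: n_subjects x n_nodes, rows aligned with ``groups`` (an array
    of "control"/"depression" labels or a boolean patient indicator); node
    columns must follow ascending atlas order.  Returns clusters sorted by
    p-value (positive sign = measure higher in controls).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 2 or values.shape[0] != len(groups):
        raise ValueError("values must be n_subjects x n_nodes aligned with groups")
    if adjacency is not None and adjacency.shape[0] != values.shape[1]:
        raise ValueError("adjacency dimension does not match node count")
    if groups.dtype.kind == "b":
        is_patient = groups
    else:
        is_patient = groups == "depression"
    mask_b = np.asarray(is_patient, dtype=bool)
    mask_a = ~mask_b
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if min(na, nb) < 2:
        raise ValueError("need at least 2 subjects per group")

    df = na + nb - 2
    thr = float(stats.t.ppf(1.0 - forming_alpha / 2.0, df))

    # observed clusters: control-minus-patient ordering so positive means Control > MDE
    order = np.concatenate([np.flatnonzero(mask_a), np.flatnonzero(mask_b)])
    data = values[order]
    t_obs = _group_t(values, mask_a, mask_b)
    signed = np.where(np.abs(t_obs) > thr, t_obs, 0.0)
    if adjacency is None:
        observed = _runs(signed)
    else:
        observed = _components(signed, adjacency)

    # max-|mass| null over group-label permutations
    rng = np.random.default_rng(seed)
    n = na + nb
    null_max = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(1, n * values.shape[1])))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        tmat = _perm_t(data, perms, na)
        if adjacency is None:
            null_max[done : done + m] = _max_run_mass(tmat, thr)
        else:
            null_max[done : done + m] = _max_component_mass(tmat, thr, adjacency)
        done += m

    clusters = []
    for members, mass in observed:
        p = float((1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm))
        clusters.append(
            NodeCluster(
                members=members,
                sign=POSITIVE if mass > 0 else NEGATIVE,
                mass=mass,
                p_value=p,
                measure=measure,
            )
        )
    clusters.sort(key=lambda c: (c.p_value, -abs(c.mass)))
    return clusters


def clusters_to_frame(clusters: list[NodeCluster], regions: RegionTable | None = None) -> pd.DataFrame:
    """Long-format cluster table mirroring the per-node report layout."""
    rows = []
    labels = regions.labels if regions is not None else None
    counters = {POSITIVE: 0, NEGATIVE: 0}
    for c in clusters:
        counters[c.sign] += 1
        cid = f"{counters[c.sign]}{'+' if c.sign == POSITIVE else '-'}"
        for node in c.members:
            rows.append(
                {
                    "cluster": cid,
                    "sign": c.sign,
                    "measure": c.measure,
                    "node": node + 1,  # 1-based atlas index
                    "region": labels[node] if labels else f"R{node + 1:03d}",
                    "mass": c.mass,
                    "p": c.p_value,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "sign", "measure", "node", "region", "mass", "p"])
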