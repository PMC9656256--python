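"""Parcel averaging and per-subject Pearson connectivity matrices.

A subject's functional connectivity is the matrix of Pearson correlation
coefficients between the parcel-averaged BOLD series

    r_ij = sum_k (x_ik - mean(x_i)) (x_jk - mean(x_j))
           / sqrt( sum_k (x_ik - mean(x_i))^2 * sum_k (x_jk - mean(x_j))^2 )

computed on the raw averaged series — deliberately no detrending, band-pass
filtering, nuisance regression or scrubbing happens here.  A constant
region series has no defined correlation and raises an error naming the
region rather than emitting NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import default_region_labels


@dataclass
class ParcelTimeSeries:
    """One subject's regions x timepoints matrix of parcel-averaged BOLD."""

    subject_id: str
    data: np.ndarray = field(repr=False)
    region_labels: list[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series data must be regions x timepoints")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: time series contains non-finite values")
        if self.region_labels is None:
            self.region_labels = default_region_labels(self.data.shape[0])
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("region label count does not match data rows")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        """Timepoint count (the n of the correlation formula)."""
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix R with unit diagonal."""

    subject_id: str
    R: np.ndarray = field(repr=False)
    region_labels: list[str] = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric (1e-12)")
        if not np.all(np.diag(self.R) == 1.0):
            raise ValueError("connectivity matrix diagonal must be exactly 1")
        if np.any(np.abs(self.R) > 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.region_labels is None:
            self.region_labels = default_region_labels(self.R.shape[0])
        if len(self.region_labels) != self.R.shape[0]:
            raise ValueError("region label count does not match matrix dimension")

    @property
    def n_regions(self) -> int:
        return self.R.shape[0]


def parcel_average(voxel_data: np.ndarray, labels) -> ParcelTimeSeries:
    """Average voxel series into parcels (unweighted mean per parcel).

    ``labels`` assigns a parcel id to each voxel row; output rows are
    ordered by ascending parcel id.  An empty parcel raises an error naming
    the parcel id.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != voxel_data.shape[0]:
        raise ValueError(
            f"labels length ({labels.shape[0]}) != voxel count ({voxel_data.shape[0]})"
        )
    parcel_ids = np.unique(labels)
    rows = []
    for pid in parcel_ids:
        mask = labels == pid
        if not mask.any():
            raise ValueError(f"parcel {pid} has no voxels")
        rows.append(voxel_data[mask].mean(axis=0))
    return ParcelTimeSeries(
        subject_id="parcellated",
        data=np.vstack(rows),
        region_labels=[str(pid) for pid in parcel_ids],
    )


def pearson_connectivity(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of all region pairs of ``ts``."""
    data = ts.data
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"{ts.subject_id}: constant time series for region(s) {bad}; "
            "correlation is undefined"
        )
    R = np.corrcoef(data)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, R=R, region_labels=list(ts.region_labels))
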