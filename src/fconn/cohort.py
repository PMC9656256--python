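"""Seeded synthetic two-group cohorts of parcellated BOLD time series.

The study this pipeline targets compared 49 healthy controls against 41
patients in a major depressive episode, with 166-region AAL3 parcel series
of 192 timepoints (TR = 2 s).  No scans are distributed, so this module
generates cohorts with a known, recoverable group contrast:

* a baseline correlation structure from a low-rank factor model with a
  positive-dominant leading factor (parcel-averaged BOLD correlations are
  predominantly positive), rescaled to a correlation matrix;
* group effects planted on contiguous atlas-index blocks — off-diagonal
  entries within a *hypo* block are scaled by ``1 - delta`` in the patient
  group, entries within a *hyper* block are moved to ``min(1, r*(1+delta))``
  — followed by projection to the nearest positive-semidefinite correlation
  matrix (eigenvalue clipping + diagonal rescale);
* optional per-subject Wishart jitter of the group covariance, so that
  between-subject variance exists and group tests are non-degenerate;
* temporally AR(1)-smoothed Gaussian innovations whose stationary
  cross-sectional covariance equals the subject covariance exactly.

Everything is deterministic given the spec's seed: per-subject streams are
spawned from one ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .connectivity import ParcelTimeSeries
from .io import default_region_labels, write_timeseries

HYPO = "hypo"
HYPER = "hyper"

#: Default planted effects, mirroring the contrasts the study reports:
#: hypo-connected occipital-like (atlas 47-54) and vermis-like (109-113)
#: blocks in patients, and a hyper-connected orbitofrontal-like block
#: (atlas 21-28).  Ranges are 0-based half-open over atlas order.
DEFAULT_EFFECT_BLOCKS = (
    (46, 54, HYPO, 0.6),
    (108, 113, HYPO, 0.6),
    (20, 28, HYPER, 0.5),
)


@dataclass(frozen=True)
class EffectBlock:
    """A contiguous run of atlas-ordered nodes carrying a planted effect."""

    start: int
    stop: int  # half-open
    direction: str  # "hypo" or "hyper"
    magnitude: float  # delta in [0, 1)

    def __post_init__(self):
        if self.direction not in (HYPO, HYPER):
            raise ValueError(f"direction must be 'hypo' or 'hyper', got {self.direction!r}")
        if not 0.0 <= self.magnitude < 1.0:
            raise ValueError(f"effect magnitude delta must be in [0, 1), got {self.magnitude}")
        if self.stop <= self.start:
            raise ValueError(f"empty effect block [{self.start}, {self.stop})")

    @property
    def nodes(self) -> range:
        return range(self.start, self.stop)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 166 AAL3 regions, 192
    timepoints, 49 controls vs 41 patients, with the default effect layout
    of occipital/vermis hypo-connectivity and orbitofrontal
    hyper-connectivity in the patient group.
    """

    n_regions: int = 166
    n_timepoints: int = 192
    n_control: int = 49
    n_patient: int = 41
    base_loading_rank: int = 4
    effect_blocks: tuple = DEFAULT_EFFECT_BLOCKS
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    subject_df: int | None = 500  # Wishart dof for per-subject jitter; None disables
    seed: int = 0

    def __post_init__(self):
        self.effect_blocks = tuple(
            b if isinstance(b, EffectBlock) else EffectBlock(*b) for b in self.effect_blocks
        )
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if min(self.n_control, self.n_patient) < 0:
            raise ValueError("group sizes must be nonnegative")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.base_loading_rank < 1:
            raise ValueError("base_loading_rank must be >= 1")
        covered = np.zeros(self.n_regions, dtype=bool)
        for blk in self.effect_blocks:
            if blk.start < 0 or blk.stop > self.n_regions:
                raise ValueError(
                    f"effect block [{blk.start}, {blk.stop}) outside [0, {self.n_regions})"
                )
            sl = covered[blk.start : blk.stop]
            if sl.any():
                raise ValueError("effect blocks must be disjoint")
            covered[blk.start : blk.stop] = True


@dataclass
class Subject:
    subject_id: str
    group: str  # "control" | "depression"
    diagnosis: str
    timeseries: ParcelTimeSeries


@dataclass
class SyntheticCohort:
    subjects: list = field(repr=False)
    ground_truth: dict = field(repr=False)
    spec: CohortSpec = None
    seed: int = 0

    def __len__(self) -> int:
        return len(self.subjects)


def _cov2corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_psd_correlation(matrix: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero, then rescale the diagonal to 1."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    return _cov2corr(repaired)


def _baseline_correlation(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-rank factor model rescaled to a correlation matrix.

    The first factor has strictly positive loadings (uniform on [0.4, 0.8]),
    which yields the positive-dominant, moderate (~0.2-0.5) correlation
    level typical of parcel-averaged BOLD; further factors add structured
    heterogeneity, and a diagonal term models region-specific noise.
    """
    p, r = spec.n_regions, spec.base_loading_rank
    loadings = np.empty((p, r))
    loadings[:, 0] = rng.uniform(0.4, 0.8, size=p)
    if r > 1:
        loadings[:, 1:] = rng.normal(0.0, 0.3, size=(p, r - 1))
    psi = rng.uniform(0.3, 0.7, size=p)
    cov = loadings @ loadings.T + np.diag(psi)
    return _cov2corr(cov)


def plant_effects(
    corr: np.ndarray, blocks: tuple, which: str = "patient"
) -> np.ndarray:
    """Apply planted within-block effects to a correlation matrix.

    Only entries with BOTH endpoints inside a block change; the result is
    projected back to the nearest PSD correlation matrix.
    """
    if which == "control":
        return corr.copy()
    out = corr.copy()
    for blk in blocks:
        sl = slice(blk.start, blk.stop)
        sub = out[sl, sl]
        if blk.direction == HYPO:
            sub = sub * (1.0 - blk.magnitude)
        else:
            sub = np.minimum(1.0, sub * (1.0 + blk.magnitude))
        np.fill_diagonal(sub, 1.0)
        out[sl, sl] = sub
    return nearest_psd_correlation(out)


def build_group_covariances(spec: CohortSpec):
    """Return (control, patient) correlation matrices with planted effects."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x0C0FFEE]))
    base = _baseline_correlation(spec, rng)
    control = base.copy()
    patient = plant_effects(base, spec.effect_blocks, which="patient")
    return control, patient


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    ar: float,
    seed,
    subject_id: str = "sub",
    region_labels: list[str] | None = None,
) -> ParcelTimeSeries:
    """Simulate an AR(1)-smoothed Gaussian series with stationary covariance ``cov``.

    ``x_t = ar * x_{t-1} + sqrt(1 - ar^2) * e_t`` with ``e_t ~ N(0, cov)``
    and ``x_0 ~ N(0, cov)``: every marginal timepoint has cross-sectional
    covariance exactly ``cov``.  ``seed`` may be an int, a SeedSequence, or
    a Generator; the output is deterministic given it.
    """
    cov = np.asarray(cov, dtype=float)
    if not 0.0 <= ar < 1.0:
        raise ValueError("ar must be in [0, 1)")
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    if w[-1] <= 0:
        raise ValueError("covariance matrix is zero or negative definite")
    if w[0] < -1e-8 * w[-1]:
        raise ValueError(
            f"covariance matrix is not positive semidefinite (min eigenvalue {w[0]:.3e})"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = cov.shape[0]
    innov = factor @ rng.standard_normal((p, n_timepoints))
    data = np.empty((p, n_timepoints))
    data[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - ar * ar)
    for t in range(1, n_timepoints):
        data[:, t] = ar * data[:, t - 1] + scale * innov[:, t]
    if region_labels is None:
        region_labels = default_region_labels(p)
    return ParcelTimeSeries(subject_id=subject_id, data=data, region_labels=region_labels)


def _subject_covariance(
    group_corr: np.ndarray, df: int | None, rng: np.random.Generator
) -> np.ndarray:
    if df is None:
        return group_corr
    p = group_corr.shape[0]
    if df < p:
        raise ValueError(f"subject_df ({df}) must be >= n_regions ({p})")
    w, v = np.linalg.eigh(group_corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    a = factor @ rng.standard_normal((p, df))
    return _cov2corr(a @ a.T / df)


def planted_edges(spec: CohortSpec) -> list:
    """All (i, j), i < j, with both endpoints inside one effect block."""
    edges = []
    for blk in spec.effect_blocks:
        nodes = list(blk.nodes)
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                edges.append((nodes[a], nodes[b], blk.direction))
    return edges


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full two-group cohort described by ``spec``."""
    control_corr, patient_corr = build_group_covariances(spec)
    labels = default_region_labels(spec.n_regions)
    n_total = spec.n_control + spec.n_patient
    streams = np.random.SeedSequence([spec.seed, 0x5EED]).spawn(n_total)

    # Patient diagnosis subgroups in the study's 35:6 MDD:bipolar proportion.
    n_bipolar = int(round(spec.n_patient * 6 / 41))
    subjects = []
    for k in range(n_total):
        is_control = k < spec.n_control
        group = "control" if is_control else "depression"
        if is_control:
            diagnosis = "none"
        else:
            patient_rank = k - spec.n_control
            diagnosis = "bipolar" if patient_rank >= spec.n_patient - n_bipolar else "mdd"
        rng = np.random.default_rng(streams[k])
        base = control_corr if is_control else patient_corr
        sub_cov = _subject_covariance(base, spec.subject_df, rng)
        ts = simulate_subject(
            sub_cov,
            spec.n_timepoints,
            spec.ar_coefficient,
            rng,
            subject_id=f"sub-{k + 1:03d}",
            region_labels=labels,
        )
        ts.data *= spec.noise_sd
        subjects.append(Subject(ts.subject_id, group, diagnosis, ts))

    ground_truth = {
        "effect_blocks": [asdict(b) for b in spec.effect_blocks],
        "planted_edges": [[i, j, d] for i, j, d in planted_edges(spec)],
        "seed": spec.seed,
    }
    return SyntheticCohort(subjects=subjects, ground_truth=ground_truth, spec=spec, seed=spec.seed)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write per-subject series (TSV), the subject table (CSV) and ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(exist_ok=True)
    rows = ["subject_id,group,diagnosis"]
    for sub in cohort.subjects:
        write_timeseries(tsdir / f"{sub.subject_id}.tsv", sub.timeseries.data, sub.timeseries.region_labels)
        rows.append(f"{sub.subject_id},{sub.group},{sub.diagnosis}")
    (outdir / "subjects.csv").write_text("\n".join(rows) + "\n")
    (outdir / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=2, sort_keys=True) + "\n"
    )
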