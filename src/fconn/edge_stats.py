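"""Edge-wise group inference and the demographic/global-measure tests.

The group comparison of connectivity matrices is a general linear model per
upper-triangle edge,

    edge ~ intercept + covariates + group,

whose group-contrast t-statistic gets a permutation p-value by
Freedman-Lane residual permutation (the reduced-model residuals are
permuted, added back to the reduced fit, and the full-model contrast t is
recomputed for every permutation), followed by Benjamini-Hochberg FDR
across all edges.  Clinical-subgroup membership (e.g. an MDD/bipolar
split within the patient group) enters as dummy-coded covariates.

Also here: the demographic tests used for cohort tables (Pearson chi-square
without continuity correction, two-sample Kolmogorov-Smirnov, one-sample KS
normality with plug-in parameters) and the two-sample pooled t-test on
network mean values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix
from .io import diagnosis_dummies


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """n_subjects x p design with the group contrast as the LAST column."""

    X: np.ndarray = field(repr=False)
    columns: list[str] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.columns is None:
            self.columns = [f"c{k}" for k in range(self.X.shape[1])]
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column name count mismatch")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(
                "design matrix is rank deficient (a covariate is confounded "
                "with the group or another covariate)"
            )

    @property
    def group_index(self) -> int:
        return self.X.shape[1] - 1

    @property
    def group(self) -> np.ndarray:
        return self.X[:, -1]


def make_design(subjects: pd.DataFrame, use_covariates: bool = True) -> DesignMatrix:
    """Build [intercept | pruned diagnosis dummies | group] from a subject table.

    Dummy columns that would make the design rank deficient together with
    the intercept and group contrast (e.g. the full set of patient
    subgroups, which sums to the group indicator) are dropped greedily in
    sorted order, keeping the design full rank.
    """
    group = (subjects["group"] == "depression").to_numpy(dtype=float)
    n = len(subjects)
    cols = [np.ones(n)]
    names = ["intercept"]
    if use_covariates:
        dummies = diagnosis_dummies(subjects)
        for name in sorted(dummies.columns):
            candidate = cols + [dummies[name].to_numpy(dtype=float), group]
            if np.linalg.matrix_rank(np.column_stack(candidate)) == len(candidate):
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
    X = np.column_stack(cols + [group])
    return DesignMatrix(X=X, columns=names + ["group"])


# ---------------------------------------------------------------------------
# edge-wise permutation test


@dataclass
class EdgeTestResult:
    """Per-edge statistics plus run parameters and summary counts."""

    table: pd.DataFrame = field(repr=False)  # i, j, region_i, region_j, t, p_perm, q_fdr, significant
    n_regions: int = 0
    alpha: float = 1e-4
    n_permutations: int = 0
    seed: int = 0
    region_labels: list[str] = field(default=None, repr=False)

    @property
    def n_significant_edges(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_involved_nodes(self) -> int:
        sig = self.table[self.table["significant"]]
        return len(set(sig["i"]) | set(sig["j"]))

    def mask(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix of significant edges."""
        m = np.zeros((self.n_regions, self.n_regions))
        sig = self.table[self.table["significant"]]
        m[sig["i"], sig["j"]] = 1.0
        m[sig["j"], sig["i"]] = 1.0
        return m

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_edges": int(len(self.table)),
            "n_significant_edges": self.n_significant_edges,
            "n_involved_nodes": self.n_involved_nodes,
        }


def _contrast_t(X, pinvX, cc, df, gidx, Y):
    """Group-contrast t for stacked outcomes Y of shape (..., n, E)."""
    beta = pinvX @ Y
    resid = Y - X @ beta
    rss = np.sum(resid * resid, axis=-2)
    s2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[..., gidx, :] / np.sqrt(s2 * cc)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def stack_edges(matrices) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Upper-triangle edge values of a list of connectivity matrices.

    Returns (Y, rows, cols, labels) with Y of shape n_subjects x n_edges in
    fixed row-major (i < j) order.
    """
    mats, labels = [], None
    for m in matrices:
        if isinstance(m, ConnectivityMatrix):
            if labels is None:
                labels = m.region_labels
            elif labels != m.region_labels:
                raise ValueError("matrices do not share one region order")
            mats.append(m.R)
        else:
            mats.append(np.asarray(m, dtype=float))
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("matrices differ in shape")
    rows, cols = np.triu_indices(shape[0], k=1)
    Y = np.stack([m[rows, cols] for m in mats])
    return Y, rows, cols, labels


def edgewise_group_test(
    matrices,
    design: DesignMatrix,
    alpha: float = 1e-4,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> EdgeTestResult:
    """Edge-wise GLM group test with Freedman-Lane permutation p-values and BH FDR.

    ``alternative``: "two-sided" (default) or "greater" (Control > patients,
    i.e. negative group coefficient; the contrast codes depression = 1).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    Y, rows, cols, labels = stack_edges(matrices)
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"{Y.shape[0]} matrices but design has {n} rows")
    g = design.group
    if min((g == g.max()).sum(), (g == g.min()).sum()) < 2 or g.max() == g.min():
        raise ValueError("need at least 2 subjects per group")
    gidx = design.group_index

    pinvX = np.linalg.pinv(X)
    cc = np.linalg.inv(X.T @ X)[gidx, gidx]
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    t_obs = _contrast_t(X, pinvX, cc, df, gidx, Y)

    # Freedman-Lane: permute reduced-model residuals, keep the reduced fit.
    Xr = np.delete(X, gidx, axis=1)
    Qr, _ = np.linalg.qr(Xr)
    fit_r = Qr @ (Qr.T @ Y)
    res_r = Y - fit_r

    rng = np.random.default_rng(seed)
    n_edges = Y.shape[1]
    exceed = np.zeros(n_edges, dtype=np.int64)
    chunk = max(1, int(2e7 // max(1, n * n_edges)))
    done = 0
    if alternative == "two-sided":
        ref = np.abs(t_obs)
    else:
        ref = -t_obs  # Control > MDE means a negative depression coefficient
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)
        Ystar = fit_r[None, :, :] + res_r[perm, :]
        t_star = _contrast_t(X, pinvX, cc, df, gidx, Ystar)
        if alternative == "two-sided":
            exceed += (np.abs(t_star) >= ref).sum(axis=0)
        else:
            exceed += (-t_star >= ref).sum(axis=0)
        done += m
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    _, q_fdr, _, _ = multipletests(p_perm, method="fdr_bh")
    significant = q_fdr <= alpha
    if labels is None:
        labels = [f"R{i + 1:03d}" for i in range(matrices[0].shape[0] if not isinstance(matrices[0], ConnectivityMatrix) else matrices[0].n_regions)]
    table = pd.DataFrame(
        {
            "i": rows,
            "j": cols,
            "region_i": [labels[i] for i in rows],
            "region_j": [labels[j] for j in cols],
            "t": t_obs,
            "p_perm": p_perm,
            "q_fdr": q_fdr,
            "significant": significant,
        }
    )
    return EdgeTestResult(
        table=table,
        n_regions=len(labels),
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
        region_labels=labels,
    )


# ---------------------------------------------------------------------------
# demographics and global-measure tests


def global_measure_test(means_control, means_patient):
    """Two-sample pooled-variance t-test (two-sided) on network mean values."""
    a = np.asarray(means_control, dtype=float)
    b = np.asarray(means_patient, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table):
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square test undefined with a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("all expected counts must be positive")
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov test (max ECDF gap, asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_normality(x):
    """One-sample KS against a normal with plug-in sample mean and SD.

    Plug-in parameters make the test liberal relative to Lilliefors-adjusted
    critical values; adequate as a screening check, documented as such.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; normality test undefined")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)
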