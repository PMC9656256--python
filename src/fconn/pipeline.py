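"""End-to-end pipeline: simulate -> connectivity -> measures -> edge test ->
cluster tests -> specific networks -> classification, with a manifest.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name (SHA-256), so changing one stage's parameters never
perturbs another stage's random stream, and two runs with the same config
produce byte-identical artifacts (hash-equal manifests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import FEATURE_VARIANTS, build_features, cross_validate, reports_to_frame
from .cluster import NEGATIVE, POSITIVE, cluster_permutation_test, clusters_to_frame
from .cohort import CohortSpec, generate_cohort, write_cohort
from .connectivity import pearson_connectivity
from .edge_stats import edgewise_group_test, global_measure_test, make_design
from .io import RegionTable, load_aal3, validate_subject_table, write_matrix
from .measures import WeightPolicy, compute_measures
from .specific import build_specific_network, export_brainnet

import pandas as pd

log = logging.getLogger("fconn")

MEASURE_NAMES = ("clustering", "strength", "centrality")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Defaults are the study-scale analysis parameters (edge alpha 1e-4 with
    100,000 permutations; 10-fold CV repeated 1000 times); the cohort block
    carries the synthetic-cohort parameters.
    """

    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    weight_policy: str = "absolute"
    edge_alpha: float = 1e-4
    edge_n_perm: int = 100_000
    forming_alpha: float = 0.05
    cluster_n_perm: int = 10_000
    k: int = 10
    repeats: int = 1000
    sig_fc_fixed_mask: bool = False
    sig_fc_inner_alpha: float = 0.05
    sig_fc_inner_n_perm: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", derive_seed(self.seed, "simulate"))
        if "effect_blocks" in kwargs:
            kwargs["effect_blocks"] = tuple(tuple(b) for b in kwargs["effect_blocks"])
        return CohortSpec(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir, regions: RegionTable | None = None) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    spec = config.cohort_spec()
    log.info("simulate: %d+%d subjects, %d regions", spec.n_control, spec.n_patient, spec.n_regions)
    cohort = generate_cohort(spec)
    write_cohort(cohort, outdir / "cohort")
    subjects = validate_subject_table(
        pd.read_csv(outdir / "cohort" / "subjects.csv")
    )
    if regions is None and spec.n_regions == 166:
        regions = load_aal3()
    if regions is not None and len(regions) != spec.n_regions:
        regions = None  # synthetic cohorts at other sizes have no atlas table
    labels = cohort.subjects[0].timeseries.region_labels

    # --- connectivity -----------------------------------------------------
    matdir = outdir / "connectivity"
    matdir.mkdir(exist_ok=True)
    matrices = []
    for sub in cohort.subjects:
        conn = pearson_connectivity(sub.timeseries)
        matrices.append(conn)
        write_matrix(matdir / f"{sub.subject_id}.tsv", conn.R, conn.region_labels)

    # --- measures ---------------------------------------------------------
    policy = WeightPolicy(config.weight_policy)
    measures = [compute_measures(m, policy) for m in matrices]
    measdir = outdir / "measures"
    measdir.mkdir(exist_ok=True)
    for m in measures:
        pd.DataFrame(
            {
                "region": labels,
                "clustering": m.clustering,
                "centrality": m.centrality,
                "strength": m.strength,
            }
        ).to_csv(measdir / f"{m.subject_id}.csv", index=False)
    means = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort.subjects],
            "group": [s.group for s in cohort.subjects],
            "mean_clustering": [m.mean_clustering for m in measures],
            "mean_centrality": [m.mean_centrality for m in measures],
            "mean_strength": [m.mean_strength for m in measures],
        }
    )
    means.to_csv(outdir / "network_means.csv", index=False)
    is_control = means["group"] == "control"
    global_tests = {}
    for col in ("mean_clustering", "mean_centrality", "mean_strength"):
        t, p = global_measure_test(means.loc[is_control, col], means.loc[~is_control, col])
        global_tests[col] = {"t": t, "p": p}
    (outdir / "global_tests.json").write_text(
        json.dumps(global_tests, indent=2, sort_keys=True) + "\n"
    )

    # --- edge-wise test ---------------------------------------------------
    design = make_design(subjects)
    edge_result = edgewise_group_test(
        matrices,
        design,
        alpha=config.edge_alpha,
        n_perm=config.edge_n_perm,
        seed=derive_seed(config.seed, "edge-test"),
    )
    edge_result.table.to_csv(outdir / "edge_test.csv", index=False)
    write_matrix(outdir / "edge_mask.tsv", edge_result.mask(), labels)
    (outdir / "edge_summary.json").write_text(
        json.dumps(edge_result.summary(), indent=2, sort_keys=True) + "\n"
    )

    # --- cluster tests ----------------------------------------------------
    groups = subjects["group"].to_numpy()
    cluster_sets = {}
    for name in MEASURE_NAMES:
        values = np.stack([np.asarray(getattr(m, name)) for m in measures])
        clusters = cluster_permutation_test(
            values,
            groups,
            forming_alpha=config.forming_alpha,
            n_perm=config.cluster_n_perm,
            seed=derive_seed(config.seed, f"cluster-{name}"),
            measure=name,
        )
        cluster_sets[name] = clusters
        clusters_to_frame(clusters, regions).to_csv(outdir / f"clusters_{name}.csv", index=False)

    # --- specific networks ------------------------------------------------
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    mask = edge_result.mask()
    for name, clusters in cluster_sets.items():
        significant = [c for c in clusters if c.p_value <= 0.05]
        for sign in (POSITIVE, NEGATIVE):
            net = build_specific_network(significant, sign, mask)
            (netdir / f"{name}_{sign}.json").write_text(
                json.dumps(net.summary(), indent=2, sort_keys=True) + "\n"
            )
            if regions is not None:
                export_brainnet(
                    net,
                    regions,
                    netdir / f"{name}_{sign}.node",
                    netdir / f"{name}_{sign}.edge",
                )

    # --- classification ---------------------------------------------------
    y = groups
    node_feats = {name: None for name in MEASURE_NAMES}
    reports = []
    for variant in FEATURE_VARIANTS:
        if variant == "full_fc":
            X = build_features("full_fc", matrices=matrices)
            selector = None
        elif variant == "significant_fc":
            X = build_features("full_fc", matrices=matrices)
            if config.sig_fc_fixed_mask:
                from .edge_stats import stack_edges

                _, rows, cols, _ = stack_edges(matrices)
                keep = np.flatnonzero(mask[rows, cols])
                if keep.size == 0:
                    log.warning("significant_fc: empty edge mask; skipping variant")
                    continue
                fixed_keep = keep

                def selector(Xa, ya, tr, keep=fixed_keep):
                    return keep

            else:
                selector = _make_fold_selector(subjects, config)
        else:
            X = build_features(variant, measures=measures)
            selector = None
        report = cross_validate(
            X,
            y,
            k=config.k,
            repeats=config.repeats,
            seed=derive_seed(config.seed, f"classify-{variant}"),
            variant=variant,
            selector=selector,
        )
        reports.append(report)
        (outdir / f"roc_{variant}.json").write_text(
            json.dumps({"auc": report.auc, **report.roc}, sort_keys=True) + "\n"
        )
    reports_to_frame(reports).to_csv(outdir / "classification.csv", index=False)

    # --- manifest ---------------------------------------------------------
    files = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            stage: derive_seed(config.seed, stage)
            for stage in ["simulate", "edge-test"]
            + [f"cluster-{m}" for m in MEASURE_NAMES]
            + [f"classify-{v}" for v in FEATURE_VARIANTS]
        },
        "config": dataclasses.asdict(config),
        "files": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _make_fold_selector(subjects, config: PipelineConfig):
    """Edge selector that re-runs the FDR analysis inside each training fold.

    Avoids selection bias for the ``significant_fc`` variant: the mask is
    recomputed from training subjects only (dummy covariates re-pruned for
    rank on the training subset), at a reduced permutation count.
    """
    from .edge_stats import edgewise_group_test as _edge_test

    def selector(X, y, train_idx):
        sub_design = make_design(subjects.iloc[train_idx].reset_index(drop=True))
        n = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
        mats = []
        for row in X[train_idx]:
            m = np.eye(n)
            iu = np.triu_indices(n, k=1)
            m[iu] = row
            m = m + m.T - np.eye(n)
            mats.append(m)
        res = _edge_test(
            mats,
            sub_design,
            alpha=config.sig_fc_inner_alpha,
            n_perm=config.sig_fc_inner_n_perm,
            seed=derive_seed(config.seed, "sig-fc-inner"),
        )
        sig = res.table["significant"].to_numpy()
        if not sig.any():
            # fall back to the strongest edges so the variant stays defined
            sig = np.zeros_like(sig)
            order = np.argsort(res.table["p_perm"].to_numpy())[: max(1, len(sig) // 100)]
            sig[order] = True
        return np.flatnonzero(sig)

    return selector
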