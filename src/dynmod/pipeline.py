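"""End-to-end orchestration: simulate → connect → partition → metrics →
derive → behavior → predict.

``run_pipeline`` executes every stage for a synthetic (or on-disk)
cohort with deterministic per-stage seeding derived from the master
seed, caches expensive per-subject stage outputs by parameter/input
hash, and emits a machine-readable report: one row of network measures
per subject (mean Q, cohesion, disjointedness, recruitment,
integration, node strength) plus the permutation-validated regression
of the behavioral PC1 on each measure, with FDR correction inside
explicitly declared families.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from ._seeds import derive_rng, derive_seed
from .allegiance import integration, module_allegiance, recruitment
from .behavior import (behavioral_pc1, binned_median_error, cluster_participants,
                       learning_measures, measures_matrix)
from .connectivity import (WindowSpec, build_multilayer, coherence_null_threshold,
                           node_strength)
from .factorization import assign_clusters, symnmf
from .modularity import QualityParams, partition_ensemble
from .reconfiguration import ensemble_reconfig
from .stats import fdr_adjust, paired_test, steiger_dependent_corr, validated_regression
from .synthetic import Cohort, CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "compare_scans"]

MEASURES = ["mean_q", "cohesion", "disjointedness", "recruitment", "integration",
            "node_strength"]


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters plus the master seed.

    Defaults are a reduced desk-scale profile (few Louvain runs, small
    nulls); study-scale values (100 runs, 250 inits, 10,000
    permutations) are plain parameter choices away.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    scale: int = 1
    window: WindowSpec = field(default_factory=WindowSpec)
    null_iters: int = 1000
    null_percentile: float = 95.0
    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 25
    symnmf_rank: int | None = None      # default: planted module count
    symnmf_inits: int = 50
    kmeans_restarts: int = 100
    k_range: tuple[int, int] = (2, 9)
    n_perm: int = 999
    seed: int = 0

    def params(self) -> QualityParams:
        return QualityParams(gamma=self.gamma, omega=self.omega)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _cache_valid(path: Path, key: str) -> bool:
    sidecar = path.with_suffix(path.suffix + ".hash")
    return path.exists() and sidecar.exists() and sidecar.read_text() == key


def _mark(path: Path, key: str) -> None:
    path.with_suffix(path.suffix + ".hash").write_text(key)


def _subject_network_measures(cfg: RunConfig, panel, subject: int, scan: int,
                              out_dir: Path | None):
    """connect + partition for one subject-scan, with file-level caching."""
    conn_key = _hash({"stage": "connect", "scale": cfg.scale,
                      "window": (cfg.window.length, cfg.window.step),
                      "null_iters": cfg.null_iters, "pct": cfg.null_percentile,
                      "seed": cfg.seed, "subject": subject, "scan": scan,
                      "cohort": _hash(vars(cfg.cohort) | {"window": None})})
    part_key = _hash({"stage": "partition", "upstream": conn_key,
                      "gamma": cfg.gamma, "omega": cfg.omega, "runs": cfg.n_runs})
    net = ens = None
    if out_dir is not None:
        net_dir = out_dir / f"sub-{subject:03d}" / f"net_rest{scan}"
        ens_dir = out_dir / f"sub-{subject:03d}" / f"ens_rest{scan}"
        if _cache_valid(net_dir / "manifest.json", conn_key):
            net = dio.read_multilayer(net_dir)
        if net is not None and _cache_valid(ens_dir / "manifest.json", part_key):
            ens = dio.read_ensemble(ens_dir)
    if net is None:
        thr_rng = derive_rng(cfg.seed, "null-threshold", subject, scan)
        thr = coherence_null_threshold(
            panel, cfg.window, cfg.scale, n_iter=max(cfg.null_iters, 100),
            percentile=cfg.null_percentile, seed=thr_rng,
        )
        net = build_multilayer(panel, cfg.window, cfg.scale, threshold=thr)
        if out_dir is not None:
            dio.write_multilayer(net_dir, net)
            _mark(net_dir / "manifest.json", conn_key)
    if ens is None:
        ens_seed = int(derive_seed(cfg.seed, "partition", subject, scan).generate_state(1)[0] % 2**31)
        ens = partition_ensemble(net, n_runs=cfg.n_runs, params=cfg.params(), seed=ens_seed)
        if out_dir is not None:
            dio.write_ensemble(ens_dir, ens)
            _mark(ens_dir / "manifest.json", part_key)
    return net, ens


def _measures_for_scan(cfg: RunConfig, cohort: Cohort, scan: int,
                       out_dir: Path | None) -> pd.DataFrame:
    """Per-subject network measures for one rest scan (shared assignment
    derived from the group allegiance of this scan)."""
    nets, ensembles = {}, {}
    for s in cohort.subjects:
        nets[s], ensembles[s] = _subject_network_measures(
            cfg, cohort.panels[(s, scan)], s, scan, out_dir
        )
    group_P = module_allegiance(
        [ensembles[s] for s in cohort.subjects], null_zero=True,
        seed=derive_rng(cfg.seed, "allegiance-null", scan),
    )
    rank = cfg.symnmf_rank or cohort.config.n_modules_planted
    fact, all_H = symnmf(
        group_P.P, rank, n_inits=cfg.symnmf_inits,
        seed=int(derive_seed(cfg.seed, "symnmf", scan).generate_state(1)[0] % 2**31),
        return_all=True,
    )
    # best init whose factors assign every region; zero-loading regions
    # fall back to their allegiance-aligned factor.  If null-zeroing left a
    # region fully isolated (possible in very small cohorts), re-derive the
    # assignment from the un-zeroed group matrix.
    def _try_assign(Y):
        f, hs = symnmf(
            Y, rank, n_inits=cfg.symnmf_inits,
            seed=int(derive_seed(cfg.seed, "symnmf", scan).generate_state(1)[0] % 2**31),
            return_all=True,
        )
        for idx in np.argsort(f.losses):
            try:
                return f, assign_clusters(hs[idx], Y=Y)
            except ValueError:
                continue
        return f, None

    assign = None
    for idx in np.argsort(fact.losses):
        try:
            assign = assign_clusters(all_H[idx], Y=group_P.P)
            break
        except ValueError:
            continue
    if assign is None:
        group_raw = module_allegiance([ensembles[s] for s in cohort.subjects])
        fact, assign = _try_assign(group_raw.P)
    if assign is None:
        raise ValueError("no SymNMF initialization produced a full region assignment")
    nets_labels = assign.networks
    rows = []
    for s in cohort.subjects:
        P_s = module_allegiance(ensembles[s])
        rec = {k: recruitment(P_s, k, assign) for k in nets_labels}
        integ = {}
        for i, k1 in enumerate(nets_labels):
            for k2 in nets_labels[i + 1:]:
                integ[(k1, k2)] = integration(P_s, k1, k2, assign)
        reconf = ensemble_reconfig(ensembles[s])
        _, strength = node_strength(nets[s])
        rows.append({
            "subject": s,
            "profile": cohort.config.profile_of(s),
            "mean_q": ensembles[s].mean_quality,
            "cohesion": reconf.mean_cohesion,
            "disjointedness": reconf.mean_disjointedness,
            "recruitment": float(np.mean(list(rec.values()))),
            "integration": float(np.mean(list(integ.values()))),
            "node_strength": strength,
            "sparsity": nets[s].sparsity,
            **{f"recruitment_net{k}": v for k, v in rec.items()},
            **{f"integration_net{k1}_{k2}": v for (k1, k2), v in integ.items()},
        })
    df = pd.DataFrame(rows)
    extras = {"network_assignment": assign.labels, "group_allegiance": group_P,
              "symnmf_rmse": fact.rmse}
    return df, extras


def _behavior_table(cfg: RunConfig, cohort: Cohort) -> tuple[pd.DataFrame, np.ndarray]:
    measures = []
    for s in cohort.subjects:
        t = cohort.trials[s]
        b1 = binned_median_error(t, day=1)
        b2 = binned_median_error(t, day=2)
        measures.append(learning_measures(b1, b2))
    X = measures_matrix(measures)
    emb = behavioral_pc1(X)
    clust = cluster_participants(
        X, range(cfg.k_range[0], cfg.k_range[1] + 1),
        restarts=cfg.kmeans_restarts,
        seed=int(derive_seed(cfg.seed, "kmeans").generate_state(1)[0] % 2**31),
    )
    df = pd.DataFrame(X, columns=["early1", "late1", "early2", "late2", "savings"])
    df.insert(0, "subject", cohort.subjects)
    df["pc1"] = emb.pc1
    df["cluster_sil"] = clust.labels_by_k[clust.k_by_silhouette]
    return df, emb, clust


def run_pipeline(config: RunConfig, out_dir=None, cohort: Cohort | None = None) -> dict:
    """Execute all stages; return (and optionally write) the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    scan_tables, scan_extras = {}, {}
    for scan in (1, 2):
        scan_tables[scan], scan_extras[scan] = _measures_for_scan(config, cohort, scan, out)
    behav, emb, clust = _behavior_table(config, cohort)
    pc1 = emb.pc1
    models = {}
    rest1 = scan_tables[1]
    for m in MEASURES:
        r = validated_regression(
            rest1[m].to_numpy(), pc1, n_perm=config.n_perm,
            seed=int(derive_seed(config.seed, "predict", m).generate_state(1)[0] % 2**31),
        )
        models[m] = {
            "beta": float(r.betas[0]), "beta0": r.beta0, "r_squared": r.r_squared,
            "f": r.f_statistic, "df": list(r.df), "p": r.p, "n": r.n,
            "loocv_mse": r.loocv_mse, "loocv_mse_sd": r.loocv_mse_sd,
            "permutation_p": r.permutation_p,
        }
    fam_p = fdr_adjust([models[m]["p"] for m in MEASURES])
    for m, adj in zip(MEASURES, fam_p):
        models[m]["p_fdr"] = float(adj)
    report = {
        "config_hash": _hash({"cohort": vars(config.cohort) | {"window": None},
                              "stages": {k: v for k, v in vars(config).items()
                                         if k not in ("cohort", "window")}}),
        "seed": config.seed,
        "measures_rest1": rest1.drop(columns=[], errors="ignore").to_dict("records"),
        "measures_rest2": scan_tables[2].to_dict("records"),
        "behavior": behav.to_dict("records"),
        "pc1_explained_variance": float(emb.explained_variance[0]),
        "clustering": {
            "k_by_silhouette": clust.k_by_silhouette,
            "k_by_calinski_harabasz": clust.k_by_calinski_harabasz,
            "indices_agree": clust.indices_agree,
        },
        "network_assignment": {
            str(scan): scan_extras[scan]["network_assignment"].tolist()
            for scan in (1, 2)
        },
        "models": models,
        "fdr_families": {"simple_models": MEASURES},
    }
    if out is not None:
        rest1.to_csv(out / "measures_rest1.tsv", sep="\t", index=False)
        scan_tables[2].to_csv(out / "measures_rest2.tsv", sep="\t", index=False)
        behav.to_csv(out / "behavior.tsv", sep="\t", index=False)
        dio.write_json(out / "report.json", report)
    report["_tables"] = {"rest1": rest1, "rest2": scan_tables[2], "behavior": behav}
    return report


def compare_scans(rest1: pd.DataFrame, rest2: pd.DataFrame, outcome: np.ndarray,
                  measures: list[str] = MEASURES) -> dict:
    """Rest-2 minus Rest-1 paired differences plus correlation-change tests.

    For each measure: a paired t-test of the scan difference, and a
    Steiger (Williams) test of whether the measure-outcome correlation
    differs between scans (using the measure's cross-scan correlation as
    the dependency term).  FDR is applied within each declared family.
    """
    if len(rest1) != len(rest2):
        raise ValueError("subject mismatch between scans")
    paired, steiger = {}, {}
    for m in measures:
        a = rest1[m].to_numpy()
        b = rest2[m].to_numpy()
        paired[m] = paired_test(b, a)
        r12 = float(np.corrcoef(a, outcome)[0, 1])
        r13 = float(np.corrcoef(b, outcome)[0, 1])
        r23 = float(np.corrcoef(a, b)[0, 1])
        steiger[m] = steiger_dependent_corr(
            np.clip(r12, -0.999, 0.999), np.clip(r13, -0.999, 0.999),
            np.clip(r23, -0.999, 0.999), len(outcome),
        ) | {"r_rest1": r12, "r_rest2": r13, "r_cross": r23}
    for fam in (paired, steiger):
        adj = fdr_adjust([fam[m]["p"] for m in measures])
        for m, q in zip(measures, adj):
            fam[m]["p_fdr"] = float(q)
    return {"paired": paired, "steiger": steiger}
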