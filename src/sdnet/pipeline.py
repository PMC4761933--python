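"""End-to-end pipeline: network -> topology -> SDN -> differential stats ->
classifiers -> permutation null.

Every stage writes its artifact under the output directory and the run ends
with a JSON manifest of SHA-256 content hashes, so a rerun with the same
configuration is verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .classify import (FeatureSet, evaluate, feature_matrix, permutation_test,
                       rank_top_features, train_svm_rfe)
from .expression import direction_concordance, select_degs, select_deps
from .factor import fit_factor_model, sdn_rank
from .network import build_network, network_stats
from .simulate import (gen_expression, gen_fold_table, gen_scalefree_network,
                       gen_seeded_interactions)
from .topology import topology_profile

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Threshold defaults follow the study settings this pipeline models:
    grade-5 interactions only, 1.5-fold / 2-peptide protein selection,
    p and q cuts of 1e-4 for gene selection, top-50 feature sets and a
    1000-set permutation null.
    """

    seeds_path: str = ""
    interactions_path: str = ""
    train_expr_path: str = ""
    train_pheno_path: str = ""
    test_cohorts: list[dict] = field(default_factory=list)  # {name, expr, pheno}
    fold_table_path: str = ""
    out_dir: str = "pipeline_out"

    min_grade: int = 5
    fold_threshold: float = 1.5
    min_peptides: int = 2
    p_cut: float = 1e-4
    q_cut: float = 1e-4
    top_k: int = 50
    min_cumulative: float = 0.95
    tuning_cv: str | int = "loo"
    rfe_cv: int = 5
    B: int = 1000
    permutation_feature_sets: list[str] = field(default_factory=lambda: ["SDN"])
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        cv = raw.get("tuning_cv")
        if isinstance(cv, str) and cv.isdigit():
            raw["tuning_cv"] = int(cv)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, detail: str = ""):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start %s", name, detail)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name} failed ({detail}): {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - self.t0)

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the result bundle (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    results: dict = {"config": asdict(cfg)}

    for label, p in [("seeds", cfg.seeds_path), ("interactions", cfg.interactions_path),
                     ("training expression", cfg.train_expr_path),
                     ("training phenotype", cfg.train_pheno_path),
                     ("fold table", cfg.fold_table_path)]:
        if p and not Path(p).exists():
            raise PipelineError(f"missing {label} file: {p}")
    for c in cfg.test_cohorts:
        for key in ("expr", "pheno"):
            if not Path(c[key]).exists():
                raise PipelineError(f"missing test cohort file: {c[key]}")

    with _stage("network", cfg.interactions_path):
        seeds = io.read_seed_list(cfg.seeds_path)
        table = io.read_interactions(cfg.interactions_path)
        net = build_network(seeds, table, min_grade=cfg.min_grade)
        stats = network_stats(net)
        io.write_edgelist(net, out / "network.tsv")
        io.write_json(stats.to_dict(), out / "network_stats.json")
        artifacts += [out / "network.tsv", out / "network_stats.json"]
        results["network_stats"] = stats.to_dict()

    with _stage("topology"):
        profile = topology_profile(net)
        io.write_topology(profile, out / "topology.tsv")
        artifacts.append(out / "topology.tsv")

    with _stage("sdn"):
        model = fit_factor_model(profile, min_cumulative=cfg.min_cumulative)
        top_k = min(cfg.top_k, len(profile.nodes))
        ranking = sdn_rank(model, profile, top_k=top_k)
        ranking.table.to_csv(out / "sdn.tsv", sep="\t", lineterminator="\n",
                             float_format="%.10g")
        io.write_json(
            {
                "n_factors": model.n_factors_,
                "contributions": model.contributions_,
                "cumulative_contribution": model.cumulative_contribution_,
                "loadings": model.loadings_,
                "uniquenesses": model.uniquenesses_,
            },
            out / "factor_model.json",
        )
        artifacts += [out / "sdn.tsv", out / "factor_model.json"]
        results["factor_model"] = {
            "n_factors": model.n_factors_,
            "contributions": model.contributions_.tolist(),
            "cumulative_contribution": model.cumulative_contribution_,
        }

    with _stage("differential", cfg.train_expr_path):
        train = io.read_expression(cfg.train_expr_path, cfg.train_pheno_path)
        degs = select_degs(train, p_cut=cfg.p_cut, q_cut=cfg.q_cut)
        degs.to_csv(out / "degs.tsv", sep="\t", lineterminator="\n",
                    float_format="%.10g")
        fold = io.read_fold_table(cfg.fold_table_path)
        deps = select_deps(fold, fold_threshold=cfg.fold_threshold,
                           min_peptides=cfg.min_peptides)
        deps.to_csv(out / "deps.tsv", sep="\t", lineterminator="\n",
                    float_format="%.10g")
        artifacts += [out / "degs.tsv", out / "deps.tsv"]
        results["n_degs"] = int(degs["selected"].sum())
        results["n_deps"] = int(deps["selected"].sum())
        try:
            tab, p_fisher = direction_concordance(deps, degs)
            results["concordance"] = {
                "table": tab.to_numpy().tolist(),
                "fisher_p": p_fisher,
            }
        except ValueError:
            results["concordance"] = None

    with _stage("classification"):
        expr_genes = set(train.genes)
        k = cfg.top_k
        sdn_fs = rank_top_features(ranking, min(k, len(ranking.table)), name="SDN")
        sdn_fs.genes = [g for g in sdn_fs.genes if g in expr_genes]
        dep_sel = deps[deps["selected"]]
        dep_fs = rank_top_features(dep_sel, min(k, max(len(dep_sel), 1)), name="DEP") \
            if len(dep_sel) else FeatureSet("DEP", [])
        dep_fs.genes = [g for g in dep_fs.genes if g in expr_genes]
        deg_sel = degs[degs["selected"]]
        deg_fs = rank_top_features(deg_sel, min(k, max(len(deg_sel), 1)), name="DEG") \
            if len(deg_sel) else FeatureSet("DEG", [])
        cf_fs = FeatureSet.union("CF", sdn_fs, dep_fs, deg_fs)
        cohorts = {
            c["name"]: io.read_expression(c["expr"], c["pheno"])
            for c in cfg.test_cohorts
        }
        reports = {}
        classifiers = {}
        for fs in (sdn_fs, dep_fs, deg_fs, cf_fs):
            if not fs.genes:
                logger.warning("feature set %s empty after expression intersection",
                               fs.name)
                continue
            clf = train_svm_rfe(train, fs, tuning_cv=cfg.tuning_cv,
                                rfe_cv=cfg.rfe_cv, random_state=cfg.seed)
            classifiers[fs.name] = clf
            reports[fs.name] = evaluate(clf, cohorts, feature_set_name=fs.name)
        results["classifiers"] = {n: r.to_dict() for n, r in reports.items()}

    with _stage("permutation"):
        universe = sorted(expr_genes)
        for name in cfg.permutation_feature_sets:
            if name not in reports or not cohorts:
                continue
            observed = reports[name].meta["accuracy"]
            set_size = len(classifiers[name].feature_names_in_)

            def eval_set(genes):
                fs = FeatureSet("null", list(genes))
                clf = train_svm_rfe(train, fs, tuning_cv=cfg.tuning_cv,
                                    rfe_cv=cfg.rfe_cv, random_state=cfg.seed)
                return evaluate(clf, cohorts).meta["accuracy"]

            null, p = permutation_test(
                eval_set, observed, universe, set_size,
                B=cfg.B, seed=cfg.seed,
            )
            reports[name].permutation_p = p
            reports[name].permutation_null = null
            results["classifiers"][name]["permutation_p"] = p
            results["classifiers"][name]["permutation_null_mean"] = float(null.mean())

    io.write_json(results, out / "results.json")
    artifacts.append(out / "results.json")

    manifest = {
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "seed": cfg.seed,
    }
    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results


def make_synthetic_bundle(
    out_dir,
    seed: int = 0,
    n_nodes: int = 400,
    n_seeds: int = 40,
    n_per_class: tuple[int, int] = (15, 15),
    signature_size: int = 20,
    effect: float = 3.0,
    top_k: int = 15,
    B: int = 10,
) -> PipelineConfig:
    """Write a self-contained synthetic input bundle and its run config.

    The bundle shares one gene-symbol universe between the network, the
    expression cohorts and the protein table, and plants part of the
    expression signature on network hub genes so that every downstream
    feature set has signal.  Scale defaults keep a full run (including the
    permutation stage) in the tens of seconds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    net, net_truth = gen_scalefree_network(n_nodes=n_nodes, exponent=1.8, seed=seed)
    seeds, table, _ = gen_seeded_interactions(
        net, n_seeds=n_seeds, grade_mix=(0.05, 0.05, 0.1, 0.2, 0.6),
        seed=seed + 1,
    )
    io.write_seed_list(seeds, out / "seeds.txt")
    io.write_interactions(table, out / "interactions.tsv")

    symbols = sorted(net.nodes)
    hubs = sorted(net_truth.planted_hubs)[: signature_size // 2]
    others = [s for s in symbols if s not in set(hubs)]
    extra = rng.choice(others, size=signature_size - len(hubs), replace=False)
    signature_genes = sorted(set(hubs) | set(extra.tolist()))

    train, truth = gen_expression(
        n_genes=len(symbols), n_per_class=n_per_class,
        signature_size=len(signature_genes), effect=effect,
        genes=symbols, signature_genes=signature_genes, seed=seed + 2,
    )
    io.write_expression(train, out / "train_expr.tsv", out / "train_pheno.tsv")
    cohorts = []
    for i in range(2):
        test, _ = gen_expression(
            n_genes=len(symbols), n_per_class=(10, 10),
            signature_size=len(signature_genes), effect=effect,
            genes=symbols, signature_genes=signature_genes, seed=seed + 10 + i,
        )
        expr_p, pheno_p = out / f"test{i+1}_expr.tsv", out / f"test{i+1}_pheno.tsv"
        io.write_expression(test, expr_p, pheno_p)
        cohorts.append({"name": f"test{i+1}", "expr": str(expr_p),
                        "pheno": str(pheno_p)})

    n_up = n_down = max(5, n_nodes // 20)
    fold, _ = gen_fold_table(n_proteins=len(symbols), n_up=n_up, n_down=n_down,
                             proteins=symbols, seed=seed + 3)
    io.write_fold_table(fold, out / "fold_table.tsv")

    cfg = PipelineConfig(
        seeds_path=str(out / "seeds.txt"),
        interactions_path=str(out / "interactions.tsv"),
        train_expr_path=str(out / "train_expr.tsv"),
        train_pheno_path=str(out / "train_pheno.tsv"),
        test_cohorts=cohorts,
        fold_table_path=str(out / "fold_table.tsv"),
        out_dir=str(out / "results"),
        top_k=top_k,
        tuning_cv=3,
        rfe_cv=3,
        B=B,
        seed=seed,
    )
    io.write_json(asdict(cfg), out / "config.json")
    return cfg
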