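"""End-to-end orchestration: simulate-or-load, decompose, split, flux,
correlate, and report.

A :class:`RunConfig` (typically read from YAML) fully determines a run; the
master seed deterministically spawns one child seed per stage, so reruns with
the same config are byte-identical and stages can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from selscape import decompose as dc
from selscape import flux as fx
from selscape import stats as st
from selscape import synthetic as syn
from selscape.errors import InvalidArgumentError
from selscape.trees import (
    Phylogeny,
    compare_subtree_constraints,
    find_split_branch,
)

logger = logging.getLogger("selscape.pipeline")

REPORT_SCHEMA_VERSION = 1

# fixed stage order for seed derivation; reordering would change streams
_STAGES = (
    "synthesize",
    "decompose",
    "classes",
    "split",
    "flux",
    "correlate",
)


@dataclass(frozen=True)
class DomainSpec:
    """A planted clade of lineages with its own covariate coupling."""

    name: str
    n_lineages: int
    covariate_rho: float


@dataclass(frozen=True)
class SyntheticScenario:
    n_lineages: int = 60
    n_genes: int = 120
    sd_F: float = 0.5
    sd_R: float = 0.5
    residual_sd: float = 0.3
    missing_fraction: float = 0.2
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    covariate_rho: float = 0.3
    domains: tuple[DomainSpec, ...] = ()
    n_classes: int = 0
    genome_tree_tips: int = 12
    genome_tree_length: float = 1.5
    flux_families: int = 200
    flux_base_gain: float = 1.0
    flux_base_loss: float = 1.0
    flux_rho: float = 0.0
    subtree_effect_sd: float = 0.0

    def __post_init__(self):
        if self.domains:
            total = sum(d.n_lineages for d in self.domains)
            if total != self.n_lineages:
                raise InvalidArgumentError(
                    "domain lineage counts must sum to n_lineages"
                )


@dataclass(frozen=True)
class InputPaths:
    matrix: str
    covariates: str
    lineage_tree: Optional[str] = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    synthetic: Optional[SyntheticScenario] = None
    inputs: Optional[InputPaths] = None
    min_mutations: float = 32.0
    min_fraction: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000
    outlier_alpha: float = 0.05
    min_genes_per_lineage: int = 10
    split_min_tips: int = 20
    split_min_depth: float = 0.2
    heterogeneity_threshold: float = 0.4
    n_bootstrap_bca: int = 1000
    subsample_draws: int = 10000
    subsample_n: int = 19

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise InvalidArgumentError(
                "exactly one of synthetic scenario or input paths required"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        synthetic = None
        if "synthetic" in raw and raw["synthetic"] is not None:
            sblock = dict(raw.pop("synthetic"))
            domains = tuple(
                DomainSpec(**d) for d in sblock.pop("domains", ()) or ()
            )
            synthetic = SyntheticScenario(domains=domains, **sblock)
        inputs = None
        if "inputs" in raw and raw["inputs"] is not None:
            inputs = InputPaths(**raw.pop("inputs"))
        raw.pop("inputs", None)
        return cls(synthetic=synthetic, inputs=inputs, **raw)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in _STAGES:
        raise InvalidArgumentError(f"unknown stage {stage!r}")
    return np.random.SeedSequence(
        entropy=[int(master_seed), _STAGES.index(stage)]
    )


def _seed_int(seq: np.random.SeedSequence, k: int = 0) -> int:
    """Stateless child-seed derivation (independent of call order)."""
    entropy = list(np.atleast_1d(seq.entropy)) + [int(k)]
    return int(
        np.random.SeedSequence(entropy=[int(e) for e in entropy]).generate_state(1)[0]
    )


# ---------------------------------------------------------------------------
# Stage implementations


def _synthesize(config: RunConfig):
    scenario = config.synthetic
    seq = stage_seed(config.seed, "synthesize")
    matrix, truth = syn.generate_dnds_matrix(
        scenario.n_lineages,
        scenario.n_genes,
        scenario.sd_F,
        scenario.sd_R,
        scenario.residual_sd,
        scenario.missing_fraction,
        scenario.outlier_fraction,
        scenario.outlier_shift,
        seed=_seed_int(seq, 0),
    )

    lineage_tree = syn.random_tree(
        scenario.n_lineages, 1.0, _seed_int(seq, 1)
    )
    domain_of: dict[str, str] = {}
    if scenario.domains:
        # contiguous clades: relabel tips so each domain is a planted block
        ordered = lineage_tree.tip_labels
        cursor = 0
        relabel = {}
        for dom in scenario.domains:
            for k in range(dom.n_lineages):
                tip = ordered[cursor]
                lineage = matrix.lineage_ids[cursor]
                relabel[tip] = lineage
                domain_of[lineage] = dom.name
                cursor += 1
        for tip in lineage_tree.tips():
            tip.label = relabel[tip.label]
    else:
        for tip, lineage in zip(lineage_tree.tips(), matrix.lineage_ids):
            tip.label = lineage
    lineage_tree = Phylogeny(lineage_tree.root)  # revalidate labels

    # covariates: per-domain coupling when domains are planted
    covariates = np.empty(scenario.n_lineages)
    if scenario.domains:
        cursor = 0
        for d_idx, dom in enumerate(scenario.domains):
            block = slice(cursor, cursor + dom.n_lineages)
            covariates[block] = syn.generate_lineage_covariates(
                truth.true_F[block],
                dom.covariate_rho,
                seed=_seed_int(seq, 2 + d_idx),
            )
            cursor += dom.n_lineages
    else:
        covariates = syn.generate_lineage_covariates(
            truth.true_F, scenario.covariate_rho, seed=_seed_int(seq, 2)
        )

    class_of_gene: dict[str, str] = {}
    if scenario.n_classes > 0:
        rng = np.random.default_rng(_seed_int(seq, 20))
        labels = rng.integers(0, scenario.n_classes, size=scenario.n_genes)
        class_of_gene = {
            g: f"class{labels[j]}" for j, g in enumerate(matrix.gene_ids)
        }

    return matrix, truth, lineage_tree, covariates, domain_of, class_of_gene


def _load_inputs(config: RunConfig):
    matrix = dc.read_matrix_tsv(config.inputs.matrix)
    table = pd.read_csv(config.inputs.covariates, sep="\t")
    required = {"lineage_id", "covariate"}
    if not required.issubset(table.columns):
        raise InvalidArgumentError(
            "covariate table needs 'lineage_id' and 'covariate' columns"
        )
    cov_map = dict(zip(table["lineage_id"].astype(str), table["covariate"]))
    missing = [l for l in matrix.lineage_ids if l not in cov_map]
    if missing:
        raise InvalidArgumentError(f"covariate missing for {missing[0]!r}")
    covariates = np.array([cov_map[l] for l in matrix.lineage_ids], float)
    lineage_tree = None
    if config.inputs.lineage_tree:
        lineage_tree = Phylogeny.read(config.inputs.lineage_tree)
    domain_of = {}
    if "domain" in table.columns:
        domain_of = dict(zip(table["lineage_id"].astype(str), table["domain"]))
    return matrix, None, lineage_tree, covariates, domain_of, {}


def _split_stage(config: RunConfig, lineages, genome_trees, fitted_f, rng):
    scenario = config.synthetic
    rows = []
    for lineage in lineages:
        tree = genome_trees[lineage]
        candidate = find_split_branch(
            tree, config.split_min_tips, config.split_min_depth
        )
        if candidate is None:
            rows.append(
                {
                    "lineage_id": lineage,
                    "splittable": False,
                    "branch_id": "",
                    "n_a": 0,
                    "n_b": 0,
                    "depth_a": np.nan,
                    "depth_b": np.nan,
                    "difference": np.nan,
                    "heterogeneous": False,
                }
            )
            continue
        effect_sd = scenario.subtree_effect_sd if scenario else 0.0
        delta = float(rng.normal(0.0, effect_sd)) if effect_sd > 0 else 0.0
        f_l = fitted_f[lineage]
        measure, flagged = compare_subtree_constraints(
            f_l + delta / 2.0,
            f_l - delta / 2.0,
            config.heterogeneity_threshold,
        )
        rows.append(
            {
                "lineage_id": lineage,
                "splittable": True,
                "branch_id": candidate.branch_id,
                "n_a": len(candidate.tips_a),
                "n_b": len(candidate.tips_b),
                "depth_a": candidate.depth_a,
                "depth_b": candidate.depth_b,
                "difference": measure,
                "heterogeneous": flagged,
            }
        )
    return pd.DataFrame(rows)


def _flux_stage(config: RunConfig, lineages, truth, seq):
    """Per-lineage presence/absence simulation, reconstruction and flux."""
    scenario = config.synthetic
    genome_trees: dict[str, Phylogeny] = {}
    rows = []
    gain_mult = np.ones(len(lineages))
    if scenario.flux_rho != 0.0 and truth is not None:
        gain_mult = syn.generate_lineage_covariates(
            truth.true_F, scenario.flux_rho, seed=_seed_int(seq, 0)
        )
    for k, lineage in enumerate(lineages):
        tree = syn.random_tree(
            scenario.genome_tree_tips,
            scenario.genome_tree_length,
            _seed_int(seq, 10 + 3 * k),
        )
        genome_trees[lineage] = tree
        params = syn.GainLossParams(
            scenario.flux_base_gain * float(gain_mult[k]),
            scenario.flux_base_loss,
            root_presence_prob=0.5,
            n_families=scenario.flux_families,
            seed=_seed_int(seq, 11 + 3 * k),
        )
        pam, _true_anc = syn.simulate_presence_absence(tree, params)
        reconstructed = fx.reconstruct_ancestral_states(tree, pam)
        rates = fx.compute_flux(tree, reconstructed)
        rows.append(
            {
                "lineage_id": lineage,
                "gains": rates.total_gains,
                "losses": rates.total_losses,
                "tree_length": rates.tree_length,
                "gain_rate": rates.gain_rate,
                "loss_rate": rates.loss_rate,
                "flux_ratio": (
                    rates.flux_ratio if rates.flux_ratio is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows), genome_trees


def _correlation_entry(result: st.CorrelationResult) -> dict[str, Any]:
    return {
        "rho": result.rho,
        "p_value": result.p_value,
        "n": result.n,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n_bootstrap": result.n_bootstrap,
        "method": result.method,
    }


def run_full_analysis(config: RunConfig, out_dir) -> dict[str, Any]:
    """Execute every stage in order and write tables, report and log.

    Returns the report dictionary (also written to ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("selscape")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        _run_stages(config, out, report)
    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage={report.get('failed_stage', 'unknown')}: {exc}\n"
        )
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _run_stages(config: RunConfig, out: Path, report: dict[str, Any]) -> None:
    report["failed_stage"] = "synthesize"
    logger.info("stage=synthesize seed=%s", config.seed)
    if config.synthetic is not None:
        (matrix, truth, lineage_tree, covariates, domain_of, class_of_gene) = (
            _synthesize(config)
        )
        lineage_tree.write(out / "lineage_tree.nwk")
        if truth is not None:
            syn.write_truth_json(truth, out / "truth.json")
    else:
        (matrix, truth, lineage_tree, covariates, domain_of, class_of_gene) = (
            _load_inputs(config)
        )
    dc.write_matrix_tsv(matrix, out / "matrix.tsv")
    report["stages"]["synthesize"] = {
        "n_lineages": len(matrix.lineage_ids),
        "n_genes": len(matrix.gene_ids),
        "n_observed": int(matrix.observed_mask.sum()),
    }

    report["failed_stage"] = "decompose"
    logger.info(
        "stage=decompose tol=%s max_iter=%s alpha=%s",
        config.tol,
        config.max_iter,
        config.outlier_alpha,
    )
    first = dc.decompose(matrix, tol=config.tol, max_iter=config.max_iter)
    fit = dc.remove_outliers_and_refit(
        matrix, first, alpha=config.outlier_alpha,
        tol=config.tol, max_iter=config.max_iter,
    )
    fit.f_table().to_csv(out / "lineage_constraints.tsv", sep="\t", index=False)
    fit.r_table().to_csv(out / "gene_constraints.tsv", sep="\t", index=False)
    pd.DataFrame(
        fit.removed_cells, columns=["lineage_id", "gene_id"]
    ).to_csv(out / "removed_outliers.tsv", sep="\t", index=False)
    report["stages"]["decompose"] = {
        "E": fit.E,
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "n_removed_outliers": len(fit.removed_cells),
    }
    fitted_f = dict(zip(fit.lineage_ids, (float(v) for v in fit.F)))

    report["failed_stage"] = "classes"
    if class_of_gene:
        logger.info("stage=classes n_classes=%d", len(set(class_of_gene.values())))
        class_fits, concordance = dc.decompose_by_class(
            matrix,
            class_of_gene,
            min_genes_per_lineage=config.min_genes_per_lineage,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        concordance.to_csv(out / "class_concordance.tsv", sep="\t", index=False)
        report["stages"]["classes"] = {
            "classes": sorted(class_fits),
            "min_concordance": (
                float(concordance["spearman_rho"].min())
                if len(concordance)
                else None
            ),
        }

    report["failed_stage"] = "flux"
    flux_seq = stage_seed(config.seed, "flux")
    if config.synthetic is not None:
        logger.info("stage=flux families=%d", config.synthetic.flux_families)
        flux_table, genome_trees = _flux_stage(
            config, list(matrix.lineage_ids), truth, flux_seq
        )
        flux_table.to_csv(out / "flux.tsv", sep="\t", index=False)
        report["stages"]["flux"] = {
            "n_lineages": len(flux_table),
            "median_flux_ratio": float(flux_table["flux_ratio"].median()),
        }
    else:
        flux_table, genome_trees = None, {}

    report["failed_stage"] = "split"
    if genome_trees:
        logger.info("stage=split min_tips=%d", config.split_min_tips)
        split_rng = np.random.default_rng(
            _seed_int(stage_seed(config.seed, "split"), 0)
        )
        split_table = _split_stage(
            config, list(matrix.lineage_ids), genome_trees, fitted_f, split_rng
        )
        split_table.to_csv(out / "splits.tsv", sep="\t", index=False)
        report["stages"]["split"] = {
            "n_splittable": int(split_table["splittable"].sum()),
            "n_heterogeneous": int(split_table["heterogeneous"].sum()),
        }

    report["failed_stage"] = "correlate"
    logger.info("stage=correlate bca=%d", config.n_bootstrap_bca)
    corr_seq = stage_seed(config.seed, "correlate")
    f_vector = np.array([fitted_f[l] for l in matrix.lineage_ids])
    corr: dict[str, Any] = {}
    corr["covariate_vs_constraint"] = _correlation_entry(
        st.correlate_with_ci(
            covariates,
            f_vector,
            n_bootstrap=config.n_bootstrap_bca,
            seed=_seed_int(corr_seq, 0),
        )
    )
    if flux_table is not None:
        ratios = flux_table["flux_ratio"].to_numpy()
        finite = np.isfinite(ratios) & (ratios > 0)
        if finite.sum() >= 8:
            corr["flux_vs_constraint"] = _correlation_entry(
                st.correlate_with_ci(
                    np.log(flux_table["flux_ratio"].to_numpy()[finite]),
                    f_vector[finite],
                    n_bootstrap=config.n_bootstrap_bca,
                    seed=_seed_int(corr_seq, 1),
                )
            )

    by_domain: dict[str, Any] = {}
    if domain_of:
        for d_idx, domain in enumerate(sorted(set(domain_of.values()))):
            members = [
                i
                for i, l in enumerate(matrix.lineage_ids)
                if domain_of.get(l) == domain
            ]
            if len(members) < 8:
                continue
            by_domain[domain] = _correlation_entry(
                st.correlate_with_ci(
                    covariates[members],
                    f_vector[members],
                    n_bootstrap=config.n_bootstrap_bca,
                    seed=_seed_int(corr_seq, 10 + d_idx),
                )
            )
    if by_domain:
        corr["by_domain"] = by_domain

    if len(covariates) > config.subsample_n:
        null = st.subsample_null(
            covariates,
            f_vector,
            subsample_size=config.subsample_n,
            n_draws=config.subsample_draws,
            seed=_seed_int(corr_seq, 2),
        )
        corr["subsample_null"] = {
            "n_draws": config.subsample_draws,
            "subsample_size": config.subsample_n,
            "minimum": null.minimum,
            "mean": float(null.rhos.mean()),
        }

    if lineage_tree is not None:
        node_table = st.per_node_correlations(
            lineage_tree,
            dict(zip(matrix.lineage_ids, covariates)),
            fitted_f,
        )
        node_table.to_csv(out / "node_correlations.tsv", sep="\t", index=False)
        corr["n_nodes_with_correlation"] = int(len(node_table))

    report["stages"]["correlate"] = corr
    del report["failed_stage"]


# ---------------------------------------------------------------------------
# Recovery experiment (simulate -> re-estimate omega and kappa)


@dataclass(frozen=True)
class RecoveryReport:
    table: pd.DataFrame = field(repr=False)
    spearman_omega: Optional[float]
    spearman_kappa: Optional[float]
    n_requested: int
    n_usable: int
    n_failed: int
    error_quantiles: dict[str, dict[str, float]] = field(default_factory=dict)


def validate_recovery_experiment(
    n_alignments: int = 200,
    n_tips: int = 10,
    tree_length: float = 1.0,
    n_codons: int = 300,
    omega_range: tuple[float, float] = (0.02, 0.8),
    kappa_range: tuple[float, float] = (1.0, 4.0),
    seed: int = 7,
) -> RecoveryReport:
    """Simulate codon alignments with known omega/kappa and re-estimate both.

    One fixed random tree is used for the whole batch; per alignment, omega
    is drawn log-uniformly and kappa uniformly. Reports Spearman correlations
    between true and estimated values plus relative-error quantiles.
    Estimation failures are excluded and counted.
    """
    from selscape.codon import (
        CodonModelParams,
        estimate_dnds_ml,
        is_boundary,
        simulate_alignment,
    )
    from selscape.errors import EstimationDegenerateError

    seq = np.random.SeedSequence(entropy=[int(seed), 0xC0D0])
    rng = np.random.default_rng(seq)
    if tree_length == 0:
        # degenerate scenario: no evolution, every estimation must fail
        tree = syn.random_tree(n_tips, 1.0, _seed_int(seq, 0))
        for node in tree.preorder():
            node.length = 0.0
    else:
        tree = syn.random_tree(n_tips, tree_length, _seed_int(seq, 0))

    rows = []
    n_failed = 0
    for k in range(n_alignments):
        omega = float(
            np.exp(rng.uniform(np.log(omega_range[0]), np.log(omega_range[1])))
        )
        kappa = float(rng.uniform(*kappa_range))
        params = CodonModelParams(omega, kappa)
        alignment = simulate_alignment(
            tree, params, n_codons, seed=_seed_int(seq, 1 + k)
        )
        try:
            est, loglik = estimate_dnds_ml(alignment, tree)
        except EstimationDegenerateError as exc:
            logger.info("replicate %d failed: %s", k, exc)
            n_failed += 1
            continue
        rows.append(
            {
                "replicate": k,
                "true_omega": omega,
                "true_kappa": kappa,
                "est_omega": est.omega,
                "est_kappa": est.kappa,
                "est_scale": est.branch_scale,
                "log_likelihood": loglik,
                "boundary": is_boundary(est),
            }
        )
    table = pd.DataFrame(rows)

    if len(table) >= 3:
        rho_omega, _ = st.spearman(table["true_omega"], table["est_omega"])
        rho_kappa, _ = st.spearman(table["true_kappa"], table["est_kappa"])
        quantiles = {}
        for name in ("omega", "kappa"):
            rel = np.abs(
                table[f"est_{name}"] / table[f"true_{name}"] - 1.0
            ).to_numpy()
            quantiles[name] = {
                "q50": float(np.quantile(rel, 0.5)),
                "q90": float(np.quantile(rel, 0.9)),
            }
    else:
        rho_omega = rho_kappa = None
        quantiles = {}
    return RecoveryReport(
        table,
        rho_omega,
        rho_kappa,
        n_alignments,
        len(table),
        n_failed,
        quantiles,
    )
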