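"""Repeated cross-validation harness, prediction metrics and method
comparison for genomic prediction experiments.

The protocol is five-fold cross-validation repeated five times (25
train/validation splits). Every method receives the identical fold plan
and identical standardized DRPs within a replicate. Three metrics are
computed per fold on the validation animals:

* accuracy — cor(sDRP, PV) divided by the mean DRP accuracy r_bar
  (mean square root of the DRP reliability) of the validation animals;
* dispersion — the slope of the regression of sDRP on PV (1 means
  neither over- nor under-dispersion);
* MSE — mean squared difference between sDRP and PV.

Replicate-level values are means over the replicate's folds; final
results are means over replicates. Methods are compared per trait with
paired two-sided t-tests on the five replicate means, Bonferroni-adjusted
over method pairs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .banns import BANNRegressor, VEMConfig, fit_banns, posterior_inclusion_probabilities, predict as banns_predict
from .bayes import BayesConfig, fit_bayesb, fit_bayescpi
from .forest import GridSearchForestRegressor
from .gblup import build_grm, fit_gblup, predict_gblup, reliability_weights
from .io import TraitRecord
from .simulate import SimArchitecture, simulate_drp, simulate_gene_map, simulate_genotypes, simulate_phenotypes
from .snp_sets import partition_by_gene, partition_by_window


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    replicate_id: int
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def make_cv_folds(n: int, k: int = 5, reps: int = 5, seed: int = 0) -> list[FoldPlan]:
    """Random k-fold plans, repeated; fold sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split n={n} individuals into k={k} folds")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, reps + 1):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, test in enumerate(folds, start=1):
            train = np.setdiff1d(perm, test)
            plans.append(FoldPlan(rep, f, np.sort(train), np.sort(test)))
    return plans


def fold_hash(plans: list[FoldPlan]) -> str:
    h = hashlib.sha256()
    for p in plans:
        h.update(np.asarray(p.train_idx, dtype=np.int64).tobytes())
        h.update(np.asarray(p.test_idx, dtype=np.int64).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def standardize_drp(drp: np.ndarray, constants: tuple[float, float] | None = None):
    """Standardize DRPs to mean 0, variance 1 (n-1 divisor).

    Pass ``constants=(mean, sd)`` from the training fold to transform
    validation animals without leaking their statistics.
    """
    drp = np.asarray(drp, dtype=float)
    if constants is None:
        mean = float(drp.mean())
        sd = float(drp.std(ddof=1))
        if sd == 0:
            raise ValueError("constant DRP vector cannot be standardized")
        return (drp - mean) / sd, (mean, sd)
    mean, sd = constants
    return (drp - mean) / sd, (mean, sd)


def accuracy(sdrp_test: np.ndarray, pv_test: np.ndarray, r_bar: float) -> float:
    """Pearson correlation between sDRP and predictions divided by r_bar."""
    sdrp_test = np.asarray(sdrp_test, dtype=float)
    pv_test = np.asarray(pv_test, dtype=float)
    if r_bar <= 0:
        raise ValueError("r_bar must be positive")
    if sdrp_test.size < 3:
        raise ValueError("need at least 3 validation animals")
    if np.std(pv_test) == 0:
        raise ValueError("predictions have zero variance; correlation undefined")
    return float(np.corrcoef(sdrp_test, pv_test)[0, 1]) / r_bar


def dispersion(sdrp_test: np.ndarray, pv_test: np.ndarray) -> float:
    """OLS slope of sDRP on predictions; 1 = neither over- nor under-dispersed."""
    pv_test = np.asarray(pv_test, dtype=float)
    sdrp_test = np.asarray(sdrp_test, dtype=float)
    v = np.var(pv_test, ddof=1)
    if v == 0:
        raise ValueError("predictions have zero variance; slope undefined")
    c = np.cov(sdrp_test, pv_test, ddof=1)[0, 1]
    return float(c / v)


def mse(sdrp_test: np.ndarray, pv_test: np.ndarray) -> float:
    sdrp_test = np.asarray(sdrp_test, dtype=float)
    pv_test = np.asarray(pv_test, dtype=float)
    if sdrp_test.shape != pv_test.shape:
        raise ValueError("vectors must have equal length")
    return float(np.mean((sdrp_test - pv_test) ** 2))


@dataclass
class MetricsResult:
    method: str
    trait: str
    replicate: int
    accuracy: float
    dispersion_slope: float
    mse: float
    r_bar: float


def compare_methods(results: pd.DataFrame, metric: str = "accuracy") -> pd.DataFrame:
    """Paired two-sided t-tests on replicate means for every method pair.

    ``results`` is a tidy frame with columns method, trait, replicate and
    the metric. P-values are Bonferroni-adjusted by the number of method
    pairs within each trait.
    """
    rows = []
    for trait, sub in results.groupby("trait"):
        wide = sub.pivot_table(index="replicate", columns="method", values=metric)
        methods = sorted(wide.columns)
        counts = {m: wide[m].notna().sum() for m in methods}
        if len(set(counts.values())) > 1:
            raise ValueError(f"unequal replicate counts per method: {counts}")
        pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
        n_pairs = max(len(pairs), 1)
        for a, b in pairs:
            diff = wide[a] - wide[b]
            if np.allclose(diff.std(ddof=1), 0.0):
                if np.allclose(diff.mean(), 0.0):
                    t, p = 0.0, 1.0
                else:
                    warnings.warn(
                        f"zero within-pair variance for ({a}, {b}) on {trait}; "
                        "degenerate t statistic treated as P -> 0"
                    )
                    t, p = np.inf, 0.0
            else:
                t, p = stats.ttest_rel(wide[a], wide[b])
            rows.append(
                dict(trait=trait, method_a=a, method_b=b,
                     mean_a=wide[a].mean(), mean_b=wide[b].mean(),
                     t_stat=float(t), p_raw=float(p),
                     p_adj=float(min(1.0, p * n_pairs)))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Synthetic study conditions, chip-like by default: ~2 SNPs / 100 kb,
    heritability in the dairy-trait range, bull-proof reliabilities."""

    n: int = 2000
    J: int = 1000
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.3
    chrom_count: int = 5
    chrom_length_bp: int | None = None
    gene_density: float = 10.0
    gene_len_bp: tuple[int, int] = (20_000, 80_000)
    pi_causal: float = 0.05
    mixture_props: tuple[float, float, float] = (0.1, 0.3, 0.6)
    mixture_vars: tuple[float, float, float] = (0.1, 0.01, 0.001)
    epistasis_frac: float = 0.0
    n_enriched_sets: int | None = None
    h2: float = 0.33
    rel_range: tuple[float, float] = (0.5, 0.9)
    trait: str = "synthetic"


@dataclass
class ExperimentConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    methods: tuple[str, ...] = (
        "banns_gene", "banns_100kb", "gblup", "bayesb", "bayescpi", "rf"
    )
    cv_k: int = 5
    cv_reps: int = 5
    window_bp: int = 100_000
    vem: dict = field(default_factory=dict)     # VEMConfig overrides
    bayes: dict = field(default_factory=dict)   # BayesConfig overrides
    rf: dict = field(default_factory=dict)      # forest grid overrides
    seed: int = 0


@dataclass
class ExperimentResult:
    fold_metrics: pd.DataFrame       # method, trait, replicate, fold, metric values
    replicate_metrics: pd.DataFrame  # means over folds
    summary: pd.DataFrame            # means over replicates
    comparisons: pd.DataFrame
    banns_summaries: pd.DataFrame    # pve/pip summaries per BANN fit
    manifest: dict

    def save(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.fold_metrics.to_csv(f"{outdir}/fold_metrics.tsv", sep="\t", index=False)
        self.replicate_metrics.to_csv(f"{outdir}/replicate_metrics.tsv", sep="\t", index=False)
        self.summary.to_csv(f"{outdir}/summary.tsv", sep="\t", index=False)
        self.comparisons.to_csv(f"{outdir}/comparisons.tsv", sep="\t", index=False)
        self.banns_summaries.to_csv(f"{outdir}/banns_summaries.tsv", sep="\t", index=False)
        with open(f"{outdir}/manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _simulate_dataset(sc: ScenarioConfig, window_bp: int, seed: int):
    ss = np.random.SeedSequence(seed)
    s_geno, s_gene, s_arch, s_drp = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    g = simulate_genotypes(
        sc.n, sc.J, sc.maf_low, sc.maf_high, sc.ld_rho, sc.chrom_count,
        seed=s_geno, chrom_length_bp=sc.chrom_length_bp,
    )
    ann = simulate_gene_map(g.variants, sc.gene_density, sc.gene_len_bp, seed=s_gene)
    part_window = partition_by_window(g.variants, window_bp)
    part_gene = partition_by_gene(g.variants, ann)
    arch = SimArchitecture(
        pi_causal=sc.pi_causal, mixture_props=sc.mixture_props,
        mixture_vars=sc.mixture_vars, epistasis_frac=sc.epistasis_frac,
        n_enriched_sets=sc.n_enriched_sets, h2_target=sc.h2, seed=s_arch,
    )
    y, truth = simulate_phenotypes(g, part_window, arch)
    traits = simulate_drp(truth, y, sc.rel_range, sc.h2, seed=s_drp,
                          sample_ids=g.sample_ids)
    return g, ann, part_window, part_gene, truth, traits


def _fit_predict(
    method: str, X, sdrp_tr, train_idx, test_idx,
    part_window, part_gene, G_joint, r2_drp, cfg: ExperimentConfig, seed: int,
):
    """Fit one method on the training fold, return predictions and extras."""
    Xtr, Xte = X[train_idx], X[test_idx]
    extras = {}
    if method in {"banns_gene", "banns_100kb"}:
        part = part_gene if method == "banns_gene" else part_window
        vem = VEMConfig(seed=seed, **cfg.vem)
        fit = fit_banns(Xtr, sdrp_tr, part, vem)
        pv = banns_predict(fit, Xte)
        pip_snp, pip_set = posterior_inclusion_probabilities(fit)
        extras = dict(
            pve_snp=fit.pve.pve_snp, pve_set=fit.pve.pve_set,
            pip_snp_mean=float(pip_snp.mean()), pip_snp_max=float(pip_snp.max()),
            pip_set_mean=float(pip_set.mean()), pip_set_max=float(pip_set.max()),
        )
    elif method == "gblup":
        D_tr = reliability_weights(r2_drp[train_idx])
        model = fit_gblup(sdrp_tr, G_joint[np.ix_(train_idx, train_idx)], D_tr, reml=True)
        pv = predict_gblup(model, G_joint, sdrp_tr, train_idx, test_idx, D_tr)
        extras = dict(sigma_g_sq=model.sigma_g_sq, sigma_e_sq=model.sigma_e_sq,
                      h2_hat=model.h2)
    elif method in {"bayesb", "bayescpi"}:
        bc = BayesConfig(seed=seed, **cfg.bayes)
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        fitter = fit_bayesb if method == "bayesb" else fit_bayescpi
        post = fitter((Xtr - mean) / sd, sdrp_tr, bc)
        pv = post.mu_mean + ((Xte - mean) / sd) @ post.beta_mean
        extras = dict(mean_beta_se=float(post.beta_se.mean()))
        if post.pi_samples is not None:
            extras["pi_mean"] = float(post.pi_samples.mean())
    elif method == "rf":
        rf = GridSearchForestRegressor(random_state=seed % 2**31, **cfg.rf)
        rf.fit(Xtr, sdrp_tr)
        pv = rf.predict(Xte)
        extras = dict(**{f"rf_{k}": v for k, v in rf.best_params_.items()})
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.asarray(pv, dtype=float), extras


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full protocol: simulate, partition, cross-validate every
    method on identical folds, compute metrics and comparisons."""
    ss = np.random.SeedSequence(cfg.seed)
    data_seed, fold_seed, method_seed = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)
    )
    g, ann, part_window, part_gene, truth, traits = _simulate_dataset(
        cfg.scenario, cfg.window_bp, data_seed
    )
    X = g.dosages
    drp = np.array([t.drp for t in traits])
    r2_drp = np.array([t.r2_drp for t in traits])
    plans = make_cv_folds(cfg.scenario.n, cfg.cv_k, cfg.cv_reps, fold_seed)
    fhash = fold_hash(plans)
    G_joint = build_grm(X) if "gblup" in cfg.methods else None

    rows = []
    extra_rows = []
    for plan in plans:
        tr, te = plan.train_idx, plan.test_idx
        sdrp_tr, consts = standardize_drp(drp[tr])
        sdrp_te, _ = standardize_drp(drp[te], consts)
        r_bar = float(np.mean(np.sqrt(r2_drp[te])))
        for method in cfg.methods:
            method_tag = int.from_bytes(
                hashlib.sha256(method.encode()).digest()[:4], "big"
            )
            seed = int(
                np.random.SeedSequence(
                    [method_seed, plan.replicate_id, plan.fold_id, method_tag]
                ).generate_state(1)[0] % 2**31
            )
            pv, extras = _fit_predict(
                method, X, sdrp_tr, tr, te, part_window, part_gene,
                G_joint, r2_drp, cfg, seed,
            )
            rows.append(
                dict(method=method, trait=cfg.scenario.trait,
                     replicate=plan.replicate_id, fold=plan.fold_id,
                     accuracy=accuracy(sdrp_te, pv, r_bar),
                     dispersion_slope=dispersion(sdrp_te, pv),
                     mse=mse(sdrp_te, pv), r_bar=r_bar,
                     fold_hash=fhash)
            )
            if extras:
                extra_rows.append(
                    dict(method=method, replicate=plan.replicate_id,
                         fold=plan.fold_id, **extras)
                )
    fold_metrics = pd.DataFrame(rows)
    replicate_metrics = (
        fold_metrics.groupby(["method", "trait", "replicate"], as_index=False)
        [["accuracy", "dispersion_slope", "mse", "r_bar"]].mean()
    )
    summary = (
        replicate_metrics.groupby(["method", "trait"], as_index=False)
        [["accuracy", "dispersion_slope", "mse"]].mean()
    )
    comparisons = (
        compare_methods(replicate_metrics)
        if cfg.cv_reps >= 2 and len(cfg.methods) >= 2
        else pd.DataFrame()
    )
    manifest = dict(
        config=asdict(cfg),
        config_hash=hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        fold_hash=fhash,
        n_snp_sets_window=part_window.G,
        n_snp_sets_gene=part_gene.G,
        realized_h2=truth.realized_h2,
    )
    return ExperimentResult(
        fold_metrics=fold_metrics,
        replicate_metrics=replicate_metrics,
        summary=summary,
        comparisons=comparisons,
        banns_summaries=pd.DataFrame(extra_rows),
        manifest=manifest,
    )
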