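"""Low- vs high-diversity contrasts, correlations, regression, orchestration.

Statistical layer on the window table: Mann-Whitney U contrasts of pN/pS
and dN/dS between low- and high-diversity regions (exact enumeration for
small samples, tie/continuity-corrected normal approximation otherwise),
Pearson correlations among window covariates, and the multiple linear
regression of pi_4D on GC content, rho, gene density and mutation rate
(per-window synonymous divergence dS), with variance-inflation-factor
diagnostics and optional pairwise-interaction model variants reported side
by side.  ``run_pipeline`` chains every stage behind one entry point and
writes all output tables plus a run manifest.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger("leptidiv")


@dataclass
class ComparisonResult:
    """One low- vs high-diversity contrast of a window statistic."""

    statistic: str
    population: str
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    n_low: int
    n_high: int
    u_statistic: float
    p_value: float
    method: str
    n_missing_excluded: int


@dataclass
class RegressionResult:
    """One fitted linear-model variant with VIF diagnostics."""

    response: str
    variant: str
    terms: pd.DataFrame  # term, estimate, se, t, p
    vif: pd.Series
    r_squared: float
    n_obs: int
    standardized: bool


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, exact_max_total: int = 20
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    For pooled sample sizes up to ``exact_max_total`` the null distribution
    of U is enumerated over all group assignments (midranks, so ties are
    handled exactly); otherwise the normal approximation with tie and
    continuity corrections is used.  Returns (U of the first sample,
    two-sided p, method tag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 + n2 <= exact_max_total:
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        m = n1 * n2
        combos = np.array(
            list(itertools.combinations(range(n1 + n2), n1)), dtype=np.int64
        )
        u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
        u_lo = min(u_obs, m - u_obs)
        u_hi = m - u_lo
        eps = 1e-9
        p = float(
            np.mean(u_all <= u_lo + eps) + np.mean(u_all >= u_hi - eps)
        )
        return float(u_obs), min(p, 1.0), "exact_enumeration"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "normal_approximation"


def compare_low_high(
    windows: pd.DataFrame, statistic: str, population: str
) -> ComparisonResult:
    """Contrast a window statistic between low- and high-diversity regions."""
    sub = windows[
        (windows["population"] == population) & windows["included"]
    ]
    missing = int(sub[statistic].isna().sum())
    sub = sub.dropna(subset=[statistic])
    low = sub.loc[sub["diversity_class"] == "low", statistic].to_numpy(float)
    high = sub.loc[sub["diversity_class"] == "high", statistic].to_numpy(float)
    if len(low) == 0 or len(high) == 0:
        raise ValueError(
            f"population {population}: empty low/high group for {statistic}"
        )
    u, p, method = mann_whitney_u(low, high)
    return ComparisonResult(
        statistic=statistic,
        population=population,
        mean_low=float(low.mean()),
        sd_low=float(low.std(ddof=1)) if len(low) > 1 else float("nan"),
        mean_high=float(high.mean()),
        sd_high=float(high.std(ddof=1)) if len(high) > 1 else float("nan"),
        n_low=len(low),
        n_high=len(high),
        u_statistic=u,
        p_value=p,
        method=method,
        n_missing_excluded=missing,
    )


def pearson_corr(
    df: pd.DataFrame, x: str, y: str
) -> tuple[float, float, int]:
    """Pearson r with two-sided p; pairwise deletion of missing values."""
    sub = df[[x, y]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs for {x} vs {y}, got {n}")
    xv = sub[x].to_numpy(float)
    yv = sub[y].to_numpy(float)
    if xv.std() == 0 or yv.std() == 0:
        return float("nan"), float("nan"), n
    r, p = scipy.stats.pearsonr(xv, yv)
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# Multiple linear regression + VIF
# ---------------------------------------------------------------------------


def compute_vif(df: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others.

    Perfect collinearity yields an infinite VIF (with a logged diagnostic)
    rather than an exception.
    """
    X = df[list(predictors)].dropna().to_numpy(float)
    X = sm.add_constant(X, has_constant="add")
    vals = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(1, X.shape[1]):
            v = variance_inflation_factor(X, j)
            vals.append(float(v))
    out = pd.Series(vals, index=list(predictors), name="vif")
    if np.isinf(out).any():
        logger.warning("perfect collinearity among predictors: %s",
                       list(out.index[np.isinf(out)]))
    return out


def _design(df, response, terms, standardize):
    cols = sorted({response, *itertools.chain.from_iterable(
        t.split(":") for t in terms
    )})
    data = df[cols].dropna().astype(float)
    y = data[response].to_numpy()
    X = np.empty((len(data), len(terms)))
    for j, t in enumerate(terms):
        parts = t.split(":")
        col = np.ones(len(data))
        for p in parts:
            v = data[p].to_numpy()
            if standardize:
                v = (v - v.mean()) / v.std(ddof=1)
            col = col * v
        X[:, j] = col
    return y, X, len(data)


def fit_mlr(
    df: pd.DataFrame,
    response: str = "pi_4d",
    predictors: tuple[str, ...] = ("gc", "rho", "gene_density", "ds"),
    variant: str = "main_effects",
    standardize: bool = False,
) -> list[RegressionResult]:
    """OLS of the response on the predictors, on complete cases.

    ``variant='main_effects'`` fits one additive model;
    ``variant='with_interactions'`` additionally fits, as separate model
    variants reported side by side, the main-effects model augmented with
    each pairwise interaction in turn.  Raises on rank-deficient designs,
    naming the collinear columns.
    """
    predictors = list(predictors)
    specs = [("main_effects", predictors)]
    if variant == "with_interactions":
        for a, b in itertools.combinations(predictors, 2):
            specs.append((f"main_effects+{a}:{b}", predictors + [f"{a}:{b}"]))
    elif variant != "main_effects":
        raise ValueError(f"unknown model variant {variant!r}")

    results = []
    for tag, terms in specs:
        y, X, n = _design(df, response, terms, standardize)
        if n < len(terms) + 2:
            raise ValueError(
                f"need at least {len(terms) + 2} complete rows, got {n}"
            )
        Xc = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            corr = np.corrcoef(X, rowvar=False)
            bad = [
                f"{terms[i]}~{terms[j]}"
                for i in range(len(terms))
                for j in range(i + 1, len(terms))
                if abs(corr[i, j]) > 0.999999
            ]
            raise ValueError(
                f"rank-deficient design (rank {rank} < {Xc.shape[1]}); "
                f"collinear columns: {bad or 'intercept-related'}"
            )
        fit = sm.OLS(y, Xc).fit()
        table = pd.DataFrame(
            {
                "term": ["intercept"] + terms,
                "estimate": fit.params,
                "se": fit.bse,
                "t": fit.tvalues,
                "p": fit.pvalues,
            }
        ).reset_index(drop=True)
        vif = compute_vif(df, predictors) if tag == "main_effects" else compute_vif(
            df.assign(**{
                t: df[t.split(":")[0]] * df[t.split(":")[1]]
                for t in terms if ":" in t
            }),
            terms,
        )
        results.append(
            RegressionResult(
                response=response,
                variant=tag,
                terms=table,
                vif=vif,
                r_squared=float(fit.rsquared),
                n_obs=n,
                standardized=standardize,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Pipeline configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds for every stage plus (optionally) the simulator knobs."""

    window_size: int = 100_000
    min_coding: int = 1000
    min_coverage: float = 0.5
    min_depth: int = 2
    min_qual: float = 15.0
    min_mq: float = 20.0
    min_callrate: float = 0.9
    qual_mq_combine: str = "or"
    bootstrap_reps: int = 200
    freq_floor: float = 0.0
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _simulation_config(cfg: PipelineConfig):
    from .synthetic_data import SimulationConfig

    kwargs = dict(cfg.simulation)
    if "populations" in kwargs:
        kwargs["populations"] = [tuple(p) for p in kwargs["populations"]]
    kwargs.setdefault("seed", cfg.seed)
    kwargs.setdefault("window_size", cfg.window_size)
    return SimulationConfig(**kwargs)


def run_pipeline(
    config: PipelineConfig,
    outdir,
    simulate: bool = False,
    fasta=None,
    gff=None,
    vcf=None,
    outgroup_fasta=None,
    rho_bed=None,
    manifest_tsv=None,
) -> dict:
    """Execute the full analysis and write every output table.

    With ``simulate=True`` the synthetic-data generator first writes a
    dataset into ``outdir/simulated`` and the analysis consumes those
    files; otherwise the file paths must all be provided.  Outputs (all
    TSV/JSON, deterministically formatted): the window table, per-class
    diversity summary, low/high comparisons, regression tables with VIF,
    the MK report, QC and a run manifest.  Any stage failure aborts with
    the stage name.
    """
    from . import __version__
    from .annotation_sites import (
        WindowGrid,
        build_site_class_map,
        class_gc,
        read_fasta,
        read_genome_bundle,
        read_rho_track,
        window_covariates,
    )
    from .popgen_stats import (
        class_diversity_summary,
        window_diversity,
        zscore_classify,
    )
    from .selection_stats import (
        call_substitutions,
        classify_polymorphisms,
        population_mk_report,
        window_selection_stats,
    )
    from .variant_filters import (
        allele_counts,
        apply_filters,
        read_manifest,
        read_vcf,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _T()

    if simulate:
        with stage("simulate"):
            sim_cfg = _simulation_config(config)
            sim_dir = outdir / "simulated"
            from .synthetic_data import simulate_dataset

            simulate_dataset(sim_cfg, sim_dir)
            fasta = sim_dir / "reference.fasta"
            gff = sim_dir / "genes.gff3"
            vcf = sim_dir / "variants.vcf"
            outgroup_fasta = sim_dir / "outgroup.fasta"
            rho_bed = sim_dir / "rho.bed"
            manifest_tsv = sim_dir / "manifest.tsv"
    missing_inputs = [
        n
        for n, v in (
            ("fasta", fasta),
            ("gff", gff),
            ("vcf", vcf),
            ("outgroup_fasta", outgroup_fasta),
            ("rho_bed", rho_bed),
            ("manifest_tsv", manifest_tsv),
        )
        if v is None
    ]
    if missing_inputs:
        raise ValueError(f"missing pipeline inputs: {missing_inputs} (or pass simulate=True)")

    with stage("annotate_sites"):
        bundle = read_genome_bundle(fasta, gff)
        scmap = build_site_class_map(bundle)
        grid = WindowGrid(config.window_size, bundle.scaffold_lengths())
        rho_track = read_rho_track(rho_bed)
        covariates = window_covariates(bundle, scmap, grid, rho_track)
        gc_by_class = class_gc(bundle, scmap)

    with stage("filter_variants"):
        ds = read_vcf(vcf)
        manifest = read_manifest(manifest_tsv)
        pv = apply_filters(
            ds,
            manifest,
            bundle.scaffold_lengths(),
            n_mask=scmap.n_mask,
            min_depth=config.min_depth,
            min_qual=config.min_qual,
            min_mq=config.min_mq,
            min_callrate=config.min_callrate,
            qual_mq_combine=config.qual_mq_combine,
        )
        outgroup = read_fasta(outgroup_fasta)
        pv = allele_counts(pv, outgroup)

    with stage("diversity"):
        wdiv = window_diversity(
            pv, scmap, grid,
            min_coding=config.min_coding,
            min_coverage=config.min_coverage,
        )
        wdiv = zscore_classify(wdiv)
        class_summary = class_diversity_summary(pv, scmap)

    with stage("selection"):
        pv = classify_polymorphisms(pv, scmap)
        subs = call_substitutions(pv, scmap, bundle.scaffolds, outgroup)
        wsel = window_selection_stats(pv, subs, scmap, grid)
        mk_report = population_mk_report(
            pv, subs, scmap,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
            freq_floor=config.freq_floor,
        )

    with stage("regional_analysis"):
        window_table = wdiv.merge(
            wsel, on=["population", "scaffold", "start", "end"], how="left"
        ).merge(covariates, on=["scaffold", "start", "end"], how="left")

        comparisons = []
        correlations = []
        regressions = []
        for pop in pv.populations():
            for statistic in ("pn_ps", "dn_ds"):
                try:
                    comparisons.append(asdict(compare_low_high(window_table, statistic, pop)))
                except ValueError as err:
                    logger.warning("comparison skipped: %s", err)
            inc = window_table[
                (window_table["population"] == pop) & window_table["included"]
            ]
            for xcol, ycol in (
                ("gene_density", "pi_4d"),
                ("rho", "theta_pi"),
                ("gc", "theta_pi"),
            ):
                try:
                    r, p, n = pearson_corr(inc, xcol, ycol)
                    correlations.append(
                        {"population": pop, "x": xcol, "y": ycol, "r": r, "p": p, "n": n}
                    )
                except ValueError as err:
                    logger.warning("correlation skipped: %s", err)
            try:
                for res in fit_mlr(inc, variant="with_interactions"):
                    tab = res.terms.copy()
                    tab.insert(0, "population", pop)
                    tab.insert(1, "model_variant", res.variant)
                    tab["r_squared"] = res.r_squared
                    tab["n_obs"] = res.n_obs
                    tab["vif"] = tab["term"].map(res.vif.to_dict()).astype(float)
                    regressions.append(tab)
            except ValueError as err:
                logger.warning("regression skipped for %s: %s", pop, err)

    with stage("write_outputs"):
        fmt = "%.10g"
        window_table.to_csv(outdir / "window_table.tsv", sep="\t", index=False,
                            float_format=fmt)
        class_summary.to_csv(outdir / "class_diversity.tsv", sep="\t", index=False,
                             float_format=fmt)
        gc_by_class.to_csv(outdir / "class_gc.tsv", sep="\t", index=False,
                           float_format=fmt)
        comp_df = pd.DataFrame(comparisons)
        comp_df.to_csv(outdir / "comparisons.tsv", sep="\t", index=False,
                       float_format=fmt)
        corr_df = pd.DataFrame(correlations)
        corr_df.to_csv(outdir / "correlations.tsv", sep="\t", index=False,
                       float_format=fmt)
        reg_df = (
            pd.concat(regressions, ignore_index=True)
            if regressions
            else pd.DataFrame()
        )
        reg_df.to_csv(outdir / "regression.tsv", sep="\t", index=False,
                      float_format=fmt)
        mk_report.to_csv(outdir / "mk_report.tsv", sep="\t", index=False,
                         float_format=fmt)
        qc = {"filters": pv.qc, "annotation": scmap.qc}
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True, default=str)
        manifest_out = {
            "package_version": __version__,
            "config": asdict(config),
            "stage_timings_s": timings,
            "n_windows_total": int(len(window_table)),
            "n_windows_included": int(window_table["included"].sum()),
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest_out, fh, indent=2, sort_keys=True, default=str)

    return {
        "window_table": window_table,
        "class_summary": class_summary,
        "class_gc": gc_by_class,
        "comparisons": comp_df,
        "correlations": corr_df,
        "regressions": reg_df,
        "mk_report": mk_report,
        "pv": pv,
        "scmap": scmap,
        "bundle": bundle,
        "qc": qc,
    }
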