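"""End-to-end orchestration: simulate (or load) -> sibling filter -> scale
scoring -> PRS -> bifactor CFA -> omega -> association -> IPW, with
sample-flow accounting and report tables, deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import AssociationResults, FactorAssociationModel
from .cfa import BifactorModel, BifactorResults, BifactorSpec
from .defaults import PRS_TRAITS, SCALE_NAMES
from .ipw import IpwConfig, comparison_summary, estimate_weights, weighted_refit
from .prs import PrsConfig, harmonize_alleles, ld_clump, threshold_sweep
from .reliability import OmegaSet
from .scales import keep_oldest_sibling, score_scales, standardize_scores
from .simulate import AvailabilityModel, SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: a simulation block (or input paths), PRS settings,
    measurement options, association flags, IPW settings and a seed."""

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    vcf_path: str | None = None
    sumstats_paths: dict[str, str] | None = None
    cohort_path: str | None = None
    prs: PrsConfig = field(default_factory=PrsConfig)
    conduct_on_specific: bool = False
    include_sex_covariate: bool = True
    association_mode: str = "fixed_measurement"
    ipw: IpwConfig = field(default_factory=IpwConfig)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.cohort_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of {input paths, simulation block} must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.load_yaml(path)
        sim = raw.pop("simulation", None)
        if sim is not None:
            avail = sim.pop("genotype_avail_model", None)
            if avail is not None:
                sim["genotype_avail_model"] = AvailabilityModel(**avail)
            for key in ("maf_range", "ld_r2_range", "item_cutpoints"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            for key in ("effect_corr_matrix", "true_loadings", "factor_betas"):
                if key in sim:
                    sim[key] = np.asarray(sim[key], dtype=float)
            sim = SimulationConfig(**sim)
        prs = raw.pop("prs", None)
        if prs is not None:
            if "threshold_sweep" in prs:
                prs["threshold_sweep"] = tuple(prs["threshold_sweep"])
            prs = PrsConfig(**prs)
        ipw = raw.pop("ipw", None)
        if ipw is not None:
            if "predictors" in ipw:
                ipw["predictors"] = tuple(ipw["predictors"])
            ipw = IpwConfig(**ipw)
        return cls(
            simulation=sim,
            prs=prs or PrsConfig(),
            ipw=ipw or IpwConfig(),
            **raw,
        )

    def config_hash(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # where outputs go is not part of the analysis
        blob = json.dumps(payload, default=_default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def enrolment_total(alive_at_1yr: int, later_enrolment: int) -> int:
    """Total enrolled children: initial cohort plus later-enrolled cases."""
    return int(alive_at_1yr) + int(later_enrolment)


def availability_percent(genotyped: int, phenotyped: int) -> int:
    """Genotype availability as a whole-number percentage of phenotyped."""
    return int(round(100.0 * genotyped / phenotyped))


def sample_flow(counts: dict[str, int]) -> pd.DataFrame:
    """Accounting table of persons per stage.

    Recognised keys (any subset, in order): alive_at_1yr, later_enrolment,
    enrolled, after_sibling_filter, phenotyped, genotyped.  When the two
    enrolment components are present their total is added; when phenotyped
    and genotyped are present the availability percentage is added.
    """
    counts = dict(counts)
    if "alive_at_1yr" in counts and "later_enrolment" in counts:
        counts["enrolled"] = enrolment_total(
            counts["alive_at_1yr"], counts["later_enrolment"]
        )
    rows = [{"stage": k, "n": int(v)} for k, v in counts.items()]
    flow = pd.DataFrame(rows)
    if "phenotyped" in counts and "genotyped" in counts:
        pct = availability_percent(counts["genotyped"], counts["phenotyped"])
        flow["pct_of_phenotyped"] = [
            pct if r["stage"] == "genotyped" else np.nan for r in rows
        ]
    return flow


@dataclass
class PipelineReport:
    """Everything one run produces, plus where it was written."""

    config: RunConfig
    flow: pd.DataFrame
    measurement: BifactorResults
    omega: OmegaSet
    prs_scores: pd.DataFrame
    sweep_counts: pd.DataFrame
    multivariable: AssociationResults
    univariable: AssociationResults
    ipw_comparison: pd.DataFrame
    warnings: list[str]
    output_dir: str | None = None

    def summary(self) -> str:
        parts = [
            f"pfactor run  (seed = {self.config.seed}, config = {self.config.config_hash()})"
        ]
        if self.warnings:
            parts += ["WARNINGS: " + "; ".join(self.warnings)]
        parts += [
            "",
            "Sample flow:",
            self.flow.to_string(index=False),
            "",
            self.measurement.summary(),
            "",
            "Omega reliability:",
            str(self.omega),
            "",
            self.multivariable.summary(),
            "",
            self.univariable.summary(),
            "",
            comparison_summary(self.ipw_comparison),
        ]
        return "\n".join(parts)


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tag = [
        f"config = {report.config.config_hash()}",
        f"seed = {report.config.seed}",
    ]
    io.write_table(report.flow, outdir / "sample_flow.tsv", tag)
    loading = report.measurement.loading_table().reset_index(names="scale")
    io.write_table(loading, outdir / "loadings.tsv", tag)
    (outdir / "measurement.json").write_text(report.measurement.to_json())
    (outdir / "omega.json").write_text(json.dumps(report.omega.as_dict(), indent=2))
    io.write_table(report.prs_scores, outdir / "prs_scores.tsv", tag)
    io.write_table(report.sweep_counts, outdir / "threshold_sweep.tsv", tag)
    io.write_table(report.multivariable.table, outdir / "association_multivariable.tsv", tag)
    io.write_table(report.univariable.table, outdir / "association_univariable.tsv", tag)
    io.write_table(report.ipw_comparison, outdir / "ipw_comparison.tsv", tag)
    (outdir / "report.txt").write_text(report.summary() + "\n")


def run(config: RunConfig) -> PipelineReport:
    """Execute the full pipeline; halts with the failing stage named."""
    warnings_log: list[str] = []
    stage = "simulate"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            panel, sumstats, cohort = simulate_cohort(sim)
        else:
            raise NotImplementedError(
                "loading external cohort inputs requires vcf/sumstats/cohort paths; "
                "use io.read_vcf/read_sumstats and the library API"
            )
        counts = {"enrolled": len(cohort)}

        stage = "sibling_filter"
        cohort = keep_oldest_sibling(cohort)
        counts["after_sibling_filter"] = len(cohort)

        stage = "scale_scoring"
        scored = score_scales(cohort)
        complete = scored.dropna(subset=list(SCALE_NAMES))
        counts["phenotyped"] = len(complete)
        scores_std = standardize_scores(scored).loc[complete.index]

        stage = "prs"
        geno = cohort[cohort["genotype_available"]]
        counts["genotyped"] = int(complete["person_id"].isin(set(geno["person_id"])).sum())
        prs_frames = {}
        sweep_rows = []
        for trait, tab in zip(PRS_TRAITS, sumstats):
            effects = harmonize_alleles(tab, panel, drop_ambiguous=config.prs.drop_ambiguous)
            retained = ld_clump(effects, panel, config.prs)
            sweep = threshold_sweep(panel, effects, retained, config.prs)
            for t, vec in sweep.items():
                sweep_rows.append(
                    {
                        "trait": trait,
                        "threshold": t,
                        "n_snps": int(vec["n_snps"].iloc[0]),
                        "primary": t == config.prs.p_threshold,
                    }
                )
            primary = sweep.get(config.prs.p_threshold)
            if primary is None:
                from .prs import compute_prs

                primary = compute_prs(panel, effects, retained, config.prs)
            prs_frames[f"prs_{trait}"] = primary.set_index("person_id")["z"]
        prs_scores = pd.DataFrame(prs_frames).reset_index()
        prs_scores = prs_scores[
            prs_scores["person_id"].isin(set(geno["person_id"]))
        ].reset_index(drop=True)
        sweep_counts = pd.DataFrame(sweep_rows)

        stage = "cfa"
        spec = BifactorSpec.default(conduct_on_specific=config.conduct_on_specific)
        model = BifactorModel.from_scores(scores_std, spec=spec)
        if model.rank_warning:
            warnings_log.append("sample covariance near rank-deficient")
        measurement = model.fit(seed=config.seed)
        if not measurement.converged:
            warnings_log.append("measurement model did not fully converge")
        if measurement.heywood:
            warnings_log.append("Heywood-adjacent unique variance in measurement model")
        measurement.sandwich_se()

        stage = "omega"
        omega_set = measurement.omega()

        stage = "association"
        predictors = prs_scores.merge(
            cohort[["person_id", "sex"]], on="person_id", how="left"
        )
        covars = ("sex",) if config.include_sex_covariate else ()
        assoc_model = FactorAssociationModel(
            measurement,
            scores_std,
            predictors,
            prs_cols=[f"prs_{t}" for t in PRS_TRAITS],
            covariate_cols=covars,
            mode=config.association_mode,
        )
        multivariable = assoc_model.fit()
        univariable = assoc_model.fit_univariable()

        stage = "ipw"
        cohort_scored = cohort[["person_id", "sex", "genotype_available"]].merge(
            scored, on="person_id"
        )
        weights = estimate_weights(
            cohort_scored,
            predictors=list(config.ipw.predictors),
            stabilize=config.ipw.stabilize,
            trim_quantile=config.ipw.trim_quantile,
        )
        if int(weights["trimmed"].sum()):
            warnings_log.append(f"{int(weights['trimmed'].sum())} IPW weights trimmed")
        _, _, ipw_comparison = weighted_refit(
            measurement,
            scores_std,
            predictors,
            weights,
            prs_cols=[f"prs_{t}" for t in PRS_TRAITS],
            covariate_cols=covars,
            mode=config.association_mode,
        )

        stage = "report"
        report = PipelineReport(
            config=config,
            flow=sample_flow(counts),
            measurement=measurement,
            omega=omega_set,
            prs_scores=prs_scores,
            sweep_counts=sweep_counts,
            multivariable=multivariable,
            univariable=univariable,
            ipw_comparison=ipw_comparison,
            warnings=warnings_log,
        )
        if config.output_dir:
            _write_outputs(report, Path(config.output_dir))
            report.output_dir = config.output_dir
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def plot_threshold_sweep(sweep_assoc: pd.DataFrame, path: str | Path) -> None:
    """Beta-by-threshold plot (one line per trait) from a sweep association
    table with columns trait, threshold, beta, se."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for trait, sub in sweep_assoc.groupby("trait"):
        sub = sub.sort_values("threshold")
        ax.errorbar(
            sub["threshold"], sub["beta"], yerr=1.96 * sub["se"], marker="o", label=trait
        )
    ax.set_xscale("log")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("p-value threshold")
    ax.set_ylabel("standardized beta")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
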