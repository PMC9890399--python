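"""End-to-end orchestration: simulate -> score -> equate -> validate.

``run_pipeline`` reproduces the full validation workflow on synthetic data
from a single seed: it generates the study, scores every arm on a common
0-195 metric (raw totals for the full arm, equipercentile-equated totals for
the short arm, expected-test-score conversion for the adaptive arm), and runs
the comparison battery (descriptives, effect sizes, density shifts, ROC/AUC
with pairwise tests per stratum, Bland-Altman agreement and within-person
correlations where the remaining-items protocol provides paired data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bank import ItemBank
from .cat import CATConfig, CATResult, administer, lookup_provider
from .equate import ConcordanceTable, ScoreDistribution, equipercentile_equate
from .errors import SrsCatError
from .io import write_study, write_summary_json
from .irt import raw_total_score
from .simulate import (
    SimulatedStudy,
    StudyDesign,
    SyntheticBankSpec,
    group_label,
    simulate_study,
)
from .stats import (
    bland_altman,
    cohens_d,
    compare_auc,
    cutoff_metrics,
    density_shift_summary,
    descriptive_table,
    roc_auc,
)

__all__ = ["RunConfig", "PipelineReport", "build_score_table", "run_pipeline",
           "replay_cat", "write_report"]

FULL_MAX = 195


@dataclass
class RunConfig:
    """One-seed configuration for the whole pipeline."""

    seed: int = 0
    out_dir: str | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    bank_spec: SyntheticBankSpec = field(default_factory=SyntheticBankSpec)
    cat: CATConfig = field(default_factory=CATConfig)
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "design": asdict(self.design),
            "bank_spec": asdict(self.bank_spec),
            "cat": {
                k: v
                for k, v in asdict(self.cat).items()
                if k not in ("prior", "grid")
            },
            "cat_prior": {"mean": self.cat.prior.mean, "sd": self.cat.prior.sd},
            "make_plots": self.make_plots,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .irt import NormalPrior

        design = StudyDesign(**{**d.get("design", {})})
        spec_d = dict(d.get("bank_spec", {}))
        if "groups" in spec_d:
            spec_d["groups"] = tuple(spec_d["groups"])
        bank_spec = SyntheticBankSpec(**spec_d)
        cat_kwargs = dict(d.get("cat", {}))
        prior_d = d.get("cat_prior")
        if prior_d:
            cat_kwargs["prior"] = NormalPrior(**prior_d)
        if "design" in d and "arms" in d["design"]:
            design = StudyDesign(**{**d["design"], "arms": tuple(d["design"]["arms"])})
        return cls(
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir"),
            design=design,
            bank_spec=bank_spec,
            cat=CATConfig(**cat_kwargs),
            make_plots=d.get("make_plots", True),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def replay_cat(
    row: pd.Series, bank: ItemBank, config: CATConfig, group: str | None
) -> CATResult:
    """Re-run the adaptive administration from a recorded response row.

    The engine is deterministic given the bank and config, so replaying the
    recorded responses reproduces the original item sequence even when only
    the administered items were recorded.
    """
    responses = {}
    for item_id in bank.item_ids:
        v = row.get(f"item_{item_id}")
        if v is not None and not pd.isna(v):
            responses[item_id] = int(v)
    return administer(lookup_provider(responses), bank, group, config)


def build_score_table(
    responses: pd.DataFrame,
    bank: ItemBank,
    cat_config: CATConfig | None = None,
    concordance: ConcordanceTable | None = None,
) -> tuple[pd.DataFrame, ConcordanceTable | None]:
    """Score every administration on the common 0-195 metric.

    full arm: raw total (= scaled score).  short arm: raw short total,
    scaled by equipercentile equating against the full arm's observed
    distribution (or a supplied concordance).  cat arm: CAT replay ->
    expected-test-score conversion.  Rows with a complete 65-item record
    (full arm, or shortened arms under the remaining-items protocol) also get
    a ``full_total`` for within-person comparisons.
    """
    cat_config = cat_config or CATConfig()
    kmax = bank.n_categories - 1
    rows = []
    for _, row in responses.iterrows():
        rec = {c: row[c] for c in
               ("respondent_id", "arm", "site", "sex", "form", "diagnosis")}
        grp = group_label(row["form"], row["sex"]) if bank.groups else None
        answered = {
            item_id: int(row[f"item_{item_id}"])
            for item_id in bank.item_ids
            if f"item_{item_id}" in row and not pd.isna(row[f"item_{item_id}"])
        }
        complete = len(answered) == bank.n_items
        rec["full_total"] = (
            raw_total_score(answered, bank, "full") if complete else np.nan
        )
        if row["arm"] == "full":
            rec["raw_score"] = raw_total_score(answered, bank, "full")
            rec["scaled_score"] = float(rec["raw_score"])
        elif row["arm"] == "short":
            rec["raw_score"] = raw_total_score(
                {i: answered[i] for i in bank.short_mask if i in answered},
                bank,
                "short",
            )
            rec["scaled_score"] = np.nan  # filled after equating
        elif row["arm"] == "cat":
            cat_responses = answered
            if complete:
                # replay sees only what the adaptive session would request
                cat_responses = dict(answered)
            result = administer(
                lookup_provider(cat_responses), bank, grp, cat_config
            )
            rec["raw_score"] = np.nan
            rec["scaled_score"] = result.cat_predicted_score
            rec["cat_n_items"] = result.n_items
            rec["cat_stop_reason"] = result.stop_reason
            rec["cat_final_eap"] = result.final_eap
            rec["cat_final_se"] = result.final_se
        else:
            raise SrsCatError(f"unknown arm {row['arm']!r}")
        rows.append(rec)
    table = pd.DataFrame(rows)

    short_mask_n = len(bank.short_mask)
    if (table["arm"] == "short").any():
        if concordance is None:
            if not (table["arm"] == "full").any():
                raise SrsCatError(
                    "cannot equate short scores: no full-arm reference "
                    "distribution and no concordance supplied"
                )
            source = ScoreDistribution.from_scores(
                table.loc[table["arm"] == "short", "raw_score"],
                0,
                kmax * short_mask_n,
            )
            target = ScoreDistribution.from_scores(
                table.loc[table["arm"] == "full", "raw_score"],
                0,
                kmax * bank.n_items,
            )
            concordance = equipercentile_equate(source, target)
        short_rows = table["arm"] == "short"
        table.loc[short_rows, "scaled_score"] = concordance.lookup(
            table.loc[short_rows, "raw_score"].to_numpy()
        )
    return table, concordance


@dataclass
class PipelineReport:
    study: SimulatedStudy
    score_table: pd.DataFrame
    concordance: ConcordanceTable | None
    descriptives: pd.DataFrame
    density_shifts: pd.DataFrame
    roc: dict
    auc_comparisons: pd.DataFrame
    cutoffs: dict
    bland_altman: dict
    summary: dict


def _strata(table: pd.DataFrame):
    yield "overall", table
    for sex in ("male", "female"):
        yield sex, table[table["sex"] == sex]


def run_validation(score_table: pd.DataFrame) -> dict:
    """Comparison battery on a scored table; returns the report pieces."""
    descriptives = descriptive_table(
        score_table, ["site", "arm", "diagnosis"], "scaled_score"
    )
    shifts = []
    for cmp_arm in ("short", "cat"):
        s = density_shift_summary(score_table, "full", cmp_arm, group_by="site")
        shifts.append(s)
    density_shifts = pd.concat(shifts, ignore_index=True)

    roc_by_stratum: dict = {}
    comparisons = []
    cutoffs: dict = {}
    for stratum, sub in _strata(score_table):
        roc_by_stratum[stratum] = {}
        cutoffs[stratum] = {}
        for arm in ("full", "short", "cat"):
            sub_arm = sub[(sub["arm"] == arm) & sub["scaled_score"].notna()]
            labels = (sub_arm["diagnosis"] == "ASD").to_numpy()
            if labels.sum() == 0 or (~labels).sum() == 0:
                continue
            roc = roc_auc(sub_arm["scaled_score"].to_numpy(), labels)
            roc_by_stratum[stratum][arm] = roc
            table, optimal = cutoff_metrics(roc)
            cutoffs[stratum][arm] = {"table": table, "optimal_cutoff": optimal}
        arms_present = list(roc_by_stratum[stratum])
        for i, arm_a in enumerate(arms_present):
            for arm_b in arms_present[i + 1 :]:
                cmp_res = compare_auc(
                    roc_by_stratum[stratum][arm_a],
                    roc_by_stratum[stratum][arm_b],
                    paired=False,
                )
                comparisons.append(
                    {
                        "stratum": stratum,
                        "arm_a": arm_a,
                        "arm_b": arm_b,
                        "auc_a": roc_by_stratum[stratum][arm_a].auc,
                        "auc_b": roc_by_stratum[stratum][arm_b].auc,
                        "chi_square": cmp_res.chi_square,
                        "df": cmp_res.df,
                        "p_value": cmp_res.p_value,
                    }
                )
    auc_comparisons = pd.DataFrame(comparisons)

    # within-person agreement where paired full totals exist (general site)
    ba: dict = {}
    correlations: dict = {}
    for arm in ("short", "cat"):
        paired = score_table[
            (score_table["arm"] == arm)
            & score_table["full_total"].notna()
            & score_table["scaled_score"].notna()
        ]
        if len(paired) >= 3:
            ba[arm] = bland_altman(
                paired["scaled_score"].to_numpy(), paired["full_total"].to_numpy()
            )
            correlations[arm] = float(
                np.corrcoef(paired["scaled_score"], paired["full_total"])[0, 1]
            )
    return {
        "descriptives": descriptives,
        "density_shifts": density_shifts,
        "roc": roc_by_stratum,
        "auc_comparisons": auc_comparisons,
        "cutoffs": cutoffs,
        "bland_altman": ba,
        "correlations": correlations,
    }


def run_pipeline(config: RunConfig | None = None) -> PipelineReport:
    """Execute simulate -> score -> equate -> validate from one seed and
    (optionally) write the report directory."""
    config = config or RunConfig()
    study = simulate_study(
        config.design, config.bank_spec, config.seed, cat_config=config.cat
    )
    score_table, concordance = build_score_table(
        study.responses, study.bank, config.cat
    )
    battery = run_validation(score_table)

    arm_counts = (
        score_table.groupby(["site", "arm"], observed=True)
        .size()
        .unstack(fill_value=0)
        .to_dict("index")
    )
    cat_rows = score_table[score_table["arm"] == "cat"]
    site_d = {}
    for arm in ("full", "short", "cat"):
        sub = score_table[score_table["arm"] == arm]
        clin = sub.loc[sub["site"] == "clinical", "scaled_score"].dropna()
        gen = sub.loc[sub["site"] == "general", "scaled_score"].dropna()
        if len(clin) >= 2 and len(gen) >= 2:
            site_d[arm] = cohens_d(clin, gen)
    summary = {
        "seed": config.seed,
        "n_respondents": int(len(score_table)),
        "arm_counts": arm_counts,
        "auc": {
            stratum: {arm: roc.auc for arm, roc in by_arm.items()}
            for stratum, by_arm in battery["roc"].items()
        },
        "cohens_d_site_by_arm": site_d,
        "cat_length": {
            "mean": float(cat_rows["cat_n_items"].mean()) if len(cat_rows) else None,
            "min": int(cat_rows["cat_n_items"].min()) if len(cat_rows) else None,
            "max": int(cat_rows["cat_n_items"].max()) if len(cat_rows) else None,
        },
        "bland_altman": {
            arm: {
                "mean_difference": r.mean_difference,
                "sd_difference": r.sd_difference,
                "limits": list(r.limits),
                "pct_within": r.pct_within,
                "n": r.n,
            }
            for arm, r in battery["bland_altman"].items()
        },
        "within_person_correlation": battery["correlations"],
    }

    report = PipelineReport(
        study=study,
        score_table=score_table,
        concordance=concordance,
        descriptives=battery["descriptives"],
        density_shifts=battery["density_shifts"],
        roc=battery["roc"],
        auc_comparisons=battery["auc_comparisons"],
        cutoffs=battery["cutoffs"],
        bland_altman=battery["bland_altman"],
        summary=summary,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir, make_plots=config.make_plots)
    return report


def write_report(report: PipelineReport, out_dir, make_plots: bool = True) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_study(report.study, out_dir / "data")
    report.score_table.to_csv(out_dir / "scores.csv", index=False)
    report.descriptives.to_csv(out_dir / "descriptives.csv", index=False)
    report.density_shifts.to_csv(out_dir / "density_shifts.csv", index=False)
    if report.concordance is not None:
        report.concordance.to_frame().to_csv(out_dir / "concordance.csv", index=False)
    report.auc_comparisons.to_csv(out_dir / "auc_comparisons.csv", index=False)
    for stratum, by_arm in report.roc.items():
        for arm, roc in by_arm.items():
            pd.DataFrame(
                {
                    "threshold": roc.thresholds,
                    "sensitivity": roc.sensitivities,
                    "specificity": roc.specificities,
                }
            ).to_csv(out_dir / f"roc_{stratum}_{arm}.csv", index=False)
    for arm, r in report.bland_altman.items():
        pd.DataFrame(
            [
                {
                    "arm": arm,
                    "mean_difference": r.mean_difference,
                    "sd_difference": r.sd_difference,
                    "lower_limit": r.limits[0],
                    "upper_limit": r.limits[1],
                    "pct_within": r.pct_within,
                    "n": r.n,
                }
            ]
        ).to_csv(out_dir / f"bland_altman_{arm}.csv", index=False)
    write_summary_json(report.summary, out_dir / "summary.json")
    if make_plots:
        _write_plots(report, out_dir)


def _write_plots(report: PipelineReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm as _norm

    colors = {"full": "tab:blue", "short": "tab:red", "cat": "tab:green"}
    # normal-density approximation of the scaled-score distributions per site
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, site in zip(axes, ("clinical", "general")):
        sub = report.score_table[report.score_table["site"] == site]
        xs = np.linspace(0, FULL_MAX, 400)
        for arm in ("full", "short", "cat"):
            vals = sub.loc[sub["arm"] == arm, "scaled_score"].dropna()
            if len(vals) >= 2:
                ax.plot(
                    xs,
                    _norm.pdf(xs, vals.mean(), vals.std(ddof=1)),
                    color=colors[arm],
                    label=arm,
                )
        ax.set_title(f"{site} site")
        ax.set_xlabel("scaled score (0-195)")
        ax.legend()
    axes[0].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(out_dir / "densities.png", dpi=120)
    plt.close(fig)

    for stratum, by_arm in report.roc.items():
        if not by_arm:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        for arm, roc in by_arm.items():
            ax.plot(
                1 - roc.specificities,
                roc.sensitivities,
                color=colors[arm],
                label=f"{arm} (AUC={roc.auc:.2f})",
            )
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC, {stratum}")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(out_dir / f"roc_{stratum}.png", dpi=120)
        plt.close(fig)

    for arm, r in report.bland_altman.items():
        paired = report.score_table[
            (report.score_table["arm"] == arm)
            & report.score_table["full_total"].notna()
        ]
        if paired.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        means = (paired["scaled_score"] + paired["full_total"]) / 2
        diffs = paired["scaled_score"] - paired["full_total"]
        ax.scatter(means, diffs, s=12, alpha=0.6)
        for y in (r.mean_difference, *r.limits):
            ax.axhline(y, color="tab:red", ls="--", lw=0.8)
        ax.set_xlabel("mean of paired scores")
        ax.set_ylabel(f"{arm} - full difference")
        ax.set_title(f"Bland-Altman, {arm} vs full")
        fig.tight_layout()
        fig.savefig(out_dir / f"bland_altman_{arm}.png", dpi=120)
        plt.close(fig)
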