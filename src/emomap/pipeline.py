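"""End-to-end analysis runner: raw cohort tables -> structured report.

Assembles the per-participant score frame (consistency, cluster distances,
concept measures, recognition accuracy, covariates), then runs

1. the five repeated-measures / regression group-comparison families
   (consistency, between-cluster distance, within-cluster distance,
   vocabulary, the two valence conceptual distances);
2. shadow-feature (Boruta) selection of the 19 candidate predictors of
   mean recognition accuracy, separately per group, with follow-up linear
   models on the confirmed + tentative features (fit twice, excluding the
   between- and within-cluster distance respectively, which are too
   strongly correlated to enter together);
3. the two forward mediation models (between-valence conceptual distance
   -> cluster distance -> recognition) and their reversed-direction
   counterparts, with BC bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AQ_SUBSCALES, TAS_SUBSCALES, CohortData
from .concepts import score_concepts
from .consistency import score_consistency
from .design import EMOTIONS
from .differentiation import score_differentiation
from .inference import (BorutaSelector, Mediation, compare_groups,
                        ols_anova, rank_regression)
from .recognition import score_recognition

MODEL_COVARIATES = ["age", "sex", "nvr", "education_years", "tas",
                    "vocab_total", "between_valence_distance",
                    "within_valence_distance", "mean_word_count"]
CONCEPT_COVARIATES = ["age", "sex", "nvr", "education_years", "tas",
                      "mean_word_count"]
BORUTA_PREDICTORS = ["consistency_mean", "dist_between_mean",
                     "dist_within_mean", "vocab_total",
                     "within_valence_distance", "between_valence_distance",
                     "aq", "tas", *AQ_SUBSCALES, *TAS_SUBSCALES,
                     "nvr", "education_years", "age"]
MEDIATION_COVARIATES = ["nvr", "aq", "tas", "education_years",
                        "vocab_total", "mean_word_count"]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters (defaults follow the package's choices)."""

    mds_components: int = 2
    mds_n_init: int = 8
    mds_max_iter: int = 300
    mds_tol: float = 1e-6
    boruta_n_iter: int = 100
    boruta_alpha: float = 0.01
    bootstrap_B: int = 2000
    seed: int = 0


def build_analysis_frames(cohort: CohortData,
                          config: AnalysisConfig | None = None) -> dict:
    """Score every task and join covariates into analysis-ready frames.

    Returns ``person`` (one row per participant) plus the three long frames
    used by the repeated-measures models.
    """
    config = config or AnalysisConfig()
    cons = score_consistency(cohort.choices)
    diff = score_differentiation(
        cohort.similarity, n_components=config.mds_components,
        n_init=config.mds_n_init, max_iter=config.mds_max_iter,
        tol=config.mds_tol, random_state=config.seed)
    conc = score_concepts(cohort.definitions, cohort.embeddings)
    rec = score_recognition(cohort.plf)

    cons_emo = cons[cons["condition"].isin(EMOTIONS)]
    cons_mean = (cons_emo.groupby("participant")["consistency"].mean()
                 .rename("consistency_mean").reset_index())
    person = (cohort.participants
              .merge(conc, on="participant")
              .merge(rec[["participant", "accuracy_mean"]], on="participant")
              .merge(diff, on="participant")
              .merge(cons_mean, on="participant"))
    if person.isna().any().any():
        raise ValueError("incomplete score frame after assembly")

    cons_long = (cons_emo.rename(columns={"condition": "emotion"})
                 .merge(person.drop(columns=["consistency_mean"]),
                        on="participant"))
    between_long = person.melt(
        id_vars=[c for c in person.columns
                 if not c.startswith("dist_between_")],
        value_vars=["dist_between_AH", "dist_between_AS", "dist_between_HS"],
        var_name="emotion_pair", value_name="dist_between")
    within_long = person.melt(
        id_vars=[c for c in person.columns
                 if not c.startswith("dist_within_")],
        value_vars=["dist_within_A", "dist_within_H", "dist_within_S"],
        var_name="emotion", value_name="dist_within")
    return dict(person=person, consistency_long=cons_long,
                between_long=between_long, within_long=within_long,
                consistency_all=cons)


def _records(df: pd.DataFrame) -> list[dict]:
    return df.to_dict("records")


def _mediation_dict(report) -> dict:
    return dict(n=report.n, B=report.B, seed=report.seed,
                paths={k: dict(estimate=v.estimate, ci_low=v.ci_low,
                               ci_high=v.ci_high, significant=v.significant)
                       for k, v in report.paths.items()})


def run_full_analysis(cohort: CohortData,
                      config: AnalysisConfig | None = None) -> dict:
    """Run every analysis family on a scored cohort; returns a JSON-safe dict."""
    config = config or AnalysisConfig()
    frames = build_analysis_frames(cohort, config)
    person = frames["person"]
    report: dict = {"config": asdict(config), "n": len(person),
                    "group_models": {}, "boruta": {}, "followup": {},
                    "mediation": {}}

    gm = report["group_models"]
    gm["consistency"] = _records(compare_groups(
        frames["consistency_long"], "consistency", within_factor="emotion",
        covariates=MODEL_COVARIATES))
    gm["dist_between"] = _records(compare_groups(
        frames["between_long"], "dist_between", within_factor="emotion_pair",
        covariates=MODEL_COVARIATES))
    gm["dist_within"] = _records(compare_groups(
        frames["within_long"], "dist_within", within_factor="emotion",
        covariates=MODEL_COVARIATES))
    gm["vocab_total"] = _records(rank_regression(
        person, "vocab_total", ["group", *CONCEPT_COVARIATES]))
    gm["between_valence_distance"] = _records(compare_groups(
        person, "between_valence_distance", covariates=CONCEPT_COVARIATES))
    gm["within_valence_distance"] = _records(compare_groups(
        person, "within_valence_distance", covariates=CONCEPT_COVARIATES))

    rng = np.random.default_rng(config.seed)
    for grp, sub in person.groupby("group"):
        sel = BorutaSelector(n_iter=config.boruta_n_iter,
                             alpha=config.boruta_alpha,
                             random_state=int(rng.integers(2 ** 31)))
        sel.fit(sub[BORUTA_PREDICTORS], sub["accuracy_mean"])
        mean_imp = np.nanmean(sel.importance_history_, axis=0)
        report["boruta"][grp] = dict(
            decisions=sel.decisions_,
            mean_importance=dict(zip(BORUTA_PREDICTORS,
                                     map(float, mean_imp))),
            n_iter=int(sel.n_iter_))
        kept = [f for f, d in sel.decisions_.items() if d != "rejected"]
        report["followup"][grp] = {}
        for variant, drop in (("excl_between", "dist_between_mean"),
                              ("excl_within", "dist_within_mean")):
            preds = [f for f in kept if f != drop]
            if not preds:
                continue
            fit = ols_anova(sub, "accuracy_mean", preds)
            report["followup"][grp][variant] = _records(fit)

    na = person[person["group"] == "non-autistic"]
    med_specs = {
        "between_forward": ("between_valence_distance", "dist_between_mean"),
        "within_forward": ("between_valence_distance", "dist_within_mean"),
        "between_reversed": ("dist_between_mean", "between_valence_distance"),
        "within_reversed": ("dist_within_mean", "between_valence_distance"),
    }
    for name, (pred, medi) in med_specs.items():
        med = Mediation(pred, medi, "accuracy_mean",
                        covariates=MEDIATION_COVARIATES,
                        B=config.bootstrap_B,
                        random_state=int(rng.integers(2 ** 31))).fit(na)
        report["mediation"][name] = _mediation_dict(med.report_)
    return report


def write_report(report: dict, out_dir) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    lines = [f"cohort n = {report['n']}", ""]
    for family, rows in report["group_models"].items():
        lines.append(f"[{family}]")
        for r in rows:
            stat = "F" if "F" in r else "t"
            lines.append(f"  {r['term']}: {stat}={r.get('F', r.get('t')):.3f}"
                         f" p={r['p']:.4f}")
        lines.append("")
    for grp, b in report["boruta"].items():
        conf = [f for f, d in b["decisions"].items() if d == "confirmed"]
        tent = [f for f, d in b["decisions"].items() if d == "tentative"]
        lines.append(f"[boruta {grp}] confirmed: {conf}; tentative: {tent}")
    lines.append("")
    for name, m in report["mediation"].items():
        p = m["paths"]["indirect"]
        sig = "significant" if p["significant"] else "n.s."
        lines.append(f"[mediation {name}] indirect={p['estimate']:.3f} "
                     f"95% CI=({p['ci_low']:.3f}, {p['ci_high']:.3f}) {sig}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
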