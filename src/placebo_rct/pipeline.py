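"""End-to-end orchestration of the analysis pipeline.

Stage order mirrors the study flow: clean app ratings → responder
stratification → questionnaire screen → network statistics → subcortical
volumes → (optionally) cross-validated prediction.  Each stage writes its
artifact into the run directory; a manifest records the config hash and
every derived seed, so reruns with the same config reproduce every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import brain, ema, prediction, questionnaires
from .blinding import make_scrambled_codes, write_key
from .config import PipelineConfig
from .io import (
    read_mask, read_matrix, read_questionnaires, read_ratings, read_visits,
    read_volumes, write_matrix, write_ratings, write_table, write_visits,
)
from .synthetic import SCAN_VISITS, CohortParams, generate_cohort

logger = logging.getLogger(__name__)


def _load_or_generate(cfg: PipelineConfig, out: Path):
    if cfg.synthetic:
        params = CohortParams(**{**cfg.cohort_params, "seed": cfg.seed})
        cohort = generate_cohort(params)
        write_ratings(cohort.ratings, out / "ratings.csv")
        write_visits({s: cohort.visit_dates for s in cohort.subject_ids},
                     out / "visits.csv")
        write_table(cohort.questionnaires, out / "questionnaires.csv")
        write_table(cohort.volumes, out / "volumes.csv")
        mdir = out / "matrices"
        mdir.mkdir(exist_ok=True)
        for (sid, visit), m in cohort.connectivity.items():
            write_matrix(m, mdir / f"{sid}_{visit}.txt")
        arms = cohort.subjects.set_index("subject_id")["arm"]
        return (cohort.ratings, {s: cohort.visit_dates for s in cohort.subject_ids},
                cohort.questionnaires, cohort.volumes, cohort.connectivity, arms)

    for name in ("ratings_csv", "visits_csv"):
        if getattr(cfg, name) is None:
            raise FileNotFoundError(f"config.{name} is required when synthetic=false")
    ratings = read_ratings(cfg.ratings_csv)
    visits = read_visits(cfg.visits_csv)
    quest = read_questionnaires(cfg.questionnaires_csv) if cfg.questionnaires_csv else None
    vols = read_volumes(cfg.volumes_csv) if cfg.volumes_csv else None
    conn = {}
    if cfg.matrices_dir:
        for f in sorted(Path(cfg.matrices_dir).glob("*.txt")):
            sid, visit = f.stem.rsplit("_", 1)
            conn[(sid, visit)] = read_matrix(f)
    arms = pd.Series({s: ("PTx" if not s.startswith("NoTx") else "NoTx")
                      for s in ratings})
    return ratings, visits, quest, vols, conn, arms


def _stratify_stage(cfg, ratings, visits, out: Path) -> pd.DataFrame:
    rows = []
    for sid, series in ratings.items():
        cleaned = ema.dedupe_ratings(
            list(zip(series.entries["timestamp"], series.entries["vas"])), sid
        )
        labeled = ema.assign_periods(cleaned, visits[sid])
        bl = labeled.period_values("BL")
        t1 = labeled.period_values("T1")
        t2 = labeled.period_values("T2")
        res = ema.stratify(
            bl, t1, t2, alpha=cfg.stratify_alpha, n_perm=cfg.stratify_n_perm,
            seed=ema.subject_seed(cfg.seed, sid), subject_id=sid,
        )
        summ = ema.magnitude_of_response(
            bl,
            ema.last_week_values(labeled, "T1", visits[sid]),
            ema.last_week_values(labeled, "T2", visits[sid]),
            subject_id=sid,
        )
        rows.append({**asdict(res), "magnitude_units": summ.magnitude_units,
                     "pct_analgesia": summ.pct_analgesia,
                     "period_of_max": summ.period_of_max})
    df = pd.DataFrame(rows)
    write_table(df, out / "stratification.csv")
    logger.info("stratify: %d subjects, %d responders", len(df),
                int((df["label"] == "Responder").sum()))
    return df


def _screen_stage(cfg, quest, strat, arms, out: Path) -> pd.DataFrame:
    table = questionnaires.SubscaleTable(quest.set_index("subject_id"))
    ptx = strat[strat["subject_id"].map(arms) == "PTx"]
    labels = ptx.set_index("subject_id")["label"]
    magnitude = ptx.set_index("subject_id")["pct_analgesia"]
    report = questionnaires.univariate_screen(
        table, labels, magnitude, m_comparisons=cfg.bonferroni_m
    )
    write_table(report.reset_index(), out / "screen.tsv", sep="\t")
    return report


def _network_stage(cfg, conn, strat, arms, out: Path):
    mask = read_mask(cfg.node_mask) if cfg.node_mask else None
    labels = strat.set_index("subject_id")["label"]
    ptx = [s for s in labels.index if arms.get(s) == "PTx"]
    ga, gb = [], []
    for sid in ptx:
        key = (sid, "V2")  # pre-treatment scan
        if key not in conn:
            continue
        m = conn[key]
        if mask:
            m = brain.restrict_to_nodes(m, mask)
        z = brain.fisher_z(m)
        (ga if labels[sid] == "Responder" else gb).append(z)
    result = brain.edgewise_permutation_test(
        ga, gb, n_perm=cfg.edgewise_n_perm, fdr_alpha=cfg.fdr_alpha,
        seed=cfg.seed + 101,
    )
    write_table(result.to_frame(), out / "edges.tsv", sep="\t")
    logger.info("network: %d edges tested, %d significant after FDR",
                len(result.p), int(result.significant.sum()))
    return result


def _volumes_stage(cfg, vols, strat, arms, out: Path) -> pd.DataFrame:
    v2 = vols[vols["visit"] == SCAN_VISITS[0]].set_index("subject_id")
    labels = strat.set_index("subject_id")["label"]
    rows = []
    for sid, row in v2.iterrows():
        if sid not in labels.index:
            continue
        rows.append({"subject_id": sid, "label": labels[sid],
                     "arm": arms.get(sid, "PTx"),
                     "asymmetry": brain.asymmetry_ratio(row),
                     "peripheral_gm": row.get("peripheral_gm", np.nan),
                     "age": row.get("age", np.nan), "sex": row.get("sex", np.nan)})
    df = pd.DataFrame(rows)
    # ANCOVA-style contrast: residualize on covariates, then group t
    cov = df[["peripheral_gm", "age", "sex"]].to_numpy(dtype=float)
    if not np.isnan(cov).any():
        adj = brain.residualize(df["asymmetry"].to_numpy(), cov)
    else:
        adj = df["asymmetry"].to_numpy()
    df["asymmetry_adjusted"] = adj
    resp = adj[(df["label"] == "Responder").to_numpy()]
    nonr = adj[(df["label"] == "NonResponder").to_numpy()]
    if len(resp) >= 2 and len(nonr) >= 2:
        t, p = sps.ttest_ind(resp, nonr)
        df.attrs["group_t"], df.attrs["group_p"] = float(t), float(p)
    write_table(df, out / "volumes_report.csv")
    return df


def _predict_stage(cfg, quest, strat, arms, out: Path):
    ptx = strat[strat["subject_id"].map(arms) == "PTx"].set_index("subject_id")
    X = quest.set_index("subject_id").loc[ptx.index]
    clf = prediction.nested_loocv_classify(
        X, ptx["label"], inner_folds=cfg.inner_folds, seed=cfg.seed + 211
    )
    reg = prediction.nested_loocv_lasso(
        X, ptx["pct_analgesia"],
        selection=None, inner_folds=cfg.inner_folds, seed=cfg.seed + 223,
        report_threshold=cfg.consensus_report_threshold,
    )
    write_table(
        pd.DataFrame({"subject_id": reg.subject_ids, "fold": range(len(reg.y_true)),
                      "predicted": reg.y_pred, "actual": reg.y_true}),
        out / "predictions.csv",
    )
    write_table(reg.consensus.to_frame().reset_index(names="feature"),
                out / "weights.tsv", sep="\t")
    report = {
        "accuracy": clf.accuracy, "accuracy_ci": list(clf.accuracy_ci),
        "sensitivity": clf.sensitivity, "sensitivity_ci": list(clf.sensitivity_ci),
        "specificity": clf.specificity, "specificity_ci": list(clf.specificity_ci),
        "confusion": clf.confusion,
        "lasso_r": reg.r_pred_actual, "lasso_p": reg.p_pred_actual,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return clf, reg


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages end to end; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ratings, visits, quest, vols, conn, arms = _load_or_generate(cfg, out)

    artifacts = {}
    strat = None
    if "stratify" in cfg.stages:
        strat = _stratify_stage(cfg, ratings, visits, out)
        artifacts["stratification"] = "stratification.csv"
        key = make_scrambled_codes(
            strat.set_index("subject_id")["label"], seed=cfg.seed + 307
        )
        write_key(key, out / "codes.csv", out / "key.json")
        artifacts["blinding"] = "codes.csv"
    if "screen" in cfg.stages and quest is not None and strat is not None:
        _screen_stage(cfg, quest, strat, arms, out)
        artifacts["screen"] = "screen.tsv"
    if "network" in cfg.stages and conn and strat is not None:
        _network_stage(cfg, conn, strat, arms, out)
        artifacts["edges"] = "edges.tsv"
    if "volumes" in cfg.stages and vols is not None and strat is not None:
        _volumes_stage(cfg, vols, strat, arms, out)
        artifacts["volumes"] = "volumes_report.csv"
    if "predict" in cfg.stages and quest is not None and strat is not None:
        _predict_stage(cfg, quest, strat, arms, out)
        artifacts["prediction"] = "report.json"

    manifest = {
        "config_hash": cfg.hash(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stage_seeds": {"stratify": "per-subject (stable hash of id)",
                        "network": cfg.seed + 101, "classify": cfg.seed + 211,
                        "lasso": cfg.seed + 223, "blinding": cfg.seed + 307},
        "artifacts": artifacts,
        "n_subjects": len(ratings),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
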