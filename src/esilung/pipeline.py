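"""End-to-end pipeline: synthesise cohort, score, cluster, validate, report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .clustering import affinity_propagation, sila_matrix
from .cohort import CohortSpec, cohort_table, generate_cohort
from .exceptions import DomainError
from .stats import (
    best_threshold,
    chi_squared,
    cv_roc,
    games_howell,
    pearson_r,
    steiger_z,
    welch_anova,
)

log = logging.getLogger("esilung")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run (defaults mirror the package's
    stated defaults throughout)."""

    seed: int = 1
    n_ne: int = 57
    n_me: int = 58
    n_se: int = 79
    noise_sd: float = 0.02
    n_grid: int = 100
    n_samples: int = 200
    damping: float = 0.7
    preference: float | None = None
    k_folds: int = 10
    write_curves: bool = True
    write_ct: bool = False
    ct_dims: tuple[int, int, int] = (30, 30, 30)

    def __post_init__(self):
        if self.seed < 0:
            raise DomainError("seed must be non-negative")
        if not 0.5 <= self.damping < 1.0:
            raise DomainError("damping must lie in [0.5, 1)")
        if self.k_folds < 2:
            raise DomainError("k_folds must be >= 2")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "ct_dims" in data:
            data["ct_dims"] = tuple(data["ct_dims"])
        return cls(**data)


def _correlation_block(table: pd.DataFrame) -> dict:
    """ESI correlations with CT and functional metrics + Steiger contrasts."""
    esi = table["esi_fit"].to_numpy(dtype=float)
    out = {"pearson": {}, "steiger": {}}
    for col in ("laa950_insp", "laa856_exp", "plda", "flda", "fev1", "fev1_fvc"):
        out["pearson"][f"esi_vs_{col}"] = pearson_r(esi, table[col].to_numpy(dtype=float))
    # is the emphysema CT metric more strongly related to ESI than to FEV1?
    n = len(table)
    for metric in ("laa950_insp", "plda"):
        m = table[metric].to_numpy(dtype=float)
        for fn in ("fev1", "fev1_fvc"):
            f = table[fn].to_numpy(dtype=float)
            res = steiger_z(pearson_r(m, esi), pearson_r(m, f), pearson_r(esi, f), n)
            out["steiger"][f"{metric}: esi_vs_{fn}"] = {"z": res.z, "p": res.p}
    return out


def _group_block(table: pd.DataFrame) -> dict:
    groups = [g for g in ("NE", "ME", "SE") if (table["group"] == g).sum() >= 2]
    if len(groups) < 2:
        log.warning("fewer than two usable groups: ANOVA/post-hoc stage skipped")
        return {"skipped": True, "reason": "fewer than two groups with n >= 2"}
    out: dict = {"skipped": False, "groups": groups, "summaries": {}, "anova": {},
                 "games_howell": {}}
    for var in ("esi_fit", "fev1", "fvc", "fev1_fvc"):
        sets = [table.loc[table["group"] == g, var].to_numpy(dtype=float) for g in groups]
        out["summaries"][var] = {
            g: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.size)}
            for g, v in zip(groups, sets)
        }
        res = welch_anova(sets)
        out["anova"][var] = {"f_star": res.f_star, "df1": res.df1,
                             "df2": res.df2, "p": res.p}
        gh = games_howell(sets)
        out["games_howell"][var] = {
            f"{groups[int(r.group1)]}/{groups[int(r.group2)]}": {
                "mean_diff": r.mean_diff, "p": r.p}
            for r in gh.itertuples()
        }
    return out


def _roc_block(table: pd.DataFrame, k_folds: int, seed: int) -> dict:
    esi = table["esi_fit"].to_numpy(dtype=float)
    out = {}
    tasks = {
        "severe_vs_rest": (table["group"] == "SE").to_numpy().astype(int),
        "absence_vs_rest": (table["group"] == "NE").to_numpy().astype(int),
    }
    for name, y in tasks.items():
        if min(y.sum(), y.size - y.sum()) < k_folds:
            log.warning("ROC task %s skipped: class too small for %d folds",
                        name, k_folds)
            out[name] = {"skipped": True}
            continue
        roc = cv_roc(esi, y, k_folds=k_folds, seed=seed)
        thr, sens, spec = best_threshold(roc)
        out[name] = {
            "skipped": False,
            "auc": roc.auc,
            "mean_fold_auc": roc.mean_fold_auc,
            "best_threshold": thr,
            "sensitivity": sens,
            "specificity": spec,
        }
    return out


def _report_markdown(report: dict) -> str:
    lines = ["# Synthetic cohort validation report", ""]
    gb = report["groups"]
    if not gb.get("skipped"):
        lines += ["## Group means (mean (SD))", "",
                  "| variable | " + " | ".join(gb["groups"]) + " | Welch p |",
                  "|---|" + "---|" * (len(gb["groups"]) + 1)]
        for var, summ in gb["summaries"].items():
            cells = [f"{summ[g]['mean']:.2f} ({summ[g]['sd']:.2f})" for g in gb["groups"]]
            lines.append(f"| {var} | " + " | ".join(cells)
                         + f" | {gb['anova'][var]['p']:.2e} |")
        lines += ["", "## Games-Howell pairwise p-values", ""]
        pairs = list(next(iter(gb["games_howell"].values())).keys())
        lines += ["| variable | " + " | ".join(pairs) + " |",
                  "|---|" + "---|" * len(pairs)]
        for var, tab in gb["games_howell"].items():
            lines.append(f"| {var} | " + " | ".join(f"{tab[p]['p']:.2e}" for p in pairs) + " |")
    lines += ["", "## ESI correlations", "", "| pair | r |", "|---|---|"]
    for k, v in report["correlations"]["pearson"].items():
        lines.append(f"| {k} | {v:.3f} |")
    lines += ["", "| Steiger contrast | z | p |", "|---|---|---|"]
    for k, v in report["correlations"]["steiger"].items():
        lines.append(f"| {k} | {v['z']:.2f} | {v['p']:.2e} |")
    if "clusters" in report and not report["clusters"].get("skipped"):
        cl = report["clusters"]
        lines += ["", "## Clustering", "",
                  f"- clusters: {cl['n_clusters']} (converged: {cl['converged']})"]
        if "chi2" in cl:
            lines.append(f"- cluster x group chi-squared: {cl['chi2']:.1f} "
                         f"(df {cl['df']:.0f}, p {cl['p']:.2e})")
    lines += ["", "## Cross-validated ROC", "",
              "| task | pooled AUC | mean fold AUC | threshold | sens | spec |",
              "|---|---|---|---|---|---|"]
    for name, r in report["roc"].items():
        if r.get("skipped"):
            lines.append(f"| {name} | skipped | | | | |")
        else:
            lines.append(
                f"| {name} | {r['auc']:.3f} | {r['mean_fold_auc']:.3f} | "
                f"{r['best_threshold']:.2f} | {r['sensitivity']:.2f} | "
                f"{r['specificity']:.2f} |")
    return "\n".join(lines) + "\n"


def validate_cohort(table: pd.DataFrame, profiles: dict | None,
                    config: RunConfig) -> dict:
    """Run the statistical battery on a cohort table (+ optional profiles)."""
    report: dict = {"n": int(len(table))}
    report["groups"] = _group_block(table)
    report["correlations"] = _correlation_block(table)
    if profiles is not None and len(profiles) >= 2:
        ids = table["id"].tolist()
        dissim = sila_matrix([profiles[i] for i in ids])
        cl = affinity_propagation(dissim, damping=config.damping,
                                  preference=config.preference,
                                  seed=config.seed)
        table["cluster"] = cl.labels
        block = {"skipped": False, "n_clusters": cl.n_clusters,
                 "converged": cl.converged, "n_iter": cl.n_iter}
        if cl.n_clusters >= 2 and table["group"].nunique() >= 2:
            ct = pd.crosstab(table["group"], table["cluster"])
            stat, df, p = chi_squared(ct.to_numpy())
            block.update({"chi2": stat, "df": df, "p": p})
        report["clusters"] = block
        report["_cluster_result"] = cl
    report["roc"] = _roc_block(table, config.k_folds, config.seed)
    return report


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Generate, score, cluster and validate a synthetic cohort; write outputs.

    Returns the report dict.  All randomness flows from ``config.seed``;
    two runs with the same config produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(n_ne=config.n_ne, n_me=config.n_me, n_se=config.n_se,
                      noise_sd=config.noise_sd, n_samples=config.n_samples,
                      seed=config.seed)
    log.info("generating cohort (n=%d)", spec.n_ne + spec.n_me + spec.n_se)
    records = generate_cohort(spec)
    table = cohort_table(records)
    profiles = {r.subject_id: r.profile for r in records}

    report = validate_cohort(table, profiles, config)
    cl = report.pop("_cluster_result", None)

    table.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
    eio.write_profiles(profiles, out / "profiles.csv")
    if cl is not None:
        eio.write_clusters(table["id"].tolist(), cl, out / "clusters.csv")
    if config.write_curves:
        curve_dir = out / "curves"
        curve_dir.mkdir(exist_ok=True)
        for r in records:
            eio.write_curve(r.curve, curve_dir / f"{r.subject_id}.csv")
    if config.write_ct:
        from .cohort import generate_paired_ct

        ct_dir = out / "ct"
        ct_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(config.seed + 10_000)
        for r in records:
            study = generate_paired_ct(
                config.ct_dims,
                {"laa950_insp": r.laa950_insp, "plda": r.plda, "flda": r.flda},
                rng=rng)
            eio.save_paired_ct(study, ct_dir / f"{r.subject_id}_insp.nii.gz",
                               ct_dir / f"{r.subject_id}_exp.nii.gz",
                               ct_dir / f"{r.subject_id}_mask.nii.gz")
    eio.write_json(report, out / "report.json")
    (out / "report.md").write_text(_report_markdown(report))
    # per-subject fit reports
    subj = {r.subject_id: {"esi_true": r.esi_true, "esi_fit": r.esi_fit,
                           "group": r.group, "severity": r.severity}
            for r in records}
    eio.write_json(subj, out / "subjects.json")
    return report
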