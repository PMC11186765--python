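"""End-to-end orchestration: generate/load -> describe -> compare ->
correlate -> ROC/PR -> cut-offs -> classify -> transfer.

Every stochastic stage receives its own seed derived deterministically from
a single root seed (stage name hashed into the root via SeedSequence), so a
stage re-run in isolation reproduces its in-pipeline output.  Each stage
writes tidy CSV/JSON artifacts; a manifest records seeds, row counts and
content hashes of all numeric outputs.
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

from . import classify as cls
from . import cohorts, mixture, roc, stats

logger = logging.getLogger("evb")

__all__ = ["AnalysisConfig", "run_pipeline", "validate_table", "stage_seed"]

REQUIRED_COLUMNS = [
    "subject_id",
    "cohort",
    "diagnosis",
    "fraction",
    "tau3r",
    "tau4r",
    "tau_ratio",
    "tdp43",
]

_STAGES = ("simulate", "inject", "roc", "cutoffs", "pr")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    Either ``table_path`` (a cohort CSV) or ``generator`` ("describe2" /
    "santpau") must be set.  ``prevalence`` maps a positive diagnosis to the
    population prevalence used for precision-recall re-expression; the
    package ships no epidemiology of its own.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    table_path: str | None = None
    generator: str | None = "describe2"
    markers: tuple[str, ...] = ("tau_ratio", "tdp43")
    fraction: str = "sEV"
    alpha: float = 0.05
    conf_level: float = 0.95
    n_boot: int = 100
    exclude_confirmed: bool = True
    weighted_crossings: bool = True
    k_components: int = 3
    prevalence: dict = field(default_factory=dict)
    roc_pairs: tuple = (("PSP", "HC", "tau_ratio"), ("ALS", "HC", "tdp43"))
    transfer_rule: cls.ClassificationRule | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError("conf_level must be in (0, 1)")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


def validate_table(path: str | Path) -> list[dict]:
    """Schema report for a cohort CSV: returns a machine-readable issue list.

    Checks column presence, numeric types, tau-ratio consistency
    (tau_ratio == tau3r/tau4r within 1e-9 relative) and duplicate
    (subject_id, fraction) keys.  An empty list means the table is clean.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    issues: list[dict] = []
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            issues.append({"issue": "missing_column", "column": col})
    if issues:
        return issues
    for col in ("tau3r", "tau4r", "tau_ratio", "tdp43"):
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        for line in (table.index[bad] + 2).tolist():  # +2: header + 1-based
            issues.append({"issue": "non_numeric", "column": col, "line": int(line)})
    ratio = table["tau3r"] / table["tau4r"]
    ok = np.isclose(ratio, table["tau_ratio"], rtol=1e-9, atol=1e-12) | ~np.isfinite(ratio)
    for line in (table.index[~ok] + 2).tolist():
        issues.append({"issue": "tau_ratio_inconsistent", "line": int(line)})
    dup = table.duplicated(subset=["subject_id", "fraction"], keep=False)
    for line in (table.index[dup] + 2).tolist():
        issues.append({"issue": "duplicate_subject_fraction", "line": int(line)})
    return issues


def _load_or_generate(config: AnalysisConfig) -> pd.DataFrame:
    if config.table_path is not None:
        issues = validate_table(config.table_path)
        fatal = [i for i in issues if i["issue"] in ("missing_column", "non_numeric")]
        if fatal:
            raise ValueError(f"schema violations in {config.table_path}: {fatal}")
        return pd.read_csv(config.table_path)
    if config.generator == "describe2":
        specs = cohorts.describe_subcohort2_specs()
        name = "DESCRIBE-2"
    elif config.generator == "santpau":
        specs = cohorts.sant_pau_specs()
        name = "SantPau"
    else:
        raise ValueError(f"unknown generator {config.generator!r}")
    table = cohorts.generate_cohort(specs, seed=stage_seed(config.seed, "simulate"), cohort=name)
    return cohorts.inject_pathology_labels(table, specs, seed=stage_seed(config.seed, "inject"))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and write per-stage artifacts plus a manifest.

    Returns a report bundle (dict) with the key results; identical config
    and seed give byte-identical numeric outputs.  A failure in one stage
    does not corrupt artifacts already written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": {k: str(v) for k, v in dataclasses.asdict(config).items()}}

    table = _load_or_generate(config)
    n_before = len(table)
    table = table[table["fraction"] == config.fraction].reset_index(drop=True)
    logger.info("fraction filter %s: %d of %d rows kept", config.fraction, len(table), n_before)
    if table.empty:
        raise ValueError(f"no rows with fraction {config.fraction!r}")
    cohorts.write_cohort(table, out_dir / "cohort.csv", seed=config.seed)

    for marker in config.markers:
        if marker not in table.columns:
            raise ValueError(f"unknown marker {marker!r}")

    # descriptives
    desc_rows = []
    for (diag, marker), grp in (
        table.melt(id_vars="diagnosis", value_vars=list(config.markers), var_name="marker")
        .groupby(["diagnosis", "marker"])
    ):
        med, q1, q3 = stats.median_iqr(grp["value"])
        desc_rows.append({"diagnosis": diag, "marker": marker, "median": med, "q1": q1, "q3": q3, "n": len(grp)})
    describe = pd.DataFrame(desc_rows)
    describe.to_csv(out_dir / "describe.csv", index=False)
    bundle["describe"] = describe

    # group comparisons
    comp_frames = []
    diagnoses = sorted(table["diagnosis"].unique())
    for marker in config.markers:
        groups = [table.loc[table["diagnosis"] == d, marker].dropna() for d in diagnoses]
        comparison = stats.dunn_pairwise(groups, diagnoses)
        frame = comparison.to_frame()
        frame.insert(0, "marker", marker)
        frame["h"] = comparison.h_statistic
        frame["p_global"] = comparison.p_global
        comp_frames.append(frame)
    compare = pd.concat(comp_frames, ignore_index=True)
    compare.to_csv(out_dir / "compare.csv", index=False)
    bundle["compare"] = compare

    # correlations with NfL, within each patient group that has NfL
    corr_frames = []
    if "nfl" in table.columns:
        for diag in diagnoses:
            sub = table[table["diagnosis"] == diag]
            if sub["nfl"].notna().sum() < 3:
                continue
            cm = stats.spearman_matrix(sub, list(config.markers) + ["nfl"])
            frame = cm.to_frame()
            frame.insert(0, "diagnosis", diag)
            corr_frames.append(frame)
    if corr_frames:
        correlate = pd.concat(corr_frames, ignore_index=True)
        correlate.to_csv(out_dir / "correlate.csv", index=False)
        bundle["correlate"] = correlate

    # ROC / PR
    roc_rows = []
    pr_rows = []
    for pos_name, neg_name, marker in config.roc_pairs:
        pos = table.loc[table["diagnosis"] == pos_name, marker].dropna()
        neg = table.loc[table["diagnosis"] == neg_name, marker].dropna()
        if pos.empty or neg.empty:
            continue
        result = roc.auc_mann_whitney(pos, neg, orientation="auto")
        roc_rows.append(
            {
                "positive": pos_name,
                "negative": neg_name,
                "marker": marker,
                "auc": result.auc,
                "se": result.se,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "orientation": result.orientation,
                "n_pos": result.n_pos,
                "n_neg": result.n_neg,
            }
        )
        rho = config.prevalence.get(pos_name)
        if rho is not None:
            pr = roc.pr_with_prevalence(
                result,
                rho,
                n_boot=config.n_boot,
                seed=stage_seed(config.seed, f"pr:{pos_name}:{marker}"),
                scores=(pos.to_numpy(), neg.to_numpy()),
            )
            pr_rows.append(
                {
                    "positive": pos_name,
                    "negative": neg_name,
                    "marker": marker,
                    "prevalence": rho,
                    "auprc": pr.auprc,
                    "ci_low": pr.ci_low,
                    "ci_high": pr.ci_high,
                }
            )
    roc_table = pd.DataFrame(roc_rows)
    roc_table.to_csv(out_dir / "roc.csv", index=False)
    bundle["roc"] = roc_table
    if pr_rows:
        pr_table = pd.DataFrame(pr_rows)
        pr_table.to_csv(out_dir / "pr.csv", index=False)
        bundle["pr"] = pr_table

    # mixture cut-offs
    fit_table = table[table["pathology"] == "unknown"] if config.exclude_confirmed else table
    cut_objs = {}
    cut_rows = []
    for marker in config.markers:
        cut = mixture.fit_marker_cutoffs(
            fit_table[marker].dropna().to_numpy(),
            marker=marker,
            cohort=str(table["cohort"].iloc[0]),
            k=config.k_components,
            n_boot=config.n_boot,
            alpha=config.alpha,
            seed=stage_seed(config.seed, f"cutoffs:{marker}"),
            weighted=config.weighted_crossings,
        )
        cut_objs[marker] = cut
        cut_rows.append(
            {
                "marker": marker,
                "lower": cut.lower,
                "upper": cut.upper,
                "k_selected": cut.meta.get("k_selected"),
                "weighted": cut.weighted,
                "n_fit": cut.meta.get("n"),
                "means": list(cut.model.means),
                "sds": list(cut.model.sds),
                "weights": list(cut.model.weights),
            }
        )
    (out_dir / "cutoffs.json").write_text(json.dumps(cut_rows, indent=2, default=float))
    bundle["cutoffs"] = cut_rows

    # classification under the fitted rule
    rule = cls.ClassificationRule(
        tau_lower=cut_objs["tau_ratio"].lower,
        tau_upper=cut_objs["tau_ratio"].upper,
        tdp_lower=cut_objs["tdp43"].lower,
        tdp_upper=cut_objs["tdp43"].upper,
        cohort=str(table["cohort"].iloc[0]),
        provenance={"source": "fitted", "seed": config.seed},
    )
    bundle["rule"] = rule
    classified = cls.classify_table(table, rule)
    classified.to_csv(out_dir / "classified.csv", index=False)

    confirmed = classified[classified["pathology"] != "unknown"]
    if not confirmed.empty and (confirmed["pathology"] == "TDP-43").any():
        perf = cls.diagnostic_performance(
            confirmed["predicted"].eq(cls.LABEL_TDP).to_numpy(),
            confirmed["pathology"].eq("TDP-43").to_numpy(),
            config.conf_level,
        )
        bundle["tdp_performance"] = perf
        (out_dir / "performance.json").write_text(json.dumps(dataclasses.asdict(perf), indent=2))

    # cross-cohort transfer
    if config.transfer_rule is not None:
        transfer = cls.transfer_cutoffs(
            config.transfer_rule,
            classified,
            truth_spec={"positive": ["TDP-43"]},
            native_rule=rule,
            conf_level=config.conf_level,
        )
        bundle["transfer"] = transfer
        (out_dir / "transfer.json").write_text(
            json.dumps({k: dataclasses.asdict(v) if v else None for k, v in transfer.items()}, indent=2)
        )

    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "rows": int(len(table)),
        "hashes": {p.name: _hash_file(p) for p in sorted(out_dir.glob("*.csv")) + sorted(out_dir.glob("*.json")) if p.name != "manifest.json"},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest

    summary = [
        f"cohort rows: {len(table)}",
        f"cut-offs tau_ratio: {rule.tau_lower:.3f} / {rule.tau_upper:.3f}",
        f"cut-offs tdp43: {rule.tdp_lower:.2f} / {rule.tdp_upper:.2f} pg/ml",
    ]
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    return bundle
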