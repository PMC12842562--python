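"""End-to-end orchestration: generate/load -> split -> calibrate -> reduce ->
select -> audit -> report.

`run_pipeline` executes the whole analysis from a single :class:`RunConfig`
and writes table analogues (item parameters, reduction trace, screening
performance, efficiency, DIF/DTF) as TSV plus one machine-readable JSON
summary.  Every output carries the configuration hash, and every p-value the
stopping rule consulted is logged into the summary, making the inference-
driven selection auditable.  Identical configuration and seeds reproduce the
JSON byte for byte.
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

from .banks import (
    REVERSE_KEYED_ITEMS,
    ScaleDefinition,
    reference_scales,
)
from .dif import dif_table
from .efficiency import bootstrap_compare_within, bootstrap_se, cross_set_z
from .irt import TwoPLModel, cronbach_alpha
from .reduction import SequentialReduction, sum_score
from .roc import (
    auc,
    chisq_two_proportions,
    cutoff_table,
    mcnemar,
    predictive_values,
    youden_cutoff,
)
from .simulate import Cohort, CohortConfig, generate_cohort, stratified_split

log = logging.getLogger("gdsirt")

__all__ = ["RunConfig", "run_pipeline", "read_response_csv"]


@dataclass
class RunConfig:
    """Configuration for one full pipeline run (all seeds explicit)."""

    # input: either a cohort CSV path or a synthetic-cohort specification
    input_csv: str | None = None
    n_subjects: int = 6525
    cohort_seed: int = 20260
    theta_case: tuple[float, float] = (1.7, 1.0)
    theta_control: tuple[float, float] = (0.0, 1.0)
    # split
    split_ratio: float = 0.5
    split_seed: int = 20261
    # IRT
    irt_tol: float = 1e-4
    irt_max_iter: int = 500
    grid_nodes: int = 61
    # reduction
    k_min: int = 4
    alpha: float = 0.05
    rule: str = "dual"
    # bootstrap
    bootstrap_B: int = 1000
    bootstrap_seed: int = 20262
    # DIF
    dif_groups: tuple[str, ...] = ("sex", "age_group", "source")
    dif_sample: str = "combined"  # or "validation"
    # output
    outdir: str = "gdsirt_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("theta_case", "theta_control", "dif_groups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("theta_case", "theta_control", "dif_groups"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # analysis identity, not output location
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_response_csv(path, keymap=REVERSE_KEYED_ITEMS):
    """Read a raw person x item CSV and key all items in the depressive
    direction.

    Expects ``item_XX`` columns, a ``diagnosis`` column and optional
    covariates (sex, age_group, source).  Items listed in ``keymap`` are
    reverse-worded and get flipped (``x -> 1 - x``).  Non-binary cells are
    rejected with the offending rows and columns identified; per-item
    missingness is recorded on the returned cohort.
    """
    df = pd.read_csv(path)
    item_cols = sorted(c for c in df.columns if c.startswith("item_"))
    if not item_cols or "diagnosis" not in df.columns:
        raise ValueError("CSV needs item_XX columns and a diagnosis column")
    item_ids = [int(c.split("_")[-1]) for c in item_cols]
    unknown = [i for i in keymap if i not in item_ids]
    if unknown:
        raise ValueError(f"keymap references absent items: {unknown}")
    resp = df[item_cols].astype(float)
    bad = ~(resp.isin([0.0, 1.0]) | resp.isna())
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        locs = [f"row {r}, column {item_cols[c]}" for r, c in zip(rows, cols)][:20]
        raise ValueError("non-binary response cells: " + "; ".join(locs))
    for item in keymap:
        col = f"item_{item:02d}"
        resp[col] = 1.0 - resp[col]
    cov_cols = [c for c in ("sex", "age_group", "source") if c in df.columns]
    cohort = Cohort(
        responses=resp,
        diagnosis=df["diagnosis"].to_numpy(dtype=int),
        covariates=df[cov_cols].copy(),
    )
    miss = resp.isna().mean()
    if miss.any():
        log.info("per-item missingness: %s", miss[miss > 0].to_dict())
    return cohort


def _scale_performance(cohort: Cohort, scale: ScaleDefinition) -> dict:
    scores = sum_score(cohort.responses, scale)
    roc = auc(scores, cohort.diagnosis)
    cut = youden_cutoff(scores, cohort.diagnosis)
    predicted = scores >= cut.cutoff
    correct = predicted == (cohort.diagnosis == 1)
    return {
        "scores": scores,
        "roc": roc,
        "cutoff": cut,
        "correct": correct,
        "tp": int(np.sum(predicted & (cohort.diagnosis == 1))),
        "tn": int(np.sum(~predicted & (cohort.diagnosis == 0))),
        "n_cases": int(np.sum(cohort.diagnosis == 1)),
        "n_controls": int(np.sum(cohort.diagnosis == 0)),
    }


def _json_safe(obj):
    """Recursively convert numpy scalars to Python and NaN to null."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the summary bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    summary: dict = {"config": config.to_dict(), "config_hash": cfg_hash}

    # ---- input -----------------------------------------------------------
    if config.input_csv is not None:
        log.info("loading cohort from %s", config.input_csv)
        cohort = read_response_csv(config.input_csv)
    else:
        cc = CohortConfig(
            n_subjects=config.n_subjects,
            theta_case=config.theta_case,
            theta_control=config.theta_control,
            seed=config.cohort_seed,
        )
        log.info("generating synthetic cohort (n=%d)", cc.n_subjects)
        cohort = generate_cohort(cc)

    # ---- split -----------------------------------------------------------
    dev, val = stratified_split(cohort, config.split_ratio, config.split_seed)
    summary["split"] = {"n_dev": dev.n, "n_val": val.n}

    # ---- calibrate on the development set --------------------------------
    from .irt import LatentGrid

    model = TwoPLModel(dev.responses)
    fit = model.fit(
        grid=LatentGrid.standard_normal(config.grid_nodes),
        tol=config.irt_tol,
        max_iter=config.irt_max_iter,
    )
    fit.attach_item_aucs(dev.diagnosis)
    ranking = fit.rank_items()
    _write_tsv(fit.item_bank.to_frame(), outdir / "item_params.tsv", cfg_hash)
    summary["irt"] = {
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "loglike": round(fit.loglike, 4),
        "ranking": [int(i) for i in ranking],
    }

    # ---- sequential reduction -------------------------------------------
    red = SequentialReduction(
        dev, val, ranking, fit.item_bank,
        k_min=config.k_min, alpha=config.alpha, rule=config.rule,
    ).fit()
    red.to_tsv(outdir / "reduction_trace.tsv")
    selected = red.selected_scale
    rule_log = [
        {
            "k": int(r.k),
            "p_dev": round(float(r.p_dev), 6),
            "p_val": round(float(r.p_val), 6),
            "passes": bool(
                r.p_dev > config.alpha
                and (config.rule == "dev_only" or r.p_val > config.alpha)
            ),
        }
        for r in red.trace.itertuples()
    ]
    summary["reduction"] = {
        "k_selected": int(red.k_selected),
        "no_reduction": bool(red.no_reduction),
        "elbow": None if red.elbow is None else int(red.elbow),
        "selected_items": list(selected.items),
        "stopping_rule_log": rule_log,
    }

    # ---- screening performance & efficiency ------------------------------
    scales = {
        name: sc
        for name, sc in reference_scales().items()
        if set(sc.items) <= set(int(i) for i in model.item_ids)
    }
    scales[selected.name] = selected
    full_name = "GDS30" if "GDS30" in scales else max(scales, key=lambda s: len(scales[s]))

    perf_rows = []
    eff_results: dict[tuple[str, str], object] = {}
    perf_cache: dict[tuple[str, str], dict] = {}
    for sname, sc in scales.items():
        for setname, half in (("development", dev), ("validation", val)):
            perf_cache[(sname, setname)] = _scale_performance(half, sc)
    for sname, sc in scales.items():
        for setname, half in (("development", dev), ("validation", val)):
            perf = perf_cache[(sname, setname)]
            eff = bootstrap_se(
                perf["scores"], half.diagnosis, len(sc),
                B=config.bootstrap_B, seed=config.bootstrap_seed, scale=sname,
            )
            eff_results[(sname, setname)] = eff
            ref = perf_cache[(full_name, setname)]
            row = {
                "scale": sname,
                "set": setname,
                "n_items": len(sc),
                "auc": perf["roc"].auc,
                "ci_low": perf["roc"].ci[0],
                "ci_high": perf["roc"].ci[1],
                "cutoff": perf["cutoff"].cutoff,
                "sensitivity": perf["cutoff"].sensitivity,
                "specificity": perf["cutoff"].specificity,
                "efficiency": eff.ratio,
                "efficiency_se": eff.se,
                "mcnemar_p_vs_full": (
                    None
                    if sname == full_name
                    else mcnemar(perf["correct"], ref["correct"])
                ),
            }
            perf_rows.append(row)
    for sname in scales:
        pdev = perf_cache[(sname, "development")]
        pval = perf_cache[(sname, "validation")]
        sens_p = chisq_two_proportions(
            pdev["tp"], pdev["n_cases"], pval["tp"], pval["n_cases"]
        )
        spec_p = chisq_two_proportions(
            pdev["tn"], pdev["n_controls"], pval["tn"], pval["n_controls"]
        )
        ed, ev = eff_results[(sname, "development")], eff_results[(sname, "validation")]
        z, p = cross_set_z(ed.ratio, ed.se, ev.ratio, ev.se)
        for row in perf_rows:
            if row["scale"] == sname:
                row["sens_cross_p"] = sens_p
                row["spec_cross_p"] = spec_p
                row["efficiency_cross_p"] = p
    perf_df = pd.DataFrame(perf_rows)
    _write_tsv(perf_df, outdir / "screening_performance.tsv", cfg_hash)
    summary["performance"] = perf_df.round(6).to_dict(orient="records")

    # bootstrap efficiency comparisons against the full scale (per set)
    eff_cmp = []
    for sname, sc in scales.items():
        if sname == full_name:
            continue
        for setname, half in (("development", dev), ("validation", val)):
            cmp = bootstrap_compare_within(
                perf_cache[(sname, setname)]["scores"], len(sc),
                perf_cache[(full_name, setname)]["scores"], len(scales[full_name]),
                half.diagnosis, B=config.bootstrap_B, seed=config.bootstrap_seed,
            )
            eff_cmp.append(
                {
                    "scale": sname,
                    "vs": full_name,
                    "set": setname,
                    "diff": cmp.diff,
                    "ci_low": cmp.ci[0],
                    "ci_high": cmp.ci[1],
                    "significant": cmp.significant,
                    "p_boot": cmp.p_boot,
                }
            )
    eff_cmp_df = pd.DataFrame(eff_cmp)
    _write_tsv(eff_cmp_df, outdir / "efficiency_comparisons.tsv", cfg_hash)
    summary["efficiency_comparisons"] = eff_cmp_df.round(6).to_dict(orient="records")

    # ---- selected-scale audits -------------------------------------------
    val_perf = perf_cache[(selected.name, "validation")]
    sens = val_perf["cutoff"].sensitivity / 100
    spec = val_perf["cutoff"].specificity / 100
    pv = {
        f"{prev:g}": dict(
            zip(("ppv", "npv"), map(lambda x: round(x, 6),
                                    predictive_values(sens, spec, prev)))
        )
        for prev in (0.038, 0.13, 0.20)
    }
    summary["selected_scale"] = {
        "name": selected.name,
        "items": list(selected.items),
        "cronbach_alpha_validation": round(
            cronbach_alpha(val.responses, selected), 6
        ),
        "youden_cutoff_validation": val_perf["cutoff"].cutoff,
        "sensitivity_validation": round(val_perf["cutoff"].sensitivity, 4),
        "specificity_validation": round(val_perf["cutoff"].specificity, 4),
        "predictive_values": pv,
    }
    _write_tsv(
        cutoff_table(val_perf["scores"], val.diagnosis),
        outdir / "cutoff_sweep.tsv",
        cfg_hash,
    )

    # ---- DIF / DTF --------------------------------------------------------
    dif_cohort = cohort if config.dif_sample == "combined" else val
    groupings = {
        g: dif_cohort.covariates[g].to_numpy()
        for g in config.dif_groups
        if g in dif_cohort.covariates
    }
    dif_df = dif_table(
        dif_cohort.responses, selected, groupings, labels=dif_cohort.diagnosis
    )
    _write_tsv(dif_df, outdir / "dif_report.tsv", cfg_hash)
    summary["dif"] = dif_df.round(6).to_dict(orient="records")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_json_safe(summary), fh, indent=2, sort_keys=True)
    log.info("pipeline complete; outputs in %s", outdir)
    return summary
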