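"""End-to-end orchestration: cohort -> episodes -> survival -> costs -> tables.

``run_pipeline`` reproduces the study's full table suite on either a
synthetic cohort or a directory of claims CSVs: the patient-flow cascade, a
demographics table and comorbidity prevalences, Kaplan-Meier persistence
rates with confidence bands and pairwise tests against a reference biologic,
the pre/post cost tables split by persistence, and the medication-gap
sensitivity grid.  Outputs are diff-able CSVs plus step-function persistence
plots; a run log records the seed and a hash of the configuration.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as coh
from .bundle import ClaimsBundle, read_bundle
from .config import DRUGS, PipelineConfig
from .costs import contrast_by_persistence, to_thousand_jpy, window_cost_table
from .persistence import build_episodes, sensitivity_grid
from .survival import km_estimate, pairwise_vs_reference, survival_at
from .synthetic import generate_cohort

log = logging.getLogger("persistkit")


def demographics_table(units: pd.DataFrame) -> pd.DataFrame:
    """n, mean age and % female per drug x {total, naive, experienced}."""
    rows = []
    strata = (
        ("total", pd.Series(True, index=units.index)),
        ("naive", units["naive"].astype(bool) if len(units) else pd.Series(dtype=bool)),
        ("experienced", ~units["naive"].astype(bool) if len(units) else pd.Series(dtype=bool)),
    )
    for stratum, mask in strata:
        pool = units[mask] if len(units) else units
        for drug in [*DRUGS, "subtotal"]:
            sub = pool if drug == "subtotal" else pool[pool["drug"] == drug]
            rows.append({
                "stratum": stratum,
                "drug": drug,
                "n": len(sub),
                "mean_age": float(sub["age"].mean()) if len(sub) else float("nan"),
                "pct_female": 100.0 * float((sub["sex"] == "F").mean()) if len(sub) else float("nan"),
            })
    return pd.DataFrame(rows)


def comorbidity_table(units: pd.DataFrame, bundle: ClaimsBundle, codes) -> pd.DataFrame:
    """Comorbidity counts and prevalences per drug over all units."""
    flags = coh.comorbidity_flags(units, bundle, codes)
    rows = []
    for drug in [*DRUGS, "subtotal"]:
        mask = pd.Series(True, index=units.index) if drug == "subtotal" else units["drug"] == drug
        n = int(mask.sum())
        row = {"drug": drug, "n": n}
        for cond in flags.columns:
            count = int(flags.loc[mask, cond].sum())
            row[cond] = count
            row[f"{cond}_pct"] = 100.0 * count / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def persistence_rate_table(
    episodes: pd.DataFrame, horizons: tuple[int, ...], reference: str
) -> pd.DataFrame:
    """KM persistence rates (+/- 95% half-widths) per drug and horizon, with
    pairwise log-rank / Wilcoxon p-values versus the reference drug.

    Cells where the Greenwood band is undefined carry ``ci_available=False``
    and NaN half-widths — an explicit unavailability marker, never silence.
    """
    samples = {}
    for drug, grp in episodes.groupby("drug"):
        samples[drug] = (grp["end_day"].to_numpy(float),
                         (grp["status"] != "censored").to_numpy(bool))
    tests = {}
    if reference in samples and len(samples) > 1:
        for row in pairwise_vs_reference(samples, reference):
            tests[(row["group"], row["test"])] = row["p_value"]
    rows = []
    for drug, (t, e) in sorted(samples.items()):
        curve = km_estimate(t, e)
        for horizon in horizons:
            est, ci = survival_at(curve, horizon)
            rows.append({
                "drug": drug,
                "horizon_days": horizon,
                "n": len(t),
                "rate_pct": 100.0 * est,
                "ci_available": ci is not None,
                "ci_half_width_pct": 100.0 * (ci[1] - ci[0]) / 2.0 if ci else float("nan"),
                "p_logrank_vs_ref": tests.get((drug, "log-rank"), float("nan")),
                "p_wilcoxon_vs_ref": tests.get((drug, "wilcoxon"), float("nan")),
            })
    return pd.DataFrame(rows)


def cost_tables(
    units: pd.DataFrame, episodes: pd.DataFrame, bundle: ClaimsBundle
) -> dict[str, pd.DataFrame]:
    """Cost-population window sums and the persistence-contrast table.

    Returns ``{"window_costs": per-unit JPY sums, "cost_contrast": means in
    thousand JPY by stratum/drug/persistence group}``.
    """
    cost_units = coh.select_cost_population(units)
    if "naive" not in cost_units.columns:
        cost_units = cost_units.merge(units[["unit_id", "naive"]], on="unit_id")
    eligible = episodes[episodes["unit_id"].isin(cost_units["unit_id"])]
    wtab = window_cost_table(cost_units, bundle.costs)
    contrast = contrast_by_persistence(cost_units, eligible, wtab)
    value_cols = [c for c in contrast.columns if c.startswith(("pre_", "increase_"))]
    report = contrast.copy()
    for col in value_cols:
        report[col] = report[col].map(
            lambda v: to_thousand_jpy(v) if pd.notna(v) else v
        )
    return {"window_costs": wtab, "cost_contrast": report}


def plot_km_curves(episodes: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for drug, grp in sorted(episodes.groupby("drug")):
        t = grp["end_day"].to_numpy(float)
        e = (grp["status"] != "censored").to_numpy(bool)
        curve = km_estimate(t, e)
        xs = np.concatenate([[0.0], np.repeat(curve.times, 2)])
        ys = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
        ax.plot(xs, ys, drawstyle="default", label=f"{drug} (n={curve.n})")
    ax.set_xlabel("days since initiation")
    ax.set_ylabel("persistence probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; write CSV tables (and plots) to the output dir.

    Returns the in-memory result dict: bundle, units, episodes and every
    emitted table.  Deterministic for a fixed config and seed.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    log.info("run start: seed=%d config=%s", config.seed, cfg_hash)

    if config.input_mode == "synthetic":
        sim = config.simulation.replace(seed=config.seed)
        bundle, truth = generate_cohort(sim)
    else:
        bundle, truth = read_bundle(config.input_dir), None
    bundle.validate()

    cascade = coh.CascadeLog()
    selected = coh.select_psoriasis_bt_patients(bundle, config.codes, cascade)
    kept = coh.apply_exclusions(selected, bundle, config.codes, cascade)
    units = coh.build_patient_units(kept, bundle)
    units["naive"] = coh.classify_naive(units, bundle)
    cascade.add("patient units (patient x biologic)", len(units))
    cascade.add("naive units", int(units["naive"].sum()) if len(units) else 0)
    for stage, count in cascade.stages:
        log.info("cascade: %s = %d", stage, count)

    episodes = build_episodes(units, bundle.drug_claims, config.gap_policy)
    naive_episodes = episodes[episodes["unit_id"].isin(units.loc[units["naive"], "unit_id"])]

    results: dict = {
        "bundle": bundle,
        "ground_truth": truth,
        "cascade": cascade.to_frame(),
        "units": units,
        "episodes": episodes,
        "table1_demographics": demographics_table(units),
        "table2_comorbidities": comorbidity_table(units, bundle, config.codes),
    }
    if len(episodes):
        results["table3_persistence_total"] = persistence_rate_table(
            episodes, config.horizons, config.reference_drug)
        results["table3_persistence_naive"] = persistence_rate_table(
            naive_episodes, config.horizons, config.reference_drug) if len(naive_episodes) else pd.DataFrame()
        results.update(cost_tables(units, episodes, bundle))
        policies = [config.gap_policy] + [
            config.gap_policy.with_gap(g) for g in config.sensitivity_gaps
        ]
        results["sensitivity_grid"] = sensitivity_grid(units, bundle.drug_claims, policies)
    else:
        for key in ("table3_persistence_total", "table3_persistence_naive",
                    "window_costs", "cost_contrast", "sensitivity_grid"):
            results[key] = pd.DataFrame()

    for name in ("cascade", "table1_demographics", "table2_comorbidities",
                 "table3_persistence_total", "table3_persistence_naive",
                 "window_costs", "cost_contrast", "sensitivity_grid", "episodes"):
        results[name].to_csv(out / f"{name}.csv", index=False)
    if config.make_plots and len(episodes):
        plot_km_curves(episodes, out / "km_total.png", "persistence, total population")
        if len(naive_episodes):
            plot_km_curves(naive_episodes, out / "km_naive.png", "persistence, naive population")
    (out / "run_log.json").write_text(json.dumps({
        "seed": config.seed,
        "config_hash": cfg_hash,
        "n_units": int(len(units)),
        "cascade": cascade.stages,
    }, indent=2))
    log.info("run complete: %d units", len(units))
    return results
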