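"""End-to-end orchestration: simulate or load a trial, then run every stage.

The pipeline configuration is a plain mapping (usually read from YAML):

    input:
      simulation: {n_genotypes: 30, seed: 7, ...}   # or
      trial_csv: path/to/long_format.csv
    stress_regimes: [MWS, SWS]
    trait: TDW
    irrigation_volume_per_plant: 1.0
    output_dir: out/

Each stage writes one CSV; a run log records the seed, a hash of the
configuration and the package version so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ammi import ammi_anova, cell_means, fit_ammi, stability_ranking
from .anova import fit_factorial_anova
from .errors import ContractError
from .genetics import genetic_summary
from .indices import build_index_table, classify_tolerance, linkage_to_newick
from .summaries import annual_yield_table, pearson_matrix
from .synthetic import SimulationSpec, generate_paired_stress_trial
from .trial_io import read_trial_table, records_to_frame, write_trial_table

STAGE_TABLES = (
    "trial_records", "anova", "genetic_summary", "drought_indices",
    "stability", "annual_yield",
)


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    if "input" not in cfg:
        raise ContractError("config must name an 'input' source")
    src = cfg["input"]
    if not isinstance(src, dict) or not ({"simulation", "trial_csv"} & src.keys()):
        raise ContractError("input must provide 'simulation' or 'trial_csv'")
    if not cfg.get("stress_regimes"):
        raise ContractError("config must list stress_regimes")
    cfg.setdefault("trait", "TDW")
    cfg.setdefault("irrigation_volume_per_plant", 1.0)
    cfg.setdefault("output_dir", "metstab_out")
    return cfg


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict of the in-memory stage tables. Deterministic given
    (config, seed).
    """
    cfg = validate_config(config)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    trait = cfg["trait"]

    if "simulation" in cfg["input"]:
        sim_kwargs = dict(cfg["input"]["simulation"])
        if seed is not None:
            sim_kwargs["seed"] = seed
        spec = SimulationSpec(**sim_kwargs)
        records, truth = generate_paired_stress_trial(spec)
        used_seed = spec.seed
    else:
        records = read_trial_table(cfg["input"]["trial_csv"])
        truth = None
        used_seed = seed

    frame = records_to_frame(records)
    write_trial_table(records, out_dir / "trial_records.csv")
    bundle: dict = {"trial_records": frame}

    anova_rows = []
    for regime in ["wet"] + list(cfg["stress_regimes"]):
        sub = frame[frame["regime"] == regime]
        if sub.empty:
            raise ContractError(f"stage anova: no records for regime {regime!r}")
        factors = ["genotype", "harvest"] if sub["harvest"].nunique() > 1 else ["genotype"]
        table = fit_factorial_anova(sub, trait, factors)
        table = table.reset_index().assign(regime=regime)
        anova_rows.append(table)
    bundle["anova"] = pd.concat(anova_rows, ignore_index=True)
    bundle["anova"].to_csv(out_dir / "anova.csv", index=False)

    gen_rows = [genetic_summary(frame, trait, regime)
                for regime in ["wet"] + list(cfg["stress_regimes"])]
    bundle["genetic_summary"] = pd.DataFrame(gen_rows)
    bundle["genetic_summary"].to_csv(out_dir / "genetic_summary.csv", index=False)

    idx_rows, stab_rows = [], []
    for regime in cfg["stress_regimes"]:
        table = build_index_table(frame, regime,
                                  cfg["irrigation_volume_per_plant"], trait)
        classified, link = classify_tolerance(table)
        (out_dir / f"dendrogram_{regime}.nwk").write_text(
            linkage_to_newick(link, list(classified.index)))
        idx_rows.append(classified.reset_index(names="genotype").assign(regime=regime))

        cm = cell_means(frame, trait, regime)
        fit = fit_ammi(cm, n_axes=2)
        stab = stability_ranking(fit, cm)
        ammi_anova(cm, fit).to_csv(out_dir / f"ammi_anova_{regime}.csv")
        stab_rows.append(stab.reset_index(names="genotype").assign(regime=regime))
    bundle["drought_indices"] = pd.concat(idx_rows, ignore_index=True)
    bundle["drought_indices"].to_csv(out_dir / "drought_indices.csv", index=False)
    bundle["stability"] = pd.concat(stab_rows, ignore_index=True)
    bundle["stability"].to_csv(out_dir / "stability.csv", index=False)

    annual = annual_yield_table(frame, cfg["stress_regimes"][0])
    bundle["annual_yield"] = annual
    annual.to_csv(out_dir / "annual_yield.csv")

    wide = (frame[frame["regime"] == cfg["stress_regimes"][0]]
            .groupby(["genotype", "trait"])["value"].mean().unstack())
    if wide.shape[1] >= 2 and len(wide) >= 3:
        r, p = pearson_matrix(wide)
        r.to_csv(out_dir / "correlations_r.csv")
        p.to_csv(out_dir / "correlations_p.csv")
        bundle["correlations"] = r

    log = {
        "seed": used_seed,
        "config_hash": _config_hash(cfg),
        "metstab_version": __version__,
        "n_records": len(frame),
        "tolerant_genotypes": list(truth.tolerant_genotypes) if truth else [],
    }
    (out_dir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    bundle["run_log"] = log
    return bundle
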