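"""End-to-end pipeline: simulate/read -> traits -> pigments -> adjustment ->
classification -> group statistics, with a reproducible run manifest.

Configuration is a YAML mapping (see README for the schema). Outputs are
deterministic for identical (config, input, seed): every table is written
with fixed float formatting and the manifest carries a hash of the resolved
configuration instead of timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import design, mvstats, pigments
from .errors import ConfigError
from .io import DesignLayout, read_measurements, records_to_frame, write_measurements, write_table
from .simulate import DEFAULT_CHECK_IDS, SimulationConfig, simulate_dataset
from .traits import ROOT_TRAITS, TraitConfig, derive_all

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    simulate: dict | None = None
    input_path: Path | None = None
    soil_volume: float = 1000.0
    pi_value: float = 3.14
    rtd_mode: str = "paper_multiply"
    n_blocks: int = 5
    check_ids: tuple = DEFAULT_CHECK_IDS
    alpha: float = 0.05
    use_adjusted: bool = True
    stepwise: bool = False
    f_enter: float = 3.84
    f_remove: float = 2.71
    correlation_scope: str = "genotypes"
    n_clusters: int = 3
    lsd_alpha: float = 0.05
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls_, cfg: dict) -> "PipelineConfig":
        if "seed" not in cfg:
            raise ConfigError("config must set a seed")
        traits = cfg.get("traits", {})
        des = cfg.get("design", {})
        clf = cfg.get("classification", {})
        ana = cfg.get("analysis", {})
        alpha = float(clf.get("alpha", 0.05))
        if not 0 < alpha < 1:
            raise ConfigError(f"classification alpha must be in (0, 1), got {alpha}")
        scope = ana.get("correlation_scope", "genotypes")
        if scope not in ("genotypes", "group_means"):
            raise ConfigError(f"correlation_scope must be genotypes|group_means, got {scope}")
        if ("simulate" in cfg) == ("input" in cfg):
            raise ConfigError("config must set exactly one of 'simulate' or 'input'")
        return cls_(
            seed=int(cfg["seed"]),
            output_dir=Path(cfg.get("output_dir", "rootgroups_out")),
            simulate=cfg.get("simulate"),
            input_path=Path(cfg["input"]) if "input" in cfg else None,
            soil_volume=float(traits.get("soil_volume_cm3", 1000.0)),
            pi_value=float(traits.get("pi_value", 3.14)),
            rtd_mode=traits.get("rtd_mode", "paper_multiply"),
            n_blocks=int(des.get("n_blocks", 5)),
            check_ids=tuple(des.get("check_ids", DEFAULT_CHECK_IDS)),
            alpha=alpha,
            use_adjusted=bool(clf.get("use_adjusted", True)),
            stepwise=bool(ana.get("stepwise", False)),
            f_enter=float(ana.get("f_enter", 3.84)),
            f_remove=float(ana.get("f_remove", 2.71)),
            correlation_scope=scope,
            n_clusters=int(ana.get("clusters", 3)),
            lsd_alpha=float(ana.get("lsd_alpha", 0.05)),
            log_level=cfg.get("log_level", "INFO"),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls_.from_mapping(cfg)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()


def _assignments_wide(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype wide view of the classification (both conditions)."""
    rows = {}
    for _, r in assignments.iterrows():
        d = rows.setdefault(int(r["genotype_id"]), {"genotype_id": int(r["genotype_id"])})
        d[f"{r['condition']}_depth"] = r["depth_class"]
        d[f"{r['condition']}_density"] = r["density_class"]
        d[f"{r['condition']}_group"] = int(r["group_index"])
    return pd.DataFrame(sorted(rows.values(), key=lambda d: d["genotype_id"]))


def _tally_frame(assignments: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cond in sorted(assignments["condition"].unique()):
        tally = cls.tally_groups(assignments, cond)
        for g, count in sorted(tally.group_counts().items()):
            rows.append({"condition": cond, "group_index": g,
                         "group_name": cls.GROUP_NAMES[g], "count": count})
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts; returns the run manifest."""
    layout = DesignLayout(
        n_blocks=cfg.n_blocks,
        check_ids=frozenset(cfg.check_ids),
        test_ids=frozenset(
            i
            for i in range(1, 106 + len(cfg.check_ids))
            if i not in set(cfg.check_ids)
        ),
    )
    warnings: list[str] = []
    outputs: dict[str, pd.DataFrame | str] = {}

    # --- acquire measurements ------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        sim_cfg = SimulationConfig(seed=cfg.seed, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg.simulate.items()
        })
        layout = sim_cfg.layout()
        records, truth = simulate_dataset(sim_cfg)
        outputs["measurements.csv"] = records_to_frame(records)
        outputs["ground_truth_genotypes.csv"] = truth.genotypes
        outputs["ground_truth_blocks.csv"] = truth.block_effects
    else:
        records = read_measurements(cfg.input_path, layout)

    # --- traits and pigments --------------------------------------------------
    tcfg = TraitConfig(cfg.soil_volume, cfg.pi_value, cfg.rtd_mode)
    table = derive_all(records, tcfg)
    table, pig_warnings = pigments.add_pigments(table)
    warnings.extend(pig_warnings)
    outputs["traits.csv"] = table

    # --- design adjustment ----------------------------------------------------
    effects = design.estimate_block_effects(table, layout)
    adjusted = design.adjust_augmented(table, effects, layout)
    outputs["block_effects.csv"] = effects
    outputs["adjusted.csv"] = adjusted
    working = adjusted if cfg.use_adjusted else design.genotype_means(table)

    # --- classification ---------------------------------------------------
    assignments = cls.classify_genotypes(working, cfg.alpha)
    outputs["table1_assignments.csv"] = _assignments_wide(assignments)
    outputs["figure3_tally.csv"] = _tally_frame(assignments)
    outputs["transitions.csv"] = cls.stability_report(assignments)

    # --- per-condition group statistics ------------------------------------
    for cond in sorted(assignments["condition"].unique()):
        sub = working[working["condition"] == cond].merge(
            assignments[assignments["condition"] == cond][["genotype_id", "group_index"]],
            on="genotype_id",
        )
        anova_rows, lsd_rows = [], []
        for trait in ROOT_TRAITS:
            at = mvstats.oneway_group_anova(sub[trait], sub["group_index"], trait)
            anova_rows.append(at.__dict__)
            if at.ms_within > 0:
                gm = sub.groupby("group_index")[trait].mean().to_dict()
                gn = sub.groupby("group_index")[trait].count().to_dict()
                lsd = mvstats.lsd_compare(gm, gn, at, cfg.lsd_alpha)
                lsd.insert(0, "trait", trait)
                lsd_rows.append(lsd)
        outputs[f"table2_3_anova_{cond}.csv"] = pd.DataFrame(anova_rows)
        if lsd_rows:
            outputs[f"lsd_{cond}.csv"] = pd.concat(lsd_rows, ignore_index=True)

        X = sub[ROOT_TRAITS].to_numpy()
        variables = list(ROOT_TRAITS)
        if cfg.stepwise:
            selected = mvstats.stepwise_select(
                X, sub["group_index"], cfg.f_enter, cfg.f_remove, variables
            )
            if selected:
                variables = selected
                X = sub[variables].to_numpy()
            else:
                warnings.append(f"{cond}: stepwise selected no variables; full model used")
        model = mvstats.canonical_lda(X, sub["group_index"].to_numpy(), variables)
        warnings.extend(f"{cond}: {w}" for w in model.warnings)
        outputs[f"table4_eigen_{cond}.csv"] = pd.DataFrame(
            {
                "function": np.arange(1, model.n_functions + 1),
                "eigenvalue": model.eigenvalues,
                "pct_variance": model.pct_variance,
                "cumulative_pct": model.cumulative_pct,
                "canonical_correlation": model.canonical_correlations,
            }
        )
        outputs[f"table5_structure_{cond}.csv"] = pd.DataFrame(
            model.structure_matrix,
            columns=[f"function_{j+1}" for j in range(model.n_functions)],
        ).assign(trait=model.variables)[
            ["trait"] + [f"function_{j+1}" for j in range(model.n_functions)]
        ]
        outputs[f"table6_centroids_{cond}.csv"] = pd.DataFrame(
            model.centroids,
            columns=[f"function_{j+1}" for j in range(model.n_functions)],
        ).assign(group_index=model.group_labels)[
            ["group_index"] + [f"function_{j+1}" for j in range(model.n_functions)]
        ]

        corr_source = (
            sub if cfg.correlation_scope == "genotypes"
            else sub.groupby("group_index").mean(numeric_only=True).reset_index()
        )
        corr_traits = [c for c in design.analysis_columns(working) if c in corr_source]
        cm = mvstats.pearson_correlation_matrix(corr_source, corr_traits)
        warnings.extend(f"{cond}: {w}" for w in cm.warnings)
        flagged = cm.r.round(6).astype(str) + cm.flags
        outputs[f"correlations_{cond}.csv"] = flagged.reset_index(names="trait")

        profiles = sub.groupby("group_index")[ROOT_TRAITS].mean()
        root = mvstats.ward_cluster(profiles)
        outputs[f"dendrogram_{cond}.nwk"] = mvstats.to_newick(root)
        outputs[f"dendrogram_merges_{cond}.csv"] = mvstats.merge_table(root)
        labels = mvstats.cut_tree(root, min(cfg.n_clusters, len(profiles)))
        outputs[f"clusters_{cond}.csv"] = pd.DataFrame(
            sorted(labels.items()), columns=["group_index", "cluster"]
        )

    # --- write everything at once (no partial outputs on failure) ----------
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in outputs.items():
        path = out_dir / name
        if isinstance(obj, str):
            path.write_text(obj + "\n", encoding="utf-8")
        elif name == "measurements.csv":
            write_measurements(records, path)
        else:
            write_table(obj, path)
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_records": len(records),
        "outputs": sorted(outputs),
        "warnings": warnings,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
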