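"""End-to-end pipeline: quantify -> bias -> shifts -> dynamics -> phenotype -> plsr."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bias as bias_mod
from . import dynamics as dyn
from . import phenotype as phen
from .config import RunConfig
from .plsr import PLSRegressionNipals, build_plsr_dataset
from .quantify import filter_tracked_clones, quantify_abundance
from .shifts import (
    LineageShiftModel,
    category_transition_table,
    label_contributions,
    shift_fractions,
)
from .tables import CellType, TimePoint

log = logging.getLogger(__name__)

STAGES = ("inputs", "quantify", "bias", "shifts", "dynamics", "phenotype", "plsr")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineReport:
    """All stage outputs of one pipeline run."""

    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def summary_json(self) -> str:
        """Machine-readable summary; byte-identical across runs with one seed."""
        return json.dumps(self.summary, sort_keys=True, indent=1, default=str)

    def report_text(self) -> str:
        lines = ["clonaging pipeline report", "=" * 40]
        for stage in STAGES:
            lines.append(f"\n[{stage}]")
            for key, value in sorted(self.summary.get(stage, {}).items()):
                lines.append(f"  {key}: {value}")
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(self.summary_json())
        (out / "report.txt").write_text(self.report_text())


def run_pipeline(
    config: RunConfig,
    counts: pd.DataFrame,
    panel: pd.DataFrame,
    mice: pd.DataFrame | None = None,
) -> PipelineReport:
    """Run every analysis stage in order; stage errors carry the stage name."""
    report = PipelineReport(config=config)
    report.summary["inputs"] = {
        "n_count_rows": int(len(counts)),
        "n_panel_rows": int(len(panel)),
        "n_mice": int(counts["mouse_id"].nunique()),
        "seed": config.seed,
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc
        return deco

    @stage("quantify")
    def _quantify():
        abundance = quantify_abundance(counts, panel)
        tracked = filter_tracked_clones(
            abundance,
            threshold=config.inclusion_threshold_pct_wbc,
            per_celltype=config.filter_per_celltype,
        )
        report.tables["abundance_all"] = abundance
        report.tables["abundance"] = tracked
        report.summary["quantify"] = {
            "n_clones_before_filter": int(
                abundance.groupby(["mouse_id", "barcode_id"]).ngroups
            ),
            "n_clones_tracked": int(tracked.groupby(["mouse_id", "barcode_id"]).ngroups),
            "inclusion_threshold_pct_wbc": config.inclusion_threshold_pct_wbc,
        }

    @stage("bias")
    def _bias():
        records = bias_mod.bias_table(report.tables["abundance"], panel, config)
        shifts = bias_mod.shift_table(records, config)
        report.tables["bias_records"] = records
        report.tables["bias_shifts"] = shifts
        report.summary["bias"] = {
            "n_bias_records": int(len(records)),
            "n_shift_pairs": int(len(shifts)),
            "n_shift_included": int(shifts["included"].sum()),
        }

    @stage("shifts")
    def _shifts():
        model = LineageShiftModel(report.tables["bias_shifts"], config.kde_settings)
        results = model.fit()
        labels = results.classify()
        report.tables["shift_labels"] = labels
        report.tables["shift_fractions"] = shift_fractions(labels)
        report.tables["shift_transitions"] = category_transition_table(labels)
        report.tables["shift_contributions"] = label_contributions(
            labels, report.tables["abundance"]
        )
        frac = labels["label"].value_counts(normalize=True)
        report.summary["shifts"] = {
            **results.params_dict(),
            "frac_stable": float(frac.get("stable", 0.0)),
            "frac_aging": float(frac.get("aging", 0.0)),
            "frac_anti_aging": float(frac.get("anti_aging", 0.0)),
            "frac_shifting": float(1.0 - frac.get("stable", 0.0)),
        }

    @stage("dynamics")
    def _dynamics():
        abundance = report.tables["abundance"]
        summary: dict = {}
        for ct in (CellType.GR.value, CellType.B.value):
            expansion = dyn.expansion_analysis(abundance, ct)
            report.tables[f"expansion_{ct}"] = expansion.fractions
            summary[f"expansion_threshold_{ct}"] = expansion.threshold
            report.tables[f"top_clones_{ct}"] = dyn.top_k_abundance(abundance, ct, k=3)
            deltas = dyn.clone_deltas(abundance, ct)
            report.tables[f"deltas_{ct}"] = deltas
            report.tables[f"change_counts_{ct}"] = dyn.change_counts(
                deltas, floor=config.change_floor_pct_wbc
            )
            stem = dyn.stem_input_export(abundance, ct, min_change=0.01)
            report.tables[f"stem_input_{ct}"] = stem
            summary[f"n_stem_clones_{ct}"] = int(len(stem))
        fates = dyn.fate_table(abundance, presence_threshold=config.presence_threshold_pct)
        report.tables["fate_labels"] = fates
        diff_idx, excluded = dyn.differentiation_index(abundance)
        report.tables["differentiation_index"] = diff_idx
        summary["n_fate_persistent"] = int((fates["label"] == "persistent").sum())
        summary["n_fate_exhausted"] = int((fates["label"] == "exhausted").sum())
        summary["n_fate_activated"] = int((fates["label"] == "activated").sum())
        summary["n_diff_index_excluded"] = int(len(excluded))
        report.summary["dynamics"] = summary

    @stage("phenotype")
    def _phenotype():
        phenotypes = phen.phenotype_table(panel)
        groups = phen.classify_mice(phenotypes)
        decomposition = phen.change_decomposition(
            report.tables["deltas_GR"], report.tables["deltas_B"]
        )
        group_summary = phen.group_decomposition_summary(decomposition, groups)
        correlation = phen.population_change_correlation(phenotypes, groups)
        report.tables["phenotypes"] = phenotypes
        report.tables["mouse_groups"] = groups
        report.tables["change_decomposition"] = decomposition
        report.tables["decomposition_summary"] = group_summary
        report.tables["population_correlation"] = correlation
        report.summary["phenotype"] = {
            "bg_threshold": float(groups.attrs["threshold"]),
            "n_early": int((groups["group"] == "early").sum()),
            "n_delayed": int((groups["group"] == "delayed").sum()),
            "n_unclassified": int(groups["unclassified"].sum()),
        }

    @stage("plsr")
    def _plsr():
        dataset = build_plsr_dataset(report.tables["abundance"], report.tables["phenotypes"])
        model = PLSRegressionNipals(
            dataset.drop(columns=["mouse_id", "bg_ratio_end"]),
            dataset["bg_ratio_end"],
            n_components=config.plsr_components,
        )
        results = model.fit()
        report.tables["plsr_dataset"] = dataset
        report.tables["plsr_vip"] = results.vip_table()
        report.summary["plsr"] = {
            "n_mice": int(len(dataset)),
            "n_components": config.plsr_components,
            "r2": float(results.r2),
            **{f"vip_{n}": float(v) for n, v in
               zip(results.model.predictor_names, results.vip)},
        }

    return report
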