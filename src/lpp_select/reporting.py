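"""Head-to-head report assembly and run manifests.

`run_full_comparison` ties the two selection procedures together on one
cohort: the mtry sweep of the random-forest procedure and forward plus
backward stepwise regression, summarised side by side — retained sets,
how many retained predictors are low-prevalence, AUCs with CIs, and the
set differences between the methods.
"""

from __future__ import annotations

import datetime
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._seeds import child_seed
from .rf_selection import DEFAULT_MTRY_SWEEP, mtry_sweep
from .stepwise import backward_stepwise, cv_logistic_auc, forward_stepwise, wald_odds_ratios
from .synthetic_data import LPP_THRESHOLD, BinaryDataset, PredictorSpec

__all__ = ["RunManifest", "run_full_comparison", "write_comparison_report"]


@dataclass
class RunManifest:
    """Reproducibility record written alongside every output directory."""

    command: str
    config: dict
    master_seed: int
    seed_scheme: str = "SeedSequence(master, *path) -> uint32 mod 2^31"
    version: str = __version__
    started: str = ""
    finished: str = ""
    row_counts: dict = field(default_factory=dict)

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "manifest.json"
        payload = {
            "command": self.command,
            "config": self.config,
            "master_seed": self.master_seed,
            "seed_scheme": self.seed_scheme,
            "version": self.version,
            "python": platform.python_version(),
            "started": self.started,
            "finished": self.finished,
            "row_counts": self.row_counts,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path


def _lpp_count(retained, specs_by_name) -> int | None:
    if specs_by_name is None:
        return None
    return sum(
        1
        for name in retained
        if name in specs_by_name and specs_by_name[name].prevalence < LPP_THRESHOLD
    )


def run_full_comparison(
    data: BinaryDataset,
    specs: list[PredictorSpec] | None = None,
    mtry_values=DEFAULT_MTRY_SWEEP,
    n_trees: int = 10_000,
    n_repeats: int = 25,
    k_folds: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Run both selection procedures on one cohort and assemble a report.

    Returns a dict with per-method entries (retained sets, AUC estimates,
    LPP counts when ``specs`` with true prevalences are supplied) plus the
    RF-vs-SWR retained-set intersection and differences.
    """
    specs_by_name = {s.name: s for s in specs} if specs is not None else None
    report: dict = {"methods": {}, "failed_stages": []}

    try:
        sweep = mtry_sweep(
            data,
            mtry_values,
            n_trees=n_trees,
            n_repeats=n_repeats,
            k_folds=k_folds,
            n_boot=n_boot,
            seed=child_seed(seed, 1),
        )
        for mtry, entry in sweep.items():
            sel = entry["selection"]
            report["methods"][f"rf_mtry{mtry}"] = {
                "retained": list(sel.retained),
                "chosen_k": sel.chosen_k,
                "n_retained": len(sel.retained),
                "n_lpp_retained": _lpp_count(sel.retained, specs_by_name),
                "full_model_auc": sel.full_model_auc.auc,
                "full_model_ci": [sel.full_model_auc.ci_low, sel.full_model_auc.ci_high],
                "importance": entry["importance"],
                "nested": entry["nested"],
            }
    except Exception as exc:  # pragma: no cover - defensive stage isolation
        report["failed_stages"].append(("rf", repr(exc)))

    for direction, runner in (("backward", backward_stepwise), ("forward", forward_stepwise)):
        try:
            res = runner(data)
            est, _ = cv_logistic_auc(
                data,
                res.retained,
                k_folds=k_folds,
                seed=child_seed(seed, 2),
                n_boot=n_boot,
            )
            res.cv_auc = est
            report["methods"][f"swr_{direction}"] = {
                "retained": list(res.retained),
                "n_retained": len(res.retained),
                "n_lpp_retained": _lpp_count(res.retained, specs_by_name),
                "cv_auc": est.auc,
                "cv_auc_ci": [est.ci_low, est.ci_high],
                "odds_ratios": wald_odds_ratios(res.final_fit),
                "trajectory": res.trajectory,
            }
        except Exception as exc:  # pragma: no cover
            report["failed_stages"].append((f"swr_{direction}", repr(exc)))

    rf_key = next((k for k in report["methods"] if k.startswith("rf_")), None)
    swr_key = "swr_backward" if "swr_backward" in report["methods"] else None
    if rf_key and swr_key:
        rf_set = set(report["methods"][rf_key]["retained"])
        swr_set = set(report["methods"][swr_key]["retained"])
        report["set_comparison"] = {
            "rf_method": rf_key,
            "swr_method": swr_key,
            "intersection": sorted(rf_set & swr_set),
            "rf_only": sorted(rf_set - swr_set),
            "swr_only": sorted(swr_set - rf_set),
        }
    return report


def write_comparison_report(report: dict, out_dir) -> None:
    """Serialise a comparison report to CSV/JSON files in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for method, entry in report["methods"].items():
        if "importance" in entry:
            entry["importance"].to_csv(out / f"{method}_importance.csv")
            nested_df = pd.DataFrame(
                [
                    {
                        "k": r.k,
                        "auc": r.auc.auc,
                        "ci_low": r.auc.ci_low,
                        "ci_high": r.auc.ci_high,
                        "delong_p_vs_full": r.delong_p_vs_full,
                    }
                    for r in entry["nested"]
                ]
            )
            nested_df.to_csv(out / f"{method}_nested_models.csv", index=False)
            auc, ci = entry["full_model_auc"], entry["full_model_ci"]
        else:
            entry["odds_ratios"].to_csv(out / f"{method}_odds_ratios.csv", index=False)
            auc, ci = entry["cv_auc"], entry["cv_auc_ci"]
        summary_rows.append(
            {
                "method": method,
                "n_retained": entry["n_retained"],
                "n_lpp_retained": entry["n_lpp_retained"],
                "auc": auc,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "retained": ";".join(entry["retained"]),
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "comparison_summary.csv", index=False)
    if "set_comparison" in report:
        (out / "set_comparison.json").write_text(
            json.dumps(report["set_comparison"], indent=2) + "\n"
        )
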