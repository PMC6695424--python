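"""End-to-end orchestration: simulate -> contractility -> quantify -> respstats.

A single JSON-style configuration drives every stage; one master seed fans
out to per-stage child seeds by fixed offsets so each stage is independently
reproducible. The default configuration is a desk-scale template of the
hybrid-myotube EPS experiment: three culture conditions (human-only myotubes
with low twitch amplitude, mouse C2C12 and hybrid myotubes with high
amplitude) imaged in three fields each, seven nuclei fields with a 14.25 %
human fraction, a marker table with a CD56+ lineage-negative satellite
population, a four-gene Ct table and the 39-analyte secretion panel
template.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from ._utils import require
from .errors import ParameterError
from . import contractility, quantify, respstats, simkit
from .io import read_stack, read_nuclei_field, read_table, write_table

__all__ = ["default_config", "validate_config", "run_all", "RunReport"]

#: Fixed per-stage seed offsets (video fields consume offset + field index).
STAGE_SEED_OFFSETS = {
    "video": 100,
    "nuclei": 300,
    "markers": 400,
    "ct": 500,
    "panel": 600,
}

_DEFAULT_CONFIG = {
    "seed": 0,
    "video": {
        "conditions": {"HSMM": 0.5, "C2C12": 4.0, "hybrid": 4.0},
        "n_fields": 3,
        "width_px": 256,
        "height_px": 256,
        "fps": 14.4,
        "stim_freq_hz": 1.0,
        "duration_s": 5.0,
        "n_myotubes": 5,
        "noise_sd": 0.01,
        "baseline": 0.1,
        "twitch_rise_s": 0.1,
        "twitch_decay_s": 0.3,
    },
    "nuclei": {
        "n_fields": 7,
        "n_nuclei_min": 67,
        "n_nuclei_max": 140,
        "human_fraction": 0.1425,
    },
    "markers": {
        "n_cells": {"satellite": 50, "blood": 60, "endothelial": 40,
                    "FAP": 30, "other": 70},
        "gate_thresholds": {m: 100.0 for m in simkit.GATE_MARKERS},
    },
    "ct": {"n_reps": 3, "noise_sd_ct": 0.2},
    "panel": {
        "n_wells": 4,
        "basal_pg_ml": 20.0,
        "fold": 20.0,
        "lod_pg_ml": 1.0,
        "noise_cv": 0.1,
    },
    "analysis": {
        "window_s": 3.0,
        "overlap_threshold": 0.5,
        "alpha": 0.05,
        "k_sd": 3.0,
    },
}


def default_config() -> dict:
    """A fresh copy of the template configuration."""
    return copy.deepcopy(_DEFAULT_CONFIG)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(config: dict | None = None) -> dict:
    """Merge a user configuration over the defaults and validate it.

    Raises :class:`ParameterError` before any compute when a stage declares
    both simulation parameters and input paths, or when scalar parameters
    are out of range.
    """
    cfg = _deep_merge(_DEFAULT_CONFIG, config or {})
    alpha = cfg["analysis"]["alpha"]
    require(0 < alpha < 1, "analysis.alpha must lie in (0, 1)")
    require(isinstance(cfg["seed"], int) and cfg["seed"] >= 0,
            "seed must be a non-negative integer")
    video = cfg["video"]
    if video.get("paths") and video.get("conditions"):
        raise ParameterError(
            "video stage declares both simulated conditions and input paths; "
            "choose one"
        )
    if not video.get("paths") and not video.get("conditions"):
        raise ParameterError("video stage needs conditions or input paths")
    user_nuclei = (config or {}).get("nuclei", {})
    if user_nuclei.get("paths") and any(
        k in user_nuclei
        for k in ("n_fields", "human_fraction", "n_nuclei_min", "n_nuclei_max")
    ):
        raise ParameterError(
            "nuclei stage declares both simulation parameters and input "
            "paths; choose one"
        )
    require(0 <= cfg["nuclei"]["human_fraction"] <= 1,
            "nuclei.human_fraction must lie in [0, 1]")
    return cfg


@dataclass
class RunReport:
    """All stage outputs of one reproducible run."""

    movement: dict
    movement_comparisons: dict
    nuclei: dict
    gating: dict
    expression: list
    panel: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "movement": self.movement,
            "movement_comparisons": self.movement_comparisons,
            "nuclei": self.nuclei,
            "gating": self.gating,
            "expression": self.expression,
            "panel": self.panel,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary_text(self) -> str:
        lines = ["twitchindex run summary", "======================", ""]
        lines.append("Movement index (mean ± SE over fields):")
        for cond, block in self.movement.items():
            se = block["se"]
            se_txt = f" ± {se:.4g}" if se is not None else ""
            lines.append(
                f"  {cond:>8s}: {block['mean']:.4g}{se_txt}"
                f"  (n={block['n_fields']})"
            )
        lines.append("Pairwise movement comparisons (pooled t-test):")
        for pair, block in self.movement_comparisons.items():
            star = " *" if block["significant"] else ""
            lines.append(f"  {pair}: p = {block['p']:.3g}{star}")
        nuc = self.nuclei
        se_txt = f" ± {nuc['se'] * 100:.2f}" if nuc["se"] is not None else ""
        lines.append(
            f"Human nuclei: {nuc['mean'] * 100:.2f}{se_txt} % "
            f"({nuc['n_fields']} fields, {min(nuc['totals'])}–"
            f"{max(nuc['totals'])} nuclei/field)"
        )
        lines.append(
            f"Satellite gate: {self.gating['n_selected']} of "
            f"{self.gating['n_cells']} cells selected"
        )
        lines.append("Relative expression (EPS fold vs control):")
        for row in self.expression:
            star = " *" if row["significant"] else ""
            lines.append(
                f"  {row['species']:>5s} {row['gene']:<6s}: "
                f"fold {row['fold']:.3g} (p = {row['p']:.3g}){star}"
            )
        lines.append("Secretion panel classes:")
        for cls, count in sorted(self.panel["class_counts"].items()):
            lines.append(f"  {cls}: {count}")
        return "\n".join(lines) + "\n"


def _field_summary_dict(summary: contractility.FieldSummary) -> dict:
    return {
        "indices": [float(v) for v in summary.indices],
        "mean": summary.mean,
        "se": summary.se,
        "n_fields": summary.n_fields,
        "field_ids": summary.field_ids,
    }


def _run_video_stage(cfg: dict, seed: int, out_dir: Path | None):
    video = cfg["video"]
    analysis = cfg["analysis"]
    summaries: dict = {}
    results: dict = {}
    if video.get("paths"):
        for cond, paths in video["paths"].items():
            res = [
                contractility.movement_index(
                    read_stack(p, fps=video.get("fps")),
                    stim_freq_hz=video["stim_freq_hz"],
                    window_s=analysis["window_s"],
                    field_id=f"{cond}_f{i + 1}",
                )
                for i, p in enumerate(paths)
            ]
            results[cond] = res
            summaries[cond] = contractility.summarize_fields(res)
        return summaries, results

    sim_keys = (
        "width_px", "height_px", "fps", "stim_freq_hz", "duration_s",
        "n_myotubes", "noise_sd", "baseline", "twitch_rise_s",
        "twitch_decay_s",
    )
    base_kwargs = {k: video[k] for k in sim_keys}
    i = 0
    for cond, amplitude in video["conditions"].items():
        res = []
        for f_idx in range(video["n_fields"]):
            config = simkit.VideoSimConfig(
                amplitude_px=amplitude,
                seed=seed + i,
                **base_kwargs,
            )
            stack, _ = simkit.simulate_myotube_field(config)
            mi = contractility.movement_index(
                stack,
                stim_freq_hz=video["stim_freq_hz"],
                window_s=analysis["window_s"],
                field_id=f"{cond}_f{f_idx + 1}",
            )
            res.append(mi)
            if out_dir is not None and f_idx == 0:
                contractility.render_pseudocolor(
                    mi.overlay, out_dir / f"overlay_{cond}.png"
                )
            i += 1
        results[cond] = res
        summaries[cond] = contractility.summarize_fields(res)
    return summaries, results


def run_all(config: dict | None = None, out_dir=None) -> RunReport:
    """Execute every enabled stage and return (and optionally write) a report.

    With an ``out_dir``, writes ``report.json``, ``summary.txt``, per-stage
    TSV tables and one pseudo-colored movement overlay per condition. The
    report is bit-identical for a fixed (config, seed) on synthetic runs.
    """
    cfg = validate_config(config)
    seed = cfg["seed"]
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    alpha = cfg["analysis"]["alpha"]

    # --- contractility ----------------------------------------------------
    summaries, _results = _run_video_stage(
        cfg, seed + STAGE_SEED_OFFSETS["video"], out_path
    )
    movement = {c: _field_summary_dict(s) for c, s in summaries.items()}
    comparisons: dict = {}
    conds = list(summaries)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            tt = respstats.compare_groups(
                summaries[a].indices, summaries[b].indices
            )
            comparisons[f"{a}_vs_{b}"] = {
                "t": tt.t,
                "p": tt.p,
                "significant": tt.p < alpha,
            }

    # --- nuclei -----------------------------------------------------------
    nuclei_cfg = cfg["nuclei"]
    counts = []
    if nuclei_cfg.get("paths"):
        for i, pair in enumerate(nuclei_cfg["paths"]):
            field = read_nuclei_field(
                pair["dapi"], pair["hna"], field_id=f"field{i + 1}"
            )
            counts.append(
                quantify.count_field(
                    field, cfg["analysis"]["overlap_threshold"]
                )
            )
    else:
        rng = np.random.default_rng(seed + STAGE_SEED_OFFSETS["nuclei"])
        for i in range(nuclei_cfg["n_fields"]):
            n = int(rng.integers(nuclei_cfg["n_nuclei_min"],
                                 nuclei_cfg["n_nuclei_max"] + 1))
            field, _ = simkit.simulate_nuclei_field(
                n_nuclei=n,
                human_fraction=nuclei_cfg["human_fraction"],
                seed=seed + STAGE_SEED_OFFSETS["nuclei"] + 1 + i,
                field_id=f"field{i + 1}",
            )
            counts.append(
                quantify.count_field(
                    field, cfg["analysis"]["overlap_threshold"]
                )
            )
    nuc_summary = quantify.ratio_summary(counts)
    nuclei = {
        "mean": nuc_summary.mean,
        "se": nuc_summary.se,
        "n_fields": nuc_summary.n_fields,
        "ratios": [float(r) for r in nuc_summary.ratios],
        "totals": [int(t) for t in nuc_summary.totals],
    }

    # --- gating -----------------------------------------------------------
    markers_cfg = cfg["markers"]
    if markers_cfg.get("path"):
        marker_table = read_table(markers_cfg["path"])
    else:
        marker_table = simkit.simulate_marker_table(
            n_cells=markers_cfg["n_cells"],
            seed=seed + STAGE_SEED_OFFSETS["markers"],
        )
    gate = quantify.GateConfig(thresholds=markers_cfg["gate_thresholds"])
    selected, subtable = quantify.gate_satellite_cells(marker_table, gate)
    gating = {
        "n_cells": int(len(marker_table)),
        "n_selected": int(selected.sum()),
        "thresholds": {k: float(v)
                       for k, v in markers_cfg["gate_thresholds"].items()},
    }

    # --- expression -------------------------------------------------------
    ct_cfg = cfg["ct"]
    if ct_cfg.get("path"):
        ct_table = read_table(ct_cfg["path"])
    else:
        ct_table, _ = simkit.simulate_ct_table(
            n_reps=ct_cfg["n_reps"],
            noise_sd_ct=ct_cfg["noise_sd_ct"],
            seed=seed + STAGE_SEED_OFFSETS["ct"],
        )
    expr_results = respstats.relative_expression(ct_table, alpha=alpha)
    expr_df = respstats.expression_table(expr_results)
    expression = expr_df.to_dict(orient="records")

    # --- secretion panel --------------------------------------------------
    panel_cfg = cfg["panel"]
    panel_obj, _ = simkit.simulate_secretion_panel(
        basal_pg_ml=panel_cfg["basal_pg_ml"],
        fold=panel_cfg["fold"],
        lod_pg_ml=panel_cfg["lod_pg_ml"],
        noise_cv=panel_cfg["noise_cv"],
        n_wells=panel_cfg["n_wells"],
        seed=seed + STAGE_SEED_OFFSETS["panel"],
    )
    classification = respstats.classify_panel(
        panel_obj, alpha=alpha, k_sd=cfg["analysis"]["k_sd"]
    )
    panel = {
        "classes": dict(sorted(classification.classes.items())),
        "class_counts": classification.class_counts(),
        "excluded": sorted(classification.excluded),
        "panel_size": panel_obj.panel_size,
    }

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    import pandas as _pd
    import scipy as _scipy
    provenance = {
        "config": cfg,
        "config_sha256": config_hash,
        "seed": seed,
        "versions": {
            "twitchindex": __version__,
            "numpy": np.__version__,
            "scipy": _scipy.__version__,
            "pandas": _pd.__version__,
        },
    }

    report = RunReport(
        movement=movement,
        movement_comparisons=comparisons,
        nuclei=nuclei,
        gating=gating,
        expression=expression,
        panel=panel,
        provenance=provenance,
    )

    if out_path is not None:
        report.to_json(out_path / "report.json")
        (out_path / "summary.txt").write_text(report.summary_text())
        write_table(expr_df, out_path / "expression.tsv")
        write_table(classification.stats, out_path / "panel_classes.tsv")
        import pandas as pd
        write_table(
            pd.DataFrame(
                [
                    {"condition": c, "field_id": fid, "movement_index": v}
                    for c, block in movement.items()
                    for fid, v in zip(block["field_ids"], block["indices"])
                ]
            ),
            out_path / "movement.tsv",
        )
        write_table(
            pd.DataFrame(
                [
                    {"field_id": c.field_id, "n_total": c.n_total,
                     "n_hna_positive": c.n_hna_positive, "ratio": c.ratio}
                    for c in counts
                ]
            ),
            out_path / "nuclei.tsv",
        )
        write_table(subtable, out_path / "satellite_cells.tsv")
    return report
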