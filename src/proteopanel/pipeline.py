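"""End-to-end orchestration: simulate (or load) -> normalize -> test -> rank.

A pipeline run is described by a :class:`PipelineConfig` (JSON-friendly),
executed stage by stage with every artifact written to the output
directory, and summarized in a manifest that records a SHA-256 hash of each
file so identical configs and seeds produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, neuro, panels, synthetic, vsn
from .containers import AbundanceMatrix, ValidationError


@dataclass
class PipelineConfig:
    """Validated run description.

    Exactly one of ``matrix_path`` (with ``groups_path``) or ``synthetic``
    must be provided.  ``neuro_recordings_path``/``synthetic_neuro`` add the
    neurophysiology stage.
    """

    out_dir: str
    matrix_path: str | None = None
    groups_path: str | None = None
    synthetic: dict | None = None
    neuro_recordings_path: str | None = None
    synthetic_neuro: dict | None = None
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 5
    n_rep: int = 100
    train_frac: float = 2.0 / 3.0
    panel_groups: tuple[str, str] = ("HC", "IBS")
    max_candidates: int = 12
    top_panels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.matrix_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValidationError("exactly one of matrix_path / synthetic required")
        if has_files and self.groups_path is None:
            raise ValidationError("groups_path required with matrix_path")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 1 <= self.k_min <= self.k_max:
            raise ValidationError("need 1 <= k_min <= k_max")
        if self.n_rep < 1:
            raise ValidationError("n_rep must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ValidationError("train_frac must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "files": {}, "summary": {}}
    stage = "setup"

    def record(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    try:
        t0 = time.perf_counter()
        stage = "input"
        if config.synthetic is not None:
            synth_cfg = synthetic.SynthProteomeConfig(
                **{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)}
            )
            matrix, truth = synthetic.gen_proteome(synth_cfg)
            matrix.to_tsv(out / "abundance.tsv", out / "groups.tsv")
            truth.differential.to_csv(out / "ground_truth_differential.csv")
            (out / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "differential_ids": list(truth.differential_ids),
                        "protease_panel": list(truth.protease_panel),
                        "target_r": truth.target_r,
                    },
                    indent=1,
                )
            )
            for name in ("abundance.tsv", "groups.tsv", "ground_truth_differential.csv", "ground_truth.json"):
                record(out / name)
        else:
            matrix = AbundanceMatrix.from_tsv(config.matrix_path, config.groups_path)
        _log(f"[input] {matrix.n_proteins} proteins x {matrix.n_samples} samples "
             f"({time.perf_counter() - t0:.1f}s)")

        stage = "normalize"
        t0 = time.perf_counter()
        nm = vsn.vsn_normalize(matrix)
        nm.to_tsv(out / "normalized.tsv", out / "vsn_params.json")
        record(out / "normalized.tsv")
        record(out / "vsn_params.json")
        _log(f"[normalize] done in {nm.diagnostics['iterations']} robust iterations "
             f"({time.perf_counter() - t0:.1f}s)")

        stage = "diffexpr"
        t0 = time.perf_counter()
        table = diffexpr.differential_table(nm, alpha=config.alpha)
        table.to_csv(out / "differential_table.tsv", sep="\t")
        record(out / "differential_table.tsv")
        selected = diffexpr.select_differential(table, alpha=config.alpha)
        manifest["summary"]["n_differential"] = len(selected)
        manifest["summary"]["d0"] = table.attrs["d0"]
        manifest["summary"]["s0_2"] = table.attrs["s0_2"]

        z = vsn.zscore_by_protein(nm, selected) if len(selected) >= 2 else None
        if z is not None:
            clust = vsn.hierarchical_cluster(z, axis=0)
            pc = vsn.pca(z)
            pc["scores"].to_csv(out / "pca_scores.csv")
            pd.Series(clust["leaf_order"]).to_csv(
                out / "heatmap_row_order.csv", index=False, header=["protein_id"]
            )
            record(out / "pca_scores.csv")
            record(out / "heatmap_row_order.csv")
            manifest["summary"]["pca_explained_var"] = [
                float(v) for v in pc["explained_var"][:2]
            ]
        _log(f"[diffexpr] {len(selected)} differential proteins at BH {config.alpha} "
             f"({time.perf_counter() - t0:.1f}s)")

        stage = "panel"
        t0 = time.perf_counter()
        g_a, g_b = config.panel_groups
        cols = matrix.samples_in(g_a) + matrix.samples_in(g_b)
        # candidates: annotated proteases significantly up in the second
        # panel group versus the first (the biomarker direction of interest)
        cand = [
            p
            for p in selected
            if table.loc[p, "is_protease"]
            and table.loc[p, f"p_{g_b}_vs_{g_a}"] < config.alpha
            and table.loc[p, f"log10_ratio_{g_b}_vs_{g_a}"] > 0
        ]
        cand = sorted(
            cand, key=lambda p: table.loc[p, f"p_{g_b}_vs_{g_a}"]
        )[: config.max_candidates]
        if len(cand) >= config.k_min:
            feats = nm.log10_values.loc[cand, cols].T
            labels = (matrix.groups.loc[cols] == g_b).astype(int).to_numpy()
            k_max = min(config.k_max, len(cand))
            results = panels.search_panels(
                feats, labels, k_min=config.k_min, k_max=k_max,
                n_rep=config.n_rep, train_frac=config.train_frac, seed=config.seed,
            )
            board = pd.DataFrame(
                {
                    "rank": [r.rank for r in results],
                    "panel": ["+".join(r.panel) for r in results],
                    "size": [len(r.panel) for r in results],
                    "mean_accuracy": [r.mean_accuracy for r in results],
                    "best_accuracy": [r.best_accuracy for r in results],
                }
            )
            board.to_csv(out / "panel_leaderboard.tsv", sep="\t", index=False)
            record(out / "panel_leaderboard.tsv")
            top = results[0]
            rocs = {}
            for pid in top.panel:
                rocs[pid] = panels.roc_for_panel(feats, labels, (pid,), positive_class=1).auc
            rocs["+".join(top.panel)] = panels.roc_for_panel(
                feats, labels, top.panel, positive_class=1
            ).auc
            (out / "roc_auc.json").write_text(json.dumps(rocs, indent=1, sort_keys=True))
            record(out / "roc_auc.json")
            manifest["summary"]["top_panel"] = list(top.panel)
            manifest["summary"]["top_panel_mean_accuracy"] = top.mean_accuracy
            manifest["summary"]["auc"] = rocs
            _log(f"[panel] {len(results)} panels from {len(cand)} candidates; top "
                 f"{top.panel} at {top.mean_accuracy:.3f} ({time.perf_counter() - t0:.1f}s)")
        else:
            manifest["summary"]["top_panel"] = None
            _log(f"[panel] skipped: only {len(cand)} candidate(s)")

        stage = "neuro"
        recs = None
        if config.neuro_recordings_path is not None:
            from .containers import recordings_from_csv

            recs = recordings_from_csv(config.neuro_recordings_path)
        elif config.synthetic_neuro is not None:
            ncfg = synthetic.SynthNeuroConfig(
                **{**config.synthetic_neuro,
                   "seed": config.synthetic_neuro.get("seed", config.seed)}
            )
            recs = synthetic.gen_ganglion_responses(ncfg)
            from .containers import recordings_to_csv

            recordings_to_csv(recs, out / "ganglion_recordings.csv")
            record(out / "ganglion_recordings.csv")
        if recs is not None:
            per_patient = neuro.patient_neuroindex(recs)
            per_patient.to_csv(out / "patient_neuroindex.csv", index=False)
            record(out / "patient_neuroindex.csv")
            by_group = {
                g: df["neuroindex"].to_numpy()
                for g, df in per_patient.groupby("group")
            }
            cmp = neuro.group_compare(by_group)
            neuro_summary = {
                "kruskal_h": cmp.h_statistic,
                "kruskal_p": cmp.p_value,
                "dunn": cmp.dunn.to_dict(orient="records"),
                "group_medians": {
                    g: float(np.median(v)) for g, v in sorted(by_group.items())
                },
            }
            (out / "neuro_stats.json").write_text(json.dumps(neuro_summary, indent=1))
            record(out / "neuro_stats.json")
            manifest["summary"]["neuro_group_medians"] = neuro_summary["group_medians"]
            _log(f"[neuro] Kruskal-Wallis p = {cmp.p_value:.3g}")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def render_report(manifest: dict | str | Path, top_panels: int = 10) -> str:
    """Markdown summary of a completed run; values are echoed, never altered."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    out_dir = Path(manifest["config"]["out_dir"])
    s = manifest.get("summary", {})
    lines = ["# Pipeline report", ""]
    lines.append(f"- seed: {manifest['config']['seed']}")
    if "n_differential" in s:
        lines.append(f"- differential proteins (BH {manifest['config']['alpha']}): "
                     f"{s['n_differential']}")
        lines.append(f"- empirical-Bayes prior: d0 = {s['d0']:.3g}, "
                     f"s0^2 = {s['s0_2']:.3g}")
    board_path = out_dir / "panel_leaderboard.tsv"
    if s.get("top_panel") and board_path.exists():
        lines += ["", "## Panel leaderboard (top entries)", ""]
        board = pd.read_csv(board_path, sep="\t").head(top_panels)
        lines.append(board.to_string(index=False))
        if "auc" in s:
            lines += ["", "## ROC AUC", ""]
            for k in sorted(s["auc"]):
                lines.append(f"- {k}: {s['auc'][k]:.3f}")
    if "neuro_group_medians" in s:
        lines += ["", "## Neuroindex group medians", ""]
        for g in sorted(s["neuro_group_medians"]):
            lines.append(f"- {g}: {s['neuro_group_medians'][g]:.1f}")
    lines.append("")
    return "\n".join(lines)
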