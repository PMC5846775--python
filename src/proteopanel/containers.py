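"""Core data containers shared across the pipeline.

The central object is the :class:`AbundanceMatrix`: a proteins x samples
table of raw label-free intensities together with a group label (HC, IBS
or UC) for every sample and a per-protein protease annotation flag.
Normalization produces a :class:`NormalizedMatrix` carrying glog-scale
values plus the per-sample calibration parameters that produced them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("HC", "IBS", "UC")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class AbundanceMatrix:
    """Raw protein intensities with sample group labels.

    Parameters
    ----------
    intensities
        DataFrame of strictly positive raw intensities, index = protein ids
        (unique strings), columns = sample ids (unique strings).
    groups
        Series mapping every sample id to a group label.
    protease
        Boolean Series flagging annotated proteases, indexed by protein id.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    protease: pd.Series

    def __post_init__(self) -> None:
        idx, cols = self.intensities.index, self.intensities.columns
        if idx.has_duplicates:
            raise ValidationError("duplicate protein ids")
        if cols.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if not set(cols) <= set(self.groups.index):
            missing = sorted(set(cols) - set(self.groups.index))
            raise ValidationError(f"samples without group label: {missing}")
        self.groups = self.groups.reindex(cols)
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        if not set(idx) <= set(self.protease.index):
            raise ValidationError("protease flag missing for some proteins")
        self.protease = self.protease.reindex(idx).astype(bool)
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("intensities must be finite and > 0")

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    # -- I/O: TSV matrix (protein_id, is_protease, <sample columns>) plus a
    #    two-column sample -> group map.
    def to_tsv(self, matrix_path: str | Path, groups_path: str | Path) -> None:
        out = self.intensities.copy()
        out.insert(0, "is_protease", self.protease.astype(int))
        out.index.name = "protein_id"
        out.to_csv(matrix_path, sep="\t")
        gm = self.groups.rename("group").to_frame()
        gm.index.name = "sample_id"
        gm.to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, groups_path: str | Path) -> "AbundanceMatrix":
        raw = pd.read_csv(matrix_path, sep="\t", index_col="protein_id")
        protease = raw.pop("is_protease").astype(bool)
        gm = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
        return cls(intensities=raw.astype(float), groups=gm, protease=protease)


@dataclass
class NormalizedMatrix:
    """glog-transformed intensities with the per-sample calibration fit.

    ``values[g, s] = arsinh((x[g, s] - offset[s]) / scale[s])``; scales are
    strictly positive.  ``diagnostics`` records the robust-fit trajectory.
    """

    values: pd.DataFrame
    offsets: pd.Series
    scales: pd.Series
    groups: pd.Series
    protease: pd.Series
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.scales.to_numpy() <= 0):
            raise ValidationError("calibration scales must be > 0")

    @property
    def log10_values(self) -> pd.DataFrame:
        """Values rescaled so large-intensity differences read as log10 ratios."""
        return self.values / np.log(10.0)

    def to_tsv(self, matrix_path: str | Path, params_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "protein_id"
        out.to_csv(matrix_path, sep="\t")
        params = {
            "offsets": {s: float(v) for s, v in self.offsets.items()},
            "scales": {s: float(v) for s, v in self.scales.items()},
            "groups": {s: g for s, g in self.groups.items()},
            "protease": {p: bool(v) for p, v in self.protease.items()},
            "diagnostics": self.diagnostics,
        }
        Path(params_path).write_text(json.dumps(params, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, params_path: str | Path) -> "NormalizedMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="protein_id")
        params = json.loads(Path(params_path).read_text())
        return cls(
            values=values,
            offsets=pd.Series(params["offsets"]).reindex(values.columns),
            scales=pd.Series(params["scales"]).reindex(values.columns),
            groups=pd.Series(params["groups"]).reindex(values.columns),
            protease=pd.Series(params["protease"]).reindex(values.index).astype(bool),
            diagnostics=params.get("diagnostics", {}),
        )


@dataclass
class GanglionRecording:
    """One imaged submucous ganglion under one stimulation condition.

    ``magnitudes`` holds the per-responder response size: spike frequency in
    Hz for voltage-sensitive-dye recordings, or peak dF/F for calcium
    imaging.  ``nicotine_responders`` is the calcium-mode denominator (the
    number of nicotine-responsive cells taken as 100%).
    """

    patient_id: str
    group: str
    condition: str
    neurons_total: int
    responders: int
    magnitudes: tuple[float, ...] = ()
    nicotine_responders: int | None = None

    def __post_init__(self) -> None:
        if self.neurons_total <= 0:
            raise ValidationError("neurons_total must be > 0")
        if not 0 <= self.responders <= self.neurons_total:
            raise ValidationError("responders must lie in [0, neurons_total]")
        if len(self.magnitudes) != self.responders:
            raise ValidationError("one magnitude per responder required")
        if any(m < 0 for m in self.magnitudes):
            raise ValidationError("response magnitudes must be >= 0")
        if self.nicotine_responders is not None and self.nicotine_responders <= 0:
            raise ValidationError("nicotine_responders must be > 0 when given")


def recordings_to_csv(recordings: list[GanglionRecording], path: str | Path) -> None:
    """Write ganglion recordings as CSV, magnitudes semicolon-joined."""
    rows = []
    for r in recordings:
        rows.append(
            {
                "patient_id": r.patient_id,
                "group": r.group,
                "condition": r.condition,
                "neurons_total": r.neurons_total,
                "responders": r.responders,
                "magnitudes": ";".join(f"{m:.6g}" for m in r.magnitudes),
                "nicotine_responders": "" if r.nicotine_responders is None else r.nicotine_responders,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def recordings_from_csv(path: str | Path) -> list[GanglionRecording]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        mags = tuple(float(m) for m in str(row["magnitudes"]).split(";") if m != "")
        nic = row.get("nicotine_responders", "")
        out.append(
            GanglionRecording(
                patient_id=str(row["patient_id"]),
                group=str(row["group"]),
                condition=str(row["condition"]),
                neurons_total=int(row["neurons_total"]),
                responders=int(row["responders"]),
                magnitudes=mags,
                nicotine_responders=None if nic in ("", None) else int(float(nic)),
            )
        )
    return out
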