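"""Plain-text storage for sweep archives and cohort tables.

No open interchange format exists for PERG sweep data (vendor formats are
proprietary), so sweeps are stored as diffable text: one TSV matrix per
subject/eye/condition block (rows = sweeps, columns = samples, values in
μV) plus a JSON sidecar carrying all metadata.  Sample times are implicit:
sample ``i`` is at ``i / sampling_rate_hz`` seconds, first sample at t=0.

Layout under an archive directory::

    provenance.json                      # free-form archive metadata
    <subject>/<eye>/<checksize>deg_<rate>rps.tsv
    <subject>/<eye>/<checksize>deg_<rate>rps.json

Cohort-level results are a single CSV with one row per subject x eye x
condition (see :data:`COHORT_COLUMNS`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd

from .stimulus import StimulusCondition

#: Canonical cohort CSV column order.  ``noise_uV`` and ``snr`` may be absent
#: for tables that never went through spectral analysis (e.g. generator ground
#: truth); unknown extra columns are preserved after the canonical ones.
COHORT_COLUMNS = [
    "subject",
    "group",
    "eye",
    "check_size_deg",
    "reversal_rate_rps",
    "amplitude_uV",
    "noise_uV",
    "snr",
    "response_time_ms",
]

REQUIRED_COHORT_COLUMNS = [
    "subject",
    "group",
    "eye",
    "check_size_deg",
    "reversal_rate_rps",
    "amplitude_uV",
    "response_time_ms",
]

_FLOAT_FMT = "%.12g"  # >= 9 significant digits for lossless round trips


@dataclass
class SweepBlock:
    """Raw fixed-length sweeps for one subject/eye/condition."""

    subject_id: str
    group: str
    eye: str
    condition: StimulusCondition
    sampling_rate_hz: float
    sweep_length_s: float
    sweeps: np.ndarray
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        try:
            self.sweeps = np.asarray(self.sweeps, dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValueError(
                "sweeps must form a rectangular 2-D matrix; ragged rows cannot "
                "be stacked") from exc
        self.validate()

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def key(self) -> tuple[str, str, float, float]:
        return (
            self.subject_id,
            self.eye,
            self.condition.check_size_deg,
            self.condition.reversal_rate_rps,
        )

    def validate(self) -> None:
        if self.sweeps.ndim != 2:
            raise ValueError(
                f"sweeps must be a 2-D matrix (got ndim={self.sweeps.ndim}); "
                "ragged sweep lists cannot be stacked"
            )
        expected = self.sampling_rate_hz * self.sweep_length_s
        if abs(expected - round(expected)) > 1e-9:
            raise ValueError(
                f"sampling_rate_hz x sweep_length_s = {expected} is not an integer "
                "number of samples"
            )
        if self.n_samples != round(expected):
            raise ValueError(
                f"block {self.subject_id}/{self.eye}/{self.condition.label()}: "
                f"{self.n_samples} samples per sweep, expected "
                f"{round(expected)} (= {self.sampling_rate_hz:g} Hz x "
                f"{self.sweep_length_s:g} s)"
            )
        if not np.all(np.isfinite(self.sweeps)):
            raise ValueError(
                f"block {self.subject_id}/{self.eye}/{self.condition.label()}: "
                "non-finite voltage values"
            )


@dataclass
class SweepArchive:
    """A collection of sweep blocks with unique (subject, eye, condition) keys."""

    blocks: list[SweepBlock]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple] = set()
        for block in self.blocks:
            if block.key in seen:
                raise ValueError(f"duplicate (subject, eye, condition) key: {block.key}")
            seen.add(block.key)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[SweepBlock]:
        return iter(self.blocks)


def _block_paths(root: Path, block: SweepBlock) -> tuple[Path, Path]:
    d = root / str(block.subject_id) / str(block.eye)
    stem = block.condition.label()
    return d / f"{stem}.tsv", d / f"{stem}.json"


def write_archive(archive: SweepArchive, path: str | Path) -> None:
    """Write an archive to ``path`` (created if needed); lossless at 12 sig. digits."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    archive.validate()
    for block in archive.blocks:
        block.validate()
        tsv, sidecar = _block_paths(root, block)
        tsv.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(tsv, block.sweeps, fmt=_FLOAT_FMT, delimiter="\t")
        meta = {
            "subject_id": block.subject_id,
            "group": block.group,
            "eye": block.eye,
            "check_size_deg": block.condition.check_size_deg,
            "reversal_rate_rps": block.condition.reversal_rate_rps,
            "sampling_rate_hz": block.sampling_rate_hz,
            "sweep_length_s": block.sweep_length_s,
            "n_sweeps": block.n_sweeps,
            "n_samples": block.n_samples,
            "extra": block.extra,
        }
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    (root / "provenance.json").write_text(
        json.dumps(archive.provenance, indent=1, sort_keys=True)
    )


def read_archive(path: str | Path) -> SweepArchive:
    """Read and validate an archive written by :func:`write_archive`."""
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"archive directory not found: {root}")
    blocks = []
    for sidecar in sorted(root.glob("*/*/*.json")):
        tsv = sidecar.with_suffix(".tsv")
        if not tsv.exists():
            raise FileNotFoundError(f"sidecar {sidecar} has no matching TSV matrix")
        meta = json.loads(sidecar.read_text())
        sweeps = np.loadtxt(tsv, delimiter="\t", ndmin=2)
        name = f"{meta['subject_id']}/{meta['eye']}"
        if sweeps.shape != (meta["n_sweeps"], meta["n_samples"]):
            raise ValueError(
                f"block {name} ({sidecar.name}): TSV matrix is {sweeps.shape}, "
                f"sidecar declares ({meta['n_sweeps']}, {meta['n_samples']})"
            )
        if not np.all(np.isfinite(sweeps)):
            raise ValueError(f"block {name} ({sidecar.name}): non-finite voltages")
        blocks.append(
            SweepBlock(
                subject_id=meta["subject_id"],
                group=meta["group"],
                eye=meta["eye"],
                condition=StimulusCondition(
                    meta["check_size_deg"], meta["reversal_rate_rps"]
                ),
                sampling_rate_hz=meta["sampling_rate_hz"],
                sweep_length_s=meta["sweep_length_s"],
                sweeps=sweeps,
                extra=meta.get("extra", {}),
            )
        )
    prov_file = root / "provenance.json"
    provenance = json.loads(prov_file.read_text()) if prov_file.exists() else {}
    return SweepArchive(blocks=blocks, provenance=provenance)


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; canonical columns first, extras preserved after."""
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    known = [c for c in COHORT_COLUMNS if c in records.columns]
    extras = [c for c in records.columns if c not in COHORT_COLUMNS]
    records[known + extras].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, checking the required columns are present."""
    df = pd.read_csv(path, dtype={"subject": str, "group": str, "eye": str})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} lacks required columns: {missing}")
    return df
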