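"""Tabular formats, run configuration, and reproducibility metadata.

Every file written by the pipeline starts with a commented metadata header
(tool version, configuration hash, seed, and the configuration itself) so
that any output can be reproduced from its own header. Readers skip
``#``-prefixed lines.

The uptake CSV mirrors the shape of a peptide-level HDX export: one row per
protein / state / peptide / timepoint / replicate with the centroid mass
shift in Da.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import DifferentialResult
from .projection import ProtectedRegion, ResidueTrack

__all__ = [
    "RunConfig",
    "read_uptake_csv",
    "write_uptake_csv",
    "write_results_tsv",
    "read_results_tsv",
    "write_track_tsv",
    "read_track_tsv",
    "write_regions_tsv",
    "read_regions_tsv",
    "write_plot_tsv",
    "read_observed_masses_csv",
]

UPTAKE_COLUMNS = [
    "protein_id", "state", "start", "end", "sequence",
    "timepoint_s", "replicate", "uptake_Da",
]
_UPTAKE_KEY = ["protein_id", "state", "start", "end", "timepoint_s", "replicate"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the pipeline, echoed into every output header."""

    min_delta_pct: float = 10.0
    alpha: float = 0.05
    min_da: float = 0.5
    skip_first: int = 1
    t_test_scope: str = "max_timepoint"
    contributing: str = "all"
    region_threshold: float = 10.0
    region_min_len: int = 2
    seed: int = 0
    pdb_offset: int = 0
    linker_d0: float = 138.06808
    doublet_delta: float = 4.025108
    tol_ppm: float = 10.0
    doublet_tol: float = 0.02

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(config: RunConfig | None = None, seed: int | None = None) -> str:
    cfg = config or RunConfig()
    lines = [f"# hdxmap {__version__}", f"# config_sha256={cfg.sha256()}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for key, val in sorted(cfg.to_dict().items()):
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path, sep: str, config, seed, float_format=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(metadata_header(config, seed))
        df.to_csv(fh, sep=sep, index=False, float_format=float_format, lineterminator="\n")


def write_uptake_csv(df: pd.DataFrame, path, config: RunConfig | None = None,
                     seed: int | None = None) -> None:
    _write_frame(df[UPTAKE_COLUMNS], path, ",", config, seed, float_format="%.10g")


def read_uptake_csv(path) -> pd.DataFrame:
    """Read and validate an uptake CSV; errors name the offending data row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df[UPTAKE_COLUMNS].copy()
    for col, kind in [("start", int), ("end", int), ("timepoint_s", float),
                      ("replicate", int), ("uptake_Da", float)]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.nonzero((bad | df[col].isna()).to_numpy())[0][0])
            raise ValueError(f"{path}: non-numeric or missing {col} in data row {row + 1}")
        df[col] = converted.astype(kind)
    dup = df.duplicated(subset=_UPTAKE_KEY, keep=False)
    if dup.any():
        rows = [int(i) + 1 for i in np.nonzero(dup.to_numpy())[0]]
        raise ValueError(f"{path}: duplicate (protein,state,peptide,timepoint,replicate) "
                         f"key in data rows {rows}")
    bad_len = df["sequence"].str.len() != (df["end"] - df["start"] + 1)
    if bad_len.any():
        row = int(np.nonzero(bad_len.to_numpy())[0][0])
        raise ValueError(f"{path}: sequence length inconsistent with start/end "
                         f"in data row {row + 1}")
    return df


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Flatten differential results; per-timepoint diffs become wide columns."""
    timepoints = sorted({t for r in results for t in r.per_timepoint["timepoint_s"]})
    rows = []
    for r in results:
        row = {
            "protein_id": r.peptide.protein_id,
            "start": r.peptide.start,
            "end": r.peptide.end,
            "sequence": r.peptide.sequence,
            "n_max": r.peptide.n_max,
        }
        by_tp = dict(zip(r.per_timepoint["timepoint_s"], r.per_timepoint["diff_pct"]))
        for t in timepoints:
            row[f"diff_pct_{t:g}s"] = round(by_tp[t], 2) if t in by_tp else np.nan
        row.update({
            "delta_hdx_pct": round(r.delta_hdx_pct, 2),
            "delta_timepoint_s": r.delta_timepoint_s,
            "delta_da": round(r.delta_da, 4),
            "p_value": r.p_value,
            "significant": r.significant,
            "direction": r.direction,
            "reasons": ";".join(r.reasons),
        })
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_tsv(results: list[DifferentialResult], path,
                      config: RunConfig | None = None, seed: int | None = None) -> None:
    _write_frame(results_frame(results), path, "\t", config, seed)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def track_frame(track: ResidueTrack) -> pd.DataFrame:
    return pd.DataFrame({
        "residue": np.arange(1, track.length + 1),
        "delta_hdx_pct": [None if c == 0 else round(v, 2)
                          for v, c in zip(track.values, track.coverage)],
        "coverage": track.coverage,
        "mixed_sign": track.mixed_sign,
    })


def write_track_tsv(track: ResidueTrack, path, config: RunConfig | None = None,
                    seed: int | None = None) -> None:
    _write_frame(track_frame(track), path, "\t", config, seed)


def read_track_tsv(path) -> ResidueTrack:
    df = pd.read_csv(path, sep="\t", comment="#")
    values = df["delta_hdx_pct"].to_numpy(dtype=float)
    coverage = df["coverage"].to_numpy(dtype=int)
    values = np.where(coverage == 0, np.nan, values)
    return ResidueTrack(protein_id="", values=values, coverage=coverage,
                        mixed_sign=df["mixed_sign"].to_numpy(dtype=bool))


def write_regions_tsv(regions: list[ProtectedRegion], path,
                      config: RunConfig | None = None, seed: int | None = None) -> None:
    df = pd.DataFrame(
        [(r.start, r.end, round(r.mean_delta_hdx, 2), r.direction) for r in regions],
        columns=["start", "end", "mean_delta_hdx_pct", "direction"],
    )
    _write_frame(df, path, "\t", config, seed)


def read_regions_tsv(path) -> list[ProtectedRegion]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ProtectedRegion(int(r.start), int(r.end), float(r.mean_delta_hdx_pct), r.direction)
        for r in df.itertuples()
    ]


def write_plot_tsv(track: ResidueTrack, comparison: str, path,
                   config: RunConfig | None = None, seed: int | None = None) -> None:
    """Long-format per-residue trace for plotting (position, value, label)."""
    df = track_frame(track)[["residue", "delta_hdx_pct"]].copy()
    df["comparison"] = comparison
    _write_frame(df, path, "\t", config, seed)


def read_observed_masses_csv(path) -> np.ndarray:
    """Single-column CSV of observed neutral masses in Da."""
    df = pd.read_csv(path, comment="#")
    col = df.columns[0]
    masses = pd.to_numeric(df[col], errors="coerce")
    if masses.isna().any():
        row = int(np.nonzero(masses.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: non-numeric mass in data row {row + 1}")
    return masses.to_numpy(dtype=float)
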