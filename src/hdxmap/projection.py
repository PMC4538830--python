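"""Peptide-to-residue projection, region extraction, and structure export.

A residue's track value is the mean ΔHDX of all peptides whose
exchange-contributing span covers it (a peptide's first residue(s) and its
prolines carry no signal and do not attribute). Contiguous same-sign runs
above a threshold become protected/deprotected regions; per-residue values
can be written into the B-factor column of a PDB file for surface coloring
in a molecular viewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .differential import DifferentialResult

__all__ = [
    "ResidueTrack",
    "ProtectedRegion",
    "project_to_residues",
    "extract_regions",
    "write_bfactor_pdb",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue mean ΔHDX with peptide coverage counts.

    ``values[i]`` is NaN wherever ``coverage[i]`` is 0 — "no data" is
    distinct from a measured zero. ``mixed_sign`` flags residues covered by
    both positive- and negative-ΔHDX peptides, where the signed mean
    averages opposing signals.
    """

    protein_id: str
    values: np.ndarray
    coverage: np.ndarray
    mixed_sign: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.coverage, dtype=int)
        m = np.asarray(self.mixed_sign, dtype=bool)
        if not (v.shape == c.shape == m.shape):
            raise ValueError("track arrays must share one shape")
        if not np.array_equal(np.isnan(v), c == 0):
            raise ValueError("values must be NaN exactly where coverage is 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "coverage", c)
        object.__setattr__(self, "mixed_sign", m)

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProtectedRegion:
    """A maximal run of covered residues sharing sign above threshold."""

    start: int
    end: int
    mean_delta_hdx: float
    direction: str  # decrease | increase

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")

    @property
    def residues(self) -> set[int]:
        return set(range(self.start, self.end + 1))


def project_to_residues(
    results: list[DifferentialResult],
    protein_length: int,
    contributing: str = "all",
    skip_first: int = 1,
) -> ResidueTrack:
    """Project peptide ΔHDX values onto residues.

    ``contributing`` is ``all`` (every analyzed peptide enters the mean,
    giving a continuous trace) or ``significant_only``.
    """
    if contributing not in ("all", "significant_only"):
        raise ValueError("contributing must be 'all' or 'significant_only'")
    sums = np.zeros(protein_length)
    counts = np.zeros(protein_length, dtype=int)
    pos_seen = np.zeros(protein_length, dtype=bool)
    neg_seen = np.zeros(protein_length, dtype=bool)
    protein_ids = set()
    for res in results:
        protein_ids.add(res.peptide.protein_id)
        if contributing == "significant_only" and not res.significant:
            continue
        if res.peptide.end > protein_length:
            raise ValueError(
                f"peptide {res.peptide.start}-{res.peptide.end} exceeds protein length"
            )
        for pos in res.peptide.contributing_positions(skip_first):
            i = pos - 1
            sums[i] += res.delta_hdx_pct
            counts[i] += 1
            if res.delta_hdx_pct > 0:
                pos_seen[i] = True
            elif res.delta_hdx_pct < 0:
                neg_seen[i] = True
    if len(protein_ids) > 1:
        raise ValueError(f"results span multiple proteins: {sorted(protein_ids)}")
    values = np.full(protein_length, np.nan)
    covered = counts > 0
    values[covered] = sums[covered] / counts[covered]
    mixed = pos_seen & neg_seen
    if mixed.any():
        logger.warning(
            "%d residue(s) covered by mixed-sign peptides; signed mean reported",
            int(mixed.sum()),
        )
    return ResidueTrack(
        protein_id=protein_ids.pop() if protein_ids else "",
        values=values, coverage=counts, mixed_sign=mixed,
    )


def extract_regions(
    track: ResidueTrack, threshold: float = 10.0, min_len: int = 2
) -> list[ProtectedRegion]:
    """Maximal runs of covered residues with |value| > threshold, one sign.

    Runs shorter than ``min_len`` are dropped (suppresses single-residue
    speckle). Direction is ``decrease`` for negative values (protection on
    binding) and ``increase`` for positive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    regions: list[ProtectedRegion] = []
    run_start = None
    run_sign = 0
    v = track.values

    def close(run_start: int, i_end: int, sign: int) -> None:
        if i_end - run_start + 1 >= min_len:
            seg = v[run_start - 1:i_end]
            regions.append(ProtectedRegion(
                start=run_start, end=i_end,
                mean_delta_hdx=float(np.mean(seg)),
                direction="decrease" if sign < 0 else "increase",
            ))

    for i in range(track.length):
        x = v[i]
        sign = 0 if (np.isnan(x) or abs(x) <= threshold) else (1 if x > 0 else -1)
        if sign == run_sign:
            continue
        if run_sign != 0:
            close(run_start, i, run_sign)
        run_start, run_sign = i + 1, sign
    if run_sign != 0:
        close(run_start, track.length, run_sign)
    return regions


def write_bfactor_pdb(
    pdb_text: str,
    track: ResidueTrack,
    chain: str,
    offset: int = 0,
) -> str:
    """Write track values into the B-factor column of PDB ATOM records.

    ``offset`` bridges structure numbering and track coordinates:
    ``track_position = pdb_residue_number - offset`` (useful when the
    structure keeps full-length numbering but the track covers a construct,
    or vice versa). Atoms of the selected chain whose residue is covered
    get B = track value (clipped to [-99.99, 999.99], two decimals) with
    their original occupancy; all other atoms get the "no data" sentinel
    B = 0.00, occupancy = 0.00. Every other byte of the file is preserved.
    """
    out_lines = []
    chain_found = False
    for line in pdb_text.splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
            line_chain = line[21]
            value = None
            if line_chain == chain:
                chain_found = True
                try:
                    resseq = int(line[22:26])
                except ValueError:
                    resseq = None
                if resseq is not None:
                    pos = resseq - offset
                    if 1 <= pos <= track.length and track.coverage[pos - 1] > 0:
                        value = float(np.clip(track.values[pos - 1], -99.99, 999.99))
            if value is None:
                occ, bfac = f"{0.0:6.2f}", f"{0.0:6.2f}"
            else:
                occ, bfac = line[54:60], f"{value:6.2f}"
            line = line[:54] + occ + bfac + line[66:]
        out_lines.append(line)
    if not chain_found:
        raise ValueError(f"chain {chain!r} not found in structure")
    return "".join(out_lines)
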