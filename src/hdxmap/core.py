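"""Peptide bookkeeping and the %HDX normalization.

In HDX-MS, each peptic peptide reports the summed deuterium content of its
backbone amide hydrogens as a centroid mass shift (Da). Normalizing that
shift by the peptide's theoretical maximum number of exchangeable amides
(N_max) puts peptides of different lengths on a common percentage scale:

    %HDX = 100 * #D / N_max,   #D = mass_shift / 1.006277 Da

N_max excludes the first ``skip_first`` residues of the peptide (the
N-terminal amide exchanges too fast to retain label; many pipelines also
drop position 2) and all prolines, which have no backbone amide hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import AMINO_ACIDS, DEUTERIUM_MASS_SHIFT

__all__ = [
    "Peptide",
    "UptakeRecord",
    "count_exchangeable",
    "contributing_positions",
    "deuterons_from_da",
    "pct_hdx",
]


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"non-standard amino-acid letter {ch!r} in sequence")


def count_exchangeable(sequence: str, skip_first: int = 1) -> int:
    """Maximum number of backbone amide hydrogens available for exchange.

    Counts ``len(sequence) - skip_first`` amides minus prolines beyond the
    skipped prefix. ``skip_first`` must be 1 (drop the N-terminal residue)
    or 2 (additionally drop position 2). Never negative.
    """
    _validate_sequence(sequence)
    if skip_first not in (1, 2):
        raise ValueError("skip_first must be 1 or 2")
    n_pro = sum(1 for i, aa in enumerate(sequence, start=1) if aa == "P" and i > skip_first)
    return max(len(sequence) - skip_first - n_pro, 0)


def contributing_positions(start: int, sequence: str, skip_first: int = 1) -> tuple[int, ...]:
    """Absolute (1-based) residue positions that carry exchange signal.

    These are the positions counted by :func:`count_exchangeable`: the
    peptide minus its first ``skip_first`` residues and minus prolines.
    Used both by the kinetic simulator (which residues contribute to the
    peptide mass shift) and by peptide-to-residue projection.
    """
    if skip_first not in (1, 2):
        raise ValueError("skip_first must be 1 or 2")
    return tuple(
        start + i
        for i, aa in enumerate(sequence)
        if i >= skip_first and aa != "P"
    )


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide located on its parent protein (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    n_max: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.protein_id}:{self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} inconsistent with coordinates"
            )
        if not 0 <= self.n_max <= len(self.sequence) - 1:
            raise ValueError("n_max out of range for peptide length")

    @classmethod
    def from_sequence(
        cls, protein_id: str, start: int, sequence: str, skip_first: int = 1
    ) -> "Peptide":
        return cls(
            protein_id=protein_id,
            start=start,
            end=start + len(sequence) - 1,
            sequence=sequence,
            n_max=count_exchangeable(sequence, skip_first),
        )

    def contributing_positions(self, skip_first: int = 1) -> tuple[int, ...]:
        return contributing_positions(self.start, self.sequence, skip_first)


@dataclass(frozen=True)
class UptakeRecord:
    """One replicate measurement of a peptide's deuterium mass shift."""

    peptide: Peptide
    state: str
    timepoint: float
    replicate: int
    mass_shift: float

    def __post_init__(self) -> None:
        if self.timepoint <= 0:
            raise ValueError("timepoint must be positive")

    @property
    def n_deuterons(self) -> float:
        return deuterons_from_da(self.mass_shift)


def deuterons_from_da(mass_shift: float) -> float:
    """Convert a centroid mass shift in Da to a deuteron count (#D)."""
    return mass_shift / DEUTERIUM_MASS_SHIFT


def pct_hdx(n_deuterons: float, n_max: int) -> float:
    """Percent exchange: 100 * #D / N_max.

    Values above the labeling ceiling (100 x D2O fraction) are possible
    under noise and are returned as-is, not clipped.
    """
    if n_max < 1:
        raise ValueError("pct_hdx undefined for n_max < 1")
    return 100.0 * n_deuterons / n_max
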