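"""Sequence masses, extinction coefficients, and SEC-MALS stoichiometry fits.

SEC-MALS reports the absolute (average) molar mass of an eluting species.
Given the component proteins of a putative complex, the copy-number vector
is inferred by exhaustive search over small non-negative integers, ranked
by the absolute residual against the measured mass; the 280 nm extinction
coefficient predicted from the composition (Gill & von Hippel) can be used
as a secondary ranking term when a UV-based mass estimate is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .constants import (
    AVERAGE_AA_MASS,
    EPSILON_CYSTINE,
    EPSILON_TRP,
    EPSILON_TYR,
    WATER_AVERAGE,
)
from .core import _validate_sequence

__all__ = [
    "Component",
    "StoichiometrySolution",
    "sequence_mass",
    "extinction_280",
    "infer_oligomer",
    "infer_stoichiometry",
]

logger = logging.getLogger(__name__)


def sequence_mass(sequence: str, kind: str = "average") -> float:
    """Molar mass of a protein sequence in kDa (average by default)."""
    if kind != "average":
        raise ValueError("SEC-MALS comparisons use average masses; kind must be 'average'")
    _validate_sequence(sequence)
    da = sum(AVERAGE_AA_MASS[aa] for aa in sequence) + WATER_AVERAGE
    return da / 1000.0


def extinction_280(sequence: str, cystines: bool = False) -> float:
    """Gill & von Hippel molar extinction coefficient at 280 nm (M^-1 cm^-1).

    ``cystines=True`` counts floor(nCys / 2) disulfides at 125 M^-1 cm^-1;
    the default assumes fully reduced cysteines.
    """
    _validate_sequence(sequence)
    eps = EPSILON_TRP * sequence.count("W") + EPSILON_TYR * sequence.count("Y")
    if cystines:
        eps += EPSILON_CYSTINE * (sequence.count("C") // 2)
    return float(eps)


@dataclass(frozen=True)
class Component:
    """One protein species that may enter a complex."""

    name: str
    average_mass: float  # kDa
    epsilon_280: float = 0.0  # M^-1 cm^-1

    def __post_init__(self) -> None:
        if self.average_mass <= 0:
            raise ValueError("average_mass must be > 0")
        if self.epsilon_280 < 0:
            raise ValueError("epsilon_280 must be >= 0")

    @classmethod
    def from_sequence(cls, name: str, sequence: str, cystines: bool = False) -> "Component":
        return cls(
            name=name,
            average_mass=sequence_mass(sequence),
            epsilon_280=extinction_280(sequence, cystines),
        )


@dataclass(frozen=True)
class StoichiometrySolution:
    """An integer copy-number assignment for a measured molar mass."""

    copy_numbers: tuple[int, ...]
    predicted_mass: float  # kDa
    residual: float  # kDa, |predicted - measured|
    epsilon_predicted: float  # M^-1 cm^-1

    @property
    def total_copies(self) -> int:
        return sum(self.copy_numbers)


def infer_oligomer(measured: float, monomer: float) -> tuple[int, float]:
    """Nearest homo-oligomer order for a measured molar mass.

    Returns ``(n, residual_kDa)`` with n >= 1; logs a warning when the
    residual exceeds 10% of the measured mass.
    """
    if monomer <= 0:
        raise ValueError("monomer mass must be > 0")
    if measured <= 0:
        raise ValueError("measured mass must be > 0")
    n = max(1, round(measured / monomer))
    residual = abs(measured - n * monomer)
    if residual > 0.1 * measured:
        logger.warning(
            "oligomer fit residual %.1f kDa exceeds 10%% of measured %.1f kDa",
            residual, measured,
        )
    return n, residual


def infer_stoichiometry(
    measured: float,
    components: list[Component],
    max_copies: int = 4,
    uv_weight: float | None = None,
    epsilon_observed: float | None = None,
) -> list[StoichiometrySolution]:
    """Rank all copy-number vectors against a measured SEC-MALS mass.

    Exhaustive search over vectors in ``{0..max_copies}^k`` (excluding
    all-zero), ranked by mass residual with ties broken by fewer total
    copies. When ``uv_weight`` is given (with ``epsilon_observed``), the
    ranking score becomes
    ``residual + uv_weight * |eps_pred - eps_obs| / eps_obs``.
    """
    if not components:
        raise ValueError("need at least one component")
    if not 1 <= len(components) <= 5:
        raise ValueError("between 1 and 5 components supported")
    if not 1 <= max_copies <= 6:
        raise ValueError("max_copies must be in 1..6")
    if measured <= 0:
        raise ValueError("measured mass must be > 0")
    if uv_weight is not None and (epsilon_observed is None or epsilon_observed <= 0):
        raise ValueError("uv_weight requires a positive epsilon_observed")

    solutions = []
    for copies in itertools.product(range(max_copies + 1), repeat=len(components)):
        if not any(copies):
            continue
        pred = sum(n * c.average_mass for n, c in zip(copies, components))
        eps = sum(n * c.epsilon_280 for n, c in zip(copies, components))
        solutions.append(StoichiometrySolution(
            copy_numbers=copies,
            predicted_mass=pred,
            residual=abs(pred - measured),
            epsilon_predicted=eps,
        ))

    def score(sol: StoichiometrySolution) -> tuple:
        s = sol.residual
        if uv_weight is not None:
            s = s + uv_weight * abs(sol.epsilon_predicted - epsilon_observed) / epsilon_observed
        return (s, sol.total_copies, sol.copy_numbers)

    solutions.sort(key=score)
    return solutions
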