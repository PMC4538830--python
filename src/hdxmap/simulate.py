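"""Synthetic two-state HDX experiments with known ground truth.

The generator follows the EX2 limit of amide exchange: a residue with
intrinsic rate k_int and protection factor P exchanges with observed rate
k_int / P, so its deuterium fraction after labeling time t in a bath with
deuterium fraction f is

    d_i(t) = f * (1 - exp(-k_int_i * t / P_i))

A peptide's noiseless centroid mass shift is the 2H-1H mass difference
times the sum of d_i over the peptide's exchange-contributing residues
(skipping the N-terminal amide and prolines, the same convention used for
N_max), optionally scaled by a back-exchange retention factor. Replicate
measurements add independent Gaussian noise on the Da scale.

Two states ("free" and "bound") share sequence and intrinsic rates and
differ only in per-residue protection factors; the set of residues where
they differ is the planted ground-truth interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BS3_D4_DELTA, DEUTERIUM_MASS_SHIFT
from .core import Peptide, contributing_positions

__all__ = [
    "LabelingConditions",
    "ProteinStatePair",
    "make_two_state_protein",
    "make_peptide_map",
    "build_peptides",
    "simulate_uptake",
    "simulate_titration",
    "simulate_xlink_observations",
    "ground_truth_frame",
]

logger = logging.getLogger(__name__)

# proline-free alphabet: prolines carry no amide signal, so the default
# synthetic sequences omit them; set proline_frac > 0 to include them
_ALPHABET = np.array(list("ACDEFGHIKLMNQRSTVWY"))

UPTAKE_COLUMNS = [
    "protein_id", "state", "start", "end", "sequence",
    "timepoint_s", "replicate", "uptake_Da",
]


@dataclass(frozen=True)
class LabelingConditions:
    """Labeling bath and measurement conditions.

    Defaults mirror a standard continuous-labeling experiment: 80% D2O,
    timepoints 3/30/300/3000 s, no back-exchange correction, 0.1 Da
    replicate noise (typical centroid repeatability, small against the
    0.5 Da significance filter), three replicates.
    """

    d2o_fraction: float = 0.8
    timepoints: tuple[float, ...] = (3.0, 30.0, 300.0, 3000.0)
    back_exchange: float = 1.0
    noise_sd: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.d2o_fraction <= 1:
            raise ValueError("d2o_fraction must be in (0, 1]")
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) < 1 or any(t <= 0 for t in tps) or list(tps) != sorted(set(tps)):
            raise ValueError("timepoints must be positive and strictly increasing")
        object.__setattr__(self, "timepoints", tps)
        if not 0 < self.back_exchange <= 1:
            raise ValueError("back_exchange must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass(frozen=True)
class ProteinStatePair:
    """A protein with per-residue kinetics in a free and a bound state."""

    protein_id: str
    sequence: str
    k_int: np.ndarray          # s^-1, > 0
    pf_free: np.ndarray        # dimensionless, >= 1
    pf_bound: np.ndarray       # dimensionless, >= 1
    interface_truth: frozenset[int]  # 1-based positions where pf differs

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("k_int", "pf_free", "pf_bound"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        if np.any(self.k_int <= 0):
            raise ValueError("all k_int must be > 0")
        if np.any(self.pf_free < 1) or np.any(self.pf_bound < 1):
            raise ValueError("all protection factors must be >= 1")
        truth = frozenset(int(i) + 1 for i in np.nonzero(self.pf_free != self.pf_bound)[0])
        if frozenset(self.interface_truth) != truth:
            raise ValueError("interface_truth inconsistent with protection factors")
        object.__setattr__(self, "interface_truth", truth)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def protection(self, state: str) -> np.ndarray:
        if state == "free":
            return self.pf_free
        if state == "bound":
            return self.pf_bound
        raise ValueError(f"unknown state {state!r} (expected 'free' or 'bound')")


def make_two_state_protein(
    length: int,
    interface_regions: list[tuple[int, int, float]],
    k_int_spec: float | tuple[float, float] = (1e-2, 1e2),
    seed: int = 0,
    protein_id: str = "synthetic",
    pf_free_base: float = 1.0,
    proline_frac: float = 0.0,
) -> ProteinStatePair:
    """Build a synthetic protein with planted interface regions.

    Each region is ``(start, end, factor)`` with 1-based inclusive bounds:
    ``pf_bound = pf_free * factor`` on its residues. ``factor > 1`` plants
    protection (exchange decrease on binding); ``factor < 1`` plants
    deprotection, in which case the free-state protection on those residues
    is raised to ``1/factor`` so both states keep protection factors >= 1.

    ``k_int_spec`` is either a constant rate (s^-1) or a ``(lo, hi)`` range
    for a per-residue log-uniform draw. The default range 1e-2..1e2 s^-1
    spans the 3-3000 s labeling window.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq_chars = rng.choice(_ALPHABET, size=length)
    if proline_frac > 0:
        is_pro = rng.random(length) < proline_frac
        seq_chars[is_pro] = "P"
    sequence = "".join(seq_chars)

    if np.isscalar(k_int_spec):
        k_int = np.full(length, float(k_int_spec))
    else:
        lo, hi = k_int_spec
        if not 0 < lo <= hi:
            raise ValueError("k_int range must satisfy 0 < lo <= hi")
        k_int = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=length)

    factor = np.ones(length)
    claimed = np.zeros(length, dtype=bool)
    for start, end, f in interface_regions:
        if not (1 <= start <= end <= length):
            raise ValueError(f"region ({start},{end}) outside [1,{length}]")
        if f <= 0:
            raise ValueError("region factor must be > 0")
        idx = slice(start - 1, end)
        conflict = claimed[idx] & (factor[idx] != f)
        if np.any(conflict):
            raise ValueError(f"region ({start},{end}) overlaps a region with a different factor")
        factor[idx] = f
        claimed[idx] = True

    pf_free = np.full(length, float(pf_free_base))
    low = factor < 1
    pf_free[low] = np.maximum(pf_free[low], 1.0 / factor[low])
    pf_bound = pf_free * factor
    truth = frozenset(int(i) + 1 for i in np.nonzero(factor != 1.0)[0])
    return ProteinStatePair(
        protein_id=protein_id, sequence=sequence, k_int=k_int,
        pf_free=pf_free, pf_bound=pf_bound, interface_truth=truth,
    )


def make_peptide_map(
    length: int,
    mean_len: int = 7,
    step: int = 2,
    len_jitter: int = 1,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Overlapping peptide spans tiling ``1..length``, emulating a pepsin map.

    Peptide starts advance by ``step``; lengths are ``mean_len`` plus a
    uniform jitter in ``[-len_jitter, +len_jitter]``, clamped so that
    consecutive peptides always overlap and every residue is covered.
    A protein shorter than ``mean_len`` yields a single full-length span.

    The defaults (mean length 7, start step 2) sit at the short, dense end
    of realistic pepsin maps. They are chosen for boundary resolution: under
    mean projection, a residue at distance d outside a protected region is
    diluted to roughly ``(m - d)^2 / (2 m^2)`` of the in-region signal for
    contributing peptide length m, so m must be ~6-7 for the 10% threshold
    to localize region edges to within ~3 residues.
    """
    if mean_len < 3:
        raise ValueError("mean_len must be >= 3")
    if step < 1:
        raise ValueError("step must be >= 1")
    if length < mean_len:
        return [(1, length)]
    rng = np.random.default_rng(seed)
    spans: list[tuple[int, int]] = []
    start, last_end = 1, 0
    while last_end < length:
        plen = mean_len + int(rng.integers(-len_jitter, len_jitter + 1))
        plen = max(plen, step + 1, 3)
        end = min(start + plen - 1, length)
        pstart = max(1, min(start, end - 2))  # keep >= 3 residues at the C-terminal edge
        spans.append((pstart, end))
        last_end = max(last_end, end)
        start += step
    return spans


def build_peptides(
    pair: ProteinStatePair,
    spans: list[tuple[int, int]],
    skip_first: int = 1,
) -> list[Peptide]:
    """Instantiate :class:`Peptide` objects for spans on a synthetic protein."""
    peptides = []
    for start, end in spans:
        if not (1 <= start <= end <= pair.length):
            raise ValueError(f"peptide ({start},{end}) outside protein of length {pair.length}")
        peptides.append(
            Peptide.from_sequence(pair.protein_id, start, pair.sequence[start - 1:end], skip_first)
        )
    return peptides


def _noiseless_shift(
    pair: ProteinStatePair, state: str, peptide: Peptide,
    cond: LabelingConditions, skip_first: int,
) -> np.ndarray:
    """Noiseless mass shift (Da) of one peptide at every timepoint."""
    pos = np.array(peptide.contributing_positions(skip_first), dtype=int)
    if pos.size == 0:
        return np.zeros(len(cond.timepoints))
    idx = pos - 1
    k_obs = pair.k_int[idx] / pair.protection(state)[idx]
    t = np.asarray(cond.timepoints)[:, None]
    d = cond.d2o_fraction * (1.0 - np.exp(-k_obs[None, :] * t))
    return cond.back_exchange * DEUTERIUM_MASS_SHIFT * d.sum(axis=1)


def simulate_uptake(
    pair: ProteinStatePair,
    state: str,
    peptides: list[Peptide],
    cond: LabelingConditions,
    seed: int = 0,
    skip_first: int = 1,
) -> pd.DataFrame:
    """Simulate replicate uptake measurements for one state.

    Returns a table with one row per peptide x timepoint x replicate and
    columns ``protein_id, state, start, end, sequence, timepoint_s,
    replicate, uptake_Da``. Byte-identical for a fixed seed.
    """
    pair.protection(state)  # validates the state label
    for pep in peptides:
        if not (1 <= pep.start <= pep.end <= pair.length):
            raise ValueError(
                f"peptide {pep.start}-{pep.end} outside protein of length {pair.length}"
            )
        if pep.sequence != pair.sequence[pep.start - 1:pep.end]:
            raise ValueError(f"peptide {pep.start}-{pep.end} sequence mismatch with protein")

    rng = np.random.default_rng(seed)
    n_t, n_rep = len(cond.timepoints), cond.n_replicates
    shifts = np.array([_noiseless_shift(pair, state, p, cond, skip_first) for p in peptides])
    noise = cond.noise_sd * rng.standard_normal((len(peptides), n_t, n_rep))
    rows = []
    for i, pep in enumerate(peptides):
        for j, t in enumerate(cond.timepoints):
            for r in range(1, n_rep + 1):
                rows.append((
                    pair.protein_id, state, pep.start, pep.end, pep.sequence,
                    t, r, shifts[i, j] + noise[i, j, r - 1],
                ))
    return pd.DataFrame(rows, columns=UPTAKE_COLUMNS)


def ground_truth_frame(pair: ProteinStatePair) -> pd.DataFrame:
    """Per-residue ground-truth sidecar: position, pf_free, pf_bound, in_interface."""
    return pd.DataFrame({
        "residue": np.arange(1, pair.length + 1),
        "pf_free": pair.pf_free,
        "pf_bound": pair.pf_bound,
        "in_interface": [i in pair.interface_truth for i in range(1, pair.length + 1)],
    })


def simulate_titration(
    deltas_pct: list[float],
    free_pct: float = 50.0,
    peptide_len: int = 21,
    timepoint: float = 30.0,
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    d2o_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[Peptide]]:
    """A panel of single-peptide proteins with exact planted %HDX differences.

    Peptide ``i`` (proline-free, length ``peptide_len``) has true mean %HDX
    ``free_pct`` in the free state and ``free_pct - deltas_pct[i]`` in the
    bound state at the single labeling ``timepoint``; the bound-state
    protection factor is solved from the EX2 closed form. Useful for
    checking that the significance thresholds act as exact bounds.
    """
    ceiling = 100.0 * d2o_fraction
    if not 0 < free_pct < ceiling:
        raise ValueError("free_pct must lie strictly below the labeling ceiling")
    k = -np.log(1.0 - free_pct / ceiling) / timepoint
    cond = LabelingConditions(
        d2o_fraction=d2o_fraction, timepoints=(timepoint,),
        noise_sd=noise_sd, n_replicates=n_replicates,
    )
    frames_free, frames_bound, peptides = [], [], []
    for i, delta in enumerate(deltas_pct):
        bound_pct = free_pct - delta
        if not 0 < bound_pct <= free_pct:
            raise ValueError(f"delta {delta} leaves no bound-state exchange")
        factor = (k * timepoint) / -np.log(1.0 - bound_pct / ceiling)
        pair = make_two_state_protein(
            peptide_len, [(1, peptide_len, factor)] if factor != 1.0 else [],
            k_int_spec=k, seed=seed + i, protein_id=f"pep{i:03d}",
        )
        peps = build_peptides(pair, [(1, peptide_len)])
        frames_free.append(simulate_uptake(pair, "free", peps, cond, seed=2 * i + seed + 1))
        frames_bound.append(simulate_uptake(pair, "bound", peps, cond, seed=2 * i + seed + 2))
        peptides.extend(peps)
    return (
        pd.concat(frames_free, ignore_index=True),
        pd.concat(frames_bound, ignore_index=True),
        peptides,
    )


def simulate_xlink_observations(
    true_pairs,
    n_decoys: int,
    ppm_sd: float = 0.0,
    seed: int = 0,
    decoy_range: tuple[float, float] = (400.0, 4000.0),
) -> np.ndarray:
    """Observed neutral masses for planted d0/d4 crosslink doublets plus decoys.

    ``true_pairs`` are crosslink candidates (anything with a
    ``theoretical_mass`` attribute) or bare d0 masses in Da. Each true (d0)
    mass m is emitted as ``m * (1 + eps)`` together with its d4 partner
    ``(m + 4.025108) * (1 + eps)`` — the same relative mass error applies to
    both members of a doublet, as they come from the same deconvolved
    spectrum. Decoys are uniform masses without partners.
    """
    if ppm_sd < 0:
        raise ValueError("ppm_sd must be >= 0")
    rng = np.random.default_rng(seed)
    masses = []
    for item in true_pairs:
        m = float(getattr(item, "theoretical_mass", item))
        eps = rng.normal(0.0, ppm_sd * 1e-6)
        masses.append(m * (1.0 + eps))
        masses.append((m + BS3_D4_DELTA) * (1.0 + eps))
    lo, hi = decoy_range
    masses.extend(rng.uniform(lo, hi, size=n_decoys))
    out = np.array(masses)
    rng.shuffle(out)
    return out
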