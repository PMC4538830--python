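"""In-silico tryptic digestion and BS3 d0/d4 crosslink candidate matching.

BS3 joins primary amines (lysine side chains and the protein N-terminus).
The d0/d4 isotope-coded reagent mix yields, for every genuine crosslinked
species, a pair of deconvolved neutral masses 4.025108 Da apart — the
doublet is the identification signature at the MS1 level. This module
enumerates theoretical crosslinked peptide pairs from tryptic digests and
confirms candidates against observed masses: a candidate is confirmed when
an observed mass matches its theoretical mass within a ppm tolerance and a
d4 partner is present at the expected offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from pyteomics import mass as pt_mass

from .constants import (
    AVERAGE_AA_MASS,
    BS3_D0_MASS,
    BS3_D4_DELTA,
    BS3_DEADEND_MASS,
    WATER_AVERAGE,
    WATER_MONO,
)
from .core import _validate_sequence

__all__ = [
    "DigestPeptide",
    "CrosslinkCandidate",
    "digest",
    "peptide_mass",
    "enumerate_candidates",
    "match_doublets",
]

_TRYPSIN = re.compile(r"[KR](?!P)")  # cleave after K/R except before P


def peptide_mass(sequence: str, kind: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da: sum of residue masses plus water."""
    _validate_sequence(sequence)
    if kind == "monoisotopic":
        return sum(pt_mass.std_aa_mass[aa] for aa in sequence) + WATER_MONO
    if kind == "average":
        return sum(AVERAGE_AA_MASS[aa] for aa in sequence) + WATER_AVERAGE
    raise ValueError("kind must be 'monoisotopic' or 'average'")


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with its crosslinkable amine positions."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    missed_cleavages: int
    monoisotopic_mass: float
    linkable_sites: tuple[int, ...]  # absolute residue positions

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with coordinates")


def digest(
    protein_id: str, sequence: str, max_missed: int = 2
) -> list[DigestPeptide]:
    """Tryptic digest: cleave after K or R except before P.

    Emits every peptide with up to ``max_missed`` internal missed
    cleavages. Linkable sites are lysine side chains — excluding a
    C-terminal lysine unless it is the protein C-terminus, since a
    crosslinked lysine cannot have been cleaved — plus the protein
    N-terminal alpha-amine on the first peptide. Default ``max_missed`` is
    2 because each crosslinked lysine necessarily adds a missed cleavage.
    """
    _validate_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    n = len(sequence)
    # 0-based cut positions (cut after sequence[c-1]); boundaries included
    cuts = [0] + [m.end() for m in _TRYPSIN.finditer(sequence) if m.end() < n] + [n]
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start0, end0 = cuts[i], cuts[j]
            seq = sequence[start0:end0]
            start, end = start0 + 1, end0  # 1-based inclusive
            sites = []
            if start == 1:
                sites.append(1)  # protein N-terminal amine
            for k, aa in enumerate(seq):
                pos = start + k
                if aa != "K":
                    continue
                if pos == end and end != n:
                    continue  # cleaved C-terminal Lys cannot carry a link
                if pos not in sites:
                    sites.append(pos)
            peptides.append(DigestPeptide(
                protein_id=protein_id, start=start, end=end, sequence=seq,
                missed_cleavages=j - i - 1,
                monoisotopic_mass=peptide_mass(seq),
                linkable_sites=tuple(sites),
            ))
    return peptides


@dataclass(frozen=True)
class CrosslinkCandidate:
    """A theoretical BS3-linked peptide pair, optionally matched to data."""

    peptide_a: DigestPeptide
    peptide_b: DigestPeptide
    site_a: int
    site_b: int
    theoretical_mass: float
    matched_observed: float | None = None
    ppm_error: float | None = None
    doublet_confirmed: bool = False


def enumerate_candidates(
    peptides_a: list[DigestPeptide],
    peptides_b: list[DigestPeptide],
    linker_d0: float = BS3_D0_MASS,
    include_deadends: bool = False,
) -> list[CrosslinkCandidate]:
    """All site-resolved crosslink candidates between two digests.

    The theoretical d0 mass is ``m_a + m_b + linker``. Pairs are
    order-normalized; loop-links (both sites on overlapping spans of the
    same protein) are excluded. With ``include_deadends``, hydrolyzed
    mono-links (peptide + 156.07864 Da) are appended for every linkable
    site.
    """
    seen = set()
    out: list[CrosslinkCandidate] = []
    for pa in peptides_a:
        for pb in peptides_b:
            if not pa.linkable_sites or not pb.linkable_sites:
                continue
            if pa.protein_id == pb.protein_id and not (
                pa.end < pb.start or pb.end < pa.start
            ):
                continue  # overlapping spans: a loop- or self-link, not a crosslink
            a, b = pa, pb
            if (b.protein_id, b.start, b.end) < (a.protein_id, a.start, a.end):
                a, b = b, a
            for sa in a.linkable_sites:
                for sb in b.linkable_sites:
                    key = (a.protein_id, a.start, a.end, sa,
                           b.protein_id, b.start, b.end, sb)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(CrosslinkCandidate(
                        peptide_a=a, peptide_b=b, site_a=sa, site_b=sb,
                        theoretical_mass=a.monoisotopic_mass + b.monoisotopic_mass + linker_d0,
                    ))
    if include_deadends:
        for p in {id(p): p for p in list(peptides_a) + list(peptides_b)}.values():
            for s in p.linkable_sites:
                out.append(CrosslinkCandidate(
                    peptide_a=p, peptide_b=p, site_a=s, site_b=s,
                    theoretical_mass=p.monoisotopic_mass + BS3_DEADEND_MASS,
                ))
    return out


def match_doublets(
    observed,
    candidates: list[CrosslinkCandidate],
    tol_ppm: float = 10.0,
    doublet_delta: float = BS3_D4_DELTA,
    doublet_tol: float = 0.02,
) -> list[CrosslinkCandidate]:
    """Confirm candidates against observed neutral masses via d0/d4 doublets.

    A candidate is confirmed iff some observed mass m lies within
    ``tol_ppm`` of its theoretical mass and another observed mass lies
    within ``doublet_tol`` Da of ``m + doublet_delta``. The best
    (smallest |ppm|) confirming mass is recorded; output is sorted by
    |ppm_error|.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    obs = np.sort(np.asarray(observed, dtype=float))
    confirmed = []
    for cand in candidates:
        m_theo = cand.theoretical_mass
        tol = m_theo * tol_ppm * 1e-6
        lo = np.searchsorted(obs, m_theo - tol, side="left")
        hi = np.searchsorted(obs, m_theo + tol, side="right")
        best = None
        for m in obs[lo:hi]:
            partner = m + doublet_delta
            plo = np.searchsorted(obs, partner - doublet_tol, side="left")
            phi = np.searchsorted(obs, partner + doublet_tol, side="right")
            if phi > plo:
                ppm = (m - m_theo) / m_theo * 1e6
                if best is None or abs(ppm) < abs(best[1]):
                    best = (m, ppm)
        if best is not None:
            confirmed.append(CrosslinkCandidate(
                peptide_a=cand.peptide_a, peptide_b=cand.peptide_b,
                site_a=cand.site_a, site_b=cand.site_b,
                theoretical_mass=m_theo,
                matched_observed=float(best[0]),
                ppm_error=float(best[1]),
                doublet_confirmed=True,
            ))
    confirmed.sort(key=lambda c: abs(c.ppm_error))
    return confirmed
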