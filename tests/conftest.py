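import numpy as np
import pytest

import hdxmap as hm


@pytest.fixture
def planted_pair():
    """563-residue protein with 100x protection planted on residues 88-114."""
    return hm.make_two_state_protein(563, [(88, 114, 100.0)], seed=11)


@pytest.fixture
def noiseless_conditions():
    return hm.LabelingConditions(noise_sd=0.0)


def make_pdb_text(n_residues: int = 6, chain: str = "A", first_resseq: int = 1) -> str:
    """A minimal synthetic PDB: one CA + one N atom per residue, poly-Ala."""
    lines = []
    serial = 1
    for i in range(n_residues):
        resseq = first_resseq + i
        for name in ("N", "CA"):
            x, y, z = 1.0 * i, 2.0 * i, 0.5
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} ALA {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{25.50:6.2f}          {'N':>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_xlink_fixture(seed: int = 5):
    """Two synthetic proteins with planted crosslink sites mimicking a
    C-terminal Lys cluster (204/205/207) paired with an N-terminal helix
    cluster (84/91/95).

    Returns (sequences, candidates, planted, observed) where sequences maps
    protein id to sequence, planted are three candidates whose theoretical
    masses are unique among all candidates within 10 ppm, and observed
    contains their d0/d4 doublets (2 ppm mass error) plus 50 partner-less
    decoys.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P

    def make_seq(length, lys_at, arg_every=15):
        seq = rng.choice(alphabet, size=length)
        for pos in range(arg_every, length, arg_every):
            seq[pos - 1] = "R"
        for pos in lys_at:
            seq[pos - 1] = "K"
        return "".join(seq)

    seq_a = make_seq(120, lys_at=(84, 91, 95, 30, 60))
    seq_b = make_seq(229, lys_at=(204, 205, 207, 50, 110))
    digest_a = hm.digest("protA", seq_a, max_missed=2)
    digest_b = hm.digest("protB", seq_b, max_missed=2)
    candidates = hm.enumerate_candidates(digest_a, digest_b)

    masses = sorted(c.theoretical_mass for c in candidates)

    def mass_unique(m):
        return sum(1 for x in masses if abs(x - m) <= m * 10e-6) == 1

    planted = []
    for sa, sb in [(84, 204), (91, 205), (95, 207)]:
        options = [
            c for c in candidates
            if {c.site_a, c.site_b} == {sa, sb} and mass_unique(c.theoretical_mass)
        ]
        assert options, f"no mass-unique candidate for sites {sa},{sb}"
        planted.append(min(options, key=lambda c: c.theoretical_mass))
    observed = hm.simulate_xlink_observations(planted, n_decoys=50, ppm_sd=2.0, seed=seed)
    return {"protA": seq_a, "protB": seq_b}, candidates, planted, observed


def brute_force_doublets(observed, candidates, tol_ppm=10.0,
                         doublet_delta=hm.BS3_D4_DELTA, doublet_tol=0.02):
    """Exhaustive O(candidates x observed^2) reference matcher."""
    confirmed = {}
    for c in candidates:
        best = None
        for m in observed:
            if abs(m - c.theoretical_mass) > c.theoretical_mass * tol_ppm * 1e-6:
                continue
            if not any(abs(m2 - (m + doublet_delta)) <= doublet_tol for m2 in observed):
                continue
            ppm = (m - c.theoretical_mass) / c.theoretical_mass * 1e6
            if best is None or abs(ppm) < abs(best[1]):
                best = (m, ppm)
        if best is not None:
            key = (c.peptide_a.protein_id, c.peptide_a.start, c.peptide_a.end, c.site_a,
                   c.peptide_b.protein_id, c.peptide_b.start, c.peptide_b.end, c.site_b)
            confirmed[key] = best
    return confirmed


def candidate_key(c):
    return (c.peptide_a.protein_id, c.peptide_a.start, c.peptide_a.end, c.site_a,
            c.peptide_b.protein_id, c.peptide_b.start, c.peptide_b.end, c.site_b)
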