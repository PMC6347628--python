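"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

PURINES = set("AG")


def literal_degeneracy_table() -> dict[str, bool]:
    """64-entry table: codon -> is fourfold-degenerate at position 3.

    Built by translating every third-position variant with Biopython —
    a route independent of the package's prefix-set implementation.
    """
    table = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                variants = {str(Seq(b1 + b2 + x).translate()) for x in "ACGT"}
                table[b1 + b2 + b3] = len(variants) == 1 and "*" not in variants
    return table


DEGENERACY_TABLE = literal_degeneracy_table()


def oracle_4dtv_counts(seq_a: str, seq_b: str) -> tuple[int, int]:
    """Brute-force per-codon-column 4DTv scan against the literal table."""
    n_4d = n_tv = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(ca) - set("ACGT") or set(cb) - set("ACGT"):
            continue
        if ca[:2] != cb[:2]:
            continue
        if not DEGENERACY_TABLE[ca]:
            continue
        n_4d += 1
        a3, b3 = ca[2], cb[2]
        if a3 != b3 and ((a3 in PURINES) != (b3 in PURINES)):
            n_tv += 1
    return n_4d, n_tv


def random_codon_alignment(
    rng: np.random.Generator, max_codons: int = 300
) -> tuple[str, str]:
    """A random codon-aware alignment pair exercising every column kind.

    Mixes matched-prefix columns, fully independent codons, whole-codon
    gaps and N-containing codons, all legal under the alignment contract.
    """
    n = int(rng.integers(1, max_codons + 1))
    bases = "ACGT"
    cols_a, cols_b = [], []
    for _ in range(n):
        kind = rng.random()
        if kind < 0.65:  # shared prefix, independent thirds
            prefix = "".join(rng.choice(list(bases), 2))
            cols_a.append(prefix + rng.choice(list(bases)))
            cols_b.append(prefix + rng.choice(list(bases)))
        elif kind < 0.85:  # independent codons
            cols_a.append("".join(rng.choice(list(bases), 3)))
            cols_b.append("".join(rng.choice(list(bases), 3)))
        elif kind < 0.93:  # whole-codon gap on one or both sides
            gap_both = rng.random() < 0.3
            cols_a.append("---")
            cols_b.append("---" if gap_both else "".join(rng.choice(list(bases), 3)))
        else:  # N contamination
            codon = list(rng.choice(list(bases), 3))
            codon[int(rng.integers(0, 3))] = "N"
            cols_a.append("".join(codon))
            cols_b.append("".join(rng.choice(list(bases), 3)))
    return "".join(cols_a), "".join(cols_b)


def brute_force_bh(p_values: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg by the textbook definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        candidate = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, candidate)
        adj[idx] = min(1.0, running_min)
    return adj


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of every table with the same margins whose
    probability does not exceed the observed table's (with a tiny
    relative tolerance for float ties).
    """
    from scipy.stats import hypergeom

    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    k_min = max(0, r1 + c1 - n)
    k_max = min(r1, c1)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
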