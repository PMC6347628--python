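"""Codon-pair simulator under a Kimura two-parameter null model.

Only the third positions of fourfold-degenerate codons evolve; first and
second codon positions and non-fourfold codons are held fixed.  This keeps
the realized fourfold-site set constant and exactly known, which is all
the 4DTv statistic reads, and makes per-pair ground truth exact.

The substitution process at each mutable site is a continuous-time Markov
chain with transition rate ``alpha`` (A<->G, C<->T) and rate ``beta``
toward EACH of the two transversion neighbours.  Because every state has
the same total exit rate ``alpha + 2*beta``, the event count over time
``t`` is Poisson and each event's type is drawn independently — an exact
simulation of the exponential-waiting-time process, vectorized.

Closed form used throughout for checking: the expected observed
transversion-difference proportion between two lineages separated by
total path ``2t`` is ``0.5 * (1 - exp(-8*beta*t))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from millet_evol.degen4dtv import FOURFOLD_PREFIXES, CodonPairAlignment

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

_STANDARD = unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(b1 + b2 + b3
           for b1 in _BASES for b2 in _BASES for b3 in _BASES
           if b1 + b2 + b3 not in _STANDARD.stop_codons)
)
FOURFOLD_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c[:2] in FOURFOLD_PREFIXES
)

# int encoding of codons as (n_codons, 3) base indices into "ACGT"
_SENSE_IDX = np.array(
    [[_BASES.index(b) for b in codon] for codon in SENSE_CODONS], dtype=np.int8
)
_SENSE_IS_4D = np.array(
    [c[:2] in FOURFOLD_PREFIXES for c in SENSE_CODONS], dtype=bool
)
_FOURFOLD_IDX = np.array(
    [[_BASES.index(b) for b in codon] for codon in FOURFOLD_CODONS],
    dtype=np.int8,
)


@dataclass(frozen=True)
class SubstitutionParams:
    """Per-site rates and a divergence time for the two-parameter model.

    alpha : transitions per third-codon-position site per Myr per lineage
    beta  : rate toward EACH of the two transversion neighbours, same units
    t     : time since the common ancestor in Myr (total path length 2t)
    """

    alpha: float
    beta: float
    t: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.t < 0:
            raise ValueError("alpha, beta and t must all be >= 0")

    @property
    def total_rate(self) -> float:
        return self.alpha + 2.0 * self.beta


def expected_4dtv(params: SubstitutionParams) -> float:
    """K2P closed-form expected transversion proportion at a fourfold site."""
    return 0.5 * (1.0 - math.exp(-8.0 * params.beta * params.t))


def beta_for_target_4dtv(target: float, t: float) -> float:
    """Invert the closed form: the beta that gives ``target`` expected 4DTv at time t.

    Raises for targets at or past saturation (>= 0.5) or non-positive t.
    """
    if not 0.0 <= target < 0.5:
        raise ValueError("target 4DTv must lie in [0, 0.5)")
    if t <= 0:
        raise ValueError("t must be > 0")
    return -math.log1p(-2.0 * target) / (8.0 * t)


def _evolve_third_positions(
    states: np.ndarray, params: SubstitutionParams, rng: np.random.Generator
) -> np.ndarray:
    """Evolve base states (ints 0..3 over ACGT) for time t on one lineage.

    Exact CTMC simulation: Poisson event count per site, each event a
    transition with probability alpha/(alpha+2beta) else one of the two
    transversions equally.  Transition partner is (s+2)%4; transversion
    partners are (s+1)%4 and (s+3)%4 under the ACGT encoding.
    """
    out = states.copy()
    lam = params.total_rate * params.t
    if lam == 0 or out.size == 0:
        return out
    n_events = rng.poisson(lam, size=out.shape)
    p_transition = params.alpha / params.total_rate
    max_events = int(n_events.max(initial=0))
    for k in range(max_events):
        active = n_events > k
        n_active = int(active.sum())
        if n_active == 0:
            break
        is_transition = rng.random(n_active) < p_transition
        # transversion target: +1 or +3 (mod 4), each equally likely
        tv_step = rng.choice(np.array([1, 3], dtype=np.int8), size=n_active)
        step = np.where(is_transition, np.int8(2), tv_step)
        out[active] = (out[active] + step) % 4
    return out


@dataclass
class CodonPairSimulation:
    """Simulated alignments plus the exact per-pair ground truth."""

    pairs: list[CodonPairAlignment]
    truth: pd.DataFrame  # pair_id, n_4d_sites, n_transversions, true_t
    params: SubstitutionParams = field(repr=False, default=None)  # type: ignore[assignment]


def _rows_to_seqs(base_idx: np.ndarray) -> list[str]:
    """(n, L, 3) int base indices -> list of n nucleotide strings."""
    flat = base_idx.reshape(base_idx.shape[0], -1)
    return [
        _BASE_BYTES[row.astype(np.intp)].tobytes().decode("ascii")
        for row in flat
    ]


def simulate_codon_pairs(
    params: SubstitutionParams,
    n_pairs: int,
    seq_len_codons: int,
    seed: int,
    fourfold_only: bool = False,
    pair_prefix: str = "pair",
) -> CodonPairSimulation:
    """Simulate diverged codon-sequence pairs with exact ground truth.

    Each pair descends from a random ancestral sequence of sense codons
    (uniform over the 61; uniform over the 32 fourfold codons when
    ``fourfold_only`` — handy for fixing the number of scorable sites at
    exactly ``seq_len_codons``).  Both lineages evolve independently for
    time ``params.t``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if seq_len_codons < 1:
        raise ValueError("seq_len_codons must be >= 1")
    rng = np.random.default_rng(seed)

    if fourfold_only:
        codon_pool, is_4d = _FOURFOLD_IDX, np.ones(len(_FOURFOLD_IDX), bool)
    else:
        codon_pool, is_4d = _SENSE_IDX, _SENSE_IS_4D

    anc_codons = rng.integers(0, len(codon_pool), size=(n_pairs, seq_len_codons))
    anc = codon_pool[anc_codons]  # (n_pairs, L, 3)
    mutable = is_4d[anc_codons]  # fourfold mask, fixed by construction

    third_anc = anc[:, :, 2][mutable]
    third_a = np.array(anc[:, :, 2])
    third_b = np.array(anc[:, :, 2])
    third_a[mutable] = _evolve_third_positions(third_anc, params, rng)
    third_b[mutable] = _evolve_third_positions(third_anc, params, rng)

    seq_a_bases = anc.copy()
    seq_b_bases = anc.copy()
    seq_a_bases[:, :, 2] = third_a
    seq_b_bases[:, :, 2] = third_b

    # ground truth straight from the integer states: transversion iff the
    # two bases differ in purine/pyrimidine class (parity of the index)
    differs = third_a != third_b
    tv = differs & ((third_a % 2) != (third_b % 2))
    n_4d_sites = mutable.sum(axis=1)
    n_tv = (tv & mutable).sum(axis=1)

    ids = [f"{pair_prefix}{i:05d}" for i in range(n_pairs)]
    seqs_a = _rows_to_seqs(seq_a_bases)
    seqs_b = _rows_to_seqs(seq_b_bases)
    pairs = [
        CodonPairAlignment(pid, f"{pid}_a", f"{pid}_b", sa, sb)
        for pid, sa, sb in zip(ids, seqs_a, seqs_b)
    ]
    truth = pd.DataFrame(
        {
            "pair_id": ids,
            "n_4d_sites": n_4d_sites,
            "n_transversions": n_tv,
            "true_t": params.t,
        }
    )
    return CodonPairSimulation(pairs=pairs, truth=truth, params=params)


def write_pairs_fasta(pairs: Sequence[CodonPairAlignment], path: str | Path) -> None:
    """Write both members of every pair as ``<pairID>_a`` / ``<pairID>_b``."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for pair in pairs:
        records.append(SeqRecord(Seq(pair.seq_a), id=pair.gene_a, description=""))
        records.append(SeqRecord(Seq(pair.seq_b), id=pair.gene_b, description=""))
    SeqIO.write(records, str(path), "fasta")
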