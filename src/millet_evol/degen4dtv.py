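"""Fourfold-degenerate transversion (4DTv) distance on aligned CDS pairs.

The 4DTv statistic is the proportion of fourfold-degenerate third codon
positions at which two aligned coding sequences differ by a transversion
(purine vs pyrimidine).  Because transversions at synonymous sites
accumulate slowly and saturate late, the statistic is a convenient proxy
for the relative age of paralog/ortholog pairs, e.g. for locating
whole-genome-duplication cohorts in a genome.

This module classifies fourfold sites, counts transversions, and applies
two standard pre/post-processing rules used when the pairs come from
synteny blocks: a minimum anchor count per collinear block, and
deduplication of tandem gene copies that match the same homeolog.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID_CHARS = frozenset("ACGTN-")

MIN_ANCHORS_PER_BLOCK = 5  # collinear blocks with fewer anchors are discarded


def _fourfold_prefixes() -> frozenset[str]:
    """Two-base prefixes whose four codons all encode one amino acid.

    Derived from the standard genetic code rather than hard-coded, so the
    degeneracy rule is traceable to the code table itself.
    """
    table = unambiguous_dna_by_id[1].forward_table
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {table.get(b1 + b2 + b3) for b3 in "ACGT"}
            if len(aas) == 1 and None not in aas:
                prefixes.add(b1 + b2)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()


class AlignmentError(ValueError):
    """Raised for malformed codon alignments."""


class NoScorablePairsError(ValueError):
    """Raised when anchor extraction yields zero alignable pairs."""


@dataclass(frozen=True)
class CodonPairAlignment:
    """One aligned pair of coding sequences, the unit 4DTv is computed on.

    Sequences must be equal-length, codon-aware alignments over
    ``{A,C,G,T,N,-}``; gaps may only occur as whole codons.
    """

    pair_id: str
    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise AlignmentError(
                f"{self.pair_id}: aligned lengths differ ({len(a)} vs {len(b)})"
            )
        if len(a) % 3 != 0:
            raise AlignmentError(
                f"{self.pair_id}: alignment length {len(a)} is not a multiple of 3"
            )
        for seq, gene in ((a, self.gene_a), (b, self.gene_b)):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"{self.pair_id}/{gene}: invalid characters {sorted(bad)}"
                )
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise AlignmentError(
                        f"{self.pair_id}/{gene}: partial-codon gap {codon!r} "
                        f"at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class FourDTvResult:
    """Counts of scored fourfold sites and transversions for one pair."""

    pair_id: str
    n_4d_sites: int
    n_transversions: int

    @property
    def defined(self) -> bool:
        return self.n_4d_sites > 0

    @property
    def value(self) -> float:
        """Raw transversion proportion; NaN when no fourfold site was scored."""
        if not self.defined:
            return math.nan
        return self.n_transversions / self.n_4d_sites


def is_fourfold_site(codon_a: str, codon_b: str) -> bool:
    """True iff this aligned codon column is scorable as a fourfold site.

    Strict-intersection convention: both codons must be gap- and N-free,
    identical at the first two positions, and that shared prefix must be
    one of the eight fourfold-degenerate families of the standard code.
    """
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise AlignmentError(
            f"codons must be 3-mers, got {codon_a!r}, {codon_b!r}"
        )
    if "-" in codon_a or "-" in codon_b or "N" in codon_a or "N" in codon_b:
        return False
    if codon_a[:2] != codon_b[:2]:
        return False
    return codon_a[:2] in FOURFOLD_PREFIXES


def is_transversion(base_a: str, base_b: str) -> bool:
    """Purine-vs-pyrimidine difference (identity and transitions are False)."""
    return (base_a in PURINES) != (base_b in PYRIMIDINES) and base_a != base_b


def compute_4dtv(
    pair: CodonPairAlignment, convention: str = "strict"
) -> FourDTvResult:
    """Score a codon-pair alignment and return 4DTv counts.

    ``convention="strict"`` (default) scores a column only when both codons
    share an identical fourfold prefix; ``"loose"`` scores whenever each
    codon's own prefix is fourfold-degenerate, without requiring the
    prefixes to match.  Raw proportion, no multiple-hit correction; see
    :func:`corrected_4dtv` for an optional saturation correction.
    """
    if convention not in ("strict", "loose"):
        raise ValueError(f"unknown convention {convention!r}")
    n_4d = 0
    n_tv = 0
    for codon_a, codon_b in pair.codons():
        if convention == "strict":
            scorable = is_fourfold_site(codon_a, codon_b)
        else:
            scorable = (
                "-" not in codon_a and "-" not in codon_b
                and "N" not in codon_a and "N" not in codon_b
                and codon_a[:2] in FOURFOLD_PREFIXES
                and codon_b[:2] in FOURFOLD_PREFIXES
            )
        if not scorable:
            continue
        n_4d += 1
        a3, b3 = codon_a[2], codon_b[2]
        if a3 != b3 and ((a3 in PURINES) != (b3 in PURINES)):
            n_tv += 1
    return FourDTvResult(pair.pair_id, n_4d, n_tv)


def corrected_4dtv(result: FourDTvResult) -> float:
    """Kimura-style saturation-corrected transversion distance.

    Inverts the two-parameter closed form Q = 0.5*(1 - exp(-2*d_tv)),
    giving d_tv = -0.5*ln(1 - 2Q).  Undefined (NaN) at or beyond
    saturation (Q >= 0.5) or when no sites were scored.
    """
    if not result.defined:
        return math.nan
    q = result.value
    if q >= 0.5:
        return math.nan
    return -0.5 * math.log1p(-2.0 * q)


# ---------------------------------------------------------------------------
# Anchor extraction and tandem deduplication
# ---------------------------------------------------------------------------


def extract_anchor_pairs(
    anchors: pd.DataFrame,
    sequences: Mapping[str, str],
    pair_table: pd.DataFrame | None = None,
    min_anchors: int = MIN_ANCHORS_PER_BLOCK,
) -> list[CodonPairAlignment]:
    """Turn a synteny anchor table into scorable codon-pair alignments.

    ``anchors`` needs columns (block_id, gene_a, gene_b).  Blocks with
    fewer than ``min_anchors`` anchor pairs are dropped entirely; anchors
    whose genes cannot be resolved in ``sequences`` are skipped with a
    logged count.  ``pair_table`` (pair_id, gene_a, gene_b) optionally
    supplies stable pair identifiers; otherwise ``geneA|geneB`` is used.
    """
    required = {"block_id", "gene_a", "gene_b"}
    if not required.issubset(anchors.columns):
        raise ValueError(f"anchor table must have columns {sorted(required)}")

    pair_ids: dict[tuple[str, str], str] = {}
    if pair_table is not None:
        for row in pair_table.itertuples(index=False):
            pair_ids[(row.gene_a, row.gene_b)] = str(row.pair_id)
            pair_ids[(row.gene_b, row.gene_a)] = str(row.pair_id)

    block_sizes = anchors.groupby("block_id").size()
    kept_blocks = set(block_sizes[block_sizes >= min_anchors].index)
    dropped_blocks = len(block_sizes) - len(kept_blocks)
    if dropped_blocks:
        logger.info(
            "dropped %d synteny block(s) with < %d anchors",
            dropped_blocks, min_anchors,
        )

    pairs: list[CodonPairAlignment] = []
    n_unresolved = 0
    for row in anchors.itertuples(index=False):
        if row.block_id not in kept_blocks:
            continue
        ga, gb = str(row.gene_a), str(row.gene_b)
        if ga not in sequences or gb not in sequences:
            n_unresolved += 1
            continue
        pid = pair_ids.get((ga, gb), f"{ga}|{gb}")
        pairs.append(
            CodonPairAlignment(pid, ga, gb, sequences[ga], sequences[gb])
        )
    if n_unresolved:
        logger.warning(
            "skipped %d anchor pair(s) with unresolvable gene IDs", n_unresolved
        )
    if not pairs:
        raise NoScorablePairsError(
            "no scorable pairs: every anchor was dropped or unresolved"
        )
    return pairs


def _tandem_clusters(
    positions: pd.DataFrame, window: int
) -> dict[str, int]:
    """Assign each gene a tandem-cluster id.

    Genes on the same chromosome within ``window`` gene ranks form a
    cluster under transitive closure (single-linkage along the rank order).
    """
    cluster_of: dict[str, int] = {}
    next_id = 0
    for _, chrom_df in positions.groupby("chrom"):
        ordered = chrom_df.sort_values("rank")
        prev_rank: int | None = None
        current = None
        for row in ordered.itertuples(index=False):
            rank = int(row.rank)
            if prev_rank is None or rank - prev_rank > window:
                current = next_id
                next_id += 1
            cluster_of[str(row.gene)] = current
            prev_rank = rank
    return cluster_of


def dedup_tandem(
    results: Sequence[FourDTvResult],
    pair_table: pd.DataFrame,
    positions: pd.DataFrame,
    window: int = 5,
) -> list[FourDTvResult]:
    """Keep one 4DTv result per tandem cluster matching a common homeolog.

    Tandem duplicates paired against the same partner gene would otherwise
    contribute several nearly identical values to the 4DTv distribution;
    they are counted once.  Within a redundant group the result with the
    most scored sites is kept (ties: lexicographically smallest gene pair).
    Results whose partners are not tandem-clustered pass through unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    genes_of = {
        str(r.pair_id): (str(r.gene_a), str(r.gene_b))
        for r in pair_table.itertuples(index=False)
    }
    known = set(positions["gene"].astype(str))
    for res in results:
        if res.pair_id not in genes_of:
            raise ValueError(f"pair {res.pair_id} missing from pair table")
        for gene in genes_of[res.pair_id]:
            if gene not in known:
                raise ValueError(f"gene {gene} missing from position table")

    cluster_of = _tandem_clusters(positions, window)

    def sort_key(res: FourDTvResult) -> tuple:
        ga, gb = genes_of[res.pair_id]
        return (-res.n_4d_sites, min(ga, gb), max(ga, gb), res.pair_id)

    # Group results that pit a tandem cluster against one shared homeolog,
    # in both orientations; keep the best representative of each group.
    dropped: set[str] = set()
    for orient in (0, 1):
        groups: dict[tuple, list[FourDTvResult]] = {}
        for res in results:
            genes = genes_of[res.pair_id]
            partner, homeolog = genes[orient], genes[1 - orient]
            key = (homeolog, cluster_of[partner])
            groups.setdefault(key, []).append(res)
        for members in groups.values():
            if len(members) < 2:
                continue
            keep = min(members, key=sort_key)
            for res in members:
                if res.pair_id != keep.pair_id:
                    dropped.add(res.pair_id)
    kept = [r for r in results if r.pair_id not in dropped]
    if dropped:
        logger.info("tandem dedup removed %d of %d results", len(dropped), len(results))
    return kept


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def results_to_frame(
    results: Sequence[FourDTvResult],
    pair_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Results as a tidy table, joined to gene/cohort metadata when given."""
    df = pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "n_4d_sites": [r.n_4d_sites for r in results],
            "n_transversions": [r.n_transversions for r in results],
            "fourdtv": [r.value for r in results],
        }
    )
    if pair_table is not None:
        meta_cols = [
            c for c in ("pair_id", "gene_a", "gene_b", "cohort_label")
            if c in pair_table.columns
        ]
        df = df.merge(pair_table[meta_cols], on="pair_id", how="left")
        ordered = [
            c for c in (
                "pair_id", "gene_a", "gene_b",
                "n_4d_sites", "n_transversions", "fourdtv", "cohort_label",
            )
            if c in df.columns
        ]
        df = df[ordered]
    return df
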