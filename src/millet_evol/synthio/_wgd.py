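"""Synthetic allotetraploid "genome" for end-to-end 4DTv/WGD-dating runs.

Emits three labelled cohorts of gene pairs — a young within-genome
homeolog cohort (the tetraploidization), a cross-species ortholog cohort,
and a deep background cohort (an old duplication shared across grasses) —
plus optional tandem duplicate triplets that all match one homeolog.
Outputs mirror what a synteny pipeline would hand the 4DTv stage: a pair
table, sequences, a block-structured anchor table and gene positions.

Divergence times are per cohort; substitution rates may be shared or
supplied per cohort.  Raw 4DTv saturates (it is bounded by 0.5), so a
single clock rate cannot place a young peak and a deep peak at arbitrary
chosen values — per-cohort rates let the generator target specific
expected 4DTv levels, e.g. via :func:`beta_for_target_4dtv`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from millet_evol.degen4dtv import CodonPairAlignment
from millet_evol.synthio._codon import (
    SubstitutionParams,
    simulate_codon_pairs,
)

COHORTS = ("wgd", "ortholog", "background")


@dataclass(frozen=True)
class WGDCohortSpec:
    """Sizes, times and sequence length for the three pair cohorts."""

    n_pairs_wgd: int = 300
    t_wgd: float = 5.8
    n_pairs_ortholog: int = 300
    t_ortholog: float = 18.0
    n_pairs_background: int = 300
    t_background: float = 70.0
    n_tandem_triplets: int = 0
    seq_len_codons: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_pairs_wgd, self.n_pairs_ortholog,
            self.n_pairs_background, self.n_tandem_triplets,
        )
        if any(c < 0 for c in counts):
            raise ValueError("pair/triplet counts must be >= 0")
        if min(self.t_wgd, self.t_ortholog, self.t_background) < 0:
            raise ValueError("divergence times must be >= 0")
        if self.seq_len_codons < 1:
            raise ValueError("seq_len_codons must be >= 1")


@dataclass
class WGDGenomeSim:
    """In-memory bundle of everything :func:`simulate_wgd_genome` emits."""

    pair_table: pd.DataFrame      # pair_id, gene_a, gene_b, cohort_label, true_t
    sequences: dict[str, str]     # gene id -> aligned CDS
    anchors: pd.DataFrame         # block_id, gene_a, gene_b
    positions: pd.DataFrame       # gene, chrom, rank
    truth: dict = field(default_factory=dict)

    def alignments(self) -> list[CodonPairAlignment]:
        return [
            CodonPairAlignment(
                str(r.pair_id), str(r.gene_a), str(r.gene_b),
                self.sequences[str(r.gene_a)], self.sequences[str(r.gene_b)],
            )
            for r in self.pair_table.itertuples(index=False)
        ]

    def write(self, out_dir: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_table.to_csv(out / "pairs.tsv", sep="\t", index=False)
        self.anchors.to_csv(out / "anchors.tsv", sep="\t", index=False)
        self.positions.to_csv(out / "positions.tsv", sep="\t", index=False)
        SeqIO.write(
            (SeqRecord(Seq(seq), id=gene, description="")
             for gene, seq in self.sequences.items()),
            str(out / "sequences.fasta"),
            "fasta",
        )
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _resolve_params(
    params: SubstitutionParams | Mapping[str, SubstitutionParams],
    cohort: str,
    t: float,
) -> SubstitutionParams:
    if isinstance(params, SubstitutionParams):
        base = params
    else:
        if cohort not in params:
            raise ValueError(f"no substitution params supplied for cohort {cohort!r}")
        base = params[cohort]
    return SubstitutionParams(alpha=base.alpha, beta=base.beta, t=t)


def simulate_wgd_genome(
    spec: WGDCohortSpec,
    params: SubstitutionParams | Mapping[str, SubstitutionParams],
    block_size: int = 10,
) -> WGDGenomeSim:
    """Simulate the three pair cohorts plus tandem triplets.

    ``params`` is either one :class:`SubstitutionParams` applied to all
    cohorts (its ``t`` is ignored; cohort times come from ``spec``) or a
    mapping from cohort label ("wgd", "ortholog", "background") to params.
    Tandem triplets evolve under the wgd cohort's rates at ``t_wgd`` and
    are labelled cohort "wgd"; their grouping is recorded in ``truth``.
    """
    cohort_plan = [
        ("wgd", spec.n_pairs_wgd, spec.t_wgd, "pmA", "pmB", "chrA", "chrB"),
        ("ortholog", spec.n_pairs_ortholog, spec.t_ortholog, "pmA", "si", "chrA", "si_chr"),
        ("background", spec.n_pairs_background, spec.t_background, "pmA", "pmB", "chrA", "chrB"),
    ]

    rows = []
    sequences: dict[str, str] = {}
    pos_rows = []
    rank_counters: dict[str, int] = {}
    truth_pairs = []

    def next_rank(chrom: str) -> int:
        r = rank_counters.get(chrom, 0)
        rank_counters[chrom] = r + 1
        return r

    for cohort, n_pairs, t, pa, pb, chrom_a, chrom_b in cohort_plan:
        if n_pairs == 0:
            continue
        p = _resolve_params(params, cohort, t)
        sim = simulate_codon_pairs(
            p, n_pairs, spec.seq_len_codons,
            seed=_cohort_seed(spec.seed, cohort),
            pair_prefix=f"{cohort}_",
        )
        for aln, truth in zip(sim.pairs, sim.truth.itertuples(index=False)):
            ga = f"{pa}_{aln.pair_id}"
            gb = f"{pb}_{aln.pair_id}"
            sequences[ga] = aln.seq_a
            sequences[gb] = aln.seq_b
            pos_rows.append((ga, chrom_a, next_rank(chrom_a)))
            pos_rows.append((gb, chrom_b, next_rank(chrom_b)))
            rows.append((aln.pair_id, ga, gb, cohort, t))
            truth_pairs.append(
                {
                    "pair_id": aln.pair_id,
                    "cohort": cohort,
                    "true_t": t,
                    "n_4d_sites": int(truth.n_4d_sites),
                    "n_transversions": int(truth.n_transversions),
                }
            )

    # tandem triplets: 3 adjacent copies on chrA, all against one chrB homeolog
    tandem_groups: dict[str, list[str]] = {}
    if spec.n_tandem_triplets > 0:
        p = _resolve_params(params, "wgd", spec.t_wgd)
        n_genes = 4 * spec.n_tandem_triplets  # homeolog + 3 copies per triplet
        sim = simulate_codon_pairs(
            p, 3 * spec.n_tandem_triplets, spec.seq_len_codons,
            seed=_cohort_seed(spec.seed, "tandem"),
            pair_prefix="tandem_",
        )
        # regenerate so the 3 copies of one triplet share an ancestor: reuse
        # sim pairs but overwrite the homeolog side with the first pair's b-seq
        k = 0
        for j in range(spec.n_tandem_triplets):
            gb = f"pmB_tandemgrp{j:03d}"
            group_pairs = []
            homeolog_seq = None
            for c in range(3):
                aln = sim.pairs[k]
                k += 1
                ga = f"pmA_{aln.pair_id}"
                if homeolog_seq is None:
                    homeolog_seq = aln.seq_b
                    sequences[gb] = homeolog_seq
                    pos_rows.append((gb, "chrB", next_rank("chrB")))
                sequences[ga] = aln.seq_a
                pos_rows.append((ga, "chrA", next_rank("chrA")))
                rows.append((aln.pair_id, ga, gb, "wgd", spec.t_wgd))
                group_pairs.append(aln.pair_id)
            tandem_groups[gb] = group_pairs

    pair_table = pd.DataFrame(
        rows, columns=["pair_id", "gene_a", "gene_b", "cohort_label", "true_t"]
    )
    positions = pd.DataFrame(pos_rows, columns=["gene", "chrom", "rank"])

    anchors = _block_anchors(pair_table, block_size)

    truth = {
        "spec": {
            "n_pairs_wgd": spec.n_pairs_wgd,
            "t_wgd": spec.t_wgd,
            "n_pairs_ortholog": spec.n_pairs_ortholog,
            "t_ortholog": spec.t_ortholog,
            "n_pairs_background": spec.n_pairs_background,
            "t_background": spec.t_background,
            "n_tandem_triplets": spec.n_tandem_triplets,
            "seq_len_codons": spec.seq_len_codons,
            "seed": spec.seed,
        },
        "tandem_groups": tandem_groups,
        "pairs": truth_pairs,
    }
    return WGDGenomeSim(
        pair_table=pair_table,
        sequences=sequences,
        anchors=anchors,
        positions=positions,
        truth=truth,
    )


def _cohort_seed(seed: int, cohort: str) -> int:
    # stable, hash()-independent per-cohort substream within int32 range
    h = 0
    for ch in cohort:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (seed * 1_000_003 + h) % (2**31)


def _block_anchors(pair_table: pd.DataFrame, block_size: int) -> pd.DataFrame:
    """Chunk each cohort's pairs into collinear-block-like anchor groups.

    Trailing chunks smaller than 5 anchors are merged into the previous
    block so every emitted block clears the minimum-anchor threshold.
    """
    rows = []
    block_no = 0
    for cohort, sub in pair_table.groupby("cohort_label", sort=False):
        ids = list(zip(sub["gene_a"], sub["gene_b"]))
        chunks = [ids[i : i + block_size] for i in range(0, len(ids), block_size)]
        if len(chunks) > 1 and len(chunks[-1]) < 5:
            chunks[-2].extend(chunks.pop())
        for chunk in chunks:
            block_id = f"block_{block_no:04d}"
            block_no += 1
            for ga, gb in chunk:
                rows.append((block_id, ga, gb))
    return pd.DataFrame(rows, columns=["block_id", "gene_a", "gene_b"])
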