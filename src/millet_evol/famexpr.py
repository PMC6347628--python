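"""Gene-family expression-diversity statistics.

Tissue specificity is summarized per gene by the Shannon entropy (bits)
of its expression proportions across tissues: a uniformly expressed gene
reaches log2(n_tissues), a single-tissue gene scores 0.  Families are
summarized per copy-number class by averaging member-gene entropies and
total expression.  Two inferential helpers round out the module: a
pooled two-proportion z test (for questions like "are transcription
factor families expanded more often than families overall?") and Fisher
exact enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntropyResult:
    gene: str
    H: float
    defined: bool


@dataclass(frozen=True)
class FamilySizeSummary:
    size_class: int
    n_families: int
    n_genes: int
    mean_H: float           # NaN when no member gene has defined entropy
    mean_expression: float


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k_study: int
    n_study: int
    k_pop: int
    n_pop: int
    p_raw: float
    p_adj: float


def tissue_entropy(expression_row: Sequence[float], gene: str = "") -> EntropyResult:
    """Shannon entropy (bits) of one gene's tissue expression proportions.

    Zero-total rows yield ``defined=False`` (entropy of an all-zero
    profile is meaningless, not zero).
    """
    x = np.asarray(expression_row, dtype=float)
    if (x < 0).any():
        raise ValueError(f"negative expression value(s) for gene {gene!r}")
    if not np.isfinite(x).all():
        raise ValueError(f"non-finite expression value(s) for gene {gene!r}")
    total = x.sum()
    if total == 0:
        return EntropyResult(gene=gene, H=math.nan, defined=False)
    h = float(stats.entropy(x, base=2))  # normalizes and skips zero cells
    return EntropyResult(gene=gene, H=h, defined=True)


def entropy_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene entropy and total expression for a genes x tissues matrix."""
    if matrix.shape[1] < 2:
        raise ValueError("expression matrix needs >= 2 tissue columns")
    results = [tissue_entropy(row, gene=str(g)) for g, row in
               zip(matrix.index, matrix.to_numpy())]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "H": [r.H for r in results],
            "defined": [r.defined for r in results],
            "total_expression": matrix.sum(axis=1).to_numpy(),
        }
    )


def family_size_summaries(
    matrix: pd.DataFrame, families: pd.DataFrame
) -> list[FamilySizeSummary]:
    """Mean entropy and mean total expression per family-size class.

    ``families`` needs columns (gene, family_id); size classes are the
    realized family sizes.  Genes missing from the matrix are skipped
    with a logged count; genes with undefined entropy are excluded from
    mean_H (but not from mean_expression) and tallied in the log.
    """
    if families.empty:
        raise ValueError("family assignment table is empty")
    missing = ~families["gene"].isin(matrix.index)
    if missing.any():
        logger.warning(
            "%d gene(s) in the family table missing from the matrix; skipped",
            int(missing.sum()),
        )
    fam = families.loc[~missing].copy()
    if "size_class" in fam.columns:  # recomputed from the realized membership
        fam = fam.drop(columns="size_class")
    sizes = fam.groupby("family_id")["gene"].size().rename("size_class")
    fam = fam.merge(sizes, on="family_id")

    ent = entropy_table(matrix.loc[fam["gene"]])
    fam = fam.reset_index(drop=True)
    fam["H"] = ent["H"].to_numpy()
    fam["defined"] = ent["defined"].to_numpy()
    fam["total_expression"] = ent["total_expression"].to_numpy()

    n_undefined = int((~fam["defined"]).sum())
    if n_undefined:
        logger.info("%d gene(s) with zero total expression excluded from mean_H",
                    n_undefined)

    out = []
    for size, sub in fam.groupby("size_class", sort=True):
        defined = sub.loc[sub["defined"], "H"]
        out.append(
            FamilySizeSummary(
                size_class=int(size),
                n_families=int(sub["family_id"].nunique()),
                n_genes=int(len(sub)),
                mean_H=float(defined.mean()) if len(defined) else math.nan,
                mean_expression=float(sub["total_expression"].mean()),
            )
        )
    return out


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Pooled two-proportion z test; returns (z, two-tailed p).

    With ``continuity`` (default) a Yates-style correction of
    0.5*(1/n1 + 1/n2) is subtracted from the absolute difference before
    standardizing; the uncorrected pooled z is available with
    ``continuity=False``.  The returned z carries the sign of p1 - p2.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("successes must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 1.0
    diff = abs(p1 - p2)
    if continuity:
        diff = max(0.0, diff - 0.5 * (1.0 / n1 + 1.0 / n2))
    z = diff / se
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return math.copysign(z, p1 - p2) if z else 0.0, p


def fisher_bh_enrichment(
    term_sets: Mapping[str, Iterable[str]],
    study_genes: Iterable[str],
    population_genes: Iterable[str],
) -> list[EnrichmentRow]:
    """Per-term Fisher exact enrichment of a study set, BH-adjusted.

    For each term the 2x2 table is (in study & in term, in study & not
    in term) vs (not in study & in term, not in study & not in term),
    with the two-sided exact p (sum of table probabilities no larger
    than the observed table's).  Rows come back sorted by adjusted p,
    then term.
    """
    study = set(study_genes)
    population = set(population_genes)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    n_study = len(study)
    n_pop = len(population)

    terms = sorted(term_sets)
    raw = []
    counts = []
    for term in terms:
        members = set(term_sets[term]) & population
        k_study = len(members & study)
        k_pop = len(members)
        table = [
            [k_study, n_study - k_study],
            [k_pop - k_study, (n_pop - n_study) - (k_pop - k_study)],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        raw.append(min(1.0, float(p)))
        counts.append((k_study, k_pop))
    if not terms:
        return []
    _, p_adj, _, _ = multipletests(raw, method="fdr_bh")
    rows = [
        EnrichmentRow(
            term=term, k_study=k_s, n_study=n_study, k_pop=k_p, n_pop=n_pop,
            p_raw=p_r, p_adj=float(p_a),
        )
        for term, (k_s, k_p), p_r, p_a in zip(terms, counts, raw, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.term))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
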