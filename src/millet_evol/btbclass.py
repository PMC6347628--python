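"""BTB-protein domain-architecture classification and copy-number tables.

BTB (broad complex/tramtrack/bric-a-brac) proteins — substrate adaptors
of CUL3 ubiquitin E3 ligases — fall into subfamilies defined by which
other domains accompany the BTB domain and in what N-to-C order (e.g.
MATH-BTB, MATH-BTB-BACK, BTB-NPH3, BTB-TAZ).  Starting from a domain-hit
table, this module filters hits by E-value, merges overlapping hits of
the same domain, orders the survivors along the protein, names the
subgroup by the ordered domain labels, and tabulates per-species copy
numbers with a fold-change flag for lineage-specific expansions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

DOMAIN_VOCABULARY = frozenset(
    {"BTB", "MATH", "BACK", "NPH3", "TAZ", "TPR", "ANK", "F5_F8", "PENT"}
)
DEFAULT_EVALUE_CUTOFF = 1e-5

_HIT_COLUMNS = ["protein", "species", "domain", "start", "end", "evalue"]


class NoBTBError(ValueError):
    """Raised when classification is asked of an architecture without BTB."""


@dataclass(frozen=True)
class DomainArchitecture:
    protein: str
    species: str
    ordered_domains: tuple[str, ...]
    subgroup: str


def filter_hits(
    hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> pd.DataFrame:
    """E-value filter plus union-merge of overlapping same-domain hits.

    The cutoff is inclusive (evalue <= cutoff is kept).  Proteins left
    without any BTB hit are dropped with a logged count; they cannot be
    classified.  A merged hit spans the union interval and keeps the best
    (smallest) E-value of its parts.
    """
    for col in _HIT_COLUMNS:
        if col not in hits.columns:
            raise ValueError(f"domain-hit table is missing column {col!r}")
    if len(hits) and (
        (hits["start"] < 1).any() or (hits["end"] < hits["start"]).any()
    ):
        raise ValueError("malformed coordinates: need 1 <= start <= end")
    kept = hits[hits["evalue"] <= evalue_cutoff].copy()

    merged_rows = []
    for (protein, species, domain), sub in kept.groupby(
        ["protein", "species", "domain"], sort=False
    ):
        sub = sub.sort_values(["start", "end"])
        cur_start = cur_end = None
        cur_e = None
        for row in sub.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_e = row.start, row.end, row.evalue
            elif row.start <= cur_end:  # overlap (or abutting inside) -> union
                cur_end = max(cur_end, row.end)
                cur_e = min(cur_e, row.evalue)
            else:
                merged_rows.append((protein, species, domain, cur_start, cur_end, cur_e))
                cur_start, cur_end, cur_e = row.start, row.end, row.evalue
        if cur_start is not None:
            merged_rows.append((protein, species, domain, cur_start, cur_end, cur_e))
    merged = pd.DataFrame(merged_rows, columns=_HIT_COLUMNS)

    if len(merged):
        has_btb = merged.groupby("protein")["domain"].transform(
            lambda d: (d == "BTB").any()
        )
        n_dropped = merged.loc[~has_btb, "protein"].nunique()
        if n_dropped:
            logger.info("dropped %d protein(s) with no BTB hit", n_dropped)
        merged = merged[has_btb]
    return merged.reset_index(drop=True)


def classify_architecture(ordered_domains: tuple[str, ...] | list[str]) -> str:
    """Subgroup label from the N-to-C domain order.

    Labels outside the vocabulary count as "other"; consecutive duplicate
    domains collapse (tandem BTB-BTB still reads "BTB"); any architecture
    containing an unrecognized domain is reported as "BTB-other".
    """
    labels = [d if d in DOMAIN_VOCABULARY else "other" for d in ordered_domains]
    if "BTB" not in labels:
        raise NoBTBError(
            f"architecture {tuple(ordered_domains)!r} contains no BTB domain"
        )
    collapsed: list[str] = []
    for label in labels:
        if not collapsed or collapsed[-1] != label:
            collapsed.append(label)
    if "other" in collapsed:
        return "BTB-other"
    return "-".join(collapsed)


def build_architectures(hits: pd.DataFrame) -> list[DomainArchitecture]:
    """Order each protein's filtered hits and classify it.

    Input should already be E-value filtered/merged (see
    :func:`filter_hits`).  Hits are ordered by start, ties broken by end
    then label, making classification a pure function of the table's
    content regardless of row order.
    """
    out = []
    for (protein, species), sub in hits.groupby(["protein", "species"], sort=True):
        ordered = tuple(
            sub.sort_values(["start", "end", "domain"])["domain"].tolist()
        )
        out.append(
            DomainArchitecture(
                protein=str(protein),
                species=str(species),
                ordered_domains=ordered,
                subgroup=classify_architecture(ordered),
            )
        )
    return out


@dataclass
class SubgroupCounts:
    """Subgroup x species copy numbers and per-subgroup expansion flags."""

    counts: pd.DataFrame       # index = subgroup, columns = species
    focal_species: str
    fold: float
    flags: pd.Series           # bool per subgroup

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df[f"expanded_in_{self.focal_species}"] = self.flags
        return df


def copy_number_table(
    architectures: list[DomainArchitecture],
    focal_species: str,
    fold: float = 2.0,
) -> SubgroupCounts:
    """Per-(subgroup, species) protein counts with expansion flags.

    A subgroup is flagged when the focal species' count is at least
    ``fold`` times the maximum count among the other species and at
    least 1.  When every other species has zero copies, any nonzero
    focal count flags.
    """
    if not architectures:
        raise ValueError("no architectures to tabulate")
    df = pd.DataFrame(
        {
            "subgroup": [a.subgroup for a in architectures],
            "species": [a.species for a in architectures],
        }
    )
    species = sorted(df["species"].unique())
    if len(species) < 2:
        raise ValueError("need >= 2 species for a copy-number comparison")
    if focal_species not in species:
        raise ValueError(f"focal species {focal_species!r} absent from input")
    counts = (
        df.groupby(["subgroup", "species"]).size().unstack(fill_value=0)
        .reindex(columns=species, fill_value=0)
        .sort_index()
    )
    others = [s for s in species if s != focal_species]
    focal = counts[focal_species]
    max_other = counts[others].max(axis=1)
    flags = (focal >= 1) & (focal >= fold * max_other)
    return SubgroupCounts(
        counts=counts, focal_species=focal_species, fold=fold, flags=flags
    )
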