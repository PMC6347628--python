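"""Three-criterion SNP marker filter for selfed RIL populations.

For an F_g population derived from a fully heterozygous F1 by repeated
selfing, the expected genotype proportions at a biallelic marker are

    p_het  = (1/2)^(g-1),   p_homA = p_homB = (1 - p_het) / 2

i.e. 31:2:31 (homA : het : homB) at F6.  A marker is retained iff

  (a) its missing-call fraction among progeny is below ``max_missing``,
  (b) a Pearson chi-squared goodness-of-fit of the observed genotype
      counts against the F_g expectation (df = 2, expected counts from
      the non-missing total) gives p above ``min_p``, and
  (c) its QUAL is at least ``min_qual``,

with only biallelic SNP records eligible at all.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class UntestableMarkerError(ValueError):
    """Raised when a segregation test is requested with no called genotypes."""


@dataclass(frozen=True)
class SegregationExpectation:
    """Expected F_g genotype proportions under single-seed-descent selfing."""

    generation: int
    p_homA: float
    p_het: float
    p_homB: float

    @property
    def proportions(self) -> tuple[float, float, float]:
        return (self.p_homA, self.p_het, self.p_homB)


def expected_genotype_proportions(generation: int) -> SegregationExpectation:
    """F_g expectation: heterozygosity halves each selfed generation."""
    if generation < 2:
        raise ValueError("generation must be >= 2 (F_g derived from an F1)")
    p_het = 0.5 ** (generation - 1)
    p_hom = (1.0 - p_het) / 2.0
    return SegregationExpectation(generation, p_hom, p_het, p_hom)


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype tallies for one marker across progeny lines."""

    n_homA: int
    n_het: int
    n_homB: int
    n_missing: int = 0

    @property
    def n_called(self) -> int:
        return self.n_homA + self.n_het + self.n_homB

    @property
    def n_total(self) -> int:
        return self.n_called + self.n_missing

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_total if self.n_total else 1.0


@dataclass(frozen=True)
class SegregationTestResult:
    chi2: float
    p: float
    df: int = 2


def segregation_chi2(
    n_homA: np.ndarray, n_het: np.ndarray, n_homB: np.ndarray,
    expectation: SegregationExpectation,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson chi-squared against the F_g expectation.

    Expected counts use each marker's own non-missing total; df = 2, no
    continuity correction.  Returns (chi2, p) arrays; markers with zero
    called genotypes get NaN.
    """
    obs = np.stack(
        [np.asarray(n_homA, float), np.asarray(n_het, float), np.asarray(n_homB, float)]
    )
    total = obs.sum(axis=0)
    props = np.asarray(expectation.proportions, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = props * total
        chi2 = np.where(total > 0, ((obs - expected) ** 2 / expected).sum(axis=0), np.nan)
    p = stats.chi2.sf(chi2, df=2)
    return chi2, p


def segregation_test(
    counts: GenotypeCounts, expectation: SegregationExpectation
) -> SegregationTestResult:
    """Chi-squared goodness-of-fit for one marker (see segregation_chi2)."""
    if counts.n_called == 0:
        raise UntestableMarkerError("all genotype calls missing for this marker")
    chi2, p = segregation_chi2(
        np.array([counts.n_homA]), np.array([counts.n_het]),
        np.array([counts.n_homB]), expectation,
    )
    return SegregationTestResult(chi2=float(chi2[0]), p=float(p[0]))


@dataclass(frozen=True)
class FilterCriteria:
    """Marker retention thresholds.

    ``max_missing`` and ``min_p`` are strict bounds (a marker passes with
    missing fraction < max_missing and p > min_p); ``min_qual`` is
    inclusive (QUAL >= min_qual passes).
    """

    max_missing: float = 0.20
    min_p: float = 1e-5
    min_qual: float = 999.0
    require_biallelic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")
        if not 0.0 <= self.min_p <= 1.0:
            raise ValueError("min_p must lie in [0, 1]")
        if not np.isfinite(self.min_qual):
            raise ValueError("min_qual must be finite")


@dataclass
class FilterReport:
    """Per-criterion failure tallies for one filtering run.

    A marker is counted against every criterion it fails, so tallies can
    sum to more than the number of failing markers.
    """

    n_records: int = 0
    n_pass: int = 0
    fail_biallelic: int = 0
    fail_missing: int = 0
    fail_segregation: int = 0
    fail_quality: int = 0
    criteria: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for key in (
                "n_records", "n_pass", "fail_biallelic",
                "fail_missing", "fail_segregation", "fail_quality",
            ):
                fh.write(f"{key}\t{getattr(self, key)}\n")


# cyvcf2 gt_types codes
_GT_HOM_REF, _GT_HET, _GT_UNKNOWN, _GT_HOM_ALT = 0, 1, 2, 3


def _is_biallelic_snp(variant) -> bool:
    return (
        len(variant.ALT) == 1
        and len(variant.REF) == 1
        and len(variant.ALT[0]) == 1
        and variant.REF in "ACGT"
        and variant.ALT[0] in "ACGT"
    )


def filter_markers(
    vcf_path: str | Path,
    criteria: FilterCriteria,
    expectation: SegregationExpectation,
    parent_ids: tuple[str, str] | None = None,
    out_vcf: str | Path | None = None,
) -> FilterReport:
    """Apply the three-criterion marker filter to a VCF.

    Parent samples named in ``parent_ids`` are excluded from all progeny
    statistics.  When ``out_vcf`` is given, passing records are written
    out preserving the input records.  Markers whose progeny calls are
    all missing fail the missing-data criterion and are not segregation
    tested.
    """
    from cyvcf2 import VCF, Writer

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    progeny_idx = np.arange(len(samples))
    if parent_ids is not None:
        missing_parents = [p for p in parent_ids if p not in samples]
        if missing_parents:
            raise ValueError(
                f"parent sample(s) {missing_parents} not present in VCF"
            )
        parent_set = set(parent_ids)
        progeny_idx = np.array(
            [i for i, s in enumerate(samples) if s not in parent_set]
        )
    if progeny_idx.size == 0:
        raise ValueError("no progeny samples left after excluding parents")

    writer = Writer(str(out_vcf), vcf) if out_vcf is not None else None
    report = FilterReport(
        criteria={
            "max_missing": criteria.max_missing,
            "min_p": criteria.min_p,
            "min_qual": criteria.min_qual,
            "generation": expectation.generation,
            "parents_excluded": list(parent_ids) if parent_ids else [],
        }
    )

    for variant in vcf:
        report.n_records += 1
        ok = True
        if criteria.require_biallelic and not _is_biallelic_snp(variant):
            report.fail_biallelic += 1
            ok = False

        gt = np.asarray(variant.gt_types)[progeny_idx]
        n_missing = int((gt == _GT_UNKNOWN).sum())
        n_total = gt.size
        if n_missing / n_total >= criteria.max_missing:
            report.fail_missing += 1
            ok = False

        counts = GenotypeCounts(
            n_homA=int((gt == _GT_HOM_REF).sum()),
            n_het=int((gt == _GT_HET).sum()),
            n_homB=int((gt == _GT_HOM_ALT).sum()),
            n_missing=n_missing,
        )
        if counts.n_called > 0:
            result = segregation_test(counts, expectation)
            if not result.p > criteria.min_p:
                report.fail_segregation += 1
                ok = False
        # all-missing markers already fail the missing criterion above

        qual = variant.QUAL
        if qual is None or qual < criteria.min_qual:
            report.fail_quality += 1
            ok = False

        if ok:
            report.n_pass += 1
            if writer is not None:
                writer.write_record(variant)

    if writer is not None:
        writer.close()
    vcf.close()
    logger.info(
        "filtered %d records: %d pass (%d biallelic, %d missing, %d segregation, "
        "%d quality failures)",
        report.n_records, report.n_pass, report.fail_biallelic,
        report.fail_missing, report.fail_segregation, report.fail_quality,
    )
    return report
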