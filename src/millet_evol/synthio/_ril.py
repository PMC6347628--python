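"""Simulator for F_g recombinant-inbred-line genotype matrices.

Each line descends from a fully heterozygous F1 by single-seed-descent
selfing, so at generation g a biallelic marker is heterozygous with
probability (1/2)^(g-1) and homozygous for either parent allele with
equal probability otherwise (31:2:31 at F6).  Markers are independent by
default; an optional per-interval recombination fraction strings
genotypes along marker order as a Markov chain whose stationary marginals
are unchanged.  Missingness and symmetric genotype miscalls are applied
after the true genotypes are drawn, and the truth is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from millet_evol.rilfilter import expected_genotype_proportions

# genotype codes in the matrices
HOM_A, HET, HOM_B, MISSING = 0, 1, 2, -1
_GT_STRINGS = {HOM_A: "0/0", HET: "0/1", HOM_B: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class RILSimConfig:
    """Population size, marker panel and noise model for one simulation."""

    n_lines: int = 132
    n_markers: int = 2000
    generation: int = 6
    missing_rate: float = 0.0
    error_rate: float = 0.0
    distorted_fraction: float = 0.0
    distortion_proportions: tuple[float, float, float] = (0.35, 0.30, 0.35)
    linkage: float | None = None  # recombination fraction between adjacent markers
    qual: float | Sequence[float] = 999.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generation < 2:
            raise ValueError("generation must be >= 2 (an F_g from an F1)")
        if self.n_lines < 1 or self.n_markers < 1:
            raise ValueError("n_lines and n_markers must be >= 1")
        for name in ("missing_rate", "error_rate", "distorted_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        props = self.distortion_proportions
        if len(props) != 3 or any(p < 0 for p in props):
            raise ValueError("distortion_proportions must be 3 non-negative values")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("distortion_proportions must sum to 1 within 1e-12")
        if self.linkage is not None and not 0.0 <= self.linkage <= 0.5:
            raise ValueError("linkage recombination fraction must lie in [0, 0.5]")


@dataclass
class RILPopulation:
    """Simulated genotypes (markers x lines) plus the generating truth."""

    config: RILSimConfig
    genotypes: np.ndarray            # int8, codes HOM_A/HET/HOM_B/MISSING
    true_genotypes: np.ndarray       # before missingness/miscalls
    distorted: np.ndarray            # bool mask per marker
    qual: np.ndarray                 # float per marker
    sample_names: list[str] = field(default_factory=list)

    def write_vcf(self, path: str | Path, include_parents: bool = False) -> None:
        """Emit a minimal VCF v4.2 with GT calls and per-marker QUAL.

        With ``include_parents`` two extra leading samples P1 (0/0
        throughout) and P2 (1/1 throughout) are added, mimicking the
        sequenced parents of a biparental cross.
        """
        n_markers, _ = self.genotypes.shape
        samples = (["P1", "P2"] if include_parents else []) + self.sample_names
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=millet-evol synthio RIL simulator\n")
            fh.write("##contig=<ID=chr1>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples) + "\n"
            )
            for j in range(n_markers):
                calls = []
                if include_parents:
                    calls.extend(["0/0", "1/1"])
                calls.extend(_GT_STRINGS[int(g)] for g in self.genotypes[j])
                qual = self.qual[j]
                qual_str = f"{qual:g}" if np.isfinite(qual) else "."
                fh.write(
                    f"chr1\t{(j + 1) * 100}\tmk{j + 1:06d}\tA\tT\t{qual_str}"
                    f"\t.\t.\tGT\t" + "\t".join(calls) + "\n"
                )


def _draw_categorical(
    rng: np.random.Generator, probs: np.ndarray, size: int
) -> np.ndarray:
    """Vector draw from a 3-state distribution via inverse CDF."""
    cum = np.cumsum(probs)
    u = rng.random(size)
    return np.searchsorted(cum, u, side="right").astype(np.int8)


def simulate_ril_population(cfg: RILSimConfig) -> RILPopulation:
    """Draw an F_g RIL genotype matrix under the configured noise model."""
    rng = np.random.default_rng(cfg.seed)
    exp = expected_genotype_proportions(cfg.generation)
    base_props = np.array([exp.p_homA, exp.p_het, exp.p_homB])
    dist_props = np.asarray(cfg.distortion_proportions, dtype=float)

    n_distorted = int(round(cfg.distorted_fraction * cfg.n_markers))
    distorted = np.zeros(cfg.n_markers, dtype=bool)
    if n_distorted:
        distorted[rng.choice(cfg.n_markers, size=n_distorted, replace=False)] = True

    geno = np.empty((cfg.n_markers, cfg.n_lines), dtype=np.int8)
    if cfg.linkage is None:
        for j in range(cfg.n_markers):
            props = dist_props if distorted[j] else base_props
            geno[j] = _draw_categorical(rng, props, cfg.n_lines)
    else:
        # Markov chain along marker order: with prob (1 - r) a line keeps
        # its state across the interval, else it redraws from the marker's
        # marginal — marginals are preserved exactly.
        r = cfg.linkage
        props0 = dist_props if distorted[0] else base_props
        geno[0] = _draw_categorical(rng, props0, cfg.n_lines)
        for j in range(1, cfg.n_markers):
            props = dist_props if distorted[j] else base_props
            redraw = rng.random(cfg.n_lines) < r
            fresh = _draw_categorical(rng, props, cfg.n_lines)
            geno[j] = np.where(redraw, fresh, geno[j - 1])

    true_geno = geno.copy()

    if cfg.error_rate > 0:
        miscall = rng.random(geno.shape) < cfg.error_rate
        shift = rng.integers(1, 3, size=geno.shape, dtype=np.int8)
        geno = np.where(miscall, (geno + shift) % 3, geno).astype(np.int8)

    if cfg.missing_rate > 0:
        missing = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(missing, np.int8(MISSING), geno)

    qual = np.broadcast_to(
        np.asarray(cfg.qual, dtype=float), (cfg.n_markers,)
    ).copy()
    samples = [f"RIL{i + 1:03d}" for i in range(cfg.n_lines)]
    return RILPopulation(
        config=cfg,
        genotypes=geno,
        true_genotypes=true_geno,
        distorted=distorted,
        qual=qual,
        sample_names=samples,
    )
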