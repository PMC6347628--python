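"""Fixture generator for protein domain-hit tables.

Emits per-protein domain hits whose coordinates realize a requested
left-to-right architecture, with E-values below a configured cutoff, in
the same tabular shape a SMART/Pfam scan summary would take.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from millet_evol.btbclass import DOMAIN_VOCABULARY

_COLUMNS = ["protein", "species", "domain", "start", "end", "evalue"]


def simulate_domain_table(
    architectures: Sequence[tuple],
    seed: int,
    species: str = "synthetic",
    evalue_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """Build a domain-hit table realizing the requested architectures.

    ``architectures`` entries are ``(labels, count)`` or
    ``(labels, count, species)`` where ``labels`` is the left-to-right
    domain order of one protein and ``count`` how many such proteins to
    emit.  Labels must come from :data:`DOMAIN_VOCABULARY`.  All emitted
    E-values are strictly below ``evalue_cutoff``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    protein_no = 0
    for entry in architectures:
        if len(entry) == 2:
            labels, count = entry
            sp = species
        elif len(entry) == 3:
            labels, count, sp = entry
        else:
            raise ValueError(
                "architecture entries must be (labels, count[, species])"
            )
        unknown = set(labels) - DOMAIN_VOCABULARY
        if unknown:
            raise ValueError(f"unknown domain label(s): {sorted(unknown)}")
        if count < 0:
            raise ValueError("architecture count must be >= 0")
        for _ in range(count):
            protein = f"prot{protein_no:05d}"
            protein_no += 1
            pos = 1
            for label in labels:
                gap = int(rng.integers(5, 40))
                length = int(rng.integers(60, 121))
                start = pos + gap
                end = start + length - 1
                pos = end
                exponent = rng.uniform(
                    -30.0, math.log10(evalue_cutoff) - 0.5
                )
                rows.append(
                    (protein, sp, label, start, end, 10.0 ** exponent)
                )
    return pd.DataFrame(rows, columns=_COLUMNS)
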