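# millet-evol

Comparative-genomics statistics for an allotetraploid cereal genome, packaged
as a tested, reusable Python library with a CLI. The analyses are the ones a
genome project runs after assembly and annotation are done:

- **4DTv distance and WGD dating** (`degen4dtv`, `wgd_dating`): score the
  transversion proportion at fourfold-degenerate third codon positions of
  aligned paralog/ortholog coding-sequence pairs, locate the modes of its
  distribution by kernel density estimation, and convert them to ages by
  linear scaling against a calibration anchor (e.g. the grass rho WGD,
  4DTv ≈ 0.38 at ~70 Myr).
- **RIL marker filtering** (`rilfilter`): the three-criterion SNP pre-filter
  for an F6 recombinant-inbred-line population — progeny missing rate < 20%,
  chi-squared fit to the 31:2:31 genotype expectation with p > 1e-5, and
  QUAL ≥ 999.
- **Gene-family expression diversity** (`famexpr`): per-gene tissue-specificity
  Shannon entropy, per-copy-number family summaries, a pooled two-proportion
  z test, and Fisher-exact enrichment with Benjamini–Hochberg correction.
- **BTB domain architectures** (`btbclass`): classify BTB-domain proteins into
  subgroups by the identity and N-to-C order of associated domains
  (MATH, BACK, NPH3, TAZ, TPR, …) and flag subgroups whose copy number in a
  focal species is at least twofold that of every other species.
- **Synthetic data with known ground truth** (`synthio`): generators for all
  of the above — codon pairs diverged under a Kimura two-parameter model, a
  three-cohort "genome" with tandem duplicates, F_g RIL genotype matrices
  with missing data / miscalls / segregation distortion, Dirichlet
  expression profiles with tunable tissue specificity, and domain-hit tables
  — so every stage is testable end-to-end without external data.

## The statistics in brief

For an aligned codon pair, a column is a **fourfold-degenerate site** when
both codons are gap- and N-free, agree at their first two bases, and that
prefix is one of the 8 fourfold families of the standard code
(TC, CT, CC, CG, AC, GT, GC, GG). With `n4` such sites and `ntv` of them
differing by a transversion (purine vs pyrimidine),

    4DTv = ntv / n4 .

Under a two-parameter substitution model with transversion rate β toward
each neighbour and divergence time `t` per lineage, E[4DTv] =
½·(1 − e^(−8βt)), so the raw statistic saturates at ½ — young cohorts sit in
the near-linear regime. A cohort of pairs born by one event (a WGD, a
speciation) leaves a mode in the 4DTv distribution; with a calibration
anchor `(D*, T*)` the age of a mode at `D` is dated as `T = D · T* / D*`.

For the RIL filter, the F_g expectation under single-seed descent is
`p_het = (1/2)^(g−1)` and `p_hom = (1 − p_het)/2` per homozygote class —
31:2:31 at F6 — tested per marker by Pearson chi-squared with df = 2
(for which the upper tail is exactly `e^(−χ²/2)`).

## Worked example

Simulate a two-peak scenario — a young homeolog cohort (t = 5.8 Myr, rates
set so E[4DTv] = 0.032) over a deep background cohort (t = 70 Myr,
E[4DTv] = 0.38) — then score, find modes, and date against the deep anchor:

```python
from millet_evol import degen4dtv, wgd_dating
from millet_evol.synthio import (SubstitutionParams, WGDCohortSpec,
                                 beta_for_target_4dtv, simulate_wgd_genome)

params = {
    "wgd": SubstitutionParams(0.003, beta_for_target_4dtv(0.032, 5.8), 5.8),
    "background": SubstitutionParams(0.003, beta_for_target_4dtv(0.38, 70.0), 70.0),
}
spec = WGDCohortSpec(n_pairs_wgd=500, n_pairs_ortholog=0,
                     n_pairs_background=500, seq_len_codons=500, seed=1)
sim = simulate_wgd_genome(spec, params)
results = [degen4dtv.compute_4dtv(a) for a in sim.alignments()]
table = degen4dtv.results_to_frame(results, sim.pair_table)
report = wgd_dating.run_dating_pipeline(
    table, "cohort_label",
    wgd_dating.Calibration(anchor_4dtv=0.38, anchor_time=70.0))
print(report.round(4).to_string(index=False))
```

prints

```
pair_class   n  mode_4dtv  density  bandwidth  time_mya
background 500      0.371  12.5930     0.0076   68.3421
background 500      0.378  12.5907     0.0076   69.6316
       wgd 500      0.032  36.1062     0.0027    5.8947
```

The young cohort's mode lands at 4DTv 0.032 and dates to ~5.9 Myr
(0.032 × 70 / 0.38); the deep cohort reproduces the anchor (~70 Myr, split
here into two near-equal grid modes by sampling noise). The same pipeline is
available from the shell:

```
millet-evol simulate wgd --n-pairs 500 --seq-len 500 --seed 1 --out-dir sim/
millet-evol fourdtv --pairs sim/pairs.tsv --fasta sim/sequences.fasta \
    --anchors sim/anchors.tsv --positions sim/positions.tsv --out fourdtv.tsv
millet-evol peaks --results fourdtv.tsv --out peaks.tsv
```

Other entry points: `millet-evol simulate {pairs|ril|expression|domains}`,
`rilfilter`, `entropy`, `enrich`, `proptest`, `btb`, `date`.

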