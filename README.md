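# sipflow

Analysis toolkit for DNA stable-isotope probing (DNA-SIP) experiments
with amplicon sequencing of CsCl density-gradient fractions.

In a DNA-SIP experiment, animals or environmental communities are fed a
substrate enriched in a heavy isotope (¹³C cellulose, ¹⁵N urea, …).
Organisms that assimilate the substrate synthesize denser DNA, which
bands deeper in an isopycnic CsCl gradient. The gradient is collected
drop-wise from the bottom of the tube into 12 or 24 fractions, fractions
are grouped into pooled density fractions (upper / medium / lower), and
the pooled fractions of the labeled and control gradients are sequenced.
`sipflow` implements the downstream arithmetic and statistics of this
design, for microbial-ecology researchers who have fraction tables and
OTU count tables in hand:

- **Gradient QC** — percent-of-gradient normalization of per-fraction
  DNA mass and 16S rRNA gene copies, pooled-fraction construction from
  named density windows, and the DNA-weighted density shift between
  labeled and control gradients.
- **Taxon activity** — for each taxon *t* and dense pooled fraction, the
  activity statistic

  *A* = 100 · tNS⁽ˡᵃᵇᵉˡᵉᵈ⁾⁄NS⁽ˡᵃᵇᵉˡᵉᵈ⁾ − 100 · tNS⁽ᶜᵒⁿᵗʳᵒˡ⁾⁄NS⁽ᶜᵒⁿᵗʳᵒˡ⁾

  where tNS is the taxon's sequence count in the pooled fraction and NS
  the fraction's total — the taxon's enrichment, in percentage points of
  relative abundance, in the dense labeled fraction. Significance by
  two-sided Fisher exact test with Benjamini–Hochberg FDR across taxa,
  tiered as ** (p<0.01), * (p<0.05), + (p<0.1); taxonomy collapsing to
  any rank; heatmap matrices and ranked-taxon tables.
- **Predicted metagenome enrichment** — 16S copy-number normalization,
  restriction to labeled families, KO (KEGG Ortholog) profile prediction
  as the abundance × gene-count cross product over user-supplied
  reference tables, and KO enrichment in dense labeled fractions using
  the same share-difference formula as *A*.
- **IRMS calibration and comparison** — δ notation
  (δ = (R_sample/R_standard − 1)·1000 ‰), two-point normalization to
  certified anchors (IAEA-N1 +0.43 ‰, IAEA-N2 +20.40 ‰), technical-
  replicate aggregation, and ¹⁵N-vs-¹⁴N group comparison with mean ± SEM
  and exact Mann–Whitney U.
- **Synthetic experiments** — a generative model of the whole design
  (Gaussian buoyant-density bands positioned by GC content and atom-
  fraction excess, bottom-first fractionation, lognormal qPCR noise,
  multinomial amplicon counts weighted by 16S copy number) with known
  per-taxon ground truth, for validating detection power and false
  discovery control.

## Worked example

Simulate a small experiment — 10 taxa, 2 of which incorporated ¹³C at
atom-fraction excess 0.8 — and test for active taxa in the dense pooled
fractions:

```python
from sipflow import (SimulationConfig, default_community, simulate_dataset,
                     compute_activity, density_shift, evaluate_detection)

taxa = default_community(n_taxa=10, n_labeled=2, atom_excess=0.8, seed=4)
ds = simulate_dataset(SimulationConfig(taxa=taxa, reads_per_pool=20_000, seed=4))

print(round(density_shift(ds.labeled_profile, ds.control_profile), 5))
rec = compute_activity(ds.labeled_counts, ds.control_counts, ds.pooling.dense_names)
print(rec.sort_values("A", ascending=False).head(3)[["taxon", "pool", "A", "q", "tier"]])
print(evaluate_detection(rec, ds.truth))
```

prints

```
0.00512
  taxon   pool      A   q   tier
OTU_009 medium 76.125 0.0 p<0.01
OTU_004  lower 32.770 0.0 p<0.01
OTU_009  lower 24.895 0.0 p<0.01
{'sensitivity': 1.0, 'specificity': 1.0, 'fdp': 0.0, 'n_flagged': 2.0, 'n_labeled': 2.0}
```

The labeled gradient's DNA is on average 0.005 g/ml denser than the
control's; the two truly labeled taxa (OTU_004 and OTU_009) are the only
ones significantly enriched (activity up to +76 percentage points,
q < 0.01) in the dense pooled fractions, and both are recovered with no
false discoveries.

The same analyses are scriptable from the shell via the `sipflow` CLI
(`simulate`, `gradient-qc`, `run`, `ko-enrich`, `irms` subcommands
driven by a YAML config; see `sipflow --help`). A ready-made config
lives at `examples/config_cellulose.yaml`, and `examples/ko_lists/`
holds synthetic placeholder KO panels to be replaced by your own curated
lists for KO-enrichment runs.

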