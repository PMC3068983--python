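# tfret — cross-species transcription-factor binding-site retention

`tfret` quantifies how the binding sites of two cooperating adipogenic
transcription factors, C/EBPα and PPARγ, are **retained**, **lost** or
**turned over** between mouse and human adipocytes, and which biological
features correlate with retention. It is aimed at regulatory genomicists
comparing ChIP-seq peak sets across species: peak BEDs, tag-position BEDs,
UCSC alignment chains, TSS tables with expression-cluster labels, region
FASTA and pairwise alignments go in; per-site fate tables,
cross-tabulations and exact statistics come out. A seeded synthetic-data
generator produces complete two-species fixtures with known ground truth,
so every stage of the pipeline is testable end to end.

## The method

**Coordinate mapping.** Each mouse site is lifted into human coordinates
through alignment chains with `minMatch = 0.1`; a site counts as mapped
only if exactly one chain covers it, and the lifted span, lifted back,
overlaps ≥ 90% of the original site (reciprocal uniqueness).

**Binary retention.** A mapped site is *retained* when a called human peak
overlaps its lifted span by strictly more than 10% of either region's
width:

    retained(m)  ⇔  ∃ h :  |m ∩ h| > 0.1·|m|  or  |m ∩ h| > 0.1·|h|

A non-retained site is *turnover* when a human-specific site of the same
factor lies within 10 kb (midpoint to midpoint) of the lifted span;
otherwise it is *lost*.

**Enrichment retention.** A continuous alternative that is independent of
peak-calling thresholds: in a window centred on the lifted span (width =
75th percentile of human site widths; 520 nt for C/EBPα, 605 nt for PPARγ
on the original data),

    log2FC = log2( (observed tags + 1) / (mean tags over 2000 random windows + 1) )

**Correlates.** Sites are classified as C/EBPα-only / PPARγ-only /
overlapping (≥ 1% of the C/EBPα site's width, ≥ 10% of the PPARγ site's
width, 1 nt in human), labelled with the expression cluster (1–4,
5 = constitutive, 6 = distal) of the closest regulated TSS within 100 kb,
stratified into binding-strength and sequence-identity quartiles, and
scanned for consensus motifs (PWM hit ≥ 80% of the model's score range on
either strand). Group contrasts use Fisher's exact test (two-sided,
probability ordering) and the Wilcoxon rank-sum test (exact for small
samples).

## Worked example

```sh
tfret simulate --seed 42 --out fx        # synthetic two-species fixture
tfret report --fixture fx --out rep --seed 42
```

or equivalently in Python:

```python
from tfret import SimConfig, generate_fixture, run_pipeline, run_report

generate_fixture(SimConfig(seed=42, n_chroms=2, chrom_len=1_000_000,
                           n_sites=300, n_genes=80), "fx")
result = run_pipeline("fx", seed=42)
report = run_report(result, "rep")
print(result.mapping)
```

which prints

```
factor  detected  mapped  mapped_pct
 CEBPA       300     225        75.0
 PPARG       300     225        75.0
```

— 75% of the 300 mouse sites per factor map uniquely and reciprocally
(the rest were planted in unalignable or duplicated chain regions). The
per-factor fate fractions recover the generator's planted conditions
(retained 0.200, turnover 0.102, lost 0.698 for both factors), and the
cluster cross-tabulation shows the planted proximity effect — sites near
moderately/highly upregulated genes (clusters 3 and 4) retain far more
often than the rest:

```
cluster  retained  lost  turnover  frac_retained
1               0    93         0          0.000
2               0    64         7          0.000
3              20     0        12          0.625
4              25     0         4          0.862
fisher p (clusters 3+4 vs rest): 3.87e-34
```

`rep/` then contains the full bundle: `fates.tsv` (per-site fate,
co-binding class, cluster, enrichment log2FC, consensus flags, identity),
retention/co-binding/consensus/quartile cross-tabs with their Fisher
p-values, enrichment violin summaries with Wilcoxon contrasts, TSS-distance
profiles, gained-site histograms, and a machine-readable `report.json`.

## Layout

| module | contents |
| --- | --- |
| `tfret.intervals_io` | interval/site/tag/gene data model, BED/TSV I/O, analysis constants |
| `tfret.cobinding` | width filter, high-confidence intersection, co-binding classes |
| `tfret.orthology` | UCSC chain reader, unique + reciprocal lift-over |
| `tfret.retention` | binary/enrichment retention, turnover, quartile bins |
| `tfret.annotation` | cluster labels, TSS orthologs, profiles, gained sites |
| `tfret.motif_identity` | PWM scanning (JASPAR PFMs), alignment identity |
| `tfret.stats_report` | Fisher/Wilcoxon, cross-tabs, violin summaries, report bundle |
| `tfret.synthetic_data` | seeded fixture generator with ground truth |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
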