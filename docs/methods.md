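# Methods

## Problem and model

Two transcription factors, C/EBPα and PPARγ, drive adipocyte
differentiation in both mouse and human, yet genome-wide ChIP profiling
shows that most individual binding sites are species-specific. `tfret`
formalises the comparison: given called peak sets ("sites", typically
100–400 nt — far wider than the underlying protein–DNA contact) in a
source species and a target species plus whole-genome alignment chains,
it scores each source site's fate in the target genome and correlates
fate with co-binding, proximity to regulated genes, binding strength,
consensus-motif content and local sequence conservation. *Retention* here
means binding detected in both species at orthologous positions — a
property of the regulatory state, distinct from DNA sequence
conservation; *turnover* means a loss compensated by a nearby
species-specific site.

All coordinates are 0-based half-open (BED convention); midpoints floor
on odd widths and midpoint-distance ties resolve toward the smaller
coordinate. Strand is ignored for sites and tags. Each ChIP tag is a
single genomic position (the position given in the tag BED, i.e. the
mapped 5′ end); no fragment extension or strand shifting is applied, and
window counting is half-open with odd windows extending one base to the
right.

## Coordinate mapping

Lifting follows the classic liftOver contract rather than re-implementing
alignment netting: a site maps only if **exactly one** chain covers at
least one of its bases (our operationalisation of "uniquely mapped"), the
covered fraction is ≥ `min_match` = 0.1 (the recommended inter-species
setting, applied to bases, not blocks), and the mapped span runs from the
target image of the first covered base to that of the last — so indels
inside a site stretch or shrink the span. The span is then lifted back
with the reverse chains; the site is kept only when the back lift is
itself uniquely mapped and overlaps ≥ 90% of the original site. Failures
are recorded as statuses (`unaligned`, `ambiguous`, `below_min_match`,
`failed_reciprocal`), never exceptions. Negative-strand chains are
normalised to forward-strand target coordinates at read time. Site loss
through whole-region deletion is out of scope: a site inside a chain gap
is simply `unaligned`.

## Retention, turnover, enrichment

The **binary** criterion is strictly `> 10%` overlap either way (of the
lifted span's width or of the human site's width). Note the deliberate
asymmetry with co-binding, which uses inclusive thresholds ("at least
1%/10%"): each boundary follows the wording that defines it, and the two
rules are used in different places. The per-site fate label is
union-based — a site is *retained* if any human site (either factor)
matches its lifted span, with `retained_as` recording which factors — so
the fate partition is consistent with the co-binding
cross-classification. *Human-specific* sites are human sites that fail
the same 10%-either-way test against every lifted span of the same
factor; turnover requires one within 10 kb midpoint-to-midpoint,
inclusive at exactly 10 kb.

The **enrichment** method scores retention continuously:
`log2((obs + 1)/(exp + 1))`, where `obs` counts tags in a window centred
on the lifted span midpoint whose width is the 75th percentile of human
site widths for the factor (computed from the data at hand; 520/605 nt
for C/EBPα/PPARγ on the original data are kept as config defaults), and
`exp` is the mean count over 2000 random windows of the same width.
Random centres are drawn once per factor/width from a seeded generator,
uniformly over the genome (per-chromosome probability proportional to
length, centres constrained so the window fits); sharing one null sample
across sites keeps per-site values comparable and reproducible. The
pseudocount of 1 guards against small counts. No gap or blacklist
exclusion is applied unless the caller filters the chromosome table.

## Gene association

A site takes the cluster label (1 = downregulated, 2 = transiently,
3 = moderately, 4 = highly upregulated) of the **closest clustered** TSS
within 100 kb of its midpoint — explicitly not the closest TSS overall;
label 5 ("constitutive") when only unclustered genes are nearby, 6
("distal") when no TSS is within 100 kb. An alternative closest-gene rule
is available behind `assign_cluster_nearest_gene` for sensitivity
analysis. Distance boundaries are inclusive (≤ 100 kb, ≤ 50 kb for gained
sites, ≤ 5 kb for TSS orthologs). TSS orthologs lift the ±50 nt flank and
pair with the nearest target-species TSS within 5 kb, inheriting the
source cluster; unliftable flanks and lonely lifted TSSs are tallied
separately, and pairs + both tallies always equal the input gene count.

## Motifs and identity

PWM counts (JASPAR PFM format) become log-odds against a uniform
background with a Laplace pseudocount: `f = (count + 0.25)/(colsum + 1)`,
`score = log2(f/0.25)`. The original scanning tool's internals are
unspecified, so this pseudocount rule is our choice; any monotone variant
preserves the threshold semantics of "80% of the score range" though
exact hit sets may differ near the boundary. Both strands are scanned;
windows containing non-ACGT characters are skipped. The bundled matrices
(`data/*_synthetic.pfm`) are **synthetic** count matrices modelling the
palindromic C/EBP element (ATTGCGCAAT) and the PPAR/RXR DR1 element
(AGGTCAAAGGTCA); supply curated JASPAR PFMs by path for real analyses.

Sequence identity of a pairwise alignment is `#identical columns /
min(len1, len2)` with case-insensitive matching and gap columns never
counting as identities — a short sequence contained in a longer one can
legitimately score 1.

## Statistics

Fisher's exact test sums hypergeometric probabilities of all tables with
the observed margins whose probability is ≤ the observed table's (within
relative tolerance 1e-7, the common probability-ordering two-sided
convention); a zero margin returns p = 1 with a warning. The Wilcoxon
rank-sum test uses midranks for ties, full enumeration when
n₁ + n₂ ≤ 12, and otherwise the normal approximation with tie and 0.5
continuity corrections. Quantiles everywhere (width filter, violin
hinges, window widths) interpolate linearly between order statistics;
quartile bins are rank-based with larger groups first and stable-order
tie-breaking. Raw p-values are reported, as in the underlying analysis; a
Benjamini–Hochberg column accompanies them for transparency but gates
nothing.

## Synthetic fixtures

The generator plants every downstream signal with construction
guarantees, organising each chromosome into per-factor, per-fate zones
separated by 30 kb buffers:

* retained sites get a human site placed exactly on their true mapped
  image (overlap ≫ 10% both ways);
* turnover sites get a same-factor human-specific partner 2–8 kb from the
  mapped midpoint, in 12 kb slots so partners never touch another lifted
  image;
* lost sites have no human site within 20 kb (retained partners nearby do
  not count — they are not human-specific);
* unalignable and duplicated (ambiguity-inducing) chain regions hold
  exactly the planted fraction of sites.

Fate counts use largest-remainder integer allocation, so planted
fractions are recovered exactly, not just in expectation. Co-bound pairs
(C/EBPα partner overlapping a PPARγ site by construction above both
thresholds) share their fate, keeping union-based and per-factor
retention identical on fixtures. Tag tracks are uniform Poisson
background (default 0.008 tags/nt) plus Poisson bursts per site (mean 32
tags; retained mouse sites boosted 1.5× to emulate the observed
strength–retention correlation). With the boost enabled (default),
cluster-3/4 genes are placed beside retained sites and other genes beside
lost sites, reproducing the cluster–retention association; gene flanks in
unalignable regions and turnover zones exercise the ortholog-tally paths.
Human region sequences (500 nt) carry the factor's consensus with
probability 1/0/0 for retained/turnover/lost fates, with rejection
sampling guaranteeing no accidental hits of either model in
consensus-free regions; mouse counterparts are derived by substituting
exactly `round((1 − identity)·L)` positions (targets 0.85/0.75/0.65 by
fate), outside protected motif intervals.

The default scale — 2 chromosomes × 5 Mb, 2000 sites per factor, 400
genes — runs the generator plus the full pipeline in a few seconds while
leaving room for all zones; the smaller scales used in unit tests shrink
the genome and site counts proportionally.

**What the fixtures do not emulate:** realistic genome composition (GC,
repeats, gaps), read-level noise, peak-width/strength correlation,
overlapping sites of the same factor, partial (sub-threshold) retention,
and negative-strand or cross-chromosome chains (supported by the reader,
exercised only in unit tests). Passing tests therefore demonstrate
correctness of the algorithms under the planted statistical structure,
not biological conclusions about real ChIP data.

## Known limitations

* "Uniquely mapped" approximates the original lift-over tool's netting
  behaviour; on real chain files with heavily fragmented chains the two
  can disagree for borderline sites.
* The enrichment null draws windows from the whole chromosome table;
  assembly gaps would need to be pre-filtered from the table (or handled
  by a gap BED upstream).
* The union-based fate label means a site can be "retained" purely via
  the partner factor's human site; per-factor analyses should condition
  on `retained_as` when that distinction matters.
* Published headline values that depend on the full genome-scale data
  (absolute site counts, specific p-values) are outside what desk-scale
  fixtures can reproduce; only the in-paper arithmetic (e.g. the 62.5%
  mapped fraction from 2176/3481) and the method's calibration behaviour
  are checked.
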