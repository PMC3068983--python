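"""Gene association: expression-cluster labels, TSS orthologs and profiles.

Binding sites are tied to putative target genes by distance: a site takes
the expression-cluster label (1-4) of the closest differentially expressed
TSS within 100 kb of the site midpoint; if only non-regulated genes are
nearby it becomes cluster 5 ("constitutive genes"), and with no TSS at all
within 100 kb it is cluster 6 ("distal sites").  Mouse genes are carried
into human by lifting the TSS +/-50 nt and pairing with the nearest human
TSS within 5 kb; the ortholog inherits the mouse cluster label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals_io import (
    AnalysisConfig,
    BindingSite,
    GeneRecord,
    GenomicInterval,
    midpoint,
)
from .orthology import ChainSet, MAPPED

CONSTITUTIVE = 5
DISTAL = 6


class GeneIndex:
    """Per-chromosome sorted TSS arrays for window queries."""

    def __init__(self, genes: Sequence[GeneRecord]):
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneRecord]]] = {}
        grouped: dict[str, list[GeneRecord]] = {}
        for g in genes:
            grouped.setdefault(g.chrom, []).append(g)
        for chrom, glist in grouped.items():
            glist.sort(key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (np.array([g.tss for g in glist]), glist)

    def in_window(self, chrom: str, center: int, radius: int) -> list[GeneRecord]:
        """Genes with |tss - center| <= radius (inclusive)."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        tss, glist = entry
        lo = int(np.searchsorted(tss, center - radius, "left"))
        hi = int(np.searchsorted(tss, center + radius, "right"))
        return glist[lo:hi]


def assign_cluster(
    site: BindingSite, genes: GeneIndex | Sequence[GeneRecord], cfg: AnalysisConfig
) -> int:
    """Cluster label (1-6) for one site; see module docstring for the rule.

    "Closest" is TSS-to-site-midpoint distance; ties go to the smaller TSS
    coordinate.  The closest *clustered* gene wins even when a non-clustered
    gene is nearer.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    mid = midpoint(site.interval)
    nearby = index.in_window(site.interval.chrom, mid, cfg.cluster_window)
    if not nearby:
        return DISTAL
    clustered = [g for g in nearby if g.cluster is not None]
    if not clustered:
        return CONSTITUTIVE
    best = min(clustered, key=lambda g: (abs(g.tss - mid), g.tss))
    return best.cluster


def assign_cluster_nearest_gene(
    site: BindingSite, genes: GeneIndex | Sequence[GeneRecord], cfg: AnalysisConfig
) -> int:
    """Alternative rule: label by the closest gene regardless of cluster membership.

    Nearby non-clustered closest gene then gives cluster 5 even if a
    clustered gene is slightly further away.  Provided for sensitivity
    analysis; the default rule above is the primary one.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    mid = midpoint(site.interval)
    nearby = index.in_window(site.interval.chrom, mid, cfg.cluster_window)
    if not nearby:
        return DISTAL
    best = min(nearby, key=lambda g: (abs(g.tss - mid), g.tss))
    return best.cluster if best.cluster is not None else CONSTITUTIVE


@dataclass
class OrthologPair:
    mouse_gene: GeneRecord
    human_gene: GeneRecord
    distance: int

    @property
    def inherited_cluster(self) -> int | None:
        return self.mouse_gene.cluster


def lift_tss_orthologs(
    mouse_genes: Sequence[GeneRecord],
    fwd: ChainSet,
    human_genes: Sequence[GeneRecord],
    cfg: AnalysisConfig,
) -> tuple[list[OrthologPair], dict[str, int]]:
    """Map mouse genes to human orthologs via lifted TSS positions.

    Lifts ``[tss - 50, tss + 50)`` for each mouse gene; genes whose flank
    cannot be lifted are tallied ``unlifted``, lifted genes with no human
    TSS within 5 kb of the lifted midpoint are tallied ``no_nearby_gene``.
    ``pairs + unlifted + no_nearby_gene`` equals the number of input genes.
    """
    human_index = GeneIndex(human_genes)
    pairs: list[OrthologPair] = []
    tally = {"unlifted": 0, "no_nearby_gene": 0}
    for g in mouse_genes:
        start = max(0, g.tss - cfg.tss_lift_flank)
        flank = GenomicInterval(g.chrom, start, g.tss + cfg.tss_lift_flank)
        lift = fwd.lift(flank, cfg.min_match)
        if lift.status != MAPPED:
            tally["unlifted"] += 1
            continue
        center = midpoint(lift.span)
        nearby = human_index.in_window(lift.span.chrom, center, cfg.tss_ortholog_max_dist)
        if not nearby:
            tally["no_nearby_gene"] += 1
            continue
        best = min(nearby, key=lambda h: (abs(h.tss - center), h.tss))
        pairs.append(OrthologPair(g, best, abs(best.tss - center)))
    return pairs, tally


def tss_site_profile(
    genes_in_cluster: Sequence[GeneRecord],
    sites: Sequence[BindingSite],
    cfg: AnalysisConfig,
) -> np.ndarray:
    """Mean site count in 10-kb bins across +/-100 kb around each TSS.

    Returns the 20-bin mean profile across genes, oriented by gene strand
    (bin 0 is the furthest upstream).
    """
    if not genes_in_cluster:
        raise ValueError("empty gene list")
    radius = cfg.cluster_window
    n_bins = (2 * radius) // cfg.tss_profile_bin
    mids_by_chrom: dict[str, np.ndarray] = {}
    grouped: dict[str, list[int]] = {}
    for s in sites:
        grouped.setdefault(s.interval.chrom, []).append(midpoint(s.interval))
    for chrom, mids in grouped.items():
        mids_by_chrom[chrom] = np.sort(np.array(mids))
    total = np.zeros(n_bins, dtype=float)
    for g in genes_in_cluster:
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            continue
        lo = int(np.searchsorted(mids, g.tss - radius, "left"))
        hi = int(np.searchsorted(mids, g.tss + radius, "left"))
        for mid in mids[lo:hi]:
            rel = mid - g.tss if g.strand == "+" else g.tss - mid
            b = (rel + radius) // cfg.tss_profile_bin
            if 0 <= b < n_bins:
                total[b] += 1
    return total / len(genes_in_cluster)


def gained_sites_per_gene(
    genes: Sequence[GeneRecord],
    human_specific: Sequence[BindingSite],
    cfg: AnalysisConfig,
) -> tuple[dict[str, int], dict[object, np.ndarray]]:
    """Per-gene counts of human-specific sites within 50 kb of the TSS.

    Returns the per-gene counts and, per cluster, a histogram of counts
    normalised to sum 1 (empty clusters are omitted).
    """
    mids_by_chrom: dict[str, np.ndarray] = {}
    grouped: dict[str, list[int]] = {}
    for s in human_specific:
        grouped.setdefault(s.interval.chrom, []).append(midpoint(s.interval))
    for chrom, mids in grouped.items():
        mids_by_chrom[chrom] = np.sort(np.array(mids))
    counts: dict[str, int] = {}
    by_cluster: dict[object, list[int]] = {}
    for g in genes:
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            c = 0
        else:
            lo = int(np.searchsorted(mids, g.tss - cfg.gain_window, "left"))
            hi = int(np.searchsorted(mids, g.tss + cfg.gain_window, "right"))
            c = hi - lo
        counts[g.gene_id] = c
        key = g.cluster if g.cluster is not None else "none"
        by_cluster.setdefault(key, []).append(c)
    histograms: dict[object, np.ndarray] = {}
    for key, vals in by_cluster.items():
        hist = np.bincount(np.array(vals, dtype=np.int64))
        histograms[key] = hist / hist.sum()
    return counts, histograms
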