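"""Core genomic-interval data model and flat-file I/O.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` nucleotides, and two intervals that
merely touch do not overlap.  Strand is ignored for binding sites and ChIP
tags; each tag is represented by the single genomic position given in its
input file (its 5' position), with no fragment extension or shifting.

Formats handled here:

* BED (3-5 columns) for binding sites -- optional name in column 4 and an
  integer tag count in column 5;
* BED positions for ChIP tags (one line per mapped tag);
* a headered TSV for gene/TSS tables (``gene_id chrom tss strand cluster``);
* a two-column TSV of chromosome sizes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

CEBPA = "CEBPA"
PPARG = "PPARG"
FACTORS = (CEBPA, PPARG)
SPECIES = ("mouse", "human")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 if on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def midpoint(a: GenomicInterval) -> int:
    """Midpoint position, floored for odd widths."""
    return (a.start + a.end) // 2


@dataclass
class BindingSite:
    """A called ChIP peak ("site"): a span plus factor, species and tag count.

    The regions produced by peak finders are typically 100-400 nt wide, i.e.
    much wider than the underlying protein-DNA contact; ``tag_count`` holds
    the number of ChIP tags in the region and serves as the binding-strength
    proxy.
    """

    site_id: str
    interval: GenomicInterval
    factor: str
    species: str
    tag_count: int = 0

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.tag_count < 0:
            raise ValueError("tag_count must be >= 0")

    @property
    def width(self) -> int:
        return self.interval.width


class SiteIndex:
    """Interval-tree index over binding sites for overlap queries."""

    def __init__(self, sites: Iterable[BindingSite]):
        self.sites = list(sites)
        self._trees: dict[str, IntervalTree] = {}
        for s in self.sites:
            tree = self._trees.setdefault(s.interval.chrom, IntervalTree())
            tree.addi(s.interval.start, s.interval.end, s)

    def overlapping(self, iv: GenomicInterval) -> list[BindingSite]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        hits.sort(key=lambda s: (s.interval.start, s.interval.end, s.site_id))
        return hits

    def __len__(self) -> int:
        return len(self.sites)


class TagTrack:
    """Per-chromosome sorted arrays of ChIP tag positions."""

    def __init__(self, positions: dict[str, np.ndarray] | None = None):
        self.positions: dict[str, np.ndarray] = {}
        for chrom, pos in (positions or {}).items():
            arr = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = np.sort(arr)

    def count(self, chrom: str, start: int, end: int) -> int:
        """Tags with ``start <= position < end``; 0 for absent chromosomes."""
        arr = self.positions.get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end, "left") - np.searchsorted(arr, start, "left"))

    def total(self) -> int:
        return sum(len(a) for a in self.positions.values())


@dataclass
class GeneRecord:
    """A gene reduced to its TSS, strand and expression-cluster label.

    ``cluster`` is 1-4 for differentially expressed genes (1 downregulated,
    2 transiently upregulated, 3 moderately upregulated, 4 highly
    upregulated during adipogenesis) and ``None`` for constitutive genes.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    cluster: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.cluster is not None and self.cluster not in (1, 2, 3, 4):
            raise ValueError(f"cluster must be 1-4 or None, got {self.cluster!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every constant of the comparative analysis, with its default value.

    Fractions are of the site's own width unless noted; distances in nt.
    """

    width_filter_frac: float = 0.05        # widest-site fraction removed pre-analysis
    cobind_frac_cebpa: float = 0.01        # C/EBPa overlap threshold (mouse)
    cobind_frac_pparg: float = 0.10        # PPARg overlap threshold (mouse)
    human_cobind_min_nt: int = 1           # relaxed 1-nt criterion in human
    min_match: float = 0.1                 # liftover minMatch
    back_overlap_frac: float = 0.90        # reciprocal-lift agreement
    retention_frac: float = 0.10           # strict >10% either-way overlap
    turnover_max_dist: int = 10_000        # midpoint-to-midpoint, inclusive
    cluster_window: int = 100_000          # TSS search window for cluster labels
    tss_lift_flank: int = 50               # TSS +/-50 nt lifted for orthologs
    tss_ortholog_max_dist: int = 5_000
    gain_window: int = 50_000              # human-specific sites near a TSS
    n_random_regions: int = 2_000          # random-window null sample size
    pseudocount: int = 1                   # added to observed and expected tags
    enrich_window_cebpa: int = 520         # 75th-pct human site width, C/EBPa
    enrich_window_pparg: int = 605         # 75th-pct human site width, PPARg
    pwm_threshold_frac: float = 0.80       # fraction of PWM score range
    tss_profile_bin: int = 10_000

    def __post_init__(self) -> None:
        for name in ("width_filter_frac", "cobind_frac_cebpa", "cobind_frac_pparg",
                     "min_match", "back_overlap_frac", "retention_frac",
                     "pwm_threshold_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("turnover_max_dist", "cluster_window", "tss_ortholog_max_dist",
                     "gain_window", "tss_profile_bin", "enrich_window_cebpa",
                     "enrich_window_pparg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path: Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_sites(path: str | Path, factor: str, species: str) -> list[BindingSite]:
    """Read binding sites from a 3-5 column BED file.

    Column 4 (name) and column 5 (tag count) are optional; a missing tag
    count is stored as 0.  Track/comment lines are skipped.  Malformed
    coordinates raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    sites: list[BindingSite] = []
    seen: set[str] = set()
    for lineno, parts in _data_lines(path):
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start < 0 or start >= end:
            raise ParseError(
                f"{path}:{lineno}: malformed coordinates [{start},{end})"
            )
        name = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") else f"site{lineno}"
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate site_id {name!r}")
        seen.add(name)
        tag_count = 0
        if len(parts) >= 5 and parts[4] not in ("", "."):
            try:
                tag_count = int(float(parts[4]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad tag count {parts[4]!r}") from exc
        sites.append(
            BindingSite(name, GenomicInterval(chrom, start, end), factor, species, tag_count)
        )
    return sites


def write_sites(path: str | Path, sites: Sequence[BindingSite]) -> None:
    with open(path, "w") as fh:
        for s in sites:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.site_id}\t{s.tag_count}\n")


def read_tags(path: str | Path) -> TagTrack:
    """Read a tag-position BED (``chrom start end``); the start is the tag position."""
    path = Path(path)
    by_chrom: dict[str, list[int]] = {}
    for lineno, parts in _data_lines(path):
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected >=2 columns")
        try:
            pos = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer position") from exc
        if pos < 0:
            raise ParseError(f"{path}:{lineno}: negative position")
        by_chrom.setdefault(parts[0], []).append(pos)
    return TagTrack({c: np.asarray(p) for c, p in by_chrom.items()})


def write_tags(path: str | Path, track: TagTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for pos in track.positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


_GENE_HEADER = ["gene_id", "chrom", "tss", "strand", "cluster"]


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read a gene table TSV with header ``gene_id chrom tss strand cluster``."""
    path = Path(path)
    genes: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_GENE_HEADER)] != _GENE_HEADER:
            raise ParseError(f"{path}:1: expected header {' '.join(_GENE_HEADER)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            cluster = None if parts[4] in ("none", "", ".") else int(parts[4])
            genes.append(GeneRecord(parts[0], parts[1], int(parts[2]), parts[3], cluster))
    return genes


def write_genes(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in genes:
            cluster = "none" if g.cluster is None else str(g.cluster)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{cluster}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, parts in _data_lines(Path(path)):
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
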