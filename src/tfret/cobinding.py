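"""Site-set preprocessing and C/EBPa--PPARg co-binding classification.

In mouse adipocytes the two factors' peak sets overlap extensively, and the
overlap is close to binary: a site is either mostly overlapped by a partner
site of the other factor, or not overlapped at all.  Classification here is
per site and per factor: a site is "overlapping" when the best partner site
covers at least that factor's threshold fraction of the site's own width
(1% for C/EBPa, 10% for the generally narrower PPARg sites).  For human
regions that correspond to mapped mouse sites the criterion relaxes to a
single shared nucleotide, since co-location in the same orthologous region
is already implied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals_io import (
    AnalysisConfig,
    BindingSite,
    SiteIndex,
    overlap_length,
)

CEBPA_ONLY = "CEBPA_only"
PPARG_ONLY = "PPARG_only"
OVERLAPPING = "overlapping"


@dataclass
class CobindClass:
    """Per-site co-binding call plus the best partner-overlap fraction."""

    label: str
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction outside [0,1]")


def filter_widest(sites: Sequence[BindingSite], frac: float) -> list[BindingSite]:
    """Drop the ``frac`` widest sites (anomalously wide peaks are unreliable).

    The width cutoff is the ``1 - frac`` quantile of site widths (linear
    interpolation between order statistics); sites strictly wider are
    removed, survivors keep their input order.
    """
    if not (0 <= frac < 1):
        raise ValueError("frac must be in [0,1)")
    sites = list(sites)
    if not sites:
        return []
    widths = np.array([s.width for s in sites], dtype=float)
    cutoff = float(np.quantile(widths, 1.0 - frac))
    return [s for s in sites if s.width <= cutoff]


def high_confidence_intersect(
    seq_sites: Sequence[BindingSite], ref_sites: Sequence[BindingSite]
) -> list[BindingSite]:
    """Keep ChIP-seq sites corroborated by >=1 nt overlap with a reference set.

    Used to intersect single-replicate ChIP-seq peaks with independent
    ChIP-chip regions; coordinates of the kept sites are unchanged.
    """
    index = SiteIndex(ref_sites)
    return [s for s in seq_sites if index.overlapping(s.interval)]


def _best_overlap(site: BindingSite, partners: SiteIndex) -> int:
    best = 0
    for p in partners.overlapping(site.interval):
        best = max(best, overlap_length(site.interval, p.interval))
    return best


def _classify_one_set(
    sites: Sequence[BindingSite],
    partners: SiteIndex,
    only_label: str,
    frac_threshold: float,
    min_nt: int | None,
) -> list[CobindClass]:
    out: list[CobindClass] = []
    for s in sites:
        best = _best_overlap(s, partners)
        frac = best / s.width
        if min_nt is not None:
            is_overlap = best >= min_nt
        else:
            is_overlap = frac >= frac_threshold
        out.append(CobindClass(OVERLAPPING if is_overlap else only_label, min(frac, 1.0)))
    return out


def classify_cobinding(
    cebpa: Sequence[BindingSite],
    pparg: Sequence[BindingSite],
    cfg: AnalysisConfig,
    mode: str = "mouse",
) -> tuple[list[CobindClass], list[CobindClass], dict[str, int]]:
    """Label every site of both factors and tally the Venn classes.

    ``mode='mouse'`` applies the per-factor width-fraction thresholds
    (inclusive, "at least"); ``mode='human'`` applies the 1-nt criterion to
    both factors.  Returns ``(cebpa_labels, pparg_labels, counts)`` with the
    labels parallel to the inputs.
    """
    if mode not in ("mouse", "human"):
        raise ValueError(f"mode must be mouse or human, got {mode!r}")
    cebpa_index = SiteIndex(cebpa)
    pparg_index = SiteIndex(pparg)
    if mode == "mouse":
        c_labels = _classify_one_set(cebpa, pparg_index, CEBPA_ONLY,
                                     cfg.cobind_frac_cebpa, None)
        p_labels = _classify_one_set(pparg, cebpa_index, PPARG_ONLY,
                                     cfg.cobind_frac_pparg, None)
    else:
        c_labels = _classify_one_set(cebpa, pparg_index, CEBPA_ONLY,
                                     0.0, cfg.human_cobind_min_nt)
        p_labels = _classify_one_set(pparg, cebpa_index, PPARG_ONLY,
                                     0.0, cfg.human_cobind_min_nt)
    counts = {
        CEBPA_ONLY: sum(1 for c in c_labels if c.label == CEBPA_ONLY),
        PPARG_ONLY: sum(1 for p in p_labels if p.label == PPARG_ONLY),
        "CEBPA_overlapping": sum(1 for c in c_labels if c.label == OVERLAPPING),
        "PPARG_overlapping": sum(1 for p in p_labels if p.label == OVERLAPPING),
    }
    return c_labels, p_labels, counts
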