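"""Seeded generator of a complete two-species fixture with known ground truth.

The generator emulates the statistical structure of a mouse/human adipocyte
ChIP-seq comparison: two coordinate spaces linked by alignment chains (with
unalignable stretches, insertions between blocks, and duplicated blocks
that make lifting ambiguous), two factors' site sets with planted fates and
co-binding structure, Poisson tag tracks with per-site enrichment, TSS
tables with expression clusters, and per-region sequences with planted
consensus motifs at controlled mouse-human identity.

Construction guarantees (each fate is placed in its own genomic zone, zones
separated by wide buffers):

* a planted-retained mouse site has a human site covering its true mapped
  image (overlap far above the 10% either-way criterion);
* a planted-turnover site has no overlapping human site but a same-factor
  human-specific site 2-8 kb from its mapped midpoint;
* a planted-lost site has no human site within 20 kb;
* sites planted in unalignable segments fail mapping as ``unaligned`` and
  sites under duplicated blocks fail as ``ambiguous`` -- exactly.

Everything is derived from the single config seed; the same seed produces a
byte-identical fixture bundle.  Fixtures are written in the real formats
(BED / UCSC chain / TSV / FASTA / MAF) and re-read by the pipeline, so
format I/O is exercised rather than bypassed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .intervals_io import (
    CEBPA,
    PPARG,
    AnalysisConfig,
    BindingSite,
    GeneRecord,
    GenomicInterval,
    TagTrack,
    write_chrom_sizes,
    write_genes,
    write_sites,
    write_tags,
)
from .motif_identity import (
    AlignedPair,
    PWMModel,
    read_jaspar_pfms,
    write_pairwise_maf,
)
from .orthology import ChainBlock, OrthologyChain, write_chain_file

RETAINED = "retained"
TURNOVER = "turnover"
LOST = "lost"
UNALIGNED = "unaligned"
AMBIGUOUS = "ambiguous"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class InfeasibleConfig(ValueError):
    """Sites/genes cannot be placed without violating the spacing guarantees."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic fixture.

    Defaults are the generator's standing conditions: a 2 x 5 Mb genome,
    2000 sites per factor with widths uniform on 150-450 nt (the typical
    called-peak range), a 36% co-binding fraction for PPARg, 20% of sites in
    unalignable regions, and per-window tag levels giving strong planted
    enrichment over a sparse Poisson background.
    """

    seed: int
    n_chroms: int = 2
    chrom_len: int = 5_000_000
    n_sites: int = 2_000                   # per factor, mouse
    frac_unalignable: float = 0.20
    frac_ambiguous: float = 0.05
    fate_fractions: tuple[float, float, float] = (0.20, 0.10, 0.70)  # retained, turnover, lost
    cobind_frac: float = 0.36              # fraction of mapped PPARg sites with a C/EBPa partner
    site_width_range: tuple[int, int] = (150, 450)
    slot_width: int = 1_000
    turnover_slot_width: int = 12_000
    zone_buffer: int = 30_000
    indel_max: int = 500                   # insertion between alignment blocks
    n_genes: int = 400
    cluster_proportions: tuple[float, float, float, float, float] = (
        0.15, 0.15, 0.20, 0.20, 0.30)      # clusters 1..4 then non-regulated
    frac_gene_unlifted: float = 0.10
    frac_gene_no_ortholog: float = 0.05
    cluster_retention_boost: bool = True   # place cluster-3/4 genes near retained sites
    tag_rate_bg: float = 0.008             # background tags per nt
    site_strength_mean: float = 32.0       # Poisson mean tags per site
    strength_retained_boost: float = 1.5   # retained mouse sites bind more strongly
    motif_plant_prob: tuple[float, float, float] = (1.0, 0.0, 0.0)  # by fate (ret, turn, lost)
    identity_by_fate: tuple[float, float, float] = (0.85, 0.75, 0.65)
    seq_len: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.fate_fractions) - 1.0) > 1e-9:
            raise ValueError("fate fractions must sum to 1")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


def _allocate(total: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder split of ``total`` into integer counts."""
    raw = [total * f for f in fractions]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


@dataclass
class _Slot:
    factor: str
    kind: str           # retained / turnover / lost / unaligned / ambiguous
    cobound: bool
    chrom: str
    pos: int
    width: int          # slot territory width


def _lay_out_slots(cfg: SimConfig) -> tuple[list[_Slot], dict[str, list[tuple[int, int]]],
                                            dict[str, list[tuple[int, int]]]]:
    """Place every site slot; return slots plus unalignable and duplicated runs."""
    n_unal = round(cfg.frac_unalignable * cfg.n_sites)
    n_amb = round(cfg.frac_ambiguous * cfg.n_sites)
    n_mapped = cfg.n_sites - n_unal - n_amb
    if n_mapped < 0:
        raise InfeasibleConfig("unalignable + ambiguous fractions exceed 1")
    n_ret, n_turn, n_lost = _allocate(n_mapped, cfg.fate_fractions)

    n_pairs = round(cfg.cobind_frac * n_mapped)
    denom = n_ret + n_lost
    if denom == 0 and n_pairs > 0:
        raise InfeasibleConfig("co-bound pairs need retained or lost slots")
    pairs_ret = min(n_ret, round(n_pairs * n_ret / denom)) if denom else 0
    pairs_lost = n_pairs - pairs_ret
    if pairs_lost > n_lost or pairs_ret > n_ret:
        raise InfeasibleConfig("co-binding fraction too high for the fate split")

    # zone plan: (factor, kind, n_slots, slot_width, cobound_first_k)
    zones = [
        (PPARG, RETAINED, n_ret, cfg.slot_width, pairs_ret),
        (PPARG, LOST, n_lost, cfg.slot_width, pairs_lost),
        (PPARG, TURNOVER, n_turn, cfg.turnover_slot_width, 0),
        (PPARG, UNALIGNED, n_unal, cfg.slot_width, 0),
        (PPARG, AMBIGUOUS, n_amb, cfg.slot_width, 0),
        (CEBPA, RETAINED, n_ret - pairs_ret, cfg.slot_width, 0),
        (CEBPA, LOST, n_lost - pairs_lost, cfg.slot_width, 0),
        (CEBPA, TURNOVER, n_turn, cfg.turnover_slot_width, 0),
        (CEBPA, UNALIGNED, n_unal, cfg.slot_width, 0),
        (CEBPA, AMBIGUOUS, n_amb, cfg.slot_width, 0),
    ]

    margin = cfg.zone_buffer
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    ci, cursor = 0, margin
    slots: list[_Slot] = []
    unal_runs: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    amb_runs: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _advance(width: int) -> tuple[str, int]:
        nonlocal ci, cursor
        if cursor + width + margin > cfg.chrom_len:
            ci += 1
            if ci >= len(chroms):
                raise InfeasibleConfig(
                    "sites cannot be placed: genome too small for the slot plan"
                )
            cursor = margin
        pos = cursor
        cursor += width
        return chroms[ci], pos

    for factor, kind, n, width, cobound_k in zones:
        for i in range(n):
            chrom, pos = _advance(width)
            slots.append(_Slot(factor, kind, i < cobound_k, chrom, pos, width))
            if kind == UNALIGNED:
                unal_runs[chrom].append((pos, pos + width))
            elif kind == AMBIGUOUS:
                amb_runs[chrom].append((pos, pos + width))
        cursor += cfg.zone_buffer

    def _merge(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        merged: list[tuple[int, int]] = []
        for s, e in sorted(runs):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    return slots, {c: _merge(r) for c, r in unal_runs.items()}, \
        {c: _merge(r) for c, r in amb_runs.items()}


@dataclass
class _ChainLayout:
    fwd_chains: list[OrthologyChain]
    rev_chains: list[OrthologyChain]
    mouse_sizes: dict[str, int]
    human_sizes: dict[str, int]
    # per chrom: sorted arrays (src_start, src_end, tgt_start) for fast mapping
    blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def map_pos(self, chrom: str, pos: int) -> int:
        starts, ends, tgts = self.blocks[chrom]
        i = int(np.searchsorted(starts, pos, "right")) - 1
        if i < 0 or pos >= ends[i]:
            raise ValueError(f"position {chrom}:{pos} is unalignable")
        return int(tgts[i] + (pos - starts[i]))


def _build_chains(
    cfg: SimConfig,
    unal_runs: dict[str, list[tuple[int, int]]],
    amb_runs: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> _ChainLayout:
    fwd: list[OrthologyChain] = []
    mouse_sizes: dict[str, int] = {}
    human_sizes: dict[str, int] = {}
    block_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        mouse_sizes[chrom] = cfg.chrom_len
        gaps = unal_runs.get(chrom, [])
        # alignable segments = complement of the unalignable runs
        segments: list[tuple[int, int]] = []
        cursor = 0
        for s, e in gaps:
            if s > cursor:
                segments.append((cursor, s))
            cursor = e
        if cursor < cfg.chrom_len:
            segments.append((cursor, cfg.chrom_len))
        offset = 0
        blocks: list[ChainBlock] = []
        for s, e in segments:
            offset += int(rng.integers(0, cfg.indel_max + 1))
            blocks.append(
                ChainBlock(
                    GenomicInterval(chrom, s, e),
                    GenomicInterval(chrom, s + offset, e + offset),
                )
            )
        fwd.append(OrthologyChain(f"{chrom}.main", blocks))
        main_end = cfg.chrom_len + offset
        # duplicated blocks map a second time into a spare region beyond the
        # main image, making any lift from under them ambiguous
        spare = main_end + 50_000
        for j, (s, e) in enumerate(amb_runs.get(chrom, [])):
            fwd.append(
                OrthologyChain(
                    f"{chrom}.dup{j}",
                    [ChainBlock(GenomicInterval(chrom, s, e),
                                GenomicInterval(chrom, spare, spare + (e - s)))],
                )
            )
            spare += (e - s) + 10_000
        human_sizes[chrom] = spare + 50_000
        block_arrays[chrom] = (
            np.array([b.src.start for b in blocks]),
            np.array([b.src.end for b in blocks]),
            np.array([b.tgt.start for b in blocks]),
        )
    rev = [
        OrthologyChain(
            f"{c.chain_id}.rev",
            [ChainBlock(b.tgt, b.src) for b in c.blocks],
        )
        for c in fwd
    ]
    return _ChainLayout(fwd, rev, mouse_sizes, human_sizes, block_arrays)


def simulate_tags(
    site_spans: Sequence[tuple[str, int, int, float]],
    rate_bg: float,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator | int,
) -> tuple[TagTrack, list[int]]:
    """Poisson ChIP tag track: uniform background plus per-site bursts.

    Background tag count per chromosome is Poisson(rate * length) with
    uniform positions; each site adds Poisson(strength) tags uniform over
    its span.  Returns the track and the realised per-site tag counts.
    """
    if rate_bg < 0:
        raise ValueError("rate_bg must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    positions: dict[str, list[np.ndarray]] = {}
    for chrom in sorted(chrom_sizes):
        n = int(rng.poisson(rate_bg * chrom_sizes[chrom]))
        if n:
            positions.setdefault(chrom, []).append(
                rng.integers(0, chrom_sizes[chrom], size=n)
            )
    site_counts: list[int] = []
    for chrom, start, end, strength in site_spans:
        k = int(rng.poisson(strength))
        site_counts.append(k)
        if k:
            positions.setdefault(chrom, []).append(rng.integers(start, end, size=k))
    track = TagTrack(
        {c: np.concatenate(parts) for c, parts in positions.items() if parts}
    )
    return track, site_counts


def mutate_to_identity(
    seq: str,
    target: float,
    protect: Sequence[tuple[int, int]] = (),
    rng: np.random.Generator | int = 0,
) -> str:
    """Substitute bases outside protected intervals to reach a target identity.

    Exactly ``round((1 - target) * len(seq))`` distinct positions are
    replaced with a different base, so the realised identity against the
    input is ``(L - k) / L``.  Protected intervals (e.g. planted motifs)
    are never touched.
    """
    if not (0 < target <= 1):
        raise ValueError("target identity must be in (0,1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    L = len(seq)
    protected = np.zeros(L, dtype=bool)
    for s, e in protect:
        if not (0 <= s < e <= L):
            raise ValueError("protected interval outside sequence")
        protected[s:e] = True
    k = round((1 - target) * L)
    candidates = np.flatnonzero(~protected)
    if k > len(candidates):
        raise ValueError("target identity unreachable given protected intervals")
    if k == 0:
        return seq
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    idx = rng.choice(candidates, size=k, replace=False)
    # map to a different base: shift by 1-3 within ACGT
    base_index = np.empty(256, dtype=np.int64)
    for i, b in enumerate(_BASES):
        base_index[b] = i
    old = base_index[arr[idx]]
    new = (old + rng.integers(1, 4, size=k)) % 4
    arr[idx] = _BASES[new]
    return arr.tobytes().decode("ascii")


def _batch_scan(regions: np.ndarray, model: PWMModel) -> np.ndarray:
    """Hit flag per region (rows of base codes 0..3), both strands."""
    R, S = regions.shape
    L = model.length
    W = S - L + 1
    best = np.full(R, -np.inf)
    for lo in (model.logodds, model.logodds[::-1, ::-1]):
        scores = np.zeros((R, W))
        for j in range(L):
            scores += lo[:, j][regions[:, j:j + W]]
        best = np.maximum(best, scores.max(axis=1))
    return best >= model.threshold


def _default_pwms(cfg_analysis: AnalysisConfig) -> dict[str, PWMModel]:
    """Bundled synthetic PWMs: stand-ins for curated JASPAR models.

    ``cebp_synthetic.pfm`` models the palindromic C/EBP element
    (ATTGCGCAAT) and ``ppar_synthetic.pfm`` the PPAR/RXR DR1 element
    (AGGTCAAAGGTCA); both are synthetic count matrices, not database
    entries.  Supply real JASPAR PFM files via ``pwm_paths`` in the
    pipeline to scan with curated models instead.
    """
    from importlib.resources import files

    data = files("tfret") / "data"
    models: dict[str, PWMModel] = {}
    for factor, fname in ((CEBPA, "cebp_synthetic.pfm"), (PPARG, "ppar_synthetic.pfm")):
        found = read_jaspar_pfms(str(data / fname), cfg_analysis)
        models[factor] = next(iter(found.values()))
    return models


def generate_fixture(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write a complete fixture bundle and return its ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    analysis_cfg = AnalysisConfig()
    pwms = _default_pwms(analysis_cfg)
    w_lo, w_hi = cfg.site_width_range
    fate_index = {RETAINED: 0, TURNOVER: 1, LOST: 2}

    slots, unal_runs, amb_runs = _lay_out_slots(cfg)
    layout = _build_chains(cfg, unal_runs, amb_runs, rng)

    mouse_sites: dict[str, list[BindingSite]] = {CEBPA: [], PPARG: []}
    human_sites: dict[str, list[BindingSite]] = {CEBPA: [], PPARG: []}
    truth_sites: dict[str, dict] = {}
    counters = {CEBPA: 0, PPARG: 0, "h" + CEBPA: 0, "h" + PPARG: 0}
    strengths: dict[str, list[float]] = {CEBPA: [], PPARG: []}
    human_strengths: dict[str, list[float]] = {CEBPA: [], PPARG: []}

    def _new_mouse_site(factor: str, chrom: str, start: int, width: int) -> BindingSite:
        counters[factor] += 1
        prefix = "c" if factor == CEBPA else "p"
        sid = f"{prefix}{counters[factor]:05d}"
        site = BindingSite(sid, GenomicInterval(chrom, start, start + width), factor, "mouse")
        mouse_sites[factor].append(site)
        return site

    def _new_human_site(factor: str, chrom: str, start: int, width: int) -> BindingSite:
        counters["h" + factor] += 1
        prefix = "hc" if factor == CEBPA else "hp"
        sid = f"{prefix}{counters['h' + factor]:05d}"
        site = BindingSite(sid, GenomicInterval(chrom, start, start + width), factor, "human")
        human_sites[factor].append(site)
        return site

    def _plant(site: BindingSite, slot: _Slot) -> None:
        fate = slot.kind
        strength = cfg.site_strength_mean
        if fate == RETAINED:
            strength *= cfg.strength_retained_boost
        strengths[site.factor].append(strength)
        entry: dict = {
            "factor": site.factor,
            "fate": fate,
            "cobound": slot.cobound,
        }
        if fate in fate_index:
            image_start = layout.map_pos(slot.chrom, site.interval.start)
            entry["image"] = [slot.chrom, image_start, image_start + site.width]
            if fate == RETAINED:
                h = _new_human_site(site.factor, slot.chrom, image_start, site.width)
                human_strengths[site.factor].append(cfg.site_strength_mean)
                entry["human_partner"] = h.site_id
            elif fate == TURNOVER:
                d = int(rng.integers(2_000, 8_001)) * int(rng.choice([-1, 1]))
                image_mid = image_start + site.width // 2
                w = int(rng.integers(w_lo, w_hi + 1))
                start_h = image_mid + d - w // 2
                h = _new_human_site(site.factor, slot.chrom, start_h, w)
                human_strengths[site.factor].append(cfg.site_strength_mean)
                entry["human_partner"] = h.site_id
                entry["partner_offset"] = d
        truth_sites[site.site_id] = entry

    for slot in slots:
        width = int(rng.integers(w_lo, w_hi + 1))
        site = _new_mouse_site(slot.factor, slot.chrom, slot.pos, width)
        _plant(site, slot)
        if slot.cobound:  # slots are owned by PPARg; add the overlapping C/EBPa partner
            o = min(100, width // 2)
            pw = int(rng.integers(w_lo, w_hi + 1))
            partner = _new_mouse_site(CEBPA, slot.chrom, slot.pos + o, pw)
            _plant(partner, dataclasses.replace(slot, factor=CEBPA))

    # ------------------------------------------------------------------ genes
    cluster_labels: list[int | None] = []
    for cluster, count in zip(
        [1, 2, 3, 4, None], _allocate(cfg.n_genes, cfg.cluster_proportions)
    ):
        cluster_labels.extend([cluster] * count)
    rng.shuffle(cluster_labels)  # type: ignore[arg-type]

    n_unlift = round(cfg.frac_gene_unlifted * cfg.n_genes)
    n_noorth = round(cfg.frac_gene_no_ortholog * cfg.n_genes)
    n_paired = cfg.n_genes - n_unlift - n_noorth

    def _pick(pool: list[_Slot], k: int, what: str) -> list[_Slot]:
        if k > len(pool):
            raise InfeasibleConfig(f"not enough {what} slots for gene placement")
        if k == 0:
            return []
        return [pool[(i * len(pool)) // k] for i in range(k)]

    unal_slots = [s for s in slots if s.kind == UNALIGNED]
    turn_slots = [s for s in slots if s.kind == TURNOVER]
    ret_slots = [s for s in slots if s.kind == RETAINED]
    lost_slots = [s for s in slots if s.kind == LOST]

    mouse_genes: list[GeneRecord] = []
    human_genes: list[GeneRecord] = []
    gene_truth: dict[str, dict] = {}
    label_iter = iter(cluster_labels)

    def _add_gene(idx: int, chrom: str, tss: int, status: str) -> GeneRecord:
        cluster = next(label_iter)
        strand = "+" if idx % 2 == 0 else "-"
        g = GeneRecord(f"mg{idx:04d}", chrom, tss, strand, cluster)
        mouse_genes.append(g)
        gene_truth[g.gene_id] = {"status": status,
                                 "cluster": "none" if cluster is None else cluster}
        if status == "paired":
            human_genes.append(
                GeneRecord(f"hg{idx:04d}", chrom, layout.map_pos(chrom, tss), strand, None)
            )
        return g

    gene_idx = 0
    for slot in _pick(unal_slots, n_unlift, "unalignable"):
        _add_gene(gene_idx, slot.chrom, slot.pos + 600, "unlifted")
        gene_idx += 1
    for slot in _pick(turn_slots, n_noorth, "turnover"):
        _add_gene(gene_idx, slot.chrom, slot.pos + 9_500, "no_nearby_gene")
        gene_idx += 1

    if cfg.cluster_retention_boost:
        # regulated-gene proximity boost: clusters 3/4 sit by retained sites,
        # everything else by lost sites
        remaining = cluster_labels[n_unlift + n_noorth:]
        hot = [c for c in remaining if c in (3, 4)]
        cold = [c for c in remaining if c not in (3, 4)]
        label_iter = iter(hot + cold)
        for slot in _pick(ret_slots, len(hot), "retained"):
            _add_gene(gene_idx, slot.chrom, slot.pos + 600, "paired")
            gene_idx += 1
        for slot in _pick(lost_slots, len(cold), "lost"):
            _add_gene(gene_idx, slot.chrom, slot.pos + 600, "paired")
            gene_idx += 1
    else:
        pool = ret_slots + lost_slots
        for slot in _pick(pool, n_paired, "mapped"):
            _add_gene(gene_idx, slot.chrom, slot.pos + 600, "paired")
            gene_idx += 1

    # ------------------------------------------------------------------- tags
    tracks: dict[tuple[str, str], TagTrack] = {}
    for factor in (CEBPA, PPARG):
        spans = [
            (s.interval.chrom, s.interval.start, s.interval.end, strengths[factor][i])
            for i, s in enumerate(mouse_sites[factor])
        ]
        track, counts = simulate_tags(spans, cfg.tag_rate_bg, layout.mouse_sizes, rng)
        tracks[("mouse", factor)] = track
        for s, k in zip(mouse_sites[factor], counts):
            s.tag_count = k
            truth_sites[s.site_id]["strength"] = k
        spans_h = [
            (s.interval.chrom, s.interval.start, s.interval.end, human_strengths[factor][i])
            for i, s in enumerate(human_sites[factor])
        ]
        track_h, counts_h = simulate_tags(spans_h, cfg.tag_rate_bg, layout.human_sizes, rng)
        tracks[("human", factor)] = track_h
        for s, k in zip(human_sites[factor], counts_h):
            s.tag_count = k

    # ------------------------------------------- sequences, motifs, alignments
    other = {CEBPA: PPARG, PPARG: CEBPA}
    fasta_by_factor: dict[str, list[tuple[str, str]]] = {}
    pairs_by_factor: dict[str, dict[str, AlignedPair]] = {}
    for factor in (CEBPA, PPARG):
        own, oth = pwms[factor], pwms[other[factor]]
        mapped = [s for s in mouse_sites[factor]
                  if truth_sites[s.site_id]["fate"] in fate_index]
        R, S = len(mapped), cfg.seq_len
        consensus = np.array([_BASES["ACGT".index(b)] for b in own.consensus])
        Lm = len(consensus)
        plant_pos = S // 2 - Lm // 2
        plant_probs = np.array(cfg.motif_plant_prob)
        planted = np.array([
            rng.random() < plant_probs[fate_index[truth_sites[s.site_id]["fate"]]]
            for s in mapped
        ])
        regions = _BASES[rng.integers(0, 4, size=(R, S))].astype(np.uint8)
        code = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(_BASES):
            code[b] = i

        def _replant(rows: np.ndarray) -> None:
            regions[rows] = _BASES[rng.integers(0, 4, size=(len(rows), S))]
            for r in rows:
                if planted[r]:
                    regions[r, plant_pos:plant_pos + Lm] = consensus

        _replant(np.arange(R))
        for _ in range(200):
            codes = code[regions]
            own_hit = _batch_scan(codes, own)
            oth_hit = _batch_scan(codes, oth)
            bad = np.flatnonzero(oth_hit | (~planted & own_hit))
            if len(bad) == 0:
                break
            _replant(bad)
        else:  # pragma: no cover - rejection failing to converge
            raise RuntimeError("motif rejection sampling did not converge")

        fasta: list[tuple[str, str]] = []
        pairs: dict[str, AlignedPair] = {}
        for i, s in enumerate(mapped):
            human_seq = regions[i].tobytes().decode("ascii")
            fate = truth_sites[s.site_id]["fate"]
            target = cfg.identity_by_fate[fate_index[fate]]
            protect = [(plant_pos, plant_pos + Lm)] if planted[i] else []
            mouse_seq = mutate_to_identity(human_seq, target, protect, rng)
            fasta.append((s.site_id, human_seq))
            pairs[s.site_id] = AlignedPair(mouse_seq, human_seq)
            k = round((1 - target) * S)
            truth_sites[s.site_id]["identity"] = (S - k) / S
            truth_sites[s.site_id]["motif_planted"] = bool(planted[i])
        fasta_by_factor[factor] = fasta
        pairs_by_factor[factor] = pairs

    # ------------------------------------------------------------------ write
    for factor in (CEBPA, PPARG):
        write_sites(outdir / f"mouse_{factor}_sites.bed", mouse_sites[factor])
        write_sites(outdir / f"human_{factor}_sites.bed", human_sites[factor])
        write_tags(outdir / f"mouse_{factor}_tags.bed", tracks[("mouse", factor)])
        write_tags(outdir / f"human_{factor}_tags.bed", tracks[("human", factor)])
        with open(outdir / f"human_regions_{factor}.fasta", "w") as fh:
            for sid, seq in fasta_by_factor[factor]:
                fh.write(f">{sid}\n{seq}\n")
        write_pairwise_maf(outdir / f"alignments_{factor}.maf", pairs_by_factor[factor])
    write_chain_file(outdir / "mouse_to_human.chain", layout.fwd_chains,
                     layout.mouse_sizes, layout.human_sizes)
    write_chain_file(outdir / "human_to_mouse.chain", layout.rev_chains,
                     layout.human_sizes, layout.mouse_sizes)
    write_genes(outdir / "mouse_genes.tsv", mouse_genes)
    write_genes(outdir / "human_genes.tsv", human_genes)
    write_chrom_sizes(outdir / "mouse_chrom_sizes.tsv", layout.mouse_sizes)
    write_chrom_sizes(outdir / "human_chrom_sizes.tsv", layout.human_sizes)
    cfg.to_yaml(outdir / "sim_config.yaml")

    truth = {
        "n_sites_per_factor": cfg.n_sites,
        "n_unaligned_per_factor": round(cfg.frac_unalignable * cfg.n_sites),
        "n_ambiguous_per_factor": round(cfg.frac_ambiguous * cfg.n_sites),
        "fate_fractions": list(cfg.fate_fractions),
        "gene_tally": {
            "paired": sum(1 for g in gene_truth.values() if g["status"] == "paired"),
            "unlifted": sum(1 for g in gene_truth.values() if g["status"] == "unlifted"),
            "no_nearby_gene": sum(
                1 for g in gene_truth.values() if g["status"] == "no_nearby_gene"
            ),
        },
        "sites": truth_sites,
        "genes": gene_truth,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return truth
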