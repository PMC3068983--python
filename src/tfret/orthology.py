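"""Chain-based coordinate mapping between two genomes with a reciprocality check.

Mouse sites are lifted into human coordinates through alignment chains
(UCSC chain files, e.g. chained BlastZ alignments, or a simplified block
TSV).  The contract mirrors the classic liftOver workflow for inter-species
comparisons:

* a site maps only if exactly one chain covers any of its bases
  ("uniquely mapped") and the covered fraction is at least ``min_match``
  (0.1, the recommended inter-species setting);
* the mapped span runs from the target image of the first covered base to
  that of the last covered base, so indels inside a site stretch or shrink
  the span;
* the human span is then lifted back, and the site is kept only if the
  back-lifted span is itself uniquely mapped and overlaps at least 90% of
  the original site.

Failures are statuses on the result, never exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .intervals_io import AnalysisConfig, BindingSite, GenomicInterval, overlap_length

MAPPED = "mapped"
UNALIGNED = "unaligned"
BELOW_MIN_MATCH = "below_min_match"
AMBIGUOUS = "ambiguous"
FAILED_RECIPROCAL = "failed_reciprocal"

LIFT_STATUSES = (MAPPED, UNALIGNED, BELOW_MIN_MATCH, AMBIGUOUS, FAILED_RECIPROCAL)


@dataclass(frozen=True)
class ChainBlock:
    """An ungapped aligned block; source and target spans have equal width.

    ``tgt`` is always on the forward strand of the target; ``tgt_reversed``
    marks blocks coming from negative-strand chains, whose within-block
    mapping runs right-to-left.
    """

    src: GenomicInterval
    tgt: GenomicInterval
    tgt_reversed: bool = False

    def __post_init__(self) -> None:
        if self.src.width != self.tgt.width:
            raise ValueError("chain block src/tgt widths differ")

    def map_position(self, pos: int) -> int:
        if not (self.src.start <= pos < self.src.end):
            raise ValueError("position outside block")
        offset = pos - self.src.start
        if self.tgt_reversed:
            return self.tgt.end - 1 - offset
        return self.tgt.start + offset


@dataclass
class OrthologyChain:
    """An ordered set of blocks linking one source region to one target region."""

    chain_id: str
    blocks: list[ChainBlock]

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.src.start < a.src.end or b.src.chrom != a.src.chrom:
                raise ValueError(f"chain {self.chain_id}: src blocks unsorted/overlapping")

    def covered_bases(self, iv: GenomicInterval) -> int:
        return sum(overlap_length(iv, b.src) for b in self.blocks)

    def map_span(self, iv: GenomicInterval) -> GenomicInterval:
        """Target span from the image of the first to the last covered base."""
        covering = [b for b in self.blocks if overlap_length(iv, b.src) > 0]
        if not covering:
            raise ValueError("interval not covered by chain")
        first_block, last_block = covering[0], covering[-1]
        first = max(iv.start, first_block.src.start)
        last = min(iv.end, last_block.src.end) - 1
        t1 = first_block.map_position(first)
        t2 = last_block.map_position(last)
        lo, hi = (t1, t2) if t1 <= t2 else (t2, t1)
        return GenomicInterval(first_block.tgt.chrom, lo, hi + 1)


@dataclass
class LiftResult:
    status: str
    span: GenomicInterval | None = None
    chain_id: str | None = None
    covered_frac: float = 0.0


@dataclass
class MappedSite:
    """A source site plus its reciprocally mapped target span, or a failure reason."""

    site: BindingSite
    status: str
    human_span: GenomicInterval | None = None
    back_overlap_frac: float = 0.0
    chain_id: str | None = None


class ChainSet:
    """A collection of chains indexed for fast per-interval coverage queries."""

    def __init__(self, chains: Iterable[OrthologyChain]):
        self.chains = list(chains)
        self._trees: dict[str, IntervalTree] = {}
        for chain in self.chains:
            for block in chain.blocks:
                tree = self._trees.setdefault(block.src.chrom, IntervalTree())
                tree.addi(block.src.start, block.src.end, chain)

    def _covering_chains(self, iv: GenomicInterval) -> list[OrthologyChain]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        seen: dict[str, OrthologyChain] = {}
        for hit in tree.overlap(iv.start, iv.end):
            seen.setdefault(hit.data.chain_id, hit.data)
        return [seen[k] for k in sorted(seen)]

    def lift(self, iv: GenomicInterval, min_match: float) -> LiftResult:
        """Lift one interval; unique-chain and min_match rules as documented."""
        if not (0 < min_match <= 1):
            raise ValueError("min_match must be in (0,1]")
        covering = self._covering_chains(iv)
        if not covering:
            return LiftResult(UNALIGNED)
        if len(covering) > 1:
            return LiftResult(AMBIGUOUS)
        chain = covering[0]
        covered = chain.covered_bases(iv)
        frac = covered / iv.width
        if frac < min_match:
            return LiftResult(BELOW_MIN_MATCH, covered_frac=frac)
        return LiftResult(MAPPED, chain.map_span(iv), chain.chain_id, frac)


def lift_interval(chains: ChainSet, iv: GenomicInterval, min_match: float) -> LiftResult:
    return chains.lift(iv, min_match)


def reciprocal_map(
    fwd: ChainSet, rev: ChainSet, site: BindingSite, cfg: AnalysisConfig
) -> MappedSite:
    """Forward lift, back lift, and the >=90%-of-original agreement test."""
    forward = fwd.lift(site.interval, cfg.min_match)
    if forward.status != MAPPED:
        return MappedSite(site, forward.status)
    back = rev.lift(forward.span, cfg.min_match)
    if back.status != MAPPED:
        return MappedSite(site, FAILED_RECIPROCAL, chain_id=forward.chain_id)
    frac = overlap_length(back.span, site.interval) / site.width
    if frac < cfg.back_overlap_frac:
        return MappedSite(site, FAILED_RECIPROCAL, back_overlap_frac=frac,
                          chain_id=forward.chain_id)
    return MappedSite(site, MAPPED, forward.span, frac, forward.chain_id)


def map_sites(
    fwd: ChainSet, rev: ChainSet, sites: Sequence[BindingSite], cfg: AnalysisConfig
) -> list[MappedSite]:
    return [reciprocal_map(fwd, rev, s, cfg) for s in sites]


def mapped_fraction(mapped: Sequence[MappedSite]) -> float:
    """|mapped| / |input sites| -- the reporting convention for mapped percentages."""
    if not mapped:
        raise ValueError("no sites")
    return sum(1 for m in mapped if m.status == MAPPED) / len(mapped)


# ---------------------------------------------------------------------------
# chain file I/O

def read_chain_file(path: str | Path) -> ChainSet:
    """Read a UCSC chain file.

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize qStrand
    qStart qEnd id``; the chain's *target* (t) side is treated as the source
    coordinate system of the lift (as in ``<from>To<To>.over.chain`` files)
    and the query (q) side as the destination.  Negative query strands are
    normalised to forward-strand target coordinates with per-block
    ``tgt_reversed`` flags.
    """
    chains: list[OrthologyChain] = []
    with open(path) as fh:
        header: list[str] | None = None
        blocks: list[ChainBlock] = []
        t = q = 0
        t_chrom = q_chrom = ""
        q_size = 0
        q_rev = False
        chain_id = ""
        done_blocks = True

        def flush() -> None:
            if header is not None and blocks:
                chains.append(OrthologyChain(chain_id, list(blocks)))

        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                parts = line.split()
                if len(parts) != 13:
                    raise ValueError(f"bad chain header: {line!r}")
                header = parts
                t_chrom, t = parts[2], int(parts[5])
                q_chrom, q_size, q_rev, q = parts[7], int(parts[8]), parts[9] == "-", int(parts[10])
                chain_id = parts[12]
                blocks = []
                done_blocks = False
                continue
            if done_blocks:
                raise ValueError("alignment line outside a chain block")
            nums = [int(x) for x in line.split()]
            size = nums[0]
            src = GenomicInterval(t_chrom, t, t + size)
            if q_rev:
                tgt = GenomicInterval(q_chrom, q_size - (q + size), q_size - q)
            else:
                tgt = GenomicInterval(q_chrom, q, q + size)
            blocks.append(ChainBlock(src, tgt, tgt_reversed=q_rev))
            if len(nums) == 3:
                t += size + nums[1]
                q += size + nums[2]
            else:
                done_blocks = True
        flush()
    return ChainSet(chains)


def write_chain_file(
    path: str | Path,
    chains: Sequence[OrthologyChain],
    src_sizes: dict[str, int],
    tgt_sizes: dict[str, int],
) -> None:
    """Write forward-strand chains in UCSC chain format (source on the t side)."""
    with open(path, "w") as fh:
        for chain in chains:
            b0, bn = chain.blocks[0], chain.blocks[-1]
            if any(b.tgt_reversed for b in chain.blocks):
                raise ValueError("only forward-strand chains can be written")
            s_chrom, t_chrom = b0.src.chrom, b0.tgt.chrom
            fh.write(
                f"chain 1000 {s_chrom} {src_sizes[s_chrom]} + {b0.src.start} {bn.src.end} "
                f"{t_chrom} {tgt_sizes[t_chrom]} + {b0.tgt.start} {bn.tgt.end} {chain.chain_id}\n"
            )
            for a, b in zip(chain.blocks, chain.blocks[1:]):
                dt = b.src.start - a.src.end
                dq = b.tgt.start - a.tgt.end
                fh.write(f"{a.src.width} {dt} {dq}\n")
            fh.write(f"{bn.src.width}\n\n")


def read_block_tsv(path: str | Path) -> ChainSet:
    """Read the simplified block TSV used for fixtures.

    Columns: ``src_chrom src_start src_end tgt_chrom tgt_start tgt_end chain_id``.
    """
    by_chain: dict[str, list[ChainBlock]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("src_chrom"):
                continue
            sc, ss, se, tc, ts, te, cid = line.split("\t")
            block = ChainBlock(
                GenomicInterval(sc, int(ss), int(se)),
                GenomicInterval(tc, int(ts), int(te)),
            )
            if cid not in by_chain:
                order.append(cid)
            by_chain.setdefault(cid, []).append(block)
    chains = []
    for cid in order:
        blocks = sorted(by_chain[cid], key=lambda b: b.src.start)
        chains.append(OrthologyChain(cid, blocks))
    return ChainSet(chains)
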