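"""End-to-end orchestration: fixture files in, fate table and report out.

The pipeline reads a fixture bundle (site BEDs for both factors and both
species, forward/reverse chain files, tag BEDs, gene TSVs, per-region
FASTA, pairwise MAF), then runs every stage in order: co-binding
classification, reciprocal coordinate mapping, binary retention and
turnover, tag-enrichment scoring against a seeded random-window null,
cluster assignment, consensus scanning and identity scoring, and finally
the cross-tabulations with their Fisher/Wilcoxon statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, cobinding, motif_identity, orthology, retention, stats_report
from .intervals_io import (
    CEBPA,
    PPARG,
    AnalysisConfig,
    BindingSite,
    SiteIndex,
    midpoint,
    read_chrom_sizes,
    read_genes,
    read_sites,
    read_tags,
)
from .orthology import MAPPED
from .retention import LOST, RETAINED, TURNOVER

FACTOR_PAIR = (CEBPA, PPARG)
_OTHER = {CEBPA: PPARG, PPARG: CEBPA}


@dataclass
class PipelineResult:
    fates: pd.DataFrame
    mapping: pd.DataFrame
    venn_mouse: dict
    venn_human: dict
    crosstabs: dict
    violins: dict
    enrichment_width: dict
    tss_profiles: pd.DataFrame | None = None
    gained_histograms: pd.DataFrame | None = None
    ortholog_tally: dict | None = None
    mapped_sites: dict | None = None
    records: dict | None = None


def _read_pwms(cfg: AnalysisConfig, pwm_paths: dict[str, Path] | None):
    if pwm_paths is None:
        from .synthetic_data import _default_pwms

        return _default_pwms(cfg)
    return {
        factor: next(iter(motif_identity.read_jaspar_pfms(path, cfg).values()))
        for factor, path in pwm_paths.items()
    }


def run_pipeline(
    fixture_dir: str | Path,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
    pwm_paths: dict[str, Path] | None = None,
) -> PipelineResult:
    """Run the full cross-species retention analysis on a fixture directory."""
    cfg = cfg or AnalysisConfig()
    d = Path(fixture_dir)
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(FACTOR_PAIR))

    mouse = {f: read_sites(d / f"mouse_{f}_sites.bed", f, "mouse") for f in FACTOR_PAIR}
    human = {f: read_sites(d / f"human_{f}_sites.bed", f, "human") for f in FACTOR_PAIR}
    fwd = orthology.read_chain_file(d / "mouse_to_human.chain")
    rev = orthology.read_chain_file(d / "human_to_mouse.chain")
    mouse_genes = read_genes(d / "mouse_genes.tsv")
    human_genes = read_genes(d / "human_genes.tsv")
    human_sizes = read_chrom_sizes(d / "human_chrom_sizes.tsv")
    human_tags = {f: read_tags(d / f"human_{f}_tags.bed") for f in FACTOR_PAIR}
    pwms = _read_pwms(cfg, pwm_paths)
    regions = {}
    alignments = {}
    for f in FACTOR_PAIR:
        fasta = d / f"human_regions_{f}.fasta"
        maf = d / f"alignments_{f}.maf"
        regions[f] = _read_fasta(fasta) if fasta.exists() else {}
        alignments[f] = (
            motif_identity.read_pairwise_maf(maf) if maf.exists() else {}
        )

    # ------------------------------------------------------ co-binding (Venn)
    c_labels, p_labels, venn_mouse = cobinding.classify_cobinding(
        mouse[CEBPA], mouse[PPARG], cfg, "mouse"
    )
    _, _, venn_human = cobinding.classify_cobinding(
        human[CEBPA], human[PPARG], cfg, "human"
    )
    cobind_by_id = {
        s.site_id: lab.label for s, lab in zip(mouse[CEBPA], c_labels)
    }
    cobind_by_id.update({s.site_id: lab.label for s, lab in zip(mouse[PPARG], p_labels)})

    # ------------------------------------------------------- reciprocal lifts
    mapped = {f: orthology.map_sites(fwd, rev, mouse[f], cfg) for f in FACTOR_PAIR}
    mapping = stats_report.mapping_summary(
        {f: len(mouse[f]) for f in FACTOR_PAIR},
        {f: sum(1 for m in mapped[f] if m.status == MAPPED) for f in FACTOR_PAIR},
    )

    # ----------------------------------------------------- fates and turnover
    union_index = SiteIndex(human[CEBPA] + human[PPARG])
    lifted_spans = {
        f: [m.human_span for m in mapped[f] if m.status == MAPPED] for f in FACTOR_PAIR
    }
    human_specific = {
        f: retention.human_specific_sites(human[f], lifted_spans[f], cfg)
        for f in FACTOR_PAIR
    }
    records = {
        f: retention.assign_fates(mapped[f], union_index, human_specific[f], cfg)
        for f in FACTOR_PAIR
    }

    # ------------------------------------------------------------- enrichment
    enrichment_width = {}
    for i, f in enumerate(FACTOR_PAIR):
        width = retention.window_width_75th(human[f]) if human[f] else (
            cfg.enrich_window_cebpa if f == CEBPA else cfg.enrich_window_pparg
        )
        enrichment_width[f] = width
        expectation = retention.RandomExpectation(
            human_tags[f], width, human_sizes, cfg.n_random_regions,
            int(rng_seeds[i]) % (2**31),
        )
        for rec in records[f]:
            rec.enrichment_log2fc = retention.enrichment_log2fc(
                rec.mapped, human_tags[f], expectation, cfg
            )

    # ---------------------------------------------- clusters, motifs, identity
    gene_index = annotation.GeneIndex(mouse_genes)
    for f in FACTOR_PAIR:
        own, oth = pwms[f], pwms[_OTHER[f]]
        for rec in records[f]:
            rec.cluster = annotation.assign_cluster(rec.site, gene_index, cfg)
            rec.cobind_label = cobind_by_id[rec.site.site_id]
            seq = regions[f].get(rec.site.site_id)
            if seq is not None:
                rec.has_own_consensus = motif_identity.has_consensus(seq, own).found
                rec.has_other_consensus = motif_identity.has_consensus(seq, oth).found
            pair = alignments[f].get(rec.site.site_id)
            if pair is not None:
                rec.identity = motif_identity.identity_score(pair)

    fates = _fate_frame(records)

    # ------------------------------------------------- cross-tabs and violins
    crosstabs: dict[str, stats_report.CrosstabResult] = {}
    violins: dict[str, tuple] = {}
    for f in FACTOR_PAIR:
        recs = records[f]
        if not recs:
            continue
        clusters_present = {r.cluster for r in recs}
        if {3, 4} & clusters_present and clusters_present - {3, 4}:
            crosstabs[f"cluster_{f}"] = stats_report.crosstab_retention(
                recs, lambda r: r.cluster,
                ((3, 4), tuple(sorted(clusters_present - {3, 4}))),
                grouping_name="cluster",
            )
        labels = {r.cobind_label for r in recs}
        if len(labels) == 2:
            only = next(l for l in labels if l != cobinding.OVERLAPPING)
            crosstabs[f"cobind_{f}"] = stats_report.crosstab_retention(
                recs, lambda r: r.cobind_label,
                ((cobinding.OVERLAPPING,), (only,)),
                grouping_name="cobind_class",
            )
        with_flags = [r for r in recs if r.has_own_consensus is not None]
        if with_flags and len({r.has_own_consensus for r in with_flags}) == 2:
            crosstabs[f"consensus_{f}"] = stats_report.crosstab_retention(
                with_flags, lambda r: r.has_own_consensus,
                ((True,), (False,)),
                grouping_name="has_own_consensus",
            )
        strengths = [r.mouse_tag_count for r in recs]
        if len(strengths) >= 4:
            qlabels = retention.quartile_bins(strengths)
            for rec, q in zip(recs, qlabels):
                rec.strength_quartile = int(q)  # type: ignore[attr-defined]
            crosstabs[f"strength_quartile_{f}"] = stats_report.crosstab_retention(
                recs, lambda r: r.strength_quartile,
                ((4,), (1, 2, 3)),
                grouping_name="strength_quartile",
            )
        with_ident = [r for r in recs if r.identity is not None]
        if len(with_ident) >= 4:
            qlabels = retention.quartile_bins([r.identity for r in with_ident])
            for rec, q in zip(with_ident, qlabels):
                rec.identity_quartile = int(q)  # type: ignore[attr-defined]
            crosstabs[f"identity_quartile_{f}"] = stats_report.crosstab_retention(
                with_ident, lambda r: r.identity_quartile,
                ((4,), (1, 2, 3)),
                grouping_name="identity_quartile",
            )
        by_cluster: dict[int, list[float]] = {}
        for r in recs:
            by_cluster.setdefault(r.cluster, []).append(r.enrichment_log2fc)
        contrast = None
        if 4 in by_cluster and len(by_cluster) > 1:
            contrast = ((4,), tuple(sorted(k for k in by_cluster if k != 4)))
        violins[f"enrichment_by_cluster_{f}"] = stats_report.violin_summary(
            dict(sorted(by_cluster.items())), contrast
        )

    # ---------------------------------------------- TSS profiles, gained sites
    pairs, tally = annotation.lift_tss_orthologs(mouse_genes, fwd, human_genes, cfg)
    tss_profiles = None
    cluster_genes: dict[int, list] = {}
    for g in mouse_genes:
        if g.cluster is not None:
            cluster_genes.setdefault(g.cluster, []).append(g)
    if cluster_genes:
        rows = {}
        for cluster in sorted(cluster_genes):
            rows[cluster] = annotation.tss_site_profile(
                cluster_genes[cluster], mouse[PPARG], cfg
            )
        tss_profiles = pd.DataFrame.from_dict(rows, orient="index")
        tss_profiles.index.name = "cluster"
        tss_profiles.columns = [
            f"bin_{i * cfg.tss_profile_bin - cfg.cluster_window}"
            for i in range(tss_profiles.shape[1])
        ]
    gained = None
    ortho_genes = [
        # human ortholog inherits the mouse cluster label
        annotation.GeneRecord(
            p.human_gene.gene_id, p.human_gene.chrom, p.human_gene.tss,
            p.human_gene.strand, p.inherited_cluster,
        )
        for p in pairs
    ]
    if ortho_genes:
        _, hists = annotation.gained_sites_per_gene(
            ortho_genes, human_specific[PPARG], cfg
        )
        if hists:
            width = max(len(h) for h in hists.values())
            gained = pd.DataFrame.from_dict(
                {
                    str(k): np.pad(v, (0, width - len(v)), constant_values=np.nan)
                    for k, v in sorted(hists.items(), key=lambda kv: str(kv[0]))
                },
                orient="index",
            )
            gained.index.name = "cluster"
            gained.columns = [f"n_{i}" for i in range(width)]

    return PipelineResult(
        fates=fates,
        mapping=mapping,
        venn_mouse=venn_mouse,
        venn_human=venn_human,
        crosstabs=crosstabs,
        violins=violins,
        enrichment_width=enrichment_width,
        tss_profiles=tss_profiles,
        gained_histograms=gained,
        ortholog_tally={"paired": len(pairs), **tally},
        mapped_sites=mapped,
        records=records,
    )


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def _fate_frame(records: dict[str, list[retention.FateRecord]]) -> pd.DataFrame:
    rows = []
    for f in FACTOR_PAIR:
        for r in records.get(f, []):
            iv = r.site.interval
            rows.append(
                {
                    "site_id": r.site.site_id,
                    "factor": f,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "status": r.mapped.status,
                    "fate": r.fate,
                    "retained_as": "+".join(sorted(r.retained_as)),
                    "log2fc": r.enrichment_log2fc,
                    "tag_count": r.mouse_tag_count,
                    "cluster": r.cluster,
                    "cobind_class": r.cobind_label,
                    "has_own_consensus": r.has_own_consensus,
                    "has_other_consensus": r.has_other_consensus,
                    "identity": r.identity,
                }
            )
    return pd.DataFrame(rows)
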