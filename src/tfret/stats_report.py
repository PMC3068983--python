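"""Exact statistics and the cross-tabulations of the end-to-end report.

Fisher's exact test (two-sided, probability-ordering convention) and the
Wilcoxon rank-sum test (exact by enumeration for small samples, normal
approximation with tie and continuity corrections otherwise) are the two
tests used throughout the retention analysis.  Quantiles everywhere use
linear interpolation between order statistics.  Raw p-values are reported;
a Benjamini-Hochberg column is emitted alongside for transparency but never
gates any output.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .retention import FateRecord, LOST, RETAINED, TURNOVER

_REL_TOL = 1e-7


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table
    (within relative tolerance 1e-7).  A zero margin makes every table with
    those margins identical; p = 1 with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("zero margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return min(p, 1.0)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value with midranks for ties.

    Exact by enumeration of all rank assignments when ``n_x + n_y <= 12``;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w_obs = float(ranks[:nx].sum())
    if n <= 12:
        sums = [
            sum(combo)
            for combo in itertools.combinations(ranks, nx)
        ]
        sums = np.asarray(sums)
        eps = 1e-9
        p_lo = float((sums <= w_obs + eps).mean())
        p_hi = float((sums >= w_obs - eps).mean())
        return min(1.0, 2.0 * min(p_lo, p_hi))
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = w_obs - mu
    if diff == 0:
        return 1.0
    z = (abs(diff) - 0.5) / math.sqrt(var)
    return min(1.0, 2.0 * float(sps.norm.sf(z)))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def quantile(values: Sequence[float], q: float) -> float:
    """Linear interpolation between order statistics (used everywhere)."""
    return float(np.quantile(np.asarray(values, dtype=float), q))


@dataclass
class ViolinSummary:
    """Distribution hinges as drawn in a violin/box plot."""

    group: object
    median: float
    quartile25: float
    quartile75: float
    n: int

    def __post_init__(self) -> None:
        if not (self.quartile25 <= self.median <= self.quartile75):
            raise ValueError("quartiles out of order")


def violin_summary(
    values_by_group: dict,
    contrast: tuple[Sequence, Sequence] | None = None,
) -> tuple[list[ViolinSummary], float | None]:
    """Median and quartile hinges per group, plus an optional Wilcoxon contrast.

    ``contrast`` names two sets of group keys; their pooled values are
    compared with the rank-sum test.
    """
    summaries = []
    for group in values_by_group:
        vals = np.asarray(values_by_group[group], dtype=float)
        if len(vals) == 0:
            raise ValueError(f"empty group {group!r}")
        summaries.append(
            ViolinSummary(
                group,
                quantile(vals, 0.5),
                quantile(vals, 0.25),
                quantile(vals, 0.75),
                len(vals),
            )
        )
    p = None
    if contrast is not None:
        ga, gb = contrast
        xa = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in ga])
        xb = np.concatenate([np.asarray(values_by_group[g], dtype=float) for g in gb])
        p = wilcoxon_rank_sum(xa, xb)
    return summaries, p


@dataclass
class CrosstabResult:
    """Per-group fate counts/fractions and one 2x2 Fisher contrast."""

    grouping: str
    counts: pd.DataFrame           # index: group; columns retained/lost/turnover/n
    comparison: tuple[tuple, tuple]
    table: list[list[int]]
    fisher_p: float


def crosstab_retention(
    fates: Sequence[FateRecord],
    grouping: Callable[[FateRecord], object],
    comparison: tuple[Sequence, Sequence],
    grouping_name: str = "group",
) -> CrosstabResult:
    """Cross-tabulate fates by a grouping and test retained-vs-not for two group sets."""
    rows: dict[object, dict[str, int]] = {}
    for f in fates:
        g = grouping(f)
        row = rows.setdefault(g, {RETAINED: 0, LOST: 0, TURNOVER: 0})
        row[f.fate] += 1
    groups = sorted(rows, key=str)
    counts = pd.DataFrame(
        [[rows[g][RETAINED], rows[g][LOST], rows[g][TURNOVER]] for g in groups],
        index=pd.Index(groups, name=grouping_name),
        columns=[RETAINED, LOST, TURNOVER],
    )
    counts["n"] = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        for col in (RETAINED, LOST, TURNOVER):
            counts[f"frac_{col}"] = counts[col] / counts["n"]
    ga, gb = tuple(comparison[0]), tuple(comparison[1])
    for side, name in ((ga, "A"), (gb, "B")):
        if not any(g in rows for g in side):
            raise ValueError(f"comparison group {name} is empty")
    ret_a = int(sum(rows[g][RETAINED] for g in ga if g in rows))
    not_a = int(sum(rows[g][LOST] + rows[g][TURNOVER] for g in ga if g in rows))
    ret_b = int(sum(rows[g][RETAINED] for g in gb if g in rows))
    not_b = int(sum(rows[g][LOST] + rows[g][TURNOVER] for g in gb if g in rows))
    table = [[ret_a, not_a], [ret_b, not_b]]
    return CrosstabResult(grouping_name, counts, (ga, gb), table, fisher_exact_2x2(table))


def mapped_percentage(n_detected: int, n_mapped: int) -> float:
    """Mapped-site percentage reported to one decimal (half-up rounding)."""
    if n_detected <= 0:
        raise ValueError("n_detected must be positive")
    pct = 100.0 * n_mapped / n_detected
    return math.floor(pct * 10 + 0.5) / 10


def mapping_summary(detected: dict[str, int], mapped: dict[str, int]) -> pd.DataFrame:
    """Per-factor detected/mapped counts with the one-decimal mapped percentage."""
    rows = []
    for factor in sorted(detected):
        n_det, n_map = detected[factor], mapped.get(factor, 0)
        rows.append((factor, n_det, n_map, mapped_percentage(n_det, n_map)))
    return pd.DataFrame(rows, columns=["factor", "detected", "mapped", "mapped_pct"])


# ---------------------------------------------------------------------------
# report bundle


def _fmt(x: object) -> object:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return None
        return float(f"{x:.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _jsonable(obj: object) -> object:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    return _fmt(obj)


def write_tsv(path: Path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def run_report(result, outdir: str | Path) -> dict:
    """Write the TSV/JSON report bundle for a completed pipeline run.

    ``result`` is a :class:`tfret.pipeline.PipelineResult`; outputs mirror
    the study's figure tables (Venn counts, retention fractions by cluster /
    strength quartile / co-binding class / consensus / identity quartile,
    enrichment violin summaries, TSS profiles, gained-site histograms) plus
    a machine-readable ``report.json``.  Regeneration from the same inputs
    is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = ("fates", "venn_mouse", "mapping", "enrichment_width")
    for name in required:
        if getattr(result, name, None) is None:
            raise ValueError(f"missing upstream stage output: {name}")

    report: dict = {}

    venn = pd.DataFrame(
        [
            {"species": sp, "class": k, "count": v}
            for sp, counts in (("mouse", result.venn_mouse), ("human", result.venn_human))
            if counts is not None
            for k, v in sorted(counts.items())
        ]
    )
    write_tsv(outdir / "venn_counts.tsv", venn, index=False)
    report["venn"] = {"mouse": result.venn_mouse, "human": result.venn_human}

    write_tsv(outdir / "mapping_summary.tsv", result.mapping, index=False)
    report["mapping"] = {
        row["factor"]: {
            "detected": int(row["detected"]),
            "mapped": int(row["mapped"]),
            "mapped_pct": float(row["mapped_pct"]),
        }
        for _, row in result.mapping.iterrows()
    }

    fates = result.fates
    write_tsv(outdir / "fates.tsv", fates, index=False)

    retention_rows = []
    report["retention"] = {}
    pvals: list[tuple[str, float]] = []
    for factor, sub in fates.groupby("factor"):
        n = len(sub)
        frac = {fate: float((sub["fate"] == fate).mean()) for fate in (RETAINED, LOST, TURNOVER)}
        retention_rows.append({"factor": factor, "n": n, **{f"frac_{k}": v for k, v in frac.items()}})
        report["retention"][factor] = {"n": n, **frac}
    write_tsv(outdir / "retention_summary.tsv", pd.DataFrame(retention_rows), index=False)

    def crosstab_to_files(name: str, ct: CrosstabResult) -> None:
        write_tsv(outdir / f"{name}.tsv", ct.counts)
        report.setdefault("crosstabs", {})[name] = {
            "fisher_p": ct.fisher_p,
            "comparison": [list(map(str, ct.comparison[0])), list(map(str, ct.comparison[1]))],
            "table": ct.table,
        }
        pvals.append((name, ct.fisher_p))

    for name, ct in sorted(result.crosstabs.items()):
        crosstab_to_files(name, ct)

    for name, (summaries, p) in sorted(result.violins.items()):
        df = pd.DataFrame(
            [
                {
                    "group": str(s.group),
                    "median": s.median,
                    "q25": s.quartile25,
                    "q75": s.quartile75,
                    "n": s.n,
                }
                for s in summaries
            ]
        )
        write_tsv(outdir / f"violin_{name}.tsv", df, index=False)
        report.setdefault("violins", {})[name] = {
            "groups": {str(s.group): {"median": s.median, "q25": s.quartile25,
                                      "q75": s.quartile75, "n": s.n} for s in summaries},
            "wilcoxon_p": p,
        }
        if p is not None:
            pvals.append((f"violin_{name}", p))

    if result.tss_profiles is not None:
        write_tsv(outdir / "tss_profiles.tsv", result.tss_profiles)
    if result.gained_histograms is not None:
        write_tsv(outdir / "gained_site_histograms.tsv", result.gained_histograms)
        report["gained_histograms"] = {
            str(c): list(result.gained_histograms.loc[c].dropna())
            for c in result.gained_histograms.index
        }
    if result.ortholog_tally is not None:
        report["tss_orthologs"] = result.ortholog_tally

    if pvals:
        adj = benjamini_hochberg([p for _, p in pvals])
        df = pd.DataFrame(
            {"test": [n for n, _ in pvals], "p": [p for _, p in pvals], "bh_fdr": adj}
        )
        write_tsv(outdir / "pvalues.tsv", df, index=False)

    report["enrichment_window"] = result.enrichment_width
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report
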