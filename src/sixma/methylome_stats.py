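"""Statistical toolkit: tau tissue specificity, 5mC-context 6mA fractions,
expression association, and gene-feature quartile enrichment.

Conventions used throughout:

* chi-square tests are Pearson without continuity correction;
* the Mann-Whitney U statistic uses midranks for ties, with the exact null
  distribution when ``n*m <= 400`` and the samples are tie-free, otherwise
  the tie-corrected normal approximation;
* the two-sample t-test is Welch's (unequal variances), two-sided;
* degenerate tables (a margin collapsing to zero) are flagged, never
  silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from sixma.feature_annotation import _RC, GeneMethylationSummary
from sixma.io_formats import (
    ExpressionMatrix,
    GenomeSequence,
    MethylationSiteSet,
    ValidationError,
)


class DegenerateTableError(ValueError):
    """A contingency table with fewer than two informative rows or columns."""


# ---------------------------------------------------------------------------
# Generic tests


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray


def chi_square(table) -> ChiSquareResult:
    """Pearson chi-square on a contingency table, dropping all-zero margins."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("negative counts in contingency table")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(
            f"table collapses to shape {obs.shape} after dropping empty margins"
        )
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), obs)


@dataclass
class TwoSampleResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str
    median_x: float = float("nan")
    median_y: float = float("nan")


def mann_whitney_u(x, y) -> TwoSampleResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Uses the exact null distribution for small tie-free samples
    (``n*m <= 400``), the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) * len(y) <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return TwoSampleResult(
        float(res.statistic), float(res.pvalue), len(x), len(y), f"mannwhitney_{method}",
        float(np.median(x)), float(np.median(y)),
    )


def two_sample_t(x, y) -> TwoSampleResult:
    """Welch's two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TwoSampleResult(
        float(res.statistic), float(res.pvalue), len(x), len(y), "welch_t",
        float(np.median(x)), float(np.median(y)),
    )


# ---------------------------------------------------------------------------
# tau tissue-specificity index


@dataclass
class TauResult:
    gene_id: str
    tau: float
    n_tissues: int
    transformed_expression: np.ndarray

    @property
    def defined(self) -> bool:
        return not np.isnan(self.tau)


def compute_tau(
    expr: ExpressionMatrix, log_base: float = 2.0, pseudocount: float = 1.0
) -> list[TauResult]:
    """Tissue-specificity index per gene.

    With x_i = log(FPKM_i + pseudocount) and xhat_i = x_i / max_i(x_i):
    tau = sum(1 - xhat_i) / (n - 1), ranging from 0 (uniform expression)
    to 1 (single-tissue expression).  Undefined (NaN) when the gene is
    silent in every tissue or fewer than two tissues are available.
    """
    mat = expr.fpkm.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValidationError("negative FPKM")
    n = mat.shape[1]
    if n < 2:
        raise ValueError("tau requires at least two tissues")
    x = np.log(mat + pseudocount) / np.log(log_base)
    results = []
    for gene_id, xi in zip(expr.gene_ids, x):
        mx = xi.max()
        if mx <= 0:
            results.append(TauResult(gene_id, float("nan"), n, xi))
            continue
        xhat = xi / mx
        tau = float(np.sum(1.0 - xhat) / (n - 1))
        results.append(TauResult(gene_id, tau, n, xhat))
    return results


def tau_to_series(results: list[TauResult]) -> pd.Series:
    return pd.Series({r.gene_id: r.tau for r in results}, name="tau")


# ---------------------------------------------------------------------------
# 6mA within 5mC contexts


@dataclass
class ContextMethylationReport:
    """Per-context tallies of adenines inside methylated-cytosine triplets.

    For each retained 5mC site the three-base context on its strand is
    inspected: CGN offers an adenine when N is A, CHG when H is A, CHH at
    either H.  A CHH occurrence with both adenines methylated (CAmAm)
    counts a single methylated event.  Denominators are occurrences
    containing at least one adenine.
    """

    contexts: tuple[str, ...] = ("CGN", "CHG", "CHH")
    occurrences_with_A: dict[str, int] = field(default_factory=dict)
    methylated_events: dict[str, int] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    chi_square: ChiSquareResult | None = None
    degenerate_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "context": list(self.contexts),
                "occurrences_with_A": [self.occurrences_with_A[c] for c in self.contexts],
                "methylated_events": [self.methylated_events[c] for c in self.contexts],
                "ratio": [self.ratios[c] for c in self.contexts],
            }
        )


_H = set("ATC")


def context_6mA_fraction(
    a_sites: MethylationSiteSet,
    c_sites: MethylationSiteSet,
    genome: GenomeSequence,
) -> ContextMethylationReport:
    """Fraction of methylated-C context occurrences whose adenines carry 6mA."""
    meth_a: set[tuple[str, int, str]] = {
        (row.chrom, int(row.pos), row.strand) for row in a_sites.df.itertuples()
    }
    occ = {c: 0 for c in ("CGN", "CHG", "CHH")}
    events = {c: 0 for c in ("CGN", "CHG", "CHH")}
    for row in c_sites.df.itertuples():
        chrom, pos, strand, context = row.chrom, int(row.pos), row.strand, row.context
        seq = genome.chroms[chrom]
        # triplet on the cytosine's strand, 5'->3'
        if strand == "+":
            if pos + 2 >= len(seq):
                continue
            triplet = seq[pos : pos + 3]
            offsets = (pos, pos + 1, pos + 2)
        else:
            if pos - 2 < 0:
                continue
            raw = seq[pos - 2 : pos + 1]
            triplet = raw.encode().translate(_RC)[::-1].decode()
            offsets = (pos, pos - 1, pos - 2)
        if triplet[0] != "C":
            raise ValidationError(
                f"5mC at {chrom}:{pos}:{strand} does not start a C on its strand"
            )
        if context == "CG":
            if triplet[1] != "G":
                raise ValidationError(
                    f"context CG at {chrom}:{pos}:{strand} inconsistent with {triplet}"
                )
            label = "CGN"
            a_offsets = [offsets[2]] if triplet[2] == "A" else []
        elif context == "CHG":
            if triplet[1] not in _H or triplet[2] != "G":
                raise ValidationError(
                    f"context CHG at {chrom}:{pos}:{strand} inconsistent with {triplet}"
                )
            label = "CHG"
            a_offsets = [offsets[1]] if triplet[1] == "A" else []
        else:  # CHH
            if triplet[1] not in _H or triplet[2] not in _H:
                raise ValidationError(
                    f"context CHH at {chrom}:{pos}:{strand} inconsistent with {triplet}"
                )
            label = "CHH"
            a_offsets = [offsets[i] for i in (1, 2) if triplet[i] == "A"]
        if not a_offsets:
            continue
        occ[label] += 1
        if any((chrom, o, strand) in meth_a for o in a_offsets):
            events[label] += 1  # CAmAm counted once
    ratios = {
        c: (events[c] / occ[c]) if occ[c] else float("nan") for c in occ
    }
    report = ContextMethylationReport(
        occurrences_with_A=occ, methylated_events=events, ratios=ratios
    )
    table = np.array(
        [[events[c] for c in report.contexts],
         [occ[c] - events[c] for c in report.contexts]]
    )
    try:
        report.chi_square = chi_square(table)
    except DegenerateTableError as exc:
        report.degenerate_reason = str(exc)
    return report


# ---------------------------------------------------------------------------
# Expression association


@dataclass
class ExpressionAssociation:
    t_test: TwoSampleResult | None
    chi2_2x2: ChiSquareResult | None
    class_comparison: dict[str, TwoSampleResult]
    group_medians: dict[str, float]
    direction: str
    degenerate_reason: str = ""


def expression_association(
    summaries: list[GeneMethylationSummary],
    expr: ExpressionMatrix,
    fpkm_threshold: float = 1.0,
) -> ExpressionAssociation:
    """Association between gene-body 6mA and focal-tissue expression.

    Reports (a) a Welch t-test of FPKM between 6mA and non-6mA genes,
    (b) a 2x2 chi-square of methylation status against the high/low
    expression split, and (c) pairwise comparisons of the three methylation
    classes (none / intermediate 1-99 / high >=100 sites).
    """
    fpkm = expr.focal_fpkm()
    rows = [(s.gene_id, s.is_methylated, s.methylation_class) for s in summaries
            if s.gene_id in fpkm.index]
    if not rows:
        raise ValueError("no genes shared between summaries and expression matrix")
    df = pd.DataFrame(rows, columns=["gene_id", "is_methylated", "mclass"])
    df["fpkm"] = fpkm.loc[df["gene_id"]].to_numpy()
    meth = df.loc[df["is_methylated"], "fpkm"].to_numpy()
    non = df.loc[~df["is_methylated"], "fpkm"].to_numpy()
    degenerate = ""
    t_res = None
    if len(meth) >= 2 and len(non) >= 2:
        t_res = two_sample_t(meth, non)
    else:
        degenerate = "one methylation group has <2 genes"
    high_expr = df["fpkm"] >= fpkm_threshold
    table = pd.crosstab(df["is_methylated"], high_expr).to_numpy()
    chi_res = None
    try:
        chi_res = chi_square(table)
    except DegenerateTableError as exc:
        degenerate = degenerate or f"2x2 chi-square degenerate: {exc}"
    class_cmp: dict[str, TwoSampleResult] = {}
    groups = {c: df.loc[df["mclass"] == c, "fpkm"].to_numpy()
              for c in ("none", "intermediate", "high")}
    for a, b in (("high", "intermediate"), ("high", "none"), ("intermediate", "none")):
        if len(groups[a]) >= 2 and len(groups[b]) >= 2:
            class_cmp[f"{a}_vs_{b}"] = two_sample_t(groups[a], groups[b])
    medians = {c: (float(np.median(v)) if len(v) else float("nan"))
               for c, v in groups.items()}
    if t_res is not None:
        direction = "6mA_higher" if t_res.statistic > 0 else "6mA_lower"
    else:
        direction = "undetermined"
    return ExpressionAssociation(
        t_test=t_res, chi2_2x2=chi_res, class_comparison=class_cmp,
        group_medians=medians, direction=direction, degenerate_reason=degenerate,
    )


# ---------------------------------------------------------------------------
# Quartile binning and enrichment


def quartile_bins(values) -> tuple[np.ndarray, np.ndarray]:
    """Assign each value to one of four quartile bins.

    Edges are the 25/50/75 empirical percentiles (linear interpolation);
    intervals are closed on the right, so a value equal to an edge falls in
    the lower bin.  Returns (bin indices 0..3, edges).
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 4:
        raise ValueError("degenerate quartiles: fewer than 4 distinct values")
    edges = np.quantile(v, [0.25, 0.5, 0.75])
    if len(np.unique(edges)) < 3:
        raise ValueError("degenerate quartiles: repeated quartile edges")
    bins = np.searchsorted(edges, v, side="left")
    return bins, edges


@dataclass
class BinEnrichmentResult:
    feature: str
    bin_edges: np.ndarray
    bin_counts: pd.DataFrame  # index bin, columns methylated / unmethylated / pct
    overall: ChiSquareResult
    pairwise: pd.DataFrame  # bin_a, bin_b, statistic, p, p_bonferroni


def bin_enrichment(
    summaries: list[GeneMethylationSummary],
    feature_values: pd.Series,
    feature_name: str = "feature",
    n_bins: int = 4,
) -> BinEnrichmentResult:
    """Percentage of 6mA genes per feature quartile, with chi-square tests.

    The overall 2 x n_bins table is tested once; every pair of bins is
    additionally tested 2x2 with Bonferroni adjustment over the pairs.
    """
    if n_bins != 4:
        raise NotImplementedError("quartile binning uses 4 bins")
    status = {s.gene_id: s.is_methylated for s in summaries}
    genes = [g for g in feature_values.index if g in status]
    if not genes:
        raise ValueError("no genes shared between summaries and feature values")
    vals = feature_values.loc[genes]
    bins, edges = quartile_bins(vals.to_numpy())
    meth = np.array([status[g] for g in genes])
    counts = np.zeros((2, 4), dtype=int)
    for b in range(4):
        counts[0, b] = int(np.sum(meth & (bins == b)))
        counts[1, b] = int(np.sum(~meth & (bins == b)))
    if (counts.sum(axis=0) == 0).any():
        empty = [b for b in range(4) if counts[:, b].sum() == 0]
        raise ValueError(f"empty quartile bin(s) {empty}; edges={edges}")
    overall = chi_square(counts)
    pair_rows = []
    pairs = [(a, b) for a in range(4) for b in range(a + 1, 4)]
    for a, b in pairs:
        sub = counts[:, [a, b]]
        try:
            res = chi_square(sub)
            stat, p = res.statistic, res.p_value
        except DegenerateTableError:
            stat, p = float("nan"), float("nan")
        pair_rows.append((a, b, stat, p, min(1.0, p * len(pairs))))
    pairwise = pd.DataFrame(
        pair_rows, columns=["bin_a", "bin_b", "statistic", "p", "p_bonferroni"]
    )
    with np.errstate(invalid="ignore"):
        pct = 100.0 * counts[0] / counts.sum(axis=0)
    bin_counts = pd.DataFrame(
        {
            "methylated": counts[0],
            "unmethylated": counts[1],
            "pct_methylated": pct,
        },
        index=pd.Index(range(4), name="bin"),
    )
    return BinEnrichmentResult(feature_name, edges, bin_counts, overall, pairwise)


# ---------------------------------------------------------------------------
# Within-orthogroup contrasts


@dataclass
class WithinOGContrast:
    n_qualifying_ogs: int
    n_methylated: int
    n_unmethylated: int
    tests: dict[str, TwoSampleResult]
    reason: str = ""


def within_og_contrast(
    og_membership: dict[str, dict[str, set[str]]],
    summaries: list[GeneMethylationSummary],
    feature_values: dict[str, pd.Series],
    species: str | None = None,
) -> WithinOGContrast:
    """Compare gene features between 6mA and non-6mA genes pooled over the
    orthogroups that contain both classes.

    ``species`` restricts membership to one species' genes; by default all
    genes with summaries qualify.
    """
    status = {s.gene_id: s.is_methylated for s in summaries}
    meth_genes: list[str] = []
    non_genes: list[str] = []
    n_ogs = 0
    for _, members in og_membership.items():
        if species is not None:
            genes = members.get(species, set())
        else:
            genes = set().union(*members.values()) if members else set()
        genes = {g for g in genes if g in status}
        m = [g for g in genes if status[g]]
        u = [g for g in genes if not status[g]]
        if m and u:
            n_ogs += 1
            meth_genes.extend(m)
            non_genes.extend(u)
    if n_ogs == 0:
        return WithinOGContrast(0, 0, 0, {}, reason="no orthogroup contains both classes")
    tests = {}
    for name, series in feature_values.items():
        x = series.reindex(meth_genes).dropna().to_numpy()
        y = series.reindex(non_genes).dropna().to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            tests[name] = mann_whitney_u(x, y)
    return WithinOGContrast(n_ogs, len(meth_genes), len(non_genes), tests)
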