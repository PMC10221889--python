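"""Conservation of 6mA across duplicate genes, orthogroups and orthologs.

A gene is "6mA-modified" here exactly when its gene body carries at least
one 6mA site (the body flag from :mod:`sixma.feature_annotation`); promoter
sites never confer the flag.  A homologous pair is *maintained* when both
genes carry the flag, *changed* when exactly one does, *neither* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sixma.feature_annotation import GeneMethylationSummary
from sixma.methylome_stats import (
    ChiSquareResult,
    DegenerateTableError,
    TwoSampleResult,
    chi_square,
    mann_whitney_u,
    quartile_bins,
)

PAIR_CLASSES = ("maintained", "changed", "neither")


def _status_map(summaries: list[GeneMethylationSummary]) -> dict[str, bool]:
    return {s.gene_id: s.is_methylated for s in summaries}


def combined_status(per_genome: dict[str, list[GeneMethylationSummary]]) -> dict[str, bool]:
    """A gene counts as 6mA-modified if methylated in ANY of the genomes."""
    status: dict[str, bool] = {}
    for summaries in per_genome.values():
        for s in summaries:
            status[s.gene_id] = status.get(s.gene_id, False) or s.is_methylated
    return status


# ---------------------------------------------------------------------------
# Duplication types


@dataclass
class DuplicationTypeFractions:
    table: pd.DataFrame  # index dup_type: n_genes, n_methylated, pct_methylated
    chi_square: ChiSquareResult | None
    degenerate_reason: str = ""


def duplication_type_fractions(
    dup_type: dict[str, str],
    status: dict[str, bool],
    types: tuple[str, ...] = (
        "singleton", "wgd_segmental", "dispersed", "proximal", "tandem", "orphan",
    ),
) -> DuplicationTypeFractions:
    """Percentage of 6mA-modified genes per duplication type, with an
    overall chi-square across types."""
    rows = []
    for t in types:
        genes = [g for g, tt in dup_type.items() if tt == t and g in status]
        n = len(genes)
        n_meth = sum(status[g] for g in genes)
        pct = 100.0 * n_meth / n if n else float("nan")
        rows.append((t, n, n_meth, pct))
    table = pd.DataFrame(
        rows, columns=["dup_type", "n_genes", "n_methylated", "pct_methylated"]
    ).set_index("dup_type")
    counts = np.array(
        [table["n_methylated"].to_numpy(),
         (table["n_genes"] - table["n_methylated"]).to_numpy()]
    )
    chi = None
    reason = ""
    try:
        chi = chi_square(counts)
    except DegenerateTableError as exc:
        reason = str(exc)
    return DuplicationTypeFractions(table, chi, reason)


# ---------------------------------------------------------------------------
# Pair classification


@dataclass
class PairClassification:
    pairs: pd.DataFrame  # gene1, gene2, dup_type (optional), pair_class
    per_type_table: pd.DataFrame | None  # maintained/changed counts per type
    per_type_chi_square: ChiSquareResult | None
    degenerate_reason: str = ""

    def class_counts(self) -> dict[str, int]:
        counts = self.pairs["pair_class"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in PAIR_CLASSES}


def classify_pairs(
    pairs: pd.DataFrame,
    status1: dict[str, bool],
    status2: dict[str, bool] | None = None,
    gene_cols: tuple[str, str] = ("gene1", "gene2"),
    type_col: str | None = "dup_type",
) -> PairClassification:
    """Partition homologous pairs into maintained / changed / neither.

    ``status2`` supplies the second gene's methylation flags when the two
    genes live in different species; by default both are looked up in
    ``status1``.  The class is symmetric in the two genes.
    """
    if status2 is None:
        status2 = status1
    c1, c2 = gene_cols
    missing = [
        (row[c1], row[c2]) for _, row in pairs.iterrows()
        if row[c1] not in status1 or row[c2] not in status2
    ]
    if missing:
        raise ValueError(
            f"{len(missing)} pairs lack methylation summaries, e.g. {missing[:3]}"
        )
    m1 = pairs[c1].map(status1).to_numpy(dtype=bool)
    m2 = pairs[c2].map(status2).to_numpy(dtype=bool)
    pair_class = np.where(m1 & m2, "maintained", np.where(m1 | m2, "changed", "neither"))
    out = pairs.copy()
    out["pair_class"] = pair_class
    per_type = None
    chi = None
    reason = ""
    if type_col is not None and type_col in out.columns:
        per_type = (
            out[out["pair_class"].isin(["maintained", "changed"])]
            .groupby([type_col, "pair_class"], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["maintained", "changed"], fill_value=0)
        )
        try:
            chi = chi_square(per_type.to_numpy().T)
        except DegenerateTableError as exc:
            reason = str(exc)
    return PairClassification(out, per_type, chi, reason)


# ---------------------------------------------------------------------------
# Best-hit ortholog pair selection


def select_best_hit_ortholog_pairs(
    hits: pd.DataFrame,
    og_membership: dict[str, dict[str, set[str]]],
    min_identity: float = 0.9,
    max_evalue: float = 1e-6,
    allow_fallback: bool = False,
) -> pd.DataFrame:
    """Closest ortholog pairs: per-query best BLAST hit within the same OG.

    Hits failing the identity/e-value filters are removed, the remaining top
    bitscore hit per query is taken (ties broken by higher identity, then
    lexicographic subject id), and the pair is kept only when query and
    subject share an orthogroup.  With ``allow_fallback`` the next-ranked
    in-OG hit is used when the best hit falls outside the query's OG.
    Deterministic regardless of input row order.
    """
    for col in ("query", "subject", "identity", "evalue", "bitscore"):
        if col not in hits.columns:
            raise ValueError(f"hits table missing column {col!r}")
    gene_to_ogs: dict[str, set[str]] = {}
    for og, members in og_membership.items():
        for genes in members.values():
            for g in genes:
                gene_to_ogs.setdefault(g, set()).add(og)
    passing = hits[(hits["identity"] > min_identity) & (hits["evalue"] < max_evalue)]
    rows = []
    n_tiebreaks = 0
    for query, sub in passing.groupby("query", sort=True):
        ranked = sub.sort_values(
            ["bitscore", "identity", "subject"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        top = ranked.iloc[0]
        if len(ranked) > 1 and ranked.iloc[1]["bitscore"] == top["bitscore"]:
            n_tiebreaks += 1
        q_ogs = gene_to_ogs.get(str(query), set())
        candidates = ranked if allow_fallback else ranked.iloc[:1]
        for _, hit in candidates.iterrows():
            shared = q_ogs & gene_to_ogs.get(str(hit["subject"]), set())
            if shared:
                rows.append(
                    (str(query), str(hit["subject"]), sorted(shared)[0],
                     float(hit["identity"]), float(hit["bitscore"]))
                )
                break
    out = pd.DataFrame(
        rows, columns=["gene_sp1", "gene_sp2", "og_id", "identity", "bitscore"]
    )
    out.attrs["n_tiebreaks"] = n_tiebreaks
    return out


# ---------------------------------------------------------------------------
# Ortholog maintenance and Ka/Ks contrast


@dataclass
class MaintenanceTest:
    table: pd.DataFrame  # 2x2: sp1 status x sp2 status
    chi_square: ChiSquareResult | None
    odds_ratio: float
    degenerate_reason: str = ""


def ortholog_maintenance_test(classified: PairClassification) -> MaintenanceTest:
    """2x2 test of species-2 6mA status conditioned on species-1 status.

    An odds ratio above 1 means orthologs of 6mA-modified genes are more
    often 6mA-modified themselves (epigenetic maintenance across species).
    """
    pairs = classified.pairs
    m1 = pairs["_m1"] if "_m1" in pairs.columns else None
    if m1 is None:
        raise ValueError("classification lacks per-gene status columns; "
                         "use classify_ortholog_pairs")
    m1 = pairs["_m1"].to_numpy(dtype=bool)
    m2 = pairs["_m2"].to_numpy(dtype=bool)
    tab = np.array(
        [[int(np.sum(m1 & m2)), int(np.sum(m1 & ~m2))],
         [int(np.sum(~m1 & m2)), int(np.sum(~m1 & ~m2))]]
    )
    table = pd.DataFrame(
        tab,
        index=pd.Index(["sp1_6mA", "sp1_non"], name="species1"),
        columns=pd.Index(["sp2_6mA", "sp2_non"], name="species2"),
    )
    a, b, c, d = tab.ravel()
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    chi = None
    reason = ""
    try:
        chi = chi_square(tab)
    except DegenerateTableError as exc:
        reason = str(exc)
    return MaintenanceTest(table, chi, float(odds), reason)


def classify_ortholog_pairs(
    pairs: pd.DataFrame,
    status_sp1: dict[str, bool],
    status_sp2: dict[str, bool],
) -> PairClassification:
    """Classify cross-species pairs and retain per-gene status columns."""
    cls = classify_pairs(
        pairs, status_sp1, status_sp2, gene_cols=("gene_sp1", "gene_sp2"), type_col=None
    )
    cls.pairs["_m1"] = cls.pairs["gene_sp1"].map(status_sp1).astype(bool)
    cls.pairs["_m2"] = cls.pairs["gene_sp2"].map(status_sp2).astype(bool)
    return cls


def kaks_contrast(classified: PairClassification) -> TwoSampleResult:
    """Mann-Whitney U of Ka/Ks: changed vs maintained pairs.

    Pairs with undefined Ka/Ks (Ks = 0) and 'neither' pairs are excluded.
    """
    pairs = classified.pairs
    if "ka_ks" not in pairs.columns:
        raise ValueError("pairs table lacks a ka_ks column")
    usable = pairs[pairs["ka_ks"].notna() & pairs["pair_class"].isin(["maintained", "changed"])]
    changed = usable.loc[usable["pair_class"] == "changed", "ka_ks"].to_numpy()
    maintained = usable.loc[usable["pair_class"] == "maintained", "ka_ks"].to_numpy()
    if len(changed) < 2 or len(maintained) < 2:
        raise ValueError("no testable pairs: need >=2 changed and >=2 maintained "
                         "pairs with defined Ka/Ks")
    return mann_whitney_u(changed, maintained)


# ---------------------------------------------------------------------------
# OG-size grouping


@dataclass
class OGSizeGrouping:
    quartile_table: pd.DataFrame | None  # per size-quartile % methylated
    quartile_chi: ChiSquareResult | None
    quartile_edges: np.ndarray | None
    small_split_table: pd.DataFrame | None  # <2 copies vs >=2 copies
    small_split_chi: ChiSquareResult | None
    monotone_decreasing: bool | None
    reason: str = ""


def og_size_grouping(
    og_membership: dict[str, dict[str, set[str]]],
    status: dict[str, bool],
    species: str | None = None,
) -> OGSizeGrouping:
    """% 6mA-modified genes grouped by orthogroup size (total copy number).

    Reports both quartile groups of OG size and the coarse '<2 copies vs
    more' split, since either reading of a small-family contrast is
    defensible; quartile edges are always included.
    """
    og_rows = []
    for og, members in og_membership.items():
        all_genes = set().union(*members.values()) if members else set()
        size = len(all_genes)
        genes = members.get(species, set()) if species is not None else all_genes
        genes = {g for g in genes if g in status}
        if not genes:
            continue
        og_rows.append((og, size, genes))
    if not og_rows:
        return OGSizeGrouping(None, None, None, None, None, None,
                              reason="no orthogroups with summarised genes")
    sizes = np.array([r[1] for r in og_rows], dtype=float)

    def _tally(group_idx: np.ndarray, labels: list[str]) -> pd.DataFrame:
        rows = []
        for gi, lab in enumerate(labels):
            genes = set()
            for (og, size, gs), idx in zip(og_rows, group_idx):
                if idx == gi:
                    genes |= gs
            n = len(genes)
            n_meth = sum(status[g] for g in genes)
            rows.append((lab, n, n_meth, 100.0 * n_meth / n if n else float("nan")))
        return pd.DataFrame(
            rows, columns=["group", "n_genes", "n_methylated", "pct_methylated"]
        ).set_index("group")

    qt_table = qt_chi = edges = None
    monotone = None
    reason = ""
    try:
        bins, edges = quartile_bins(sizes)
        qt_table = _tally(bins, [f"Q{i + 1}" for i in range(4)])
        counts = np.array(
            [qt_table["n_methylated"].to_numpy(),
             (qt_table["n_genes"] - qt_table["n_methylated"]).to_numpy()]
        )
        try:
            qt_chi = chi_square(counts)
        except DegenerateTableError as exc:
            reason = str(exc)
        pct = qt_table["pct_methylated"].to_numpy()
        monotone = bool(np.all(np.diff(pct[~np.isnan(pct)]) <= 0))
    except ValueError as exc:
        reason = str(exc)
    small_idx = (sizes >= 2).astype(int)
    small_table = _tally(small_idx, ["lt2_copies", "ge2_copies"])
    small_chi = None
    try:
        counts = np.array(
            [small_table["n_methylated"].to_numpy(),
             (small_table["n_genes"] - small_table["n_methylated"]).to_numpy()]
        )
        small_chi = chi_square(counts)
    except DegenerateTableError as exc:
        reason = reason or str(exc)
    return OGSizeGrouping(qt_table, qt_chi, edges, small_table, small_chi, monotone, reason)
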