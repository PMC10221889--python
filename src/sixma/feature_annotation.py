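"""Genome partition into functional elements and per-gene 6mA summaries.

Two complementary views of the same annotation are produced:

* an *exclusive* partition (every base labelled exactly once, precedence
  exon > intron > promoter > intergenic) used for the site-distribution
  table, and
* *per-gene* summaries where a site may count for one gene's body and
  another gene's promoter simultaneously — overlapping roles are counted
  for every gene they touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from sixma.io_formats import (
    GeneModel,
    GenomeSequence,
    MethylationSiteSet,
    ValidationError,
)

INTERGENIC, PROMOTER, INTRON, EXON = 0, 1, 2, 3
LABEL_NAMES = {EXON: "exon", INTRON: "intron", PROMOTER: "promoter", INTERGENIC: "intergenic"}
FEATURE_ORDER = ("exon", "intron", "promoter", "intergenic")

DEFAULT_PROMOTER_LENGTH = 2000

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class FeaturePartition:
    """Per-chromosome base labels (uint8 codes, see ``LABEL_NAMES``)."""

    labels: dict[str, np.ndarray]
    promoter_length: int = DEFAULT_PROMOTER_LENGTH

    def label_at(self, chrom: str, pos: int) -> str:
        if chrom not in self.labels:
            return "intergenic"
        return LABEL_NAMES[int(self.labels[chrom][pos])]

    def base_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in FEATURE_ORDER}
        for arr in self.labels.values():
            binc = np.bincount(arr, minlength=4)
            for code, name in LABEL_NAMES.items():
                counts[name] += int(binc[code])
        return counts


@dataclass
class GeneMethylationSummary:
    """6mA tallies for one gene; 'body' is the unspliced gss..ges span."""

    gene_id: str
    n_6mA_body: int
    n_6mA_promoter: int

    @property
    def is_methylated(self) -> bool:
        return self.n_6mA_body >= 1

    @property
    def methylation_class(self) -> str:
        if self.n_6mA_body == 0:
            return "none"
        return "intermediate" if self.n_6mA_body <= 99 else "high"


@dataclass
class FeatureSiteCounts:
    counts: dict[str, int]
    fractions: dict[str, float]
    total: int
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(FEATURE_ORDER),
                "n_sites": [self.counts[f] for f in FEATURE_ORDER],
                "fraction": [self.fractions[f] for f in FEATURE_ORDER],
            }
        )


def partition_genome(
    genes: list[GeneModel],
    genome: GenomeSequence,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> FeaturePartition:
    """Label every base exon/intron/promoter/intergenic, exactly once.

    Features are painted in increasing precedence order so that where
    features of different genes overlap the highest-precedence label wins.
    """
    labels = {
        chrom: np.zeros(length, dtype=np.uint8)
        for chrom, length in genome.lengths.items()
    }
    for g in genes:
        if g.chrom not in labels:
            raise ValidationError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.end > len(labels[g.chrom]):
            raise ValidationError(f"gene {g.gene_id} extends beyond {g.chrom}")
    for g in genes:
        s, e = g.promoter(promoter_length, len(labels[g.chrom]))
        labels[g.chrom][s:e] = np.maximum(labels[g.chrom][s:e], PROMOTER)
    for g in genes:
        for s, e in g.introns():
            labels[g.chrom][s:e] = np.maximum(labels[g.chrom][s:e], INTRON)
    for g in genes:
        for s, e in g.exons:
            labels[g.chrom][s:e] = EXON
    return FeaturePartition(labels, promoter_length)


def assign_sites(sites: MethylationSiteSet, partition: FeaturePartition) -> FeatureSiteCounts:
    """Count sites per feature label; unannotated chromosomes are intergenic."""
    counts = {name: 0 for name in FEATURE_ORDER}
    for chrom, sub in sites.df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if chrom not in partition.labels:
            counts["intergenic"] += len(pos)
            continue
        binc = np.bincount(partition.labels[chrom][pos], minlength=4)
        for code, name in LABEL_NAMES.items():
            counts[name] += int(binc[code])
    total = sum(counts.values())
    if total == 0:
        return FeatureSiteCounts(counts, {n: 0.0 for n in FEATURE_ORDER}, 0, empty=True)
    return FeatureSiteCounts(
        counts, {n: counts[n] / total for n in FEATURE_ORDER}, total
    )


def summarize_genes(
    sites: MethylationSiteSet,
    genes: list[GeneModel],
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GeneMethylationSummary]:
    """Per-gene 6mA body and promoter counts (closed interval gss..ges).

    Counts are independent across genes: a site lying in gene A's body and
    gene B's promoter increments both.  Duplicate gene ids are an error.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene id {g.gene_id}")
        seen.add(g.gene_id)
    positions = sites.positions_by_chrom()
    out = []
    for g in genes:
        pos = positions.get(g.chrom)
        if pos is None or len(pos) == 0:
            out.append(GeneMethylationSummary(g.gene_id, 0, 0))
            continue
        n_body = int(
            np.searchsorted(pos, g.end, side="left")
            - np.searchsorted(pos, g.start, side="left")
        )
        chrom_len = (
            chrom_lengths[g.chrom]
            if chrom_lengths is not None
            else (int(pos[-1]) + promoter_length + 1)
        )
        ps, pe = g.promoter(promoter_length, chrom_len)
        n_prom = int(
            np.searchsorted(pos, pe, side="left") - np.searchsorted(pos, ps, side="left")
        )
        out.append(GeneMethylationSummary(g.gene_id, n_body, n_prom))
    return out


def summaries_to_frame(summaries: list[GeneMethylationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "n_6mA_body": [s.n_6mA_body for s in summaries],
            "n_6mA_promoter": [s.n_6mA_promoter for s in summaries],
            "is_methylated": [s.is_methylated for s in summaries],
            "methylation_class": [s.methylation_class for s in summaries],
        }
    ).set_index("gene_id")


def site_count_histogram(
    summaries: list[GeneMethylationSummary],
    bin_starts: tuple[int, ...] = (1, 5, 10, 50, 100),
) -> dict[str, int]:
    """Histogram of methylated genes by body-site count.

    ``bin_starts`` gives the lower edge of each bin; the last bin is
    open-ended.  Unmethylated genes are excluded.
    """
    edges = list(bin_starts) + [None]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{lo}-{hi - 1}" if hi is not None else f">={lo}")
    hist = {lab: 0 for lab in labels}
    for s in summaries:
        n = s.n_6mA_body
        if n < bin_starts[0]:
            continue
        for lab, lo, hi in zip(labels, edges[:-1], edges[1:]):
            if n >= lo and (hi is None or n < hi):
                hist[lab] += 1
                break
    return hist


def common_methylated_genes(
    per_genome_summaries: dict[str, list[GeneMethylationSummary]],
) -> dict[tuple[str, ...], int]:
    """Venn region counts over methylated-gene sets of several genomes.

    Returns counts of *exclusive* regions keyed by the sorted tuple of genome
    names whose sets (and only whose sets) contain the genes; all 2^k - 1
    regions are present and sum to the size of the union.
    """
    sets = {
        name: {s.gene_id for s in summaries if s.is_methylated}
        for name, summaries in per_genome_summaries.items()
    }
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set().union(*(sets[n] for n in names if n not in members)) if len(members) < len(names) else set()
            regions[members] = len(inside - outside)
    return regions


@dataclass
class FlankExtraction:
    sequences: list[str]
    n_skipped: int = 0
    site_ids: list[str] = field(default_factory=list)


def extract_flanks(
    sites: MethylationSiteSet, genome: GenomeSequence, k: int = 4
) -> FlankExtraction:
    """(2k+1)-mers centred on each methylated adenine, oriented to its strand.

    Minus-strand flanks are reverse-complemented so the output always reads
    5'->3' on the methylated strand with the A at index ``k``.  Sites within
    ``k`` of a chromosome end are skipped and counted.
    """
    seqs: list[str] = []
    ids: list[str] = []
    skipped = 0
    bad: list[str] = []
    for _, row in sites.df.iterrows():
        chrom, pos, strand = row["chrom"], int(row["pos"]), row["strand"]
        length = len(genome.chroms[chrom])
        if pos - k < 0 or pos + k + 1 > length:
            skipped += 1
            continue
        window = genome.chroms[chrom][pos - k : pos + k + 1]
        if strand == "-":
            window = window.encode().translate(_RC)[::-1].decode()
        if window[k] != "A":
            bad.append(f"{chrom}:{pos}:{strand}")
            continue
        seqs.append(window)
        ids.append(f"{chrom}:{pos}:{strand}")
    if bad:
        raise ValidationError(
            f"{len(bad)} sites whose centre base is not A after strand resolution: "
            + ", ".join(bad[:10])
        )
    return FlankExtraction(seqs, skipped, ids)


def write_flanks_fasta(flanks: FlankExtraction, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(flanks.site_ids, flanks.sequences):
            fh.write(f">{sid}\n{seq}\n")
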