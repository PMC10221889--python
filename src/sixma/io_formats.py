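"""Readers, writers and validated in-memory containers for every external format.

All internal coordinates are 0-based half-open.  BED input is already
0-based; GFF3 (1-based inclusive) is converted on read.  A methylated base
is always addressed by the 0-based reference position of the modified
nucleotide itself — for a minus-strand 6mA call that position carries a
``T`` in the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sixma")

VALID_5MC_CONTEXTS = ("CG", "CHG", "CHH")
DUP_TYPES = (
    "singleton",
    "wgd_segmental",
    "dispersed",
    "proximal",
    "tandem",
    "orphan",
)

COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


class FormatError(ValueError):
    """A malformed record in an external file."""


class ValidationError(ValueError):
    """A record inconsistent with the attached genome or with an invariant."""


# ---------------------------------------------------------------------------
# Genome


@dataclass
class GenomeSequence:
    """Uppercase chromosome sequences over the alphabet {A,C,G,T,N}."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        folded = {}
        for name, seq in self.chroms.items():
            if name in folded:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            folded[name] = seq.upper()
        self.chroms = folded
        self._arrays: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def as_array(self, chrom: str) -> np.ndarray:
        """Chromosome as a read-only uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            arr = np.frombuffer(self.chroms[chrom].encode("ascii"), dtype=np.uint8)
            self._arrays[chrom] = arr
        return self._arrays[chrom]

    def base_at(self, chrom: str, pos: int, strand: str = "+") -> str:
        base = self.chroms[chrom][pos]
        if strand == "-":
            base = base.encode().translate(COMPLEMENT).decode()
        return base

    def total_length(self) -> int:
        return sum(self.lengths.values())


def read_genome(path) -> GenomeSequence:
    chroms = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate chromosome {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise FormatError(f"no sequences found in {path}")
    return GenomeSequence(chroms)


def write_genome(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """A gene's span, strand and exon structure (0-based half-open).

    ``gss``/``ges`` are the strand-aware transcription start and end as
    0-based reference positions: on ``+`` the gene start site is ``start``;
    on ``-`` it is ``end - 1``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start must precede end")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValidationError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span or overlapping"
                )
            prev_end = e
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: at least one exon required")

    @property
    def gss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def ges(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_length(self) -> int:
        return self.length - self.exon_length

    def introns(self) -> list[tuple[int, int]]:
        out = []
        prev = self.start
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = e
        if self.end > prev:
            out.append((prev, self.end))
        return out

    def promoter(self, length: int, chrom_length: int) -> tuple[int, int]:
        """Strand-aware upstream window, clipped at chromosome ends."""
        if self.strand == "+":
            return max(0, self.start - length), self.start
        return self.end, min(chrom_length, self.end + length)


def read_gene_models(path) -> list[GeneModel]:
    """Parse GFF3 into gene models.

    When a gene carries several mRNAs the transcript with the longest total
    CDS defines the exon structure (ties broken by transcript id).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        if g.strand not in "+-":
            raise FormatError(f"gene {g.id}: missing or invalid strand {g.strand!r}")
        start, end = g.start - 1, g.end  # to 0-based half-open
        best = None  # (cds_length, transcript_id, exons)
        for mrna in db.children(g, featuretype="mRNA"):
            exons = [(e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")]
            cds_len = sum(c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS"))
            if not exons:
                exons = [(mrna.start - 1, mrna.end)]
            key = (cds_len, mrna.id)
            if best is None or key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = (cds_len, mrna.id, exons)
        if best is None:
            exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
            cds_len = sum(c.end - c.start + 1 for c in db.children(g, featuretype="CDS"))
            if not exons:
                exons = [(start, end)]
            best = (cds_len, g.id, exons)
        cds_len, _, exons = best
        for s, e in exons:
            if s < start or e > end:
                raise FormatError(
                    f"gene {g.id}: exon {s + 1}..{e} outside gene span {start + 1}..{end}"
                )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=start,
                end=end,
                exons=exons,
                cds_length=cds_len if cds_len else sum(e - s for s, e in exons),
            )
        )
    return genes


def write_gene_models(genes: list[GeneModel], path) -> None:
    """Emit gene/mRNA/exon/CDS records (1-based inclusive per GFF3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsixma\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsixma\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsixma\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
                fh.write(
                    f"{g.chrom}\tsixma\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# Methylation sites


@dataclass
class MethylationSiteSet:
    """Per-site modification calls for one modification class.

    The backing frame has columns ``chrom, pos, strand, mod_type, context,
    coverage`` and is kept sorted by ``(chrom, pos, strand)``.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "strand", "mod_type", "context", "coverage"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"site table missing columns {missing}")
        self.df = (
            self.df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mod_type(self) -> str:
        return self.df["mod_type"].iloc[0] if len(self.df) else "6mA"

    def positions_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted unique modified positions per chromosome (strands pooled)."""
        return {
            chrom: np.unique(sub["pos"].to_numpy(dtype=np.int64))
            for chrom, sub in self.df.groupby("chrom", sort=True)
        }

    def validate_against(self, genome: GenomeSequence) -> None:
        """Check positions in bounds and the modified base correct per strand."""
        bad: list[str] = []
        for _, row in self.df.iterrows():
            chrom, pos, strand, mod = row["chrom"], row["pos"], row["strand"], row["mod_type"]
            if chrom not in genome:
                bad.append(f"{chrom}:{pos} unknown chromosome")
                continue
            if pos >= len(genome.chroms[chrom]):
                bad.append(f"{chrom}:{pos} beyond chromosome end")
                continue
            base = genome.base_at(chrom, pos, strand)
            want = "A" if mod == "6mA" else "C"
            if base != want:
                bad.append(f"{chrom}:{pos}:{strand} base {base} is not {want}")
        if bad:
            head = "; ".join(bad[:10])
            raise ValidationError(f"{len(bad)} invalid sites: {head}")


def read_methylation_sites(path, mod_type: str, min_coverage: int) -> MethylationSiteSet:
    """Read a BED6(+1) site file, dropping records below ``min_coverage``.

    Columns: chrom, start, end (= start+1), name, coverage (score), strand,
    and for 5mC an optional 7th column giving the context (CG/CHG/CHH).
    """
    if mod_type not in ("6mA", "5mC"):
        raise ValueError(f"mod_type must be 6mA or 5mC, got {mod_type!r}")
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 fields, got {len(parts)}")
            chrom, start_s, end_s, _name, cov_s, strand = parts[:6]
            try:
                start, end, cov = int(start_s), int(end_s), int(float(cov_s))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate or coverage") from exc
            if end != start + 1:
                raise FormatError(f"{path}:{lineno}: end must equal start+1 for a single base")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            if mod_type == "5mC":
                if len(parts) < 7:
                    raise FormatError(f"{path}:{lineno}: 5mC record lacks context column")
                context = parts[6]
                if context not in VALID_5MC_CONTEXTS:
                    raise FormatError(f"{path}:{lineno}: unknown context token {context!r}")
            else:
                context = "NA"
            if cov < min_coverage:
                dropped += 1
                continue
            rows.append((chrom, start, strand, mod_type, context, cov))
    logger.info(
        "read %d %s sites from %s (%d dropped below %dx coverage)",
        len(rows), mod_type, path, dropped, min_coverage,
    )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "mod_type", "context", "coverage"]
    )
    if df.empty:
        df = df.astype({"pos": np.int64, "coverage": np.int64})
    return MethylationSiteSet(df, n_dropped=dropped)


def write_methylation_sites(sites: MethylationSiteSet, path) -> None:
    with open(path, "w") as fh:
        for _, row in sites.df.iterrows():
            fields = [
                row["chrom"], str(row["pos"]), str(row["pos"] + 1),
                row["mod_type"], str(row["coverage"]), row["strand"],
            ]
            if row["mod_type"] == "5mC":
                fields.append(row["context"])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM matrix with a designated focal tissue."""

    fpkm: pd.DataFrame
    focal_tissue: str = ""

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            dup = self.fpkm.index[self.fpkm.index.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate gene ids in expression matrix: {dup}")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValidationError("negative FPKM values")
        if not self.focal_tissue:
            self.focal_tissue = str(self.fpkm.columns[0])
        elif self.focal_tissue not in self.fpkm.columns:
            raise ValidationError(f"focal tissue {self.focal_tissue!r} not a column")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def n_tissues(self) -> int:
        return self.fpkm.shape[1]

    def focal_fpkm(self) -> pd.Series:
        return self.fpkm[self.focal_tissue]


def read_expression_matrix(path, focal_tissue: str = "") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(df.astype(float), focal_tissue=focal_tissue)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Homology tables


@dataclass
class HomologyTables:
    """Duplicate-type assignments, paralog pairs and cross-species ortholog pairs.

    ``ka_ks`` is NaN where ``ks == 0`` (undefined ratio); such pairs are
    retained but excluded from Ka/Ks contrasts downstream.
    """

    dup_type: dict[str, str]
    paralog_pairs: pd.DataFrame
    ortholog_pairs: pd.DataFrame
    og_membership: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, t in self.dup_type.items():
            if t not in DUP_TYPES:
                raise FormatError(f"unknown dup_type {t!r} for gene {g}")
        op = self.ortholog_pairs
        if len(op):
            if (op["ka"] < 0).any() or (op["ks"] < 0).any():
                raise ValidationError("negative Ka or Ks")
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(op["ks"] > 0, op["ka"] / op["ks"], np.nan)
            self.ortholog_pairs = op.assign(ka_ks=ratio)
        if self.og_membership:
            for _, row in self.ortholog_pairs.iterrows():
                og = row["og_id"]
                members = self.og_membership.get(og, {})
                all_members = set().union(*members.values()) if members else set()
                if row["gene_sp1"] not in all_members or row["gene_sp2"] not in all_members:
                    raise ValidationError(
                        f"ortholog pair ({row['gene_sp1']},{row['gene_sp2']}) "
                        f"not both members of {og}"
                    )


def read_homology_tables(dup_path, pair_path, ortho_path, og_path=None) -> HomologyTables:
    """Load the three (optionally four) homology TSVs.

    A gene listed twice in the duplicate-type table with conflicting types
    is an error; the orthogroup table, when given, has columns
    ``og_id, species, gene_id``.
    """
    dup_df = pd.read_csv(dup_path, sep="\t")
    dup_type: dict[str, str] = {}
    for _, row in dup_df.iterrows():
        g, t = str(row["gene_id"]), str(row["dup_type"])
        if g in dup_type and dup_type[g] != t:
            raise ValidationError(f"gene {g} assigned two dup types: {dup_type[g]}, {t}")
        dup_type[g] = t
    paralogs = pd.read_csv(pair_path, sep="\t")
    orthologs = pd.read_csv(ortho_path, sep="\t")
    for col in ("gene_sp1", "gene_sp2", "og_id", "ka", "ks"):
        if col not in orthologs.columns:
            raise FormatError(f"ortholog table missing column {col!r}")
    og_membership: dict[str, dict[str, set[str]]] = {}
    if og_path is not None:
        og_df = pd.read_csv(og_path, sep="\t")
        for _, row in og_df.iterrows():
            og_membership.setdefault(str(row["og_id"]), {}).setdefault(
                str(row["species"]), set()
            ).add(str(row["gene_id"]))
    else:
        for _, row in orthologs.iterrows():
            og = str(row["og_id"])
            og_membership.setdefault(og, {}).setdefault("sp1", set()).add(str(row["gene_sp1"]))
            og_membership[og].setdefault("sp2", set()).add(str(row["gene_sp2"]))
    return HomologyTables(
        dup_type=dup_type,
        paralog_pairs=paralogs,
        ortholog_pairs=orthologs,
        og_membership=og_membership,
    )
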