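"""Seeded generators for every pipeline input, with planted ground truth.

The generator emulates the structure of a plant 6mA methylome study at desk
scale: chromosome sequences with non-overlapping genes, a background 6mA
density around 1-1.5% of adenines, excess 6mA near gene start sites, a
per-gene 6mA rate coupled to expression, 5mC placed per sequence context
independently of 6mA, multi-tissue FPKM with controllable tissue
specificity, and homology tables with per-duplication-type 6mA maintenance
probabilities.  Every draw flows from a single seed; identical
configurations give byte-identical output files.

Methylation is independent per-base Bernoulli — no spatial clustering
beyond the planted positional factors — which is the simplest model
consistent with everything the downstream stages measure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sixma import io_formats
from sixma.io_formats import GeneModel, GenomeSequence, MethylationSiteSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass
class HomologyConfig:
    """Planted parameters for duplicate-gene and ortholog tables."""

    pairs_per_type: dict[str, int] = field(
        default_factory=lambda: {
            "wgd_segmental": 300, "tandem": 300, "dispersed": 200, "proximal": 200,
        }
    )
    # probability that a paralog pair keeps 6mA in both copies, given that
    # at least one copy is methylated
    maintenance_prob: dict[str, float] = field(
        default_factory=lambda: {
            "wgd_segmental": 0.6, "tandem": 0.3, "dispersed": 0.45, "proximal": 0.35,
        }
    )
    neither_fraction: float = 0.1
    n_singletons: int = 150
    n_orphans: int = 100
    # marginal methylation probability for unpaired genes, by type
    unpaired_meth_prob: dict[str, float] = field(
        default_factory=lambda: {"singleton": 0.7, "orphan": 0.2}
    )
    n_orthogroups: int = 500
    og_extra_copy_mean: float = 1.0
    og_base_meth_prob: float = 0.6
    og_meth_slope: float = 0.0  # decrease in meth prob per extra total copy
    ortholog_maintain_prob: float = 0.7  # P(sp2 6mA | sp1 6mA)
    ortholog_gain_prob: float = 0.4  # P(sp2 6mA | sp1 not)
    kaks_log_mu: float = float(np.log(0.2))
    kaks_log_sigma: float = 0.4
    kaks_changed_shift: float = 0.05
    ks_log_mu: float = float(np.log(0.5))
    ks_log_sigma: float = 0.3
    frac_ks_zero: float = 0.02
    hit_frac_low_identity: float = 0.05
    hit_frac_out_of_og: float = 0.05


@dataclass
class SimulationConfig:
    """All planted parameters of the synthetic study."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 400
    gc_content: float = 0.39
    mean_gene_length: int = 2000
    min_gene_length: int = 300
    mean_exon_count: float = 4.0
    n_tissues: int = 4
    fraction_tissue_specific: float = 0.3
    fraction_silent: float = 0.1
    base_6mA_rate: float = 0.015
    gss_enrichment_factor: float = 3.0
    gss_enrichment_window: int = 2000
    expression_link_slope: float = 0.5
    motif_preference: float = 1.0
    context_5mC_rates: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.05}
    )
    # absolute per-occurrence 6mA probability at adenines inside
    # methylated-C context triplets; None leaves the background model alone
    context_6mA_probs: dict[str, float] | None = None
    min_coverage_6mA: int = 10
    min_coverage_5mC: int = 5
    mean_extra_coverage: float = 15.0
    low_coverage_decoy_fraction: float = 0.1
    homology: HomologyConfig = field(default_factory=HomologyConfig)

    def validate(self) -> None:
        for name, p in (
            ("gc_content", self.gc_content),
            ("base_6mA_rate", self.base_6mA_rate),
            ("fraction_tissue_specific", self.fraction_tissue_specific),
            ("low_coverage_decoy_fraction", self.low_coverage_decoy_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_genes * self.mean_gene_length > 0.6 * self.total_length:
            raise ValueError(
                "capacity: n_genes * mean_gene_length exceeds 60% of the genome"
            )

    @property
    def total_length(self) -> int:
        return self.n_chromosomes * self.chromosome_length

    def manifest(self) -> dict:
        d = asdict(self)
        return d


def _spawn(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[index])


# ---------------------------------------------------------------------------
# Genome and genes


def simulate_genome_and_genes(cfg: SimulationConfig) -> tuple[GenomeSequence, list[GeneModel], dict]:
    """I.i.d. genome at the configured GC plus non-overlapping gene models."""
    cfg.validate()
    rng = _spawn(cfg.seed, 0)
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chroms = {}
    for i in range(cfg.n_chromosomes):
        codes = rng.choice(4, size=cfg.chromosome_length, p=probs)
        chroms[f"chr{i + 1}"] = _BASES[codes].tobytes().decode("ascii")
    genome = GenomeSequence(chroms)

    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    for ci, (chrom, n_here) in enumerate(zip(chroms, per_chrom)):
        if n_here == 0:
            continue
        shape = 4.0
        lengths = np.maximum(
            cfg.min_gene_length,
            rng.gamma(shape, cfg.mean_gene_length / shape, size=n_here).astype(int),
        )
        slack = cfg.chromosome_length - int(lengths.sum())
        if slack < n_here + 1:
            raise ValueError(f"{chrom}: gene lengths exceed chromosome capacity")
        gaps = rng.multinomial(slack - (n_here + 1), rng.dirichlet(np.ones(n_here + 1))) + 1
        pos = 0
        for gi in range(n_here):
            pos += int(gaps[gi])
            start, end = pos, pos + int(lengths[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = 1 + int(rng.poisson(max(cfg.mean_exon_count - 1, 0)))
            n_exons = min(n_exons, (end - start + 1) // 2)
            n_exons = max(n_exons, 1)
            if n_exons == 1:
                exons = [(start, end)]
            else:
                inner = rng.choice(
                    np.arange(start + 1, end), size=2 * (n_exons - 1), replace=False
                )
                cuts = np.sort(inner)
                bounds = [start, *cuts.tolist(), end]
                exons = [
                    (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_exons)
                ]
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_no:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds_length=sum(e - s for s, e in exons),
                )
            )
            pos = end
    manifest = {
        "seed": cfg.seed,
        "gc_content": cfg.gc_content,
        "n_genes": len(genes),
        "mean_gene_length": cfg.mean_gene_length,
    }
    return genome, genes, manifest


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    cfg: SimulationConfig, genes: list[GeneModel]
) -> tuple[io_formats.ExpressionMatrix, dict]:
    """Multi-tissue FPKM with a planted tissue-specific fraction.

    Three planted classes per gene: silent (all zero), tissue-specific (one
    dominant tissue, others zero) and broad (lognormal level shared across
    tissues with mild per-tissue noise).
    """
    if cfg.n_tissues < 2:
        raise ValueError("need at least two tissues")
    rng = _spawn(cfg.seed, 1)
    n = len(genes)
    classes = rng.choice(
        ["silent", "specific", "broad"],
        size=n,
        p=[
            cfg.fraction_silent,
            cfg.fraction_tissue_specific,
            1 - cfg.fraction_silent - cfg.fraction_tissue_specific,
        ],
    )
    mat = np.zeros((n, cfg.n_tissues))
    for i, cls in enumerate(classes):
        if cls == "silent":
            continue
        if cls == "specific":
            t = rng.integers(cfg.n_tissues)
            mat[i, t] = rng.lognormal(np.log(20), 1.0)
        else:
            base = rng.lognormal(np.log(5), 1.0)
            mat[i] = base * rng.lognormal(0.0, 0.25, size=cfg.n_tissues)
    tissues = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]
    df = pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=tissues)
    df.index.name = "gene_id"
    expr = io_formats.ExpressionMatrix(df, focal_tissue=tissues[0])
    manifest = {
        "true_class": dict(zip(df.index, classes.tolist())),
        "fraction_tissue_specific": cfg.fraction_tissue_specific,
        "fraction_silent": cfg.fraction_silent,
    }
    return expr, manifest


# ---------------------------------------------------------------------------
# Methylome


def _wtaak_plus_mask(arr: np.ndarray) -> np.ndarray:
    """Adenines whose 5-mer [p-3..p+1] on the plus strand matches WTAAK
    with the methylated A at the fourth position."""
    L = len(arr)
    m = np.zeros(L, dtype=bool)
    if L < 5:
        return m
    p = np.arange(3, L - 1)
    w = (arr[p - 3] == _A) | (arr[p - 3] == _T)
    t = arr[p - 2] == _T
    a1 = arr[p - 1] == _A
    a2 = arr[p] == _A
    k = (arr[p + 1] == _G) | (arr[p + 1] == _T)
    m[p] = w & t & a1 & a2 & k
    return m


def _wtaak_minus_mask(arr: np.ndarray) -> np.ndarray:
    """Reference-T positions that are the methylated A of a minus-strand
    WTAAK match (reference pattern M T T A W over [p-1..p+3])."""
    L = len(arr)
    m = np.zeros(L, dtype=bool)
    if L < 5:
        return m
    p = np.arange(1, L - 3)
    mm = (arr[p - 1] == _C) | (arr[p - 1] == _A)  # comp(K) = M
    t0 = arr[p] == _T
    t1 = arr[p + 1] == _T
    a = arr[p + 2] == _A
    w = (arr[p + 3] == _T) | (arr[p + 3] == _A)
    m[p] = mm & t0 & t1 & a & w
    return m


def _coverage(rng, n, min_cov, mean_extra, decoy_fraction):
    cov = min_cov + rng.poisson(mean_extra, size=n)
    if decoy_fraction > 0 and min_cov > 1:
        decoy = rng.random(n) < decoy_fraction
        cov[decoy] = rng.integers(1, min_cov, size=int(decoy.sum()))
    return cov


def simulate_methylome(
    cfg: SimulationConfig,
    genome: GenomeSequence,
    genes: list[GeneModel],
    expression: io_formats.ExpressionMatrix | None = None,
) -> tuple[MethylationSiteSet, MethylationSiteSet, dict]:
    """Draw 6mA and 5mC calls with the planted positional structure.

    Each adenine (either strand) is methylated independently with rate
    ``base_6mA_rate`` times the GSS-window, gene-expression and motif
    factors that apply to its position; 5mC is placed per context rate,
    positionally independent of 6mA.  Coverage is drawn above the read
    filter except for a planted fraction of low-coverage decoys.
    """
    if cfg.expression_link_slope != 0 and expression is None:
        raise ValueError("expression must be simulated first when the "
                         "expression link is active")
    rng = _spawn(cfg.seed, 2)
    fpkm = expression.focal_fpkm() if expression is not None else None
    a_rows = []
    c_rows = []
    for chrom in genome.chroms:
        arr = genome.as_array(chrom)
        L = len(arr)
        rate = np.full(L, cfg.base_6mA_rate)
        for g in genes:
            if g.chrom != chrom:
                continue
            if cfg.gss_enrichment_factor != 1.0:
                lo = max(0, g.gss - cfg.gss_enrichment_window)
                hi = min(L, g.gss + cfg.gss_enrichment_window + 1)
                rate[lo:hi] *= cfg.gss_enrichment_factor
            if cfg.expression_link_slope != 0 and fpkm is not None:
                x = np.log2(fpkm.get(g.gene_id, 0.0) + 1.0)
                factor = 2.0 / (1.0 + np.exp(-cfg.expression_link_slope * x))
                rate[g.start:g.end] *= factor
        rate = np.minimum(rate, 0.95)
        is_a_plus = arr == _A
        is_a_minus = arr == _T
        rate_plus = rate.copy()
        rate_minus = rate.copy()
        if cfg.motif_preference != 1.0:
            rate_plus[_wtaak_plus_mask(arr)] *= cfg.motif_preference
            rate_minus[_wtaak_minus_mask(arr)] *= cfg.motif_preference
            rate_plus = np.minimum(rate_plus, 0.95)
            rate_minus = np.minimum(rate_minus, 0.95)
        meth_plus = is_a_plus & (rng.random(L) < rate_plus)
        meth_minus = is_a_minus & (rng.random(L) < rate_minus)

        # 5mC by context; contexts classified on the cytosine's strand
        is_c_plus = arr == _C
        is_c_minus = arr == _G
        ctx_plus = np.full(L, -1, dtype=np.int8)
        ctx_minus = np.full(L, -1, dtype=np.int8)
        p = np.arange(0, L - 2)
        cg = arr[p + 1] == _G
        chg = ~cg & (arr[p + 2] == _G)
        ctx_plus[p[cg & is_c_plus[p]]] = 0
        ctx_plus[p[chg & is_c_plus[p]]] = 1
        chh = ~cg & ~chg
        ctx_plus[p[chh & is_c_plus[p]]] = 2
        q = np.arange(2, L)
        cg_m = arr[q - 1] == _C
        chg_m = ~cg_m & (arr[q - 2] == _C)
        chh_m = ~cg_m & ~chg_m
        ctx_minus[q[cg_m & is_c_minus[q]]] = 0
        ctx_minus[q[chg_m & is_c_minus[q]]] = 1
        ctx_minus[q[chh_m & is_c_minus[q]]] = 2
        ctx_names = ("CG", "CHG", "CHH")
        meth_c_plus = np.zeros(L, dtype=bool)
        meth_c_minus = np.zeros(L, dtype=bool)
        for code, name in enumerate(ctx_names):
            r = cfg.context_5mC_rates[name]
            meth_c_plus |= (ctx_plus == code) & (rng.random(L) < r)
            meth_c_minus |= (ctx_minus == code) & (rng.random(L) < r)

        if cfg.context_6mA_probs is not None:
            # plant occurrence-level 6mA probabilities at adenines inside
            # methylated-C triplets; both CHH adenines methylated together
            # so the CAmAm single-count rule is exercised
            for pos in np.flatnonzero(meth_c_plus):
                if pos + 2 >= L:
                    continue
                code = ctx_plus[pos]
                name = {0: "CGN", 1: "CHG", 2: "CHH"}[int(code)]
                if name == "CGN":
                    a_off = [pos + 2] if arr[pos + 2] == _A else []
                elif name == "CHG":
                    a_off = [pos + 1] if arr[pos + 1] == _A else []
                else:
                    a_off = [o for o in (pos + 1, pos + 2) if arr[o] == _A]
                if not a_off:
                    continue
                hit = rng.random() < cfg.context_6mA_probs[name]
                for o in a_off:
                    meth_plus[o] = hit
            for pos in np.flatnonzero(meth_c_minus):
                if pos - 2 < 0:
                    continue
                code = ctx_minus[pos]
                name = {0: "CGN", 1: "CHG", 2: "CHH"}[int(code)]
                if name == "CGN":
                    a_off = [pos - 2] if arr[pos - 2] == _T else []
                elif name == "CHG":
                    a_off = [pos - 1] if arr[pos - 1] == _T else []
                else:
                    a_off = [o for o in (pos - 1, pos - 2) if arr[o] == _T]
                if not a_off:
                    continue
                hit = rng.random() < cfg.context_6mA_probs[name]
                for o in a_off:
                    meth_minus[o] = hit

        for mask, strand in ((meth_plus, "+"), (meth_minus, "-")):
            pos_arr = np.flatnonzero(mask)
            cov = _coverage(rng, len(pos_arr), cfg.min_coverage_6mA,
                            cfg.mean_extra_coverage, cfg.low_coverage_decoy_fraction)
            for pp, cc in zip(pos_arr.tolist(), cov.tolist()):
                a_rows.append((chrom, pp, strand, "6mA", "NA", cc))
        for mask, ctx, strand in (
            (meth_c_plus, ctx_plus, "+"), (meth_c_minus, ctx_minus, "-"),
        ):
            pos_arr = np.flatnonzero(mask)
            cov = _coverage(rng, len(pos_arr), cfg.min_coverage_5mC,
                            cfg.mean_extra_coverage, cfg.low_coverage_decoy_fraction)
            for pp, cc in zip(pos_arr.tolist(), cov.tolist()):
                c_rows.append((chrom, pp, strand, "5mC", ctx_names[int(ctx[pp])], cc))

    cols = ["chrom", "pos", "strand", "mod_type", "context", "coverage"]
    a_sites = MethylationSiteSet(pd.DataFrame(a_rows, columns=cols))
    c_sites = MethylationSiteSet(pd.DataFrame(c_rows, columns=cols))
    manifest = {
        "base_6mA_rate": cfg.base_6mA_rate,
        "gss_enrichment_factor": cfg.gss_enrichment_factor,
        "gss_enrichment_window": cfg.gss_enrichment_window,
        "expression_link_slope": cfg.expression_link_slope,
        "motif_preference": cfg.motif_preference,
        "context_5mC_rates": cfg.context_5mC_rates,
        "context_6mA_probs": cfg.context_6mA_probs,
        "low_coverage_decoy_fraction": cfg.low_coverage_decoy_fraction,
        "n_6mA": len(a_sites),
        "n_5mC": len(c_sites),
    }
    return a_sites, c_sites, manifest


# ---------------------------------------------------------------------------
# Homology


@dataclass
class SimulatedHomology:
    dup_type: dict[str, str]
    paralog_pairs: pd.DataFrame
    ortholog_pairs: pd.DataFrame
    og_membership: dict[str, dict[str, set[str]]]
    hits: pd.DataFrame
    statuses: dict[str, dict[str, bool]]  # species -> gene -> 6mA flag
    manifest: dict


def simulate_homology(
    cfg: SimulationConfig,
    genes: list[GeneModel] | None = None,
    summaries=None,
) -> SimulatedHomology:
    """Duplicate-type, paralog, ortholog and BLAST-hit tables with planted
    maintenance probabilities.

    Without ``summaries`` the pair genes live in their own namespace and
    6mA statuses are drawn per type; with ``summaries`` (and ``genes``)
    duplicate types are assigned to real genome genes and statuses come
    from the measured methylome.
    """
    h = cfg.homology
    rng = _spawn(cfg.seed, 3)
    dup_type: dict[str, str] = {}
    status1: dict[str, bool] = {}
    pair_rows = []
    if summaries is not None and genes is not None:
        meas = {s.gene_id: s.is_methylated for s in summaries}
        ids = [g.gene_id for g in genes]
        rng.shuffle(ids)
        cursor = 0
        for t, n_pairs in h.pairs_per_type.items():
            n_pairs = min(n_pairs, (len(ids) - cursor) // 2)
            for _ in range(n_pairs):
                g1, g2 = ids[cursor], ids[cursor + 1]
                cursor += 2
                dup_type[g1] = t
                dup_type[g2] = t
                pair_rows.append((g1, g2, t))
        for t, n_unpaired in (("singleton", h.n_singletons), ("orphan", h.n_orphans)):
            take = min(n_unpaired, len(ids) - cursor)
            for g in ids[cursor:cursor + take]:
                dup_type[g] = t
            cursor += take
        status1 = {g: meas.get(g, False) for g in dup_type}
    else:
        for t, n_pairs in h.pairs_per_type.items():
            p_maint = h.maintenance_prob[t]
            for i in range(n_pairs):
                g1, g2 = f"sp1_{t}_{i:05d}a", f"sp1_{t}_{i:05d}b"
                dup_type[g1] = t
                dup_type[g2] = t
                pair_rows.append((g1, g2, t))
                u = rng.random()
                if u < h.neither_fraction:
                    s1 = s2 = False
                elif rng.random() < p_maint:
                    s1 = s2 = True
                else:
                    if rng.random() < 0.5:
                        s1, s2 = True, False
                    else:
                        s1, s2 = False, True
                status1[g1], status1[g2] = s1, s2
        for t, n_unpaired in (("singleton", h.n_singletons), ("orphan", h.n_orphans)):
            p = h.unpaired_meth_prob[t]
            for i in range(n_unpaired):
                g = f"sp1_{t}_{i:05d}"
                dup_type[g] = t
                status1[g] = bool(rng.random() < p)
    paralog_pairs = pd.DataFrame(pair_rows, columns=["gene1", "gene2", "dup_type"])

    # orthogroups across three species; the first sp1/sp2 members form the
    # closest ortholog pair with the planted conditional maintenance
    og_membership: dict[str, dict[str, set[str]]] = {}
    status2: dict[str, bool] = {}
    ortho_rows = []
    hit_rows = []
    expected_strict: list[str] = []
    for i in range(h.n_orthogroups):
        og = f"OG{i:05d}"
        members: dict[str, set[str]] = {}
        copies = {}
        for sp in ("sp1", "sp2", "sp3"):
            c = 1 + int(rng.poisson(h.og_extra_copy_mean))
            copies[sp] = c
            members[sp] = {f"{sp}_{og}_{j}" for j in range(c)}
        og_membership[og] = members
        total = sum(copies.values())
        p_og = float(np.clip(h.og_base_meth_prob - h.og_meth_slope * (total - 3), 0.05, 0.95))
        q1 = f"sp1_{og}_0"
        s1 = rng.random() < p_og
        status1[q1] = bool(s1)
        for g in sorted(members["sp1"] - {q1}):
            status1[g] = bool(rng.random() < p_og)
        o2 = f"sp2_{og}_0"
        p2 = h.ortholog_maintain_prob if s1 else h.ortholog_gain_prob
        s2 = rng.random() < p2
        status2[o2] = bool(s2)
        for g in sorted(members["sp2"] - {o2}):
            status2[g] = bool(rng.random() < p_og)
        # divergence statistics conditional on the pair's conservation class
        if s1 and s2:
            cls_shift = 0.0
        elif s1 or s2:
            cls_shift = h.kaks_changed_shift
        else:
            cls_shift = 0.0
        kaks = rng.lognormal(h.kaks_log_mu, h.kaks_log_sigma) + cls_shift
        if rng.random() < h.frac_ks_zero:
            ks = 0.0
            ka = rng.lognormal(h.kaks_log_mu + h.ks_log_mu, h.kaks_log_sigma)
        else:
            ks = rng.lognormal(h.ks_log_mu, h.ks_log_sigma)
            ka = kaks * ks
        ortho_rows.append((q1, o2, og, ka, ks, kaks if ks > 0 else np.nan))
        # BLAST-style hits for best-hit selection
        u = rng.random()
        ident = float(rng.uniform(0.91, 0.99))
        evalue = float(10 ** rng.uniform(-30, -10))
        bits = float(300 + 400 * ident + rng.normal(0, 5))
        if u < h.hit_frac_low_identity:
            hit_rows.append((q1, o2, 0.85, evalue, bits))
        elif u < h.hit_frac_low_identity + h.hit_frac_out_of_og:
            other = f"sp2_OG{(i + 1) % h.n_orthogroups:05d}_0"
            hit_rows.append((q1, other, ident, evalue, bits + 50))
            hit_rows.append((q1, o2, ident - 0.01, evalue, bits - 50))
        else:
            hit_rows.append((q1, o2, ident, evalue, bits))
            decoy = f"sp2_OG{(i + 2) % h.n_orthogroups:05d}_1"
            hit_rows.append((q1, decoy, float(rng.uniform(0.91, 0.95)), evalue * 10, bits - 120))
            expected_strict.append(q1)
    ortholog_pairs = pd.DataFrame(
        ortho_rows, columns=["gene_sp1", "gene_sp2", "og_id", "ka", "ks", "ka_ks"]
    )
    hits = pd.DataFrame(
        hit_rows, columns=["query", "subject", "identity", "evalue", "bitscore"]
    )
    manifest = {
        "maintenance_prob": h.maintenance_prob,
        "neither_fraction": h.neither_fraction,
        "ortholog_maintain_prob": h.ortholog_maintain_prob,
        "ortholog_gain_prob": h.ortholog_gain_prob,
        "kaks_changed_shift": h.kaks_changed_shift,
        "n_expected_strict_best_hits": len(expected_strict),
        "expected_strict_queries": expected_strict,
    }
    return SimulatedHomology(
        dup_type=dup_type,
        paralog_pairs=paralog_pairs,
        ortholog_pairs=ortholog_pairs,
        og_membership=og_membership,
        hits=hits,
        statuses={"sp1": status1, "sp2": status2},
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# One-call driver writing the full input directory


def simulate_all(cfg: SimulationConfig, outdir: str | Path | None = None) -> dict:
    """Run all four generators; optionally write every file format to disk.

    Returns a dict with the in-memory objects and the merged truth manifest.
    """
    genome, genes, man_g = simulate_genome_and_genes(cfg)
    expr, man_e = simulate_expression(cfg, genes)
    a_sites, c_sites, man_m = simulate_methylome(cfg, genome, genes, expr)
    hom = simulate_homology(cfg)
    manifest = {
        "config": cfg.manifest(),
        "genome": man_g,
        "expression": {k: v for k, v in man_e.items() if k != "true_class"},
        "methylome": man_m,
        "homology": {k: v for k, v in hom.manifest.items()
                     if k != "expected_strict_queries"},
    }
    result = {
        "genome": genome,
        "genes": genes,
        "expression": expr,
        "sites_6mA": a_sites,
        "sites_5mC": c_sites,
        "homology": hom,
        "expression_truth": man_e,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_formats.write_genome(genome, outdir / "genome.fa")
        io_formats.write_gene_models(genes, outdir / "genes.gff3")
        io_formats.write_methylation_sites(a_sites, outdir / "sites_6mA.bed")
        io_formats.write_methylation_sites(c_sites, outdir / "sites_5mC.bed")
        io_formats.write_expression_matrix(expr, outdir / "expression.tsv")
        pd.DataFrame(
            sorted(hom.dup_type.items()), columns=["gene_id", "dup_type"]
        ).to_csv(outdir / "dup_types.tsv", sep="\t", index=False)
        hom.paralog_pairs.to_csv(outdir / "paralog_pairs.tsv", sep="\t", index=False)
        hom.ortholog_pairs.to_csv(
            outdir / "ortholog_pairs.tsv", sep="\t", index=False, float_format="%.6g"
        )
        og_rows = [
            (og, sp, g)
            for og, members in sorted(hom.og_membership.items())
            for sp, gs in sorted(members.items())
            for g in sorted(gs)
        ]
        pd.DataFrame(og_rows, columns=["og_id", "species", "gene_id"]).to_csv(
            outdir / "og_membership.tsv", sep="\t", index=False
        )
        hom.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False, float_format="%.8g")
        for sp, status in hom.statuses.items():
            pd.DataFrame(
                sorted(status.items()), columns=["gene_id", "is_methylated"]
            ).to_csv(outdir / f"statuses_{sp}.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
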