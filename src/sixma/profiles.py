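"""Windowed methylation-occupancy profiles.

Occupancy in a window is the number of methylated bases divided by the
number of countable bases of the same letter.  By default adenines on both
strands are countable (reference ``A`` plus reference ``T``, the latter
being an adenine on the minus strand) and methylated calls on either strand
enter the numerator; a reference-strand-only mode is available.  Windows are
non-overlapping ("tumbling") of the stated size, one value per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sixma.io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomeSequence,
    MethylationSiteSet,
)

BOTH_STRANDS = "both_strands"
REFERENCE_ONLY = "reference_only"

_BASE_LETTERS = {
    ("A", BOTH_STRANDS): (ord("A"), ord("T")),
    ("A", REFERENCE_ONLY): (ord("A"),),
    ("C", BOTH_STRANDS): (ord("C"), ord("G")),
    ("C", REFERENCE_ONLY): (ord("C"),),
}


@dataclass
class OccupancyProfile:
    """Aggregated per-window counts around a set of oriented anchors.

    ``offsets`` are window midpoints relative to the anchor, negative =
    upstream in transcription orientation.  Windows with zero countable
    bases have occupancy NaN, never a silent zero.
    """

    anchor: str
    window_size: int
    offsets: np.ndarray
    methylated_counts: np.ndarray
    total_base_counts: np.ndarray
    n_anchors: int

    @property
    def occupancy(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            occ = self.methylated_counts / self.total_base_counts
        return np.where(self.total_base_counts > 0, occ, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "methylated": self.methylated_counts,
                "total": self.total_base_counts,
                "occupancy": self.occupancy,
            }
        )


@dataclass
class GeneScaledProfile:
    """Fixed-bp flanks plus a proportionally binned gene body."""

    gene_set_label: str
    window_size: int
    flank: int
    body_bins: int
    upstream_methylated: np.ndarray
    upstream_total: np.ndarray
    body_methylated: np.ndarray
    body_total: np.ndarray
    downstream_methylated: np.ndarray
    downstream_total: np.ndarray
    n_genes: int
    n_excluded: int = 0
    seed: int | None = None

    @staticmethod
    def _occ(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            occ = meth / total
        return np.where(total > 0, occ, np.nan)

    @property
    def upstream_occupancy(self) -> np.ndarray:
        return self._occ(self.upstream_methylated, self.upstream_total)

    @property
    def body_occupancy(self) -> np.ndarray:
        return self._occ(self.body_methylated, self.body_total)

    @property
    def downstream_occupancy(self) -> np.ndarray:
        return self._occ(self.downstream_methylated, self.downstream_total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg, meth, tot in (
            ("upstream", self.upstream_methylated, self.upstream_total),
            ("body", self.body_methylated, self.body_total),
            ("downstream", self.downstream_methylated, self.downstream_total),
        ):
            occ = self._occ(meth, tot)
            for i in range(len(meth)):
                rows.append((self.gene_set_label, seg, i, int(meth[i]), int(tot[i]), occ[i]))
        return pd.DataFrame(
            rows, columns=["set", "segment", "bin", "methylated", "total", "occupancy"]
        )


def _base_mask(genome: GenomeSequence, chrom: str, base: str, count_mode: str) -> np.ndarray:
    letters = _BASE_LETTERS[(base, count_mode)]
    arr = genome.as_array(chrom)
    mask = arr == letters[0]
    for code in letters[1:]:
        mask = mask | (arr == code)
    return mask


def _meth_mask(genome: GenomeSequence, sites: MethylationSiteSet) -> dict[str, np.ndarray]:
    """Boolean per-position methylation indicator (strands pooled)."""
    masks = {}
    for chrom, pos in sites.positions_by_chrom().items():
        if chrom not in genome:
            continue
        m = np.zeros(len(genome.chroms[chrom]), dtype=bool)
        m[pos] = True
        masks[chrom] = m
    return masks


def _prefix(mask: np.ndarray) -> np.ndarray:
    out = np.zeros(len(mask) + 1, dtype=np.int64)
    np.cumsum(mask, out=out[1:])
    return out


def anchor_occupancy_profile(
    sites: MethylationSiteSet,
    genome: GenomeSequence,
    anchors: list[tuple[str, int, str]],
    base: str = "A",
    window: int = 50,
    span: int = 2000,
    count_mode: str = BOTH_STRANDS,
    anchor_label: str = "anchor",
) -> OccupancyProfile:
    """Occupancy in tumbling windows over [-span, +span) around each anchor.

    Anchors are (chrom, 0-based position, orientation); for minus-oriented
    anchors offsets follow the transcription direction, so "downstream"
    means lower genomic coordinates.  Windows truncated by a chromosome end
    contribute only their in-bounds positions.
    """
    if span % window != 0:
        raise ValueError(f"span {span} not divisible by window {window}")
    n_win = 2 * span // window
    off_starts = -span + window * np.arange(n_win)
    meth_masks = _meth_mask(genome, sites)
    base_prefix: dict[str, np.ndarray] = {}
    meth_prefix: dict[str, np.ndarray] = {}
    total = np.zeros(n_win, dtype=np.int64)
    meth = np.zeros(n_win, dtype=np.int64)
    for chrom, pos, orient in anchors:
        if chrom not in base_prefix:
            base_prefix[chrom] = _prefix(_base_mask(genome, chrom, base, count_mode))
            mm = meth_masks.get(chrom)
            if mm is None:
                mm = np.zeros(len(genome.chroms[chrom]), dtype=bool)
            meth_prefix[chrom] = _prefix(mm)
        length = len(genome.chroms[chrom])
        if orient == "+":
            lo = pos + off_starts
            hi = lo + window
        else:
            # offset o maps to genomic pos - o; window [o, o+w) -> (pos-o-w, pos-o]
            hi = pos - off_starts + 1
            lo = hi - window
        lo = np.clip(lo, 0, length)
        hi = np.clip(hi, 0, length)
        bp = base_prefix[chrom]
        mp = meth_prefix[chrom]
        total += bp[hi] - bp[lo]
        meth += mp[hi] - mp[lo]
    return OccupancyProfile(
        anchor=anchor_label,
        window_size=window,
        offsets=off_starts + (window - 1) / 2.0,
        methylated_counts=meth,
        total_base_counts=total,
        n_anchors=len(anchors),
    )


def gene_anchors(genes: list[GeneModel], which: str = "GSS") -> list[tuple[str, int, str]]:
    """Oriented (chrom, pos, strand) anchors at gene start or end sites."""
    if which not in ("GSS", "GES"):
        raise ValueError("which must be GSS or GES")
    return [
        (g.chrom, g.gss if which == "GSS" else g.ges, g.strand) for g in genes
    ]


def cooccupancy_5mC_around_6mA(
    c_sites: MethylationSiteSet,
    a_sites: MethylationSiteSet,
    genome: GenomeSequence,
    window: int = 50,
    span: int = 2000,
    count_mode: str = BOTH_STRANDS,
) -> OccupancyProfile:
    """5mC occupancy (5mC / total C) in windows around every 6mA site.

    Under positional independence of the two marks the profile is flat at
    the global 5mC density.
    """
    anchors = [
        (row.chrom, int(row.pos), "+") for row in a_sites.df.itertuples()
    ]
    return anchor_occupancy_profile(
        c_sites, genome, anchors, base="C", window=window, span=span,
        count_mode=count_mode, anchor_label="site",
    )


def base_frequency_profile(
    genome: GenomeSequence,
    anchors: list[tuple[str, int, str]],
    base: str = "A",
    window: int = 50,
    span: int = 2000,
    count_mode: str = BOTH_STRANDS,
) -> OccupancyProfile:
    """Per-window base frequency (count of the base / in-bounds positions).

    Serves as the adenine-bias control for the anchor occupancy profiles.
    """
    if span % window != 0:
        raise ValueError(f"span {span} not divisible by window {window}")
    n_win = 2 * span // window
    off_starts = -span + window * np.arange(n_win)
    base_prefix: dict[str, np.ndarray] = {}
    count = np.zeros(n_win, dtype=np.int64)
    positions = np.zeros(n_win, dtype=np.int64)
    for chrom, pos, orient in anchors:
        if chrom not in base_prefix:
            base_prefix[chrom] = _prefix(_base_mask(genome, chrom, base, count_mode))
        length = len(genome.chroms[chrom])
        if orient == "+":
            lo = pos + off_starts
            hi = lo + window
        else:
            hi = pos - off_starts + 1
            lo = hi - window
        lo = np.clip(lo, 0, length)
        hi = np.clip(hi, 0, length)
        bp = base_prefix[chrom]
        count += bp[hi] - bp[lo]
        positions += hi - lo
    return OccupancyProfile(
        anchor="base_frequency",
        window_size=window,
        offsets=off_starts + (window - 1) / 2.0,
        methylated_counts=count,
        total_base_counts=positions,
        n_anchors=len(anchors),
    )


def gene_scaled_profile(
    sites: MethylationSiteSet,
    genome: GenomeSequence,
    genes: list[GeneModel],
    expression: ExpressionMatrix,
    flank: int = 5000,
    window: int = 100,
    body_bins: int = 60,
    fpkm_threshold: float = 1.0,
    random_control_size: int = 10000,
    seed: int = 0,
    count_mode: str = BOTH_STRANDS,
    high_inclusive: bool = True,
) -> dict[str, GeneScaledProfile]:
    """Metagene profiles (-flank..GSS | scaled body | GES..+flank) per gene set.

    Gene sets: ``high_expression`` (focal-tissue FPKM >= threshold, or > if
    ``high_inclusive`` is False), ``low_expression`` (the complement), and a
    ``random_control`` of up to ``random_control_size`` genes drawn without
    replacement from all genes with the recorded ``seed``.  Genes shorter
    than twice the window are excluded from body mapping and counted.
    """
    if flank % window != 0:
        raise ValueError(f"flank {flank} not divisible by window {window}")
    fpkm = expression.focal_fpkm()
    have_expr = [g for g in genes if g.gene_id in fpkm.index]
    if high_inclusive:
        high = [g for g in have_expr if fpkm[g.gene_id] >= fpkm_threshold]
    else:
        high = [g for g in have_expr if fpkm[g.gene_id] > fpkm_threshold]
    high_ids = {g.gene_id for g in high}
    low = [g for g in have_expr if g.gene_id not in high_ids]
    rng = np.random.default_rng(seed)
    n_ctl = min(random_control_size, len(have_expr))
    ctl_idx = rng.choice(len(have_expr), size=n_ctl, replace=False)
    control = [have_expr[i] for i in sorted(ctl_idx)]
    sets = {
        "high_expression": high,
        "low_expression": low,
        "random_control": control,
    }
    for label, gene_set in sets.items():
        if not gene_set:
            raise ValueError(f"gene set {label!r} is empty after filtering")
    meth_masks = _meth_mask(genome, sites)
    base_masks = {
        chrom: _base_mask(genome, chrom, "A", count_mode) for chrom in genome.chroms
    }
    out: dict[str, GeneScaledProfile] = {}
    n_flank_win = flank // window
    for label, gene_set in sets.items():
        up_m = np.zeros(n_flank_win, dtype=np.int64)
        up_t = np.zeros(n_flank_win, dtype=np.int64)
        dn_m = np.zeros(n_flank_win, dtype=np.int64)
        dn_t = np.zeros(n_flank_win, dtype=np.int64)
        bd_m = np.zeros(body_bins, dtype=np.int64)
        bd_t = np.zeros(body_bins, dtype=np.int64)
        excluded = 0
        for g in gene_set:
            if g.length < 2 * window:
                excluded += 1
                continue
            bmask = base_masks[g.chrom]
            mmask = meth_masks.get(g.chrom)
            if mmask is None:
                mmask = np.zeros(len(bmask), dtype=bool)
                meth_masks[g.chrom] = mmask
            length = len(bmask)
            # upstream of GSS / downstream of GES in transcription orientation
            if g.strand == "+":
                up_slice = (g.start - flank, g.start)
                dn_slice = (g.end, g.end + flank)
            else:
                up_slice = (g.end, g.end + flank)
                dn_slice = (g.start - flank, g.start)
            for (lo, hi), meth_acc, tot_acc, reverse in (
                (up_slice, up_m, up_t, g.strand == "-"),
                (dn_slice, dn_m, dn_t, g.strand == "-"),
            ):
                clo, chi = max(lo, 0), min(hi, length)
                if chi <= clo:
                    continue
                idx = np.arange(clo, chi)
                rel = idx - lo
                if reverse:
                    rel = (hi - lo - 1) - rel
                win_idx = rel // window
                tot_acc += np.bincount(win_idx, weights=bmask[clo:chi], minlength=n_flank_win).astype(np.int64)
                meth_acc += np.bincount(win_idx, weights=mmask[clo:chi], minlength=n_flank_win).astype(np.int64)
            # body: linear map of gss..ges onto body_bins bins
            body = np.arange(g.start, g.end)
            rel = body - g.start
            if g.strand == "-":
                rel = (g.length - 1) - rel
            bin_idx = (rel * body_bins) // g.length
            bd_t += np.bincount(bin_idx, weights=bmask[g.start:g.end], minlength=body_bins).astype(np.int64)
            bd_m += np.bincount(bin_idx, weights=mmask[g.start:g.end], minlength=body_bins).astype(np.int64)
        out[label] = GeneScaledProfile(
            gene_set_label=label,
            window_size=window,
            flank=flank,
            body_bins=body_bins,
            upstream_methylated=up_m,
            upstream_total=up_t,
            body_methylated=bd_m,
            body_total=bd_t,
            downstream_methylated=dn_m,
            downstream_total=dn_t,
            n_genes=len(gene_set) - excluded,
            n_excluded=excluded,
            seed=seed if label == "random_control" else None,
        )
    return out
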