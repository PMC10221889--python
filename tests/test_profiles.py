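"""Occupancy profiles against brute-force window oracles and planted signals."""

import numpy as np
import pytest

from sixma import profiles as pr
from sixma.io_formats import GeneModel, GenomeSequence, ExpressionMatrix
from tests.conftest import make_sites, random_genome
import pandas as pd


def brute_force_profile(genome, anchors, site_positions, base, window, span,
                        count_mode=pr.BOTH_STRANDS):
    """Per-base double loop: assign every offset to its window."""
    n_win = 2 * span // window
    total = np.zeros(n_win, dtype=int)
    meth = np.zeros(n_win, dtype=int)
    letters = {"A": "AT", "C": "CG"}[base] if count_mode == pr.BOTH_STRANDS else base
    meth_set = {(c, p) for c, ps in site_positions.items() for p in ps}
    for chrom, pos, orient in anchors:
        seq = genome.chroms[chrom]
        for off in range(-span, span):
            g = pos + off if orient == "+" else pos - off
            if g < 0 or g >= len(seq):
                continue
            w = (off + span) // window
            if seq[g] in letters:
                total[w] += 1
            if (chrom, g) in meth_set:
                meth[w] += 1
    return meth, total


class TestAnchorOccupancy:
    def test_site_at_plus75_lands_in_downstream_window_1(self):
        genome = GenomeSequence({"c": "A" * 1000})
        sites = make_sites([("c", 575, "+")])
        prof = pr.anchor_occupancy_profile(
            sites, genome, [("c", 500, "+")], window=50, span=100
        )
        # windows: [-100,-50), [-50,0), [0,50), [50,100); +75 is index 3
        assert prof.methylated_counts.tolist() == [0, 0, 0, 1]

    def test_minus_anchor_reflection(self):
        genome = GenomeSequence({"c": "A" * 1000})
        sites = make_sites([("c", 425, "+")])  # anchor-75 for a minus anchor at 500
        prof = pr.anchor_occupancy_profile(
            sites, genome, [("c", 500, "-")], window=50, span=100
        )
        assert prof.methylated_counts.tolist() == [0, 0, 0, 1]

    def test_fully_methylated_window_occupancy_one(self):
        genome = GenomeSequence({"c": "A" * 200})
        sites = make_sites([("c", p, "+") for p in range(100, 150)])
        prof = pr.anchor_occupancy_profile(
            sites, genome, [("c", 100, "+")], window=50, span=50
        )
        assert prof.occupancy[1] == 1.0

    def test_matches_brute_force_on_random_anchors(self, tiny_genome):
        rng = np.random.default_rng(12)
        anchors = [
            ("chr1", int(rng.integers(0, 10_000)), "+" if rng.random() < 0.5 else "-")
            for _ in range(30)
        ] + [("chr2", int(rng.integers(0, 8000)), "-") for _ in range(20)]
        rows = []
        for chrom, L in tiny_genome.lengths.items():
            seq = tiny_genome.chroms[chrom]
            for p in rng.choice(L, size=400, replace=False):
                p = int(p)
                if seq[p] == "A":
                    rows.append((chrom, p, "+"))
                elif seq[p] == "T":
                    rows.append((chrom, p, "-"))
        sites = make_sites(rows)
        prof = pr.anchor_occupancy_profile(
            sites, tiny_genome, anchors, window=50, span=500
        )
        meth, total = brute_force_profile(
            tiny_genome, anchors, sites.positions_by_chrom(), "A", 50, 500
        )
        assert prof.methylated_counts.tolist() == meth.tolist()
        assert prof.total_base_counts.tolist() == total.tolist()
        # total methylated equals sites within span of any anchor, per anchor
        assert prof.methylated_counts.sum() == meth.sum()

    def test_span_not_divisible_raises(self, tiny_genome):
        with pytest.raises(ValueError, match="divisible"):
            pr.anchor_occupancy_profile(
                make_sites([]), tiny_genome, [], window=30, span=100
            )

    def test_invariant_to_chromosome_renaming_and_order(self, tiny_genome):
        rng = np.random.default_rng(3)
        seq = tiny_genome.chroms["chr1"]
        rows = [("chr1", p, "+") for p in range(0, 9000, 37) if seq[p] == "A"]
        anchors = [("chr1", 4000, "+"), ("chr1", 7000, "-")]
        p1 = pr.anchor_occupancy_profile(make_sites(rows), tiny_genome, anchors)
        renamed = GenomeSequence({"zz": seq, "chr2": tiny_genome.chroms["chr2"]})
        rows2 = [("zz", p, s) for _, p, s in rng.permutation(rows).tolist()]
        rows2 = [(c, int(p), s) for c, p, s in rows2]
        p2 = pr.anchor_occupancy_profile(
            make_sites(rows2), renamed, [("zz", 4000, "+"), ("zz", 7000, "-")]
        )
        assert p1.methylated_counts.tolist() == p2.methylated_counts.tolist()
        assert p1.total_base_counts.tolist() == p2.total_base_counts.tolist()

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(8)
        genome = random_genome(rng, {"c": 5000})
        seq = genome.chroms["c"]
        L = len(seq)
        rows = []
        for p in rng.choice(L, size=150, replace=False):
            p = int(p)
            if seq[p] == "A":
                rows.append(("c", p, "+"))
            elif seq[p] == "T":
                rows.append(("c", p, "-"))
        anchors = [("c", 1500, "+"), ("c", 3500, "-")]
        p1 = pr.anchor_occupancy_profile(make_sites(rows), genome, anchors,
                                         window=50, span=500)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        genome_rc = GenomeSequence({"c": rc})
        rows_rc = [("c", L - 1 - p, "-" if s == "+" else "+") for _, p, s in rows]
        anchors_rc = [("c", L - 1 - p, "-" if s == "+" else "+") for _, p, s in anchors]
        p2 = pr.anchor_occupancy_profile(make_sites(rows_rc), genome_rc, anchors_rc,
                                         window=50, span=500)
        assert p1.methylated_counts.tolist() == p2.methylated_counts.tolist()
        assert p1.total_base_counts.tolist() == p2.total_base_counts.tolist()


class TestCooccupancy:
    def test_flat_under_independence(self):
        rng = np.random.default_rng(21)
        genome = random_genome(rng, {"c": 200_000})
        seq = genome.chroms["c"]
        arr = genome.as_array("c")
        a_pos = np.flatnonzero(arr == ord("A"))
        c_pos = np.flatnonzero((arr == ord("C")) | (arr == ord("G")))
        a_sites = make_sites(
            [("c", int(p), "+") for p in rng.choice(a_pos, 300, replace=False)]
        )
        density = 0.08
        chosen = c_pos[rng.random(len(c_pos)) < density]
        c_sites = make_sites(
            [("c", int(p), "+" if seq[p] == "C" else "-") for p in chosen],
            mod_type="5mC",
        )
        prof = pr.cooccupancy_5mC_around_6mA(c_sites, a_sites, genome,
                                             window=200, span=2000)
        occ = prof.occupancy
        se = np.sqrt(density * (1 - density) / prof.total_base_counts)
        assert np.all(np.abs(occ - density) < 4 * se)

    def test_zero_5mC_all_zero(self, tiny_genome):
        a_sites = make_sites([("chr1", 5000, "+")])
        prof = pr.cooccupancy_5mC_around_6mA(
            make_sites([], mod_type="5mC"), a_sites, tiny_genome
        )
        assert prof.methylated_counts.sum() == 0

    def test_planted_proximity_recovered(self):
        rng = np.random.default_rng(22)
        genome = random_genome(rng, {"c": 100_000})
        seq = genome.chroms["c"]
        arr = genome.as_array("c")
        a_pos = rng.choice(np.flatnonzero(arr == ord("A"))[20:-20], 200, replace=False)
        a_sites = make_sites([("c", int(p), "+") for p in a_pos])
        c_rows = []
        for p in a_pos:  # plant 5mC only within +-100 bp of each 6mA
            for q in range(max(0, p - 100), min(len(seq), p + 101)):
                if seq[q] in "CG" and rng.random() < 0.4:
                    c_rows.append(("c", q, "+" if seq[q] == "C" else "-"))
        prof = pr.cooccupancy_5mC_around_6mA(
            make_sites(c_rows, mod_type="5mC"), a_sites, genome,
            window=100, span=1000,
        )
        occ = prof.occupancy
        central = occ[9:11].mean()  # [-100,0) and [0,100)
        flanks = np.concatenate([occ[:5], occ[-5:]]).mean()
        # anchors ~500 bp apart on average, so flank windows still catch
        # 5mC planted around neighbouring sites; the centre must dominate
        assert central > 3 * max(flanks, 1e-9)


class TestBaseFrequency:
    def test_homopolymer_frequency_one(self):
        genome = GenomeSequence({"c": "A" * 5000})
        prof = pr.base_frequency_profile(genome, [("c", 2500, "+")], "A")
        assert np.all(prof.occupancy == 1.0)

    def test_uniform_genome_frequency_half_both_strands(self):
        # counting both strands, A+T letters ~ 0.5 of an equal-composition genome
        rng = np.random.default_rng(31)
        genome = random_genome(rng, {"c": 100_000}, p=(0.25, 0.25, 0.25, 0.25))
        anchors = [("c", int(p), "+") for p in rng.integers(3000, 97_000, size=40)]
        prof = pr.base_frequency_profile(genome, anchors, "A", window=50, span=2000)
        freq = prof.occupancy
        se = np.sqrt(0.25 / prof.total_base_counts)  # binomial, p=0.5
        assert np.all(np.abs(freq - 0.5) < 4 * se)

    def test_gc_patch_shows_dip_matching_oracle(self):
        seq = "AT" * 2000 + "GC" * 500 + "AT" * 2000
        genome = GenomeSequence({"c": seq})
        anchor = [("c", 4000, "+")]  # GC patch starts at 4000
        prof = pr.base_frequency_profile(genome, anchor, "A", window=100, span=1000)
        # oracle: direct count per window
        for i, start in enumerate(range(-1000, 1000, 100)):
            window_seq = seq[4000 + start : 4000 + start + 100]
            expect = sum(1 for ch in window_seq if ch in "AT") / len(window_seq)
            assert prof.occupancy[i] == pytest.approx(expect)


def _expr(gene_ids, values, tissue="t1"):
    return ExpressionMatrix(
        pd.DataFrame({tissue: values}, index=pd.Index(gene_ids, name="gene_id")),
        focal_tissue=tissue,
    )


class TestGeneScaledProfile:
    def test_planted_body_signal_in_high_expression_genes(self):
        rng = np.random.default_rng(41)
        genome = random_genome(rng, {"c": 300_000})
        seq = genome.chroms["c"]
        genes, fpkm, rows = [], [], []
        for i in range(60):
            start = 2500 + i * 4800
            end = start + 2400
            high = i % 2 == 0
            genes.append(GeneModel(f"g{i}", "c", "+", start, end, [(start, end)]))
            fpkm.append(10.0 if high else 0.1)
            body_rate, flank_rate = (0.09 if high else 0.03), 0.03
            for p in range(start - 2000, end + 2000):
                if p < 0 or p >= len(seq):
                    continue
                rate = body_rate if start <= p < end else flank_rate
                if seq[p] == "A" and rng.random() < rate:
                    rows.append(("c", p, "+"))
                elif seq[p] == "T" and rng.random() < rate:
                    rows.append(("c", p, "-"))
        profs = pr.gene_scaled_profile(
            make_sites(rows), genome, genes, _expr([g.gene_id for g in genes], fpkm),
            flank=2000, window=100, body_bins=20, seed=1,
        )
        hi, lo = profs["high_expression"], profs["low_expression"]
        assert np.all(hi.body_occupancy > lo.body_occupancy)
        assert hi.n_genes == 30 and lo.n_genes == 30

    def test_null_profiles_agree(self):
        rng = np.random.default_rng(42)
        genome = random_genome(rng, {"c": 200_000})
        seq = genome.chroms["c"]
        rows = []
        for p in range(len(seq)):
            if seq[p] == "A" and rng.random() < 0.05:
                rows.append(("c", p, "+"))
        genes = [
            GeneModel(f"g{i}", "c", "+", 3000 + i * 4000, 3000 + i * 4000 + 2000,
                      [(3000 + i * 4000, 3000 + i * 4000 + 2000)])
            for i in range(45)
        ]
        fpkm = [10.0 if i % 2 == 0 else 0.1 for i in range(45)]
        profs = pr.gene_scaled_profile(
            make_sites(rows), genome, genes, _expr([g.gene_id for g in genes], fpkm),
            flank=1000, window=100, body_bins=10, seed=0,
        )
        hi, lo = profs["high_expression"], profs["low_expression"]
        pooled = (hi.body_methylated + lo.body_methylated).sum() / (
            hi.body_total + lo.body_total
        ).sum()
        se = np.sqrt(pooled * (1 - pooled) * (1 / hi.body_total + 1 / lo.body_total))
        assert np.all(np.abs(hi.body_occupancy - lo.body_occupancy) < 4 * se)

    def test_single_gene_one_base_per_bin_matches_lookup(self):
        rng = np.random.default_rng(43)
        genome = random_genome(rng, {"c": 2000})
        seq = genome.chroms["c"]
        start, end, bins = 800, 1000, 200
        g = GeneModel("g1", "c", "+", start, end, [(start, end)])
        other = GeneModel("g2", "c", "+", 1400, 1800, [(1400, 1800)])
        rows = [("c", p, "+") for p in range(start, end) if seq[p] == "A"][:30]
        profs = pr.gene_scaled_profile(
            make_sites(rows), genome, [g, other], _expr(["g1", "g2"], [5.0, 0.1]),
            flank=400, window=100, body_bins=bins, seed=0,
        )
        prof = profs["high_expression"]
        meth_pos = {p for _, p, _ in rows}
        for b in range(bins):
            p = start + b
            assert prof.body_total[b] == (1 if seq[p] in "AT" else 0)
            assert prof.body_methylated[b] == (1 if p in meth_pos else 0)

    def test_short_genes_excluded_and_counted(self):
        rng = np.random.default_rng(44)
        genome = random_genome(rng, {"c": 20_000})
        genes = [
            GeneModel("short", "c", "+", 5000, 5100, [(5000, 5100)]),
            GeneModel("long", "c", "+", 8000, 10_000, [(8000, 10_000)]),
            GeneModel("low", "c", "+", 12_000, 14_000, [(12_000, 14_000)]),
        ]
        profs = pr.gene_scaled_profile(
            make_sites([]), genome, genes, _expr(["short", "long", "low"],
                                                 [5.0, 5.0, 0.1]),
            flank=1000, window=100, body_bins=10, seed=0,
        )
        assert profs["high_expression"].n_excluded == 1

    def test_empty_gene_set_raises(self):
        rng = np.random.default_rng(45)
        genome = random_genome(rng, {"c": 10_000})
        g = GeneModel("g1", "c", "+", 2000, 4000, [(2000, 4000)])
        with pytest.raises(ValueError, match="low_expression"):
            pr.gene_scaled_profile(
                make_sites([]), genome, [g], _expr(["g1"], [5.0]),
                flank=1000, window=100, body_bins=10, seed=0,
            )
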