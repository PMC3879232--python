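"""Promoter window arithmetic, repeat coverage against a per-base bitmap
oracle, the permutation null against exhaustive subset enumeration, GC
counting, and the Welch comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgsig.enrichment import (
    WindowSpec,
    five_prime_window,
    gc_comparison_test,
    gc_percent,
    permutation_enrichment,
    repeat_coverage,
)


def gene_row(gid, start, end, strand, chrom="chr1"):
    return {"gene_id": gid, "chrom": chrom, "start": start, "end": end, "strand": strand}


def bitmap_coverage(genes, repeats, w):
    """Per-base boolean-mask oracle for aggregate window coverage."""
    total = 0
    covered = 0
    for _, g in genes.iterrows():
        lo, hi, _ = five_prime_window(g, w)
        mask = np.zeros(hi - lo, dtype=bool)
        for _, r in repeats.iterrows():
            if r["chrom"] != g["chrom"]:
                continue
            s, e = max(r["start"], lo), min(r["end"], hi)
            if s < e:
                mask[s - lo : e - lo] = True
        total += hi - lo
        covered += int(mask.sum())
    return covered / total


class TestWindow:
    def test_plus_strand(self):
        g = gene_row("g", 10_000, 12_000, "+")
        assert five_prime_window(g, WindowSpec(2000, 500))[:2] == (8000, 10_500)

    def test_minus_strand_mirror(self):
        g = gene_row("g", 10_000, 12_000, "-")
        assert five_prime_window(g, WindowSpec(2000, 500))[:2] == (11_500, 14_000)

    def test_clipping_at_chromosome_start(self):
        g = gene_row("g", 1000, 2000, "+")
        lo, hi, clipped = five_prime_window(g, WindowSpec(2000, 500))
        assert (lo, hi, clipped) == (0, 1500, True)

    def test_clipping_at_chromosome_end(self):
        g = gene_row("g", 500, 900, "-")
        lo, hi, clipped = five_prime_window(g, WindowSpec(2000, 500), chrom_length=1000)
        assert (lo, hi, clipped) == (400, 1000, True)

    def test_undefined_strand_raises(self):
        with pytest.raises(ValueError):
            five_prime_window(gene_row("g", 0, 10, "."), WindowSpec(10, 10))


class TestCoverage:
    w = WindowSpec(100, 50)

    def repeats(self, rows, cls="LTR"):
        return pd.DataFrame(
            [{"chrom": c, "start": s, "end": e, "repeat_class": cls} for c, s, e in rows],
            columns=["chrom", "start", "end", "repeat_class"],
        )

    def genes(self):
        return pd.DataFrame(
            [
                gene_row("g1", 1000, 2000, "+"),
                gene_row("g2", 3000, 4000, "-"),
                gene_row("g3", 5000, 6000, "+"),
            ]
        )

    def test_no_repeats_zero(self):
        assert repeat_coverage(self.genes(), self.repeats([]), self.w, "LTR") == 0.0

    def test_fully_tiled_one(self):
        rows = [("chr1", 0, 10_000)]
        assert repeat_coverage(self.genes(), self.repeats(rows), self.w, "LTR") == 1.0

    def test_overlapping_repeats_match_bitmap_oracle(self):
        rows = [
            ("chr1", 920, 980),
            ("chr1", 950, 1040),  # overlaps the previous one
            ("chr1", 3950, 4080),
            ("chr1", 4900, 4910),
        ]
        repeats = self.repeats(rows)
        got = repeat_coverage(self.genes(), repeats, self.w, "LTR")
        assert got == pytest.approx(bitmap_coverage(self.genes(), repeats, self.w))

    def test_random_instances_match_bitmap_oracle(self, rng):
        genes = self.genes()
        for _ in range(10):
            starts = rng.integers(800, 6100, size=6)
            rows = [("chr1", int(s), int(s + rng.integers(5, 200))) for s in starts]
            repeats = self.repeats(rows)
            got = repeat_coverage(genes, repeats, self.w, "LTR")
            assert got == pytest.approx(bitmap_coverage(genes, repeats, self.w))

    def test_invariant_to_splitting_repeats_and_gene_order(self, rng):
        whole = self.repeats([("chr1", 900, 1040)])
        split = self.repeats([("chr1", 900, 960), ("chr1", 960, 1040)])
        genes = self.genes()
        shuffled = genes.sample(frac=1, random_state=1)
        assert repeat_coverage(genes, whole, self.w, "LTR") == pytest.approx(
            repeat_coverage(shuffled, split, self.w, "LTR")
        )

    def test_class_selectivity(self):
        rows = self.repeats([("chr1", 900, 1050)], cls="SINE")
        assert repeat_coverage(self.genes(), rows, self.w, "LTR") == 0.0
        assert repeat_coverage(self.genes(), rows, self.w, "SINE") > 0.0

    def test_no_genes_raises(self):
        with pytest.raises(ValueError):
            repeat_coverage(pd.DataFrame(columns=["gene_id"]), self.repeats([]), self.w, "LTR")


class TestPermutation:
    def setup_toy(self, coverages, w=WindowSpec(0, 100)):
        """One + strand gene per 1 kb slot; gene i's window has coverages[i]
        fraction covered by an LTR repeat."""
        genes = []
        repeats = []
        for i, c in enumerate(coverages):
            start = 1000 * i + 200
            genes.append(gene_row(f"g{i}", start, start + 500, "+"))
            if c > 0:
                repeats.append(
                    {
                        "chrom": "chr1",
                        "start": start,
                        "end": start + int(round(100 * c)),
                        "repeat_class": "LTR",
                    }
                )
        return (
            pd.DataFrame(genes),
            pd.DataFrame(repeats, columns=["chrom", "start", "end", "repeat_class"]),
            w,
        )

    def test_degenerate_target_equals_universe(self):
        genes, repeats, w = self.setup_toy([0.5, 0.2, 0.9])
        ids = list(genes["gene_id"])
        res = permutation_enrichment(ids, ids, genes, repeats, w, n_sets=50)
        assert res.p_value == 1.0

    def test_null_size_and_p_floor(self):
        genes, repeats, w = self.setup_toy([1.0] * 3 + [0.0] * 9)
        target = ["g0", "g1", "g2"]
        res = permutation_enrichment(
            target, list(genes["gene_id"]), genes, repeats, w,
            n_sets=200, rng_seed=1, exclude_target=True,
        )
        assert len(res.null_values) == 200
        assert res.p_value == pytest.approx(1 / 201)

    def test_matches_exhaustive_enumeration(self, rng):
        coverages = rng.uniform(0, 1, size=8).round(2)
        genes, repeats, w = self.setup_toy(coverages)
        ids = list(genes["gene_id"])
        target = ids[:3]
        res = permutation_enrichment(
            target, ids, genes, repeats, w, n_sets=4000, rng_seed=0
        )
        obs = res.observed
        exceed = 0
        total = 0
        for combo in itertools.combinations(range(8), 3):
            cov = float(np.mean([coverages[i] for i in combo]))
            exceed += cov >= obs - 1e-12
            total += 1
        exact_p = exceed / total
        assert res.p_value == pytest.approx(exact_p, abs=0.03)

    def test_reproducible_under_seed(self):
        genes, repeats, w = self.setup_toy([0.1, 0.9, 0.4, 0.6, 0.3])
        ids = list(genes["gene_id"])
        r1 = permutation_enrichment(ids[:2], ids, genes, repeats, w, n_sets=30, rng_seed=9)
        r2 = permutation_enrichment(ids[:2], ids, genes, repeats, w, n_sets=30, rng_seed=9)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.p_value == r2.p_value

    def test_target_outside_universe_raises(self):
        genes, repeats, w = self.setup_toy([0.1, 0.2])
        with pytest.raises(ValueError):
            permutation_enrichment(["gX"], ["g0", "g1"], genes, repeats, w, n_sets=5)


class TestGC:
    seqs = {"chr1": "ATATGCGCACGTNacgt"}

    def test_pure_at_and_gc(self):
        assert gc_percent({"c": "ATAT"}, "c", 0, 4) == 0.0
        assert gc_percent({"c": "GCGC"}, "c", 0, 4) == 100.0

    def test_ambiguous_bases_in_denominator_only(self):
        assert gc_percent({"c": "ACGTN"}, "c", 0, 5) == pytest.approx(40.0)

    def test_case_insensitive(self):
        assert gc_percent({"c": "acgt"}, "c", 0, 4) == pytest.approx(50.0)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            gc_percent(self.seqs, "chr1", 10, 100)

    def test_pyfaidx_source(self, tmp_path):
        import pyfaidx

        from mgsig.io import write_fasta

        path = tmp_path / "toy.fa"
        write_fasta({"chr1": "ACGT" * 30}, path)
        fa = pyfaidx.Fasta(str(path))
        assert gc_percent(fa, "chr1", 0, 40) == pytest.approx(50.0)


class TestGCComparison:
    def test_identical_groups(self):
        res = gc_comparison_test([40.0, 41.0, 42.0], [40.0, 41.0, 42.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        a, b = [40.0, 42.0, 44.0], [50.0, 52.0, 54.0]
        res = gc_comparison_test(a, b)
        # textbook Welch: t = (mean_a - mean_b) / sqrt(s2a/na + s2b/nb)
        s2a = np.var(a, ddof=1)
        s2b = np.var(b, ddof=1)
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(s2a / 3 + s2b / 3)
        assert res.t_statistic == pytest.approx(t_hand)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.direction == "lower"

    def test_label_swap_antisymmetry(self, rng):
        a = list(rng.normal(50, 2, size=10))
        b = list(rng.normal(47, 2, size=12))
        r1 = gc_comparison_test(a, b)
        r2 = gc_comparison_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_zero_variance(self):
        res = gc_comparison_test([50.0, 50.0], [50.0, 50.0])
        assert res.p_value == 1.0

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            gc_comparison_test([50.0], [40.0, 41.0])
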