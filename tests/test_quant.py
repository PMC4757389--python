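"""Quantification: read mapping, EM resolution of multi-mapping reads, TPM
arithmetic and its invariants, bootstrap CIs, ranking and histograms."""

import numpy as np
import pytest

from pherotome import synthetic
from pherotome.quant import (
    bootstrap_ci,
    effective_length,
    em_counts,
    log_likelihood,
    map_reads,
    quantify,
    summarize_expression,
    tpm,
    tpm_histogram,
)
from pherotome.readqc import Read


def _reads_from(seqs):
    return [Read(f"r{i}", s, [40] * len(s)) for i, s in enumerate(seqs)]


class TestMapReads:
    def test_error_free_read_finds_its_origin(self):
        pool = synthetic.make_pool(seed=0)
        contigs = [(t.id, t.nucleotide) for t in pool]
        reads, manifest = synthetic.simulate_reads(pool, 200, error_model="none", seed=0)
        cand_sets, n_unmapped = map_reads(reads, contigs)
        assert n_unmapped == 0
        ids = [cid for cid, _ in contigs]
        for cands, origin in zip(cand_sets, manifest["origin_id"]):
            assert ids.index(origin) in cands

    def test_duplicated_region_maps_to_both_contigs(self):
        rng = np.random.default_rng(1)
        shared = "".join(rng.choice(list("ACGT"), 80))
        a = shared + "".join(rng.choice(list("ACGT"), 100))
        b = "".join(rng.choice(list("ACGT"), 100)) + shared
        contigs = [("A", a), ("B", b)]
        read = _reads_from([shared[10:60]])
        cand_sets, _ = map_reads(read, contigs)
        assert cand_sets[0] == frozenset({0, 1})

    def test_reverse_strand_reads_map(self):
        from pherotome.util import revcomp

        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 200))
        cand_sets, _ = map_reads(_reads_from([revcomp(seq[40:90])]), [("A", seq)])
        assert cand_sets[0] == frozenset({0})

    def test_random_read_unmapped(self):
        # chance of a shared canonical 20-mer is ~ n * 4^-20: effectively zero
        pool = synthetic.make_pool(seed=3)
        contigs = [(t.id, t.nucleotide) for t in pool]
        rng = np.random.default_rng(3)
        reads = _reads_from(["".join(rng.choice(list("ACGT"), 50)) for _ in range(50)])
        _sets, n_unmapped = map_reads(reads, contigs)
        assert n_unmapped == 50

    def test_mismatch_budget(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 120))
        base = seq[30:80]

        def mutate(s, k):
            chars = list(s)
            for j in range(k):
                pos = 45 + j  # keep the seed region intact
                chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
            return "".join(chars)

        contigs = [("A", seq)]
        ok2, _ = map_reads(_reads_from([mutate(base, 2)]), contigs, max_mismatch=2)
        bad3, _ = map_reads(_reads_from([mutate(base, 3)]), contigs, max_mismatch=2)
        assert ok2[0] == frozenset({0}) and bad3[0] == frozenset()


class TestEm:
    def test_unique_reads_give_raw_counts(self):
        cand_sets = [frozenset({0})] * 7 + [frozenset({1})] * 3
        counts = em_counts(cand_sets, [100.0, 100.0])
        assert counts == pytest.approx([7.0, 3.0])

    def test_single_contig_gets_all_reads(self):
        counts = em_counts([frozenset({0})] * 12, [50.0])
        assert counts[0] == pytest.approx(12.0)

    def test_two_transcript_ambiguity_resolved_toward_evidence(self):
        """100 fully ambiguous reads + 10 unique to A: the EM fixed point of
        this instance (solved analytically: L = theta_A^10 is maximized at
        theta_A = 1) pushes all ambiguous mass to A."""
        cand_sets = [frozenset({0, 1})] * 100 + [frozenset({0})] * 10
        counts = em_counts(cand_sets, [200.0, 200.0])
        assert counts[0] > 100 + 10 - 1e-3  # A receives (almost) everything
        assert counts[0] + counts[1] == pytest.approx(110.0)

    def test_matches_grid_search_mle_on_two_transcripts(self):
        """EM theta must agree with a brute-force grid maximum-likelihood
        solution on 2-transcript instances with partial ambiguity."""
        eff = np.array([80.0, 160.0])
        for n_a, n_b, n_ab in [(30, 10, 60), (5, 5, 90), (50, 40, 10)]:
            cand_sets = (
                [frozenset({0})] * n_a + [frozenset({1})] * n_b + [frozenset({0, 1})] * n_ab
            )
            counts = em_counts(cand_sets, eff)
            theta_em = counts[0] / counts.sum()
            grid = np.linspace(1e-6, 1 - 1e-6, 100001)
            ll = (
                n_a * np.log(grid / eff[0])
                + n_b * np.log((1 - grid) / eff[1])
                + n_ab * np.log(grid / eff[0] + (1 - grid) / eff[1])
            )
            theta_grid = grid[np.argmax(ll)]
            assert theta_em == pytest.approx(theta_grid, abs=1e-3)

    def test_log_likelihood_non_decreasing_over_iterations(self):
        rng = np.random.default_rng(5)
        eff = np.array([60.0, 120.0, 240.0])
        cand_sets = [
            frozenset(rng.choice(3, size=int(rng.integers(1, 4)), replace=False).tolist())
            for _ in range(200)
        ]
        previous = None
        for iters in (1, 2, 4, 8, 16, 64):
            counts = em_counts(cand_sets, eff, max_iter=iters, tol=0.0)
            theta = counts / counts.sum()
            ll = log_likelihood(theta, cand_sets, eff)
            if previous is not None:
                assert ll >= previous - 1e-9
            previous = ll


class TestTpm:
    def test_closed_form_two_contigs(self):
        values = tpm([10.0, 10.0], [100.0, 200.0])
        assert values == pytest.approx([666666.67, 333333.33], rel=1e-6)

    def test_single_contig_is_million(self):
        assert tpm([5.0], [123.0])[0] == pytest.approx(1e6)

    def test_scale_invariance(self):
        a = tpm([3.0, 9.0, 1.0], [50.0, 70.0, 90.0])
        b = tpm([21.0, 63.0, 7.0], [50.0, 70.0, 90.0])
        assert a == pytest.approx(b)

    def test_all_zero_counts_stay_zero(self):
        assert tpm([0.0, 0.0], [10.0, 10.0]) == pytest.approx([0.0, 0.0])

    def test_sums_to_one_million_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            counts = rng.poisson(40, n).astype(float)
            if counts.sum() == 0:
                counts[0] = 1
            eff = rng.uniform(1, 500, n)
            assert tpm(counts, eff).sum() == pytest.approx(1e6, rel=1e-9)

    def test_effective_length_floor(self):
        assert effective_length(30, 50) == 1
        assert effective_length(149, 50) == 100


class TestBootstrap:
    def test_single_contig_ci_degenerate_at_million(self):
        ci = bootstrap_ci([frozenset({0})] * 40, [100.0], n_boot=50, seed=0)
        assert ci[0, 0] == pytest.approx(1e6) and ci[0, 1] == pytest.approx(1e6)

    def test_fixed_seed_reproducible(self):
        cand_sets = [frozenset({0})] * 30 + [frozenset({1})] * 10 + [frozenset({0, 1})] * 10
        a = bootstrap_ci(cand_sets, [100.0, 100.0], seed=7)
        b = bootstrap_ci(cand_sets, [100.0, 100.0], seed=7)
        assert np.array_equal(a, b)

    def test_ci_width_shrinks_with_read_depth(self):
        def width(n):
            cand_sets = [frozenset({0})] * (3 * n) + [frozenset({1})] * n
            ci = bootstrap_ci(cand_sets, [100.0, 100.0], n_boot=100, seed=8)
            return ci[0, 1] - ci[0, 0]

        assert width(1000) < width(100) / 2  # ~ sqrt(10) shrink expected


class TestSummaries:
    def test_activity_thresholds(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "contig_id": ["a", "b", "c"],
                "est_count": [1.0, 2.0, 3.0],
                "eff_len": [10.0, 10.0, 10.0],
                "tpm": [1.9, 2.0, 150.0],
                "ci_low": [0.0] * 3,
                "ci_high": [1e6] * 3,
            }
        )
        out = summarize_expression(df)
        assert int(out["active"].sum()) == 2
        assert int(out["highly_expressed"].sum()) == 1
        assert list(out["contig_id"]) == ["c", "b", "a"]

    def test_tied_tpm_ranked_by_contig_id(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "contig_id": ["z", "a", "m"],
                "est_count": [1.0] * 3,
                "eff_len": [10.0] * 3,
                "tpm": [5.0, 5.0, 5.0],
                "ci_low": [0.0] * 3,
                "ci_high": [0.0] * 3,
            }
        )
        out = summarize_expression(df)
        assert list(out["contig_id"]) == ["a", "m", "z"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_empty_record_set(self):
        import pandas as pd

        out = summarize_expression(
            pd.DataFrame(columns=["contig_id", "est_count", "eff_len", "tpm", "ci_low", "ci_high"])
        )
        assert out.empty

    def test_histogram_binning_scheme(self):
        bins = tpm_histogram([0.5, 1.2, 99.9, 100.5, 101.0, 250.0, 7000.0])
        assert (bins[0]["lo"], bins[0]["hi"]) == (0, 1)
        assert bins[0]["count"] == 1  # 0.5
        assert bins[1]["count"] == 1  # 1.2
        assert bins[99]["count"] == 1  # 99.9
        assert bins[100]["count"] == 1  # 100.5 falls in the last unit bin
        unit_bins = 101
        assert bins[unit_bins]["lo"] == 101 and bins[unit_bins]["hi"] == 201
        assert bins[unit_bins]["count"] == 1  # 101.0
        assert bins[unit_bins + 1]["count"] == 1  # 250.0 in [201, 301)
        assert bins[-1]["hi"] is None
        assert bins[-1]["count"] == 1  # 7000
        assert sum(b["count"] for b in bins) == 7


class TestParameterRecovery:
    def test_tpm_recovery_at_hundredfold_coverage(self):
        """On a >= 5-transcript pool at ~100x mean coverage with zero error,
        estimated TPM tracks truth: Pearson r >= 0.99 and every relative
        error <= 10%."""
        rng = np.random.default_rng(10)
        # geometric 4x spread keeps signal variance above counting noise
        weights = [0.5, 0.65, 0.85, 1.1, 1.5, 2.0]
        pool = []
        for i, w in enumerate(weights):
            protein = "".join(rng.choice(list("ADEFGHIKLNPQRSTVWY"), int(rng.integers(200, 280))))
            nt = synthetic.reverse_translate(protein, seed=100 + i, utr5=20, utr3=20)
            pool.append(synthetic.TranscriptRecord(f"t{i}", "decoy", protein, nt, w))
        total_len = sum(len(t.nucleotide) for t in pool)
        n_reads = int(100 * total_len / 50)
        reads, _manifest = synthetic.simulate_reads(
            pool, n_reads, error_model="none", seed=10
        )
        contigs = [(t.id, t.nucleotide) for t in pool]
        table = quantify(reads, contigs, read_len=50, n_boot=0)
        table = table.set_index("contig_id")
        w = np.array(weights)
        truth = {f"t{i}": t for i, t in enumerate(w / w.sum() * 1e6)}
        est = np.array([table.loc[k, "tpm"] for k in truth])
        true = np.array(list(truth.values()))
        r = np.corrcoef(est, true)[0, 1]
        assert r >= 0.99
        assert np.max(np.abs(est - true) / true) <= 0.10
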