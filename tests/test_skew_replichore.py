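"""GC skew, replichore inference, strand bias and GC-island calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from borgtools import (
    BorgSpec,
    elevated_gc_genes,
    gc_skew,
    infer_replichores,
    revcomp,
    simulate_borg_genome,
    strand_bias,
)
from borgtools.genome import decode
from borgtools.synthetic_data import _draw_codes


class TestGcSkew:
    def test_pure_g_window(self):
        prof = gc_skew("G" * 10, window=10, step=10)
        assert prof.skew.tolist() == [1.0]
        assert prof.cumulative[-1] == 10

    def test_alternating_gc_oscillates(self):
        prof = gc_skew("GC" * 20, window=10, step=2)
        assert np.all(prof.skew == 0.0)
        assert set(np.unique(prof.cumulative)) == {0, 1}

    def test_gc_free_windows_flagged_zero(self):
        prof = gc_skew("AT" * 20, window=10, step=10)
        assert np.all(prof.skew == 0.0) and np.all(prof.zero_gc_windows)

    def test_windowed_sums_conserve_cumulative_total(self, rng):
        seq = decode(_draw_codes(rng, 5_000, 0.5))
        prof = gc_skew(seq, window=100, step=100)  # non-overlapping tiling
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        per_window = []
        for s in range(0, 5_000, 100):
            w = seq[s : s + 100]
            per_window.append(w.count("G") - w.count("C"))
        assert sum(per_window) == prof.cumulative[-1]

    def test_revcomp_antisymmetry(self, rng):
        seq = decode(_draw_codes(rng, 3_000, 0.4, skew=0.2))
        fwd = gc_skew(seq, window=500, step=500)
        rev = gc_skew(revcomp(seq), window=500, step=500)
        assert np.allclose(rev.skew, -fwd.skew[::-1])

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            gc_skew("ACGT" * 100, window=0)
        with pytest.raises(ValueError):
            gc_skew("ACGT" * 10, window=1_000)


class TestInferReplichores:
    @staticmethod
    def _two_segment_seq(rng, L, T, strength=0.1, gc=0.33):
        a = _draw_codes(rng, T, gc, +strength)
        b = _draw_codes(rng, L - T, gc, -strength)
        return decode(np.concatenate([a, b]))

    def test_planted_boundary_recovered(self, rng):
        L, T = 120_000, 72_000  # 60/40 split: replichores of unequal length
        seq = self._two_segment_seq(rng, L, T)
        prof = infer_replichores(gc_skew(seq))
        assert prof.flag is None
        assert abs(prof.terminus - T) < 2_000
        assert prof.origin == (0, L)
        r1, r2 = prof.replichores
        assert (r1.start, r1.end, r1.leading_strand) == (0, prof.terminus, "+")
        assert (r2.start, r2.end, r2.leading_strand) == (prof.terminus, L, "-")

    def test_c_rich_then_g_rich_swaps_leading_strands(self, rng):
        L, T = 100_000, 40_000
        a = _draw_codes(rng, T, 0.33, -0.1)
        b = _draw_codes(rng, L - T, 0.33, +0.1)
        prof = infer_replichores(gc_skew(decode(np.concatenate([a, b]))))
        assert abs(prof.terminus - T) < 2_000
        assert [r.leading_strand for r in prof.replichores] == ["-", "+"]

    def test_monotone_cumulative_flagged_not_bidirectional(self, rng):
        seq = decode(_draw_codes(rng, 50_000, 0.33, +0.15))  # G-rich throughout
        prof = infer_replichores(gc_skew(seq))
        assert prof.flag == "not_bidirectional_from_ends"
        assert prof.replichores is None

    def test_flat_cumulative_flagged_no_signal(self, rng):
        seq = decode(_draw_codes(rng, 50_000, 0.33, 0.0))
        prof = infer_replichores(gc_skew(seq))
        assert prof.flag == "no_replichore_signal"

    def test_window_choice_moves_terminus_by_at_most_one_window(self, rng):
        L, T = 100_000, 55_000
        seq = self._two_segment_seq(rng, L, T)
        t1 = infer_replichores(gc_skew(seq, window=1_000, step=100)).terminus
        t2 = infer_replichores(gc_skew(seq, window=5_000, step=500)).terminus
        # terminus comes from the per-base cumulative curve: identical
        assert t1 == t2


class TestStrandBias:
    @staticmethod
    def _genes(rows):
        return pd.DataFrame(rows, columns=["start", "end", "strand"])

    def test_perfect_segregation(self):
        from borgtools.skew_replichore import Replichore

        rows = [(i * 100, i * 100 + 80, "+") for i in range(50)]
        rows += [(5_000 + i * 100, 5_000 + i * 100 + 80, "-") for i in range(50)]
        rep = strand_bias(self._genes(rows), [Replichore(0, 5_000, "+"), Replichore(5_000, 10_000, "-")])
        assert [b.fraction for b in rep.replichores] == [1.0, 1.0]
        assert rep.concordant is True

    def test_simulated_fidelity_within_binomial_error(self, rng):
        spec = BorgSpec(
            genome_length=200_000, itr_length=1_200, n_repeat_arrays=5,
            strand_fidelity=0.95, n_elevated_gc_genes=0, replichore_split=0.5,
        )
        _, genes, truth = simulate_borg_genome(spec, rng, "b")
        from borgtools.skew_replichore import Replichore

        reps = [Replichore(0, truth["terminus"], "+"), Replichore(truth["terminus"], 200_000, "-")]
        rep = strand_bias(genes, reps)
        for b in rep.replichores:
            se = 3 * np.sqrt(0.95 * 0.05 / b.n_genes)
            assert abs(b.fraction - 0.95) < se + 0.01
        assert rep.concordant is True

    def test_empty_replichore_reported_undefined(self):
        from borgtools.skew_replichore import Replichore

        rep = strand_bias(
            self._genes([(0, 50, "+")]), [Replichore(0, 100, "+"), Replichore(100, 200, "-")]
        )
        assert rep.replichores[1].n_genes == 0
        assert rep.replichores[1].fraction is None
        assert rep.concordant is None


class TestElevatedGcGenes:
    def test_planted_islands_all_recovered_with_calibrated_false_positives(self, rng):
        spec = BorgSpec(
            genome_length=300_000, itr_length=1_200, n_repeat_arrays=5,
            n_elevated_gc_genes=5, elevated_gc_delta=10.0,
        )
        genome, genes, truth = simulate_borg_genome(spec, rng, "b")
        table = elevated_gc_genes(genome, genes, z_threshold=2.0)
        flagged = set(table.loc[table["elevated"], "gene_id"])
        planted = set(truth["elevated_genes"])
        assert planted <= flagged  # +10 GC points is ~6 robust SDs: never missed
        # false positives bounded by the z=2 normal tail (with sampling slack)
        n_baseline = len(genes) - len(planted)
        p_tail = 0.0228
        bound = n_baseline * p_tail + 4 * np.sqrt(n_baseline * p_tail)
        assert len(flagged - planted) <= bound
        flagged_gc = table.loc[table["gene_id"].isin(planted), "gc"]
        assert np.allclose(flagged_gc, 0.43, atol=0.02)

    def test_uniform_composition_flags_within_null_rate(self, rng):
        seq = decode(_draw_codes(rng, 200_000, 0.4))
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(180)],
                "start": [i * 1_100 for i in range(180)],
                "end": [i * 1_100 + 1_000 for i in range(180)],
            }
        )
        table = elevated_gc_genes(seq, genes, z_threshold=2.0)
        assert table["elevated"].mean() <= 0.0455 + 4 * np.sqrt(0.0455 / 180)

    def test_identical_genes_flag_nothing(self):
        seq = "ACGT" * 5_000
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(12)],
                "start": [i * 1_000 for i in range(12)],
                "end": [i * 1_000 + 400 for i in range(12)],
            }
        )
        table = elevated_gc_genes(seq, genes)
        assert not table["elevated"].any()

    def test_errors_on_few_or_out_of_bounds_genes(self):
        seq = "ACGT" * 1_000
        few = pd.DataFrame({"gene_id": ["a"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            elevated_gc_genes(seq, few)
        bad = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(12)],
                "start": [i * 400 for i in range(12)],
                "end": [i * 400 + 300 for i in range(12)],
            }
        )
        with pytest.raises(ValueError):
            elevated_gc_genes(seq, bad)
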