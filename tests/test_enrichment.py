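"""Empirical p-values, reporting convention, permutation engine, gene bootstrap."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from xregenrich import (
    AnnotationTrack,
    ChromosomeModel,
    EnrichmentConfig,
    GeneSetEnrichment,
    GenomicInterval,
    RegionEnrichment,
    RegionSet,
    empirical_p,
    format_p,
    format_pct,
    geneset_bootstrap,
    load_pbc_methylation_genes,
    run_track_enrichment,
)

from conftest import random_track


class TestEmpiricalP:
    def test_equality_counts_as_extreme(self):
        pct, p = empirical_p(0, [0, 0, 0, 0])
        assert p == 1.0 and pct == 100.0

    def test_no_qualifying_iteration(self):
        pct, p = empirical_p(5, [1, 2, 3, 4])
        assert p == 0.0 and pct == 0.0

    def test_matches_loop_recount_on_poisson_null(self, rng):
        null = rng.poisson(8, size=1000)
        observed = 10
        pct, p = empirical_p(observed, null)
        k = sum(1 for c in null if c >= observed)
        assert p == k / 1000 and pct == 100 * k / 1000

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1, [])


class TestFormatting:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (245, 1000, "0.25"),
            (51, 1000, "0.05"),
            (465, 1000, "0.47"),
            (636, 1000, "0.64"),
            (0, 1000, "0.00"),
            (1000, 1000, "1.00"),
        ],
    )
    def test_fraction_to_p_string(self, k, n, expected):
        """Ties round away from zero on the exact rational, so .5 boundary
        fractions like 245/1000 print as 0.25, not bankers' 0.24."""
        assert format_p(Fraction(k, n)) == expected
        assert format_p(k / n) == expected  # float input recovers the rational

    @pytest.mark.parametrize(
        "k,n,expected", [(245, 1000, "24.5"), (51, 1000, "5.1"), (636, 1000, "63.6")]
    )
    def test_percent_formatting(self, k, n, expected):
        assert format_pct(Fraction(100 * k, n)) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            format_p(1.5)


def _small_setup(rng, n_elements=300, length=1_000_000):
    model = ChromosomeModel("chrX", length)
    query = RegionSet(
        "q",
        (
            GenomicInterval("chrX", 100_000, 130_000),
            GenomicInterval("chrX", 400_000, 420_000),
            GenomicInterval("chrX", 700_000, 750_000),
        ),
    )
    track = random_track(rng, n_elements, name="lncRNA", length=length, max_width=2_000,
                         element_class="lncRNA")
    return model, query, track


class TestRegionEnrichment:
    def test_empty_track_gives_p_one(self, rng):
        model, query, _ = _small_setup(rng)
        empty = AnnotationTrack("empty", "other", ())
        res = RegionEnrichment(query, [empty], model).fit(n_iter=50, seed=1)
        r = res.results[0]
        assert r.observed == 0 and r.null_mean == 0.0 and r.p_emp == 1.0

    def test_same_seed_reproduces_counts(self, rng):
        model, query, track = _small_setup(rng)
        a = RegionEnrichment(query, [track], model).fit(n_iter=100, seed=5)
        b = RegionEnrichment(query, [track], model).fit(n_iter=100, seed=5)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.results == b.results

    def test_shared_null_across_tracks(self, rng):
        """Per iteration all tracks see the same random set: a track tested
        alone yields the same null vector as tested alongside others."""
        model, query, track = _small_setup(rng)
        other = random_track(rng, 100, name="miRNA", length=1_000_000, max_width=100,
                             element_class="miRNA")
        alone = RegionEnrichment(query, [track], model).fit(n_iter=100, seed=5)
        together = RegionEnrichment(query, [track, other], model).fit(n_iter=100, seed=5)
        assert np.array_equal(alone.null_counts[0], together.null_counts[0])

    def test_p_equals_pct_over_100_and_stored_recount(self, rng):
        model, query, track = _small_setup(rng)
        res = RegionEnrichment(query, [track], model).fit(n_iter=200, seed=2)
        r = res.results[0]
        assert r.p_emp == pytest.approx(r.pct_ge / 100, abs=0)
        k = int((res.null_counts[0] >= r.observed).sum())
        assert r.p_emp == k / r.n_iter

    def test_observed_matches_standalone_count(self, rng):
        from xregenrich import count_overlapping_elements

        model, query, track = _small_setup(rng)
        res = RegionEnrichment(query, [track], model).fit(n_iter=10, seed=1)
        assert res.results[0].observed == count_overlapping_elements(track, query).count

    def test_conservative_estimator(self, rng):
        model, query, track = _small_setup(rng)
        cfg = EnrichmentConfig(n_iter=100, seed=3, conservative=True)
        res = RegionEnrichment(query, [track], model).fit(config=cfg)
        r = res.results[0]
        k = int((res.null_counts[0] >= r.observed).sum())
        assert r.p_emp == (k + 1) / 101

    def test_null_sd_uses_sample_denominator(self, rng):
        model, query, track = _small_setup(rng)
        res = RegionEnrichment(query, [track], model).fit(n_iter=50, seed=4)
        assert res.results[0].null_sd == pytest.approx(
            float(np.std(res.null_counts[0], ddof=1))
        )

    def test_functional_wrapper_and_order(self, rng):
        model, query, track = _small_setup(rng)
        other = random_track(rng, 50, name="z", length=1_000_000)
        out = run_track_enrichment(
            query, [track, other], model, EnrichmentConfig(n_iter=20, seed=1)
        )
        assert [r.track_name for r in out] == [track.name, other.name]

    def test_query_off_model_chromosome_rejected(self, rng):
        model, query, track = _small_setup(rng)
        bad = RegionSet("q", (GenomicInterval("chr7", 0, 100),))
        with pytest.raises(ValueError):
            RegionEnrichment(bad, [track], model)

    def test_summary_and_table_round_trip(self, rng):
        model, query, track = _small_setup(rng)
        res = RegionEnrichment(query, [track], model).fit(n_iter=100, seed=8)
        table = res.to_table()
        assert list(table["Set"]) == [
            "query", "random mean", "random SD", "% >= observed", "p value",
        ]
        r = res.results[0]
        k = int((res.null_counts[0] >= r.observed).sum())
        assert table[f"{r.track_name} (n)"].iloc[4] == format_p(Fraction(k, 100))
        assert "width/count-matched" in res.summary()

    def test_json_sidecar(self, rng, tmp_path):
        import json

        model, query, track = _small_setup(rng)
        res = RegionEnrichment(query, [track], model).fit(n_iter=20, seed=8)
        path = tmp_path / "run.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["metadata"]["seed"] == 8
        assert payload["null_counts"][track.name] == res.null_counts[0].tolist()


class TestGeneSetBootstrap:
    def test_curated_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = GeneSetEnrichment(universe[:5], universe, universe).fit(n_iter=200, seed=1)
        assert res.result.p_emp == 1.0

    def test_zero_observed_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = GeneSetEnrichment(universe[:5], universe[10:14], universe[:10] + universe[10:]).fit(
            n_iter=100, seed=1
        )
        # candidates g0..g4, curated g10..g13: overlap 0 -> every draw >= 0
        assert res.result.observed_overlap == 5 - 5  # no shared genes
        assert res.result.p_emp == 1.0

    def test_converges_to_exact_hypergeometric_tail(self):
        """10-gene universe, curated 4, candidates 5 with observed overlap 4:
        the Monte-Carlo p lands within 3 SEs of the tail computed by
        exhaustive enumeration of all C(10,5) = 252 subsets."""
        universe = [f"g{i}" for i in range(10)]
        curated = universe[:4]
        candidates = universe[:4] + [universe[9]]
        n_iter = 20_000
        res = GeneSetEnrichment(candidates, curated, universe).fit(n_iter=n_iter, seed=7)
        assert res.result.observed_overlap == 4

        cur = set(curated)
        tail = sum(
            1 for sub in itertools.combinations(universe, 5) if len(cur & set(sub)) >= 4
        ) / 252
        se = np.sqrt(tail * (1 - tail) / n_iter)
        assert abs(res.result.p_emp - tail) <= 3 * se

        # scipy's hypergeometric as a second, closed-form cross-check
        from scipy import stats

        assert tail == pytest.approx(stats.hypergeom.sf(3, 10, 4, 5))

    def test_out_of_universe_genes_dropped_with_warning(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="not in the universe"):
            m = GeneSetEnrichment(universe[:3] + ["ALIEN"], universe[:2], universe)
        assert m.candidates == [g.upper() for g in universe[:3]]

    def test_case_normalisation_and_dedup(self):
        universe = ["TP53", "brca1", "Pten"]
        m = GeneSetEnrichment(["tp53", "TP53"], ["BRCA1"], universe)
        assert m.candidates == ["TP53"]
        assert m.observed_overlap == 0

    def test_with_replacement_flag_runs(self):
        universe = [f"g{i}" for i in range(30)]
        res = GeneSetEnrichment(universe[:5], universe[:3], universe).fit(
            n_iter=500, seed=2, with_replacement=True
        )
        assert 0 <= res.result.p_emp <= 1

    def test_functional_wrapper(self):
        universe = [f"g{i}" for i in range(30)]
        r = geneset_bootstrap(
            universe[:5], universe[2:8], universe, EnrichmentConfig(n_iter=100, seed=1)
        )
        assert r.observed_overlap == 3 and r.n_universe == 30

    def test_determinism(self):
        universe = [f"g{i}" for i in range(50)]
        a = GeneSetEnrichment(universe[:8], universe[4:12], universe).fit(n_iter=300, seed=9)
        b = GeneSetEnrichment(universe[:8], universe[4:12], universe).fit(n_iter=300, seed=9)
        assert np.array_equal(a.null_overlaps, b.null_overlaps)


def test_packaged_curated_gene_list():
    genes = load_pbc_methylation_genes()
    assert genes == [
        "PIN4", "NHS", "IL1RAPL2", "SHROOM2", "ATP6AP2",
        "PQBP1", "MAGEB2", "NSDHL", "PIM2",
    ]
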