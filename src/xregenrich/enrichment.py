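"""Permutation enrichment engine and bootstrap gene-set test.

Two model classes, each following the model/results idiom of statistical
modelling packages:

* :class:`RegionEnrichment` — observed annotation-element overlap counts in
  a query region set versus a width/count-matched random-region null.
  ``fit()`` generates ONE shared null ensemble, evaluates every track
  against the same random set in each iteration, and returns a
  :class:`RegionEnrichmentResults` carrying per-track observed counts, null
  mean/SD, the percent of iterations with the same-or-larger count, and the
  empirical p-value.

* :class:`GeneSetEnrichment` — overlap of a candidate gene list with a
  curated list, versus candidate-set-sized draws from a gene universe.

The empirical p-value is the fraction of null iterations whose statistic is
at least as large as the observed one (the comparison includes equality):
``p = k/n`` with ``k = #{null >= observed}``.  The published convention
rounds this fraction with ties away from zero on the exact rational —
245/1000 prints as 0.25, 465/1000 as 0.47 — which binary-float bankers'
rounding would break; :func:`format_p` implements it.  A conservative
``(k+1)/(n+1)`` estimator is available behind a flag and off by default.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationTrack,
    RegionSet,
    count_overlapping_elements,
    read_bed,
    read_bed_regions,
)
from .regions import RegionSummary, summarize_region_set
from .sampling import ChromosomeModel, NullEnsemble, make_null_ensemble, read_chromosome_model
from .intervals import _overlap_mask, merge_intervals

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "GeneSetResult",
    "RegionEnrichment",
    "RegionEnrichmentResults",
    "GeneSetEnrichment",
    "GeneSetResults",
    "empirical_p",
    "format_p",
    "format_pct",
    "run_track_enrichment",
    "geneset_bootstrap",
    "load_pbc_methylation_genes",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Empirical p-value and its reporting convention
# ---------------------------------------------------------------------------

def empirical_p(observed: int, null_counts: Sequence[int]) -> tuple[float, float]:
    """Fraction of null iterations with a same-or-larger count.

    Returns ``(pct_ge, p_emp)`` where ``pct_ge = 100*k/n`` and
    ``p_emp = k/n`` with ``k = #{c in null_counts : c >= observed}``.
    """
    counts = np.asarray(null_counts)
    if counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    k = int(np.count_nonzero(counts >= observed))
    n = counts.size
    return 100.0 * k / n, k / n


def _round_fraction(frac: Fraction, decimals: int) -> str:
    """Decimal string of a non-negative rational, ties away from zero."""
    scaled = frac * 10**decimals
    q, r = divmod(scaled.numerator, scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    if decimals == 0:
        return str(q)
    return f"{q // 10**decimals}.{q % 10**decimals:0{decimals}d}"


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    # recover the exact k/n behind a binary float (n up to 1e7)
    return Fraction(value).limit_denominator(10_000_000)


def format_p(p_emp, decimals: int = 2) -> str:
    """Format an empirical p-value, rounding ties away from zero on the
    exact rational k/n (never on the binary float): 245/1000 -> "0.25",
    51/1000 -> "0.05", 465/1000 -> "0.47"."""
    frac = _as_fraction(p_emp)
    if not (0 <= frac <= 1):
        raise ValueError(f"p must lie in [0, 1], got {p_emp}")
    return _round_fraction(frac, decimals)


def format_pct(pct, decimals: int = 1) -> str:
    """Format a same-or-larger percentage (0..100) with the same exact-
    rational, ties-away-from-zero convention as :func:`format_p`."""
    frac = _as_fraction(pct)
    if not (0 <= frac <= 100):
        raise ValueError(f"percent must lie in [0, 100], got {pct}")
    return _round_fraction(frac, decimals)


# ---------------------------------------------------------------------------
# Configuration and result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the permutation test.

    n_iter : number of random region sets (published analysis used 1,000).
    seed : root PRNG seed; per-iteration substreams are derived from it.
    p_decimals / pct_decimals : reporting precision (2 and 1 as printed).
    conservative : report (k+1)/(n+1) instead of k/n.
    max_attempts / allow_overlap : forwarded to the null sampler.
    """

    n_iter: int = 1000
    seed: int = 1000
    p_decimals: int = 2
    pct_decimals: int = 1
    conservative: bool = False
    max_attempts: int = 10_000
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.p_decimals < 0 or self.pct_decimals < 0:
            raise ValueError("decimals must be >= 0")


@dataclass(frozen=True)
class EnrichmentResult:
    """The machine twin of one column of the published enrichment table."""

    track_name: str
    observed: int
    null_mean: float
    null_sd: float
    pct_ge: float
    p_emp: float
    n_iter: int
    seed: int


@dataclass(frozen=True)
class GeneSetResult:
    """Outcome of the bootstrap gene-set enrichment test."""

    n_candidates: int
    n_curated: int
    n_universe: int
    observed_overlap: int
    p_emp: float
    n_iter: int
    seed: int


# ---------------------------------------------------------------------------
# Region enrichment model
# ---------------------------------------------------------------------------

class RegionEnrichment:
    """Permutation test of annotation-element enrichment in a region set.

    Parameters
    ----------
    query : RegionSet
        The disease-associated regions (all on the model chromosome).
    tracks : sequence of AnnotationTrack
        Annotation classes to test (lncRNA, circRNA, miRNA, superenhancer...).
    model : ChromosomeModel
        The chromosome defining the null sampling space.
    """

    def __init__(
        self,
        query: RegionSet,
        tracks: Sequence[AnnotationTrack],
        model: ChromosomeModel,
    ):
        if query.n == 0:
            raise ValueError("query region set must be non-empty")
        if not tracks:
            raise ValueError("at least one annotation track is required")
        bad = [c for c in query.chroms if c != model.name]
        if bad:
            raise ValueError(
                f"query regions on {bad} but the chromosome model is {model.name!r}"
            )
        self.query = query
        self.tracks = list(tracks)
        self.model = model

    @classmethod
    def from_files(
        cls,
        query_bed,
        track_files: dict[str, object],
        chrom_tsv,
        exclusions_bed=None,
        track_classes: dict[str, str] | None = None,
    ) -> "RegionEnrichment":
        """Build the model from a query BED, named track BEDs and a
        chromosome TSV (name, length)."""
        query = read_bed_regions(query_bed, "query")
        classes = track_classes or {}
        tracks = [
            read_bed(path, name, classes.get(name, "other"))
            for name, path in track_files.items()
        ]
        model = read_chromosome_model(chrom_tsv, exclusions_bed)
        return cls(query, tracks, model)

    def _track_arrays(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per track: (starts, ends) of the elements on the model chromosome."""
        out = []
        for tr in self.tracks:
            ivs = [iv for _, iv in tr.elements if iv.chrom == self.model.name]
            out.append(
                (
                    np.fromiter((iv.start for iv in ivs), dtype=np.int64),
                    np.fromiter((iv.end for iv in ivs), dtype=np.int64),
                )
            )
        return out

    def fit(
        self,
        n_iter: int | None = None,
        seed: int | None = None,
        config: EnrichmentConfig | None = None,
    ) -> "RegionEnrichmentResults":
        """Run the permutation test.

        One shared null ensemble is generated and every track is evaluated
        against the same random set per iteration, mirroring a single
        "random sets" block shared across annotation classes.
        """
        cfg = config or EnrichmentConfig()
        if n_iter is not None or seed is not None:
            cfg = EnrichmentConfig(
                n_iter=n_iter if n_iter is not None else cfg.n_iter,
                seed=seed if seed is not None else cfg.seed,
                p_decimals=cfg.p_decimals,
                pct_decimals=cfg.pct_decimals,
                conservative=cfg.conservative,
                max_attempts=cfg.max_attempts,
                allow_overlap=cfg.allow_overlap,
            )
        ensemble = make_null_ensemble(
            self.model,
            self.query,
            cfg.n_iter,
            cfg.seed,
            max_attempts=cfg.max_attempts,
            allow_overlap=cfg.allow_overlap,
        )
        track_arrays = self._track_arrays()
        observed = [
            count_overlapping_elements(tr, self.query).count for tr in self.tracks
        ]
        null_counts = np.empty((len(self.tracks), cfg.n_iter), dtype=np.int64)
        for i in range(cfg.n_iter):
            reg_starts, reg_ends = ensemble._starts_sorted(i)
            if cfg.allow_overlap:
                reg_starts, reg_ends = _merge_sorted_arrays(reg_starts, reg_ends)
            for t, (el_starts, el_ends) in enumerate(track_arrays):
                if el_starts.size == 0:
                    null_counts[t, i] = 0
                else:
                    null_counts[t, i] = int(
                        _overlap_mask(el_starts, el_ends, reg_starts, reg_ends).sum()
                    )
        results = []
        for t, tr in enumerate(self.tracks):
            pct_ge, p_emp = empirical_p(observed[t], null_counts[t])
            if cfg.conservative:
                k = round(p_emp * cfg.n_iter)
                p_emp = (k + 1) / (cfg.n_iter + 1)
            results.append(
                EnrichmentResult(
                    track_name=tr.name,
                    observed=observed[t],
                    null_mean=float(null_counts[t].mean()),
                    null_sd=float(null_counts[t].std(ddof=1)) if cfg.n_iter > 1 else float("nan"),
                    pct_ge=pct_ge,
                    p_emp=p_emp,
                    n_iter=cfg.n_iter,
                    seed=cfg.seed,
                )
            )
        return RegionEnrichmentResults(
            model=self, config=cfg, results=results, null_counts=null_counts
        )


def _merge_sorted_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # union of position-sorted, possibly overlapping intervals
    out_s, out_e = [], []
    cs, ce = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= ce:
            ce = max(ce, int(e))
        else:
            out_s.append(cs)
            out_e.append(ce)
            cs, ce = int(s), int(e)
    out_s.append(cs)
    out_e.append(ce)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class RegionEnrichmentResults:
    """Fitted permutation-test results.

    Attributes
    ----------
    results : list of EnrichmentResult, in input track order.
    null_counts : int array of shape (n_tracks, n_iter) — the full null
        overlap-count vectors, one row per track, shared iteration axis.
    query_summary : RegionSummary of the query set.
    """

    def __init__(
        self,
        model: RegionEnrichment,
        config: EnrichmentConfig,
        results: list[EnrichmentResult],
        null_counts: np.ndarray,
    ):
        self.model = model
        self.config = config
        self.results = results
        self.null_counts = null_counts
        self.query_summary: RegionSummary = summarize_region_set(model.query)

    def result_for(self, track_name: str) -> EnrichmentResult:
        for r in self.results:
            if r.track_name == track_name:
                return r
        raise KeyError(track_name)

    def to_frame(self) -> pd.DataFrame:
        """Long-form results: one row per track."""
        return pd.DataFrame(
            {
                "track": [r.track_name for r in self.results],
                "observed": [r.observed for r in self.results],
                "null_mean": [r.null_mean for r in self.results],
                "null_sd": [r.null_sd for r in self.results],
                "pct_ge": [r.pct_ge for r in self.results],
                "p_emp": [r.p_emp for r in self.results],
            }
        )

    def to_table(self) -> pd.DataFrame:
        """Wide table mirroring the published layout: geometry columns plus
        one column per track; rows for the query set, the random-set mean,
        SD, percent same-or-larger and p-value."""
        qs = self.query_summary
        cfg = self.config
        cols: dict[str, list] = {
            "Set": ["query", "random mean", "random SD", "% >= observed", "p value"],
            "Regions (n)": [qs.n_regions, float(qs.n_regions), "-", "-", "-"],
            "Regions (kb)": [qs.mean_width_kb, qs.mean_width_kb, "-", "-", "-"],
            "DNA content (Mb)": [qs.total_width_mb, qs.total_width_mb, "-", "-", "-"],
        }
        for t, r in enumerate(self.results):
            k = int(np.count_nonzero(self.null_counts[t] >= r.observed))
            cols[f"{r.track_name} (n)"] = [
                r.observed,
                round(r.null_mean, 1),
                round(r.null_sd, 1),
                format_pct(Fraction(100 * k, r.n_iter), cfg.pct_decimals),
                format_p(Fraction(k, r.n_iter) if not cfg.conservative
                         else Fraction(k + 1, r.n_iter + 1), cfg.p_decimals),
            ]
        return pd.DataFrame(cols)

    def summary(self) -> str:
        """Human-readable report in the shape of the published table."""
        m = self.model.model
        head = (
            "Region enrichment vs width/count-matched random sets\n"
            f"chromosome: {m.name} ({m.length:,} bp, "
            f"{len(m.exclusions)} exclusion(s)); "
            f"n_iter={self.config.n_iter}, seed={self.config.seed}, "
            f"p = k/n{' (conservative (k+1)/(n+1))' if self.config.conservative else ''}, "
            "null SD: sample (n-1)\n"
        )
        return head + self.to_table().to_string(index=False)

    def to_json(self, path) -> None:
        """JSON sidecar: run metadata plus the full null-count vectors."""
        import xregenrich

        payload = {
            "metadata": {
                "n_iter": self.config.n_iter,
                "seed": self.config.seed,
                "conservative": self.config.conservative,
                "chromosome": {
                    "name": self.model.model.name,
                    "length": self.model.model.length,
                },
                "query": asdict(self.query_summary),
                "xregenrich_version": xregenrich.__version__,
                "numpy_version": np.__version__,
            },
            "results": [asdict(r) for r in self.results],
            "null_counts": {
                r.track_name: self.null_counts[t].tolist()
                for t, r in enumerate(self.results)
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_track_enrichment(
    query: RegionSet,
    tracks: Sequence[AnnotationTrack],
    model: ChromosomeModel,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Functional wrapper: fit a :class:`RegionEnrichment` and return the
    per-track results in input order."""
    return RegionEnrichment(query, tracks, model).fit(config=config).results


# ---------------------------------------------------------------------------
# Gene-set bootstrap
# ---------------------------------------------------------------------------

def _normalize_genes(genes: Iterable[str], label: str) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        key = str(g).strip().upper()
        if key:
            seen.setdefault(key, None)
    out = list(seen)
    return out


class GeneSetEnrichment:
    """Bootstrap enrichment of a candidate gene list in a curated list.

    The observed statistic is ``|candidates ∩ curated|``; the null draws
    candidate-set-sized gene sets from the universe without replacement
    (with-replacement draws are available behind a flag) and the empirical p
    is the fraction of draws with a same-or-larger overlap.  As the number
    of draws grows this converges to the hypergeometric tail
    ``P(X >= observed)``.

    Gene symbols are case-normalized; candidates or curated genes missing
    from the universe are dropped with a warning.
    """

    def __init__(
        self,
        candidates: Iterable[str],
        curated: Iterable[str],
        universe: Iterable[str],
    ):
        self.universe = _normalize_genes(universe, "universe")
        uni = set(self.universe)
        self.candidates = self._subset(_normalize_genes(candidates, "candidates"), uni, "candidates")
        self.curated = self._subset(_normalize_genes(curated, "curated"), uni, "curated")
        if len(self.candidates) > len(self.universe):
            raise ValueError("more candidates than universe genes")

    @staticmethod
    def _subset(genes: list[str], universe: set[str], label: str) -> list[str]:
        missing = [g for g in genes if g not in universe]
        if missing:
            warnings.warn(
                f"{len(missing)} {label} gene(s) not in the universe dropped: "
                f"{missing[:5]}",
                stacklevel=3,
            )
        return [g for g in genes if g in universe]

    @property
    def observed_overlap(self) -> int:
        return len(set(self.candidates) & set(self.curated))

    def fit(
        self,
        n_iter: int = 1000,
        seed: int = 1000,
        *,
        with_replacement: bool = False,
        conservative: bool = False,
    ) -> "GeneSetResults":
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n_uni = len(self.universe)
        n_cand = len(self.candidates)
        curated_mask = np.zeros(n_uni, dtype=bool)
        curated_idx = {g: i for i, g in enumerate(self.universe)}
        for g in self.curated:
            curated_mask[curated_idx[g]] = True
        observed = self.observed_overlap
        null_overlaps = _draw_overlaps(
            rng, n_uni, n_cand, curated_mask, n_iter, with_replacement
        )
        k = int(np.count_nonzero(null_overlaps >= observed))
        p_emp = (k + 1) / (n_iter + 1) if conservative else k / n_iter
        result = GeneSetResult(
            n_candidates=n_cand,
            n_curated=len(self.curated),
            n_universe=n_uni,
            observed_overlap=observed,
            p_emp=p_emp,
            n_iter=n_iter,
            seed=seed,
        )
        return GeneSetResults(self, result, null_overlaps)


def _draw_overlaps(
    rng: np.random.Generator,
    n_universe: int,
    n_candidates: int,
    curated_mask: np.ndarray,
    n_iter: int,
    with_replacement: bool,
    chunk: int = 20_000,
) -> np.ndarray:
    """Null overlap counts from resampled candidate-sized gene draws."""
    if n_candidates == 0:
        return np.zeros(n_iter, dtype=np.int64)
    out = np.empty(n_iter, dtype=np.int64)
    if with_replacement:
        for i in range(n_iter):
            draw = rng.integers(0, n_universe, size=n_candidates)
            out[i] = int(curated_mask[np.unique(draw)].sum())
        return out
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        # uniform random keys; the n_candidates smallest per row form a
        # uniformly distributed subset without replacement
        keys = rng.random((m, n_universe))
        idx = np.argpartition(keys, n_candidates - 1, axis=1)[:, :n_candidates]
        out[done : done + m] = curated_mask[idx].sum(axis=1)
        done += m
    return out


class GeneSetResults:
    """Fitted gene-set bootstrap: the result record plus the null vector."""

    def __init__(
        self,
        model: GeneSetEnrichment,
        result: GeneSetResult,
        null_overlaps: np.ndarray,
    ):
        self.model = model
        self.result = result
        self.null_overlaps = null_overlaps

    def summary(self) -> str:
        r = self.result
        return (
            "Gene-set bootstrap enrichment\n"
            f"universe={r.n_universe}, curated={r.n_curated}, "
            f"candidates={r.n_candidates}\n"
            f"observed overlap: {r.observed_overlap}\n"
            f"null overlap mean: {self.null_overlaps.mean():.3f}\n"
            f"p (overlap >= observed, {r.n_iter} draws, seed {r.seed}): "
            f"{r.p_emp:.4f}"
        )


def geneset_bootstrap(
    candidates: Iterable[str],
    curated: Iterable[str],
    universe: Iterable[str],
    config: EnrichmentConfig = EnrichmentConfig(),
    *,
    with_replacement: bool = False,
) -> GeneSetResult:
    """Functional wrapper around :class:`GeneSetEnrichment`."""
    return (
        GeneSetEnrichment(candidates, curated, universe)
        .fit(
            n_iter=config.n_iter,
            seed=config.seed,
            with_replacement=with_replacement,
            conservative=config.conservative,
        )
        .result
    )


def load_pbc_methylation_genes() -> list[str]:
    """The literature-curated differentially methylated PBC gene list that
    ships with the package (nine X-chromosome genes)."""
    text = (
        resources.files("xregenrich")
        .joinpath("data/pbc_methylation_genes.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
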