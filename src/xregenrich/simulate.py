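"""Synthetic chromosomes, tracks, SNP tables and gene universes.

The study's real inputs (the full X-chromosome association table and the
annotation databases) are not deposited anywhere, so every pipeline stage is
exercised against generated data with *known planted truth*.  Planted truths
are exact, not expected: the generated query set has exactly the requested
region count and total width, gene lists have exactly the requested overlap,
and tracks have exactly the requested element count, which lets downstream
tests assert equalities.

Default geometry copies the published query set — 62 regions totalling
9.3 Mb on a 155 Mb X-scale chromosome — and default track densities are
chosen so that a null scenario's expected in-query element counts sit near
the published random-set means.

Annotation enrichment is planted by reweighting the element *midpoint*
density: weight ``enrichment_fold`` inside query regions, 1 outside.  This
gives a closed-form expected in-query midpoint fraction
``f*W / ((L - W) + f*W)`` (W = query width, L = effective chromosome
length) that tests can check; fold 1 is the null and fold 0 plants strict
depletion, with boundary-straddling elements clipped to stay outside.

Every generator is a pure function of ``(scenario, seed)``: the same
scenario yields bit-identical output on every call.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationTrack,
    GenomicInterval,
    RegionSet,
    merge_intervals,
    write_bed,
)
from .regions import SnpRecord
from .sampling import ChromosomeModel, sample_region_set

__all__ = [
    "TrackSpec",
    "SnpSpec",
    "GeneSpec",
    "SyntheticScenario",
    "make_chromosome",
    "make_query_regions",
    "make_annotation_track",
    "make_snp_table",
    "make_gene_universe",
    "write_scenario",
]

#: default element width ranges (bases) per annotation class
_WIDTH_RANGES = {
    "miRNA": (22, 100),
    "lncRNA": (200, 20_000),
    "circRNA": (200, 5_000),
    "superenhancer": (10_000, 50_000),
    "other": (100, 10_000),
}


@dataclass(frozen=True)
class TrackSpec:
    """One synthetic annotation track.

    ``enrichment_fold`` is the midpoint-density weight inside query regions:
    1 = null, >1 = planted enrichment, 0 = planted absence.  Width bounds
    default to class-typical ranges (point-like miRNAs, broad
    superenhancers).
    """

    element_class: str
    n_elements: int
    width_min: int | None = None
    width_max: int | None = None
    enrichment_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.element_class not in _WIDTH_RANGES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.n_elements < 0:
            raise ValueError("n_elements must be >= 0")
        if self.enrichment_fold < 0:
            raise ValueError("enrichment_fold must be >= 0")
        lo, hi = _WIDTH_RANGES[self.element_class]
        object.__setattr__(self, "width_min", self.width_min or lo)
        object.__setattr__(self, "width_max", self.width_max or hi)
        if not (1 <= self.width_min <= self.width_max):
            raise ValueError("need 1 <= width_min <= width_max")


@dataclass(frozen=True)
class SnpSpec:
    """Synthetic association table: background SNPs with Uniform(0,1)
    p-values plus positionally tight signal clusters whose p-values fall
    below the 5e-4 threshold (scaled by ``signal_p_scale``)."""

    n_snps: int = 5000
    n_signal_clusters: int = 5
    signal_p_scale: float = 1.0
    snps_per_cluster: int = 10

    def __post_init__(self) -> None:
        if self.n_signal_clusters * self.snps_per_cluster > self.n_snps:
            raise ValueError("more cluster SNPs than n_snps")
        if not (0 < self.signal_p_scale <= 1):
            raise ValueError("signal_p_scale must lie in (0, 1]")


@dataclass(frozen=True)
class GeneSpec:
    """Synthetic gene universe with an exactly planted candidate/curated
    overlap."""

    n_universe: int = 800
    n_curated: int = 9
    n_candidates: int = 45
    planted_overlap: int = 3

    def __post_init__(self) -> None:
        if self.n_curated > self.n_universe or self.n_candidates > self.n_universe:
            raise ValueError("curated/candidates cannot exceed the universe")
        if self.planted_overlap > min(self.n_curated, self.n_candidates):
            raise ValueError("planted_overlap exceeds list sizes")
        if self.n_candidates - self.planted_overlap > self.n_universe - self.n_curated:
            raise ValueError("planted_overlap infeasible for these sizes")


def _default_tracks() -> tuple[TrackSpec, ...]:
    return (
        TrackSpec("lncRNA", 300),
        TrackSpec("circRNA", 2900),
        TrackSpec("miRNA", 160),
        TrackSpec("superenhancer", 5000),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of one synthetic study, with X-scale defaults."""

    seed: int = 1000
    chrom_name: str = "chrX"
    chrom_length: int = 155_000_000
    exclusion_fraction: float = 0.0
    n_exclusions: int = 10
    n_query_regions: int = 62
    query_total_width: int = 9_300_000
    query_width_cv: float = 0.78  # width SD / mean, matching ~117/150 kb
    track_specs: tuple[TrackSpec, ...] = field(default_factory=_default_tracks)
    snp_spec: SnpSpec = field(default_factory=SnpSpec)
    gene_spec: GeneSpec = field(default_factory=GeneSpec)

    def __post_init__(self) -> None:
        if not (0 <= self.exclusion_fraction < 1):
            raise ValueError("exclusion_fraction must lie in [0, 1)")
        if self.query_total_width >= self.chrom_length:
            raise ValueError("query_total_width must be below chrom_length")
        if self.n_query_regions < 1 or self.n_query_regions > self.query_total_width:
            raise ValueError("n_query_regions infeasible for query_total_width")


def _rng(scenario: SyntheticScenario, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_chromosome(scenario: SyntheticScenario) -> ChromosomeModel:
    """Chromosome of the scenario's length; optional disjoint exclusion
    zones totalling exactly ``round(exclusion_fraction * length)`` bases."""
    if scenario.exclusion_fraction == 0:
        return ChromosomeModel(scenario.chrom_name, scenario.chrom_length)
    rng = _rng(scenario, 0)
    total = int(round(scenario.exclusion_fraction * scenario.chrom_length))
    widths = _partition_total(total, scenario.n_exclusions, rng)
    bare = ChromosomeModel(scenario.chrom_name, scenario.chrom_length)
    placed = sample_region_set(bare, widths, rng, name="exclusions")
    return ChromosomeModel(scenario.chrom_name, scenario.chrom_length, placed.intervals)


def _partition_total(total: int, n: int, rng: np.random.Generator) -> list[int]:
    """n positive integer widths summing exactly to total."""
    n = min(n, total)
    props = rng.dirichlet(np.full(n, 5.0))
    widths = np.maximum(1, np.round(props * total).astype(np.int64))
    widths[-1] += total - widths.sum()
    # borrow if the adjustment pushed the last width below 1
    i = 0
    while widths[-1] < 1:
        take = min(widths[i] - 1, 1 - widths[-1])
        widths[i] -= take
        widths[-1] += take
        i += 1
    return [int(w) for w in widths]


def make_query_regions(scenario: SyntheticScenario, model: ChromosomeModel) -> RegionSet:
    """Disjoint query regions: exactly ``n_query_regions`` intervals whose
    widths sum to exactly ``query_total_width``.

    Widths are drawn lognormal with the scenario's coefficient of variation,
    rescaled to the exact total with the residual applied to the last
    region; placement avoids exclusions.
    """
    rng = _rng(scenario, 1)
    n = scenario.n_query_regions
    total = scenario.query_total_width
    if n == 1:
        widths = [total]
    else:
        cv = scenario.query_width_cv
        sigma2 = np.log1p(cv**2)
        mu = np.log(total / n) - sigma2 / 2
        raw = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        widths_arr = np.maximum(1, np.round(raw * (total / raw.sum())).astype(np.int64))
        widths_arr[-1] += total - widths_arr.sum()
        i = 0
        while widths_arr[-1] < 1:
            take = min(widths_arr[i] - 1, 1 - widths_arr[-1])
            widths_arr[i] -= take
            widths_arr[-1] += take
            i += 1
        widths = [int(w) for w in widths_arr]
    return sample_region_set(model, widths, rng, name="query")


def _union_arrays(regions: RegionSet) -> tuple[np.ndarray, np.ndarray]:
    merged = merge_intervals(regions)
    return (
        np.fromiter((iv.start for iv in merged), dtype=np.int64, count=merged.n),
        np.fromiter((iv.end for iv in merged), dtype=np.int64, count=merged.n),
    )


def _complement_arrays(
    starts: np.ndarray, ends: np.ndarray, length: int
) -> tuple[np.ndarray, np.ndarray]:
    gap_starts = np.concatenate(([0], ends))
    gap_ends = np.concatenate((starts, [length]))
    keep = gap_ends > gap_starts
    return gap_starts[keep], gap_ends[keep]


def _sample_from_union(
    starts: np.ndarray, ends: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform integer positions from a union of disjoint intervals."""
    widths = ends - starts
    cum = np.concatenate(([0], np.cumsum(widths)))
    offsets = rng.integers(0, cum[-1], size=size)
    idx = np.searchsorted(cum, offsets, side="right") - 1
    return starts[idx] + (offsets - cum[idx])


def make_annotation_track(
    scenario: SyntheticScenario,
    model: ChromosomeModel,
    query: RegionSet,
    spec: TrackSpec,
    stream: int | None = None,
) -> AnnotationTrack:
    """Generate one annotation track with a planted in-query enrichment.

    Midpoints follow the two-component density described in the module
    docstring; widths are uniform integers in the spec's range; intervals
    are clipped to the chromosome.  With fold 0 no element overlaps the
    query: straddling widths are clipped back to the flanking gap.
    """
    if stream is None:
        stream = (
            scenario.track_specs.index(spec) if spec in scenario.track_specs else 0
        )
    rng = _rng(scenario, 2, stream)
    n = spec.n_elements
    if n == 0:
        return AnnotationTrack(spec.element_class, spec.element_class, ())

    q_starts, q_ends = _union_arrays(query)
    W = int((q_ends - q_starts).sum())
    ex_starts, ex_ends = model._excl_arrays
    L_eff = model.length - model.excluded_bases
    f = spec.enrichment_fold
    p_in = f * W / ((L_eff - W) + f * W)

    in_query = rng.random(n) < p_in
    n_in = int(in_query.sum())
    mids = np.empty(n, dtype=np.int64)
    if n_in:
        mids[in_query] = _sample_from_union(q_starts, q_ends, n_in, rng)
    if n - n_in:
        # complement of query and exclusions
        blocked = RegionSet(
            "blocked",
            tuple(query)
            + tuple(model.exclusions),
        )
        b_starts, b_ends = _union_arrays(blocked)
        c_starts, c_ends = _complement_arrays(b_starts, b_ends, model.length)
        mids[~in_query] = _sample_from_union(c_starts, c_ends, n - n_in, rng)

    widths = rng.integers(spec.width_min, spec.width_max + 1, size=n)
    starts = np.clip(mids - widths // 2, 0, None)
    starts = np.minimum(starts, model.length - widths)
    ends = starts + widths

    if f == 0:
        # clip straddlers so nothing touches the query
        prev_idx = np.searchsorted(q_ends, mids, side="right") - 1
        prev_end = np.where(prev_idx >= 0, q_ends[np.maximum(prev_idx, 0)], 0)
        next_idx = np.searchsorted(q_starts, mids, side="right")
        next_start = np.where(
            next_idx < len(q_starts), q_starts[np.minimum(next_idx, len(q_starts) - 1)],
            model.length,
        )
        starts = np.maximum(starts, prev_end)
        ends = np.minimum(ends, next_start)

    elements = tuple(
        (f"{spec.element_class}_{i:05d}", GenomicInterval(model.name, int(s), int(e)))
        for i, (s, e) in enumerate(zip(starts, ends))
    )
    return AnnotationTrack(spec.element_class, spec.element_class, elements)


def make_snp_table(
    scenario: SyntheticScenario, model: ChromosomeModel
) -> list[SnpRecord]:
    """Synthetic association table: uniform background p-values plus tight
    signal clusters (within 50 kb) whose p-values sit below 5e-4."""
    spec = scenario.snp_spec
    rng = _rng(scenario, 3)
    L = model.length
    records: list[SnpRecord] = []
    n_cluster_snps = spec.n_signal_clusters * spec.snps_per_cluster

    # cluster centers kept >= 1 Mb apart (and off the ends) so the default
    # flank-and-merge construction yields one region per cluster
    centers: list[int] = []
    margin = 200_000
    while len(centers) < spec.n_signal_clusters:
        c = int(rng.integers(margin, L - margin))
        if all(abs(c - other) >= 1_000_000 for other in centers):
            centers.append(c)
    i = 0
    for c in centers:
        for _ in range(spec.snps_per_cluster):
            pos = int(c + rng.integers(0, 50_000)) + 1  # 1-based
            p = float(rng.uniform(1e-300, 0.0005 * spec.signal_p_scale))
            records.append(SnpRecord(f"rs_sig{i:05d}", model.name, pos, p))
            i += 1
    n_bg = spec.n_snps - n_cluster_snps
    positions = rng.integers(1, L + 1, size=n_bg)
    pvals = 1.0 - rng.random(n_bg)  # (0, 1]
    for j in range(n_bg):
        records.append(
            SnpRecord(f"rs_bg{j:05d}", model.name, int(positions[j]), float(pvals[j]))
        )
    return records


def make_gene_universe(
    scenario: SyntheticScenario,
) -> tuple[list[str], list[str], list[str]]:
    """Return ``(universe, curated, candidates)`` synthetic gene symbol
    lists with ``|candidates ∩ curated|`` exactly equal to the planted
    overlap."""
    spec = scenario.gene_spec
    rng = _rng(scenario, 4)
    universe = [f"GENE{i:05d}" for i in range(spec.n_universe)]
    curated_idx = rng.choice(spec.n_universe, size=spec.n_curated, replace=False)
    curated = [universe[i] for i in sorted(curated_idx)]
    rest = [g for g in universe if g not in set(curated)]
    overlap_pick = rng.choice(spec.n_curated, size=spec.planted_overlap, replace=False)
    extra_pick = rng.choice(
        len(rest), size=spec.n_candidates - spec.planted_overlap, replace=False
    )
    candidates = sorted(
        [curated[i] for i in overlap_pick] + [rest[i] for i in extra_pick]
    )
    return universe, curated, candidates


# ---------------------------------------------------------------------------
# Scenario export
# ---------------------------------------------------------------------------

def write_scenario(scenario: SyntheticScenario, out_dir) -> dict:
    """Materialise a scenario on disk and return its manifest.

    Writes: chromosome TSV, query BED, one BED per track, SNP TSV, gene
    list files and ``scenario.json`` capturing all planted truths.
    """
    os.makedirs(out_dir, exist_ok=True)
    model = make_chromosome(scenario)
    query = make_query_regions(scenario, model)
    tracks = [
        make_annotation_track(scenario, model, query, spec, stream=t)
        for t, spec in enumerate(scenario.track_specs)
    ]
    snps = make_snp_table(scenario, model)
    universe, curated, candidates = make_gene_universe(scenario)

    p = lambda name: os.path.join(out_dir, name)
    with open(p("chromosome.tsv"), "w") as fh:
        fh.write(f"{model.name}\t{model.length}\n")
    if model.exclusions:
        write_bed(RegionSet("exclusions", model.exclusions), p("exclusions.bed"))
    write_bed(query, p("query.bed"))
    track_files = {}
    for tr in tracks:
        fn = f"track_{tr.name}.bed"
        write_bed(tr, p(fn))
        track_files[tr.name] = fn
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos": [s.position for s in snps],
            "p": [s.assoc_p for s in snps],
        }
    ).to_csv(p("snps.tsv"), sep="\t", index=False)
    for name, genes in (
        ("genes_universe.txt", universe),
        ("genes_curated.txt", curated),
        ("genes_candidates.txt", candidates),
    ):
        with open(p(name), "w") as fh:
            fh.write("\n".join(genes) + "\n")

    manifest = {
        "scenario": asdict(scenario),
        "files": {
            "chromosome": "chromosome.tsv",
            "query": "query.bed",
            "tracks": track_files,
            "snps": "snps.tsv",
            "genes": {
                "universe": "genes_universe.txt",
                "curated": "genes_curated.txt",
                "candidates": "genes_candidates.txt",
            },
        },
        "planted": {
            "n_query_regions": query.n,
            "query_total_width": query.total_width,
            "track_elements": {tr.name: tr.n for tr in tracks},
            "enrichment_folds": {
                spec.element_class: spec.enrichment_fold
                for spec in scenario.track_specs
            },
            "gene_overlap": len(set(candidates) & set(curated)),
        },
    }
    with open(p("scenario.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
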