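"""Synthetic multi-caller SV call sets over structured populations.

The generator emulates the downstream products of a multi-caller WGS SV
pipeline: a ground-truth SV set placed on a genome, per-sample genotypes
drawn under Hardy-Weinberg equilibrium from per-population allele
frequencies, and one noisy call set per caller with caller-specific
breakpoint jitter, false negatives, and caller-private false positives.
A configurable number of "selected" deletions get an elevated frequency in
the focal population so the selection scan has planted positives with a
known effect size.

Neutral sites share one baseline allele frequency across populations
(exchangeable neutral model: any differentiation at a neutral site is pure
binomial sampling noise). Everything is driven by one integer seed and is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import GeneModel, GenotypeMatrix, PopulationMap, SVCall
from . import io as svio

_DEFAULT_GENOME = (("chr1", 30_000_000), ("chr2", 25_000_000), ("chr3", 20_000_000))
_DEFAULT_N_SITES = {"DEL": 500, "INS": 50, "INV": 10, "DUP": 30, "TRA": 5}
_DEFAULT_SVLEN_BOUNDS = {
    "DEL": (100, 10_000),
    "INS": (50, 500),
    "INV": (1_000, 100_000),
    "DUP": (1_000, 100_000),
}


@dataclass(frozen=True)
class CallerProfile:
    """Error profile of one emulated caller.

    fnr: per-site false-negative rate; fpr_per_mb: false-positive density
    per megabase of genome; jitter_sd: sd in bp of the Gaussian breakpoint
    noise added independently at each end; genotyping: whether the caller
    emits genotypes; genotype_error: per-genotype probability of reporting
    a wrong (uniformly chosen other) genotype.
    """

    name: str
    fnr: float = 0.2
    fpr_per_mb: float = 0.5
    jitter_sd: float = 30.0
    genotyping: bool = False
    genotype_error: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("fnr", "fpr_per_mb", "genotype_error"):
            v = getattr(self, attr)
            if attr == "fpr_per_mb":
                if v < 0:
                    raise ValueError(f"{attr} must be >= 0, got {v}")
            elif not 0 <= v <= 1:
                raise ValueError(f"{attr} must be in [0,1], got {v}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def default_callers() -> tuple[CallerProfile, ...]:
    """Six callers mirroring a typical read-pair / split-read / read-depth
    mix; three of them genotype their calls."""
    return (
        CallerProfile("delly", genotyping=True),
        CallerProfile("manta", genotyping=True),
        CallerProfile("genomestrip", genotyping=True),
        CallerProfile("breakdancer"),
        CallerProfile("pindel"),
        CallerProfile("cnvnator"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set."""

    genome: tuple[tuple[str, int], ...] = _DEFAULT_GENOME
    n_sites: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_SITES))
    svlen_bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_SVLEN_BOUNDS)
    )
    populations: tuple[tuple[str, int], ...] = (("MS", 50), ("DU", 50), ("TB", 50))
    focal: str = "MS"
    af_range: tuple[float, float] = (0.05, 0.95)
    n_selected_sites: int = 0
    selected_focal_af: float = 0.9
    selected_ref_af: float = 0.1
    callers: tuple[CallerProfile, ...] = field(default_factory=default_callers)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.populations]
        if self.focal not in labels:
            raise ValueError(f"focal {self.focal!r} not among populations {labels}")
        lo, hi = self.af_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"af_range must satisfy 0 <= lo <= hi <= 1, got {self.af_range}")
        for f in (self.selected_focal_af, self.selected_ref_af):
            if not 0 <= f <= 1:
                raise ValueError("selected allele frequencies must be in [0,1]")
        if self.n_selected_sites > 0 and self.selected_focal_af == self.selected_ref_af:
            raise ValueError(
                "selected sites need selected_focal_af != selected_ref_af"
            )
        if self.n_selected_sites > self.n_sites.get("DEL", 0):
            raise ValueError("n_selected_sites exceeds the number of DEL sites")
        names = [c.name for c in self.callers]
        if len(set(names)) != len(names):
            raise ValueError("caller names must be unique")

    def population_map(self) -> PopulationMap:
        assignments = {
            f"{label}_{i:03d}": label
            for label, n in self.populations
            for i in range(n)
        }
        references = tuple(lab for lab, _ in self.populations if lab != self.focal)
        return PopulationMap(assignments, self.focal, references)

    @property
    def genome_mb(self) -> float:
        return sum(length for _, length in self.genome) / 1e6


@dataclass
class TruthSet:
    """Ground truth: SVs (caller="truth"), per-population true allele
    frequencies, selected-site flags, and per-sample HWE genotypes."""

    svs: list[SVCall]
    genotypes: GenotypeMatrix
    pop_freqs: dict[str, np.ndarray]
    selected: np.ndarray
    popmap: PopulationMap
    config: SimulationConfig


def _seed_children(config: SimulationConfig) -> list[np.random.SeedSequence]:
    """Independent, deterministic RNG streams for truth / callsets / genes."""
    return np.random.SeedSequence(config.seed).spawn(3)


def _draw_svlen(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


class _Placer:
    """Uniform placement without same-type overlap, via per-(chrom, type)
    sorted interval lists."""

    MAX_TRIES = 200

    def __init__(self, genome: Sequence[tuple[str, int]], rng: np.random.Generator) -> None:
        self.chroms = [c for c, _ in genome]
        self.lengths = dict(genome)
        self.weights = np.array([self.lengths[c] for c in self.chroms], dtype=float)
        self.weights /= self.weights.sum()
        self.rng = rng
        self.occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def place(self, svtype: str, svlen: int) -> tuple[str, int, int]:
        for _ in range(self.MAX_TRIES):
            chrom = self.chroms[self.rng.choice(len(self.chroms), p=self.weights)]
            span = svlen if svtype not in ("INS", "TRA") else 1
            limit = self.lengths[chrom] - span + 1
            if limit < 1:
                continue
            start = int(self.rng.integers(1, limit + 1))
            end = start + span - 1
            ivs = self.occupied.setdefault((chrom, svtype), [])
            i = bisect_left(ivs, (start, end))
            if i > 0 and ivs[i - 1][1] >= start:
                continue
            if i < len(ivs) and ivs[i][0] <= end:
                continue
            insort(ivs, (start, end))
            return chrom, start, end
        raise RuntimeError(
            f"could not place a {svtype} of {svlen} bp without same-type "
            f"overlap after {self.MAX_TRIES} tries; genome too small or too full"
        )


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Place true SVs, assign per-population allele frequencies, and draw
    per-sample genotypes under HWE (hom_alt f^2, het 2f(1-f))."""
    rng = np.random.default_rng(_seed_children(config)[0])
    popmap = config.population_map()
    placer = _Placer(config.genome, rng)

    sites: list[dict] = []
    for svtype in ("DEL", "INS", "INV", "DUP", "TRA"):
        for _ in range(config.n_sites.get(svtype, 0)):
            if svtype == "TRA":
                chrom, start, end = placer.place("TRA", 1)
                others = [c for c in placer.chroms if c != chrom] or [chrom]
                mate_chrom = others[int(rng.integers(len(others)))]
                mate_pos = int(rng.integers(1, placer.lengths[mate_chrom] + 1))
                sites.append(
                    dict(chrom=chrom, start=start, end=end, svtype="TRA", svlen=0,
                         mate_chrom=mate_chrom, mate_pos=mate_pos, selected=False)
                )
            else:
                svlen = _draw_svlen(rng, config.svlen_bounds[svtype])
                chrom, start, end = placer.place(svtype, svlen)
                sites.append(
                    dict(chrom=chrom, start=start, end=end, svtype=svtype,
                         svlen=svlen, mate_chrom=None, mate_pos=None, selected=False)
                )

    del_idx = [i for i, s in enumerate(sites) if s["svtype"] == "DEL"]
    if config.n_selected_sites:
        chosen = rng.choice(len(del_idx), size=config.n_selected_sites, replace=False)
        for k in chosen:
            sites[del_idx[int(k)]]["selected"] = True

    sites.sort(key=lambda s: (s["chrom"], s["start"], s["end"], s["svtype"]))
    svs = [
        SVCall(s["chrom"], s["start"], s["end"], s["svtype"], s["svlen"], "truth",
               mate_chrom=s["mate_chrom"], mate_pos=s["mate_pos"])
        for s in sites
    ]
    selected = np.array([s["selected"] for s in sites], dtype=bool)

    n_sites = len(sites)
    base = rng.uniform(config.af_range[0], config.af_range[1], size=n_sites)
    pop_freqs: dict[str, np.ndarray] = {}
    for label, _ in config.populations:
        f = base.copy()
        f[selected] = (
            config.selected_focal_af if label == config.focal else config.selected_ref_af
        )
        pop_freqs[label] = f

    samples = popmap.samples
    codes = np.empty((n_sites, len(samples)), dtype=np.int8)
    col = 0
    for label, n in config.populations:
        f = pop_freqs[label][:, None]
        u = rng.random((n_sites, n))
        g = np.where(u < f * f, 2, np.where(u < f * f + 2 * f * (1 - f), 1, 0))
        codes[:, col : col + n] = g.astype(np.int8)
        col += n
    matrix = GenotypeMatrix(svs, samples, codes)
    return TruthSet(svs, matrix, pop_freqs, selected, popmap, config)


def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(round(rng.normal(0.0, sd))) if sd > 0 else 0


def _noisy_call(sv: SVCall, caller: CallerProfile, rng: np.random.Generator,
                genotypes: Optional[dict[str, int]]) -> SVCall:
    if sv.svtype == "TRA":
        start = max(1, sv.start + _jitter(rng, caller.jitter_sd))
        mate = max(1, sv.mate_pos + _jitter(rng, caller.jitter_sd))
        return SVCall(sv.chrom, start, start, "TRA", 0, caller.name,
                      genotypes=genotypes, mate_chrom=sv.mate_chrom, mate_pos=mate)
    if sv.svtype == "INS":
        start = max(1, sv.start + _jitter(rng, caller.jitter_sd))
        svlen = max(1, sv.svlen + _jitter(rng, caller.jitter_sd))
        return SVCall(sv.chrom, start, start, "INS", svlen, caller.name,
                      genotypes=genotypes)
    start = max(1, sv.start + _jitter(rng, caller.jitter_sd))
    end = max(1, sv.end + _jitter(rng, caller.jitter_sd))
    if end < start:  # restore order when noise inverts the breakpoints
        start, end = end, start
    return SVCall(sv.chrom, start, end, sv.svtype, end - start + 1, caller.name,
                  genotypes=genotypes)


def _erred_genotypes(row: np.ndarray, samples: Sequence[str], error: float,
                     rng: np.random.Generator) -> dict[str, int]:
    gts = {}
    for s, g in zip(samples, row):
        g = int(g)
        if g != -1 and error > 0 and rng.random() < error:
            g = int(rng.choice([x for x in (0, 1, 2) if x != g]))
        gts[s] = g
    return gts


def simulate_callsets(
    truth: TruthSet, config: Optional[SimulationConfig] = None
) -> dict[str, list[SVCall]]:
    """One noisy call set per configured caller.

    Each true site is emitted with probability 1-fnr, with independent
    Gaussian breakpoint jitter at each end. False positives are placed
    uniformly at fpr_per_mb (Poisson count), are private to their caller,
    and for genotyping callers carry HWE genotypes at a random baseline
    frequency. Genotyping callers copy true genotypes subject to the
    per-genotype error rate.
    """
    config = config or truth.config
    caller_seqs = _seed_children(config)[1].spawn(len(config.callers))
    caller_rngs = [np.random.default_rng(c) for c in caller_seqs]

    samples = truth.popmap.samples
    type_names = [t for t in ("DEL", "INS", "INV", "DUP") if config.n_sites.get(t, 0) > 0]
    type_w = np.array([config.n_sites[t] for t in type_names], dtype=float)
    if type_w.sum() == 0:
        type_names, type_w = ["DEL"], np.array([1.0])
    type_w /= type_w.sum()

    callsets: dict[str, list[SVCall]] = {}
    for caller, rng in zip(config.callers, caller_rngs):
        calls: list[SVCall] = []
        detected = rng.random(len(truth.svs)) >= caller.fnr
        for i, sv in enumerate(truth.svs):
            if not detected[i]:
                continue
            gts = None
            if caller.genotyping:
                gts = _erred_genotypes(
                    truth.genotypes.codes[i], samples, caller.genotype_error, rng
                )
            calls.append(_noisy_call(sv, caller, rng, gts))

        n_fp = rng.poisson(caller.fpr_per_mb * config.genome_mb)
        placer = _Placer(config.genome, rng)
        for _ in range(n_fp):
            svtype = type_names[int(rng.choice(len(type_names), p=type_w))]
            svlen = _draw_svlen(rng, config.svlen_bounds[svtype])
            try:
                chrom, start, end = placer.place(svtype, svlen)
            except RuntimeError:
                continue
            gts = None
            if caller.genotyping:
                f = rng.uniform(*config.af_range)
                u = rng.random(len(samples))
                row = np.where(u < f * f, 2, np.where(u < f * f + 2 * f * (1 - f), 1, 0))
                gts = dict(zip(samples, (int(x) for x in row)))
            if svtype == "INS":
                calls.append(SVCall(chrom, start, start, "INS", svlen, caller.name,
                                    genotypes=gts))
            else:
                calls.append(SVCall(chrom, start, end, svtype, end - start + 1,
                                    caller.name, genotypes=gts))
        calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.svtype))
        callsets[caller.name] = calls
    return callsets


def simulate_genes(config: SimulationConfig, n_genes: int = 60) -> list[GeneModel]:
    """Uniformly placed gene models (for annotation tests): log-uniform
    spans of 5-50 kb, 1-8 exons, random strand."""
    rng = np.random.default_rng(_seed_children(config)[2])
    placer = _Placer(config.genome, rng)
    genes = []
    for i in range(n_genes):
        span = _draw_svlen(rng, (5_000, 50_000))
        chrom, start, end = placer.place("GENE", span)  # type: ignore[arg-type]
        n_exons = int(rng.integers(1, 9))
        cuts = np.sort(rng.choice(np.arange(start, end + 1), size=min(2 * n_exons, span), replace=False))
        exons = tuple(
            (int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(len(cuts) // 2)
        )
        if not exons:
            exons = ((start, end),)
        exons = ((start, exons[0][1]),) + exons[1:-1] + ((exons[-1][0], end),) if len(exons) > 1 else ((start, end),)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{i:04d}", chrom, start, end, strand, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_simulation_bundle(
    truth: TruthSet,
    callsets: Mapping[str, Sequence[SVCall]],
    outdir: str | os.PathLike,
    n_genes: int = 60,
) -> dict[str, str]:
    """Write the full bundle: one VCF per caller, the truth VCF (with true
    genotypes), the population map TSV, a BED12 gene-model file, and a JSON
    manifest recording the config. Re-running with the same config and seed
    reproduces every file byte-for-byte."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    samples = truth.popmap.samples
    truth_calls = []
    for i, sv in enumerate(truth.svs):
        gts = dict(zip(samples, (int(g) for g in truth.genotypes.codes[i])))
        truth_calls.append(dataclasses.replace(sv, genotypes=gts))
    paths["truth"] = os.path.join(outdir, "truth.vcf")
    svio.write_sv_vcf(truth_calls, paths["truth"], samples=samples)

    for caller, calls in callsets.items():
        p = os.path.join(outdir, f"{caller}.vcf")
        has_gt = any(c.genotypes for c in calls)
        svio.write_sv_vcf(list(calls), p, samples=samples if has_gt else [])
        paths[caller] = p

    paths["popmap"] = os.path.join(outdir, "popmap.tsv")
    svio.write_population_map(truth.popmap, paths["popmap"])

    paths["genes"] = os.path.join(outdir, "genes.bed")
    svio.write_gene_models_bed(simulate_genes(truth.config, n_genes), paths["genes"])

    manifest = dataclasses.asdict(truth.config)
    manifest["n_sites"] = dict(manifest["n_sites"])
    manifest["svlen_bounds"] = {k: list(v) for k, v in manifest["svlen_bounds"].items()}
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return paths
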