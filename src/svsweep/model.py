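"""Core domain types for the SV consensus and selection-scan pipeline.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted at the I/O boundary. Genotypes are stored as small integer codes
equal to the alt-allele dosage (``HOM_REF=0, HET=1, HOM_ALT=2``) with
``MISSING=-1``, so a genotype matrix doubles as an allele-count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

SVTYPES = ("DEL", "INS", "INV", "DUP", "TRA")
#: Types with a genomic span for which reciprocal overlap is defined.
SPANNING_TYPES = frozenset({"DEL", "INV", "DUP"})

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
GENOTYPE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
GENOTYPE_CODES = {name: code for code, name in GENOTYPE_NAMES.items()}


class SVFormatError(ValueError):
    """A record in an input file violates the format contract."""


@dataclass(frozen=True, slots=True)
class SVCall:
    """A single caller's call for one locus.

    ``svlen`` is canonicalised: for spanning types (DEL/INV/DUP) it always
    equals ``end - start + 1``; for INS it is the inserted-sequence length
    (``end == start``); for TRA it is 0 and the second breakend lives in
    ``mate_chrom``/``mate_pos``.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    caller: str
    genotypes: Optional[Mapping[str, int]] = field(default=None, compare=False)
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.svtype == "TRA":
            if self.mate_chrom is None or self.mate_pos is None:
                raise ValueError("TRA call requires mate_chrom and mate_pos")
            object.__setattr__(self, "svlen", 0)
            return
        if self.svtype == "INS":
            if self.end != self.start:
                raise ValueError("INS call must have end == start")
            if self.svlen <= 0:
                raise ValueError("INS call requires svlen > 0")
            return
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        object.__setattr__(self, "svlen", self.end - self.start + 1)
        if self.svlen <= 0:  # pragma: no cover - implied by end >= start
            raise ValueError("svlen must be positive")

    @property
    def span(self) -> int:
        """Interval length in bp (1 for INS/TRA point records)."""
        return self.end - self.start + 1

    @property
    def site_id(self) -> str:
        return f"{self.svtype}:{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, slots=True)
class ConsensusSV:
    """A merged site supported by >=2 distinct callers.

    Breakpoints are the medians of the member calls' breakpoints (floor of
    the midpoint mean for even counts, keeping integer coordinates).
    """

    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    callers: tuple[str, ...]
    members: tuple[SVCall, ...] = field(default=(), compare=False, repr=False)
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "callers", tuple(sorted(set(self.callers))))
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")

    @property
    def n_callers(self) -> int:
        return len(self.callers)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def site_id(self) -> str:
        return f"{self.svtype}:{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class PopulationMap:
    """sample -> population assignment plus the scan's focal/reference roles.

    The selection scan contrasts the focal population against the mean of
    the reference populations, so at least two references are required at
    scan time (validated there, not here, so a two-population map can still
    drive genotyping).
    """

    assignments: Mapping[str, str]
    focal: str
    references: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        object.__setattr__(self, "references", tuple(self.references))
        pops = set(self.assignments.values())
        if self.focal not in pops:
            raise ValueError(f"focal population {self.focal!r} has no samples")
        if self.focal in self.references:
            raise ValueError("focal population cannot also be a reference")
        for ref in self.references:
            if ref not in pops:
                raise ValueError(f"reference population {ref!r} has no samples")

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    @property
    def scan_populations(self) -> list[str]:
        """Focal population followed by the reference populations."""
        return [self.focal, *self.references]

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]


@dataclass(frozen=True)
class GeneModel:
    """A gene span with (merged, non-overlapping) exon intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(f"bad gene span {self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        merged = merge_intervals(self.exons)
        for lo, hi in merged:
            if lo < self.start or hi > self.end:
                raise ValueError(
                    f"exon [{lo},{hi}] outside gene span "
                    f"[{self.start},{self.end}] for {self.gene_id}"
                )
        object.__setattr__(self, "exons", merged)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of 1-based inclusive intervals; adjacent/overlapping runs merge."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for lo, hi in ivs:
        if hi < lo:
            raise ValueError(f"bad interval [{lo},{hi}]")
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return tuple(out)


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype codes (int8; alt-allele dosage, -1 missing).

    ``sites`` may hold :class:`SVCall`/:class:`ConsensusSV` objects or, when
    reconstructed from a TSV, their bare site-id strings.
    """

    sites: Sequence
    samples: Sequence[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.sites = list(self.sites)
        self.samples = list(self.samples)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.codes, (MISSING, HOM_REF, HET, HOM_ALT))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def site_ids(self) -> list[str]:
        return [s if isinstance(s, str) else s.site_id for s in self.sites]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.site_ids == other.site_ids
            and self.samples == other.samples
            and np.array_equal(self.codes, other.codes)
        )


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-site alt-allele frequencies.

    ``freqs`` maps population label -> frequency (``None`` when the
    population has no non-missing genotype at the site). ``pooled`` is the
    count-pooled frequency over all samples of the scan populations jointly,
    not the mean of the per-population frequencies.
    """

    site: object
    freqs: Mapping[str, Optional[float]]
    pooled: Optional[float]
    n_nonmissing: Mapping[str, int]

    @property
    def site_id(self) -> str:
        s = self.site
        return s if isinstance(s, str) else s.site_id


@dataclass(frozen=True)
class ScanResult:
    """Per-site scan statistics and significance flags."""

    site: object
    delta_af: float
    rfd: float
    pass_daf: bool
    pass_rfd: bool

    @property
    def significant(self) -> bool:
        return self.pass_daf and self.pass_rfd

    @property
    def site_id(self) -> str:
        s = self.site
        return s if isinstance(s, str) else s.site_id


@dataclass(frozen=True)
class SelectionRegion:
    """A run of nearby significant sites merged into one candidate region."""

    chrom: str
    start: int
    end: int
    sites: tuple[ScanResult, ...]
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end < start")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class RegionClass:
    """Region-based annotation of one SV (exonic > intronic > upstream_1kb >
    downstream_1kb > intergenic precedence)."""

    region_class: str
    gene_ids: tuple[str, ...] = ()

    CLASSES = ("exonic", "intronic", "upstream_1kb", "downstream_1kb", "intergenic")

    def __post_init__(self) -> None:
        if self.region_class not in self.CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
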