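"""Allele-frequency differentiation scan over deletion sites.

Two statistics are computed per deletion site from the focal population
(e.g. Meishan) and the reference populations (e.g. Duroc and Tibetan wild
boar):

* ``ΔAF = |f_focal − mean(f_ref)|`` — the absolute allele-frequency
  difference, in [0, 1];
* ``RFD = (f_focal − mean(f_ref)) / f_pooled`` — the relative frequency
  difference, where ``f_pooled`` is the count-pooled frequency over all
  samples of the scan populations. RFD is signed: positive when the focal
  population is enriched for the deletion.

Before scanning, sites are filtered to deletions of at most 100 kb whose
pooled frequency is at least 0.01 and which have at least one non-missing
genotype in every scan population. Each statistic is thresholded at its own
empirical top 5% (nearest-rank 95th percentile, strict >, so ties at the
cutoff are not flagged); a site is a selection signature only when it is in
the top tail of *both* statistics. Significant sites within ``join_gap`` bp
of each other on a chromosome are merged into candidate selection regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    FrequencyRecord,
    PopulationMap,
    ScanResult,
    SelectionRegion,
)


@dataclass(frozen=True)
class ScanParams:
    """Scan thresholds. Defaults follow the discovery pipeline: deletions
    over 100 kb removed, pooled frequency < 0.01 removed, top 5% tails,
    and a 100 kb region-joining gap (the joining gap is a package choice;
    the source pipeline reports regions without stating its rule)."""

    max_del_len: int = 100_000
    min_pooled_freq: float = 0.01
    top_fraction: float = 0.05
    join_gap: int = 100_000


def scan_filter(
    records: Sequence[FrequencyRecord],
    popmap: PopulationMap,
    params: ScanParams = ScanParams(),
) -> list[FrequencyRecord]:
    """Keep deletion sites eligible for the scan: svtype DEL, svlen <=
    ``max_del_len``, pooled frequency >= ``min_pooled_freq``, and every scan
    population observed (>=1 non-missing genotype)."""
    out = []
    for rec in records:
        site = rec.site
        if getattr(site, "svtype", None) != "DEL":
            continue
        if site.svlen > params.max_del_len:
            continue
        if rec.pooled is None or rec.pooled < params.min_pooled_freq:
            continue
        if any(rec.freqs.get(pop) is None for pop in popmap.scan_populations):
            continue
        out.append(rec)
    return out


def delta_af(record: FrequencyRecord, popmap: PopulationMap) -> float:
    """|f_focal − mean over reference populations| (in [0, 1])."""
    f_focal = record.freqs[popmap.focal]
    refs = [record.freqs[pop] for pop in popmap.references]
    if f_focal is None or any(f is None for f in refs):
        raise ValueError(f"undefined population frequency at {record.site_id}")
    return abs(f_focal - sum(refs) / len(refs))


def rfd(record: FrequencyRecord, popmap: PopulationMap) -> float:
    """(f_focal − mean over reference populations) / pooled frequency.

    The pooled frequency is the count-pooled all-sample frequency and must
    be positive (guaranteed by the >=0.01 filter)."""
    f_focal = record.freqs[popmap.focal]
    refs = [record.freqs[pop] for pop in popmap.references]
    if f_focal is None or any(f is None for f in refs):
        raise ValueError(f"undefined population frequency at {record.site_id}")
    if not record.pooled or record.pooled <= 0:
        raise ValueError(
            f"pooled frequency must be > 0 at {record.site_id} "
            "(apply scan_filter first)"
        )
    return (f_focal - sum(refs) / len(refs)) / record.pooled


def empirical_top_fraction(
    values: Sequence[float], fraction: float = 0.05
) -> np.ndarray:
    """Boolean flags for the empirical top ``fraction`` of ``values``.

    The cutoff Q is the nearest-rank (1-fraction) percentile — the
    ceil((1-fraction)*n)-th smallest value — and a value is flagged iff it
    is strictly greater than Q, so ties at the cutoff are never flagged and
    at most floor(fraction*n) values are flagged.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empirical_top_fraction needs at least one value")
    if arr.size < 20:
        warnings.warn(
            f"only {arr.size} values: the top {fraction:.0%} tail is poorly "
            "defined below 20 observations",
            stacklevel=2,
        )
    rank = int(np.ceil((1.0 - fraction) * arr.size))
    cutoff = np.sort(arr)[rank - 1]
    return arr > cutoff


def run_scan(
    records: Sequence[FrequencyRecord],
    popmap: PopulationMap,
    params: ScanParams = ScanParams(),
) -> list[ScanResult]:
    """Compute ΔAF and RFD on a pre-filtered site set, threshold each at its
    own top 5%, and mark sites significant when they pass both."""
    if len(popmap.references) < 2:
        raise ValueError(
            f"scan needs >=2 reference populations, got {len(popmap.references)}"
        )
    if not records:
        return []
    dafs = np.array([delta_af(rec, popmap) for rec in records])
    rfds = np.array([rfd(rec, popmap) for rec in records])
    pass_daf = empirical_top_fraction(dafs, params.top_fraction)
    pass_rfd = empirical_top_fraction(rfds, params.top_fraction)
    return [
        ScanResult(rec.site, float(d), float(r), bool(pd_), bool(pr))
        for rec, d, r, pd_, pr in zip(records, dafs, rfds, pass_daf, pass_rfd)
    ]


def scan_deletions(
    records: Sequence[FrequencyRecord],
    popmap: PopulationMap,
    params: ScanParams = ScanParams(),
) -> list[ScanResult]:
    """Convenience composition: scan_filter then run_scan."""
    return run_scan(scan_filter(records, popmap, params), popmap, params)


def build_regions(
    results: Sequence[ScanResult],
    join_gap: int = 100_000,
) -> list[SelectionRegion]:
    """Merge significant sites into regions: per chromosome, consecutive
    significant sites whose inter-site gap (bp between the end of one and
    the start of the next) is <= ``join_gap`` share a region; the region
    spans the members' envelope."""
    sig = sorted(
        (r for r in results if r.significant),
        key=lambda r: (r.site.chrom, r.site.start, r.site.end),
    )
    regions: list[SelectionRegion] = []
    current: list[ScanResult] = []

    def _flush() -> None:
        if current:
            regions.append(
                SelectionRegion(
                    current[0].site.chrom,
                    min(r.site.start for r in current),
                    max(r.site.end for r in current),
                    tuple(current),
                )
            )

    cur_chrom: Optional[str] = None
    cur_end = 0
    for res in sig:
        site = res.site
        if site.chrom != cur_chrom or site.start - cur_end - 1 > join_gap:
            _flush()
            current = [res]
            cur_chrom, cur_end = site.chrom, site.end
        else:
            current.append(res)
            cur_end = max(cur_end, site.end)
    _flush()
    return regions


def plot_rfd(
    results: Sequence[ScanResult],
    path: str,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Manhattan-style plot of RFD along the genome, marking the top-5%
    cutoff and significant sites."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("nothing to plot")
    chroms = list(dict.fromkeys(r.site.chrom for r in results))
    if chrom_lengths is None:
        chrom_lengths = {
            c: max(r.site.end for r in results if r.site.chrom == c) for c in chroms
        }
    offsets = {}
    total = 0
    for c in chroms:
        offsets[c] = total
        total += chrom_lengths[c]
    xs = np.array([offsets[r.site.chrom] + r.site.start for r in results])
    ys = np.array([r.rfd for r in results])
    sig = np.array([r.significant for r in results])

    fig, ax = plt.subplots(figsize=(9, 3))
    for i, c in enumerate(chroms):
        mask = np.array([r.site.chrom == c for r in results])
        ax.scatter(xs[mask], ys[mask], s=6, color=["0.45", "0.7"][i % 2])
    ax.scatter(xs[sig], ys[sig], s=12, color="crimson", label="significant")
    rfds = np.sort(ys)
    cutoff = rfds[int(np.ceil(0.95 * len(rfds))) - 1]
    ax.axhline(cutoff, ls="--", lw=0.8, color="k")
    ax.set_xticks([offsets[c] + chrom_lengths[c] / 2 for c in chroms])
    ax.set_xticklabels(chroms, fontsize=7)
    ax.set_ylabel("RFD")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
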