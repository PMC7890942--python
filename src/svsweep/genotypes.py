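"""Consensus genotyping and allele-frequency estimation.

A site/sample genotype is accepted when at least two genotyping callers
assert the same non-missing genotype; anything short of two concordant
calls is missing. Allele frequencies are estimated per population as
(2*hom_alt + het) / (2 * non-missing samples); the pooled frequency is
count-pooled over all samples of the scan populations jointly, i.e. the
sample-size-weighted combination of allele counts, not the mean of the
per-population frequencies.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    MISSING,
    ConsensusSV,
    FrequencyRecord,
    GenotypeMatrix,
    PopulationMap,
    SVCall,
)


def consensus_genotype(per_caller: Mapping[str, int]) -> int:
    """Genotype asserted by >=2 callers, else MISSING.

    Missing entries never count as agreement. With more than three callers
    a two-way tie at >=2 votes is unresolvable and yields MISSING.
    """
    votes: dict[int, int] = {}
    for gt in per_caller.values():
        if gt != MISSING:
            votes[gt] = votes.get(gt, 0) + 1
    if not votes:
        return MISSING
    best = max(votes.values())
    if best < 2:
        return MISSING
    winners = [gt for gt, n in votes.items() if n == best]
    return winners[0] if len(winners) == 1 else MISSING


def _consensus_codes(stack: np.ndarray) -> np.ndarray:
    """Vectorised consensus over a (n_callers, sites, samples) code stack."""
    votes = np.stack([(stack == g).sum(axis=0) for g in (0, 1, 2)])
    best = votes.max(axis=0)
    top = (votes == best).sum(axis=0)
    winner = votes.argmax(axis=0).astype(np.int8)
    out = np.where((best >= 2) & (top == 1), winner, np.int8(MISSING))
    return out.astype(np.int8)


def build_genotype_matrix(
    consensus: Sequence[ConsensusSV],
    callsets: Mapping[str, Sequence[SVCall]],
    popmap: PopulationMap,
    genotyping_callers: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Per-sample consensus genotypes at each merged site.

    The member-call <-> site assignment comes from the merge clusters
    (``ConsensusSV.members``). ``genotyping_callers`` defaults to every
    caller whose calls carry genotypes. If one caller contributed several
    member calls to a site, the first in coordinate order is used.
    """
    samples = popmap.samples
    if genotyping_callers is None:
        genotyping_callers = sorted(
            caller
            for caller, calls in callsets.items()
            if any(c.genotypes for c in calls)
        )
    if not genotyping_callers:
        raise ValueError("no caller in the call sets carries genotypes")

    covered = set()
    for caller in genotyping_callers:
        for call in callsets[caller]:
            if call.genotypes:
                covered.update(call.genotypes)
    for sample in samples:
        if sample not in covered:
            raise ValueError(
                f"sample {sample!r} from the population map is absent from "
                "every genotyping call set"
            )

    n_sites, n_samples = len(consensus), len(samples)
    sample_idx = {s: j for j, s in enumerate(samples)}
    stack = np.full((len(genotyping_callers), n_sites, n_samples), MISSING, dtype=np.int8)
    caller_idx = {c: k for k, c in enumerate(genotyping_callers)}
    for i, sv in enumerate(consensus):
        seen: set[str] = set()
        for member in sv.members:  # members are in coordinate order
            k = caller_idx.get(member.caller)
            if k is None or member.caller in seen or not member.genotypes:
                continue
            seen.add(member.caller)
            for sample, gt in member.genotypes.items():
                j = sample_idx.get(sample)
                if j is not None:
                    stack[k, i, j] = gt
    return GenotypeMatrix(list(consensus), samples, _consensus_codes(stack))


def allele_frequencies(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> list[FrequencyRecord]:
    """Per-population and pooled alt-allele frequencies for every site.

    Missing genotypes are excluded from denominators. Populations with zero
    non-missing genotypes at a site get frequency ``None`` (the site is
    flagged rather than coerced to 0).
    """
    codes = matrix.codes
    sample_pos = {s: j for j, s in enumerate(matrix.samples)}
    pops = popmap.populations
    pop_cols = {
        pop: np.array(
            [sample_pos[s] for s in popmap.samples_in(pop) if s in sample_pos],
            dtype=np.intp,
        )
        for pop in pops
    }

    def _af(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nm = (sub != MISSING).sum(axis=1)
        alt = np.where(sub != MISSING, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(nm > 0, alt / np.maximum(2 * nm, 1), np.nan)
        return af, nm

    per_pop = {pop: _af(codes[:, cols]) for pop, cols in pop_cols.items() if cols.size}
    scan_cols = np.concatenate(
        [pop_cols[pop] for pop in popmap.scan_populations if pop_cols[pop].size]
    )
    pooled_af, _ = _af(codes[:, scan_cols])

    records = []
    for i, site in enumerate(matrix.sites):
        freqs = {}
        counts = {}
        for pop in pops:
            if pop not in per_pop:
                freqs[pop], counts[pop] = None, 0
                continue
            af, nm = per_pop[pop]
            counts[pop] = int(nm[i])
            freqs[pop] = float(af[i]) if nm[i] > 0 else None
        pooled = float(pooled_af[i]) if not np.isnan(pooled_af[i]) else None
        records.append(FrequencyRecord(site, freqs, pooled, counts))
    return records
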