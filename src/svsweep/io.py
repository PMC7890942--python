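"""Readers and writers for the formats the pipeline touches.

VCF records are read through cyvcf2 (htslib) so malformed files fail the way
a production VCF parser fails; the writers emit plain VCF 4.2 / TSV / BED
text so the round-trip contract (read(write(x)) == x) is exact.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    GENOTYPE_CODES,
    GENOTYPE_NAMES,
    MISSING,
    SPANNING_TYPES,
    SVTYPES,
    ConsensusSV,
    GeneModel,
    GenotypeMatrix,
    PopulationMap,
    SVCall,
    SVFormatError,
)

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based inclusive end position (mate position for TRA)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Structural variant length in bp">',
    '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome for TRA">',
    '##INFO=<ID=END2,Number=1,Type=Integer,Description="Mate position for TRA">',
    '##INFO=<ID=SUPP_CALLERS,Number=.,Type=String,Description="Callers supporting the consensus site">',
    '##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Number of distinct supporting callers">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _check_sorted(calls: Sequence) -> None:
    seen_chroms: set[str] = set()
    prev_chrom: Optional[str] = None
    prev_start = 0
    for call in calls:
        if call.chrom != prev_chrom:
            if call.chrom in seen_chroms:
                raise ValueError(f"input not sorted: chromosome {call.chrom} is split")
            seen_chroms.add(call.chrom)
            prev_chrom, prev_start = call.chrom, call.start
        elif call.start < prev_start:
            raise ValueError(
                f"input not sorted: {call.chrom}:{call.start} after {prev_start}"
            )
        else:
            prev_start = call.start


def write_sv_vcf(
    calls: Sequence[SVCall | ConsensusSV],
    path: str | os.PathLike,
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Write calls (sorted by chrom, start) as a VCF 4.2 file.

    Consensus records carry SUPP_CALLERS/NCALLERS; calls with genotypes get
    GT columns for ``samples`` (default: the sorted union of sample names
    seen across calls, so pass an explicit order when it matters).
    """
    _check_sorted(calls)
    if samples is None:
        names: set[str] = set()
        for call in calls:
            gts = getattr(call, "genotypes", None)
            if gts:
                names.update(gts)
        samples = sorted(names)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom in dict.fromkeys(c.chrom for c in calls):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            cols += ["FORMAT", *samples]
        fh.write("\t".join(cols) + "\n")
        for call in calls:
            info = [f"SVTYPE={call.svtype}"]
            if call.svtype == "TRA":
                info.append(f"END={call.start}")
                info.append(f"CHR2={call.mate_chrom}")
                info.append(f"END2={call.mate_pos}")
            else:
                info.append(f"END={call.end}")
                info.append(f"SVLEN={call.svlen}")
            if isinstance(call, ConsensusSV):
                info.append("SUPP_CALLERS=" + ",".join(call.callers))
                info.append(f"NCALLERS={call.n_callers}")
            fields = [
                call.chrom,
                str(call.start),
                call.site_id,
                "N",
                f"<{call.svtype}>",
                ".",
                "PASS",
                ";".join(info),
            ]
            if samples:
                gts = getattr(call, "genotypes", None) or {}
                fields.append("GT")
                fields += [_GT_STRINGS[gts.get(s, MISSING)] for s in samples]
            fh.write("\t".join(fields) + "\n")


def _parse_vcf_records(path: str | os.PathLike):
    """Yield (index, record, samples) for each VCF record, with error context."""
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise SVFormatError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    idx = 0
    while True:
        try:
            rec = next(vcf, None)
        except Exception as exc:
            raise SVFormatError(f"{path}: malformed record #{idx + 1}: {exc}") from exc
        if rec is None:
            break
        idx += 1
        yield idx, rec, samples
    vcf.close()


def _record_to_call(idx, rec, samples, caller: str) -> Optional[SVCall]:
    if rec.ALT and len(rec.ALT) > 1:
        raise SVFormatError(
            f"record #{idx} at {rec.CHROM}:{rec.POS}: multi-allelic SV records "
            "are not supported (sites are treated as biallelic)"
        )
    svtype = rec.INFO.get("SVTYPE")
    if svtype is None:
        raise SVFormatError(f"record #{idx} at {rec.CHROM}:{rec.POS}: missing SVTYPE")
    if svtype not in SVTYPES:
        logger.warning(
            "record #%d at %s:%d: unknown SVTYPE %r skipped", idx, rec.CHROM, rec.POS, svtype
        )
        return None
    pos = int(rec.POS)
    end_info = rec.INFO.get("END")
    svlen_info = rec.INFO.get("SVLEN")
    if isinstance(svlen_info, (tuple, list)):
        svlen_info = svlen_info[0]

    genotypes = None
    if samples:
        genotypes = {}
        for s, gt in zip(samples, rec.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                genotypes[s] = MISSING
            elif any(a > 1 for a in alleles):
                raise SVFormatError(
                    f"record #{idx} at {rec.CHROM}:{pos}: non-biallelic genotype for {s}"
                )
            else:
                genotypes[s] = int(sum(alleles))

    try:
        if svtype == "TRA":
            mate_chrom = rec.INFO.get("CHR2") or rec.CHROM
            # our writer uses END2; delly-style TRA records put the mate in END
            end2 = rec.INFO.get("END2")
            if end2 is not None:
                mate_pos = int(end2)
            else:
                mate_pos = int(end_info) if end_info is not None else pos
            return SVCall(rec.CHROM, pos, pos, "TRA", 0, caller,
                          genotypes=genotypes, mate_chrom=mate_chrom, mate_pos=mate_pos)
        if svtype == "INS":
            if svlen_info is None:
                raise SVFormatError(
                    f"record #{idx} at {rec.CHROM}:{pos}: INS record lacks SVLEN"
                )
            return SVCall(rec.CHROM, pos, pos, "INS", abs(int(svlen_info)), caller,
                          genotypes=genotypes)
        # spanning types: END wins; fall back to POS + |SVLEN| - 1
        if end_info is not None:
            end = int(end_info)
        elif svlen_info is not None:
            end = pos + abs(int(svlen_info)) - 1
        else:
            raise SVFormatError(
                f"record #{idx} at {rec.CHROM}:{pos}: {svtype} record lacks both END and SVLEN"
            )
        return SVCall(rec.CHROM, pos, end, svtype, end - pos + 1, caller,
                      genotypes=genotypes)
    except ValueError as exc:
        raise SVFormatError(f"record #{idx} at {rec.CHROM}:{pos}: {exc}") from exc


def read_sv_vcf(path: str | os.PathLike, caller: str) -> list[SVCall]:
    """Read one caller's SV call set from a VCF 4.x file.

    Coordinates are VCF POS and INFO/END; when END is absent for a spanning
    type, END = POS + |SVLEN| - 1. Records with an SVTYPE outside
    DEL/INS/INV/DUP/TRA are skipped with a warning; malformed records raise
    :class:`SVFormatError` naming the record.
    """
    calls = []
    for idx, rec, samples in _parse_vcf_records(path):
        call = _record_to_call(idx, rec, samples, caller)
        if call is not None:
            calls.append(call)
    return calls


def read_consensus_vcf(path: str | os.PathLike) -> list[ConsensusSV]:
    """Read a consensus VCF written by :func:`write_sv_vcf` back into
    :class:`ConsensusSV` records (members are not recoverable from VCF)."""
    out = []
    for idx, rec, samples in _parse_vcf_records(path):
        call = _record_to_call(idx, rec, samples, caller="consensus")
        if call is None:
            continue
        callers = rec.INFO.get("SUPP_CALLERS")
        if callers is None:
            raise SVFormatError(
                f"record #{idx} at {rec.CHROM}:{rec.POS}: missing SUPP_CALLERS"
            )
        if isinstance(callers, str):
            callers = tuple(callers.split(","))
        out.append(
            ConsensusSV(call.chrom, call.start, call.end, call.svtype, call.svlen,
                        tuple(callers), mate_chrom=call.mate_chrom, mate_pos=call.mate_pos)
        )
    return out


# --------------------------------------------------------------------------
# Population map
# --------------------------------------------------------------------------

def read_population_map(
    path: str | os.PathLike,
    focal: str,
    references: Optional[Sequence[str]] = None,
) -> PopulationMap:
    """Read a sample->population TSV (columns: sample, population).

    A header row named ``sample``/``population`` is optional. ``references``
    defaults to every non-focal population in order of first appearance.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise SVFormatError(f"{path}: population map needs 2 columns")
    if df.iloc[0, 0].lower() == "sample":
        df = df.iloc[1:]
    samples = df.iloc[:, 0].tolist()
    pops = df.iloc[:, 1].tolist()
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise SVFormatError(f"{path}: duplicate sample(s): {sorted(dupes)}")
    assignments = dict(zip(samples, pops))
    if focal not in set(pops):
        raise SVFormatError(f"{path}: focal population {focal!r} absent from file")
    if references is None:
        references = [p for p in dict.fromkeys(pops) if p != focal]
    return PopulationMap(assignments, focal, tuple(references))


def write_population_map(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


# --------------------------------------------------------------------------
# Gene models
# --------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GFF3 (1-based).

    BED4 records become single-exon genes spanning the whole interval (the
    BED default when block fields are absent); BED12 block fields give the
    exon structure. The format is chosen by extension, falling back to
    content sniffing. Internal coordinates are 1-based inclusive.
    """
    name = str(path).lower()
    if name.endswith((".bed", ".bed4", ".bed12")):
        return _read_bed(path)
    if name.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return _read_gff3(path)
            if line.strip() and not line.startswith("#"):
                ncols = len(line.rstrip("\n").split("\t"))
                if ncols == 9:
                    return _read_gff3(path)
                return _read_bed(path)
    return []


def _read_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if len(cols) < 4:
                    raise ValueError("BED gene line needs >=4 columns")
                chrom, bed_start, bed_end, gid = cols[0], int(cols[1]), int(cols[2]), cols[3]
                start, end = bed_start + 1, bed_end
                strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
                if len(cols) >= 12 and cols[9].strip():
                    sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
                    exons = tuple(
                        (start + off, start + off + size - 1)
                        for off, size in zip(offsets, sizes)
                    )
                else:
                    exons = ((start, end),)
                genes.append(GeneModel(gid, chrom, start, end, strand, exons))
            except ValueError as exc:
                raise SVFormatError(f"{path} line {lineno}: {exc}") from exc
    return genes


def _read_gff3(path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise SVFormatError(f"{path}: cannot parse as GFF3: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        biotype = (
            feat.attributes.get("biotype", feat.attributes.get("gene_biotype", ["protein_coding"]))
        )[0]
        exons = tuple(
            (child.start, child.end)
            for child in db.children(feat, featuretype="exon", order_by="start")
        )
        if not exons:
            exons = ((feat.start, feat.end),)
        strand = feat.strand if feat.strand in "+-" else "+"
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end, strand, exons, biotype))
    return genes


def write_gene_models_bed(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as BED12 (exon structure in the block fields)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(hi - lo + 1) for lo, hi in g.exons) + ","
            offsets = ",".join(str(lo - g.start) for lo, hi in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.start - 1), str(g.end), g.gene_id, "0", g.strand,
                        str(g.start - 1), str(g.end), "0", str(len(g.exons)), sizes, offsets,
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# Genotype matrix / frequency / scan tables
# --------------------------------------------------------------------------

def write_genotype_matrix(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a sites x samples TSV of genotype names."""
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(matrix.samples) + "\n")
        for sid, row in zip(matrix.site_ids, matrix.codes):
            fh.write(sid + "\t" + "\t".join(GENOTYPE_NAMES[int(c)] for c in row) + "\n")


def read_genotype_matrix(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a genotype-matrix TSV; sites come back as site-id strings."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        codes = df.map(GENOTYPE_CODES.__getitem__).to_numpy(dtype=np.int8)
    except KeyError as exc:
        raise SVFormatError(f"{path}: unknown genotype label {exc}") from exc
    return GenotypeMatrix(list(df.index), list(df.columns), codes)


def frequency_table(records: Sequence, popmap: PopulationMap) -> pd.DataFrame:
    """Frequency records as a DataFrame (one af_/n_ column pair per scan
    population plus the count-pooled frequency)."""
    pops = popmap.scan_populations
    rows = []
    for rec in records:
        site = rec.site
        row = {
            "site_id": rec.site_id,
            "chrom": getattr(site, "chrom", None),
            "start": getattr(site, "start", None),
            "end": getattr(site, "end", None),
            "svtype": getattr(site, "svtype", None),
            "svlen": getattr(site, "svlen", None),
        }
        for pop in pops:
            row[f"af_{pop}"] = rec.freqs.get(pop)
            row[f"n_{pop}"] = rec.n_nonmissing.get(pop)
        row["f_pooled"] = rec.pooled
        rows.append(row)
    return pd.DataFrame(rows)


def write_frequency_table(records: Sequence, popmap: PopulationMap,
                          path: str | os.PathLike) -> None:
    frequency_table(records, popmap).to_csv(path, sep="\t", index=False)


def scan_table(results: Sequence) -> pd.DataFrame:
    rows = []
    for r in results:
        site = r.site
        rows.append(
            {
                "site_id": r.site_id,
                "chrom": getattr(site, "chrom", None),
                "start": getattr(site, "start", None),
                "end": getattr(site, "end", None),
                "delta_af": r.delta_af,
                "rfd": r.rfd,
                "pass_daf": r.pass_daf,
                "pass_rfd": r.pass_rfd,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def write_scan_results(results: Sequence, path: str | os.PathLike) -> None:
    scan_table(results).to_csv(path, sep="\t", index=False)


def write_regions(regions: Sequence, bed_path: str | os.PathLike,
                  tsv_path: Optional[str | os.PathLike] = None) -> None:
    """Write selection regions as BED4 (and optionally a TSV with site
    counts and overlapping gene lists)."""
    with open(bed_path, "w") as fh:
        for i, region in enumerate(regions, 1):
            fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\tregion_{i}\n")
    if tsv_path is not None:
        rows = [
            {
                "region_id": f"region_{i}",
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_sites": r.n_sites,
                "genes": ",".join(r.genes),
            }
            for i, r in enumerate(regions, 1)
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def consensus_summary(svs: Sequence[ConsensusSV]) -> dict[str, pd.DataFrame]:
    """Per-type counts plus length histograms (100-bp bins for deletions,
    10-bp bins for insertions)."""
    counts = pd.Series([sv.svtype for sv in svs]).value_counts().rename_axis("svtype")
    out = {"type_counts": counts.to_frame("n").reset_index()}
    for svtype, binsize in (("DEL", 100), ("INS", 10)):
        lens = np.array([sv.svlen for sv in svs if sv.svtype == svtype])
        if lens.size:
            bins = np.arange(0, lens.max() + binsize + 1, binsize)
            hist, edges = np.histogram(lens, bins=bins)
            df = pd.DataFrame(
                {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int), "n": hist}
            )
            df = df[df["n"] > 0].reset_index(drop=True)
        else:
            df = pd.DataFrame(columns=["bin_start", "bin_end", "n"])
        out[f"{svtype.lower()}_length_hist"] = df
    return out


def write_consensus_summary(svs: Sequence[ConsensusSV], prefix: str | os.PathLike) -> None:
    for name, df in consensus_summary(svs).items():
        df.to_csv(f"{prefix}.{name}.tsv", sep="\t", index=False)
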