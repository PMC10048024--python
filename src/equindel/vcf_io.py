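"""VCF / GVF reading and writing, and multi-sample integration.

Reads anchored VCF 4.2 with per-sample GT calls through :mod:`pysam`,
keeps only insertion/deletion allele pairs (unequal Ref/Alt lengths),
normalizes allele representations, and merges per-sample call sets into
one loci-by-samples :class:`~equindel.loci.GenotypeMatrix`.

The registered-variant reader accepts both an anchored VCF rendering and
an Ensembl-style GVF rendering (anchor-free ``Reference_seq`` /
``Variant_seq`` attributes); both reduce to the same normalized event
keys, so novelty lookup is format-independent.
"""

from __future__ import annotations

import io
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .loci import (
    MISSING,
    GenotypeMatrix,
    MalformedVariantError,
    VariantLocus,
    event_key,
    is_indel_pair,
    normalize_alleles,
    sort_loci_order,
)
from .novelty import KnownVariantSet

pysam.set_verbosity(0)  # silence htslib header-sanity chatter on plain-text VCFs

_INFO_FLOAT_FIELDS = ("QD", "MQ0", "HRun", "SB")


def _format_float(x: float) -> str:
    s = f"{float(x):.6g}"
    return s


def natural_chrom_order(chroms: Iterable[str]) -> list[str]:
    """Autosomes numerically, then X, MT, then anything else."""
    def rank(c: str):
        name = c[3:] if c.lower().startswith("chr") else c
        if name.isdigit():
            return (0, int(name), c)
        if name.upper() == "X":
            return (1, 0, c)
        if name.upper() in {"MT", "M"}:
            return (2, 0, c)
        return (3, 0, c)

    return sorted(set(chroms), key=rank)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, normalize: bool = True) -> GenotypeMatrix:
    """Load INDEL records from a VCF into a genotype matrix.

    SNV records and equal-length substitutions are excluded.  On records
    mixing SNV and INDEL alternative alleles, the equal-length alleles are
    dropped and calls referencing them become missing.  Per-record INFO
    (DP, QUAL, QD, MQ0, HRun, SB, ANN) is attached to ``matrix.info``.
    """
    loci: list[VariantLocus] = []
    infos: list[dict] = []
    rows: list[np.ndarray] = []
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise MalformedVariantError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vf.header.samples)
    for line_no, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
        if rec.alts is None:
            continue
        keep = [a for a in rec.alts if is_indel_pair(rec.ref, a)]
        if not keep:
            continue
        # remap allele indices after dropping non-INDEL alts
        remap = {0: 0}
        for old, a in enumerate(rec.alts, start=1):
            if a in keep:
                remap[old] = 1 + keep.index(a)
        pos, ref, alts = rec.pos, rec.ref, tuple(keep)
        if normalize:
            pos, ref, alts = normalize_alleles(pos, ref, alts)
        try:
            locus = VariantLocus(rec.chrom, pos, ref, alts)
        except MalformedVariantError as exc:
            raise MalformedVariantError(f"{path}: record {line_no}: {exc}") from exc
        row = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or len(gt) != 2 or any(g is None for g in gt):
                continue
            if any(g not in remap for g in gt):
                continue  # call referenced a dropped non-INDEL allele
            row[j] = sorted(remap[g] for g in gt)
        info = {}
        if rec.qual is not None:
            info["QUAL"] = float(rec.qual)
        for k in ("DP", *(f for f in _INFO_FLOAT_FIELDS)):
            if k in rec.info:
                v = rec.info[k]
                info[k] = float(v) if k != "DP" else int(v)
        if "ANN" in rec.info:
            ann = rec.info["ANN"]
            info["ANN"] = ",".join(ann) if isinstance(ann, tuple) else str(ann)
        loci.append(locus)
        infos.append(info)
        rows.append(row)
    calls = np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int16)
    return GenotypeMatrix(loci, samples, calls, infos)


def _vcf_header(samples: Sequence[str], chrom_lengths: Optional[dict] = None) -> str:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=equindel\n")
    if chrom_lengths:
        for name, length in chrom_lengths.items():
            buf.write(f"##contig=<ID={name},length={length}>\n")
    buf.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
    buf.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
    buf.write('##INFO=<ID=MQ0,Number=1,Type=Float,Description="Reads with mapping quality zero">\n')
    buf.write('##INFO=<ID=HRun,Number=1,Type=Float,Description="Homopolymer run length">\n')
    buf.write('##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias score">\n')
    buf.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: Allele|Annotation|Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|Biotype">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *samples]
    buf.write("\t".join(cols) + "\n")
    return buf.getvalue()


def format_info(info: dict) -> str:
    parts = []
    if "DP" in info:
        parts.append(f"DP={int(info['DP'])}")
    for k in _INFO_FLOAT_FIELDS:
        if k in info:
            parts.append(f"{k}={_format_float(info[k])}")
    if info.get("ANN"):
        parts.append(f"ANN={info['ANN']}")
    return ";".join(parts) if parts else "."


def write_vcf(path: str, matrix: GenotypeMatrix, chrom_lengths: Optional[dict] = None) -> None:
    """Write a genotype matrix as uncompressed VCF 4.2 (deterministic text)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(matrix.samples, chrom_lengths))
        for i, locus in enumerate(matrix.loci):
            info = matrix.info[i]
            qual = _format_float(info["QUAL"]) if "QUAL" in info else "."
            gts = []
            for j in range(matrix.n_samples):
                a, b = matrix.calls[i, j]
                gts.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.pos),
                        ".",
                        locus.ref,
                        ",".join(locus.alts),
                        qual,
                        ".",
                        format_info(info),
                        "GT",
                        *gts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate(
    paths: Sequence[str],
    assume_hom_ref: bool = False,
    chrom_order: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Merge per-sample VCFs into one loci-by-samples matrix.

    Loci are matched on the normalized (chromosome, position, Ref) anchor;
    distinct Alt alleles at one anchor merge into a multiallelic locus with
    Alts ordered by (length, sequence).  A sample without a record at a
    locus seen in other samples receives a missing call by default;
    ``assume_hom_ref=True`` assigns homozygous reference instead (for
    inputs that assert reference calls, gVCF-style).

    Duplicate sample names across files are rejected.
    """
    if not paths:
        raise ValueError("integrate() needs at least one VCF path")
    samples: list[str] = []
    # key -> {"alts": list, "calls": {sample: (a0, a1) in local alt space}}
    merged: dict[tuple, dict] = {}
    all_info: dict[tuple, dict] = {}
    for path in paths:
        m = read_vcf(path)
        for s in m.samples:
            if s in samples:
                raise ValueError(f"duplicate sample name {s!r} in {path}")
        base = len(samples)
        samples.extend(m.samples)
        for i, locus in enumerate(m.loci):
            key = (locus.chrom, locus.pos, locus.ref)
            slot = merged.setdefault(key, {"alts": [], "calls": {}})
            all_info.setdefault(key, m.info[i])
            local = []
            for alt in locus.alts:
                if alt not in slot["alts"]:
                    slot["alts"].append(alt)
                local.append(slot["alts"].index(alt) + 1)
            remap = {0: 0, **{k + 1: v for k, v in enumerate(local)}}
            for j, s in enumerate(m.samples):
                a, b = m.calls[i, j]
                if a == MISSING:
                    continue
                slot["calls"][base + j] = (remap[int(a)], remap[int(b)])
    order = list(chrom_order) if chrom_order else natural_chrom_order(k[0] for k in merged)
    default = (0, 0) if assume_hom_ref else (MISSING, MISSING)
    loci: list[VariantLocus] = []
    infos: list[dict] = []
    rows: list[np.ndarray] = []
    for key in merged:
        chrom, pos, ref = key
        slot = merged[key]
        alts_sorted = sorted(slot["alts"], key=lambda a: (len(a), a))
        alt_remap = {0: 0, **{slot["alts"].index(a) + 1: k + 1 for k, a in enumerate(alts_sorted)}}
        locus = VariantLocus(chrom, pos, ref, tuple(alts_sorted))
        row = np.empty((len(samples), 2), dtype=np.int16)
        for j in range(len(samples)):
            pair = slot["calls"].get(j)
            if pair is None:
                row[j] = default
            else:
                row[j] = sorted(alt_remap[g] for g in pair)
        loci.append(locus)
        infos.append(all_info[key])
        rows.append(row)
    calls = np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int16)
    matrix = GenotypeMatrix(loci, samples, calls, infos)
    idx = sort_loci_order(matrix.loci, order)
    return matrix.subset(np.asarray(idx))


# ---------------------------------------------------------------------------
# Known-variant sets (VCF and Ensembl-style GVF)
# ---------------------------------------------------------------------------

def read_known_set(path: str, fmt: str) -> KnownVariantSet:
    """Load a registered-variant collection from VCF or GVF.

    Every Ref/Alt pair is stored under its normalized event key; lookups
    are exact-match on those keys.
    """
    if fmt == "vcf":
        return _known_from_vcf(path)
    if fmt == "gvf":
        return _known_from_gvf(path)
    raise ValueError(f"unknown known-set format {fmt!r} (expected 'vcf' or 'gvf')")


def _known_from_vcf(path: str) -> KnownVariantSet:
    keys: dict[tuple, str] = {}
    n = 0
    vf = pysam.VariantFile(path)
    for rec in vf:
        if rec.alts is None:
            continue
        ident = rec.id or f"{rec.chrom}:{rec.pos}"
        for alt in rec.alts:
            if not is_indel_pair(rec.ref, alt):
                continue
            pos, ref, (a,) = normalize_alleles(rec.pos, rec.ref, (alt,))
            keys[event_key(rec.chrom, pos, ref, a)] = ident
            n += 1
    return KnownVariantSet(keys, total_registered=n)


def _known_from_gvf(path: str) -> KnownVariantSet:
    keys: dict[tuple, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise MalformedVariantError(f"{path}: GVF line with {len(cols)} columns")
            chrom, _source, sotype, start, end, _score, _strand, _phase, attrs = cols[:9]
            start = int(start)
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            ident = attr.get("ID", f"{chrom}:{start}")
            ref_seq = attr.get("Reference_seq", "-")
            for var_seq in attr.get("Variant_seq", "-").split(","):
                if var_seq == ref_seq:
                    continue
                if ref_seq == "-" and var_seq != "-":
                    keys[("ins", chrom, start, var_seq)] = ident
                elif var_seq == "-" and ref_seq != "-":
                    keys[("del", chrom, start, ref_seq)] = ident
                else:
                    # length-changing substitution, keyed anchor-free
                    keys[("cx", chrom, start, ref_seq, var_seq)] = ident
                n += 1
    return KnownVariantSet(keys, total_registered=n)


def write_known_set_vcf(
    path: str,
    entries: Sequence[tuple[str, int, str, str, str]],
    chrom_lengths: Optional[dict] = None,
) -> None:
    """Write registered pairs as an anchored sites-only VCF.

    ``entries``: (chrom, pos, ref, alt, identifier) in output order.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=equindel-knownset\n")
        for name, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, ident in entries:
            fh.write(f"{chrom}\t{pos}\t{ident}\t{ref}\t{alt}\t.\t.\t.\n")


def write_known_set_gvf(path: str, entries: Sequence[tuple[str, int, str, str, str]]) -> None:
    """Write registered pairs as Ensembl-style GVF 1.0 (anchor-free).

    Insertions use a zero-length interval (start = anchor+1, end = anchor);
    deletions span the deleted bases.
    """
    with open(path, "w") as fh:
        fh.write("##gvf-version 1.0\n")
        for chrom, pos, ref, alt, ident in entries:
            npos, nref, (nalt,) = normalize_alleles(pos, ref, (alt,))
            if len(nref) == 1 and nalt[0] == nref:
                start, end = npos + 1, npos
                sotype, ref_seq, var_seq = "insertion", "-", nalt[1:]
            elif len(nalt) == 1 and nref[0] == nalt:
                start, end = npos + 1, npos + len(nref) - 1
                sotype, ref_seq, var_seq = "deletion", nref[1:], "-"
            else:
                start, end = npos, npos + len(nref) - 1
                sotype, ref_seq, var_seq = "indel", nref, nalt
            fh.write(
                f"{chrom}\tequindel\t{sotype}\t{start}\t{end}\t.\t+\t.\t"
                f"ID={ident};Reference_seq={ref_seq};Variant_seq={var_seq}\n"
            )


# ---------------------------------------------------------------------------
# Chromosome table
# ---------------------------------------------------------------------------

def read_chrom_table(path: str) -> dict[str, int]:
    """Two-column TSV (name, length-bp) -> ordered mapping."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'name<TAB>length'")
            table[parts[0]] = int(parts[1])
    return table


def write_chrom_table(path: str, table: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in table.items():
            fh.write(f"{name}\t{length}\n")
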