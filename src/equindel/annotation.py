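"""Functional annotation parsing and region summaries.

Consumes SnpEff-style ``ANN`` INFO strings (pipe-delimited, one entry per
comma-separated annotation) and reduces each locus to a single primary
functional class using a fixed precedence, so that region tallies
partition the locus set.  Also provides the frameshift/non-frameshift
split (an exonic INDEL shifts the reading frame iff its size delta is not
a multiple of 3), a scan for genes whose exonic frameshift loci carry no
reference allele in the whole population, and a category-by-frequency
density matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .loci import VariantLocus, chromosome_compartment, round_half_up
from .popstats import SiteFrequencyRecord

REGION_CLASSES = (
    "exon",
    "splice-site",
    "5'-UTR",
    "3'-UTR",
    "intron",
    "upstream",
    "downstream",
    "lncRNA",
    "pseudogene",
    "intergenic",
)
#: precedence for choosing one primary class per locus (highest first)
PRECEDENCE = {c: i for i, c in enumerate(REGION_CLASSES)}

FRAMESHIFT = "frameshift"
NON_FRAMESHIFT = "non-frameshift"
OTHER = "other"

_TERM_TO_REGION = {
    "frameshift_variant": "exon",
    "inframe_insertion": "exon",
    "inframe_deletion": "exon",
    "conservative_inframe_insertion": "exon",
    "conservative_inframe_deletion": "exon",
    "disruptive_inframe_insertion": "exon",
    "disruptive_inframe_deletion": "exon",
    "stop_gained": "exon",
    "stop_lost": "exon",
    "start_lost": "exon",
    "coding_sequence_variant": "exon",
    "exon_variant": "exon",
    "splice_acceptor_variant": "splice-site",
    "splice_donor_variant": "splice-site",
    "splice_region_variant": "splice-site",
    "5_prime_UTR_variant": "5'-UTR",
    "5_prime_UTR_truncation": "5'-UTR",
    "3_prime_UTR_variant": "3'-UTR",
    "3_prime_UTR_truncation": "3'-UTR",
    "intron_variant": "intron",
    "upstream_gene_variant": "upstream",
    "downstream_gene_variant": "downstream",
    "intergenic_region": "intergenic",
    "intragenic_variant": "intron",
    "non_coding_transcript_exon_variant": "lncRNA",
    "non_coding_transcript_variant": "lncRNA",
}

_FRAMESHIFT_TERMS = {"frameshift_variant"}
_INFRAME_TERMS = {
    "inframe_insertion",
    "inframe_deletion",
    "conservative_inframe_insertion",
    "conservative_inframe_deletion",
    "disruptive_inframe_insertion",
    "disruptive_inframe_deletion",
}


@dataclass
class AnnotationRecord:
    locus: VariantLocus
    region_class: str
    effect_class: str
    gene_id: str
    gene_name: str = ""
    impact: str = ""
    unannotated: bool = False

    @property
    def is_coding_exonic(self) -> bool:
        return self.region_class == "exon" and self.effect_class in (FRAMESHIFT, NON_FRAMESHIFT)


def _classify_entry(term: str, biotype: str) -> Optional[str]:
    b = biotype.lower()
    for t in term.split("&"):
        region = _TERM_TO_REGION.get(t)
        if region is None:
            continue
        if region in ("exon", "lncRNA") and "pseudogene" in b:
            return "pseudogene"
        if region == "exon" and ("lnc" in b or b in ("lincrna", "antisense")):
            return "lncRNA"
        return region
    return None


def parse_ann(ann: Optional[str], locus: VariantLocus) -> tuple[Optional[AnnotationRecord], int]:
    """Reduce one ANN string to the locus's primary annotation.

    Layout per entry: ``Allele|Annotation|Impact|Gene_Name|Gene_ID|
    Feature_Type|Feature_ID|Biotype|...`` — only the first eight fields
    are consulted.  Returns (record, n_malformed_entries); an empty or
    fully malformed ANN yields an "unannotated" intergenic record.
    """
    n_bad = 0
    candidates: list[AnnotationRecord] = []
    if ann:
        for entry in ann.split(","):
            fields = entry.split("|")
            if len(fields) < 2 or not fields[1]:
                n_bad += 1
                continue
            term = fields[1]
            impact = fields[2] if len(fields) > 2 else ""
            gene_name = fields[3] if len(fields) > 3 else ""
            gene_id = fields[4] if len(fields) > 4 else ""
            biotype = fields[7] if len(fields) > 7 else ""
            region = _classify_entry(term, biotype)
            if region is None:
                n_bad += 1
                continue
            if region == "exon":
                if any(t in _FRAMESHIFT_TERMS for t in term.split("&")):
                    effect = FRAMESHIFT
                elif any(t in _INFRAME_TERMS for t in term.split("&")):
                    effect = NON_FRAMESHIFT
                else:
                    effect = OTHER
            else:
                effect = OTHER
            candidates.append(
                AnnotationRecord(locus, region, effect, gene_id, gene_name, impact)
            )
    if not candidates:
        return (
            AnnotationRecord(locus, "intergenic", OTHER, "", unannotated=True),
            n_bad,
        )
    best = min(candidates, key=lambda r: PRECEDENCE[r.region_class])
    return best, n_bad


def annotate_matrix(loci: Sequence[VariantLocus], infos: Sequence[dict]) -> tuple[list[AnnotationRecord], int]:
    """Primary annotation per locus from per-record INFO maps."""
    records = []
    warnings = 0
    for locus, info in zip(loci, infos):
        rec, bad = parse_ann(info.get("ANN"), locus)
        records.append(rec)
        warnings += bad
    return records, warnings


def region_tally(records: Sequence[AnnotationRecord], collapsed: bool = False) -> pd.DataFrame:
    """Counts of loci per functional region and genome compartment.

    Each locus counts exactly once under its primary class, so column
    sums equal the per-compartment locus totals.  ``collapsed=True``
    folds lncRNA/pseudogene into the exon row and splice-site into the
    intron row, matching the compact seven-row report layout.
    """
    comps = ("autosomes", "X", "MT")
    classes = (
        ("upstream", "5'-UTR", "exon", "intron", "3'-UTR", "downstream", "intergenic")
        if collapsed
        else REGION_CLASSES
    )
    data = {c: {rc: 0 for rc in classes} for c in comps}
    for r in records:
        comp = chromosome_compartment(r.locus.chrom)
        if comp not in data:
            continue
        rc = r.region_class
        if collapsed:
            rc = {"lncRNA": "exon", "pseudogene": "exon", "splice-site": "intron"}.get(rc, rc)
        data[comp][rc] += 1
    df = pd.DataFrame(data)
    df = df.reindex(list(classes))
    df.index.name = "region"
    return df


def frameshift_consistency(record: AnnotationRecord) -> tuple[str, bool]:
    """Check the ANN effect label against the divisible-by-3 rule.

    Returns (effect_class, discrepant).  The rule says an exonic INDEL is
    a frameshift iff |size delta| mod 3 != 0; when the ANN label
    disagrees (annotation context can override the naive rule, e.g.
    alleles spanning intron/exon boundaries), the label wins and the
    discrepancy is reported.
    """
    if not record.is_coding_exonic:
        raise ValueError("frameshift consistency applies to coding exonic loci")
    delta = record.locus.size_delta
    rule = FRAMESHIFT if abs(delta) % 3 != 0 else NON_FRAMESHIFT
    return record.effect_class, record.effect_class != rule


def all_alt_frameshift_genes(
    records: Sequence[AnnotationRecord],
    frequencies: Sequence[SiteFrequencyRecord],
) -> pd.DataFrame:
    """Genes with exonic frameshift loci carrying zero Ref alleles.

    A locus qualifies when its primary annotation is an exonic frameshift
    and every called genotype carries only alternative alleles
    (ref_count == 0 with at least one call) — i.e. the reference allele
    is absent from the whole population.  Returns one row per qualifying
    locus with its gene; the distinct gene list is the scan result.
    """
    by_key = {f.locus.key: f for f in frequencies}
    rows = []
    for r in records:
        if r.effect_class != FRAMESHIFT:
            continue
        f = by_key.get(r.locus.key)
        if f is None or f.n_called == 0:
            continue
        if f.ref_count == 0:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "gene_name": r.gene_name,
                    "chrom": r.locus.chrom,
                    "pos": r.locus.pos,
                    "n_called": f.n_called,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "pos", "n_called"])


def density_category(record: AnnotationRecord) -> str:
    """Category used in the frequency-density matrix.

    Coding exonic loci split into frameshift / non-frameshift; all other
    loci report their primary region class.
    """
    if record.is_coding_exonic:
        return record.effect_class
    return record.region_class


def frequency_density(
    records: Sequence[AnnotationRecord],
    frequencies: Sequence[SiteFrequencyRecord],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Row-normalized density of loci across Ref-allele-frequency bins.

    Rows are annotation categories, columns equal-width Ref-frequency
    bins over [0, 1]; each cell is the percentage of the row's loci in
    that bin, so rows sum to 100.  Diallelic loci only.
    """
    by_key = {f.locus.key: f for f in frequencies}
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cats: dict[str, list[float]] = {}
    for r in records:
        f = by_key.get(r.locus.key)
        if f is None or not r.locus.is_diallelic or f.n_called == 0:
            continue
        cats.setdefault(density_category(r), []).append(f.ref_frequency)
    rows = {}
    for cat, freqs in sorted(cats.items()):
        hist, _ = np.histogram(freqs, bins=edges)
        # right-closed last bin already handled by histogram
        rows[cat] = 100.0 * hist / hist.sum()
    labels = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(n_bins)]
    df = pd.DataFrame(rows, index=labels).T
    df.index.name = "category"
    return df
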