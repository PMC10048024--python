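"""Suspect-locus signatures diagnostic of mapping artifacts.

Short-read mapping collapses near-identical duplicated regions onto one
reference locus; reads from the two copies then call a variant that is
heterozygous in *every* individual at MAF 0.5.  Under Hardy-Weinberg
random mating the probability of that genotype pattern is (2pq)^n — at
MAF 0.5 and n=101 samples, 2^-101 — so such loci are flagged as "fake
variant" candidates rather than true segregating sites.  The complementary
signature, homozygous-alternative in every sample, marks positions where
the reference assembly itself carries the minor (or erroneous) allele.

Flags are reported, never silently removed; downstream selection steps
(marker panels, population databases) can exclude them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .popstats import SiteFrequencyRecord

ALL_HET_MAF05 = "ALL_HET_MAF05"
ALL_ALT_HOM = "ALL_ALT_HOM"


@dataclass
class SuspectLocusReport:
    record: SiteFrequencyRecord
    signature: str
    n_samples_supporting: int
    complete_calls: bool
    novelty: str = "unknown"  # {novel, registered, unknown}

    @property
    def locus(self):
        return self.record.locus


@dataclass
class SuspectRegion:
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    n_suspect_loci: int
    signature_mix: dict[str, int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start beyond end")


def flag_all_het(
    records: Sequence[SiteFrequencyRecord],
    n_samples: int,
    require_complete: bool = True,
) -> list[SuspectLocusReport]:
    """Flag diallelic loci heterozygous in every sample at MAF 0.5.

    The strict signature requires a complete call set: every one of the
    ``n_samples`` genotypes called and heterozygous (which forces MAF 0.5
    exactly).  With ``require_complete=False``, loci where every *called*
    genotype is heterozygous are also flagged, marked incomplete.
    Loci reaching MAF 0.5 through a mix of homozygotes are never flagged.
    """
    out: list[SuspectLocusReport] = []
    for r in records:
        if not r.locus.is_diallelic or r.n_called == 0:
            continue
        all_het_called = r.n_het == r.n_called
        complete = r.n_called == n_samples
        if not all_het_called:
            continue
        if complete and r.maf == 0.5:
            out.append(SuspectLocusReport(r, ALL_HET_MAF05, r.n_het, True))
        elif not require_complete:
            out.append(SuspectLocusReport(r, ALL_HET_MAF05, r.n_het, False))
    return out


def flag_all_alt_hom(
    records: Sequence[SiteFrequencyRecord],
    n_samples: int,
    require_complete: bool = True,
) -> list[SuspectLocusReport]:
    """Flag diallelic loci homozygous-alternative in every sample."""
    out: list[SuspectLocusReport] = []
    for r in records:
        if not r.locus.is_diallelic or r.n_called == 0:
            continue
        if r.n_hom_alt != r.n_called:
            continue
        complete = r.n_called == n_samples
        if complete:
            out.append(SuspectLocusReport(r, ALL_ALT_HOM, r.n_hom_alt, True))
        elif not require_complete:
            out.append(SuspectLocusReport(r, ALL_ALT_HOM, r.n_hom_alt, False))
    return out


def cluster_suspects(
    reports: Sequence[SuspectLocusReport],
    max_gap: int = 100_000,
    min_loci: int = 10,
) -> list[SuspectRegion]:
    """Single-linkage merge of suspect loci into candidate regions.

    Consecutive suspect loci on one chromosome closer than ``max_gap`` bp
    join one region; regions holding fewer than ``min_loci`` loci are
    dropped.  Output regions are sorted and non-overlapping.
    """
    items = sorted(reports, key=lambda r: (r.locus.chrom, r.locus.pos))
    regions: list[SuspectRegion] = []
    group: list[SuspectLocusReport] = []

    def flush():
        if len(group) >= min_loci:
            mix: dict[str, int] = {}
            for g in group:
                mix[g.signature] = mix.get(g.signature, 0) + 1
            regions.append(
                SuspectRegion(
                    chrom=group[0].locus.chrom,
                    start=group[0].locus.pos,
                    end=group[-1].locus.pos,
                    n_suspect_loci=len(group),
                    signature_mix=mix,
                )
            )

    for rep in items:
        if group and (
            rep.locus.chrom != group[-1].locus.chrom
            or rep.locus.pos - group[-1].locus.pos > max_gap
        ):
            flush()
            group = []
        group.append(rep)
    if group:
        flush()
    return regions


def hwe_het_probability(n_samples: int, maf: float) -> float:
    """Probability that every sample is heterozygous under Hardy-Weinberg.

    (2 * maf * (1 - maf)) ** n_samples.  At maf 0.5 this is 2**-n: with
    101 diploid samples, ~3.9e-31 — the quantitative basis for treating
    the all-heterozygous signature as a mapping artifact.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return float((2.0 * maf * (1.0 - maf)) ** n_samples)


def suspect_report_tsv(reports: Sequence[SuspectLocusReport]) -> str:
    lines = ["chrom\tpos\tref\talt\tsignature\tn_supporting\tcomplete\tnovelty"]
    for r in reports:
        l = r.locus
        lines.append(
            f"{l.chrom}\t{l.pos}\t{l.ref}\t{','.join(l.alts)}\t{r.signature}"
            f"\t{r.n_samples_supporting}\t{int(r.complete_calls)}\t{r.novelty}"
        )
    return "\n".join(lines) + "\n"
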