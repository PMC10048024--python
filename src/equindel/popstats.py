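"""Population summaries: allele frequencies, spectra, sizes, densities.

All statistics operate on an integrated :class:`GenotypeMatrix`.  Allele
frequencies and the allele-frequency spectrum (AFS) are defined for
diallelic loci only; multiallelic loci carry per-allele counts but no
single MAF.  Missing genotypes are excluded from every denominator.

The X chromosome is counted as diploid for all samples (pooled-sex
panels); callers combining sexes should read X summaries with that in
mind — a warning flag is attached to X-compartment outputs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .loci import MISSING, GenotypeMatrix, VariantLocus, round_half_up


@dataclass
class SiteFrequencyRecord:
    """Per-locus allele counts and derived frequencies."""

    locus: VariantLocus
    n_called: int
    ref_count: int
    alt_counts: tuple[int, ...]
    n_het: int
    n_hom_ref: int
    n_hom_alt: int

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_called

    @property
    def ref_frequency(self) -> float:
        if self.n_called == 0:
            return math.nan
        return self.ref_count / self.n_alleles

    @property
    def alt_frequency(self) -> float:
        """Total Alt-allele frequency (1 - Ref frequency)."""
        if self.n_called == 0:
            return math.nan
        return sum(self.alt_counts) / self.n_alleles

    @property
    def maf(self) -> float:
        """Minor allele frequency; defined for diallelic loci only."""
        if not self.locus.is_diallelic:
            return math.nan
        if self.n_called == 0:
            return math.nan
        f = self.ref_frequency
        return min(f, 1.0 - f)

    @property
    def is_defined(self) -> bool:
        return self.n_called > 0


def site_frequencies(matrix: GenotypeMatrix) -> list[SiteFrequencyRecord]:
    """Compute allele counts and zygosity census per locus.

    Ref_count + sum(alt_counts) == 2 * n_called at every locus, missing
    calls excluded.  Heterozygote/homozygote censuses use the unordered
    allele pair: het means the two alleles differ; hom-alt means both
    alleles equal and non-reference.
    """
    if matrix.n_loci == 0:
        return []
    out: list[SiteFrequencyRecord] = []
    calls = matrix.calls
    for i, locus in enumerate(matrix.loci):
        row = calls[i]
        called = row[:, 0] != MISSING
        sub = row[called]
        n_called = int(called.sum())
        flat = sub.ravel()
        n_alt = len(locus.alts)
        counts = np.bincount(flat, minlength=n_alt + 1) if flat.size else np.zeros(n_alt + 1, int)
        het = sub[:, 0] != sub[:, 1]
        hom_ref = (sub[:, 0] == 0) & (sub[:, 1] == 0)
        hom_alt = (~het) & (sub[:, 0] > 0)
        out.append(
            SiteFrequencyRecord(
                locus=locus,
                n_called=n_called,
                ref_count=int(counts[0]),
                alt_counts=tuple(int(c) for c in counts[1:]),
                n_het=int(het.sum()),
                n_hom_ref=int(hom_ref.sum()),
                n_hom_alt=int(hom_alt.sum()),
            )
        )
    return out


def afs(records: Sequence[SiteFrequencyRecord], n_samples: int) -> np.ndarray:
    """Allele-frequency spectrum: histogram of Ref-allele counts (0..2n).

    Diallelic records only; bin b counts loci whose Ref allele was seen b
    times among the 2*n_samples chromosomes.  Loci with incomplete calls
    contribute at their observed Ref count.
    """
    hist = np.zeros(2 * n_samples + 1, dtype=int)
    for r in records:
        if not r.locus.is_diallelic:
            raise ValueError("AFS is defined for diallelic records only")
        if r.n_called == 0:
            continue
        hist[r.ref_count] += 1
    return hist


def size_spectrum(loci: Sequence[VariantLocus]) -> tuple[Counter, int, int]:
    """Size-delta histogram plus (n_deletions, n_insertions).

    Diallelic loci; delta = Alt length - Ref length (negative: deletion).
    """
    spectrum: Counter = Counter()
    for locus in loci:
        if not locus.is_diallelic:
            raise ValueError("size spectrum is defined for diallelic loci only")
        d = locus.size_delta
        if d == 0:
            raise ValueError(f"zero size delta at {locus.chrom}:{locus.pos}")
        spectrum[d] += 1
    n_del = sum(c for d, c in spectrum.items() if d < 0)
    n_ins = sum(c for d, c in spectrum.items() if d > 0)
    return spectrum, n_del, n_ins


def density(counts: dict[str, int], chrom_table: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome variant density, expressed per 1000 bp.

    density = count / chromosome length * 1000.
    """
    rows = []
    for chrom, n in counts.items():
        if chrom not in chrom_table:
            raise KeyError(f"no length for chromosome {chrom!r}")
        length = chrom_table[chrom]
        rows.append(
            {
                "chrom": chrom,
                "n_indels": n,
                "length_bp": length,
                "per_kb": n / length * 1000.0,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "n_indels", "length_bp", "per_kb"])


def mean_spacing(total_count: int, total_length_bp: int) -> int:
    """Average distance between consecutive variants, rounded to whole bp.

    total_length / total_count, rounded half away from zero.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    return int(round_half_up(total_length_bp / total_count, 0))


def count_by_chromosome(loci: Sequence[VariantLocus]) -> dict[str, int]:
    c: Counter = Counter(l.chrom for l in loci)
    return dict(c)


def summary_counts(loci: Sequence[VariantLocus]) -> pd.DataFrame:
    """All / diallelic / multiallelic counts per genome compartment.

    Mirrors the canonical layout of discovery reports: rows are INDEL
    categories, columns genome compartments (autosomes, X, MT).
    """
    from .loci import chromosome_compartment

    comps = ("autosomes", "X", "MT")
    data = {c: {"all": 0, "diallelic": 0, "multiallelic": 0} for c in comps}
    for locus in loci:
        comp = chromosome_compartment(locus.chrom)
        if comp not in data:
            continue
        data[comp]["all"] += 1
        data[comp][locus.allelicity] += 1
    df = pd.DataFrame(data)
    df.index.name = "category"
    return df


def spectrum_table(spectrum: Counter) -> pd.DataFrame:
    deltas = sorted(spectrum)
    total = sum(spectrum.values())
    return pd.DataFrame(
        {
            "size_delta": deltas,
            "n_loci": [spectrum[d] for d in deltas],
            "percent": [round_half_up(100.0 * spectrum[d] / total, 2) if total else 0.0 for d in deltas],
        }
    )
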