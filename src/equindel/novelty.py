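"""Novelty classification against a registered-variant set.

Each integrated locus is compared with a collection of registered
variants (e.g. an Ensembl variation release) by exact match on normalized
event keys.  The summary decomposes counts into the three strata used
when reporting discovery panels: ordinary diallelic loci, diallelic loci
heterozygous in every sample at MAF 0.5 (suspect mapping artifacts), and
multiallelic loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .loci import VariantLocus, percent


@dataclass
class KnownVariantSet:
    """Registered variants indexed by normalized event key.

    ``total_registered`` may exceed the number of indexed keys when the
    source collection is larger than the loaded subset (it is the
    denominator for coverage percentages).
    """

    keys: dict[tuple, str] = field(default_factory=dict)
    total_registered: int = 0

    def __post_init__(self) -> None:
        if self.total_registered < len(self.keys):
            self.total_registered = len(self.keys)

    def __len__(self) -> int:
        return len(self.keys)

    def lookup(self, key: tuple) -> Optional[str]:
        return self.keys.get(key)

    def contains_locus(self, locus: VariantLocus, mode: str = "any") -> bool:
        """Registered status of a locus.

        mode='any': registered when any Ref/Alt pair matches (registered
        collections index alleles individually).  mode='all': every pair
        must match.
        """
        hits = [k in self.keys for k in locus.pair_keys()]
        return all(hits) if mode == "all" else any(hits)


@dataclass
class NoveltyReport:
    n_total: int
    n_registered: int
    n_novel: int
    percent_novel: float
    percent_registered: float
    percent_of_known_set_covered: Optional[float]
    strata: dict[str, dict[str, int]]

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_registered": self.n_registered,
            "n_novel": self.n_novel,
            "percent_novel": self.percent_novel,
            "percent_registered": self.percent_registered,
            "percent_of_known_set_covered": self.percent_of_known_set_covered,
            "strata": self.strata,
        }


def classify_novelty(
    loci: Sequence[VariantLocus],
    known: KnownVariantSet,
    mode: str = "any",
    all_het_flags: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, NoveltyReport]:
    """Per-locus registered/novel calls plus a stratified summary.

    Returns a boolean array (True = registered) aligned with ``loci``.
    ``all_het_flags`` marks diallelic loci heterozygous in every sample
    (MAF 0.5); when given, the report's strata separate them from other
    diallelic loci, mirroring how discovery studies quarantine suspected
    mapping artifacts from headline novelty rates.
    """
    registered = np.array([known.contains_locus(l, mode=mode) for l in loci], dtype=bool)
    n_total = len(loci)
    n_reg = int(registered.sum())
    n_novel = n_total - n_reg
    if all_het_flags is None:
        all_het_flags = np.zeros(n_total, dtype=bool)
    else:
        all_het_flags = np.asarray(all_het_flags, dtype=bool)
    strata: dict[str, dict[str, int]] = {}
    dial = np.array([l.is_diallelic for l in loci], dtype=bool)
    masks = {
        "diallelic_excl_all_het": dial & ~all_het_flags,
        "diallelic_all_het_maf05": dial & all_het_flags,
        "multiallelic": ~dial,
    }
    for name, mask in masks.items():
        strata[name] = {
            "n_total": int(mask.sum()),
            "n_registered": int((mask & registered).sum()),
            "n_novel": int((mask & ~registered).sum()),
        }
    coverage = (
        known_set_coverage(n_reg, known.total_registered)
        if known.total_registered
        else None
    )
    report = NoveltyReport(
        n_total=n_total,
        n_registered=n_reg,
        n_novel=n_novel,
        percent_novel=percent(n_novel, n_total) if n_total else 0.0,
        percent_registered=percent(n_reg, n_total) if n_total else 0.0,
        percent_of_known_set_covered=coverage,
        strata=strata,
    )
    return registered, report


def known_set_coverage(n_registered_matched: int, known_total: int) -> float:
    """Share of the registered collection rediscovered, as a percentage."""
    if known_total <= 0:
        raise ValueError("known_total must be positive")
    return percent(n_registered_matched, known_total)


def novelty_by_afs(
    ref_allele_counts: Sequence[int],
    registered: Sequence[bool],
    n_alleles_total: int,
) -> dict[str, np.ndarray]:
    """Allele-frequency spectra stratified by novelty.

    Histograms of per-locus Ref-allele counts (0 .. 2n) for novel and
    registered diallelic loci; their bin-wise sum is the unstratified
    spectrum.
    """
    counts = np.asarray(ref_allele_counts, dtype=int)
    reg = np.asarray(registered, dtype=bool)
    if counts.shape != reg.shape:
        raise ValueError("ref_allele_counts and registered must align")
    bins = np.arange(n_alleles_total + 2)
    novel_h, _ = np.histogram(counts[~reg], bins=bins)
    reg_h, _ = np.histogram(counts[reg], bins=bins)
    return {"novel": novel_h, "registered": reg_h, "all": novel_h + reg_h}
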