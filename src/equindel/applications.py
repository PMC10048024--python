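"""Applied selections: parentage-marker panels and gene-editing screens.

Parentage panels want diallelic autosomal markers that are easy to type
on capillary electrophoresis (size deltas of 2-4 bp in either direction)
and informative (balanced allele frequencies, Ref frequency in
[0.25, 0.75]), with all-heterozygous suspect loci excluded.

The gene-editing (gene-doping) screen flags a sample genotype as a
candidate artificial modification when it is homozygous for an
alternative-type INDEL that the population variant database has never
seen.  Rare registered variants (population Alt frequency below a
configurable bound, default 0.5%) yield a caveat rather than a clean
verdict, since de novo and rare natural variants are hard to tell from
edits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .loci import MISSING, VariantLocus, chromosome_compartment, event_key, normalize_alleles
from .novelty import KnownVariantSet
from .popstats import SiteFrequencyRecord

SUSPECT_EDIT = "SUSPECT_EDIT"
KNOWN_VARIANT = "KNOWN_VARIANT"
RARE_VARIANT_CAVEAT = "RARE_VARIANT_CAVEAT"
REFERENCE = "REFERENCE"


@dataclass(frozen=True)
class PanelCriteria:
    size_deltas: frozenset[int] = frozenset({-4, -3, -2, 2, 3, 4})
    af_min: float = 0.25
    af_max: float = 0.75
    exclude_all_het: bool = True
    autosomes_only: bool = True
    require_complete: bool = False

    def __post_init__(self) -> None:
        if not self.af_min < self.af_max:
            raise ValueError("af_min must be below af_max")
        if 0 in self.size_deltas:
            raise ValueError("size delta 0 is not an INDEL")


def select_panel(
    records: Sequence[SiteFrequencyRecord],
    criteria: PanelCriteria = PanelCriteria(),
) -> list[SiteFrequencyRecord]:
    """Select parentage-marker candidates.

    A record qualifies iff it is diallelic, autosomal (when
    ``autosomes_only``), its size delta is in the allowed set, its Ref
    allele frequency lies in [af_min, af_max] (bounds inclusive), and it
    is not heterozygous in every called sample (when
    ``exclude_all_het``).
    """
    out = []
    for r in records:
        if not r.locus.is_diallelic or r.n_called == 0:
            continue
        if criteria.autosomes_only and chromosome_compartment(r.locus.chrom) != "autosomes":
            continue
        if r.locus.size_delta not in criteria.size_deltas:
            continue
        f = r.ref_frequency
        if not (criteria.af_min <= f <= criteria.af_max):
            continue
        if criteria.exclude_all_het and r.n_het == r.n_called:
            continue
        out.append(r)
    return out


def panel_tsv(records: Sequence[SiteFrequencyRecord]) -> str:
    lines = ["chrom\tpos\tref\talt\tsize_delta\tref_frequency\tn_called"]
    for r in records:
        l = r.locus
        lines.append(
            f"{l.chrom}\t{l.pos}\t{l.ref}\t{l.alts[0]}\t{l.size_delta}"
            f"\t{r.ref_frequency:.5f}\t{r.n_called}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Population frequency database
# ---------------------------------------------------------------------------

@dataclass
class PopulationDB:
    """Normalized event key -> (Alt-allele frequency, n_called, flags)."""

    entries: dict[tuple, dict] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, key: tuple, include_masked: bool = False) -> Optional[dict]:
        e = self.entries.get(key)
        if e is None:
            return None
        if e.get("masked") and not include_masked:
            return None
        return e


def build_population_db(
    records: Sequence[SiteFrequencyRecord],
    suspect_keys: Optional[set] = None,
    exclude_suspects: bool = False,
    meta: Optional[dict] = None,
) -> PopulationDB:
    """Serialize per-allele population frequencies into a screening DB.

    One entry per normalized Ref/Alt pair.  Loci flagged as suspect
    artifacts are carried with a ``suspect`` flag; with
    ``exclude_suspects`` they are masked — present for bookkeeping but
    invisible to screening lookups.
    """
    suspect_keys = suspect_keys or set()
    db = PopulationDB(meta=dict(meta or {}))
    for r in records:
        if r.n_called == 0:
            continue
        locus = r.locus
        pair_keys = locus.pair_keys()
        suspect = locus.key in suspect_keys
        for alt_idx, key in enumerate(pair_keys):
            db.entries[key] = {
                "chrom": locus.chrom,
                "pos": locus.pos,
                "ref": locus.ref,
                "alt": locus.alts[alt_idx],
                "alt_frequency": r.alt_counts[alt_idx] / r.n_alleles,
                "n_called": r.n_called,
                "suspect": suspect,
                "masked": bool(suspect and exclude_suspects),
            }
    return db


def write_population_db(db: PopulationDB, path: str) -> None:
    """Sorted TSV with a JSON metadata header line (bgzip-compatible text)."""
    with open(path, "w") as fh:
        fh.write("#" + json.dumps({"format": "equindel-popdb-v1", **db.meta}, sort_keys=True) + "\n")
        fh.write("#chrom\tpos\tref\talt\talt_frequency\tn_called\tsuspect\tmasked\n")
        items = sorted(db.entries.values(), key=lambda e: (e["chrom"], e["pos"], e["ref"], e["alt"]))
        for e in items:
            fh.write(
                f"{e['chrom']}\t{e['pos']}\t{e['ref']}\t{e['alt']}"
                f"\t{e['alt_frequency']:.6f}\t{e['n_called']}"
                f"\t{int(e['suspect'])}\t{int(e['masked'])}\n"
            )


def read_population_db(path: str) -> PopulationDB:
    db = PopulationDB()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#{"):
                db.meta = json.loads(line[1:])
                continue
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, ref, alt, freq, n_called, suspect, masked = line.rstrip("\n").split("\t")
            pos = int(pos)
            npos, nref, (nalt,) = normalize_alleles(pos, ref, (alt,))
            db.entries[event_key(chrom, npos, nref, nalt)] = {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_frequency": float(freq),
                "n_called": int(n_called),
                "suspect": bool(int(suspect)),
                "masked": bool(int(masked)),
            }
    return db


# ---------------------------------------------------------------------------
# Gene-editing screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    locus: VariantLocus
    genotype: tuple[int, int]
    verdict: str
    db_frequency: Optional[float] = None
    detail: str = ""


def screen_genotype(
    locus: VariantLocus,
    genotype: tuple[int, int],
    db: PopulationDB,
    known: Optional[KnownVariantSet] = None,
    rare_threshold: float = 0.005,
) -> ScreenResult:
    """Screen one sample genotype for artificial-modification signatures.

    Homozygous-alternative genotypes at alleles absent from both the
    population database and the registered set are SUSPECT_EDIT;
    present-but-rare alleles (frequency < ``rare_threshold``) give
    RARE_VARIANT_CAVEAT; common alleles KNOWN_VARIANT.  Genotypes
    carrying a reference allele are REFERENCE when homozygous reference;
    heterozygous alternative calls are reported against the database but
    never SUSPECT_EDIT (the screen criterion targets homozygous
    alternative-type variants).
    """
    a, b = genotype
    if a == MISSING or b == MISSING:
        raise ValueError("cannot screen a missing genotype")
    if max(a, b) > len(locus.alts):
        raise ValueError("genotype allele index out of range for locus")
    if a == 0 and b == 0:
        return ScreenResult(locus, genotype, REFERENCE)

    pair_keys = locus.pair_keys()
    carried = sorted({g for g in (a, b) if g > 0})
    freqs = []
    in_known = False
    for g in carried:
        key = pair_keys[g - 1]
        entry = db.lookup(key)
        freqs.append(entry["alt_frequency"] if entry else None)
        if known is not None and known.lookup(key) is not None:
            in_known = True

    hom_alt = a == b and a > 0
    absent = all(f is None for f in freqs)
    min_known_freq = min((f for f in freqs if f is not None), default=None)

    if hom_alt and absent and not in_known:
        return ScreenResult(locus, genotype, SUSPECT_EDIT, detail="hom-Alt allele unseen in population")
    if absent:
        # het novel, or hom-alt registered externally but unseen here
        return ScreenResult(
            locus,
            genotype,
            RARE_VARIANT_CAVEAT,
            detail="allele absent from population frequencies",
        )
    if min_known_freq is not None and min_known_freq < rare_threshold:
        return ScreenResult(
            locus,
            genotype,
            RARE_VARIANT_CAVEAT,
            db_frequency=min_known_freq,
            detail=f"population frequency {min_known_freq:.4g} below {rare_threshold}",
        )
    return ScreenResult(locus, genotype, KNOWN_VARIANT, db_frequency=min_known_freq)
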