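"""Synthetic diploid INDEL population generator.

Emulates the file-level outputs of a short-read resequencing pipeline
(per-sample annotated VCFs, their multi-sample integration, a
registered-variant subset, a chromosome table) for a population of
diploid samples, so the whole downstream analysis is testable without
sequence data.

The generative model, per locus:

* a true Alt-allele frequency drawn from Beta(a, b) — a right-skewed
  default reproduces the empirical excess of rare alternative alleles in
  closed breeding populations;
* diploid genotypes drawn under Hardy-Weinberg equilibrium at that
  frequency (two independent allele draws per sample);
* a size delta (Alt length minus Ref length) drawn from a spectrum
  concentrated at 1-4 bp, deletions slightly outnumbering insertions;
* multiallelic loci modelled as microsatellite-like expanded-repeat
  insertions (one shared anchor, alternative alleles adding 1..k copies
  of a short unit) with allele frequencies from a symmetric Dirichlet;
* injected artifact loci heterozygous in every sample (the collapsed-
  duplication signature) and injected loci homozygous-alternative in
  every sample;
* a functional-region class drawn from a configurable mix and rendered
  as a SnpEff-style ANN string, with exonic effects (frameshift vs
  in-frame) consistent with the size delta;
* hard-filter INFO fields (DP, QUAL, QD, MQ0, HRun, SB) drawn in their
  passing ranges, with configurable per-criterion violation fractions.

Every draw flows from one seeded generator; identical config + seed
yields byte-identical files.  A ground-truth table records, per locus,
the true frequency, size delta, injection flags, novelty, annotation and
injected filter violations, serving as the oracle for recovery tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .loci import MISSING, GenotypeMatrix, VariantLocus, sort_loci_order
from .vcf_io import (
    write_chrom_table,
    write_known_set_gvf,
    write_known_set_vcf,
    write_vcf,
)

_BASES = np.array(list("ACGT"))

#: share of loci per size magnitude (1..4 bp dominate; geometric tail to 20)
_SIZE_MAGNITUDE_SHARES = {1: 0.5214, 2: 0.1603, 3: 0.0739, 4: 0.0609}
_DELETION_SHARE = 0.54

#: functional-region mix, roughly the relative genome shares of a
#: mammalian annotation: intergenic and intronic dominate, coding is rare
_DEFAULT_ANNOTATION_MIX = {
    "intergenic": 0.5133,
    "intron": 0.3408,
    "upstream": 0.0674,
    "downstream": 0.0647,
    "exon": 0.0054,
    "lncRNA": 0.0036,
    "3'-UTR": 0.0022,
    "5'-UTR": 0.0014,
    "splice-site": 0.0010,
    "pseudogene": 0.0002,
}

_REGION_TERM = {
    "upstream": ("upstream_gene_variant", "MODIFIER", "protein_coding"),
    "downstream": ("downstream_gene_variant", "MODIFIER", "protein_coding"),
    "intergenic": ("intergenic_region", "MODIFIER", ""),
    "intron": ("intron_variant", "MODIFIER", "protein_coding"),
    "5'-UTR": ("5_prime_UTR_variant", "MODIFIER", "protein_coding"),
    "3'-UTR": ("3_prime_UTR_variant", "MODIFIER", "protein_coding"),
    "splice-site": ("splice_region_variant", "LOW", "protein_coding"),
    "lncRNA": ("non_coding_transcript_exon_variant", "MODIFIER", "lncRNA"),
    "pseudogene": ("non_coding_transcript_exon_variant", "MODIFIER", "processed_pseudogene"),
}

#: INFO criteria the generator can violate on demand
FAILABLE = ("MQ0", "DP", "QUAL", "LOWQUAL", "QD", "HRun", "SB")


def default_size_distribution() -> dict[int, float]:
    """Size-delta pmf over {-20..-1, +1..+20}, zero mass at 0."""
    mags = dict(_SIZE_MAGNITUDE_SHARES)
    remaining = 1.0 - sum(mags.values())
    tail = np.array([0.75 ** i for i in range(16)])
    tail = tail / tail.sum() * remaining
    for i, m in enumerate(range(5, 21)):
        mags[m] = float(tail[i])
    dist = {}
    for m, p in mags.items():
        dist[-m] = p * _DELETION_SHARE
        dist[m] = p * (1.0 - _DELETION_SHARE)
    return dist


@dataclass
class SimulationConfig:
    """Population structure and emission parameters of one simulation."""

    n_samples: int = 101
    chromosomes: tuple[tuple[str, int], ...] = (
        ("1", 3_000_000),
        ("2", 2_500_000),
        ("3", 2_000_000),
        ("X", 1_500_000),
        ("MT", 16_660),
    )
    n_diallelic: int = 4000
    n_multiallelic: int = 560
    afs_shape: tuple[float, float] = (0.5, 2.0)
    size_distribution: dict[int, float] = field(default_factory=default_size_distribution)
    n_artifact_allhet: int = 50
    n_all_alt_hom: int = 20
    known_fraction: float = 0.502
    annotation_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ANNOTATION_MIX))
    missing_rate: float = 0.0
    filter_fail_fractions: dict[str, float] = field(default_factory=dict)
    min_spacing: int = 50
    multiallelic_dirichlet: float = 1.0
    seed: int = 2023

    def validate(self) -> None:
        for name in ("n_samples", "n_diallelic", "n_multiallelic", "n_artifact_allhet", "n_all_alt_hom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples == 0:
            raise ValueError("n_samples must be positive")
        a, b = self.afs_shape
        if a <= 0 or b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        sd = self.size_distribution
        if 0 in sd and sd[0] != 0:
            raise ValueError("size distribution must have zero mass at delta 0")
        if abs(sum(sd.values()) - 1.0) > 1e-9:
            raise ValueError("size distribution must sum to 1")
        if abs(sum(self.annotation_mix.values()) - 1.0) > 1e-9:
            raise ValueError("annotation mix must sum to 1")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise ValueError("known_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for c, f in self.filter_fail_fractions.items():
            if c not in FAILABLE:
                raise ValueError(f"unknown filter criterion {c!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fail fraction for {c} out of [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.n_diallelic + self.n_multiallelic + self.n_artifact_allhet + self.n_all_alt_hom


@dataclass
class SimulationResult:
    config: SimulationConfig
    matrix: GenotypeMatrix
    truth: pd.DataFrame
    chrom_table: dict[str, int]
    paths: dict[str, object]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _draw_positions(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Chromosome + position per locus, spaced >= ~min_spacing/2 apart.

    Loci are allotted to chromosomes in proportion to length, then placed
    on a jittered grid so that no two loci fall within one hard-filter
    cluster window by construction (clustered layouts are built
    explicitly in tests, not sampled accidentally).
    """
    names = [c for c, _ in cfg.chromosomes]
    lengths = np.array([l for _, l in cfg.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    assignment = rng.choice(len(names), size=cfg.n_loci, p=probs)
    out: list[tuple[str, int]] = []
    for ci, name in enumerate(names):
        n_here = int((assignment == ci).sum())
        if n_here == 0:
            continue
        length = int(lengths[ci])
        grid = np.arange(100, max(length - 100, 101), cfg.min_spacing)
        if n_here > len(grid):
            raise ValueError(
                f"requested {n_here} loci on chromosome {name} but only "
                f"{len(grid)} distinct positions available at spacing "
                f"{cfg.min_spacing} over {length} bp"
            )
        chosen = np.sort(rng.choice(grid, size=n_here, replace=False))
        jitter = rng.integers(0, max(cfg.min_spacing - 30, 1), size=n_here)
        for p in chosen + jitter:
            out.append((name, int(p)))
    return out


def _make_alleles(
    rng: np.random.Generator,
    delta: int,
) -> tuple[str, tuple[str, ...]]:
    anchor = str(_BASES[rng.integers(0, 4)])
    if delta > 0:
        return anchor, (anchor + _random_seq(rng, delta),)
    return anchor + _random_seq(rng, -delta), (anchor,)


def _make_multiallelic(
    rng: np.random.Generator,
) -> tuple[str, tuple[str, ...]]:
    """Expanded-repeat insertion: anchor plus 1..k copies of a short unit."""
    anchor = str(_BASES[rng.integers(0, 4)])
    unit = _random_seq(rng, int(rng.integers(1, 4)))
    n_alts = int(rng.integers(2, 4))  # 3-4 alleles including Ref
    alts = tuple(anchor + unit * (k + 1) for k in range(n_alts))
    return anchor, alts


def _ann_string(
    region: str,
    effect_delta: Optional[int],
    alts: Sequence[str],
    gene_id: str,
    gene_name: str,
) -> str:
    entries = []
    for alt in alts:
        if region == "exon":
            d = effect_delta if effect_delta is not None else 1
            if abs(d) % 3 != 0:
                term, impact = "frameshift_variant", "HIGH"
            else:
                term = (
                    "conservative_inframe_insertion" if d > 0 else "conservative_inframe_deletion"
                )
                impact = "MODERATE"
            biotype = "protein_coding"
        else:
            term, impact, biotype = _REGION_TERM[region]
        entries.append(
            f"{alt}|{term}|{impact}|{gene_name}|{gene_id}|transcript|{gene_id}.t1|{biotype}"
        )
    return ",".join(entries)


def write_filter_fields(
    n_records: int,
    rng: np.random.Generator,
    fail_fractions: Optional[dict[str, float]] = None,
    protect: Optional[np.ndarray] = None,
) -> tuple[list[dict], list[frozenset]]:
    """Draw hard-filter INFO fields, injecting criterion violations.

    Baseline values pass every criterion (DP 20-60, QUAL 60-200, QD 2-20,
    MQ0 0, HRun 0-3, SB in [-1, -0.2]).  For each criterion named in
    ``fail_fractions``, an independent Bernoulli(fraction) per record
    replaces the field with a violating value; QUAL and LOWQUAL are
    mutually exclusive (a hard QUAL failure wins).  ``protect`` masks
    records that must stay clean (injected artifact signatures emulate
    well-covered mismapped reads, which sail through these filters).
    Returns (info dicts, per-record violated-criterion sets).
    """
    fail_fractions = fail_fractions or {}
    infos: list[dict] = []
    violations: list[set] = [set() for _ in range(n_records)]
    protect = (
        np.zeros(n_records, dtype=bool) if protect is None else np.asarray(protect, dtype=bool)
    )
    dp = rng.integers(20, 61, size=n_records)
    qual = np.round(rng.uniform(60.0, 200.0, size=n_records), 1)
    qd = np.round(rng.uniform(2.0, 20.0, size=n_records), 2)
    mq0 = np.zeros(n_records)
    hrun = rng.integers(0, 4, size=n_records).astype(float)
    sb = np.round(rng.uniform(-1.0, -0.2, size=n_records), 2)
    draws = {c: rng.random(n_records) < fail_fractions.get(c, 0.0) for c in FAILABLE}
    for i in range(n_records):
        if not protect[i]:
            if draws["DP"][i]:
                dp[i] = rng.integers(0, 10)
                violations[i].add("DP")
            if draws["QUAL"][i]:
                qual[i] = round(rng.uniform(0.0, 29.9), 1)
                violations[i].add("QUAL")
            elif draws["LOWQUAL"][i]:
                qual[i] = round(rng.uniform(30.0, 49.9), 1)
                violations[i].add("LOWQUAL")
            if draws["QD"][i]:
                qd[i] = round(rng.uniform(0.0, 1.49), 2)
                violations[i].add("QD")
            if draws["MQ0"][i]:
                # ratio > 0.1 of (possibly already lowered) depth, floor 4
                mq0[i] = max(4.0, float(int(0.1 * dp[i]) + 1))
                violations[i].add("MQ0")
            if draws["HRun"][i]:
                hrun[i] = float(rng.integers(6, 13))
                violations[i].add("HRun")
            if draws["SB"][i]:
                sb[i] = round(rng.uniform(0.0, 1.0), 2)
                violations[i].add("SB")
        infos.append(
            {
                "DP": int(dp[i]),
                "QUAL": float(qual[i]),
                "QD": float(qd[i]),
                "MQ0": float(mq0[i]),
                "HRun": float(hrun[i]),
                "SB": float(sb[i]),
            }
        )
    return infos, [frozenset(v) for v in violations]


def simulate_population(
    config: SimulationConfig,
    outdir: Optional[str] = None,
) -> SimulationResult:
    """Generate a synthetic population and (optionally) its file bundle.

    When ``outdir`` is given, writes: ``population.vcf`` (multi-sample),
    ``samples/<name>.vcf`` (one per sample, carrying only that sample's
    non-reference calls), ``known.vcf`` + ``known.gvf`` (registered
    subset in both renderings), ``chromosomes.tsv`` and ``truth.tsv``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    n_samples = config.n_samples

    positions = _draw_positions(config, rng)
    # deterministic genome order for the emitted loci
    chrom_rank = {c: i for i, (c, _) in enumerate(config.chromosomes)}
    positions.sort(key=lambda cp: (chrom_rank[cp[0]], cp[1]))

    kinds = np.array(
        ["diallelic"] * config.n_diallelic
        + ["multiallelic"] * config.n_multiallelic
        + ["artifact_allhet"] * config.n_artifact_allhet
        + ["all_alt_hom"] * config.n_all_alt_hom
    )
    rng.shuffle(kinds)

    deltas_pool = np.array(sorted(config.size_distribution))
    delta_probs = np.array([config.size_distribution[d] for d in deltas_pool])

    a_shape, b_shape = config.afs_shape
    region_names = list(config.annotation_mix)
    region_probs = np.array([config.annotation_mix[r] for r in region_names])

    loci: list[VariantLocus] = []
    calls = np.empty((n, n_samples, 2), dtype=np.int16)
    truth_rows: list[dict] = []
    gene_counter = 0

    for i, (chrom, pos) in enumerate(positions):
        kind = kinds[i]
        region = str(rng.choice(region_names, p=region_probs))
        if kind == "multiallelic":
            ref, alts = _make_multiallelic(rng)
            k = len(alts)
            freqs = rng.dirichlet(np.full(k + 1, config.multiallelic_dirichlet))
            geno = rng.choice(k + 1, size=(n_samples, 2), p=freqs)
            true_alt_freq = float(1.0 - freqs[0])
            delta = None
        else:
            delta = int(rng.choice(deltas_pool, p=delta_probs))
            ref, alts = _make_alleles(rng, delta)
            if kind == "artifact_allhet":
                true_alt_freq = 0.5
                geno = np.tile([0, 1], (n_samples, 1))
            elif kind == "all_alt_hom":
                true_alt_freq = 1.0
                geno = np.ones((n_samples, 2), dtype=int)
            else:
                true_alt_freq = float(rng.beta(a_shape, b_shape))
                geno = (rng.random((n_samples, 2)) < true_alt_freq).astype(int)
        geno = np.sort(geno, axis=1)
        if config.missing_rate > 0 and kind == "diallelic":
            miss = rng.random(n_samples) < config.missing_rate
            geno[miss] = MISSING
        calls[i] = geno
        locus = VariantLocus(chrom, pos, ref, tuple(alts))
        loci.append(locus)

        if region == "intergenic":
            gene_id = gene_name = ""
        else:
            gene_counter += 1
            gene_id = f"SYNGENE{gene_counter:011d}"
            gene_name = f"G{gene_counter}"
        if region == "exon":
            d = delta if delta is not None else locus.size_deltas[0]
            effect = "frameshift" if abs(d) % 3 != 0 else "non-frameshift"
        else:
            effect = "other"
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alts": ",".join(alts),
                "allelicity": "diallelic" if len(alts) == 1 else "multiallelic",
                "true_alt_freq": true_alt_freq,
                "size_delta": delta if delta is not None else pd.NA,
                "artifact_all_het": kind == "artifact_allhet",
                "all_alt_hom": kind == "all_alt_hom",
                "region_class": region,
                "effect_class": effect,
                "gene_id": gene_id,
            }
        )

    protect = np.array([k in ("artifact_allhet", "all_alt_hom") for k in kinds])
    infos, violations = write_filter_fields(n, rng, config.filter_fail_fractions, protect)
    known_flags = rng.random(n) < config.known_fraction

    ann_infos = []
    for i, locus in enumerate(loci):
        row = truth_rows[i]
        info = dict(infos[i])
        info["ANN"] = _ann_string(
            row["region_class"],
            row["size_delta"] if row["size_delta"] is not pd.NA else None,
            locus.alts,
            row["gene_id"],
            row["gene_id"][:1] and f"G{row['gene_id'][7:].lstrip('0')}" or "",
        )
        ann_infos.append(info)
        row["known"] = bool(known_flags[i])
        row["filter_violations"] = ";".join(sorted(violations[i]))

    samples = [f"HORSE{j + 1:03d}" for j in range(n_samples)]
    matrix = GenotypeMatrix(loci, samples, calls, ann_infos)
    truth = pd.DataFrame(truth_rows)
    dup = truth.duplicated(subset=["chrom", "pos", "ref", "alts"])
    if dup.any():
        raise RuntimeError("duplicate locus keys in truth table")
    chrom_table = {c: l for c, l in config.chromosomes}

    paths: dict[str, object] = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        sample_dir = os.path.join(outdir, "samples")
        os.makedirs(sample_dir, exist_ok=True)
        pop_vcf = os.path.join(outdir, "population.vcf")
        write_vcf(pop_vcf, matrix, chrom_table)
        sample_paths = []
        for j, sample in enumerate(samples):
            sp = os.path.join(sample_dir, f"{sample}.vcf")
            _write_single_sample_vcf(sp, matrix, j, chrom_table)
            sample_paths.append(sp)
        known_entries = []
        for i, locus in enumerate(loci):
            if not known_flags[i]:
                continue
            for k, alt in enumerate(locus.alts):
                known_entries.append((locus.chrom, locus.pos, locus.ref, alt, f"rs{i + 1}_{k + 1}"))
        known_vcf = os.path.join(outdir, "known.vcf")
        known_gvf = os.path.join(outdir, "known.gvf")
        write_known_set_vcf(known_vcf, known_entries, chrom_table)
        write_known_set_gvf(known_gvf, known_entries)
        chrom_path = os.path.join(outdir, "chromosomes.tsv")
        write_chrom_table(chrom_path, chrom_table)
        truth_path = os.path.join(outdir, "truth.tsv")
        truth.to_csv(truth_path, sep="\t", index=False)
        paths = {
            "population_vcf": pop_vcf,
            "sample_vcfs": sample_paths,
            "known_vcf": known_vcf,
            "known_gvf": known_gvf,
            "chrom_table": chrom_path,
            "truth": truth_path,
        }
    return SimulationResult(config, matrix, truth, chrom_table, paths)


def _write_single_sample_vcf(
    path: str,
    matrix: GenotypeMatrix,
    sample_idx: int,
    chrom_table: dict[str, int],
) -> None:
    """Emit one sample's non-reference calls, alleles renumbered locally.

    Mirrors a single-sample caller's output: loci where the sample is
    homozygous reference or uncalled are absent, and only the alternative
    alleles the sample actually carries are listed.
    """
    keep = []
    local_loci: list[VariantLocus] = []
    local_calls: list[list[int]] = []
    local_infos: list[dict] = []
    for i, locus in enumerate(matrix.loci):
        a, b = matrix.calls[i, sample_idx]
        if a == MISSING or (a == 0 and b == 0):
            continue
        carried = sorted({g for g in (int(a), int(b)) if g > 0})
        local_alts = tuple(locus.alts[g - 1] for g in carried)
        remap = {0: 0, **{g: k + 1 for k, g in enumerate(carried)}}
        info = dict(matrix.info[i])
        if info.get("ANN"):
            entries = info["ANN"].split(",")
            info["ANN"] = ",".join(entries[g - 1] for g in carried) if len(entries) == len(locus.alts) else info["ANN"]
        local_loci.append(VariantLocus(locus.chrom, locus.pos, locus.ref, local_alts))
        local_calls.append(sorted(remap[int(g)] for g in (a, b)))
        local_infos.append(info)
        keep.append(i)
    calls = (
        np.array(local_calls, dtype=np.int16).reshape(len(local_calls), 1, 2)
        if local_calls
        else np.empty((0, 1, 2), dtype=np.int16)
    )
    sub = GenotypeMatrix(local_loci, [matrix.samples[sample_idx]], calls, local_infos)
    write_vcf(path, sub, chrom_table)
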