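"""Hard-filter engine for INDEL call quality control.

Re-implements the per-record threshold rules commonly applied after
haplotype-based calling: minimum depth (DP), call quality (QUAL) with a
low-confidence band, quality-by-depth (QD), homopolymer-run length
(HRun), strand-bias score (SB), a mapping-quality-zero fraction rule
(MQ0), and a positional cluster rule (too many variants inside a short
window).  Each criterion is evaluated independently and every violated
criterion is reported, so filter summaries can count per-criterion
failures.

Default thresholds::

    cluster window 10 bp (>=3 variants), MQ0 >= 4 and MQ0/DP > 0.1,
    DP < 10, QUAL < 30.0, 30 <= QUAL < 50 (low-confidence band),
    QD < 1.5, HRun > 5, SB > -0.1
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .loci import GenotypeMatrix, VariantLocus

PASS = "PASS"
FAIL = "FAIL"
LOWQUAL = "LOWQUAL"

#: criterion names, in reporting order
CRITERIA = ("CLUSTER", "MQ0", "DP", "QUAL", "LOWQUAL", "QD", "HRun", "SB")


@dataclass(frozen=True)
class FilterThresholds:
    cluster_window: int = 10
    cluster_size: int = 3
    mq0_min: float = 4
    mq0_dp_ratio: float = 0.1
    dp_min: float = 10
    qual_min: float = 30.0
    qual_low_max: float = 50.0
    qd_min: float = 1.5
    hrun_max: float = 5
    sb_max: float = -0.1

    def __post_init__(self) -> None:
        if self.qual_low_max < self.qual_min:
            raise ValueError("low-quality band upper bound below qual_min")
        if self.cluster_window < 1 or self.cluster_size < 2:
            raise ValueError("cluster window must be >=1 bp and cluster size >=2")

    @classmethod
    def from_yaml(cls, path: str) -> "FilterThresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterVerdict:
    status: str
    reasons: frozenset[str] = frozenset()
    not_evaluated: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        self.not_evaluated = frozenset(self.not_evaluated)
        if self.status == PASS and self.reasons:
            raise ValueError("PASS verdict with reasons")
        if self.status == LOWQUAL and self.reasons != {"LOWQUAL"}:
            raise ValueError("LOWQUAL verdict must carry exactly the LOWQUAL reason")


def filter_record(
    info: dict,
    thresholds: FilterThresholds = FilterThresholds(),
    cluster_flagged: bool = False,
) -> FilterVerdict:
    """Evaluate one record's INFO fields against every criterion.

    Missing fields are recorded as not-evaluated rather than failed:
    annotation-dependent fields (HRun, SB) are frequently absent and
    failing on absence would silently discard whole call sets.  The
    low-confidence QUAL band yields LOWQUAL when it is the only firing
    criterion.
    """
    reasons: set[str] = set()
    skipped: set[str] = set()

    dp = info.get("DP")
    if dp is not None and dp < 0:
        raise ValueError(f"negative DP ({dp})")

    if cluster_flagged:
        reasons.add("CLUSTER")

    mq0 = info.get("MQ0")
    if mq0 is None or dp is None:
        skipped.add("MQ0")
    elif mq0 >= thresholds.mq0_min and dp > 0 and (mq0 / (1.0 * dp)) > thresholds.mq0_dp_ratio:
        reasons.add("MQ0")

    if dp is None:
        skipped.add("DP")
    elif dp < thresholds.dp_min:
        reasons.add("DP")

    qual = info.get("QUAL")
    if qual is None:
        skipped.update(("QUAL", "LOWQUAL"))
    else:
        if qual < thresholds.qual_min:
            reasons.add("QUAL")
        elif qual < thresholds.qual_low_max:
            reasons.add("LOWQUAL")

    qd = info.get("QD")
    if qd is None:
        skipped.add("QD")
    elif qd < thresholds.qd_min:
        reasons.add("QD")

    hrun = info.get("HRun")
    if hrun is None:
        skipped.add("HRun")
    elif hrun > thresholds.hrun_max:
        reasons.add("HRun")

    sb = info.get("SB")
    if sb is None:
        skipped.add("SB")
    elif sb > thresholds.sb_max:
        reasons.add("SB")

    if not reasons:
        status = PASS
    elif reasons == {"LOWQUAL"}:
        status = LOWQUAL
    else:
        status = FAIL
    return FilterVerdict(status, frozenset(reasons), frozenset(skipped))


def filter_clusters(
    loci: Sequence[VariantLocus],
    thresholds: FilterThresholds = FilterThresholds(),
) -> np.ndarray:
    """Flag loci falling in dense positional clusters.

    A locus is flagged iff at least ``cluster_size`` variants (itself
    included) lie within some ``cluster_window``-bp window containing it.
    Input must be sorted by chromosome then position; a sliding two-pointer
    pass makes this O(n).
    """
    n = len(loci)
    flags = np.zeros(n, dtype=bool)
    for i in range(1, n):
        a, b = loci[i - 1], loci[i]
        if a.chrom == b.chrom and a.pos > b.pos:
            raise ValueError(f"loci not sorted at {b.chrom}:{b.pos}")
    w = thresholds.cluster_window
    k = thresholds.cluster_size
    start = 0
    for end in range(n):
        while (
            loci[start].chrom != loci[end].chrom
            or loci[end].pos - loci[start].pos > w - 1
        ):
            start += 1
        if end - start + 1 >= k:
            flags[start : end + 1] = True
    return flags


def apply_filters(
    matrix: GenotypeMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
    retain_lowqual: bool = False,
    use_cluster: bool = True,
) -> tuple[GenotypeMatrix, dict[str, int], np.ndarray]:
    """Filter a matrix; return (retained matrix, per-criterion counts, verdicts).

    ``counts[c]`` is the number of records on which criterion ``c`` fired
    (a record can fire several).  Records with FAIL status are removed;
    LOWQUAL records are removed unless ``retain_lowqual``.
    """
    cluster = (
        filter_clusters(matrix.loci, thresholds)
        if use_cluster
        else np.zeros(matrix.n_loci, dtype=bool)
    )
    counts = {c: 0 for c in CRITERIA}
    keep = np.zeros(matrix.n_loci, dtype=bool)
    verdicts = np.empty(matrix.n_loci, dtype=object)
    for i in range(matrix.n_loci):
        v = filter_record(matrix.info[i], thresholds, cluster_flagged=bool(cluster[i]))
        verdicts[i] = v
        for r in v.reasons:
            counts[r] += 1
        keep[i] = v.status == PASS or (retain_lowqual and v.status == LOWQUAL)
    return matrix.subset(keep), counts, verdicts


def filter_report_tsv(counts: dict[str, int]) -> str:
    lines = ["criterion\tn_failed"]
    for c in CRITERIA:
        lines.append(f"{c}\t{counts.get(c, 0)}")
    return "\n".join(lines) + "\n"
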