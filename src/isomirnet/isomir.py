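"""IsomiR analysis: anchored comparison, typing, enrichment, read support.

An isomiR is a sequence variant of a mature miRNA arising from imprecise
processing, terminal addition/deletion, or internal modification. Eight
types are distinguished: 5' and 3' addition, deletion and replacement,
plus single- (SNP) and multi-nucleotide (MNP) polymorphic isomiRs. A
sequence may carry several labels at once (e.g. a trimmed-and-tailed
variant is both a deletion and an addition isomiR).

Classification rests on an anchored, ungapped comparison of the isomiR
against its reference miRNA: the relative offset maximizing the number of
matching positions in the overlap determines the 5'/3' end offsets, and
mismatches inside the overlap split into terminal runs (replacements) and
internal substitutions (SNP/MNP). Gapped variants never reach this stage
because gapped alignments are discarded upstream in the chimera pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .errors import DataError, ParameterError, UnclassifiableError

ISOMIR_TYPE_ORDER = (
    "5p_add", "5p_del", "5p_rep",
    "3p_add", "3p_del", "3p_rep",
    "snp", "mnp",
)


@dataclass(frozen=True)
class AnchorResult:
    """Outcome of the anchored ungapped comparison.

    ``offset_5p`` is the isomiR start relative to the reference start
    (negative = extra 5' bases on the isomiR); ``offset_3p`` the isomiR end
    relative to the reference end (positive = extra 3' bases). Mismatch
    positions are in reference coordinates; terminal runs are maximal
    mismatch runs contiguous with an end of the overlap.
    """

    offset_5p: int
    offset_3p: int
    internal_mismatch_positions: tuple[int, ...]
    terminal_run_5p: int = 0
    terminal_run_3p: int = 0


@dataclass
class IsomiRCall:
    mirna_id: str
    isomir_seq: str
    offset_5p: int
    offset_3p: int
    internal_mismatch_positions: tuple[int, ...]
    types: frozenset[str]
    support_reads: int = 0


@dataclass
class EnrichmentResult:
    mirna_id: str
    type: str
    observed: int
    total: int
    expected_prob: float
    p_raw: float
    p_corrected: float
    significant: bool = field(default=False)


def anchor_align(isomir_seq: str, ref_seq: str, max_shift: int = 6) -> AnchorResult:
    """Anchor an isomiR to its reference by the best ungapped offset.

    Scans relative offsets in [-max_shift, +max_shift] (isomiR start minus
    reference start) and keeps the one maximizing matching positions in the
    overlap; ties prefer the smallest absolute offset, then the negative
    one. Raises :class:`UnclassifiableError` when no offset reaches 50%
    identity in its overlap.
    """
    if len(isomir_seq) < 10 or len(ref_seq) < 10:
        raise ParameterError("sequences must be at least 10 nt for anchoring")
    n_iso, n_ref = len(isomir_seq), len(ref_seq)
    best: tuple[int, int, int] | None = None  # (matches, |d|, d-pref) -> d
    best_d = 0
    for d in sorted(range(-max_shift, max_shift + 1), key=lambda x: (abs(x), x)):
        lo = max(0, -d)
        hi = min(n_iso, n_ref - d)
        if hi <= lo:
            continue
        matches = sum(
            1 for i in range(lo, hi) if isomir_seq[i] == ref_seq[i + d]
        )
        if best is None or matches > best[0]:
            best = (matches, hi - lo, 0)
            best_d = d
    if best is None:
        raise UnclassifiableError("no overlapping offset within max_shift")
    d = best_d
    lo = max(0, -d)
    hi = min(n_iso, n_ref - d)
    matches, overlap = best[0], hi - lo
    if matches < 0.5 * overlap:
        raise UnclassifiableError(
            f"best anchoring reaches only {matches}/{overlap} identity"
        )
    mism = [i + d for i in range(lo, hi) if isomir_seq[i] != ref_seq[i + d]]
    # split terminal mismatch runs off the internal ones (ref coordinates)
    ov_start, ov_end = lo + d, hi + d  # overlap in ref coordinates
    run5 = 0
    while run5 < len(mism) and mism[run5] == ov_start + run5:
        run5 += 1
    run3 = 0
    while run3 < len(mism) - run5 and mism[-1 - run3] == ov_end - 1 - run3:
        run3 += 1
    internal = tuple(mism[run5: len(mism) - run3])
    return AnchorResult(
        offset_5p=d,
        offset_3p=(n_iso + d) - n_ref,
        internal_mismatch_positions=internal,
        terminal_run_5p=run5,
        terminal_run_3p=run3,
    )


def classify_isomir(
    isomir_seq: str, ref_seq: str, max_shift: int = 6
) -> frozenset[str]:
    """Assign the eight-type label set to an isomiR given its reference.

    Returns the empty set for an exact match. Labels follow the anchored
    offsets: a negative 5' offset is a 5' addition, a positive one a 5'
    deletion; an offset of zero with a terminal mismatch run is a 5'
    replacement; symmetric at the 3' end. Exactly one internal substitution
    is a SNP, two or more an MNP.
    """
    a = anchor_align(isomir_seq, ref_seq, max_shift=max_shift)
    types: set[str] = set()
    if a.offset_5p < 0:
        types.add("5p_add")
    elif a.offset_5p > 0:
        types.add("5p_del")
    elif a.terminal_run_5p > 0:
        types.add("5p_rep")
    if a.offset_3p > 0:
        types.add("3p_add")
    elif a.offset_3p < 0:
        types.add("3p_del")
    elif a.terminal_run_3p > 0:
        types.add("3p_rep")
    n_internal = len(a.internal_mismatch_positions)
    if n_internal == 1:
        types.add("snp")
    elif n_internal >= 2:
        types.add("mnp")
    return frozenset(types)


def variant_read_positions(isomir_seq: str, ref_seq: str, max_shift: int = 6) -> list[int]:
    """Read-coordinate positions of the isomiR that differ from the reference.

    Covers unaligned 5'/3' overhangs (additions) and every mismatch in the
    overlap (terminal replacements and internal substitutions). Used by the
    pipeline's quality check at variation positions.
    """
    a = anchor_align(isomir_seq, ref_seq, max_shift=max_shift)
    n_iso = len(isomir_seq)
    pos: list[int] = []
    if a.offset_5p < 0:
        pos.extend(range(-a.offset_5p))
    if a.offset_3p > 0:
        pos.extend(range(n_iso - a.offset_3p, n_iso))
    lo = max(0, -a.offset_5p)
    hi = min(n_iso, len(ref_seq) - a.offset_5p)
    for i in range(lo, hi):
        if isomir_seq[i] != ref_seq[i + a.offset_5p]:
            pos.append(i)
    return sorted(set(pos))


# -- type enrichment ---------------------------------------------------------

def type_enrichment(
    counts: pd.DataFrame,
    background: dict[str, float] | None = None,
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-miRNA one-sided binomial enrichment of isomiR types.

    ``counts`` needs columns (mirna_id, type, observed, total) with
    ``total`` the number of isomiR interactions of that miRNA. Each type is
    tested marginally against its expected frequency: P(X >= observed) for
    X ~ Binomial(total, expected). When ``background`` is None the expected
    frequency of each type is its pooled frequency across all miRNAs.
    Correction is Bonferroni over all tests performed (capped at 1).
    """
    required = {"mirna_id", "type", "observed", "total"}
    if not required.issubset(counts.columns):
        raise DataError(f"counts table needs columns {sorted(required)}")
    if (counts["observed"] > counts["total"]).any():
        raise DataError("observed count exceeds total")
    if correction not in ("bonferroni", "none"):
        raise ParameterError(f"unknown correction {correction!r}")
    if background is None:
        pooled = counts.groupby("type")["observed"].sum()
        totals = counts.groupby("type")["total"].sum()
        background = {t: float(pooled[t]) / float(totals[t]) if totals[t] else 0.0
                      for t in pooled.index}
    rows = []
    n_tests = len(counts)
    for rec in counts.itertuples(index=False):
        p_exp = float(background.get(rec.type, 0.0))
        p_raw = float(binom.sf(rec.observed - 1, rec.total, p_exp)) if rec.observed > 0 else 1.0
        factor = n_tests if correction == "bonferroni" else 1
        p_corr = min(1.0, p_raw * factor)
        rows.append(EnrichmentResult(
            mirna_id=rec.mirna_id, type=rec.type, observed=int(rec.observed),
            total=int(rec.total), expected_prob=p_exp, p_raw=p_raw,
            p_corrected=p_corr, significant=bool(p_corr < alpha),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def type_counts_from_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an isomiR call table into per-(miRNA, type) counts.

    ``calls`` needs columns (mirna_id, types) with types a semicolon list;
    ``total`` per miRNA is its number of isomiR interactions.
    """
    rows = []
    for mirna_id, grp in calls.groupby("mirna_id"):
        total = len(grp)
        tallies: dict[str, int] = {t: 0 for t in ISOMIR_TYPE_ORDER}
        for ts in grp["types"]:
            for t in str(ts).split(";"):
                if t in tallies:
                    tallies[t] += 1
        for t, obs in tallies.items():
            rows.append({"mirna_id": mirna_id, "type": t,
                         "observed": obs, "total": total})
    return pd.DataFrame(rows, columns=["mirna_id", "type", "observed", "total"])


# -- read-support probability ------------------------------------------------

def support_probability(
    n_reads: int, read_len: int, error_rate: float, threshold: int
) -> float:
    """Chance that one specific single-error variant recurs >= threshold times.

    Models the probability that sequencing error alone produces the same
    isomiR sequence in at least ``threshold`` of ``n_reads`` reads of a
    ``read_len``-nt miRNA: a single read shows that exact variant with
    probability p = e * (1-e)^(read_len-1) (one specific erroneous base,
    all other positions correct), and the recurrence count is
    Binomial(n_reads, p). The upper tail is summed exactly in log space.

    At the canonical operating point (1000 reads, 22 nt, error rate 0.001,
    threshold 10) this is ~8.87e-08, which is why a 10-read support cutoff
    makes error-born isomiRs negligible.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ParameterError("error_rate must be in [0, 1)")
    if n_reads < 0 or threshold < 0 or read_len < 1:
        raise ParameterError("counts must be non-negative, read_len >= 1")
    if threshold > n_reads:
        return 0.0
    if threshold == 0:
        return 1.0
    if error_rate == 0.0:
        return 0.0
    p = error_rate * (1.0 - error_rate) ** (read_len - 1)
    log_p, log_q = math.log(p), math.log1p(-p)
    ks = np.arange(threshold, n_reads + 1)
    log_terms = (
        [math.lgamma(n_reads + 1) - math.lgamma(k + 1) - math.lgamma(n_reads - k + 1)
         + k * log_p + (n_reads - k) * log_q for k in ks]
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))
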