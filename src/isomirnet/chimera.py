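"""Chimeric-read deconvolution: from reads + alignment hits to interactions.

A chimeric read from a crosslink-ligation experiment carries a miRNA (or
isomiR) fragment ligated to the mRNA target site it was bound to, with at
most a few nucleotides between the two portions. This module implements
the call chain:

    dedup reads -> filter hits -> pair miRNA/mRNA hits per read ->
    keep the best pair(s) -> compare the miRNA portion against its
    reference (exact miRNA vs quality-checked isomiR) -> require
    read support -> emit the interaction table.

Filtering defaults follow standard CLASH practice: hits kept at e-value
<= 0.1 on the sense strand with no alignment gaps; portions at most 4 nt
apart in the read; variant positions accepted only above Phred 30; and a
miRNA/isomiR portion must recur in at least 10 chimeric reads, a cutoff
at which sequencing error alone would reproduce a variant with
probability ~9e-08 (see :func:`isomirnet.isomir.support_probability`).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import io as ionet
from .errors import DataError, ParameterError
from .isomir import classify_isomir, variant_read_positions
from .errors import UnclassifiableError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChimericRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise DataError(
                f"read {self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.qualities and not (0 <= min(self.qualities) <= max(self.qualities) <= 93):
            raise DataError(f"read {self.read_id}: Phred values outside [0, 93]")


@dataclass(frozen=True)
class AlignmentHit:
    """One read-vs-reference local alignment, 0-based half-open coordinates."""

    read_id: str
    subject_id: str
    subject_db: str  # "mirna" | "transcript"
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    mismatches: int
    gap_openings: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class ChimeraCall:
    read_id: str
    mirna_hit: AlignmentHit
    mrna_hit: AlignmentHit
    gap_nt: int
    mirna_portion_seq: str
    mrna_portion_seq: str
    combined_evalue: float
    combined_bitscore: float


@dataclass
class PipelineConfig:
    max_evalue: float = 0.1
    min_support_reads: int = 10
    max_gap: int = 4
    max_overlap: int = 0
    min_variant_quality: int = 30  # exclusive: variant bases need quality > 30
    top_k_pairs: int = 1
    require_mirna_first: bool = True
    count_multiplicity: bool = True

    def __post_init__(self) -> None:
        if self.max_evalue <= 0 or self.min_support_reads < 1 or self.top_k_pairs < 1:
            raise ParameterError("thresholds must be positive")
        if self.max_gap < 0 or self.max_overlap < 0 or self.min_variant_quality < 0:
            raise ParameterError("thresholds must be non-negative")


def hits_from_table(df: pd.DataFrame, subject_db: str) -> list[AlignmentHit]:
    """Convert a BLAST outfmt-6 table (1-based inclusive) to AlignmentHits.

    Minus-strand alignments are detected by sstart > send and converted to
    forward 0-based half-open subject intervals with strand '-'.
    """
    hits = []
    for i, rec in enumerate(df.itertuples(index=False)):
        sstart, send = int(rec.sstart), int(rec.send)
        strand = "+" if sstart <= send else "-"
        lo, hi = (sstart, send) if strand == "+" else (send, sstart)
        qstart, qend = int(rec.qstart), int(rec.qend)
        if qstart < 1 or qend < qstart or lo < 1:
            raise DataError(f"hit table row {i + 1}: invalid coordinates")
        hits.append(AlignmentHit(
            read_id=str(rec.qseqid), subject_id=str(rec.sseqid),
            subject_db=subject_db,
            query_start=qstart - 1, query_end=qend,
            subject_start=lo - 1, subject_end=hi,
            strand=strand, mismatches=int(rec.mismatch),
            gap_openings=int(rec.gapopen),
            evalue=float(rec.evalue), bitscore=float(rec.bitscore),
        ))
    return hits


def dedup_reads(
    reads,
) -> tuple[list[ChimericRead], dict[str, int]]:
    """Collapse exact-sequence duplicates, keeping the first record seen.

    Returns the unique reads and a {sequence: multiplicity} table. Real
    libraries carry PCR/optical duplicates; multiplicity is preserved so
    read-support filters can count original reads.
    """
    uniques: list[ChimericRead] = []
    mult: dict[str, int] = {}
    for item in reads:
        read = item if isinstance(item, ChimericRead) else ChimericRead(
            item[0], item[1], tuple(item[2])
        )
        if read.sequence in mult:
            mult[read.sequence] += 1
        else:
            mult[read.sequence] = 1
            uniques.append(read)
    return uniques, mult


def filter_hits(hits: list[AlignmentHit], config: PipelineConfig) -> list[AlignmentHit]:
    """Keep sense-strand, ungapped hits with e-value <= max_evalue.

    Antisense mappings are discarded because a chimeric fragment reads off
    the transcript's sense strand; gapped ('looped') alignments are
    discarded so that miRNA variant calling stays substitution/end-edit
    only.
    """
    return [
        h for h in hits
        if h.evalue <= config.max_evalue and h.strand == "+" and h.gap_openings == 0
    ]


def call_chimeras(
    read: ChimericRead,
    mirna_hits: list[AlignmentHit],
    mrna_hits: list[AlignmentHit],
    config: PipelineConfig,
) -> list[ChimeraCall]:
    """Enumerate valid (miRNA hit, mRNA hit) pairings within one read.

    A valid pairing has disjoint query intervals separated by at most
    ``max_gap`` nt (overlaps beyond ``max_overlap`` are rejected: ligation
    inserts spacer, it does not merge fragments), with the miRNA portion
    upstream when ``require_mirna_first`` is set. The combined e-value is
    the max of the two hits' (conservative on the weaker mate); the
    combined bit score their sum.
    """
    calls = []
    for mh in mirna_hits:
        if mh.read_id != read.read_id:
            continue
        for th in mrna_hits:
            if th.read_id != read.read_id:
                continue
            if mh.query_start <= th.query_start:
                first, second = mh, th
            else:
                first, second = th, mh
            gap = second.query_start - first.query_end
            if gap < -config.max_overlap or gap > config.max_gap:
                continue
            if config.require_mirna_first and first is not mh:
                continue
            calls.append(ChimeraCall(
                read_id=read.read_id, mirna_hit=mh, mrna_hit=th, gap_nt=gap,
                mirna_portion_seq=read.sequence[mh.query_start:mh.query_end],
                mrna_portion_seq=read.sequence[th.query_start:th.query_end],
                combined_evalue=max(mh.evalue, th.evalue),
                combined_bitscore=mh.bitscore + th.bitscore,
            ))
    return calls


def select_best_pairs(calls: list[ChimeraCall], config: PipelineConfig) -> list[ChimeraCall]:
    """Order one read's candidate pairs and keep the top k.

    Order: smaller combined e-value, then larger combined bit score, then
    lexicographic (miRNA id, transcript id) as a deterministic final
    tie-break; the result is independent of input ordering.
    """
    ordered = sorted(calls, key=lambda c: (
        c.combined_evalue, -c.combined_bitscore,
        c.mirna_hit.subject_id, c.mrna_hit.subject_id,
        c.mirna_hit.query_start, c.mrna_hit.query_start,
    ))
    return ordered[: config.top_k_pairs]


def filter_support(
    calls: list[ChimeraCall],
    config: PipelineConfig,
    multiplicity: dict[str, int] | None = None,
    read_sequences: dict[str, str] | None = None,
) -> list[ChimeraCall]:
    """Require each miRNA-portion sequence to recur in enough chimeric reads.

    Support for a portion is the number of chimeric reads whose call
    carries that exact sequence. With ``count_multiplicity`` (default),
    collapsed duplicate reads count once per original read, since exact
    duplicates of a chimera are still independent observations of the same
    miRNA portion once PCR duplicates are removed upstream.
    """
    support = support_counts(calls, config, multiplicity, read_sequences)
    keep = [c for c in calls if support[c.mirna_portion_seq] >= config.min_support_reads]
    return keep


def support_counts(
    calls: list[ChimeraCall],
    config: PipelineConfig,
    multiplicity: dict[str, int] | None = None,
    read_sequences: dict[str, str] | None = None,
) -> Counter:
    """Read-support per distinct miRNA-portion sequence across all calls."""
    seen: set[tuple[str, str]] = set()
    support: Counter = Counter()
    for c in calls:
        key = (c.read_id, c.mirna_portion_seq)
        if key in seen:
            continue
        seen.add(key)
        weight = 1
        if config.count_multiplicity and multiplicity is not None and read_sequences is not None:
            weight = multiplicity.get(read_sequences.get(c.read_id, ""), 1)
        support[c.mirna_portion_seq] += weight
    return support


def call_variant(
    call: ChimeraCall,
    reference_seq: str,
    qualities: tuple[int, ...] | list[int],
    config: PipelineConfig,
) -> str:
    """Classify a call's miRNA portion against its reference miRNA.

    Returns ``"exact_mirna"`` for a perfect match, ``"isomir"`` when every
    variation position has Phred quality strictly greater than
    ``min_variant_quality``, else ``"rejected"``.
    """
    portion = call.mirna_portion_seq
    if len(qualities) < call.mirna_hit.query_end:
        raise DataError(
            f"read {call.read_id}: quality string shorter than the miRNA portion"
        )
    if portion == reference_seq:
        return "exact_mirna"
    try:
        var_pos = variant_read_positions(portion, reference_seq)
    except (UnclassifiableError, ParameterError):
        return "rejected"
    offset = call.mirna_hit.query_start
    if all(qualities[offset + p] > config.min_variant_quality for p in var_pos):
        return "isomir"
    return "rejected"


# -- pipeline orchestration --------------------------------------------------

@dataclass
class PipelineResult:
    interactions: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    reads,
    mirna_seqs: dict[str, str],
    mirna_hits_table: pd.DataFrame,
    tx_hits_table: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full chimera pipeline from reads + hit tables to an interaction table.

    The output table has one row per surviving call with columns
    (read_support, mirna_id, isomir_seq ('=' for an exact miRNA match),
    transcript_id, site_start, site_end, gap_nt, evalue, bitscore); site
    coordinates are 0-based half-open on the transcript.
    """
    config = config or PipelineConfig()
    uniques, mult = dedup_reads(reads)
    n_reads_in = sum(mult.values())
    read_by_id = {r.read_id: r for r in uniques}
    read_seq_by_id = {r.read_id: r.sequence for r in uniques}

    mirna_hits = filter_hits(hits_from_table(mirna_hits_table, "mirna"), config)
    tx_hits = filter_hits(hits_from_table(tx_hits_table, "transcript"), config)
    by_read_m: dict[str, list[AlignmentHit]] = {}
    for h in mirna_hits:
        by_read_m.setdefault(h.read_id, []).append(h)
    by_read_t: dict[str, list[AlignmentHit]] = {}
    for h in tx_hits:
        by_read_t.setdefault(h.read_id, []).append(h)

    selected: list[ChimeraCall] = []
    for read in uniques:
        cand = call_chimeras(
            read, by_read_m.get(read.read_id, []), by_read_t.get(read.read_id, []), config
        )
        selected.extend(select_best_pairs(cand, config))

    # exact-vs-isomiR decision with the quality check
    verdicts: dict[int, str] = {}
    kept: list[ChimeraCall] = []
    for c in selected:
        ref = mirna_seqs.get(c.mirna_hit.subject_id)
        if ref is None:
            raise DataError(f"unknown miRNA reference {c.mirna_hit.subject_id!r}")
        verdict = call_variant(c, ref, read_by_id[c.read_id].qualities, config)
        if verdict != "rejected":
            verdicts[id(c)] = verdict
            kept.append(c)

    supported = filter_support(kept, config, mult, read_seq_by_id)
    support = support_counts(kept, config, mult, read_seq_by_id)

    rows = []
    for c in supported:
        verdict = verdicts[id(c)]
        rows.append({
            "read_support": support[c.mirna_portion_seq],
            "mirna_id": c.mirna_hit.subject_id,
            "isomir_seq": "=" if verdict == "exact_mirna" else c.mirna_portion_seq,
            "transcript_id": c.mrna_hit.subject_id,
            "site_start": c.mrna_hit.subject_start,
            "site_end": c.mrna_hit.subject_end,
            "gap_nt": c.gap_nt,
            "evalue": c.combined_evalue,
            "bitscore": c.combined_bitscore,
        })
    interactions = pd.DataFrame(rows, columns=ionet.INTERACTION_COLUMNS)
    counts = {
        "reads_in": n_reads_in,
        "reads_after_dedup": len(uniques),
        "mirna_hits_after_filter": len(mirna_hits),
        "tx_hits_after_filter": len(tx_hits),
        "calls_selected": len(selected),
        "calls_after_variant_check": len(kept),
        "calls_after_support": len(supported),
    }
    logger.info("pipeline stage counts: %s", counts)
    return PipelineResult(interactions=interactions, stage_counts=counts)


def classify_interactions(
    interactions: pd.DataFrame, mirna_seqs: dict[str, str]
) -> pd.DataFrame:
    """Type every isomiR row of an interaction table.

    Returns an isomiR call table (mirna_id, isomir_seq, offset_5p,
    offset_3p, mismatch_positions, types, support_reads); exact-miRNA rows
    ('=') are skipped.
    """
    from .isomir import anchor_align  # local import to avoid cycle at module load

    rows = []
    for rec in interactions.itertuples(index=False):
        if rec.isomir_seq == "=":
            continue
        ref = mirna_seqs[rec.mirna_id]
        a = anchor_align(rec.isomir_seq, ref)
        types = classify_isomir(rec.isomir_seq, ref)
        rows.append({
            "mirna_id": rec.mirna_id,
            "isomir_seq": rec.isomir_seq,
            "offset_5p": a.offset_5p,
            "offset_3p": a.offset_3p,
            "mismatch_positions": ";".join(map(str, a.internal_mismatch_positions)),
            "types": ";".join(sorted(types)),
            "support_reads": rec.read_support,
        })
    return pd.DataFrame(rows, columns=[
        "mirna_id", "isomir_seq", "offset_5p", "offset_3p",
        "mismatch_positions", "types", "support_reads",
    ])
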