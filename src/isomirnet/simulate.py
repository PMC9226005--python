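"""Synthetic chimeric-read libraries with a known truth manifest.

Real miRNA/isomiR-target interaction studies start from crosslink-ligation
(CLASH / CLEAR-CLIP) sequencing libraries, where a single read carries a
miRNA or isomiR fragment ligated to its bound mRNA target site, separated
by at most a few nucleotides. This module generates structurally equivalent
synthetic inputs — mature miRNA references, transcripts with an annotated
3'UTR, planted target sites, isomiR variants of known type, and chimeric
FASTQ reads with configurable per-base error — together with a truth
manifest, so every downstream stage of the pipeline can be exercised and
scored without external data.

The per-base substitution error rate defaults to 0.001, the canonical
Illumina short-read error rate. Qualities are Phred+33: error positions
receive ``low_q`` (default 20) and correct positions ``high_q`` (default
40), so a quality cutoff of 30 separates them in both directions.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by the configuration, and outputs are byte-identical across reruns of the
same configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as ionet
from .errors import ParameterError, PlacementError
from .seq import DNA_ALPHABET, revcomp, seed_region

#: Canonical labels for the eight isomiR types.
ISOMIR_TYPES = (
    "5p_add", "5p_del", "5p_rep",
    "3p_add", "3p_del", "3p_rep",
    "snp", "mnp",
)

SITE_MODELS = ("seed_complement_only", "seed_plus_3prime")

MANIFEST_COLUMNS = [
    "read_id", "mirna_id", "isomir_sequence", "isomir_true_types",
    "transcript_id", "site_start", "site_end", "gap_nt",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic chimeric-read experiment."""

    n_mirnas: int = 20
    mirna_len_range: tuple[int, int] = (20, 24)
    n_transcripts: int = 10
    transcript_len_range: tuple[int, int] = (400, 700)
    reads_per_pair: int = 12
    base_error_rate: float = 0.001
    quality_model: tuple[int, int] = (40, 20)  # (high_q, low_q)
    seed: int = 0
    utr_fraction: float = 0.4
    n_pairs: int | None = None          # default: one interaction per miRNA
    isomir_fraction: float = 0.5
    site_model: str = "seed_complement_only"
    site_len: int = 35
    mirna_first: bool = True
    max_spacer: int = 4

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_transcripts < 1 or self.reads_per_pair < 1:
            raise ParameterError("counts must be >= 1")
        for lo, hi in (self.mirna_len_range, self.transcript_len_range):
            if lo > hi:
                raise ParameterError(f"inverted length range ({lo}, {hi})")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ParameterError("base_error_rate must be in [0, 1)")
        if not 0.0 < self.utr_fraction <= 1.0:
            raise ParameterError("utr_fraction must be in (0, 1]")
        if self.site_model not in SITE_MODELS:
            raise ParameterError(f"unknown site model {self.site_model!r}")
        if not 0 <= self.max_spacer <= 4:
            raise ParameterError("max_spacer must be in [0, 4]")


@dataclass(frozen=True)
class PlannedPair:
    """One planted miRNA/isomiR-target interaction."""

    pair_id: str
    mirna_id: str
    isomir_seq: str
    isomir_types: frozenset[str]
    transcript_id: str
    site_start: int
    site_end: int
    site_seq: str


@dataclass(frozen=True)
class PlantedSite:
    interval: tuple[int, int]
    seed_offset: int  # offset of the seed complement within the site
    site_seq: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in DNA_ALPHABET if b != base]
    return choices[int(rng.integers(len(choices)))]


def gen_references(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate miRNA and transcript references plus the 3'UTR table.

    Returns ``(mirnas, transcripts, utr_table)`` where the UTR occupies the
    final ``utr_fraction`` of each transcript. miRNA sequences are pairwise
    distinct; generation is deterministic under the configured seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mirnas: dict[str, str] = {}
    seen: set[str] = set()
    lo, hi = config.mirna_len_range
    i = 0
    while len(mirnas) < config.n_mirnas:
        length = int(rng.integers(lo, hi + 1))
        s = _random_seq(rng, length)
        if s in seen:
            continue
        seen.add(s)
        mirnas[f"mir-{i:04d}"] = s
        i += 1
    transcripts: dict[str, str] = {}
    utr_rows = []
    tlo, thi = config.transcript_len_range
    for j in range(config.n_transcripts):
        length = int(rng.integers(tlo, thi + 1))
        tid = f"tx-{j:04d}"
        transcripts[tid] = _random_seq(rng, length)
        utr_start = int(round(length * (1.0 - config.utr_fraction)))
        utr_rows.append({"transcript_id": tid, "utr_start": utr_start, "utr_end": length})
    utr = pd.DataFrame(utr_rows, columns=ionet.UTR_COLUMNS)
    return mirnas, transcripts, utr


# -- isomiR construction -----------------------------------------------------

_MIN_MIRNA_LEN = 17  # shortest small RNA handled by the classifier


def gen_isomir(
    mirna_seq: str,
    kind: str,
    size: int = 1,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, frozenset[str]]:
    """Construct an isomiR of a single requested type from a reference miRNA.

    ``kind`` is one of :data:`ISOMIR_TYPES`; ``size`` is the edit size (number
    of added/deleted/replaced terminal nucleotides, or the number of internal
    substitutions for ``mnp``). Constructions are unambiguous: the edit can
    not be reproduced by a different single type, so anchored classification
    recovers exactly the returned type set.
    """
    if kind not in ISOMIR_TYPES:
        raise ParameterError(f"unknown isomiR type {kind!r}")
    if len(mirna_seq) < _MIN_MIRNA_LEN:
        raise ParameterError(
            f"reference miRNA shorter than {_MIN_MIRNA_LEN} nt"
        )
    if size < 1:
        raise ParameterError("edit size must be >= 1")
    if kind in ("5p_del", "3p_del") and size >= len(mirna_seq):
        raise ParameterError("deletion size must be smaller than the sequence")
    if kind == "snp" and size != 1:
        raise ParameterError("snp means exactly one internal substitution")
    if kind == "mnp" and size < 2:
        raise ParameterError("mnp needs >= 2 internal substitutions")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    s = list(mirna_seq)
    L = len(s)
    if kind == "5p_add":
        iso = _random_seq(rng, size) + mirna_seq
    elif kind == "5p_del":
        iso = mirna_seq[size:]
    elif kind == "5p_rep":
        if size > 2:
            raise ParameterError("terminal replacement size limited to 2")
        for p in range(size):
            s[p] = _substitute(rng, s[p])
        iso = "".join(s)
    elif kind == "3p_add":
        iso = mirna_seq + _random_seq(rng, size)
    elif kind == "3p_del":
        iso = mirna_seq[:-size]
    elif kind == "3p_rep":
        if size > 2:
            raise ParameterError("terminal replacement size limited to 2")
        for p in range(L - size, L):
            s[p] = _substitute(rng, s[p])
        iso = "".join(s)
    elif kind == "snp":
        p = int(rng.integers(2, L - 2))
        s[p] = _substitute(rng, s[p])
        iso = "".join(s)
    else:  # mnp
        if size > L - 4:
            raise ParameterError("too many internal substitutions requested")
        positions = rng.choice(np.arange(2, L - 2), size=size, replace=False)
        for p in sorted(int(q) for q in positions):
            s[p] = _substitute(rng, s[p])
        iso = "".join(s)
    return iso, frozenset({kind})


# -- target-site planting ----------------------------------------------------

def _build_site(
    mirna_seq: str, site_model: str, site_len: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Return (site_seq, seed_offset) with the seed complement placed once."""
    core = revcomp(seed_region(mirna_seq))
    if site_model == "seed_plus_3prime":
        supp = revcomp(mirna_seq[9:16])
        needed = len(supp) + 4 + len(core) + 4
    else:
        supp = ""
        needed = len(core) + 8
    if site_len < needed:
        raise ParameterError(f"site_len {site_len} too short for model {site_model}")
    for _ in range(100):
        # mRNA 5'->3': complement of the miRNA 3' region precedes the seed
        # complement, because the duplex is antiparallel.
        if supp:
            pad_b = 4
            pad_mid = 4
            pad_a = site_len - len(supp) - pad_mid - len(core) - pad_b
            site = (
                _random_seq(rng, pad_a) + supp + _random_seq(rng, pad_mid)
                + core + _random_seq(rng, pad_b)
            )
            seed_offset = pad_a + len(supp) + pad_mid
        else:
            seed_offset = int(rng.integers(2, site_len - len(core) - 2))
            site = (
                _random_seq(rng, seed_offset) + core
                + _random_seq(rng, site_len - seed_offset - len(core))
            )
        if site.count(core) == 1:
            return site, seed_offset
    raise PlacementError("could not build a site with a unique seed match")


def plant_target_site(
    transcript_seq: str,
    mirna_seq: str,
    site_model: str = "seed_complement_only",
    position: int = 0,
    rng: np.random.Generator | int | None = None,
    existing: Sequence[tuple[int, int]] = (),
    site_len: int = 35,
) -> tuple[str, PlantedSite]:
    """Overwrite ``site_len`` transcript bases at ``position`` with a target site.

    The planted site contains the reverse complement of miRNA positions 2-7
    (and, under the ``seed_plus_3prime`` model, also of positions 10-16
    upstream of it). Overlap with any interval in ``existing`` or running
    past the transcript end raises :class:`PlacementError`.
    """
    if site_model not in SITE_MODELS:
        raise ParameterError(f"unknown site model {site_model!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    start, end = position, position + site_len
    if start < 0 or end > len(transcript_seq):
        raise PlacementError(
            f"site [{start}, {end}) outside transcript of length {len(transcript_seq)}"
        )
    for a, b in existing:
        if start < b and a < end:
            raise PlacementError(f"site [{start}, {end}) overlaps existing [{a}, {b})")
    site, seed_offset = _build_site(mirna_seq, site_model, site_len, rng)
    new_seq = transcript_seq[:start] + site + transcript_seq[end:]
    return new_seq, PlantedSite((start, end), seed_offset, site)


# -- chimeric reads ----------------------------------------------------------

def _aligned_core(isomir_seq: str, ref_seq: str) -> str:
    """The part of an isomiR a trimmed local alignment against its
    reference would report: unaligned overhangs and terminal mismatch runs
    stripped."""
    from .isomir import anchor_align

    a = anchor_align(isomir_seq, ref_seq)
    start = max(0, -a.offset_5p) + a.terminal_run_5p
    end = min(len(isomir_seq), len(ref_seq) - a.offset_5p) - a.terminal_run_3p
    return isomir_seq[start:end]


def _read_recovers(
    read_seq: str,
    pair: PlannedPair,
    mirna_seq: str,
    transcript_seq: str,
    expected_portion: str,
) -> bool:
    """Would the chimera caller recover this planted pair from the read?

    Runs the actual aligner and caller on the single error-free read
    against the pair's own references and checks that the top call carries
    the canonical miRNA portion and a site overlapping the planted
    interval. Junction artifacts (a spacer base coincidentally extending
    the miRNA reference or the transcript context) fail this check and
    trigger a spacer redraw, which keeps planted pairs recoverable by
    construction.
    """
    from .chimera import (
        ChimericRead, PipelineConfig, call_chimeras, filter_hits,
        hits_from_table, select_best_pairs,
    )

    cfg = PipelineConfig()
    probe = [(pair.pair_id, read_seq, [40] * len(read_seq))]
    mh_df = gen_alignment_hits(probe, {pair.mirna_id: mirna_seq}, max_mismatches=2)
    th_df = gen_alignment_hits(probe, {pair.transcript_id: transcript_seq}, max_mismatches=2)
    mh = filter_hits(hits_from_table(mh_df, "mirna"), cfg)
    th = filter_hits(hits_from_table(th_df, "transcript"), cfg)
    read = ChimericRead(pair.pair_id, read_seq, tuple([40] * len(read_seq)))
    best = select_best_pairs(call_chimeras(read, mh, th, cfg), cfg)
    for c in best:
        if (
            c.mirna_portion_seq == expected_portion
            and c.mrna_hit.subject_id == pair.transcript_id
            and c.mrna_hit.subject_start < pair.site_end
            and pair.site_start < c.mrna_hit.subject_end
        ):
            return True
    return False


def gen_chimeric_reads(
    pairs: Sequence[PlannedPair],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mirnas: dict[str, str] | None = None,
    transcripts: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str, list[int]]], pd.DataFrame]:
    """Emit chimeric FASTQ reads and the truth manifest for planned pairs.

    Each read is the isomiR portion, a spacer of 0..max_spacer random
    nucleotides, and the target-site portion (miRNA first by default, the
    CLASH chimera convention; set ``mirna_first=False`` for the reverse
    layout). ``reads_per_pair`` copies are emitted per pair so read-support
    filters are exercisable; per-base substitution errors are applied at
    ``base_error_rate`` with low quality at error positions.

    When the reference dicts are supplied, each error-free read layout is
    validated with the actual aligner+caller (see :func:`_read_recovers`)
    and redrawn on junction artifacts, so that with no sequencing error
    every planted pair is recoverable end to end.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    high_q, low_q = config.quality_model
    reads: list[tuple[str, str, list[int]]] = []
    rows = []
    for pair in pairs:
        validate = mirnas is not None and transcripts is not None
        if validate:
            ref = mirnas[pair.mirna_id]
            expected_portion = (
                _aligned_core(pair.isomir_seq, ref)
                if pair.isomir_seq != ref else ref
            )
        for copy in range(config.reads_per_pair):
            for _attempt in range(50):
                gap = int(rng.integers(0, config.max_spacer + 1))
                spacer = _random_seq(rng, gap)
                if config.mirna_first:
                    base_seq = pair.isomir_seq + spacer + pair.site_seq
                else:
                    base_seq = pair.site_seq + spacer + pair.isomir_seq
                if not validate or _read_recovers(
                    base_seq, pair, ref, transcripts[pair.transcript_id],
                    expected_portion,
                ):
                    break
            chars = list(base_seq)
            quals = [high_q] * len(chars)
            if config.base_error_rate > 0:
                err = rng.random(len(chars)) < config.base_error_rate
                for p in np.nonzero(err)[0]:
                    chars[p] = _substitute(rng, chars[p])
                    quals[p] = low_q
            read_id = f"{pair.pair_id}:r{copy}"
            reads.append((read_id, "".join(chars), quals))
            rows.append({
                "read_id": read_id,
                "mirna_id": pair.mirna_id,
                "isomir_sequence": pair.isomir_seq,
                "isomir_true_types": ";".join(sorted(pair.isomir_types)),
                "transcript_id": pair.transcript_id,
                "site_start": pair.site_start,
                "site_end": pair.site_end,
                "gap_nt": gap,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["read_id"].duplicated().any():
        raise ParameterError("duplicate read ids in manifest")
    return reads, manifest


# -- alignment-hit generation (test-only stand-in for BLAST) -----------------

def _segments_with_mismatches(
    match: np.ndarray, max_mismatches: int, min_len: int
) -> list[tuple[int, int]]:
    """Maximal [start, end) windows with <= max_mismatches False entries,
    trimmed so they never start or end on a mismatch, length >= min_len."""
    n = match.size
    out: list[tuple[int, int]] = []
    right = 0
    bad = 0
    best: tuple[int, int] | None = None
    for left in range(n):
        if right < left:
            right, bad = left, 0
        while right < n and (match[right] or bad < max_mismatches):
            if not match[right]:
                bad += 1
            right += 1
        a, b = left, right
        while a < b and not match[a]:
            a += 1
        while b > a and not match[b - 1]:
            b -= 1
        if b - a >= min_len:
            if best is None or not (best[0] <= a and b <= best[1]):
                out.append((a, b))
                best = (a, b)
        if left < n and not match[left]:
            bad -= 1
    # remove windows contained in a later, larger one
    out = [
        (a, b) for (a, b) in out
        if not any((c <= a and b <= d) and (a, b) != (c, d) for (c, d) in out)
    ]
    return out


def _surrogate_stats(ref_len: int, length: int, mismatch: int) -> tuple[float, float]:
    """Surrogate (evalue, bitscore): monotone stand-ins for BLAST statistics."""
    evalue = ref_len * 4.0 ** (-(length - 2 * mismatch))
    bitscore = 2.0 * (length - mismatch)
    return evalue, bitscore


def gen_alignment_hits(
    reads: Iterable[tuple[str, str, list[int]]],
    references: dict[str, str],
    max_mismatches: int = 0,
    min_anchor: int = 16,
) -> pd.DataFrame:
    """Ungapped substring search of references in reads, as an outfmt-6 table.

    A documented test-only stand-in for BLAST: every maximal ungapped match
    (allowing up to ``max_mismatches`` substitutions) of length >=
    ``min_anchor`` is emitted with 1-based inclusive coordinates, gapopen 0,
    and surrogate e-value/bit score monotone in mismatches and match length.
    Antisense matches are reported with sstart > send.
    """
    rows = []
    base_idx = {b: i for i, b in enumerate("ACGTN")}
    for read_id, read_seq, _quals in reads:
        q = np.array([base_idx.get(c, 4) for c in read_seq], dtype=np.int8)
        m = q.size
        for ref_id, ref_seq in references.items():
            for sense in ("+", "-"):
                target = ref_seq if sense == "+" else revcomp(ref_seq)
                s = np.array([base_idx.get(c, 4) for c in target], dtype=np.int8)
                n = s.size
                if n < min_anchor or m < min_anchor:
                    continue
                eq = q[:, None] == s[None, :]
                for d in range(-(m - min_anchor), n - min_anchor + 1):
                    diag = np.diagonal(eq, offset=d)
                    if diag.size < min_anchor or int(diag.sum()) < min_anchor - max_mismatches:
                        continue
                    lo = max(0, -d)  # query index of diagonal start
                    for a, b in _segments_with_mismatches(diag, max_mismatches, min_anchor):
                        qs, qe = lo + a, lo + b          # query, 0-based half-open
                        ss, se = qs + d, qe + d          # target, 0-based half-open
                        length = qe - qs
                        mism = int((~diag[a:b]).sum())
                        ev, bs = _surrogate_stats(n, length, mism)
                        if sense == "+":
                            sstart, send = ss + 1, se
                        else:
                            sstart, send = n - ss, n - se + 1
                        rows.append({
                            "qseqid": read_id, "sseqid": ref_id,
                            "pident": round(100.0 * (length - mism) / length, 2),
                            "length": length, "mismatch": mism, "gapopen": 0,
                            "qstart": qs + 1, "qend": qe,
                            "sstart": sstart, "send": send,
                            "evalue": ev, "bitscore": bs,
                        })
    return pd.DataFrame(rows, columns=ionet.OUTFMT6_COLUMNS)


# -- end-to-end simulation ---------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    mirnas: dict[str, str]
    transcripts: dict[str, str]
    utr_table: pd.DataFrame
    pairs: list[PlannedPair]
    reads: list[tuple[str, str, list[int]]]
    manifest: pd.DataFrame

    def alignment_hits(
        self, max_mismatches: int = 2, min_anchor: int = 16
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(miRNA-db hits, transcript-db hits) for the generated reads."""
        mirna_hits = gen_alignment_hits(self.reads, self.mirnas, max_mismatches, min_anchor)
        tx_hits = gen_alignment_hits(self.reads, self.transcripts, max_mismatches, min_anchor)
        return mirna_hits, tx_hits

    def write(self, outdir: str | Path, with_hits: bool = True) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirnas": outdir / "mirnas.fa",
            "transcripts": outdir / "transcripts.fa",
            "utr": outdir / "utr.tsv",
            "reads": outdir / "reads.fastq",
            "manifest": outdir / "manifest.tsv",
        }
        ionet.write_fasta(self.mirnas, paths["mirnas"])
        ionet.write_fasta(self.transcripts, paths["transcripts"])
        ionet.write_table(self.utr_table, paths["utr"])
        ionet.write_fastq(self.reads, paths["reads"])
        ionet.write_table(self.manifest, paths["manifest"])
        if with_hits:
            mh, th = self.alignment_hits()
            paths["mirna_hits"] = outdir / "mirna_hits.tsv"
            paths["tx_hits"] = outdir / "tx_hits.tsv"
            ionet.write_hits(mh, paths["mirna_hits"])
            ionet.write_hits(th, paths["tx_hits"])
        return paths


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic experiment from one configuration.

    Each planned interaction pairs one miRNA (round-robin over the panel,
    so every miRNA is represented) with a target site planted inside the
    3'UTR of a randomly chosen transcript; about ``isomir_fraction`` of the
    small-RNA portions are isomiRs of a random type.
    """
    rng = np.random.default_rng(config.seed)
    mirnas, transcripts, utr = gen_references(config, rng)
    utr_ix = utr.set_index("transcript_id")
    n_pairs = config.n_pairs if config.n_pairs is not None else config.n_mirnas
    mirna_ids = list(mirnas)
    tx_ids = list(transcripts)
    planted: dict[str, list[tuple[int, int]]] = {t: [] for t in tx_ids}
    pairs: list[PlannedPair] = []
    for i in range(n_pairs):
        mirna_id = mirna_ids[i % len(mirna_ids)]
        mirna_seq = mirnas[mirna_id]
        if rng.random() < config.isomir_fraction:
            kind = ISOMIR_TYPES[int(rng.integers(len(ISOMIR_TYPES)))]
            size = 2 if kind == "mnp" else int(rng.integers(1, 3))
            if kind in ("5p_rep", "3p_rep", "snp"):
                size = 1
            iso_seq, types = gen_isomir(mirna_seq, kind, size, rng)
        else:
            iso_seq, types = mirna_seq, frozenset()
        placed = False
        for _attempt in range(200):
            tx_id = tx_ids[int(rng.integers(len(tx_ids)))]
            u0, u1 = int(utr_ix.loc[tx_id, "utr_start"]), int(utr_ix.loc[tx_id, "utr_end"])
            if u1 - u0 < config.site_len + 2:
                continue
            pos = int(rng.integers(u0, u1 - config.site_len + 1))
            try:
                new_tx, site = plant_target_site(
                    transcripts[tx_id], mirna_seq, config.site_model, pos,
                    rng, existing=planted[tx_id], site_len=config.site_len,
                )
            except PlacementError:
                continue
            transcripts[tx_id] = new_tx
            planted[tx_id].append(site.interval)
            pairs.append(PlannedPair(
                pair_id=f"pair-{i:04d}", mirna_id=mirna_id, isomir_seq=iso_seq,
                isomir_types=types, transcript_id=tx_id,
                site_start=site.interval[0], site_end=site.interval[1],
                site_seq=site.site_seq,
            ))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place site for pair {i}: UTRs too crowded"
            )
    reads, manifest = gen_chimeric_reads(pairs, config, rng, mirnas, transcripts)
    return SimulatedDataset(config, mirnas, transcripts, utr, pairs, reads, manifest)


# -- separable training set for learning-sanity checks -----------------------

def gen_separable_pairs(
    n_pos: int,
    seed: int = 0,
    n_mirnas: int = 8,
    mirna_len: int = 22,
    site_len: int = 60,
    duplex_span: tuple[int, int] = (1, 16),
    anchor_offset: int = 20,
    anchor_jitter: int = 6,
    decoy_fraction: float = 0.5,
) -> pd.DataFrame:
    """A separable miRNA-target training set emulating chimera-derived pairs.

    Positives pair each miRNA of a small panel with a site carrying the
    reverse complement of miRNA positions ``duplex_span`` (default 2-16:
    seed through the 3'-supplementary region, mirroring the extensive
    pairing of crosslink-captured duplexes) planted at a ligation-anchored
    offset (``anchor_offset`` plus a small jitter — chimeric sites carry
    the bound region at a roughly fixed position relative to the ligation
    point, not uniformly). Negatives keep the same small RNA and are, with
    probability ``decoy_fraction``, a site built for a different panel
    miRNA (a specificity decoy forcing the model to consult the small-RNA
    branch) and otherwise a shuffle of the positive site (a composition
    decoy). One negative per positive; labels balanced.

    The panel size (default 8) keeps the per-miRNA pair density at
    n_pos=2000 near that of real crosslinking libraries (several hundred
    interactions per miRNA).
    """
    if n_pos < 1 or n_mirnas < 1:
        raise ParameterError("counts must be >= 1")
    lo, hi = duplex_span
    if not 0 <= lo < hi <= mirna_len:
        raise ParameterError("invalid duplex span")
    if anchor_offset + anchor_jitter + (hi - lo) > site_len:
        raise ParameterError("duplex anchor does not fit in the site")
    rng = np.random.default_rng(seed)
    mirnas: dict[str, str] = {}
    while len(mirnas) < n_mirnas:
        s = _random_seq(rng, mirna_len)
        mirnas.setdefault(f"mir-{len(mirnas):04d}", s)
    ids = list(mirnas)

    def make_site(mseq: str) -> str:
        core = revcomp(seed_region(mseq))
        duplex = revcomp(mseq[lo:hi])
        for _ in range(100):
            off = anchor_offset + int(rng.integers(0, anchor_jitter + 1))
            site = (
                _random_seq(rng, off) + duplex
                + _random_seq(rng, site_len - off - len(duplex))
            )
            if site.count(core) == 1:
                return site
        raise PlacementError("could not build a site with a unique seed match")

    rows = []
    for i in range(n_pos):
        mid = ids[i % n_mirnas]
        mseq = mirnas[mid]
        core = revcomp(seed_region(mseq))
        site = make_site(mseq)
        rows.append({"small_rna_seq": mseq, "site_seq": site, "label": 1,
                     "mirna_id": mid, "provenance": "clash-like"})
        if n_mirnas > 1 and rng.random() < decoy_fraction:
            other = mid
            while other == mid:
                other = ids[int(rng.integers(n_mirnas))]
            neg = make_site(mirnas[other])
            for _ in range(20):  # the decoy must not carry the own core
                if core not in neg:
                    break
                neg = make_site(mirnas[other])
        else:
            chars = np.array(list(site))
            neg = site
            for _ in range(50):
                neg = "".join(rng.permutation(chars))
                if core not in neg:
                    break
        rows.append({"small_rna_seq": mseq, "site_seq": neg, "label": 0,
                     "mirna_id": mid, "provenance": "negative-sampled"})
    return pd.DataFrame(rows)
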