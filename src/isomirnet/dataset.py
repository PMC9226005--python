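"""Labeled interaction pairs for training: extension, negatives, splits.

Positive pairs come from chimera interaction calls: the mRNA site of each
call is extended by 25 nt at its 3' end to capture the complete target
site, and extended sites shorter than 30 nt are dropped. For every
positive pair a negative is drawn with the same small RNA and a decoy
site in the 3'UTR of the same transcript, at least 10 nt away from every
positive site and passing a duplex-energy screen.

Two duplex-energy backends exist: ``builtin_proxy`` (default), a
documented pairing-strength proxy computed in closed form, and
``external_cofold``, which shells out to an RNAcofold-compatible
executable and parses its free energy. The acceptance predicate compares
the signed kcal/mol value against the threshold (default: energy < +10,
i.e. permissive); users reading the criterion as requiring a stable duplex
can flip the threshold to -10 via configuration.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParameterError
from .seq import normalize

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "small_rna_seq", "site_seq", "label", "transcript_id",
    "site_start", "site_end", "mirna_id", "provenance",
]

MIN_SITE_LEN = 30
DEFAULT_EXTENSION = 25


@dataclass
class NegativeConfig:
    min_distance: int = 10
    energy_threshold: float = 10.0
    energy_predicate: str = "lt"      # accept iff energy < threshold
    energy_backend: str = "builtin_proxy"
    max_attempts: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ParameterError("min_distance must be >= 0")
        if self.max_attempts < 1:
            raise ParameterError("max_attempts must be >= 1")
        if self.energy_predicate not in ("lt", "gt"):
            raise ParameterError("energy_predicate must be 'lt' or 'gt'")
        if self.energy_backend not in ("builtin_proxy", "external_cofold"):
            raise ParameterError(f"unknown energy backend {self.energy_backend!r}")


def extend_site(
    transcript_seq: str,
    site_interval: tuple[int, int],
    extension: int = DEFAULT_EXTENSION,
    min_len: int = MIN_SITE_LEN,
) -> tuple[int, int] | None:
    """Advance a site's 3' end by up to ``extension`` nt; None if too short.

    The 3' end moves by min(extension, distance to the transcript end);
    the extended interval is rejected (None) when shorter than ``min_len``.
    """
    start, end = site_interval
    if start < 0 or end > len(transcript_seq) or start >= end:
        raise DataError(f"site interval {site_interval} outside transcript")
    new_end = min(len(transcript_seq), end + extension)
    if new_end - start < min_len:
        return None
    return (start, new_end)


# -- duplex energy -----------------------------------------------------------

_PAIR_SCORE = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}


def _proxy_energy(small_rna_seq: str, site_seq: str) -> float:
    """-(3*GC + 2*AU + 1*GU) over the best ungapped antiparallel alignment.

    The small RNA (5'->3') is slid along the reversed site so aligned
    positions face each other as in an antiparallel duplex; the returned
    value is the negative of the best total pairing score, a monotone
    proxy for hybridization free energy in kcal/mol-like units.
    """
    a = normalize(small_rna_seq, context="small RNA")
    b = normalize(site_seq, context="site")[::-1]
    best = 0.0
    for off in range(-(len(a) - 1), len(b)):
        score = 0.0
        lo = max(0, -off)
        hi = min(len(a), len(b) - off)
        for i in range(lo, hi):
            score += _PAIR_SCORE.get((a[i], b[i + off]), 0.0)
        best = max(best, score)
    return -best


def _cofold_energy(small_rna_seq: str, site_seq: str, executable: str = "RNAcofold") -> float:
    if shutil.which(executable) is None:
        raise ConfigurationError(
            f"energy backend 'external_cofold' needs {executable!r} on PATH"
        )
    rna = lambda s: normalize(s).replace("T", "U")
    proc = subprocess.run(
        [executable, "--noPS"],
        input=f"{rna(small_rna_seq)}&{rna(site_seq)}\n",
        capture_output=True, text=True, check=True,
    )
    last = proc.stdout.strip().splitlines()[-1]
    # e.g. ".((...))&...((..))  ( -7.80)"
    energy = last[last.rfind("(") + 1: last.rfind(")")]
    return float(energy)


def duplex_energy(
    small_rna_seq: str, site_seq: str, backend: str = "builtin_proxy"
) -> float:
    """Hybridization energy (kcal/mol; more negative = stronger pairing)."""
    if not small_rna_seq or not site_seq:
        raise ParameterError("sequences must be non-empty")
    if backend == "builtin_proxy":
        return _proxy_energy(small_rna_seq, site_seq)
    if backend == "external_cofold":
        return _cofold_energy(small_rna_seq, site_seq)
    raise ConfigurationError(f"unknown energy backend {backend!r}")


# -- negative sampling -------------------------------------------------------

def _far_enough(start: int, end: int, positives, min_distance: int) -> bool:
    for a, b in positives:
        if start < b + min_distance and a - min_distance < end:
            return False
    return True


def sample_negative(
    transcript_seq: str,
    utr_interval: tuple[int, int],
    positive_sites,
    length: int,
    small_rna_seq: str,
    config: NegativeConfig,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Draw a decoy site interval from the 3'UTR, or None.

    Candidate start positions are sampled uniformly without replacement
    over the UTR; the first candidate at least ``min_distance`` nt from
    every positive site whose duplex energy with the small RNA satisfies
    the configured predicate is accepted. None after ``max_attempts``
    candidates (or when the UTR cannot hold the requested length).
    """
    u0, u1 = utr_interval
    if u1 - u0 < length:
        logger.debug("UTR [%d, %d) shorter than requested length %d", u0, u1, length)
        return None
    starts = np.arange(u0, u1 - length + 1)
    order = rng.permutation(starts)
    for s in order[: config.max_attempts]:
        start, end = int(s), int(s) + length
        if not _far_enough(start, end, positive_sites, config.min_distance):
            continue
        e = duplex_energy(small_rna_seq, transcript_seq[start:end], config.energy_backend)
        ok = e < config.energy_threshold if config.energy_predicate == "lt" \
            else e > config.energy_threshold
        if ok:
            return (start, end)
    return None


def build_pairs(
    interactions: pd.DataFrame,
    transcripts: dict[str, str],
    mirna_seqs: dict[str, str],
    utr_table: pd.DataFrame,
    neg_config: NegativeConfig | None = None,
    extension: int = DEFAULT_EXTENSION,
) -> pd.DataFrame:
    """Positive + negative labeled pairs from an interaction table.

    One positive per interaction call (after 3' extension and the >=30-nt
    filter) and, when sampling succeeds, one matched negative of the same
    length with the same small RNA on the same transcript's 3'UTR.
    """
    neg_config = neg_config or NegativeConfig()
    rng = np.random.default_rng(neg_config.rng_seed)
    utr_ix = utr_table.set_index("transcript_id")
    pos_by_tx: dict[str, list[tuple[int, int]]] = {}
    extended = []
    for rec in interactions.itertuples(index=False):
        tx = transcripts[rec.transcript_id]
        iv = extend_site(tx, (int(rec.site_start), int(rec.site_end)), extension)
        if iv is None:
            continue
        small = mirna_seqs[rec.mirna_id] if rec.isomir_seq == "=" else rec.isomir_seq
        extended.append((rec, iv, small))
        pos_by_tx.setdefault(rec.transcript_id, []).append(iv)
    rows = []
    for rec, (start, end), small in extended:
        tx = transcripts[rec.transcript_id]
        rows.append({
            "small_rna_seq": small, "site_seq": tx[start:end], "label": 1,
            "transcript_id": rec.transcript_id, "site_start": start,
            "site_end": end, "mirna_id": rec.mirna_id, "provenance": "clash-like",
        })
        if rec.transcript_id not in utr_ix.index:
            logger.warning("no UTR annotation for %s; negative skipped", rec.transcript_id)
            continue
        u0 = int(utr_ix.loc[rec.transcript_id, "utr_start"])
        u1 = int(utr_ix.loc[rec.transcript_id, "utr_end"])
        neg = sample_negative(
            tx, (u0, u1), pos_by_tx[rec.transcript_id], end - start, small,
            neg_config, rng,
        )
        if neg is None:
            logger.warning("no negative site found on %s", rec.transcript_id)
            continue
        rows.append({
            "small_rna_seq": small, "site_seq": tx[neg[0]:neg[1]], "label": 0,
            "transcript_id": rec.transcript_id, "site_start": neg[0],
            "site_end": neg[1], "mirna_id": rec.mirna_id,
            "provenance": "negative-sampled",
        })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# -- train/test split --------------------------------------------------------

def split(
    pairs: pd.DataFrame,
    train_fraction: float = 0.8,
    mode: str = "by_pair",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test split.

    ``by_pair`` stratifies by label with round(train_fraction * n) training
    pairs per label. ``by_mirna`` partitions miRNA identities so no
    reference miRNA contributes pairs to both sides — the miRNA-disjoint
    evaluation that tests generalization to unseen miRNAs.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "by_pair":
        train_idx: list[int] = []
        test_idx: list[int] = []
        for _label, grp in pairs.groupby("label"):
            idx = grp.index.to_numpy()
            perm = rng.permutation(idx)
            n_train = round(train_fraction * len(idx))
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
        return pairs.loc[sorted(train_idx)], pairs.loc[sorted(test_idx)]
    if mode == "by_mirna":
        if "mirna_id" not in pairs.columns:
            raise DataError("by_mirna split needs a mirna_id column")
        ids = np.array(sorted(pairs["mirna_id"].unique()))
        perm = rng.permutation(ids)
        n_train = round(train_fraction * len(ids))
        train_ids = set(perm[:n_train])
        mask = pairs["mirna_id"].isin(train_ids)
        return pairs[mask], pairs[~mask]
    raise ParameterError(f"unknown split mode {mode!r}")
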