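"""Model interpretation: kernel motifs, motif-database matching, perturbation.

Two complementary views of what the trained interaction model learned:

* **Kernel motif analysis** exports each convolutional kernel as a 4 x k
  weight matrix, converts it column-wise to nucleotide fractions, flags
  kernels whose columns are too close to the uniform 25% baseline to favor
  any nucleotide, and matches the informative ones against a motif
  database in JASPAR PFM format by maximal Pearson correlation over all
  full-overlap offsets.

* **Input perturbation** slides a 4-nt N mask along each input sequence,
  records the change in prediction probability per window start, and
  aggregates mean and variance per position over a dataset — the model's
  positional sensitivity profile. miRNAs can then be clustered by the
  correlation of their sensitivity profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError, ParseError
from .model import ModelConfig, Predictor, encode

logger = logging.getLogger(__name__)

_KERNEL_ROWS = "ATCG"  # row order of kernel weight matrices


@dataclass
class KernelMotif:
    branch: str           # "mirna" | "site"
    kernel_index: int
    weights: np.ndarray           # 4 x k raw weights
    column_fractions: np.ndarray  # 4 x k, columns sum to 1
    informative: bool


def _to_fractions(weights: np.ndarray) -> np.ndarray:
    """Min-shift each column to non-negative and normalize to sum 1.

    A constant column maps to the uniform 0.25 baseline, which is exactly
    the reference point of the informativeness rule.
    """
    shifted = weights - weights.min(axis=0, keepdims=True)
    sums = shifted.sum(axis=0, keepdims=True)
    out = np.where(sums > 0, shifted / np.where(sums == 0, 1, sums), 0.25)
    return out


def extract_kernel_motifs(
    predictor: Predictor, delta: float = 0.05
) -> list[KernelMotif]:
    """Export all convolutional kernels of both branches as motifs.

    A kernel is informative when at least half of its columns have a
    maximal nucleotide fraction above 0.25 + delta; kernels whose weights
    stay too close to the uniform 25% baseline carry no nucleotide
    preference. On an untrained model the flag is meaningless (warned).
    """
    if not predictor.history:
        logger.warning("kernel analysis on an untrained model")
    motifs = []
    for branch, key in (("mirna", "convW_m"), ("site", "convW_s")):
        W = predictor.net.params[key]  # (K, 4, k)
        for k in range(W.shape[0]):
            weights = W[k]
            fr = _to_fractions(weights)
            strong = (fr.max(axis=0) > 0.25 + delta).sum()
            motifs.append(KernelMotif(
                branch=branch, kernel_index=k, weights=weights.copy(),
                column_fractions=fr,
                informative=bool(strong >= fr.shape[1] / 2),
            ))
    return motifs


# -- JASPAR PFM parsing and matching ----------------------------------------

def parse_jaspar(path) -> dict[str, np.ndarray]:
    """Parse a JASPAR-style PFM text file into {motif_id: 4 x L matrix}.

    Accepts '>ID NAME' headers followed by four base rows like
    ``A  [ 4 19 0 ... ]`` (brackets optional); rows are reordered to
    (A, T, C, G) to match kernel matrices.
    """
    motifs: dict[str, np.ndarray] = {}
    current_id = None
    rows: dict[str, list[float]] = {}

    def _flush():
        nonlocal rows, current_id
        if current_id is None:
            return
        if set(rows) != set("ACGT"):
            raise ParseError(f"motif {current_id}: missing base rows")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ParseError(f"motif {current_id}: ragged rows")
        motifs[current_id] = np.array([rows[b] for b in _KERNEL_ROWS])
        rows = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0]
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if not parts or parts[0].upper() not in "ACGT":
                    raise ParseError(f"line {lineno}: unrecognized PFM row")
                try:
                    rows[parts[0].upper()] = [float(x) for x in parts[1:]]
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-numeric count") from exc
    _flush()
    return motifs


def _pfm_to_freq(pfm: np.ndarray) -> np.ndarray:
    sums = pfm.sum(axis=0, keepdims=True)
    return pfm / np.where(sums == 0, 1, sums)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    av, bv = a.ravel(), b.ravel()
    if av.std() == 0 or bv.std() == 0:
        return 0.0  # degenerate (uniform) matrix: similarity 0 by convention
    return float(np.corrcoef(av, bv)[0, 1])


def match_motifs(
    motif: KernelMotif,
    db: dict[str, np.ndarray],
    reverse_complement: bool = False,
    min_len: int = 4,
) -> list[tuple[str, float]]:
    """Rank database motifs by similarity to one kernel motif.

    Similarity is the maximal Pearson correlation between the kernel's
    column fractions and the database motif's frequency matrix over all
    full-overlap offsets (the shorter matrix slid along the longer).
    Sorted descending with a deterministic tie-break on motif id.
    """
    kernel = motif.column_fractions
    results = []
    for motif_id in sorted(db):
        freq = _pfm_to_freq(db[motif_id].astype(float))
        if freq.shape[1] < min_len:
            logger.warning("motif %s shorter than %d columns; skipped", motif_id, min_len)
            continue
        variants = [freq]
        if reverse_complement:
            variants.append(freq[::-1, ::-1])
        best = -np.inf
        for mat in variants:
            short, long_ = (kernel, mat) if kernel.shape[1] <= mat.shape[1] else (mat, kernel)
            w = short.shape[1]
            for off in range(long_.shape[1] - w + 1):
                best = max(best, _pearson(short, long_[:, off:off + w]))
        results.append((motif_id, best))
    results.sort(key=lambda r: (-r[1], r[0]))
    return results


# -- input perturbation ------------------------------------------------------

def _padded(seq: str, target_len: int) -> str:
    s = seq.upper().replace("U", "T")
    return (s[:target_len] + "N" * max(0, target_len - len(s)))


def perturbation_scan(
    predictor: Predictor,
    pairs: pd.DataFrame,
    mask_len: int = 4,
    batch_size: int = 512,
) -> pd.DataFrame:
    """Sliding N-mask sensitivity profile for both branches.

    For every pair and every window start s in each sequence separately,
    delta(s) = p(original) - p(masked), where masking replaces mask_len
    raw characters with N before encoding (uniform 0.25 columns). A
    positive delta means the region supports the interaction call.
    Returns one row per (branch, position) with mean, variance (ddof=0),
    mean |delta| and the number of pairs aggregated.
    """
    cfg: ModelConfig = predictor.config
    if mask_len > min(cfg.mirna_len, cfg.site_len):
        raise ParameterError("mask_len exceeds input length")
    lens = {"mirna": cfg.mirna_len, "site": cfg.site_len}
    cols = {"mirna": "small_rna_seq", "site": "site_seq"}
    base_prob = predictor.predict_proba(pairs, batch_size=batch_size)
    records = []
    for branch, L in lens.items():
        n_windows = L - mask_len + 1
        deltas = np.zeros((len(pairs), n_windows))
        for row_i, rec in enumerate(pairs.itertuples(index=False)):
            small = _padded(getattr(rec, "small_rna_seq"), cfg.mirna_len)
            site = _padded(getattr(rec, "site_seq"), cfg.site_len)
            target = small if branch == "mirna" else site
            xm_list, xs_list, starts = [], [], []
            for s in range(n_windows):
                masked = target[:s] + "N" * mask_len + target[s + mask_len:]
                if masked == target:
                    continue  # identity perturbation: delta exactly 0
                starts.append(s)
                if branch == "mirna":
                    xm_list.append(encode(masked, cfg.mirna_len))
                    xs_list.append(encode(site, cfg.site_len))
                else:
                    xm_list.append(encode(small, cfg.mirna_len))
                    xs_list.append(encode(masked, cfg.site_len))
            if starts:
                prob = predictor.predict_encoded(
                    np.stack(xm_list), np.stack(xs_list), batch_size=batch_size
                )
                deltas[row_i, starts] = base_prob[row_i] - prob
        for s in range(n_windows):
            d = deltas[:, s]
            records.append({
                "branch": branch, "position": s,
                "mean_delta": float(d.mean()),
                "var_delta": float(d.var()),
                "mean_abs_delta": float(np.abs(d).mean()),
                "n": len(d),
            })
    return pd.DataFrame(records)


def per_mirna_profiles(
    predictor: Predictor, pairs: pd.DataFrame, mask_len: int = 4
) -> pd.DataFrame:
    """Per-miRNA mean-delta vectors over miRNA-branch mask positions."""
    if "mirna_id" not in pairs.columns:
        raise ParameterError("pairs need a mirna_id column for per-miRNA profiles")
    out = {}
    for mirna_id, grp in pairs.groupby("mirna_id"):
        prof = perturbation_scan(predictor, grp.reset_index(drop=True), mask_len)
        out[mirna_id] = prof[prof["branch"] == "mirna"]["mean_delta"].to_numpy()
    return pd.DataFrame(out).T


def cluster_sensitivity(
    profiles: pd.DataFrame,
    n_clusters: int | None = None,
    distance_cutoff: float | None = None,
) -> pd.Series:
    """Cluster miRNAs by their positional sensitivity profiles.

    Agglomerative clustering with average linkage on the distance
    1 - Pearson correlation between profiles; a constant (zero-variance)
    profile is assigned distance 1 to all others with a warning. Exactly
    one of ``n_clusters`` / ``distance_cutoff`` selects the flat clusters.
    """
    if len(profiles) < 2:
        raise ParameterError("clustering needs at least 2 profiles")
    if (n_clusters is None) == (distance_cutoff is None):
        raise ParameterError("give exactly one of n_clusters or distance_cutoff")
    X = profiles.to_numpy(dtype=float)
    stds = X.std(axis=1)
    if (stds == 0).any():
        logger.warning("constant sensitivity profile(s); distance set to 1")
    n = len(X)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if stds[i] > 0 and stds[j] > 0:
                dist[i, j] = dist[j, i] = 1.0 - float(np.corrcoef(X[i], X[j])[0, 1])
    Z = linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(Z, t=distance_cutoff, criterion="distance")
    return pd.Series(labels, index=profiles.index, name="cluster")
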