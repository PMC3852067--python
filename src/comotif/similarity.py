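"""Motif-motif similarity by best ungapped column alignment.

The column metric is the Pearson correlation of the two probability 4-vectors
(both have mean exactly 0.25, so the correlation reduces to a dot product of
centered, normalized columns). Significance is an empirical p-value against
column-order-shuffled copies of the target, so a near-copy of a canonical
motif can be flagged as a false-positive cofactor by the p < alpha rule.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .motifs import PWM, reverse_complement

_EPS = 1e-12


@dataclass(frozen=True)
class SimilarityResult:
    query_id: str
    target_id: str
    offset: int  # query start minus target start in the best alignment
    orientation: str  # 'forward' or 'reverse'
    overlap: int
    mean_column_score: float
    p_value: float | None = None

    @property
    def total_score(self) -> float:
        """Sum of column similarities over the aligned overlap (the
        alignment-selection objective)."""
        return self.mean_column_score * self.overlap


def stable_seed(base_seed: int, *parts: str) -> int:
    """Deterministic per-key seed derivation (independent of PYTHONHASHSEED)."""
    h = zlib.crc32("|".join(parts).encode("utf-8"))
    return (int(base_seed) * 1_000_003 + h) % (2**32)


def _centered_unit_columns(probs: np.ndarray) -> np.ndarray:
    """Columns centered at 0.25 and normalized; zero-variance columns -> 0."""
    c = probs - 0.25
    norms = np.sqrt((c * c).sum(axis=0))
    out = np.zeros_like(c)
    ok = norms > _EPS
    out[:, ok] = c[:, ok] / norms[ok]
    return out


def column_similarity(col_a: Sequence[float], col_b: Sequence[float]) -> float:
    """Pearson correlation of two probability columns; 0 for uniform columns."""
    a = np.asarray(col_a, dtype=float).reshape(4, 1)
    b = np.asarray(col_b, dtype=float).reshape(4, 1)
    for col, label in ((a, "a"), (b, "b")):
        if abs(col.sum() - 1.0) > 1e-6:
            raise ValueError(f"column {label} does not sum to 1")
    ua = _centered_unit_columns(a)[:, 0]
    ub = _centered_unit_columns(b)[:, 0]
    return float(np.dot(ua, ub))


def _default_min_overlap(query: PWM, target: PWM) -> int:
    return min(4, query.width, target.width)


def _diagonal_scores(S: np.ndarray, min_overlap: int):
    """Yield (offset, overlap, total score) over all ungapped alignments.

    ``S[i, j]`` is the similarity of query column i and target column j; at
    offset k, query column i aligns target column i + k. Alignments are
    ranked by the TOTAL similarity over the overlap (not the mean): the mean
    is degenerate, preferring minimum-overlap alignments of a few
    near-duplicate columns, which saturates the shuffle null and makes
    near-copies of a motif unflaggable.
    """
    wq, wt = S.shape
    for k in range(-(wq - min_overlap), wt - min_overlap + 1):
        i0 = max(0, -k)
        i1 = min(wq, wt - k)
        overlap = i1 - i0
        if overlap < min_overlap:
            continue
        idx = np.arange(i0, i1)
        yield k, overlap, float(S[idx, idx + k].sum())


def best_ungapped_alignment(
    query: PWM, target: PWM, min_overlap: int | None = None
) -> SimilarityResult:
    """Maximize the total column similarity over offsets and both orientations.

    Ties broken by larger overlap, then smaller |offset|, then forward
    orientation. The offset is the query start minus the target start;
    ``mean_column_score`` reports the per-column mean over the best overlap.
    """
    if min_overlap is None:
        min_overlap = _default_min_overlap(query, target)
    if min_overlap > min(query.width, target.width):
        raise ValueError("min_overlap exceeds the smaller motif width")
    uq = _centered_unit_columns(query.probs)
    best = None
    for orientation, tgt in (("forward", target), ("reverse", reverse_complement(target))):
        ut = _centered_unit_columns(tgt.probs)
        S = uq.T @ ut
        for k, overlap, total in _diagonal_scores(S, min_overlap):
            key = (total, overlap, -abs(k), orientation == "forward")
            if best is None or key > best[0]:
                best = (key, k, orientation, overlap, total)
    assert best is not None
    return SimilarityResult(
        query_id=query.motif_id,
        target_id=target.motif_id,
        offset=best[1],
        orientation=best[2],
        overlap=best[3],
        mean_column_score=best[4] / best[3],
    )


def _best_scores_for_perms(
    uq: np.ndarray, ut: np.ndarray, perms: np.ndarray, min_overlap: int
) -> np.ndarray:
    """Best alignment score for each column permutation of the target.

    ``perms`` has shape (n, wt); for each permutation the target columns are
    reordered and both orientations searched. Vectorized over permutations.
    """
    ut_rev_rows = ut[::-1]  # base complement; column reversal handled by index math
    Sf = uq.T @ ut  # (wq, wt)
    Sr = uq.T @ ut_rev_rows
    wq, wt = Sf.shape
    n = perms.shape[0]
    best = np.full(n, -np.inf)
    for k in range(-(wq - min_overlap), wt - min_overlap + 1):
        i0 = max(0, -k)
        i1 = min(wq, wt - k)
        if i1 - i0 < min_overlap:
            continue
        idx = np.arange(i0, i1)
        # forward: shuffled target column j is original column perms[:, j]
        cols_f = perms[:, idx + k]  # (n, overlap)
        vals_f = Sf[idx[None, :], cols_f].sum(axis=1)
        # reverse: rc of shuffled target reverses the permuted column order
        cols_r = perms[:, wt - 1 - (idx + k)]
        vals_r = Sr[idx[None, :], cols_r].sum(axis=1)
        np.maximum(best, vals_f, out=best)
        np.maximum(best, vals_r, out=best)
    return best


def similarity_pvalue(
    query: PWM,
    target: PWM,
    library: Iterable[PWM] | None = None,
    n_null: int = 999,
    seed: int = 0,
    min_overlap: int | None = None,
) -> SimilarityResult:
    """Empirical alignment p-value against column-order-shuffled targets.

    ``p = (1 + #{null >= observed}) / (n_null + 1)`` on the total alignment
    score, where each null score is the best ungapped alignment of the query
    against a copy of the target
    whose column order was independently permuted. ``library`` is accepted for
    interface compatibility but the null is built from target shuffles only.
    """
    del library
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    if min_overlap is None:
        min_overlap = _default_min_overlap(query, target)
    observed = best_ungapped_alignment(query, target, min_overlap=min_overlap)
    rng = np.random.default_rng(seed)
    wt = target.width
    perms = np.argsort(rng.random((n_null, wt)), axis=1)
    uq = _centered_unit_columns(query.probs)
    ut = _centered_unit_columns(target.probs)
    null = _best_scores_for_perms(uq, ut, perms, min_overlap)
    exceed = int(np.sum(null >= observed.total_score - _EPS))
    p = (1 + exceed) / (n_null + 1)
    return SimilarityResult(
        query_id=observed.query_id,
        target_id=observed.target_id,
        offset=observed.offset,
        orientation=observed.orientation,
        overlap=observed.overlap,
        mean_column_score=observed.mean_column_score,
        p_value=p,
    )


def is_false_positive(
    candidate: PWM,
    target_motifs: Sequence[PWM],
    alpha: float = 0.05,
    n_null: int = 999,
    seed: int = 0,
) -> bool:
    """True iff the candidate is significantly similar (p < alpha) to ANY
    target motif — i.e. it is likely the target's own motif, not a cofactor."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    targets = list(target_motifs)
    if not targets:
        raise ValueError("target_motifs must be non-empty")
    for target in targets:
        pair_seed = stable_seed(seed, candidate.motif_id, target.motif_id)
        result = similarity_pvalue(
            candidate, target, n_null=n_null, seed=pair_seed
        )
        if result.p_value < alpha:
            return True
    return False


def write_similarity_tsv(results, path, alpha: float = 0.05) -> None:
    """Similarity report: query, target, alignment, score, p, flagged."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\ttarget_id\toffset\torientation\tmean_column_score"
            "\tp_value\tflagged\n"
        )
        for r in results:
            flagged = r.p_value is not None and r.p_value < alpha
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(
                f"{r.query_id}\t{r.target_id}\t{r.offset}\t{r.orientation}"
                f"\t{r.mean_column_score:.6f}\t{p}\t{int(flagged)}\n"
            )
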