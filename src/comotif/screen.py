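"""Proximal/distal co-occurrence screening of cofactor motifs.

Pipeline over curated (COLD) peaks: partition each experiment's peaks by
canonical-motif presence, tabulate per-(experiment, motif, class) abundances,
flag within-experiment enrichment at the 95th percentile, drop ubiquitous
motifs by flag fraction across experiments (< 20% proximal, < 10% distal),
apply the cell-type- and TF-specificity screens, and finally discard
candidate cofactors too similar to the target's canonical motif(s).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import Experiment, Peak
from .motifs import PWM, Background, encode_sequence, pwm_to_logodds
from .scan import batch_window_scores, score_distribution
from .similarity import is_false_positive

logger = logging.getLogger(__name__)

PROXIMAL = "proximal"
DISTAL = "distal"


@dataclass(frozen=True)
class PeakPartition:
    exp_id: str
    positive_peak_ids: frozenset[str]
    negative_peak_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_peak_ids & self.negative_peak_ids:
            raise ValueError("positive and negative peak sets must be disjoint")


@dataclass(frozen=True)
class AbundanceRecord:
    exp_id: str
    motif_id: str
    cls: str  # proximal | distal
    n_peaks: int
    n_present: int

    @property
    def abundance(self) -> float:
        return self.n_present / self.n_peaks


@dataclass(frozen=True)
class EnrichmentFlag:
    exp_id: str
    motif_id: str
    cls: str
    q95: float
    flagged: bool


@dataclass(frozen=True)
class ScreenThresholds:
    """All screening knobs in one place (defaults are the published values)."""

    hot_fraction: float = 0.5
    pct: float = 95.0  # within-experiment enrichment percentile
    prox_ubiq: float = 0.20  # flag-fraction ceiling, proximal
    dist_ubiq: float = 0.10  # flag-fraction ceiling, distal
    ct_min_abund: float = 0.15
    ct_min_exps: int = 10
    ct_min_tfs: int = 4  # "> 3" TFs, strict
    tf_min_abund: float = 0.20
    tf_min_sisters: int = 3
    sim_alpha: float = 0.05
    presence_p: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("hot_fraction", "prox_ubiq", "dist_ubiq", "ct_min_abund",
                     "tf_min_abund", "sim_alpha", "presence_p"):
            v = getattr(self, name)
            if not 0 < v < 1 and not (name == "presence_p" and v == 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("ct_min_exps", "ct_min_tfs", "tf_min_sisters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.pct < 100:
            raise ValueError("pct must be in (0, 100)")


@dataclass(frozen=True)
class SpecificCall:
    motif_id: str
    scope: str  # cell_type | tf
    key: str
    cls: str  # proximal | distal
    supporting_exp_ids: frozenset[str]
    min_abundance: float


class ScanContext:
    """Shared scanning state: background policy, pseudocount, scale, presence
    threshold, plus per-(motif, background) caches of score distributions."""

    def __init__(
        self,
        pseudocount: float = 0.1,
        scale: float = 1000.0,
        presence_p: float = 1e-4,
        bg_floor: float = 0.01,
        background: Background | None = None,
    ) -> None:
        self.pseudocount = pseudocount
        self.scale = scale
        self.presence_p = presence_p
        self.bg_floor = bg_floor
        self.fixed_background = background
        self._cache: dict[tuple, tuple] = {}

    def background_for(self, sequences: Sequence[str]) -> Background:
        if self.fixed_background is not None:
            return self.fixed_background
        return Background.from_sequences(
            sequences, floor=self.bg_floor, symmetrize=True
        )

    def _lom_dist(self, pwm: PWM, bg: Background):
        key = (pwm.motif_id, tuple(np.round(bg.freqs, 6)))
        if key not in self._cache:
            lom = pwm_to_logodds(pwm, bg, self.pseudocount, self.scale)
            self._cache[key] = (lom, score_distribution(lom, bg))
        return self._cache[key]

    def presence_vector(
        self, peak_codes: np.ndarray, pwm: PWM, bg: Background
    ) -> np.ndarray:
        """Boolean presence call for each row of an encoded sequence matrix.

        Equivalent to per-peak ``motif_present`` (best hit on either strand
        with p <= presence_p), thresholded on the integer score for speed:
        present iff some valid window score reaches the smallest integer
        score whose exact tail probability is <= presence_p.
        """
        lom, dist = self._lom_dist(pwm, bg)
        s_min = dist.score_threshold(self.presence_p)
        present = np.zeros(peak_codes.shape[0], dtype=bool)
        for mat in (lom, lom.reverse_complement()):
            scores = batch_window_scores(peak_codes, mat)
            if scores.size:
                present |= (scores >= s_min).any(axis=1)
        return present


def encode_peak_matrix(peaks: Sequence[Peak]) -> np.ndarray:
    """Stack peak sequences into a code matrix, right-padded with 4 (invalid)."""
    for p in peaks:
        if p.sequence is None:
            raise ValueError(f"peak {p.peak_id!r} has no sequence attached")
    max_len = max(len(p.sequence) for p in peaks)
    X = np.full((len(peaks), max_len), 4, dtype=np.uint8)
    for i, p in enumerate(peaks):
        X[i, : len(p.sequence)] = encode_sequence(p.sequence)
    return X


def experiment_presence(
    peaks: Sequence[Peak],
    pwms: Sequence[PWM],
    ctx: ScanContext,
) -> pd.DataFrame:
    """Presence matrix (peaks x motifs) for one experiment's peaks."""
    if not peaks:
        return pd.DataFrame(index=pd.Index([], dtype=object),
                            columns=[p.motif_id for p in pwms], dtype=bool)
    bg = ctx.background_for([p.sequence for p in peaks])
    X = encode_peak_matrix(peaks)
    data = {pwm.motif_id: ctx.presence_vector(X, pwm, bg) for pwm in pwms}
    return pd.DataFrame(data, index=[p.peak_id for p in peaks])


def partition_peaks(
    exp: Experiment,
    peaks: Sequence[Peak],
    canon: Mapping[str, Sequence[str]],
    pwms_by_id: Mapping[str, PWM],
    ctx: ScanContext,
    presence: pd.DataFrame | None = None,
) -> PeakPartition:
    """Split an experiment's COLD peaks into canonical-positive and -negative.

    A peak is positive iff ANY canonical motif of the experiment's TF is
    present (union over multiple canonical motifs). ``presence`` may carry a
    precomputed presence matrix including the canonical motif columns.
    """
    motif_ids = canon.get(exp.tf_name)
    if not motif_ids:
        raise ValueError(f"TF {exp.tf_name!r} has no canonical motifs")
    if not peaks:
        return PeakPartition(exp.exp_id, frozenset(), frozenset())
    if presence is None:
        canon_pwms = [pwms_by_id[m] for m in motif_ids]
        presence = experiment_presence(peaks, canon_pwms, ctx)
    positive = presence[list(motif_ids)].any(axis=1)
    pos_ids = frozenset(presence.index[positive])
    neg_ids = frozenset(presence.index[~positive])
    return PeakPartition(exp.exp_id, pos_ids, neg_ids)


def abundance_table(
    partitions: Mapping[str, PeakPartition],
    presence_by_exp: Mapping[str, pd.DataFrame],
    canon_by_exp: Mapping[str, Sequence[str]],
) -> list[AbundanceRecord]:
    """Per (experiment, library motif, class) presence fractions.

    The experiment's own canonical motifs are excluded; classes with zero
    peaks are omitted.
    """
    records: list[AbundanceRecord] = []
    for exp_id in sorted(partitions):
        part = partitions[exp_id]
        presence = presence_by_exp[exp_id]
        own = set(canon_by_exp.get(exp_id, ()))
        motif_ids = [m for m in presence.columns if m not in own]
        for cls, ids in ((PROXIMAL, part.positive_peak_ids),
                         (DISTAL, part.negative_peak_ids)):
            if not ids:
                continue
            sub = presence.loc[sorted(ids), motif_ids]
            n_peaks = len(ids)
            counts = sub.sum(axis=0)
            for motif_id in motif_ids:
                records.append(
                    AbundanceRecord(
                        exp_id=exp_id,
                        motif_id=motif_id,
                        cls=cls,
                        n_peaks=n_peaks,
                        n_present=int(counts[motif_id]),
                    )
                )
    return records


def percentile_linear(values: Sequence[float], pct: float) -> float:
    """pct-th percentile with linear interpolation between order statistics:
    position ``pct/100 * (n - 1)`` in the ascending sort."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot take a percentile of an empty group")
    pos = pct / 100.0 * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def enrichment_flags(
    records: Sequence[AbundanceRecord],
    pct: float = 95.0,
) -> list[EnrichmentFlag]:
    """Within-experiment enrichment: flagged iff abundance strictly exceeds
    the pct-th percentile of all motif abundances in that (experiment, class)
    group."""
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    groups: dict[tuple[str, str], list[AbundanceRecord]] = {}
    for r in records:
        groups.setdefault((r.exp_id, r.cls), []).append(r)
    flags: list[EnrichmentFlag] = []
    for (exp_id, cls), group in sorted(groups.items()):
        if len(group) < 20:
            logger.warning(
                "percentile over only %d motifs for (%s, %s)",
                len(group), exp_id, cls,
            )
        q95 = percentile_linear([r.abundance for r in group], pct)
        for r in group:
            flags.append(
                EnrichmentFlag(
                    exp_id=exp_id,
                    motif_id=r.motif_id,
                    cls=cls,
                    q95=q95,
                    flagged=r.abundance > q95,
                )
            )
    return flags


def ubiquity_filter(
    flags: Sequence[EnrichmentFlag],
    n_exps: int,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> set[tuple[str, str]]:
    """Retain (motif, class) pairs flagged somewhere but not ubiquitously:
    0 < flag fraction < prox_ubiq (proximal) or < dist_ubiq (distal)."""
    if n_exps < 1:
        raise ValueError("n_exps must be >= 1")
    counts: dict[tuple[str, str], int] = {}
    for f in flags:
        if f.flagged:
            counts[(f.motif_id, f.cls)] = counts.get((f.motif_id, f.cls), 0) + 1
    retained: set[tuple[str, str]] = set()
    for (motif_id, cls), n in counts.items():
        frac = n / n_exps
        ceiling = thresholds.prox_ubiq if cls == PROXIMAL else thresholds.dist_ubiq
        if 0 < frac < ceiling:
            retained.add((motif_id, cls))
    return retained


def _flagged_abundances(
    flags: Sequence[EnrichmentFlag],
    records: Sequence[AbundanceRecord],
) -> dict[tuple[str, str, str], float]:
    """(exp, motif, cls) -> abundance, restricted to flagged entries."""
    flagged = {(f.exp_id, f.motif_id, f.cls) for f in flags if f.flagged}
    return {
        (r.exp_id, r.motif_id, r.cls): r.abundance
        for r in records
        if (r.exp_id, r.motif_id, r.cls) in flagged
    }


def cell_type_specific_screen(
    flags: Sequence[EnrichmentFlag],
    records: Sequence[AbundanceRecord],
    experiments: Sequence[Experiment],
    thresholds: ScreenThresholds = ScreenThresholds(),
    retained: set[tuple[str, str]] | None = None,
) -> list[SpecificCall]:
    """Motifs co-occurring across many experiments of ONE cell type.

    A (motif, cell type, class) is called iff the motif is flagged with
    abundance > ct_min_abund in >= ct_min_exps experiments of that cell type
    spanning >= ct_min_tfs distinct TFs.
    """
    if retained is None:
        retained = {(r.motif_id, r.cls) for r in records}
    exp_by_id = {e.exp_id: e for e in experiments}
    abund = _flagged_abundances(flags, records)
    support: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    for (exp_id, motif_id, cls), a in abund.items():
        if (motif_id, cls) not in retained or exp_id not in exp_by_id:
            continue
        if a > thresholds.ct_min_abund:
            key = (motif_id, exp_by_id[exp_id].cell_type, cls)
            support.setdefault(key, []).append((exp_id, a))
    calls: list[SpecificCall] = []
    for (motif_id, cell_type, cls), exps in sorted(support.items()):
        tfs = {exp_by_id[e].tf_name for e, _ in exps}
        if len(exps) >= thresholds.ct_min_exps and len(tfs) >= thresholds.ct_min_tfs:
            calls.append(
                SpecificCall(
                    motif_id=motif_id,
                    scope="cell_type",
                    key=cell_type,
                    cls=cls,
                    supporting_exp_ids=frozenset(e for e, _ in exps),
                    min_abundance=min(a for _, a in exps),
                )
            )
    return calls


def tf_specific_screen(
    flags: Sequence[EnrichmentFlag],
    records: Sequence[AbundanceRecord],
    experiments: Sequence[Experiment],
    thresholds: ScreenThresholds = ScreenThresholds(),
    retained: set[tuple[str, str]] | None = None,
) -> list[SpecificCall]:
    """Motifs co-occurring with ONE TF across sister experiments.

    A (motif, TF, class) is called iff the motif is flagged in sister
    experiments of that TF spanning >= tf_min_sisters distinct cell types AND
    its abundance exceeds tf_min_abund in ALL of those flagged experiments.
    """
    if retained is None:
        retained = {(r.motif_id, r.cls) for r in records}
    exp_by_id = {e.exp_id: e for e in experiments}
    abund = _flagged_abundances(flags, records)
    support: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    for (exp_id, motif_id, cls), a in abund.items():
        if (motif_id, cls) not in retained or exp_id not in exp_by_id:
            continue
        key = (motif_id, exp_by_id[exp_id].tf_name, cls)
        support.setdefault(key, []).append((exp_id, a))
    calls: list[SpecificCall] = []
    for (motif_id, tf_name, cls), exps in sorted(support.items()):
        cell_types = {exp_by_id[e].cell_type for e, _ in exps}
        if len(cell_types) < thresholds.tf_min_sisters:
            continue
        if any(a <= thresholds.tf_min_abund for _, a in exps):
            continue
        calls.append(
            SpecificCall(
                motif_id=motif_id,
                scope="tf",
                key=tf_name,
                cls=cls,
                supporting_exp_ids=frozenset(e for e, _ in exps),
                min_abundance=min(a for _, a in exps),
            )
        )
    return calls


def remove_similar(
    calls: Sequence[SpecificCall],
    canon: Mapping[str, Sequence[str]],
    pwms_by_id: Mapping[str, PWM],
    experiments: Sequence[Experiment],
    thresholds: ScreenThresholds = ScreenThresholds(),
    seed: int = 0,
    n_null: int = 999,
) -> list[SpecificCall]:
    """Drop calls whose motif is significantly similar to the target TF's
    canonical motif(s): for TF-scope calls the call TF's motifs, for
    cell-type-scope calls the union over TFs of the supporting experiments."""
    exp_by_id = {e.exp_id: e for e in experiments}
    kept: list[SpecificCall] = []
    for call in calls:
        if call.scope == "tf":
            tf_names = [call.key]
        else:
            tf_names = sorted(
                {exp_by_id[e].tf_name for e in call.supporting_exp_ids
                 if e in exp_by_id}
            )
        target_ids = sorted({m for tf in tf_names for m in canon.get(tf, ())})
        targets = [pwms_by_id[m] for m in target_ids if m in pwms_by_id]
        candidate = pwms_by_id[call.motif_id]
        if targets and is_false_positive(
            candidate, targets, alpha=thresholds.sim_alpha,
            n_null=n_null, seed=seed,
        ):
            continue
        kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def records_frame(
    records: Sequence[AbundanceRecord],
    flags: Sequence[EnrichmentFlag],
) -> pd.DataFrame:
    flag_by_key = {(f.exp_id, f.motif_id, f.cls): f for f in flags}
    rows = []
    for r in records:
        f = flag_by_key.get((r.exp_id, r.motif_id, r.cls))
        rows.append(
            {
                "exp_id": r.exp_id,
                "motif_id": r.motif_id,
                "cls": r.cls,
                "n_peaks": r.n_peaks,
                "n_present": r.n_present,
                "abundance": r.abundance,
                "q95": f.q95 if f else float("nan"),
                "flagged": bool(f.flagged) if f else False,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["exp_id", "motif_id", "cls", "n_peaks", "n_present",
                 "abundance", "q95", "flagged"],
    )
    return df.sort_values(["exp_id", "motif_id", "cls"]).reset_index(drop=True)


def calls_frame(calls: Sequence[SpecificCall]) -> pd.DataFrame:
    rows = [
        {
            "motif_id": c.motif_id,
            "scope": c.scope,
            "key": c.key,
            "cls": c.cls,
            "n_supporting": len(c.supporting_exp_ids),
            "supporting_exp_ids": ",".join(sorted(c.supporting_exp_ids)),
            "min_abundance": c.min_abundance,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=["motif_id", "scope", "key", "cls", "n_supporting",
                 "supporting_exp_ids", "min_abundance"],
    )
    return df.sort_values(["scope", "key", "cls", "motif_id"]).reset_index(drop=True)


def summary_frame(calls: Sequence[SpecificCall]) -> pd.DataFrame:
    """One row per screen key: comma-joined motif ids and the total count."""
    groups: dict[tuple[str, str], list[str]] = {}
    for c in calls:
        groups.setdefault((c.scope, c.key), []).append(c.motif_id)
    rows = [
        {
            "scope": scope,
            "key": key,
            "motif_ids": ", ".join(sorted(set(ids))),
            "total": len(set(ids)),
        }
        for (scope, key), ids in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=["scope", "key", "motif_ids", "total"])


def write_reports(
    calls: Sequence[SpecificCall],
    records: Sequence[AbundanceRecord],
    flags: Sequence[EnrichmentFlag],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit the per-class abundance tables, per-call tables, and summaries.

    Re-running on identical inputs produces byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = records_frame(records, flags)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        try:
            frame.to_csv(path, index=False, float_format="%.6g")
        except OSError as exc:
            raise OSError(f"failed to write report {path}: {exc}") from exc
        paths[name] = path

    emit("proximal.csv", df[df["cls"] == PROXIMAL].reset_index(drop=True))
    emit("distal.csv", df[df["cls"] == DISTAL].reset_index(drop=True))
    calls_df = calls_frame(calls)
    emit("cell_type_specific.csv",
         calls_df[calls_df["scope"] == "cell_type"].reset_index(drop=True))
    emit("tf_specific.csv",
         calls_df[calls_df["scope"] == "tf"].reset_index(drop=True))
    emit("summary.csv", summary_frame(calls))
    return paths
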