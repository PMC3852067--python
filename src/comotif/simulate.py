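"""Seeded synthetic compendium generator with planted ground truth.

Produces everything the curation and screening stages consume — genome FASTA,
per-experiment BED files, metadata and canonical-map TSVs, a JASPAR-dialect
motif library — plus a truth table recording, per planted cofactor scenario,
whether the specificity screens are expected to call it.

Scenario kinds:
  cell_type_specific  planted in every experiment of one cell type
  tf_specific         planted in every sister experiment of one TF
  ubiquitous          planted across (at least 30% of) ALL experiments
  decoy_similar_to_canonical  one-column perturbation of a canonical motif
  hot_only            planted only inside planted HOT regions

All outputs are pure functions of the design (seed included).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import Experiment
from .motifs import BASES, PWM, write_jaspar
from .screen import ScreenThresholds
from .similarity import similarity_pvalue, stable_seed

SCENARIO_KINDS = (
    "cell_type_specific",
    "tf_specific",
    "ubiquitous",
    "decoy_similar_to_canonical",
    "hot_only",
)


class MotifGenerationError(RuntimeError):
    """Raised when a dissimilar motif cannot be generated within the retry
    budget."""


@dataclass(frozen=True)
class CofactorScenario:
    motif_id: str
    kind: str
    key: str  # cell type (cell_type_specific) or TF (tf_specific, decoy)
    plant_rate: float
    cls: str  # proximal | distal | both (ubiquitous distractors)

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0 <= self.plant_rate <= 1:
            raise ValueError("plant_rate must be in [0, 1]")
        if self.cls not in ("proximal", "distal", "both"):
            raise ValueError(f"invalid cls {self.cls!r}")


@dataclass
class CompendiumDesign:
    tfs_per_cell_type: dict[str, list[str]]
    peaks_per_exp: int = 200
    peak_len: int = 180
    genome_len: int = 3_500_000
    gc: float = 0.5
    canonical_plant_rate: float = 0.5
    scenarios: list[CofactorScenario] = field(default_factory=list)
    n_background_motifs: int = 10
    hot_region_count: int = 2
    hot_exp_fraction: float = 0.6  # fraction of screenable exps placing a peak
    seed: int = 42
    multi_canonical_tfs: tuple[str, ...] = ()
    no_pwm_tfs: tuple[str, ...] = ()  # TFs deliberately absent from the map
    widths: tuple[int, int] = (8, 12)
    information_content_range: tuple[float, float] = (0.9, 0.97)

    @property
    def n_cell_types(self) -> int:
        return len(self.tfs_per_cell_type)

    def experiments(self) -> list[Experiment]:
        exps = []
        for ct in sorted(self.tfs_per_cell_type):
            for tf in self.tfs_per_cell_type[ct]:
                exps.append(Experiment(exp_id=f"{ct}.{tf}", tf_name=tf,
                                       cell_type=ct))
        return exps


def default_design(seed: int = 42) -> CompendiumDesign:
    """The default planted-truth compendium.

    73 screenable experiments over 7 cell types: CT1 carries 12 experiments
    across 12 TFs (exercising the >=10-experiment / >=4-TF cell-type screen),
    TF T01 is assayed in 5 cell types (exercising the >=3-sister TF screen),
    and every other TF appears in exactly 2 cell types so nothing else is an
    orphan. Five extra experiments are curation fodder: two CTCF targets, one
    orphan TF, and a TF without a canonical motif. Four extra ubiquitous
    motifs at graded plant rates occupy each experiment's 95th-percentile
    band, making enrichment flags deterministic for planted cofactors.
    """
    cts = [f"CT{i}" for i in range(1, 8)]
    tfs_per_ct: dict[str, list[str]] = {ct: [] for ct in cts}
    ct1_tfs = [f"T{i:02d}" for i in range(1, 13)]
    tfs_per_ct["CT1"] = list(ct1_tfs)
    for ct in ("CT2", "CT3", "CT4", "CT5"):
        tfs_per_ct[ct].append("T01")
    others = cts[1:]  # CT2..CT7
    for i, tf in enumerate(ct1_tfs[1:]):  # T02..T12: one sister each
        tfs_per_ct[others[i % len(others)]].append(tf)
    extra_tfs = [f"T{i:02d}" for i in range(13, 36)]  # 23 TFs x 2 cell types
    for i, tf in enumerate(extra_tfs):
        a = others[i % len(others)]
        b = others[(i + 1) % len(others)]
        tfs_per_ct[a].append(tf)
        tfs_per_ct[b].append(tf)
    # curation fodder (filtered out before screening)
    tfs_per_ct["CT2"].append("CTCF")
    tfs_per_ct["CT3"].append("CTCF")
    tfs_per_ct["CT2"].append("TORPH")  # orphan: single cell type
    tfs_per_ct["CT2"].append("TNOPWM")  # no canonical-motif entry
    tfs_per_ct["CT3"].append("TNOPWM")
    scenarios = [
        CofactorScenario("CF_CT1", "cell_type_specific", "CT1", 0.55, "proximal"),
        CofactorScenario("CF_T01", "tf_specific", "T01", 0.50, "distal"),
        CofactorScenario("UB1", "ubiquitous", "", 0.30, "both"),
        CofactorScenario("UB2", "ubiquitous", "", 0.27, "both"),
        CofactorScenario("UB3", "ubiquitous", "", 0.24, "both"),
        CofactorScenario("UB4", "ubiquitous", "", 0.21, "both"),
        CofactorScenario("UB5", "ubiquitous", "", 0.18, "both"),
        CofactorScenario("DECOY_T01", "decoy_similar_to_canonical", "T01",
                         0.50, "proximal"),
        CofactorScenario("HOTM", "hot_only", "", 1.0, "proximal"),
    ]
    return CompendiumDesign(
        tfs_per_cell_type=tfs_per_ct,
        scenarios=scenarios,
        seed=seed,
        multi_canonical_tfs=("T02",),
        no_pwm_tfs=("CTCF", "TNOPWM"),
    )


# ---------------------------------------------------------------------------
# genome & motifs
# ---------------------------------------------------------------------------

def generate_genome(genome_len: int, gc: float, seed: int) -> dict[str, str]:
    """Single-chromosome i.i.d. genome with P(G) = P(C) = gc / 2."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in the open interval (0, 1)")
    if genome_len < 1:
        raise ValueError("genome_len must be positive")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=genome_len, p=probs)
    seq = "".join(BASES[c] for c in codes)
    return {"chr1": seq}


def _random_informative_pwm(
    motif_id: str, width: int, ic_range: tuple[float, float],
    rng: np.random.Generator,
) -> PWM:
    probs = np.empty((4, width))
    for i in range(width):
        dom = int(rng.integers(4))
        p_dom = float(rng.uniform(*ic_range))
        rest = rng.dirichlet([1.0, 1.0, 1.0]) * (1 - p_dom)
        col = np.empty(4)
        col[dom] = p_dom
        col[[b for b in range(4) if b != dom]] = rest
        probs[:, i] = col / col.sum()
    return PWM(motif_id=motif_id, name=motif_id, source="synthetic", probs=probs)


def _perturb_one_column(pwm: PWM, motif_id: str, rng: np.random.Generator) -> PWM:
    """Copy with exactly one column replaced (different dominant base)."""
    probs = pwm.probs.copy()
    j = int(rng.integers(pwm.width))
    old_dom = int(np.argmax(probs[:, j]))
    new_dom = int(rng.choice([b for b in range(4) if b != old_dom]))
    p_dom = 0.94
    rest = rng.dirichlet([1.0, 1.0, 1.0]) * (1 - p_dom)
    col = np.empty(4)
    col[new_dom] = p_dom
    col[[b for b in range(4) if b != new_dom]] = rest
    probs[:, j] = col / col.sum()
    return PWM(motif_id=motif_id, name=motif_id, source="synthetic", probs=probs)


def generate_motif_library(
    n_background_motifs: int,
    widths: tuple[int, int] = (8, 12),
    information_content_range: tuple[float, float] = (0.9, 0.97),
    seed: int = 0,
    tf_names: Sequence[str] = (),
    multi_canonical_tfs: Sequence[str] = (),
    no_pwm_tfs: Sequence[str] = (),
    scenarios: Sequence[CofactorScenario] = (),
    dissimilarity_p: float = 0.1,
    sim_n_null: int = 999,
    max_retries: int = 2000,
) -> tuple[list[PWM], dict[str, list[str]]]:
    """Canonical, scenario, decoy, and background motifs plus the canonical map.

    Specificity-scenario motifs (the ones expected to survive the similarity
    false-positive filter) are checked at generation time for dissimilarity
    against the full canonical set — exactly the comparisons the filter later
    performs — and resampled until the column-shuffle p-value is >=
    ``dissimilarity_p`` for every canonical motif. The per-pair seeds match
    the screening filter's derivation (``stable_seed(seed, query, target)``),
    so with the same base seed and ``sim_n_null`` the filter recomputes the
    identical p-values and can never flag a checked motif. The check is NOT
    applied between arbitrary pairs: the empirical p-value is uniform for
    unrelated motifs, so a library-wide pairwise constraint would be violated
    by ~``dissimilarity_p`` of all pairs no matter how the motifs are drawn;
    motifs that never face the filter (canonical, ubiquitous, hot-only,
    background) are drawn unchecked. Decoys are exempt by design: each is a
    one-column perturbation of its key TF's first canonical motif.
    """
    if not (6 <= widths[0] <= widths[1] <= 15):
        raise ValueError("widths must lie within [6, 15]")
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    canonicals: list[PWM] = []
    canonical_map: dict[str, list[str]] = {}

    def draw(motif_id: str) -> PWM:
        width = int(rng.integers(widths[0], widths[1] + 1))
        return _random_informative_pwm(
            motif_id, width, information_content_range, rng
        )

    def add_unchecked(motif_id: str) -> PWM:
        cand = draw(motif_id)
        pwms.append(cand)
        return cand

    def add_dissimilar(motif_id: str) -> PWM:
        for _ in range(max_retries):
            cand = draw(motif_id)
            # cheap prefilter before the seed-matched (binding) estimate
            if any(
                similarity_pvalue(cand, other, n_null=119, seed=1).p_value < 0.1
                for other in canonicals
            ):
                continue
            ok = all(
                similarity_pvalue(
                    cand, other, n_null=sim_n_null,
                    seed=stable_seed(seed, motif_id, other.motif_id),
                ).p_value >= dissimilarity_p
                for other in canonicals
            )
            if ok:
                pwms.append(cand)
                return cand
        raise MotifGenerationError(
            f"could not generate a dissimilar motif for {motif_id!r} "
            f"within {max_retries} retries"
        )

    for tf in tf_names:
        if tf in no_pwm_tfs:
            continue
        ids = [f"CANON_{tf}"]
        if tf in multi_canonical_tfs:
            ids = [f"CANON_{tf}a", f"CANON_{tf}b"]
        for motif_id in ids:
            canonicals.append(add_unchecked(motif_id))
        canonical_map[tf] = ids

    decoys = []
    checked_kinds = {"cell_type_specific", "tf_specific"}
    for sc in scenarios:
        if sc.kind == "decoy_similar_to_canonical":
            decoys.append(sc)
        elif sc.kind in checked_kinds:
            add_dissimilar(sc.motif_id)
        else:
            add_unchecked(sc.motif_id)
    for sc in decoys:
        target_ids = canonical_map.get(sc.key)
        if not target_ids:
            raise ValueError(f"decoy {sc.motif_id!r}: key TF {sc.key!r} has no "
                             "canonical motif")
        target = next(p for p in pwms if p.motif_id == target_ids[0])
        pwms.append(_perturb_one_column(target, sc.motif_id, rng))

    for i in range(n_background_motifs):
        add_unchecked(f"BG{i + 1:02d}")
    return pwms, canonical_map


def sample_word(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one site sequence from the PWM's column distributions."""
    return "".join(
        BASES[int(rng.choice(4, p=pwm.probs[:, i]))] for i in range(pwm.width)
    )


# ---------------------------------------------------------------------------
# compendium assembly
# ---------------------------------------------------------------------------

#: layout constants: canonical sites go in the left planting zone, cofactor
#: sites are stacked from _COFACTOR_ZONE with a 2-nt gap so multiple plants
#: in one peak never overwrite each other.
_CANON_ZONE = (5, 60)
_COFACTOR_ZONE = 70
_SLOT_MARGIN = 20
_SLOT_GAP = 40


def _exp_sort_key(exp: Experiment) -> tuple[str, str]:
    return (exp.cell_type, exp.tf_name)


def generate_compendium(
    design: CompendiumDesign,
    out_dir: str | Path,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> dict[str, object]:
    """Write a complete synthetic compendium and return its file paths.

    Peaks are placed on a non-overlapping slot grid, except at the planted
    HOT slots where ``hot_exp_fraction`` of the screenable experiments share
    an identical interval. Canonical sites (words sampled from the PWM, not
    the fixed consensus) go into ``canonical_plant_rate`` of each experiment's
    peaks; scenario sites are planted per kind with proximal plants confined
    to canonical-positive peaks and distal plants to canonical-free peaks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(design.seed)

    exps = sorted(design.experiments(), key=_exp_sort_key)
    tf_names = sorted({e.tf_name for e in exps})
    pwms, canonical_map = generate_motif_library(
        design.n_background_motifs,
        widths=design.widths,
        information_content_range=design.information_content_range,
        seed=design.seed,
        tf_names=tf_names,
        multi_canonical_tfs=design.multi_canonical_tfs,
        no_pwm_tfs=design.no_pwm_tfs,
        scenarios=design.scenarios,
    )
    pwms_by_id = {p.motif_id: p for p in pwms}

    # experiments that survive curation (used for HOT planting arithmetic)
    excluded = {"CTCF"}
    ct_per_tf: dict[str, set[str]] = {}
    for e in exps:
        if e.tf_name not in excluded:
            ct_per_tf.setdefault(e.tf_name, set()).add(e.cell_type)
    screenable = [
        e for e in exps
        if e.tf_name not in excluded
        and len(ct_per_tf.get(e.tf_name, ())) > 1
        and e.tf_name in canonical_map
    ]
    n_screenable = len(screenable)

    slot_size = design.peak_len + _SLOT_GAP
    n_slots = design.genome_len // slot_size
    n_needed = len(exps) * design.peaks_per_exp + design.hot_region_count
    if n_slots < n_needed:
        raise ValueError(
            f"genome too small: {n_needed} peak slots needed, {n_slots} available"
        )

    genome = generate_genome(design.genome_len, design.gc,
                             int(rng.integers(2**31)))
    garr = np.frombuffer(genome["chr1"].encode("ascii"), dtype=np.uint8).copy()

    def plant(start: int, word: str) -> None:
        garr[start : start + len(word)] = np.frombuffer(
            word.encode("ascii"), dtype=np.uint8
        )

    slot_order = rng.permutation(n_slots)
    hot_slots = slot_order[: design.hot_region_count]
    cursor = design.hot_region_count

    n_ubiq_min = math.ceil(0.30 * n_screenable)
    scen_exps: dict[str, list[str]] = {}
    for sc in design.scenarios:
        if sc.kind == "cell_type_specific":
            ids = [e.exp_id for e in screenable if e.cell_type == sc.key]
        elif sc.kind in ("tf_specific", "decoy_similar_to_canonical"):
            ids = [e.exp_id for e in screenable if e.tf_name == sc.key]
        elif sc.kind == "ubiquitous":
            ids = [e.exp_id for e in screenable]
            if len(ids) < n_ubiq_min:
                raise ValueError("too few experiments for a ubiquitous scenario")
        else:  # hot_only: planted in HOT slots, not per-experiment
            ids = []
        scen_exps[sc.motif_id] = ids

    bed_rows: dict[str, list[tuple[int, int]]] = {e.exp_id: [] for e in exps}
    for exp in exps:
        slots = slot_order[cursor : cursor + design.peaks_per_exp]
        cursor += design.peaks_per_exp
        starts = np.sort(slots * slot_size + _SLOT_MARGIN)
        n = design.peaks_per_exp
        canon_ids = canonical_map.get(exp.tf_name, [])
        n_canon = round(design.canonical_plant_rate * n) if canon_ids else 0
        canon_idx = rng.choice(n, size=n_canon, replace=False)
        is_canon = np.zeros(n, dtype=bool)
        is_canon[canon_idx] = True
        cofactor_cursor = np.full(n, _COFACTOR_ZONE, dtype=int)

        for rank, i in enumerate(np.sort(canon_idx)):
            pwm = pwms_by_id[canon_ids[rank % len(canon_ids)]]
            offset = int(rng.integers(_CANON_ZONE[0],
                                      _CANON_ZONE[1] - pwm.width + 1))
            plant(int(starts[i]) + offset, sample_word(pwm, rng))

        for sc in design.scenarios:
            if exp.exp_id not in scen_exps[sc.motif_id]:
                continue
            pwm = pwms_by_id[sc.motif_id]
            classes = ("proximal", "distal") if sc.cls == "both" else (sc.cls,)
            for cls in classes:
                pool = np.flatnonzero(is_canon if cls == "proximal" else ~is_canon)
                k = round(sc.plant_rate * len(pool))
                if k == 0:
                    continue
                chosen = rng.choice(pool, size=k, replace=False)
                for i in np.sort(chosen):
                    pos = int(starts[i]) + int(cofactor_cursor[i])
                    if cofactor_cursor[i] + pwm.width > design.peak_len - 3:
                        raise ValueError(
                            f"peak too short to stack plants (exp {exp.exp_id})"
                        )
                    plant(pos, sample_word(pwm, rng))
                    cofactor_cursor[i] += pwm.width + 2

        bed_rows[exp.exp_id] = [
            (int(s), int(s) + design.peak_len) for s in starts
        ]

    # HOT slots: a shared interval overlapped by > 50% of screenable exps
    hot_motifs = [sc for sc in design.scenarios if sc.kind == "hot_only"]
    n_hot_exps = math.ceil(design.hot_exp_fraction * n_screenable)
    hot_intervals: list[tuple[int, int]] = []
    for slot in hot_slots:
        start = int(slot) * slot_size + _SLOT_MARGIN
        hot_intervals.append((start, start + design.peak_len))
        chosen = rng.permutation([e.exp_id for e in screenable])[:n_hot_exps]
        for exp_id in chosen:
            bed_rows[exp_id].append((start, start + design.peak_len))
        pos = start + _COFACTOR_ZONE
        for sc in hot_motifs:
            pwm = pwms_by_id[sc.motif_id]
            plant(pos, sample_word(pwm, rng))
            pos += pwm.width + 2

    genome_seq = garr.tobytes().decode("ascii")

    # -- outputs ------------------------------------------------------------
    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i : i + 80] + "\n")

    metadata_path = out_dir / "metadata.tsv"
    meta = pd.DataFrame(
        [
            {"exp_id": e.exp_id, "tf_name": e.tf_name,
             "cell_type": e.cell_type, "treatment": e.treatment}
            for e in exps
        ]
    )
    meta.to_csv(metadata_path, sep="\t", index=False)

    canon_path = out_dir / "canonical_map.tsv"
    with open(canon_path, "w") as fh:
        fh.write("tf_name\tmotif_id\n")
        for tf in sorted(canonical_map):
            for motif_id in canonical_map[tf]:
                fh.write(f"{tf}\t{motif_id}\n")

    motifs_path = out_dir / "motifs.jaspar"
    write_jaspar(pwms, motifs_path)

    bed_paths = {}
    for exp in exps:
        path = peaks_dir / f"{exp.exp_id}.bed"
        with open(path, "w") as fh:
            for start, end in sorted(bed_rows[exp.exp_id]):
                fh.write(f"chr1\t{start}\t{end}\n")
        bed_paths[exp.exp_id] = path

    truth = build_truth_table(design, screenable, thresholds)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)

    manifest = {
        "seed": design.seed,
        "n_experiments": len(exps),
        "n_screenable": n_screenable,
        "n_motifs": len(pwms),
        "hot_intervals": [[s, e] for s, e in sorted(hot_intervals)],
    }
    (out_dir / "design_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return {
        "genome": genome_path,
        "metadata": metadata_path,
        "canonical_map": canon_path,
        "motifs": motifs_path,
        "peaks_dir": peaks_dir,
        "truth": truth_path,
        "bed_paths": bed_paths,
        "hot_intervals": [("chr1", s, e) for s, e in sorted(hot_intervals)],
    }


def build_truth_table(
    design: CompendiumDesign,
    screenable: Sequence[Experiment],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> pd.DataFrame:
    """One row per scenario motif with the screen outcome the design implies.

    A specificity scenario is expected to be called only when its planting
    margin clears the screen thresholds: plant rate >= 1.5x the abundance
    threshold, enough supporting experiments / TF diversity / sisters, and a
    flag fraction below the ubiquity ceiling. Ubiquitous, decoy and hot-only
    scenarios are always expected-negative (removed by the ubiquity filter,
    the similarity filter, and HOT-peak curation respectively).
    """
    n = len(screenable)
    rows = []
    for sc in design.scenarios:
        expected = False
        if sc.kind == "cell_type_specific":
            support = [e for e in screenable if e.cell_type == sc.key]
            tfs = {e.tf_name for e in support}
            ceiling = (thresholds.prox_ubiq if sc.cls == "proximal"
                       else thresholds.dist_ubiq)
            expected = (
                len(support) >= thresholds.ct_min_exps
                and len(tfs) >= thresholds.ct_min_tfs
                and sc.plant_rate >= 1.5 * thresholds.ct_min_abund
                and len(support) / n < ceiling
            )
        elif sc.kind == "tf_specific":
            support = [e for e in screenable if e.tf_name == sc.key]
            cts = {e.cell_type for e in support}
            ceiling = (thresholds.prox_ubiq if sc.cls == "proximal"
                       else thresholds.dist_ubiq)
            expected = (
                len(cts) >= thresholds.tf_min_sisters
                and sc.plant_rate >= 1.5 * thresholds.tf_min_abund
                and len(support) / n < ceiling
            )
        rows.append(
            {
                "motif_id": sc.motif_id,
                "kind": sc.kind,
                "key": sc.key,
                "cls": sc.cls,
                "expected_call": expected,
            }
        )
    return pd.DataFrame(
        rows, columns=["motif_id", "kind", "key", "cls", "expected_call"]
    )


_SCOPE_BY_KIND = {"cell_type_specific": "cell_type", "tf_specific": "tf"}


def evaluate_against_truth(
    calls: Sequence,
    truth: pd.DataFrame,
) -> tuple[float, float, pd.DataFrame]:
    """Precision/recall of SpecificCalls against the planted truth table.

    A truth row with expected_call counts as recovered iff some call matches
    its (motif_id, scope, key, cls); every call not matching an expected row
    (background motifs included) counts against precision.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    expected = {
        (r.motif_id, _SCOPE_BY_KIND.get(r.kind), r.key, r.cls)
        for r in truth.itertuples()
        if r.expected_call
    }
    call_keys = {(c.motif_id, c.scope, c.key, c.cls) for c in calls}
    n_correct = len(call_keys & expected)
    precision = n_correct / len(call_keys) if call_keys else 1.0
    recall = n_correct / len(expected) if expected else 1.0
    outcome_rows = []
    for r in truth.itertuples():
        key = (r.motif_id, _SCOPE_BY_KIND.get(r.kind), r.key, r.cls)
        called = key in call_keys or any(
            c.motif_id == r.motif_id for c in calls
        )
        outcome_rows.append(
            {
                "motif_id": r.motif_id,
                "kind": r.kind,
                "key": r.key,
                "cls": r.cls,
                "expected_call": bool(r.expected_call),
                "called": called,
                "outcome": (
                    "recovered" if r.expected_call and key in call_keys
                    else "missed" if r.expected_call
                    else "spurious" if called
                    else "correctly_absent"
                ),
            }
        )
    spurious = call_keys - expected
    for key in sorted(spurious):
        motif_id, scope, sc_key, cls = key
        if any(row["motif_id"] == motif_id and row["outcome"] == "spurious"
               for row in outcome_rows):
            continue
        outcome_rows.append(
            {
                "motif_id": motif_id,
                "kind": "unplanted",
                "key": sc_key,
                "cls": cls,
                "expected_call": False,
                "called": True,
                "outcome": "spurious",
            }
        )
    outcome = pd.DataFrame(
        outcome_rows,
        columns=["motif_id", "kind", "key", "cls", "expected_call", "called",
                 "outcome"],
    )
    return precision, recall, outcome
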