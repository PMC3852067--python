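"""Compendium loading and curation: metadata, peaks, genome, canonical map.

Filters follow the published curation order: drop general-machinery/CTCF
targets, drop orphan experiments (TF assayed in a single cell type), drop TFs
without a canonical motif, then remove peaks overlapping HOT regions (bases
covered by peaks from strictly more than ``hot_fraction`` of all experiments).
Coordinates are 0-based half-open throughout (BED convention).
"""
from __future__ import annotations

import io
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: default excluded target names (general machinery + CTCF), case-insensitive
DEFAULT_EXCLUDED_TFS = frozenset(
    {"POLR2A", "POLR3A", "POL2", "POL3", "TBP", "CTCF"}
)


@dataclass(frozen=True)
class Experiment:
    exp_id: str
    tf_name: str
    cell_type: str
    treatment: str = ""


@dataclass(frozen=True)
class Peak:
    peak_id: str
    exp_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"peak {self.peak_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError(f"peak {self.peak_id!r}: sequence length mismatch")


@dataclass
class CurationReport:
    """Ordered per-stage accounting: (experiments retained, peaks retained,
    peaks removed at this stage)."""

    rows: list[tuple[str, int, int, int]]

    def add(self, stage: str, n_exps: int, n_peaks: int, n_removed: int) -> None:
        self.rows.append((stage, n_exps, n_peaks, n_removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["stage", "experiments_retained", "peaks_retained",
                     "peaks_removed"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_experiments(metadata_text: str) -> list[Experiment]:
    """Parse the experiment metadata TSV (exp_id, tf_name, cell_type,
    treatment); duplicate exp_ids and missing columns are errors."""
    df = pd.read_csv(
        io.StringIO(metadata_text), sep="\t", dtype=str, keep_default_na=False
    )
    required = ["exp_id", "tf_name", "cell_type", "treatment"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    dupes = df["exp_id"][df["exp_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate exp_id(s): {', '.join(dupes)}")
    return [
        Experiment(
            exp_id=row.exp_id,
            tf_name=row.tf_name,
            cell_type=row.cell_type,
            treatment=row.treatment,
        )
        for row in df.itertuples()
    ]


def load_peaks(bed_text: str, exp_id: str) -> list[Peak]:
    """Parse BED3+ lines into peaks; peak_id is ``exp_id:line_number``
    (1-based). Columns beyond the third are ignored."""
    peaks: list[Peak] = []
    for lineno, raw in enumerate(bed_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-integer coordinate in {fields[1:3]!r}"
            ) from None
        if start >= end:
            raise ValueError(
                f"line {lineno}: start {start} >= end {end}"
            )
        peaks.append(
            Peak(peak_id=f"{exp_id}:{lineno}", exp_id=exp_id,
                 chrom=chrom, start=start, end=end)
        )
    return peaks


def load_canonical_map(text: str) -> dict[str, list[str]]:
    """Parse the canonical-map TSV (tf_name, motif_id; one pair per row)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    for col in ("tf_name", "motif_id"):
        if col not in df.columns:
            raise ValueError(f"canonical map is missing column {col!r}")
    mapping: dict[str, list[str]] = {}
    for row in df.itertuples():
        mapping.setdefault(row.tf_name, []).append(row.motif_id)
    return mapping


def filter_experiments(
    exps: Sequence[Experiment],
    canon: Mapping[str, Sequence[str]],
    excluded_tfs: Iterable[str] = DEFAULT_EXCLUDED_TFS,
) -> tuple[list[Experiment], list[tuple[str, int, int]]]:
    """Apply the experiment-level curation filters in order.

    1. drop experiments targeting an excluded TF (general machinery, CTCF);
    2. drop orphans: TFs seen in only one cell type among the survivors;
    3. drop experiments whose TF has no canonical-motif entry.

    Returns the retained experiments and per-stage report rows
    ``(stage, experiments_retained, experiments_removed)``.
    """
    excluded = {t.upper() for t in excluded_tfs}
    report: list[tuple[str, int, int]] = []

    stage1 = [e for e in exps if e.tf_name.upper() not in excluded]
    report.append(("excluded_tfs", len(stage1), len(exps) - len(stage1)))

    cell_types_per_tf: dict[str, set[str]] = {}
    for e in stage1:
        cell_types_per_tf.setdefault(e.tf_name, set()).add(e.cell_type)
    stage2 = [e for e in stage1 if len(cell_types_per_tf[e.tf_name]) > 1]
    report.append(("orphans", len(stage2), len(stage1) - len(stage2)))

    stage3 = [e for e in stage2 if canon.get(e.tf_name)]
    report.append(("missing_pwm", len(stage3), len(stage2) - len(stage3)))
    return stage3, report


def _merged_intervals_per_experiment(
    peaks: Iterable[Peak],
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """chrom -> exp_id -> merged sorted intervals (one coverage per exp/base)."""
    by: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for p in peaks:
        by.setdefault(p.chrom, {}).setdefault(p.exp_id, []).append((p.start, p.end))
    for chrom_map in by.values():
        for exp_id, ivs in chrom_map.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            chrom_map[exp_id] = [(s, e) for s, e in merged]
    return by


def find_hot_regions(
    peaks: Sequence[Peak],
    n_experiments: int,
    hot_fraction: float = 0.5,
) -> list[tuple[str, int, int]]:
    """Maximal intervals of bases covered by peaks from strictly more than
    ``hot_fraction * n_experiments`` distinct experiments.

    Sweep line over per-experiment merged intervals, so multiple peaks of one
    experiment count once per base. Strict inequality: with 4 experiments and
    fraction 0.5, a base needs coverage from 3 distinct experiments.
    """
    if not 0 < hot_fraction <= 1:
        raise ValueError("hot_fraction must be in (0, 1]")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    threshold = hot_fraction * n_experiments
    regions: list[tuple[str, int, int]] = []
    for chrom, per_exp in sorted(_merged_intervals_per_experiment(peaks).items()):
        events: list[tuple[int, int]] = []
        for ivs in per_exp.values():
            for s, e in ivs:
                events.append((s, 1))
                events.append((e, -1))
        events.sort()
        depth = 0
        open_start: int | None = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth > threshold and open_start is None:
                open_start = pos
            elif depth <= threshold and open_start is not None:
                regions.append((chrom, open_start, pos))
                open_start = None
        assert open_start is None  # every +1 has a matching -1
    return regions


def remove_hot_peaks(
    peaks: Sequence[Peak],
    hot: Sequence[tuple[str, int, int]],
) -> tuple[list[Peak], int]:
    """Drop peaks overlapping any HOT interval by >= 1 base (half-open test).

    Conserves peaks: ``len(cold) + n_removed == len(peaks)``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in hot:
        by_chrom.setdefault(chrom, []).append((s, e))
    starts: dict[str, list[int]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts[chrom] = [s for s, _ in ivs]
    cold: list[Peak] = []
    n_removed = 0
    for p in peaks:
        ivs = by_chrom.get(p.chrom)
        overlapped = False
        if ivs:
            # candidate: last HOT interval starting before the peak end
            j = bisect_right(starts[p.chrom], p.end - 1) - 1
            if j >= 0 and ivs[j][1] > p.start:
                overlapped = True
        if overlapped:
            n_removed += 1
        else:
            cold.append(p)
    return cold, n_removed


def extract_sequences(
    peaks: Sequence[Peak],
    genome: Mapping[str, str] | str | Path,
) -> list[Peak]:
    """Attach the uppercased forward-strand genome slice to every peak.

    ``genome`` is a chrom -> sequence mapping or a FASTA path (read with
    pyfaidx). Unknown chromosomes and out-of-bounds intervals are errors.
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome), as_raw=True, rebuild=False)
        lookup = {name: fasta[name] for name in fasta.keys()}
        lengths = {name: len(fasta[name]) for name in fasta.keys()}
    else:
        lookup = dict(genome)
        lengths = {name: len(seq) for name, seq in lookup.items()}
    out: list[Peak] = []
    for p in peaks:
        if p.chrom not in lookup:
            raise ValueError(f"peak {p.peak_id!r}: unknown chromosome {p.chrom!r}")
        if p.end > lengths[p.chrom]:
            raise ValueError(
                f"peak {p.peak_id!r}: interval [{p.start}, {p.end}) exceeds "
                f"{p.chrom} length {lengths[p.chrom]}"
            )
        seq = str(lookup[p.chrom][p.start : p.end]).upper()
        out.append(replace(p, sequence=seq))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
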