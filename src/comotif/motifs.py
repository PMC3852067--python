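"""Binding-site motif models: parsing, probability/log-odds forms, serialization.

Motifs are represented as column-stochastic probability matrices (PWMs) with a
fixed base order A, C, G, T. Two input dialects are supported: the JASPAR
count-matrix text format and the UniPROBE tab-separated probability format.
An internal tab-separated probability serialization round-trips exactly.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: probability-column tolerance for PWM validation
_COLSUM_TOL = 1e-9


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed; names the offending record."""


@dataclass(frozen=True)
class PWM:
    """A position weight matrix: per-column base probabilities.

    ``probs`` has shape ``(4, width)`` with rows in A, C, G, T order and every
    column summing to 1.
    """

    motif_id: str
    name: str
    source: str  # one of {"jaspar", "uniprobe", "synthetic"}
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(
                f"PWM {self.motif_id!r}: probs must have shape (4, width), "
                f"got {probs.shape}"
            )
        if probs.shape[1] < 2:
            raise ValueError(f"PWM {self.motif_id!r}: width must be >= 2")
        if np.any(probs < -_COLSUM_TOL) or np.any(probs > 1 + _COLSUM_TOL):
            raise ValueError(f"PWM {self.motif_id!r}: probabilities outside [0, 1]")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COLSUM_TOL):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"PWM {self.motif_id!r}: column {bad} sums to {colsums[bad]!r}, not 1"
            )
        probs = np.clip(probs, 0.0, 1.0)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        """Most probable base at each position (ties broken by base order)."""
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))


@dataclass(frozen=True)
class Background:
    """0-order background base frequencies in A, C, G, T order."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (4,):
            raise ValueError("Background needs exactly 4 frequencies (A, C, G, T)")
        if np.any(freqs <= 0):
            raise ValueError("Background frequencies must all be > 0")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"Background frequencies sum to {freqs.sum()!r}, not 1")
        freqs = freqs.copy()
        freqs.setflags(write=False)
        object.__setattr__(self, "freqs", freqs)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        floor: float = 0.01,
        symmetrize: bool = True,
    ) -> "Background":
        """Estimate 0-order frequencies from sequences.

        Non-ACGT characters are ignored. With ``symmetrize`` the A/T and C/G
        counts are pooled so the background is strand-complement symmetric,
        which makes double-strand scanning p-values exactly strand-symmetric.
        Frequencies are floored at ``floor`` and renormalized.
        """
        counts = np.zeros(4)
        for seq in sequences:
            su = seq.upper()
            for i, b in enumerate(BASES):
                counts[i] += su.count(b)
        if counts.sum() == 0:
            return cls.uniform()
        if symmetrize:
            at = (counts[0] + counts[3]) / 2.0
            cg = (counts[1] + counts[2]) / 2.0
            counts = np.array([at, cg, cg, at])
        freqs = counts / counts.sum()
        freqs = np.maximum(freqs, floor)
        return cls(freqs / freqs.sum())


@dataclass(frozen=True)
class LogOddsMatrix:
    """Integer-scaled log-odds scores for a PWM against a background.

    The real-valued log-odds ``log2(p'(b, i) / bg(b))`` is recovered from the
    integers as ``scores / scale + offset``; with ``offset`` equal to the
    minimum real score, all integer entries are non-negative, which bounds the
    score-distribution dynamic-programming table.
    """

    motif_id: str
    scores: np.ndarray  # (4, width) non-negative integers
    scale: float
    offset: float
    background: Background

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[0] != 4:
            raise ValueError("LogOddsMatrix scores must have shape (4, width)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        scores = scores.astype(np.int64)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def real_scores(self) -> np.ndarray:
        return self.scores / self.scale + self.offset

    def reverse_complement(self) -> "LogOddsMatrix":
        return LogOddsMatrix(
            motif_id=self.motif_id,
            scores=self.scores[::-1, ::-1],
            scale=self.scale,
            offset=self.offset,
            background=self.background,
        )


def counts_to_probabilities(
    counts: np.ndarray,
    pseudocount: float,
    motif_id: str = "",
    name: str = "",
    source: str = "synthetic",
) -> PWM:
    """Normalize a ``(4, width)`` count matrix into a PWM.

    ``prob(b, i) = (count(b, i) + pseudocount) / (colsum(i) + 4 * pseudocount)``
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must have shape (4, width)")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(counts < 0):
        raise ValueError(f"motif {motif_id!r}: negative counts")
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError(
            f"motif {motif_id!r}: all-zero column with pseudocount 0"
        )
    probs = (counts + pseudocount) / (colsums + 4.0 * pseudocount)
    return PWM(motif_id=motif_id, name=name, source=source, probs=probs)


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse-complement a PWM: columns reversed, A<->T and C<->G swapped."""
    return PWM(
        motif_id=pwm.motif_id,
        name=pwm.name,
        source=pwm.source,
        probs=pwm.probs[::-1, ::-1],
    )


def pwm_to_logodds(
    pwm: PWM,
    bg: Background,
    pseudocount: float = 0.1,
    scale: float = 1000.0,
) -> LogOddsMatrix:
    """Convert a PWM to an integer-scaled log-odds matrix.

    Probabilities are smoothed as ``p' = (p + pc * bg(b)) / (1 + pc)`` before
    the log, so a positive pseudocount is required whenever any probability is
    zero. The real score is ``log2(p' / bg(b))``; integers are
    ``round(scale * (real - offset))`` with ``offset = min(real)``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(pwm.probs == 0):
        raise ValueError(
            f"motif {pwm.motif_id!r}: zero probability requires pseudocount > 0"
        )
    bgcol = bg.freqs[:, None]
    smoothed = (pwm.probs + pseudocount * bgcol) / (1.0 + pseudocount)
    real = np.log2(smoothed / bgcol)
    offset = float(real.min())
    scores = np.rint(scale * (real - offset)).astype(np.int64)
    return LogOddsMatrix(
        motif_id=pwm.motif_id,
        scores=scores,
        scale=scale,
        offset=offset,
        background=bg,
    )


# ---------------------------------------------------------------------------
# JASPAR count-matrix dialect
# ---------------------------------------------------------------------------

def _parse_number_row(tokens: Sequence[str], record_id: str) -> list[float]:
    values = []
    for tok in tokens:
        try:
            values.append(float(tok))
        except ValueError:
            raise MotifParseError(
                f"record {record_id!r}: non-numeric count {tok!r}"
            ) from None
    return values


def parse_jaspar(text: str, pseudocount: float = 0.25) -> list[PWM]:
    """Parse motifs in the JASPAR count-matrix dialect.

    Each record is a ``>`` header line (``>ID optional name``) followed by four
    base rows ``A [n1 n2 ...]`` (brackets optional). Counts are converted to
    probabilities with the given pseudocount per cell.
    """
    pwms: list[PWM] = []
    record_id = None
    name = ""
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal record_id, name, rows
        if record_id is None:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise MotifParseError(
                f"record {record_id!r}: missing base row(s) {', '.join(missing)}"
            )
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise MotifParseError(
                f"record {record_id!r}: base rows of unequal length"
            )
        if lengths == {0}:
            raise MotifParseError(f"record {record_id!r}: empty base rows")
        counts = np.array([rows[b] for b in BASES])
        pwms.append(
            counts_to_probabilities(
                counts, pseudocount, motif_id=record_id, name=name, source="jaspar"
            )
        )
        record_id, name, rows = None, "", {}

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split(None, 1)
            if not header:
                raise MotifParseError("header line with no motif id")
            record_id = header[0]
            name = header[1].strip() if len(header) > 1 else ""
            continue
        if record_id is None:
            raise MotifParseError(f"matrix row before any header: {line!r}")
        cleaned = line.replace("[", " ").replace("]", " ")
        tokens = cleaned.split()
        base = tokens[0].upper() if tokens else ""
        if base in BASE_INDEX and len(base) == 1:
            if base in rows:
                raise MotifParseError(
                    f"record {record_id!r}: duplicate base row {base}"
                )
            rows[base] = _parse_number_row(tokens[1:], record_id)
        else:
            # unlabeled rows: assign in A, C, G, T order
            for b in BASES:
                if b not in rows:
                    rows[b] = _parse_number_row(tokens, record_id)
                    break
            else:
                raise MotifParseError(
                    f"record {record_id!r}: more than four matrix rows"
                )
    flush()
    return pwms


def write_jaspar(pwms: Iterable[PWM], path: str | Path, total: float = 100.0) -> None:
    """Write PWMs in the JASPAR count dialect with counts = probs * total."""
    with open(path, "w") as fh:
        for pwm in pwms:
            header = f">{pwm.motif_id}"
            if pwm.name:
                header += f" {pwm.name}"
            fh.write(header + "\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v * total:.4f}" for v in pwm.probs[bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# UniPROBE probability dialect
# ---------------------------------------------------------------------------

def parse_uniprobe(text: str) -> list[PWM]:
    """Parse motifs in the UniPROBE tab-separated probability dialect.

    Each record is a name line (kept verbatim as the motif id, including any
    ``primary``/``secondary`` tag) followed by four rows ``A:\\t...`` etc.
    Column sums off by more than 0.05 are a parse error; smaller rounding
    deviations are renormalized silently.
    """
    pwms: list[PWM] = []
    blocks: list[list[str]] = [[]]
    for raw in text.splitlines():
        if raw.strip():
            blocks[-1].append(raw.rstrip("\n"))
        elif blocks[-1]:
            blocks.append([])
    for block in blocks:
        if not block:
            continue
        record_id = block[0].strip()
        rows: dict[str, list[float]] = {}
        for line in block[1:]:
            parts = [p for p in line.replace("\t", " ").split() if p]
            if not parts:
                continue
            base = parts[0].rstrip(":").upper()
            if base not in BASE_INDEX:
                raise MotifParseError(
                    f"record {record_id!r}: unexpected row label {parts[0]!r}"
                )
            if base in rows:
                raise MotifParseError(f"record {record_id!r}: duplicate {base} row")
            rows[base] = _parse_number_row(parts[1:], record_id)
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise MotifParseError(
                f"record {record_id!r}: missing base row(s) {', '.join(missing)}"
            )
        if len({len(rows[b]) for b in BASES}) != 1:
            raise MotifParseError(f"record {record_id!r}: base rows of unequal length")
        probs = np.array([rows[b] for b in BASES])
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 0.05):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise MotifParseError(
                f"record {record_id!r}: column {bad} sums to {colsums[bad]:.4f}"
            )
        pwms.append(
            PWM(
                motif_id=record_id,
                name=record_id,
                source="uniprobe",
                probs=probs / colsums,
            )
        )
    return pwms


# ---------------------------------------------------------------------------
# internal probability serialization (exact round-trip)
# ---------------------------------------------------------------------------

def write_pwm_tsv(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"#id\t{pwm.motif_id}\t{pwm.name}\n")
            fh.write(f"#source\t{pwm.source}\n")
            for bi, base in enumerate(BASES):
                row = "\t".join(repr(float(v)) for v in pwm.probs[bi])
                fh.write(f"{base}\t{row}\n")
            fh.write("\n")


def read_pwm_tsv(path: str | Path) -> list[PWM]:
    pwms: list[PWM] = []
    motif_id = name = source = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal motif_id, name, source, rows
        if motif_id is None:
            return
        if set(rows) != set(BASES):
            raise MotifParseError(f"record {motif_id!r}: incomplete base rows")
        probs = np.array([rows[b] for b in BASES])
        pwms.append(
            PWM(motif_id=motif_id, name=name or "", source=source or "synthetic",
                probs=probs)
        )
        motif_id = name = source = None
        rows = {}

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split("\t")
            if parts[0] == "#id":
                flush()
                motif_id = parts[1]
                name = parts[2] if len(parts) > 2 else ""
            elif parts[0] == "#source":
                source = parts[1]
            else:
                rows[parts[0].upper()] = [float(v) for v in parts[1:]]
    flush()
    return pwms


def load_motifs(path: str | Path, fmt: str | None = None,
                pseudocount: float = 0.25) -> list[PWM]:
    """Load motifs, auto-detecting the dialect from the extension if needed."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in {".jaspar", ".pfm", ".jpfm"}:
            fmt = "jaspar"
        elif suffix in {".uniprobe", ".up"}:
            fmt = "uniprobe"
        else:
            fmt = "tsv"
    if fmt == "jaspar":
        return parse_jaspar(path.read_text(), pseudocount=pseudocount)
    if fmt == "uniprobe":
        return parse_uniprobe(path.read_text())
    if fmt == "tsv":
        return read_pwm_tsv(path)
    raise ValueError(f"unknown motif format {fmt!r}")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0, C=1, G=2, T=3, other=4."""
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
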