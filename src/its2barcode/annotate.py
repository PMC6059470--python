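"""ITS2 annotation: trim amplicons to the spacer by locating the
conserved 5.8S / 28S flanking motifs, and compute composition statistics.

Flank motifs are modelled as position weight matrices scored by log-odds
against a uniform background; the full spacer is whatever lies strictly
between the end of the 5' motif hit and the start of the 3' motif hit.
The flanks of ITS2 are strongly conserved and essentially gap-free, so a
PWM scan recovers the same boundaries a profile HMM would.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import SequenceRecord

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BACKGROUND = 0.25


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and anything else (gaps, ambiguity) as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class MotifProfile:
    """Position-specific nucleotide frequency matrix scored as log-odds."""

    frequencies: np.ndarray  # (width, 4), rows sum to 1
    min_score: float

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):  # zero-pseudocount profiles -> -inf
            return np.log(self.frequencies / _BACKGROUND)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_sequences(
        cls,
        motifs: Sequence[str],
        pseudocount: float = 0.5,
        min_score_fraction: float = 0.6,
    ) -> "MotifProfile":
        """Build a profile from equal-length motif instances.

        ``min_score`` defaults to ``min_score_fraction`` of the maximum
        attainable log-odds score; a pseudocount per cell keeps unseen
        bases from scoring -inf.
        """
        if not motifs:
            raise ValueError("need at least one motif sequence")
        widths = {len(m) for m in motifs}
        if len(widths) != 1:
            raise ValueError("motif instances must have equal length")
        (width,) = widths
        if width == 0:
            raise ValueError("motif width must be positive")
        counts = np.full((width, 4), pseudocount, dtype=float)
        for m in motifs:
            enc = encode(m)
            if (enc == 4).any():
                raise ValueError(f"motif contains non-ACGT symbols: {m}")
            counts[np.arange(width), enc] += 1.0
        freqs = counts / counts.sum(axis=1, keepdims=True)
        prof = cls(frequencies=freqs, min_score=-math.inf)
        prof.min_score = min_score_fraction * prof.max_score
        return prof

    def write(self, path) -> None:
        """Column-frequency text format: one row per position, A C G T."""
        header = f"# min_score {self.min_score:.6f}\n# A C G T\n"
        body = "\n".join(
            " ".join(f"{v:.6f}" for v in row) for row in self.frequencies
        )
        with open(path, "w") as fh:
            fh.write(header + body + "\n")

    @classmethod
    def read(cls, path) -> "MotifProfile":
        min_score = -math.inf
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if parts[:1] == ["min_score"]:
                        min_score = float(parts[1])
                    continue
                rows.append([float(v) for v in line.split()])
        freqs = np.asarray(rows, dtype=float)
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
        return cls(frequencies=freqs, min_score=min_score)


@dataclass
class ScanHit:
    offset: int
    score: float
    found: bool = True


NO_HIT = ScanHit(offset=-1, score=-math.inf, found=False)


def scan_profile(seq: str, profile: MotifProfile) -> ScanHit:
    """Best-scoring placement of the profile along the sequence.

    Scores every offset with the summed per-position log-odds (non-ACGT
    symbols contribute 0, i.e. background); ties resolve to the smallest
    offset.  Sequences shorter than the profile yield a no-hit result.
    """
    enc = encode(seq)
    w = profile.width
    if enc.size < w:
        return NO_HIT
    lo = profile.log_odds  # (w, 4)
    n_offsets = enc.size - w + 1
    # windows[o, k] = encoded base at offset o, motif position k
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = windows < 4
    scores = np.where(
        valid, lo[np.arange(w)[None, :], np.clip(windows, 0, 3)], 0.0
    ).sum(axis=1)
    best = int(np.argmax(scores))  # argmax returns the first (smallest) offset
    return ScanHit(offset=best, score=float(scores[best]))


@dataclass
class AnnotatedBarcode:
    """Trimming outcome for one amplicon."""

    specimen_id: str
    its2_sequence: str
    span: tuple[int, int]  # 0-based, half-open, amplicon coordinates
    score_5p: float
    score_3p: float
    status: str  # ok | flank5_not_found | flank3_not_found | flanks_out_of_order | empty_its2

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def trim_its2(
    record: SequenceRecord,
    profile_5p: MotifProfile,
    profile_3p: MotifProfile,
) -> AnnotatedBarcode:
    """Cut an amplicon down to the ITS2 between the two flank motifs.

    The spacer is the subsequence strictly between the end of the 5'
    motif hit and the start of the 3' motif hit.  Failure statuses:
    a flank scoring below its profile's ``min_score`` (or not placeable),
    hits out of order / overlapping, or an empty spacer.
    """

    def _fail(status: str, s5: float, s3: float) -> AnnotatedBarcode:
        return AnnotatedBarcode(record.specimen_id, "", (0, 0), s5, s3, status)

    hit5 = scan_profile(record.sequence, profile_5p)
    if not hit5.found or hit5.score < profile_5p.min_score:
        return _fail("flank5_not_found", hit5.score, -math.inf)
    hit3 = scan_profile(record.sequence, profile_3p)
    if not hit3.found or hit3.score < profile_3p.min_score:
        return _fail("flank3_not_found", hit5.score, hit3.score)
    start = hit5.offset + profile_5p.width
    end = hit3.offset
    if end < start:
        return _fail("flanks_out_of_order", hit5.score, hit3.score)
    if end == start:
        return _fail("empty_its2", hit5.score, hit3.score)
    return AnnotatedBarcode(
        record.specimen_id,
        record.sequence[start:end],
        (start, end),
        hit5.score,
        hit3.score,
        "ok",
    )


def annotate_records(
    records: Iterable[SequenceRecord],
    profile_5p: MotifProfile,
    profile_3p: MotifProfile,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Trim a batch; returns the successfully annotated barcodes and a
    per-record report (specimen_id, start, end, score5, score3, status)."""
    trimmed, rows = [], []
    for rec in records:
        ann = trim_its2(rec, profile_5p, profile_3p)
        rows.append(
            (
                ann.specimen_id,
                ann.span[0],
                ann.span[1],
                ann.score_5p,
                ann.score_3p,
                ann.status,
            )
        )
        if ann.ok:
            trimmed.append(SequenceRecord(ann.specimen_id, ann.its2_sequence))
    report = pd.DataFrame(
        rows, columns=["specimen_id", "start", "end", "score5", "score3", "status"]
    )
    return trimmed, report


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------

def seq_stats(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Per-record length, GC fraction and base composition.

    Length counts non-gap characters; GC = (G+C)/(A+C+G+T) with
    ambiguity codes excluded from the denominator.  Empty sequences are
    excluded with a warning.
    """
    rows = []
    for rec in records:
        seq = rec.sequence.replace("-", "")
        if not seq:
            warnings.warn(f"empty sequence excluded: {rec.specimen_id}")
            continue
        enc = encode(seq)
        counts = np.bincount(enc[enc < 4], minlength=4)
        acgt = counts.sum()
        gc = (counts[1] + counts[2]) / acgt if acgt else np.nan
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "length": len(seq),
                "gc": gc,
                "frac_a": counts[0] / acgt if acgt else np.nan,
                "frac_c": counts[1] / acgt if acgt else np.nan,
                "frac_g": counts[2] / acgt if acgt else np.nan,
                "frac_t": counts[3] / acgt if acgt else np.nan,
            }
        )
    if not rows:
        raise ValueError("no non-empty sequences")
    return pd.DataFrame(rows)


def group_summary(
    stats: pd.DataFrame, labels: dict[str, str] | pd.Series, value: str = "length"
) -> pd.DataFrame:
    """Median / quartile summary of a per-record statistic by group label.

    Quartiles use linear interpolation between order statistics (numpy
    default), matching the convention of standard box plots.
    """
    df = stats.copy()
    df["group"] = df["specimen_id"].map(dict(labels) if not isinstance(labels, dict) else labels)
    out = []
    for group, sub in df.groupby("group", sort=True):
        vals = sub[value].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        out.append(
            {
                "group": group,
                "n": len(vals),
                "median": med,
                "q25": q25,
                "q75": q75,
                "iqr": q75 - q25,
                "mean": vals.mean(),
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(out)
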