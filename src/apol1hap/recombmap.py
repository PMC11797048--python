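"""Recombination-rate maps: BED-like interval tracks in cM/Mb."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateInterval:
    chrom: str
    start: int  # 0-based, half-open [start, end)
    end: int
    rate: float  # cM/Mb


@dataclass
class RecombMap:
    """Sorted, non-overlapping half-open intervals with cM/Mb rates.

    An empty map is valid; rate queries against it return an undefined
    status (None) rather than a number.
    """

    intervals: list[RateInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))
        prev: RateInterval | None = None
        for iv in self.intervals:
            if iv.end <= iv.start:
                raise ValidationError(f"empty/inverted interval {iv}")
            if not np.isfinite(iv.rate) or iv.rate < 0:
                raise ValidationError(f"rate must be finite and >= 0, got {iv.rate}")
            if prev and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValidationError(
                    f"overlapping intervals {prev} and {iv}"
                )
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)


def read_recomb_map(path) -> RecombMap:
    """Read a BED-like rate track: chrom, start (0-based), end, rate (cM/Mb).

    Tab- or whitespace-separated, optional header line, '#' comments
    allowed. Unsorted rows are sorted with a logged notice; overlapping
    intervals and negative rates are rejected.
    """
    rows: list[RateInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValidationError(
                    f"{path} line {line_no}: expected >= 4 columns, got {len(parts)}"
                )
            chrom, start_s, end_s, rate_s = parts[:4]
            try:
                start, end, rate = int(start_s), int(end_s), float(rate_s)
            except ValueError:
                if line_no == 1:  # tolerated header line
                    continue
                raise ValidationError(f"{path} line {line_no}: non-numeric fields")
            rows.append(RateInterval(chrom, start, end, rate))
    keys = [(iv.chrom, iv.start) for iv in rows]
    if keys != sorted(keys):
        logger.info("recombination map %s was not sorted; sorting", path)
    return RecombMap(rows)
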