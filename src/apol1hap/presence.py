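"""Unphased presence profiles for low-coverage (ancient-DNA-style) samples.

A presence profile records, per panel site, whether any sequencing read
supported the alternate allele. It deliberately carries less information
than a phased haplotype: "alt_observed" at a site means the carrier has at
least one alternate allele there, "ref_only" means only reference reads were
seen, and "no_data" means the site had no coverage at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import VariantPanel

ALT_OBSERVED = "alt_observed"
REF_ONLY = "ref_only"
NO_DATA = "no_data"
CALLS = (ALT_OBSERVED, REF_ONLY, NO_DATA)


@dataclass
class PresenceProfile:
    """Per-site presence calls plus the raw read counts they came from."""

    panel: VariantPanel
    calls: list[str]
    alt_reads: np.ndarray
    ref_reads: np.ndarray
    min_alt_reads: int = 1

    def __post_init__(self) -> None:
        L = len(self.panel)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        if not (len(self.calls) == len(self.alt_reads) == len(self.ref_reads) == L):
            raise ValidationError("profile arrays must match the panel length")
        for c in self.calls:
            if c not in CALLS:
                raise ValidationError(f"unknown presence call {c!r}")

    def n_informative(self) -> int:
        return sum(c != NO_DATA for c in self.calls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": self.panel.variant_ids,
            "call": self.calls,
            "alt_reads": self.alt_reads,
            "ref_reads": self.ref_reads,
        })


def presence_from_counts(
    panel: VariantPanel,
    alt_reads,
    ref_reads,
    min_alt_reads: int = 1,
) -> PresenceProfile:
    """Collapse per-site read counts into presence calls.

    A site is ``alt_observed`` when alt_reads >= min_alt_reads (default 1:
    a single alternate read marks presence), ``no_data`` when it has no
    reads at all, and ``ref_only`` otherwise. Monotone in ``min_alt_reads``:
    raising the threshold can only move sites out of ``alt_observed``.
    """
    if min_alt_reads < 1:
        raise ValidationError("min_alt_reads must be a positive integer")
    alt = np.asarray(alt_reads, dtype=np.int64)
    ref = np.asarray(ref_reads, dtype=np.int64)
    if alt.shape != ref.shape or alt.ndim != 1 or len(alt) != len(panel):
        raise ValidationError("counts must be 1-D arrays covering every panel site")
    if (alt < 0).any() or (ref < 0).any():
        raise ValidationError("read counts must be non-negative")
    calls = []
    for a, r in zip(alt, ref):
        if a >= min_alt_reads:
            calls.append(ALT_OBSERVED)
        elif a + r == 0:
            calls.append(NO_DATA)
        else:
            calls.append(REF_ONLY)
    return PresenceProfile(panel=panel, calls=calls, alt_reads=alt,
                           ref_reads=ref, min_alt_reads=min_alt_reads)


def read_presence_counts(path, panel: VariantPanel,
                         min_alt_reads: int = 1) -> PresenceProfile:
    """Read a counts TSV (variant_id, alt_reads, ref_reads) and build a profile.

    Every panel variant must appear exactly once.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "alt_reads", "ref_reads"}
    if missing := required - set(df.columns):
        raise ValidationError(f"counts file {path} lacks columns {sorted(missing)}")
    counts = df.set_index("variant_id")
    if counts.index.duplicated().any():
        raise ValidationError(f"counts file {path} has duplicate variant ids")
    ids = panel.variant_ids
    if absent := [i for i in ids if i not in counts.index]:
        raise ValidationError(f"counts file {path} misses panel variants {absent}")
    alt = counts.loc[ids, "alt_reads"].to_numpy()
    ref = counts.loc[ids, "ref_reads"].to_numpy()
    return presence_from_counts(panel, alt, ref, min_alt_reads=min_alt_reads)
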