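"""The phased-cohort container: per-sample pairs of binary haplotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .panel import VariantPanel


@dataclass
class HaplotypeMatrix:
    """Binary allele matrix for a phased diploid cohort.

    ``alleles`` has shape (n_samples, 2, L): two haplotypes per sample over
    the L panel sites, 0 = reference allele, 1 = panel alternate allele.
    Row order of :meth:`gametes` is sample-major (sample 0 haplotype A,
    sample 0 haplotype B, sample 1 haplotype A, ...).
    """

    panel: VariantPanel
    sample_ids: list[str]
    alleles: np.ndarray
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValidationError(
                f"alleles must have shape (n, 2, L), got {self.alleles.shape}"
            )
        if self.alleles.shape[0] != len(self.sample_ids):
            raise ValidationError("sample_ids length disagrees with allele matrix")
        if self.alleles.shape[2] != len(self.panel):
            raise ValidationError(
                f"allele matrix has {self.alleles.shape[2]} sites, panel has "
                f"{len(self.panel)}"
            )
        if self.alleles.size and self.alleles.max() > 1:
            raise ValidationError("alleles must be binary (0=ref, 1=alt)")
        if not self.populations:
            self.populations = ["NA"] * len(self.sample_ids)
        elif len(self.populations) != len(self.sample_ids):
            raise ValidationError("populations length disagrees with sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.panel)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    def gametes(self) -> np.ndarray:
        """All 2N haplotypes as a (2N, L) array, sample-major order."""
        return self.alleles.reshape(-1, self.n_sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alternate-allele frequency over all 2N haplotypes."""
        if self.n_samples == 0:
            raise ValidationError("empty matrix has no allele frequencies")
        return self.gametes().mean(axis=0)
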