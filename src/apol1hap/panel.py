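"""Variant panels: the ordered catalog of sites that defines a haplotype.

A haplotype in this package is a binary vector over a fixed, position-sorted
panel of biallelic variants (0 = reference allele, 1 = alternate). Panel
variants may carry *role tags* that give them semantic meaning for APOL1
haplotype classification:

``G1_snp1``/``G1_snp2``
    the two missense SNPs whose joint presence defines the G1 risk allele
    (rs73885319 S342G and rs60910145 I384M),
``G2_del``
    the 6 bp in-frame deletion defining G2 (rs71785313, N388Y389del),
``M1``
    the protective p.N264K missense variant (rs73885316),
``bg150``/``bg228``/``bg255``
    the coding positions 150/228/255 whose alleles spell the EMR/EIK/KIK
    haplotype backgrounds (E150K, M228I, R255K).

Positions are 1-based, as in VCF. A second coordinate build can be attached
per variant as plain data (``pos_alt_build``) — no liftover is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PanelError

logger = logging.getLogger(__name__)

ANNOTATION_CLASSES = ("exonic", "intronic", "utr3", "intergenic")
ROLE_TAGS = ("G1_snp1", "G1_snp2", "G2_del", "M1", "bg150", "bg228", "bg255")
#: role tags classify_haplotype needs; "none" marks untagged panel members
ROLES = ROLE_TAGS + ("none",)

PANEL_COLUMNS = ("variant_id", "chrom", "pos", "pos_alt_build", "ref", "alt",
                 "class", "role")


@dataclass(frozen=True)
class PanelVariant:
    """One biallelic marker of the panel.

    Indels are written as full REF/ALT strings in the VCF's own
    normalization (e.g. the G2 deletion ``AATAATT>A``); no left-alignment is
    attempted here, so the panel must match the convention of the VCFs it
    will be queried against.
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    annotation_class: str
    role: str = "none"
    pos_alt_build: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise PanelError(f"{self.variant_id}: pos must be positive, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise PanelError(
                f"{self.variant_id}: unknown annotation class {self.annotation_class!r}"
            )
        if self.role not in ROLES:
            raise PanelError(f"{self.variant_id}: unknown role {self.role!r}")


@dataclass
class VariantPanel:
    """Position-sorted panel with unique ids, positions and role tags."""

    variants: list[PanelVariant]
    build: str = "Hg38"

    def __post_init__(self) -> None:
        if not self.variants:
            raise PanelError("panel must contain at least one variant")
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.pos))
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int]] = set()
        roles: dict[str, str] = {}
        for v in self.variants:
            if v.variant_id in seen_ids:
                raise PanelError(f"duplicate variant id {v.variant_id}")
            if (v.chrom, v.pos) in seen_pos:
                raise PanelError(f"duplicate position {v.chrom}:{v.pos}")
            seen_ids.add(v.variant_id)
            seen_pos.add((v.chrom, v.pos))
            if v.role != "none":
                if v.role in roles:
                    raise PanelError(
                        f"role {v.role} tagged on both {roles[v.role]} and {v.variant_id}"
                    )
                roles[v.role] = v.variant_id
        self._role_index = {
            role: i for i, v in enumerate(self.variants)
            for role in [v.role] if role != "none"
        }

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[PanelVariant]:
        return iter(self.variants)

    def __getitem__(self, i: int) -> PanelVariant:
        return self.variants[i]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def index_of_role(self, role: str) -> int:
        """Panel index of the variant tagged with ``role``.

        Raises KeyError when the panel does not carry the tag; callers that
        need tags for classification wrap this into a ConfigurationError.
        """
        return self._role_index[role]

    def has_role(self, role: str) -> bool:
        return role in self._role_index

    def index_of_id(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.variant_id == variant_id:
                return i
        raise KeyError(variant_id)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in ANNOTATION_CLASSES}
        for v in self.variants:
            counts[v.annotation_class] += 1
        return counts

    def subset(self, keep: Sequence[int]) -> "VariantPanel":
        """Panel restricted to the given site indices (used by drop-site policy)."""
        return VariantPanel([self.variants[i] for i in keep], build=self.build)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
                "pos_alt_build": "" if v.pos_alt_build is None else v.pos_alt_build,
                "ref": v.ref_allele, "alt": v.alt_allele,
                "class": v.annotation_class, "role": v.role,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows, columns=list(PANEL_COLUMNS))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_panel(path, build: str = "Hg38") -> VariantPanel:
    """Read a panel TSV (columns: variant_id, chrom, pos, pos_alt_build, ref,
    alt, class, role) into a validated :class:`VariantPanel`.

    Unsorted input is accepted and sorted with a logged notice; duplicate
    ids/positions and duplicate role tags are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelError(f"cannot parse panel file {path}: {exc}") from exc
    required = {"variant_id", "chrom", "pos", "ref", "alt", "class", "role"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file {path} lacks columns: {sorted(missing)}")
    if df.empty:
        raise PanelError(f"panel file {path} contains no variants")

    variants: list[PanelVariant] = []
    for line_no, row in enumerate(df.to_dict("records"), start=2):
        try:
            pos = int(row["pos"])
        except ValueError:
            raise PanelError(f"{path} line {line_no}: non-integer pos {row['pos']!r}")
        alt_build: Optional[int] = None
        raw_alt = row.get("pos_alt_build", "")
        if raw_alt not in ("", "."):
            try:
                alt_build = int(raw_alt)
            except ValueError:
                raise PanelError(
                    f"{path} line {line_no}: non-integer pos_alt_build {raw_alt!r}"
                )
        try:
            variants.append(PanelVariant(
                variant_id=row["variant_id"], chrom=row["chrom"], pos=pos,
                ref_allele=row["ref"], alt_allele=row["alt"],
                annotation_class=row["class"],
                role=row["role"] or "none", pos_alt_build=alt_build,
            ))
        except PanelError as exc:
            raise PanelError(f"{path} line {line_no}: {exc}") from exc

    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        logger.info("panel file %s was not position-sorted; sorting", path)
    return VariantPanel(variants, build=build)


def load_core_panel() -> VariantPanel:
    """The shipped APOL1 core panel: the four tag variants with published
    Hg38 coordinates (M1, the two G1 SNPs, the G2 deletion)."""
    with resources.as_file(
        resources.files("apol1hap").joinpath("data/apol1_core_panel.tsv")
    ) as p:
        return load_panel(p)
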