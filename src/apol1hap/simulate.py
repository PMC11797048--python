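"""Synthetic phased cohorts with the APOL1 haplotype structure under study.

The generator emulates the haplotype model of the locus: the EIK and KIK
coding backgrounds descend from an ancestral G0; G1 and G2 arose by
independent mutations on EIK backgrounds; the protective M1 (p.N264K)
variant appeared on a KIK background together with three M1-lineage
intronic markers; and a single historical crossover between the M1 and G2
positions joined the left (KIK, M1) half of an M1-G0 haplotype to the right
(G2) half of a G2-EIK haplotype, creating the M1-G2 founder.

Default founder frequencies follow the cohort arithmetic of an AFR
reference panel of ~1,760 chromosomes: G1 0.21 and G2 0.13 (typical AFR
risk-allele frequencies), M1-G0 0.018 and the M1-G2 recombinant 0.004
(7 of 1,762 chromosomes), with the remaining G0 mass split between the EIK
(0.398) and KIK (0.24) backgrounds.

The default synthetic panel has 28 sites. The five tag variants with
published Hg38 coordinates sit at their real positions — M1 at
chr22:36265628, the G1 SNPs at 36265860/36265988, the G2 deletion at
36265995 (REF AATAATT > ALT A) — so the inferred M1-G2 breakpoint window
is literally 367 bp wide. All other sites, including the background codons
and the three M1-lineage intronic markers, are synthetic placements inside
the study region (chr22:36253528-36270279) and carry ``syn_``-prefixed ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ValidationError
from .haplotypes import HaplotypeMatrix
from .panel import PanelVariant, VariantPanel
from .presence import PresenceProfile, presence_from_counts

REGION_CHROM = "chr22"
REGION_START = 36253528
REGION_END = 36270279

# (variant_id, pos, class, role, alleles on each founder in FOUNDER_ORDER)
# Founder columns: G0_EIK, G0_KIK, G1_EIK, G2_EIK, M1G0_KIK.
# syn_* ids mark synthetic coordinate placements (no published position);
# the three exclusive intronic markers are modeled on rs136155, rs136161
# and rs713753 and sit upstream of M1 so the recombinant inherits them.
_PANEL_TABLE = [
    ("syn_22_36253700", 36253700, "intergenic", "none",    (0, 1, 1, 1, 1)),
    ("syn_22_36254400", 36254400, "intergenic", "none",    (1, 0, 1, 1, 0)),
    ("syn_22_36255100", 36255100, "intergenic", "none",    (0, 0, 1, 1, 0)),
    ("syn_22_36256000", 36256000, "intronic",   "none",    (1, 1, 0, 1, 1)),
    ("syn_rs136155",    36257000, "intronic",   "none",    (0, 0, 0, 0, 1)),
    ("syn_22_36258000", 36258000, "intronic",   "none",    (1, 1, 1, 0, 1)),
    ("syn_rs136161",    36259000, "intronic",   "none",    (0, 0, 0, 0, 1)),
    ("syn_22_36259800", 36259800, "intronic",   "none",    (0, 1, 0, 1, 1)),
    ("syn_rs713753",    36261000, "intronic",   "none",    (0, 0, 0, 0, 1)),
    ("syn_22_36261800", 36261800, "intronic",   "none",    (1, 0, 1, 1, 0)),
    ("syn_22_36262500", 36262500, "intronic",   "none",    (0, 0, 1, 0, 0)),
    ("syn_22_36263200", 36263200, "intronic",   "none",    (0, 0, 0, 1, 0)),
    ("syn_22_36263900", 36263900, "intronic",   "none",    (1, 1, 1, 1, 0)),
    ("syn_22_36264600", 36264600, "intronic",   "none",    (0, 1, 0, 1, 1)),
    ("syn_rs2239785",   36265284, "exonic",     "bg150",   (0, 1, 0, 0, 1)),
    ("syn_rs136175",    36265460, "exonic",     "bg228",   (1, 1, 1, 1, 1)),
    ("syn_rs136176",    36265540, "exonic",     "bg255",   (1, 1, 1, 1, 1)),
    ("rs73885316",      36265628, "exonic",     "M1",      (0, 0, 0, 0, 1)),
    ("rs73885319",      36265860, "exonic",     "G1_snp1", (0, 0, 1, 0, 0)),
    ("rs60910145",      36265988, "exonic",     "G1_snp2", (0, 0, 1, 0, 0)),
    ("rs71785313",      36265995, "exonic",     "G2_del",  (0, 0, 0, 1, 0)),
    ("syn_22_36266400", 36266400, "utr3",       "none",    (1, 1, 0, 1, 1)),
    ("syn_22_36267000", 36267000, "utr3",       "none",    (0, 0, 1, 1, 0)),
    ("syn_22_36267600", 36267600, "utr3",       "none",    (1, 0, 1, 0, 1)),
    ("syn_22_36268200", 36268200, "utr3",       "none",    (0, 1, 0, 1, 0)),
    ("syn_22_36268900", 36268900, "intergenic", "none",    (1, 1, 1, 0, 1)),
    ("syn_22_36269600", 36269600, "intergenic", "none",    (0, 0, 1, 1, 1)),
    ("syn_22_36270100", 36270100, "intergenic", "none",    (1, 0, 0, 1, 0)),
]

FOUNDER_ORDER = ("G0_EIK", "G0_KIK", "G1_EIK", "G2_EIK", "M1G0_KIK")
RECOMBINANT_LABEL = "M1G2_KIK_rec"
EXCLUSIVE_MARKER_IDS = ("syn_rs136155", "syn_rs136161", "syn_rs713753")

DEFAULT_FREQUENCIES = {
    "G0_EIK": 0.398,
    "G0_KIK": 0.240,
    "G1_EIK": 0.210,
    "G2_EIK": 0.130,
    "M1G0_KIK": 0.018,
    RECOMBINANT_LABEL: 0.004,
}

_SPECIAL_ALLELES = {
    "rs73885316": ("C", "A"),
    "rs73885319": ("A", "G"),
    "rs60910145": ("T", "G"),
    "rs71785313": ("AATAATT", "A"),
}
_BASES = "ACGT"


def default_panel() -> VariantPanel:
    """The 28-site synthetic analysis panel (see module docstring)."""
    variants = []
    for i, (vid, pos, vclass, role, _) in enumerate(_PANEL_TABLE):
        ref, alt = _SPECIAL_ALLELES.get(
            vid, (_BASES[i % 4], _BASES[(i + 1) % 4])
        )
        variants.append(PanelVariant(
            variant_id=vid, chrom=REGION_CHROM, pos=pos, ref_allele=ref,
            alt_allele=alt, annotation_class=vclass, role=role,
        ))
    return VariantPanel(variants, build="Hg38")


@dataclass(frozen=True)
class Founder:
    label: str
    haplotype: np.ndarray
    frequency: float


def build_default_founders(
    panel: Optional[VariantPanel] = None,
    frequencies: Optional[dict[str, float]] = None,
) -> list[Founder]:
    """The five founder haplotypes of the default scenario.

    G0/EIK, G0/KIK, G1/EIK, G2/EIK and M1-G0/KIK (the latter carrying the
    three exclusive intronic markers). No founder combines M1 with a G1 tag
    — no M1-G1 haplotype has ever been observed.
    """
    panel = panel or default_panel()
    for role in ("G1_snp1", "G1_snp2", "G2_del", "M1", "bg150", "bg228", "bg255"):
        if not panel.has_role(role):
            raise ConfigurationError(f"founder panel lacks role tag {role}")
    freqs = frequencies or DEFAULT_FREQUENCIES
    if len(panel) != len(_PANEL_TABLE) or any(
        panel[i].variant_id != _PANEL_TABLE[i][0] for i in range(len(panel))
    ):
        raise ConfigurationError(
            "build_default_founders requires the default synthetic panel"
        )
    out = []
    for col, label in enumerate(FOUNDER_ORDER):
        hap = np.array([row[4][col] for row in _PANEL_TABLE], dtype=np.uint8)
        out.append(Founder(label=label, haplotype=hap,
                           frequency=float(freqs[label])))
    return out


@dataclass
class SimConfig:
    """Parameters of a forward multinomial cohort simulation.

    ``crossover_pos`` fixes the recombination point of the M1-G2 founder;
    None draws it uniformly from the open (M1, G2) interval. Sites at
    positions strictly below the crossover come from parent A (M1-G0/KIK),
    all others from parent B (G2/EIK). ``per_site_flip_rate`` applies
    independent allele flips after construction (default 0: noise-free).
    """

    panel: VariantPanel = field(default_factory=default_panel)
    founders: Optional[list[Founder]] = None
    recombinant_frequency: float = DEFAULT_FREQUENCIES[RECOMBINANT_LABEL]
    recomb_parent_a: str = "M1G0_KIK"
    recomb_parent_b: str = "G2_EIK"
    crossover_pos: Optional[int] = None
    n_individuals: int = 500
    per_site_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders is None:
            base = build_default_founders(self.panel)
            scale = (1.0 - self.recombinant_frequency) / sum(
                f.frequency for f in base
            )
            # keep founder proportions, rescale so totals (with the
            # recombinant) sum to one even for a non-default recombinant freq
            self.founders = [
                Founder(f.label, f.haplotype, f.frequency * scale) for f in base
            ]
        if self.n_individuals < 0:
            raise ValidationError("n_individuals must be >= 0")
        if not 0.0 <= self.per_site_flip_rate < 0.5:
            raise ValidationError("per_site_flip_rate must be in [0, 0.5)")
        if not 0.0 <= self.recombinant_frequency < 1.0:
            raise ValidationError("recombinant_frequency must be in [0, 1)")
        total = sum(f.frequency for f in self.founders) + self.recombinant_frequency
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"founder + recombinant frequencies sum to {total}, not 1"
            )
        labels = [f.label for f in self.founders]
        for parent in (self.recomb_parent_a, self.recomb_parent_b):
            if self.recombinant_frequency > 0 and parent not in labels:
                raise ValidationError(f"unknown recombination parent {parent}")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    founder_labels: np.ndarray        # (n_individuals, 2) of founder labels
    crossover_pos: Optional[int]      # None when no recombinant is modeled
    pre_noise_alleles: np.ndarray     # (n, 2, L) before per-site flips
    recombinant_haplotype: Optional[np.ndarray]
    config: SimConfig


def _make_recombinant(cfg: SimConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, int]:
    by_label = {f.label: f.haplotype for f in cfg.founders}
    a = by_label[cfg.recomb_parent_a]
    b = by_label[cfg.recomb_parent_b]
    m1_pos = int(cfg.panel.positions[cfg.panel.index_of_role("M1")])
    g2_pos = int(cfg.panel.positions[cfg.panel.index_of_role("G2_del")])
    if cfg.crossover_pos is not None:
        cross = int(cfg.crossover_pos)
        if not m1_pos < cross < g2_pos:
            raise ValidationError(
                f"crossover_pos must lie strictly within ({m1_pos}, {g2_pos})"
            )
    else:
        cross = int(rng.integers(m1_pos + 1, g2_pos))
    rec = np.where(cfg.panel.positions < cross, a, b).astype(np.uint8)
    return rec, cross


def simulate_population(cfg: SimConfig) -> tuple[HaplotypeMatrix, SimTruth]:
    """Draw 2N haplotypes multinomially from founders plus the recombinant.

    Fully reproducible from ``cfg.seed``: the crossover draw (when not
    fixed), the lineage assignment and the noise flips all flow from one
    generator.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(cfg.panel)
    pool = [f.haplotype for f in cfg.founders]
    probs = [f.frequency for f in cfg.founders]
    labels = [f.label for f in cfg.founders]
    cross: Optional[int] = None
    rec: Optional[np.ndarray] = None
    if cfg.recombinant_frequency > 0:
        rec, cross = _make_recombinant(cfg, rng)
        pool.append(rec)
        probs.append(cfg.recombinant_frequency)
        labels.append(RECOMBINANT_LABEL)
    pool_arr = np.asarray(pool, dtype=np.uint8)
    probs_arr = np.asarray(probs, dtype=float)

    n = cfg.n_individuals
    draw = rng.choice(len(pool_arr), size=2 * n, p=probs_arr)
    alleles = pool_arr[draw].reshape(n, 2, L)
    founder_labels = np.array([labels[i] for i in draw]).reshape(n, 2)
    pre_noise = alleles.copy()
    if cfg.per_site_flip_rate > 0 and n > 0:
        flips = rng.random(alleles.shape) < cfg.per_site_flip_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.uint8)

    sample_ids = [f"SIM{i:05d}" for i in range(n)]
    hm = HaplotypeMatrix(panel=cfg.panel, sample_ids=sample_ids,
                         alleles=alleles,
                         populations=["SYN"] * n)
    truth = SimTruth(founder_labels=founder_labels, crossover_pos=cross,
                     pre_noise_alleles=pre_noise,
                     recombinant_haplotype=rec, config=cfg)
    return hm, truth


def degrade_to_presence(
    hm: HaplotypeMatrix,
    sample_id: str,
    mean_depth: float,
    seed: int,
    min_alt_reads: int = 1,
) -> PresenceProfile:
    """Ancient-DNA-style degradation of one sample to a presence profile.

    Per-site read depth is Poisson(``mean_depth``); each read is drawn from
    one of the sample's two haplotypes with equal probability, so a
    heterozygous alternate allele is detected with probability
    1 - E[(1/2)^depth] = 1 - exp(-mean_depth/2).
    """
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    s = hm.sample_index(sample_id)
    L = hm.n_sites
    alt = np.zeros(L, dtype=np.int64)
    ref = np.zeros(L, dtype=np.int64)
    depths = rng.poisson(mean_depth, size=L)
    for site in range(L):
        d = int(depths[site])
        if d == 0:
            continue
        haps = rng.integers(0, 2, size=d)
        n_alt = int(hm.alleles[s, haps, site].sum())
        alt[site] = n_alt
        ref[site] = d - n_alt
    return presence_from_counts(hm.panel, alt, ref, min_alt_reads=min_alt_reads)
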