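"""End-to-end orchestration: extract → tally → exclusivity → cluster → LD →
four-gamete → breakpoint inference → recombination-map overlay.

Recombinant candidates are the unique haplotypes carrying both the M1 and
G2 tag alleles; their candidate parents are the M1-carrying non-G2 records
(left segment) and the G2 non-M1 records (right segment). All numeric
output is printed at 6 significant digits so re-running an identical
configuration yields byte-identical files.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .haplotypes import HaplotypeMatrix
from .linkage import four_gamete, ld_matrix
from .panel import load_panel
from .breakpoint import FEASIBLE, infer_breakpoint, map_rate_in_interval
from .recombmap import RecombMap, read_recomb_map
from .repertoire import (HaplotypeRecord, cluster_haplotypes,
                         exclusive_variants, tally_unique)
from .vcfio import extract_haplotypes

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Paths and policy switches of a full pipeline run."""

    vcf: str
    panel: str
    out_dir: str
    recomb_map: Optional[str] = None
    keep_samples: Optional[list[str]] = None
    exclude_samples: Optional[list[str]] = None
    missing_site: str = "error"
    unphased: str = "error"
    missing_genotype: str = "drop-sample"
    linkage_method: str = "complete"
    ld_stat: str = "r2"
    min_fraction_a: float = 1.0
    max_mismatch: int = 0
    min_count: int = 1
    exclusive_classes: Optional[list[str]] = field(
        default_factory=lambda: ["intronic"]
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.vcf, self.panel, self.recomb_map):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def _records_frame(records: Sequence[HaplotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "alleles": r.allele_string,
            "count": r.count,
            "risk": r.classification.risk,
            "m1": r.classification.m1,
            "background": r.classification.background,
            "conflict": r.classification.conflict,
            "carrier_samples": ",".join(r.carrier_samples),
        }
        for r in records
    ])


def analyze_matrix(
    hm: HaplotypeMatrix,
    recomb_map: Optional[RecombMap] = None,
    linkage_method: str = "complete",
    ld_stat: str = "r2",
    min_fraction_a: float = 1.0,
    max_mismatch: int = 0,
    min_count: int = 1,
    exclusive_classes: Optional[Sequence[str]] = ("intronic",),
) -> dict:
    """Run every analysis stage on an in-memory cohort; returns a result
    dict (records, exclusive set, tree, LD frame, four-gamete, breakpoints)."""
    panel = hm.panel
    records = tally_unique(hm)

    m1_recs = [r for r in records
               if r.classification.m1 and r.classification.risk != "G2"]
    g2_recs = [r for r in records
               if not r.classification.m1 and r.classification.risk == "G2"]
    candidates = [(i, r) for i, r in enumerate(records)
                  if r.classification.m1 and r.classification.risk == "G2"]

    exclusive: Optional[set] = None
    if m1_recs and g2_recs:
        exclusive = exclusive_variants(
            records, panel,
            group_a=lambda c: c.m1,
            group_b=lambda c: (not c.m1) and c.risk in ("G1", "G2"),
            min_fraction_a=min_fraction_a,
            annotation_classes=exclusive_classes,
        )

    tree = None
    if len(records) >= 2:
        tree = cluster_haplotypes(records, method=linkage_method)

    ld = None
    freqs = hm.allele_frequencies()
    if int(((freqs > 0) & (freqs < 1)).sum()) >= 2:
        ld = ld_matrix(hm, stat=ld_stat)

    fg = None
    m1_idx = panel.index_of_role("M1") if panel.has_role("M1") else None
    g2_idx = panel.index_of_role("G2_del") if panel.has_role("G2_del") else None
    if m1_idx is not None and g2_idx is not None:
        fg = four_gamete(hm, m1_idx, g2_idx, min_count=min_count)

    breakpoints = []
    for rec_index, r in candidates:
        if not (m1_recs and g2_recs):
            break
        bp = infer_breakpoint(
            r.alleles,
            [p.alleles for p in m1_recs],
            [p.alleles for p in g2_recs],
            panel,
            max_mismatch=max_mismatch,
        )
        rate = None
        if (recomb_map is not None and bp.status == FEASIBLE):
            rate = map_rate_in_interval(recomb_map, panel[0].chrom,
                                        bp.left_pos, bp.right_pos)
        breakpoints.append({
            "record_index": rec_index,
            "count": r.count,
            "status": bp.status,
            "left_pos": bp.left_pos,
            "right_pos": bp.right_pos,
            "width": bp.width,
            "parent_a": bp.parent_a_id,
            "parent_b": bp.parent_b_id,
            "mismatches": bp.mismatches,
            "map_rate_cm_mb": rate,
        })
    if not candidates:
        logger.info("breakpoint stage: no M1-G2 recombinant candidates")

    return {
        "records": records,
        "exclusive": exclusive,
        "tree": tree,
        "ld": ld,
        "four_gamete": fg,
        "breakpoints": breakpoints,
        "n_candidates": len(candidates),
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the pipeline from files and write the report bundle.

    Outputs under ``config.out_dir``: haplotypes.tsv, exclusive.tsv,
    tree.nwk, ld_<stat>.tsv, four_gamete.tsv, breakpoints.tsv and
    run_log.json (versions, seed, policies).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel)
    hm = extract_haplotypes(
        config.vcf, panel,
        keep_samples=config.keep_samples,
        exclude_samples=config.exclude_samples,
        missing_site=config.missing_site,
        unphased=config.unphased,
        missing_genotype=config.missing_genotype,
    )
    rmap = read_recomb_map(config.recomb_map) if config.recomb_map else None
    res = analyze_matrix(
        hm, recomb_map=rmap,
        linkage_method=config.linkage_method, ld_stat=config.ld_stat,
        min_fraction_a=config.min_fraction_a,
        max_mismatch=config.max_mismatch, min_count=config.min_count,
        exclusive_classes=config.exclusive_classes,
    )

    _records_frame(res["records"]).to_csv(out / "haplotypes.tsv", sep="\t",
                                          index=False)
    pd.DataFrame({"variant_id": sorted(res["exclusive"] or [])}).to_csv(
        out / "exclusive.tsv", sep="\t", index=False)
    if res["tree"] is not None:
        (out / "tree.nwk").write_text(res["tree"].to_newick() + "\n")
    if res["ld"] is not None:
        res["ld"].to_csv(out / f"ld_{config.ld_stat}.tsv", sep="\t",
                         float_format=_FLOAT_FMT)
    if res["four_gamete"] is not None:
        fg = res["four_gamete"]
        pd.DataFrame([{"pair": "M1,G2_del", "all_four": fg.all_four,
                       **fg.gamete_counts}]).to_csv(
            out / "four_gamete.tsv", sep="\t", index=False)
    bp_df = pd.DataFrame(
        res["breakpoints"],
        columns=["record_index", "count", "status", "left_pos", "right_pos",
                 "width", "parent_a", "parent_b", "mismatches",
                 "map_rate_cm_mb"],
    )
    bp_df.to_csv(out / "breakpoints.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)

    log = {
        "apol1hap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "n_samples": hm.n_samples,
        "n_sites": hm.n_sites,
        "policies": {
            "missing_site": config.missing_site,
            "unphased": config.unphased,
            "missing_genotype": config.missing_genotype,
            "linkage_method": config.linkage_method,
            "ld_stat": config.ld_stat,
            "min_fraction_a": config.min_fraction_a,
            "max_mismatch": config.max_mismatch,
            "min_count": config.min_count,
        },
        "n_recombinant_candidates": res["n_candidates"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True)
                                      + "\n")
    return res
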