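"""Phased VCF input/output over a variant panel.

Reading uses cyvcf2 and matches VCF records to panel variants by
(chrom, pos, REF, ALT). The panel defines biallelic markers: in a
multiallelic record the panel alternate is located among the ALTs, and any
haplotype carrying a *different* alternate allele at that site is an
allele-mismatch error (never silently recoded).

Policies (all explicit, none silent):

missing_site
    ``"error"`` (default): a panel variant absent from the VCF aborts.
    ``"drop-site"``: the analysis proceeds on the reduced panel, logged.
unphased
    ``"error"`` (default) on a '/'-separated genotype at a panel site;
    ``"drop-sample"`` removes the offending sample with a log line.
missing_genotype
    ``"drop-sample"`` (default) on ``./.``; ``"error"`` aborts.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import (AlleleMismatchError, DataError, MissingSiteError,
                     UnphasedGenotypeError, ValidationError)
from .haplotypes import HaplotypeMatrix
from .panel import VariantPanel

logger = logging.getLogger(__name__)

_MISSING = -1


def extract_haplotypes(
    vcf_path,
    panel: VariantPanel,
    keep_samples: Optional[Sequence[str]] = None,
    exclude_samples: Optional[Sequence[str]] = None,
    populations: Optional[dict[str, str]] = None,
    missing_site: str = "error",
    unphased: str = "error",
    missing_genotype: str = "drop-sample",
) -> HaplotypeMatrix:
    """Split phased genotypes at the panel sites into a binary haplotype matrix.

    Column order follows the panel, not the VCF record order. Samples listed
    in ``exclude_samples`` (e.g. known APOL1 copy-number-variant carriers,
    supplied as data) are dropped before any policy is applied.
    """
    if missing_site not in ("error", "drop-site"):
        raise ValidationError(f"unknown missing_site policy {missing_site!r}")
    if unphased not in ("error", "drop-sample"):
        raise ValidationError(f"unknown unphased policy {unphased!r}")
    if missing_genotype not in ("error", "drop-sample"):
        raise ValidationError(f"unknown missing_genotype policy {missing_genotype!r}")

    vcf = VCF(str(vcf_path), gts012=False, lazy=False)
    try:
        samples = list(vcf.samples)
        if keep_samples is not None:
            keep = [s for s in samples if s in set(keep_samples)]
        else:
            keep = samples
        if exclude_samples:
            excl = set(exclude_samples)
            keep = [s for s in keep if s not in excl]
        if not keep:
            raise ValidationError("no samples retained after include/exclude filters")
        col_of = {s: i for i, s in enumerate(samples)}
        keep_cols = np.array([col_of[s] for s in keep])

        site_of = {(v.chrom, v.pos): i for i, v in enumerate(panel)}
        L = len(panel)
        n = len(keep)
        alleles = np.full((n, 2, L), _MISSING, dtype=np.int16)
        seen = np.zeros(L, dtype=bool)
        drop_sample_reasons: dict[int, str] = {}

        for rec in vcf:
            key = (rec.CHROM, rec.POS)
            site = site_of.get(key)
            if site is None:
                continue
            pv = panel[site]
            if seen[site]:
                raise DataError(f"duplicate VCF record at panel site {pv.variant_id}")
            if rec.REF != pv.ref_allele:
                raise AlleleMismatchError(
                    f"{pv.variant_id}: VCF REF {rec.REF} != panel ref {pv.ref_allele}"
                )
            alts = list(rec.ALT)
            if pv.alt_allele not in alts:
                raise AlleleMismatchError(
                    f"{pv.variant_id}: panel alt {pv.alt_allele} not among VCF ALTs {alts}"
                )
            want_code = alts.index(pv.alt_allele) + 1
            seen[site] = True

            gts = rec.genotypes  # per sample: [allele0, allele1, ..., phased]
            for row, col in enumerate(keep_cols):
                gt = gts[col]
                calls, phased = gt[:-1], gt[-1]
                if len(calls) != 2:
                    raise DataError(
                        f"{pv.variant_id}, sample {keep[row]}: non-diploid genotype"
                    )
                if any(c == _MISSING for c in calls):
                    if missing_genotype == "error":
                        raise DataError(
                            f"{pv.variant_id}, sample {keep[row]}: missing genotype"
                        )
                    drop_sample_reasons.setdefault(row, f"./. at {pv.variant_id}")
                    continue
                if not phased and calls[0] != calls[1]:
                    if unphased == "error":
                        raise UnphasedGenotypeError(
                            f"{pv.variant_id}, sample {keep[row]}: unphased genotype"
                        )
                    drop_sample_reasons.setdefault(
                        row, f"unphased at {pv.variant_id}"
                    )
                    continue
                for h, c in enumerate(calls):
                    if c == 0:
                        alleles[row, h, site] = 0
                    elif c == want_code:
                        alleles[row, h, site] = 1
                    else:
                        raise AlleleMismatchError(
                            f"{pv.variant_id}, sample {keep[row]}: haplotype carries "
                            f"ALT allele {alts[c - 1]} not in the panel"
                        )
    finally:
        vcf.close()

    out_panel = panel
    if not seen.all():
        missing_ids = [panel[i].variant_id for i in np.nonzero(~seen)[0]]
        if missing_site == "error":
            raise MissingSiteError(
                f"panel variants absent from {vcf_path}: {missing_ids}"
            )
        logger.warning("dropping %d panel site(s) absent from VCF: %s",
                       len(missing_ids), missing_ids)
        keep_sites = np.nonzero(seen)[0]
        if keep_sites.size == 0:
            raise MissingSiteError("no panel variant found in the VCF")
        out_panel = panel.subset(keep_sites.tolist())
        alleles = alleles[:, :, keep_sites]

    if drop_sample_reasons:
        for row, reason in sorted(drop_sample_reasons.items()):
            logger.warning("dropping sample %s: %s", keep[row], reason)
        keep_rows = [i for i in range(n) if i not in drop_sample_reasons]
        if not keep_rows:
            raise DataError("all samples dropped by genotype policies")
        alleles = alleles[keep_rows]
        keep = [keep[i] for i in keep_rows]

    if (alleles == _MISSING).any():  # pragma: no cover - guarded above
        raise DataError("internal error: unfilled genotype cells")
    pops = [populations.get(s, "NA") for s in keep] if populations else None
    return HaplotypeMatrix(panel=out_panel, sample_ids=keep,
                           alleles=alleles.astype(np.uint8),
                           populations=pops or [])


def write_vcf(hm: HaplotypeMatrix, path) -> None:
    """Write the matrix as a phased VCF v4.2 text file ('|' GT separators).

    Round-trips with :func:`extract_haplotypes`: reading the written file
    against the same panel reproduces ``hm.alleles`` exactly.
    """
    panel = hm.panel
    chroms: dict[str, int] = {}
    for v in panel:
        end = v.pos + max(len(v.ref_allele), len(v.alt_allele))
        chroms[v.chrom] = max(chroms.get(v.chrom, 0), end + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=apol1hap\n")
        for chrom, length in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT"] + list(hm.sample_ids)
        fh.write("\t".join(cols) + "\n")
        for site, v in enumerate(panel):
            gts = [f"{a}|{b}" for a, b in hm.alleles[:, :, site]]
            row = [v.chrom, str(v.pos), v.variant_id, v.ref_allele,
                   v.alt_allele, ".", "PASS", ".", "GT"] + gts
            fh.write("\t".join(row) + "\n")
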