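"""Readers and writers for the tab-separated interchange formats.

Count table (one row per site): chrom, pos, ref, alt, t_depth, t_alt,
n_depth, n_alt.  Segment table: chrom, start, end, cn_normal, cn_tumour
[, cn_major] with 1-based inclusive coordinates.  Malformed rows are skipped
with a logged count, never silently.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from .caller import IndelCandidate
from .model import CopyNumberSegment, SiteObservation
from .simbench import TruthRecord

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "t_depth", "t_alt", "n_depth", "n_alt"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "cn_normal", "cn_tumour"]


def read_count_table(path: str) -> list[SiteObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} missing columns: {missing}")
    sites = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            sites.append(
                SiteObservation(
                    chrom=str(row.chrom), pos=int(row.pos),
                    ref_allele=str(row.ref), alt_allele=str(row.alt),
                    tumour_depth=int(row.t_depth), tumour_alt=int(row.t_alt),
                    normal_depth=int(row.n_depth), normal_alt=int(row.n_alt),
                )
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed count row: %s (%s)", tuple(row), exc)
    if skipped:
        logger.warning("skipped %d malformed row(s) in %s", skipped, path)
    return sites


def write_count_table(sites: Sequence[SiteObservation], path: str) -> None:
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref_allele for s in sites],
            "alt": [s.alt_allele for s in sites],
            "t_depth": [s.tumour_depth for s in sites],
            "t_alt": [s.tumour_alt for s in sites],
            "n_depth": [s.normal_depth for s in sites],
            "n_alt": [s.normal_alt for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table {path} missing columns: {missing}")
    segs = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            cn_major = getattr(row, "cn_major", None)
            segs.append(
                CopyNumberSegment(
                    chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                    cn_normal=int(row.cn_normal), cn_tumour=int(row.cn_tumour),
                    cn_major=int(cn_major) if cn_major is not None and not pd.isna(cn_major) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            skipped += 1
            logger.warning("skipping malformed segment row: %s (%s)", tuple(row), exc)
    if skipped:
        logger.warning("skipped %d malformed segment row(s) in %s", skipped, path)
    return segs


def write_truth_table(truths: Sequence[TruthRecord], path: str) -> None:
    df = pd.DataFrame(
        {
            "chrom": [t.chrom for t in truths],
            "pos": [t.pos for t in truths],
            "true_class": [t.true_class for t in truths],
            "k_g": [t.true_pair.k_g for t in truths],
            "k_t": [t.true_pair.k_t for t in truths],
            "true_tumour_vaf": [t.true_tumour_vaf for t in truths],
            "alpha_t": [t.alpha_t for t in truths],
            "alpha_n": [t.alpha_n for t in truths],
            "t_depth": [t.t_depth for t in truths],
            "n_depth": [t.n_depth for t in truths],
            "error": [t.error for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_assignments(path: str) -> dict[str, str]:
    """Variant-to-clone assignment TSV (columns: variant_id, clone_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant_id", "clone_id"):
        if col not in df.columns:
            raise ValueError(f"assignment table {path} missing column {col}")
    return dict(zip(df["variant_id"], df["clone_id"]))


def read_indel_candidates(
    vcf_path: str,
    counts: Sequence[SiteObservation],
    normal_flag: str = "F015",
) -> list[IndelCandidate]:
    """Indel candidates from an upstream caller's VCF plus the count table.

    A candidate is marked flagged_in_normal when the upstream FILTER field
    contains ``normal_flag`` (the "present in matched normal" rejection).
    Read evidence is joined from the count table by (chrom, pos).
    """
    from cyvcf2 import VCF

    by_site = {(s.chrom, s.pos): s for s in counts}
    out = []
    unmatched = 0
    for rec in VCF(vcf_path):
        key = (rec.CHROM, rec.POS)
        site = by_site.get(key)
        if site is None:
            unmatched += 1
            continue
        filters = rec.FILTER or ""
        flagged = normal_flag in filters.split(";")
        tumour_vaf = site.tumour_alt / site.tumour_depth if site.tumour_depth else 0.0
        out.append(
            IndelCandidate(
                chrom=rec.CHROM, pos=rec.POS,
                ref_allele=rec.REF, alt_allele=rec.ALT[0] if rec.ALT else ".",
                flagged_in_normal=flagged,
                tumour_vaf=tumour_vaf,
                normal_alt=site.normal_alt,
                normal_depth=site.normal_depth,
            )
        )
    if unmatched:
        logger.warning("%d VCF record(s) had no matching count-table row", unmatched)
    return out
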