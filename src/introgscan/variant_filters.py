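"""Hard filtering of variant calls before introgression analysis.

Implements three sequential cleaning steps commonly applied to joint
genotype call sets:

1. site-level hard filters on annotation values (QUAL, MQ, QD, FS, SOR,
   MQRankSum, ReadPosRankSum), with separate rule sets for SNVs and
   indels;
2. genotype-level masking of low-confidence calls (GQ < 20 or DP < 3
   set to missing);
3. removal of SNVs within a small window (default 3 bp) of an indel.

All threshold comparisons are strict: a site sitting exactly on a
cutoff passes. Proximity to an indel is measured against the indel's
reference-affected interval (a deletion at position p with REF length L
occupies [p, p+L-1]; an insertion occupies only its anchor base), not
just the anchor position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenotypeCall",
    "SiteRecord",
    "FilterThresholds",
    "DEFAULT_THRESHOLDS",
    "apply_site_hard_filters",
    "mask_low_quality_genotypes",
    "remove_snvs_near_indels",
    "read_vcf_sites",
    "write_vcf_sites",
]

logger = logging.getLogger(__name__)

MISSING = -1  # allele code for a missing call


@dataclass
class GenotypeCall:
    """One diploid call: allele indices (0=ref, 1..=alt, -1=missing)."""

    alleles: tuple
    gq: Optional[int] = None
    dp: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return all(a == MISSING for a in self.alleles)

    def as_missing(self) -> "GenotypeCall":
        return GenotypeCall(tuple(MISSING for _ in self.alleles), self.gq, self.dp)


@dataclass
class SiteRecord:
    """One VCF record with the annotations the hard filters consult."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple
    qual: Optional[float] = None
    annotations: dict = field(default_factory=dict)
    genotypes: list = field(default_factory=list)
    site_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def site_type(self) -> str:
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "SNV"
        return "indel"

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def affected_interval(self) -> tuple:
        """Reference interval this variant touches (1-based inclusive).

        Deletions span their deleted bases; SNVs and insertions occupy
        their anchor base only.
        """
        return (self.pos, self.pos + len(self.ref) - 1)


# (metric, comparator, cutoff); "lt" removes when value < cutoff,
# "gt" removes when value > cutoff. Order fixes the reported reason.
SNV_RULES = (
    ("QUAL", "lt", 30.0),
    ("MQ", "lt", 40.0),
    ("QD", "lt", 2.0),
    ("FS", "gt", 60.0),
    ("SOR", "gt", 3.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
)

INDEL_RULES = (
    ("QUAL", "lt", 30.0),
    ("QD", "lt", 2.0),
    ("FS", "gt", 200.0),
    ("ReadPosRankSum", "lt", -20.0),
)


@dataclass(frozen=True)
class FilterThresholds:
    snv_rules: tuple = SNV_RULES
    indel_rules: tuple = INDEL_RULES
    gq_min: int = 20
    dp_min: int = 3
    indel_window: int = 3

    def __post_init__(self) -> None:
        if self.indel_window < 0:
            raise ValueError("indel_window must be >= 0")


DEFAULT_THRESHOLDS = FilterThresholds()


def _site_metric(site: SiteRecord, metric: str) -> Optional[float]:
    if metric == "QUAL":
        return site.qual
    return site.annotations.get(metric)


def _first_failing_rule(site: SiteRecord, rules) -> Optional[str]:
    for metric, comparator, cutoff in rules:
        value = _site_metric(site, metric)
        if value is None:
            logger.debug(
                "site %s:%d missing annotation %s; rule skipped",
                site.chrom, site.pos, metric,
            )
            continue
        if comparator == "lt" and value < cutoff:
            return metric
        if comparator == "gt" and value > cutoff:
            return metric
    return None


def apply_site_hard_filters(
    sites: Sequence[SiteRecord],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
):
    """Split sites into (passing, removed) by the annotation hard filters.

    Returns ``(kept, removed)`` where ``removed`` is a list of
    ``(site, reason)`` pairs tagged with the first failing metric in
    rule order. Sites with an annotation absent are not removed by that
    rule (the rule is skipped and logged).
    """
    kept: list[SiteRecord] = []
    removed: list[tuple] = []
    for site in sites:
        stype = site.site_type
        if stype == "SNV":
            rules = thresholds.snv_rules
        elif stype == "indel":
            rules = thresholds.indel_rules
        else:  # pragma: no cover - site_type is computed
            raise ValueError(f"unknown site type {stype!r}")
        reason = _first_failing_rule(site, rules)
        if reason is None:
            kept.append(site)
        else:
            removed.append((site, reason))
    return kept, removed


def mask_low_quality_genotypes(
    sites: Sequence[SiteRecord], gq_min: int = 20, dp_min: int = 3
):
    """Set low-confidence genotype calls to missing.

    A call is masked iff GQ < gq_min or DP < dp_min; calls with GQ or
    DP absent are masked (conservative). Returns ``(new_sites,
    n_masked)``; input records are not modified.
    """
    n_masked = 0
    out: list[SiteRecord] = []
    for site in sites:
        new_gts = []
        for call in site.genotypes:
            fails = (
                call.gq is None
                or call.dp is None
                or call.gq < gq_min
                or call.dp < dp_min
            )
            if fails and not call.is_missing:
                n_masked += 1
                new_gts.append(call.as_missing())
            elif fails:
                new_gts.append(call.as_missing())
            else:
                new_gts.append(call)
        out.append(replace(site, genotypes=new_gts))
    return out, n_masked


def _check_sorted(sites: Sequence[SiteRecord], what: str) -> None:
    prev = None
    for s in sites:
        key = (s.chrom, s.pos)
        if prev is not None and key < prev:
            raise ValueError(f"{what} not sorted by (chrom, pos) at {key}")
        prev = key


def remove_snvs_near_indels(
    snvs: Sequence[SiteRecord],
    indels: Sequence[SiteRecord],
    window: int = 3,
):
    """Drop SNVs within ``window`` bp of any indel's affected interval.

    Both inputs must be sorted by (chrom, pos). The distance between an
    SNV at position p and an indel interval [s, e] is 0 if s <= p <= e,
    else min(|p-s|, |p-e|); the SNV is removed iff distance <= window.
    Returns ``(kept, removed)``.
    """
    _check_sorted(snvs, "SNVs")
    _check_sorted(indels, "indels")

    # per-chromosome padded intervals, merged scan
    by_chrom: dict[str, list[tuple]] = {}
    for ind in indels:
        s, e = ind.affected_interval()
        by_chrom.setdefault(ind.chrom, []).append((s - window, e + window))

    kept: list[SiteRecord] = []
    removed: list[SiteRecord] = []
    for snv in snvs:
        intervals = by_chrom.get(snv.chrom, ())
        hit = any(lo <= snv.pos <= hi for lo, hi in intervals)
        (removed if hit else kept).append(snv)
    return kept, removed


# ---------------------------------------------------------------------------
# VCF I/O

_SITE_METRICS = ("MQ", "QD", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


def read_vcf_sites(path) -> tuple:
    """Read a VCF into SiteRecords. Returns (sites, sample_names)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[SiteRecord] = []
    for v in vcf:
        annotations = {}
        for m in _SITE_METRICS:
            val = v.INFO.get(m)
            if val is not None:
                annotations[m] = float(val)
        gts = []
        gq = v.format("GQ")
        dp = v.format("DP")
        for i, g in enumerate(v.genotypes):
            alleles = tuple(MISSING if a == -1 else int(a) for a in g[:-1])
            gts.append(
                GenotypeCall(
                    alleles,
                    gq=None if gq is None or gq[i][0] < 0 else int(gq[i][0]),
                    dp=None if dp is None or dp[i][0] < 0 else int(dp[i][0]),
                )
            )
        sites.append(
            SiteRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=v.QUAL,
                annotations=annotations,
                genotypes=gts,
                site_id=v.ID or ".",
            )
        )
    return sites, samples


def write_vcf_sites(
    sites: Sequence[SiteRecord],
    samples: Sequence[str],
    path,
    filter_tags: Optional[dict] = None,
) -> None:
    """Write SiteRecords as VCF v4.2 text.

    ``filter_tags`` maps id(site) -> reason string for the FILTER
    column; untagged sites get PASS. Masked genotypes are written as
    ``./.``.
    """
    filter_tags = filter_tags or {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for m in _SITE_METRICS:
            fh.write(f'##INFO=<ID={m},Number=1,Type=Float,Description="{m}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        chroms = sorted({s.chrom for s in sites})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + list(samples)
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            info = ";".join(
                f"{k}={v:g}" for k, v in s.annotations.items()
            ) or "."
            tag = filter_tags.get(id(s), "PASS")
            fields = [
                s.chrom, str(s.pos), s.site_id, s.ref,
                ",".join(s.alts) or ".",
                "." if s.qual is None else f"{s.qual:g}",
                tag, info, "GT:GQ:DP",
            ]
            for call in s.genotypes:
                gt = "/".join("." if a == MISSING else str(a)
                              for a in call.alleles)
                gq = "." if call.gq is None else str(call.gq)
                dp = "." if call.dp is None else str(call.dp)
                fields.append(f"{gt}:{gq}:{dp}")
            fh.write("\t".join(fields) + "\n")
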