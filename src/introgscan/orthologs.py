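"""Coverage-based single-copy ortholog selection and CDS alignments.

Single-copy status is inferred purely from read depth: a gene is kept
only if, in every sample, its mean depth is at least 10x, no more than
twice that sample's exon-wide baseline depth (putative duplications),
and at least 75% of its bases are covered by 10 or more reads. Kept
genes are then thinned so consecutive loci on a chromosome are at least
20 kb apart (greedy left-to-right scan), reducing nonindependence.

Per-gene alignments are built by substituting filtered variants into
the reference CDS: SNVs replace the reference base (heterozygotes as
IUPAC ambiguity codes), deleted bases become ``-``, and insertions are
ignored so columns stay in 1:1 correspondence with reference CDS
positions. Missing genotypes keep the reference base and are recorded
in a sidecar mask. Alignments are dropped if they contain no
parsimony-informative site or their length is not a multiple of three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_filters import MISSING, SiteRecord

__all__ = [
    "GeneModel",
    "CdsAlignment",
    "read_gene_models",
    "read_coverage_table",
    "filter_genes_by_coverage",
    "enforce_min_spacing",
    "build_cds_alignment",
    "count_parsimony_informative_sites",
    "alignment_passes_filters",
    "write_fasta",
    "read_fasta",
]

logger = logging.getLogger(__name__)

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
}

UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class GeneModel:
    """A gene with 1-based inclusive coordinates and CDS intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    cds_intervals: tuple = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        prev_end = None
        for s, e in self.cds_intervals:
            if s > e:
                raise ValueError(f"{self.gene_id}: CDS interval {s}>{e}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap/unsorted")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def cds_column(self, pos: int) -> Optional[int]:
        """0-based CDS column of reference position ``pos``, or None."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
        return None


@dataclass
class CdsAlignment:
    """Rectangular per-gene alignment over reference CDS columns."""

    gene_id: str
    sequences: Dict[str, str]
    mask: Dict[str, str] = field(default_factory=dict)  # 'N' = masked column

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: ragged alignment {lengths}")
        if lengths and next(iter(lengths)) == 0:
            raise ValueError(f"{self.gene_id}: empty alignment")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


# ---------------------------------------------------------------------------
# gene model I/O

def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GFF3 (1-based).

    Dialect chosen by extension (.bed vs .gff/.gff3); validated on load.
    For GFF3, ``gene`` features define the span and ``CDS`` features
    with a matching Parent/ID define the coding intervals; for BED, the
    whole span is used as a single CDS interval.
    """
    path = str(path)
    if path.endswith(".bed"):
        return _read_bed(path)
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    raise ValueError(f"cannot infer gene-model dialect from extension: {path}")


def _read_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            start1 = start0 + 1
            genes.append(GeneModel(name, chrom, start1, end,
                                   ((start1, end),), strand))
    return genes


def _gff_attrs(s: str) -> dict:
    out = {}
    for item in s.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path) -> list[GeneModel]:
    spans: dict[str, tuple] = {}
    cds: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attrs = _gff_attrs(attrs)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"gene feature without ID: {line!r}")
                spans[gid] = (chrom, int(start), int(end), strand)
            elif ftype == "CDS":
                parent = attrs.get("Parent") or attrs.get("ID")
                if parent:
                    cds.setdefault(parent, []).append((int(start), int(end)))
    genes = []
    for gid, (chrom, start, end, strand) in spans.items():
        intervals = tuple(sorted(cds.get(gid, [(start, end)])))
        genes.append(GeneModel(gid, chrom, start, end, intervals, strand))
    return genes


# ---------------------------------------------------------------------------
# coverage filtering

def read_coverage_table(path) -> pd.DataFrame:
    """Read the tab-separated coverage summary
    (gene_id, sample, mean_depth, frac_ge10)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample", "mean_depth", "frac_ge10"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return df


def filter_genes_by_coverage(
    genes: Sequence[GeneModel],
    coverage: pd.DataFrame,
    baselines: Mapping[str, float],
    min_depth: float = 10.0,
    max_baseline_ratio: float = 2.0,
    min_frac_ge10: float = 0.75,
):
    """Keep genes that look single-copy in every sample.

    A gene fails if ANY sample has mean_depth < 10, mean_depth more
    than double that sample's exon baseline, or fewer than 75% of bases
    covered at >= 10 reads. All comparisons are strict, so a gene
    exactly on a threshold passes. Returns ``(kept_genes,
    fail_reasons)`` with fail_reasons mapping gene_id -> reason string.
    Raises if any gene x sample summary is absent.
    """
    samples = sorted(baselines)
    cov = coverage.set_index(["gene_id", "sample"])
    kept: list[GeneModel] = []
    reasons: dict[str, str] = {}
    for gene in genes:
        reason = None
        for sample in samples:
            try:
                row = cov.loc[(gene.gene_id, sample)]
            except KeyError:
                raise KeyError(
                    f"no coverage summary for gene {gene.gene_id!r} "
                    f"x sample {sample!r}"
                ) from None
            depth = float(row["mean_depth"])
            frac = float(row["frac_ge10"])
            if depth < min_depth:
                reason = f"low_depth:{sample}"
            elif depth > max_baseline_ratio * baselines[sample]:
                reason = f"putative_duplication:{sample}"
            elif frac < min_frac_ge10:
                reason = f"low_breadth:{sample}"
            if reason:
                break
        if reason is None:
            kept.append(gene)
        else:
            reasons[gene.gene_id] = reason
    return kept, reasons


def enforce_min_spacing(
    genes: Sequence[GeneModel], min_gap: int = 20_000
) -> list[GeneModel]:
    """Greedy left-to-right thinning: keep a gene iff its start is at
    least ``min_gap`` bp past the end of the last kept gene on the same
    chromosome. Input must be sorted by (chrom, start)."""
    prev_key = None
    last_kept_end: dict[str, int] = {}
    kept: list[GeneModel] = []
    for g in genes:
        key = (g.chrom, g.start)
        if prev_key is not None and key < prev_key:
            raise ValueError("genes must be sorted by (chrom, start)")
        prev_key = key
        last = last_kept_end.get(g.chrom)
        if last is None or g.start - last >= min_gap:
            kept.append(g)
            last_kept_end[g.chrom] = g.end
    return kept


# ---------------------------------------------------------------------------
# alignment construction

def build_cds_alignment(
    gene: GeneModel,
    ref_cds: str,
    variants: Sequence[SiteRecord],
    samples: Sequence[str],
) -> CdsAlignment:
    """Substitute filtered variants into the reference CDS per sample.

    Columns map 1:1 to reference CDS positions: SNV alleles replace the
    reference base (heterozygous calls as IUPAC ambiguity codes),
    deleted bases become '-', insertions are skipped. Missing genotypes
    keep the reference base and are flagged 'N' in the sidecar mask.
    Variants outside the CDS intervals are ignored with a warning.
    """
    if len(ref_cds) != gene.cds_length:
        raise ValueError(
            f"{gene.gene_id}: reference CDS length {len(ref_cds)} != "
            f"model CDS length {gene.cds_length}"
        )
    ref_cds = ref_cds.upper()
    cols = {s: list(ref_cds) for s in samples}
    mask = {s: ["."] * len(ref_cds) for s in samples}

    for v in variants:
        col = gene.cds_column(v.pos)
        if col is None:
            logger.warning(
                "%s: variant at %s:%d outside CDS; ignored",
                gene.gene_id, v.chrom, v.pos,
            )
            continue
        for sample, call in zip(samples, v.genotypes):
            alleles = call.alleles
            if all(a == MISSING for a in alleles):
                mask[sample][col] = "N"
                continue
            obs = {a for a in alleles if a != MISSING}
            alt_idx = max(obs)
            if alt_idx == 0:
                continue  # homozygous reference
            alt = v.alts[alt_idx - 1]
            if len(v.ref) == 1 and len(alt) == 1:  # SNV
                bases = frozenset(
                    v.ref if a == 0 else v.alts[a - 1]
                    for a in obs
                )
                code = IUPAC.get(bases)
                if code is None:
                    raise ValueError(
                        f"{gene.gene_id}: cannot encode alleles {bases}"
                    )
                cols[sample][col] = code
            elif len(alt) < len(v.ref):  # deletion
                n_del = len(v.ref) - len(alt)
                if col + len(v.ref) > len(ref_cds):
                    raise ValueError(
                        f"{gene.gene_id}: deletion at {v.pos} runs past CDS end"
                    )
                # bases after the retained prefix are gapped
                for k in range(len(alt), len(v.ref)):
                    cols[sample][col + k] = "-"
            else:  # insertion: ignored to keep reference coordinates
                continue

    return CdsAlignment(
        gene_id=gene.gene_id,
        sequences={s: "".join(c) for s, c in cols.items()},
        mask={s: "".join(m) for s, m in mask.items()},
    )


def count_parsimony_informative_sites(alignment: CdsAlignment) -> int:
    """Number of columns with >= 2 distinct unambiguous nucleotide
    states each carried by >= 2 sequences. Gaps, N and IUPAC ambiguity
    codes count as missing."""
    seqs = list(alignment.sequences.values())
    if not seqs or not seqs[0]:
        raise ValueError(f"{alignment.gene_id}: empty alignment")
    n = 0
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in UNAMBIGUOUS:
                counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            n += 1
    return n


def alignment_passes_filters(alignment: CdsAlignment):
    """True iff the alignment has >= 1 parsimony-informative site and a
    length that is a multiple of three. Returns (bool, reason)."""
    if alignment.length % 3 != 0:
        return False, "length_not_multiple_of_3"
    if count_parsimony_informative_sites(alignment) < 1:
        return False, "no_parsimony_informative_sites"
    return True, "pass"


# ---------------------------------------------------------------------------
# FASTA I/O

def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
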