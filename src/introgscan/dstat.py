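"""Patterson's D (ABBA-BABA) and the Dp introgression proportion.

For a rooted triplet ((P1,P2),P3) with outgroup O, biallelic sites are
polarized by the outgroup majority allele and contribute
frequency-weighted site-pattern counts

    ABBA = (1-f1) f2 f3 (1-fO)
    BABA = f1 (1-f2) f3 (1-fO)
    BBAA = f1 f2 (1-f3) (1-fO)

where fX is the derived-allele frequency in population X (with a single
diploid sample f is in {0, 1/2, 1}). Under incomplete lineage sorting
alone E[ABBA] = E[BABA]; the imbalance

    D  = (ABBA - BABA) / (ABBA + BABA)
    Dp = (ABBA - BABA) / (BBAA + ABBA + BABA)

measures introgression, Dp approximating the genome-wide introgressed
proportion. Significance comes from a delete-one block jackknife over
large genomic windows (default 1 Mb), which is robust to linkage
between nearby sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import treeops

__all__ = [
    "GenotypeMatrix",
    "TripletSpec",
    "PatternCounts",
    "DResult",
    "derived_allele_frequencies",
    "site_pattern_weights",
    "pattern_counts",
    "compute_d",
    "compute_dp",
    "block_jackknife",
    "dstat_for_triplet",
    "enumerate_triplets",
    "run_dtrios",
    "read_species_map",
    "format_p",
]

DEFAULT_BLOCK_SIZE = 1_000_000


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes: alleles coded 0 (ref) / 1 (alt) / -1 missing.

    ``gt`` has shape (n_sites, n_samples, ploidy).
    """

    chrom: np.ndarray          # (n_sites,) chromosome ids
    pos: np.ndarray            # (n_sites,) 1-based positions
    samples: list
    gt: np.ndarray             # int8 (n_sites, n_samples, ploidy)
    ref: Optional[np.ndarray] = None
    alt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape[:2] != (len(self.pos), len(self.samples)):
            raise ValueError("genotype array shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Load biallelic SNVs from a VCF; other records are skipped."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        chroms, poss, gts, refs, alts = [], [], [], [], []
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            gts.append([[a if a >= 0 else -1 for a in g[:-1]]
                        for g in v.genotypes])
        gt = np.array(gts, dtype=np.int8) if gts else \
            np.zeros((0, len(samples), 2), dtype=np.int8)
        return cls(np.array(chroms), np.array(poss, dtype=np.int64),
                   samples, gt, np.array(refs), np.array(alts))


@dataclass(frozen=True)
class TripletSpec:
    """Sample groupings for one ABBA-BABA test, oriented ((P1,P2),P3),O."""

    p1_samples: tuple
    p2_samples: tuple
    p3_samples: tuple
    outgroup_samples: tuple

    def __post_init__(self) -> None:
        groups = [self.p1_samples, self.p2_samples,
                  self.p3_samples, self.outgroup_samples]
        if any(not g for g in groups):
            raise ValueError("all four sample groups must be nonempty")
        flat = [s for g in groups for s in g]
        if len(set(flat)) != len(flat):
            raise ValueError("sample groups must be disjoint")

    def swap_p1_p2(self) -> "TripletSpec":
        return TripletSpec(self.p2_samples, self.p1_samples,
                           self.p3_samples, self.outgroup_samples)


@dataclass
class PatternCounts:
    """Accumulated BBAA/ABBA/BABA weights, genome-wide and per block."""

    bbaa: float
    abba: float
    baba: float
    per_block: Dict = field(default_factory=dict)
    block_size: int = DEFAULT_BLOCK_SIZE
    n_sites_used: int = 0
    n_sites_skipped: int = 0


@dataclass
class DResult:
    p1: str
    p2: str
    p3: str
    d: float
    dp: float
    se: float
    z: float
    p: float
    counts: PatternCounts = None


def _group_freqs(gt: np.ndarray, idx: np.ndarray) -> tuple:
    """Per-site ALT-allele frequency over a sample group.

    Returns (freq, n_called_alleles); freq is NaN where no allele is
    called.
    """
    sub = gt[:, idx, :].reshape(gt.shape[0], -1)
    called = sub >= 0
    n = called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    freq[n == 0] = np.nan
    return freq, n


def derived_allele_frequencies(gm: GenotypeMatrix, triplet: TripletSpec):
    """Per-site derived-allele frequencies (f1, f2, f3, fO) and a
    validity mask.

    The ancestral allele at each site is the majority allele among
    outgroup calls; sites with a tied outgroup or any population
    entirely missing are flagged invalid.
    """
    freqs = []
    ns = []
    for group in (triplet.p1_samples, triplet.p2_samples,
                  triplet.p3_samples, triplet.outgroup_samples):
        f, n = _group_freqs(gm.gt, gm.sample_index(group))
        freqs.append(f)
        ns.append(n)
    f1, f2, f3, fo = freqs
    valid = np.ones(gm.n_sites, dtype=bool)
    for n in ns:
        valid &= n > 0
    # outgroup majority polarization; exact ties are dropped
    tied = np.isclose(fo, 0.5)
    valid &= ~tied
    derived_is_alt = fo < 0.5  # majority outgroup allele = ancestral
    out = np.empty((gm.n_sites, 4))
    for j, f in enumerate((f1, f2, f3, fo)):
        out[:, j] = np.where(derived_is_alt, f, 1.0 - f)
    out[~valid] = np.nan
    return out, valid


def site_pattern_weights(f1, f2, f3, fo):
    """Frequency-weighted (BBAA, ABBA, BABA) contributions."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    f3 = np.asarray(f3, dtype=float)
    fo = np.asarray(fo, dtype=float)
    w_abba = (1 - f1) * f2 * f3 * (1 - fo)
    w_baba = f1 * (1 - f2) * f3 * (1 - fo)
    w_bbaa = f1 * f2 * (1 - f3) * (1 - fo)
    return w_bbaa, w_abba, w_baba


def pattern_counts(
    gm: GenotypeMatrix,
    triplet: TripletSpec,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> PatternCounts:
    """Accumulate pattern weights genome-wide and per jackknife block.

    Blocks are fixed half-open windows [k*block_size, (k+1)*block_size)
    in reference coordinates, per chromosome; empty blocks are dropped.
    """
    freqs, valid = derived_allele_frequencies(gm, triplet)
    w_bbaa, w_abba, w_baba = site_pattern_weights(
        freqs[:, 0], freqs[:, 1], freqs[:, 2], freqs[:, 3]
    )
    w = np.where(valid[:, None], np.stack([w_bbaa, w_abba, w_baba], axis=1), 0.0)

    block_idx = (gm.pos - 1) // block_size
    per_block: Dict = {}
    keys = np.array([f"{c}:{b}" for c, b in zip(gm.chrom, block_idx)])
    for key in np.unique(keys[valid]):
        sel = (keys == key) & valid
        s = w[sel].sum(axis=0)
        per_block[key] = (float(s[0]), float(s[1]), float(s[2]))
    totals = w[valid].sum(axis=0)
    return PatternCounts(
        bbaa=float(totals[0]), abba=float(totals[1]), baba=float(totals[2]),
        per_block=per_block, block_size=block_size,
        n_sites_used=int(valid.sum()),
        n_sites_skipped=int((~valid).sum()),
    )


def compute_d(counts: PatternCounts) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); NaN when undefined."""
    denom = counts.abba + counts.baba
    if denom <= 0:
        return math.nan
    return (counts.abba - counts.baba) / denom


def compute_dp(counts: PatternCounts) -> float:
    """Dp = (ABBA - BABA) / (BBAA + ABBA + BABA); NaN when undefined."""
    denom = counts.bbaa + counts.abba + counts.baba
    if denom <= 0:
        return math.nan
    return (counts.abba - counts.baba) / denom


def block_jackknife(counts: PatternCounts, weighted: bool = False):
    """Delete-one-block jackknife SE, Z and two-tailed p for D.

    Only blocks contributing informative weight (ABBA + BABA > 0) are
    deleted in turn. With fewer than two contributing blocks the SE is
    undefined (NaN). The default is the unweighted delete-one formula
        SE^2 = (n-1)/n * sum_j (D_(-j) - mean_j D_(-j))^2 ;
    ``weighted=True`` weights each pseudovalue by the block's share of
    informative sites (ABBA+BABA weight).
    """
    d_full = compute_d(counts)
    blocks = [
        v for v in counts.per_block.values() if v[1] + v[2] > 0
    ]
    n = len(blocks)
    if n < 2 or math.isnan(d_full):
        return math.nan, math.nan, math.nan
    arr = np.array(blocks, dtype=float)
    tot = np.array([counts.bbaa, counts.abba, counts.baba])
    loo = tot[None, :] - arr  # leave-one-out totals
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = (loo[:, 1] - loo[:, 2]) / (loo[:, 1] + loo[:, 2])
    if weighted:
        m_j = arr[:, 1] + arr[:, 2]
        m = m_j.sum()
        # Busing et al. delete-m_j jackknife
        h_j = m / m_j
        pseudo = h_j * d_full - (h_j - 1) * d_loo
        theta = np.sum(pseudo / h_j) - d_full * (n - np.sum(1 / h_j))
        var = np.sum((pseudo - theta) ** 2 / (h_j - 1)) / n
        se = math.sqrt(var)
    else:
        se = math.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2))
    if se == 0:
        z = math.inf if d_full != 0 else math.nan
    else:
        z = d_full / se
    p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else (math.nan if math.isnan(z) else 0.0)
    return se, z, float(p)


def dstat_for_triplet(
    gm: GenotypeMatrix,
    triplet: TripletSpec,
    block_size: int = DEFAULT_BLOCK_SIZE,
    labels: tuple = ("P1", "P2", "P3"),
) -> DResult:
    counts = pattern_counts(gm, triplet, block_size)
    d = compute_d(counts)
    dp = compute_dp(counts)
    se, z, p = block_jackknife(counts)
    return DResult(labels[0], labels[1], labels[2], d, dp, se, z, p, counts)


# ---------------------------------------------------------------------------
# triplet enumeration and the Dtrios-style driver

def enumerate_triplets(
    species_tree, ingroup: Sequence[str]
) -> list:
    """All rooted triplets ((P1,P2),P3) among ``ingroup`` species that
    are consistent with the species tree.

    For every 3-subset the species tree resolves exactly one pairing:
    P1 and P2 are the two taxa whose most recent common ancestor
    excludes the third. P1/P2 order follows their order in ``ingroup``.
    """
    if isinstance(species_tree, str):
        species_tree = treeops.read_trees(species_tree, rooted=True)[0]
    present = treeops.leaf_labels(species_tree)
    missing = set(ingroup) - present
    if missing:
        raise KeyError(f"species not in tree: {sorted(missing)}")
    # leaf sets below each node identify the sister pair per triple
    triplets = []
    for trio in itertools.combinations(ingroup, 3):
        pair = _sister_pair(species_tree, trio)
        if pair is None:
            raise ValueError(f"species tree does not resolve trio {trio}")
        p3 = next(t for t in trio if t not in pair)
        p1, p2 = (t for t in trio if t in pair)
        triplets.append((p1, p2, p3))
    return triplets


def _sister_pair(tree, trio) -> Optional[frozenset]:
    # the sister pair of a rooted trio is the unique 2-element
    # restriction of some clade of the species tree
    trio_set = frozenset(trio)
    for side in treeops.restricted_bipartitions(tree, trio_set):
        if len(side) == 2:
            return frozenset(side)
    return None


def read_species_map(path) -> Dict[str, str]:
    """Two-column tab-separated sample -> species mapping."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, species = line.split("\t")[:2]
            mapping[sample] = species
    return mapping


def run_dtrios(
    gm: GenotypeMatrix,
    species_map: Mapping[str, str],
    species_tree,
    outgroup: Sequence[str],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """D and Dp for every species-tree-consistent triplet of ingroup
    species, polarized against ``outgroup`` species.

    P1/P2 within each sister pair are oriented so that D >= 0, i.e. P2
    is the taxon sharing excess derived alleles with P3 (the Dsuite
    BBAA convention). Rows are sorted by P3 then (P1, P2).
    """
    if isinstance(species_tree, str):
        species_tree = treeops.read_trees(species_tree, rooted=True)[0]
    outgroup = list(outgroup)
    by_species: Dict[str, list] = {}
    for sample, sp in species_map.items():
        by_species.setdefault(sp, []).append(sample)
    missing = [sp for sp in by_species if sp not in
               treeops.leaf_labels(species_tree) and sp not in outgroup]
    if missing:
        raise KeyError(f"species not in tree: {sorted(missing)}")
    for sp in by_species:
        gm.sample_index(by_species[sp])  # raises if absent

    ingroup = [sp for sp in by_species if sp not in outgroup]
    out_samples = tuple(s for sp in outgroup for s in by_species[sp])
    rows = []
    for p1, p2, p3 in enumerate_triplets(species_tree, ingroup):
        trip = TripletSpec(
            tuple(by_species[p1]), tuple(by_species[p2]),
            tuple(by_species[p3]), out_samples,
        )
        res = dstat_for_triplet(gm, trip, block_size, labels=(p1, p2, p3))
        if not math.isnan(res.d) and res.d < 0:
            res = dstat_for_triplet(
                gm, trip.swap_p1_p2(), block_size, labels=(p2, p1, p3)
            )
        rows.append({
            "P1": res.p1, "P2": res.p2, "P3": res.p3,
            "D": res.d, "Z": res.z, "p": res.p, "Dp": res.dp,
            "BBAA": res.counts.bbaa, "ABBA": res.counts.abba,
            "BABA": res.counts.baba,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["P3", "P1", "P2"]).reset_index(drop=True)
    return df


def format_p(p: float) -> str:
    """p to 3 decimals, printing values below 0.0005 as '.000'."""
    if math.isnan(p):
        return "NA"
    return f"{p:.3f}".lstrip("0") if p >= 0 else "NA"
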