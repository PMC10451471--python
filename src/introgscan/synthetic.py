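"""Multispecies-coalescent simulation with admixture pulses.

Generates every input the analysis stages consume — gene trees,
biallelic genotype matrices, per-locus alignments, locus coordinates,
and coverage tables — so the whole pipeline is testable without any
external data.

Model
-----
Loci are independent (free recombination between loci, none within).
Gene trees are drawn under the multispecies coalescent on a species
tree whose branch lengths are in coalescent units (2N generations);
population sizes are constant along branches. An introgression pulse
(donor, recipient, time, proportion gamma) is an instantaneous event:
moving pastward, each recipient-side lineage present at the pulse time
jumps to the donor population independently with probability gamma.
Ancestry is simulated with msprime, parameterized so one unit of
msprime time equals one coalescent unit.

Mutations follow the infinite-sites model: each locus receives
Poisson(theta/2 x total tree length) mutations placed uniformly on
branches, each yielding one new biallelic site whose derived allele is
carried by the leaves below the mutated branch. Sites get sequential
reference coordinates, with loci tiled along one synthetic chromosome
separated by fixed gaps (default 20 kb) so that genomic blocking and
the locus-spacing filter are exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .dstat import GenotypeMatrix
from .orthologs import GeneModel

__all__ = [
    "Pulse",
    "SimulationConfig",
    "simulate_gene_trees",
    "mutate_to_sites",
    "simulate_genotypes",
    "simulate_coverage_table",
    "locus_models",
    "write_vcf",
    "write_config",
    "read_config",
]

CHROM = "chrSim"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Pulse:
    """Instantaneous admixture: at ``time`` (coalescent units before
    present) a fraction ``proportion`` of the recipient's lineages
    derive from the donor."""

    donor: str
    recipient: str
    time: float
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("pulse proportion must be in [0, 1]")
        if self.time < 0:
            raise ValueError("pulse time must be >= 0")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    species_tree: rooted newick with ultrametric branch lengths in
    coalescent units. theta is the population-scaled mutation rate per
    locus (expected pairwise diversity contribution; mutations per
    locus ~ Poisson(theta/2 x tree length)).
    """

    species_tree: str
    n_loci: int = 1000
    locus_length: int = 5_000
    locus_spacing: int = 20_000
    theta: float = 2.0
    samples_per_species: int = 1  # diploid individuals
    pulses: tuple = ()
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be positive")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        self.pulses = tuple(
            p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses
        )


# ---------------------------------------------------------------------------
# demography

def _parse_species_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted",
                             suppress_internal_node_taxa=True)
    return tree


def _node_ages(tree: dendropy.Tree) -> Dict[int, float]:
    """Node ages assuming an ultrametric tree (leaves at age 0)."""
    ages: Dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            child_ages = [
                ages[id(ch)] + (ch.edge.length or 0.0)
                for ch in node._child_nodes
            ]
            if max(child_ages) - min(child_ages) > 1e-6 * max(max(child_ages), 1.0):
                raise ValueError(
                    "species tree must be ultrametric in coalescent units"
                )
            ages[id(node)] = float(np.mean(child_ages))
    return ages


def build_demography(config: SimulationConfig):
    """msprime Demography in coalescent-unit time.

    Haploid lineages with population size 1 make the pairwise
    coalescence rate 1 per unit time, so msprime time equals coalescent
    units directly.
    """
    import msprime

    tree = _parse_species_tree(config.species_tree)
    ages = _node_ages(tree)
    demography = msprime.Demography()
    names: Dict[int, str] = {}
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
        else:
            counter += 1
            name = f"anc{counter}"
        names[id(node)] = name
        demography.add_population(name=name, initial_size=1.0)
    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]

    # species origin times (when the population splits off, pastward)
    origin: Dict[str, float] = {name: math.inf for name in
                                [names[id(n)] for n in tree.preorder_node_iter()]}
    for node in tree.postorder_node_iter():
        if node.parent_node is not None:
            origin[names[id(node)]] = ages[id(node.parent_node)]
    root_name = names[id(tree.seed_node)]

    events = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        derived = [names[id(ch)] for ch in node._child_nodes]
        events.append(("split", ages[id(node)], derived, names[id(node)]))
    for pulse in config.pulses:
        for pop in (pulse.donor, pulse.recipient):
            if pop not in origin:
                raise ValueError(f"pulse population {pop!r} not in tree")
            if pulse.time >= origin[pop]:
                raise ValueError(
                    f"pulse at t={pulse.time} predates origin of {pop!r} "
                    f"(t={origin[pop]})"
                )
        events.append(("pulse", pulse.time,
                       pulse.recipient, pulse.donor, pulse.proportion))
    events.sort(key=lambda e: e[1])
    for ev in events:
        if ev[0] == "split":
            demography.add_population_split(
                time=ev[1], derived=ev[2], ancestral=ev[3]
            )
        else:
            demography.add_mass_migration(
                time=ev[1], source=ev[2], dest=ev[3], proportion=ev[4]
            )
    demography.sort_events()
    return demography, leaf_names


# ---------------------------------------------------------------------------
# gene trees

def _tskit_to_dendropy(ts_tree, labels: Sequence[str],
                       namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Build a dendropy tree (branch lengths in coalescent units) from a
    tskit tree by direct node construction."""
    tree = dendropy.Tree(taxon_namespace=namespace)
    nodes: Dict[int, dendropy.Node] = {}

    def make(u: int) -> dendropy.Node:
        node = dendropy.Node()
        children = ts_tree.children(u)
        if not children:
            node.taxon = namespace.get_taxon(labels[u]) or \
                namespace.new_taxon(labels[u])
        for ch in children:
            child = make(ch)
            child.edge.length = ts_tree.time(u) - ts_tree.time(ch)
            node.add_child(child)
        nodes[u] = node
        return node

    root = make(ts_tree.root)
    tree.seed_node = root
    return tree


def simulate_gene_trees(
    config: SimulationConfig,
    lineages_per_species: Optional[int] = None,
    as_dendropy: bool = True,
):
    """Draw one gene tree per locus under the configured model.

    With one lineage per species (the default for topology work) tips
    are labeled with species names; with k > 1, tips are
    ``species_0 ... species_{k-1}``. Returns a list of dendropy trees,
    or of tskit trees when ``as_dendropy=False`` (fast path used
    internally).
    """
    import msprime

    demography, leaf_names = build_demography(config)
    if lineages_per_species is None:
        lineages_per_species = 2 * config.samples_per_species
    k = lineages_per_species
    samples = {name: k for name in leaf_names}
    labels = []
    for name in leaf_names:
        if k == 1:
            labels.append(name)
        else:
            labels.extend(f"{name}_{i}" for i in range(k))
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        num_replicates=config.n_loci,
        random_seed=_msprime_seed(config.seed),
    )
    if not as_dendropy:
        return [ts.first() for ts in reps], labels
    namespace = dendropy.TaxonNamespace(labels)
    trees = []
    for ts in reps:
        trees.append(_tskit_to_dendropy(ts.first(), labels, namespace))
    return trees


def _msprime_seed(seed: int) -> int:
    # msprime requires 0 < seed < 2^32
    return (int(seed) % (2**31 - 1)) + 1


# ---------------------------------------------------------------------------
# infinite-sites mutation layer

def _tree_edges(tree: dendropy.Tree, label_index: Mapping[str, int]):
    """(leaf-bitmask, length) per edge, via one postorder pass."""
    masks: Dict[int, int] = {}
    edges = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = 1 << label_index[node.taxon.label]
        else:
            mask = 0
            for ch in node._child_nodes:
                mask |= masks[id(ch)]
        masks[id(node)] = mask
        if node.parent_node is not None and (node.edge.length or 0.0) > 0:
            edges.append((mask, float(node.edge.length)))
    return edges


def _edges_from_tskit(ts_tree, n_tips: int):
    """(leaf-bitmask, length) per edge of a tskit tree; tip bit = node id."""
    masks: Dict[int, int] = {}
    edges = []

    def visit(u: int) -> int:
        children = ts_tree.children(u)
        if not children:
            mask = 1 << u
        else:
            mask = 0
            for ch in children:
                mask |= visit(ch)
        masks[u] = mask
        parent = ts_tree.parent(u)
        if parent != -1:
            length = ts_tree.time(parent) - ts_tree.time(u)
            if length > 0:
                edges.append((mask, length))
        return mask

    visit(ts_tree.root)
    return edges


def mutate_to_sites(
    trees: Sequence[dendropy.Tree],
    theta: float,
    locus_length: int = 5_000,
    locus_spacing: int = 20_000,
    seed: int = 1,
    make_alignments: bool = False,
):
    """Place infinite-sites mutations on gene trees.

    Per locus, the mutation count is Poisson(theta/2 x total branch
    length); each mutation picks a branch with probability proportional
    to its length and a uniform position within the locus, producing a
    biallelic site whose derived allele is carried by the leaves below
    that branch. Mutations on the root edge (all leaves derived) are
    never produced because root edges have no length.

    Tip labels of the form ``species_i`` are paired into diploid
    samples per species; bare labels become haploid samples. Returns
    ``(GenotypeMatrix, alignments)`` where alignments is a list of
    per-locus dicts sample -> sequence (IUPAC at heterozygous sites)
    or None unless requested.
    """
    if not trees:
        raise ValueError("no trees given")
    rng = np.random.default_rng(seed)
    tip_labels = sorted(
        lf.taxon.label for lf in trees[0].leaf_node_iter()
    )
    label_index = {lab: i for i, lab in enumerate(tip_labels)}
    edge_lists = (_tree_edges(t, label_index) for t in trees)
    return _sites_from_edge_lists(
        edge_lists, len(trees), tip_labels, theta,
        locus_length, locus_spacing, rng, make_alignments,
    )


def _sites_from_edge_lists(edge_lists, n_loci, tip_labels, theta,
                           locus_length, locus_spacing, rng,
                           make_alignments):
    sample_of, samples, ploidy = _group_tips(tip_labels)
    all_pos: List[int] = []
    all_masks: List[int] = []
    locus_of_site: List[int] = []
    pitch = locus_length + locus_spacing
    for i, edges in enumerate(edge_lists):
        if not edges:
            continue
        lengths = np.array([e[1] for e in edges])
        total = lengths.sum()
        k = rng.poisson(theta / 2.0 * total)
        if k == 0:
            continue
        choice = rng.choice(len(edges), size=k, p=lengths / total)
        offsets = np.sort(rng.integers(0, locus_length, size=k))
        base = i * pitch
        for j, off in zip(choice, offsets):
            all_pos.append(base + int(off) + 1)
            all_masks.append(edges[j][0])
            locus_of_site.append(i)

    n_sites = len(all_pos)
    n_tips = len(tip_labels)
    mask_arr = np.array(all_masks, dtype=np.int64).reshape(n_sites, 1)
    carried = ((mask_arr >> np.arange(n_tips)) & 1).astype(np.int8)

    gt = np.zeros((n_sites, len(samples), ploidy), dtype=np.int8)
    for t, lab in enumerate(tip_labels):
        si, ai = sample_of[lab]
        gt[:, si, ai] = carried[:, t]

    refalt = _draw_ref_alt(rng, n_sites)
    gm = GenotypeMatrix(
        chrom=np.array([CHROM] * n_sites),
        pos=np.array(all_pos, dtype=np.int64),
        samples=samples,
        gt=gt,
        ref=refalt[0],
        alt=refalt[1],
    )
    alignments = None
    if make_alignments:
        alignments = _build_alignments(
            gm, np.array(locus_of_site, dtype=int), n_loci,
            locus_length, pitch, rng,
        )
    return gm, alignments


def _group_tips(tip_labels: Sequence[str]):
    """Pair ``species_i`` tips into diploid samples; bare labels stay
    haploid. Returns (tip -> (sample_idx, allele_idx), samples, ploidy)."""
    groups: Dict[str, list] = {}
    for lab in tip_labels:
        sp, _, idx = lab.rpartition("_")
        if sp and idx.isdigit():
            groups.setdefault(sp, []).append(lab)
        else:
            groups.setdefault(lab, []).append(lab)
    samples = sorted(groups)
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("unequal lineage counts per species")
    ploidy = sizes.pop()
    sample_of = {}
    for si, sp in enumerate(samples):
        for ai, lab in enumerate(sorted(groups[sp])):
            sample_of[lab] = (si, ai)
    return sample_of, samples, ploidy


def _draw_ref_alt(rng, n_sites: int):
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def _build_alignments(gm, locus_of_site, n_loci, locus_length, pitch, rng):
    alignments = []
    for i in range(n_loci):
        background = _BASES[rng.integers(0, 4, size=locus_length)]
        seqs = {s: background.copy() for s in gm.samples}
        sel = np.nonzero(locus_of_site == i)[0]
        for s_idx in sel:
            col = int(gm.pos[s_idx] - 1 - i * pitch)
            ref, alt = gm.ref[s_idx], gm.alt[s_idx]
            for j, sample in enumerate(gm.samples):
                alleles = gm.gt[s_idx, j, :]
                bases = {ref if a == 0 else alt for a in alleles if a >= 0}
                if not bases:
                    seqs[sample][col] = "N"
                elif len(bases) == 1:
                    seqs[sample][col] = bases.pop()
                else:
                    seqs[sample][col] = _IUPAC_PAIR[frozenset(bases)]
        alignments.append({s: "".join(v) for s, v in seqs.items()})
    return alignments


def simulate_genotypes(config: SimulationConfig,
                       make_alignments: bool = False,
                       return_trees: bool = False):
    """End-to-end: coalescent gene trees plus infinite-sites mutations.

    Returns ``(GenotypeMatrix, gene_trees, alignments)`` with one
    diploid sample per species (two sampled lineages) by default.
    ``gene_trees`` is None unless ``return_trees`` (the default fast
    path runs on the raw ancestry without building tree objects).
    """
    k = 2 * config.samples_per_species
    rng = np.random.default_rng(config.seed + 1_000_003)
    if return_trees:
        trees = simulate_gene_trees(config, lineages_per_species=k)
        gm, alignments = mutate_to_sites(
            trees, config.theta, config.locus_length, config.locus_spacing,
            seed=config.seed + 1_000_003, make_alignments=make_alignments,
        )
        return gm, trees, alignments
    ts_trees, labels = simulate_gene_trees(
        config, lineages_per_species=k, as_dendropy=False
    )
    # tskit sample node id i carries label labels[i]; sort labels and
    # remap bits so the mutation layer sees a sorted tip order
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    rank = {i: r for r, i in enumerate(order)}
    tip_labels = [labels[i] for i in order]

    def remapped(edges):
        return [(_remap_mask(m, rank, len(labels)), ln) for m, ln in edges]

    edge_lists = (
        remapped(_edges_from_tskit(t, len(labels))) for t in ts_trees
    )
    gm, alignments = _sites_from_edge_lists(
        edge_lists, config.n_loci, tip_labels, config.theta,
        config.locus_length, config.locus_spacing, rng, make_alignments,
    )
    return gm, None, alignments


def _remap_mask(mask: int, rank: Mapping[int, int], n: int) -> int:
    out = 0
    for i in range(n):
        if mask >> i & 1:
            out |= 1 << rank[i]
    return out


def locus_models(config: SimulationConfig) -> list:
    """GeneModel records for the tiled loci (BED-compatible)."""
    pitch = config.locus_length + config.locus_spacing
    genes = []
    for i in range(config.n_loci):
        start = i * pitch + 1
        end = start + config.locus_length - 1
        genes.append(GeneModel(f"locus{i:05d}", CHROM, start, end,
                               ((start, end),), "+"))
    return genes


# ---------------------------------------------------------------------------
# coverage fixtures

def simulate_coverage_table(
    gene_ids: Sequence[str],
    baselines: Mapping[str, float],
    n_low: int = 0,
    n_dup: int = 0,
    n_low_breadth: int = 0,
    noise_sd: float = 1.0,
    seed: int = 1,
):
    """Coverage summaries with planted filter violations.

    Normal genes draw mean depths near each sample's exon baseline
    (Gaussian noise, truncated to stay inside all pass conditions) with
    high breadth. The first ``n_low`` genes get one sample below 10x,
    the next ``n_dup`` one sample above twice its baseline, the next
    ``n_low_breadth`` one sample under 75% breadth. Returns
    ``(DataFrame, planted)`` where planted maps gene_id -> violation
    type.

    Baselines must exceed ~13x so that passing depths (>= 10x and
    <= 2x baseline) exist for every sample.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = sorted(baselines)
    n_planted = n_low + n_dup + n_low_breadth
    if n_planted > len(gene_ids):
        raise ValueError("more planted violations than genes")
    planted: Dict[str, str] = {}
    rows = []
    for gi, gene in enumerate(gene_ids):
        kind = None
        if gi < n_low:
            kind = "low_depth"
        elif gi < n_low + n_dup:
            kind = "putative_duplication"
        elif gi < n_planted:
            kind = "low_breadth"
        if kind:
            planted[gene] = kind
        bad_sample = samples[gi % len(samples)] if kind else None
        for sample in samples:
            base = baselines[sample]
            depth = float(np.clip(rng.normal(base, noise_sd),
                                  10.5, 2.0 * base - 0.5))
            frac = float(rng.uniform(0.85, 1.0))
            if sample == bad_sample:
                if kind == "low_depth":
                    depth = float(rng.uniform(2.0, 9.5))
                elif kind == "putative_duplication":
                    depth = float(rng.uniform(2.05, 3.0)) * base
                else:
                    frac = float(rng.uniform(0.2, 0.7))
            rows.append({"gene_id": gene, "sample": sample,
                         "mean_depth": round(depth, 3),
                         "frac_ge10": round(frac, 4)})
    return pd.DataFrame(rows), planted


# ---------------------------------------------------------------------------
# writers / config

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as plain-text VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introgscan-synthetic\n")
        for c in sorted(set(map(str, gm.chrom))):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        ref = gm.ref if gm.ref is not None else np.array(["A"] * gm.n_sites)
        alt = gm.alt if gm.alt is not None else np.array(["T"] * gm.n_sites)
        for i in range(gm.n_sites):
            gts = []
            for j in range(len(gm.samples)):
                alleles = gm.gt[i, j, :]
                gts.append("/".join("." if a < 0 else str(int(a))
                                    for a in alleles))
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{ref[i]}\t{alt[i]}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_config(config: SimulationConfig, path) -> None:
    """Write a SimulationConfig as ``key = value`` text."""
    with open(path, "w") as fh:
        fh.write(f"species_tree = {config.species_tree}\n")
        fh.write(f"n_loci = {config.n_loci}\n")
        fh.write(f"locus_length = {config.locus_length}\n")
        fh.write(f"locus_spacing = {config.locus_spacing}\n")
        fh.write(f"theta = {config.theta}\n")
        fh.write(f"samples_per_species = {config.samples_per_species}\n")
        fh.write(f"seed = {config.seed}\n")
        for p in config.pulses:
            fh.write(f"pulse = {p.donor},{p.recipient},{p.time},{p.proportion}\n")


def read_config(path) -> SimulationConfig:
    kwargs: Dict = {"pulses": []}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = (x.strip() for x in line.split("=", 1))
            if key == "pulse":
                d, r, t, g = value.split(",")
                kwargs["pulses"].append(Pulse(d, r, float(t), float(g)))
            elif key == "species_tree":
                kwargs[key] = value
            elif key == "theta":
                kwargs[key] = float(value)
            elif key in {"n_loci", "locus_length", "locus_spacing",
                         "samples_per_species", "seed"}:
                kwargs[key] = int(value)
    if "seed" not in kwargs:
        raise ValueError("config must set a seed")
    kwargs["pulses"] = tuple(kwargs["pulses"])
    return SimulationConfig(**kwargs)
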