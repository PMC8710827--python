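"""Synthetic genome pairs for WGD inference.

The generator builds an ancestral gene order, applies a shared ancient WGD
(present in both genomes), a speciation split, and a lineage-specific WGD in
the focal genome only, followed by Bernoulli fractionation, end-to-end
chromosome fusions and segmental inversions. Coding sequences evolve along
the implied gene tree with the codon substitution process of
:mod:`wgdkit.simulate.codon`, so every pairwise divergence class (young
paralogs, old paralogs, orthologs) hits its target synonymous divergence in
expectation. The truth table records each surviving gene's ancestry, which
is sufficient to score multiplicity, Ks peaks, painting and paralog-pair
recovery downstream without re-reading scenario internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .. import codon as ct
from ..io import GeneModel, Genome
from .codon import evolve_branch, random_cds

GENE_LENGTH_BP = 1000
GENE_SPACING_BP = 2000


@dataclass
class WGDScenario:
    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    shared_wgd_ds: float = 0.6     # pairwise Ks target of the ancient shared event
    specific_wgd_ds: float = 0.15  # pairwise Ks target of the lineage-specific event
    ortholog_ds: float = 0.45      # pairwise Ks target across the speciation split
    retention_prob: float = 0.7    # per-copy survival through fractionation
    n_fusions: int = 0
    inversion_rate: float = 0.0    # expected inversions per focal chromosome
    omega: float = 0.2             # Ka/Ks of the substitution process
    min_codons: int = 120
    max_codons: int = 240
    with_sequences: bool = True
    skip_shared_wgd: bool = False  # reference reduces to a single subgenome
    extra_specific_wgds: int = 0   # stack further specific events (multiplicity 4, 8, ...)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in (0, 1]")
        if not self.specific_wgd_ds < self.shared_wgd_ds:
            raise ValueError("specific_wgd_ds must be younger (smaller) than shared_wgd_ds")
        if not self.specific_wgd_ds < self.ortholog_ds < self.shared_wgd_ds:
            raise ValueError("ortholog_ds must lie between the two WGD divergences")


def _branch(codons, length, omega, rng, with_seq):
    if not with_seq:
        return None
    return evolve_branch(codons, length, omega, rng)


def simulate_wgd_genome(scenario: WGDScenario) -> tuple[Genome, Genome, pd.DataFrame]:
    """Simulate (focal genome, reference genome, truth table).

    The reference carries only the shared WGD; the focal genome additionally
    carries the lineage-specific WGD(s), per-copy Bernoulli(1 - retention)
    deletion, ``n_fusions`` end-to-end chromosome joins and Poisson-many
    segmental inversions per chromosome. Truth-table columns: gene_id,
    genome, chromosome, subgenome, wgd_copy, ancestral_gene,
    ancestral_chromosome.
    """
    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    t_shared = sc.shared_wgd_ds / 2.0
    t_split = sc.ortholog_ds / 2.0
    t_specific = sc.specific_wgd_ds / 2.0

    subgenomes = ["A"] if sc.skip_shared_wgd else ["A", "B"]
    n_spec_events = 1 + sc.extra_specific_wgds
    n_focal_copies = 2 ** n_spec_events
    # depths of the stacked specific events, oldest first, all below t_split
    spec_depths = [t_specific * (n_spec_events - i) / n_spec_events
                   for i in range(n_spec_events)] if n_spec_events else []

    for attempt in range(6):
        focal_rows, ref_rows = [], []
        focal_cds, ref_cds = {}, {}
        for c in range(1, sc.n_chromosomes + 1):
            anc_chrom = f"AGK{c}"
            for g in range(1, sc.genes_per_chromosome + 1):
                anc_id = f"anc_c{c}g{g}"
                n_cod = int(rng.integers(sc.min_codons, sc.max_codons + 1))
                anc = random_cds(n_cod, rng) if sc.with_sequences else None
                for sub in subgenomes:
                    # lineage root of this subgenome at the shared WGD
                    root = _branch(anc, 0.0, sc.omega, rng, sc.with_sequences)
                    at_split = _branch(root, t_shared - t_split, sc.omega, rng,
                                       sc.with_sequences)
                    # reference leaf
                    ref_id = f"ref_{sub}_c{c}g{g}"
                    leaf = _branch(at_split, t_split, sc.omega, rng, sc.with_sequences)
                    ref_rows.append((ref_id, f"ref_chr{c}{sub}", sub, 0, anc_id, anc_chrom, g))
                    if sc.with_sequences:
                        ref_cds[ref_id] = ct.indices_to_cds(leaf)
                    # focal lineage: stacked specific WGDs
                    lineages = [(at_split, t_split)]  # (codons at depth, depth)
                    for depth in spec_depths:
                        nxt = []
                        for codons, at_depth in lineages:
                            pre = _branch(codons, at_depth - depth, sc.omega, rng,
                                          sc.with_sequences)
                            nxt.append((pre, depth))
                            nxt.append((pre, depth))
                        lineages = nxt
                    for copy_i, (codons, at_depth) in enumerate(lineages, start=1):
                        gid = f"foc_{sub}{copy_i}_c{c}g{g}"
                        leaf_f = _branch(codons, at_depth, sc.omega, rng, sc.with_sequences)
                        focal_rows.append((gid, f"foc_chr{c}{sub}{copy_i}", sub, copy_i,
                                           anc_id, anc_chrom, g))
                        if sc.with_sequences:
                            focal_cds[gid] = ct.indices_to_cds(leaf_f)
        # fractionation: every focal copy survives independently
        keep = rng.random(len(focal_rows)) < sc.retention_prob
        kept_rows = [r for r, k in zip(focal_rows, keep) if k]
        chrom_counts = pd.Series([r[1] for r in kept_rows]).value_counts()
        n_chroms_expected = sc.n_chromosomes * len(subgenomes) * n_focal_copies
        if len(chrom_counts) == n_chroms_expected and (chrom_counts >= 2).all():
            break
        if attempt == 5:
            raise RuntimeError(
                "fractionation emptied a chromosome in every retry; "
                "raise retention_prob or genes_per_chromosome")
        import warnings
        warnings.warn("fractionation emptied a chromosome; regenerating", stacklevel=2)
    focal_rows = kept_rows
    focal_cds = {r[0]: focal_cds[r[0]] for r in focal_rows} if sc.with_sequences else None

    # chromosome-level rearrangements in the focal genome
    order: dict[str, list[tuple]] = {}
    for r in focal_rows:
        order.setdefault(r[1], []).append(r)
    for chrom in order:
        order[chrom].sort(key=lambda r: r[6])
    chrom_names = sorted(order)
    # inversions
    for chrom in chrom_names:
        genes = order[chrom]
        for _ in range(rng.poisson(sc.inversion_rate)):
            if len(genes) < 2:
                break
            i, j = sorted(rng.integers(0, len(genes), size=2))
            genes[i:j + 1] = genes[i:j + 1][::-1]
    # fusions: join disjoint chromosome pairs with distinct ancestral origins
    # end to end, so each fusion is visible to karyotype painting
    if sc.n_fusions * 2 > len(chrom_names):
        raise ValueError("n_fusions too large for the chromosome count")
    anc_of = lambda name: order[name][0][5]
    pool_names = list(rng.permutation(chrom_names))
    for f in range(sc.n_fusions):
        a = pool_names.pop(0)
        try:
            b = next(n for n in pool_names if anc_of(n) != anc_of(a))
        except StopIteration:
            raise ValueError("cannot place fusions across distinct ancestral "
                             "chromosomes; increase n_chromosomes") from None
        pool_names.remove(b)
        order[f"foc_fus{f + 1}"] = order.pop(a) + order.pop(b)

    def build_rows(order_map):
        rows, genes = [], []
        for chrom in sorted(order_map):
            for pos, r in enumerate(order_map[chrom]):
                start = pos * GENE_SPACING_BP + 1
                genes.append(GeneModel(r[0], chrom, start, start + GENE_LENGTH_BP - 1, "+"))
                rows.append({"gene_id": r[0], "genome": "focal", "chromosome": chrom,
                             "subgenome": r[2], "wgd_copy": r[3],
                             "ancestral_gene": r[4], "ancestral_chromosome": r[5]})
        return rows, genes

    truth_focal, focal_genes = build_rows(order)
    focal = Genome(name="focal", genes=focal_genes, cds=focal_cds,
                   proteins={g: ct.translate(s) for g, s in focal_cds.items()}
                   if sc.with_sequences else None)

    ref_order: dict[str, list[tuple]] = {}
    for r in ref_rows:
        ref_order.setdefault(r[1], []).append(r)
    truth_ref, ref_genes = [], []
    for chrom in sorted(ref_order):
        for pos, r in enumerate(sorted(ref_order[chrom], key=lambda r: r[6])):
            start = pos * GENE_SPACING_BP + 1
            ref_genes.append(GeneModel(r[0], chrom, start, start + GENE_LENGTH_BP - 1, "+"))
            truth_ref.append({"gene_id": r[0], "genome": "reference", "chromosome": chrom,
                              "subgenome": r[2], "wgd_copy": 0,
                              "ancestral_gene": r[4], "ancestral_chromosome": r[5]})
    reference = Genome(name="reference", genes=ref_genes, cds=ref_cds or None,
                       proteins={g: ct.translate(s) for g, s in ref_cds.items()}
                       if sc.with_sequences else None)
    truth = pd.DataFrame(truth_focal + truth_ref)
    return focal, reference, truth


# ---------------------------------------------------------------------------
# truth-table helpers
# ---------------------------------------------------------------------------

def true_paralog_pairs(truth: pd.DataFrame) -> pd.DataFrame:
    """Surviving focal pairs descending from the youngest specific WGD.

    For the single-event case these are (copy 1, copy 2) of each
    (ancestral gene, subgenome); with stacked events, copies are paired by
    the youngest split (1,2), (3,4), ...
    """
    foc = truth[truth["genome"] == "focal"]
    rows = []
    for (anc, sub), grp in foc.groupby(["ancestral_gene", "subgenome"]):
        copies = dict(zip(grp["wgd_copy"], grp["gene_id"]))
        for c1 in sorted(copies):
            if c1 % 2 == 1 and c1 + 1 in copies:
                rows.append({"copy_1": copies[c1], "copy_2": copies[c1 + 1],
                             "ancestral_gene": anc, "subgenome": sub})
    return pd.DataFrame(rows, columns=["copy_1", "copy_2", "ancestral_gene", "subgenome"])


def true_ortholog_map(truth: pd.DataFrame) -> pd.DataFrame:
    """(reference gene, focal gene) ortholog pairs: same ancestral gene and subgenome."""
    foc = truth[truth["genome"] == "focal"]
    ref = truth[truth["genome"] == "reference"]
    merged = ref.merge(foc, on=["ancestral_gene", "subgenome"], suffixes=("_ref", "_focal"))
    return merged[["gene_id_ref", "gene_id_focal", "ancestral_gene", "subgenome"]]


def ancestral_gene_map(truth: pd.DataFrame, genome: str = "focal") -> dict[str, str]:
    """gene_id -> ancestral chromosome label, the input to karyotype painting."""
    sub = truth[truth["genome"] == genome]
    return dict(zip(sub["gene_id"], sub["ancestral_chromosome"]))
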