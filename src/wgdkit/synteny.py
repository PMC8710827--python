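"""Homologous-gene detection and collinear block chaining.

Homology search runs an all-against-all protein comparison (NCBI BLAST+
behind the scenes) filtered at E-value <= 1e-5 and >= 50% match length of
the shorter protein, with per-query best-hit ranks. Anchor chaining is a
longest-collinear-chain dynamic programme with a maximal order-index gap of
50 genes between consecutive collinear pairs on both axes, searched in both
orientations; chains shorter than five pairs are discarded.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Genome, ValidationError, write_fasta

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass
class HomologyHit:
    query_gene: str
    subject_gene: str
    score: float           # bit score
    evalue: float
    match_fraction: float  # aligned length / shorter protein length
    rank: int = 0          # 1 = best subject for this query, by score


@dataclass
class SyntenyBlock:
    block_id: str
    genome_a: str
    chrom_a: str
    genome_b: str
    chrom_b: str
    pairs: list[tuple[str, str, int]]   # (gene_a, gene_b, hit rank)
    orientation: str                    # "same" | "inverted"
    mean_ks: float | None = None
    block_class: str | None = None      # "orthologous" | "outparalogous"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# homology search
# ---------------------------------------------------------------------------

def _check_proteome(proteins: dict[str, str], label: str) -> None:
    if not proteins:
        raise ValueError(f"empty proteome {label!r}")
    for gid, seq in proteins.items():
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise ValidationError(f"{label}/{gid}: non-amino-acid characters {sorted(bad)}")


def find_homologs(proteins_a: dict[str, str], proteins_b: dict[str, str],
                  evalue_max: float = 1e-5, min_match_fraction: float = 0.5,
                  self_search: bool | None = None, threads: int = 1) -> list[HomologyHit]:
    """All-against-all protein homology search with the study's two filters.

    ``self_search`` excludes query==subject hits; it defaults to true when
    the two proteomes are the same object. Retained hits carry per-query
    ranks by descending bit score (ties broken by subject id).
    """
    _check_proteome(proteins_a, "a")
    _check_proteome(proteins_b, "b")
    if self_search is None:
        self_search = proteins_a is proteins_b
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("NCBI BLAST+ (blastp/makeblastdb) not found on PATH")
    with tempfile.TemporaryDirectory(prefix="wgdkit_blast_") as tmp:
        tmp = Path(tmp)
        qf, dbf = tmp / "query.faa", tmp / "db.faa"
        write_fasta(proteins_a, qf)
        write_fasta(proteins_b, dbf)
        subprocess.run(["makeblastdb", "-in", str(dbf), "-dbtype", "prot"],
                       check=True, capture_output=True)
        out = tmp / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(qf), "-db", str(dbf), "-evalue", f"{evalue_max:g}",
             "-outfmt", "6 qseqid sseqid bitscore evalue length qlen slen",
             "-max_target_seqs", "100", "-num_threads", str(threads), "-out", str(out)],
            check=True, capture_output=True)
        cols = ["query", "subject", "bitscore", "evalue", "length", "qlen", "slen"]
        if out.stat().st_size == 0:
            return []
        df = pd.read_csv(out, sep="\t", names=cols)
    if self_search:
        df = df[df["query"] != df["subject"]]
    df["match_fraction"] = df["length"] / df[["qlen", "slen"]].min(axis=1)
    df = df[(df["evalue"] <= evalue_max) & (df["match_fraction"] >= min_match_fraction)]
    # best HSP per (query, subject)
    df = df.sort_values(["query", "subject", "bitscore"], ascending=[True, True, False])
    df = df.drop_duplicates(["query", "subject"], keep="first")
    df = df.sort_values(["query", "bitscore", "subject"], ascending=[True, False, True])
    df["rank"] = df.groupby("query").cumcount() + 1
    return [HomologyHit(r.query, r.subject, float(r.bitscore), float(r.evalue),
                        float(r.match_fraction), int(r.rank))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# anchor chaining
# ---------------------------------------------------------------------------

def _best_chain(anchors: list[tuple[int, int, int]], max_gap: int, orientation: str
                ) -> list[int]:
    """Longest orientation-consistent chain (indices into ``anchors``).

    ``anchors`` holds (ia, ib, original_index) sorted by (ia, ib). A chain
    step requires 1 <= ia_j - ia_i <= max_gap and, on axis b,
    1 <= ib_j - ib_i <= max_gap (same) or 1 <= ib_i - ib_j <= max_gap
    (inverted).
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        ia_j, ib_j, _ = anchors[j]
        for i in range(j):
            ia_i, ib_i, _ = anchors[i]
            da = ia_j - ia_i
            if da < 1:
                continue
            if da > max_gap:
                continue
            db = ib_j - ib_i if orientation == "same" else ib_i - ib_j
            if not (1 <= db <= max_gap):
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_anchors(hits: list[HomologyHit], genome_a: Genome, genome_b: Genome,
                  max_gap: int = 50, min_block_pairs: int = 5,
                  diagonal_exclusion: int = 5) -> list[SyntenyBlock]:
    """Chain homologous gene pairs into collinear blocks.

    Blocks are extracted greedily: per chromosome pair, the longest
    orientation-consistent chain is taken (same orientation preferred on
    ties), its anchors removed, and the search repeated while chains reach
    ``min_block_pairs``. For an intra-genome run (same genome on both axes)
    mirror pairs are collapsed and anchors within ``diagonal_exclusion``
    gene positions of the self-diagonal are dropped.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    intra = genome_a is genome_b or genome_a.name == genome_b.name
    om_a = genome_a.order_map()
    om_b = genome_b.order_map()
    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str, int]]] = {}
    seen: set[tuple[str, str]] = set()
    for h in hits:
        if h.query_gene not in om_a or h.subject_gene not in om_b:
            continue
        ca, ia = om_a[h.query_gene]
        cb, ib = om_b[h.subject_gene]
        if intra:
            key = tuple(sorted((h.query_gene, h.subject_gene)))
            if key in seen:
                continue
            seen.add(key)
            if (ca, ia) > (cb, ib):  # upper triangle only
                ca, ia, cb, ib = cb, ib, ca, ia
            if ca == cb and abs(ia - ib) <= diagonal_exclusion:
                continue
        by_pair.setdefault((ca, cb), []).append((ia, ib, h.query_gene, h.subject_gene, h.rank))

    blocks: list[SyntenyBlock] = []
    counter = 0
    for (ca, cb) in sorted(by_pair):
        pool = sorted(by_pair[(ca, cb)])
        while len(pool) >= min_block_pairs:
            anchors = [(ia, ib, k) for k, (ia, ib, *_rest) in enumerate(pool)]
            chains = {o: _best_chain(anchors, max_gap, o) for o in ("same", "inverted")}
            orient = max(("same", "inverted"), key=lambda o: (len(chains[o]), o == "same"))
            chain = chains[orient]
            if len(chain) < min_block_pairs:
                break
            counter += 1
            members = [pool[anchors[c][2]] for c in chain]
            pairs = [(ga, gb, rank) for _ia, _ib, ga, gb, rank in members]
            blocks.append(SyntenyBlock(
                block_id=f"b{counter:04d}", genome_a=genome_a.name, chrom_a=ca,
                genome_b=genome_b.name, chrom_b=cb, pairs=pairs, orientation=orient))
            taken = {anchors[c][2] for c in chain}
            pool = [p for k, p in enumerate(pool) if k not in taken]
    return blocks


def block_summary(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Per chromosome pair: block count, pair count and largest block id.

    Ties for the largest block break lexicographically on block_id.
    """
    if not blocks:
        return pd.DataFrame(columns=["genome_a", "chrom_a", "genome_b", "chrom_b",
                                     "n_blocks", "n_pairs", "largest_block",
                                     "largest_block_pairs"])
    rows = []
    key = lambda b: (b.genome_a, b.chrom_a, b.genome_b, b.chrom_b)
    groups: dict[tuple, list[SyntenyBlock]] = {}
    for b in blocks:
        groups.setdefault(key(b), []).append(b)
    for (ga, ca, gb, cb), bl in sorted(groups.items()):
        largest = max(bl, key=lambda b: (b.n_pairs, [-ord(c) for c in b.block_id]))
        rows.append({"genome_a": ga, "chrom_a": ca, "genome_b": gb, "chrom_b": cb,
                     "n_blocks": len(bl), "n_pairs": sum(b.n_pairs for b in bl),
                     "largest_block": largest.block_id,
                     "largest_block_pairs": largest.n_pairs})
    return pd.DataFrame(rows)
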