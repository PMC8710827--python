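"""Standard-genetic-code tables shared by the sequence simulator and the Ks estimator.

Everything here is precomputed once at import time from the NCBI standard
codon table (via Biopython): per-codon synonymous/nonsynonymous site counts
in the Nei–Gojobori sense, single-nucleotide codon neighbourhoods used by
the substitution simulator, and the 61x61 pairwise difference tables
(synonymous and nonsynonymous differences averaged over all minimal
mutational pathways, pathways through stop codons excluded).
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
CODONS: list[str] = ["".join(p) for p in itertools.product(BASES, repeat=3)]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: list[str] = [c for c in CODONS if c not in STOP_CODONS]

CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

N_SENSE = len(SENSE_CODONS)  # 61


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, ``*`` for a stop codon."""
    return CODON_TO_AA.get(codon, "*")


def _neighbours(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1:])
    return out


def _is_synonymous(c1: str, c2: str) -> bool:
    return translate_codon(c1) == translate_codon(c2) and c1 not in STOP_CODONS


# --- per-codon site counts (Nei–Gojobori): each codon position contributes the
# fraction of its three possible changes that are synonymous; changes to stop
# codons count as nonsynonymous.
SYN_SITES = np.zeros(N_SENSE)
for _c, _i in SENSE_INDEX.items():
    s = 0.0
    for _pos in range(3):
        for _b in BASES:
            if _b == _c[_pos]:
                continue
            _n = _c[:_pos] + _b + _c[_pos + 1:]
            if _n not in STOP_CODONS and translate_codon(_n) == translate_codon(_c):
                s += 1.0 / 3.0
    SYN_SITES[_i] = s
NONSYN_SITES = 3.0 - SYN_SITES

# --- single-step neighbourhoods for the simulator (stop codons never entered)
SYN_NEIGHBOURS: list[list[int]] = []
NONSYN_NEIGHBOURS: list[list[int]] = []
for _c in SENSE_CODONS:
    syn, nonsyn = [], []
    for _n in _neighbours(_c):
        if _n in STOP_CODONS:
            continue
        (syn if translate_codon(_n) == translate_codon(_c) else nonsyn).append(SENSE_INDEX[_n])
    SYN_NEIGHBOURS.append(syn)
    NONSYN_NEIGHBOURS.append(nonsyn)


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts for one codon pair.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are discarded (if every pathway is blocked, all are
    kept and stop-involving steps count as nonsynonymous).
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:  # extremely rare; keep every pathway
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _is_synonymous(a, b) and b not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


# --- 61x61 pairwise difference tables
SD_PAIR = np.zeros((N_SENSE, N_SENSE))
ND_PAIR = np.zeros((N_SENSE, N_SENSE))
for _i, _c1 in enumerate(SENSE_CODONS):
    for _j, _c2 in enumerate(SENSE_CODONS):
        if _i < _j:
            sd, nd = _pathway_counts(_c1, _c2)
            SD_PAIR[_i, _j] = SD_PAIR[_j, _i] = sd
            ND_PAIR[_i, _j] = ND_PAIR[_j, _i] = nd


def codons_to_indices(cds: str) -> np.ndarray:
    """Encode a CDS string as an array of sense-codon indices.

    Raises ``ValueError`` on length not divisible by three or on internal
    stop codons / unknown characters.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    idx = np.empty(len(cds) // 3, dtype=np.int64)
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at nucleotide {i + 1}")
        if codon not in SENSE_INDEX:
            raise ValueError(f"unrecognised codon {codon!r} at nucleotide {i + 1}")
        idx[i // 3] = SENSE_INDEX[codon]
    return idx


def indices_to_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def translate(cds: str) -> str:
    """Translate a stop-free CDS into its amino-acid sequence."""
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))
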