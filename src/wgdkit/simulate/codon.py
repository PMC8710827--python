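"""Codon-sequence simulation at controlled synonymous divergence.

The substitution process is deliberately simple: synonymous events arrive as
a Poisson process at rate ``ds`` per synonymous site and nonsynonymous events
at rate ``omega * ds`` per nonsynonymous site, with site counts taken from
the Nei–Gojobori tables. Every realised change is a single-nucleotide codon
swap drawn uniformly from the codon's synonymous (or sense nonsynonymous)
neighbours, so stop codons are never created. Divergence is therefore exactly
checkable against NG86 counting with Jukes–Cantor correction, which is the
point: the simulator exists to calibrate and test the estimator chain, not to
be a full Markov codon model.
"""

from __future__ import annotations

import numpy as np

from .. import codon as ct

MAX_TARGET_DS = 2.0
MIN_PAIR_CODONS = 50


def random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral CDS as sense-codon indices (uniform over the 61 sense codons)."""
    return rng.integers(0, ct.N_SENSE, size=n_codons)


def evolve_branch(codons: np.ndarray, length_ds: float, omega: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Evolve a codon-index array along a branch of the given synonymous length.

    ``length_ds`` is the expected number of synonymous substitutions per
    synonymous site on this branch. Event counts are drawn per codon from the
    branch-start site counts; events within a codon are applied sequentially.
    """
    if length_ds < 0:
        raise ValueError("branch length must be non-negative")
    out = codons.copy()
    if length_ds == 0:
        return out
    lam_syn = length_ds * ct.SYN_SITES[out]
    lam_non = omega * length_ds * ct.NONSYN_SITES[out]
    n_syn = rng.poisson(lam_syn)
    n_non = rng.poisson(lam_non)
    hit = np.nonzero(n_syn + n_non)[0]
    for i in hit:
        events = ["s"] * int(n_syn[i]) + ["n"] * int(n_non[i])
        rng.shuffle(events)
        c = int(out[i])
        for ev in events:
            nbrs = ct.SYN_NEIGHBOURS[c] if ev == "s" else ct.NONSYN_NEIGHBOURS[c]
            if not nbrs:
                continue  # e.g. no synonymous neighbour for Met/Trp codons
            c = int(nbrs[rng.integers(len(nbrs))])
        out[i] = c
    return out


def evolve_cds_pair(length_codons: int, target_ds: float, omega: float = 0.2,
                    seed: int | np.random.Generator = 0) -> tuple[str, str, dict]:
    """Generate a CDS pair at a target pairwise synonymous divergence.

    Returns ``(cds1, cds2, truth)`` where ``truth`` records the target dS,
    the realised substitution-event counts, and the ancestral CDS. Each copy
    evolves independently for ``target_ds / 2`` so the expected pairwise
    synonymous divergence is ``target_ds`` and the expected nonsynonymous
    divergence ``omega * target_ds``.
    """
    if length_codons < MIN_PAIR_CODONS:
        raise ValueError(f"length_codons must be >= {MIN_PAIR_CODONS}")
    if not 0.0 <= target_ds <= MAX_TARGET_DS:
        raise ValueError(
            f"target_ds {target_ds} outside [0, {MAX_TARGET_DS}]: synonymous sites "
            "saturate beyond that range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = random_cds(length_codons, rng)
    copies = []
    events = []
    for _ in range(2):
        before = anc
        after = evolve_branch(before, target_ds / 2.0, omega, rng)
        events.append(int((after != before).sum()))
        copies.append(after)
    truth = {
        "target_ds": target_ds,
        "omega": omega,
        "n_changed_codons": events,
        "ancestral_cds": ct.indices_to_cds(anc),
    }
    return ct.indices_to_cds(copies[0]), ct.indices_to_cds(copies[1]), truth
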