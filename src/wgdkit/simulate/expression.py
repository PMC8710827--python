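"""Negative-binomial RNA-seq counts with planted salt-response effects.

Counts emulate the salt-treatment design (root and shoot, 0/6/24 h, four
biological replicates): log-normal baseline abundances, NB noise with
variance mu + alpha mu^2, library-size factors, and planted (tissue,
time)-specific fold changes. Paralog pairs can be planted to realise target
proportions of the four expression-fate patterns so the downstream
classifier is scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..io import DesignTable, TISSUES

# observed fate proportions in the study system, used as planting defaults
DEFAULT_CATEGORY_MIX = (0.7868, 0.1541, 0.0591)          # neither, one, both
DEFAULT_PATTERN_MIX = (0.6418, 0.2686, 0.0249, 0.0647)   # I, II, III, IV


def build_design(n_replicates: int = 4, drop_shoot_24_replicate: bool = False) -> DesignTable:
    """The salt-stress sample sheet: root/shoot x 0/6/24 h x replicates.

    ``drop_shoot_24_replicate`` removes one shoot 24 h replicate, mirroring a
    discarded outlier sample; by default all samples are kept.
    """
    rows = []
    for tissue in TISSUES:
        for t in (0, 6, 24):
            for r in range(1, n_replicates + 1):
                if drop_shoot_24_replicate and tissue == "shoot" and t == 24 and r == n_replicates:
                    continue
                rows.append({"sample_id": f"{tissue}_{t}h_r{r}", "tissue": tissue,
                             "time_h": t, "replicate": r})
    return DesignTable(pd.DataFrame(rows))


@dataclass
class ExpressionScenario:
    n_genes: int = 4000
    baseline_log_mean: float = 4.0   # natural-log mean of baseline expression
    baseline_log_sd: float = 1.2
    nb_dispersion: float = 0.1       # alpha in var = mu + alpha mu^2
    de_fraction: float = 0.1         # background genes with planted effects
    de_log2fc: float = 2.0
    design: DesignTable = field(default_factory=build_design)
    category_mix: tuple = DEFAULT_CATEGORY_MIX
    pattern_mix: tuple = DEFAULT_PATTERN_MIX
    library_size_log_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if abs(sum(self.pattern_mix) - 1.0) > 1e-6:
            raise ValueError("pattern_mix must sum to 1")
        if abs(sum(self.category_mix) - 1.0) > 1e-6:
            raise ValueError("category_mix must sum to 1")


def _pattern_effects(pattern: str, rng: np.random.Generator) -> tuple[list, list]:
    """Planted (tissue, direction) effects for the two copies of a pair."""
    t1, t2 = rng.permutation(TISSUES)[:2]
    up_down = ("up", "down") if rng.random() < 0.5 else ("down", "up")
    d1 = rng.choice(["up", "down"])
    if pattern == "I":
        return [(t1, d1)], [(t1, d1)]
    if pattern == "II":
        return [(t1, d1)], [(t2, d1)]
    if pattern == "III":
        return [(t1, up_down[0])], [(t1, up_down[1])]
    # IV: different tissues and opposite directions
    return [(t1, up_down[0])], [(t2, up_down[1])]


def simulate_counts(scenario: ExpressionScenario, paralog_pairs: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate (counts, DE truth, pair truth, gene lengths).

    ``paralog_pairs`` (columns copy_1, copy_2) are planted with categories
    drawn from ``category_mix`` and, for both-DEG pairs, patterns from
    ``pattern_mix``; remaining genes get independent effects at rate
    ``de_fraction``. Planted effects apply at both 6 and 24 h. DE truth lists
    every planted (gene, tissue, time, log2fc); pair truth records each
    pair's planted category/pattern.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    design = sc.design.frame
    pair_genes: list[str] = []
    if paralog_pairs is not None and len(paralog_pairs):
        pair_genes = list(pd.unique(paralog_pairs[["copy_1", "copy_2"]].to_numpy().ravel()))
    n_background = max(sc.n_genes - len(pair_genes), 0)
    genes = pair_genes + [f"bg_{i:05d}" for i in range(n_background)]

    baseline = pd.Series(
        np.exp(rng.normal(sc.baseline_log_mean, sc.baseline_log_sd, size=len(genes))),
        index=genes)
    lengths = pd.Series(rng.integers(500, 4001, size=len(genes)), index=genes,
                        name="length_bp")

    effects: dict[str, list[tuple[str, str]]] = {g: [] for g in genes}
    pair_truth_rows = []
    if paralog_pairs is not None and len(paralog_pairs):
        n_pairs = len(paralog_pairs)
        cats = rng.choice(["neither_deg", "one_deg", "both_deg"], size=n_pairs,
                          p=np.asarray(sc.category_mix))
        pats = rng.choice(list("I II III IV".split()), size=n_pairs,
                          p=np.asarray(sc.pattern_mix))
        for (row, cat, pat) in zip(paralog_pairs.itertuples(index=False), cats, pats):
            if cat == "neither_deg":
                pair_truth_rows.append((row.copy_1, row.copy_2, cat, ""))
                continue
            if cat == "one_deg":
                target = row.copy_1 if rng.random() < 0.5 else row.copy_2
                effects[target].append((rng.choice(TISSUES), rng.choice(["up", "down"])))
                pair_truth_rows.append((row.copy_1, row.copy_2, cat, ""))
                continue
            e1, e2 = _pattern_effects(pat, rng)
            effects[row.copy_1].extend(e1)
            effects[row.copy_2].extend(e2)
            pair_truth_rows.append((row.copy_1, row.copy_2, cat, pat))
    for g in genes[len(pair_genes):]:
        if rng.random() < sc.de_fraction:
            effects[g].append((rng.choice(TISSUES), rng.choice(["up", "down"])))

    sf = np.exp(rng.normal(0.0, sc.library_size_log_sd, size=len(design)))
    counts = np.zeros((len(genes), len(design)), dtype=np.int64)
    de_truth_rows = []
    lfc_matrix = np.zeros((len(genes), len(design)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, effs in effects.items():
        for tissue, direction in effs:
            sign = 1.0 if direction == "up" else -1.0
            for t in (6, 24):
                de_truth_rows.append({"gene_id": g, "tissue": tissue, "time_h": t,
                                      "log2fc": sign * sc.de_log2fc})
                mask = (design["tissue"] == tissue) & (design["time_h"] == t)
                lfc_matrix[gene_index[g], mask.to_numpy()] += sign * sc.de_log2fc

    mu = baseline.to_numpy()[:, None] * (2.0 ** lfc_matrix) * sf[None, :]
    if sc.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / sc.nb_dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=design["sample_id"].tolist())
    de_truth = pd.DataFrame(de_truth_rows,
                            columns=["gene_id", "tissue", "time_h", "log2fc"])
    pair_truth = pd.DataFrame(pair_truth_rows,
                              columns=["copy_1", "copy_2", "category", "pattern"])
    return counts_df, de_truth, pair_truth, lengths
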