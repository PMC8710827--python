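"""Expression quantification, differential-expression calls and duplicate-pair fates.

Quantification is TPM. Differential expression follows the classic
negative-binomial recipe: median-of-ratios size factors, per-gene
method-of-moments dispersion taken as the maximum of the gene-wise estimate
and a fitted mean–dispersion trend (the conservative sharing rule), a Wald
test on the log fold change, and Benjamini–Hochberg correction within each
(tissue, time) contrast. A gene is called differentially expressed when
|log2FC| >= 1 and FDR < 0.05.

Duplicate-pair fates collapse time points into per-copy signatures — the set
of (tissue, direction) values over a copy's DEG calls — and classify pairs
whose copies are both differentially expressed into four patterns:
I identical signatures (redundancy), II disjoint tissues, III same tissues
with opposite directions, IV tissue divergence and direction reversal
combined.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import DesignTable, ValidationError

PATTERNS = ("I", "II", "III", "IV")
CATEGORIES = ("neither_deg", "one_deg", "both_deg")


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: per-kilobase rates renormalised to 1e6 per sample."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValidationError(f"genes without lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        import warnings
        warnings.warn(f"all-zero samples: {denom.index[zero].tolist()}", stacklevel=2)
        denom[zero] = 1.0
    return rate.div(denom, axis=1) * 1e6


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame
    gene_lengths: pd.Series
    design: DesignTable

    def __post_init__(self):
        self.counts = self.counts.loc[:, self.design.sample_ids]
        self.tpm = compute_tpm(self.counts, self.gene_lengths)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors (genes with any zero excluded)."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = np.isfinite(log_ref) & counts.gt(0).all(axis=1)
    if usable.sum() < 1:
        raise ValidationError("no all-positive genes for median-of-ratios")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a + b / mu on genes with a positive moment estimate."""
    ok = (disp > 0) & (mean > 0)
    if ok.sum() < 20:
        a, b = max(np.median(disp[disp > 0]) if (disp > 0).any() else 0.01, 1e-4), 1.0
    else:
        def resid(p):
            return np.log(p[0] + p[1] / mean[ok]) - np.log(disp[ok])
        fit = optimize.least_squares(resid, x0=[0.05, 1.0], bounds=([1e-6, 1e-6], [10, 1e4]),
                                     loss="soft_l1")
        a, b = fit.x
    return a + b / np.maximum(mean, 1e-8)


def call_degs(matrix: ExpressionMatrix, tissue: str, time_h: int,
              fdr_threshold: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """NB Wald test of (tissue, time_h) against the (tissue, 0 h) control.

    Returns one row per tested gene: ``gene_id, tissue, time_h, base_mean,
    log2fc, pvalue, fdr, is_deg, direction``. Genes with zero counts in every
    sample of both groups are excluded from testing and from the BH family.
    """
    if int(time_h) == 0:
        raise ValueError("time_h must be a treatment time point (6 or 24)")
    trt = matrix.design.samples_for(tissue, time_h)
    ctl = matrix.design.samples_for(tissue, 0)
    if len(trt) < 2 or len(ctl) < 2:
        raise ValidationError(
            f"need >= 2 replicates in treatment and control for {tissue} {time_h} h")
    sf = size_factors(matrix.counts)
    norm = matrix.counts.div(sf, axis=1)
    nt_df, nc_df = norm[trt], norm[ctl]
    tested = (matrix.counts[trt + ctl].sum(axis=1) > 0).to_numpy()
    nt = nt_df.to_numpy()[tested]
    nc = nc_df.to_numpy()[tested]
    genes = matrix.counts.index[tested]

    m_t, m_c = nt.mean(axis=1), nc.mean(axis=1)
    v_t, v_c = nt.var(axis=1, ddof=1), nc.var(axis=1, ddof=1)
    # pooled method-of-moments dispersion, then conservative trend sharing
    mean_all = 0.5 * (m_t + m_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_t = (v_t - m_t) / np.square(np.maximum(m_t, 1e-8))
        a_c = (v_c - m_c) / np.square(np.maximum(m_c, 1e-8))
    alpha_mom = np.maximum(0.5 * (np.nan_to_num(a_t) + np.nan_to_num(a_c)), 0.0)
    alpha = np.maximum(alpha_mom, _dispersion_trend(mean_all, alpha_mom))

    pseudo = 0.5
    lfc = np.log2((m_t + pseudo) / (m_c + pseudo))
    var_ln_t = (m_t + alpha * m_t ** 2) / (len(trt) * np.square(m_t + pseudo))
    var_ln_c = (m_c + alpha * m_c ** 2) / (len(ctl) * np.square(m_c + pseudo))
    se_ln = np.sqrt(var_ln_t + var_ln_c)
    z = np.where(se_ln > 0, lfc * np.log(2.0) / np.maximum(se_ln, 1e-12), 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    _, fdr, _, _ = multipletests(pval, method="fdr_bh")
    is_deg = (fdr < fdr_threshold) & (np.abs(lfc) >= lfc_threshold)
    direction = np.where(lfc > 0, "up", "down")
    return pd.DataFrame({
        "gene_id": genes, "tissue": tissue, "time_h": int(time_h),
        "base_mean": mean_all, "log2fc": lfc, "pvalue": pval, "fdr": fdr,
        "is_deg": is_deg, "direction": np.where(is_deg, direction, ""),
    }).reset_index(drop=True)


def call_all_degs(matrix: ExpressionMatrix) -> pd.DataFrame:
    """DEG calls for every (tissue, treatment time) contrast in the design."""
    frames = []
    design = matrix.design.frame
    for tissue in sorted(design["tissue"].unique()):
        for t in sorted(design.loc[design["tissue"] == tissue, "time_h"].unique()):
            if t == 0:
                continue
            frames.append(call_degs(matrix, tissue, int(t)))
    return pd.concat(frames, ignore_index=True)


def fold_regulation(tpm: pd.DataFrame, design: DesignTable, tissue: str, time_h: int,
                    pseudo: float = 0.5) -> pd.Series:
    """Per-gene TPM_treatment / TPM_control with a pseudo-count on both means."""
    trt = design.samples_for(tissue, time_h)
    ctl = design.samples_for(tissue, 0)
    if not trt or not ctl:
        raise ValidationError(f"missing group for {tissue} {time_h} h")
    return (tpm[trt].mean(axis=1) + pseudo) / (tpm[ctl].mean(axis=1) + pseudo)


# ---------------------------------------------------------------------------
# paralog pairing and expression fates
# ---------------------------------------------------------------------------

def pair_paralogs(intra_blocks, labeled_inter_blocks, young_ks_threshold: float | None = None,
                  ks_peaks=None) -> pd.DataFrame:
    """Two focal copies tied to one syntenic reference gene.

    Emits (copy_1, copy_2, reference_gene) for gene pairs that are collinear
    partners in an intra-focal block attributed to the lineage-specific WGD
    (block mean Ks below the midpoint of the two youngest focal Ks peaks, or
    below an explicit ``young_ks_threshold``) and that both sit in
    orthologous focal-vs-reference blocks against the same reference gene.
    Reference genes with more than two focal copies are excluded, and pairs
    are deduplicated.
    """
    if young_ks_threshold is None:
        if ks_peaks is None or len(ks_peaks) < 2:
            raise ValueError(
                "need young_ks_threshold or >= 2 Ks peaks; run detect_ks_peaks first")
        modes = sorted(p.mode for p in ks_peaks)
        young_ks_threshold = 0.5 * (modes[0] + modes[1])
    focal_to_ref: dict[str, set[str]] = {}
    for b in labeled_inter_blocks:
        if b.block_class != "orthologous":
            continue
        for ref_gene, focal_gene, _rank in b.pairs:
            focal_to_ref.setdefault(focal_gene, set()).add(ref_gene)
    candidates = []
    for b in intra_blocks:
        if b.mean_ks is None or b.mean_ks >= young_ks_threshold:
            continue
        for g1, g2, _rank in b.pairs:
            shared = focal_to_ref.get(g1, set()) & focal_to_ref.get(g2, set())
            for r in sorted(shared):
                c1, c2 = sorted((g1, g2))
                candidates.append((c1, c2, r))
    if not candidates:
        return pd.DataFrame(columns=["copy_1", "copy_2", "reference_gene"])
    df = pd.DataFrame(set(candidates), columns=["copy_1", "copy_2", "reference_gene"])
    copies_per_ref = df.melt(id_vars="reference_gene", value_name="copy").groupby(
        "reference_gene")["copy"].nunique()
    ok_refs = copies_per_ref[copies_per_ref <= 2].index
    df = df[df["reference_gene"].isin(ok_refs)]
    return df.sort_values(["reference_gene", "copy_1"]).reset_index(drop=True)


def _signature(degs: pd.DataFrame, gene: str) -> frozenset:
    sub = degs[(degs["gene_id"] == gene) & degs["is_deg"]]
    return frozenset(zip(sub["tissue"], sub["direction"]))


def classify_fate(pairs: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Assign each paralog pair its DEG category and, if both copies respond,
    its divergence pattern (I–IV).

    Time points collapse by union: a copy's signature is the set of
    (tissue, direction) over all its DEG calls, so a copy that goes up at
    6 h and down at 24 h in one tissue carries both directions there.
    """
    needed = {"gene_id", "tissue", "direction", "is_deg"}
    if not needed <= set(degs.columns):
        raise ValidationError(f"DEG table missing columns {sorted(needed - set(degs.columns))}")
    sig_cache: dict[str, frozenset] = {}
    out = pairs.copy()
    categories, patterns = [], []
    for row in out.itertuples(index=False):
        s1 = sig_cache.setdefault(row.copy_1, _signature(degs, row.copy_1))
        s2 = sig_cache.setdefault(row.copy_2, _signature(degs, row.copy_2))
        if not s1 and not s2:
            categories.append("neither_deg")
            patterns.append("")
            continue
        if not s1 or not s2:
            categories.append("one_deg")
            patterns.append("")
            continue
        categories.append("both_deg")
        t1 = {t for t, _ in s1}
        t2 = {t for t, _ in s2}
        opposite = any(d1 != d2 for _, d1 in s1 for _, d2 in s2)
        if s1 == s2:
            patterns.append("I")       # redundancy
        elif opposite and t1 != t2:
            patterns.append("IV")      # tissue divergence and direction reversal
        elif opposite:
            patterns.append("III")     # same tissues, opposite direction
        else:
            patterns.append("II")      # tissue divergence, compatible directions
    out["category"] = categories
    out["pattern"] = patterns
    return out


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage rounded half-up to ``decimals`` (the reporting convention)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def summarize_fate(classified_pairs: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category and, within both-DEG pairs, per pattern."""
    if classified_pairs.empty:
        return pd.DataFrame(columns=["level", "name", "count", "percent"])
    total = len(classified_pairs)
    rows = []
    for cat in CATEGORIES:
        n = int((classified_pairs["category"] == cat).sum())
        rows.append({"level": "category", "name": cat, "count": n,
                     "percent": percent(n, total)})
    both = classified_pairs[classified_pairs["category"] == "both_deg"]
    n_both = len(both)
    for pat in PATTERNS:
        n = int((both["pattern"] == pat).sum())
        rows.append({"level": "pattern", "name": pat, "count": n,
                     "percent": percent(n, n_both) if n_both else 0.0})
    return pd.DataFrame(rows)
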