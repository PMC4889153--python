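"""qRT-PCR relative quantification and reference-gene stability.

The comparative CT (ΔΔCT) chain: technical replicates are averaged after a
per-replicate non-detect filter (CT > 35 omitted; a sample×gene counts as
non-detected only when *all* replicates fail), each sample's gene CT is
normalized by the reference gene (ΔCT), centered on the calibrator group's
mean ΔCT (ΔΔCT), and expressed as a relative quantity RQ = 2^(−ΔΔCT). Species
are compared per gene and tissue with an exact two-sided Wilcoxon rank-sum
test, annotated ``*`` for 0.01 ≤ p ≤ 0.05 and ``**`` for p < 0.01.

Reference-gene candidates are ranked by three standard stability measures:
geNorm's mean pairwise log-ratio variation M (with iterative exclusion and
V(n/n+1) pairwise variation of normalization factors), BestKeeper's raw-CT
dispersion and correlation with the geometric-mean index, and a NormFinder-
style intra-/inter-group variance decomposition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, norm, pearsonr, rankdata

from clonephase.errors import ClonephaseError

CT_COLUMNS = ["species", "tissue", "individual", "gene", "tech_replicate", "ct"]
DEFAULT_CT_CEILING = 35.0
EXACT_WILCOXON_MAX_N = 20


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ClonephaseError(f"CT table missing columns {missing}")
    if (table.ct <= 0).any():
        raise ClonephaseError("CT values must be positive")
    key = ["species", "tissue", "individual", "gene", "tech_replicate"]
    if table.duplicated(key).any():
        raise ClonephaseError("duplicate (sample, gene, replicate) rows in CT table")
    return table


# ---------------------------------------------------------------------------
# ΔΔCT chain


def collapse_technical_replicates(
    table: pd.DataFrame, ct_ceiling: float = DEFAULT_CT_CEILING
) -> pd.DataFrame:
    """Mean CT of the replicates that pass the non-detect filter.

    Replicates with CT above the ceiling are omitted individually; a
    sample×gene is non-detected only if every replicate fails.
    """
    validate_ct_table(table)
    key = ["species", "tissue", "individual", "gene"]

    def agg(grp: pd.DataFrame) -> pd.Series:
        ok = grp.ct[grp.ct <= ct_ceiling]
        if ok.empty:
            return pd.Series({"ct_mean": np.nan, "detected": False, "n_replicates": 0})
        return pd.Series(
            {"ct_mean": ok.mean(), "detected": True, "n_replicates": len(ok)}
        )

    out = table.groupby(key, sort=True).apply(agg, include_groups=False).reset_index()
    out["detected"] = out["detected"].astype(bool)
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator: tuple[str, str],
    ct_ceiling: float = DEFAULT_CT_CEILING,
) -> pd.DataFrame:
    """Per-sample ΔCT, ΔΔCT and RQ = 2^(−ΔΔCT), calibrated to one group.

    ``calibrator`` is a (species, tissue) pair — its mean ΔCT per gene defines
    ΔΔCT = 0, so the calibrator group's geometric-mean RQ is 1 for every gene.
    Samples whose reference gene is non-detected are excluded; genes entirely
    non-detected in a group keep ``detected=False`` rows with RQ = NaN (they
    are reported as not expressed, never as RQ 0).
    """
    collapsed = (
        table
        if "ct_mean" in table.columns
        else collapse_technical_replicates(table, ct_ceiling)
    )
    ref = collapsed[(collapsed.gene == reference_gene) & collapsed.detected]
    ref = ref.set_index(["species", "tissue", "individual"]).ct_mean
    targets = collapsed[collapsed.gene != reference_gene].copy()

    idx = pd.MultiIndex.from_frame(targets[["species", "tissue", "individual"]])
    targets["ref_ct"] = ref.reindex(idx).to_numpy()
    dropped = targets.ref_ct.isna() & targets.detected
    if dropped.any():
        import warnings

        warnings.warn(
            f"excluding {int(dropped.sum())} sample×gene rows lacking a detected "
            f"reference gene ({reference_gene})",
            stacklevel=2,
        )
    targets = targets[~targets.ref_ct.isna() | ~targets.detected]
    targets["delta_ct"] = targets.ct_mean - targets.ref_ct

    cal_sp, cal_ti = calibrator
    out_rows = []
    for gene, grp in targets.groupby("gene", sort=True):
        cal = grp[
            (grp.species == cal_sp) & (grp.tissue == cal_ti) & grp.detected
        ]
        if cal.empty:
            raise ClonephaseError(
                f"calibrator group {calibrator} has no detected sample for {gene}"
            )
        cal_mean = cal.delta_ct.mean()
        g = grp.copy()
        g["delta_delta_ct"] = g.delta_ct - cal_mean
        g["rq"] = np.power(2.0, -g.delta_delta_ct)
        out_rows.append(g)
    out = pd.concat(out_rows, ignore_index=True)
    cols = [
        "species",
        "tissue",
        "individual",
        "gene",
        "ct_mean",
        "detected",
        "delta_ct",
        "delta_delta_ct",
        "rq",
    ]
    return out[cols]


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum


def wilcoxon_exact(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For combined n ≤ 20 the p-value comes from complete enumeration of the
    permutation distribution of the rank sum (mid-ranks for ties); larger
    samples use the normal approximation with tie correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ClonephaseError("both groups must be non-empty")
    n, m = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    t_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0

    if n + m <= EXACT_WILCOXON_MAX_N:
        dev_obs = abs(t_obs - mu) - 1e-9  # guard float noise in rank sums
        total = 0
        hits = 0
        for combo in itertools.combinations(range(n + m), n):
            t = ranks[list(combo)].sum()
            total += 1
            if abs(t - mu) >= dev_obs:
                hits += 1
        return hits / total

    # normal approximation with tie correction
    sizes = pd.Series(ranks).value_counts().to_numpy()
    tie_term = ((sizes**3 - sizes).sum()) / ((n + m) * (n + m - 1))
    var = n * m / 12.0 * ((n + m + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (t_obs - mu) / math.sqrt(var)
    return float(2 * norm.sf(abs(z)))


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def compare_species(
    results: pd.DataFrame,
    value_col: str = "rq",
    adjust: bool = True,
) -> pd.DataFrame:
    """All pairwise species comparisons per gene and tissue.

    Expects the output of :func:`delta_delta_ct`. Groups with no detected
    sample are skipped (flagged, not tested). A Benjamini–Hochberg column is
    emitted alongside the raw p-values for transparency; the star annotation
    uses the raw p-values.
    """
    rows = []
    for (gene, tissue), grp in results.groupby(["gene", "tissue"], sort=True):
        species = sorted(grp.species.unique())
        for sp1, sp2 in itertools.combinations(species, 2):
            g1 = grp[(grp.species == sp1) & grp.detected][value_col].dropna()
            g2 = grp[(grp.species == sp2) & grp.detected][value_col].dropna()
            row = {
                "gene": gene,
                "tissue": tissue,
                "species_1": sp1,
                "species_2": sp2,
                "n_1": len(g1),
                "n_2": len(g2),
            }
            if g1.empty or g2.empty:
                row.update({"p_value": np.nan, "stars": "", "skipped": True})
            else:
                p = wilcoxon_exact(g1, g2)
                row.update({"p_value": p, "stars": stars(p), "skipped": False})
            rows.append(row)
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out["p_bh"] = _benjamini_hochberg(out.p_value.to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan, dtype=float)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm)
    adj = pm[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    q[mask] = vals
    return q


# ---------------------------------------------------------------------------
# Reference-gene stability


@dataclass
class StabilityResult:
    table: pd.DataFrame  # one row per candidate with the method's metrics
    ranking: list[str]  # most stable first
    method: str
    pairwise_variation: dict[str, float] = field(default_factory=dict)  # geNorm V


def _ct_matrix(table: pd.DataFrame, candidates: Sequence[str]) -> pd.DataFrame:
    """Samples × candidate-genes matrix of collapsed CT values."""
    collapsed = (
        table
        if "ct_mean" in table.columns
        else collapse_technical_replicates(table)
    )
    sub = collapsed[collapsed.gene.isin(candidates)]
    if not sub.detected.all():
        raise ClonephaseError("reference-gene candidates must be detected in all samples")
    mat = sub.pivot_table(
        index=["species", "tissue", "individual"], columns="gene", values="ct_mean"
    )
    if mat.isna().any().any():
        raise ClonephaseError("candidate CT matrix has missing sample×gene cells")
    return mat[list(candidates)]


def genorm_stability(table: pd.DataFrame, candidates: Sequence[str]) -> StabilityResult:
    """geNorm expression-stability M with iterative exclusion and V(n/n+1).

    M_j is the mean, over all partner genes k≠j, of the standard deviation
    across samples of log2(q_j/q_k), where q = 2^(−CT). The ranking comes from
    iteratively removing the gene with the highest M; V(n/n+1) is the standard
    deviation of log2 ratios of normalization factors (geometric means of the
    n and n+1 most stable genes).
    """
    if len(candidates) < 3:
        raise ClonephaseError("geNorm requires at least 3 candidate genes")
    mat = _ct_matrix(table, candidates)
    if mat.shape[0] < 2:
        raise ClonephaseError("geNorm requires at least 2 samples")
    logq = -mat  # log2 relative quantity = -CT up to a per-gene constant

    def m_values(genes: list[str]) -> dict[str, float]:
        out = {}
        for gj in genes:
            sds = [
                float(np.std(logq[gj] - logq[gk], ddof=1))
                for gk in genes
                if gk != gj
            ]
            out[gj] = float(np.mean(sds))
        return out

    full_m = m_values(list(candidates))

    remaining = list(candidates)
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = max(remaining, key=lambda g: (m[g], g))
        exclusion_order.append(worst)
        remaining.remove(worst)
    # the final two are tied most-stable; order them by their full-panel M
    ranking = sorted(remaining, key=lambda g: (full_m[g], g)) + exclusion_order[::-1]

    # pairwise variation of normalization factors
    pairwise: dict[str, float] = {}
    for k in range(2, len(candidates)):
        top_k = ranking[:k]
        top_k1 = ranking[: k + 1]
        nf_k = logq[top_k].mean(axis=1)
        nf_k1 = logq[top_k1].mean(axis=1)
        pairwise[f"V{k}/{k + 1}"] = float(np.std(nf_k - nf_k1, ddof=1))

    tab = pd.DataFrame(
        {"gene": list(candidates), "genorm_m": [full_m[g] for g in candidates]}
    )
    return StabilityResult(tab, ranking, "geNorm", pairwise)


def bestkeeper_stability(
    table: pd.DataFrame, candidates: Sequence[str]
) -> StabilityResult:
    """BestKeeper descriptors: raw-CT SD and CV per gene, plus the Pearson
    correlation of each gene with the BestKeeper index (per-sample geometric
    mean of the candidate CTs). Ranking: ascending SD.
    """
    if len(candidates) < 2:
        raise ClonephaseError("BestKeeper requires at least 2 candidate genes")
    mat = _ct_matrix(table, candidates)
    index = np.exp(np.log(mat).mean(axis=1))  # geometric mean of CTs per sample
    rows = []
    for g in candidates:
        ct = mat[g]
        sd = float(ct.std(ddof=1))
        cv = float(100.0 * sd / ct.mean())
        if sd == 0:
            r, r_def = np.nan, False
        else:
            r = float(pearsonr(ct, index)[0])
            r_def = True
        rows.append(
            {
                "gene": g,
                "bestkeeper_sd": sd,
                "bestkeeper_cv": cv,
                "bestkeeper_r": r,
                "r_defined": r_def,
            }
        )
    tab = pd.DataFrame(rows)
    ranking = list(tab.sort_values(["bestkeeper_sd", "gene"]).gene)
    return StabilityResult(tab, ranking, "BestKeeper")


def normfinder_stability(
    table: pd.DataFrame,
    candidates: Sequence[str],
    group_col: str = "species",
) -> StabilityResult:
    """Model-based stability from an intra-/inter-group variance decomposition.

    Following the NormFinder model, each gene's CT (a log-scale quantity) is
    decomposed into sample and gene effects per group; a gene's stability value
    combines its inter-group bias (deviation of its group-specific gene effect
    from the across-group mean) with its intra-group residual variance:

        stability_j = sqrt( var_g(d_gj) + mean_g( s²_gj / n_g ) )

    where d_gj is gene j's group-g effect after removing sample and gene means
    and s²_gj its residual variance within group g. Lower is more stable. With
    a single group the measure degenerates to the intra-group term (a warning
    is emitted).
    """
    if len(candidates) < 2:
        raise ClonephaseError("NormFinder requires at least 2 genes")
    collapsed = (
        table
        if "ct_mean" in table.columns
        else collapse_technical_replicates(table)
    )
    sub = collapsed[collapsed.gene.isin(candidates)]
    if group_col not in sub.columns:
        raise ClonephaseError(f"unknown group column {group_col!r}")
    groups = sorted(sub[group_col].unique())
    if len(groups) < 2:
        import warnings

        warnings.warn(
            "single group: NormFinder degenerates to intra-group variance ranking",
            stacklevel=2,
        )

    d = {g: {} for g in candidates}
    s2 = {g: {} for g in candidates}
    n_g = {}
    for grp_name in groups:
        block = sub[sub[group_col] == grp_name].pivot_table(
            index=["species", "tissue", "individual"], columns="gene", values="ct_mean"
        )[list(candidates)]
        if block.isna().any().any():
            raise ClonephaseError("candidate CT matrix has missing cells")
        # remove per-sample effects, then per-gene group means
        resid = block.sub(block.mean(axis=1), axis=0)
        gene_effect = resid.mean(axis=0)
        n_g[grp_name] = block.shape[0]
        for g in candidates:
            d[g][grp_name] = float(gene_effect[g])
            s2[g][grp_name] = float(resid[g].var(ddof=1)) if block.shape[0] > 1 else 0.0

    rows = []
    for g in candidates:
        effects = np.array([d[g][x] for x in groups])
        bias_var = float(np.var(effects - effects.mean(), ddof=0)) if len(groups) > 1 else 0.0
        intra = float(np.mean([s2[g][x] / max(n_g[x], 1) for x in groups]))
        rows.append({"gene": g, "normfinder_stability": math.sqrt(bias_var + intra)})
    tab = pd.DataFrame(rows)
    ranking = list(tab.sort_values(["normfinder_stability", "gene"]).gene)
    return StabilityResult(tab, ranking, "NormFinder")


# ---------------------------------------------------------------------------
# Amplification efficiency


@dataclass
class EfficiencyResult:
    slope: float
    efficiency: float  # 1.0 == 100%
    r_squared: float
    within_band: bool


def efficiency_from_dilution(
    points: Sequence[tuple[float, float]],
    band: tuple[float, float] = (0.9, 1.1),
) -> EfficiencyResult:
    """Amplification efficiency from a dilution series of (log10 input, CT).

    E = 10^(−1/slope) − 1; a perfect doubling per cycle gives slope −3.3219 and
    E = 1.0. The efficiency check is QC only — quantification assumes E ≈ 1.
    """
    if len(points) < 3:
        raise ClonephaseError("at least 3 dilution points required")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    fit = linregress(x, y)
    if fit.slope >= 0:
        raise ClonephaseError("invalid dilution series: CT must decrease with input")
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyResult(
        slope=float(fit.slope),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
        within_band=bool(band[0] <= eff <= band[1]),
    )


# ---------------------------------------------------------------------------
# Plotting


def plot_expression(results: pd.DataFrame, ax=None):
    """Log-scale RQ per gene × tissue × species as a grouped bar chart.

    Returns the matplotlib Figure. Non-detected groups are omitted from the
    axes (they would be flagged, not plotted at zero).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    detected = results[results.detected & results.rq.notna()]
    genes = sorted(detected.gene.unique())
    fig, axes = plt.subplots(
        1, max(len(genes), 1), figsize=(3 * max(len(genes), 1), 3), squeeze=False
    )
    for k, gene in enumerate(genes):
        ax = axes[0][k]
        sub = detected[detected.gene == gene]
        tissues = sorted(sub.tissue.unique())
        species = sorted(sub.species.unique())
        for si, sp in enumerate(species):
            xs, ys = [], []
            for ti, t in enumerate(tissues):
                vals = sub[(sub.species == sp) & (sub.tissue == t)].rq
                xs.extend(np.full(len(vals), ti + (si - 1) * 0.2))
                ys.extend(vals)
            ax.scatter(xs, ys, s=12, label=sp)
        ax.set_yscale("log")
        ax.set_xticks(range(len(tissues)))
        ax.set_xticklabels(tissues, rotation=45)
        ax.set_title(gene)
        if k == 0:
            ax.set_ylabel("relative quantity (log scale)")
            ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
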