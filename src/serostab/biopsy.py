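"""Cross-tissue validation of serum panels against muscle-biopsy mRNA.

Selected serum proteins are mapped to microarray probes (strict ``_at``
antisense probes only, maximum-variance probe per UniProt accession),
tested for normal-vs-DMD differential expression with an empirical-Bayes
moderated t-statistic, correlated with ordinal histopathology grade within
dystrophinopathy samples (oriented "toward mild/normal": positive means
higher expression with milder disease), and correlated with clinical
outcomes in serum (Spearman). All p-values are adjusted jointly across the
trait panels by Benjamini–Hochberg FDR. Unsupervised clustering orders are
produced for heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BiopsyExpression",
    "map_probes_to_genes",
    "moderated_two_group_test",
    "severity_correlation",
    "serum_outcome_spearman",
    "bh_adjust",
    "heatmap_order",
    "build_validation_table",
]

GRADE_CODE = {"mild": 1, "moderate": 2, "severe": 3}


@dataclass
class BiopsyExpression:
    """Probe/gene × sample log2 matrix with diagnosis and histology grade."""

    expression: pd.DataFrame
    metadata: pd.DataFrame
    probe_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            dup = self.expression.index[self.expression.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dup}")
        missing = set(self.expression.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        diag = self.metadata["diagnosis"]
        bad = diag.index[~diag.isin(["normal", "DMD", "BMD"])].tolist()
        if bad:
            raise ValueError(f"unknown diagnosis for samples: {bad}")
        dyst = self.metadata[diag != "normal"]
        ungraded = dyst.index[~dyst["grade"].isin(GRADE_CODE)].tolist()
        if ungraded:
            raise ValueError(f"dystrophinopathy samples without grade: {ungraded}")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def diagnosis(self) -> pd.Series:
        return self.metadata.loc[self.samples, "diagnosis"]

    def grades(self) -> pd.Series:
        return self.metadata.loc[self.samples, "grade"]


def _is_antisense_probe(probe_id: str) -> bool:
    # plain "<stem>_at" only: extension codes ("_s_at", "_x_at", ...) excluded
    return probe_id.endswith("_at") and probe_id.count("_") == 1


def map_probes_to_genes(
    expr: pd.DataFrame,
    annotations: pd.DataFrame,
    panel_uniprot: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse probes × samples to one row per UniProt accession.

    Probes whose identifier is not a plain ``<stem>_at`` (i.e. carries an
    extension code such as ``_s_at`` or ``_x_at``) are dropped; among the
    surviving probes of each accession the one with maximum variance across
    samples is kept (the most responsive probe captures intergroup
    variation). Returns the collapsed matrix (indexed by gene symbol, with
    ``uniprot`` and ``probe_id`` columns carried alongside) and the list of
    panel accessions with no surviving probe ("unmapped" is a reported
    state, not an error).
    """
    missing = set(expr.index) - set(annotations.index)
    if missing:
        raise ValueError(f"probes without annotation: {sorted(missing)[:10]}")
    keep = [p for p in expr.index if _is_antisense_probe(str(p))]
    sub = expr.loc[keep]
    ann = annotations.loc[keep]
    variances = sub.var(axis=1, ddof=1)
    rows = []
    for uniprot, grp in ann.groupby("uniprot", sort=True):
        probes = list(grp.index)
        best = variances.loc[probes].idxmax()
        rows.append((grp.loc[best, "gene"], uniprot, best))
    chosen = pd.DataFrame(rows, columns=["gene", "uniprot", "probe_id"])
    gene_expr = sub.loc[chosen["probe_id"]].copy()
    gene_expr.index = pd.Index(chosen["gene"], name="gene")
    gene_expr.insert(0, "uniprot", chosen["uniprot"].to_numpy())
    gene_expr.insert(1, "probe_id", chosen["probe_id"].to_numpy())
    unmapped: list[str] = []
    if panel_uniprot is not None:
        mapped = set(chosen["uniprot"])
        unmapped = [u for u in panel_uniprot if u not in mapped]
    return gene_expr, unmapped


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match an inverse-chi-square prior to observed gene variances.

    Works on log variances: with e = log(s²) − ψ(d/2) + log(d/2), the prior
    degrees of freedom d0 solve ψ'(d0/2) = var(e) − ψ'(d/2) and the prior
    variance s0² follows from the mean of e. Infinite d0 (no excess
    dispersion beyond sampling noise) is returned as ``inf``.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        raise ValueError("too few positive gene variances to fit prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_two_group_test(
    expr: pd.DataFrame, groups: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Moderated normal-vs-DMD differential expression on log2 values.

    ``expr`` is genes × samples; ``groups`` labels each sample "normal" or
    "DMD" (other labels are excluded). Per gene, the pooled two-sample
    variance is shrunk toward an inverse-chi-square prior fitted by
    moment-matching across genes, and the moderated t-statistic is referred
    to d0 + d degrees of freedom. The fold change is reported on the linear
    scale and signed ``+`` when the gene is higher in normal muscle.

    Returns a DataFrame with columns log2_diff, fold_change, t, p.
    """
    g = pd.Series(np.asarray(groups), index=expr.columns)
    norm_cols = list(g.index[g == "normal"])
    dmd_cols = list(g.index[g == "DMD"])
    n1, n2 = len(norm_cols), len(dmd_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group (normal={n1}, DMD={n2})")
    a = expr[norm_cols].to_numpy(dtype=float)
    b = expr[dmd_cols].to_numpy(dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    df_resid = float(n1 + n2 - 2)
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    if np.all(s2 == 0):
        warnings.warn("all genes have zero within-group variance; unmoderated t")
        d0, s02 = 0.0, 0.0
        s2_post = s2
        df_total = df_resid
    else:
        try:
            d0, s02 = _fit_variance_prior(s2, df_resid)
        except ValueError:
            warnings.warn("variance-prior fit failed; falling back to unmoderated t")
            d0, s02 = 0.0, 0.0
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    fold = np.sign(diff) * np.exp2(np.abs(diff))
    fold[diff == 0] = 1.0
    return pd.DataFrame(
        {"log2_diff": diff, "fold_change": fold, "t": t, "p": p}, index=expr.index
    )


def severity_correlation(
    expr_gene: np.ndarray | pd.Series, grades: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Toward-mild Spearman correlation of expression with histology grade.

    Grades are coded mild = 1, moderate = 2, severe = 3; the Spearman
    correlation with expression is sign-flipped so a positive value means
    higher expression in milder tissue.
    """
    x = np.asarray(expr_gene, dtype=float)
    gr = np.asarray(
        [GRADE_CODE.get(g, g) if isinstance(g, str) else g for g in np.asarray(grades)],
        dtype=float,
    )
    if len(x) != len(gr) or len(x) < 3:
        raise ValueError("need >=3 aligned graded samples")
    if np.all(gr == gr[0]):
        warnings.warn("all grades equal: severity correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, gr)
    return float(-rho), float(p)


def serum_outcome_spearman(
    protein: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Spearman ρ of a serum protein with an outcome, two-sided p."""
    x = np.asarray(protein, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >=4 aligned subjects")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through unchanged and excluded from the family.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    if (p[mask] <= 0).any() or (p[mask] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def heatmap_order(matrix: pd.DataFrame) -> dict:
    """Unsupervised two-way clustering order for heatmap display.

    Rows (features) are z-scored; average-linkage hierarchical clustering
    with Euclidean distance is applied to rows and columns of the z-scored
    matrix. Constant rows are dropped with a warning. Returns the leaf
    orders and linkage merge lists for both axes (rendering is up to the
    caller).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant rows")
    keep = sd > 0
    rows = matrix.index[keep]
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    row_link = linkage(z, method="average", metric="euclidean")
    col_link = linkage(z.T, method="average", metric="euclidean")
    return {
        "row_order": [rows[i] for i in leaves_list(row_link)],
        "col_order": [matrix.columns[i] for i in leaves_list(col_link)],
        "row_linkage": row_link.tolist(),
        "col_linkage": col_link.tolist(),
    }


def build_validation_table(
    panels: dict[str, pd.DataFrame],
    serum_log: pd.DataFrame,
    outcome_means: pd.DataFrame,
    bexpr: BiopsyExpression,
) -> dict[str, pd.DataFrame]:
    """Per-trait validation tables with jointly BH-adjusted p-values.

    ``panels`` maps trait → DataFrame(protein, uniprot, gene) of selected
    serum proteins; ``serum_log`` is the subjects × proteins log matrix;
    ``outcome_means`` is subjects × traits. Each table reports, per panel
    protein: Spearman correlation of the serum protein with the trait,
    moderated normal-vs-DMD fold change of its muscle mRNA, and the
    toward-mild correlation of mRNA with histology grade. Within each
    validation column, raw p-values from all trait panels are pooled into
    one family before BH adjustment; BMD samples are excluded from the
    two-group test but included in the severity correlation.
    """
    ann = bexpr.probe_annotation
    if ann is None:
        raise ValueError("biopsy expression lacks probe annotations")
    all_uniprot = sorted({u for df in panels.values() for u in df["uniprot"]})
    gene_expr, unmapped = map_probes_to_genes(
        bexpr.expression, ann, panel_uniprot=all_uniprot
    )
    expr_only = gene_expr.drop(columns=["uniprot", "probe_id"])
    by_uniprot = gene_expr.set_index("uniprot")

    diag = bexpr.diagnosis()
    de = moderated_two_group_test(expr_only, diag)
    de.index = gene_expr["uniprot"].to_numpy()

    dyst = [s for s in bexpr.samples if diag[s] != "normal"]
    grades = bexpr.grades()[dyst]

    rows: list[dict] = []
    for trait, panel in panels.items():
        y = outcome_means[trait]
        common = serum_log.index.intersection(y.index)
        for _, rec in panel.iterrows():
            prot, uni, gene = rec["protein"], rec["uniprot"], rec["gene"]
            rho_s, p_s = serum_outcome_spearman(
                serum_log.loc[common, prot], y.loc[common]
            )
            if uni in by_uniprot.index:
                fc = float(de.loc[uni, "fold_change"])
                p_fc = float(de.loc[uni, "p"])
                gvec = by_uniprot.loc[uni].drop(["probe_id"]).astype(float)
                rho_m, p_m = severity_correlation(gvec[dyst], grades)
            else:
                fc = p_fc = rho_m = p_m = float("nan")
            rows.append(
                {
                    "trait": trait,
                    "protein": prot,
                    "uniprot": uni,
                    "gene": gene,
                    "serum_rho": rho_s,
                    "serum_p": p_s,
                    "fold_change": fc,
                    "fold_change_p": p_fc,
                    "severity_rho": rho_m,
                    "severity_p": p_m,
                    "mapped": uni in by_uniprot.index,
                }
            )
    table = pd.DataFrame(rows)
    for col in ("serum_p", "fold_change_p", "severity_p"):
        table[col.replace("_p", "_p_adj")] = bh_adjust(table[col])
    out = {}
    for trait in panels:
        sub = table[table["trait"] == trait].drop(columns=["trait"])
        out[trait] = sub.reset_index(drop=True)
    out["_unmapped"] = pd.DataFrame({"uniprot": unmapped})
    return out
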