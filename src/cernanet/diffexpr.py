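"""Differential expression screening for grouped log2 expression matrices.

The screen follows the standard two-group microarray workflow: per-gene log2
fold change (case minus control), an empirical-Bayes moderated t-statistic in
which each gene's sample variance is shrunk toward a pooled prior estimated by
moment-matching of the log sample variances, and Benjamini-Hochberg control of
the false discovery rate.  Genes are called differentially expressed when
|log2FC| exceeds a fold-change threshold and the adjusted P falls below an FDR
threshold (both strict by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ContractError, LoadError

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)
BIOTYPES = ("lncRNA", "mRNA")


# ---------------------------------------------------------------------------
# Expression container
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for biotyped genes across grouped samples.

    Parameters
    ----------
    values
        genes x samples frame of log2 expression; index = gene ids,
        columns = sample ids.
    groups
        sample id -> ``"case"`` or ``"control"``.
    biotype
        gene id -> ``"lncRNA"`` or ``"mRNA"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    biotype: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate gene ids after collapse: {dups[:5]}")
        if v.columns.has_duplicates:
            raise LoadError("duplicate sample ids in expression matrix")
        if v.isna().any().any():
            raise LoadError("expression matrix contains missing values")
        missing_group = [s for s in v.columns if s not in self.groups.index]
        if missing_group:
            raise LoadError(
                f"samples missing from groups file: {missing_group}"
            )
        bad_groups = set(self.groups.loc[list(v.columns)]) - set(GROUPS)
        if bad_groups:
            raise LoadError(f"unknown group labels: {sorted(bad_groups)}")
        missing_bt = [g for g in v.index if g not in self.biotype.index]
        if missing_bt:
            raise LoadError(
                f"genes missing from biotype file: {missing_bt[:5]}"
            )
        bad_bt = set(self.biotype.loc[list(v.index)]) - set(BIOTYPES)
        if bad_bt:
            raise LoadError(f"unknown biotype labels: {sorted(bad_bt)}")
        for grp in GROUPS:
            if len(self.samples_in(grp)) < 2:
                raise LoadError(f"fewer than 2 samples in group '{grp}'")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def load_expression(expr_path, groups_path, biotype_path) -> ExpressionMatrix:
    """Load and validate an expression matrix from the three standard TSVs.

    Duplicate gene ids (multiple probes mapping to one symbol) are collapsed
    by the per-sample mean.  Every sample needs a group and every gene a
    biotype; a non-numeric cell is reported with its location.
    """
    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    try:
        vals = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise LoadError(
                    f"non-numeric value at gene '{row}', sample '{col}'"
                ) from None
        raise
    if vals.index.has_duplicates:
        vals = vals.groupby(level=0, sort=False).mean()

    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    groups = pd.Series(
        groups_df.iloc[:, 1].values, index=groups_df.iloc[:, 0].values
    )
    biotype_df = pd.read_csv(biotype_path, sep="\t", dtype=str)
    biotype = pd.Series(
        biotype_df.iloc[:, 1].values, index=biotype_df.iloc[:, 0].values
    )
    return ExpressionMatrix(values=vals, groups=groups, biotype=biotype)


# ---------------------------------------------------------------------------
# Fold change
# ---------------------------------------------------------------------------

def log2_fold_change(m: ExpressionMatrix, gene: str) -> float:
    """mean(case) - mean(control) on the log2 scale for one gene."""
    if gene not in m.values.index:
        raise KeyError(gene)
    row = m.values.loc[gene]
    return float(row[m.samples_in(CASE)].mean() - row[m.samples_in(CONTROL)].mean())


def _log2fc_all(m: ExpressionMatrix) -> pd.Series:
    case = m.values[m.samples_in(CASE)]
    ctrl = m.values[m.samples_in(CONTROL)]
    return case.mean(axis=1) - ctrl.mean(axis=1)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone reparameterization recommended for this inversion;
    converges in a handful of steps for any y > 0.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


@dataclass(frozen=True)
class VariancePrior:
    """Moment-matched prior for the gene-variance distribution.

    df is the prior degrees of freedom d0 (np.inf when the observed log
    variances are no more dispersed than sampling alone explains); scale is
    the prior variance s0^2.
    """

    df: float
    scale: float


def fit_variance_prior(s2: np.ndarray, df_resid: int) -> VariancePrior:
    """Estimate (d0, s0^2) from per-gene sample variances.

    Matches the first two moments of log(s2) to the scaled F-distribution
    implied by the hierarchical inverse-chi-square model: under the model,
    log(s2_g) = const + log-chi2 noise with variance trigamma(d/2) plus
    between-gene variance trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return VariancePrior(df=0.0, scale=float(np.median(s2)) if len(s2) else 1.0)
    z = np.log(s2[ok])
    d = float(df_resid)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0sq = np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        s0sq = np.exp(emean)
    return VariancePrior(df=float(d0), scale=float(s0sq))


def moderated_t(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene moderated t-statistic and two-sided raw P value.

    The gene-wise pooled sample variance (residual df d = n1+n2-2) is shrunk
    toward the moment-matched prior: s2_post = (d0*s0^2 + d*s2)/(d0+d), and
    t = log2FC / sqrt(s2_post*(1/n1+1/n2)) is referred to a t-distribution
    with d0+d degrees of freedom (the normal limit when d0 is infinite).

    A single-gene matrix carries no information to pool, so the statistic
    falls back to the ordinary two-sample pooled-variance t.
    A gene with zero variance and zero mean difference yields t=0, p=1.
    """
    case = m.values[m.samples_in(CASE)].to_numpy(float)
    ctrl = m.values[m.samples_in(CONTROL)].to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ContractError("need >=2 samples per group for moderated t")
    d = n1 + n2 - 2
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if len(s2) < 2:
        prior = VariancePrior(df=0.0, scale=0.0)
    else:
        prior = fit_variance_prior(s2, d)
    d0, s0sq = prior.df, prior.scale

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    # zero posterior variance with zero difference: no evidence, t=0
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    if np.any((se == 0) & (diff != 0)):
        raise ContractError(
            "zero posterior variance with nonzero difference; "
            "degenerate constant-valued input"
        )
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"t_stat": t, "p_raw": p}, index=m.values.index
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_scale"] = s0sq
    out.attrs["residual_df"] = d
    return out


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, original order.

    adj_(i) = min_{j>=i} ( p_(j) * m / j ), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ContractError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContractError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------

@dataclass
class DESets:
    """Differentially expressed genes partitioned by biotype and direction."""

    de_lnc_up: set = field(default_factory=set)
    de_lnc_down: set = field(default_factory=set)
    de_mrna_up: set = field(default_factory=set)
    de_mrna_down: set = field(default_factory=set)

    @property
    def de_lnc(self) -> set:
        return self.de_lnc_up | self.de_lnc_down

    @property
    def de_mrna(self) -> set:
        return self.de_mrna_up | self.de_mrna_down

    @property
    def all_de(self) -> set:
        return self.de_lnc | self.de_mrna


def differential_expression(
    m: ExpressionMatrix,
    fc_threshold: float = 1.0,
    adj_threshold: float = 0.05,
    strict: bool = True,
) -> pd.DataFrame:
    """Full DE table: log2fc, moderated t, raw and BH-adjusted P, call flags.

    ``strict=True`` uses |log2FC| > fc and p_adj < alpha; ``strict=False``
    relaxes both to >= / <=.
    """
    tt = moderated_t(m)
    lfc = _log2fc_all(m)
    p_adj = adjust_bh(tt["p_raw"].to_numpy())
    table = pd.DataFrame(
        {
            "gene_id": m.values.index,
            "biotype": self_biotypes(m),
            "log2fc": lfc.to_numpy(),
            "t_stat": tt["t_stat"].to_numpy(),
            "p_raw": tt["p_raw"].to_numpy(),
            "p_adj": p_adj,
        }
    )
    if strict:
        is_de = (table["log2fc"].abs() > fc_threshold) & (table["p_adj"] < adj_threshold)
    else:
        is_de = (table["log2fc"].abs() >= fc_threshold) & (table["p_adj"] <= adj_threshold)
    table["is_de"] = is_de
    table["direction"] = np.where(
        ~is_de, "none", np.where(table["log2fc"] > 0, "up", "down")
    )
    table.attrs.update(tt.attrs)
    return table


def self_biotypes(m: ExpressionMatrix) -> np.ndarray:
    return m.biotype.loc[list(m.values.index)].to_numpy()


def select_de(
    records: pd.DataFrame,
    fc_threshold: float = 1.0,
    adj_threshold: float = 0.05,
    strict: bool = True,
) -> DESets:
    """Call DE genes from a table with log2fc/p_adj and partition them.

    Strict thresholds by default: |log2FC| > fc_threshold AND
    p_adj < adj_threshold; a gene sitting exactly on either threshold is
    excluded.
    """
    if strict:
        is_de = (records["log2fc"].abs() > fc_threshold) & (
            records["p_adj"] < adj_threshold
        )
    else:
        is_de = (records["log2fc"].abs() >= fc_threshold) & (
            records["p_adj"] <= adj_threshold
        )
    sets = DESets()
    de = records[is_de]
    for _, r in de.iterrows():
        key = (
            "de_lnc_" if r["biotype"] == "lncRNA" else "de_mrna_"
        ) + ("up" if r["log2fc"] > 0 else "down")
        getattr(sets, key).add(r["gene_id"])
    return sets


def write_de_table(records: pd.DataFrame, path) -> None:
    cols = ["gene_id", "biotype", "log2fc", "t_stat", "p_raw", "p_adj", "direction"]
    records[cols].to_csv(path, sep="\t", index=False)
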