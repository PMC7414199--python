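"""Two-study differential-expression meta-analysis.

Per-study two-group testing on log2 expression (pooled-variance Student t
or an empirical-Bayes moderated t), Fisher sum-of-logs combination of the
per-study p-values across studies, Benjamini-Hochberg FDR adjustment, and
a fold-change screen that splits significant genes into up- and
down-regulated lists.

The combined statistic for one gene over K studies is

    X = -2 * sum_k ln(p_k),     X ~ chi-square with 2K df under H0,

and the combined p-value is the chi-square upper tail at X.  Combination is
applied to genes common to all studies; genes private to one study are
reported separately and never screened.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")

#: Floor used when a zero-pooled-variance gene has unequal group means.
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class ExpressionStudy:
    """One study's log2 gene x sample expression matrix with group labels.

    ``data`` is genes x samples; ``groups`` maps each sample to
    ``"case"`` or ``"control"``.
    """

    study_id: str
    data: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.data.columns)
        if self.groups.isna().any():
            missing = list(self.data.columns[self.groups.isna()])
            raise ValueError(
                f"study {self.study_id!r}: samples missing a group label: {missing}")
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: unknown group labels {bad}; "
                f"expected one of {GROUPS}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                f"study {self.study_id!r}: need >=2 case and >=2 control "
                f"samples, got {self.n_case} case / {self.n_control} control")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError(
                f"study {self.study_id!r}: expression matrix contains "
                "missing or non-finite values")
        if self.data.index.duplicated().any():
            dup = list(self.data.index[self.data.index.duplicated()][:5])
            raise ValueError(
                f"study {self.study_id!r}: duplicated gene identifiers {dup}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())

    @property
    def n_samples(self) -> int:
        return len(self.data.columns)

    def case_matrix(self) -> pd.DataFrame:
        return self.data.loc[:, self.groups[self.groups == "case"].index]

    def control_matrix(self) -> pd.DataFrame:
        return self.data.loc[:, self.groups[self.groups == "control"].index]


def collapse_probes(
    probe_study: ExpressionStudy,
    probe_to_gene: pd.DataFrame,
) -> ExpressionStudy:
    """Collapse a probe-level matrix to gene level by averaging.

    Values of all probes mapped to the same gene are averaged per sample
    (arithmetic mean on the log2 scale).  Unmapped probes are dropped and
    counted in the log.  A probe mapped to several genes contributes to
    each of them.

    ``probe_to_gene`` needs columns ``probe`` and ``gene``; one row per
    (probe, gene) pair.
    """
    if probe_to_gene.empty:
        raise ValueError("probe-to-gene mapping is empty")
    for col in ("probe", "gene"):
        if col not in probe_to_gene.columns:
            raise ValueError(f"probe map lacks required column {col!r}")
    mapping = probe_to_gene[["probe", "gene"]].drop_duplicates()
    mapped = mapping[mapping["probe"].isin(probe_study.data.index)]
    n_unmapped = probe_study.data.index.size - mapped["probe"].nunique()
    if n_unmapped:
        logger.info(
            "collapse_probes[%s]: dropped %d unmapped probes",
            probe_study.study_id, n_unmapped)
    if mapped.empty:
        raise ValueError(
            f"study {probe_study.study_id!r}: no probe in the matrix is "
            "covered by the mapping")
    expanded = probe_study.data.loc[mapped["probe"]]
    expanded.index = pd.Index(mapped["gene"], name="gene")
    collapsed = expanded.groupby(level=0, sort=True).mean()
    return ExpressionStudy(
        study_id=probe_study.study_id,
        data=collapsed,
        groups=probe_study.groups,
    )


# ---------------------------------------------------------------------------
# per-study testing


def _moment_match_prior(variances: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-inverse-chi-square variance prior.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0), the marginal
    moments of the gene-wise sample variances give

        E[s^2]   = s0^2 * d0 / (d0 - 2)
        Var[s^2] = 2 s0^4 d0^2 (df + d0 - 2) / (df (d0-2)^2 (d0-4)),

    which moment matching inverts.  When the observed variances are less
    dispersed than a chi-square with ``df`` degrees of freedom allows, the
    prior df is effectively infinite and full pooling is returned.
    """
    v = variances[np.isfinite(variances) & (variances > 0)]
    if v.size < 2:
        return math.inf, float(np.mean(variances)) if variances.size else 1.0
    m1 = float(np.mean(v))
    m2 = float(np.var(v, ddof=1))
    ratio = m2 / (m1 * m1)
    denom = ratio * df - 2.0
    if denom <= 0:
        return math.inf, m1
    d0 = (2.0 * df - 4.0 + 4.0 * ratio * df) / denom
    if d0 <= 4.0:
        # heavy-tailed variance distribution: weak shrinkage
        d0 = max(d0, 0.1)
        s0_sq = m1
    else:
        s0_sq = m1 * (d0 - 2.0) / d0
    return d0, s0_sq


def per_study_test(
    study: ExpressionStudy,
    test_mode: str = "moderated",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-sided two-group test per gene.

    Returns a frame indexed by gene with columns ``lfc`` (case mean minus
    control mean, log2 scale), ``p``, ``t``, ``df`` and ``zero_variance``.

    ``student`` uses the pooled-variance Student t with n1+n2-2 df.
    ``moderated`` shrinks each gene's pooled variance toward a prior
    variance s0^2 estimated from all genes,

        s~^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

    and refers t = lfc / sqrt(s~^2 (1/n1 + 1/n2)) to a t distribution with
    df + d0 degrees of freedom.  ``d0_override`` fixes d0 (0 recovers the
    Student test exactly).

    Zero-pooled-variance genes with unequal group means get the smallest
    representable positive p and are flagged.
    """
    if test_mode not in ("student", "moderated"):
        raise ValueError(f"unknown test_mode {test_mode!r}")
    case = study.case_matrix().to_numpy(dtype=float)
    ctrl = study.control_matrix().to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    df_resid = n1 + n2 - 2
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    pooled_var = ss / df_resid

    if test_mode == "student":
        d0, s0_sq = 0.0, 0.0
    else:
        if d0_override is not None:
            d0 = float(d0_override)
            _, s0_sq = _moment_match_prior(pooled_var, df_resid)
        else:
            d0, s0_sq = _moment_match_prior(pooled_var, df_resid)

    if math.isinf(d0):
        shrunk_var = np.full_like(pooled_var, s0_sq)
        df_total = math.inf
    else:
        shrunk_var = (d0 * s0_sq + df_resid * pooled_var) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(shrunk_var * (1.0 / n1 + 1.0 / n2))
    zero_var = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(zero_var, 0.0, lfc / np.where(zero_var, 1.0, se))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.minimum(p, 1.0)

    degenerate = zero_var & (lfc != 0.0)
    p = np.where(degenerate, P_FLOOR, p)
    p = np.where(zero_var & (lfc == 0.0), 1.0, p)
    if degenerate.any():
        logger.warning(
            "per_study_test[%s]: %d zero-variance genes with unequal means; "
            "p clamped to smallest positive value",
            study.study_id, int(degenerate.sum()))

    t_out = np.asarray(tstat, dtype=float).copy()
    t_out[degenerate] = np.sign(lfc[degenerate]) * np.inf
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "t": t_out,
            "df": float(df_total),
            "zero_variance": zero_var,
        },
        index=study.genes,
    )


# ---------------------------------------------------------------------------
# combination and screening


def fisher_combine(pvalues) -> tuple[float, float]:
    """Fisher sum-of-logs combination of K independent p-values.

    Returns ``(X, p_comb)`` with X = -2 sum(ln p) referred to a chi-square
    distribution with 2K degrees of freedom.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(p <= 0.0):
        raise ValueError("p-values must be > 0 (log undefined at 0)")
    if np.any(p > 1.0):
        raise ValueError("p-values must be <= 1")
    x = float(-2.0 * np.sum(np.log(p)))
    p_comb = float(stats.chi2.sf(x, df=2 * p.size))
    return x, p_comb


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(lfcs: np.ndarray, mean_lfc: float) -> str:
    pos = np.any(lfcs > 0)
    neg = np.any(lfcs < 0)
    if pos and neg:
        return "conflict"
    if mean_lfc > 0:
        return "up"
    if mean_lfc < 0:
        return "down"
    return "ns"


def meta_analyze(
    studies: list[ExpressionStudy],
    test_mode: str = "moderated",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run per-study tests and combine them gene-wise across studies.

    Returns ``(deg_table, study_specific)``.  ``deg_table`` covers genes
    common to every study, one row per gene, with per-study ``p_<id>`` and
    ``lfc_<id>`` columns, the Fisher statistic ``chi2_stat``, combined
    ``p_comb``, ``bh_p``, the sample-size-weighted ``mean_lfc`` and a
    ``direction`` call in {up, down, conflict, ns}.  ``study_specific``
    lists genes private to a subset of studies; they are never screened.
    """
    if not studies:
        raise ValueError("need at least one study")
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study ids: {ids}")

    per_study = {s.study_id: per_study_test(s, test_mode=test_mode) for s in studies}
    common = per_study[ids[0]].index
    for sid in ids[1:]:
        common = common.intersection(per_study[sid].index)
    common = common.sort_values()

    weights = np.array([s.n_samples for s in studies], dtype=float)
    pmat = np.column_stack([per_study[sid].loc[common, "p"] for sid in ids])
    lmat = np.column_stack([per_study[sid].loc[common, "lfc"] for sid in ids])

    chi2_stat = -2.0 * np.log(pmat).sum(axis=1)
    p_comb = stats.chi2.sf(chi2_stat, df=2 * len(ids))
    bh_p = bh_adjust(p_comb)
    mean_lfc = lmat @ (weights / weights.sum())
    direction = [
        _direction(lmat[i], mean_lfc[i]) for i in range(len(common))
    ]

    table = pd.DataFrame(index=common)
    table.index.name = "gene"
    for j, sid in enumerate(ids):
        table[f"p_{sid}"] = pmat[:, j]
        table[f"lfc_{sid}"] = lmat[:, j]
    table["chi2_stat"] = chi2_stat
    table["p_comb"] = p_comb
    table["bh_p"] = bh_p
    table["mean_lfc"] = mean_lfc
    table["direction"] = direction

    rows = []
    for sid in ids:
        private = per_study[sid].index.difference(common)
        for g in private:
            rec = per_study[sid].loc[g]
            rows.append({"gene": g, "study_id": sid,
                         "p": rec["p"], "lfc": rec["lfc"]})
    study_specific = pd.DataFrame(
        rows, columns=["gene", "study_id", "p", "lfc"]
    ).sort_values(["gene", "study_id"]).reset_index(drop=True)

    logger.info(
        "meta_analyze: %d common genes across %d studies, %d study-specific",
        len(common), len(ids), len(study_specific))
    return table, study_specific


def screen_degs(
    deg_table: pd.DataFrame,
    de_alpha: float = 0.05,
    lfc_cut: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Screen the combined table into up/down DEG lists.

    A gene is upregulated iff ``bh_p < de_alpha`` and ``mean_lfc > lfc_cut``
    with a consistent positive direction; downregulated symmetrically.
    Both inequalities are strict.  Direction-conflicted significant genes
    are excluded and logged.
    """
    sig = deg_table["bh_p"] < de_alpha
    up = deg_table.index[
        sig & (deg_table["mean_lfc"] > lfc_cut) & (deg_table["direction"] == "up")
    ]
    down = deg_table.index[
        sig & (deg_table["mean_lfc"] < -lfc_cut) & (deg_table["direction"] == "down")
    ]
    n_conflict = int((sig & (deg_table["direction"] == "conflict")).sum())
    if n_conflict:
        logger.info(
            "screen_degs: excluded %d significant direction-conflicted genes",
            n_conflict)
    logger.info("screen_degs: %d up, %d down", len(up), len(down))
    return sorted(up), sorted(down)
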