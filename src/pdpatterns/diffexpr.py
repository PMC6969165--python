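"""Placebo-vs-treatment differential expression.

Three layers of contrast, mirroring a per-disease, per-visit significance
grid plus its pooled margins:

* :func:`moderated_de` — per-analyte linear model of log2 expression on
  treatment arm at one visit, with empirical-Bayes variance moderation
  (per-analyte residual variances shrunk toward a common prior fitted by
  moment matching on the log sample variances) and BH FDR;
* :func:`mixed_de` — pooled visits: per-analyte random-intercept model
  (subject) with fixed arm, visit and arm x visit effects, REML-fitted;
  the arm main effect is tested with sum-coded visits so it is the
  average arm effect across the pooled visits;
* :func:`meta_de` — pooled diseases: one fixed-effect model on the
  analyte intersection with disease as a covariate and a shared arm
  effect, moderated as above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ._stats import fdr_bh, squeeze_var
from .preprocess import AnalytePanel

__all__ = ["DEResult", "MixedEffectFit", "moderated_de", "mixed_de", "meta_de"]

TREATED, CONTROL = "apremilast", "placebo"


@dataclass
class DEResult:
    table: pd.DataFrame           # analyte-indexed: effect, t, p, fdr
    contrast: str
    prior_df: float = np.nan      # d0 (0 = no shrinkage, inf = full pooling)
    prior_var: float = np.nan     # s0^2
    excluded: list = field(default_factory=list)  # analytes dropped (singular fits)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["fdr"] < 0.05]


@dataclass
class MixedEffectFit:
    analyte: str
    fixed_effects: dict           # term -> (beta, SE, p)
    subject_var: float
    residual_var: float
    converged: bool


def _moderated_lm(Y: np.ndarray, design: np.ndarray, coef: int,
                  prior_df=None) -> tuple[pd.DataFrame, float, float]:
    """Fit one linear model per column of Y; moderate the tested coefficient.

    ``prior_df=None`` estimates the prior df by moment matching;
    ``prior_df=0`` switches shrinkage off (ordinary t statistics).
    """
    n, k = design.shape
    df = n - k
    if df <= 0:
        raise ValueError(f"zero residual degrees of freedom (n={n}, terms={k})")
    xtx_inv = np.linalg.pinv(design.T @ design)
    beta = xtx_inv @ design.T @ Y
    resid = Y - design @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    stdev_unscaled = np.sqrt(xtx_inv[coef, coef])

    if prior_df == 0:
        d0, s0sq, post = 0.0, float("nan"), sigma2
    elif prior_df is None:
        d0, s0sq, post = squeeze_var(sigma2, df)
    else:
        raise ValueError("prior_df must be None (estimate) or 0 (off)")

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[coef] / (np.sqrt(post) * stdev_unscaled)
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame({"effect": beta[coef], "t": t, "p": p})
    return table, d0, s0sq


def _check_arms(arm: pd.Series, min_per_arm: int = 3) -> None:
    counts = arm.value_counts()
    for label in (TREATED, CONTROL):
        if counts.get(label, 0) < min_per_arm:
            raise ValueError(
                f"arm {label!r} has {counts.get(label, 0)} samples; "
                f"need >= {min_per_arm}"
            )


def moderated_de(
    panel: AnalytePanel,
    meta: pd.DataFrame,
    visit: str,
    prior_df=None,
    contrast: str = "",
) -> DEResult:
    """Treated-vs-placebo contrast at one visit with moderated t statistics."""
    if panel.state != "normalized":
        raise ValueError("differential expression runs on the normalized panel")
    m = meta.loc[meta.index.intersection(panel.samples)]
    m = m[m["visit"] == visit]
    _check_arms(m["arm"])
    Y = panel.values.loc[m.index].to_numpy(dtype=float)
    treated = (m["arm"] == TREATED).to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(treated), treated])
    table, d0, s0sq = _moderated_lm(Y, design, coef=1, prior_df=prior_df)
    table.index = panel.analytes
    table["fdr"] = fdr_bh(table["p"].to_numpy())
    return DEResult(table=table, contrast=contrast or f"arm@{visit}",
                    prior_df=d0, prior_var=s0sq)


def mixed_de(
    panel: AnalytePanel,
    meta: pd.DataFrame,
    visits: tuple = ("week4", "week16"),
    contrast: str = "",
) -> tuple[DEResult, dict]:
    """Pooled-visit random-intercept models, one per analyte.

    Returns the DE table plus a per-analyte :class:`MixedEffectFit`.
    Analytes whose REML fit fails are flagged, excluded from the BH family
    and reported in ``DEResult.excluded``.
    """
    if panel.state != "normalized":
        raise ValueError("differential expression runs on the normalized panel")
    m = meta.loc[meta.index.intersection(panel.samples)]
    m = m[m["visit"].isin(visits)].copy()
    _check_arms(m["arm"])
    m["arm_t"] = (m["arm"] == TREATED).astype(float)
    pooled_disease = m["disease"].nunique() > 1
    rhs = "arm_t * C(visit, Sum)"
    if pooled_disease:
        rhs += " + C(disease)"

    rows, fits, excluded = [], {}, []
    for a in panel.analytes:
        df = m.copy()
        df["expr"] = panel.values.loc[df.index, a]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(f"expr ~ {rhs}", data=df, groups=df["subject"])
                fit = model.fit(reml=True)
            if not fit.converged or not np.isfinite(fit.bse["arm_t"]):
                raise RuntimeError("non-converged or singular fit")
        except Exception as err:  # singular / failed fits
            warnings.warn(f"mixed model failed for {a}: {err}")
            excluded.append(a)
            continue
        beta = float(fit.params["arm_t"])
        se = float(fit.bse["arm_t"])
        p = float(fit.pvalues["arm_t"])
        rows.append({"analyte": a, "effect": beta, "t": beta / se, "p": p})
        fits[a] = MixedEffectFit(
            analyte=a,
            fixed_effects={term: (float(fit.params[term]), float(fit.bse[term]),
                                  float(fit.pvalues[term]))
                           for term in fit.params.index if term != "Group Var"},
            subject_var=float(fit.cov_re.iloc[0, 0]),
            residual_var=float(fit.scale),
            converged=bool(fit.converged),
        )
    if not rows:
        raise ValueError("every analyte failed the mixed-model fit")
    table = pd.DataFrame(rows).set_index("analyte")
    table["fdr"] = fdr_bh(table["p"].to_numpy())
    label = contrast or f"arm@{'+'.join(visits)}"
    return DEResult(table=table, contrast=label, excluded=excluded), fits


def meta_de(
    panels: dict,
    meta: pd.DataFrame,
    visit: str,
    prior_df=None,
    interaction: bool = False,
    contrast: str = "",
) -> DEResult:
    """Pooled-disease contrast on the analyte intersection.

    One fixed-effect model per analyte with a shared arm effect and disease
    as a covariate.  With ``interaction=True`` arm x disease terms are added
    (the arm coefficient then refers to the reference disease); the default
    assumes a common arm effect.
    """
    diseases = sorted(panels)
    common = None
    for d in diseases:
        cols = set(panels[d].analytes)
        common = cols if common is None else (common & cols)
    common = sorted(common or [])
    if not common:
        raise ValueError("empty analyte intersection across diseases")

    blocks, metas = [], []
    for d in diseases:
        p = panels[d]
        m = meta.loc[meta.index.intersection(p.samples)]
        m = m[(m["visit"] == visit) & (m["disease"] == d)]
        blocks.append(p.values.loc[m.index, common])
        metas.append(m)
    Y = pd.concat(blocks).to_numpy(dtype=float)
    m = pd.concat(metas)
    _check_arms(m["arm"])

    treated = (m["arm"] == TREATED).to_numpy(dtype=float)
    cols = [np.ones_like(treated), treated]
    for d in diseases[1:]:
        cols.append((m["disease"] == d).to_numpy(dtype=float))
    if interaction:
        for d in diseases[1:]:
            cols.append(treated * (m["disease"] == d).to_numpy(dtype=float))
    design = np.column_stack(cols)
    table, d0, s0sq = _moderated_lm(Y, design, coef=1, prior_df=prior_df)
    table.index = pd.Index(common, name="analyte")
    table["fdr"] = fdr_bh(table["p"].to_numpy())
    label = contrast or f"meta@{visit}" + (":interaction" if interaction else "")
    return DEResult(table=table, contrast=label, prior_df=d0, prior_var=s0sq)
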