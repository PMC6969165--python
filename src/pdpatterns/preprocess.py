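"""Panel preprocessing: QC filtering, imputation, log2 + quantile normalization.

Raw immunoassay panels (pg/mL) carry two kinds of unusable cells: values
below the analyte's lower limit of quantitation (LLOQ, censored) and
outright missing measurements.  The preprocessing contract is:

1. ``qc_filter`` — drop analytes, then samples, whose combined
   missing + censored fraction exceeds a threshold (default 0.5, strict).
2. ``impute`` — remaining missing cells are set to the analyte's observed
   mean; remaining censored cells to half the analyte's LLOQ.
3. ``log2_quantile_normalize`` — log2 transform followed by quantile
   normalization across samples, forcing every sample onto the common
   rank-wise mean distribution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "AnalytePanel",
    "QCReport",
    "qc_filter",
    "impute",
    "log2_quantile_normalize",
    "read_panel",
    "write_panel",
    "read_meta",
]

#: sentinel written to TSV cells that were measured below the LLOQ
CENSORED_TOKEN = "<LLOQ"


@dataclass
class AnalytePanel:
    """Sample-by-analyte concentration matrix with LLOQ metadata.

    ``values`` is a samples x analytes float frame; cells flagged in
    ``missing_mask`` or ``censored_mask`` hold NaN until imputation.
    ``state`` tracks the processing stage: ``raw`` (pg/mL),
    ``imputed`` (pg/mL, no NaN) or ``normalized`` (log2 units).
    """

    values: pd.DataFrame
    lloq: pd.Series
    missing_mask: pd.DataFrame = None
    censored_mask: pd.DataFrame = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.censored_mask is None:
            self.censored_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.lloq = self.lloq.reindex(self.values.columns)
        if (self.lloq <= 0).any() or self.lloq.isna().any():
            bad = self.lloq.index[(self.lloq <= 0) | self.lloq.isna()].tolist()
            raise ValueError(f"LLOQ must be positive for every analyte; bad: {bad}")
        if (self.missing_mask.to_numpy() & self.censored_mask.to_numpy()).any():
            raise ValueError("missing_mask and censored_mask overlap")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def analytes(self) -> pd.Index:
        return self.values.columns

    def bad_mask(self) -> pd.DataFrame:
        """Union of missing and censored cells."""
        return self.missing_mask | self.censored_mask

    def copy(self) -> "AnalytePanel":
        return AnalytePanel(
            values=self.values.copy(),
            lloq=self.lloq.copy(),
            missing_mask=self.missing_mask.copy(),
            censored_mask=self.censored_mask.copy(),
            state=self.state,
        )


@dataclass
class QCReport:
    """Record of what QC removed and with which settings."""

    threshold: float
    order: str  # "analytes_first" or "samples_first"
    dropped_analytes: dict = field(default_factory=dict)  # id -> bad fraction
    dropped_samples: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def qc_filter(
    panel: AnalytePanel, threshold: float = 0.5, order: str = "analytes_first"
) -> tuple[AnalytePanel, QCReport]:
    """Drop analytes and samples with a bad-cell fraction strictly above
    ``threshold``.

    A cell is bad if missing or censored.  Analytes are filtered first, then
    samples over the retained analytes (order switchable); the two sweeps
    alternate until a fixed point, so no retained analyte or sample exceeds
    the threshold over the final panel and the filter is idempotent.
    "More than" is strict: a fraction exactly equal to the threshold is
    retained.
    """
    if panel.state != "raw":
        raise ValueError(f"qc_filter expects a raw panel, got state={panel.state!r}")
    if order not in ("analytes_first", "samples_first"):
        raise ValueError(f"unknown QC order {order!r}")

    bad = panel.bad_mask()
    report = QCReport(threshold=threshold, order=order)
    keep_s = panel.samples
    keep_a = panel.analytes

    def _drop_analytes():
        frac = bad.loc[keep_s, keep_a].mean(axis=0)
        dropped = frac[frac > threshold]
        report.dropped_analytes.update(dropped.to_dict())
        return keep_a[~keep_a.isin(dropped.index)], len(dropped)

    def _drop_samples():
        frac = bad.loc[keep_s, keep_a].mean(axis=1)
        dropped = frac[frac > threshold]
        report.dropped_samples.update(dropped.to_dict())
        return keep_s[~keep_s.isin(dropped.index)], len(dropped)

    sweeps = (_drop_analytes, _drop_samples) if order == "analytes_first" \
        else (_drop_samples, _drop_analytes)
    while True:
        n_dropped = 0
        for sweep in sweeps:
            kept, n = sweep()
            if sweep is _drop_analytes:
                keep_a = kept
            else:
                keep_s = kept
            n_dropped += n
            if len(keep_a) == 0 or len(keep_s) == 0:
                break
        if n_dropped == 0 or len(keep_a) == 0 or len(keep_s) == 0:
            break

    if len(keep_a) == 0:
        raise ValueError("panel empty after QC: all analytes dropped")
    if len(keep_s) == 0:
        raise ValueError("panel empty after QC: all samples dropped")

    out = AnalytePanel(
        values=panel.values.loc[keep_s, keep_a].copy(),
        lloq=panel.lloq.loc[keep_a].copy(),
        missing_mask=panel.missing_mask.loc[keep_s, keep_a].copy(),
        censored_mask=panel.censored_mask.loc[keep_s, keep_a].copy(),
        state="raw",
    )
    return out, report


def impute(panel: AnalytePanel) -> AnalytePanel:
    """Fill missing cells with the analyte mean and censored cells with LLOQ/2.

    The analyte mean is the arithmetic mean of the observed
    (non-missing, non-censored) raw-scale values.  Masks are cleared on the
    returned panel: downstream stages treat every cell as observed.
    """
    if panel.state != "raw":
        raise ValueError(f"impute expects a raw (QC-filtered) panel, got {panel.state!r}")
    values = panel.values.copy()
    observed = ~panel.bad_mask()
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = panel.analytes[n_obs == 0].tolist()
        raise ValueError(f"analyte(s) with zero observed values, mean undefined: {bad}")

    means = values.where(observed).mean(axis=0)
    for a in panel.analytes:
        miss = panel.missing_mask[a]
        cens = panel.censored_mask[a]
        if miss.any():
            values.loc[miss, a] = means[a]
        if cens.any():
            values.loc[cens, a] = 0.5 * panel.lloq[a]

    return AnalytePanel(values=values, lloq=panel.lloq.copy(), state="imputed")


def log2_quantile_normalize(panel: AnalytePanel) -> AnalytePanel:
    """log2-scale then quantile-normalize across samples.

    Every sample's k-th smallest value is replaced by the mean over samples of
    k-th smallest values; ties within a sample receive the average of the tied
    rank means, so the map is deterministic and rank-preserving.
    """
    if panel.state != "imputed":
        raise ValueError(f"expects an imputed panel, got state={panel.state!r}")
    X = panel.values.to_numpy(dtype=float)
    if (X <= 0).any():
        i, j = np.argwhere(X <= 0)[0]
        raise ValueError(
            "nonpositive value at sample "
            f"{panel.samples[i]!r}, analyte {panel.analytes[j]!r}: {X[i, j]}"
        )
    L = np.log2(X)
    n = L.shape[1]
    mean_sorted = np.sort(L, axis=1).mean(axis=0)
    out = np.empty_like(L)
    grid = np.arange(1, n + 1, dtype=float)
    for i in range(L.shape[0]):
        ranks = rankdata(L[i], method="average")
        out[i] = np.interp(ranks, grid, mean_sorted)
    values = pd.DataFrame(out, index=panel.samples, columns=panel.analytes)
    return AnalytePanel(values=values, lloq=panel.lloq.copy(), state="normalized")


# ---------------------------------------------------------------------------
# TSV I/O (dialect shared with the synthetic cohort writer)
# ---------------------------------------------------------------------------

def write_panel(panel: AnalytePanel, analytes_path, lloq_path) -> None:
    """Write a raw panel as analytes.tsv + lloq.tsv.

    Censored cells are written as ``<LLOQ``, missing cells as empty strings.
    """
    if len(panel.analytes) == 0:
        raise ValueError("refusing to write a panel with no analytes")
    out = panel.values.astype(object).copy()
    out = out.where(~panel.censored_mask, CENSORED_TOKEN)
    out = out.where(~panel.missing_mask, "")
    out.index.name = "sample_id"
    out.to_csv(analytes_path, sep="\t")
    lloq = panel.lloq.rename("lloq").to_frame()
    lloq.index.name = "analyte"
    lloq.to_csv(lloq_path, sep="\t")


def read_panel(analytes_path, lloq_path) -> AnalytePanel:
    """Read the TSV dialect back into a raw :class:`AnalytePanel`."""
    raw = pd.read_csv(analytes_path, sep="\t", index_col="sample_id", dtype=str,
                      keep_default_na=False)
    raw.index.name = None
    raw.columns.name = None
    censored = raw == CENSORED_TOKEN
    missing = raw == ""
    values = raw.mask(censored | missing).astype(float)
    lloq = pd.read_csv(lloq_path, sep="\t", index_col="analyte")["lloq"]
    return AnalytePanel(
        values=values,
        lloq=lloq,
        missing_mask=missing,
        censored_mask=censored,
        state="raw",
    )


def read_meta(path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by sample_id."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")
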