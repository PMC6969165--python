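"""Seeded synthetic trial-cohort generator with known ground truth.

The three placebo-controlled trials this package analyzes (ankylosing
spondylitis AS, psoriasis PSOR, psoriatic arthritis PSA) measured 121-155
plasma analytes per disease at week 0, week 4 and week 16, but the raw
measurements are not publicly deposited.  This module therefore emulates
their structure so every downstream stage is testable against a known
ground truth:

* per-analyte log-normal concentrations (immunoassay values are strictly
  positive and right-skewed) with a per-subject random intercept so repeated
  visits of one subject are correlated;
* LLOQ censoring calibrated to the published structure — ~15% of analytes
  censored in nearly all samples, ~5% partially censored (0-50%), the rest
  fully quantifiable;
* planted severity-correlated analytes: the clinical severity score of each
  subject at each visit is a linear function of the planted analytes'
  log2 concentrations plus age/gender terms and Gaussian noise;
* planted subgroup trajectory templates: multiplicative per-visit factors
  applied to member analytes, keyed by treatment arm (optionally arm and
  responder status), e.g. a placebo "bump" at week 4 versus a sustained
  decline under treatment;
* a low rate of missing-not-censored cells to exercise mean imputation
  separately from LLOQ handling.

Identical config + seed reproduces the cohort bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AnalytePanel, write_panel

__all__ = [
    "PlantedSeverity",
    "PatternTemplate",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "default_config",
    "generate_cohort",
    "write_cohort",
]

VISITS = ("week0", "week4", "week16")

#: primary severity score column per disease
SEVERITY_SCORE = {"AS": "ASDAS", "PSOR": "PASI", "PSA": "DAS28"}

#: enrollment per (disease, arm, response) cell
DEFAULT_CELLS = {
    ("AS", "placebo", "none"): 80,
    ("AS", "apremilast", "ANR"): 108,
    ("AS", "apremilast", "AR"): 67,
    ("PSOR", "placebo", "none"): 51,
    ("PSOR", "apremilast", "ANR"): 59,
    ("PSOR", "apremilast", "AR"): 34,
    ("PSA", "placebo", "none"): 47,
    ("PSA", "apremilast", "ANR"): 63,
    ("PSA", "apremilast", "AR"): 17,
}

DEFAULT_N_ANALYTES = {"AS": 121, "PSOR": 122, "PSA": 155}


@dataclass(frozen=True)
class PlantedSeverity:
    """One analyte truly linked to the severity score.

    ``beta`` multiplies the analyte's log2 concentration in the severity
    model; ``noise_sd`` is the residual SD of the severity equation (shared
    across entries of one disease; the first entry's value is used).
    """

    analyte: str
    beta: float
    noise_sd: float = 3.7


@dataclass(frozen=True)
class PatternTemplate:
    """A subgroup trajectory template applied to member analytes.

    ``factors`` maps a subgroup key to one multiplicative factor per visit.
    Keys are either an arm name (``"placebo"``, ``"apremilast"``) or
    ``"arm:response"`` (e.g. ``"apremilast:AR"``); the more specific key
    wins.  Subjects in subgroups without a key keep flat trajectories.
    """

    name: str
    analytes: tuple
    factors: dict

    def factor_row(self, arm: str, response: str, visits) -> np.ndarray:
        key = f"{arm}:{response}"
        if key in self.factors:
            f = self.factors[key]
        elif arm in self.factors:
            f = self.factors[arm]
        else:
            f = (1.0,) * len(visits)
        if len(f) != len(visits):
            raise ValueError(
                f"template {self.name!r}: {len(f)} factors for {len(visits)} visits"
            )
        return np.asarray(f, dtype=float)


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults emulate the three trials."""

    n_per_cell: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    n_analytes: dict = field(default_factory=lambda: dict(DEFAULT_N_ANALYTES))
    visits: tuple = VISITS
    frac_all_lloq: float = 0.15
    frac_partial_lloq: float = 0.05
    planted_severity: dict = field(default_factory=dict)  # disease -> [PlantedSeverity]
    planted_patterns: dict = field(default_factory=dict)  # disease -> [PatternTemplate]
    missing_rate: float = 0.02
    seed: int = 0
    # log2 geometric-mean range and within-analyte SD range of the panel
    log2_gm_range: tuple = (5.0, 13.0)
    log2_sd_range: tuple = (0.3, 0.7)
    # optional per-analyte overrides of the log2 geometric mean, e.g. to
    # plant analyte families with comparable abundance
    log2_gm_overrides: dict = field(default_factory=dict)
    # fraction of an analyte's log2 SD attributed to the subject intercept
    subject_sd_frac: float = 0.7

    def validate(self) -> None:
        for frac in (self.frac_all_lloq, self.frac_partial_lloq, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {frac}")
        if self.frac_all_lloq + self.frac_partial_lloq > 1.0:
            raise ValueError("frac_all_lloq + frac_partial_lloq exceeds 1")
        if len(self.visits) != 3:
            raise ValueError("exactly three ordered visits are required")
        for cell, n in self.n_per_cell.items():
            if n < 2:
                raise ValueError(f"cell {cell} has {n} subjects; at least 2 required "
                                 "(subgroup standard errors undefined below 2)")
        for disease in self.diseases():
            n = self.n_analytes[disease]
            names = set(analyte_names(n))
            for ps in self.planted_severity.get(disease, ()):
                if ps.analyte not in names:
                    raise ValueError(f"planted severity analyte {ps.analyte!r} "
                                     f"not in the {disease} panel")
            for tmpl in self.planted_patterns.get(disease, ()):
                missing = set(tmpl.analytes) - names
                if missing:
                    raise ValueError(f"template {tmpl.name!r} analytes not in "
                                     f"the {disease} panel: {sorted(missing)}")

    def diseases(self):
        return sorted({d for (d, _, _) in self.n_per_cell})


@dataclass
class GroundTruth:
    """What was planted, for use as a test oracle."""

    severity_analytes: dict = field(default_factory=dict)  # disease -> {analyte: beta}
    pattern_membership: dict = field(default_factory=dict)  # disease -> {analyte: template}
    response_effect: dict = field(default_factory=dict)  # disease -> {analyte: AR-ANR decline diff}
    true_log2: dict = field(default_factory=dict)  # disease -> uncensored log2 frame


@dataclass
class Cohort:
    panels: dict  # disease -> raw AnalytePanel
    meta: pd.DataFrame  # sample_id-indexed clinical annotations
    truth: GroundTruth
    config: CohortConfig


def analyte_names(n: int) -> list:
    """Panel analyte ids; panels of different sizes share a common prefix,
    so cross-disease analyses have a nonempty intersection."""
    return [f"ANL{i:04d}" for i in range(1, n + 1)]


def default_config(seed: int = 0) -> CohortConfig:
    """Study-shaped defaults: three trials, Table-sized cells, planted effects.

    PSOR carries two severity analytes with betas 3.5/3.4 (log2 scale) and a
    residual SD giving a combined R^2 near 0.3; AS carries one (beta 0.5 on
    the ASDAS scale); PSA none.  Each disease carries three trajectory
    templates: a placebo week-4 bump, a treated sustained decline whose
    week4->week16 rate differs between responders and non-responders, and a
    treated early rise.
    """
    def templates():
        a = analyte_names(121)  # use the shared prefix for pattern members
        return (
            PatternTemplate(
                "placebo_bump",
                tuple(a[30:40]),
                {"placebo": (1.0, 1.35, 1.0), "apremilast": (1.0, 0.95, 0.9)},
            ),
            # the two severity biomarkers belong to the decline pattern too,
            # mirroring how the severity pair also responds to treatment
            PatternTemplate(
                "treated_decline",
                tuple(a[0:2]) + tuple(a[40:50]),
                {
                    "placebo": (1.0, 1.15, 1.05),
                    "apremilast:AR": (1.0, 0.85, 0.55),
                    "apremilast:ANR": (1.0, 0.85, 0.75),
                },
            ),
            PatternTemplate(
                "treated_early_rise",
                tuple(a[50:60]),
                {"placebo": (1.0, 0.95, 1.0), "apremilast": (1.0, 1.3, 1.4)},
            ),
        )

    names = analyte_names(121)
    return CohortConfig(
        planted_severity={
            "PSOR": (PlantedSeverity(names[0], 3.5, 3.7),
                     PlantedSeverity(names[1], 3.4, 3.7)),
            "AS": (PlantedSeverity(names[2], 0.5, 0.55),),
        },
        planted_patterns={d: templates() for d in ("AS", "PSOR", "PSA")},
        seed=seed,
    )


def _lloq_for(mu, sigma, kind, rng):
    """Pick a per-analyte LLOQ (pg/mL) realizing the requested censoring kind."""
    from scipy.stats import norm

    if kind == "all":        # above ~99.9% of the distribution
        return float(2.0 ** (mu + 3.0 * sigma))
    if kind == "partial":    # censors a Uniform(5%, 50%) tail
        q = rng.uniform(0.05, 0.50)
        return float(2.0 ** (mu + sigma * norm.ppf(q)))
    # "none": far below the observed range (wide margin so planted
    # trajectory shifts cannot cross it), positive, log2(LLOQ/2) > 0
    # given the default gm range
    return float(max(2.0 ** (mu - 6.0 * sigma), 1.0))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate raw panels, sample metadata and ground truth for every disease."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    diseases = config.diseases()
    streams = dict(zip(diseases, master.spawn(len(diseases))))

    panels, meta_rows = {}, []
    truth = GroundTruth()
    visits = list(config.visits)
    n_visits = len(visits)

    for disease in diseases:
        rng = np.random.default_rng(streams[disease])
        n_analytes = config.n_analytes[disease]
        names = analyte_names(n_analytes)

        lo, hi = config.log2_gm_range
        mu = rng.uniform(lo, hi, size=n_analytes)
        for aname, gm in config.log2_gm_overrides.items():
            if aname in names:
                mu[names.index(aname)] = float(gm)
        slo, shi = config.log2_sd_range
        sigma = rng.uniform(slo, shi, size=n_analytes)
        subj_sd = config.subject_sd_frac * sigma
        resid_sd = np.sqrt(np.maximum(sigma**2 - subj_sd**2, 1e-12))

        # censoring classes, fixed per analyte; planted analytes stay
        # quantifiable (discoverable biomarkers are, by definition, measured)
        protected = {ps.analyte for ps in config.planted_severity.get(disease, ())}
        for tmpl in config.planted_patterns.get(disease, ()):
            protected.update(tmpl.analytes)
        n_all = int(np.floor(config.frac_all_lloq * n_analytes))
        n_partial = int(np.floor(config.frac_partial_lloq * n_analytes))
        kinds = np.array(["none"] * n_analytes, dtype=object)
        eligible = np.array([j for j in rng.permutation(n_analytes)
                             if names[j] not in protected], dtype=int)
        kinds[eligible[:n_all]] = "all"
        kinds[eligible[n_all:n_all + n_partial]] = "partial"
        lloq = pd.Series(
            [_lloq_for(mu[j], sigma[j], kinds[j], rng) for j in range(n_analytes)],
            index=names, name="lloq",
        )

        # subjects
        cells = sorted((arm, resp, n) for (d, arm, resp), n in config.n_per_cell.items()
                       if d == disease)
        subjects = []
        for arm, resp, n in cells:
            for _ in range(n):
                subjects.append((f"{disease}_S{len(subjects):04d}", arm, resp))
        n_subj = len(subjects)
        age = np.clip(rng.normal(45.0, 12.0, size=n_subj), 18, 80).round(1)
        gender = rng.choice(["F", "M"], size=n_subj)

        # log2 concentrations: analyte mean + subject intercept + visit noise
        # + log2 of the subgroup template factor
        subj_eff = rng.normal(0.0, 1.0, size=(n_subj, n_analytes)) * subj_sd
        log2x = np.empty((n_subj, n_visits, n_analytes))
        for v in range(n_visits):
            eps = rng.normal(0.0, 1.0, size=(n_subj, n_analytes)) * resid_sd
            log2x[:, v, :] = mu + subj_eff + eps

        templates = config.planted_patterns.get(disease, ())
        membership = {}
        for tmpl in templates:
            cols = [names.index(a) for a in tmpl.analytes]
            for a in tmpl.analytes:
                membership[a] = tmpl.name
            for s, (sid, arm, resp) in enumerate(subjects):
                fac = tmpl.factor_row(arm, resp, visits)
                log2x[s, :, cols] += np.log2(fac)  # broadcast per visit

        # severity scores
        planted = config.planted_severity.get(disease, ())
        score_col = SEVERITY_SCORE[disease]
        noise_sd = planted[0].noise_sd if planted else 3.0
        beta_age, beta_gender, intercept = 0.02, 0.3, 8.0
        signal = np.zeros((n_subj, n_visits))
        for ps in planted:
            j = names.index(ps.analyte)
            signal += ps.beta * log2x[:, :, j]
        if planted:
            signal -= signal.mean()  # center so scores sit near the intercept
        gender_num = (gender == "M").astype(float)
        scores = (intercept + signal
                  + beta_age * (age - 45.0)[:, None]
                  + beta_gender * gender_num[:, None]
                  + rng.normal(0.0, noise_sd, size=(n_subj, n_visits)))

        # assemble the sample-indexed frames
        sample_ids = [f"{sid}_{v}" for (sid, _, _) in subjects for v in visits]
        flat = log2x.reshape(n_subj * n_visits, n_analytes)
        conc = pd.DataFrame(2.0 ** flat, index=sample_ids, columns=names)
        truth.true_log2[disease] = pd.DataFrame(flat, index=sample_ids, columns=names)

        censored = conc.lt(lloq, axis=1)
        missing = pd.DataFrame(
            rng.random(conc.shape) < config.missing_rate,
            index=conc.index, columns=conc.columns,
        ) & ~censored
        values = conc.mask(censored | missing)
        panels[disease] = AnalytePanel(
            values=values, lloq=lloq,
            missing_mask=missing, censored_mask=censored, state="raw",
        )

        for s, (sid, arm, resp) in enumerate(subjects):
            for v, visit in enumerate(visits):
                row = {
                    "sample_id": f"{sid}_{visit}",
                    "subject": sid, "disease": disease, "arm": arm,
                    "response": resp, "visit": visit,
                    "age": age[s], "gender": gender[s],
                    "PASI": np.nan, "ASDAS": np.nan, "DAS28": np.nan,
                    "BASDAI": np.nan, "BASFI": np.nan,
                }
                row[score_col] = scores[s, v]
                meta_rows.append(row)

        truth.severity_analytes[disease] = {ps.analyte: ps.beta for ps in planted}
        truth.pattern_membership[disease] = membership
        effect = {}
        for tmpl in templates:
            ar = tmpl.factor_row("apremilast", "AR", visits)
            anr = tmpl.factor_row("apremilast", "ANR", visits)
            diff = (np.log2(ar[-1]) - np.log2(ar[-2])) - (np.log2(anr[-1]) - np.log2(anr[-2]))
            for a in tmpl.analytes:
                effect[a] = float(diff)
        truth.response_effect[disease] = effect

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    if "AS" in panels:  # secondary AS scores tracking the primary one
        as_rows = meta["disease"] == "AS"
        rng = np.random.default_rng(master.spawn(1)[0])
        n = int(as_rows.sum())
        meta.loc[as_rows, "BASDAI"] = (0.8 * meta.loc[as_rows, "ASDAS"]
                                       + rng.normal(0, 0.5, n))
        meta.loc[as_rows, "BASFI"] = (0.7 * meta.loc[as_rows, "ASDAS"]
                                      + rng.normal(0, 0.6, n))
    return Cohort(panels=panels, meta=meta, truth=truth, config=config)


def write_cohort(cohort: Cohort, out_dir, overwrite: bool = False) -> dict:
    """Write per-disease analytes.tsv + lloq.tsv and a shared meta.tsv.

    Returns a {label: path} map.  Refuses to clobber existing files unless
    ``overwrite`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    targets = [out / "meta.tsv"]
    for disease in cohort.panels:
        targets += [out / disease / "analytes.tsv", out / disease / "lloq.tsv"]
    if not overwrite:
        clashes = [str(p) for p in targets if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite: {clashes}")

    for disease, panel in cohort.panels.items():
        ddir = out / disease
        ddir.mkdir(exist_ok=True)
        write_panel(panel, ddir / "analytes.tsv", ddir / "lloq.tsv")
        paths[f"{disease}/analytes"] = ddir / "analytes.tsv"
        paths[f"{disease}/lloq"] = ddir / "lloq.tsv"
    cohort.meta.to_csv(out / "meta.tsv", sep="\t")
    paths["meta"] = out / "meta.tsv"
    return paths
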