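"""Measurement table assembly and the split-plot repeated-measures ANOVA.

Each crab contributes two rows to the measurement table — its camouflage
metrics averaged against mudflat (MF) backgrounds and against rock pool
(RP) backgrounds. The design is a 2×2 split plot: habitat of origin is the
between-subjects factor, background habitat the within-subjects factor.

For a 2×2 mixed design, type-III tests with sum-to-zero coding reduce
exactly to contrasts on per-subject sums and differences:

* between (origin): two-sample pooled test on subject means;
* within (background): test of the unweighted grand mean of the per-subject
  RP−MF differences;
* interaction: test of the difference in group means of those differences;

all against their stratum error with 1 and N−2 degrees of freedom. This is
the behaviour of R's ``ezANOVA``/``car::Anova`` (type III) on unbalanced
groups. Homogeneity of variance is checked with Levene's test
(Brown–Forsythe median centring by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

METRIC_COLUMNS = ["jnd_colour_avian", "jnd_colour_fish", "jnd_lum_avian",
                  "jnd_lum_fish", "ped", "gabrat"]
FACTOR_COLUMNS = ["crab_id", "origin", "background"]
LEVELS = ("MF", "RP")

#: Metrics log-transformed before the ANOVA by default (natural log); the
#: avian colour JND distribution is right-skewed.
DEFAULT_LOG_METRICS = ("jnd_colour_avian",)


@dataclass
class LeveneResult:
    statistic: float
    df: tuple[int, int]
    p: float
    center: str

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("Levene statistic must be non-negative")


def levene_test(values, groups, center: str = "median") -> LeveneResult:
    """Levene's homogeneity-of-variance test (one-way ANOVA on absolute
    deviations from each group's centre; median centring = Brown–Forsythe).
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    stat, p = sps.levene(*samples, center=center)
    df = (len(samples) - 1, sum(len(s) for s in samples) - len(samples))
    return LeveneResult(statistic=float(stat), df=df, p=float(p), center=center)


def validate_measurement_table(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Check the two-rows-per-crab / constant-origin invariants and return a
    clean copy with rows holding the dependent variable."""
    for col in FACTOR_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"measurement table lacks column {col!r}")
    if dv not in table.columns:
        raise ValueError(f"measurement table lacks metric {dv!r}")
    t = table.loc[:, FACTOR_COLUMNS + [dv]].dropna(subset=[dv]).copy()
    bad_levels = set(t["background"]) - set(LEVELS)
    if bad_levels:
        raise ValueError(f"unknown background levels {bad_levels}")
    for cid, grp in t.groupby("crab_id", sort=False):
        if sorted(grp["background"]) != sorted(LEVELS):
            raise ValueError(
                f"crab {cid!r} must have exactly one row per background "
                f"level, got {list(grp['background'])}")
        if grp["origin"].nunique() != 1:
            raise ValueError(f"crab {cid!r} has inconsistent origin labels")
    return t


@dataclass
class AnovaTable:
    """Type-III F tests for the three effects of the 2×2 split plot."""

    effects: pd.DataFrame  # index: origin, background, origin:background

    def f(self, effect: str) -> float:
        return float(self.effects.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])

    def df_den(self, effect: str) -> int:
        return int(self.effects.loc[effect, "df_den"])

    def interaction_contrast(self) -> float:
        """Signed interaction contrast: mean(RP−MF diff | RP origin) −
        mean(RP−MF diff | MF origin)."""
        return float(self.effects.loc["origin:background", "contrast"])


def splitplot_anova(table: pd.DataFrame, dv: str,
                    log_dv: bool = False) -> AnovaTable:
    """2×2 split-plot repeated-measures ANOVA with type-III sums of squares.

    ``log_dv`` applies a natural-log transform to the metric first (used for
    skewed JND data). Unbalanced group sizes are handled via unweighted
    (effect-coded) contrasts. Raises if a crab lacks one of its two rows or
    if an error stratum has zero variance.
    """
    t = validate_measurement_table(table, dv)
    y = t[dv].astype(float)
    if log_dv:
        if (y <= 0).any():
            raise ValueError(f"cannot log-transform non-positive {dv!r}")
        y = np.log(y)
    t = t.assign(_y=y)

    wide = t.pivot_table(index=["crab_id", "origin"], columns="background",
                         values="_y", aggfunc="first").reset_index()
    d = (wide["RP"] - wide["MF"]).to_numpy()       # within-subject difference
    m = 0.5 * (wide["RP"] + wide["MF"]).to_numpy() # subject mean
    g = (wide["origin"] == "RP").to_numpy()
    n_rp, n_mf = int(g.sum()), int((~g).sum())
    N = n_rp + n_mf
    if min(n_rp, n_mf) < 2:
        raise ValueError("need at least 2 crabs per origin group")
    inv_n = 1.0 / n_rp + 1.0 / n_mf
    df_den = N - 2

    def _pooled_var(x):
        ss = ((x[g] - x[g].mean()) ** 2).sum() + ((x[~g] - x[~g].mean()) ** 2).sum()
        return ss / df_den, ss

    s2_m, ss_m = _pooled_var(m)
    s2_d, ss_d = _pooled_var(d)
    if s2_m <= 0 or s2_d <= 0:
        raise ValueError("zero error variance in a stratum")

    rows = []
    # between-subjects: origin, against subjects-within-group error
    c_a = m[g].mean() - m[~g].mean()
    f_a = c_a ** 2 / (s2_m * inv_n)
    ms_err_b = 2.0 * s2_m                     # per-observation scale
    rows.append(("origin", c_a, f_a, f_a * ms_err_b, 2.0 * ss_m))
    # within-subject stratum: background and interaction vs subject×background
    ms_err_w = 0.5 * s2_d
    c_b = 0.5 * (d[g].mean() + d[~g].mean())
    f_b = c_b ** 2 / (0.25 * s2_d * inv_n)
    rows.append(("background", c_b, f_b, f_b * ms_err_w, 0.5 * ss_d))
    c_i = d[g].mean() - d[~g].mean()
    f_i = c_i ** 2 / (s2_d * inv_n)
    rows.append(("origin:background", c_i, f_i, f_i * ms_err_w, 0.5 * ss_d))

    eff = pd.DataFrame(
        [{"effect": name, "df_num": 1, "df_den": df_den, "F": F,
          "p": float(sps.f.sf(F, 1, df_den)), "ss": ss, "ss_error": ss_err,
          "contrast": c}
         for name, c, F, ss, ss_err in rows]).set_index("effect")
    return AnovaTable(effects=eff)


def cell_means(table: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Group-by-cell (origin × background) means of each metric."""
    metrics = metrics or [m for m in METRIC_COLUMNS if m in table.columns]
    return table.groupby(["origin", "background"])[metrics].mean()


def run_full_analysis(table: pd.DataFrame,
                      log_metrics: tuple[str, ...] = DEFAULT_LOG_METRICS,
                      levene_center: str = "median") -> dict:
    """Full statistical surface: one ANOVA per available metric, Levene
    diagnostics over the four origin×background cells, and cell means.

    Deterministic and invariant to row order. Metrics that are entirely
    missing are skipped with a warning.
    """
    table = table.sort_values(["crab_id", "background"]).reset_index(drop=True)
    present = [m for m in METRIC_COLUMNS if m in table.columns]
    anovas: dict[str, AnovaTable] = {}
    levenes: dict[str, LeveneResult] = {}
    for metric in present:
        sub = table.dropna(subset=[metric])
        if sub.empty:
            warnings.warn(f"metric {metric!r} has no data; skipped")
            continue
        anovas[metric] = splitplot_anova(table, metric,
                                         log_dv=metric in log_metrics)
        cells = sub["origin"] + ":" + sub["background"]
        levenes[metric] = levene_test(sub[metric], cells, center=levene_center)
    return {"anova": anovas, "levene": levenes,
            "cell_means": cell_means(table, list(anovas))}


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a run_full_analysis report to one row per metric × effect."""
    rows = []
    for metric, at in report["anova"].items():
        for effect, r in at.effects.iterrows():
            rows.append({"metric": metric, "effect": effect,
                         "df_num": int(r["df_num"]), "df_den": int(r["df_den"]),
                         "F": r["F"], "p": r["p"]})
    return pd.DataFrame(rows)
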