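"""Method-comparison and reliability statistics for trial tables.

The toolkit mirrors a standard validity/reliability analysis of paired
hematocrit measurements: Bland–Altman limits of agreement, intraclass
correlation with typical error, Pearson correlation, one-way
repeated-measures ANOVA with partial eta squared, Bonferroni-corrected
paired t tests, and Cohen's d — each with its conventional
interpretation bands.

Conventions (stated because the usual literature leaves them implicit):

* All SDs use the n-1 (sample) denominator, including Bland–Altman.
* Limits of agreement are mean difference ± 1.96 × SD of the paired
  differences; agreement is "good" when |mean difference| < 1.2
  percentage points (1.2 % of a typical Hct of 45 is ~0.5 points, the
  smallest credible division of a mechanical microhaematocrit reader).
* The default ICC is the two-way random-effects, absolute-agreement,
  single-measure form (ICC2,1) — absolute agreement is what pairs
  naturally with Bland–Altman. Other forms are available via ``form``.
* Typical error is the SD of between-trial difference scores divided by
  sqrt(2), averaged over trial pairs when there are more than two trials.
* Partial eta squared bands: small 0.02 / medium 0.13 / large 0.26;
  Cohen's d bands: small 0.2 / medium 0.5 / large 0.8 (on |d|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import (
    ConfigError,
    DegenerateDataError,
    DesignError,
    InsufficientDataError,
)

__all__ = [
    "TrialTable",
    "BlandAltmanResult",
    "ReliabilityResult",
    "EffectSummary",
    "bland_altman",
    "icc",
    "typical_error",
    "pearson_r",
    "rm_anova",
    "paired_t_bonferroni",
    "cohens_d",
    "eta_sq_band",
    "cohens_d_band",
    "GOOD_AGREEMENT_PCT",
    "good_agreement_equivalent_hct",
    "simulate_trial_table",
]

#: Good-agreement rule for Bland–Altman mean differences (percentage points).
GOOD_AGREEMENT_PCT = 1.2

#: Typical hematocrit used to express the relative threshold in Hct points.
TYPICAL_HCT_PCT = 45.0

_ETA_BANDS = ((0.26, "large"), (0.13, "medium"), (0.02, "small"))
_D_BANDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


def good_agreement_equivalent_hct(typical_hct: float = TYPICAL_HCT_PCT) -> float:
    """The 1.2 % relative threshold expressed in absolute Hct points.

    1.2 % of a typical Hct of 45 % is 0.54, i.e. ~0.5 points — the
    smallest difference a mechanical reader can credibly resolve.
    """
    return GOOD_AGREEMENT_PCT / 100.0 * typical_hct


def eta_sq_band(eta_sq: float) -> str:
    for cut, name in _ETA_BANDS:
        if eta_sq >= cut:
            return name
    return "negligible"


def cohens_d_band(d: float) -> str:
    for cut, name in _D_BANDS:
        if abs(d) >= cut:
            return name
    return "negligible"


# -- trial table -----------------------------------------------------------

REQUIRED_COLUMNS = ("sample_id", "rater", "method", "trial", "hct_pct")


@dataclass(frozen=True)
class TrialTable:
    """Long-format trial data: one measurement per row.

    Columns: sample_id, rater (e.g. novice/expert), method (e.g. MHR vs
    app condition), trial (integer index), hct_pct. The (sample, rater,
    method, trial) key must be unique and hct_pct within [0, 100].
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise DesignError(f"trial table missing columns: {sorted(missing)}")
        key = ["sample_id", "rater", "method", "trial"]
        if self.data.duplicated(subset=key).any():
            raise DesignError("duplicate (sample, rater, method, trial) rows")
        hct = self.data["hct_pct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(hct)) or hct.min() < 0 or hct.max() > 100:
            raise DesignError("hct_pct must be finite and within [0, 100]")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "TrialTable":
        return cls(pd.DataFrame.from_records(records, columns=REQUIRED_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))

    def pivot(self, measurement: str) -> pd.DataFrame:
        """Subjects x measurement grid; raises on unbalanced designs.

        ``measurement`` is the column whose levels form the repeated
        measurements ('trial', 'method' or 'rater'); remaining factors
        must be constant or are averaged out (trials are averaged when
        pivoting on rater/method, the conventional 'definitive value').
        """
        if measurement not in ("trial", "method", "rater"):
            raise ConfigError(f"cannot pivot on {measurement!r}")
        df = (
            self.data.groupby(["sample_id", measurement], sort=True)["hct_pct"]
            .mean()
            .unstack(measurement)
        )
        if df.isna().any().any():
            raise DesignError(
                f"unbalanced design: missing cells in subjects x {measurement} grid"
            )
        return df


# -- Bland–Altman ----------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    good_agreement: bool
    pair_means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)

    def plot_data(self) -> pd.DataFrame:
        """Per-pair means and differences plus the three reference lines."""
        df = pd.DataFrame({"pair_mean": self.pair_means, "difference": self.differences})
        df["mean_diff"] = self.mean_diff
        df["loa_low"] = self.loa_low
        df["loa_high"] = self.loa_high
        return df


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired measurement series.

    Differences are x - y; limits of agreement are mean ± 1.96 SD of the
    differences (sample SD). ``good_agreement`` applies the 1.2-point
    rule to |mean difference|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be equal-length 1-D series")
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {x.size}")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        good_agreement=abs(mean) < GOOD_AGREEMENT_PCT,
        pair_means=(x + y) / 2.0,
        differences=d,
    )


# -- reliability -----------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    icc_ci95: tuple[float, float]
    typical_error: float
    design: str  # 'intra' | 'inter'
    form: str  # pingouin ICC type label, e.g. 'ICC2'
    degenerate: bool = False


def typical_error(grid: pd.DataFrame | np.ndarray) -> float:
    """Within-subject typical error from a subjects x measurements grid.

    SD of the between-measurement difference scores divided by sqrt(2);
    with more than two measurement columns the value is averaged over
    all column pairs.
    """
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need a subjects x >=2 measurements grid")
    k = arr.shape[1]
    tes = [
        np.std(arr[:, i] - arr[:, j], ddof=1) / math.sqrt(2.0)
        for i in range(k)
        for j in range(i + 1, k)
    ]
    return float(np.mean(tes))


_ICC_FORMS = {"ICC1", "ICC2", "ICC3", "ICC1k", "ICC2k", "ICC3k"}

#: pingouin labels its ICC rows differently across versions; normalize to
#: the McGraw-Wong shorthand (ICC2 = two-way random, absolute agreement,
#: single measure = ICC(A,1)).
_PINGOUIN_TYPE_ALIASES = {
    "ICC(1,1)": "ICC1",
    "ICC(A,1)": "ICC2",
    "ICC(C,1)": "ICC3",
    "ICC(1,k)": "ICC1k",
    "ICC(A,k)": "ICC2k",
    "ICC(C,k)": "ICC3k",
}


def icc(table: TrialTable, design: str, form: str = "ICC2") -> ReliabilityResult:
    """Intraclass correlation + typical error for a reliability design.

    ``design='intra'`` treats the repeated trials of a single rater and
    method as the measurements (the table must contain exactly one rater
    and one method); ``design='inter'`` compares raters' definitive
    (trial-mean) values (single method required). The default form is
    the two-way absolute-agreement single-measure ICC; the 95 % CI is the
    standard F-based interval. Zero total variance yields a degenerate
    result (ICC undefined, flagged) rather than a number.
    """
    import pingouin as pg

    if design == "intra":
        for col in ("rater", "method"):
            if table.data[col].nunique() != 1:
                raise DesignError(f"intra-rater design requires a single {col}")
        measurement = "trial"
    elif design == "inter":
        if table.data["method"].nunique() != 1:
            raise DesignError("inter-rater design requires a single method")
        measurement = "rater"
    else:
        raise ConfigError(f"design must be 'intra' or 'inter', got {design!r}")
    if form not in _ICC_FORMS:
        raise ConfigError(f"unknown ICC form {form!r}; choose from {sorted(_ICC_FORMS)}")

    grid = table.pivot(measurement)
    te = typical_error(grid)
    values = grid.to_numpy(dtype=float)
    if np.allclose(values, values.flat[0]):
        return ReliabilityResult(
            icc=float("nan"),
            icc_ci95=(float("nan"), float("nan")),
            typical_error=te,
            design=design,
            form=form,
            degenerate=True,
        )
    long = grid.reset_index().melt(
        id_vars="sample_id", var_name="judge", value_name="value"
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = pg.intraclass_corr(
            data=long, targets="sample_id", raters="judge", ratings="value"
        )
    res = res.set_index(res["Type"].map(_PINGOUIN_TYPE_ALIASES).fillna(res["Type"]))
    row = res.loc[form]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci = tuple(float(v) for v in row[ci_col])
    return ReliabilityResult(
        icc=float(row["ICC"]),
        icc_ci95=ci,
        typical_error=te,
        design=design,
        form=form,
    )


# -- correlation -----------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product–moment correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InsufficientDataError("need equal-length 1-D series with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("values must be finite")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise DegenerateDataError("correlation undefined: zero variance")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)


# -- ANOVA and effect sizes ------------------------------------------------


@dataclass(frozen=True)
class EffectSummary:
    name: str
    statistic: float
    p_value: float
    effect_size: float
    effect_name: str  # 'partial_eta_sq' | 'cohens_d'
    band: str
    detail: dict = field(default_factory=dict)


def rm_anova(
    table: TrialTable,
    within_factor: str = "method",
    correction: bool = False,
) -> EffectSummary:
    """One-way repeated-measures ANOVA with subject blocking.

    Partial eta squared = SS_effect / (SS_effect + SS_error). Sphericity
    correction (Greenhouse–Geisser) is off by default and available via
    ``correction=True``.
    """
    import pingouin as pg

    grid = table.pivot(within_factor)  # validates completeness
    long = grid.reset_index().melt(
        id_vars="sample_id", var_name=within_factor, value_name="hct"
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = pg.rm_anova(
            data=long,
            dv="hct",
            within=within_factor,
            subject="sample_id",
            correction=correction,
            detailed=True,
            effsize="np2",
        )
    row = aov.iloc[0]
    if "F" not in aov.columns or math.isclose(float(row["SS"]), 0.0, abs_tol=1e-12):
        # no condition effect at all: SS_effect = 0 forces eta = 0 even when
        # the error SS is also zero (identical conditions; pingouin then
        # omits the F/p columns entirely)
        eta, f, p = 0.0, 0.0, 1.0
    else:

        def _col(*names: str) -> str:
            for n in names:  # pingouin renamed p columns across versions
                if n in aov.columns:
                    return n
            raise KeyError(names)

        if correction:
            p = float(row[_col("p_GG_corr", "p-GG-corr")])
        else:
            p = float(row[_col("p_unc", "p-unc")])
        eta = float(row["np2"])
        f = float(row["F"])
    return EffectSummary(
        name=f"rm_anova({within_factor})",
        statistic=f,
        p_value=p,
        effect_size=eta,
        effect_name="partial_eta_sq",
        band=eta_sq_band(eta),
        detail={
            "df_effect": float(row["DF"]),
            "df_error": float(aov.iloc[1]["DF"]),
            "ss_effect": float(row["SS"]),
            "ss_error": float(aov.iloc[1]["SS"]),
        },
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> tuple[float, str]:
    """Cohen's d: difference in means over the pooled sample SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise DegenerateDataError("pooled SD is zero; effect size undefined")
    d = float((a.mean() - b.mean()) / pooled)
    return d, cohens_d_band(d)


def paired_t_bonferroni(
    table: TrialTable,
    comparisons: Sequence[tuple[str, str]],
    factor: str = "method",
) -> list[EffectSummary]:
    """Post hoc paired t tests with Bonferroni correction and Cohen's d.

    Adjusted p = min(1, raw p x number of comparisons). Cohen's d uses
    the pooled-SD definition (not the paired-difference SD).
    """
    if len(comparisons) == 0:
        raise ConfigError("comparison list is empty")
    grid = table.pivot(factor)
    m = len(comparisons)
    out = []
    for a_name, b_name in comparisons:
        for name in (a_name, b_name):
            if name not in grid.columns:
                raise DesignError(f"condition {name!r} not present in the table")
        a = grid[a_name].to_numpy(dtype=float)
        b = grid[b_name].to_numpy(dtype=float)
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = _sps.ttest_rel(a, b)
        try:
            d, band = cohens_d(a, b)
        except DegenerateDataError:
            d, band = 0.0, "negligible"
        out.append(
            EffectSummary(
                name=f"{a_name} vs {b_name}",
                statistic=float(t),
                p_value=min(1.0, float(p) * m),
                effect_size=d,
                effect_name="cohens_d",
                band=band,
                detail={"p_raw": float(p), "n_comparisons": m, "n_pairs": int(a.size)},
            )
        )
    return out


# -- simulation helper -----------------------------------------------------


def simulate_trial_table(
    n_subjects: int,
    n_trials: int,
    subject_sd: float,
    error_sd: float,
    mean: float = 42.0,
    rater: str = "novice",
    method: str = "app",
    seed: int = 0,
) -> TrialTable:
    """Trial table with known variance components, for parameter recovery.

    Model: hct[i, t] = mean + s_i + e_it with s ~ N(0, subject_sd^2) and
    e ~ N(0, error_sd^2); the population ICC is
    subject_sd^2 / (subject_sd^2 + error_sd^2). Values are clipped to
    [0, 100] (harmless at realistic SDs).
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, subject_sd, size=n_subjects)
    e = rng.normal(0.0, error_sd, size=(n_subjects, n_trials))
    vals = np.clip(mean + s[:, None] + e, 0.0, 100.0)
    records = [
        (f"S{i:03d}", rater, method, t + 1, float(vals[i, t]))
        for i in range(n_subjects)
        for t in range(n_trials)
    ]
    return TrialTable.from_records(records)
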