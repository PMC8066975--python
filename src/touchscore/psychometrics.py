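"""Psychometric battery for outcome tables.

Implements the statistics used to validate a hand-function assessment:

* convergent validity — Pearson r between app measures and clinical
  scores, with a strength band assigned to |r| (excellent > 0.8,
  strong (0.6, 0.8], moderate (0.4, 0.6], weak (0.2, 0.4], very weak
  <= 0.2);
* reliability — ICC(2,1): two-way random-effects, absolute-agreement,
  single-measurement intraclass correlation, with the derived standard
  error of measurement SEM = SD * sqrt(1 - ICC) and minimal detectable
  change MDC95 = 1.96 * sqrt(2) * SEM;
* outlier handling — per-measure |z| > 3 cells removed, participants
  flagged in more than two measures dropped entirely;
* severity stratification — Fugl-Meyer Assessment for Upper Extremity
  (FMA-UE, 0-66): 19-46 moderate, >= 47 mild — and two-sided
  equal-variance Student's t comparison between the groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

SQRT2 = math.sqrt(2.0)
Z95 = 1.96  # two-sided 95% normal quantile, as conventionally rounded


# ---------------------------------------------------------------------------
# convergent validity


def band_of(r: float) -> str:
    """Strength band of a correlation coefficient, from |r|.

    Boundaries are half-open downward: exactly 0.8 is "strong",
    exactly 0.4 is "weak", etc.  Negative coefficients band by magnitude.
    """
    a = abs(r)
    if a > 0.8:
        return "excellent"
    if a > 0.6:
        return "strong"
    if a > 0.4:
        return "moderate"
    if a > 0.2:
        return "weak"
    return "very weak"


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    band: str
    n: int


def pearson_validity(x, y) -> PearsonResult:
    """Pearson correlation between paired scores with a strength band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), band_of(res.statistic), len(x))


def validity_matrix(outcomes: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """All pairwise validity results between app measures and clinical scores.

    Both frames are wide, indexed by participant id.  Pairs with fewer
    than 3 shared complete observations are marked unavailable rather
    than erroring.  ``highlight`` flags |r| > 0.4 (moderate or stronger),
    mirroring how validity tables are conventionally reported.
    """
    rows = []
    for m in outcomes.columns:
        for c in clinical.columns:
            joined = pd.concat(
                [outcomes[m], clinical[c]], axis=1, join="inner"
            ).dropna()
            if len(joined) < 3:
                rows.append(
                    dict(measure=m, clinical=c, n=len(joined), r=np.nan,
                         p=np.nan, band="", highlight=False, available=False)
                )
                continue
            try:
                res = pearson_validity(joined.iloc[:, 0], joined.iloc[:, 1])
            except UndefinedStatisticError:
                rows.append(
                    dict(measure=m, clinical=c, n=len(joined), r=np.nan,
                         p=np.nan, band="", highlight=False, available=False)
                )
                continue
            rows.append(
                dict(measure=m, clinical=c, n=res.n, r=res.r, p=res.p,
                     band=res.band, highlight=abs(res.r) > 0.4, available=True)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reliability


@dataclass(frozen=True)
class ReliabilityInput:
    """Complete participants x sessions score matrix for one measure."""

    measure_name: str
    scores: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("scores must be an n>=2 by k>=2 matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("scores must be complete and finite")
        object.__setattr__(self, "scores", arr)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def icc_2_1(data) -> tuple[float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA without replication with rows = participants
    and columns = sessions/raters::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The p-value is from the F test for the row (participant) effect,
    F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
    """
    if isinstance(data, ReliabilityInput):
        y = data.scores
    else:
        y = np.asarray(data, dtype=float)
        if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
            raise ValueError("need an n>=2 by k>=2 matrix")
    n, k = y.shape
    gm = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    sst = float(((y - gm) ** 2).sum())
    if sst == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    ssr = k * float(((row_means - gm) ** 2).sum())
    ssc = n * float(((col_means - gm) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        # e.g. perfectly anti-symmetric matrices: no agreement variance to scale by
        raise UndefinedStatisticError("ICC undefined: zero denominator")
    icc = (msr - mse) / denom
    if mse <= 0.0:
        p = 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def sem(scores, icc: float) -> float:
    """Standard error of measurement: SD(scores) * sqrt(1 - ICC).

    ``scores`` are the pooled measurements of the reliability subsample
    (conventionally the two intra-rater sessions flattened); SD uses the
    n-1 denominator.
    """
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    arr = np.asarray(scores, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least 2 scores")
    return float(np.std(arr, ddof=1) * math.sqrt(1.0 - icc))


def mdc95(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 * sqrt(2) * SEM."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return Z95 * SQRT2 * sem_value


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-measure reliability bundle: ICC, SEM and MDC95 in measure units."""

    measure_name: str
    icc: float
    icc_p: float
    sem: float
    mdc95: float
    n: int
    k: int
    sd_source: str = "pooled intra-rater sessions"

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if not math.isclose(self.mdc95, Z95 * SQRT2 * self.sem, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("mdc95 must equal 1.96*sqrt(2)*sem")


def reliability_report(data: ReliabilityInput) -> ReliabilityReport:
    """ICC(2,1) + SEM + MDC95 for one measure's score matrix."""
    icc, p = icc_2_1(data)
    s = sem(data.scores, icc)
    return ReliabilityReport(
        measure_name=data.measure_name,
        icc=icc,
        icc_p=p,
        sem=s,
        mdc95=mdc95(s),
        n=data.n,
        k=data.k,
    )


def analyze_reliability(
    long_df: pd.DataFrame,
    intra_sessions: tuple[int, int] = (1, 2),
    inter_sessions: tuple[int, int] = (1, 3),
) -> pd.DataFrame:
    """Reliability table from a long outcome frame with repeated sessions.

    Expects columns participant_id, exercise_id, measure_name, value,
    session_idx.  By protocol, sessions 1-2 are administered by the same
    rater (intra-rater pair) and session 3 by a second rater; the
    inter-rater ICC pairs the first session with session 3.  SEM and
    MDC95 are derived from the intra-rater pair.  One row per
    (exercise_id, measure_name); measures missing a complete session
    pair are skipped.
    """
    rows = []
    for (ex, meas), grp in long_df.groupby(["exercise_id", "measure_name"], sort=True):
        wide = grp.pivot_table(
            index="participant_id", columns="session_idx", values="value"
        )
        label = f"{ex}:{meas}"
        row: dict = {"exercise_id": ex, "measure_name": meas, "measure": label}
        for kind, pair in (("intra", intra_sessions), ("inter", inter_sessions)):
            if not set(pair).issubset(wide.columns):
                continue
            mat = wide[list(pair)].dropna()
            if len(mat) < 2:
                continue
            try:
                icc, p = icc_2_1(mat.to_numpy())
            except UndefinedStatisticError:
                continue
            row[f"icc_{kind}"] = icc
            row[f"icc_{kind}_p"] = p
            row[f"n_{kind}"] = len(mat)
            if kind == "intra":
                s = sem(mat.to_numpy(), icc)
                row["sem"] = s
                row["mdc95"] = mdc95(s)
        rows.append(row)
    cols = [
        "measure", "exercise_id", "measure_name",
        "icc_intra", "icc_intra_p", "n_intra",
        "icc_inter", "icc_inter_p", "n_inter",
        "sem", "mdc95",
    ]
    df = pd.DataFrame(rows)
    return df.reindex(columns=[c for c in cols if c in df.columns])


# ---------------------------------------------------------------------------
# outliers


@dataclass
class OutlierLog:
    """What the outlier pass removed, at cell and participant level."""

    cells: list[tuple[str, str, float, float]] = field(default_factory=list)
    participants_removed: list[str] = field(default_factory=list)
    skipped_measures: list[str] = field(default_factory=list)


def remove_outliers(
    table: pd.DataFrame, z_threshold: float = 3.0, max_flags: int = 2
) -> tuple[pd.DataFrame, OutlierLog]:
    """Two-level outlier removal on a participants x measures table.

    Per measure, cells with |value - mean| / SD > ``z_threshold`` are
    removed (set to NaN); participants flagged in more than ``max_flags``
    measures are dropped entirely.  Zero-SD measures are skipped with a
    warning.  Returns the filtered table and a removal log.
    """
    out = table.copy()
    log = OutlierLog()
    flags: dict = {}
    for col in table.columns:
        vals = table[col].astype(float)
        ok = vals.dropna()
        if len(ok) < 3:
            raise ValueError(f"measure {col!r} needs >= 3 participants")
        sd = ok.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"measure {col!r} has zero SD; outlier pass skipped")
            log.skipped_measures.append(col)
            continue
        z = (vals - ok.mean()) / sd
        for pid in vals.index[z.abs() > z_threshold]:
            log.cells.append((pid, col, float(vals[pid]), float(z[pid])))
            out.loc[pid, col] = np.nan
            flags[pid] = flags.get(pid, 0) + 1
    drop = [pid for pid, c in flags.items() if c > max_flags]
    log.participants_removed = sorted(drop, key=str)
    out = out.drop(index=drop)
    return out, log


# ---------------------------------------------------------------------------
# severity stratification and group comparison


@dataclass(frozen=True)
class SeverityGroup:
    label: str
    fma_range: tuple[int, int]


MODERATE = SeverityGroup("moderate", (19, 46))
MILD = SeverityGroup("mild", (47, 66))


def classify_severity(fma_ue: float) -> SeverityGroup:
    """Severity group from the FMA-UE score (0-66).

    19-46 is moderate and >= 47 mild (47 resolves to mild so the ranges
    are contiguous).  Scores below 19 indicate severe impairment, outside
    the population this battery was characterised on, and raise.
    """
    if not (0 <= fma_ue <= 66):
        raise ValueError(f"FMA-UE score {fma_ue} outside [0, 66]")
    if fma_ue >= 47:
        return MILD
    if fma_ue >= 19:
        return MODERATE
    raise ValueError(
        f"FMA-UE score {fma_ue} indicates severe impairment, outside scope"
    )


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    p: float
    significant: bool
    alpha: float = 0.05


def compare_groups(
    mild, moderate, alpha: float = 0.05, welch: bool = False
) -> GroupComparison:
    """Two-sided Student's t comparison of the two severity groups.

    Equal-variance by default (df = n1 + n2 - 2); Welch's correction is
    available behind a flag.
    """
    a = np.asarray(mild, dtype=float)
    b = np.asarray(moderate, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return GroupComparison(float(res.statistic), df, float(res.pvalue), bool(res.pvalue < alpha), alpha)


def compare_groups_table(
    outcomes: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-measure severity comparison over a wide outcome table.

    ``groups`` maps participant id to "mild"/"moderate".  Returns one row
    per measure with group means/SDs/counts and the t-test result,
    mirroring how sensitivity-to-severity tables are reported.
    """
    rows = []
    for col in outcomes.columns:
        vals = outcomes[col].dropna()
        g = groups.reindex(vals.index)
        a = vals[g == "mild"]
        b = vals[g == "moderate"]
        row = dict(
            measure=col,
            n_mild=len(a), mean_mild=a.mean(), sd_mild=a.std(ddof=1),
            n_moderate=len(b), mean_moderate=b.mean(), sd_moderate=b.std(ddof=1),
        )
        if len(a) >= 2 and len(b) >= 2:
            cmp = compare_groups(a, b, alpha=alpha)
            row.update(t=cmp.t, df=cmp.df, p=cmp.p, significant=cmp.significant)
        rows.append(row)
    return pd.DataFrame(rows)
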