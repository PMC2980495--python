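"""Plate-level screen statistics.

Implements the analytics layer of a whole-organism high-content screen:
assay quality (Z'-factor), per-plate standardization (z-scores), robust
removal of row/column artifacts (two-way median polish and B-scores on the
MAD scale), cross-screen rank aggregation, hit calling, dose-response
verification, and slope/r^2 agreement regression for validating detectors
against ground truth.

Conventions
-----------
* z-scores use the sample SD (ddof=1) over sample wells only (controls and
  excluded wells never enter the mean/SD) unless control pooling is
  requested explicitly.
* The B-score divides median-polish residuals by the raw MAD of the sample
  residuals; no 1.4826 Normal-consistency factor is applied, so thresholds
  are interpreted on the MAD scale.
* Medians of an even number of values are the mean of the two central
  values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegeneratePlateError, UndefinedStatisticError

ROLES = ("negative_control", "positive_control", "sample", "excluded")


@dataclass
class ControlStats:
    """Mean/SD of the positive- and negative-control readout populations."""

    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float

    def __post_init__(self):
        if self.sigma_p < 0 or self.sigma_n < 0:
            raise DataError("control SDs must be non-negative")

    @classmethod
    def from_samples(cls, positive, negative) -> "ControlStats":
        positive = np.asarray(positive, dtype=float)
        negative = np.asarray(negative, dtype=float)
        return cls(mu_p=positive.mean(), sigma_p=positive.std(ddof=1),
                   mu_n=negative.mean(), sigma_n=negative.std(ddof=1))


@dataclass
class PlateData:
    """Readout matrix for one plate with per-well layout annotations.

    ``values[i, j]`` is the chosen readout at row ``i``, column ``j``;
    ``roles`` assigns each well one of ``negative_control``,
    ``positive_control``, ``sample`` or ``excluded``; ``compound_ids``
    names the compound in each sample well (empty string elsewhere).
    """

    plate_id: str
    values: np.ndarray
    roles: np.ndarray
    compound_ids: np.ndarray
    exclusion_reasons: dict = field(default_factory=dict)  # (row, col) -> reason

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("plate values must be a 2-D matrix")
        if self.roles.shape != self.values.shape or self.compound_ids.shape != self.values.shape:
            raise DataError("roles/compound_ids must match the value matrix shape")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise DataError(f"unknown roles: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def sample_mask(self) -> np.ndarray:
        return self.roles == "sample"

    def exclude_well(self, row: int, col: int, reason: str) -> None:
        """Flag a well (e.g. autofluorescent compound) out of all statistics."""
        self.roles[row, col] = "excluded"
        self.exclusion_reasons[(row, col)] = reason

    def control_stats(self) -> ControlStats:
        pos = self.values[self.roles == "positive_control"]
        neg = self.values[self.roles == "negative_control"]
        if pos.size < 2 or neg.size < 2:
            raise DataError("need >= 2 wells of each control to estimate ControlStats")
        return ControlStats.from_samples(pos, neg)

    def to_frame(self) -> pd.DataFrame:
        n_rows, n_cols = self.shape
        rows = []
        for i in range(n_rows):
            for j in range(n_cols):
                rows.append(dict(plate=self.plate_id, row=i, col=j,
                                 value=self.values[i, j], role=self.roles[i, j],
                                 compound_id=self.compound_ids[i, j]))
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, plate_id: str | None = None) -> "PlateData":
        if plate_id is not None:
            df = df[df["plate"] == plate_id]
        else:
            ids = df["plate"].unique()
            if len(ids) != 1:
                raise DataError("frame holds multiple plates; pass plate_id")
            plate_id = ids[0]
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        values = np.full((n_rows, n_cols), np.nan)
        roles = np.full((n_rows, n_cols), "excluded", dtype=object)
        compounds = np.full((n_rows, n_cols), "", dtype=object)
        for _, r in df.iterrows():
            i, j = int(r["row"]), int(r["col"])
            values[i, j] = r["value"]
            roles[i, j] = r["role"]
            compounds[i, j] = r["compound_id"] if pd.notna(r["compound_id"]) else ""
        return cls(plate_id=str(plate_id), values=values, roles=roles,
                   compound_ids=compounds)


@dataclass
class PolishResult:
    """Decomposition of a plate into overall + row + column effects + residuals."""

    mu_hat: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray  # NaN outside the polished (sample) cells
    mad: float
    n_iterations: int
    converged: bool
    sample_mask: np.ndarray
    plate_median_abs: float  # median |readout| of polished cells, for the MAD floor


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope_vs_1: float
    stderr_slope: float


@dataclass
class DoseResponseResult:
    verdict: str  # "confirmed" | "failed"
    pvalues: pd.DataFrame  # per concentration: mean, n, p
    spearman_rho: float


# ---------------------------------------------------------------------------
# Assay quality and normalization
# ---------------------------------------------------------------------------

def zprime(controls: ControlStats) -> float:
    """Z'-factor: 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n|.

    Values between 0.5 and 1.0 indicate a wide separation band between the
    control populations (an excellent assay); below 0 the assay is
    unsuitable for screening.
    """
    sep = abs(controls.mu_p - controls.mu_n)
    if sep == 0:
        raise UndefinedStatisticError("Z'-factor undefined: control means are equal")
    return 1.0 - 3.0 * (controls.sigma_p + controls.sigma_n) / sep


def plate_zscores(plate: PlateData, pool_controls: bool = False) -> np.ndarray:
    """Per-well z-scores of sample wells against the plate's sample population.

    Returns a matrix shaped like the plate with NaN outside sample wells.
    With ``pool_controls=True`` the mean/SD pool control wells with samples
    (appropriate when negative-control and sample levels are similar).
    """
    mask = plate.sample_mask
    if pool_controls:
        mask = mask | (plate.roles == "negative_control") | (plate.roles == "positive_control")
    vals = plate.values[mask]
    if vals.size < 2:
        raise DataError("need >= 2 non-excluded sample wells for z-scores")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("z-scores undefined: zero SD across sample wells")
    out = np.full(plate.shape, np.nan)
    sm = plate.sample_mask
    out[sm] = (plate.values[sm] - vals.mean()) / sd
    return out


def _nanmedian_or_zero(a: np.ndarray, axis: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(a, axis=axis)
    return np.where(np.isnan(med), 0.0, med), np.isnan(med)


def median_polish(plate: PlateData | np.ndarray, mask: np.ndarray | None = None,
                  tol: float = 1e-12, max_iter: int = 500) -> PolishResult:
    """Two-way median polish of the sample wells of a plate.

    Alternates row-median and column-median sweeps until the largest
    median subtracted in a full sweep falls below ``tol`` times the
    plate's median absolute readout (or ``max_iter`` sweeps).  Running the
    sweeps to this fixed point — rather than stopping when the sum of
    absolute residuals stalls — makes the residuals insensitive to
    additive offsets on whole rows or columns, which is the property the
    B-score depends on.  Control and excluded wells never enter any median
    and carry no residual.  The decomposition reconstructs every polished
    cell exactly: y = mu_hat + row_effect + col_effect + residual.
    """
    if isinstance(plate, PlateData):
        values = plate.values
        mask = plate.sample_mask if mask is None else mask
    else:
        values = np.asarray(plate, dtype=float)
        mask = np.ones_like(values, dtype=bool) if mask is None else mask
    mask = mask & np.isfinite(values)
    n_rows, n_cols = values.shape
    if (mask.any(axis=1).sum() < 2) or (mask.any(axis=0).sum() < 2):
        raise DataError("median polish needs >= 2 rows and >= 2 columns of sample wells")

    r = np.where(mask, values, np.nan)
    mu = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    row_undef = ~mask.any(axis=1)
    col_undef = ~mask.any(axis=0)

    scale = max(float(np.median(np.abs(values[mask]))), 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rm, _ = _nanmedian_or_zero(r, axis=1)
        r -= rm[:, None]
        row_eff += rm
        if (~col_undef).any():
            dm = np.median(col_eff[~col_undef])
            col_eff[~col_undef] -= dm
            mu += dm

        cm, _ = _nanmedian_or_zero(r, axis=0)
        r -= cm[None, :]
        col_eff += cm
        if (~row_undef).any():
            dm = np.median(row_eff[~row_undef])
            row_eff[~row_undef] -= dm
            mu += dm

        if max(np.abs(rm).max(), np.abs(cm).max()) <= tol * scale:
            converged = True
            break

    # enforce exact reconstruction on polished cells (absorb rounding into r)
    fitted = mu + row_eff[:, None] + col_eff[None, :]
    r = np.where(mask, values - fitted, np.nan)

    row_effects = row_eff.copy()
    col_effects = col_eff.copy()
    row_effects[row_undef] = np.nan
    col_effects[col_undef] = np.nan

    res_vals = r[mask]
    mad = float(np.median(np.abs(res_vals - np.median(res_vals))))
    return PolishResult(
        mu_hat=float(mu), row_effects=row_effects, col_effects=col_effects,
        residuals=r, mad=mad, n_iterations=it, converged=converged,
        sample_mask=mask,
        plate_median_abs=float(np.median(np.abs(values[mask]))),
    )


def bscore(polish: PolishResult, mad_floor: float | None = None) -> np.ndarray:
    """B-scores: median-polish residuals divided by the plate MAD (unscaled).

    ``mad_floor`` defaults to 1e-12 times the plate's median absolute
    readout; a MAD at or below the floor flags the plate as unanalyzable.
    Returns a matrix shaped like the plate, NaN outside sample wells.
    """
    if mad_floor is None:
        mad_floor = 1e-12 * max(polish.plate_median_abs, 1.0)
    if polish.mad <= mad_floor:
        raise DegeneratePlateError(
            f"plate MAD {polish.mad:.3g} at or below floor {mad_floor:.3g}")
    return polish.residuals / polish.mad


def plate_bscores(plate: PlateData, **polish_kwargs) -> np.ndarray:
    """Convenience: median polish then B-scores for one plate."""
    return bscore(median_polish(plate, **polish_kwargs))


# ---------------------------------------------------------------------------
# Rank aggregation and hit calling
# ---------------------------------------------------------------------------

def rank_scores(bscores_by_screen: pd.DataFrame) -> pd.DataFrame:
    """Average per-screen compound ranks (ascending B-score, ties averaged).

    ``bscores_by_screen`` has one row per compound (index = compound id) and
    one column per replicate screen.  Compounds missing a B-score in any
    screen are excluded (returned with NaN rank_score and a reason column).
    """
    df = bscores_by_screen.copy()
    if df.shape[1] < 2:
        raise DataError("rank_scores needs B-scores from >= 2 screens")
    complete = df.notna().all(axis=1)
    ranks = pd.DataFrame(index=df.index)
    for col in df.columns:
        ranks[f"rank_{col}"] = np.nan
        ranks.loc[complete, f"rank_{col}"] = sps.rankdata(df.loc[complete, col])
    out = ranks.copy()
    out["rank_score"] = ranks.mean(axis=1)
    out["excluded_reason"] = np.where(complete, "", "missing in >=1 screen")
    return out


def call_hits(rank_score: pd.Series, low_cut: float | None = None,
              high_cut: float | None = None,
              reference_n: int = 1280) -> pd.Series:
    """Classify compounds by rank-score with strict thresholds.

    Defaults are the 110 / 1225 cuts defined on a 1280-compound library;
    when the screened compound count differs, the cuts scale as the same
    fractions of the library size (110/1280 and 1225/1280).  Rank-scores
    strictly below the low cut are ``decreaser_candidate``; strictly above
    the high cut, ``increaser_candidate``; boundary values are ``none``.
    """
    n = int(rank_score.notna().sum())
    if low_cut is None:
        low_cut = 110.0 * (n / reference_n) if n != reference_n else 110.0
    if high_cut is None:
        high_cut = 1225.0 * (n / reference_n) if n != reference_n else 1225.0
    if not low_cut < high_cut:
        raise DataError("low_cut must be below high_cut")
    out = pd.Series("none", index=rank_score.index, dtype=object)
    out[rank_score < low_cut] = "decreaser_candidate"
    out[rank_score > high_cut] = "increaser_candidate"
    out[rank_score.isna()] = "none"
    return out


# ---------------------------------------------------------------------------
# Dose-response verification and agreement regression
# ---------------------------------------------------------------------------

def dose_response(series: pd.DataFrame, dmso, direction: str,
                  alpha: float = 0.01, min_animals: int = 2) -> DoseResponseResult:
    """Verify a dose-dependent response against the DMSO control.

    ``series`` holds per-animal readouts with columns ``concentration`` and
    ``readout`` (non-zero concentrations); ``dmso`` is the array of control
    readouts; ``direction`` is ``"decrease"`` or ``"increase"``.

    A compound is confirmed iff (a) at least 2 of the upper half of the
    tested concentrations are significant at one-tailed P < ``alpha`` in the
    hypothesized direction versus DMSO, and (b) the Spearman correlation
    between concentration and per-concentration mean readout has the
    hypothesized sign.  Concentrations with fewer than ``min_animals``
    measured animals are dropped with a warning.
    """
    if direction not in ("decrease", "increase"):
        raise DataError("direction must be 'decrease' or 'increase'")
    dmso = np.asarray(dmso, dtype=float)
    if dmso.size == 0:
        raise DataError("DMSO control readouts required")
    concs = sorted(c for c in series["concentration"].unique() if c > 0)
    if len(concs) < 3:
        raise DataError("dose-response needs >= 3 non-zero concentrations")

    alternative = "less" if direction == "decrease" else "greater"
    rows = []
    for c in concs:
        vals = series.loc[series["concentration"] == c, "readout"].to_numpy(float)
        if vals.size < min_animals:
            warnings.warn(f"concentration {c} dropped: only {vals.size} animals")
            continue
        t = sps.ttest_ind(vals, dmso, equal_var=True, alternative=alternative)
        rows.append(dict(concentration=c, mean=vals.mean(), n=vals.size,
                         p=float(t.pvalue)))
    pvals = pd.DataFrame(rows)
    if len(pvals) < 3:
        raise DataError("fewer than 3 usable concentrations after dropping")

    top_half = pvals.iloc[len(pvals) // 2:]
    n_sig = int((top_half["p"] < alpha).sum())
    rho = float(sps.spearmanr(pvals["concentration"], pvals["mean"]).statistic)
    sign_ok = (rho < 0) if direction == "decrease" else (rho > 0)
    verdict = "confirmed" if (n_sig >= 2 and sign_ok) else "failed"
    return DoseResponseResult(verdict=verdict, pvalues=pvals, spearman_rho=rho)


def agreement_regression(detected, truth) -> RegressionResult:
    """OLS of detected values on ground truth, with a t-test of slope == 1.

    Used to validate detector output against known quantities (e.g. percent
    dead, percent adults).  A perfect identity fit has a degenerate slope
    test and is reported as non-significant (P = 1).
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if detected.size != truth.size or detected.size < 3:
        raise DataError("agreement_regression needs >= 3 paired points")
    if np.ptp(truth) == 0:
        raise UndefinedStatisticError("regression undefined: zero variance in truth")
    res = sps.linregress(truth, detected)
    if res.stderr == 0:
        p = 1.0 if res.slope == 1.0 else 0.0
    else:
        t = (res.slope - 1.0) / res.stderr
        p = float(2.0 * sps.t.sf(abs(t), df=detected.size - 2))
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2), p_slope_vs_1=p,
                            stderr_slope=float(res.stderr))
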