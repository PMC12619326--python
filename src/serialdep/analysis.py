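"""Behavioral bias-analysis pipeline for orientation-adjustment trial data.

Stages, mirroring the standard serial-dependence workflow:

1. :func:`preprocess` — per participant, remove the idiosyncratic
   orientation-dependent ("cardinal") bias by harmonic regression of the
   signed error on sin/cos of the doubled and quadrupled stimulus angle,
   flag outlier trials, and flag whole participants whose error circular SD
   exceeds a threshold.
2. :func:`signed_bias` — per-trial signed error multiplied by the sign of
   the direction to the previous inducer; positive = attraction.
3. :func:`density_asymmetry_curve` — kernel-weighted curve over
   dissimilarity 0..90 deg of (a) the toward-minus-away sign asymmetry
   (unitless, in [-1, 1]) and (b) the mean signed bias in degrees, with
   bootstrap confidence bands.
4. :func:`mean_bias_test` / :func:`per_degree_condition_tests` — one-sample
   t-tests of the mean bias, and per-degree t / repeated-measures-F tests
   with maximal contiguous significant runs ("clusters", descriptive — no
   family-wise correction).
5. :func:`peak_location` — dissimilarity of the maximum of a smoothed curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circ_mean_sd, ori_diff

__all__ = [
    "preprocess",
    "signed_bias",
    "density_asymmetry_curve",
    "participant_curves",
    "mean_bias_test",
    "per_degree_condition_tests",
    "rm_anova_oneway",
    "peak_location",
    "BiasCurve",
    "ClusterReport",
]

DEG_GRID = np.arange(0.0, 91.0)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _harmonic_design(theta_deg: np.ndarray) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.column_stack(
        [np.ones_like(t), np.sin(2 * t), np.cos(2 * t), np.sin(4 * t), np.cos(4 * t)]
    )


def fit_orientation_bias(stimulus: np.ndarray, error: np.ndarray) -> np.ndarray:
    """Least-squares two-harmonic fit of signed error on the stimulus angle.

    Returns the fitted orientation-dependent bias at each input stimulus.
    The basis (sin/cos of 2*theta and 4*theta, theta the orientation in
    radians) spans smooth 180- and 90-deg-periodic biases, which covers the
    classic cardinal-bias shape.
    """
    X = _harmonic_design(stimulus)
    coef, *_ = np.linalg.lstsq(X, error, rcond=None)
    return X @ coef


def preprocess(
    raw: pd.DataFrame,
    outlier_sd_mult: float = 3.0,
    exclusion_circ_sd: float = 30.0,
    min_trials: int = 50,
) -> pd.DataFrame:
    """Per-participant cardinal-bias removal and outlier/participant exclusion.

    Adds columns: ``error`` (raw signed error), ``corrected_error`` (after
    subtracting the fitted orientation-dependent bias), and sets
    ``excluded`` True for outlier trials (|corrected error| beyond
    ``outlier_sd_mult`` circular SDs) and for every trial of participants
    whose error circular SD exceeds ``exclusion_circ_sd`` (the
    whole-participant accuracy rule).  Participants with fewer than
    ``min_trials`` usable trials are skipped (flagged, not corrected) and
    listed in ``result.attrs["skipped_participants"]``.
    """
    df = raw.copy()
    df["error"] = ori_diff(df["response_ori"].to_numpy(), df["stimulus_ori"].to_numpy())
    df["corrected_error"] = df["error"].astype(float)
    df["excluded"] = df.get("excluded", False)
    skipped: list = []
    for pid, idx in df.groupby("participant_id").groups.items():
        sub = df.loc[idx]
        if len(sub) < min_trials:
            skipped.append(pid)
            continue
        fitted = fit_orientation_bias(
            sub["stimulus_ori"].to_numpy(), sub["error"].to_numpy()
        )
        corr = sub["error"].to_numpy() - fitted
        df.loc[idx, "corrected_error"] = corr
        sd = circ_mean_sd(corr).sd
        df.loc[idx, "excluded"] = np.abs(corr) > outlier_sd_mult * sd
        if circ_mean_sd(sub["error"].to_numpy()).sd > exclusion_circ_sd:
            df.loc[idx, "excluded"] = True
    df.attrs["skipped_participants"] = skipped
    return df


# ---------------------------------------------------------------------------
# signed bias
# ---------------------------------------------------------------------------


def signed_bias(
    trials: pd.DataFrame,
    reference: str = "prev_target",
    error_col: str = "corrected_error",
) -> pd.DataFrame:
    """Attach signed bias and dissimilarity columns; drop unusable rows.

    ``reference`` chooses the inducer: "prev_target" uses the
    ``prev_inducer_ori`` column, "prev_distractor" uses
    ``prev_distractor_ori``.  Rows whose reference is missing, flagged
    excluded, or exactly 0 / +-90 deg from the stimulus (bias direction
    undefined) are dropped; the dropped-undefined count is stored in
    ``result.attrs["n_undefined_direction"]``.
    """
    col = {"prev_target": "prev_inducer_ori", "prev_distractor": "prev_distractor_ori"}
    if reference not in col:
        raise ValueError(f"unknown reference {reference!r}")
    refcol = col[reference]
    if refcol not in trials.columns:
        raise KeyError(f"column {refcol!r} not present in trial table")
    df = trials.loc[~trials["excluded"].astype(bool)].copy()
    df = df.dropna(subset=[refcol, error_col])
    delta = ori_diff(df[refcol].to_numpy(), df["stimulus_ori"].to_numpy())
    ok = (delta != 0.0) & (np.abs(delta) != 90.0)
    n_undef = int((~ok).sum())
    df = df.loc[ok]
    delta = delta[ok]
    df["delta"] = delta
    df["abs_delta"] = np.abs(delta)
    df["bias"] = df[error_col].to_numpy() * np.sign(delta)
    df.attrs["n_undefined_direction"] = n_undef
    return df


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


@dataclass
class BiasCurve:
    """Serial-dependence curve over dissimilarity 0..90 deg.

    ``asymmetry`` is the kernel-weighted toward-minus-away sign proportion
    (unitless, in [-1, 1]); ``mean_deg`` the parallel kernel-weighted mean
    signed bias in degrees.  ``ci_low``/``ci_high`` bracket the asymmetry.
    """

    diffs: np.ndarray
    asymmetry: np.ndarray
    mean_deg: np.ndarray
    n_effective: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def value(self) -> np.ndarray:
        return self.asymmetry


def _kernel_weights(abs_delta: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-0.5 * ((abs_delta[None, :] - DEG_GRID[:, None]) / bandwidth) ** 2)


def _weighted_curve(w, sign_bias, bias):
    sw = w.sum(axis=1)
    safe = np.where(sw > 0, sw, 1.0)
    asym = np.where(sw > 0, w @ sign_bias / safe, np.nan)
    mean = np.where(sw > 0, w @ bias / safe, np.nan)
    return asym, mean, sw


def density_asymmetry_curve(
    trials: pd.DataFrame,
    bandwidth: float = 10.0,
    n_boot: int = 0,
    ci: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> BiasCurve:
    """Kernel-weighted density-asymmetry (and mean-bias) curve.

    Every trial contributes to every dissimilarity step, weighted by a
    Gaussian kernel on |Delta_i - Delta| so nearby differences dominate;
    the asymmetry at a step is the weighted mean of sign(bias) — the excess
    probability of erring toward versus away from the inducer.  With
    ``n_boot > 0`` a trial-resampling bootstrap CI for the asymmetry is
    attached.  Expects the output of :func:`signed_bias`.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if len(trials) == 0:
        raise ValueError("no usable trials")
    ad = trials["abs_delta"].to_numpy()
    bias = trials["bias"].to_numpy()
    sgn = np.sign(bias)
    w = _kernel_weights(ad, bandwidth)
    asym, mean, sw = _weighted_curve(w, sgn, bias)
    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(bias)
        boots = np.empty((n_boot, len(DEG_GRID)))
        for b in range(n_boot):
            take = rng.integers(0, n, size=n)
            boots[b] = _weighted_curve(w[:, take], sgn[take], bias[take])[0]
        alpha = (1.0 - ci) / 2.0
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return BiasCurve(
        diffs=DEG_GRID.copy(),
        asymmetry=asym,
        mean_deg=mean,
        n_effective=sw,
        ci_low=lo,
        ci_high=hi,
    )


def participant_curves(
    trials: pd.DataFrame,
    by: str | None = None,
    bandwidth: float = 10.0,
    statistic: str = "asymmetry",
) -> pd.DataFrame:
    """Per-participant (optionally per-condition) curves, long format.

    ``statistic`` selects "asymmetry" (sign-based, unitless) or "mean_deg".
    Returns columns participant_id, [condition,] delta, value.
    """
    frames = []
    keys = ["participant_id"] + ([by] if by else [])
    for key, sub in trials.groupby(keys):
        curve = density_asymmetry_curve(sub, bandwidth=bandwidth)
        vals = curve.asymmetry if statistic == "asymmetry" else curve.mean_deg
        d = pd.DataFrame({"delta": curve.diffs, "value": vals})
        if by:
            d.insert(0, by, key[1])
            d.insert(0, "participant_id", key[0])
        else:
            d.insert(0, "participant_id", key if np.isscalar(key) else key[0])
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def mean_bias_test(trials: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Per-participant mean bias with a two-sided one-sample t-test vs 0.

    The headline statistic is the mean *sign* of the bias per participant
    (asymmetry units, in [-1, 1]); the mean signed bias in degrees is
    reported alongside.  With fewer than 2 participants the result is
    descriptive only (NaN test statistics).  Rows with zero variance across
    participants get ``degenerate=True``.
    """
    keys = [by] if by else []

    def per_participant(sub):
        return pd.Series(
            {
                "mean_asym": np.sign(sub["bias"]).mean(),
                "mean_bias_deg": sub["bias"].mean(),
                "n_trials": len(sub),
            }
        )

    per = (
        trials.groupby(["participant_id"] + keys)
        .apply(per_participant, include_groups=False)
        .reset_index()
    )
    rows = []
    groups = per.groupby(by) if by else [("all", per)]
    for cond, sub in groups:
        vals = sub["mean_asym"].to_numpy()
        degs = sub["mean_bias_deg"].to_numpy()
        row = {
            "condition": cond,
            "n_participants": len(vals),
            "mean_asym": vals.mean(),
            "sd_asym": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "mean_bias_deg": degs.mean(),
            "t": np.nan,
            "df": len(vals) - 1,
            "p": np.nan,
            "degenerate": False,
        }
        if len(vals) >= 2:
            if np.allclose(vals, vals[0]):
                row["degenerate"] = True
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
                row["t"], row["p"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def rm_anova_oneway(data: np.ndarray):
    """One-way repeated-measures ANOVA, vectorized over trailing axes.

    ``data`` has shape (participants, conditions, ...).  Returns (F, p,
    df1, df2) with the uncorrected univariate F test; with two conditions
    F equals the squared paired t statistic.
    """
    data = np.asarray(data, dtype=float)
    n, c = data.shape[0], data.shape[1]
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)
    cond = data.mean(axis=0)
    ss_cond = n * ((cond - grand) ** 2).sum(axis=0)
    resid = data - subj[:, None] - cond[None, :] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1 = c - 1
    df2 = (n - 1) * (c - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    # degenerate case (e.g. literally identical conditions): define F = 0
    scale = np.maximum((data**2).mean(axis=(0, 1)), 1.0)
    tiny = 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(
            ms_err > tiny,
            ms_cond / np.where(ms_err > tiny, ms_err, 1.0),
            np.where(ms_cond > tiny, np.inf, 0.0),
        )
    p = stats.f.sf(F, df1, df2)
    return F, p, df1, df2


@dataclass
class ClusterReport:
    """Per-degree statistics and maximal contiguous significant runs."""

    diffs: np.ndarray
    per_condition: dict = field(default_factory=dict)  # cond -> dict(t, p, mean)
    anova_F: np.ndarray | None = None
    anova_p: np.ndarray | None = None
    clusters: list = field(default_factory=list)  # dicts: kind, condition, lo, hi, direction
    alpha: float = 0.05


def _runs(mask: np.ndarray):
    """Maximal runs of True; yields (lo, hi) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    yield from zip(starts, ends)


def per_degree_condition_tests(
    curves: pd.DataFrame, conditions=None, alpha: float = 0.05
) -> ClusterReport:
    """Per-degree one-sample t-tests and repeated-measures ANOVA with clusters.

    ``curves`` is the long-format output of :func:`participant_curves`
    (columns participant_id, condition, delta, value).  Every participant
    must have a curve for every condition.  Clusters are maximal contiguous
    degree runs significant at ``alpha`` (descriptive: no family-wise
    correction).
    """
    if "condition" not in curves.columns:
        raise ValueError("curves must carry a 'condition' column")
    conds = list(conditions) if conditions is not None else sorted(
        curves["condition"].unique()
    )
    pids = sorted(curves["participant_id"].unique())
    grid = np.sort(curves["delta"].unique())
    cube = np.full((len(pids), len(conds), len(grid)), np.nan)
    piv = curves.set_index(["participant_id", "condition", "delta"])["value"]
    for i, pid in enumerate(pids):
        for j, c in enumerate(conds):
            try:
                cube[i, j] = piv.loc[(pid, c)].reindex(grid).to_numpy()
            except KeyError:
                raise ValueError(f"participant {pid!r} lacks condition {c!r}") from None
    if np.isnan(cube).any():
        raise ValueError("missing curve values for some (participant, condition, delta)")

    report = ClusterReport(diffs=grid, alpha=alpha)
    for j, c in enumerate(conds):
        t, p = stats.ttest_1samp(cube[:, j, :], 0.0, axis=0)
        mean = cube[:, j, :].mean(axis=0)
        report.per_condition[c] = {"t": t, "p": p, "mean": mean}
        for lo, hi in _runs((p < alpha) & (mean > 0)):
            report.clusters.append(
                {"kind": "t", "condition": c, "lo": grid[lo], "hi": grid[hi],
                 "direction": "attractive"}
            )
        for lo, hi in _runs((p < alpha) & (mean < 0)):
            report.clusters.append(
                {"kind": "t", "condition": c, "lo": grid[lo], "hi": grid[hi],
                 "direction": "repulsive"}
            )
    if len(conds) >= 2:
        F, p, df1, df2 = rm_anova_oneway(cube)
        report.anova_F, report.anova_p = F, p
        for lo, hi in _runs(p < alpha):
            report.clusters.append(
                {"kind": "anova", "condition": None, "lo": grid[lo], "hi": grid[hi],
                 "direction": "difference"}
            )
    return report


def peak_location(curve) -> dict:
    """Dissimilarity (deg) of the curve maximum.

    Accepts a :class:`BiasCurve` (uses the asymmetry values) or a
    (diffs, values) pair.  Returns a dict with ``peak`` plus ``boundary``
    (max at 0 or 90) and ``flat`` (undefined: constant curve) flags; a flat
    curve has ``peak=None``.
    """
    if isinstance(curve, BiasCurve):
        diffs, vals = curve.diffs, curve.asymmetry
    else:
        diffs, vals = curve
        diffs = np.asarray(diffs, dtype=float)
        vals = np.asarray(vals, dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("curve has no non-empty bins")
    diffs, vals = diffs[ok], vals[ok]
    if np.allclose(vals, vals[0]):
        return {"peak": None, "boundary": False, "flat": True}
    i = int(np.argmax(vals))
    return {
        "peak": float(diffs[i]),
        "boundary": bool(i == 0 or i == len(vals) - 1),
        "flat": False,
    }
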