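"""Seeded synthetic trial tables with the statistical structure of the
three orientation-adjustment experiments.

Only the data-generating statistics are emulated (no stimulus rendering):

* Experiment 1 — "streaks" of two sequentially shown Gabors.  Stimulus 1 is
  cued on a third of streaks (report-and-hold-in-memory); Stimulus 2 never.
  Rows are emitted per response: Response 1 (Stimulus 1, immediate),
  Response 2 (Stimulus 2), and for cued streaks Response 3 (Stimulus 1
  again, delayed and noisier).  648 trials (= 324 streaks x 2 stimuli) per
  participant by default.
* Experiments 2 and 3 — two simultaneous Gabors per trial, one reported;
  the cue matches the reported item on 75% of trials (congruent).  One row
  per trial with target and distractor orientations and a
  (previous, current) congruence condition label (cc / ci / ic / ii).

Responses are the stimulus plus a planted derivative-of-Gaussian serial
bias toward the previous reported inducer, an optional cardinal bias
(sinusoid of the quadrupled orientation angle), wrapped-normal response
noise, and optional uniform outliers.  Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import PERIOD, ori_diff, wrap_ori

__all__ = [
    "DesignSpec",
    "SDProfile",
    "NoiseSpec",
    "dog_bias",
    "generate_experiment",
    "generate_dataset",
]

#: ratio of delayed-report (Response 3) noise to immediate-report noise;
#: matched to the roughly doubled absolute error of delayed reports.
R3_NOISE_MULT = 2.0


@dataclass(frozen=True)
class DesignSpec:
    """Synthetic experiment layout."""

    experiment: str = "exp1"
    n_participants: int = 18
    n_trials: int = 648
    cue_fraction: float = 1.0 / 3.0  # exp1: fraction of cued streaks
    congruent_fraction: float = 0.75  # exp2/exp3

    def __post_init__(self):
        if self.experiment not in ("exp1", "exp2", "exp3"):
            raise ValueError("experiment must be exp1, exp2 or exp3")
        for name in ("cue_fraction", "congruent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_participants < 1 or self.n_trials < 2:
            raise ValueError("need >= 1 participant and >= 2 trials")

    @classmethod
    def exp1(cls, n_participants: int = 18, n_trials: int = 648) -> "DesignSpec":
        return cls("exp1", n_participants, n_trials, cue_fraction=1.0 / 3.0)

    @classmethod
    def exp2(cls, n_participants: int = 36, n_trials: int = 720) -> "DesignSpec":
        return cls("exp2", n_participants, n_trials, congruent_fraction=0.75)

    @classmethod
    def exp3(cls, n_participants: int = 36, n_trials: int = 720) -> "DesignSpec":
        return cls("exp3", n_participants, n_trials, congruent_fraction=0.75)


@dataclass(frozen=True)
class SDProfile:
    """Planted serial-dependence shape: a first-derivative-of-Gaussian curve
    with peak attraction ``amplitude`` (deg) at dissimilarity ``width`` (deg).
    Negative amplitude plants repulsion."""

    amplitude: float = 2.0
    width: float = 35.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Response-noise model: wrapped-normal SD, cardinal-bias amplitude
    (deg, sinusoid of the quadrupled orientation), and uniform-outlier rate."""

    response_sd: float = 9.0
    cardinal_amplitude: float = 0.0
    outlier_rate: float = 0.0

    def __post_init__(self):
        if self.response_sd <= 0:
            raise ValueError("response_sd must be positive")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValueError("outlier_rate must lie in [0, 0.2]")


def dog_bias(delta, profile: SDProfile):
    """Derivative-of-Gaussian bias (deg) at signed dissimilarity ``delta`` (deg).

    ``amplitude * (delta/width) * exp(1/2 - delta^2 / (2 width^2))``:
    odd in delta, zero at 0, and exactly ``amplitude`` at ``delta == width``.
    """
    delta = np.asarray(delta, dtype=float)
    u = delta / profile.width
    out = profile.amplitude * u * np.exp(0.5 - 0.5 * u**2)
    if out.ndim == 0:
        return float(out)
    return out


def _cardinal(theta, amplitude: float):
    """Idiosyncratic orientation-dependent bias: amplitude * sin(4 theta)."""
    return amplitude * np.sin(np.deg2rad(4.0 * np.asarray(theta, dtype=float)))


def _make_response(stimulus, bias, noise: NoiseSpec, sd, rng):
    resp = (
        stimulus
        + bias
        + _cardinal(stimulus, noise.cardinal_amplitude)
        + rng.normal(size=np.shape(stimulus)) * sd
    )
    resp = wrap_ori(resp)
    if noise.outlier_rate > 0:
        out = rng.random(np.shape(stimulus)) < noise.outlier_rate
        resp = np.where(out, rng.uniform(0.0, PERIOD, size=np.shape(stimulus)), resp)
    return resp


def _profile_for(profiles, condition) -> SDProfile:
    try:
        return profiles[condition]
    except KeyError:
        raise KeyError(f"no SDProfile supplied for condition {condition!r}") from None


def _generate_exp1_participant(design, profiles, noise, amp_offset, rng):
    n_streaks = design.n_trials // 2
    cued = rng.random(n_streaks) < design.cue_fraction
    s1 = rng.uniform(0.0, PERIOD, size=n_streaks)
    s2 = rng.uniform(0.0, PERIOD, size=n_streaks)

    rows = []
    trial_idx = 0
    for k in range(n_streaks):
        streak_cond = "cued" if cued[k] else "non-cued"
        # Response 1: Stimulus 1, inducer = previous streak's Stimulus 2;
        # its condition is the cue status of the streak containing the inducer.
        if k > 0:
            prev_cond = "cued" if cued[k - 1] else "non-cued"
            inducer_r1 = s2[k - 1]
        else:
            prev_cond = streak_cond
            inducer_r1 = np.nan
        rows.append(
            (k, trial_idx, "response1", cued[k], prev_cond, s1[k], inducer_r1, 1.0)
        )
        trial_idx += 1
        # Response 2: Stimulus 2, inducer = Stimulus 1 of the same streak.
        rows.append(
            (k, trial_idx, "response2", cued[k], streak_cond, s2[k], s1[k], 1.0)
        )
        trial_idx += 1
        # Response 3 (cued streaks): delayed re-report of Stimulus 1.  No
        # serial bias is planted (the delayed report showed none) and the
        # noise is inflated.
        if cued[k]:
            rows.append(
                (k, trial_idx, "response3", True, streak_cond, s1[k], s2[k], R3_NOISE_MULT)
            )
            trial_idx += 1

    df = pd.DataFrame(
        rows,
        columns=[
            "streak_index",
            "trial_index",
            "role",
            "cue",
            "condition",
            "stimulus_ori",
            "prev_inducer_ori",
            "noise_mult",
        ],
    )
    amp = np.zeros(len(df))
    wid = np.full(len(df), 35.0)
    for cond in df["condition"].unique():
        prof = _profile_for(profiles, cond)
        m = (df["condition"] == cond).to_numpy()
        amp[m] = prof.amplitude + amp_offset
        wid[m] = prof.width
    delta = np.where(
        np.isfinite(df["prev_inducer_ori"].to_numpy()),
        ori_diff(
            np.nan_to_num(df["prev_inducer_ori"].to_numpy()),
            df["stimulus_ori"].to_numpy(),
        ),
        0.0,
    )
    planted = np.where(
        df["role"].to_numpy() == "response3",
        0.0,
        amp * (delta / wid) * np.exp(0.5 - 0.5 * (delta / wid) ** 2),
    )
    df["response_ori"] = _make_response(
        df["stimulus_ori"].to_numpy(),
        planted,
        noise,
        noise.response_sd * df["noise_mult"].to_numpy(),
        rng,
    )
    return df.drop(columns="noise_mult")


def _generate_exp23_participant(design, profiles, noise, amp_offset, rng,
                                distractor_profiles=None):
    n = design.n_trials
    congruent = rng.random(n) < design.congruent_fraction
    target = rng.uniform(0.0, PERIOD, size=n)
    distractor = rng.uniform(0.0, PERIOD, size=n)
    prev_congruent = np.roll(congruent, 1)
    labels = np.where(
        prev_congruent,
        np.where(congruent, "cc", "ci"),
        np.where(congruent, "ic", "ii"),
    )
    prev_target = np.roll(target, 1)
    prev_distractor = np.roll(distractor, 1)

    amp = np.zeros(n)
    wid = np.full(n, 35.0)
    for cond in np.unique(labels):
        prof = _profile_for(profiles, cond)
        m = labels == cond
        amp[m] = prof.amplitude + amp_offset
        wid[m] = prof.width
    delta = ori_diff(prev_target, target)
    planted = amp * (delta / wid) * np.exp(0.5 - 0.5 * (delta / wid) ** 2)
    if distractor_profiles is not None:
        for cond in np.unique(labels):
            prof = _profile_for(distractor_profiles, cond)
            m = labels == cond
            dd = ori_diff(prev_distractor, target)
            planted[m] += dog_bias(dd[m], prof)
    planted[0] = 0.0

    df = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "role": "target",
            "cue": congruent,
            "congruent_curr": congruent,
            "congruent_prev": prev_congruent,
            "condition": labels,
            "stimulus_ori": target,
            "distractor_ori": distractor,
            "prev_inducer_ori": prev_target,
            "prev_distractor_ori": prev_distractor,
        }
    )
    df.loc[0, ["prev_inducer_ori", "prev_distractor_ori"]] = np.nan
    df["response_ori"] = _make_response(
        target, planted, noise, noise.response_sd, rng
    )
    return df


def generate_experiment(
    design: DesignSpec,
    profiles: dict[str, SDProfile] | SDProfile | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
    participant_amp_sd: float = 0.5,
    distractor_profiles: dict[str, SDProfile] | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic dataset (all participants) for one design.

    Parameters
    ----------
    profiles : condition -> SDProfile map, or a single profile used for all
        conditions (exp1 conditions: "cued", "non-cued"; exp2/3: "cc", "ci",
        "ic", "ii").
    participant_amp_sd : between-participant SD (deg) of a bias-amplitude
        offset shared across conditions; set 0 for identical participants.
    distractor_profiles : optional condition map planting an additional bias
        toward the previous distractor (exp2/3 only).

    Returns a tidy TrialTable with one row per (participant, trial, role);
    the same seed always yields a byte-identical table.
    """
    noise = noise or NoiseSpec()
    if profiles is None:
        profiles = SDProfile()
    if isinstance(profiles, SDProfile):
        conds = (
            ("cued", "non-cued")
            if design.experiment == "exp1"
            else ("cc", "ci", "ic", "ii")
        )
        profiles = {c: profiles for c in conds}
    root = np.random.default_rng(seed)
    frames = []
    for p in range(design.n_participants):
        rng = np.random.default_rng(root.integers(2**31))
        amp_offset = rng.normal(0.0, participant_amp_sd) if participant_amp_sd > 0 else 0.0
        if design.experiment == "exp1":
            df = _generate_exp1_participant(design, profiles, noise, amp_offset, rng)
        else:
            df = _generate_exp23_participant(
                design, profiles, noise, amp_offset, rng,
                distractor_profiles=distractor_profiles,
            )
        df.insert(0, "participant_id", p)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["excluded"] = False
    return out


def generate_dataset(*args, **kwargs) -> pd.DataFrame:
    """Alias for :func:`generate_experiment`."""
    return generate_experiment(*args, **kwargs)
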