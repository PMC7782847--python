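"""Generative models of pre/post-sleep placement behavior.

The study's competing accounts of multi-item cueing differ in how a cue's
consolidation benefit is distributed over the k items linked to one sound:

* ``PRH`` (parallel reactivation): every cued item gains the full benefit
  Δ, independent of k.
* ``LCH_divided`` (limited capacity, divided): each cued item gains Δ/k.
* ``LCH_random_subset``: each of the n cue repetitions reactivates one
  item of the set sampled uniformly; an item sampled at least once gains
  the full Δ, an item never sampled shares the non-cued fate. The
  at-least-once probability is 1 − ((k−1)/k)^n.
* ``LCH_biased_subset``: one fixed item per set (chosen once) gains Δ;
  the others share the non-cued fate.
* ``null``: cueing does nothing; every item shares the non-cued fate.

Non-cued items drift by a forgetting increment over sleep. Benefits act on
the radial placement error (each item's realized pre-sleep error is
carried over sleep, shifted by the model, perturbed by a consolidation
noise term, floored at zero, and re-expressed in a fresh random
direction), which is the scale on which the study measures memory.

Pre-sleep placements mix three processes: a uniform random guess on the
grid disc (probability ``p_guess``, the mechanism that produces swap-like
errors at every set size), a within-set misbinding (probability scaling
with k − 1, the placement is centered on another same-set item's location
— the mechanism that produces genuinely size-dependent swap errors), and
otherwise Gaussian placement noise around the true location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CueSchedule, Design

__all__ = [
    "ReactivationModelParams",
    "MODELS",
    "reactivation_probability",
    "simulate_pre_sleep",
    "simulate_post_sleep",
    "simulate_training_exposure",
]

MODELS = ("PRH", "LCH_divided", "LCH_random_subset", "LCH_biased_subset", "null")


@dataclass
class ReactivationModelParams:
    """Parameters of the behavioral generator.

    ``delta_px`` is the cueing benefit Δ (radial error reduction, pixels);
    ``forget_px`` the non-cued drift (error increase over sleep);
    ``sigma_pre_px`` the isotropic placement-noise scale;
    ``sigma_sleep_px`` the scale of the item-level consolidation noise
    added to the radial error over sleep; ``sigma_set_px`` the scale of a
    per-set shared consolidation effect (sets differ in how well their
    theme consolidates, which is what makes within-set benefits agree more
    than across sets); ``p_guess`` the
    probability that a placement is a uniform random guess; ``p_confuse``
    the per-additional-same-set-item misbinding probability (a placement
    centered on another item of the set), chosen so that simulated
    pre-sleep swap rates approximate the study's observed 0.385 (six-item) /
    0.175 (two-item) / 0.1 (one-item) means; ``n_reps_per_sound`` the
    nominal number of cue repetitions during sleep. ``incremental_subset``
    switches the random-subset model from all-or-nothing to per-sampling
    incremental benefit.
    """

    model: str = "PRH"
    delta_px: float = 8.0
    forget_px: float = 5.0
    sigma_pre_px: float = 45.0
    sigma_sleep_px: float = 8.0
    sigma_set_px: float = 8.0
    p_guess: float = 0.1
    p_confuse: float = 0.07
    n_reps_per_sound: int = 11
    incremental_subset: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.delta_px < 0:
            raise ValueError("delta_px must be >= 0")
        if not 0.0 <= self.p_guess <= 1.0:
            raise ValueError("p_guess must be in [0, 1]")
        if not 0.0 <= self.p_confuse <= 1.0:
            raise ValueError("p_confuse must be in [0, 1]")
        if self.n_reps_per_sound < 0:
            raise ValueError("n_reps_per_sound must be >= 0")


def reactivation_probability(size_k: int, n: int) -> float:
    """Probability an item is reactivated at least once in n cue repetitions
    when each repetition reactivates exactly one item of its k-item set,
    sampled uniformly: 1 − ((k−1)/k)^n.
    """
    if size_k < 1:
        raise ValueError("size_k must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(1.0 - ((size_k - 1) / size_k) ** n)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _uniform_disc(rng: np.random.Generator, radius: float, n: int) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _clip_to_disc(points: np.ndarray, radius: float) -> np.ndarray:
    r = np.linalg.norm(points, axis=1)
    over = r > radius
    if over.any():
        points = points.copy()
        points[over] *= (radius / r[over])[:, None]
    return points


def _other_item_centers(design: Design, rng: np.random.Generator) -> np.ndarray:
    """For each item, a uniformly chosen *other* same-set item location
    (the item's own location for singletons, where misbinding is impossible)."""
    items = design.items
    xy = items[["x", "y"]].to_numpy()
    centers = xy.copy()
    codes, _ = pd.factorize(items["set_id"])
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        m = len(idx)
        if m < 2:
            continue
        # random nonzero cyclic offset picks a uniformly random other item
        off = rng.integers(1, m, size=m)
        centers[idx] = xy[idx[(np.arange(m) + off) % m]]
    return centers


def _place(
    design: Design,
    params: ReactivationModelParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one pre-sleep placement per item.

    With probability ``p_guess`` uniform on the disc; otherwise with the
    size-dependent misbinding probability centered on another same-set item
    (plus Gaussian noise); otherwise Gaussian noise around the true
    location. All placements are clipped to the grid disc. Returns
    (placements, guess flags, misbinding flags).
    """
    items = design.items
    n = len(items)
    R = design.grid.radius_px
    true_xy = items[["x", "y"]].to_numpy(float)
    k = items["size_k"].to_numpy(int)

    guess = rng.uniform(size=n) < params.p_guess
    p_conf = np.clip(params.p_confuse * (k - 1), 0.0, 1.0)
    confuse = (~guess) & (rng.uniform(size=n) < p_conf)

    placed = true_xy + rng.normal(scale=params.sigma_pre_px, size=(n, 2))
    if confuse.any():
        wrong = _other_item_centers(design, rng)
        placed[confuse] = wrong[confuse] + rng.normal(
            scale=params.sigma_pre_px, size=(int(confuse.sum()), 2)
        )
    placed[guess] = _uniform_disc(rng, R, int(guess.sum()))
    return _clip_to_disc(placed, R), guess, confuse


def simulate_pre_sleep(
    design: Design,
    params: ReactivationModelParams,
    rng_seed,
    participant_id: str = "p01",
) -> pd.DataFrame:
    """Simulate the pre-sleep placement test (one row per item).

    The returned records carry the latent ``guess``/``confused`` flags so
    the post-sleep simulator can model a contaminated placement as a lapse
    of the test, not of the underlying spatial memory.
    """
    rng = _rng(rng_seed)
    placed, guess, confuse = _place(design, params, rng)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "item_id": design.items["item_id"].to_numpy(),
            "phase": "pre",
            "x": placed[:, 0],
            "y": placed[:, 1],
            "guess": guess,
            "confused": confuse,
        }
    )


def _cued_benefit(
    design: Design,
    reps: pd.Series,
    params: ReactivationModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-item signed radial-error change (negative = improvement)."""
    items = design.items
    cued_sets = set(design.sets.loc[design.sets["cued"] == True, "set_id"])  # noqa: E712
    k = items["size_k"].to_numpy(int)
    change = np.full(len(items), params.forget_px)
    is_cued = items["set_id"].isin(cued_sets).to_numpy()
    if params.model == "null":
        return change
    if params.model == "PRH":
        change[is_cued] = -params.delta_px
    elif params.model == "LCH_divided":
        change[is_cued] = -params.delta_px / k[is_cued]
    elif params.model == "LCH_biased_subset":
        for sid, grp in items[is_cued].groupby("set_id"):
            lucky = grp.index[rng.integers(len(grp))]
            for i in grp.index:
                change[items.index.get_loc(i)] = (
                    -params.delta_px if i == lucky else params.forget_px
                )
    elif params.model == "LCH_random_subset":
        for sid, grp in items[is_cued].groupby("set_id"):
            n = int(reps.get(grp["sound_id"].iloc[0], params.n_reps_per_sound))
            draws = rng.integers(len(grp), size=n)
            counts = np.bincount(draws, minlength=len(grp))
            if params.incremental_subset:
                # full benefit once sampled the expected n/k times
                unit = params.delta_px / max(1, round(n / len(grp)))
                ben = np.minimum(counts * unit, params.delta_px)
            else:
                ben = np.where(counts > 0, params.delta_px, 0.0)
            for i, b in zip(grp.index, ben):
                change[items.index.get_loc(i)] = -b if b > 0 else params.forget_px
    return change


def simulate_post_sleep(
    pre_records: pd.DataFrame,
    design: Design,
    cue_schedule: CueSchedule | int,
    params: ReactivationModelParams,
    rng_seed,
) -> pd.DataFrame:
    """Simulate the post-sleep placement test from the pre-sleep records.

    Each item's realized pre-sleep radial error is carried over sleep: the
    reactivation model adds its signed change (cued sets are those flagged
    in ``design.sets``; repetition counts come from the cue schedule), an
    independent consolidation-noise term of scale ``sigma_sleep_px`` is
    added, the result is floored at zero, and the placement direction is
    re-randomized. Because the radial-error distribution is preserved up to
    the model change, swap rates stay comparable across the two tests, as
    observed in this paradigm.
    """
    rng = _rng(rng_seed)
    items = design.items
    pre = pre_records.set_index("item_id").loc[items["item_id"]]
    pre_err = np.linalg.norm(
        pre[["x", "y"]].to_numpy(float) - items[["x", "y"]].to_numpy(float), axis=1
    )
    if isinstance(cue_schedule, CueSchedule):
        reps = cue_schedule.reps_per_sound()
    else:  # a flat repetition count for every cued sound
        reps = {s: int(cue_schedule) for s in items["sound_id"].unique()}
    change = _cued_benefit(design, reps, params, rng)
    noise = rng.normal(scale=params.sigma_sleep_px, size=len(items)) if params.sigma_sleep_px else 0.0
    if params.sigma_set_px:
        codes, uniq = pd.factorize(items["set_id"])
        noise = noise + rng.normal(scale=params.sigma_set_px, size=len(uniq))[codes]
    post_err = np.maximum(0.0, pre_err + change + noise)
    # direction resampled until the placement lies inside the grid, so the
    # radial error is preserved exactly (radial clipping would bias benefits
    # upward for items near the rim)
    true_xy = items[["x", "y"]].to_numpy(float)
    R = design.grid.radius_px
    placed = np.empty_like(true_xy)
    todo = np.arange(len(items))
    for _ in range(200):
        th = rng.uniform(0.0, 2.0 * np.pi, size=len(todo))
        cand = true_xy[todo] + post_err[todo, None] * np.column_stack([np.cos(th), np.sin(th)])
        ok = np.linalg.norm(cand, axis=1) <= R
        placed[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if not len(todo):
            break
    if len(todo):  # geometrically impossible radii: fall back to radial clip
        th = rng.uniform(0.0, 2.0 * np.pi, size=len(todo))
        cand = true_xy[todo] + post_err[todo, None] * np.column_stack([np.cos(th), np.sin(th)])
        placed[todo] = _clip_to_disc(cand, R)
    return pd.DataFrame(
        {
            "participant_id": pre["participant_id"].to_numpy(),
            "item_id": items["item_id"].to_numpy(),
            "phase": "post",
            "x": placed[:, 0],
            "y": placed[:, 1],
        }
    )


def simulate_training_exposure(
    design: Design,
    rng_seed,
    mean_trials: float = 3.63,
    plays_per_trial: int = 3,
    exposure_plays: int = 2,
    deterministic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate trials-to-criterion per item and sound presentations per set.

    Trials to reach the learning criterion are 2 + Poisson(mean_trials − 2)
    per item (positive integers, mean matching the study's reported
    3.63 trials per image); each positioning trial plays the set's sound
    ``plays_per_trial`` times and each item adds ``exposure_plays`` plays
    from the exposure phase. The per-set play count is the familiarity
    covariate: sounds of larger sets are heard more often during training.
    With ``deterministic`` every item takes exactly 3 trials.
    """
    rng = _rng(rng_seed)
    items = design.items
    if deterministic:
        trials = np.full(len(items), 3, dtype=int)
    else:
        trials = 2 + rng.poisson(mean_trials - 2.0, size=len(items))
    item_trials = pd.DataFrame(
        {
            "item_id": items["item_id"].to_numpy(),
            "set_id": items["set_id"].to_numpy(),
            "sound_id": items["sound_id"].to_numpy(),
            "trials": trials,
            "sound_plays": plays_per_trial * trials + exposure_plays,
        }
    )
    sound_counts = (
        item_trials.groupby(["set_id", "sound_id"], as_index=False)
        .agg(n_items=("item_id", "size"), sound_plays=("sound_plays", "sum"),
             trials=("trials", "sum"))
    )
    return item_trials, sound_counts
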