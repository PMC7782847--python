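"""Placement scoring: swap errors, accuracy errors, lenient correctness,
and the sleep benefit.

A *swap error* is a placement that lands closer to another candidate
location of the item's set than to the item's own location. Swap
classification always uses six candidate locations per set — the set's real
item locations plus unused phantom locations — so that a pure guess is
equally likely to be classified as a swap at every set size. Without the
phantom correction, large guessing errors would be absorbed as swaps in
six-item sets but counted as accuracy errors in one-item sets, biasing the
size comparison.

Accuracy error is the Euclidean pixel distance from the true location and
is only defined for unswapped placements. The sleep benefit of an item is
pre-sleep error minus post-sleep error (positive = improvement), computed
only for items unswapped in both tests so pre/post means cover identical
item sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design

__all__ = [
    "ScoringConfig",
    "classify_swap",
    "classify_swaps",
    "accuracy_error",
    "score_dataset",
    "presleep_set_summaries",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """``correct_criterion_px``: the training criterion (placements closer
    than this count as correct, strictly); ``n_candidates``: candidate
    locations per set used by swap classification."""

    correct_criterion_px: float = 100.0
    n_candidates: int = 6

    def __post_init__(self) -> None:
        if self.correct_criterion_px <= 0:
            raise ValueError("correct_criterion_px must be > 0")


def classify_swaps(
    placed: np.ndarray,
    candidates: np.ndarray,
    own_idx: np.ndarray,
    n_candidates: int = 6,
) -> np.ndarray:
    """Vectorized swap classification.

    ``placed``: (n, 2) placements; ``candidates``: (n, 6, 2) per-item
    candidate locations; ``own_idx``: (n,) index of each item's own location
    among its candidates. Swapped iff the distance to some *other* candidate
    is strictly smaller than to the own location (exact ties are not swaps).
    """
    candidates = np.asarray(candidates, float)
    if candidates.shape[1] != n_candidates:
        raise ValueError(
            f"expected {n_candidates} candidate locations, got {candidates.shape[1]}"
        )
    d = np.linalg.norm(candidates - np.asarray(placed, float)[:, None, :], axis=2)
    n = len(d)
    own = d[np.arange(n), own_idx]
    other = d.copy()
    other[np.arange(n), own_idx] = np.inf
    return other.min(axis=1) < own


def classify_swap(placed, candidates, own_idx: int, n_candidates: int = 6) -> bool:
    """Swap classification for a single placement (see :func:`classify_swaps`)."""
    return bool(
        classify_swaps(
            np.asarray(placed, float)[None, :],
            np.asarray(candidates, float)[None, :, :],
            np.array([own_idx]),
            n_candidates=n_candidates,
        )[0]
    )


def accuracy_error(placed, true_location) -> float:
    """Euclidean distance in pixels between placement and true location."""
    return float(np.linalg.norm(np.asarray(placed, float) - np.asarray(true_location, float)))


def score_dataset(
    placements: pd.DataFrame,
    design: Design,
    config: ScoringConfig | None = None,
    include_practice: bool = False,
    compute_summaries: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Score a pre/post placement table.

    ``placements`` needs columns participant_id, item_id, phase ('pre' or
    'post'), x, y; both phases must be present per item (items missing a
    phase are dropped with a warning). Returns ``(scored, summaries)``:

    ``scored`` — one row per participant × item with per-phase swap flags,
    accuracy errors (NaN when swapped), lenient-correct flags
    (error strictly below the criterion), and the benefit
    (pre − post error, only when unswapped in both phases).

    ``summaries`` — participant × set size × cued means: swap rate per
    phase, accuracy errors, benefit, lenient proportions, and the per-set
    cumulative benefit averaged within the condition.
    """
    config = config or ScoringConfig()
    items = design.items if include_practice else design.scored_items
    meta = items.set_index("item_id")
    cued_by_set = design.sets.set_index("set_id")["cued"]

    pre = placements[placements["phase"] == "pre"][["participant_id", "item_id", "x", "y"]]
    post = placements[placements["phase"] == "post"][["participant_id", "item_id", "x", "y"]]
    wide = pre.merge(
        post, on=["participant_id", "item_id"], how="outer", suffixes=("_pre", "_post")
    )
    have_both = wide[["x_pre", "x_post"]].notna().all(axis=1)
    if not have_both.all():
        dropped = wide.loc[~have_both, "item_id"].tolist()
        logger.warning("dropping %d item(s) missing a test phase: %s", len(dropped), dropped)
        wide = wide[have_both]
    wide = wide[wide["item_id"].isin(meta.index)].reset_index(drop=True)

    item_ids = wide["item_id"]
    sub = meta.loc[item_ids]
    cand = np.stack([design.candidates[s] for s in sub["set_id"]])
    own_idx = sub["cand_idx"].to_numpy(int)
    true_xy = sub[["x", "y"]].to_numpy(float)

    out = pd.DataFrame(
        {
            "participant_id": wide["participant_id"].to_numpy(),
            "item_id": item_ids.to_numpy(),
            "set_id": sub["set_id"].to_numpy(),
            "size_k": sub["size_k"].to_numpy(int),
            "cued": cued_by_set.loc[sub["set_id"]].to_numpy(dtype=object),
        }
    )
    for phase in ("pre", "post"):
        placed = np.column_stack([wide[f"x_{phase}"], wide[f"y_{phase}"]])
        swapped = classify_swaps(placed, cand, own_idx, config.n_candidates)
        err = np.linalg.norm(placed - true_xy, axis=1)
        out[f"swap_{phase}"] = swapped
        out[f"err_{phase}"] = np.where(swapped, np.nan, err)
        out[f"lenient_{phase}"] = np.where(
            swapped, False, err < config.correct_criterion_px
        ).astype(bool)
    both_clean = ~(out["swap_pre"] | out["swap_post"])
    out["benefit"] = np.where(both_clean, out["err_pre"] - out["err_post"], np.nan)
    if not compute_summaries:
        return out, None

    grp = out.groupby(["participant_id", "size_k", "cued"], dropna=False)
    summaries = grp.agg(
        n_items=("item_id", "size"),
        swap_pre=("swap_pre", "mean"),
        swap_post=("swap_post", "mean"),
        err_pre=("err_pre", "mean"),
        err_post=("err_post", "mean"),
        benefit=("benefit", "mean"),
        lenient_pre=("lenient_pre", "mean"),
        lenient_post=("lenient_post", "mean"),
    ).reset_index()
    set_cum = (
        out.groupby(["participant_id", "set_id", "size_k", "cued"], dropna=False)["benefit"]
        .sum(min_count=1)
        .reset_index(name="cumulative_benefit")
    )
    cum = (
        set_cum.groupby(["participant_id", "size_k", "cued"], dropna=False)[
            "cumulative_benefit"
        ]
        .mean()
        .reset_index()
    )
    summaries = summaries.merge(cum, on=["participant_id", "size_k", "cued"], how="left")
    return out, summaries


def score_single_phase(
    placements: pd.DataFrame,
    design: Design,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Score one test phase alone (used before cuing has been assigned).

    Returns one row per placement with swap flag, accuracy error (NaN when
    swapped), and lenient-correct flag; columns are named like
    :func:`score_dataset` output for the phase present in ``placements``.
    """
    config = config or ScoringConfig()
    meta = design.scored_items.set_index("item_id")
    df = placements[placements["item_id"].isin(meta.index)].reset_index(drop=True)
    phases = df["phase"].unique()
    if len(phases) != 1:
        raise ValueError(f"expected a single phase, got {sorted(phases)}")
    phase = phases[0]
    sub = meta.loc[df["item_id"]]
    cand = np.stack([design.candidates[s] for s in sub["set_id"]])
    placed = df[["x", "y"]].to_numpy(float)
    swapped = classify_swaps(placed, cand, sub["cand_idx"].to_numpy(int), config.n_candidates)
    err = np.linalg.norm(placed - sub[["x", "y"]].to_numpy(float), axis=1)
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "item_id": df["item_id"].to_numpy(),
            "set_id": sub["set_id"].to_numpy(),
            "size_k": sub["size_k"].to_numpy(int),
            f"swap_{phase}": swapped,
            f"err_{phase}": np.where(swapped, np.nan, err),
            f"lenient_{phase}": np.where(swapped, False, err < config.correct_criterion_px).astype(bool),
        }
    )


def presleep_set_summaries(scored: pd.DataFrame, config: ScoringConfig | None = None) -> pd.DataFrame:
    """Per-set pre-sleep summaries used to balance cuing.

    ``n_incorrect`` counts placements beyond the training criterion
    (swapped placements included); ``n_swaps`` counts swap errors;
    ``abs_err_px`` sums accuracy error over unswapped placements.
    """
    config = config or ScoringConfig()
    df = scored.copy()
    df["incorrect"] = ~df["lenient_pre"]
    agg = (
        df.groupby(["set_id", "size_k"], as_index=False)
        .agg(
            n_incorrect=("incorrect", "sum"),
            n_swaps=("swap_pre", "sum"),
            abs_err_px=("err_pre", "sum"),
        )
        .fillna({"abs_err_px": 0.0})
    )
    return agg
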