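"""Experimental design generation for a multi-item TMR spatial-memory study.

The study teaches participants the locations of 90 images on a circular grid.
Images are grouped into semantically coherent *sets* of one, two, or six items,
each set linked to a single sound. Half of the sounds are replayed during
post-learning NREM sleep (targeted memory reactivation). This module builds
the full design:

* constrained random spatial layouts — every set receives six candidate
  locations (its real item locations plus unused "phantom" locations), so
  swap-error scoring can treat all set sizes identically;
* the random partition of multi-item sets into two- and six-item sets;
* the learning-block schedule (six blocks of 15 items, same-set items never
  share a block, two-item sets occupy consecutive blocks);
* cued/non-cued balancing based on pre-sleep performance;
* the randomized-blocks sleep cue sequence (each pass presents every cued
  sound and one novel sound exactly once).

Coordinates are continuous pixels with the origin at the grid center,
x rightward and y downward.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "CueEvent",
    "CueSchedule",
    "Design",
    "Layout",
    "LayoutInfeasibleError",
    "ScheduleInfeasibleError",
    "sample_set_locations",
    "build_layout",
    "build_design",
    "schedule_blocks",
    "balance_cuing",
    "build_cue_sequence",
    "audit_layout",
]

N_CANDIDATES = 6  # candidate locations per set, regardless of set size


class LayoutInfeasibleError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the spatial constraints."""


class ScheduleInfeasibleError(RuntimeError):
    """Raised when no valid block schedule is found within the retry cap."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the circular placement grid and its layout constraints.

    Distances are in screen pixels; ``px_to_mm`` converts to millimetres
    (the 125-px images measured 34.6 mm on the study display).
    """

    radius_px: float = 540.0
    px_to_mm: float = 34.6 / 125.0
    min_center_dist: float = 50.0
    min_border_dist: float = 50.0
    min_pairwise_dist: float = 41.0
    min_within_set_dist: float = 400.0

    def __post_init__(self) -> None:
        if not self.radius_px > self.min_center_dist + self.min_border_dist:
            raise ValueError("radius_px must exceed min_center_dist + min_border_dist")
        if not self.min_within_set_dist > self.min_pairwise_dist:
            raise ValueError("min_within_set_dist must exceed min_pairwise_dist")

    @property
    def r_lo(self) -> float:
        return self.min_center_dist

    @property
    def r_hi(self) -> float:
        return self.radius_px - self.min_border_dist


@dataclass(frozen=True)
class CueEvent:
    """One sound presentation during sleep."""

    sound_id: str
    size_k: int  # number of items linked to the sound (0 = novel sound)
    onset_s: float
    pass_idx: int
    rep_idx: int  # 0-based repetition index of this sound
    iti_s: float


@dataclass
class CueSchedule:
    events: list[CueEvent]
    pass_count: int
    iti_choices: tuple[float, ...] = (4.5, 5.0, 5.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sound_id": e.sound_id,
                    "size_k": e.size_k,
                    "onset_s": e.onset_s,
                    "pass": e.pass_idx,
                    "rep": e.rep_idx,
                    "iti_s": e.iti_s,
                }
                for e in self.events
            ]
        )

    def reps_per_sound(self) -> pd.Series:
        return self.to_frame().groupby("sound_id").size() if self.events else pd.Series(dtype=int)


@dataclass
class Design:
    """A complete per-participant design.

    ``sets`` has one row per set (plus the itemless novel-sound row);
    ``items`` one row per placed image; ``candidates`` maps set label to its
    (6, 2) candidate-location array.
    """

    grid: GridSpec
    sets: pd.DataFrame
    items: pd.DataFrame
    candidates: dict[str, np.ndarray]

    @property
    def scored_items(self) -> pd.DataFrame:
        return self.items[~self.items["practice"]].reset_index(drop=True)

    def item_candidates(self, items: pd.DataFrame | None = None) -> np.ndarray:
        """(n_items, 6, 2) candidate array aligned with ``items`` rows."""
        items = self.items if items is None else items
        return np.stack([self.candidates[s] for s in items["set_id"]])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


class _FeasibleLattice:
    """Equal-area lattice over the admissible annulus, used as a proposal
    distribution for constrained placement.

    Cells are squares of side ``cell_px``; a proposal picks a uniformly
    random currently-feasible cell and jitters within it, so the proposal is
    uniform over the feasible region up to discretization. Every accepted
    point is verified against the *exact* constraints, so discretization
    never produces an invalid layout — it only shapes proposal efficiency.
    """

    def __init__(self, grid: GridSpec, cell_px: float = 6.0):
        self.grid = grid
        self.cell_px = float(cell_px)
        ax = np.arange(-grid.r_hi, grid.r_hi + cell_px, cell_px)
        cx, cy = np.meshgrid(ax, ax)
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        rad = np.linalg.norm(centers, axis=1)
        self.centers = centers[(rad >= grid.r_lo) & (rad <= grid.r_hi)]
        self.free = np.ones(len(self.centers), dtype=bool)

    def carve(self, points: np.ndarray) -> None:
        """Mark cells within the cross-set minimum of ``points`` infeasible."""
        for p in np.atleast_2d(points):
            self.free &= (
                np.linalg.norm(self.centers - p, axis=1) >= self.grid.min_pairwise_dist
            )

    def place_set(
        self,
        existing: np.ndarray,
        rng: np.random.Generator,
        set_tries: int = 200,
        jitter_tries: int = 20,
    ) -> np.ndarray | None:
        """Place six mutually-distant points; None if the retry cap is hit."""
        g = self.grid
        existing = np.atleast_2d(existing) if len(existing) else np.empty((0, 2))
        for _ in range(set_tries):
            chosen: list[np.ndarray] = []
            feas = self.free
            ok = True
            for _j in range(N_CANDIDATES):
                idx = np.flatnonzero(feas)
                if idx.size == 0:
                    ok = False
                    break
                accepted = None
                for _t in range(jitter_tries):
                    c = self.centers[idx[rng.integers(idx.size)]]
                    pt = c + rng.uniform(-self.cell_px / 2, self.cell_px / 2, size=2)
                    r = float(np.hypot(*pt))
                    if not (g.r_lo <= r <= g.r_hi):
                        continue
                    if len(existing) and (
                        np.linalg.norm(existing - pt, axis=1) < g.min_pairwise_dist
                    ).any():
                        continue
                    if chosen and (
                        np.linalg.norm(np.asarray(chosen) - pt, axis=1) < g.min_within_set_dist
                    ).any():
                        continue
                    accepted = pt
                    break
                if accepted is None:
                    ok = False
                    break
                chosen.append(accepted)
                feas = feas & (
                    np.linalg.norm(self.centers - accepted, axis=1) >= g.min_within_set_dist
                )
            if ok:
                return np.asarray(chosen)
        return None


def sample_set_locations(
    grid: GridSpec,
    existing: np.ndarray | None,
    rng_seed,
    max_tries: int = 200,
    cell_px: float = 6.0,
) -> np.ndarray:
    """Sample one set's six candidate locations.

    Each point is at least ``min_center_dist`` from the center, at least
    ``min_border_dist`` inside the border, at least ``min_pairwise_dist``
    from every point in ``existing`` (item locations of other sets), and at
    least ``min_within_set_dist`` from the other five points of the set.

    Rejection sampling with an informed proposal: candidate points are drawn
    uniformly over the currently feasible region (lattice cells + jitter)
    and verified against the exact constraints; a stuck set restarts.
    Raises :class:`LayoutInfeasibleError` after ``max_tries`` set attempts,
    signalling an over-constrained grid.
    """
    rng = _rng(rng_seed)
    existing = np.empty((0, 2)) if existing is None or len(existing) == 0 else np.asarray(existing, float)
    lattice = _FeasibleLattice(grid, cell_px=cell_px)
    if len(existing):
        lattice.carve(existing)
    pts = lattice.place_set(existing, rng, set_tries=max_tries)
    if pts is None:
        raise LayoutInfeasibleError(
            f"layout infeasible: could not place {N_CANDIDATES} points after {max_tries} attempts"
        )
    return pts


@dataclass
class Layout:
    """Candidate geometry for every set.

    ``candidates`` maps set label to a (6, 2) array; ``true_idx`` to the
    candidate indices that hold real items (the rest are phantoms);
    ``sizes`` to the set size k the layout was built for.
    """

    candidates: dict[str, np.ndarray]
    true_idx: dict[str, np.ndarray]
    sizes: dict[str, int]

    def true_points(self) -> np.ndarray:
        return np.vstack(
            [self.candidates[lb][self.true_idx[lb]] for lb in self.candidates if len(self.true_idx[lb])]
        )


def build_layout(
    grid: GridSpec,
    sizes: dict[str, int],
    rng_seed,
    cell_px: float = 6.0,
    max_restarts: int = 50,
) -> Layout:
    """Sample candidate locations (real + phantom) for every set.

    Each set receives six candidate locations, mutually at least
    ``min_within_set_dist`` apart, inside the admissible annulus, and at
    least ``min_pairwise_dist`` from every *item* (true location) already
    placed for other sets — phantoms of different sets are mutually
    unconstrained, since they are never displayed and exist only for swap
    scoring. ``sizes[label]`` of each set's candidates are then designated
    true item locations at random.

    The six within-set locations must form near-hexagonal configurations in
    the outer ring, so blind uniform rejection is extremely slow; proposals
    are instead drawn uniformly over a fine lattice of currently feasible
    cells (equal-area cells, so the proposal stays uniform over the feasible
    region up to discretization), jittered within the cell, and every
    accepted point is verified against the exact constraints. Sets are
    placed in random order; a stuck set restarts, and repeated failures
    restart the whole layout.
    """
    rng = _rng(rng_seed)
    for _ in range(max_restarts):
        order = list(sizes)
        rng.shuffle(order)
        candidates: dict[str, np.ndarray] = {}
        true_idx: dict[str, np.ndarray] = {}
        existing_true = np.empty((0, 2))
        lattice = _FeasibleLattice(grid, cell_px=cell_px)
        failed = False
        for label in order:
            pts = lattice.place_set(existing_true, rng, set_tries=60)
            if pts is None:
                failed = True
                break
            candidates[label] = pts
            ti = np.sort(rng.choice(N_CANDIDATES, size=sizes[label], replace=False))
            true_idx[label] = ti
            if len(ti):
                existing_true = np.vstack([existing_true, pts[ti]])
                lattice.carve(pts[ti])
        if not failed:
            return Layout(
                candidates={lb: candidates[lb] for lb in sizes},
                true_idx={lb: true_idx[lb] for lb in sizes},
                sizes=dict(sizes),
            )
    raise LayoutInfeasibleError("layout infeasible: full-design restarts exhausted")


def audit_layout(grid: GridSpec, layout: Layout) -> bool:
    """Brute-force audit of all four distance rules.

    Independent of the sampler: every candidate is checked against the
    annulus bounds, every within-set pair against the within-set minimum,
    and every cross-set pair of *true item* locations against the cross-set
    minimum. Returns True iff all constraints hold.
    """
    labels = list(layout.candidates)
    for lb in labels:
        pts = layout.candidates[lb]
        r = np.linalg.norm(pts, axis=1)
        if (r < grid.r_lo - 1e-9).any() or (r > grid.r_hi + 1e-9).any():
            return False
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        iu = np.triu_indices(len(pts), k=1)
        if (d[iu] < grid.min_within_set_dist - 1e-9).any():
            return False
    tp = [layout.candidates[lb][layout.true_idx[lb]] for lb in labels]
    sizes = [len(p) for p in tp]
    allt = np.vstack(tp)
    setidx = np.repeat(np.arange(len(labels)), sizes)
    d = np.linalg.norm(allt[:, None, :] - allt[None, :, :], axis=2)
    iu = np.triu_indices(len(allt), k=1)
    cross = setidx[iu[0]] != setidx[iu[1]]
    if (d[iu][cross] < grid.min_pairwise_dist - 1e-9).any():
        return False
    return True


def build_design(
    rng_seed,
    grid: GridSpec | None = None,
    n_multi: int = 24,
    n_six: int = 6,
    n_single: int = 21,
    n_practice: int = 3,
    layout: Layout | None = None,
    assign_blocks: bool = True,
) -> Design:
    """Build one participant's design.

    The ``n_multi`` multi-item sets are randomly partitioned into ``n_six``
    six-item sets and the rest two-item sets (per participant, so that set
    content is not confounded with set size). Each set's true locations are a
    random subset of its six candidates. ``n_practice`` of the single-item
    sets are practice/filler sets, excluded from scoring and cuing. A
    :class:`Layout` may be supplied to reuse geometry across participants
    (the partition is then the layout's); everything else is re-randomized.
    """
    rng = _rng(rng_seed)
    grid = grid or GridSpec()

    multi_labels = [f"M{i + 1:02d}" for i in range(n_multi)]
    single_labels = [f"S{i + 1:02d}" for i in range(n_single)]
    practice_ids = set(rng.choice(single_labels, size=n_practice, replace=False))
    if layout is None:
        six_ids = set(rng.choice(multi_labels, size=n_six, replace=False))
        sizes = {lb: (6 if lb in six_ids else 2) for lb in multi_labels}
        sizes.update({lb: 1 for lb in single_labels})
        layout = build_layout(grid, sizes, rng)
    else:
        missing = set(multi_labels + single_labels) - set(layout.candidates)
        if missing:
            raise ValueError(f"layout missing sets: {sorted(missing)}")

    labels = multi_labels + single_labels
    sizes_arr = np.array([layout.sizes[lb] for lb in labels])
    practice_arr = np.array([lb in practice_ids for lb in labels])
    # the novel sound is presented during sleep only and has no items
    sets = pd.DataFrame(
        {
            "set_id": labels + ["NOVEL"],
            "size_k": np.append(sizes_arr, 0),
            "sound_id": [f"snd_{lb}" for lb in labels] + ["snd_NOVEL"],
            "practice": np.append(practice_arr, False),
        }
    )
    sets["cued"] = pd.NA

    i_label = np.repeat(np.arange(len(labels)), sizes_arr)
    within = np.concatenate([np.arange(k) for k in sizes_arr])
    cand_idx = np.concatenate([layout.true_idx[lb] for lb in labels]).astype(int)
    xy = np.vstack([layout.candidates[lb][layout.true_idx[lb]] for lb in labels])
    lab_of = np.array(labels, dtype=object)
    items = pd.DataFrame(
        {
            "item_id": [f"{lab_of[i]}_i{j + 1}" for i, j in zip(i_label, within)],
            "set_id": lab_of[i_label],
            "size_k": sizes_arr[i_label],
            "sound_id": [f"snd_{lab_of[i]}" for i in i_label],
            "practice": practice_arr[i_label],
            "cand_idx": cand_idx,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    items["block"] = 0
    design = Design(grid=grid, sets=sets, items=items, candidates=dict(layout.candidates))
    if assign_blocks:
        design.items = schedule_blocks(design.items, rng)
    return design


def schedule_blocks(items: pd.DataFrame, rng_seed, max_tries: int = 10_000) -> pd.DataFrame:
    """Assign the 90 scored items to six learning blocks of 15.

    Constraints: no two items of one set share a block; the two items of a
    two-item set occupy consecutive blocks (1-2 ... 5-6); six-item sets span
    all six blocks. Practice items keep block 0 (learned first, unscored).
    Constructive randomized assignment: two-item sets draw a random starting
    block, singles fill the remaining per-block capacity; redraw until every
    block holds exactly 15 items.
    """
    rng = _rng(rng_seed)
    items = items.copy()
    scored = items[~items["practice"]]
    six_sets = sorted(scored.loc[scored["size_k"] == 6, "set_id"].unique())
    two_sets = sorted(scored.loc[scored["size_k"] == 2, "set_id"].unique())
    one_sets = sorted(scored.loc[scored["size_k"] == 1, "set_id"].unique())
    n_blocks = 6
    if len(scored) != n_blocks * 15:
        raise ValueError(f"expected {n_blocks * 15} scored items, got {len(scored)}")

    ids_by_set = {s: grp["item_id"].tolist() for s, grp in scored.groupby("set_id")}
    # capacity left per block after the six-item sets (one item in every block)
    cap = 15 - len(six_sets)
    for _ in range(max_tries):
        starts = rng.integers(1, n_blocks, size=len(two_sets))  # start block in 1..5
        two_load = np.zeros(n_blocks + 1, dtype=int)
        for b in starts:
            two_load[b] += 1
            two_load[b + 1] += 1
        single_slots = cap - two_load[1:]
        if (single_slots < 0).any() or single_slots.sum() != len(one_sets):
            continue
        block_of: dict[str, int] = {}
        for s in six_sets:
            perm = rng.permutation(n_blocks) + 1
            for item_id, b in zip(ids_by_set[s], perm):
                block_of[item_id] = int(b)
        for s, b in zip(two_sets, starts):
            ids = ids_by_set[s]
            first = int(rng.integers(0, 2))
            block_of[ids[first]] = int(b)
            block_of[ids[1 - first]] = int(b) + 1
        pool = rng.permutation(np.repeat(np.arange(1, n_blocks + 1), single_slots))
        for s, b in zip(one_sets, pool):
            block_of[ids_by_set[s][0]] = int(b)
        items.loc[~items["practice"], "block"] = items.loc[~items["practice"], "item_id"].map(block_of)
        return items
    raise ScheduleInfeasibleError(f"schedule infeasible after {max_tries} tries")


@functools.lru_cache(maxsize=8)
def _half_splits(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All combinations choosing n//2 of n, as indices and a one-hot matrix
    (cached across calls; the matmul form makes the exhaustive search cheap)."""
    combos = np.array(list(itertools.combinations(range(n), n // 2)))
    onehot = np.zeros((len(combos), n), dtype=np.float32)
    np.put_along_axis(onehot, combos, 1.0, axis=1)
    return combos, onehot


def balance_cuing(pre_scores: pd.DataFrame, rng_seed) -> pd.Series:
    """Choose which sets to cue, balancing pre-sleep performance.

    ``pre_scores`` needs one row per non-practice set with columns
    ``set_id``, ``size_k``, ``n_incorrect`` (items placed beyond the training
    criterion), ``n_swaps`` and ``abs_err_px`` (summed absolute pixel error).
    Within each size class independently, exactly half of the sets are cued;
    the chosen split minimizes |difference in incorrect-placement counts|,
    breaking ties by |difference in swap counts|, then |difference in summed
    error|, then uniformly at random. The search is exhaustive over all
    half-splits. Returns a boolean Series indexed by set_id.
    """
    rng = _rng(rng_seed)
    cued: dict[str, bool] = {}
    for _, grp in pre_scores.groupby("size_k"):
        n = len(grp)
        if n % 2:
            raise ValueError(f"odd number of sets ({n}) in a size class; cannot split in half")
        half = n // 2
        combos, onehot = _half_splits(n)
        V = grp[["n_incorrect", "n_swaps", "abs_err_px"]].to_numpy(np.float32)
        objective = np.abs(V.sum(axis=0)[None, :] - 2.0 * (onehot @ V))
        # lexicographic minimum via successive filtering (cheaper than lexsort)
        ties = np.arange(len(combos))
        for j in range(3):
            col = objective[ties, j]
            ties = ties[col == col.min()]
        pick = combos[ties[rng.integers(len(ties))]]
        flags = np.zeros(n, dtype=bool)
        flags[pick] = True
        cued.update(dict(zip(grp["set_id"], flags)))
    return pd.Series(cued, name="cued")


def build_cue_sequence(
    cued_sets: pd.DataFrame,
    n_passes: int,
    rng_seed,
    cue_duration_s: float = 0.6,
    iti_choices: tuple[float, ...] = (4.5, 5.0, 5.5),
    start_s: float = 10.0,
) -> CueSchedule:
    """Build the sleep cue sequence as randomized blocks.

    ``cued_sets`` holds one row per cued sound plus the novel sound, with
    columns ``sound_id`` and ``size_k``. Each pass presents every sound
    exactly once in a fresh random order; the inter-cue interval is sampled
    uniformly from ``iti_choices`` and onsets accumulate cue duration + ITI,
    so repetition counts never differ by more than one at any truncation
    point.
    """
    rng = _rng(rng_seed)
    sound_ids = cued_sets["sound_id"].to_numpy()
    sizes = cued_sets["size_k"].to_numpy(int)
    n_sounds = len(sound_ids)
    events: list[CueEvent] = []
    itis = np.asarray(iti_choices, float)[
        rng.integers(len(iti_choices), size=n_passes * n_sounds)
    ]
    onsets = start_s + np.concatenate([[0.0], np.cumsum(cue_duration_s + itis[:-1])]) if n_passes else []
    rep_count: dict[str, int] = {}
    pos = 0
    for p in range(n_passes):
        order = rng.permutation(n_sounds)
        for i in order:
            sid = sound_ids[i]
            events.append(
                CueEvent(
                    sound_id=sid,
                    size_k=int(sizes[i]),
                    onset_s=float(onsets[pos]),
                    pass_idx=p,
                    rep_idx=rep_count.get(sid, 0),
                    iti_s=float(itis[pos]),
                )
            )
            rep_count[sid] = rep_count.get(sid, 0) + 1
            pos += 1
    return CueSchedule(events=events, pass_count=n_passes, iti_choices=tuple(iti_choices))
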