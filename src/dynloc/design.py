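"""Source grids, test lists, and static/dynamic session trial plans.

The default source layout places 41 directions on sagittal planes
(constant-lateral "cones of confusion"): a densely sampled median plane
(11 directions, extra density around and above the overhead region) plus
symmetric lateral-angle pairs at ±20°, ±40° and ±60°.  All elevations stay
within the coverage of a loudspeaker array spanning −47°…90°.  Median-plane
directions are tested twice per block, giving the canonical 52-entry test
list.

A static session is organized in blocks of one 52-trial pass per
condition × repetition; a dynamic session crosses the test list with four
instructed head-rotation arrows (left/right → yaw, up/down → pitch), giving
208-trial blocks.  All randomization is driven by a single session seed
through a splittable seed scheme, so plans are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import interaural_to_sph, wrap_polar

__all__ = [
    "SourceGrid",
    "default_layout",
    "make_source_grid",
    "make_test_list",
    "make_static_session",
    "make_dynamic_session",
    "STATIC_CONDITIONS",
    "DYNAMIC_CONDITIONS",
    "ARROW_TO_ROTATION",
]

STATIC_CONDITIONS = ("full", "flat", "free_field")
DYNAMIC_CONDITIONS = ("full", "flat", "frozen", "free_field")
ARROW_TO_ROTATION = {"left": "yaw", "right": "yaw", "up": "pitch", "down": "pitch"}

#: Elevation coverage of the reference loudspeaker array (degrees).
ELEVATION_RANGE = (-47.0, 90.0)

PLAN_COLUMNS = [
    "subject_id",
    "session",
    "block_index",
    "cue_condition",
    "rotation",
    "arrow",
    "target_az_deg",
    "target_el_deg",
    "target_lat_deg",
    "target_pol_deg",
    "repetition_index",
]


@dataclass(frozen=True)
class SourceGrid:
    """Sound-source directions with a median-plane flag per direction."""

    lat_deg: np.ndarray
    pol_deg: np.ndarray
    az_deg: np.ndarray
    el_deg: np.ndarray
    on_median: np.ndarray

    def __len__(self) -> int:
        return len(self.lat_deg)

    @property
    def n_median(self) -> int:
        return int(np.sum(self.on_median))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lat_deg": self.lat_deg,
                "pol_deg": self.pol_deg,
                "az_deg": self.az_deg,
                "el_deg": self.el_deg,
                "on_median": self.on_median,
            }
        )


def default_layout() -> dict:
    """Default sagittal-plane layout: 41 directions, 11 on the median plane.

    Polar sampling on the median plane is densest between the front-overhead
    region and the rear, where head-rotation benefits are expected to be
    largest; the lateral planes carry five directions each.
    """
    return {
        "planes": {
            0.0: [-30.0, 0.0, 30.0, 60.0, 75.0, 90.0, 105.0, 120.0, 150.0, 180.0, 210.0],
            20.0: [-30.0, 0.0, 45.0, 90.0, 135.0],
            -20.0: [-30.0, 0.0, 45.0, 90.0, 135.0],
            40.0: [-30.0, 0.0, 45.0, 90.0, 135.0],
            -40.0: [-30.0, 0.0, 45.0, 90.0, 135.0],
            60.0: [-30.0, 0.0, 45.0, 90.0, 135.0],
            -60.0: [-30.0, 0.0, 45.0, 90.0, 135.0],
        }
    }


def make_source_grid(layout: dict | None = None) -> SourceGrid:
    """Build a source grid from a ``{lateral: [polar, ...]}`` plane layout.

    Raises ``ValueError`` on duplicate directions or elevations outside the
    array's coverage.
    """
    if layout is None:
        layout = default_layout()
    lats, pols = [], []
    for lat, plane_pols in layout["planes"].items():
        for pol in plane_pols:
            lats.append(float(lat))
            pols.append(float(wrap_polar(pol)))
    lat = np.array(lats)
    pol = np.array(pols)
    az, el = interaural_to_sph(lat, pol)
    lo, hi = ELEVATION_RANGE
    if np.any(el < lo - 1e-9) or np.any(el > hi + 1e-9):
        bad = np.argmax((el < lo - 1e-9) | (el > hi + 1e-9))
        raise ValueError(
            f"direction (lat={lat[bad]}, pol={pol[bad]}) has elevation "
            f"{el[bad]:.2f}° outside [{lo}, {hi}]"
        )
    key = set(zip(np.round(lat, 9), np.round(pol, 9)))
    if len(key) != len(lat):
        raise ValueError("layout contains duplicate directions")
    on_median = np.abs(lat) < 1e-9
    return SourceGrid(lat, pol, np.asarray(az), np.asarray(el), on_median)


def make_test_list(grid: SourceGrid) -> pd.DataFrame:
    """Per-block test list: every direction once, median-plane ones twice.

    Median-plane directions cannot be disambiguated from their mirror image
    by left-right symmetry, so they are presented an extra time to balance
    per-hemifield trial counts.
    """
    frame = grid.to_frame()
    doubled = pd.concat([frame, frame[frame.on_median]], ignore_index=True)
    return doubled.reset_index(drop=True)


def _block_rows(test_list: pd.DataFrame, order: np.ndarray, **meta) -> pd.DataFrame:
    rows = test_list.iloc[order].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "target_az_deg": rows.az_deg,
            "target_el_deg": rows.el_deg,
            "target_lat_deg": rows.lat_deg,
            "target_pol_deg": rows.pol_deg,
        }
    )
    for k, v in meta.items():
        out[k] = v
    return out


def _assemble(blocks: list[pd.DataFrame]) -> pd.DataFrame:
    plan = pd.concat(blocks, ignore_index=True)
    return plan[PLAN_COLUMNS]


def make_static_session(
    grid: SourceGrid,
    conditions: tuple[str, ...] = STATIC_CONDITIONS,
    reps: int = 3,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S1",
) -> pd.DataFrame:
    """Static-listening session: ``reps × len(conditions)`` blocks of one
    seeded-shuffled pass through the test list each; no instructed rotation."""
    if reps < 1 or not conditions:
        raise ValueError("need reps >= 1 and at least one condition")
    test_list = make_test_list(grid)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    order_rng, *block_rngs = [np.random.default_rng(s) for s in ss.spawn(1 + reps * len(conditions))]
    cells = [(c, r) for r in range(reps) for c in conditions]
    block_order = order_rng.permutation(len(cells))
    blocks = []
    for block_index, cell_idx in enumerate(block_order):
        cond, rep = cells[cell_idx]
        order = block_rngs[cell_idx].permutation(len(test_list))
        blocks.append(
            _block_rows(
                test_list,
                order,
                subject_id=subject_id,
                session="static",
                block_index=block_index,
                cue_condition=cond,
                rotation="static",
                arrow="none",
                repetition_index=rep,
            )
        )
    return _assemble(blocks)


def make_dynamic_session(
    grid: SourceGrid,
    conditions: tuple[str, ...] = DYNAMIC_CONDITIONS,
    reps: int = 3,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S1",
) -> pd.DataFrame:
    """Dynamic-listening session: each block crosses the four rotation arrows
    with the full test list (4 × 52 = 208 trials by default), seeded-shuffled."""
    if reps < 1 or not conditions:
        raise ValueError("need reps >= 1 and at least one condition")
    test_list = make_test_list(grid)
    arrows = ["up", "down", "left", "right"]
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    order_rng, *block_rngs = [np.random.default_rng(s) for s in ss.spawn(1 + reps * len(conditions))]
    cells = [(c, r) for r in range(reps) for c in conditions]
    block_order = order_rng.permutation(len(cells))
    n = len(test_list)
    blocks = []
    for block_index, cell_idx in enumerate(block_order):
        cond, rep = cells[cell_idx]
        # cross arrows × test list, then shuffle the crossed trials
        crossed = np.arange(4 * n)
        order = block_rngs[cell_idx].permutation(crossed)
        arrow_col = [arrows[i // n] for i in order]
        target_order = order % n
        block = _block_rows(
            test_list,
            target_order,
            subject_id=subject_id,
            session="dynamic",
            block_index=block_index,
            cue_condition=cond,
            rotation="",
            arrow=arrow_col,
            repetition_index=rep,
        )
        block["rotation"] = block.arrow.map(ARROW_TO_ROTATION)
        blocks.append(block)
    return _assemble(blocks)
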