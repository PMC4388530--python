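"""Synthetic benchmarks scoring the pipeline against known ground truth.

Real fermentation series cannot ship with the package, so the tracking
claims are validated on generated scenes where the answer is known
exactly: speed recovery against ground-truth kinematics, invisibility of
static debris, optimality of the association step against exhaustive
enumeration, identity preservation at path crossings, the crowding QC
rule, and calibration of the Mann-Whitney stage comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .motility_stats import compare_stages
from .pipeline import RunConfig, run_pipeline_on_stack
from .synthetic import BacteriumSpec, DebrisSpec, SceneSpec, random_scene, render_scene
from .tracker import CostMatrix, associate


@dataclass
class RecoveryResult:
    seed: int
    noise_sd: float
    true_mean: float      # um/s, ground truth over all steps
    recovered_mean: float  # um/s, pipeline output
    rel_err_pct: float
    n_tracks: int
    n_bacteria: int


def velocity_recovery(seeds=range(1, 11), noise_sd: float = 0.0,
                      n_bacteria: int = 5,
                      speed_range: tuple[float, float] = (40.0, 60.0),
                      config: RunConfig | None = None
                      ) -> list[RecoveryResult]:
    """Recover mean swimming speed on randomized canonical scenes.

    Each seed renders a 1280 x 960 x 30-frame scene with ``n_bacteria``
    rods at speeds uniform in ``speed_range`` and the given noise level,
    runs the full pipeline, and compares the recovered mean velocity with
    the ground-truth mean per-step speed.
    """
    out = []
    for seed in seeds:
        spec = random_scene(n_bacteria=n_bacteria, seed=seed,
                            speed_range=speed_range, noise_sd=noise_sd)
        stack, gt = render_scene(spec)
        res, _, tracks = run_pipeline_on_stack(stack, config)
        true = gt.mean_speed()
        rel = abs(res.mean_velocity - true) / true * 100.0
        out.append(RecoveryResult(seed=seed, noise_sd=noise_sd,
                                  true_mean=true,
                                  recovered_mean=res.mean_velocity,
                                  rel_err_pct=rel, n_tracks=len(tracks),
                                  n_bacteria=n_bacteria))
    return out


def debris_only_scene(seed: int = 0, width_px: int = 1280,
                      height_px: int = 960) -> SceneSpec:
    """Turbid-media control: static particles, no bacteria, no noise."""
    rng = np.random.default_rng(seed)
    debris = [DebrisSpec(center_xy=(float(rng.uniform(20, width_px - 20)),
                                    float(rng.uniform(20, height_px - 20))),
                         radius=float(rng.uniform(0.3, 2.0)),
                         intensity=float(rng.uniform(100, 250)))
              for _ in range(8)]
    return SceneSpec(width_px=width_px, height_px=height_px, n_frames=30,
                     noise_sd=0.0, debris=debris, rng_seed=seed)


def static_suppression(seed: int = 0) -> tuple[int, int]:
    """(detected particles, velocity vectors) on a debris-only scene;
    both are zero when static content is fully suppressed."""
    stack, _ = render_scene(debris_only_scene(seed))
    res, table, _ = run_pipeline_on_stack(stack)
    return len(table), res.n_vectors


def brute_force_min_cost(cost: np.ndarray) -> float:
    """Exhaustive minimum total cost over all complete assignments."""
    n, m = cost.shape
    if n > m:
        return brute_force_min_cost(cost.T)
    return min(sum(cost[i, j] for i, j in enumerate(cols))
               for cols in itertools.permutations(range(m), n))


def association_oracle(n_matrices: int = 200, seed: int = 0,
                       max_size: int = 6) -> tuple[int, float]:
    """Compare the assignment step against exhaustive enumeration.

    Returns (number of matrices where the totals differ, largest absolute
    difference) over random fully admissible cost matrices.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    worst = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(1, max_size + 1))
        m = int(rng.integers(1, max_size + 1))
        cost = rng.random((n, m)) * 10.0
        e = CostMatrix(entries=cost, admissible=np.ones((n, m), bool),
                       gate_px=np.inf)
        matches, _, _ = associate(e)
        total = sum(cost[i, j] for i, j in matches)
        ref = brute_force_min_cost(cost)
        diff = abs(total - ref)
        worst = max(worst, diff)
        if diff > 1e-9:
            mismatches += 1
    return mismatches, worst


def crossing_scene(seed: int = 0) -> SceneSpec:
    """Two rods of clearly different size whose straight paths cross.

    The large rod swims +x through (200, 200) around frame 6; the smaller,
    slower one swims +y through the same point around frame 10, so the
    paths intersect in space while the bodies stay ~45 px apart at closest
    approach — the regime where shape features must keep identities apart.
    """
    big = BacteriumSpec(start_xy=(100.0, 200.0), speed=50.0, heading=0.0,
                        heading_sd_per_step=0.0, length=3.0, width=1.0,
                        intensity=230.0)
    small = BacteriumSpec(start_xy=(200.0, 60.0), speed=40.0, heading=90.0,
                          heading_sd_per_step=0.0, length=1.5, width=0.6,
                          intensity=200.0)
    return SceneSpec(width_px=700, height_px=500, n_frames=30, noise_sd=5.0,
                     bacteria=[big, small], rng_seed=seed)


def crossing_check(seed: int = 0) -> tuple[int, int]:
    """(number of tracks, identity swaps) on the crossing scene.

    A swap is a track whose nearest ground-truth bacterium changes along
    its length.
    """
    stack, gt = render_scene(crossing_scene(seed))
    _, _, tracks = run_pipeline_on_stack(stack)
    g = gt.table
    swaps = 0
    for t in tracks.tracks:
        ids = []
        for f, x, y in zip(t.frames, t.xs, t.ys):
            rows = g[g["frame"] == f]
            if rows.empty:
                continue
            d = np.hypot(rows["x_px"] - x, rows["y_px"] - y)
            ids.append(int(rows.iloc[int(np.argmin(d))]["bacterium_id"]))
        if len(set(ids)) > 1:
            swaps += 1
    return len(tracks), swaps


def crowded_scene(n_bacteria: int = 20, seed: int = 3) -> SceneSpec:
    """More bodies than the tracker is rated for (QC limit is 15/image).

    Bodies start on a grid with ~120 px spacing and swim slowly, so even
    with occasional merges and border exits well over 15 remain detected
    in every frame.
    """
    rng = np.random.default_rng(seed)
    cols = 5
    rows = (n_bacteria + cols - 1) // cols
    bacteria = []
    for i in range(n_bacteria):
        x = 90.0 + 130.0 * (i % cols)
        y = 90.0 + 130.0 * (i // cols)
        bacteria.append(BacteriumSpec(
            start_xy=(x, y), speed=float(rng.uniform(10, 18)),
            heading=float(rng.uniform(0, 360)), heading_sd_per_step=5.0))
    return SceneSpec(width_px=130 * cols + 50, height_px=130 * rows + 50,
                     n_frames=30, noise_sd=0.0, bacteria=bacteria,
                     rng_seed=seed)


def crowding_check(n_bacteria: int = 20, seed: int = 3) -> tuple[float, str]:
    """(mean detected bacteria per image, qc flag) on a crowded scene."""
    stack, _ = render_scene(crowded_scene(n_bacteria, seed))
    res, _, _ = run_pipeline_on_stack(stack)
    return res.mean_bacteria_per_image, res.qc_flag


def mann_whitney_type1_rate(n_pairs: int = 1000, n: int = 50,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate on null pairs drawn from one velocity distribution."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_pairs):
        a = rng.normal(50.0, 10.0, n)
        b = rng.normal(50.0, 10.0, n)
        if compare_stages(a, b).p_value < alpha:
            rejections += 1
    return rejections / n_pairs


def mann_whitney_shift_p(shift: float = 10.0, n: int = 500,
                         seed: int = 0) -> float:
    """p-value for a +shift um/s stage contrast at n per group."""
    rng = np.random.default_rng(seed)
    a = rng.normal(30.0, 10.0, n)
    b = rng.normal(30.0 + shift, 10.0, n)
    return compare_stages(a, b).p_value
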