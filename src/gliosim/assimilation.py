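"""Matching simulations to time-stamped imaging masks.

The simulated density is compared with binary volumes of interest (VOIs)
by binarising it at a detection threshold (what the scan can see) and
counting disagreeing voxels; the per-observation mismatch is the
Euclidean norm of the binary difference and the overall objective is the
maximum over observation times.  The seeding concentration controller
``xi`` is searched dyadically: a run whose disagreement exceeds the halt
threshold (default 5000 voxels) is stopped early and scored infinite,
and ``xi`` is doubled (simulation over-spread) or halved (under-spread)
until a bracket is found, then bisected in log2(xi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import GridMismatchError

HALT_VOXELS_DEFAULT = 5000
DETECT_THRESHOLD_DEFAULT = 0.05


@dataclass
class ObservationSet:
    """Time-stamped binary VOI masks on the simulation grid."""

    times: list[float]  # days, strictly increasing
    masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.masks):
            raise ValueError("times and masks must pair up")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("observation times must be strictly increasing")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise GridMismatchError("all observation masks must share one grid")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FitResult:
    best_xi: float
    best_dist: float
    evaluations: dict[float, float] = field(default_factory=dict)
    mismatch_trace: dict[float, list[float]] = field(default_factory=dict)
    halted_early: dict[float, bool] = field(default_factory=dict)
    converged: bool = True
    n_iterations: int = 0


def mismatch(c_sim: np.ndarray, mask: np.ndarray,
             detect_threshold: float = DETECT_THRESHOLD_DEFAULT
             ) -> tuple[float, int]:
    """Binary mismatch between a simulated density and a VOI mask.

    Binarises ``c_sim`` at ``detect_threshold`` and returns
    ``(l2, voxel_count)`` where ``l2`` is the Euclidean norm of the
    difference of the two binary fields and ``voxel_count = l2^2`` is
    the number of disagreeing voxels.
    """
    c_sim = np.asarray(c_sim)
    mask = np.asarray(mask, dtype=bool)
    if c_sim.shape != mask.shape:
        raise GridMismatchError(
            f"simulated field {c_sim.shape} vs mask {mask.shape}"
        )
    detected = c_sim >= detect_threshold
    count = int(np.sum(detected ^ mask))
    return float(np.sqrt(count)), count


def dist_over_times(sim_fields: dict[float, np.ndarray],
                    observations: ObservationSet,
                    detect_threshold: float = DETECT_THRESHOLD_DEFAULT) -> float:
    """Objective of the least-squares assimilation: the maximum over
    observation times of the per-time mismatch l2 norm."""
    vals = []
    for t, mask in zip(observations.times, observations.masks):
        if t not in sim_fields:
            raise KeyError(f"simulation provides no field at observation time {t}")
        vals.append(mismatch(sim_fields[t], mask, detect_threshold)[0])
    return max(vals)


def _spread_direction(sim_fields, observations, detect_threshold) -> int:
    """+1 if the simulation over-spreads the worst observation (detected
    volume larger than the mask), -1 if it under-spreads."""
    worst, sign = -1.0, 0
    for t, mask in zip(observations.times, observations.masks):
        l2, _ = mismatch(sim_fields[t], mask, detect_threshold)
        if l2 >= worst:
            worst = l2
            vol_sim = int(np.sum(np.asarray(sim_fields[t]) >= detect_threshold))
            vol_obs = int(np.sum(mask))
            sign = 1 if vol_sim >= vol_obs else -1
    return sign


def dyadic_fit(forward_model, observations: ObservationSet, xi0: float = 2.0,
               halt_voxels: int = HALT_VOXELS_DEFAULT,
               detect_threshold: float = DETECT_THRESHOLD_DEFAULT,
               max_iter: int = 20, tol_log2: float = 0.25) -> FitResult:
    """Dyadic search for the seeding controller ``xi``.

    ``forward_model(xi, halt_voxels)`` must return
    ``(sim_fields, halted)``: density fields keyed by observation time
    (possibly truncated when the disagreement exceeded ``halt_voxels``)
    and whether the run halted early.  Early-halted runs score infinite.
    ``xi`` moves by factors of two in the spread-reducing direction
    (over-spread means the cells were too dispersed: increase ``xi``)
    until two consecutive guesses disagree on the direction, then the
    bracket is bisected in log2(xi).  Returns the tested ``xi`` with the
    smallest objective.
    """
    result = FitResult(best_xi=xi0, best_dist=np.inf)

    def evaluate(xi: float) -> tuple[float, int]:
        sim_fields, halted = forward_model(xi, halt_voxels)
        result.halted_early[xi] = bool(halted)
        trace = []
        for t, mask in zip(observations.times, observations.masks):
            if t in sim_fields:
                trace.append(mismatch(sim_fields[t], mask, detect_threshold)[0])
        result.mismatch_trace[xi] = trace
        if halted or any(
            t not in sim_fields for t in observations.times
        ):
            d = np.inf
            direction = 1  # halted runs over-spread by construction
        else:
            d = dist_over_times(sim_fields, observations, detect_threshold)
            direction = _spread_direction(sim_fields, observations, detect_threshold)
        result.evaluations[xi] = d
        if d < result.best_dist or (d == result.best_dist and np.isfinite(d)):
            result.best_dist = d
            result.best_xi = xi
        return d, direction

    xi = float(xi0)
    lo = hi = None  # log2 bracket
    for it in range(max_iter):
        result.n_iterations = it + 1
        d, direction = evaluate(xi)
        if d == 0.0:
            result.converged = True
            return result
        if direction > 0:  # over-spread: concentrate more
            lo = np.log2(xi)
            nxt = xi * 2.0
        else:  # under-spread: relax concentration, floored above 1
            hi = np.log2(xi)
            nxt = xi / 2.0 if xi / 2.0 > 1.0 else 0.5 * (1.0 + xi)
        if lo is not None and hi is not None:
            if hi - lo <= tol_log2:
                result.converged = True
                return result
            nxt = 2.0 ** (0.5 * (lo + hi))
        if abs(np.log2(nxt) - np.log2(xi)) < 1e-12:
            result.converged = True
            return result
        xi = nxt
    result.converged = lo is not None and hi is not None
    return result
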