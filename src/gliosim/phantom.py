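"""Synthetic brain phantoms: tissue maps, tensor field and VOI masks.

The phantom stands in for the clinical imaging pipeline: a brain-shaped
ellipsoidal domain with a white-matter shell carrying smooth, tangentially
aligned fibre tracts (anisotropic diffusion tensors, dominant/transverse
eigenvalue ratio 10:1), near-isotropic grey matter (ratio 1.2:1), a
spherical tumour mask and an enclosing oedema mask.  Subtracting tumour
from oedema yields the surgical-cavity geometry used for seeding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import Grid3D, ball_indicator

WM_EIGEN_RATIO = 10.0
GM_EIGEN_RATIO = 1.2


class PhantomSpecError(ValueError):
    """Phantom geometry violates containment constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic brain phantom.

    Lengths are in physical units of the grid (default spacing 1/voxel).
    The oedema must strictly contain the tumour and both must fit inside
    the brain ellipsoid.
    """

    grid: Grid3D = field(default_factory=lambda: Grid3D((48, 48, 48)))
    brain_semi_axes: tuple[float, float, float] | None = None
    wm_shell: tuple[float, float] = (0.35, 0.75)  # fractional radii of WM shell
    tumour_centre: tuple[float, float, float] | None = None
    tumour_radius: float = 4.0
    oedema_radius: float = 9.0
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        n = np.asarray(self.grid.shape)
        h = np.asarray(self.grid.spacing)
        o = np.asarray(self.grid.origin)
        centre = o + 0.5 * n * h
        semi = (
            np.asarray(self.brain_semi_axes)
            if self.brain_semi_axes is not None
            else 0.44 * n * h
        )
        tc = (
            np.asarray(self.tumour_centre)
            if self.tumour_centre is not None
            else centre + np.array([0.12, 0.0, 0.0]) * n * h
        )
        return PhantomSpec(
            self.grid, tuple(semi), self.wm_shell, tuple(tc),
            self.tumour_radius, self.oedema_radius, self.seed,
        )

    def validate(self) -> "PhantomSpec":
        spec = self.resolved()
        if spec.tumour_radius < 0 or spec.oedema_radius <= 0:
            raise PhantomSpecError("radii must be nonnegative (oedema > 0)")
        if spec.oedema_radius <= spec.tumour_radius:
            raise PhantomSpecError("oedema must strictly contain the tumour")
        n = np.asarray(spec.grid.shape)
        h = np.asarray(spec.grid.spacing)
        o = np.asarray(spec.grid.origin)
        centre = o + 0.5 * n * h
        offset = np.abs(np.asarray(spec.tumour_centre) - centre)
        if np.any(offset + spec.oedema_radius >= np.asarray(spec.brain_semi_axes)):
            raise PhantomSpecError("oedema does not fit inside the brain ellipsoid")
        return spec


def _anisotropic_tensor(directions: np.ndarray, ratio: float) -> np.ndarray:
    """Trace-3 tensors with dominant eigenvector along ``directions`` (..., 3)."""
    lam_par = 3.0 * ratio / (ratio + 2.0)
    lam_perp = 3.0 / (ratio + 2.0)
    d = directions / np.maximum(np.linalg.norm(directions, axis=-1, keepdims=True), 1e-300)
    outer = d[..., :, None] * d[..., None, :]
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * outer


def tract_directions(grid: Grid3D, centre) -> np.ndarray:
    """Synthetic white-matter tract tangents: nested horizontal arcs.

    The tract family is a fixed set of circular arcs around the vertical
    axis through the brain centre, mimicking the smoothly curving
    appearance of major association tracts at desk scale.
    """
    X, Y, Z = grid.coords()
    dx = np.broadcast_to(X - centre[0], grid.shape)
    dy = np.broadcast_to(Y - centre[1], grid.shape)
    tang = np.stack([-dy, dx, 0.1 * np.ones(grid.shape)], axis=-1)
    r = np.linalg.norm(tang, axis=-1, keepdims=True)
    return tang / np.maximum(r, 1e-12)


def generate_phantom(spec: PhantomSpec) -> dict:
    """Generate a synthetic brain phantom; a pure function of (spec, seed).

    Returns a dict with ``wm_fraction``, ``gm_fraction``, ``tensor_field``
    (shape + (3, 3), SPD), ``tumour_mask``, ``oedema_mask`` and
    ``brain_mask``.
    """
    spec = spec.validate()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)

    n = np.asarray(grid.shape)
    h = np.asarray(grid.spacing)
    o = np.asarray(grid.origin)
    centre = o + 0.5 * n * h

    X, Y, Z = grid.coords()
    semi = np.asarray(spec.brain_semi_axes)
    rho2 = (
        ((X - centre[0]) / semi[0]) ** 2
        + ((Y - centre[1]) / semi[1]) ** 2
        + ((Z - centre[2]) / semi[2]) ** 2
    )
    rho = np.sqrt(rho2)
    brain = rho <= 1.0

    lo, hi = spec.wm_shell
    # Smooth white-matter weight peaking mid-shell, zero at shell edges.
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    wm = np.clip(1.0 - ((rho - mid) / half) ** 2, 0.0, 1.0) * brain
    gm = np.clip(brain.astype(float) - wm, 0.0, 1.0)

    tracts = tract_directions(grid, centre)
    wm_tensors = _anisotropic_tensor(tracts, WM_EIGEN_RATIO)
    gm_dirs = rng.standard_normal(grid.shape + (3,))
    gm_tensors = _anisotropic_tensor(gm_dirs, GM_EIGEN_RATIO)
    bg = np.eye(3) * np.clip(1.0 - wm - gm, 0.0, 1.0)[..., None, None]
    tensors = wm[..., None, None] * wm_tensors + gm[..., None, None] * gm_tensors + bg

    tumour = (
        ball_indicator(grid, spec.tumour_centre, spec.tumour_radius)
        if spec.tumour_radius > 0
        else np.zeros(grid.shape, dtype=bool)
    )
    oedema = ball_indicator(grid, spec.tumour_centre, spec.oedema_radius)

    return {
        "spec": spec,
        "wm_fraction": wm,
        "gm_fraction": gm,
        "tensor_field": tensors,
        "tumour_mask": tumour,
        "oedema_mask": oedema,
        "brain_mask": brain,
        "tract_directions": tracts,
    }


def make_cavity_mask(tumour_mask: np.ndarray, oedema_mask: np.ndarray):
    """Surgical-cavity geometry from the pre-surgical tumour and oedema VOIs.

    The resected region is the tumour mask itself; the seedable shell is
    oedema minus tumour.  If the tumour is not contained in the oedema a
    warning is issued and the intersection is used.
    """
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    oedema_mask = np.asarray(oedema_mask, dtype=bool)
    if tumour_mask.shape != oedema_mask.shape:
        raise ValueError("tumour and oedema masks must share one grid")
    if np.any(tumour_mask & ~oedema_mask):
        warnings.warn(
            "tumour mask not contained in oedema mask; proceeding with the "
            "intersection", stacklevel=2,
        )
    cavity = tumour_mask
    shell = oedema_mask & ~tumour_mask
    return cavity, shell


def fractional_anisotropy(tensors: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(tensors)
    mean = w.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5 * np.sum((w - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(w**2, axis=-1))
    return num / np.maximum(den, 1e-300)


def is_single_component(mask: np.ndarray) -> bool:
    """True if the mask is one nonempty 6-connected component."""
    labels, count = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    return count == 1
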