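"""Spatial discretisations: WENO5 advection and flux-form tensor diffusion.

All operators act on cell-centred fields with even-reflection ghost cells,
consistent with zero-flux boundary conditions, and are written in flux
(conservative) form so that transport conserves total mass exactly when
face fluxes are masked at domain boundaries.
"""

from __future__ import annotations

import numpy as np

_WENO_EPS = 1e-6


def _pad_symmetric(a: np.ndarray, axis: int, width: int) -> np.ndarray:
    pad = [(0, 0)] * a.ndim
    pad[axis] = (width, width)
    return np.pad(a, pad, mode="symmetric")


def _weno5_left(f: np.ndarray) -> np.ndarray:
    """Left-biased WENO5 reconstruction at faces i+1/2 along axis 0.

    ``f`` must carry 3 ghost layers on each end along axis 0; the result
    has length n+1 (one value per interior face including both ends).
    """
    # Stencil cells i-2 .. i+2 for face i+1/2.
    fm2, fm1, f0, fp1, fp2 = f[:-4], f[1:-3], f[2:-2], f[3:-1], f[4:]
    p0 = (2 * fm2 - 7 * fm1 + 11 * f0) / 6.0
    p1 = (-fm1 + 5 * f0 + 2 * fp1) / 6.0
    p2 = (2 * f0 + 5 * fp1 - fp2) / 6.0
    b0 = 13 / 12 * (fm2 - 2 * fm1 + f0) ** 2 + 0.25 * (fm2 - 4 * fm1 + 3 * f0) ** 2
    b1 = 13 / 12 * (fm1 - 2 * f0 + fp1) ** 2 + 0.25 * (fm1 - fp1) ** 2
    b2 = 13 / 12 * (f0 - 2 * fp1 + fp2) ** 2 + 0.25 * (3 * f0 - 4 * fp1 + fp2) ** 2
    a0 = 0.1 / (_WENO_EPS + b0) ** 2
    a1 = 0.6 / (_WENO_EPS + b1) ** 2
    a2 = 0.3 / (_WENO_EPS + b2) ** 2
    s = a0 + a1 + a2
    return (a0 * p0 + a1 * p1 + a2 * p2) / s


def weno5_face_values(c: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Upwind-biased WENO5 face values of ``c`` along ``axis``.

    Returns ``(c_minus, c_plus)``: the reconstructions from the left and
    right of every face (n+1 faces along the axis, including the two
    physical boundary faces).  Ghost cells by even reflection.
    """
    a = np.moveaxis(c, axis, 0)
    n = a.shape[0]
    ext = _pad_symmetric(a, 0, 3)
    # Face k-1/2 (k = 0..n): left-biased stencil is cells k-3..k+1.
    cm = _weno5_left(ext)[: n + 1]
    # Right-biased reconstruction is the mirror of the left-biased one.
    cp = _weno5_left(ext[::-1])[: n + 1][::-1]
    return np.moveaxis(cm, 0, axis), np.moveaxis(cp, 0, axis)


def advection_divergence(c: np.ndarray, velocity: list[np.ndarray],
                         spacing, face_open: list[np.ndarray] | None = None
                         ) -> np.ndarray:
    """Conservative WENO5 divergence of the advective flux ``c * A``.

    ``velocity`` holds the three cell-centred components of A.  Face
    velocities are arithmetic means of the adjacent cells; the face value
    of ``c`` is the WENO5 reconstruction upwinded by the face velocity
    sign.  ``face_open[axis]`` (shape with n+1 along axis) multiplies the
    face flux — used to impose zero flux at the grid frame and across the
    tumour interface.  Returns ``div(cA)``.
    """
    out = np.zeros_like(c, dtype=np.float64)
    for axis in range(3):
        v = np.moveaxis(np.asarray(velocity[axis], dtype=np.float64), axis, 0)
        a = np.moveaxis(c, axis, 0)
        vext = np.concatenate([v[:1], v, v[-1:]], axis=0)
        vface = 0.5 * (vext[:-1] + vext[1:])  # n+1 faces
        cm, cp = weno5_face_values(c, axis)
        cm = np.moveaxis(cm, axis, 0)
        cp = np.moveaxis(cp, axis, 0)
        cface = np.where(vface >= 0, cm, cp)
        flux = vface * cface
        flux[0] = 0.0
        flux[-1] = 0.0
        if face_open is not None:
            flux = flux * np.moveaxis(face_open[axis], axis, 0)
        div = (flux[1:] - flux[:-1]) / spacing[axis]
        out += np.moveaxis(div, 0, axis)
    return out


def _cell_gradient(g: np.ndarray, axis: int, h: float) -> np.ndarray:
    ext = _pad_symmetric(np.moveaxis(g, axis, 0), 0, 1)
    grad = (ext[2:] - ext[:-2]) / (2 * h)
    return np.moveaxis(grad, 0, axis)


def tensor_diffusion(c: np.ndarray, tensors: np.ndarray, spacing,
                     face_open: list[np.ndarray] | None = None) -> np.ndarray:
    """Full anisotropic diffusion ``div(div(D c))`` in conservative form.

    Writes the operator as the divergence of the vector
    ``G_i = sum_j d(D_ij c)/dx_j`` evaluated at faces: the normal
    component uses an exact two-point difference across the face, the
    tangential components are cell-centred central differences averaged
    to the face.  For isotropic constant D this reduces exactly to the
    7-point Laplacian; central differences are exact on quadratics.
    """
    tensors = np.asarray(tensors, dtype=np.float64)
    if tensors.ndim == 2:
        tensors = np.broadcast_to(tensors, c.shape + (3, 3))
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), atol=1e-12):
        raise ValueError("diffusion tensor field must be symmetric")

    out = np.zeros_like(c, dtype=np.float64)
    for i in range(3):
        hi = spacing[i]
        # Normal part: d(D_ii c)/dx_i as a two-point face difference.
        gii = tensors[..., i, i] * c
        a = np.moveaxis(gii, i, 0)
        aext = np.concatenate([a[:1], a, a[-1:]], axis=0)  # even reflection
        flux = (aext[1:] - aext[:-1]) / hi  # n+1 faces along axis i
        # Tangential parts: cell-centred d(D_ij c)/dx_j averaged to faces.
        for j in range(3):
            if j == i:
                continue
            gij = tensors[..., i, j] * c
            cell = np.moveaxis(_cell_gradient(gij, j, spacing[j]), i, 0)
            cext = np.concatenate([cell[:1], cell, cell[-1:]], axis=0)
            flux = flux + 0.5 * (cext[:-1] + cext[1:])
        flux[0] = 0.0
        flux[-1] = 0.0
        if face_open is not None:
            flux = flux * np.moveaxis(face_open[i], i, 0)
        out += np.moveaxis((flux[1:] - flux[:-1]) / hi, 0, i)
    return out


def divergence_of_tensor(tensors: np.ndarray, spacing) -> np.ndarray:
    """Cell-centred ``(div D)_i = sum_j dD_ij/dx_j`` (shape + (3,))."""
    out = np.zeros(tensors.shape[:-2] + (3,))
    for i in range(3):
        for j in range(3):
            out[..., i] += _cell_gradient(tensors[..., i, j], j, spacing[j])
    return out


def gradient(c: np.ndarray, spacing) -> np.ndarray:
    """Cell-centred central-difference gradient, even-reflection ghosts."""
    return np.stack([_cell_gradient(c, ax, spacing[ax]) for ax in range(3)], axis=-1)


def interface_face_open(inside: np.ndarray) -> list[np.ndarray]:
    """Face masks that close every face with an outside cell on either side.

    Zeroing these face fluxes imposes zero flux across the tumour
    interface, so transport conserves mass inside Omega exactly.
    """
    masks = []
    for axis in range(3):
        a = np.moveaxis(inside.astype(bool), axis, 0)
        interior = a[:-1] & a[1:]
        n1 = np.concatenate(
            [np.zeros_like(a[:1]), interior, np.zeros_like(a[:1])], axis=0
        )
        masks.append(np.moveaxis(n1.astype(np.float64), 0, axis))
    return masks
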