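"""Ptychography forward operator and its adjoint.

The forward operator ``G = F Q`` maps a complex object image ``psi`` (the exit
wave, shape ``(H, W)``) to a stack of complex far-field waves, one per scan
position:

* ``Q`` extracts the ``S x S`` patch of the object under each probe footprint
  and multiplies it elementwise by the known probe ``p``;
* ``F`` applies an independent 2-D *orthonormal* discrete Fourier transform to
  each patch.

With the orthonormal convention ``F^H`` is exactly the inverse transform and
the adjoint identity ``<G x, y> = <x, G^H y>`` holds to machine precision,
which the solver relies on.  Detector intensities are ``|G psi|^2``.

Scan positions are 0-based ``(row, col)`` integers addressing the *top-left*
corner of a half-open ``[row, row+S) x [col, col+S)`` footprint; footprints
must lie fully inside the object (no wrapping, no clipping).
"""

from __future__ import annotations

import numpy as np

from ._exceptions import GeometryError

__all__ = [
    "validate_geometry",
    "extract_patches",
    "scatter_patches",
    "forward",
    "adjoint",
    "intensities",
]


def _as_positions(positions) -> np.ndarray:
    pos = np.asarray(positions)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise GeometryError(
            f"scan positions must have shape (n, 2), got {pos.shape}"
        )
    if not np.issubdtype(pos.dtype, np.integer):
        if not np.all(pos == np.round(pos)):
            raise GeometryError("scan positions must be integers")
        pos = pos.astype(np.int64)
    return pos


def validate_geometry(shape, probe, positions) -> np.ndarray:
    """Check that every probe footprint fits inside the object grid.

    Returns the positions as an ``(n, 2)`` integer array.  Raises
    :class:`GeometryError` naming the first offending pattern index.
    """
    H, W = int(shape[0]), int(shape[1])
    probe = np.asarray(probe)
    if probe.ndim != 2 or probe.shape[0] != probe.shape[1]:
        raise GeometryError(f"probe must be square 2-D, got shape {probe.shape}")
    S = probe.shape[0]
    if S <= 0:
        raise GeometryError("probe side must be positive")
    if H < S or W < S:
        raise GeometryError(
            f"object {H}x{W} smaller than probe side {S}"
        )
    pos = _as_positions(positions)
    if len(pos) < 1:
        raise GeometryError("at least one scan position is required")
    bad = np.where(
        (pos[:, 0] < 0)
        | (pos[:, 0] > H - S)
        | (pos[:, 1] < 0)
        | (pos[:, 1] > W - S)
    )[0]
    if bad.size:
        j = int(bad[0])
        raise GeometryError(
            f"scan position {j} = {tuple(pos[j])} puts a {S}x{S} footprint "
            f"outside the {H}x{W} object"
        )
    return pos


def extract_patches(obj, probe, positions) -> np.ndarray:
    """Apply ``Q``: probe-weighted patch extraction.

    Patch ``j`` is ``probe * obj[r_j:r_j+S, c_j:c_j+S]``.  The input object is
    not modified.
    """
    obj = np.asarray(obj)
    probe = np.asarray(probe)
    pos = validate_geometry(obj.shape, probe, positions)
    S = probe.shape[0]
    out = np.empty((len(pos), S, S), dtype=np.result_type(obj, probe, np.complex64))
    for j, (r, c) in enumerate(pos):
        out[j] = probe * obj[r : r + S, c : c + S]
    return out


def scatter_patches(patches, probe, positions, shape) -> np.ndarray:
    """Apply ``Q^H``: conjugate-probe weighting and scatter-add.

    Accumulates ``conj(probe) * patches[j]`` into an ``H x W`` zero grid at
    each scan position; overlapping footprints add up.  Patterns are
    accumulated in ascending index order, which fixes the floating-point
    summation order (the partitioned solver depends on this for exact
    owned-block agreement).
    """
    patches = np.asarray(patches)
    probe = np.asarray(probe)
    pos = validate_geometry(shape, probe, positions)
    S = probe.shape[0]
    if patches.shape != (len(pos), S, S):
        raise GeometryError(
            f"patch stack shape {patches.shape} does not match "
            f"{(len(pos), S, S)} expected from scan and probe"
        )
    out = np.zeros(tuple(shape), dtype=np.result_type(patches, probe, np.complex64))
    pconj = np.conj(probe)
    for j, (r, c) in enumerate(pos):
        out[r : r + S, c : c + S] += pconj * patches[j]
    return out


def forward(obj, probe, positions) -> np.ndarray:
    """Apply ``G = F Q``: one orthonormal 2-D DFT per probe-weighted patch."""
    return np.fft.fft2(extract_patches(obj, probe, positions), norm="ortho")


def adjoint(waves, probe, positions, shape) -> np.ndarray:
    """Apply ``G^H = Q^H F^H`` (exact adjoint of :func:`forward`)."""
    return scatter_patches(
        np.fft.ifft2(np.asarray(waves), norm="ortho"), probe, positions, shape
    )


def intensities(waves) -> np.ndarray:
    """Detector intensities ``|waves|^2`` (elementwise squared modulus)."""
    waves = np.asarray(waves)
    return waves.real**2 + waves.imag**2
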