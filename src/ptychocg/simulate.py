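"""Synthetic ptychography datasets.

Procedural stand-ins for the usual bench objects: a Siemens-star-style
resolution target and a smooth random-texture object, complex-valued with
configurable amplitude and phase contrast; disk or Gaussian probes; jittered
raster scans with guaranteed footprint containment; and noise-free or
Poisson-noisy diffraction stacks produced by the exact forward model, with
the ground truth retained so reconstructions can be scored.

Everything is deterministic given a :class:`SimulationSpec` and its seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError
from .operators import forward, intensities, validate_geometry

__all__ = [
    "SimulationSpec",
    "make_star",
    "make_texture",
    "make_probe",
    "make_scan",
    "decimate_scan",
    "simulate",
    "make_dataset",
    "estimate_diffraction_bytes",
]


@dataclass
class SimulationSpec:
    """Complete description of one synthetic dataset.

    Defaults match the desk-scale study conditions used throughout the test
    suite: a 512x512 star object scanned by a 64x64 disk probe on a jittered
    raster with step 16 (75% linear overlap), noise-free.
    """

    object_kind: str = "star"      # star | texture
    H: int = 512
    W: int = 512
    S: int = 64
    step: int = 16
    jitter: int = 2
    probe_kind: str = "disk"       # disk | gaussian
    noise: str = "none"            # none | poisson
    flux: float = 1e5
    seed: int = 0
    n_spokes: int = 32

    def __post_init__(self):
        if self.object_kind not in ("star", "texture"):
            raise ConfigurationError(f"unknown object_kind {self.object_kind!r}")
        if self.probe_kind not in ("disk", "gaussian"):
            raise ConfigurationError(f"unknown probe_kind {self.probe_kind!r}")
        if self.noise not in ("none", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.noise!r}")

    def to_dict(self):
        return asdict(self)


def make_star(
    size,
    n_spokes=32,
    inner_radius=8.0,
    outer_radius=None,
    amp_range=(0.5, 1.0),
    phase_range=(0.0, np.pi / 3),
) -> np.ndarray:
    """Siemens-star-style complex transmission target.

    ``n_spokes`` bright sectors alternate with ``n_spokes`` dark ones inside
    the annulus ``inner_radius < r <= outer_radius`` (outer radius defaults
    to 45% of the image side, leaving a uniform margin that overlapping scans
    can fully illuminate).  Bright/dark sectors map to the upper/lower ends
    of ``amp_range`` and ``phase_range``; the background (hub and exterior)
    is exactly ``1 + 0j``.  Deterministic.
    """
    if size < 64:
        raise ConfigurationError("star size must be >= 64")
    if n_spokes < 2:
        raise ConfigurationError("n_spokes must be >= 2")
    for name, (lo, hi) in (("amp_range", amp_range), ("phase_range", phase_range)):
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ConfigurationError(f"invalid {name}: ({lo}, {hi})")
    if amp_range[0] < 0:
        raise ConfigurationError("amplitudes must be non-negative")
    if outer_radius is None:
        outer_radius = 0.45 * size
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)
    spoke = (np.cos(n_spokes * theta) >= 0).astype(float)
    mask = (r > inner_radius) & (r <= outer_radius)
    amp = np.ones((size, size))
    phase = np.zeros((size, size))
    amp[mask] = amp_range[0] + (amp_range[1] - amp_range[0]) * spoke[mask]
    phase[mask] = phase_range[0] + (phase_range[1] - phase_range[0]) * spoke[mask]
    return amp * np.exp(1j * phase)


def make_texture(
    size,
    seed=0,
    correlation_length=16.0,
    amp_range=(0.5, 1.0),
    phase_range=(0.0, np.pi / 3),
) -> np.ndarray:
    """Smooth procedural texture object (a coins-photograph stand-in).

    Gaussian-filtered seeded white noise, rescaled to the given amplitude and
    phase ranges; the outer margin (beyond 45% of the side) is flattened to
    the ``1 + 0j`` background like the star target.
    """
    if size < 64:
        raise ConfigurationError("texture size must be >= 64")
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma=correlation_length
    )
    lo, hi = float(field.min()), float(field.max())
    u = (field - lo) / (hi - lo) if hi > lo else np.zeros_like(field)
    amp = amp_range[0] + (amp_range[1] - amp_range[0]) * u
    phase = phase_range[0] + (phase_range[1] - phase_range[0]) * u
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    outside = np.hypot(yy - c, xx - c) > 0.45 * size
    amp[outside] = 1.0
    phase[outside] = 0.0
    return amp * np.exp(1j * phase)


def make_probe(S, kind="disk", radius=None, sigma=None, phase_curvature=0.0):
    """Complex illumination of side ``S``, normalized to unit peak amplitude.

    ``disk``: top-hat amplitude of the given radius (default ``S/4``).
    ``gaussian``: ``exp(-rho^2 / 2 sigma^2)`` (default ``sigma = S/8``).
    ``phase_curvature`` adds a quadratic phase ``exp(i * curvature *
    (rho/S)^2)`` emulating a defocused focal spot.
    """
    if S < 8:
        raise ConfigurationError("probe side S must be >= 8")
    c = (S - 1) / 2.0
    yy, xx = np.mgrid[0:S, 0:S]
    rho2 = (yy - c) ** 2 + (xx - c) ** 2
    if kind == "disk":
        radius = S / 4 if radius is None else float(radius)
        if radius <= 0:
            raise ConfigurationError("disk radius must be positive")
        amp = (rho2 <= radius**2).astype(float)
    elif kind == "gaussian":
        sigma = S / 8 if sigma is None else float(sigma)
        if sigma <= 0:
            raise ConfigurationError("gaussian sigma must be positive")
        amp = np.exp(-rho2 / (2.0 * sigma**2))
    else:
        raise ConfigurationError(f"unknown probe kind {kind!r}")
    amp = amp / amp.max()
    return amp * np.exp(1j * phase_curvature * rho2 / S**2)


def make_scan(H, W, S, step, jitter=0, seed=0) -> np.ndarray:
    """Jittered raster scan of top-left footprint corners.

    Requires ``step < S`` (adjacent footprints must overlap) and
    ``jitter < step/2``.  Jitter offsets are seeded integer perturbations,
    clipped so every footprint stays inside the object.
    """
    if step >= S:
        raise ConfigurationError(
            f"insufficient overlap: scan step {step} must be smaller than "
            f"the probe side {S}"
        )
    if step < 1:
        raise ConfigurationError("scan step must be >= 1")
    if jitter < 0 or jitter >= step / 2:
        raise ConfigurationError("jitter must satisfy 0 <= jitter < step/2")
    rows = np.arange(0, H - S + 1, step)
    cols = np.arange(0, W - S + 1, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pos = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.int64)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.integers(-jitter, jitter + 1, size=pos.shape)
        pos[:, 0] = np.clip(pos[:, 0], 0, H - S)
        pos[:, 1] = np.clip(pos[:, 1], 0, W - S)
    return pos


def decimate_scan(positions, n_target, mode="grid", seed=0) -> np.ndarray:
    """Subsample a scan to ``n_target`` patterns.

    ``grid`` (default) keeps evenly spaced indices; ``random`` draws a seeded
    sorted sample without replacement.
    """
    positions = np.asarray(positions)
    n = len(positions)
    if not (1 <= n_target <= n):
        raise ConfigurationError(f"n_target must be in [1, {n}]")
    if mode == "grid":
        idx = np.unique(np.linspace(0, n - 1, n_target).round().astype(int))
    elif mode == "random":
        idx = np.sort(
            np.random.default_rng(seed).choice(n, size=n_target, replace=False)
        )
    else:
        raise ConfigurationError(f"unknown decimation mode {mode!r}")
    return positions[idx]


def simulate(obj, probe, positions, noise="none", flux=1e5, seed=0) -> np.ndarray:
    """Diffraction stack ``d = |F Q psi|^2`` from a known object.

    With ``noise="poisson"`` the frames are seeded Poisson draws with mean
    ``flux * d / max(d)`` (a single global flux scale); otherwise the exact
    noise-free intensities are returned.
    """
    d = intensities(forward(obj, probe, positions))
    if noise == "none":
        return d
    if noise == "poisson":
        if flux <= 0:
            raise ConfigurationError("poisson flux must be positive")
        rng = np.random.default_rng(seed)
        return rng.poisson(d * (flux / d.max())).astype(float)
    raise ConfigurationError(f"unknown noise model {noise!r}")


def make_dataset(spec: SimulationSpec):
    """Realize a :class:`SimulationSpec` into a :class:`~ptychocg.io.Dataset`
    (data + probe + positions + retained ground truth)."""
    from .io import Dataset

    if spec.object_kind == "star":
        obj = make_star(max(spec.H, spec.W), n_spokes=spec.n_spokes)[
            : spec.H, : spec.W
        ]
    else:
        obj = make_texture(max(spec.H, spec.W), seed=spec.seed)[: spec.H, : spec.W]
    probe = make_probe(spec.S, kind=spec.probe_kind)
    positions = make_scan(
        spec.H, spec.W, spec.S, spec.step, jitter=spec.jitter, seed=spec.seed
    )
    validate_geometry((spec.H, spec.W), probe, positions)
    data = simulate(
        obj, probe, positions, noise=spec.noise, flux=spec.flux, seed=spec.seed
    )
    return Dataset(
        data=data,
        probe=probe,
        positions=positions,
        shape=(spec.H, spec.W),
        ground_truth=obj,
        spec=spec.to_dict(),
    )


def estimate_diffraction_bytes(S, n, bytes_per_value) -> int:
    """Memory footprint ``S^2 * n * bytes_per_value`` of a diffraction stack
    of ``n`` frames of side ``S`` (e.g. 512, 16384, 4 -> 16 GiB), the planning
    number that motivates distributing the frames across workers."""
    S, n, bpv = int(S), int(n), int(bytes_per_value)
    if S <= 0 or bpv <= 0 or n < 0:
        raise ConfigurationError("dimensions must be positive (n may be 0)")
    return S * S * n * bpv
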