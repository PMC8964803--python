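"""Poisson maximum-likelihood solver with Dai-Yuan conjugate gradients.

The negative Poisson log-likelihood (up to psi-independent constants) of the
measured intensities ``d`` given the object ``psi`` is

    F(psi) = sum_j sum_pixels { |G psi|^2 - 2 d log|G psi| },

whose Wirtinger gradient (derivative with respect to ``conj(psi)``, the
convention under which the first-order change of F along a perturbation
``eta`` is ``2 Re<grad, eta>``) is

    grad F(psi) = G^H ( G psi - d / conj(G psi) ).

Each iteration runs four stages: GRAD (compute the gradient), DIR (Dai-Yuan
conjugate direction), LS (backtracking line search on F along the direction)
and the update ``psi <- psi + gamma * eta``.  Because ``G`` is linear, the
cost along a ray ``psi + gamma*eta`` is evaluated from the two far-field
stacks ``G psi`` and ``G eta`` with cheap elementwise algebra, so each extra
line-search trial costs no Fourier transforms.

A plain gradient-descent solver with a constant step is provided for
comparison; it needs no line search but converges more slowly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ConfigurationError, DataError
from .operators import forward, scatter_patches, validate_geometry
from .metrics import score_reconstruction

__all__ = [
    "SolverConfig",
    "ConvergenceRecord",
    "cost",
    "gradient",
    "dai_yuan_direction",
    "line_search",
    "reconstruct",
    "gd_reconstruct",
]

#: default clamp applied to |G psi| inside logarithms and divisions
DEFAULT_EPS_GUARD = 1e-32


@dataclass
class SolverConfig:
    """Tunable parameters of the iterative reconstruction.

    Attributes
    ----------
    n_iters:
        Number of outer iterations (default 128, the protocol used for the
        reference reconstructions).
    gamma0:
        Initial (large) trial step of the backtracking line search; reset at
        every iteration, no warm start.
    shrink:
        Multiplicative step-shrink factor in (0, 1).
    t:
        Line-search termination parameter: a step ``gamma`` is accepted once
        ``F(psi + gamma*eta) <= F(psi) + gamma*t``.  ``t = 0`` (the practical
        default) accepts any non-increase.
    max_ls_steps:
        Cap on shrinks per line search; hitting it returns the last trial
        step with a warning instead of looping forever.
    eps_guard:
        Small positive clamp on ``|G psi|`` guarding the logarithm and the
        division in the gradient.
    init_mode:
        Object initialization: ``"ones"`` (unit transmission, default) or
        ``"random"`` (unit transmission plus a small seeded complex
        perturbation).
    seed:
        Seed for any randomized initialization.
    stop_tol:
        Optional plateau criterion: stop early once the iterate change
        ``||psi_m - psi_{m-1}||`` falls below ``stop_tol * ||psi_m||``.
    dtype:
        ``"double"`` (complex128, default) or ``"single"`` (complex64, for
        speed at reduced accuracy).
    """

    n_iters: int = 128
    gamma0: float = 1.0
    shrink: float = 0.5
    t: float = 0.0
    max_ls_steps: int = 32
    eps_guard: float = DEFAULT_EPS_GUARD
    init_mode: str = "ones"
    seed: int = 0
    stop_tol: float | None = None
    dtype: str = "double"

    def __post_init__(self):
        if self.n_iters < 1:
            raise ConfigurationError("n_iters must be >= 1")
        if not (0.0 < self.shrink < 1.0):
            raise ConfigurationError("shrink must be in (0, 1)")
        if self.gamma0 <= 0:
            raise ConfigurationError("gamma0 must be positive")
        if self.eps_guard <= 0:
            raise ConfigurationError("eps_guard must be positive")
        if self.max_ls_steps < 0:
            raise ConfigurationError("max_ls_steps must be >= 0")
        if self.init_mode not in ("ones", "random"):
            raise ConfigurationError(
                f"unknown init_mode {self.init_mode!r} (expected 'ones' or 'random')"
            )
        if self.dtype not in ("double", "single"):
            raise ConfigurationError("dtype must be 'double' or 'single'")

    @property
    def complex_dtype(self):
        return np.complex128 if self.dtype == "double" else np.complex64


@dataclass
class ConvergenceRecord:
    """Per-iteration log of a reconstruction run.

    ``cost[m]`` is the accepted cost value ``F(psi_{m+1})`` after iteration
    ``m``; ``diff_norm[m]`` is ``||psi_{m+1} - psi_m||_2``; ``ls_shrinks[m]``
    counts line-search shrinks; ``ls_capped[m]`` flags a hit shrink cap.
    ``ssim``/``psnr`` are filled only when a reference object is supplied.
    """

    initial_cost: float = float("nan")
    cost: list = field(default_factory=list)
    diff_norm: list = field(default_factory=list)
    ls_shrinks: list = field(default_factory=list)
    ls_capped: list = field(default_factory=list)
    ssim: list | None = None
    psnr: list | None = None

    def __len__(self):
        return len(self.cost)


def _check_data(data):
    data = np.asarray(data)
    if np.any(data < 0):
        j = int(np.argwhere(data.min(axis=(1, 2)) < 0)[0][0])
        raise DataError(f"diffraction frame {j} contains negative intensities")
    return data


def cost(obj, data, probe, positions, eps_guard=DEFAULT_EPS_GUARD) -> float:
    """Poisson ML cost ``sum { |G psi|^2 - 2 d log|G psi| }``.

    ``|G psi|`` is clamped below at ``eps_guard`` inside the logarithm, and
    pixels with ``d = 0`` contribute only the intensity term.
    """
    data = _check_data(data)
    ff = forward(obj, probe, positions)
    I = ff.real**2 + ff.imag**2
    # 2 log|g| = log|g|^2, clamping the modulus == clamping the intensity at eps^2
    return float(I.sum() - (data * np.log(np.maximum(I, eps_guard**2))).sum())


def gradient(obj, data, probe, positions, eps_guard=DEFAULT_EPS_GUARD) -> np.ndarray:
    """Wirtinger gradient ``G^H ( G psi - d / conj(G psi) )``.

    The division keeps the phase of ``G psi`` while clamping its modulus at
    ``eps_guard``; where ``G psi`` vanishes exactly the ratio is taken as 0.
    """
    data = _check_data(data)
    obj = np.asarray(obj)
    ff = forward(obj, probe, positions)
    resid = _ml_residual(ff, data, eps_guard)
    return scatter_patches(
        np.fft.ifft2(resid, norm="ortho"), probe, positions, obj.shape
    )


def _ml_residual(ff, data, eps_guard):
    """``G psi - d / conj(G psi)`` with the modulus clamp (d/conj(g) = d*g/|g|^2)."""
    mod2 = ff.real**2 + ff.imag**2
    return ff - data * ff / np.maximum(mod2, eps_guard**2)


def dai_yuan_direction(grad, grad_prev, eta_prev, eps_guard=DEFAULT_EPS_GUARD):
    """Dai-Yuan conjugate direction ``-g_m + alpha * eta_{m-1}``.

    ``alpha = ||g_m||^2 / Re<eta_{m-1}, g_m - g_{m-1}>`` with the inner
    product ``<a,b> = sum conj(a)*b``; the real part makes the coefficient
    well defined on complex grids.  A vanishing denominator (magnitude below
    ``eps_guard``) triggers a steepest-descent restart.
    """
    grad = np.asarray(grad)
    if grad.shape != np.shape(grad_prev) or grad.shape != np.shape(eta_prev):
        raise ConfigurationError(
            "gradient / direction grids must share the object shape"
        )
    denom = float(np.real(np.vdot(eta_prev, grad - grad_prev)))
    if abs(denom) < eps_guard:
        return -grad
    alpha = float(np.real(np.vdot(grad, grad))) / denom
    return -grad + alpha * eta_prev


class CostAlongRay:
    """Cheap evaluator of ``F(psi + gamma*eta)`` as a function of ``gamma``.

    By linearity ``G(psi + gamma*eta) = G psi + gamma * G eta``, so with
    ``A = |G psi|^2``, ``B = |G eta|^2`` and ``R = Re(conj(G psi) * G eta)``
    the trial intensity is the pointwise quadratic ``A + 2*gamma*R +
    gamma^2*B``.  The intensity term of the cost reduces to a scalar
    quadratic; the log term needs elementwise work only where ``d > 0``.
    """

    def __init__(self, ff_psi, ff_eta, data, eps_guard=DEFAULT_EPS_GUARD):
        A = ff_psi.real**2 + ff_psi.imag**2
        B = ff_eta.real**2 + ff_eta.imag**2
        R = ff_psi.real * ff_eta.real + ff_psi.imag * ff_eta.imag
        self.sum_A = float(A.sum())
        self.sum_R = float(R.sum())
        self.sum_B = float(B.sum())
        mask = data > 0
        self.d = np.asarray(data)[mask]
        self.A = A[mask]
        self.R = R[mask]
        self.B = B[mask]
        self.eps2 = float(eps_guard) ** 2

    def __call__(self, gamma: float) -> float:
        g = float(gamma)
        total_I = self.sum_A + 2.0 * g * self.sum_R + g * g * self.sum_B
        I = self.A + (2.0 * g) * self.R + (g * g) * self.B
        return total_I - float(self.d @ np.log(np.maximum(I, self.eps2)))


def _backtrack(f, cfg: SolverConfig):
    """Shrink ``gamma`` geometrically from ``gamma0`` until
    ``f(gamma) <= f(0) + gamma * t`` or the cap is reached.

    Returns ``(gamma, shrinks, f_accepted, f0, capped)``; ``gamma`` is always
    positive.
    """
    f0 = f(0.0)
    gamma = cfg.gamma0
    shrinks = 0
    while True:
        fg = f(gamma)
        if fg <= f0 + gamma * cfg.t:
            return gamma, shrinks, fg, f0, False
        if shrinks >= cfg.max_ls_steps:
            warnings.warn(
                f"line search hit the shrink cap ({cfg.max_ls_steps}); "
                f"returning the last trial step {gamma:.3e}",
                stacklevel=3,
            )
            return gamma, shrinks, fg, f0, True
        gamma *= cfg.shrink
        shrinks += 1


def line_search(obj, eta, data, probe, positions, cfg: SolverConfig):
    """Backtracking line search on the ML cost along direction ``eta``.

    Returns ``(gamma, shrinks)`` with the accepted step (the last trial step,
    with a warning, if the shrink cap is hit).
    """
    data = _check_data(data)
    ray = CostAlongRay(
        forward(obj, probe, positions),
        forward(eta, probe, positions),
        data,
        cfg.eps_guard,
    )
    gamma, shrinks, _, _, _ = _backtrack(ray, cfg)
    return gamma, shrinks


def init_object(shape, cfg: SolverConfig) -> np.ndarray:
    """Initial object estimate: unit transmission, optionally with a small
    seeded complex perturbation (relative scale 1e-2)."""
    psi = np.ones(tuple(shape), dtype=cfg.complex_dtype)
    if cfg.init_mode == "random":
        rng = np.random.default_rng(cfg.seed)
        psi += (
            0.01
            * (rng.standard_normal(psi.shape) + 1j * rng.standard_normal(psi.shape))
        ).astype(cfg.complex_dtype)
    return psi


def _record_metrics(record, psi, reference):
    if reference is not None:
        s, p = score_reconstruction(psi, reference)
        record.ssim.append(s)
        record.psnr.append(p)


def reconstruct(data, probe, positions, shape, cfg: SolverConfig, reference=None):
    """Monolithic (single-worker) CG-ML reconstruction.

    Runs ``cfg.n_iters`` iterations of GRAD -> DIR -> LS -> update, recording
    cost, iterate 2-norm change and line-search effort per iteration (plus
    SSIM/PSNR when a ground-truth ``reference`` is given).  Fully
    deterministic given ``cfg``.
    """
    positions = validate_geometry(shape, probe, positions)
    data = _check_data(data).astype(
        np.float64 if cfg.dtype == "double" else np.float32
    )
    psi = init_object(shape, cfg)
    record = ConvergenceRecord()
    if reference is not None:
        record.ssim, record.psnr = [], []
    grad_prev = eta_prev = None
    for m in range(cfg.n_iters):
        try:
            ff = forward(psi, probe, positions)
            resid = _ml_residual(ff, data, cfg.eps_guard)
            grad = scatter_patches(
                np.fft.ifft2(resid, norm="ortho"), probe, positions, tuple(shape)
            )
            if m == 0:
                eta = -grad
            else:
                eta = dai_yuan_direction(grad, grad_prev, eta_prev, cfg.eps_guard)
            ff_eta = forward(eta, probe, positions)
            ray = CostAlongRay(ff, ff_eta, data, cfg.eps_guard)
            gamma, shrinks, f_new, f0, capped = _backtrack(ray, cfg)
            psi = psi + gamma * eta
        except Exception as exc:
            exc.add_note(f"while running solver iteration {m}")
            raise
        if m == 0:
            record.initial_cost = f0
        record.cost.append(f_new)
        record.diff_norm.append(gamma * float(np.linalg.norm(eta)))
        record.ls_shrinks.append(shrinks)
        record.ls_capped.append(capped)
        _record_metrics(record, psi, reference)
        grad_prev, eta_prev = grad, eta
        if (
            cfg.stop_tol is not None
            and record.diff_norm[-1] <= cfg.stop_tol * float(np.linalg.norm(psi))
        ):
            break
    return psi, record


def gd_reconstruct(data, probe, positions, shape, cfg: SolverConfig, gamma: float):
    """Plain gradient descent ``psi <- psi - gamma * grad F(psi)`` with a
    constant step; the slower baseline the CG solver is compared against."""
    if gamma < 0:
        raise ConfigurationError("gd step gamma must be non-negative")
    positions = validate_geometry(shape, probe, positions)
    data = _check_data(data).astype(
        np.float64 if cfg.dtype == "double" else np.float32
    )
    psi = init_object(shape, cfg)
    record = ConvergenceRecord()
    record.initial_cost = cost(psi, data, probe, positions, cfg.eps_guard)
    for m in range(cfg.n_iters):
        try:
            g = gradient(psi, data, probe, positions, cfg.eps_guard)
            psi = psi - gamma * g
        except Exception as exc:
            exc.add_note(f"while running gradient-descent iteration {m}")
            raise
        record.cost.append(cost(psi, data, probe, positions, cfg.eps_guard))
        record.diff_norm.append(gamma * float(np.linalg.norm(g)))
        record.ls_shrinks.append(0)
        record.ls_capped.append(False)
    return psi, record
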