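"""Reconstruction quality and convergence metrics.

The Poisson likelihood depends on the object only through ``|G psi|``, so a
reconstruction is defined up to a global phase factor.  All image comparisons
here therefore first remove the optimal global phase and then score the
*amplitude* images with SSIM and PSNR; convergence progress within a run is
tracked by the 2-norm of successive iterate differences.
"""

from __future__ import annotations

import csv
import warnings

import numpy as np
from skimage.metrics import structural_similarity

from ._exceptions import GeometryError, PtychoError

__all__ = [
    "align_global_phase",
    "ssim",
    "psnr",
    "iterate_diff_norm",
    "score_reconstruction",
    "run_accuracy_experiment",
    "curves_to_csv",
]


def _check_same_shape(a, b):
    if np.shape(a) != np.shape(b):
        raise GeometryError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def align_global_phase(est, ref):
    """Remove the global phase ambiguity of ``est`` relative to ``ref``.

    Multiplies ``est`` by ``exp(-i*theta)`` with ``theta = arg <ref, est>``
    (inner product ``<a,b> = sum conj(a)*b``), which minimizes
    ``||est*exp(-i*theta) - ref||_2`` over all global phases.  If the inner
    product vanishes the phase is undefined and ``est`` is returned unchanged
    with a warning.
    """
    est = np.asarray(est)
    ref = np.asarray(ref)
    _check_same_shape(est, ref)
    c = np.vdot(ref, est)
    if c == 0:
        warnings.warn(
            "global phase is undefined (<ref, est> = 0); returning the "
            "estimate unchanged",
            stacklevel=2,
        )
        return est.copy()
    return est * np.exp(-1j * np.angle(c))


def ssim(a, b, data_range=None, gaussian=True, win_size=None) -> float:
    """Structural similarity between two real images.

    Defaults to the canonical Gaussian-window formulation (sigma = 1.5,
    population covariances, standard stabilization constants).  ``data_range``
    defaults to the joint peak-to-peak range of the two images.  Symmetric in
    its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_same_shape(a, b)
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo
        if data_range == 0:
            return 1.0  # both images constant and equal
    if gaussian:
        return float(
            structural_similarity(
                a,
                b,
                data_range=data_range,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
            )
        )
    return float(
        structural_similarity(a, b, data_range=data_range, win_size=win_size)
    )


def psnr(a, b, peak=None) -> float:
    """Peak signal-to-noise ratio ``10*log10(peak^2 / MSE)`` in dB.

    ``peak`` defaults to the maximum of the reference image ``b``.  Identical
    images return ``inf`` (the zero-MSE sentinel).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_same_shape(a, b)
    if peak is None:
        peak = float(b.max())
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def iterate_diff_norm(psi_m, psi_prev) -> float:
    """2-norm of the change between successive iterates; 0 iff identical."""
    psi_m = np.asarray(psi_m)
    psi_prev = np.asarray(psi_prev)
    _check_same_shape(psi_m, psi_prev)
    return float(np.linalg.norm(psi_m - psi_prev))


def score_reconstruction(est, ref):
    """Phase-align ``est`` to ``ref`` and return ``(ssim, psnr)`` of the
    amplitude images, with the SSIM data range and the PSNR peak taken from
    the reference amplitude."""
    aligned = align_global_phase(est, ref)
    ref_amp = np.abs(ref)
    est_amp = np.abs(aligned)
    dr = float(ref_amp.max() - ref_amp.min()) or 1.0
    return (
        ssim(est_amp, ref_amp, data_range=dr),
        psnr(est_amp, ref_amp, peak=float(ref_amp.max())),
    )


def run_accuracy_experiment(
    dataset,
    cfg,
    P_list=(1,),
    backend="serial",
    curve_tol=1e-4,
    check_agreement=True,
):
    """Reconstruct one dataset with several worker counts and compare curves.

    For each ``P`` in ``P_list`` the dataset is reconstructed (monolithically
    for ``P = 1``, partitioned otherwise) while recording per-iteration SSIM
    and PSNR against the stored ground truth.  Worker count must not change
    the mathematics, so when ``check_agreement`` is set the per-iteration SSIM
    curves are required to agree across ``P`` within ``curve_tol``.

    Returns ``{"records": {P: ConvergenceRecord}, "final": {P: (ssim, psnr)}}``.
    """
    from .solver import reconstruct
    from .partition import partitioned_reconstruct

    if dataset.ground_truth is None:
        raise PtychoError("accuracy experiment requires a stored ground truth")
    records, finals = {}, {}
    for P in P_list:
        if P == 1:
            est, rec = reconstruct(
                dataset.data,
                dataset.probe,
                dataset.positions,
                dataset.shape,
                cfg,
                reference=dataset.ground_truth,
            )
        else:
            est, rec = partitioned_reconstruct(
                dataset.data,
                dataset.probe,
                dataset.positions,
                dataset.shape,
                P,
                cfg,
                backend=backend,
                reference=dataset.ground_truth,
            )
        records[P] = rec
        finals[P] = score_reconstruction(est, dataset.ground_truth)
    if check_agreement and len(P_list) > 1:
        base = np.asarray(records[P_list[0]].ssim)
        for P in P_list[1:]:
            dev = float(np.max(np.abs(np.asarray(records[P].ssim) - base)))
            if dev > curve_tol:
                raise PtychoError(
                    f"SSIM convergence curves diverge between P={P_list[0]} "
                    f"and P={P} (max deviation {dev:.3e} > {curve_tol:.1e})"
                )
    return {"records": records, "final": finals}


def curves_to_csv(records, path):
    """Write per-iteration metric curves (one row per iteration and worker
    count) to a CSV file suitable for plotting."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["P", "iteration", "cost", "diff_norm", "ls_shrinks", "ssim", "psnr"])
        for P, rec in records.items():
            for i in range(len(rec.cost)):
                w.writerow(
                    [
                        P,
                        i,
                        rec.cost[i],
                        rec.diff_norm[i],
                        rec.ls_shrinks[i],
                        rec.ssim[i] if rec.ssim is not None else "",
                        rec.psnr[i] if rec.psnr is not None else "",
                    ]
                )
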