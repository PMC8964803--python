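"""Partitioned (multi-worker) execution of the CG-ML solver.

The object grid is split into ``P`` contiguous strips along its longer axis,
one per logical worker.  Each worker owns the diffraction patterns whose
footprint centers fall in its strip and additionally stores *halo* duplicates
of neighboring patterns, so that every pattern touching its owned strip is
locally available; its local object slice is the owned strip dilated by one
probe side ``S`` on internal borders.  Per iteration:

* GRAD: each worker computes the ML gradient over its halo-extended slice
  from its local patterns.  The restriction to the owned strip is exactly the
  corresponding block of the monolithic gradient.
* DIR (gather-scatter): the master (worker 0) assembles the full gradient
  from the owned blocks, evaluates the Dai-Yuan direction exactly as the
  monolithic solver, and scatters halo-extended slices back.  The
  matrices-to-scalar reduction in the Dai-Yuan coefficient is what makes a
  purely local direction computation impossible.
* LS (all-reduce): each trial step, every worker reduces the partial cost
  over its *owned* patterns only (each pattern counted exactly once); the
  partials are summed in ascending worker order and compared against the
  global acceptance condition, so all workers agree on the same step.
* Update + border exchange: workers update their slices and then overwrite
  their halo strips with the owning neighbor's pixels.

Workers are logical: the ``backend`` argument selects how per-worker stage
functions are executed (in-process loop, process pool, or a device-parallel
extension point), and does not change the numbers beyond floating-point
summation order, which is fixed by sorting all reductions by worker id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ConfigurationError, NumericError, ProtocolError
from .metrics import score_reconstruction
from .operators import validate_geometry
from .solver import (
    CostAlongRay,
    ConvergenceRecord,
    SolverConfig,
    _backtrack,
    _check_data,
    dai_yuan_direction,
    init_object,
)

__all__ = [
    "Partition",
    "WorkerState",
    "partition_object",
    "local_grad_stage",
    "dir_stage_gather_scatter",
    "ls_stage_allreduce",
    "update_and_exchange",
    "stitch",
    "partitioned_reconstruct",
    "get_backend",
    "SerialBackend",
    "ProcessBackend",
]


# --------------------------------------------------------------------------
# partitioning


@dataclass(frozen=True)
class Partition:
    """One worker's share of the problem.

    ``owned_span``/``halo_span`` are half-open intervals on the split axis;
    on the other axis every worker spans the full grid.  ``owned_patterns``
    are globally unique; ``halo_patterns`` duplicate neighbors' patterns
    whose footprints intersect the halo-extended slice.
    """

    worker_id: int
    n_workers: int
    axis: int
    owned_span: tuple
    halo_span: tuple
    owned_patterns: np.ndarray
    halo_patterns: np.ndarray
    neighbors: tuple


def partition_object(shape, P, S, positions):
    """Split the object into ``P`` strips and assign pattern ownership.

    Strips are contiguous, near-equal, along the longer object axis, and each
    must be at least ``S`` tall (otherwise the split is infeasible).  Each
    strip is dilated by a halo of width ``S`` on internal borders, which
    guarantees that every footprint touching an owned strip lies fully inside
    the halo-extended slice.  A pattern is owned by the strip containing its
    footprint center (boundary ties go to the lower worker id) and is a halo
    duplicate wherever its footprint intersects a halo-extended slice it does
    not own.
    """
    if P < 1:
        raise ConfigurationError("worker count P must be >= 1")
    H, W = int(shape[0]), int(shape[1])
    S = int(S)
    pos = validate_geometry(shape, np.ones((S, S)), positions)
    axis = 0 if H >= W else 1
    L = shape[axis]
    bounds = [round(i * L / P) for i in range(P + 1)]
    widths = np.diff(bounds)
    if np.any(widths < S):
        raise ConfigurationError(
            f"cannot split length {L} into {P} strips of at least S={S}: "
            f"smallest strip would be {int(widths.min())}"
        )
    centers = pos[:, axis] + S / 2.0
    ends = np.asarray(bounds[1:], dtype=float)
    owner = np.searchsorted(ends, centers, side="left")  # tie -> lower id
    starts_fp = pos[:, axis]
    parts = []
    for w in range(P):
        o0, o1 = bounds[w], bounds[w + 1]
        h0, h1 = max(0, o0 - S), min(L, o1 + S)
        touches = (starts_fp + S > h0) & (starts_fp < h1)
        owned = np.where(owner == w)[0]
        halo = np.where(touches & (owner != w))[0]
        neighbors = tuple(v for v in (w - 1, w + 1) if 0 <= v < P)
        parts.append(
            Partition(
                worker_id=w,
                n_workers=P,
                axis=axis,
                owned_span=(int(o0), int(o1)),
                halo_span=(int(h0), int(h1)),
                owned_patterns=owned,
                halo_patterns=halo,
                neighbors=neighbors,
            )
        )
    return parts


@dataclass
class WorkerState:
    """Mutable per-worker state carried across the four stages.

    ``psi`` covers the halo-extended slice.  Local scan positions are global
    positions shifted by the halo offset on the split axis; halo patterns not
    touching the owned strip may stick out of the local slice and are handled
    by clipped patch extraction (their contributions never reach owned
    pixels).
    """

    part: Partition
    psi: np.ndarray
    data: np.ndarray           # frames of local (owned + halo) patterns
    positions: np.ndarray      # local coordinates, ascending global index
    local_idx: np.ndarray      # global indices of the local patterns
    owned_mask: np.ndarray     # which local patterns the worker owns
    halo_fresh: bool = True
    m: int = 0
    grad: np.ndarray | None = None
    eta: np.ndarray | None = None
    ff_psi_owned: np.ndarray | None = None
    ray: CostAlongRay | None = None


def _local_slice(part: Partition, full: np.ndarray) -> np.ndarray:
    h0, h1 = part.halo_span
    return full[h0:h1, :] if part.axis == 0 else full[:, h0:h1]


def _owned_block(part: Partition, local: np.ndarray) -> np.ndarray:
    o0, o1 = part.owned_span
    h0, _ = part.halo_span
    sl = slice(o0 - h0, o1 - h0)
    return local[sl, :] if part.axis == 0 else local[:, sl]


def make_worker(part: Partition, psi0, data, positions) -> WorkerState:
    """Build a worker's local state from the global inputs."""
    local_idx = np.sort(
        np.concatenate([part.owned_patterns, part.halo_patterns])
    ).astype(np.int64)
    pos_local = np.array(positions)[local_idx].astype(np.int64)
    pos_local[:, part.axis] -= part.halo_span[0]
    owned = np.isin(local_idx, part.owned_patterns)
    return WorkerState(
        part=part,
        psi=_local_slice(part, np.asarray(psi0)).copy(),
        data=np.asarray(data)[local_idx].copy(),
        positions=pos_local,
        local_idx=local_idx,
        owned_mask=owned,
    )


# --------------------------------------------------------------------------
# clipped patch operators (halo patterns may overhang the local slice)


def _extract_clipped(grid, probe, positions):
    Hg, Wg = grid.shape
    S = probe.shape[0]
    out = np.zeros((len(positions), S, S), dtype=np.result_type(grid, probe))
    for j, (r, c) in enumerate(positions):
        r0, r1 = max(r, 0), min(r + S, Hg)
        c0, c1 = max(c, 0), min(c + S, Wg)
        if r0 < r1 and c0 < c1:
            out[j, r0 - r : r1 - r, c0 - c : c1 - c] = (
                probe[r0 - r : r1 - r, c0 - c : c1 - c] * grid[r0:r1, c0:c1]
            )
    return out


def _scatter_clipped(patches, probe, positions, shape):
    Hg, Wg = shape
    S = probe.shape[0]
    out = np.zeros(shape, dtype=np.result_type(patches, probe))
    pconj = np.conj(probe)
    for j, (r, c) in enumerate(positions):
        r0, r1 = max(r, 0), min(r + S, Hg)
        c0, c1 = max(c, 0), min(c + S, Wg)
        if r0 < r1 and c0 < c1:
            out[r0:r1, c0:c1] += (
                pconj[r0 - r : r1 - r, c0 - c : c1 - c]
                * patches[j, r0 - r : r1 - r, c0 - c : c1 - c]
            )
    return out


# --------------------------------------------------------------------------
# stages


def local_grad_stage(worker: WorkerState, probe, eps_guard) -> WorkerState:
    """GRAD: local ML gradient over the halo-extended slice.

    Uses all local (owned + halo) patterns; caches the owned patterns'
    far-field waves for the line-search stage.  Requires fresh halos.
    """
    if not worker.halo_fresh:
        raise ProtocolError(
            f"worker {worker.part.worker_id}: gradient requested with stale "
            "halo (border exchange skipped)"
        )
    grid = worker.psi
    ff = np.fft.fft2(
        _extract_clipped(grid, probe, worker.positions), norm="ortho"
    )
    mod2 = ff.real**2 + ff.imag**2
    resid = ff - worker.data * ff / np.maximum(mod2, eps_guard**2)
    worker.grad = _scatter_clipped(
        np.fft.ifft2(resid, norm="ortho"), probe, worker.positions, grid.shape
    )
    worker.ff_psi_owned = ff[worker.owned_mask]
    return worker


@dataclass
class MasterState:
    """Gradient/direction history retained by the master across iterations."""

    shape: tuple
    grad_prev: np.ndarray | None = None
    eta_prev: np.ndarray | None = None
    m: int = 0


def dir_stage_gather_scatter(workers, master: MasterState):
    """DIR: gather owned gradient blocks, run Dai-Yuan on the master, scatter.

    Each pixel of the assembled gradient is taken from its unique owner, so
    the assembly is exact (halo-duplicated patterns would double count under
    summation).  Returns the full direction for bookkeeping; each worker
    receives its halo-extended slice.
    """
    full_grad = np.empty(master.shape, dtype=complex)
    for w in workers:
        if w.grad is None:
            raise ProtocolError(
                f"worker {w.part.worker_id}: gradient block missing at DIR stage"
            )
        o0, o1 = w.part.owned_span
        blk = _owned_block(w.part, w.grad)
        if w.part.axis == 0:
            full_grad[o0:o1, :] = blk
        else:
            full_grad[:, o0:o1] = blk
    if master.m == 0:
        eta = -full_grad
    else:
        eta = dai_yuan_direction(full_grad, master.grad_prev, master.eta_prev)
    master.grad_prev = full_grad
    master.eta_prev = eta
    for w in workers:
        w.eta = _local_slice(w.part, eta).copy()
    return eta


def _prepare_ray(worker: WorkerState, probe, eps_guard) -> WorkerState:
    """Build the worker's partial line-search evaluator over owned patterns."""
    ff_eta = np.fft.fft2(
        _extract_clipped(worker.eta, probe, worker.positions), norm="ortho"
    )[worker.owned_mask]
    worker.ray = CostAlongRay(
        worker.ff_psi_owned, ff_eta, worker.data[worker.owned_mask], eps_guard
    )
    return worker


def allreduce_cost(workers, gamma: float) -> float:
    """Sum per-worker partial costs in ascending worker order and validate
    finiteness (the all-reduce of the LS stage)."""
    total = 0.0
    for w in sorted(workers, key=lambda w: w.part.worker_id):
        partial = w.ray(gamma)
        if not np.isfinite(partial):
            raise NumericError(
                f"worker {w.part.worker_id} produced a non-finite partial "
                f"cost at step {gamma:.3e}"
            )
        total += partial
    return total


def ls_stage_allreduce(workers, probe, cfg: SolverConfig):
    """LS: global backtracking line search on all-reduced partial costs.

    Every worker's partial covers its owned patterns only, so each pattern is
    counted exactly once; the shrink loop runs on the global scalar and the
    returned step is identical for all workers.

    Returns ``(gamma, shrinks, f_accepted, f0, capped)``.
    """
    for w in workers:
        if w.eta is None:
            raise ProtocolError(
                f"worker {w.part.worker_id}: direction slice missing at LS stage"
            )
        _prepare_ray(w, probe, cfg.eps_guard)
    return _backtrack(lambda g: allreduce_cost(workers, g), cfg)


def update_and_exchange(workers, gamma: float):
    """Update every worker's slice by ``psi + gamma*eta`` and refresh halos.

    After the exchange each worker's halo pixels are bitwise equal to the
    owning neighbor's values for the same coordinates.
    """
    by_id = {w.part.worker_id: w for w in workers}
    for w in workers:
        w.psi = w.psi + gamma * w.eta
        w.halo_fresh = False
        w.m += 1
    for w in workers:
        h0, h1 = w.part.halo_span
        o0, o1 = w.part.owned_span
        for nb_id in w.part.neighbors:
            nb = by_id.get(nb_id)
            if nb is None or w.part.worker_id not in nb.part.neighbors:
                raise ProtocolError(
                    f"worker {w.part.worker_id}: inconsistent neighbor link "
                    f"to {nb_id}"
                )
            # coordinate range of w's halo strip on nb's side
            if nb_id < w.part.worker_id:
                lo, hi = h0, o0
            else:
                lo, hi = o1, h1
            if lo >= hi:
                continue
            nb_h0 = nb.part.halo_span[0]
            src = (
                nb.psi[lo - nb_h0 : hi - nb_h0, :]
                if w.part.axis == 0
                else nb.psi[:, lo - nb_h0 : hi - nb_h0]
            )
            if w.part.axis == 0:
                w.psi[lo - h0 : hi - h0, :] = src
            else:
                w.psi[:, lo - h0 : hi - h0] = src
        w.halo_fresh = True
    return workers


def stitch(workers, shape) -> np.ndarray:
    """Concatenate owned blocks (halos discarded) into the full object."""
    out = np.empty(tuple(shape), dtype=complex)
    covered = np.zeros(tuple(shape), dtype=bool)
    for w in workers:
        o0, o1 = w.part.owned_span
        blk = _owned_block(w.part, w.psi)
        if w.part.axis == 0:
            out[o0:o1, :] = blk
            covered[o0:o1, :] = True
        else:
            out[:, o0:o1] = blk
            covered[:, o0:o1] = True
    if not covered.all():
        raise ProtocolError("stitch: owned regions do not cover the object grid")
    return out


# --------------------------------------------------------------------------
# backends


class SerialBackend:
    """Run per-worker stage functions in a plain in-process loop."""

    def map(self, fn, items):
        return [fn(it) for it in items]

    def close(self):
        pass


class ProcessBackend:
    """Run per-worker stage functions on a process pool.

    Demonstrates that the stage protocol is transport-agnostic: worker state
    is shipped to the pool and back for each stage, so this backend trades
    serialization overhead for parallelism and is only worthwhile for large
    per-worker workloads.
    """

    def __init__(self, max_workers=None):
        from concurrent.futures import ProcessPoolExecutor

        self._pool = ProcessPoolExecutor(max_workers=max_workers)

    def map(self, fn, items):
        return list(self._pool.map(fn, items))

    def close(self):
        self._pool.shutdown()


def get_backend(name: str):
    """Resolve a backend by name: ``serial`` | ``process`` | ``device``."""
    if name == "serial":
        return SerialBackend()
    if name == "process":
        return ProcessBackend()
    if name == "device":
        try:
            import cupy  # noqa: F401
        except ImportError:
            raise ConfigurationError(
                "the 'device' backend requires cupy, which is not installed; "
                "use 'serial' or 'process'"
            ) from None
        raise ConfigurationError(
            "the 'device' backend is an extension point and is not implemented "
            "in this release; use 'serial' or 'process'"
        )
    raise ConfigurationError(
        f"unknown backend {name!r} (expected 'serial', 'process' or 'device')"
    )


# module-level so they are picklable by the process backend
def _grad_stage_fn(args):
    worker, probe, eps_guard = args
    return local_grad_stage(worker, probe, eps_guard)


# --------------------------------------------------------------------------
# orchestration


def partitioned_reconstruct(
    data,
    probe,
    positions,
    shape,
    P,
    cfg: SolverConfig,
    backend="serial",
    reference=None,
):
    """Four-stage partitioned CG-ML reconstruction over ``P`` logical workers.

    Contractually equivalent to :func:`ptychocg.solver.reconstruct`: the
    iterate sequence matches the monolithic one up to floating-point
    reassociation in the cost reduction (and bitwise for ``P = 1``).  The
    returned :class:`ConvergenceRecord` has identical semantics.
    """
    probe = np.asarray(probe)
    positions = validate_geometry(shape, probe, positions)
    data = _check_data(data).astype(
        np.float64 if cfg.dtype == "double" else np.float32
    )
    S = probe.shape[0]
    parts = partition_object(shape, P, S, positions)
    owned_total = sum(len(p.owned_patterns) for p in parts)
    if owned_total != len(positions):
        raise ProtocolError(
            f"pattern ownership is not a partition: {owned_total} owned "
            f"of {len(positions)}"
        )
    psi0 = init_object(shape, cfg)
    workers = [make_worker(p, psi0, data, positions) for p in parts]
    master = MasterState(shape=tuple(shape))
    be = backend if hasattr(backend, "map") else get_backend(backend)
    record = ConvergenceRecord()
    if reference is not None:
        record.ssim, record.psnr = [], []
    try:
        for m in range(cfg.n_iters):
            try:
                workers = be.map(
                    _grad_stage_fn, [(w, probe, cfg.eps_guard) for w in workers]
                )
                dir_stage_gather_scatter(workers, master)
                gamma, shrinks, f_new, f0, capped = ls_stage_allreduce(
                    workers, probe, cfg
                )
                update_and_exchange(workers, gamma)
                master.m += 1
            except Exception as exc:
                exc.add_note(f"while running partitioned iteration {m}")
                raise
            if m == 0:
                record.initial_cost = f0
            record.cost.append(f_new)
            eta_sq = 0.0
            for w in sorted(workers, key=lambda w: w.part.worker_id):
                blk = _owned_block(w.part, w.eta)
                eta_sq += float(np.vdot(blk, blk).real)
            record.diff_norm.append(gamma * np.sqrt(eta_sq))
            record.ls_shrinks.append(shrinks)
            record.ls_capped.append(capped)
            if reference is not None:
                s, p = score_reconstruction(stitch(workers, shape), reference)
                record.ssim.append(s)
                record.psnr.append(p)
            if cfg.stop_tol is not None:
                psi_norm = np.sqrt(
                    sum(
                        float(np.vdot(b, b).real)
                        for b in (
                            _owned_block(w.part, w.psi)
                            for w in sorted(
                                workers, key=lambda w: w.part.worker_id
                            )
                        )
                    )
                )
                if record.diff_norm[-1] <= cfg.stop_tol * psi_norm:
                    break
    finally:
        if not hasattr(backend, "map"):
            be.close()
    return stitch(workers, shape), record
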