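"""Discrete stochastic terminal-relocation dynamics with density compensation.

Each of ``n_rgc`` RGC axons owns ``terminals_per_axon`` terminals living on
a line of ``n_sc`` SC cells.  At every step one terminal is chosen
uniformly at random among all terminals; if the total branching inhibition
(molecular + compensation) for its axon is strictly lower in a neighbouring
SC cell, the terminal moves to the neighbour with the lowest total
inhibition (ties between two equally low neighbours broken uniformly at
random).  After every move attempt the compensation level c_j of every SC
cell is updated from the terminal density rho_j (column sums of the counts
matrix)::

    c_j  <-  c_j + epsilon * (rho_j - mu * c_j)

``epsilon`` defaults to the reciprocal of the total number of terminals so
that the mapping progresses at the same apparent rate in systems of
different sizes.  ``mu = 0`` is the strong-compensation regime (the
compensation can only accumulate); ``mu > 0`` lets it decay, with fixed
point rho_j / mu, giving weak compensation.

Two runners produce bit-identical trajectories: a naive reference that
applies the global compensation update after every step, and a fast path
that updates compensation lazily per cell.  The lazy form is exact because
rho_j is constant between the moves that touch cell j, so the elapsed
updates can be applied in closed form:

* mu = 0:  c_j += epsilon * rho_j * (elapsed steps)
* mu > 0:  c_j -> rho_j/mu + (1 - epsilon*mu)^elapsed * (c_j - rho_j/mu)

Both runners draw two uniforms per step (terminal choice, tie-break) so
their random streams coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .gradients import ExponentialGradient, GradientSet
from .genotypes import (Genotype, WILD_TYPE, apply_math5,
                        build_genotype_retinal_epha, knockin_labels,
                        rgc_positions, sc_positions)
from .inhibition import inhibition_matrix

__all__ = ["SimConfig", "SimState", "SimResult", "init_state",
           "attempt_move", "update_compensation", "run"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    ``epsilon=None`` resolves to 1/(n_rgc * terminals_per_axon), after the
    Math5 survival fraction (if any) has reduced n_rgc.
    """

    n_rgc: int = 240
    n_sc: int = 240
    terminals_per_axon: int = 16
    epsilon: Optional[float] = None
    mu: float = 0.0
    n_steps: int = 1_000_000
    snapshot_steps: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_rgc, self.n_sc, self.terminals_per_axon) < 1:
            raise ValueError("n_rgc, n_sc and terminals_per_axon must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.resolved_epsilon * self.mu >= 1.0:
            raise ValueError("epsilon * mu must be < 1 for a stable update")

    @property
    def n_terminals(self) -> int:
        return self.n_rgc * self.terminals_per_axon

    @property
    def resolved_epsilon(self) -> float:
        if self.epsilon is None:
            return 1.0 / self.n_terminals
        return self.epsilon


@dataclass
class SimState:
    """Lattice state: terminal counts, compensation and density.

    ``counts[i, j]`` is the number of terminals of RGC ``i`` on SC cell
    ``j``; every row always sums to ``terminals_per_axon``.  ``density`` is
    the per-SC-cell column sum of ``counts``.
    """

    counts: np.ndarray
    compensation: np.ndarray
    density: np.ndarray
    step: int = 0

    def copy(self) -> "SimState":
        return SimState(self.counts.copy(), self.compensation.copy(),
                        self.density.copy(), self.step)

    def validate(self, terminals_per_axon: Optional[int] = None) -> None:
        if np.any(self.counts < 0) or np.any(self.compensation < 0):
            raise ValueError("counts and compensation must be non-negative")
        if not np.array_equal(self.density, self.counts.sum(axis=0)):
            raise ValueError("density inconsistent with counts")
        if terminals_per_axon is not None and not np.all(
                self.counts.sum(axis=1) == terminals_per_axon):
            raise ValueError("row sums must equal terminals_per_axon")


def init_state(config: SimConfig,
               rng: Optional[np.random.Generator] = None) -> SimState:
    """Allocate every terminal to a uniform-random SC cell; compensation 0."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells = rng.integers(0, config.n_sc, size=(config.n_rgc,
                                               config.terminals_per_axon))
    counts = np.zeros((config.n_rgc, config.n_sc), dtype=np.int64)
    for i in range(config.n_rgc):
        np.add.at(counts[i], cells[i], 1)
    return SimState(counts=counts,
                    compensation=np.zeros(config.n_sc),
                    density=counts.sum(axis=0))


def _choose_neighbour(here: float, left: Optional[float],
                      right: Optional[float], u_tie: float) -> int:
    """Return -1 (move left), +1 (move right) or 0 (stay).

    Only strictly lower neighbours are eligible; an exact tie between two
    strictly lower neighbours is broken by ``u_tie`` < 0.5 -> left.
    """
    left_ok = left is not None and left < here
    right_ok = right is not None and right < here
    if left_ok and right_ok:
        if left < right:
            return -1
        if right < left:
            return 1
        return -1 if u_tie < 0.5 else 1
    if left_ok:
        return -1
    if right_ok:
        return 1
    return 0


def attempt_move(state: SimState, total_inhibition_for_axon: np.ndarray,
                 terminal: tuple[int, int],
                 rng: Optional[np.random.Generator] = None,
                 u_tie: Optional[float] = None) -> bool:
    """Attempt to move one terminal of RGC ``i`` sitting on SC cell ``j``.

    Mutates ``state`` in place; returns whether the terminal moved.
    ``total_inhibition_for_axon`` is the per-SC-cell total inhibition for
    that axon.  A tie between two strictly-lower neighbours is broken with
    ``u_tie`` (drawn from ``rng`` if not given).
    """
    i, j = terminal
    if state.counts[i, j] < 1:
        raise ValueError(f"no terminal of RGC {i} on SC cell {j}")
    tot = total_inhibition_for_axon
    n_sc = state.counts.shape[1]
    left = float(tot[j - 1]) if j > 0 else None
    right = float(tot[j + 1]) if j < n_sc - 1 else None
    if u_tie is None:
        u_tie = float(rng.random()) if rng is not None else 0.0
    d = _choose_neighbour(float(tot[j]), left, right, u_tie)
    if d == 0:
        return False
    state.counts[i, j] -= 1
    state.counts[i, j + d] += 1
    state.density[j] -= 1
    state.density[j + d] += 1
    return True


def update_compensation(state: SimState, epsilon: float, mu: float) -> None:
    """One global compensation update c += epsilon * (rho - mu * c)."""
    if epsilon < 0 or mu < 0:
        raise ValueError("epsilon and mu must be >= 0")
    state.compensation += epsilon * (state.density - mu * state.compensation)


@dataclass
class SimResult:
    """Everything a run produced, sufficient to reproduce and analyse it."""

    config: SimConfig
    genotype: Genotype
    final: SimState
    snapshots: dict              # step -> SimState
    molecular: np.ndarray        # (n_rgc, n_sc) inhibition matrix
    retinal_pos: np.ndarray      # per simulated RGC
    sc_pos: np.ndarray
    labels: np.ndarray           # per simulated RGC population label
    rgc_index: np.ndarray        # index into the wild-type complement
    moves_accepted: int = 0
    accept_trace: list = field(default_factory=list)  # (step, accepted rate, comp min, comp max)

    @property
    def accepted_rate(self) -> float:
        return self.moves_accepted / max(self.config.n_steps, 1)


def _resolve_populations(config: SimConfig, gradients: GradientSet,
                         genotype: Genotype):
    """Per-simulated-RGC positions, EphA/ephrin-A levels and labels."""
    x_all = rgc_positions(config.n_rgc)
    if isinstance(gradients.retinal_epha, ExponentialGradient):
        epha_all = gradients.retinal_epha(x_all)
        labels_all = knockin_labels(config.n_rgc, genotype)
        if genotype.epha3_knockin != "none":
            raise ValueError(
                "knock-in genotypes need a per-RGC retinal EphA vector; "
                "build one with build_genotype_retinal_epha"
            )
    else:
        epha_all = np.asarray(gradients.retinal_epha, dtype=float)
        if epha_all.shape != (config.n_rgc,):
            raise ValueError("per-RGC EphA vector must have length n_rgc")
        labels_all = knockin_labels(config.n_rgc, genotype)
    keep = np.arange(config.n_rgc)
    if genotype.rgc_survival_fraction < 1.0:
        keep = apply_math5(genotype, config.n_rgc, seed=config.seed)
    return (keep, x_all[keep], epha_all[keep],
            gradients.retinal_ephrina(x_all[keep]), labels_all[keep])


def run(config: SimConfig, gradients: GradientSet,
        genotype: Genotype = WILD_TYPE, *, method: str = "lazy") -> SimResult:
    """Run the full relocation dynamics; reproducible under ``config.seed``.

    Identical (config, gradients, genotype, method) give bit-identical
    trajectories.  ``method="lazy"`` (default) and ``method="naive"`` apply
    algebraically identical updates and consume the same random stream, so
    they produce the same move sequences up to floating-point round-off in
    the compensation; the naive runner is the reference implementation.
    """
    keep, x, epha, ephrina, labels = _resolve_populations(config, gradients,
                                                          genotype)
    eff = replace(config, n_rgc=len(keep))
    y = sc_positions(config.n_sc)
    M = inhibition_matrix(epha, ephrina, gradients, y)
    rng = np.random.default_rng(config.seed)
    state = init_state(eff, rng)
    runner = _run_lazy if method == "lazy" else _run_naive
    if method not in ("lazy", "naive"):
        raise ValueError(f"unknown method {method!r}")
    snapshots, accepted, trace = runner(state, M, eff, rng)
    return SimResult(config=eff, genotype=genotype, final=state,
                     snapshots=snapshots, molecular=M, retinal_pos=x,
                     sc_pos=y, labels=labels, rgc_index=keep,
                     moves_accepted=accepted, accept_trace=trace)


_CHUNK = 65_536
_TRACE_EVERY = 50_000


def _run_naive(state: SimState, M: np.ndarray, config: SimConfig, rng):
    eps, mu = config.resolved_epsilon, config.mu
    tpa, n_sc = config.terminals_per_axon, config.n_sc
    term_sc = _terminal_cells(state, config)
    total = config.n_terminals
    snapshots = {}
    accepted = 0
    trace = []
    want = set(config.snapshot_steps)
    if 0 in want:
        snapshots[0] = state.copy()
    for t in range(config.n_steps):
        u_pick, u_tie = rng.random(2)
        k = min(int(u_pick * total), total - 1)
        i, j = k // tpa, term_sc[k]
        tot = M[i] + state.compensation
        left = float(tot[j - 1]) if j > 0 else None
        right = float(tot[j + 1]) if j < n_sc - 1 else None
        d = _choose_neighbour(float(tot[j]), left, right, u_tie)
        if d != 0:
            state.counts[i, j] -= 1
            state.counts[i, j + d] += 1
            state.density[j] -= 1
            state.density[j + d] += 1
            term_sc[k] = j + d
            accepted += 1
        update_compensation(state, eps, mu)
        state.step = t + 1
        if state.step in want:
            snapshots[state.step] = state.copy()
        if state.step % _TRACE_EVERY == 0:
            trace.append((state.step, accepted / state.step,
                          float(state.compensation.min()),
                          float(state.compensation.max())))
    return snapshots, accepted, trace


def _terminal_cells(state: SimState, config: SimConfig) -> np.ndarray:
    """Flat per-terminal SC-cell array consistent with the counts matrix."""
    cells = np.empty(config.n_terminals, dtype=np.int64)
    tpa = config.terminals_per_axon
    for i in range(state.counts.shape[0]):
        cells[i * tpa:(i + 1) * tpa] = np.repeat(
            np.nonzero(state.counts[i])[0],
            state.counts[i][state.counts[i] > 0])
    return cells


def _run_lazy(state: SimState, M: np.ndarray, config: SimConfig, rng):
    # hot loop: plain-Python scalars/lists beat numpy indexing here
    eps, mu = config.resolved_epsilon, config.mu
    tpa, n_sc = config.terminals_per_axon, config.n_sc
    lam = 1.0 - eps * mu
    term_sc = _terminal_cells(state, config).tolist()
    total = config.n_terminals
    counts = state.counts
    c = state.compensation.tolist()
    rho = state.density.tolist()
    last = [0] * n_sc                # update count at last refresh
    Ml = M.tolist()
    n_steps = config.n_steps
    snapshots = {}
    accepted = 0
    trace = []
    want = sorted(set(config.snapshot_steps))
    if want and want[0] == 0:
        snapshots[0] = state.copy()
        want = want[1:]
    snap_set = set(want)
    zero_eps = eps == 0.0

    def refresh(j: int, upto: int) -> None:
        dt = upto - last[j]
        if dt:
            if zero_eps:
                pass
            elif mu == 0.0:
                c[j] += eps * rho[j] * dt
            else:
                fp = rho[j] / mu
                c[j] = fp + lam ** dt * (c[j] - fp)
            last[j] = upto

    def sync(upto: int) -> None:
        for jj in range(n_sc):
            refresh(jj, upto)
        state.compensation = np.asarray(c, dtype=float)
        state.density = np.asarray(rho, dtype=np.int64)
        state.step = upto

    buf = []
    pos = 0
    last_j = n_sc - 1
    for t in range(n_steps):
        if pos >= len(buf):
            buf = rng.random(2 * min(_CHUNK, n_steps - t)).tolist()
            pos = 0
        u_pick = buf[pos]
        u_tie = buf[pos + 1]
        pos += 2
        k = int(u_pick * total)
        if k >= total:
            k = total - 1
        i = k // tpa
        j = term_sc[k]
        Mi = Ml[i]
        # decision uses compensation after t global updates
        refresh(j, t)
        here = Mi[j] + c[j]
        d = 0
        if j > 0:
            refresh(j - 1, t)
            left = Mi[j - 1] + c[j - 1]
        else:
            left = None
        if j < last_j:
            refresh(j + 1, t)
            right = Mi[j + 1] + c[j + 1]
        else:
            right = None
        if left is not None and left < here:
            if right is not None and right < here:
                if left < right:
                    d = -1
                elif right < left:
                    d = 1
                else:
                    d = -1 if u_tie < 0.5 else 1
            else:
                d = -1
        elif right is not None and right < here:
            d = 1
        if d:
            # both cells were refreshed to time t, so the density change
            # applies to all subsequent updates, as in the naive schedule
            counts[i, j] -= 1
            counts[i, j + d] += 1
            rho[j] -= 1
            rho[j + d] += 1
            term_sc[k] = j + d
            accepted += 1
        step_done = t + 1
        if step_done in snap_set:
            sync(step_done)
            snapshots[step_done] = state.copy()
        if step_done % _TRACE_EVERY == 0:
            for jj in range(n_sc):
                refresh(jj, step_done)
            trace.append((step_done, accepted / step_done,
                          min(c), max(c)))
    sync(n_steps)
    return snapshots, accepted, trace
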