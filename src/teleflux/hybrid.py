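"""Hybrid stochastic/deterministic single-cell and population simulation.

The gene-expression layer (promoters + mRNA counts) of every attached gene is
advanced by the exact Gillespie algorithm; between its events the full species
vector follows the deterministic mass-action ODE system (reaction fluxes +
first-order degradation + per-gene synthesis ``k_p * m``), integrated with a
stiff solver.  Because gene-layer propensities never depend on protein levels
the whole event schedule can be sampled up front ("presample" mode, the
default) or consumed event by event ("interleave" mode); both are exact and
produce identical trajectories for the same seed.

Two fast paths are used when they are exact:

* a *quiescent* phase (every reaction permanently inert because a reactant is
  a zero-level species that cannot be produced, e.g. a resting cell before
  ligand addition) is advanced analytically through the gene layer alone;
* a *synthesis-blocked* phase (cycloheximide idealization, all ``k_p = 0``)
  makes the ODE system independent of the gene layer, so it is integrated in
  one sweep without event segmentation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import odeint as _odeint

from teleflux.network import CellState, Intervention, ReactionNetwork
from teleflux.turnover import (
    GeneExpressionState,
    TurnoverParams,
    _run_ssa_events,
    _ssa_final_state,
    sample_stationary_state,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "CellTrajectory",
    "IntegrationError",
    "simulate_cell",
    "build_population",
    "divide_cell",
    "population_frame",
]


class IntegrationError(RuntimeError):
    """The stiff solver failed; the message carries the time (and cell id if any)."""


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-solver and output-grid settings.

    ``rtol``/``atol`` are the relative/absolute integration tolerances (atol in
    molecules); ``grid`` the output/recording step in hours.  Negative
    excursions larger than ``atol`` are clipped to zero with a logged warning,
    smaller ones are clipped silently.
    """

    rtol: float = 1e-6
    atol: float = 1e-3
    grid: float = 0.05
    max_steps: int = 100000


@dataclass
class CellTrajectory:
    """Recorded trajectory of one cell on the output grid (+ event times)."""

    times: np.ndarray
    levels: np.ndarray  # shape (n_times, n_recorded)
    recorded_species: list[str]
    final_state: CellState
    stats: dict

    def level(self, name: str) -> np.ndarray:
        return self.levels[:, self.recorded_species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=self.recorded_species)
        df.insert(0, "time", self.times)
        return df


# ---------------------------------------------------------------------------
# numba kernels: mass-action right-hand side and Jacobian
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rhs_kernel(y, rates, r_idx, r_st, net_idx, net_coef, deg, synth, out):
    ns = y.shape[0]
    for i in range(ns):
        out[i] = synth[i] - deg[i] * y[i]
    nr = rates.shape[0]
    for j in range(nr):
        flux = rates[j]
        for s in range(r_idx.shape[1]):
            idx = r_idx[j, s]
            if idx < 0:
                break
            for _ in range(r_st[j, s]):
                flux *= y[idx]
        if flux != 0.0:
            for s in range(net_idx.shape[1]):
                idx = net_idx[j, s]
                if idx < 0:
                    break
                out[idx] += net_coef[j, s] * flux


@njit(cache=True)
def _jac_kernel(y, rates, r_idx, r_st, net_idx, net_coef, deg, out):
    ns = y.shape[0]
    for i in range(ns):
        for k in range(ns):
            out[i, k] = 0.0
        out[i, i] = -deg[i]
    nr = rates.shape[0]
    for j in range(nr):
        for u in range(r_idx.shape[1]):
            iu = r_idx[j, u]
            if iu < 0:
                break
            d = rates[j] * r_st[j, u]
            for v in range(r_idx.shape[1]):
                iv = r_idx[j, v]
                if iv < 0:
                    break
                st = r_st[j, v]
                if v == u:
                    st -= 1
                for _ in range(st):
                    d *= y[iv]
            if d != 0.0:
                for s in range(net_idx.shape[1]):
                    idx = net_idx[j, s]
                    if idx < 0:
                        break
                    out[net_idx[j, s], iu] += net_coef[j, s] * d


class _OdeDriver:
    """Thin wrapper around LSODA with a mutable per-gene synthesis vector."""

    def __init__(self, network: ReactionNetwork, solver: SolverConfig):
        comp = network.compiled()
        self.comp = comp
        ns = network.n_species
        self.synth = np.zeros(ns)
        self._f_out = np.empty(ns)
        self._j_out = np.empty((ns, ns))

        def f(t, y):
            _rhs_kernel(
                y, comp.rates, comp.reactant_idx, comp.reactant_st,
                comp.net_idx, comp.net_coef, comp.deg, self.synth, self._f_out,
            )
            return self._f_out

        def jac(t, y):
            _jac_kernel(
                y, comp.rates, comp.reactant_idx, comp.reactant_st,
                comp.net_idx, comp.net_coef, comp.deg, self._j_out,
            )
            return self._j_out

        self.solver = solver
        self._f = f
        self._jac = jac
        self.n_segments = 0
        self.n_clips = 0
        self.worst_negative = 0.0

    def rhs(self, y: np.ndarray) -> np.ndarray:
        _rhs_kernel(
            y, self.comp.rates, self.comp.reactant_idx, self.comp.reactant_st,
            self.comp.net_idx, self.comp.net_coef, self.comp.deg, self.synth,
            self._f_out,
        )
        return self._f_out.copy()

    def step(self, y: np.ndarray, t0: float, t1: float) -> np.ndarray:
        """Integrate from t0 to t1 with a fresh solver start (RHS may have jumped)."""
        if t1 <= t0:
            return y
        out, info = _odeint(
            self._f, y, [t0, t1], Dfun=self._jac, rtol=self.solver.rtol,
            atol=self.solver.atol, mxstep=self.solver.max_steps,
            tfirst=True, full_output=True, printmessg=False,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"stiff solver failed at t = {t1:.4f} h: {info['message']}"
            )
        ynew = out[-1]
        self.n_segments += 1
        neg = ynew < 0.0
        if np.any(neg):
            worst = float(ynew.min())
            self.worst_negative = min(self.worst_negative, worst)
            if worst < -self.solver.atol:
                self.n_clips += 1
                logger.warning(
                    "clipped negative species level %.3g at t = %.4f h", worst, t1
                )
            ynew = np.where(neg, 0.0, ynew)
        return ynew


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------


def _phase_is_quiescent(
    network: ReactionNetwork, y: np.ndarray, blocked: bool, ztol: float
) -> bool:
    """True if every reaction is inert for the whole phase and unattached
    species are constant, so the gene layer alone is the exact dynamics."""
    attached = set(network.turnover)
    for i, s in enumerate(network.species):
        if s not in attached and y[i] > ztol and network.degradation.get(s, 0.0) > 0:
            return False
    for rxn in network.reactions:
        if rxn.rate == 0.0:
            continue
        inert = False
        for s, _ in rxn.reactants:
            if y[network.index[s]] <= ztol and (s not in attached or blocked):
                inert = True
                break
        if not inert:
            return False
        if not rxn.reactants:
            return False
    return True


# ---------------------------------------------------------------------------
# gene-layer helpers
# ---------------------------------------------------------------------------


def _blocked_params(tv: TurnoverParams) -> TurnoverParams:
    return dataclasses.replace(tv, k_p=0.0)


def _gene_events(
    tv: TurnoverParams, state: GeneExpressionState, duration: float, seed: int
):
    """Event-time arrays (t, g, m, p) for one gene over ``duration`` hours."""
    return _run_ssa_events(tv, state, duration, seed)


def _protein_on_grid(t_ev, m_ev, p_ev, kp, gp, t_query):
    """Exact protein level at query times given the event-time records."""
    idx = np.searchsorted(t_ev, t_query, side="right") - 1
    idx = np.clip(idx, 0, len(t_ev) - 1)
    dt = t_query - t_ev[idx]
    m = m_ev[idx].astype(float)
    p = p_ev[idx]
    if gp > 0:
        pinf = kp * m / gp
        return pinf + (p - pinf) * np.exp(-gp * dt)
    return p + kp * m * dt


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> np.uint32(1))


def simulate_cell(
    network: ReactionNetwork,
    cell: CellState,
    duration: float,
    interventions: list[Intervention] | tuple = (),
    solver: SolverConfig | None = None,
    seed: int = 0,
    record_species: list[str] | None = None,
    mode: str = "presample",
) -> CellTrajectory:
    """Simulate one cell for ``duration`` hours and record it on the output grid.

    The gene layer is exact (Gillespie); the species ODE system is integrated
    between gene events with LSODA at the configured tolerances.  Interventions
    are applied as discontinuities at their times.  Reproducible given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if mode not in ("presample", "interleave"):
        raise ValueError(f"unknown mode {mode!r}")
    solver = solver or SolverConfig()
    comp = network.compiled()
    state = cell.copy()
    t_start, t_end = state.time, state.time + duration
    for iv in interventions:
        if not (t_start <= iv.time <= t_end):
            raise ValueError(f"intervention at t={iv.time} outside [{t_start},{t_end}]")
    record_species = list(record_species) if record_species else list(network.species)
    rec_idx = np.array([network.index[s] for s in record_species], dtype=np.int64)

    # sync native species to their gene states
    for g in comp.gene_names:
        state.species_levels[network.index[g]] = state.gene_states[g].protein

    driver = _OdeDriver(network, solver)
    grid = np.arange(t_start, t_end + 0.5 * solver.grid, solver.grid)
    rec_t: list[float] = []
    rec_y: list[np.ndarray] = []

    def record(t: float, y: np.ndarray) -> None:
        if rec_t and abs(rec_t[-1] - t) < 1e-12:
            rec_y[-1] = y[rec_idx].copy()
        else:
            rec_t.append(t)
            rec_y.append(y[rec_idx].copy())

    # phase boundaries at intervention times
    iv_times = sorted({iv.time for iv in interventions})
    bounds = [t_start] + [t for t in iv_times if t_start < t < t_end] + [t_end]
    blocked = False
    ss = np.random.SeedSequence(seed)
    phase_seeds = ss.spawn(len(bounds) - 1 + 1)

    y = state.species_levels.astype(float).copy()
    record(t_start, y)

    for ph in range(len(bounds) - 1):
        a, b = bounds[ph], bounds[ph + 1]
        for iv in interventions:
            if iv.time == a or (ph == 0 and iv.time == t_start):
                if iv.action == "add_species":
                    y[network.index[iv.species]] += iv.amount
                elif iv.action == "rescale_dose":
                    y[network.index[iv.species]] *= iv.factor
                elif iv.action == "block_synthesis":
                    blocked = True
        # final-boundary interventions (at t_end) apply after the loop
        if b == t_end:
            pass
        gene_seeds = phase_seeds[ph].spawn(max(len(comp.gene_names), 1))
        phase_grid = grid[(grid > a + 1e-12) & (grid < b - 1e-12)]
        quiescent = _phase_is_quiescent(network, y, blocked, solver.atol)

        if quiescent and comp.gene_names:
            _run_quiescent_phase(
                network, comp, state, y, a, b, blocked, gene_seeds, phase_grid, record
            )
        elif blocked or not comp.gene_names:
            _run_unsegmented_phase(
                network, comp, state, driver, y, a, b, blocked, gene_seeds,
                phase_grid, record,
            )
        else:
            _run_active_phase(
                network, comp, state, driver, y, a, b, gene_seeds, phase_grid,
                record, mode,
            )
        record(b, y)

    state.time = t_end
    state.species_levels = y
    for g in comp.gene_names:
        state.gene_states[g].protein = float(y[network.index[g]])
    times = np.array(rec_t)
    levels = np.array(rec_y)
    stats = {
        "n_segments": driver.n_segments,
        "n_clips": driver.n_clips,
        "worst_negative": driver.worst_negative,
        "seed": seed,
    }
    return CellTrajectory(times, levels, record_species, state, stats)


def _advance_gene_blocked(network, state, gene, tv, dur, seed):
    """Advance promoter/mRNA exactly; protein handled by the ODE layer."""
    gs = state.gene_states[gene]
    g, m, _ = _ssa_final_state(
        tv.k_on, tv.k_off, tv.k_m, tv.gamma_m, 0.0, tv.gamma_p,
        1 if gs.promoter_on else 0, gs.mrna, 0.0, dur, np.uint32(seed),
    )
    gs.promoter_on = bool(g)
    gs.mrna = int(m)


def _run_quiescent_phase(
    network, comp, state, y, a, b, blocked, gene_seeds, phase_grid, record
):
    """All reactions inert: every gene evolves as an isolated turnover model."""
    dur = b - a
    prot_grid = {}
    for gi, gene in enumerate(comp.gene_names):
        tv = network.turnover[gene]
        kp_eff = 0.0 if blocked else tv.k_p
        tv_eff = dataclasses.replace(tv, k_p=kp_eff)
        gs = state.gene_states[gene]
        t_ev, g_ev, m_ev, p_ev = _gene_events(
            tv_eff, gs, dur, _spawn_seed(gene_seeds[gi])
        )
        if len(phase_grid):
            prot_grid[gene] = _protein_on_grid(
                t_ev, m_ev, p_ev, kp_eff, tv.gamma_p, phase_grid - a
            )
        gs.promoter_on = bool(g_ev[-1])
        gs.mrna = int(m_ev[-1])
        gs.protein = float(p_ev[-1])
        y[network.index[gene]] = gs.protein
    for k, t in enumerate(phase_grid):
        yk = y.copy()
        for gene in comp.gene_names:
            yk[network.index[gene]] = prot_grid[gene][k]
        record(t, yk)


def _run_unsegmented_phase(
    network, comp, state, driver, y, a, b, blocked, gene_seeds, phase_grid, record
):
    """Synthesis-blocked (or gene-free) phase: one ODE sweep, grid recording."""
    driver.synth[:] = 0.0
    if not blocked:
        for gi, gene in enumerate(comp.gene_names):
            driver.synth[network.index[gene]] = (
                network.turnover[gene].k_p * state.gene_states[gene].mrna
            )
    t_cur = a
    for t in list(phase_grid) + [b]:
        y[:] = driver.step(y, t_cur, t)
        t_cur = t
        if t < b:
            record(t, y)
    for gi, gene in enumerate(comp.gene_names):
        _advance_gene_blocked(
            network, state, gene, network.turnover[gene], b - a,
            _spawn_seed(gene_seeds[gi]),
        )
        state.gene_states[gene].protein = float(y[network.index[gene]])


def _run_active_phase(
    network, comp, state, driver, y, a, b, gene_seeds, phase_grid, record, mode
):
    """Full hybrid phase: segmented stiff integration between gene-layer events."""
    dur = b - a
    n_genes = len(comp.gene_names)
    events = []
    for gi, gene in enumerate(comp.gene_names):
        tv = network.turnover[gene]
        gs = state.gene_states[gene]
        t_ev, g_ev, m_ev, _ = _gene_events(tv, gs, dur, _spawn_seed(gene_seeds[gi]))
        events.append((t_ev, g_ev, m_ev))

    # breakpoints where some gene's mRNA count changes (promoter flips do not
    # alter the ODE right-hand side)
    if mode == "presample":
        m_change = []
        for t_ev, g_ev, m_ev in events:
            chg = np.nonzero(np.diff(m_ev) != 0)[0] + 1
            m_change.append(t_ev[chg])
        breakpts = np.unique(
            np.concatenate(
                [np.concatenate(m_change) + a if m_change else np.empty(0)]
                + [phase_grid, np.array([b])]
            )
        )
        breakpts = breakpts[(breakpts > a + 1e-12) & (breakpts <= b)]
        t_cur = a
        grid_set = set(np.round(phase_grid, 9))
        for t_next in breakpts:
            # synthesis from each gene's mRNA on [t_cur, t_next)
            for gi in range(n_genes):
                t_ev, g_ev, m_ev = events[gi]
                k = np.searchsorted(t_ev, t_cur - a, side="right") - 1
                driver.synth[comp.gene_idx[gi]] = comp.k_p[gi] * m_ev[max(k, 0)]
            y[:] = driver.step(y, t_cur, t_next)
            t_cur = t_next
            if t_next < b:
                record(t_next, y)
    else:  # interleave: consume the same per-gene schedules event by event
        ptr = np.zeros(n_genes, dtype=np.int64)
        m_now = np.array([ev[2][0] for ev in events], dtype=np.int64)
        t_cur = a
        next_grid = list(phase_grid) + [np.inf]
        gpos = 0
        while t_cur < b - 1e-12:
            t_next_ev, gi_next = np.inf, -1
            for gi in range(n_genes):
                t_ev, g_ev, m_ev = events[gi]
                j = ptr[gi] + 1
                while j < len(t_ev) and m_ev[j] == m_ev[j - 1]:
                    j += 1
                if j < len(t_ev) and t_ev[j] + a < t_next_ev:
                    t_next_ev, gi_next = t_ev[j] + a, gi
            t_next = min(t_next_ev, next_grid[gpos], b)
            for gi in range(n_genes):
                driver.synth[comp.gene_idx[gi]] = comp.k_p[gi] * m_now[gi]
            y[:] = driver.step(y, t_cur, t_next)
            if t_next == next_grid[gpos]:
                record(t_next, y)
                gpos += 1
            elif t_next < b:
                record(t_next, y)
            if t_next == t_next_ev and gi_next >= 0:
                t_ev, g_ev, m_ev = events[gi_next]
                j = ptr[gi_next] + 1
                while j < len(t_ev) and m_ev[j] == m_ev[j - 1]:
                    j += 1
                ptr[gi_next] = j
                m_now[gi_next] = m_ev[j]
            t_cur = t_next

    for gi, gene in enumerate(comp.gene_names):
        t_ev, g_ev, m_ev = events[gi]
        gs = state.gene_states[gene]
        gs.promoter_on = bool(g_ev[-1])
        gs.mrna = int(m_ev[-1])
        gs.protein = float(y[network.index[gene]])


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


def build_population(network: ReactionNetwork, n: int, seed: int) -> list[CellState]:
    """n cells at stationarity: gene states Monte-Carlo sampled, native species
    set consistently, unattached species at their configured initial values."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    genes = network.genes
    gene_samples = {}
    for child, g in zip(ss.spawn(max(len(genes), 1)), genes):
        gene_samples[g] = sample_stationary_state(
            network.turnover[g], n, _spawn_seed(child)
        )
    y0 = np.zeros(network.n_species)
    for s, v in network.initial.items():
        y0[network.index[s]] = v
    cells = []
    for i in range(n):
        y = y0.copy()
        gene_states = {}
        for g in genes:
            gs = gene_samples[g][i]
            gene_states[g] = gs
            y[network.index[g]] = gs.protein
        cells.append(CellState(0.0, gene_states, y))
    return cells


def divide_cell(cell: CellState) -> tuple[CellState, CellState]:
    """Duplicate the mother state (equal-repartition assumption): each daughter
    starts with the mother's promoter states, mRNA counts and species levels;
    their subsequent stochastic histories are independent."""
    return cell.copy(), cell.copy()


def population_frame(cells: list[CellState], network: ReactionNetwork) -> pd.DataFrame:
    """One row per cell: every species level plus per-gene promoter/mRNA state."""
    data = {}
    levels = np.array([c.species_levels for c in cells])
    for i, s in enumerate(network.species):
        data[f"level_{s}"] = levels[:, i]
    for g in network.genes:
        data[f"promoter_{g}"] = [c.gene_states[g].promoter_on for c in cells]
        data[f"mrna_{g}"] = [c.gene_states[g].mrna for c in cells]
    return pd.DataFrame(data)
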