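"""In-silico experiment protocols and their quantifications.

Protocols
---------
* **Sister-cell experiment** — mother cells sampled at stationarity divide at
  a uniform random time inside a pre-treatment window; both daughters are
  simulated through a TRAIL (+/- cycloheximide) treatment and their MOMP
  times compared (fate-inheritance decay with sister age).
* **Repeated-TRAIL experiment** — a population is treated, dead cells are
  removed, survivors are propagated with divisions (gaussian cell cycle) and
  re-challenged after a configurable interval together with a naive control;
  the ratio of survival fractions is the resistance gain.
* **Determinants analyses** — over-representation of protein levels and
  promoter activity among future survivors at treatment time, and the
  relaxation of survivor protein levels back to naive levels over days.

Quantifications: MOMP-time histograms and surviving fractions, sliding-bin
Pearson correlation of sister MOMP times versus sister age, a symmetric
model-data agreement score, and a promoter-switching-time grid scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from teleflux.earm import DoseMap, FateDetectorConfig, detect_death, detect_momp, dose_to_ligand
from teleflux.hybrid import SolverConfig, build_population, divide_cell, simulate_cell
from teleflux.network import CellState, Intervention, ReactionNetwork
from teleflux.turnover import stationary_moments

__all__ = [
    "SisterExperimentConfig",
    "RepeatedTrailConfig",
    "MompStatistics",
    "EmptyInputError",
    "UndefinedCurveError",
    "BinningError",
    "UndefinedAnalysisError",
    "MissingReferenceError",
    "run_sister_experiment",
    "momp_statistics",
    "sister_correlation_curve",
    "agreement_score",
    "grid_scan",
    "run_repeated_trail",
    "determinants_analysis",
    "recovery_curve",
]


class EmptyInputError(ValueError):
    pass


class UndefinedCurveError(ValueError):
    pass


class BinningError(ValueError):
    pass


class UndefinedAnalysisError(ValueError):
    pass


class MissingReferenceError(ValueError):
    pass


#: species recorded during treatment phases (enough for both fate detectors)
DETECTOR_SPECIES = ["mSmac", "AM_mSmac", "aSmac", "cSmac", "cSmac_XIAP", "PARP", "C3_PARP", "cPARP"]


@dataclass(frozen=True)
class SisterExperimentConfig:
    """Protocol of the sister-cell fate-correlation experiment.

    ``dose`` in ng/mL; ``chx`` adds a full synthesis blockade at treatment
    time; mothers divide uniformly within ``division_window`` hours before
    treatment; fates are observed for ``observation`` hours after treatment.
    """

    dose: float
    chx: bool = False
    division_window: float = 20.0
    n_pairs: int = 10000
    observation: float = 8.0
    dose_map: DoseMap = field(default_factory=DoseMap)

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.observation <= 0 or self.division_window < 0:
            raise ValueError("invalid sister-experiment configuration")


@dataclass(frozen=True)
class RepeatedTrailConfig:
    """Protocol of the repeated-TRAIL reversible-resistance experiment."""

    first_dose: float
    second_dose: float
    intervals: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)  # days
    n_cells: int = 10000
    cycle_mean: float = 27.0
    cycle_sd: float = 3.0
    assay_window: float = 24.0
    population_cap: int | None = None
    dose_map: DoseMap = field(default_factory=DoseMap)

    def __post_init__(self) -> None:
        if any(i <= 0 for i in self.intervals):
            raise ValueError("intervals must be positive (days)")
        if self.cycle_mean <= 0 or self.cycle_sd <= 0:
            raise ValueError("cell-cycle parameters must be positive")


@dataclass(frozen=True)
class MompStatistics:
    """MOMP-time histogram (frequencies relative to all cells) + survival."""

    bin_edges: np.ndarray
    counts: np.ndarray
    surviving_fraction: float
    n_total: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_total


def _treatment_interventions(
    dose: float, chx: bool, dose_map: DoseMap, at: float = 0.0
) -> list[Intervention]:
    ivs = [
        Intervention(time=at, action="add_species", species="L",
                     amount=dose_to_ligand(dose, dose_map))
    ]
    if chx:
        ivs.append(Intervention(time=at, action="block_synthesis"))
    return ivs


def _spawn_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> np.uint32(1))


def _snapshot_columns(cell: CellState, network: ReactionNetwork) -> dict:
    out = {}
    for g in network.genes:
        out[f"level_{g}"] = cell.gene_states[g].protein
        out[f"promoter_{g}"] = bool(cell.gene_states[g].promoter_on)
    return out


def _record_list(network: ReactionNetwork) -> list[str]:
    present = [s for s in DETECTOR_SPECIES if s in network.index]
    return present if present else list(network.species)


def run_sister_experiment(
    network: ReactionNetwork,
    cfg: SisterExperimentConfig,
    seed: int,
    detector_cfg: FateDetectorConfig | None = None,
    solver: SolverConfig | None = None,
    momp_detector=None,
    death_detector=None,
) -> pd.DataFrame:
    """Simulate ``cfg.n_pairs`` sister pairs through treatment.

    Returns one row per cell with pair identifiers, the division time
    (hours, negative = before treatment), MOMP and death times (hours after
    treatment, NaN if the event did not occur within the observation window),
    the fate, and the native protein levels / promoter states at treatment
    time.
    """
    detector_cfg = detector_cfg or FateDetectorConfig()
    solver = solver or SolverConfig()
    momp_fn = momp_detector or (lambda frame: detect_momp(frame, detector_cfg))
    death_fn = death_detector or (lambda frame: detect_death(frame, detector_cfg))
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed + 1)
    mothers = build_population(network, cfg.n_pairs, _spawn_int(ss))
    division_times = -rng.uniform(0.0, cfg.division_window, size=cfg.n_pairs)
    if cfg.division_window == 0:
        division_times[:] = 0.0
    record_species = _record_list(network)

    rows = []
    pair_seeds = np.random.SeedSequence(seed + 2).spawn(cfg.n_pairs)
    for i, mother in enumerate(mothers):
        t_div = float(division_times[i])
        mother.time = t_div
        d1, d2 = divide_cell(mother)
        cell_seeds = pair_seeds[i].spawn(2)
        for j, daughter in enumerate((d1, d2)):
            if t_div < 0:
                pre = simulate_cell(
                    network, daughter, -t_div, solver=solver,
                    seed=_spawn_int(cell_seeds[j].spawn(1)[0]),
                    record_species=record_species[:1] or None,
                )
                daughter = pre.final_state
            snapshot = _snapshot_columns(daughter, network)
            traj = simulate_cell(
                network,
                daughter,
                cfg.observation,
                interventions=_treatment_interventions(cfg.dose, cfg.chx, cfg.dose_map),
                solver=solver,
                seed=_spawn_int(cell_seeds[j]),
                record_species=record_species,
            )
            frame = traj.to_frame()
            momp = momp_fn(frame)
            death = death_fn(frame)
            rows.append(
                {
                    "cell_id": 2 * i + j,
                    "pair_id": i,
                    "sister_id": 2 * i + (1 - j),
                    "division_time": t_div,
                    "momp_time": np.nan if momp is None else momp,
                    "death_time": np.nan if death is None else death,
                    "fate": "survived" if momp is None else "died",
                    **snapshot,
                }
            )
    return pd.DataFrame(rows)


def momp_statistics(
    records: pd.DataFrame, bin_width: float = 0.5, observation: float | None = None
) -> MompStatistics:
    """Histogram of MOMP times over the observation window + surviving fraction.

    The surviving fraction is the fraction of cells with no MOMP; histogram
    frequencies are relative to *all* cells so the two are commensurate.
    """
    if len(records) == 0:
        raise EmptyInputError("no records")
    momp = records["momp_time"].to_numpy(dtype=float)
    if observation is None:
        observation = float(np.nanmax(momp)) if np.isfinite(momp).any() else bin_width
    edges = np.arange(0.0, observation + bin_width * 0.999, bin_width)
    if edges[-1] < observation:
        edges = np.append(edges, observation)
    counts, _ = np.histogram(momp[np.isfinite(momp)], bins=edges)
    surviving = float(np.mean(~np.isfinite(momp)))
    return MompStatistics(edges, counts, surviving, len(records))


def sister_correlation_curve(
    records: pd.DataFrame,
    bin_width: float = 2.0,
    step: float = 1.0,
    min_pairs: int = 50,
) -> pd.DataFrame:
    """Pearson correlation of sister MOMP times in sliding bins of sister age.

    The age of a pair is the division-to-MOMP duration averaged between the
    two sisters.  The correlation within a bin is computed on the symmetrized
    pair set {(a,b), (b,a)} (an intraclass-correlation estimator, insensitive
    to the arbitrary sister order).  Bins with fewer than ``min_pairs`` pairs
    are omitted.
    """
    both = records.dropna(subset=["momp_time"]).groupby("pair_id").filter(
        lambda g: len(g) == 2
    )
    if len(both) == 0:
        raise UndefinedCurveError("no pair has both sisters with a MOMP time")
    pairs = both.sort_values(["pair_id", "cell_id"]).groupby("pair_id")
    a = pairs.nth(0).reset_index(drop=True)
    b = pairs.nth(1).reset_index(drop=True)
    age = ((a["momp_time"] - a["division_time"]) + (b["momp_time"] - b["division_time"])).to_numpy() / 2.0
    x = a["momp_time"].to_numpy()
    y = b["momp_time"].to_numpy()
    lo, hi = age.min(), age.max()
    centers, corr, n_in = [], [], []
    c = lo
    while c <= hi + 1e-9:
        sel = (age >= c - bin_width / 2) & (age < c + bin_width / 2)
        n = int(sel.sum())
        if n >= max(min_pairs, 2):
            xs = np.concatenate([x[sel], y[sel]])
            ys = np.concatenate([y[sel], x[sel]])
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(xs, ys)[0, 1])
            if np.isfinite(r):
                centers.append(c)
                corr.append(r)
                n_in.append(n)
        c += step
    if not centers:
        raise UndefinedCurveError(
            f"no sliding bin contains >= {min_pairs} complete pairs"
        )
    return pd.DataFrame({"age": centers, "correlation": corr, "n_pairs": n_in})


def agreement_score(
    model_stats: MompStatistics,
    data_stats: MompStatistics,
    survival_weight: float = 1.0,
) -> float:
    """Symmetric model-data discrepancy (0 iff identical summaries).

    Mean squared difference of MOMP-time histogram frequencies plus
    ``survival_weight`` times the squared surviving-fraction difference.
    """
    if len(model_stats.bin_edges) != len(data_stats.bin_edges) or not np.allclose(
        model_stats.bin_edges, data_stats.bin_edges
    ):
        raise BinningError("histograms must share bin edges")
    hist_term = float(np.mean((model_stats.frequencies - data_stats.frequencies) ** 2))
    surv_term = (model_stats.surviving_fraction - data_stats.surviving_fraction) ** 2
    return hist_term + survival_weight * float(surv_term)


def grid_scan(
    network_factory,
    grid: list[dict],
    data_stats: MompStatistics,
    cfg: SisterExperimentConfig,
    seed: int,
    data_correlation: pd.DataFrame | None = None,
    bin_width: float = 0.5,
    detector_cfg: FateDetectorConfig | None = None,
    solver: SolverConfig | None = None,
    min_pairs: int = 10,
    momp_detector=None,
    death_detector=None,
) -> pd.DataFrame:
    """Model-data agreement over a promoter-switching-rate grid.

    ``grid`` is a list of keyword mappings (e.g. ``{"t_on": 16, "t_off": 24}``)
    passed to ``network_factory``.  For each point the sister experiment is run
    and the agreement recorded for the objectives ``momp_histogram``,
    ``surviving_fraction``, ``both`` and (when ``data_correlation`` is given)
    ``sister_correlation``.  Simulation failures are recorded per point and do
    not abort the scan.
    """
    if not grid:
        raise ValueError("empty grid")
    rows = []
    point_seeds = np.random.SeedSequence(seed).spawn(len(grid))
    for k, point in enumerate(grid):
        row = dict(point)
        try:
            network = network_factory(**point)
            records = run_sister_experiment(
                network, cfg, _spawn_int(point_seeds[k]), detector_cfg, solver,
                momp_detector=momp_detector, death_detector=death_detector,
            )
            stats = momp_statistics(
                records, bin_width=bin_width,
                observation=float(data_stats.bin_edges[-1]),
            )
            row["momp_histogram"] = float(
                np.mean((stats.frequencies - data_stats.frequencies) ** 2)
            )
            row["surviving_fraction"] = float(
                (stats.surviving_fraction - data_stats.surviving_fraction) ** 2
            )
            row["both"] = agreement_score(stats, data_stats)
            if data_correlation is not None:
                try:
                    curve = sister_correlation_curve(records, min_pairs=min_pairs)
                    merged = pd.merge_asof(
                        data_correlation.sort_values("age"),
                        curve.sort_values("age"),
                        on="age", suffixes=("_data", "_model"), direction="nearest",
                    )
                    row["sister_correlation"] = float(
                        np.mean(
                            (merged["correlation_data"] - merged["correlation_model"]) ** 2
                        )
                    )
                except UndefinedCurveError as exc:
                    row["sister_correlation"] = np.nan
                    row["error"] = str(exc)
            row["error"] = row.get("error", "")
        except Exception as exc:  # noqa: BLE001 - scan must continue
            row["error"] = f"{type(exc).__name__}: {exc}"
            for obj in ("momp_histogram", "surviving_fraction", "both"):
                row.setdefault(obj, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-TRAIL protocol
# ---------------------------------------------------------------------------


@dataclass
class _LiveCell:
    state: CellState
    next_division: float


def _assay_population(
    network, cells, dose, dose_map, window, seed, death_fn, solver
) -> float:
    """Treat a snapshot population and return its survival fraction
    (death = cleaved-PARP criterion within the assay window)."""
    if not cells:
        return float("nan")
    record_species = _record_list(network)
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    survived = 0
    for cell, cseed in zip(cells, seeds):
        c = cell.copy()
        t0 = c.time
        # medium change: any residual ligand is washed out, fresh dose added
        ivs = [Intervention(time=t0, action="rescale_dose", species="L", factor=0.0)]
        ivs += _treatment_interventions(dose, False, dose_map, at=t0)
        traj = simulate_cell(
            network, c, window, interventions=ivs,
            solver=solver, seed=_spawn_int(cseed), record_species=record_species,
        )
        if death_fn(traj.to_frame()) is None:
            survived += 1
    return survived / len(cells)


def run_repeated_trail(
    network: ReactionNetwork,
    cfg: RepeatedTrailConfig,
    seed: int,
    detector_cfg: FateDetectorConfig | None = None,
    solver: SolverConfig | None = None,
    death_detector=None,
) -> pd.DataFrame:
    """The two-treatment reversible-resistance protocol.

    A naive population is treated at day 0; cells whose cleaved-PARP fraction
    crosses the death threshold are removed; the ligand is washed out at the
    end of the assay window; survivors are propagated with divisions
    (gaussian cycle, duplication at division, uniform subsampling to the
    population cap).  At each requested interval, the current survivors and a
    fresh naive control are challenged with ``second_dose`` and assayed.

    Returns one row per interval with the two survival fractions, the
    resistance gain (pretreated / naive) and an extinction flag.
    """
    detector_cfg = detector_cfg or FateDetectorConfig()
    solver = solver or SolverConfig()
    death_fn = death_detector or (lambda frame: detect_death(frame, detector_cfg))
    cap = cfg.population_cap or cfg.n_cells
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed + 10)
    record_species = _record_list(network)

    population = [
        _LiveCell(c, float(rng.uniform(0, max(rng.normal(cfg.cycle_mean, cfg.cycle_sd), 1.0))))
        for c in build_population(network, cfg.n_cells, _spawn_int(ss.spawn(1)[0]))
    ]

    checkpoints = sorted({cfg.assay_window} | {d * 24.0 for d in cfg.intervals})
    results = []
    first_treatment = _treatment_interventions(cfg.first_dose, False, cfg.dose_map, at=0.0)

    # lazily evaluated naive control per dose (same for every interval)
    naive_cache: dict[float, float] = {}

    def naive_survival(dose: float) -> float:
        if dose not in naive_cache:
            control = build_population(network, cfg.n_cells, _spawn_int(ss.spawn(1)[0]))
            naive_cache[dose] = _assay_population(
                network, control, dose, cfg.dose_map, cfg.assay_window,
                _spawn_int(ss.spawn(1)[0]), death_fn, solver,
            )
        return naive_cache[dose]

    for t_next in checkpoints:
        # advance every live cell from t_now to t_next, dividing as needed
        new_population: list[_LiveCell] = []
        for live in population:
            stack = [live]
            while stack:
                item = stack.pop()
                cell = item.state
                dead = False
                while cell.time < t_next - 1e-9:
                    t_stop = min(item.next_division, t_next)
                    ivs = []
                    if cell.time == 0.0:
                        ivs += first_treatment
                    if cell.time <= cfg.assay_window < t_stop:
                        ivs.append(Intervention(time=cfg.assay_window,
                                                action="rescale_dose",
                                                species="L", factor=0.0))
                    traj = simulate_cell(
                        network, cell, t_stop - cell.time, interventions=ivs,
                        solver=solver, seed=_spawn_int(ss.spawn(1)[0]),
                        record_species=record_species,
                    )
                    if death_fn(traj.to_frame()) is not None:
                        dead = True
                        break
                    cell = traj.final_state
                    if t_stop == item.next_division and t_stop < t_next - 1e-9:
                        d1, d2 = divide_cell(cell)
                        cycle = max(rng.normal(cfg.cycle_mean, cfg.cycle_sd), 1.0)
                        cycle2 = max(rng.normal(cfg.cycle_mean, cfg.cycle_sd), 1.0)
                        stack.append(_LiveCell(d2, t_stop + cycle2))
                        item = _LiveCell(d1, t_stop + cycle)
                        cell = item.state
                if not dead:
                    item.state = cell
                    new_population.append(item)
        if len(new_population) > cap:
            keep = rng.choice(len(new_population), size=cap, replace=False)
            new_population = [new_population[i] for i in sorted(keep)]
        population = new_population

        day = t_next / 24.0
        if any(abs(day - d) < 1e-9 for d in cfg.intervals):
            if not population:
                results.append({
                    "interval_days": day, "n_survivors": 0,
                    "pretreated_survival": np.nan,
                    "naive_survival": naive_survival(cfg.second_dose),
                    "resistance_gain": np.nan, "extinct": True,
                })
                continue
            pre = _assay_population(
                network, [lc.state for lc in population], cfg.second_dose,
                cfg.dose_map, cfg.assay_window, _spawn_int(ss.spawn(1)[0]),
                death_fn, solver,
            )
            naive = naive_survival(cfg.second_dose)
            results.append({
                "interval_days": day, "n_survivors": len(population),
                "pretreated_survival": pre, "naive_survival": naive,
                "resistance_gain": pre / naive if naive > 0 else np.inf,
                "extinct": False,
            })
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# molecular determinants and recovery
# ---------------------------------------------------------------------------


def determinants_analysis(
    population: pd.DataFrame,
    survivor_mask: np.ndarray | pd.Series,
    seed: int = 0,
    n_permutations: int = 10000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of protein levels / promoter activity in survivors.

    ``population`` holds one row per cell with ``level_<gene>`` columns (and
    optionally ``promoter_<gene>`` Booleans) at treatment time;
    ``survivor_mask`` flags the future survivors.  For each feature the ratio
    of the survivor mean to the whole-population mean is reported together
    with a two-sided permutation p-value (survivors vs. non-survivors mean
    difference) and significance flags at level ``alpha`` — both per-feature
    (``significant``) and Benjamini-Hochberg adjusted across features
    (``significant_bh``).
    """
    mask = np.asarray(survivor_mask, dtype=bool)
    if mask.shape[0] != len(population):
        raise ValueError("survivor_mask length mismatch")
    m = int(mask.sum())
    if m == 0:
        raise UndefinedAnalysisError("empty survivor set")
    feats = [c for c in population.columns if c.startswith(("level_", "promoter_"))]
    if not feats:
        raise ValueError("population frame has no level_/promoter_ columns")
    X = population[feats].to_numpy(dtype=float)
    n = X.shape[0]
    overall = X.mean(axis=0)
    surv_mean = X[mask].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(overall != 0, surv_mean / overall, np.nan)
    obs = surv_mean - X[~mask].mean(axis=0) if m < n else np.zeros(len(feats))

    rng = np.random.default_rng(seed)
    if 0 < m < n:
        exceed = np.zeros(len(feats), dtype=np.int64)
        total = X.sum(axis=0)
        batch = max(1, min(n_permutations, int(2e7 // max(n, 1))))
        done = 0
        while done < n_permutations:
            b = min(batch, n_permutations - done)
            # random survivor sets of the same size via partial permutation
            sel = np.zeros((b, n), dtype=bool)
            for r in range(b):
                sel[r, rng.choice(n, size=m, replace=False)] = True
            s_mean = (sel @ X) / m
            ns_mean = (total - s_mean * m) / (n - m)
            exceed += (np.abs(s_mean - ns_mean) >= np.abs(obs) - 1e-12).sum(axis=0)
            done += b
        pvals = (1.0 + exceed) / (n_permutations + 1.0)
    else:
        pvals = np.ones(len(feats))

    order = np.argsort(pvals)
    ranked = pvals[order]
    k = len(feats)
    bh_thresh = alpha * (np.arange(1, k + 1)) / k
    passed = ranked <= bh_thresh
    cutoff = ranked[passed].max() if passed.any() else -1.0
    sig_bh = pvals <= cutoff

    kinds = ["promoter" if f.startswith("promoter_") else "level" for f in feats]
    names = [f.split("_", 1)[1] for f in feats]
    return pd.DataFrame(
        {
            "feature": feats,
            "protein": names,
            "kind": kinds,
            "ratio": ratio,
            "p_value": pvals,
            "significant": pvals <= alpha,
            "significant_bh": sig_bh,
        }
    )


def recovery_curve(
    survivor_levels_by_day: dict[float, pd.DataFrame],
    naive_population: pd.DataFrame,
    network: ReactionNetwork,
) -> pd.DataFrame:
    """Observed survivor/naive level ratios per day and the turnover-only
    expectation ``mean + (l0 - mean) * exp(-gamma_p * t)``.

    ``survivor_levels_by_day`` maps days since treatment to population frames
    with ``level_<gene>`` columns; day 0 provides the reference level ``l0``.
    Deviation of the observed ratio from the expected one indicates selection
    or residual signaling rather than plain turnover relaxation.
    """
    if len(naive_population) == 0 or not survivor_levels_by_day:
        raise EmptyInputError("populations must be non-empty")
    if 0 not in survivor_levels_by_day and 0.0 not in survivor_levels_by_day:
        raise MissingReferenceError("day 0 reference population is required")
    ref = survivor_levels_by_day.get(0, survivor_levels_by_day.get(0.0))
    rows = []
    for g in network.genes:
        col = f"level_{g}"
        if col not in naive_population.columns:
            continue
        naive_mean = float(naive_population[col].mean())
        mean = stationary_moments(network.turnover[g]).mean_protein
        l0 = float(ref[col].mean())
        gp = network.turnover[g].gamma_p
        for day in sorted(survivor_levels_by_day):
            t = float(day) * 24.0
            obs = float(survivor_levels_by_day[day][col].mean())
            expected = mean + (l0 - mean) * np.exp(-gp * t)
            rows.append(
                {
                    "day": float(day),
                    "protein": g,
                    "observed_ratio": obs / naive_mean if naive_mean else np.nan,
                    "expected_ratio": expected / naive_mean if naive_mean else np.nan,
                }
            )
    return pd.DataFrame(rows)
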