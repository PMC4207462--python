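"""The TRAIL-apoptosis application layer.

Loads the vendored extrinsic-apoptosis mass-action network (EARM), attaches a
stochastic turnover model to each of its 17 native proteins according to a
named preset, maps TRAIL doses (ng/mL) to ligand molecules per cell, and
provides the cell-fate detectors (MOMP via mitochondrial Smac release, death
via PARP cleavage).

Presets
-------
All native proteins carry the *standard* turnover model (protein half-life
27 h, mRNA half-life 9 h, mean mRNA 17, promoter mean ON/OFF durations
0.1 h/2.6 h) except the short-lived anti-apoptotic proteins Flip and Mcl1:

``non_fitted``
    Flip/Mcl1 keep standard promoter switching but short half-lives
    (protein 0.5 h, mRNA 2 h).
``fitted``
    Flip/Mcl1 have short half-lives (protein 0.4 h, mRNA 1 h) and *slow*
    promoter switching (mean ON 16 h, mean OFF 24 h), the regime of large,
    rare fluctuations that reproduces fractional killing quantitatively.
``mcl1_only_low_switching``
    As ``fitted`` but only Mcl1 switches slowly; Flip keeps standard
    switching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from teleflux.network import ReactionNetwork, Reaction, network_from_dict
from teleflux.turnover import TurnoverObservables

LN2 = math.log(2.0)

__all__ = [
    "EarmPreset",
    "DoseMap",
    "FateDetectorConfig",
    "SchemaError",
    "IncompletePresetError",
    "get_preset",
    "load_earm",
    "dose_to_ligand",
    "detect_momp",
    "detect_death",
    "NATIVE_PROTEINS",
]

NATIVE_PROTEINS = [
    "R", "flip", "pC8", "BAR", "pC3", "pC6", "XIAP", "PARP", "Bid",
    "Mcl1", "Bax", "Bcl2", "M", "mCytoC", "mSmac", "Apaf", "pC9",
]

#: standard long-lived turnover observables shared by most native proteins
STANDARD_TURNOVER = {
    "mean_mrna": 17.0,
    "mrna_half_life": 9.0,
    "protein_half_life": 27.0,
    "t_on": 0.1,
    "t_off": 2.6,
}

_SHORT_LIVED = ("flip", "Mcl1")

_PRESET_OVERRIDES: dict[str, dict[str, dict]] = {
    "non_fitted": {
        g: {"protein_half_life": 0.5, "mrna_half_life": 2.0, "t_on": 0.1, "t_off": 2.6}
        for g in _SHORT_LIVED
    },
    "fitted": {
        g: {"protein_half_life": 0.4, "mrna_half_life": 1.0, "t_on": 16.0, "t_off": 24.0}
        for g in _SHORT_LIVED
    },
    "mcl1_only_low_switching": {
        "flip": {"protein_half_life": 0.4, "mrna_half_life": 1.0, "t_on": 0.1, "t_off": 2.6},
        "Mcl1": {"protein_half_life": 0.4, "mrna_half_life": 1.0, "t_on": 16.0, "t_off": 24.0},
    },
}


class SchemaError(KeyError):
    """A trajectory is missing species required by a fate detector."""


class IncompletePresetError(ValueError):
    """A preset does not populate every native protein."""


@dataclass(frozen=True)
class EarmPreset:
    """Turnover parameterization of the 17 native proteins plus model toggles.

    ``active_form_half_life`` (hours) sets the first-order degradation of all
    non-native forms (complexes, cleaved/translocated species);
    ``feedback_enabled`` keeps or removes the effector-to-initiator caspase
    feedback (cleavage of pro-caspase 6 by caspase 3).
    """

    name: str
    observables: dict[str, TurnoverObservables] = field(repr=False)
    active_form_half_life: float = 15.0
    feedback_enabled: bool = False

    def __post_init__(self) -> None:
        missing = [g for g in NATIVE_PROTEINS if g not in self.observables]
        if missing:
            raise IncompletePresetError(f"preset {self.name!r} missing {missing}")
        if not self.active_form_half_life > 0:
            raise ValueError("active_form_half_life must be > 0")


@dataclass(frozen=True)
class DoseMap:
    """Linear map from TRAIL dose (ng/mL) to ligand molecules per cell.

    The default anchor is the base model's convention: 50 ng/mL corresponds to
    3000 ligand molecules per cell.
    """

    reference_dose: float = 50.0
    reference_molecules: float = 3000.0

    def __post_init__(self) -> None:
        if not (self.reference_dose > 0 and self.reference_molecules > 0):
            raise ValueError("dose-map anchors must be positive")


@dataclass(frozen=True)
class FateDetectorConfig:
    """Thresholds of the fate detectors, as fractions of the relevant pool.

    MOMP is called when ``momp_fraction`` of the (current) mitochondrial Smac
    pool has been released; death when ``cparp_fraction`` of total PARP is
    cleaved.
    """

    momp_fraction: float = 0.5
    cparp_fraction: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.momp_fraction, self.cparp_fraction):
            if not (0.0 < v < 1.0) and v != 1.0:
                raise ValueError("detector fractions must be in (0, 1]")


def get_preset(
    name: str,
    active_form_half_life: float = 15.0,
    feedback_enabled: bool = False,
    mean_levels: dict[str, float] | None = None,
) -> EarmPreset:
    """Build one of the named presets (mean protein levels from the base model)."""
    if name not in _PRESET_OVERRIDES:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_OVERRIDES)}"
        )
    means = dict(_load_earm_doc()["initial"]) if mean_levels is None else mean_levels
    obs = {}
    for g in NATIVE_PROTEINS:
        block = dict(STANDARD_TURNOVER)
        block.update(_PRESET_OVERRIDES[name].get(g, {}))
        obs[g] = TurnoverObservables(mean_protein=float(means[g]), **block)
    return EarmPreset(
        name=name,
        observables=obs,
        active_form_half_life=active_form_half_life,
        feedback_enabled=feedback_enabled,
    )


def _load_earm_doc() -> dict:
    with resources.files("teleflux.data").joinpath("earm.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_earm(preset: EarmPreset | str) -> ReactionNetwork:
    """The vendored EARM network configured by ``preset``.

    Applies (a) feedback removal (pro-caspase-6 cleavage by caspase 3 zeroed,
    the default), (b) degradation of every non-native form at
    ln2/active_form_half_life, (c) a turnover model on each native protein.
    The ligand L starts at zero and is added by a treatment intervention.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    doc = _load_earm_doc()
    net = network_from_dict(doc)
    natives = set(doc["natives"])

    reactions = net.reactions
    if not preset.feedback_enabled:
        # zero the whole pC6-cleavage-by-C3 reaction group (binding included,
        # so the inert pro-form does not become an unintended caspase-3 sink)
        def touches_feedback(r: Reaction) -> bool:
            names = {s for s, _ in r.reactants + r.products}
            return "C3_pC6" in names

        reactions = [
            Reaction(r.reactants, r.products, 0.0) if touches_feedback(r) else r
            for r in reactions
        ]

    gamma_active = LN2 / preset.active_form_half_life
    degradation = {
        s: gamma_active for s in net.species if s not in natives and s != "L"
    }
    # complexes containing the short-lived inhibitors inherit their fast
    # ubiquitin-driven turnover (the complex is degraded with its client
    # bound), which is what makes Mcl1 an effective tBid sink
    for g in _SHORT_LIVED:
        gp = LN2 / preset.observables[g].protein_half_life
        for s in net.species:
            if s in natives or s == "L":
                continue
            if g in s.split("_"):
                degradation[s] = max(degradation[s], gp)
    turnover = {g: preset.observables[g] for g in NATIVE_PROTEINS}
    initial = {s: 0.0 for s in net.species}
    initial.update({g: float(doc["initial"][g]) for g in doc["initial"]})

    return ReactionNetwork(
        species=net.species,
        reactions=reactions,
        degradation=degradation,
        turnover=turnover,
        initial=initial,
    )


def dose_to_ligand(dose: float, dose_map: DoseMap | None = None) -> float:
    """Ligand molecules per cell for a TRAIL dose in ng/mL (linear scaling)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    dose_map = dose_map or DoseMap()
    return dose * dose_map.reference_molecules / dose_map.reference_dose


# ---------------------------------------------------------------------------
# fate detectors
# ---------------------------------------------------------------------------

_MOMP_RELEASED = ("aSmac", "cSmac", "cSmac_XIAP")
_MOMP_MITO = ("mSmac", "AM_mSmac")
_DEATH_CLEAVED = ("cPARP",)
_DEATH_TOTAL = ("PARP", "C3_PARP", "cPARP")


def _as_frame(trajectory) -> pd.DataFrame:
    if hasattr(trajectory, "to_frame"):
        return trajectory.to_frame()
    return trajectory


def _fraction_crossing(
    df: pd.DataFrame, num_cols, den_cols, threshold: float
) -> float | None:
    missing = [c for c in (*num_cols, *den_cols) if c not in df.columns]
    if missing or "time" not in df.columns:
        raise SchemaError(f"trajectory missing columns {missing or ['time']}")
    num = df[list(num_cols)].sum(axis=1).to_numpy()
    den = num + df[list(den_cols)].sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / den, 0.0)
    t = df["time"].to_numpy()
    above = frac >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    # linear interpolation between the bracketing grid points
    f0, f1 = frac[k - 1], frac[k]
    if f1 == f0:
        return float(t[k])
    return float(t[k - 1] + (threshold - f0) / (f1 - f0) * (t[k] - t[k - 1]))


def detect_momp(trajectory, cfg: FateDetectorConfig | None = None) -> float | None:
    """First time (hours) at which the released fraction of mitochondrial Smac
    crosses ``cfg.momp_fraction``; None if never crossed."""
    cfg = cfg or FateDetectorConfig()
    df = _as_frame(trajectory)
    released = [c for c in _MOMP_RELEASED if c in df.columns] or list(_MOMP_RELEASED)
    mito = [c for c in _MOMP_MITO if c in df.columns] or list(_MOMP_MITO)
    # require at least the core species
    if "mSmac" not in df.columns:
        raise SchemaError("trajectory missing mitochondrial Smac ('mSmac')")
    return _fraction_crossing(df, released, mito, cfg.momp_fraction)


def detect_death(trajectory, cfg: FateDetectorConfig | None = None) -> float | None:
    """First time at which the cleaved fraction of total PARP crosses
    ``cfg.cparp_fraction``; None if never crossed."""
    cfg = cfg or FateDetectorConfig()
    df = _as_frame(trajectory)
    if "cPARP" not in df.columns:
        raise SchemaError("trajectory missing cleaved PARP ('cPARP')")
    total_rest = [c for c in ("PARP", "C3_PARP") if c in df.columns] or ["PARP"]
    return _fraction_crossing(df, list(_DEATH_CLEAVED), total_rest, cfg.cparp_fraction)
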